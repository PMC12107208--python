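"""Exception hierarchy for the audit pipeline."""


class EHRAuditError(Exception):
    """Base class for all package errors."""


class ValidationError(EHRAuditError, ValueError):
    """Invalid value or inconsistent input (bad probability vector, unknown category, ...)."""


class RegistryError(EHRAuditError, KeyError):
    """Lookup of an unknown disease, model or attribute."""


class ConfigurationError(EHRAuditError):
    """Malformed configuration artefact (uncompilable pattern, empty phrasing pool, ...)."""
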
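"""Prompt bank and disease registry.

The generation protocol instantiates a fixed bank of prompt templates, each
carrying a single ``{disease}`` placeholder, over a registry of 20 diseases
grouped into 5 protocol categories (epidemics, chronic conditions, mental
health disorders, rare diseases, and diseases associated with geographic or
socioeconomic factors). Expansion is pure string substitution: no randomness,
no model calls.

The shipped template wordings and the disease→category mapping are editorial
defaults (the protocol fixes the shape — 10 templates × 20 diseases — not the
wording); both are replaceable from plain-text config files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError, RegistryError, ValidationError

PLACEHOLDER = "{disease}"

#: The five protocol disease categories.
CATEGORIES = (
    "epidemics",
    "chronic conditions",
    "mental health disorders",
    "rare diseases",
    "geographic/socioeconomic",
)


@dataclass(frozen=True)
class PromptTemplate:
    """One template of the bank; ``text`` contains exactly one placeholder."""

    template_id: int
    text: str

    def __post_init__(self) -> None:
        if self.text.count(PLACEHOLDER) != 1:
            raise ValidationError(
                f"template {self.template_id} must contain exactly one "
                f"'{PLACEHOLDER}' placeholder: {self.text!r}"
            )


@dataclass(frozen=True)
class DiseaseSpec:
    """A registered disease and its protocol category."""

    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown disease category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


class PromptBank:
    """Ordered collection of prompt templates with unique ids."""

    def __init__(self, templates: list[PromptTemplate]):
        ids = [t.template_id for t in templates]
        if len(set(ids)) != len(ids):
            raise ValidationError("template_id values must be unique within a bank")
        self.templates = sorted(templates, key=lambda t: t.template_id)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)


class DiseaseRegistry:
    """Case-insensitive registry of diseases and their categories."""

    def __init__(self, diseases: list[DiseaseSpec]):
        self._by_key: dict[str, DiseaseSpec] = {}
        for d in diseases:
            key = d.name.lower()
            if key in self._by_key:
                raise ValidationError(f"duplicate disease {d.name!r}")
            self._by_key[key] = d

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_key

    def get(self, name: str) -> DiseaseSpec:
        try:
            return self._by_key[name.lower()]
        except KeyError:
            raise RegistryError(f"unknown disease {name!r}") from None

    def list_diseases(self, category: str | None = None) -> list[DiseaseSpec]:
        """All diseases, alphabetical; optionally filtered by category."""
        if category is not None and category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {category!r}; expected one of {CATEGORIES}"
            )
        specs = sorted(self._by_key.values(), key=lambda d: d.name.lower())
        if category is not None:
            specs = [d for d in specs if d.category == category]
        return specs


def expand_prompts(disease: str, bank: PromptBank, registry: DiseaseRegistry | None = None) -> list[str]:
    """Instantiate every template of *bank* for *disease*, in template_id order.

    When a registry is given the disease must be registered (its canonical
    name is substituted); without one, the name is substituted verbatim.
    """
    if registry is not None:
        disease = registry.get(disease).name
    return [t.text.replace(PLACEHOLDER, disease) for t in bank]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ehraudit.data") / name))


def load_prompt_bank(path: str | Path | None = None) -> PromptBank:
    """Read a bank from a plain-text file: one template per non-empty line.

    Lines starting with ``#`` are comments. Template ids are assigned 1..n in
    file order.
    """
    path = _data_path("prompt_templates.txt") if path is None else Path(path)
    templates = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        templates.append(PromptTemplate(template_id=len(templates) + 1, text=line))
    if not templates:
        raise ConfigurationError(f"no templates found in {path}")
    return PromptBank(templates)


def load_disease_registry(path: str | Path | None = None) -> DiseaseRegistry:
    """Read the registry from a CSV with columns ``name,category``."""
    import pandas as pd

    path = _data_path("diseases.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    return DiseaseRegistry(
        [DiseaseSpec(name=r["name"], category=r["category"]) for _, r in df.iterrows()]
    )


def default_prompt_bank() -> PromptBank:
    return load_prompt_bank(None)


def default_disease_registry() -> DiseaseRegistry:
    return load_disease_registry(None)
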
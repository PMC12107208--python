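"""Regex-based demographic attribute extraction and completeness taxonomy.

Each record's free text is scanned with an ordered set of case-insensitive,
word-boundary patterns per (attribute, category). The first matching category
in priority order is assigned; a record matching two or more distinct
categories of one attribute is flagged as a conflict (default policy: keep
the highest-priority match; strict policy: demote to ``not_available``). A
record with no extractable attribute at all is *irrelevant*; with every
attribute extracted, *full*; otherwise *partial*. These three classes
partition any corpus and feed the completeness scores.

Known limitations: negation ("not Hispanic") is not handled, and recall of
the shipped default patterns is only guaranteed on the canonical phrasing
pools of the synthetic generator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import EHRRecord, NOT_AVAILABLE
from .errors import ConfigurationError, ValidationError

IRRELEVANT, PARTIAL, FULL = "irrelevant", "partial", "full"


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered attributes and their category labels.

    ``not_available`` is reserved in every attribute and must not appear
    among the configured categories.
    """

    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "gender": ("male", "female"),
            "race": ("White", "Black", "Hispanic", "Asian"),
        }
    )

    def __post_init__(self) -> None:
        for attr, cats in self.categories.items():
            if NOT_AVAILABLE in cats:
                raise ValidationError(
                    f"{NOT_AVAILABLE!r} is reserved and implicit in {attr!r}"
                )
            if len(set(cats)) != len(cats):
                raise ValidationError(f"duplicate category labels in {attr!r}")

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.categories)


@dataclass(frozen=True)
class ExtractionPattern:
    attribute: str
    category: str
    pattern: str
    priority: int

    def compile(self) -> re.Pattern:
        try:
            return re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ConfigurationError(
                f"pattern for {self.attribute}={self.category!r} does not "
                f"compile: {exc}"
            ) from exc


@dataclass(frozen=True)
class ExtractedRecord:
    record_id: str
    model_label: str
    disease: str
    categories: dict[str, str]
    conflict_flags: dict[str, bool]
    completeness_class: str


class PatternSet:
    """Compiled patterns grouped by attribute, sorted by ascending priority."""

    def __init__(self, patterns: list[ExtractionPattern]):
        seen: set[tuple[str, int]] = set()
        self._by_attr: dict[str, list[tuple[ExtractionPattern, re.Pattern]]] = {}
        for p in patterns:
            key = (p.attribute, p.priority)
            if key in seen:
                raise ValidationError(f"duplicate (attribute, priority) {key}")
            seen.add(key)
            self._by_attr.setdefault(p.attribute, []).append((p, p.compile()))
        for plist in self._by_attr.values():
            plist.sort(key=lambda pc: pc[0].priority)

    def for_attribute(self, attribute: str) -> list[tuple[ExtractionPattern, re.Pattern]]:
        return self._by_attr.get(attribute, [])

    def validate_coverage(self, schema: AttributeSchema) -> None:
        """Every non-reserved category of every attribute must have a pattern."""
        for attr, cats in schema.categories.items():
            covered = {p.category for p, _ in self.for_attribute(attr)}
            missing = set(cats) - covered
            if missing:
                raise ConfigurationError(
                    f"no pattern for {attr} categories {sorted(missing)}"
                )


def classify_record(categories: dict[str, str], schema: AttributeSchema) -> str:
    """Three-way completeness class from per-attribute assignments."""
    missing = [a for a in schema.attributes if a not in categories]
    if missing:
        raise ValidationError(f"assignments missing attributes {missing}")
    available = [a for a in schema.attributes if categories[a] != NOT_AVAILABLE]
    if not available:
        return IRRELEVANT
    if len(available) == len(schema.attributes):
        return FULL
    return PARTIAL


def extract_attributes(
    record: EHRRecord,
    patterns: PatternSet,
    schema: AttributeSchema | None = None,
    strict_conflicts: bool = False,
) -> ExtractedRecord:
    """Assign a category per schema attribute from the record text.

    Patterns are tried in ascending priority; the first match wins. Matches
    for two or more distinct categories raise the attribute's conflict flag
    and, under ``strict_conflicts``, demote the assignment to
    ``not_available``.
    """
    schema = schema or AttributeSchema()
    cats: dict[str, str] = {}
    conflicts: dict[str, bool] = {}
    for attr in schema.attributes:
        matched: list[str] = []
        for pat, compiled in patterns.for_attribute(attr):
            if pat.category not in matched and compiled.search(record.text):
                matched.append(pat.category)
        conflicts[attr] = len(matched) > 1
        if not matched or (conflicts[attr] and strict_conflicts):
            cats[attr] = NOT_AVAILABLE
        else:
            cats[attr] = matched[0]
    return ExtractedRecord(
        record_id=record.record_id,
        model_label=record.model_label,
        disease=record.disease,
        categories=cats,
        conflict_flags=conflicts,
        completeness_class=classify_record(cats, schema),
    )


def extract_corpus(
    records: list[EHRRecord],
    patterns: PatternSet | None = None,
    schema: AttributeSchema | None = None,
    strict_conflicts: bool = False,
) -> list[ExtractedRecord]:
    schema = schema or AttributeSchema()
    patterns = patterns or default_patterns()
    patterns.validate_coverage(schema)
    return [extract_attributes(r, patterns, schema, strict_conflicts) for r in records]


def load_patterns(path: str | Path) -> PatternSet:
    """Read a pattern table: CSV with columns attribute,category,pattern,priority."""
    import pandas as pd

    df = pd.read_csv(path)
    return PatternSet(
        [
            ExtractionPattern(
                attribute=r["attribute"],
                category=r["category"],
                pattern=r["pattern"],
                priority=int(r["priority"]),
            )
            for _, r in df.iterrows()
        ]
    )


def load_synonyms(path: str | Path | None = None):
    """Synonym table (attribute, category, synonym) used to build the default
    patterns; editable so new surface forms can be added without touching
    regex syntax."""
    import pandas as pd

    if path is None:
        path = Path(str(resources.files("ehraudit.data") / "synonyms.csv"))
    return pd.read_csv(path)


def default_patterns(synonyms_path: str | Path | None = None) -> PatternSet:
    """Build the default pattern set from the shipped synonym table.

    One alternation pattern per (attribute, category), word-bounded and
    case-insensitive; priorities follow table order within each attribute.
    """
    syn = load_synonyms(synonyms_path)
    patterns: list[ExtractionPattern] = []
    priority: dict[str, int] = {}
    for (attr, cat), grp in syn.groupby(["attribute", "category"], sort=False):
        alts = "|".join(re.escape(s) for s in grp["synonym"])
        priority[attr] = priority.get(attr, 0) + 1
        patterns.append(
            ExtractionPattern(
                attribute=attr,
                category=cat,
                pattern=rf"\b(?:{alts})\b",
                priority=priority[attr],
            )
        )
    return PatternSet(patterns)
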
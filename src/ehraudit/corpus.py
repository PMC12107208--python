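"""Synthetic EHR corpus generator with known ground truth.

Model-generated record corpora are the natural input of the audit pipeline,
but auditing code must be testable without hosting any language model. This
module emulates such corpora with a fully parameterised generative process:

* with probability ``p_irrelevant`` a record is an off-target narrative
  carrying no demographic token at all (emulating hallucinated/unusable
  output);
* otherwise each schema attribute is omitted with its ``p_missing``
  probability, and when present its category is drawn from a configurable
  distribution and rendered through one of several surface phrasings.

Because the realised category of every attribute is recorded as ground
truth, extraction, completeness scoring and bias statistics can all be
checked for exact parameter recovery. Generation is deterministic given
``(config, seed)``: one ``numpy`` Generator per corpus, draws consumed in
record order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError

NOT_AVAILABLE = "not_available"

#: Default surface phrasings per attribute category. At least three forms per
#: category so that extraction is exercised beyond a single keyword.
DEFAULT_PHRASINGS: dict[str, dict[str, list[str]]] = {
    "gender": {
        "female": [
            "Sex: Female.",
            "The patient is a {age}-year-old woman.",
            "This female patient presented to the clinic.",
        ],
        "male": [
            "Sex: Male.",
            "The patient is a {age}-year-old man.",
            "This male patient presented to the clinic.",
        ],
    },
    "race": {
        "White": [
            "Race: White.",
            "The patient is of White ethnicity.",
            "The patient identifies as Caucasian.",
        ],
        "Black": [
            "Race: Black.",
            "The patient is of Black ethnicity.",
            "The patient identifies as African American.",
        ],
        "Hispanic": [
            "Ethnicity: Hispanic.",
            "The patient is of Hispanic origin.",
            "The patient identifies as Latino.",
        ],
        "Asian": [
            "Race: Asian.",
            "The patient is of Asian descent.",
            "The patient identifies as Asian American.",
        ],
    },
}

# Off-target narratives: deliberately free of any demographic token.
_IRRELEVANT_TEMPLATES = [
    "Administrative note regarding {disease}: the requested record could not "
    "be located; general guidance on {disease} screening was filed instead.",
    "Department memo: staffing for the {disease} clinic was reviewed. No "
    "individual patient details are recorded in this entry.",
    "Literature summary on {disease}: recent trials were discussed at the "
    "weekly seminar; no case information is included.",
]

_CLOSINGS = [
    "Chief complaint and findings are consistent with {disease}.",
    "Assessment: {disease}; plan documented in the chart.",
    "History, examination and plan recorded for {disease} follow-up.",
]


@dataclass(frozen=True)
class EHRRecord:
    """One generated free-text record with provenance."""

    record_id: str
    model_label: str
    disease: str
    prompt_id: int
    text: str


@dataclass(frozen=True)
class GroundTruth:
    """Realised per-attribute categories for one record."""

    record_id: str
    categories: dict[str, str]  # attribute -> category or not_available
    completeness_class: str     # irrelevant | partial | full


@dataclass
class GenerationConfig:
    """Parameters of one synthetic corpus.

    ``category_dist`` maps attribute -> {category: probability}; a
    ``not_available`` entry is allowed and behaves as additional missingness
    (useful for reproducing printed generated distributions, which report the
    unextractable share as its own category). Each distribution must sum to 1.
    """

    disease: str
    model_label: str = "synthetic-model"
    n_records: int = 1000          # protocol default: 1000 records per disease
    p_irrelevant: float = 0.0
    p_missing: dict[str, float] = field(default_factory=dict)
    category_dist: dict[str, dict[str, float]] = field(default_factory=dict)
    phrasing_pool: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    n_prompts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValidationError("n_records must be positive")
        if not 0.0 <= self.p_irrelevant <= 1.0:
            raise ValidationError("p_irrelevant must be in [0, 1]")
        if not self.category_dist:
            raise ValidationError("category_dist must define at least one attribute")
        for attr, p in self.p_missing.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p_missing[{attr!r}] must be in [0, 1]")
        for attr, dist in self.category_dist.items():
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"negative probability in category_dist[{attr!r}]")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"category_dist[{attr!r}] sums to {total!r}, expected 1"
                )

    @property
    def attributes(self) -> list[str]:
        return list(self.category_dist)

    def pool_for(self, attribute: str, category: str) -> list[str]:
        pools = self.phrasing_pool or DEFAULT_PHRASINGS
        pool = pools.get(attribute, {}).get(category)
        if not pool:
            raise ConfigurationError(
                f"no phrasings configured for {attribute}={category!r}"
            )
        return pool


def expected_full_fraction(config: GenerationConfig) -> float:
    """Closed-form probability that a generated record is fully relevant.

    A record is full iff it is not irrelevant and every attribute is both
    rendered (prob ``1 - p_missing``) and drawn to a real category (prob
    ``1 - P(not_available)`` under ``category_dist``).
    """
    p = 1.0 - config.p_irrelevant
    for attr in config.attributes:
        p_na = config.category_dist[attr].get(NOT_AVAILABLE, 0.0)
        p *= (1.0 - config.p_missing.get(attr, 0.0)) * (1.0 - p_na)
    return p


def _classify(categories: dict[str, str]) -> str:
    available = [c for c in categories.values() if c != NOT_AVAILABLE]
    if not available:
        return "irrelevant"
    if len(available) == len(categories):
        return "full"
    return "partial"


def generate_corpus(config: GenerationConfig) -> tuple[list[EHRRecord], list[GroundTruth]]:
    """Draw ``config.n_records`` records plus their ground truth.

    Deterministic: identical ``(config, seed)`` yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    records: list[EHRRecord] = []
    truths: list[GroundTruth] = []
    attrs = config.attributes
    dists = {
        a: (list(config.category_dist[a]), np.array(list(config.category_dist[a].values())))
        for a in attrs
    }
    for i in range(config.n_records):
        rid = f"{config.model_label}-{config.disease}-{i:06d}".replace(" ", "_")
        prompt_id = (i % config.n_prompts) + 1
        if rng.random() < config.p_irrelevant:
            tmpl = _IRRELEVANT_TEMPLATES[rng.integers(len(_IRRELEVANT_TEMPLATES))]
            text = tmpl.format(disease=config.disease)
            cats = {a: NOT_AVAILABLE for a in attrs}
        else:
            cats = {}
            parts = [f"Record {rid}."]
            for a in attrs:
                if rng.random() < config.p_missing.get(a, 0.0):
                    cats[a] = NOT_AVAILABLE
                    continue
                names, probs = dists[a]
                cat = names[rng.choice(len(names), p=probs / probs.sum())]
                cats[a] = cat
                if cat == NOT_AVAILABLE:
                    continue
                phrase = config.pool_for(a, cat)[rng.integers(len(config.pool_for(a, cat)))]
                parts.append(phrase.format(age=int(rng.integers(18, 91))))
            parts.append(_CLOSINGS[rng.integers(len(_CLOSINGS))].format(disease=config.disease))
            text = " ".join(parts)
        records.append(
            EHRRecord(
                record_id=rid,
                model_label=config.model_label,
                disease=config.disease,
                prompt_id=prompt_id,
                text=text,
            )
        )
        truths.append(
            GroundTruth(record_id=rid, categories=dict(cats), completeness_class=_classify(cats))
        )
    return records, truths


def config_from_percentages(
    disease: str,
    gender_pct: dict[str, float] | None = None,
    race_pct: dict[str, float] | None = None,
    **kwargs,
) -> GenerationConfig:
    """Build a config whose category distributions mirror printed percentage
    columns (values on the 0-100 scale, including a ``not_available`` share).

    Convenience for replaying a published generated distribution through the
    pipeline. Percentages are renormalised to remove 1-decimal rounding slack.
    """
    dist: dict[str, dict[str, float]] = {}
    for attr, pct in (("gender", gender_pct), ("race", race_pct)):
        if pct is None:
            continue
        total = sum(pct.values())
        if total <= 0:
            raise ValidationError(f"{attr} percentages sum to {total}")
        dist[attr] = {c: v / total for c, v in pct.items()}
    return GenerationConfig(disease=disease, category_dist=dist, **kwargs)


def replace(config: GenerationConfig, **changes) -> GenerationConfig:
    """Functional update of a config (dataclasses.replace with validation)."""
    return dataclasses.replace(config, **changes)
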
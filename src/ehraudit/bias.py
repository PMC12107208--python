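"""Demographic bias statistics for generated record corpora.

The central quantity is the statistical parity difference

    SPD = P_generated - P_real          (percentage points),

where P_generated is a category's share of *all* records in a group (the
unextractable ``not_available`` share counts in the denominator, mirroring
the published layout of generated-distribution tables) and P_real is the
real-world prevalence of that category for the disease, which excludes
``not_available``. Consequently the category SPDs of a group sum to minus
the group's not-available percentage. A category is flagged overrepresented
when SPD > +10 and underrepresented when SPD < -10, on the unrounded value.

Bias *presence* is detected by a chi-square goodness-of-fit test of the
observed non-reserved category counts against expectations rescaled from the
prevalence benchmark (alpha = 0.05 by default, no continuity correction, no
multiple-testing adjustment across the disease x model grid). Polarization —
the drift of one category's SPD with model size inside a model family — is
summarised by a scan over models ordered by parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import NOT_AVAILABLE
from .errors import RegistryError, ValidationError
from .extraction import ExtractedRecord

OVER, UNDER, NONE = "overrepresented", "underrepresented", "none"


# ---------------------------------------------------------------------------
# benchmark and model metadata registries

class PrevalenceBenchmark:
    """Real-world category proportions per (disease, attribute).

    Proportions are fractions in [0, 1]; the non-reserved categories of each
    (disease, attribute) must sum to 1 (tolerance 1e-6) and ``not_available``
    carries no benchmark entry.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"disease", "attribute", "category", "proportion"}
        if not required.issubset(table.columns):
            raise ValidationError(f"benchmark table needs columns {sorted(required)}")
        if (table["category"] == NOT_AVAILABLE).any():
            raise ValidationError(f"{NOT_AVAILABLE!r} cannot have a benchmark entry")
        sums = table.groupby(["disease", "attribute"])["proportion"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if not bad.empty:
            raise ValidationError(f"benchmark proportions do not sum to 1: {bad.to_dict()}")
        self.table = table.reset_index(drop=True)
        self._index: dict[tuple[str, str], dict[str, float]] = {}
        for (dis, attr), grp in table.groupby(["disease", "attribute"]):
            self._index[(dis.lower(), attr)] = dict(
                zip(grp["category"], grp["proportion"])
            )

    def has(self, disease: str, attribute: str) -> bool:
        return (disease.lower(), attribute) in self._index

    def proportions(self, disease: str, attribute: str) -> dict[str, float]:
        try:
            return dict(self._index[(disease.lower(), attribute)])
        except KeyError:
            raise RegistryError(
                f"no benchmark for disease={disease!r}, attribute={attribute!r}"
            ) from None

    def percent(self, disease: str, attribute: str, category: str) -> float:
        props = self.proportions(disease, attribute)
        try:
            return 100.0 * props[category]
        except KeyError:
            raise RegistryError(
                f"no benchmark for category {category!r} of {disease}/{attribute}"
            ) from None


@dataclass(frozen=True)
class ModelMeta:
    name: str
    family: str
    size_billion: float
    mmlu: float | None = None
    ceval: float | None = None

    def __post_init__(self) -> None:
        if self.size_billion <= 0:
            raise ValidationError("size_billion must be positive")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ehraudit.data") / name))


def load_benchmarks(path: str | Path | None = None) -> PrevalenceBenchmark:
    path = _data_path("benchmarks.csv") if path is None else Path(path)
    return PrevalenceBenchmark(pd.read_csv(path))


def load_model_meta(path: str | Path | None = None) -> pd.DataFrame:
    path = _data_path("models.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    if df["name"].duplicated().any():
        raise ValidationError("model names must be unique")
    return df


def load_printed_ratios(which: str = "gender") -> pd.DataFrame:
    """Published generated-distribution columns shipped as package fixtures
    (long format: model, disease, category, ratio_pct)."""
    name = {"gender": "gender_ratios.csv", "race": "race_ratios.csv"}[which]
    return pd.read_csv(_data_path(name))


def load_printed_spd_means() -> pd.DataFrame:
    """Published per-model mean SPD by racial group (summary-table fixture)."""
    return pd.read_csv(_data_path("model_race_spd_means.csv"))


# ---------------------------------------------------------------------------
# core operations

@dataclass(frozen=True)
class ProportionTable:
    model: str
    disease: str
    attribute: str
    percent: dict[str, float]  # category (incl. not_available) -> % of group
    n: int

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"group percentages sum to {total}, expected 100")


@dataclass(frozen=True)
class SPDResult:
    model: str
    disease: str
    attribute: str
    spd: dict[str, float]            # non-reserved category -> pp
    classification: dict[str, str]   # category -> over/under/none
    percent: dict[str, float]        # generated % incl. not_available
    threshold: float = 10.0


@dataclass(frozen=True)
class ChiSquareResult:
    model: str
    disease: str
    attribute: str
    statistic: float
    df: int
    p: float
    significant: bool
    alpha: float
    low_expected: bool = False  # any expected cell < 5: asymptotic caveat


@dataclass(frozen=True)
class AggregateSPD:
    model: str
    category: str
    mean: float
    sd: float  # population SD (divisor n)
    n_diseases: int


@dataclass(frozen=True)
class PolarizationResult:
    family: str
    disease: str
    attribute: str
    polarized_category: str
    spd_by_size: tuple[tuple[float, float], ...]  # (size_billion, spd)
    effect_present: bool
    monotone: bool


def category_counts(
    extracted: list[ExtractedRecord], attribute: str
) -> dict[str, int]:
    """Counts of assigned categories (including not_available) for one group."""
    counts: dict[str, int] = {}
    for rec in extracted:
        cat = rec.categories.get(attribute, NOT_AVAILABLE)
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def proportions(
    extracted: list[ExtractedRecord],
    attribute: str,
    categories: tuple[str, ...] | None = None,
) -> ProportionTable:
    """Per-category percentage of all records in the group (NA included)."""
    if not extracted:
        raise ValidationError("cannot compute proportions of an empty group")
    counts = category_counts(extracted, attribute)
    n = len(extracted)
    cats = list(categories) if categories else sorted(counts)
    for c in counts:
        if c not in cats:
            cats.append(c)
    if NOT_AVAILABLE not in cats:
        cats.append(NOT_AVAILABLE)
    pct = {c: 100.0 * counts.get(c, 0) / n for c in cats}
    first = extracted[0]
    return ProportionTable(
        model=first.model_label, disease=first.disease, attribute=attribute,
        percent=pct, n=n,
    )


def spd(p_generated: float, p_real: float) -> float:
    """Statistical parity difference, both arguments in percent."""
    for name, v in (("p_generated", p_generated), ("p_real", p_real)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name} must be a percentage in [0, 100], got {v}")
    return p_generated - p_real


def classify_spd(spd_value: float, threshold: float = 10.0) -> str:
    """Over/under/none by strict comparison of the unrounded SPD."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if spd_value > threshold:
        return OVER
    if spd_value < -threshold:
        return UNDER
    return NONE


def spd_result(
    table: ProportionTable,
    benchmark: PrevalenceBenchmark,
    threshold: float = 10.0,
) -> SPDResult:
    """SPD and classification for every benchmarked category of a group."""
    real = benchmark.proportions(table.disease, table.attribute)
    spds = {
        cat: spd(table.percent.get(cat, 0.0), 100.0 * p_real)
        for cat, p_real in real.items()
    }
    return SPDResult(
        model=table.model, disease=table.disease, attribute=table.attribute,
        spd=spds,
        classification={c: classify_spd(v, threshold) for c, v in spds.items()},
        percent=dict(table.percent),
        threshold=threshold,
    )


def chi_square_bias(
    counts: dict[str, int],
    benchmark: PrevalenceBenchmark,
    disease: str,
    attribute: str,
    alpha: float = 0.05,
    model: str = "",
) -> ChiSquareResult:
    """Goodness-of-fit of observed non-reserved counts against prevalence.

    Expected counts are the benchmark proportions rescaled to the observed
    non-reserved total, so the test concerns the composition of the records
    in which the attribute was extractable. df = k - 1.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    real = benchmark.proportions(disease, attribute)
    if len(real) < 2:
        raise ValidationError("chi-square needs at least 2 benchmarked categories")
    observed = np.array([counts.get(c, 0) for c in real], dtype=float)
    total = observed.sum()
    if total <= 0:
        raise ValidationError(
            f"no non-reserved observations for {disease}/{attribute}"
        )
    expected = np.array([real[c] for c in real]) * total
    if np.any(expected == 0):
        raise ValidationError(
            f"expected count of 0 for {disease}/{attribute}; "
            "remove zero-prevalence categories from the benchmark"
        )
    statistic, p = stats.chisquare(observed, f_exp=expected)
    return ChiSquareResult(
        model=model, disease=disease, attribute=attribute,
        statistic=float(statistic), df=len(real) - 1, p=float(p),
        significant=bool(p < alpha), alpha=alpha,
        low_expected=bool(np.any(expected < 5)),
    )


def count_biased_diseases(
    results: list[ChiSquareResult],
) -> tuple[int, list[str]]:
    """Number of significant diseases and the alphabetical list of the rest."""
    seen: set[str] = set()
    unbiased: list[str] = []
    n_biased = 0
    for r in results:
        if r.disease in seen:
            raise ValidationError(f"duplicate disease {r.disease!r}")
        seen.add(r.disease)
        if r.significant:
            n_biased += 1
        else:
            unbiased.append(r.disease)
    return n_biased, sorted(unbiased)


def aggregate_spd(
    spd_values: list[float], model: str = "", category: str = ""
) -> AggregateSPD:
    """Mean and population SD (divisor n) of per-disease SPDs."""
    if not spd_values:
        raise ValidationError("cannot aggregate an empty SPD list")
    arr = np.asarray(spd_values, dtype=float)
    return AggregateSPD(
        model=model, category=category,
        mean=float(arr.mean()), sd=float(arr.std(ddof=0)),
        n_diseases=len(arr),
    )


def mean_across_models(per_model_means: list[float]) -> float:
    """Arithmetic mean of per-model mean SPDs."""
    if not per_model_means:
        raise ValidationError("empty input")
    return float(np.mean(per_model_means))


def polarization_scan(
    family_results: list[tuple[ModelMeta, SPDResult]],
    attribute: str,
) -> PolarizationResult:
    """Trace a category's SPD across a model family ordered by size.

    The polarized category is the one with maximal SPD in the largest model;
    the effect is present when that category's SPD is strictly larger in the
    largest model than in the smallest, and monotone when it never decreases
    along the size ordering.
    """
    if len(family_results) < 2:
        raise ValidationError("polarization scan needs at least 2 models")
    sizes = [m.size_billion for m, _ in family_results]
    if len(set(sizes)) != len(sizes):
        raise ValidationError("model sizes within a family must be distinct")
    ordered = sorted(family_results, key=lambda mr: mr[0].size_billion)
    families = {m.family for m, _ in ordered}
    diseases = {r.disease for _, r in ordered}
    if len(families) != 1 or len(diseases) != 1:
        raise ValidationError("scan expects one family and one disease")
    largest = ordered[-1][1]
    polarized = max(largest.spd, key=lambda c: largest.spd[c])
    series = tuple(
        (m.size_billion, r.spd[polarized]) for m, r in ordered
    )
    values = [v for _, v in series]
    return PolarizationResult(
        family=next(iter(families)), disease=next(iter(diseases)),
        attribute=attribute, polarized_category=polarized,
        spd_by_size=series,
        effect_present=values[-1] > values[0],
        monotone=all(b >= a for a, b in zip(values, values[1:])),
    )


def spd_sum_identity(result: SPDResult) -> float:
    """Diagnostic: sum of category SPDs + not_available percentage (≈ 0)."""
    return sum(result.spd.values()) + result.percent.get(NOT_AVAILABLE, 0.0)
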
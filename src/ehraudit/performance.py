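"""Completeness tallies and performance scores.

A corpus of N extracted records partitions into irrelevant (N_i), partially
relevant (N_s) and fully relevant (N_a) records, N = N_i + N_s + N_a. The
overall performance score is the fully-relevant fraction on a 0-100 scale,

    EPS = 100 * N_a / N,

and the attribute-specific score counts records in which attribute A_i is
present — the partial records containing it (N_{s-i}) plus all full records:

    EPS_i = 100 * (N_{s-i} + N_a) / N.

EPS <= EPS_i <= 100 always, since N_{s-i} >= 0 and N_{s-i} + N_a <= N.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .corpus import NOT_AVAILABLE
from .errors import ValidationError
from .extraction import FULL, IRRELEVANT, PARTIAL, AttributeSchema, ExtractedRecord


@dataclass(frozen=True)
class CompletenessCounts:
    n: int
    n_irrelevant: int
    n_partial: int
    n_full: int
    n_partial_with: dict[str, int]  # attribute -> partial records containing it

    def __post_init__(self) -> None:
        if self.n != self.n_irrelevant + self.n_partial + self.n_full:
            raise ValidationError(
                f"counts do not partition: {self.n} != "
                f"{self.n_irrelevant} + {self.n_partial} + {self.n_full}"
            )
        for attr, k in self.n_partial_with.items():
            if not 0 <= k <= self.n_partial:
                raise ValidationError(
                    f"n_partial_with[{attr!r}] = {k} outside [0, {self.n_partial}]"
                )


@dataclass(frozen=True)
class EPSResult:
    eps: float
    eps_by_attribute: dict[str, float]
    n: int


def tally_counts(
    extracted: list[ExtractedRecord], schema: AttributeSchema | None = None
) -> CompletenessCounts:
    """Count the three completeness classes and per-attribute partial presence."""
    if not extracted:
        raise ValidationError("cannot tally an empty record list")
    schema = schema or AttributeSchema()
    n_i = n_s = n_a = 0
    partial_with = {a: 0 for a in schema.attributes}
    for rec in extracted:
        cls = rec.completeness_class
        if cls == IRRELEVANT:
            n_i += 1
        elif cls == FULL:
            n_a += 1
        elif cls == PARTIAL:
            n_s += 1
            for a in schema.attributes:
                if rec.categories.get(a, NOT_AVAILABLE) != NOT_AVAILABLE:
                    partial_with[a] += 1
        else:
            raise ValidationError(f"unknown completeness class {cls!r}")
    return CompletenessCounts(
        n=len(extracted),
        n_irrelevant=n_i,
        n_partial=n_s,
        n_full=n_a,
        n_partial_with=partial_with,
    )


def eps(counts: CompletenessCounts) -> float:
    """Overall performance score, 0-100."""
    if counts.n == 0:
        raise ValidationError("EPS undefined for N = 0")
    return 100.0 * counts.n_full / counts.n


def eps_attr(counts: CompletenessCounts, attribute: str) -> float:
    """Attribute-specific performance score, 0-100."""
    if counts.n == 0:
        raise ValidationError("EPS_i undefined for N = 0")
    try:
        n_partial_with = counts.n_partial_with[attribute]
    except KeyError:
        raise ValidationError(f"unknown attribute {attribute!r}") from None
    return 100.0 * (n_partial_with + counts.n_full) / counts.n


def score(
    extracted: list[ExtractedRecord], schema: AttributeSchema | None = None
) -> EPSResult:
    """Tally and score in one step."""
    schema = schema or AttributeSchema()
    counts = tally_counts(extracted, schema)
    return EPSResult(
        eps=eps(counts),
        eps_by_attribute={a: eps_attr(counts, a) for a in schema.attributes},
        n=counts.n,
    )


def performance_table(
    extracted: list[ExtractedRecord],
    schema: AttributeSchema | None = None,
    model_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-model performance summary (one row per model, EPS columns).

    Scores aggregate over all diseases present for the model; pass-through
    metadata columns (size, benchmark scores) are merged when provided.
    Sorted by descending EPS.
    """
    schema = schema or AttributeSchema()
    rows = []
    by_model: dict[str, list[ExtractedRecord]] = {}
    for rec in extracted:
        by_model.setdefault(rec.model_label, []).append(rec)
    for model, recs in by_model.items():
        res = score(recs, schema)
        row = {"model": model, "n": res.n, "eps": res.eps}
        for a in schema.attributes:
            row[f"eps_{a}"] = res.eps_by_attribute[a]
        rows.append(row)
    df = pd.DataFrame(rows)
    if model_meta is not None:
        df = df.merge(model_meta, left_on="model", right_on="name", how="left").drop(
            columns=["name"]
        )
    return df.sort_values("eps", ascending=False, kind="mergesort").reset_index(drop=True)
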
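"""End-to-end audit: extract -> tally -> performance -> bias -> aggregate ->
polarization, with deterministic, stably sorted tabular outputs.

The report mirrors the layouts a bias audit needs side by side: a per-model
performance table, per-(model, disease) bias tables for each attribute with
generated percentages, SPD, classification and the chi-square test, a
per-model bias-count table, per-model SPD aggregates over diseases, a
polarization table per model family, and a disease x model SPD matrix per
category for heatmap rendering. Groups lacking a prevalence benchmark are
skipped and enumerated in the report manifest rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bias as _bias
from .bias import (
    ChiSquareResult, ModelMeta, PrevalenceBenchmark, SPDResult,
    aggregate_spd, category_counts, chi_square_bias, count_biased_diseases,
    polarization_scan, proportions, spd_result,
)
from .corpus import EHRRecord, NOT_AVAILABLE
from .errors import ValidationError
from .extraction import AttributeSchema, ExtractedRecord, PatternSet, extract_corpus
from .io import write_table
from .performance import performance_table

log = logging.getLogger("ehraudit")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on (pure function of this + corpus)."""

    alpha: float = 0.05
    spd_threshold: float = 10.0
    schema: AttributeSchema = field(default_factory=AttributeSchema)
    patterns: PatternSet | None = None
    strict_conflicts: bool = False
    output_format: str = "csv"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.spd_threshold <= 0:
            raise ValidationError("spd_threshold must be positive")


@dataclass
class AuditReport:
    performance: pd.DataFrame
    bias_tables: dict[str, pd.DataFrame]       # attribute -> long bias table
    bias_counts: dict[str, pd.DataFrame]       # attribute -> per-model counts
    aggregates: dict[str, pd.DataFrame]        # attribute -> per-model x category
    polarization: pd.DataFrame
    heatmaps: dict[tuple[str, str], pd.DataFrame]  # (attribute, category) -> disease x model SPD
    skipped: list[dict]
    metadata: dict

    def write(self, outdir: str | Path, fmt: str = "csv") -> list[Path]:
        """Write every table plus the run manifest; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = {"csv": "csv", "tsv": "tsv", "json": "json"}[fmt]
        written: list[Path] = []

        def _emit(df: pd.DataFrame, stem: str) -> None:
            p = outdir / f"{stem}.{ext}"
            write_table(df, p, fmt)
            written.append(p)

        _emit(self.performance, "performance")
        for attr, df in self.bias_tables.items():
            _emit(df, f"bias_{attr}")
        for attr, df in self.bias_counts.items():
            _emit(df, f"bias_counts_{attr}")
        for attr, df in self.aggregates.items():
            _emit(df, f"aggregate_spd_{attr}")
        _emit(self.polarization, "polarization")
        for (attr, cat), df in self.heatmaps.items():
            _emit(df.reset_index(), f"heatmap_{attr}_{cat}".replace(" ", "_"))
        manifest = outdir / "manifest.json"
        manifest.write_text(
            json.dumps({"metadata": self.metadata, "skipped": self.skipped}, indent=2)
            + "\n",
            encoding="utf-8",
        )
        written.append(manifest)
        return written


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "alpha": config.alpha,
            "spd_threshold": config.spd_threshold,
            "attributes": {a: list(c) for a, c in config.schema.categories.items()},
            "strict_conflicts": config.strict_conflicts,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(
    records: list[EHRRecord],
    benchmark: PrevalenceBenchmark,
    config: RunConfig | None = None,
    model_meta: pd.DataFrame | None = None,
) -> AuditReport:
    """Run every audit stage on an in-memory corpus and assemble the report."""
    config = config or RunConfig()
    if not records:
        raise ValidationError("empty corpus")
    t0 = time.perf_counter()
    extracted = extract_corpus(
        records, config.patterns, config.schema, config.strict_conflicts
    )
    log.info("extracted %d records in %.2fs", len(extracted), time.perf_counter() - t0)

    perf = performance_table(extracted, config.schema, model_meta)

    groups: dict[tuple[str, str], list[ExtractedRecord]] = {}
    for rec in extracted:
        groups.setdefault((rec.model_label, rec.disease), []).append(rec)

    skipped: list[dict] = []
    spd_results: dict[str, list[SPDResult]] = {a: [] for a in config.schema.attributes}
    chi_results: dict[str, list[ChiSquareResult]] = {a: [] for a in config.schema.attributes}
    for (model, disease) in sorted(groups):
        recs = groups[(model, disease)]
        for attr in config.schema.attributes:
            if not benchmark.has(disease, attr):
                skipped.append({"model": model, "disease": disease, "attribute": attr,
                                "reason": "no benchmark"})
                log.warning("no %s benchmark for %s; group skipped", attr, disease)
                continue
            table = proportions(recs, attr, config.schema.categories[attr])
            spd_results[attr].append(spd_result(table, benchmark, config.spd_threshold))
            try:
                chi = chi_square_bias(
                    category_counts(recs, attr), benchmark, disease, attr,
                    config.alpha, model=model,
                )
            except ValidationError as exc:
                skipped.append({"model": model, "disease": disease, "attribute": attr,
                                "reason": f"chi-square: {exc}"})
                continue
            chi_results[attr].append(chi)

    bias_tables = {
        attr: _bias_frame(spd_results[attr], chi_results[attr])
        for attr in config.schema.attributes
    }
    bias_counts = {
        attr: _count_frame(chi_results[attr]) for attr in config.schema.attributes
    }
    aggregates = {
        attr: _aggregate_frame(spd_results[attr], config.schema.categories[attr])
        for attr in config.schema.attributes
    }
    polar = _polarization_frame(spd_results, model_meta, config)
    heatmaps = _heatmap_frames(spd_results, config)

    metadata = {
        "n_records": len(records),
        "n_models": len({r.model_label for r in records}),
        "n_diseases": len({r.disease for r in records}),
        "alpha": config.alpha,
        "spd_threshold": config.spd_threshold,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    return AuditReport(
        performance=perf, bias_tables=bias_tables, bias_counts=bias_counts,
        aggregates=aggregates, polarization=polar, heatmaps=heatmaps,
        skipped=skipped, metadata=metadata,
    )


def _bias_frame(spds: list[SPDResult], chis: list[ChiSquareResult]) -> pd.DataFrame:
    chi_by_group = {(c.model, c.disease): c for c in chis}
    rows = []
    for r in spds:
        chi = chi_by_group.get((r.model, r.disease))
        for cat in sorted(r.percent):
            row = {
                "model": r.model, "disease": r.disease, "category": cat,
                "ratio_pct": r.percent[cat],
                "spd_pct": r.spd.get(cat),
                "classification": r.classification.get(cat),
            }
            if chi is not None:
                row.update(chi_statistic=chi.statistic, chi_df=chi.df,
                           chi_p=chi.p, significant=chi.significant)
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["disease", "model", "category"], kind="mergesort")
    return df.reset_index(drop=True)


def _count_frame(chis: list[ChiSquareResult]) -> pd.DataFrame:
    by_model: dict[str, list[ChiSquareResult]] = {}
    for c in chis:
        by_model.setdefault(c.model, []).append(c)
    rows = []
    for model in sorted(by_model):
        n, unbiased = count_biased_diseases(by_model[model])
        rows.append({"model": model, "n_diseases": len(by_model[model]),
                     "n_biased": n, "unbiased_diseases": "; ".join(unbiased)})
    return pd.DataFrame(rows)


def _aggregate_frame(spds: list[SPDResult], categories: tuple[str, ...]) -> pd.DataFrame:
    by_model: dict[str, list[SPDResult]] = {}
    for r in spds:
        by_model.setdefault(r.model, []).append(r)
    rows = []
    for model in sorted(by_model):
        for cat in categories:
            vals = [r.spd[cat] for r in by_model[model] if cat in r.spd]
            if not vals:
                continue
            agg = aggregate_spd(vals, model=model, category=cat)
            rows.append({"model": model, "category": cat, "mean_spd": agg.mean,
                         "sd_spd": agg.sd, "n_diseases": agg.n_diseases})
    return pd.DataFrame(rows)


def _polarization_frame(
    spd_results: dict[str, list[SPDResult]],
    model_meta: pd.DataFrame | None,
    config: RunConfig,
) -> pd.DataFrame:
    if model_meta is None:
        return pd.DataFrame(
            columns=["family", "disease", "attribute", "polarized_category",
                     "effect_present", "monotone", "spd_by_size"]
        )
    meta = {
        r["name"]: ModelMeta(r["name"], r["family"], float(r["size_billion"]))
        for _, r in model_meta.iterrows()
    }
    rows = []
    for attr, results in spd_results.items():
        fam_dis: dict[tuple[str, str], list[tuple[ModelMeta, SPDResult]]] = {}
        for r in results:
            m = meta.get(r.model)
            if m is None:
                continue
            fam_dis.setdefault((m.family, r.disease), []).append((m, r))
        for (family, disease) in sorted(fam_dis):
            pairs = fam_dis[(family, disease)]
            if len(pairs) < 2:
                continue
            pol = polarization_scan(pairs, attr)
            rows.append({
                "family": family, "disease": disease, "attribute": attr,
                "polarized_category": pol.polarized_category,
                "effect_present": pol.effect_present,
                "monotone": pol.monotone,
                "spd_by_size": "; ".join(f"{s}B:{v:+.1f}" for s, v in pol.spd_by_size),
            })
    return pd.DataFrame(rows, columns=["family", "disease", "attribute",
                                       "polarized_category", "effect_present",
                                       "monotone", "spd_by_size"])


def _heatmap_frames(
    spd_results: dict[str, list[SPDResult]], config: RunConfig
) -> dict[tuple[str, str], pd.DataFrame]:
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for attr, results in spd_results.items():
        if not results:
            continue
        for cat in config.schema.categories[attr]:
            rows = [
                {"disease": r.disease, "model": r.model, "spd": r.spd[cat]}
                for r in results if cat in r.spd
            ]
            if not rows:
                continue
            df = pd.DataFrame(rows).pivot(index="disease", columns="model", values="spd")
            out[(attr, cat)] = df.sort_index()
    return out
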
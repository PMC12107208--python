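"""SPD, classification, chi-square detection, aggregation, polarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ehraudit as ea
from ehraudit.extraction import ExtractedRecord


def _group(counts_by_cat, attribute="gender", model="m", disease="Lupus"):
    """Build extracted records realising exact category counts."""
    recs = []
    i = 0
    for cat, n in counts_by_cat.items():
        for _ in range(n):
            cats = {attribute: cat}
            recs.append(
                ExtractedRecord(
                    record_id=f"r{i}", model_label=model, disease=disease,
                    categories=cats, conflict_flags={attribute: False},
                    completeness_class="full" if cat != ea.NOT_AVAILABLE else "irrelevant",
                )
            )
            i += 1
    return recs


# --- proportions -----------------------------------------------------------

def test_proportions_published_layout():
    recs = _group({"female": 772, "male": 75, ea.NOT_AVAILABLE: 153})
    table = ea.proportions(recs, "gender", ("male", "female"))
    assert table.percent["female"] == pytest.approx(77.2)
    assert table.percent["male"] == pytest.approx(7.5)
    assert table.percent[ea.NOT_AVAILABLE] == pytest.approx(15.3)
    assert table.n == 1000


def test_proportions_degenerate_and_sum():
    table = ea.proportions(_group({"female": 10}), "gender", ("male", "female"))
    assert table.percent["female"] == 100.0
    assert table.percent["male"] == 0.0
    assert sum(table.percent.values()) == pytest.approx(100.0)
    with pytest.raises(ea.ValidationError):
        ea.proportions([], "gender")


# --- SPD and classification ------------------------------------------------

@pytest.mark.parametrize(
    "p_gen,p_real,expected",
    [(77.2, 89.3, -12.1), (95.7, 52.2, 43.5), (33.3, 33.3, 0.0)],
)
def test_spd_worked_examples(p_gen, p_real, expected):
    assert ea.spd(p_gen, p_real) == pytest.approx(expected)


def test_spd_rejects_out_of_range():
    with pytest.raises(ea.ValidationError):
        ea.spd(101.0, 50.0)
    with pytest.raises(ea.ValidationError):
        ea.spd(50.0, -0.1)


@pytest.mark.parametrize(
    "value,expected",
    [
        (43.5, "overrepresented"),
        (-12.1, "underrepresented"),
        (9.9, "none"),
        (10.0, "none"),      # strict: the threshold itself is not a hit
        (-10.0, "none"),
        (10.06, "overrepresented"),  # unrounded value decides, not the display
        (-10.06, "underrepresented"),
    ],
)
def test_classify_spd_strict_threshold(value, expected):
    assert ea.classify_spd(value) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(-100, 100, allow_nan=False), st.floats(0.1, 50))
def test_classify_spd_sign_symmetric(value, threshold):
    pos = ea.classify_spd(value, threshold)
    neg = ea.classify_spd(-value, threshold)
    flip = {"overrepresented": "underrepresented",
            "underrepresented": "overrepresented", "none": "none"}
    assert neg == flip[pos]


def test_spd_sum_identity(benchmark):
    recs = _group({"female": 772, "male": 75, ea.NOT_AVAILABLE: 153})
    table = ea.proportions(recs, "gender", ("male", "female"))
    res = ea.spd_result(table, benchmark)
    # benchmarks sum to 100, so category SPDs sum to -(NA share)
    assert sum(res.spd.values()) == pytest.approx(-table.percent[ea.NOT_AVAILABLE])
    assert ea.spd_sum_identity(res) == pytest.approx(0.0, abs=1e-9)


# --- chi-square ------------------------------------------------------------

@pytest.fixture(scope="module")
def even_benchmark():
    return ea.PrevalenceBenchmark(
        pd.DataFrame(
            {"disease": ["d", "d"], "attribute": ["gender"] * 2,
             "category": ["male", "female"], "proportion": [0.5, 0.5]}
        )
    )


def test_chi_square_hand_computed(even_benchmark):
    res = ea.chi_square_bias({"male": 600, "female": 400}, even_benchmark, "d", "gender")
    assert res.statistic == pytest.approx(40.0)  # 2 * 100^2 / 500
    assert res.df == 1
    assert res.significant


def test_chi_square_exact_fit_not_significant(even_benchmark):
    res = ea.chi_square_bias({"male": 500, "female": 500}, even_benchmark, "d", "gender")
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    assert not res.significant


def test_chi_square_excludes_not_available(even_benchmark):
    with_na = ea.chi_square_bias(
        {"male": 600, "female": 400, ea.NOT_AVAILABLE: 123}, even_benchmark, "d", "gender"
    )
    without = ea.chi_square_bias({"male": 600, "female": 400}, even_benchmark, "d", "gender")
    assert with_na.statistic == pytest.approx(without.statistic)


def test_chi_square_low_expected_flag(even_benchmark):
    res = ea.chi_square_bias({"male": 4, "female": 5}, even_benchmark, "d", "gender")
    assert res.low_expected


def test_chi_square_degenerate_inputs(even_benchmark, benchmark):
    with pytest.raises(ea.ValidationError):
        ea.chi_square_bias({"male": 0, "female": 0}, even_benchmark, "d", "gender")
    zero_bm = ea.PrevalenceBenchmark(
        pd.DataFrame(
            {"disease": ["d"] * 2, "attribute": ["gender"] * 2,
             "category": ["male", "female"], "proportion": [1.0, 0.0]}
        )
    )
    with pytest.raises(ea.ValidationError):
        ea.chi_square_bias({"male": 9, "female": 1}, zero_bm, "d", "gender")


def test_chi_square_matches_brute_force_oracle(benchmark):
    """Statistic equals the direct sum (obs-exp)^2/exp on random tables."""
    rng = np.random.default_rng(2024)
    real = benchmark.proportions("Hypertension", "race")
    cats = list(real)
    for _ in range(200):
        obs = {c: int(rng.integers(1, 200)) for c in cats}
        res = ea.chi_square_bias(obs, benchmark, "Hypertension", "race")
        total = sum(obs.values())
        brute = sum(
            (obs[c] - real[c] * total) ** 2 / (real[c] * total) for c in cats
        )
        assert res.statistic == pytest.approx(brute, abs=1e-9)
        assert res.df == len(cats) - 1


def test_p_monotone_in_statistic(even_benchmark):
    stats_p = [
        ea.chi_square_bias({"male": 500 + d, "female": 500 - d}, even_benchmark, "d", "gender")
        for d in (0, 20, 40, 80)
    ]
    ps = [r.p for r in stats_p]
    assert ps == sorted(ps, reverse=True)


# --- counting biased diseases ---------------------------------------------

def _chi(disease, significant):
    return ea.ChiSquareResult(
        model="m", disease=disease, attribute="gender", statistic=1.0,
        df=1, p=0.01 if significant else 0.5, significant=significant, alpha=0.05,
    )


def test_count_biased_diseases():
    results = [_chi(f"d{i}", i < 18) for i in range(20)]
    n, unbiased = ea.count_biased_diseases(results)
    assert n == 18
    assert unbiased == ["d18", "d19"]
    n0, un0 = ea.count_biased_diseases([_chi(f"d{i}", False) for i in range(20)])
    assert n0 == 0 and len(un0) == 20
    with pytest.raises(ea.ValidationError):
        ea.count_biased_diseases([_chi("d", True), _chi("d", False)])


# --- aggregation -----------------------------------------------------------

def _fixture_spds(model, category, benchmark):
    """Per-disease SPDs recomputed from the shipped printed ratio fixture."""
    ratios = ea.load_printed_ratios("race")
    sub = ratios[(ratios["model"] == model) & (ratios["category"] == category)]
    return [
        ea.spd(row["ratio_pct"], benchmark.percent(row["disease"], "race", category))
        for _, row in sub.iterrows()
    ]


def test_aggregate_reproduces_published_black_group_values(benchmark):
    vals = _fixture_spds("Yi-34B", "Black", benchmark)
    agg = ea.aggregate_spd(vals, model="Yi-34B", category="Black")
    assert agg.n_diseases == 20
    assert agg.mean == pytest.approx(14.9, abs=0.1)
    assert agg.sd == pytest.approx(27.16, abs=0.01)
    small = ea.aggregate_spd(_fixture_spds("Yi-6B", "Black", benchmark))
    assert small.mean == pytest.approx(-17.0, abs=0.1)
    assert small.sd == pytest.approx(7.86, abs=0.01)


def test_aggregate_single_value_and_empty():
    assert ea.aggregate_spd([3.5]).sd == 0.0
    with pytest.raises(ea.ValidationError):
        ea.aggregate_spd([])


def test_mean_across_models_published_rows():
    means = ea.load_printed_spd_means()
    assert ea.mean_across_models(list(means["Hispanic"])) == pytest.approx(-11.93, abs=0.01)
    assert ea.mean_across_models(list(means["Asian"])) == pytest.approx(-0.77, abs=0.01)
    assert ea.mean_across_models([2.5, 2.5]) == 2.5


# --- polarization ----------------------------------------------------------

def _meta(name, family, size):
    return ea.ModelMeta(name=name, family=family, size_billion=size)


def _spd_res(model, spd_map, disease="Hypertension", attribute="gender"):
    return ea.SPDResult(
        model=model, disease=disease, attribute=attribute, spd=spd_map,
        classification={c: ea.classify_spd(v) for c, v in spd_map.items()},
        percent={**{c: 0.0 for c in spd_map}, ea.NOT_AVAILABLE: 0.0},
    )


def test_polarization_scan_published_trajectory():
    # male SPD rises with size across the 1.8B/7B/14B family for a
    # near-balanced disease: classic polarization
    pairs = [
        (_meta("Qwen-1.8B", "Qwen", 1.8), _spd_res("Qwen-1.8B", {"male": -5.4, "female": -3.4})),
        (_meta("Qwen-7B", "Qwen", 7), _spd_res("Qwen-7B", {"male": 40.4, "female": -42.8})),
        (_meta("Qwen-14B", "Qwen", 14), _spd_res("Qwen-14B", {"male": 45.1, "female": -46.1})),
    ]
    res = ea.polarization_scan(pairs, "gender")
    assert res.polarized_category == "male"
    assert res.effect_present and res.monotone
    assert res.spd_by_size == ((1.8, -5.4), (7, 40.4), (14, 45.1))


def test_polarization_constant_and_decreasing():
    flat = [
        (_meta("a", "f", 1), _spd_res("a", {"male": 5.0, "female": -5.0})),
        (_meta("b", "f", 2), _spd_res("b", {"male": 5.0, "female": -5.0})),
    ]
    assert not ea.polarization_scan(flat, "gender").effect_present
    falling = [
        (_meta("a", "f", 1), _spd_res("a", {"male": 20.0, "female": -20.0})),
        (_meta("b", "f", 2), _spd_res("b", {"male": 12.0, "female": -12.0})),
        (_meta("c", "f", 4), _spd_res("c", {"male": 15.0, "female": -15.0})),
    ]
    res = ea.polarization_scan(falling, "gender")
    assert not res.effect_present and not res.monotone


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=6))
def test_polarization_flags_match_direct_comparison(values):
    pairs = [
        (_meta(f"m{i}", "f", i + 1), _spd_res(f"m{i}", {"male": v, "female": -v}))
        for i, v in enumerate(values)
    ]
    res = ea.polarization_scan(pairs, "gender")
    cat_series = [v if res.polarized_category == "male" else -v for v in values]
    assert res.effect_present == (cat_series[-1] > cat_series[0])
    assert res.monotone == all(b >= a for a, b in zip(cat_series, cat_series[1:]))


def test_polarization_requires_two_distinct_sizes():
    one = [(_meta("a", "f", 1), _spd_res("a", {"male": 1.0}))]
    with pytest.raises(ea.ValidationError):
        ea.polarization_scan(one, "gender")
    dup = one + [(_meta("b", "f", 1), _spd_res("b", {"male": 2.0}))]
    with pytest.raises(ea.ValidationError):
        ea.polarization_scan(dup, "gender")


# --- benchmark registry ----------------------------------------------------

def test_benchmark_fixture_integrity(benchmark):
    tbl = benchmark.table
    # 17 diseases with gender baselines, 20 with race baselines
    assert tbl[tbl["attribute"] == "gender"]["disease"].nunique() == 17
    assert tbl[tbl["attribute"] == "race"]["disease"].nunique() == 20
    assert benchmark.percent("Lupus", "gender", "female") == pytest.approx(89.3)
    assert benchmark.percent("Hypertension", "gender", "male") == pytest.approx(52.2)
    assert not benchmark.has("Preeclampsia", "gender")
    assert benchmark.has("Preeclampsia", "race")


def test_benchmark_rejects_bad_tables():
    with pytest.raises(ea.ValidationError):
        ea.PrevalenceBenchmark(
            pd.DataFrame({"disease": ["d"], "attribute": ["gender"],
                          "category": ["male"], "proportion": [0.9]})
        )
    with pytest.raises(ea.ValidationError):
        ea.PrevalenceBenchmark(
            pd.DataFrame({"disease": ["d"] * 2, "attribute": ["gender"] * 2,
                          "category": ["male", ea.NOT_AVAILABLE],
                          "proportion": [0.5, 0.5]})
        )
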
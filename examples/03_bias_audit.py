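"""Audit a polarized corpus against real-world prevalence (SPD + chi-square).

A corpus is generated with 97.9% female records for lupus — the kind of
amplified skew large models show for female-dominated diseases — and
compared with the shipped prevalence benchmark (89.3% female).
SPD = P_generated - P_real; |SPD| > 10 points flags over/underrepresentation,
and a chi-square goodness-of-fit test (alpha = .05) detects bias presence.
"""

import ehraudit as ea

config = ea.config_from_percentages(
    "Lupus",
    gender_pct={"female": 97.9, "male": 0.5, "not_available": 1.6},
    model_label="demo-large-model",
    n_records=1000,
    seed=5,
)
records, _ = ea.generate_corpus(config)

benchmark = ea.load_benchmarks()
schema = ea.AttributeSchema(categories={"gender": ("male", "female")})
extracted = ea.extract_corpus(records, schema=schema)

table = ea.proportions(extracted, "gender", schema.categories["gender"])
result = ea.spd_result(table, benchmark)
for cat in ("female", "male"):
    print(f"{cat:>7}: generated {table.percent[cat]:5.1f}%  "
          f"real {benchmark.percent('Lupus', 'gender', cat):5.1f}%  "
          f"SPD {result.spd[cat]:+5.1f}  [{result.classification[cat]}]")

chi = ea.chi_square_bias(
    ea.category_counts(extracted, "gender"), benchmark, "Lupus", "gender")
verdict = "biased" if chi.significant else "not biased"
print(f"chi-square: stat={chi.statistic:.1f} df={chi.df} p={chi.p:.3g} -> {verdict}")
# Expect female SPD near +8.6 (inflated but under the 10-point flag) and a
# male SPD near -10.2 (underrepresented); the chi-square still detects the
# distributional shift decisively at n=1000.
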
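"""Trace SPD across a model family ordered by size (polarization effect).

Three synthetic "models" of increasing size generate hypertension records
with progressively stronger male skew, emulating the tendency of larger
models to converge on one bias-polarized gender. The scan reports which
category polarizes, whether the effect is present (largest > smallest) and
whether the drift is monotone in size.
"""

import ehraudit as ea

benchmark = ea.load_benchmarks()
schema = ea.AttributeSchema(categories={"gender": ("male", "female")})

# male share rises with parameter count
family = [
    ("demo-2B", 2, {"male": 46.8, "female": 44.4, "not_available": 8.8}),
    ("demo-7B", 7, {"male": 92.6, "female": 5.0, "not_available": 2.4}),
    ("demo-14B", 14, {"male": 97.3, "female": 1.7, "not_available": 1.0}),
]

pairs = []
for name, size, pct in family:
    cfg = ea.config_from_percentages(
        "Hypertension", gender_pct=pct, model_label=name, n_records=1000, seed=size)
    records, _ = ea.generate_corpus(cfg)
    extracted = ea.extract_corpus(records, schema=schema)
    table = ea.proportions(extracted, "gender", schema.categories["gender"])
    pairs.append((ea.ModelMeta(name, "demo", size), ea.spd_result(table, benchmark)))

scan = ea.polarization_scan(pairs, "gender")
print(f"polarized category: {scan.polarized_category}")
for size, value in scan.spd_by_size:
    print(f"  {size:>4}B  SPD {value:+5.1f}")
print(f"effect present: {scan.effect_present}   monotone: {scan.monotone}")
# Male SPD should climb from about -5 to about +45 points across the family:
# a present, monotone polarization toward the male group.
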
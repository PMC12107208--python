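# ehraudit

Audit pipeline for **completeness and demographic bias in model-generated
electronic health records (EHRs)**.

Synthetic free-text EHRs produced by large language models are increasingly
used for clinical education and model training, but generated corpora can be
incomplete (records missing required demographic fields, or off-target
altogether) and demographically skewed relative to real-world disease
epidemiology. `ehraudit` is a library — plus a thin CLI — for researchers and
auditors who need to quantify both failure modes reproducibly: it extracts
demographic attributes from free text, scores corpus completeness, and
measures representational bias against disease-specific prevalence
benchmarks. A seeded synthetic-corpus generator with known ground truth makes
every stage testable end to end without hosting any language model.

## The statistics at the core

Every record of a corpus of size *N* falls into one of three classes:
irrelevant (*Nᵢ*, no required attribute present), partially relevant (*Nₛ*),
or fully relevant (*Nₐ*), so that *N = Nᵢ + Nₛ + Nₐ*. Completeness is scored
on a 0–100 scale by the EHR performance score and its per-attribute variant
(*N*₍ₛ₋ᵢ₎ counts partial records containing attribute *Aᵢ*):

    EPS   = 100 · Nₐ / N
    EPSᵢ  = 100 · (N₍ₛ₋ᵢ₎ + Nₐ) / N          (EPS ≤ EPSᵢ ≤ 100)

Representational bias of a demographic category in a (model, disease) group
is the **statistical parity difference**, in percentage points:

    SPD = P_generated − P_real

where *P_generated* is the category's share of all records in the group
(records with no extractable value count in the denominator as
`not_available`) and *P_real* is the category's real-world prevalence for
that disease. SPD > +10 flags overrepresentation, SPD < −10
underrepresentation (strict comparison on the unrounded value). Bias
*presence* is tested by a chi-square goodness of fit of the observed
non-reserved category counts against prevalence-proportional expectations
(α = .05). The **polarization scan** orders a model family by parameter
count and asks whether the top category's SPD grows with size — the
signature of larger models converging on one bias-polarized gender or race.

The package ships prevalence benchmarks for 20 diseases (gender baselines
for the 17 diseases with published two-sex prevalence; race baselines for
Black/White reconstructed from published generated-ratio/SPD pairs, with the
Hispanic/Asian remainder split by 2020 US census shares and flagged as
reconstructed), plus the published generated-distribution columns of seven
open models as replayable fixtures.

## Worked example

```python
import ehraudit as ea

config = ea.config_from_percentages(
    "Lupus",
    gender_pct={"female": 97.9, "male": 0.5, "not_available": 1.6},
    model_label="demo-large-model", n_records=1000, seed=5,
)
records, _ = ea.generate_corpus(config)

schema = ea.AttributeSchema(categories={"gender": ("male", "female")})
extracted = ea.extract_corpus(records, schema=schema)
table = ea.proportions(extracted, "gender", schema.categories["gender"])
result = ea.spd_result(table, ea.load_benchmarks())
```

Running `python examples/03_bias_audit.py` (the script around the snippet)
prints:

```
 female: generated  97.7%  real  89.3%  SPD  +8.4  [none]
   male: generated   0.6%  real  10.7%  SPD -10.1  [underrepresented]
chi-square: stat=104.7 df=1 p=1.4e-24 -> biased
```

The generated corpus amplifies the real-world female dominance of lupus
(97.7% vs 89.3%): the female surplus (+8.4 points) stays under the 10-point
flag, the male group is squeezed below the −10-point line, and the
chi-square test detects the distributional shift decisively at n = 1000.
The other scripts in `examples/` walk through corpus generation,
completeness scoring, polarization scans across a model family, and the
full multi-table report.

## Command line

Each stage is independently invocable:

```bash
ehraudit generate --disease Hypertension --n-records 1000 --seed 1 --out corpus.jsonl
ehraudit score --corpus corpus.jsonl
ehraudit bias --corpus corpus.jsonl
ehraudit report --corpus corpus.jsonl --out audit/ --format csv
```

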
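# fiska

Fuzzy-inference ranking of kidney-transplant waiting lists, with the two
conventional allocation baselines (weighted point scoring and
urgency/waiting-time filtering), decision-tree rule extraction, evaluation
metrics, and a seeded synthetic-cohort generator.

Given a deceased-donor offer and a waiting list, the package ranks candidates
three ways:

- **fiska** — a Mamdani multi-input single-output fuzzy system: trapezoidal
  membership functions, min-fired rules, max aggregation of clipped
  consequents, and center-of-gravity defuzzification on a 0–100 priority
  universe. Its rule base is distilled from data: patients are scored with the
  weight table, scores are quantized into five priority classes, a
  classification tree is induced, and each root-to-leaf path becomes a fuzzy
  rule (every crisp threshold interval maps to the fuzzy set with maximal
  membership integral over that interval).
- **scoring** — the weighted point system itself: a three-level weight table
  (criterion → sub-criterion → attribute bin) covering medical urgency,
  sensitization (PRA > 80), pediatric age bins, waiting time (linear, per
  year), HLA mismatch bins 0–5, ABO identical/compatible, donor–recipient age
  difference, and predicted post-transplant survival.
- **filtering** — ABO-compatible candidates, urgent tier first, sorted by
  waiting time, truncated to six (top two recipients, next four reserves).

Agreement between rankings is measured by the top-six *overlapping rate*
(percent, truncated to one decimal) and the unordered *two-first-choices*
metric; allocation outcomes are compared via mean raw EPTS (estimated
post-transplant survival) score, waiting time, donor–recipient age gap, and
the identical-ABO fraction.

## Layout

| Module | Contents |
| --- | --- |
| `fiska.core` | Patient/donor records, ABO relation, HLA mismatch count, waiting time, CSV schemas |
| `fiska.scoring` | Weight-table loading/validation, total score, five-class quantization |
| `fiska.fuzzy` | Fuzzy sets, linguistic variables, rule bases (JSON), Mamdani inference, COG |
| `fiska.induction` | Training tables, tree fitting, path→rule conversion, stratified k-fold CV |
| `fiska.metrics` | The three ranking policies, agreement metrics, raw EPTS, outcome reports |
| `fiska.cohort` | Seeded synthetic waiting lists, donor pools, labeled training tables |
| `fiska.cli` | `fiska` command-line interface |

Packaged defaults live in `src/fiska/data/`: `table2_weights.yaml` (the
allocation weight table) and `default_variables.json` (the eight input
linguistic variables — set counts 2, 4, 3, 3, 4, 6, 4, 2, whose product is the
full 13,824-rule grid — plus the five-set output variable). `fixtures/`
holds a 30-patient cohort, one donor, and a pre-extracted rule base used by
the tests and CLI examples.

## CLI

```bash
# synthesize a cohort
fiska simulate --n-patients 200 --n-donors 10 --seed 1 --out-dir scratch/cohort

# extract a fuzzy rule base from a simulated labeled table, with 10-fold CV
fiska extract-rules --simulate 5000 --seed 1 \
    --out-rules scratch/rules.json --out-cv scratch/cv.csv

# rank one waiting list for one donor under all three policies
fiska rank --waitlist fixtures/waitlist.csv --donors fixtures/donor.csv \
    --rules fixtures/rules.json --method all --fallback-rule --out-dir scratch/ranked

# pairwise agreement metrics + outcome table
fiska evaluate --ranked scratch/ranked/ranked_fiska.csv \
    --ranked scratch/ranked/ranked_scoring.csv \
    --ranked scratch/ranked/ranked_filtering.csv \
    --waitlist fixtures/waitlist.csv --donors fixtures/donor.csv \
    --out-dir scratch/eval

# raw EPTS score for one candidate (age, diabetes, prior transplant, dialysis years)
fiska epts 40 1 1 2
```

Exit codes: 0 success, 2 configuration/schema error, 3 domain error (e.g.
`--strict` with no compatible candidate). `--fallback-rule` scores patients
the rule base does not cover at the centroid of the `medium` output set
instead of failing.

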
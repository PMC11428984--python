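# apsi — Agricultural Protection Against Stress Index

`apsi` computes a 0–100 composite score for candidate plant-growth-promoting
rhizobacteria (PGPR). Screening a bacterial strain for agricultural use
involves a heterogeneous panel of assays — pot trials under irrigation and
drought, dual-culture antagonism/antibiosis against phytopathogenic fungi,
phosphate/potassium solubilization halos, siderophore production,
phytohormone titers, urease activity — whose raw readouts live on
incommensurable scales. The index makes strains directly comparable by
mapping every assay onto a bounded subscore and summing under an explicit
category weighting, so that an agronomist or product developer can rank
candidates and decide whether a strain warrants field trials.

## The index

Each assay *t* belongs to a category *c* (growth promotion, drought
protection, antifungal activity, phytohormones, solubilization,
siderophores, urease) with weight *w\_c* percent, split equally over the
*n\_c* tests of the category, so test *t* is worth at most
*m\_t = w\_c / n\_c* points. The default weights (20/27/28/9/8/4/4) give the
18-test battery per-test maxima {5, 9, 7, 3, 4, 4, 4} summing to 100. The
total for strain *s* is

&nbsp;&nbsp;&nbsp;&nbsp;APSI(s) = Σ\_t s\_t,&nbsp;&nbsp; 0 ≤ s\_t ≤ m\_t,

with a decision cutoff at 50 ± 0.5: strains above the band are *suitable*,
below it they *need more tests*, inside it the call is left open.

Raw measurements reach their subscores by one of three schemes:

- **tiered** — the strain's mean effect is located between a negative and a
  positive reference as a ratio r = (x − neg)/(pos − neg) and quantized to
  the quartile lattice {0, ¼, ½, ¾, 1}·*m\_t*, with Tukey-HSD significance
  overriding at the ends (indistinguishable from the positive reference →
  full points; not significantly above the negative → none);
- **probit** — a continuous score *m\_t*·Φ(z), Φ the standard normal CDF and
  z the effect standardized against the reference distribution;
- **binary** — all-or-nothing, with an explicit *missing* state distinct
  from negative.

Category weights can also be elicited from experts by an iterative Delphi
procedure (component-wise median aggregation with contraction toward the
consensus until the interquartile ranges close), and the robustness of
totals and rankings is quantified by Dirichlet weight perturbation and a
replicate bootstrap.

## Worked example

The package ships the published scorecard of four commercial strains of the
*Bacillus amyloliquefaciens* operational group as a fixture:

```python
from apsi import compute_apsi, load_table3, ranking_frame

results = compute_apsi(load_table3().subscores(), missing_policy="zero")
print(ranking_frame(results).to_string(index=False))
```

prints

```
 rank strain_id  total classification
    1        A6  78.95       suitable
    2     FZB42  67.75       suitable
    3      D747  65.25       suitable
    4      DSM7  61.50       suitable
```

Each total is the strain's share of the 100 attainable points (FZB42's
urease assay was not performed; the missing cell contributes nothing under
the default policy), and all four strains clear the 50 ± 0.5 band. The
`examples/` directory holds one short script per capability — aggregating
the reference scorecard, recovering a known tier profile from a noisy
synthetic panel, Delphi weight elicitation, and weight-sensitivity
analysis — each printing the numbers it computes and what they mean.

A command-line interface mirrors the pipeline stages:

```sh
apsi simulate --profile table3:A6 --seed 1 -o panel.csv
apsi score --panel panel.csv -o subscores.csv
apsi aggregate --subscores subscores.csv -o report.json
apsi check-table3
```

## Layout

- `src/apsi/panel.py` — assay-panel data model, validation, long-format CSV
  I/O, relative water content, PGPR/drought-protectant trait flags
- `src/apsi/groupstats.py` — outlier screening, normality check, one-way
  ANOVA, Tukey HSD, compact letter display
- `src/apsi/scoring.py` — tiered/probit/binary schemes, fungal inhibition,
  subscore tables
- `src/apsi/weighting.py` — weight schemes, Delphi aggregation, budget
  allocation
- `src/apsi/core.py` — aggregation, cutoff classification, ranking
- `src/apsi/sensitivity.py` — Dirichlet weight perturbation, replicate
  bootstrap
- `src/apsi/synthetic.py` — synthetic panel and expert-panel generators
- `src/apsi/table3.py` + `src/apsi/data/table3.csv` — the packaged
  reference scorecard
- `src/apsi/cli.py` — the `apsi` command

See `docs/methods.md` for the statistical details and design choices.
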
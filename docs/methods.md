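# Methods

This note documents the statistical procedures behind the package, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the design decisions taken where the published
description of the index left the construction open.

## The assay panel

A panel holds long-format replicate measurements for a set of candidate
strains plus control strains, in one fixed unit convention (grams,
centimeters, µg/L, hours, days; loaders reject anything else so that
scorecards are comparable across panels). Five measurement families are
modeled:

- **plant biometry** — fresh, dry and fully turgid weight, root and stem
  length per plant, under `irrigated` or `drought` condition, at day 0 or
  the end of the trial. Relative water content is derived as
  RWC = (FW − DW)/(TW − DW), a dimensionless hydration measure that is 1 at
  full turgor. Fresh weights marginally outside [DW, TW] (weighing noise)
  raise by default; an opt-in clip mode clamps them with a warning, since
  the measurement procedure itself implies FW ≤ TW.
- **fungal colony diameters** by fungus (*Fusarium oxysporum*, *Botrytis
  cinerea*), dual-culture mode (antagonism: bacteria inoculated before the
  fungal plug; antibiosis: after) and sampling day (5/10/15).
- **solubilization halos** (phosphate, potassium) in cm.
- **phytohormone titers** (IAA, IBA, GA3) at 24 h and 72 h.
- **qualitative outcomes** (siderophores, urease, qualitative potassium
  solubilization) with a three-state domain: positive, negative, missing.
  Missing is first-class and never silently coerced to negative — the
  reference scorecard itself contains one blank cell whose published total
  only works if the blank contributes nothing *as a missing value*.

Trait flags follow the panel's operational definitions: a strain is PGPR
when its mean combined root + stem length under irrigation exceeds the
non-inoculated control, and drought-protectant when both dry weight and RWC
under drought exceed that control. "Exceeds" defaults to a significant
Tukey-HSD difference at α = 0.05; a raw mean comparison is available by
flag.

## Group grading

Replicate groups are graded by a conventional pot/plate pipeline:

1. **Outlier screening** — iterative Bonferroni test on externally
   studentized residuals of the one-way group-means model (statsmodels'
   `outlier_test`): per iteration at most the single most extreme
   observation is removed, if its Bonferroni-adjusted two-sided p-value is
   below α; screening never empties a sample and is skipped below n = 4.
   Residuals are screened per model (assay), not per group — the procedure
   needs a variance estimate, and the model residuals pool it.
2. **Normality** — Shapiro–Wilk on the centered residuals; p ≤ 0.05 is
   recorded as a panel-quality warning but does not abort the pipeline
   (only outliers are excluded, not non-normal groups).
3. **One-way ANOVA** — classical fixed-effects F (scipy). Degenerate
   inputs: all values identical → F = 0, p = 1; zero within-group variance
   with unequal means → F = ∞, p = 0.
4. **Tukey HSD** — all-pairs adjusted p-values from the studentized-range
   distribution with pooled within-group variance (scipy), using the
   Tukey–Kramer standard error for unbalanced groups. Zero pooled variance
   is mapped to p = 0 (unequal means) / p = 1 (equal means) so that
   noise-free synthetic panels grade deterministically.
5. **Compact letter display** — insert-and-absorb: start with one letter
   set containing all groups; for every significant pair split each set
   containing both, then absorb subsets. The construction guarantees the
   defining biconditional (two groups share a letter iff their adjusted p ≥
   α), which a property test verifies on random p-matrices.

α defaults to 0.05 everywhere and is overridable per call.

## Scoring schemes

**Tiered.** The published scorecard places 71 of its 72 strain×test cells
on the quartile lattice {0, ¼, ½, ¾, 1}·max, but the raw→score rule behind
it was never stated; the lattice rule here is therefore a calibration owned
by this package. With r = (x − neg)/(pos − neg) clipped below at 0:

| condition | fraction |
|---|---|
| not significantly below the positive reference, or r ≥ 0.75 | 1.0 |
| 0.5 ≤ r < 0.75 | 0.75 |
| 0.25 ≤ r < 0.5 | 0.5 |
| 0 < r < 0.25 and significantly above the negative reference | 0.25 |
| otherwise | 0 |

Significance clauses use Tukey-adjusted p-values against the panel's
control groups when replicates allow; without them the ratio alone decides
(exceedance of the negative assumed, indistinguishability from the positive
not). If a resampled or degenerate panel inverts the references
(pos ≤ neg), the test's dynamic range has collapsed and the scheme degrades
to a two-way call against the positive reference rather than erroring.

Known limitation of any such calibration: the published scorecard is not
uniquely invertible to one rule (e.g. two strains reported as statistically
similar on the phosphate assay carry different published points, and some
drought cells are at 0.75·max for strains described as indistinguishable
from controls). The lattice rule is documented as this package's own
convention, not a reconstruction.

**Probit.** max·Φ((x − ref\_mean)/ref\_sd), strictly increasing, (0, max)
open interval. The reference distribution defaults to the relevant negative
control group's (mean, SD). The single off-lattice cell of the reference
scorecard (5.95 of 7) equals 7·Φ(z) at z ≈ 1.0364, which is why the probit
scheme is offered for the fungal tests; tiered is the default elsewhere.
The two schemes agree at the extremes (far below the reference → ≈0, far
above → ≈max); near the reference mean the probit gives max/2 where the
tiered gives 0, by design — it grades distance in noise units rather than
span fractions.

**Fungal summarization.** Per replicate, inhibition(day) = 1 −
d\_strain(day)/d\_control(day); the public summary clips to [0, 1] and
averages the three sampling days (no aggregate was published, so the
unweighted mean is used). Internally, replicate summaries are left
unclipped so the control's inhibition distribution keeps its spread —
clipping at 0 would collapse the probit reference SD and bias group means.
The tiered scale for fungal tests runs from control-level growth (0) to
complete suppression (1).

**Hormones.** Production is summarized per replicate as the peak over the
two sampling times (some hormones appear only at 24 h), then referenced
against the negative/positive control producers.

**Binary.** positive → max, negative → 0, missing → missing.

## Weights, Delphi, aggregation

Weights are percentages summing to 100 (tolerance 10⁻⁹). The default
scheme is 20 (growth), 27 (drought), 28 (fungal), 9 (hormones),
8 (solubilization), 4 (siderophores), 4 (urease). The hormone category's
9% is an inference: the stated percentages sum to 91, and the three
3-point hormone tests of the battery supply the remaining 9.

Delphi aggregation uses the component-wise **median** (standard Delphi
practice, robust to one extreme panelist); each round moves every expert a
fraction `contraction` toward the consensus and renormalizes to 100, and
iteration stops when every component's interquartile range is below the
tolerance (default 0.1 points) or `max_rounds` is reached (non-convergence
is flagged, e.g. contraction 0 with a disagreeing panel). Category budgets
are split **equally** across each category's tests — the published maxima
force this (27 → 9×3, 28 → 7×4, 20 → 5×4, 9 → 3×3, 8 → 4×2).

Totals are plain sums. The default missing policy is **zero** (missing
tests contribute nothing; the reference scorecard's blank cell reproduces
its published total only this way); `renormalize` rescales to the
attainable maximum ×100 when a strain was run on a subset of the battery.
The 50 ± 0.5 cutoff is read as a three-way band — whether exactly 50
passes was never specified, so the borderline class is explicit. Ranking
is descending competition ranking; totals within 10⁻⁹ share a rank and
keep input order in display.

## Sensitivity analyses

**Weight perturbation.** w ~ 100·Dirichlet(κ·baseline/100): the Dirichlet
is the natural simplex-respecting noise model (mass stays at 100 by
construction, mean equals the baseline, spread set by the concentration κ;
κ ≥ 10⁹ is treated as the degenerate no-noise limit). Because a strain's
achieved *fraction* of each test maximum is weight-invariant, each draw
only reallocates budgets and rescales; reported are per-strain rank
retention probability, 2.5–97.5% total intervals, and the probability of
falling below the decision band.

**Replicate bootstrap.** Resamples replicates with replacement within each
(strain, assay, condition) group — whole plants, whole fungal replicate
tracks, whole hormone time-courses, so within-unit coupling survives —
re-runs scoring and aggregation, and summarizes as above. Percentile
intervals (not BCa): simpler and adequate at desk scale. Groups with one
replicate are carried through unresampled with a warning. Both analyses
are byte-deterministic given their seed.

## Synthetic panels

The generator emulates exactly the statistical structure the pipeline
assumes: replicate groups, negative/positive controls per assay family,
monotone treatment effects, multiplicative noise. Each strain carries a
true effect tier per test. The group mean is placed at a *representative
ratio* — the piecewise-linear map through (0, 0), (¼, 0.125), (½, 0.375),
(¾, 0.625), (1, 1) — chosen so a lattice tier scores back to itself
exactly at zero noise (a tier placed exactly on a threshold such as 0.75
would otherwise quantize upward); intermediate tiers remain strictly
monotone. Defaults model the study conditions at desk scale: 6 replicates
per group, 5% coefficient of variation, fungal sampling at days 5/10/15
with control diameters 3/5/7 cm, a 3.3 cm positive phosphate halo, hormone
references 212 (IAA), 0.88 (IBA) and 0.87 (GA3) µg/L against low or zero
negative producers, and plant biometry levels typical of month-old pepper
plants (replicate counts per assay were never published; 6 is a realistic
pot-trial group size).

Noise models: mean-preserving lognormal for strictly positive biometry,
colony diameters and titers; truncated normal for halo diameters (a zero
negative-control halo stays exactly zero). Plant rows are built
dry-weight-first — turgid weight a fixed multiple (default 4×, i.e. ~75%
water content), fresh weight interpolated from the target RWC — so
DW ≤ FW ≤ TW holds by construction, never by rejection. Binary outcomes
are deterministic: positive iff tier ≥ 0.5; a test absent from a profile
is generated as missing (binary) or at the negative-control level
(quantitative).

What the generator does **not** emulate: growth-curve dynamics, spatial
plate structure, between-assay correlations within a strain, non-lognormal
error, day-0 baselines. Passing recovery tests therefore certify the
pipeline's arithmetic and its statistical decisions under the assumed
noise model — not the field behavior of real strains.

Expert panels are generated as baseline + truncated-normal noise,
renormalized to 100. Note the component median of n experts has sampling
error ≈ 1.253·sd/√n, so a 9-expert panel at sd 5 recovers the baseline to
about 2 points per category on average — individual categories in a single
elicitation can deviate by more.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: scorecard
aggregation is exact arithmetic on 18×4 values; property tests use
hundreds to a thousand random instances; weight perturbation uses 2000
draws (Monte-Carlo error on a retention probability ≈ 1%); parameter
recovery uses 20 seeds at 6 replicates. Ties in ranking and weight-sum
checks use a 10⁻⁹ tolerance; Tukey p-values are clipped to [0, 1] and
symmetrized against floating-point asymmetry. Scorecard anchors
(per-test points, totals, maxima) are stored and compared exactly.

## Known discrepancies in the published anchors

The prose of the source description quotes totals of 54.5 (D747), 62.25
(FZB42) and, in one comparison, 63.7 (A6) that contradict the scorecard's
own column sums (65.25, 67.75, 78.95). The column arithmetic confirms the
scorecard, which this package adopts throughout; the discrepancy is
documented here and not reconciled.
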
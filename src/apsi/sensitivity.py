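"""Robustness of index totals and rankings to weight uncertainty and noise.

The index is modular: category weights are a policy choice, and replicate
noise propagates through scoring. Two complementary analyses quantify how
much the conclusions depend on them:

* :func:`perturb_weights` draws category-weight vectors from a Dirichlet
  distribution centered on the baseline scheme (the simplex-respecting
  noise model: mass stays at 100 by construction), reallocates per-test
  budgets, rescales subscores proportionally and re-ranks.
* :func:`bootstrap_totals` resamples replicates within each measurement
  group, re-runs scoring and aggregation, and reports percentile intervals
  and rank stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import TestDefinition, category_counts
from .core import DEFAULT_BAND, DEFAULT_CUTOFF, compute_apsi, rank_strains
from .panel import AssayPanel
from .scoring import SubscoreTable, build_subscore_table
from .weighting import WeightScheme

#: concentrations above this are treated as the degenerate (no-noise) limit
CONCENTRATION_CAP = 1e9


@dataclass
class SensitivityReport:
    """Monte-Carlo summary of index robustness.

    ``rank_stability`` maps each strain to the probability that it retains
    its baseline rank; ``total_intervals`` to the (2.5%, 97.5%) quantiles of
    its total; ``crossing_probability`` to the probability of falling below
    the decision band.
    """

    n_draws: int
    weight_concentration: float | None
    baseline_totals: dict[str, float]
    baseline_ranks: dict[str, int]
    rank_stability: dict[str, float]
    total_intervals: dict[str, tuple[float, float]]
    crossing_probability: dict[str, float]
    totals: pd.DataFrame = field(repr=False, default=None)  # draws × strains
    weights_drawn: pd.DataFrame | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_draws": int(self.n_draws),
            "weight_concentration": (
                None if self.weight_concentration is None else float(self.weight_concentration)
            ),
            "baseline_totals": {k: float(v) for k, v in self.baseline_totals.items()},
            "baseline_ranks": {k: int(v) for k, v in self.baseline_ranks.items()},
            "rank_stability": {k: float(v) for k, v in self.rank_stability.items()},
            "total_intervals": {
                k: [float(lo), float(hi)] for k, (lo, hi) in self.total_intervals.items()
            },
            "crossing_probability": {k: float(v) for k, v in self.crossing_probability.items()},
        }


def _ranks_of(totals: dict[str, float]) -> dict[str, int]:
    from .core import ApsiResult

    results = [
        ApsiResult(strain_id=s, total=t, by_category={}, classification="suitable")
        for s, t in totals.items()
    ]
    return {res.strain_id: r for r, res in rank_strains(results)}


def _summarize(
    totals: pd.DataFrame,
    baseline_totals: dict[str, float],
    cutoff: float,
    band: float,
    n_draws: int,
    concentration: float | None,
    weights_drawn: pd.DataFrame | None = None,
) -> SensitivityReport:
    baseline_ranks = _ranks_of(baseline_totals)
    strains = list(totals.columns)
    rank_hits = {s: 0 for s in strains}
    for _, row in totals.iterrows():
        ranks = _ranks_of(row.to_dict())
        for s in strains:
            if ranks[s] == baseline_ranks[s]:
                rank_hits[s] += 1
    n = len(totals)
    return SensitivityReport(
        n_draws=n_draws,
        weight_concentration=concentration,
        baseline_totals=baseline_totals,
        baseline_ranks=baseline_ranks,
        rank_stability={s: rank_hits[s] / n for s in strains},
        total_intervals={
            s: (
                float(np.percentile(totals[s], 2.5)),
                float(np.percentile(totals[s], 97.5)),
            )
            for s in strains
        },
        crossing_probability={
            s: float((totals[s] < cutoff - band).mean()) for s in strains
        },
        totals=totals,
        weights_drawn=weights_drawn,
    )


def perturb_weights(
    subscores: SubscoreTable,
    scheme: WeightScheme,
    concentration: float = 100.0,
    n_draws: int = 2000,
    seed: int = 0,
    *,
    missing_policy: str = "zero",
    cutoff: float = DEFAULT_CUTOFF,
    band: float = DEFAULT_BAND,
) -> SensitivityReport:
    """Dirichlet perturbation of the category weights.

    Draws weight vectors w ~ 100·Dirichlet(concentration · baseline/100):
    the mean is the baseline scheme and the spread shrinks as
    ``concentration`` grows (above :data:`CONCENTRATION_CAP` every draw
    equals the baseline). For each draw the per-test maxima are reallocated
    and each subscore rescaled proportionally (the strain's achieved score
    *fraction* per test is weight-invariant), then totals and ranks are
    recomputed. Deterministic given ``seed``.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    cats = scheme.categories
    base = scheme.as_series().loc[cats].to_numpy()
    counts = category_counts(subscores.battery)

    baseline = compute_apsi(subscores, missing_policy, cutoff=cutoff, band=band)
    baseline_totals = {s: r.total for s, r in baseline.items()}

    # achieved fraction of each test's maximum (NaN = missing → 0 under both
    # the baseline and every draw, so missing tests never contribute)
    maxima = subscores.maxima()
    fractions = subscores.scores.div(maxima, axis=0).fillna(0.0)
    test_cats = pd.Series({t.test_id: t.category for t in subscores.battery})

    if concentration >= CONCENTRATION_CAP:
        draws = np.tile(base, (n_draws, 1))
    else:
        draws = 100.0 * rng.dirichlet(concentration * base / 100.0, size=n_draws)

    per_cat_count = np.array([counts.get(c, 0) for c in cats], dtype=float)
    if (per_cat_count < 1).any():
        missing = [c for c, k in zip(cats, per_cat_count) if k < 1]
        raise ValueError(f"weighted categories without tests: {missing}")

    rows = []
    for d in range(n_draws):
        per_test_max = pd.Series(dict(zip(cats, draws[d] / per_cat_count)))
        new_max = test_cats.map(per_test_max)
        totals = (fractions.mul(new_max, axis=0)).sum(axis=0)
        rows.append(totals)
    totals_df = pd.DataFrame(rows).reset_index(drop=True)
    weights_df = pd.DataFrame(draws, columns=cats)
    return _summarize(
        totals_df, baseline_totals, cutoff, band, n_draws, concentration, weights_df
    )


def _resample_panel(panel: AssayPanel, rng: np.random.Generator) -> AssayPanel:
    """Resample replicates with replacement within each measurement group.

    Groups with a single replicate are carried over unchanged (warned about
    by :func:`bootstrap_totals`); binary outcomes are deterministic and not
    resampled.
    """
    def resample(df: pd.DataFrame, keys: list[str], unit: str) -> pd.DataFrame:
        if len(df) == 0:
            return df.copy()
        parts = []
        for _, g in df.groupby(keys, sort=False):
            units = g[unit].unique()
            if len(units) < 2:
                parts.append(g)
                continue
            chosen = rng.choice(units, size=len(units), replace=True)
            for new_id, u in enumerate(chosen, start=1):
                block = g[g[unit] == u].copy()
                block[unit] = new_id
                parts.append(block)
        return pd.concat(parts, ignore_index=True)

    return AssayPanel(
        strains=set(panel.strains),
        controls=dict(panel.controls),
        plants=resample(panel.plants, ["strain_id", "condition", "day"], "replicate"),
        fungal=resample(panel.fungal, ["strain_id", "fungus", "mode"], "replicate"),
        halos=resample(panel.halos, ["strain_id", "assay"], "replicate"),
        hormones=resample(panel.hormones, ["strain_id", "hormone"], "replicate"),
        binary=panel.binary.copy(),
    )


def bootstrap_totals(
    panel: AssayPanel,
    battery: list[TestDefinition],
    n_boot: int = 200,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    use_significance: bool = True,
    scheme_override: str | None = None,
    missing_policy: str = "zero",
    cutoff: float = DEFAULT_CUTOFF,
    band: float = DEFAULT_BAND,
) -> SensitivityReport:
    """Replicate bootstrap of the whole scoring + aggregation pipeline.

    Resamples replicates with replacement within each (strain, assay,
    condition) group, rebuilds the subscore table and totals ``n_boot``
    times, and summarizes percentile intervals, rank stability against the
    observed panel's ranking, and the probability of crossing below the
    decision band. Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)

    singletons = []
    for df, keys, unit in (
        (panel.plants, ["strain_id", "condition", "day"], "replicate"),
        (panel.fungal, ["strain_id", "fungus", "mode"], "replicate"),
        (panel.halos, ["strain_id", "assay"], "replicate"),
        (panel.hormones, ["strain_id", "hormone"], "replicate"),
    ):
        if len(df):
            counts = df.groupby(keys)[unit].nunique()
            singletons.extend(counts.index[counts < 2].tolist())
    if singletons:
        warnings.warn(
            f"{len(singletons)} group(s) with a single replicate excluded from resampling",
            stacklevel=2,
        )

    base_scores = build_subscore_table(
        panel, battery, alpha=alpha, use_significance=use_significance,
        scheme_override=scheme_override,
    )
    baseline = compute_apsi(base_scores, missing_policy, cutoff=cutoff, band=band)
    baseline_totals = {s: r.total for s, r in baseline.items()}

    rows = []
    for _ in range(n_boot):
        bpanel = _resample_panel(panel, rng)
        scores = build_subscore_table(
            bpanel, battery, alpha=alpha, use_significance=use_significance,
            scheme_override=scheme_override,
        )
        res = compute_apsi(scores, missing_policy, cutoff=cutoff, band=band)
        rows.append({s: r.total for s, r in res.items()})
    totals_df = pd.DataFrame(rows)
    return _summarize(totals_df, baseline_totals, cutoff, band, n_boot, None)
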
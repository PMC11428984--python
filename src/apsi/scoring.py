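"""Raw assay outcomes → per-test subscores.

Two quantitative schemes are offered:

* **tiered** — the strain's effect is located between a negative and a
  positive reference and awarded a quartile fraction of the test maximum
  ({0, ¼, ½, ¾, 1}·max). A strain statistically indistinguishable from the
  positive reference earns the full score regardless of its ratio; a strain
  not significantly above the negative reference earns nothing.
* **probit** — a continuous score max·Φ(z), Φ the standard normal CDF and z
  the strain's effect standardized against a reference distribution.

Binary assays (siderophores, qualitative potassium solubilization, urea
hydrolysis) score all-or-nothing, with an explicit missing state distinct
from negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .battery import TestDefinition
from .groupstats import DEFAULT_ALPHA, tukey_hsd
from .panel import AssayPanel, PanelValidationError

TIER_LATTICE = (0.0, 0.25, 0.5, 0.75, 1.0)


def tier_fraction(
    strain_effect: float,
    negative_effect: float,
    positive_effect: float,
    *,
    p_vs_positive: float | None = None,
    p_vs_negative: float | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Quartile score fraction for an effect between two references.

    Let r = (strain − negative)/(positive − negative), clipped below at 0.
    Returns 1.0 when the strain is not significantly below the positive
    reference or r >= 0.75; 0.75 for r in [0.5, 0.75); 0.5 for r in
    [0.25, 0.5); 0.25 for r in (0, 0.25) provided the strain is
    significantly above the negative reference; otherwise 0.

    ``p_vs_positive`` / ``p_vs_negative`` are Tukey-adjusted p-values from a
    group comparison; when ``None`` the corresponding significance clause is
    decided by the ratio alone (indistinguishability from the positive is
    not assumed; exceedance of the negative is).
    """
    if positive_effect <= negative_effect:
        raise ValueError(
            f"positive reference ({positive_effect}) must exceed negative ({negative_effect})"
        )
    r = max((strain_effect - negative_effect) / (positive_effect - negative_effect), 0.0)
    not_sig_below_positive = strain_effect >= positive_effect or (
        p_vs_positive is not None and p_vs_positive >= alpha
    )
    if r >= 0.75 or not_sig_below_positive:
        return 1.0
    if r >= 0.5:
        return 0.75
    if r >= 0.25:
        return 0.5
    if r > 0:
        sig_above_negative = True if p_vs_negative is None else p_vs_negative < alpha
        return 0.25 if sig_above_negative else 0.0
    return 0.0


def probit_score(x: float, ref_mean: float, ref_sd: float, max_score: float) -> float:
    """Continuous score max·Φ((x − ref_mean)/ref_sd).

    Strictly increasing in ``x``; equals max/2 at the reference mean and
    approaches 0 / max for effects far below / above the reference.
    """
    if ref_sd <= 0:
        raise ValueError("reference scale must be positive")
    return float(max_score * norm.cdf((x - ref_mean) / ref_sd))


def score_binary(outcome: str, max_score: float) -> float | None:
    """All-or-nothing score; ``missing`` maps to None, never to 0."""
    if outcome == "positive":
        return float(max_score)
    if outcome == "negative":
        return 0.0
    if outcome == "missing":
        return None
    raise ValueError(f"unknown binary outcome {outcome!r}")


def fungal_inhibition(
    strain_track: dict[int, float] | pd.Series,
    control_track: dict[int, float] | pd.Series,
) -> tuple[pd.Series, float]:
    """Per-day growth inhibition of a fungus and its mean over days.

    inhibition(day) = 1 − d_strain(day)/d_control(day), clipped to [0, 1]:
    0 when the colony grows as in the uninoculated control, 1 when growth is
    completely suppressed.
    """
    s = pd.Series(dict(strain_track), dtype=float).sort_index()
    c = pd.Series(dict(control_track), dtype=float).sort_index()
    if set(s.index) != set(c.index):
        raise ValueError("strain and control tracks must cover the same days")
    if (c <= 0).any():
        raise ValueError("control colony diameter must be positive")
    inh = (1.0 - s / c).clip(0.0, 1.0)
    return inh, float(inh.mean())


@dataclass
class SubscoreTable:
    """Per-strain, per-test points, bounded by each test's maximum.

    ``scores`` is indexed by test_id with one column per strain; NaN marks
    an explicitly missing entry (assay not run), which aggregation treats
    according to its missing policy — never silently as zero points here.
    """

    scores: pd.DataFrame
    battery: list[TestDefinition]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        maxima = pd.Series({t.test_id: t.max_score for t in self.battery})
        missing_rows = [i for i in self.scores.index if i not in maxima.index]
        if missing_rows:
            raise ValueError(f"scores contain unknown tests {missing_rows}")
        aligned = maxima.reindex(self.scores.index)
        over = (self.scores.gt(aligned, axis=0) | self.scores.lt(0)).any(axis=None)
        if bool(over):
            raise ValueError("subscores must satisfy 0 <= points <= max_score")

    @property
    def strains(self) -> list[str]:
        return list(self.scores.columns)

    def maxima(self) -> pd.Series:
        return pd.Series({t.test_id: float(t.max_score) for t in self.battery})

    def missing_tests(self, strain: str) -> list[str]:
        col = self.scores[strain]
        return [str(i) for i in col.index[col.isna()]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: strain, test_id, points, max, missing."""
        maxima = self.maxima()
        rows = []
        for strain in self.strains:
            for tid, pts in self.scores[strain].items():
                rows.append({
                    "strain": strain,
                    "test_id": tid,
                    "points": None if pd.isna(pts) else float(pts),
                    "max": float(maxima[tid]),
                    "missing": bool(pd.isna(pts)),
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, battery: list[TestDefinition]) -> "SubscoreTable":
        wide = df.pivot(index="test_id", columns="strain", values="points")
        wide = wide.reindex([t.test_id for t in battery])
        wide = wide[list(dict.fromkeys(df["strain"]))]  # keep input order
        wide.columns.name = None
        return cls(scores=wide, battery=battery)


# ---------------------------------------------------------------------------
# panel → subscores
# ---------------------------------------------------------------------------

def _group_values(df: pd.DataFrame, id_col: str, value_col: str) -> dict[str, np.ndarray]:
    out = {}
    for sid, g in df.groupby(id_col):
        vals = g[value_col].dropna().to_numpy(float)
        if len(vals):
            out[str(sid)] = vals
    return out


def _tiered_from_groups(
    strain_ids: list[str],
    groups: dict[str, np.ndarray],
    negative_id: str,
    positive_id: str | None,
    positive_level: float | None,
    max_score: float,
    alpha: float,
    use_significance: bool,
) -> dict[str, float | None]:
    """Score a set of strains from replicate groups against reference groups.

    Either a positive control group (``positive_id``) or a fixed positive
    level (``positive_level``, e.g. complete fungal suppression = 1) anchors
    the top of the scale.
    """
    if negative_id not in groups:
        raise PanelValidationError(f"no measurements for negative reference {negative_id!r}")
    neg = groups[negative_id]
    if positive_id is not None:
        if positive_id not in groups:
            raise PanelValidationError(f"no measurements for positive reference {positive_id!r}")
        pos_mean = float(groups[positive_id].mean())
    else:
        assert positive_level is not None
        pos_mean = float(positive_level)
    neg_mean = float(neg.mean())

    ids_for_tukey = [negative_id] + ([positive_id] if positive_id else [])
    scores: dict[str, float | None] = {}
    for sid in strain_ids:
        if sid not in groups:
            scores[sid] = None
            continue
        vals = groups[sid]
        p_pos = p_neg = None
        if use_significance:
            comp_ids = [i for i in ids_for_tukey if i != sid] + [sid]
            comp_groups = [groups[i] for i in comp_ids]
            if all(len(g) >= 2 for g in comp_groups) and len(comp_groups) >= 2:
                pmat = tukey_hsd(comp_groups, alpha)
                j = len(comp_ids) - 1
                if negative_id in comp_ids:
                    p_neg = float(pmat[j, comp_ids.index(negative_id)])
                if positive_id is not None and positive_id in comp_ids:
                    p_pos = float(pmat[j, comp_ids.index(positive_id)])
        mean = float(vals.mean())
        if pos_mean <= neg_mean:
            # collapsed dynamic range (the positive reference failed to
            # separate from the negative, e.g. under resampling noise):
            # degrade to a two-way call against the positive reference
            full = mean >= pos_mean or (p_pos is not None and p_pos >= alpha)
            scores[sid] = max_score if full else 0.0
            continue
        frac = tier_fraction(
            mean, neg_mean, pos_mean,
            p_vs_positive=p_pos, p_vs_negative=p_neg, alpha=alpha,
        )
        scores[sid] = frac * max_score
    return scores


def _probit_from_groups(
    strain_ids: list[str],
    groups: dict[str, np.ndarray],
    ref_id: str,
    max_score: float,
) -> dict[str, float | None]:
    if ref_id not in groups:
        raise PanelValidationError(f"no measurements for probit reference {ref_id!r}")
    ref = groups[ref_id]
    ref_mean = float(ref.mean())
    ref_sd = float(ref.std(ddof=1)) if len(ref) > 1 else 0.0
    scores: dict[str, float | None] = {}
    for sid in strain_ids:
        if sid not in groups:
            scores[sid] = None
            continue
        x = float(groups[sid].mean())
        if ref_sd > 0:
            scores[sid] = probit_score(x, ref_mean, ref_sd, max_score)
        else:
            # degenerate reference: step score
            scores[sid] = max_score if x > ref_mean else (0.5 * max_score if x == ref_mean else 0.0)
    return scores


def _fungal_inhibition_by_replicate(
    panel: AssayPanel, fungus: str, mode: str, control: str
) -> dict[str, np.ndarray]:
    """Mean-over-days inhibition per replicate track, keyed by strain."""
    sub = panel.fungal[(panel.fungal["fungus"] == fungus) & (panel.fungal["mode"] == mode)]
    if control not in set(sub["strain_id"]):
        raise PanelValidationError(
            f"no fungal control {control!r} for {fungus}/{mode}"
        )
    ctrl_track = (
        sub[sub["strain_id"] == control]
        .groupby("day")["colony_diameter"].mean()
    )
    out: dict[str, list[float]] = {}
    for (sid, rep), g in sub.groupby(["strain_id", "replicate"]):
        track = g.set_index("day")["colony_diameter"]
        common = [d for d in track.index if d in ctrl_track.index]
        if not common:
            continue
        # unclipped per-replicate summary: clipping at 0 would collapse the
        # control's spread and bias group means; the tier ratio clips later
        mean_inh = float((1.0 - track[common] / ctrl_track[common]).mean())
        out.setdefault(str(sid), []).append(mean_inh)
    return {k: np.asarray(v, float) for k, v in out.items()}


def build_subscore_table(
    panel: AssayPanel,
    battery: list[TestDefinition],
    *,
    alpha: float = DEFAULT_ALPHA,
    use_significance: bool = True,
    scheme_override: str | None = None,
) -> SubscoreTable:
    """Score every (strain, test) pair of a panel against its battery.

    Growth tests read the irrigated condition, drought tests the drought
    condition, both at the latest sampling day in the panel. Fungal tests
    summarize the sampling days by mean inhibition versus the uninoculated
    control and anchor the tier scale at complete suppression. Halo and
    hormone tests are referenced against the panel's negative and positive
    control strains. Missing assays yield explicit missing entries.

    ``scheme_override`` forces ``"tiered"`` or ``"probit"`` for every
    quantitative test, regardless of the battery's per-test scheme.
    """
    strains = sorted(panel.strains)
    plants = panel.plants_with_rwc(clip=True)
    if len(plants):
        plants = plants[plants["day"] == plants["day"].max()]
    controls = panel.controls

    def require(role: str, test_id: str) -> str:
        if role not in controls:
            raise PanelValidationError(
                f"test {test_id!r} needs control role {role!r}, absent from panel"
            )
        return controls[role]

    table: dict[str, dict[str, float | None]] = {}
    for t in battery:
        scheme = scheme_override if (scheme_override and t.scheme != "binary") else t.scheme
        if t.category in ("growth", "drought"):
            sub = plants[plants["condition"] == t.condition]
            groups = _group_values(sub, "strain_id", t.metric)
            neg = require("plant_negative", t.test_id)
            pos_role = "growth_positive" if t.category == "growth" else "drought_positive"
            pos = require(pos_role, t.test_id)
            if scheme == "probit":
                row = _probit_from_groups(strains, groups, neg, t.max_score)
            else:
                row = _tiered_from_groups(
                    strains, groups, neg, pos, None, t.max_score, alpha, use_significance
                )
        elif t.category == "fungal":
            ctrl = require("fungal_control", t.test_id)
            inh = _fungal_inhibition_by_replicate(panel, t.fungus, t.mode, ctrl)
            if scheme == "probit":
                row = _probit_from_groups(strains, inh, ctrl, t.max_score)
            else:
                # anchors: control inhibition (≈0) to complete suppression (1)
                row = _tiered_from_groups(
                    strains, inh, ctrl, None, 1.0, t.max_score, alpha, use_significance
                )
        elif t.category == "solubilization" and t.halo_assay is not None:
            sub = panel.halos[panel.halos["assay"] == t.halo_assay]
            groups = _group_values(sub, "strain_id", "halo_diameter")
            neg = require("halo_negative", t.test_id)
            pos = require("halo_positive", t.test_id)
            if scheme == "probit":
                row = _probit_from_groups(strains, groups, neg, t.max_score)
            else:
                row = _tiered_from_groups(
                    strains, groups, neg, pos, None, t.max_score, alpha, use_significance
                )
        elif t.category == "hormone":
            sub = panel.hormones[panel.hormones["hormone"] == t.hormone]
            # peak production: max over sampling times of each replicate
            peak = (
                sub.groupby(["strain_id", "replicate"])["concentration"].max().reset_index()
            )
            groups = _group_values(peak, "strain_id", "concentration")
            neg = require("hormone_negative", t.test_id)
            pos = require("hormone_positive", t.test_id)
            if scheme == "probit":
                row = _probit_from_groups(strains, groups, neg, t.max_score)
            else:
                row = _tiered_from_groups(
                    strains, groups, neg, pos, None, t.max_score, alpha, use_significance
                )
        else:  # binary
            sub = panel.binary[panel.binary["assay"] == t.binary_assay]
            outcomes = dict(zip(sub["strain_id"], sub["outcome"]))
            row = {}
            for sid in strains:
                out = outcomes.get(sid, "missing")
                row[sid] = score_binary(out, t.max_score)
        table[t.test_id] = row

    scores = pd.DataFrame(
        {sid: {tid: table[tid][sid] for tid in table} for sid in strains},
        dtype=float,
    ).reindex([t.test_id for t in battery])
    return SubscoreTable(scores=scores, battery=battery)
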
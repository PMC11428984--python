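"""Synthetic assay-panel generator.

Emulates the statistical structure the scoring pipeline assumes — replicate
groups with negative and positive controls, monotone treatment effects and
multiplicative measurement noise — so every stage of the index is testable
without laboratory data.

Each synthetic strain carries a *true effect tier* per test: a fraction in
[0, 1] locating it between the negative and positive reference of that
assay. Group means are placed at a representative effect ratio whose tiered
score equals the requested tier when the tier lies on the quartile lattice,
so at zero noise the tier profile → subscore recovery is an identity; under
noise it is a parameter-recovery problem.

Noise models: lognormal (mean-preserving) for strictly positive biometry,
colony diameters and hormone titers; truncated normal for halo diameters.
Plant rows are built dry-weight-first (turgid weight a fixed multiple,
fresh weight from the target relative water content), which guarantees
dry ≤ fresh ≤ turgid by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import TestDefinition, default_battery
from .panel import AssayPanel
from .weighting import WeightScheme, DelphiState

#: tiered-score thresholds on the effect ratio, and the representative
#: ratio the generator uses for each lattice tier (bracket midpoints,
#: except the exact anchors 0 and 1)
_TIER_ANCHORS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_RATIO_ANCHORS = np.array([0.0, 0.125, 0.375, 0.625, 1.0])

#: control strain identifiers used by generated panels
SYNTH_CONTROLS = {
    "plant_negative": "CTRL",
    "growth_positive": "PGPR_POS",
    "drought_positive": "DRT_POS",
    "fungal_control": "FUNGAL_CTRL",
    "halo_negative": "HALO_NEG",
    "halo_positive": "HALO_POS",
    "hormone_negative": "HORM_NEG",
    "hormone_positive": "HORM_POS",
}


def ratio_for_tier(tier: float) -> float:
    """Representative effect ratio for a true tier fraction.

    Piecewise-linear and strictly increasing on [0, 1]; lattice tiers map to
    ratios that the tiered scheme scores back to exactly that tier.
    """
    if not 0.0 <= tier <= 1.0:
        raise ValueError(f"tier {tier} outside [0, 1]")
    return float(np.interp(tier, _TIER_ANCHORS, _RATIO_ANCHORS))


@dataclass
class ControlLevels:
    """Reference means per assay family (negative, positive).

    Units: grams for weights, centimeters for lengths/diameters, µg/L for
    hormone titers. Defaults are desk-scale values in the range reported
    for pepper-plant trials and *Bacillus*/reference-strain assays.
    """

    plant: dict[tuple[str, str], tuple[float, float]] = field(default_factory=lambda: {
        ("root_length", "irrigated"): (8.0, 14.0),
        ("stem_length", "irrigated"): (10.0, 16.0),
        ("dry_weight", "irrigated"): (1.0, 1.6),
        ("rwc", "irrigated"): (0.90, 0.97),
        ("rwc", "drought"): (0.40, 0.85),
        ("root_length", "drought"): (6.0, 12.0),
        ("dry_weight", "drought"): (0.5, 0.9),
        ("stem_length", "drought"): (8.0, 12.0),
    })
    fungal: dict[int, float] = field(default_factory=lambda: {5: 3.0, 10: 5.0, 15: 7.0})
    halo: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "phosphate": (0.0, 3.3),
        "potassium": (0.0, 3.0),
    })
    hormone: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "IAA": (5.0, 212.0),
        "IBA": (0.05, 0.88),
        "GA3": (0.0, 0.87),
    })

    def validate(self) -> None:
        for key, (neg, pos) in {**self.plant, **self.halo, **self.hormone}.items():
            if pos <= neg:
                raise ValueError(f"control levels for {key}: positive {pos} <= negative {neg}")
        if any(d <= 0 for d in self.fungal.values()):
            raise ValueError("fungal control diameters must be positive")


@dataclass
class SyntheticPanelConfig:
    """Generation recipe: true tier profiles, replication, noise, seed.

    Parameters
    ----------
    strains
        Strain id → {test_id: tier in [0, 1]}. A quantitative test absent
        from a profile defaults to tier 0; an absent binary test yields a
        missing outcome.
    replicates
        Replicates per (strain, assay, condition) group.
    noise_cv
        Coefficient of variation of the measurement noise (single value for
        all assay families).
    """

    strains: dict[str, dict[str, float]]
    replicates: int = 6
    noise_cv: float = 0.05
    control_levels: ControlLevels = field(default_factory=ControlLevels)
    days: tuple[int, ...] = (5, 10, 15)
    plant_day: int = 31
    turgid_ratio: float = 4.0
    seed: int = 0

    def validate(self, battery: list[TestDefinition]) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.turgid_ratio <= 1:
            raise ValueError("turgid_ratio must exceed 1")
        known = {t.test_id for t in battery}
        for sid, profile in self.strains.items():
            for tid, tier in profile.items():
                if tid not in known:
                    raise ValueError(f"strain {sid!r}: unknown test {tid!r}")
                if not 0.0 <= float(tier) <= 1.0:
                    raise ValueError(f"strain {sid!r}: tier {tier} outside [0, 1]")
        self.control_levels.validate()


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Mean-preserving lognormal draws; degenerate at cv = 0 or mean = 0."""
    if mean <= 0 or cv <= 0:
        return np.full(size, float(max(mean, 0.0)))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, float(max(mean, 0.0)))
    return np.clip(rng.normal(mean, sd, size), 0.0, None)


def generate_panel(
    config: SyntheticPanelConfig,
    battery: list[TestDefinition] | None = None,
) -> AssayPanel:
    """Draw a full assay panel from a tier-profile configuration.

    Reproducible from ``config.seed``; control strains (see
    :data:`SYNTH_CONTROLS`) are generated alongside the candidates.
    """
    battery = battery if battery is not None else default_battery()
    config.validate(battery)
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv
    nrep = config.replicates
    lv = config.control_levels
    tests = {t.test_id: t for t in battery}

    def tier_of(sid: str, test_id: str, default: float | None = 0.0) -> float | None:
        return config.strains[sid].get(test_id, default)

    # --- plants ---------------------------------------------------------
    plant_tests = {
        (t.metric, t.condition): t.test_id
        for t in battery if t.category in ("growth", "drought")
    }

    def plant_targets(role: str, sid: str, condition: str) -> dict[str, float]:
        """Target group means per metric for a strain or control role."""
        out = {}
        for metric in ("root_length", "stem_length", "dry_weight", "rwc"):
            neg, pos = lv.plant[(metric, condition)]
            if role == "negative":
                out[metric] = neg
            elif role == "positive":
                out[metric] = pos
            else:
                tid = plant_tests.get((metric, condition))
                if tid is None:
                    out[metric] = neg
                else:
                    out[metric] = neg + ratio_for_tier(tier_of(sid, tid)) * (pos - neg)
        return out

    plant_rows = []
    plant_members = [(sid, "candidate") for sid in config.strains]
    plant_members += [
        (SYNTH_CONTROLS["plant_negative"], "negative"),
        (SYNTH_CONTROLS["growth_positive"], "growth_positive"),
        (SYNTH_CONTROLS["drought_positive"], "drought_positive"),
    ]
    for sid, role in plant_members:
        for condition in ("irrigated", "drought"):
            if role == "growth_positive":
                eff_role = "positive" if condition == "irrigated" else "negative"
            elif role == "drought_positive":
                eff_role = "positive" if condition == "drought" else "negative"
            else:
                eff_role = role
            tgt = plant_targets(eff_role, sid, condition)
            dw = _lognormal(rng, tgt["dry_weight"], cv, nrep)
            rwc_sd = cv * tgt["rwc"]
            rwc = np.clip(rng.normal(tgt["rwc"], rwc_sd, nrep) if rwc_sd > 0
                          else np.full(nrep, tgt["rwc"]), 0.001, 0.999)
            tw = dw * config.turgid_ratio
            fw = dw + rwc * (tw - dw)
            rl = _lognormal(rng, tgt["root_length"], cv, nrep)
            sl = _lognormal(rng, tgt["stem_length"], cv, nrep)
            for r in range(nrep):
                plant_rows.append({
                    "strain_id": sid, "condition": condition, "day": config.plant_day,
                    "replicate": r + 1, "fresh_weight": fw[r], "dry_weight": dw[r],
                    "turgid_weight": tw[r], "root_length": rl[r], "stem_length": sl[r],
                })

    # --- fungal ---------------------------------------------------------
    fungal_rows = []
    fungal_tests = [t for t in battery if t.category == "fungal"]
    fungal_members = list(config.strains) + [SYNTH_CONTROLS["fungal_control"]]
    for t in fungal_tests:
        for sid in fungal_members:
            if sid == SYNTH_CONTROLS["fungal_control"]:
                inhibition = 0.0
            else:
                inhibition = ratio_for_tier(tier_of(sid, t.test_id))
            for r in range(nrep):
                for day in config.days:
                    target = lv.fungal[day] * (1.0 - inhibition)
                    diam = _lognormal(rng, target, cv, 1)[0]
                    fungal_rows.append({
                        "strain_id": sid, "fungus": t.fungus, "mode": t.mode,
                        "day": day, "replicate": r + 1, "colony_diameter": diam,
                    })

    # --- halos ----------------------------------------------------------
    halo_rows = []
    halo_tests = [t for t in battery if t.category == "solubilization" and t.halo_assay]
    for t in halo_tests:
        neg, pos = lv.halo[t.halo_assay]
        members = [(sid, neg + ratio_for_tier(tier_of(sid, t.test_id)) * (pos - neg))
                   for sid in config.strains]
        members += [(SYNTH_CONTROLS["halo_negative"], neg), (SYNTH_CONTROLS["halo_positive"], pos)]
        for sid, target in members:
            vals = _truncnorm(rng, target, cv * target, nrep)
            for r in range(nrep):
                halo_rows.append({
                    "strain_id": sid, "assay": t.halo_assay,
                    "replicate": r + 1, "halo_diameter": vals[r],
                })

    # --- hormones -------------------------------------------------------
    hormone_rows = []
    hormone_tests = [t for t in battery if t.category == "hormone"]
    for t in hormone_tests:
        neg, pos = lv.hormone[t.hormone]
        members = [(sid, neg + ratio_for_tier(tier_of(sid, t.test_id)) * (pos - neg))
                   for sid in config.strains]
        members += [(SYNTH_CONTROLS["hormone_negative"], neg), (SYNTH_CONTROLS["hormone_positive"], pos)]
        for sid, target in members:
            for r in range(nrep):
                for time_h in (24, 72):
                    conc = _lognormal(rng, target, cv, 1)[0]
                    hormone_rows.append({
                        "strain_id": sid, "hormone": t.hormone, "time_h": time_h,
                        "replicate": r + 1, "concentration": conc,
                    })

    # --- binary outcomes ------------------------------------------------
    binary_rows = []
    for t in battery:
        if t.scheme != "binary":
            continue
        for sid in config.strains:
            tier = tier_of(sid, t.test_id, default=None)
            if tier is None:
                outcome = "missing"
            else:
                outcome = "positive" if tier >= 0.5 else "negative"
            binary_rows.append({"strain_id": sid, "assay": t.binary_assay, "outcome": outcome})

    return AssayPanel(
        strains=set(config.strains),
        controls=dict(SYNTH_CONTROLS),
        plants=pd.DataFrame(plant_rows),
        fungal=pd.DataFrame(fungal_rows),
        halos=pd.DataFrame(halo_rows),
        hormones=pd.DataFrame(hormone_rows),
        binary=pd.DataFrame(binary_rows),
    )


def generate_expert_panel(
    n_experts: int,
    baseline: WeightScheme,
    disagreement_sd: float,
    seed: int = 0,
) -> DelphiState:
    """Simulated expert weight vectors around a baseline scheme.

    Each vector is the baseline plus truncated-normal noise (sd in percent
    points), renormalized to sum 100. Reproducible from ``seed``.
    """
    if n_experts < 2:
        raise ValueError("need at least two experts")
    if disagreement_sd < 0:
        raise ValueError("disagreement_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = baseline.as_series()
    rows = {}
    for e in range(n_experts):
        if disagreement_sd > 0:
            v = np.clip(base + rng.normal(0.0, disagreement_sd, len(base)), 0.0, None)
            if v.sum() <= 0:
                v = base.copy()
        else:
            v = base.copy()
        rows[f"expert_{e + 1}"] = (100.0 * v / v.sum()).to_dict()
    return DelphiState.from_experts(rows)
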
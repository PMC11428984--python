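"""Assay-panel data model: raw measurements for a set of bacterial strains.

The panel gathers everything the index pipeline consumes: whole-plant
biometry under irrigated and drought conditions, dual-culture fungal colony
diameters, solubilization halo diameters, phytohormone titers and
qualitative (positive/negative) assay outcomes, together with the control
strains each assay family is referenced against.

Measurements are stored long-format in pandas DataFrames with one strictly
validated unit convention: grams, centimeters, µg/L, hours, days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import CONTROL_ROLES

CONDITIONS = ("irrigated", "drought")
FUNGI = ("F_oxysporum", "B_cinerea")
FUNGAL_MODES = ("antagonism", "antibiosis")
HORMONES = ("IAA", "IBA", "GA3")
BINARY_ASSAYS = ("siderophore", "urease", "potassium_qualitative")
BINARY_OUTCOMES = ("positive", "negative", "missing")
HALO_ASSAYS = ("phosphate", "potassium")

PLANT_METRICS = ("fresh_weight", "dry_weight", "turgid_weight", "root_length", "stem_length")

#: long-format CSV column order
PANEL_COLUMNS = (
    "strain", "assay", "condition", "fungus", "mode", "hormone",
    "day", "time_h", "replicate", "value", "unit",
)

_EXPECTED_UNITS = {
    "fresh_weight": "g", "dry_weight": "g", "turgid_weight": "g",
    "root_length": "cm", "stem_length": "cm",
    "fungal_growth": "cm", "phosphate_halo": "cm", "potassium_halo": "cm",
    "hormone": "ug/L",
}


class PanelValidationError(ValueError):
    """Raised when a panel file or frame violates the schema."""


def compute_rwc(fw: float, dw: float, tw: float, *, clip: bool = False) -> float:
    """Relative water content, RWC = (FW − DW) / (TW − DW).

    Dimensionless hydration measure: 1 at full turgor (fresh weight equal to
    fully turgid weight), 0 when the plant holds no more water than its dry
    mass.

    Parameters
    ----------
    fw, dw, tw
        Fresh, dry and fully turgid weight in grams, with ``dw ≤ fw ≤ tw``.
    clip
        If True, fresh weights marginally outside ``[dw, tw]`` (measurement
        noise) are clamped into range with a warning instead of raising.
    """
    if tw <= dw:
        raise ValueError(f"degenerate denominator: turgid weight {tw} <= dry weight {dw}")
    if fw < dw or fw > tw:
        if not clip:
            raise ValueError(
                f"fresh weight {fw} outside [dry={dw}, turgid={tw}]; "
                "pass clip=True to clamp"
            )
        warnings.warn(f"fresh weight {fw} clamped into [{dw}, {tw}]", stacklevel=2)
        fw = min(max(fw, dw), tw)
    return (fw - dw) / (tw - dw)


def _empty(columns: dict[str, type]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in columns.items()})


def empty_plants() -> pd.DataFrame:
    return _empty({
        "strain_id": str, "condition": str, "day": int, "replicate": int,
        "fresh_weight": float, "dry_weight": float, "turgid_weight": float,
        "root_length": float, "stem_length": float,
    })


def empty_fungal() -> pd.DataFrame:
    return _empty({
        "strain_id": str, "fungus": str, "mode": str, "day": int,
        "replicate": int, "colony_diameter": float,
    })


def empty_halos() -> pd.DataFrame:
    return _empty({"strain_id": str, "assay": str, "replicate": int, "halo_diameter": float})


def empty_hormones() -> pd.DataFrame:
    return _empty({
        "strain_id": str, "hormone": str, "time_h": int, "replicate": int,
        "concentration": float,
    })


def empty_binary() -> pd.DataFrame:
    return _empty({"strain_id": str, "assay": str, "outcome": str})


@dataclass
class AssayPanel:
    """All raw measurements for a set of strains plus their controls.

    Attributes
    ----------
    strains
        Identifiers of the candidate strains under evaluation.
    controls
        Mapping of control role (see :data:`apsi.battery.CONTROL_ROLES`) to
        the identifier carrying that control's measurements.
    plants, fungal, halos, hormones, binary
        Long-format measurement frames; see the ``empty_*`` constructors for
        their columns.
    """

    strains: set[str]
    controls: dict[str, str] = field(default_factory=dict)
    plants: pd.DataFrame = field(default_factory=empty_plants)
    fungal: pd.DataFrame = field(default_factory=empty_fungal)
    halos: pd.DataFrame = field(default_factory=empty_halos)
    hormones: pd.DataFrame = field(default_factory=empty_hormones)
    binary: pd.DataFrame = field(default_factory=empty_binary)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def known_ids(self) -> set[str]:
        return set(self.strains) | set(self.controls.values())

    def validate(self) -> None:
        errors: list[str] = []
        for role in self.controls:
            if role not in CONTROL_ROLES:
                errors.append(f"unknown control role {role!r}")
        known = self.known_ids()

        def chk_ids(df: pd.DataFrame, name: str) -> None:
            bad = sorted(set(df["strain_id"]) - known)
            if bad:
                errors.append(f"{name}: unknown strain ids {bad}")

        def chk_nonneg(df: pd.DataFrame, col: str, name: str) -> None:
            if len(df) and (df[col] < 0).any():
                rows = df.index[df[col] < 0].tolist()
                errors.append(f"{name}: negative {col} at rows {rows}")

        def chk_enum(df: pd.DataFrame, col: str, allowed: tuple, name: str) -> None:
            if len(df):
                bad = sorted(set(df[col]) - set(allowed))
                if bad:
                    errors.append(f"{name}: invalid {col} values {bad} (allowed: {list(allowed)})")

        p = self.plants
        chk_ids(p, "plants")
        chk_enum(p, "condition", CONDITIONS, "plants")
        for c in ("fresh_weight", "dry_weight", "turgid_weight", "root_length", "stem_length"):
            chk_nonneg(p, c, "plants")
        if len(p) and (p["day"] < 0).any():
            errors.append("plants: negative day")

        f = self.fungal
        chk_ids(f, "fungal")
        chk_enum(f, "fungus", FUNGI, "fungal")
        chk_enum(f, "mode", FUNGAL_MODES, "fungal")
        chk_nonneg(f, "colony_diameter", "fungal")

        h = self.halos
        chk_ids(h, "halos")
        chk_enum(h, "assay", HALO_ASSAYS, "halos")
        chk_nonneg(h, "halo_diameter", "halos")

        ho = self.hormones
        chk_ids(ho, "hormones")
        chk_enum(ho, "hormone", HORMONES, "hormones")
        chk_nonneg(ho, "concentration", "hormones")

        b = self.binary
        chk_ids(b, "binary")
        chk_enum(b, "assay", BINARY_ASSAYS, "binary")
        chk_enum(b, "outcome", BINARY_OUTCOMES, "binary")

        if errors:
            raise PanelValidationError("; ".join(errors))

    # -- derived quantities ---------------------------------------------
    def plants_with_rwc(self, *, clip: bool = False) -> pd.DataFrame:
        """Plant frame with an ``rwc`` column appended (NaN where degenerate)."""
        df = self.plants.copy()
        rwc = np.full(len(df), np.nan)
        for i, (fw, dw, tw) in enumerate(
            zip(df["fresh_weight"], df["dry_weight"], df["turgid_weight"])
        ):
            if tw > dw:
                rwc[i] = compute_rwc(float(fw), float(dw), float(tw), clip=clip)
        df["rwc"] = rwc
        return df


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------

def load_panel(
    path: str | Path,
    *,
    controls: dict[str, str] | None = None,
    strains: set[str] | None = None,
    clip: bool = False,
) -> AssayPanel:
    """Read a long-format ``panel.csv`` into a validated :class:`AssayPanel`.

    The file has columns ``strain,assay,condition,fungus,mode,hormone,day,
    time_h,replicate,value,unit`` with unused fields left empty. Enum fields
    are parsed strictly; offending rows are reported by line number.

    Parameters
    ----------
    controls
        Control-role mapping, usually taken from the ``tests.yaml`` config.
    strains
        Declared strain set; inferred from the data (ids that are not
        controls) when omitted.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"{path}: missing columns {missing_cols}")
    controls = dict(controls or {})

    plants_wide: dict[tuple, dict] = {}
    fungal_rows, halo_rows, hormone_rows, binary_rows = [], [], [], []
    errors: list[str] = []
    seen_keys: set[tuple] = set()

    def fail(i: int, msg: str) -> None:
        errors.append(f"row {i + 2}: {msg}")  # +2: header + 1-based

    def num(i: int, s: str, what: str) -> float | None:
        try:
            v = float(s)
        except ValueError:
            fail(i, f"non-numeric {what} {s!r}")
            return None
        if v < 0:
            fail(i, f"negative {what} {v}")
            return None
        return v

    def intval(i: int, s: str, what: str, default: int | None = None) -> int | None:
        if s == "" and default is not None:
            return default
        try:
            return int(float(s))
        except ValueError:
            fail(i, f"non-integer {what} {s!r}")
            return None

    def check_unit(i: int, unit: str, assay: str) -> None:
        exp = _EXPECTED_UNITS.get(assay)
        if exp is not None and unit not in (exp, ""):
            fail(i, f"unit {unit!r} for assay {assay!r}; expected {exp!r}")

    for i, row in enumerate(df.itertuples(index=False)):
        strain = row.strain
        assay = row.assay
        if not strain:
            fail(i, "empty strain id")
            continue
        check_unit(i, row.unit, assay)
        if assay in PLANT_METRICS:
            cond = row.condition
            if cond not in CONDITIONS:
                fail(i, f"condition {row.condition!r} not one of {list(CONDITIONS)}")
                continue
            day = intval(i, row.day, "day", default=0)
            rep = intval(i, row.replicate, "replicate", default=1)
            v = num(i, row.value, assay)
            if None in (day, rep, v):
                continue
            key = (strain, assay, cond, day, rep)
            if key in seen_keys:
                fail(i, f"duplicate measurement key {key}")
                continue
            seen_keys.add(key)
            plants_wide.setdefault((strain, cond, day, rep), {})[assay] = v
        elif assay == "fungal_growth":
            if row.fungus not in FUNGI:
                fail(i, f"fungus {row.fungus!r} not one of {list(FUNGI)}")
                continue
            if row.mode not in FUNGAL_MODES:
                fail(i, f"mode {row.mode!r} not one of {list(FUNGAL_MODES)}")
                continue
            day = intval(i, row.day, "day")
            rep = intval(i, row.replicate, "replicate", default=1)
            v = num(i, row.value, "colony diameter")
            if None in (day, rep, v):
                continue
            key = (strain, assay, row.fungus, row.mode, day, rep)
            if key in seen_keys:
                fail(i, f"duplicate measurement key {key}")
                continue
            seen_keys.add(key)
            fungal_rows.append((strain, row.fungus, row.mode, day, rep, v))
        elif assay in ("phosphate_halo", "potassium_halo"):
            rep = intval(i, row.replicate, "replicate", default=1)
            v = num(i, row.value, "halo diameter")
            if None in (rep, v):
                continue
            key = (strain, assay, rep)
            if key in seen_keys:
                fail(i, f"duplicate measurement key {key}")
                continue
            seen_keys.add(key)
            halo_rows.append((strain, assay.replace("_halo", ""), rep, v))
        elif assay == "hormone":
            if row.hormone not in HORMONES:
                fail(i, f"hormone {row.hormone!r} not one of {list(HORMONES)}")
                continue
            t = intval(i, row.time_h, "time_h")
            rep = intval(i, row.replicate, "replicate", default=1)
            v = num(i, row.value, "concentration")
            if None in (t, rep, v):
                continue
            key = (strain, assay, row.hormone, t, rep)
            if key in seen_keys:
                fail(i, f"duplicate measurement key {key}")
                continue
            seen_keys.add(key)
            hormone_rows.append((strain, row.hormone, t, rep, v))
        elif assay in BINARY_ASSAYS:
            key = (strain, assay)
            if key in seen_keys:
                fail(i, f"duplicate outcome for {key}")
                continue
            seen_keys.add(key)
            if row.value == "":
                outcome = "missing"
            elif row.value in ("1", "1.0", "positive"):
                outcome = "positive"
            elif row.value in ("0", "0.0", "negative"):
                outcome = "negative"
            else:
                fail(i, f"binary value {row.value!r}; expected 1/0/empty")
                continue
            binary_rows.append((strain, assay, outcome))
        else:
            fail(i, f"unknown assay {assay!r}")

    if errors:
        raise PanelValidationError("; ".join(errors))

    plant_records = []
    for (strain, cond, day, rep), metrics in plants_wide.items():
        rec = {"strain_id": strain, "condition": cond, "day": day, "replicate": rep}
        rec.update({m: metrics.get(m, np.nan) for m in PLANT_METRICS})
        plant_records.append(rec)

    ids_in_data = (
        {r["strain_id"] for r in plant_records}
        | {r[0] for r in fungal_rows}
        | {r[0] for r in halo_rows}
        | {r[0] for r in hormone_rows}
        | {r[0] for r in binary_rows}
    )
    if strains is None:
        strains = ids_in_data - set(controls.values())

    panel = AssayPanel(
        strains=set(strains),
        controls=controls,
        plants=pd.DataFrame(plant_records) if plant_records else empty_plants(),
        fungal=pd.DataFrame(
            fungal_rows, columns=["strain_id", "fungus", "mode", "day", "replicate", "colony_diameter"]
        ) if fungal_rows else empty_fungal(),
        halos=pd.DataFrame(
            halo_rows, columns=["strain_id", "assay", "replicate", "halo_diameter"]
        ) if halo_rows else empty_halos(),
        hormones=pd.DataFrame(
            hormone_rows, columns=["strain_id", "hormone", "time_h", "replicate", "concentration"]
        ) if hormone_rows else empty_hormones(),
        binary=pd.DataFrame(
            binary_rows, columns=["strain_id", "assay", "outcome"]
        ) if binary_rows else empty_binary(),
    )
    if clip:
        panel.plants_with_rwc(clip=True)
    return panel


def write_panel(panel: AssayPanel, path: str | Path) -> None:
    """Write an :class:`AssayPanel` back to long-format CSV.

    Inverse of :func:`load_panel` up to row order and float formatting.
    """
    rows: list[dict] = []

    def base(strain: str) -> dict:
        return {c: "" for c in PANEL_COLUMNS} | {"strain": strain}

    for r in panel.plants.itertuples(index=False):
        for metric in PLANT_METRICS:
            v = getattr(r, metric)
            if pd.isna(v):
                continue
            rec = base(r.strain_id)
            rec.update(
                assay=metric, condition=r.condition, day=int(r.day),
                replicate=int(r.replicate), value=repr(float(v)),
                unit=_EXPECTED_UNITS[metric],
            )
            rows.append(rec)
    for r in panel.fungal.itertuples(index=False):
        rec = base(r.strain_id)
        rec.update(
            assay="fungal_growth", fungus=r.fungus, mode=r.mode, day=int(r.day),
            replicate=int(r.replicate), value=repr(float(r.colony_diameter)), unit="cm",
        )
        rows.append(rec)
    for r in panel.halos.itertuples(index=False):
        rec = base(r.strain_id)
        rec.update(
            assay=f"{r.assay}_halo", replicate=int(r.replicate),
            value=repr(float(r.halo_diameter)), unit="cm",
        )
        rows.append(rec)
    for r in panel.hormones.itertuples(index=False):
        rec = base(r.strain_id)
        rec.update(
            assay="hormone", hormone=r.hormone, time_h=int(r.time_h),
            replicate=int(r.replicate), value=repr(float(r.concentration)), unit="ug/L",
        )
        rows.append(rec)
    for r in panel.binary.itertuples(index=False):
        rec = base(r.strain_id)
        value = {"positive": "1", "negative": "0", "missing": ""}[r.outcome]
        rec.update(assay=r.assay, value=value)
        rows.append(rec)

    out = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trait classification
# ---------------------------------------------------------------------------

def classify_strain_traits(
    panel: AssayPanel,
    alpha: float = 0.05,
    *,
    method: str = "significance",
) -> pd.DataFrame:
    """Flag each strain as plant-growth-promoting and/or drought-protectant.

    A strain is PGPR when its mean combined root + stem length under
    irrigation exceeds the non-inoculated control's; it is drought-protectant
    when both dry weight and relative water content under drought exceed the
    control's. With ``method="significance"`` (default) exceedance must also
    be significant in a Tukey HSD comparison at ``alpha``; ``method="mean"``
    compares raw group means only.

    Returns a DataFrame indexed by strain with boolean columns ``is_pgpr``
    and ``is_drought_protectant``.
    """
    from .groupstats import tukey_hsd

    if method not in ("significance", "mean"):
        raise ValueError(f"unknown method {method!r}")
    control = panel.controls.get("plant_negative")
    if control is None:
        raise PanelValidationError("panel declares no plant_negative control")

    df = panel.plants_with_rwc(clip=True)
    if len(df) == 0:
        raise PanelValidationError("panel has no plant measurements")
    df = df[df["day"] == df["day"].max()]

    def group_values(sub: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
        out = {}
        for sid, g in sub.groupby("strain_id"):
            vals = g[col].dropna().to_numpy(float)
            if len(vals):
                out[sid] = vals
        return out

    def exceeds(sub: pd.DataFrame, col: str) -> dict[str, bool]:
        groups = group_values(sub, col)
        if control not in groups:
            raise PanelValidationError(
                f"no {col} measurements for control {control!r}"
            )
        ids = sorted(groups)
        flags = {}
        if method == "significance" and len(ids) >= 2 and all(len(groups[i]) >= 2 for i in ids):
            pmat = tukey_hsd([groups[i] for i in ids], alpha=alpha)
            ci = ids.index(control)
            cmean = groups[control].mean()
            for j, sid in enumerate(ids):
                flags[sid] = groups[sid].mean() > cmean and pmat[j, ci] < alpha
        else:
            cmean = groups[control].mean()
            for sid in ids:
                flags[sid] = groups[sid].mean() > cmean
        return flags

    irr = df[df["condition"] == "irrigated"].copy()
    irr["combined_length"] = irr["root_length"] + irr["stem_length"]
    dro = df[df["condition"] == "drought"]

    pgpr = exceeds(irr, "combined_length") if len(irr) else {}
    dwf = exceeds(dro, "dry_weight") if len(dro) else {}
    rwcf = exceeds(dro, "rwc") if len(dro) else {}

    records = []
    for sid in sorted(panel.strains):
        records.append({
            "strain_id": sid,
            "is_pgpr": bool(pgpr.get(sid, False)),
            "is_drought_protectant": bool(dwf.get(sid, False) and rwcf.get(sid, False)),
        })
    return pd.DataFrame(records).set_index("strain_id")
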
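"""Test battery definitions for the Agricultural Protection Against Stress Index.

A *battery* is the ordered list of assays ("tests") that enter the index,
each with a category (growth promotion, drought protection, antifungal
activity, ...), a scoring scheme and a maximum attainable score. The
per-test maxima are usually derived from category weight percentages via
:func:`apsi.weighting.allocate_budgets`; the default battery below carries
the published allocation (maxima summing to 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Index categories, in display order.
CATEGORIES = (
    "growth",
    "drought",
    "fungal",
    "siderophore",
    "solubilization",
    "hormone",
    "urease",
)

SCHEMES = ("tiered", "probit", "binary")

# assay-family control roles a panel may declare
CONTROL_ROLES = (
    "plant_negative",      # non-inoculated plants
    "growth_positive",     # reference growth-promoting strain (irrigated trial)
    "drought_positive",    # reference drought-protectant strain
    "fungal_control",      # fungus grown without bacteria
    "halo_negative",
    "halo_positive",       # reference solubilizer
    "hormone_negative",
    "hormone_positive",    # reference phytohormone producer
)


@dataclass(frozen=True)
class TestDefinition:
    """One assay in the battery.

    Parameters
    ----------
    test_id
        Unique identifier, e.g. ``"root_length_drought"``.
    category
        One of :data:`CATEGORIES`.
    scheme
        Raw-measurement → points mapping: ``"tiered"`` (quartile lattice
        keyed to effect ratios and significance), ``"probit"`` (continuous
        cumulative-normal score) or ``"binary"`` (all-or-nothing).
    max_score
        Points awarded for a maximal outcome; battery maxima conventionally
        sum to 100.
    metric
        For plant tests: which biometric drives the score
        (``root_length``/``stem_length``/``dry_weight``/``rwc``).
    condition
        For plant tests: ``irrigated`` or ``drought``.
    fungus, mode
        For antifungal tests: target fungus and dual-culture mode.
    halo_assay
        For solubilization-halo tests: ``phosphate`` or ``potassium``.
    hormone
        For phytohormone tests: ``IAA``, ``IBA`` or ``GA3``.
    binary_assay
        For binary tests: key into the panel's qualitative outcomes.
    """

    test_id: str
    category: str
    scheme: str
    max_score: float
    metric: str | None = None
    condition: str | None = None
    fungus: str | None = None
    mode: str | None = None
    halo_assay: str | None = None
    hormone: str | None = None
    binary_assay: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for test {self.test_id!r}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r} for test {self.test_id!r}")
        if not self.max_score > 0:
            raise ValueError(f"max_score must be positive for test {self.test_id!r}")


def default_battery() -> list[TestDefinition]:
    """The 18-test battery with the published per-test maxima.

    Category budgets (percent of the 100-point index): growth 20, drought 27,
    fungal 28, hormones 9, solubilization 8, siderophores 4, urease 4 — split
    equally within each category, giving per-test maxima 5/9/7/3/4/4/4.
    """
    t = TestDefinition
    return [
        t("root_length_pgpr", "growth", "tiered", 5, metric="root_length", condition="irrigated"),
        t("stem_length_pgpr", "growth", "tiered", 5, metric="stem_length", condition="irrigated"),
        t("dry_weight_pgpr", "growth", "tiered", 5, metric="dry_weight", condition="irrigated"),
        t("rwc_pgpr", "growth", "tiered", 5, metric="rwc", condition="irrigated"),
        t("rwc_drought", "drought", "tiered", 9, metric="rwc", condition="drought"),
        t("root_length_drought", "drought", "tiered", 9, metric="root_length", condition="drought"),
        t("dry_weight_drought", "drought", "tiered", 9, metric="dry_weight", condition="drought"),
        t("antagonism_b_cinerea", "fungal", "tiered", 7, fungus="B_cinerea", mode="antagonism"),
        t("antagonism_f_oxysporum", "fungal", "tiered", 7, fungus="F_oxysporum", mode="antagonism"),
        t("antibiosis_b_cinerea", "fungal", "tiered", 7, fungus="B_cinerea", mode="antibiosis"),
        t("antibiosis_f_oxysporum", "fungal", "tiered", 7, fungus="F_oxysporum", mode="antibiosis"),
        t("siderophores", "siderophore", "binary", 4, binary_assay="siderophore"),
        t("phosphate_solubilization", "solubilization", "tiered", 4, halo_assay="phosphate"),
        t("potassium_solubilization", "solubilization", "binary", 4, binary_assay="potassium_qualitative"),
        t("iaa_production", "hormone", "tiered", 3, hormone="IAA"),
        t("iba_production", "hormone", "tiered", 3, hormone="IBA"),
        t("ga3_production", "hormone", "tiered", 3, hormone="GA3"),
        t("urea_hydrolysis", "urease", "binary", 4, binary_assay="urease"),
    ]


def category_counts(battery: list[TestDefinition]) -> dict[str, int]:
    """Number of tests per category, for budget allocation."""
    counts: dict[str, int] = {}
    for t in battery:
        counts[t.category] = counts.get(t.category, 0) + 1
    return counts


def battery_total(battery: list[TestDefinition]) -> float:
    return float(sum(t.max_score for t in battery))


@dataclass
class BatteryConfig:
    """Parsed ``tests.yaml``: the battery plus the panel's control strains."""

    battery: list[TestDefinition]
    controls: dict[str, str] = field(default_factory=dict)


def load_battery_config(path: str | Path) -> BatteryConfig:
    """Read a battery/controls declaration from YAML.

    Expected layout::

        controls:
          plant_negative: CTRL
          ...
        tests:
          - test_id: root_length_pgpr
            category: growth
            scheme: tiered
            max_score: 5
            metric: root_length
            condition: irrigated
          ...

    An absent ``tests`` key yields the default battery.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    controls = dict(raw.get("controls") or {})
    for role in controls:
        if role not in CONTROL_ROLES:
            raise ValueError(f"unknown control role {role!r}")
    if "tests" in raw and raw["tests"]:
        battery = [TestDefinition(**entry) for entry in raw["tests"]]
        ids = [t.test_id for t in battery]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate test_id in battery")
    else:
        battery = default_battery()
    return BatteryConfig(battery=battery, controls=controls)


def write_battery_config(config: BatteryConfig, path: str | Path) -> None:
    payload = {
        "controls": dict(config.controls),
        "tests": [
            {k: v for k, v in vars(t).items() if v is not None}
            for t in config.battery
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
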
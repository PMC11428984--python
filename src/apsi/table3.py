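"""Packaged reference scorecard for the four commercial strains.

The published worked example of the index scores *B. velezensis* A6 and the
commercial strains FZB42, DSM7 and D747 over the 18-test battery. The
per-test points and totals are shipped as a small CSV fixture; the totals
(78.95, 67.75, 61.5, 65.25) are reproduced at load time by summing the
columns, with FZB42's not-performed urease assay as an explicitly missing
cell contributing nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .battery import TestDefinition, default_battery
from .scoring import SubscoreTable

STRAIN_ORDER = ("A6", "FZB42", "DSM7", "D747")

#: published totals per strain
TOTALS = {"A6": 78.95, "FZB42": 67.75, "DSM7": 61.5, "D747": 65.25}


@dataclass
class Table3Fixture:
    """The reference battery plus the four strains' subscore columns."""

    battery: list[TestDefinition]
    scores: pd.DataFrame  # index test_id, columns strains, NaN = missing
    totals: dict[str, float]

    def subscores(self) -> SubscoreTable:
        return SubscoreTable(scores=self.scores.copy(), battery=self.battery)

    def check(self) -> None:
        """Verify column sums (missing → 0) reproduce the stored totals."""
        sums = self.scores.fillna(0.0).sum(axis=0)
        for strain, total in self.totals.items():
            if abs(float(sums[strain]) - total) > 1e-9:
                raise AssertionError(
                    f"fixture column {strain} sums to {sums[strain]}, expected {total}"
                )
        maxima = sum(t.max_score for t in self.battery)
        if abs(maxima - 100.0) > 1e-9:
            raise AssertionError(f"battery maxima sum to {maxima}, expected 100")


def load_table3() -> Table3Fixture:
    """Load and self-check the packaged reference scorecard."""
    with resources.files("apsi.data").joinpath("table3.csv").open("r") as fh:
        df = pd.read_csv(fh)
    # merge the fixture's scheme/maxima with the default battery's assay
    # descriptors (metric, condition, fungus, ...) so the battery is runnable
    defaults = {t.test_id: t for t in default_battery()}
    battery: list[TestDefinition] = []
    for row in df.itertuples(index=False):
        base = defaults.get(row.test_id)
        if base is None:
            base = TestDefinition(row.test_id, row.category, row.scheme,
                                  float(row.max_score))
        if base.category != row.category:
            raise AssertionError(f"fixture category mismatch for {row.test_id}")
        battery.append(
            replace(base, scheme=row.scheme, max_score=float(row.max_score))
        )
    scores = df.set_index("test_id")[list(STRAIN_ORDER)].astype(float)
    fixture = Table3Fixture(battery=battery, scores=scores, totals=dict(TOTALS))
    fixture.check()
    return fixture


def tier_profile(strain: str) -> dict[str, float]:
    """A strain's scorecard column as score fractions (points / max).

    Useful as a true effect-tier profile for the synthetic panel generator;
    missing cells are omitted.
    """
    fx = load_table3()
    if strain not in fx.scores.columns:
        raise KeyError(f"unknown strain {strain!r}; have {list(fx.scores.columns)}")
    maxima = {t.test_id: t.max_score for t in fx.battery}
    col = fx.scores[strain]
    return {
        str(tid): float(v) / maxima[str(tid)]
        for tid, v in col.items()
        if pd.notna(v)
    }
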
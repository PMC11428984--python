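"""Aggregation of subscores into the 0–100 index, classification and ranking.

The index total for a strain is the plain sum of its per-test points; with
the default battery the attainable maximum is 100. A decision cutoff of
50 ± 0.5 splits strains into three classes: ``suitable`` above the band,
``needs_more_tests`` below it, and ``borderline`` inside it — the band is
explicit because a total of exactly 50 is not silently resolved either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import SubscoreTable

DEFAULT_CUTOFF = 50.0
DEFAULT_BAND = 0.5
_TIE_TOL = 1e-9

CLASSES = ("suitable", "borderline", "needs_more_tests")


@dataclass
class ApsiResult:
    """Index outcome for one strain."""

    strain_id: str
    total: float
    by_category: dict[str, float]
    classification: str
    missing_tests: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "total": float(self.total),
            "by_category": {k: float(v) for k, v in self.by_category.items()},
            "classification": self.classification,
            "missing_tests": list(self.missing_tests),
        }


def classify(
    total: float,
    cutoff: float = DEFAULT_CUTOFF,
    band: float = DEFAULT_BAND,
) -> str:
    """Three-way decision: below the band more tests are needed; inside it
    the call is deliberately left open."""
    if band < 0:
        raise ValueError("band must be non-negative")
    if total < cutoff - band:
        return "needs_more_tests"
    if total > cutoff + band:
        return "suitable"
    return "borderline"


def compute_apsi(
    subscores: SubscoreTable,
    missing_policy: str = "zero",
    *,
    cutoff: float = DEFAULT_CUTOFF,
    band: float = DEFAULT_BAND,
) -> dict[str, ApsiResult]:
    """Sum per-test points into per-strain index results.

    Parameters
    ----------
    subscores
        Validated subscore table.
    missing_policy
        ``"zero"`` (default): a missing test contributes nothing, so the
        total is read against the full battery maximum. ``"renormalize"``:
        the total is rescaled to the maximum attainable over the tests the
        strain was actually run on, ×100.
    """
    if missing_policy not in ("zero", "renormalize"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    maxima = subscores.maxima()
    battery_max = float(maxima.sum())
    if missing_policy == "zero" and abs(battery_max - 100.0) > 1e-9:
        warnings.warn(
            f"battery maxima sum to {battery_max}, not 100; "
            "index reported on the battery's own scale",
            stacklevel=2,
        )
    categories = {t.test_id: t.category for t in subscores.battery}
    results: dict[str, ApsiResult] = {}
    for strain in subscores.strains:
        col = subscores.scores[strain]
        missing = subscores.missing_tests(strain)
        by_cat: dict[str, float] = {}
        for tid, pts in col.items():
            cat = categories[str(tid)]
            by_cat.setdefault(cat, 0.0)
            if not pd.isna(pts):
                by_cat[cat] += float(pts)
        total = float(sum(by_cat.values()))
        if missing_policy == "renormalize":
            attainable = float(maxima[~col.isna()].sum())
            if attainable <= 0:
                raise ValueError(f"strain {strain!r} has no scored tests to renormalize on")
            scale = 100.0 / attainable
            total *= scale
            by_cat = {k: v * scale for k, v in by_cat.items()}
        results[strain] = ApsiResult(
            strain_id=strain,
            total=total,
            by_category=by_cat,
            classification=classify(total, cutoff, band),
            missing_tests=missing,
        )
    return results


def rank_strains(results: list[ApsiResult]) -> list[tuple[int, ApsiResult]]:
    """Descending competition ranking of index results.

    Totals within 1e-9 of each other share a rank (the next rank is skipped,
    so two strains tied at rank 1 are followed by rank 3); exact ties keep
    their input order in the display.
    """
    if not results:
        raise ValueError("no results to rank")
    order = sorted(
        range(len(results)), key=lambda i: (-results[i].total, i)
    )
    ranked: list[tuple[int, ApsiResult]] = []
    rank = 1
    for pos, i in enumerate(order):
        if pos > 0:
            prev = results[order[pos - 1]]
            if abs(prev.total - results[i].total) >= _TIE_TOL:
                rank = pos + 1
        ranked.append((rank, results[i]))
    return ranked


def ranking_frame(results: dict[str, ApsiResult]) -> pd.DataFrame:
    """Convenience table: rank, strain, total, classification."""
    ranked = rank_strains(list(results.values()))
    return pd.DataFrame(
        [
            {
                "rank": r,
                "strain_id": res.strain_id,
                "total": res.total,
                "classification": res.classification,
            }
            for r, res in ranked
        ]
    )
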
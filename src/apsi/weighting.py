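"""Category weights: Delphi aggregation of expert opinion and budget allocation.

The index assigns each assay category a percentage of the 100-point total
(growth promotion 20, drought protection 27, antifungal activity 28,
phytohormones 9, solubilization 8, siderophores 4, urease 4 in the default
scheme). Weights can come from a panel of experts via an iterative Delphi
procedure — component-wise median aggregation with optional contraction of
each expert toward the consensus — and are then split equally across the
tests of each category to yield per-test maxima.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from pathlib import Path

import yaml

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WeightScheme:
    """Category → percent of the total index; percentages sum to 100."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty weight scheme")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 100.0) > _SUM_TOL:
            raise ValueError(f"weights sum to {total}, expected 100")

    @property
    def categories(self) -> list[str]:
        return list(self.weights)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, dtype=float)

    @classmethod
    def normalized(cls, raw: dict[str, float]) -> "WeightScheme":
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("cannot normalize non-positive weights")
        return cls({k: 100.0 * v / total for k, v in raw.items()})


def default_scheme() -> WeightScheme:
    """The published category percentages (hormones' 9% closes the 100)."""
    return WeightScheme({
        "growth": 20.0,
        "drought": 27.0,
        "fungal": 28.0,
        "hormone": 9.0,
        "solubilization": 8.0,
        "siderophore": 4.0,
        "urease": 4.0,
    })


def load_scheme(path: str | Path) -> WeightScheme:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return WeightScheme({str(k): float(v) for k, v in raw["weights"].items()})


def save_scheme(scheme: WeightScheme, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"weights": {k: float(v) for k, v in scheme.weights.items()}}, fh)


# ---------------------------------------------------------------------------
# Delphi aggregation
# ---------------------------------------------------------------------------

@dataclass
class DelphiState:
    """State of the elicitation after some number of rounds.

    ``expert_vectors`` has one row per expert, one column per category; every
    row sums to 100. ``aggregate`` is the component-wise median,
    ``dispersion`` the per-component interquartile range.
    """

    expert_vectors: pd.DataFrame
    round: int = 0
    aggregate: pd.Series = field(init=False)
    dispersion: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        v = self.expert_vectors
        if len(v) < 1:
            raise ValueError("empty expert panel")
        sums = v.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("every expert vector must sum to 100")
        self.aggregate = v.median(axis=0)
        self.dispersion = v.quantile(0.75, axis=0) - v.quantile(0.25, axis=0)

    @classmethod
    def from_experts(cls, vectors: dict[str, dict[str, float]] | pd.DataFrame) -> "DelphiState":
        df = pd.DataFrame(vectors).T if isinstance(vectors, dict) else vectors.copy()
        return cls(expert_vectors=df.astype(float))


@dataclass
class DelphiOutcome:
    scheme: WeightScheme
    converged: bool
    rounds: int
    state: DelphiState


def delphi_round(state: DelphiState, contraction: float) -> DelphiState:
    """One elicitation round: experts move toward the current consensus.

    Each expert vector moves a fraction ``contraction`` of the way to the
    component-wise median and is renormalized to sum 100. ``contraction`` 0
    models experts who never revise; 1 collapses the panel in one round.
    """
    if not 0.0 <= contraction <= 1.0:
        raise ValueError("contraction must lie in [0, 1]")
    if len(state.expert_vectors) < 2:
        raise ValueError("a Delphi round needs at least two experts")
    agg = state.aggregate
    moved = state.expert_vectors + contraction * (agg - state.expert_vectors)
    moved = moved.clip(lower=0.0)
    moved = moved.div(moved.sum(axis=1), axis=0) * 100.0
    return DelphiState(expert_vectors=moved, round=state.round + 1)


def delphi_converge(
    initial: DelphiState,
    tolerance: float = 0.1,
    max_rounds: int = 50,
    contraction: float = 0.5,
) -> DelphiOutcome:
    """Iterate rounds until every component IQR drops below ``tolerance``.

    Returns the final aggregate renormalized to 100; ``converged`` is False
    when the IQR bound was not reached within ``max_rounds`` (e.g. with
    contraction 0 and a disagreeing panel).
    """
    state = initial
    converged = bool((state.dispersion < tolerance).all())
    rounds = 0
    while not converged and rounds < max_rounds:
        state = delphi_round(state, contraction)
        rounds = state.round
        converged = bool((state.dispersion < tolerance).all())
    scheme = WeightScheme.normalized(dict(state.aggregate))
    return DelphiOutcome(scheme=scheme, converged=converged, rounds=rounds, state=state)


def load_expert_panel(path: str | Path) -> DelphiState:
    """Read an experts CSV (rows = experts, columns = category percentages)."""
    df = pd.read_csv(path, index_col=0).astype(float)
    return DelphiState.from_experts(df)


# ---------------------------------------------------------------------------
# budget allocation
# ---------------------------------------------------------------------------

def allocate_budgets(
    scheme: WeightScheme, counts: dict[str, int]
) -> dict[str, float]:
    """Split each category's percentage equally over its tests.

    Returns per-test maxima by category; the battery's total mass is
    preserved: sum over categories of count × per-test max equals 100.
    """
    out: dict[str, float] = {}
    for cat, w in scheme.weights.items():
        n = counts.get(cat, 0)
        if n < 1:
            if w > 0:
                raise ValueError(f"category {cat!r} has weight {w} but no tests")
            continue
        out[cat] = w / n
    return out


def apply_budgets(battery, scheme: WeightScheme):
    """Return a copy of the battery with maxima set from a weight scheme."""
    from dataclasses import replace
    from .battery import category_counts

    per_test = allocate_budgets(scheme, category_counts(battery))
    return [replace(t, max_score=per_test[t.category]) for t in battery]
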
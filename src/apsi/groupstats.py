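"""Statistical grading of replicate groups.

The pipeline mirrors common practice for plate and pot experiments:
Bonferroni-corrected studentized-residual outlier screening, a Shapiro–Wilk
normality check, one-way ANOVA across treatment groups, Tukey HSD pairwise
comparisons (Tukey–Kramer for unbalanced groups) and a compact letter
display so that two groups share a letter exactly when they are not
significantly different at the chosen level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of grading a set of replicate groups.

    ``pairwise_p`` is symmetric with a unit diagonal; two groups share at
    least one letter in ``letters`` iff their adjusted p-value is >= the
    alpha the comparison was run at.
    """

    group_ids: list[str]
    means: np.ndarray
    n: np.ndarray
    anova_F: float
    anova_p: float
    pairwise_p: np.ndarray
    letters: list[str]
    alpha: float = DEFAULT_ALPHA
    normality_p: float | None = None
    outliers_removed: int = 0
    warnings: list[str] = field(default_factory=list)

    def p_between(self, a: str, b: str) -> float:
        i, j = self.group_ids.index(a), self.group_ids.index(b)
        return float(self.pairwise_p[i, j])

    def mean_of(self, a: str) -> float:
        return float(self.means[self.group_ids.index(a)])

    def to_dict(self) -> dict:
        return {
            "group_ids": list(self.group_ids),
            "means": [float(m) for m in self.means],
            "n": [int(k) for k in self.n],
            "anova_F": float(self.anova_F),
            "anova_p": float(self.anova_p),
            "pairwise_p": [[float(p) for p in row] for row in self.pairwise_p],
            "letters": list(self.letters),
            "alpha": float(self.alpha),
            "normality_p": None if self.normality_p is None else float(self.normality_p),
            "outliers_removed": int(self.outliers_removed),
            "warnings": list(self.warnings),
        }


def check_normality(values: np.ndarray) -> float:
    """Shapiro–Wilk p-value; p > 0.05 is conventionally read as normal."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or len(values) > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("normality undefined for a constant sample")
    return float(scipy.stats.shapiro(values).pvalue)


def remove_outliers(
    values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    *,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Iterative Bonferroni outlier screen on studentized residuals.

    Each iteration fits an intercept-only model (or a one-way group-means
    model when ``groups`` is given), studentizes the residuals and flags the
    single observation with the largest absolute studentized residual whose
    Bonferroni-adjusted two-sided p-value is below ``alpha``. Iteration
    stops when no observation is significant.

    Returns the kept values and the (original) indices that were flagged.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("outlier screen skipped: fewer than 4 observations", stacklevel=2)
        return values, []
    idx = np.arange(len(values))
    grp = None if groups is None else np.asarray(groups)
    flagged: list[int] = []
    while len(idx) >= 4:
        y = values[idx]
        if grp is None:
            X = np.ones((len(y), 1))
        else:
            X = pd.get_dummies(pd.Series(grp[idx]), dtype=float).to_numpy()
        if np.allclose(np.ptp(y), 0):
            break
        res = sm.OLS(y, X).fit()
        if res.df_resid <= 1:
            break
        try:
            test = res.outlier_test(method="bonf")
        except (ValueError, np.linalg.LinAlgError):
            break
        bonf_p = np.asarray(test)[:, 2]
        student = np.abs(np.asarray(test)[:, 0])
        worst = int(np.nanargmax(student))
        if np.isfinite(bonf_p[worst]) and bonf_p[worst] < alpha:
            flagged.append(int(idx[worst]))
            idx = np.delete(idx, worst)
        else:
            break
    return values[idx], sorted(flagged)


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F statistic and p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    means = [g.mean() for g in groups]
    if np.ptp(means) == 0 and all(np.ptp(g) == 0 for g in groups):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = scipy.stats.f_oneway(*groups)
    if not np.isfinite(F):  # zero within-group variance, unequal means
        return float("inf"), 0.0
    return float(F), float(p)


def tukey_hsd(groups: list[np.ndarray], alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """All-pairs Tukey HSD adjusted p-values (Tukey–Kramer when unbalanced).

    Returns a symmetric matrix with unit diagonal. Degenerate case: when the
    pooled within-group variance is zero, pairs with unequal means get p = 0
    and pairs with equal means p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Tukey HSD requires at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if sse <= 0:
        p = np.where(np.abs(means[:, None] - means[None, :]) > 0, 0.0, 1.0)
        np.fill_diagonal(p, 1.0)
        return p
    res = scipy.stats.tukey_hsd(*groups)
    p = np.clip(np.asarray(res.pvalue, dtype=float), 0.0, 1.0)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0)
    return p


def compact_letters(pairwise_p: np.ndarray, alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Produces per-group letter strings such that two groups share a letter
    iff their adjusted p-value is >= ``alpha`` (i.e. they are not
    significantly different). Letters are ordered so that the first group
    carries 'a'.
    """
    p = np.asarray(pairwise_p, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k) or not np.allclose(p, p.T):
        raise ValueError("pairwise_p must be a symmetric square matrix")
    # start with one letter set holding everyone; split on significant pairs
    sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if p[i, j] < alpha:
            new_sets: list[set[int]] = []
            for s in sets:
                if i in s and j in s:
                    new_sets.append(s - {i})
                    new_sets.append(s - {j})
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            sets = [
                s for s in new_sets
                if s and not any(s < t for t in new_sets)
            ]
            # deduplicate
            uniq: list[set[int]] = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    # order letter sets by their smallest member for stable display
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = [
        alphabet[i] if i < 26 else f"l{i}" for i in range(len(sets))
    ]
    out = []
    for g in range(k):
        out.append("".join(lab for lab, s in zip(labels, sets) if g in s))
    return out


def grade_groups(
    samples: dict[str, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    *,
    screen_outliers: bool = True,
) -> GroupComparison:
    """Full grading pipeline over named replicate groups.

    Outlier screening (on the one-way model residuals) precedes the
    normality check and ANOVA; a failed normality check does not abort the
    pipeline but is recorded as a warning on the result.
    """
    ids = list(samples)
    if len(ids) < 2:
        raise ValueError("need at least two groups")
    values = np.concatenate([np.asarray(samples[i], dtype=float) for i in ids])
    labels = np.concatenate([[i] * len(samples[i]) for i in ids])
    notes: list[str] = []
    removed = 0
    if screen_outliers and len(values) >= 4:
        kept, flagged = remove_outliers(values, alpha, groups=labels)
        if flagged:
            removed = len(flagged)
            keep_mask = np.ones(len(values), bool)
            keep_mask[flagged] = False
            values, labels = values[keep_mask], labels[keep_mask]
            notes.append(f"removed {removed} outlier(s)")
    groups = [values[labels == i] for i in ids]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2 after outlier screening")
    norm_p: float | None = None
    resid = np.concatenate([g - g.mean() for g in groups])
    if 3 <= len(resid) <= 5000 and np.ptp(resid) > 0:
        norm_p = check_normality(resid)
        if norm_p <= 0.05:
            notes.append(f"residual normality check failed (p={norm_p:.3g})")
    F, p_anova = oneway_anova(groups)
    pmat = tukey_hsd(groups, alpha)
    letters = compact_letters(pmat, alpha)
    return GroupComparison(
        group_ids=ids,
        means=np.array([g.mean() for g in groups]),
        n=np.array([len(g) for g in groups]),
        anova_F=F,
        anova_p=p_anova,
        pairwise_p=pmat,
        letters=letters,
        alpha=alpha,
        normality_p=norm_p,
        outliers_removed=removed,
        warnings=notes,
    )
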
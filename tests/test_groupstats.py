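"""Statistical grading: normality, outliers, ANOVA, Tukey HSD, letters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from apsi import (
    check_normality,
    compact_letters,
    grade_groups,
    oneway_anova,
    remove_outliers,
    tukey_hsd,
)


class TestNormality:
    def test_probability_bounds(self):
        rng = np.random.default_rng(0)
        p = check_normality(rng.normal(size=30))
        assert 0.0 <= p <= 1.0

    def test_calibration_on_normal_samples(self):
        """Normal samples should pass the check in the vast majority of runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            if check_normality(rng.normal(size=200)) > 0.05:
                hits += 1
        assert hits >= 90

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(1)
        sample = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])
        assert check_normality(sample) < 0.05
        # agrees with the reference implementation it wraps
        assert check_normality(sample) == pytest.approx(stats.shapiro(sample).pvalue)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            check_normality(np.ones(10))


def _brute_force_outlier(values, alpha):
    """Externally studentized residuals + Bonferroni bound, by hand."""
    y = np.asarray(values, float)
    n = len(y)
    flags = []
    for i in range(n):
        rest = np.delete(y, i)
        m, s = rest.mean(), rest.std(ddof=1)
        t = (y[i] - m) / (s * np.sqrt(1 + 1 / len(rest)))
        p = 2 * stats.t.sf(abs(t), df=len(rest) - 1) * n
        flags.append((abs(t), p))
    worst = max(range(n), key=lambda i: flags[i][0])
    return worst if flags[worst][1] < alpha else None


class TestOutliers:
    def test_homogeneous_sample_unflagged(self):
        kept, flagged = remove_outliers(np.array([1.0, 1.1, 0.9, 1.05]))
        assert flagged == []
        assert len(kept) == 4

    def test_gross_outlier_flagged(self):
        values = np.array([1.0, 1.1, 0.9, 1.05, 25.0])
        kept, flagged = remove_outliers(values)
        assert flagged == [4]
        assert 25.0 not in kept
        # brute-force oracle agrees the extreme point is significant
        assert _brute_force_outlier(values, 0.05) == 4

    def test_never_empties_the_sample(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = rng.normal(size=8) * rng.uniform(0.1, 50)
            kept, flagged = remove_outliers(values)
            assert len(flagged) < len(values)
            assert len(kept) + len(flagged) == len(values)

    def test_small_sample_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            kept, flagged = remove_outliers(np.array([1.0, 2.0, 50.0]))
        assert flagged == [] and len(kept) == 3


def _brute_force_anova(groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, stats.f.sf(F, dfb, dfw)


class TestAnova:
    def test_identical_groups_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        F, p = oneway_anova([g, g.copy()])
        assert F == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self):
        F, p = oneway_anova([np.array([0, 0, 0.001]), np.array([10, 10, 10.001])])
        assert p < 1e-6

    def test_matches_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-2, 2), 1, rng.integers(3, 8))
                      for _ in range(rng.integers(2, 5))]
            F, p = oneway_anova(groups)
            F2, p2 = _brute_force_anova(groups)
            assert F == pytest.approx(F2, rel=1e-10)
            assert p == pytest.approx(p2, rel=1e-10)

    def test_single_replicate_group_errors(self):
        with pytest.raises(ValueError):
            oneway_anova([np.array([1.0]), np.array([1.0, 2.0])])


def _tukey_oracle(groups):
    """Adjusted p-values straight from the studentized-range distribution."""
    k = len(groups)
    n = [len(g) for g in groups]
    means = [g.mean() for g in groups]
    df = sum(n) - k
    s2 = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(s2 / 2 * (1 / n[i] + 1 / n[j]))  # Tukey–Kramer
        q = abs(means[i] - means[j]) / se
        p[i, j] = p[j, i] = stats.studentized_range.sf(q, k, df)
    return p


class TestTukey:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        p = tukey_hsd([g, g.copy()])
        assert p[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_unit_diagonal_and_bounded(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 5) for m in (0, 1, 3)]
        p = tukey_hsd(groups)
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)
        assert ((p >= 0) & (p <= 1)).all()
        # invariant to group relabeling
        perm = [2, 0, 1]
        p2 = tukey_hsd([groups[i] for i in perm])
        assert np.allclose(p2, p[np.ix_(perm, perm)])

    def test_agrees_with_studentized_range_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), 1, 5) for _ in range(3)]
            p = tukey_hsd(groups)
            p_ref = _tukey_oracle(groups)
            assert np.allclose(p, p_ref, atol=1e-6)

    def test_unbalanced_agrees_with_kramer_oracle(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 4), rng.normal(1, 1, 7), rng.normal(2, 1, 5)]
        assert np.allclose(tukey_hsd(groups), _tukey_oracle(groups), atol=1e-6)

    def test_zero_variance_degenerate(self):
        a = np.array([1.0, 1.0])
        b = np.array([2.0, 2.0])
        p = tukey_hsd([a, b, a.copy()])
        assert p[0, 1] == 0.0 and p[0, 2] == 1.0

    def test_monotone_in_mean_difference(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 1, 6)
        base -= base.mean()
        noise = rng.normal(0, 1, 6)
        noise -= noise.mean()  # now |mean difference| = delta exactly
        last = 1.1
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            p = tukey_hsd([base, noise + delta])[0, 1]
            assert p <= last + 1e-12
            last = p


def _letters_satisfy_biconditional(pmat, letters, alpha):
    k = len(letters)
    for i, j in itertools.combinations(range(k), 2):
        share = bool(set(letters[i]) & set(letters[j]))
        if share != (pmat[i, j] >= alpha):
            return False
    return all(letters)


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        p = np.full((4, 4), 0.8)
        np.fill_diagonal(p, 1.0)
        assert compact_letters(p) == ["a", "a", "a", "a"]

    def test_all_significant_distinct_letters(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        assert compact_letters(p) == ["a", "b", "c"]

    def test_chain_case(self):
        p = np.array([
            [1.0, 0.2, 0.01],
            [0.2, 1.0, 0.2],
            [0.01, 0.2, 1.0],
        ])
        assert compact_letters(p) == ["a", "ab", "b"]

    @given(st.integers(0, 10_000), st.integers(2, 7))
    @settings(max_examples=200, deadline=None)
    def test_biconditional_on_random_matrices(self, seed, k):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=(k, k))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        letters = compact_letters(p, alpha=0.05)
        assert _letters_satisfy_biconditional(p, letters, 0.05)


class TestPipeline:
    def test_deterministic(self):
        rng = np.random.default_rng(13)
        samples = {s: rng.normal(m, 1, 6) for s, m in zip("abc", (0, 1, 5))}
        r1 = grade_groups(samples)
        r2 = grade_groups({k: v.copy() for k, v in samples.items()})
        assert r1.letters == r2.letters
        assert np.allclose(r1.pairwise_p, r2.pairwise_p)
        assert r1.anova_F == r2.anova_F

    def test_letters_match_pairwise_matrix(self):
        rng = np.random.default_rng(14)
        samples = {s: rng.normal(m, 0.5, 8) for s, m in zip("abcd", (0, 0.2, 3, 3.1))}
        res = grade_groups(samples)
        assert _letters_satisfy_biconditional(res.pairwise_p, res.letters, res.alpha)

    def test_outlier_removed_before_anova(self):
        rng = np.random.default_rng(15)
        samples = {
            "a": np.append(rng.normal(0, 0.1, 6), 40.0),
            "b": rng.normal(0.5, 0.1, 6),
        }
        res = grade_groups(samples)
        assert res.outliers_removed == 1
        assert res.n[0] == 6
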
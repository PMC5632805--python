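"""Kruskal-Wallis, Conover post-hoc, compact letter display, Pearson."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from phenowell.stats import (PosthocResult, conover_posthoc, kruskal_wallis,
                             letter_display, pearson_validation)


def conover_oracle(groups, alpha=0.05):
    """Independent direct-formula Conover-Iman implementation (textbook
    rank sums, pooled rank variance, t on N-k df), written against the
    published formulas without reference to the package internals."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    split, i = [], 0
    for g in groups:
        split.append(ranks[i:i + len(g)])
        i += len(g)
    n = np.array([len(g) for g in groups])
    rbar = np.array([r.mean() for r in split])
    # tie-corrected H
    h = 12 / (N * (N + 1)) * np.sum(n * (rbar - (N + 1) / 2) ** 2)
    _, cnt = np.unique(pooled, return_counts=True)
    h /= 1 - np.sum(cnt**3 - cnt) / (N**3 - N)
    s2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4) / (N - 1)
    p = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            t = (rbar[a] - rbar[b]) / np.sqrt(
                s2 * ((N - 1 - h) / (N - k)) * (1 / n[a] + 1 / n[b]))
            p[a, b] = p[b, a] = min(1.0, 2 * sps.t.sf(abs(t), N - k))
    return p


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 on {1..3},{4..6},{7..9}
        gives H = 7.2."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.h == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2
        assert res.p_value == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_degenerate_all_equal(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5], [5]])
        assert res.h == 0.0 and res.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(i, 1, 12) for i in range(3)]
        h1 = kruskal_wallis(groups).h
        h2 = kruskal_wallis([np.exp(g) for g in groups]).h
        h3 = kruskal_wallis([g**3 for g in groups]).h
        assert h1 == pytest.approx(h2) == pytest.approx(h3)

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 8, 15).astype(float) for _ in range(4)]
        res = kruskal_wallis(groups)
        h_ref, p_ref = sps.kruskal(*groups)
        assert res.h == pytest.approx(h_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestConover:
    def test_identical_groups_p_near_one(self):
        res = conover_posthoc([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res.p_matrix[0, 1] > 0.95

    def test_separated_groups_all_significant(self):
        groups = [np.arange(10) + 100 * i for i in range(3)]
        res = conover_posthoc(groups)
        iu = np.triu_indices(3, 1)
        assert np.all(res.p_matrix[iu] < 0.01)

    def test_oracle_equality_random_instance(self, rng):
        """Direct-formula oracle agreement to 1e-10 on a 3x5 instance."""
        groups = [rng.normal(i * 0.8, 1, 5) for i in range(3)]
        res = conover_posthoc(groups)
        np.testing.assert_allclose(res.p_matrix, conover_oracle(groups),
                                   atol=1e-10)

    def test_oracle_equality_with_ties(self, rng):
        groups = [rng.integers(0, 5, 8).astype(float) for _ in range(4)]
        res = conover_posthoc(groups)
        np.testing.assert_allclose(res.p_matrix, conover_oracle(groups),
                                   atol=1e-10)

    def test_p_monotone_in_rank_gap(self):
        """Shifting one group further away can only reduce its p-value."""
        base = np.arange(10, dtype=float)
        prev = 1.1
        for shift in (2, 6, 12, 25):
            res = conover_posthoc([base, base + shift])
            assert res.p_matrix[0, 1] <= prev + 1e-12
            prev = res.p_matrix[0, 1]

    def test_holm_adjustment_never_decreases_p(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(4)]
        raw = conover_posthoc(groups).p_matrix
        adj = conover_posthoc(groups, adjust="holm").p_matrix
        assert np.all(adj + 1e-15 >= raw)

    def test_matrix_is_symmetric_unit_diagonal(self, rng):
        groups = [rng.normal(i, 1, 6) for i in range(4)]
        p = conover_posthoc(groups).p_matrix
        np.testing.assert_allclose(p, p.T)
        np.testing.assert_allclose(np.diag(p), 1.0)


def _posthoc_from_matrix(p, medians, alpha=0.05):
    labels = [f"g{i}" for i in range(len(medians))]
    return PosthocResult(group_labels=labels, p_matrix=np.asarray(p, float),
                         alpha=alpha, medians=np.asarray(medians, float))


class TestLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        ph = _posthoc_from_matrix(np.ones((3, 3)), [3, 2, 1])
        assert set(letter_display(ph).values()) == {"a"}

    def test_all_pairs_significant(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        letters = letter_display(_posthoc_from_matrix(p, [30, 20, 10]))
        assert letters == {"g0": "a", "g1": "b", "g2": "c"}

    def test_only_extremes_differ_gives_a_ab_b(self):
        """Three groups where just the extremes differ: a / ab / b (the
        classic replicate-comparison pattern)."""
        p = np.ones((3, 3))
        p[0, 2] = p[2, 0] = 0.001
        letters = letter_display(_posthoc_from_matrix(p, [30, 20, 10]))
        assert letters == {"g0": "a", "g1": "ab", "g2": "b"}

    def test_letters_anchored_to_descending_median(self):
        p = np.full((2, 2), 0.001)
        np.fill_diagonal(p, 1.0)
        letters = letter_display(_posthoc_from_matrix(p, [5, 50]))
        assert letters == {"g0": "b", "g1": "a"}

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_clique_consistency_exhaustive(self, k):
        """Exhaustively over every significance pattern of k groups: two
        groups share a letter iff their pairwise p >= alpha."""
        pairs = list(itertools.combinations(range(k), 2))
        for bits in range(2 ** len(pairs)):
            p = np.ones((k, k))
            for b, (i, j) in enumerate(pairs):
                if bits >> b & 1:
                    p[i, j] = p[j, i] = 0.001
            letters = letter_display(
                _posthoc_from_matrix(p, list(range(k, 0, -1))))
            for i, j in pairs:
                shared = set(letters[f"g{i}"]) & set(letters[f"g{j}"])
                if p[i, j] < 0.05:
                    assert not shared, (k, bits, letters)
                else:
                    assert shared, (k, bits, letters)


class TestPearsonValidation:
    def test_proportional_is_perfect(self):
        areas = np.array([10.0, 20, 30, 40])
        r, p = pearson_validation(areas, 0.37 * areas)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_matches_covariance_formula(self, rng):
        x = rng.uniform(0, 100, 10)
        y = rng.uniform(0, 50, 10)
        r, _ = pearson_validation(x, y)
        oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_synthetic_area_fresh_weight_pairs(self, rng):
        """Areas with proportional mean fresh weight and 10% noise, n = 144:
        the validation statistic lands in the strongly-correlated regime."""
        areas = rng.uniform(500, 8000, 144)
        fw = 0.005 * areas * (1 + rng.normal(0, 0.10, 144))
        r, p = pearson_validation(areas, fw)
        assert r > 0.9 and p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_validation([1, 1, 1], [2, 3, 4])


def test_kw_power_with_shifted_group(rng):
    """One of three groups shifted by 1.5 SD (n = 20): rejection rate over
    2000 replicates comfortably exceeds 0.8."""
    rejections = 0
    reps = 2000
    for _ in range(reps):
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                  rng.normal(1.5, 1, 20)]
        if kruskal_wallis(groups).p_value < 0.05:
            rejections += 1
    assert rejections / reps > 0.8
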
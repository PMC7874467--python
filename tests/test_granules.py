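"""Rank/overlap statistics against brute-force and enumeration oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from l1ripseq import granules


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH the slow way: q_(i) = min_{j>=i} p_(j) n / j."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * n / j for j in range(rank_i, n + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_worked_example(self):
        q = granules.bh_fdr([0.01, 0.02, 0.04, 0.05])
        assert q == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_all_equal_and_singleton(self):
        assert granules.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert granules.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(1, 40)
            p = rng.random(n)
            assert granules.bh_fdr(p) == pytest.approx(brute_force_bh(p))

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            granules.bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            granules.bh_fdr([-0.1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_order_invariance(self, ps, rnd):
        p = np.array(ps)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = granules.bh_fdr(p)
        q_perm = granules.bh_fdr(p[perm])
        assert q_perm == pytest.approx(q[perm])


class TestOverlapTest:
    def test_direct_odds_ratio(self):
        universe = set(range(25))
        a = set(range(15))  # a=10,b=5 with b_set
        b = set(range(10)) | set(range(15, 17))
        res = granules.overlap_test(a, b, universe)
        assert res.table == (10, 5, 2, 8)
        assert res.odds_ratio == pytest.approx(8.0)
        assert not res.haldane_corrected

    def test_identical_sets_need_haldane_correction(self):
        u = set(range(10))
        a = set(range(4))
        res = granules.overlap_test(a, a, u)
        assert res.haldane_corrected
        assert math.isfinite(res.odds_ratio) and res.odds_ratio > 1

    def test_subset_violation_is_an_error(self):
        with pytest.raises(ValueError, match="subsets"):
            granules.overlap_test({1, 99}, {1}, set(range(10)))

    def test_exact_p_matches_hypergeometric_enumeration(self):
        """One-sided p equals the explicit hypergeometric tail sum for
        every table with universe size <= 60 (enumeration via math.comb)."""
        for M in range(1, 61, 3):
            for K in range(0, M + 1, 5):
                for N in range(0, M + 1, 5):
                    lo, hi = max(0, K + N - M), min(K, N)
                    tail = 0.0
                    # enumerate pmf from the top
                    for a in range(hi, lo - 1, -1):
                        tail += (
                            math.comb(K, a)
                            * math.comb(M - K, N - a)
                            / math.comb(M, N)
                        )
                        u = set(range(M))
                        sa = set(range(K))
                        sb = set(range(K - a, K - a + N)) if N else set()
                        res = granules.overlap_test(sa, sb & u, u)
                        if len(sa & sb) == a and len(sb) == N:
                            assert res.p_value == pytest.approx(
                                min(tail, 1.0), rel=1e-9, abs=1e-12
                            ), (M, K, N, a)

    def test_matches_scipy_fisher_one_sided(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            M = int(rng.integers(10, 200))
            u = set(range(M))
            a = set(rng.choice(M, size=rng.integers(1, M), replace=False).tolist())
            b = set(rng.choice(M, size=rng.integers(1, M), replace=False).tolist())
            res = granules.overlap_test(a, b, u)
            t = res.table
            want = stats.fisher_exact(
                [[t[0], t[1]], [t[2], t[3]]], alternative="greater"
            ).pvalue
            assert res.p_value == pytest.approx(want, rel=1e-8, abs=1e-300)

    def test_null_p_values_are_superuniform(self):
        """Independent random sets: P(p <= alpha) <= alpha (validity of the
        exact test), checked over many draws."""
        rng = np.random.default_rng(2)
        M = 400
        u = list(range(M))
        ps = []
        for _ in range(500):
            a = set(rng.choice(M, 150, replace=False).tolist())
            b = set(rng.choice(M, 150, replace=False).tolist())
            ps.append(granules.overlap_test(a, b, set(u)).p_value)
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / 500)


class TestSpearman:
    def test_perfect_monotone_relationships(self):
        x = np.arange(10.0)
        rho, _ = granules.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = granules.spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_enumeration_n6(self):
        rng = np.random.default_rng(3)
        x = rng.random(6)
        y = rng.random(6)
        rho, p = granules.spearman(x, y)
        obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(
            abs(stats.spearmanr(x, np.asarray(y)[list(perm)]).statistic) >= obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        assert p == pytest.approx(count / math.factorial(6))

    def test_constant_vector_is_undefined(self):
        rho, p = granules.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(50), rng.random(50)
        rho, p = granules.spearman(x, y)
        rho2, p2 = granules.spearman(np.exp(5 * x), y**3)
        assert rho2 == pytest.approx(rho)
        assert p2 == pytest.approx(p)

    def test_agrees_with_scipy_at_large_n(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(200), rng.random(200)
        rho, p = granules.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestPartialSpearman:
    def rank_residual_partial(self, x, y, z):
        """Independent oracle: correlation of rank-regression residuals."""
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rz = stats.rankdata(z)
        bx = np.polyfit(rz, rx, 1)
        by = np.polyfit(rz, ry, 1)
        ex = rx - np.polyval(bx, rz)
        ey = ry - np.polyval(by, rz)
        return float(np.corrcoef(ex, ey)[0, 1])

    def test_matches_rank_residual_method(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = 0.5 * z + rng.normal(size=n)
            rho, _ = granules.partial_spearman(x, y, z)
            assert rho == pytest.approx(self.rank_residual_partial(x, y, z), abs=0.02)

    def test_independent_confounder_changes_nothing(self):
        rng = np.random.default_rng(7)
        n = 3000
        x, y = rng.normal(size=n), rng.normal(size=n)
        y = 0.5 * x + y
        z = rng.normal(size=n)
        rho_plain, _ = granules.spearman(x, y)
        rho_part, _ = granules.partial_spearman(x, y, z)
        assert abs(rho_part - rho_plain) < 3 / math.sqrt(n - 3)

    def test_shared_driver_is_explained_away(self):
        """x and y both copies of z plus tiny noise: the raw correlation is
        ~1 but the partial correlation given z collapses to ~0."""
        rng = np.random.default_rng(8)
        n = 2000
        z = rng.normal(size=n)
        x = z + 0.05 * rng.normal(size=n)
        y = z + 0.05 * rng.normal(size=n)
        rho_raw, _ = granules.spearman(x, y)
        rho_part, _ = granules.partial_spearman(x, y, z)
        assert rho_raw > 0.95
        assert abs(rho_part) < 0.1

    def test_degenerate_control_is_undefined(self):
        z = np.arange(10.0)
        rho, p = granules.partial_spearman(z, np.arange(10.0)[::-1], z)
        assert math.isnan(rho)


class TestJoinAndCompare:
    def _enrichment_table(self, rng, n=200):
        vals = rng.normal(size=n)
        return pd.DataFrame(
            {
                "log2_enrichment": vals,
                "fdr": rng.random(n) * 0.2,
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="feature_id"),
        )

    def test_self_comparison_is_perfect(self):
        rng = np.random.default_rng(9)
        enr = self._enrichment_table(rng)
        ext = pd.DataFrame(
            {"gene_id": enr.index, "value": enr["log2_enrichment"].to_numpy()}
        )
        res = granules.join_and_compare(enr, ext)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.overlap.odds_ratio > 1

    def test_disjoint_namespaces_hard_error(self):
        rng = np.random.default_rng(10)
        enr = self._enrichment_table(rng)
        ext = pd.DataFrame({"gene_id": ["x1", "x2"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="joined"):
            granules.join_and_compare(enr, ext)

    def test_latent_factor_construction_recovers_rho(self):
        """External vector sharing a latent factor with the enrichment
        (loading 0.6): the measured Spearman lands within 3 SE of the
        construction's true rank correlation."""
        rng = np.random.default_rng(11)
        n = 500
        g = rng.normal(size=n)
        ip = 0.6 * g + 0.8 * rng.normal(size=n)
        ext_vals = 0.9 * g + math.sqrt(1 - 0.81) * rng.normal(size=n)
        enr = pd.DataFrame(
            {"log2_enrichment": ip, "fdr": np.full(n, 0.01)},
            index=pd.Index([f"g{i}" for i in range(n)], name="feature_id"),
        )
        ext = pd.DataFrame({"gene_id": enr.index, "value": ext_vals})
        res = granules.join_and_compare(enr, ext)
        # Pearson of the underlying normals, mapped to Spearman's scale
        r = 0.6 * 0.9
        want = 6 / math.pi * math.asin(r / 2)
        assert abs(res.spearman_rho - want) <= 3 / math.sqrt(n - 3)

    def test_null_overlap_odds_ratio_centres_on_one(self):
        rng = np.random.default_rng(12)
        ors = []
        for _ in range(200):
            n = 150
            enr = pd.DataFrame(
                {
                    "log2_enrichment": rng.normal(size=n),
                    "fdr": rng.random(n),
                },
                index=pd.Index([f"g{i}" for i in range(n)], name="feature_id"),
            )
            ext = pd.DataFrame({"gene_id": enr.index, "value": rng.normal(size=n)})
            res = granules.join_and_compare(enr, ext, fdr_gate=0.5)
            ors.append(res.overlap.odds_ratio)
        assert np.median(ors) == pytest.approx(1.0, abs=0.25)
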
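import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from wsinet import de
from wsinet.io_formats import ExpressionMatrix


def make_matrix(ratios, fg=None, bg=None):
    ratios = np.asarray(ratios, dtype=float)
    n, k = ratios.shape
    return ExpressionMatrix(
        contrast="c",
        probes=[f"p{i + 1}" for i in range(n)],
        replicates=[f"R{j + 1}" for j in range(k)],
        dye_swap=np.array([j % 2 == 1 for j in range(k)]),
        ratios=ratios * np.where([j % 2 == 1 for j in range(k)], -1.0, 1.0),
        foreground=fg,
        background=bg,
    )


def rank_product_grid_oracle(values, direction="up"):
    """Exact null by the independent-rank grid.

    Under within-replicate permutation, a fixed gene's rank in each
    replicate is uniform on {1..n} and independent across replicates, so
    p_g = #{(a_1..a_k) : geometric mean <= RP_obs_g} / n^k.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = rankdata(-values if direction == "up" else values, axis=0)
    rp_obs = np.exp(np.log(ranks).mean(axis=1))
    ps = []
    for g in range(n):
        count = sum(
            np.exp(np.mean(np.log(a))) <= rp_obs[g] + 1e-12
            for a in itertools.product(range(1, n + 1), repeat=k)
        )
        ps.append(count / n**k)
    return rp_obs, np.array(ps)


class TestFilterExpressed:
    def test_support_rule(self):
        fg = np.array([[10, 10, 10, 10], [10, 10, 1, 1], [10, 10, 10, 1]], float)
        bg = np.full((3, 4), 5.0)
        m = make_matrix(np.zeros((3, 4)), fg=fg, bg=bg)
        assert de.filter_expressed(m, min_support=3) == {"p1", "p3"}
        assert de.filter_expressed(m, min_support=0) == {"p1", "p2", "p3"}

    def test_missing_background_raises(self):
        m = make_matrix(np.zeros((2, 4)))
        with pytest.raises(ValueError, match="background"):
            de.filter_expressed(m)

    def test_min_support_above_replicates_raises(self):
        m = make_matrix(np.zeros((2, 4)), fg=np.ones((2, 4)), bg=np.zeros((2, 4)))
        with pytest.raises(ValueError):
            de.filter_expressed(m, min_support=5)


class TestRankProduct:
    def test_top_ranked_gene_has_minimum_rp(self, rng):
        values = rng.normal(size=(6, 3))
        values[2] = 10.0 + rng.uniform(size=3)  # always rank 1
        res = de.rank_product(values, n_perm=10, seed=0)
        assert res.loc["g3", "rp"] == pytest.approx(1.0)
        assert res["rp"].min() == res.loc["g3", "rp"]

    @pytest.mark.parametrize("direction", ["up", "down"])
    @pytest.mark.parametrize("shape", [(2, 2), (3, 2), (4, 2), (3, 3)])
    def test_exhaustive_matches_independent_rank_grid(self, rng, shape, direction):
        values = rng.normal(size=shape)
        res = de.rank_product(values, n_perm="exhaustive", direction=direction)
        rp, p = rank_product_grid_oracle(values, direction=direction)
        np.testing.assert_allclose(res["rp"].to_numpy(), rp)
        np.testing.assert_allclose(res["p"].to_numpy(), p)

    def test_replicate_order_invariance(self, rng):
        values = rng.normal(size=(5, 4))
        a = de.rank_product(values, n_perm=50, seed=1)
        b = de.rank_product(values[:, ::-1], n_perm=50, seed=1)
        np.testing.assert_allclose(a["rp"], b["rp"])

    def test_constant_replicate_warns(self):
        values = np.column_stack([np.zeros(4), np.arange(4, dtype=float)])
        with pytest.warns(UserWarning, match="constant"):
            de.rank_product(values, n_perm=5, seed=0)

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError):
            de.rank_product(rng.normal(size=(3, 2)), n_perm=0)

    def test_null_pvalues_super_uniform(self):
        # under a pure-noise matrix, P(p <= t) must not exceed t by more
        # than simulation error (KS-style bound 0.05 at these sizes)
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(40):
            values = rng.normal(size=(25, 3))
            res = de.rank_product(values, n_perm=49, seed=int(rng.integers(2**31)))
            ps.extend(res["p"])
        ps = np.sort(ps)
        grid = np.linspace(0.05, 1.0, 20)
        exceed = max(np.mean(ps <= t) - t for t in grid)
        assert exceed <= 0.05


class TestSamStatistic:
    def test_all_zero_gene_has_d_zero(self):
        values = np.vstack([np.zeros(4), [1.0, 2.0, 1.5, 2.5]])
        res = de.sam_statistic(values, n_perm=16)
        assert res.loc["g1", "d"] == 0.0

    def test_two_replicates_exhaustive_sign_flip_values(self):
        # single gene, 2 replicates: 4 sign patterns; with the +1
        # correction p lies on the grid (c+1)/5
        res = de.sam_statistic(np.array([[1.0, 1.2]]), n_perm=4)
        assert float(res["p"].iloc[0]) in {0.2, 0.4, 0.6, 0.8, 1.0}

    def test_scaling_preserves_ranking(self, rng):
        values = rng.normal(size=(8, 4)) + np.linspace(0, 2, 8)[:, None]
        a = de.sam_statistic(values, n_perm=16)
        b = de.sam_statistic(values * 2.0, n_perm=16)
        assert list(a.sort_values("d").index) == list(b.sort_values("d").index)

    def test_fixed_s0_requires_value(self, rng):
        with pytest.raises(ValueError):
            de.sam_statistic(rng.normal(size=(3, 3)), s0_rule="fixed")

    def test_planted_gene_detected_with_pooled_null(self, rng):
        values = rng.normal(0, 0.3, size=(100, 4))
        values[0] += 2.0
        res = de.sam_statistic(values, n_perm=16, pool_null=True)
        assert res["p"].iloc[0] <= 0.05
        assert res["p"].iloc[1:].min() > res["p"].iloc[0]


class TestCallDe:
    def test_dual_rule(self):
        rp = {"a": 0.01, "b": 0.04, "c": 0.2}
        sam = {"a": 0.2, "b": 0.05, "c": 0.01}
        sig, table = de.call_de(rp, sam)
        assert sig == {"b"}  # boundary inclusive on both
        assert table.set_index("gene").loc["a", "significant"] == False  # noqa: E712

    def test_empty_input(self):
        sig, table = de.call_de({}, {})
        assert sig == set() and table.empty

    def test_mismatched_universe_raises(self):
        with pytest.raises(ValueError, match="b"):
            de.call_de({"a": 0.1, "b": 0.1}, {"a": 0.1})

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        ps=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=20
        ),
        a1=st.floats(0.001, 0.5),
        a2=st.floats(0.001, 0.5),
    )
    def test_monotone_in_alpha(self, ps, a1, a2):
        lo, hi = sorted([a1, a2])
        rp = {f"g{i}": p[0] for i, p in enumerate(ps)}
        sam = {f"g{i}": p[1] for i, p in enumerate(ps)}
        sig_lo, _ = de.call_de(rp, sam, alpha=lo)
        sig_hi, _ = de.call_de(rp, sam, alpha=hi)
        assert sig_lo <= sig_hi


class TestDeltaCt:
    @pytest.mark.parametrize(
        "target,reference,expected,tol",
        [
            (20.0, 20.0, 1.0, 0),
            (19.0, 20.0, 2.0, 0),
            (23.3219, 20.0, 0.1, 1e-4),
        ],
    )
    def test_closed_form(self, target, reference, expected, tol):
        assert de.delta_ct_relative_expression(target, reference) == pytest.approx(
            expected, abs=tol or 1e-12
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            de.delta_ct_relative_expression(float("nan"), 20.0)


class TestPipeline:
    def test_columns_and_dual_consistency(self, small_config):
        from wsinet.synthetic import CONTRAST_APP, simulate_expression

        sim = simulate_expression(small_config)
        table = de.de_pipeline(sim.matrices[CONTRAST_APP], seed=0, n_perm_rp=50,
                               n_perm_sam=64)
        assert list(table.columns) == [
            "gene", "mean_fc", "rp_up_p", "rp_down_p", "sam_d", "sam_p",
            "significant",
        ]
        rp_two = np.minimum(1, 2 * np.minimum(table.rp_up_p, table.rp_down_p))
        expected = (rp_two <= 0.05) & (table.sam_p <= 0.05)
        assert (table.significant == expected).all()
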
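import math

import numpy as np
import pytest
import scipy.sparse as sp

from telocus.model import (
    ModelParams,
    assign_pools,
    complete_data_log_likelihood,
    e_step,
    fit_em,
    fragment_probability,
    m_step,
    model_selection,
    observed_data_log_likelihood,
)

from conftest import make_weight_matrix, random_weight_matrix


def uniform_params(pools, n_features):
    return ModelParams.uniform(list(pools.pool_ids), n_features)


def params_for(pools, pi_by_name, theta_by_name, matrix):
    """Dense params from {feature_name: value} dicts (single pool)."""
    k1 = matrix.n_features
    pi = np.zeros((1, k1))
    th = np.zeros((1, k1))
    name_to_col = {f: j for j, f in enumerate(matrix.feature_ids)}
    for f, v in pi_by_name.items():
        pi[0, name_to_col[f]] = v
    for f, v in theta_by_name.items():
        th[0, name_to_col[f]] = v
    # pad remaining mass onto an unused column so rows sum to 1
    pi[0, 0] += 1.0 - pi.sum()
    th[0, 0] += 1.0 - th.sum()
    return ModelParams(pool_ids=list(pools.pool_ids), pi=pi, theta=th)


class TestAssignPools:
    def test_pseudobulk(self):
        p = assign_pools(["c1", "c2", "c3"], "pseudobulk")
        assert p.D == 1
        assert len(set(p.cell_to_pool.values())) == 1

    def test_individual(self):
        p = assign_pools(["c1", "c2", "c3"], "individual")
        assert p.D == 3
        assert p.cell_to_pool == {"c1": "c1", "c2": "c2", "c3": "c3"}

    def test_celltype(self):
        p = assign_pools(["c1", "c2", "c3"], "celltype", {"c1": "T", "c2": "T", "c3": "B"})
        assert p.D == 2
        assert p.cell_to_pool == {"c1": "T", "c2": "T", "c3": "B"}

    def test_celltype_missing_label_lists_barcodes(self):
        with pytest.raises(ValueError, match="c3"):
            assign_pools(["c1", "c3"], "celltype", {"c1": "T"})

    def test_celltype_without_labels(self):
        with pytest.raises(ValueError):
            assign_pools(["c1"], "celltype")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            assign_pools(["c1"], "bulk")


class TestFragmentProbability:
    def test_unique_read(self):
        pi = np.array([0.0, 0.4, 0.6])
        th = np.array([1 / 3, 1 / 3, 1 / 3])
        assert fragment_probability(pi, th, {1: 1.0}, y=0) == pytest.approx(0.4)

    def test_symmetric_ambiguous(self):
        pi = np.array([0.0, 0.5, 0.5])
        th = np.array([0.0, 0.5, 0.5])
        assert fragment_probability(pi, th, {1: 1.0, 2: 1.0}, y=1) == pytest.approx(0.5)

    def test_hand_computed(self):
        # 0.6*0.7*1 + 0.4*0.3*0.5 = 0.48
        pi = np.array([0.0, 0.6, 0.4])
        th = np.array([0.0, 0.7, 0.3])
        assert fragment_probability(pi, th, {1: 1.0, 2: 0.5}, y=1) == pytest.approx(0.48)

    def test_empty_row_is_error(self):
        with pytest.raises(ValueError):
            fragment_probability(np.array([1.0]), np.array([1.0]), {}, 0)


class TestEStep:
    def test_unique_read_posterior_one(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        x = e_step(uniform_params(pools, m.n_features), m, pools)
        assert x[0, m.feature_ids.index("A")] == pytest.approx(1.0)

    def test_proportional_to_pi_when_theta_uniform(self):
        m = make_weight_matrix([{"A": 1, "B": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        params = params_for(
            pools, {"A": 0.75, "B": 0.25}, {"A": 0.5, "B": 0.5}, m
        )
        x = e_step(params, m, pools)
        assert x[0, m.feature_ids.index("A")] == pytest.approx(0.75)
        assert x[0, m.feature_ids.index("B")] == pytest.approx(0.25)

    def test_derived_normalization(self):
        # pi=(.5,.5), theta=(.5,.5), q=(1,.5) -> unnormalized (.25,.125) -> (2/3,1/3)
        m = make_weight_matrix([{"A": 1, "B": 0.5}])
        pools = assign_pools(["cellA"], "pseudobulk")
        params = params_for(pools, {"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5}, m)
        x = e_step(params, m, pools)
        assert x[0, m.feature_ids.index("A")] == pytest.approx(2 / 3)
        assert x[0, m.feature_ids.index("B")] == pytest.approx(1 / 3)

    def test_brute_force_oracle_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_frag = int(rng.integers(1, 10))
            n_loci = int(rng.integers(1, 5))  # <=5 features incl NO_FEATURE
            m = random_weight_matrix(rng, n_frag, n_loci, n_cells=2)
            pools = assign_pools(sorted(set(m.barcodes)), "individual")
            pi = rng.dirichlet(np.ones(m.n_features), size=pools.D)
            th = rng.dirichlet(np.ones(m.n_features), size=pools.D)
            params = ModelParams(pool_ids=list(pools.pool_ids), pi=pi, theta=th)
            x = e_step(params, m, pools)
            pidx = pools.pool_index()
            for i in range(n_frag):
                d = pidx[pools.cell_to_pool[m.barcodes[i]]]
                row = m.weights[i].toarray().ravel()
                un = np.zeros_like(row)
                for j in np.flatnonzero(row):
                    un[j] = pi[d, j] * (th[d, j] if m.ambiguous[i] else 1.0) * row[j]
                expected = un / un.sum()
                got = x[i].toarray().ravel()
                assert np.max(np.abs(got - expected)) < 1e-12

    def test_sparsity_pattern_preserved_and_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        m = random_weight_matrix(rng, 30, 6, n_cells=3)
        pools = assign_pools(sorted(set(m.barcodes)), "pseudobulk")
        x = e_step(uniform_params(pools, m.n_features), m, pools)
        assert np.array_equal(x.indices, m.weights.indices)
        assert np.array_equal(x.indptr, m.weights.indptr)
        assert np.allclose(np.asarray(x.sum(axis=1)).ravel(), 1.0)

    def test_zero_probability_row_falls_back_to_q(self, caplog):
        m = make_weight_matrix([{"A": 1, "B": 0.5}])
        pools = assign_pools(["cellA"], "pseudobulk")
        k1 = m.n_features
        pi = np.zeros((1, k1))
        pi[0, 0] = 1.0  # all mass on NO_FEATURE, which the row lacks
        th = np.full((1, k1), 1.0 / k1)
        params = ModelParams(pool_ids=list(pools.pool_ids), pi=pi, theta=th)
        x = e_step(params, m, pools)
        assert x[0, m.feature_ids.index("A")] == pytest.approx(1 / 1.5)


class TestMStep:
    def test_all_certain_on_one_locus(self):
        m = make_weight_matrix([{"A": 1}] * 4)
        pools = assign_pools(["cellA"], "pseudobulk")
        x = e_step(uniform_params(pools, m.n_features), m, pools)
        params = m_step(x, m, pools, pi_prior=0.0, theta_prior=0.0)
        assert params.pi[0, m.feature_ids.index("A")] == pytest.approx(1.0)

    def test_column_sum_update(self):
        # posteriors {A:1}, {A:.5,B:.5} -> pi = (1.5, .5)/2
        m = make_weight_matrix([{"A": 1}, {"A": 1, "B": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        x = m.weights.copy()
        x.data = np.array([1.0, 0.5, 0.5])
        params = m_step(x, m, pools, pi_prior=0.0, theta_prior=0.0)
        assert params.pi[0, m.feature_ids.index("A")] == pytest.approx(0.75)
        assert params.pi[0, m.feature_ids.index("B")] == pytest.approx(0.25)

    def test_huge_theta_prior_gives_uniform_theta(self):
        rng = np.random.default_rng(1)
        m = random_weight_matrix(rng, 25, 5)
        pools = assign_pools(["cell0"], "pseudobulk")
        x = e_step(uniform_params(pools, m.n_features), m, pools)
        params = m_step(x, m, pools, pi_prior=0.0, theta_prior=1e12)
        assert np.allclose(params.theta[0], 1.0 / m.n_features, atol=1e-9)

    def test_empty_pool_uniform_and_flagged(self):
        m = make_weight_matrix([{"A": 1}], barcodes=["c1"])
        pools = assign_pools(["c1", "c2"], "individual")
        x = e_step(uniform_params(pools, m.n_features), m, pools)
        params = m_step(x, m, pools)
        assert "c2" in params.empty_pools
        d = pools.pool_index()["c2"]
        assert np.allclose(params.pi[d], 1.0 / m.n_features)


class TestLogLikelihood:
    def test_certain_read_pi_one(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        k1 = m.n_features
        pi = np.zeros((1, k1))
        pi[0, m.feature_ids.index("A")] = 1.0
        params = ModelParams(
            pool_ids=list(pools.pool_ids), pi=pi, theta=np.full((1, k1), 1 / k1)
        )
        x = e_step(params, m, pools)
        assert complete_data_log_likelihood(params, x, m, pools) == pytest.approx(0.0)

    def test_certain_read_pi_half(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        params = params_for(pools, {"A": 0.5}, {}, m)
        x = e_step(params, m, pools)
        assert complete_data_log_likelihood(params, x, m, pools) == pytest.approx(
            math.log(0.5)
        )

    def test_brute_force_accumulation(self):
        m = make_weight_matrix([{"A": 1, "B": 0.5}, {"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        params = params_for(pools, {"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5}, m)
        x = e_step(params, m, pools)
        # oracle: direct per-term accumulation
        expected = 0.0
        for i in range(2):
            row_q = m.weights[i].toarray().ravel()
            row_x = x[i].toarray().ravel()
            for j in np.flatnonzero(row_x):
                term = params.pi[0, j] * (
                    params.theta[0, j] if m.ambiguous[i] else 1.0
                ) * row_q[j]
                expected += row_x[j] * math.log(term)
        assert complete_data_log_likelihood(params, x, m, pools) == pytest.approx(expected)


class TestFitEM:
    def test_all_unique_reads_empirical_proportions(self):
        rows = [{"A": 1}] * 6 + [{"B": 1}] * 2
        m = make_weight_matrix(rows)
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools, pi_prior=0.0, theta_prior=0.0)
        assert f.iterations <= 2
        assert f.params.pi[0, m.feature_ids.index("A")] == pytest.approx(0.75)
        assert f.params.pi[0, m.feature_ids.index("B")] == pytest.approx(0.25)

    def test_symmetric_instance_symmetric_pi(self):
        rows = [{"A": 1, "B": 1}] * 10
        m = make_weight_matrix(rows)
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools)
        jA, jB = m.feature_ids.index("A"), m.feature_ids.index("B")
        assert f.params.pi[0, jA] == pytest.approx(f.params.pi[0, jB])

    def test_empty_matrix_error(self):
        m = make_weight_matrix([{"A": 1}]).subset_rows(np.array([], dtype=np.int64))
        pools = assign_pools(["cellA"], "pseudobulk")
        with pytest.raises(ValueError):
            fit_em(m, pools)

    def test_monotone_trace_100_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n_frag = int(rng.integers(2, 51))
            n_loci = int(rng.integers(1, 10))
            n_cells = int(rng.integers(1, 5))
            m = random_weight_matrix(rng, n_frag, n_loci, n_cells=n_cells)
            mode = ["individual", "pseudobulk", "celltype"][trial % 3]
            cells = sorted(set(m.barcodes))
            labels = {c: f"t{i % 2}" for i, c in enumerate(cells)} if mode == "celltype" else None
            f = fit_em(m, assign_pools(cells, mode, labels))
            diffs = np.diff(np.array(f.lnL_trace))
            assert np.all(diffs >= -1e-9)

    def test_pool_independence_celltype(self):
        rng = np.random.default_rng(12)
        m = random_weight_matrix(rng, 40, 5, n_cells=4)
        cells = sorted(set(m.barcodes))
        labels = {c: ("A" if i < 2 else "B") for i, c in enumerate(cells)}
        pools = assign_pools(cells, "celltype", labels)
        f1 = fit_em(m, pools)
        # permute pool-A fragments only
        in_a = np.array([labels[b] == "A" for b in m.barcodes])
        perm = np.arange(m.n_fragments)
        a_idx = np.flatnonzero(in_a)
        perm[a_idx] = a_idx[::-1]
        f2 = fit_em(m.subset_rows(perm), pools)
        dB = pools.pool_index()["B"]
        assert np.allclose(f1.params.pi[dB], f2.params.pi[dB], atol=1e-12)
        assert np.allclose(f1.params.theta[dB], f2.params.theta[dB], atol=1e-12)

    def test_pooling_equivalence_one_cell(self):
        rng = np.random.default_rng(3)
        m = random_weight_matrix(rng, 30, 5, n_cells=1)
        cells = sorted(set(m.barcodes))
        f_pb = fit_em(m, assign_pools(cells, "pseudobulk"))
        f_ind = fit_em(m, assign_pools(cells, "individual"))
        assert np.allclose(f_pb.params.pi, f_ind.params.pi, atol=1e-12)
        assert np.allclose(f_pb.params.theta, f_ind.params.theta, atol=1e-12)
        assert np.allclose(f_pb.posterior.toarray(), f_ind.posterior.toarray(), atol=1e-12)

    def test_pooling_equivalence_single_label(self):
        rng = np.random.default_rng(5)
        m = random_weight_matrix(rng, 40, 6, n_cells=3)
        cells = sorted(set(m.barcodes))
        f_pb = fit_em(m, assign_pools(cells, "pseudobulk"))
        f_ct = fit_em(m, assign_pools(cells, "celltype", {c: "only" for c in cells}))
        assert np.allclose(f_pb.params.pi, f_ct.params.pi, atol=1e-12)
        assert np.allclose(f_pb.params.theta, f_ct.params.theta, atol=1e-12)
        assert np.allclose(f_pb.posterior.toarray(), f_ct.posterior.toarray(), atol=1e-12)

    def test_fixed_point_is_grid_maximum(self):
        # two loci, three fragments: exhaustive grid over pi confirms the EM
        # fixed point maximizes the observed-data objective (theta pinned
        # uniform by a huge prior; pi constrained to the {A,B} simplex edge)
        m = make_weight_matrix([{"A": 1, "B": 0.8}, {"A": 0.6, "B": 1}, {"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools, pi_prior=0.0, theta_prior=1e12, tol=1e-13, max_iter=2000)
        k1 = m.n_features
        jA, jB = m.feature_ids.index("A"), m.feature_ids.index("B")

        def objective(pa):
            pi = np.zeros((1, k1))
            pi[0, jA], pi[0, jB] = pa, 1.0 - pa
            params = ModelParams(
                pool_ids=list(pools.pool_ids), pi=pi, theta=np.full((1, k1), 1 / k1)
            )
            return observed_data_log_likelihood(params, m, pools)

        grid_best = max(objective(p) for p in np.arange(0.001, 1.0, 0.001))
        fitted_val = objective(f.params.pi[0, jA] / (f.params.pi[0, jA] + f.params.pi[0, jB]))
        assert fitted_val >= grid_best - 1e-6

    def test_k_and_n_bookkeeping(self):
        m = make_weight_matrix(
            [{"A": 1}, {"A": 1, "B": 1}, {"C": 1}],
            barcodes=["c1", "c1", "c2"],
        )
        pools = assign_pools(["c1", "c2"], "individual")
        f = fit_em(m, pools)
        # pool c1 observes {A, B}; pool c2 observes {C}: k = 2*(2 + 1)
        assert f.k == 6
        assert f.n == 3


class TestModelSelection:
    def test_hand_computed_example(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools)
        f.k, f.n, f.lnL = 2, 100, -50.0
        bic, aic = model_selection(f)
        assert bic == pytest.approx(2 * math.log(100) + 100)
        assert bic == pytest.approx(109.2103403719, abs=1e-9)
        assert aic == pytest.approx(104.0)

    def test_degenerate_k_zero(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools)
        f.k, f.lnL = 0, -7.5
        bic, aic = model_selection(f)
        assert bic == aic == pytest.approx(15.0)

    def test_monotone_in_lnL(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools)
        f.k, f.n = 4, 50
        f.lnL = -10.0
        b1, a1 = model_selection(f)
        f.lnL = -5.0
        b2, a2 = model_selection(f)
        assert b2 < b1 and a2 < a1

    def test_zero_observations_error(self):
        m = make_weight_matrix([{"A": 1}])
        pools = assign_pools(["cellA"], "pseudobulk")
        f = fit_em(m, pools)
        f.n = 0
        with pytest.raises(ValueError):
            model_selection(f)
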
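import numpy as np
import pandas as pd
import pytest

from trflpdyn import (
    chi_square_standardize,
    fit_cca,
    forward_select,
    permutation_test,
    planted_driver_scenario,
    simulate_campaign,
)


def random_table(rng, n=6, m=4):
    """Strictly positive random abundance table (no zero rows/columns)."""
    return rng.uniform(0.5, 10.0, size=(n, m))


def brute_force_Q(Y):
    """Independent chi-square standardization via explicit loops."""
    Y = np.asarray(Y, dtype=float)
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = np.zeros_like(P)
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            Q[i, j] = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    return Q, r, c


class TestChiSquareStandardize:
    def test_independent_table_has_zero_inertia(self):
        rows = np.array([0.2, 0.5, 0.3])
        cols = np.array([10.0, 30.0, 40.0, 20.0])
        Y = np.outer(rows, cols)
        Q, _, _ = chi_square_standardize(Y)
        assert np.abs(Q).max() < 1e-12

    def test_perfect_2x2_association_has_inertia_one(self):
        Q, _, _ = chi_square_standardize(np.array([[10.0, 0.0], [0.0, 10.0]]))
        assert (Q**2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_weighted_centering_identity(self, rng):
        Y = random_table(rng)
        Q, r, _ = chi_square_standardize(Y)
        colsums = np.sqrt(r) @ Q
        assert np.abs(colsums).max() < 1e-12

    def test_matches_brute_force(self, rng):
        Y = random_table(rng)
        Q, r, c = chi_square_standardize(Y)
        Qb, rb, cb = brute_force_Q(Y)
        assert np.allclose(Q, Qb, atol=1e-14)
        assert np.allclose(r, rb) and np.allclose(c, cb)

    def test_zero_row_named(self):
        Y = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="row"):
            chi_square_standardize(Y)


class TestFitCCA:
    def test_constant_constraint_explains_nothing(self, rng):
        Y = random_table(rng)
        X = np.ones((6, 1))
        with pytest.warns(UserWarning, match="constant"):
            res = fit_cca(Y, X)
        assert res.constrained_inertia == 0.0
        assert res.n_axes == 0
        assert res.residual_inertia == pytest.approx(res.total_inertia)

    def test_full_rank_constraints_recover_unconstrained_ca(self, rng):
        Y = random_table(rng)
        X = rng.standard_normal((6, 5))  # spans the sample space (with intercept)
        res = fit_cca(Y, X, vif_threshold=None)
        Q, _, _ = brute_force_Q(Y)
        ca_eig = np.linalg.svd(Q, compute_uv=False) ** 2
        k = res.n_axes
        assert np.allclose(res.eigenvalues, ca_eig[:k], atol=1e-8)
        assert res.constrained_inertia == pytest.approx((Q**2).sum(), abs=1e-8)

    def test_inertia_conservation(self, rng):
        for _ in range(10):
            Y = random_table(rng)
            X = rng.standard_normal((6, 2))
            res = fit_cca(Y, X)
            assert (
                abs(res.constrained_inertia + res.residual_inertia - res.total_inertia)
                < 1e-9
            )

    def test_affine_rescaling_of_constraints_is_invariant(self, rng):
        Y = random_table(rng, n=8)
        X = rng.standard_normal((8, 3))
        X2 = X * np.array([2.0, -5.0, 0.1]) + np.array([1.0, -3.0, 10.0])
        a = fit_cca(Y, X)
        b = fit_cca(Y, X2)
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        assert np.allclose(
            np.abs(a.species_scores.to_numpy()),
            np.abs(b.species_scores.to_numpy()),
            atol=1e-8,
        )

    def test_site_scores_weighted_orthogonal_across_axes(self, rng):
        Y = random_table(rng, n=10, m=5)
        X = rng.standard_normal((10, 3))
        res = fit_cca(Y, X)
        _, r, _ = chi_square_standardize(Y)
        S = res.site_scores.to_numpy()
        G = (S * r[:, None]).T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-10

    def test_collinear_column_dropped_with_warning(self, rng):
        Y = random_table(rng)
        x = rng.standard_normal(6)
        X = pd.DataFrame({"a": x, "b": 2.0 * x, "c": rng.standard_normal(6)})
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_cca(Y, X)
        assert len(res.dropped_variables) == 1

    def test_matches_skbio_eigenvalues(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        Y = pd.DataFrame(
            random_table(rng, n=10, m=5),
            index=[f"s{i}" for i in range(10)],
            columns=[f"b{j}" for j in range(5)],
        )
        X = pd.DataFrame(
            rng.standard_normal((10, 3)),
            index=Y.index,
            columns=["x1", "x2", "x3"],
        )
        ours = fit_cca(Y, X)
        theirs = skbio_ord.cca(Y, X)
        k = ours.n_axes
        assert np.allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-8
        )


class TestPermutationTest:
    def test_minimum_p_with_499_permutations(self):
        sc = planted_driver_scenario(seed=0)
        env, series, _ = simulate_campaign(sc)
        X = env.set_index("sample_id")[["temperature"]]
        p = permutation_test(series.matrix(), X, n_perm=499, seed=5)
        assert p == pytest.approx(1 / 500)

    def test_reproducible_from_seed(self, rng):
        Y = random_table(rng, n=12, m=4)
        X = rng.standard_normal((12, 3))
        p1 = permutation_test(Y, X, n_perm=199, seed=7)
        p2 = permutation_test(Y, X, n_perm=199, seed=7)
        assert p1 == p2

    def test_first_axis_statistic_differs_from_trace(self, rng):
        Y = random_table(rng, n=12, m=5)
        X = rng.standard_normal((12, 4))
        # both run without error and give valid probabilities
        for stat in ("trace", "first"):
            p = permutation_test(Y, X, statistic=stat, n_perm=99, seed=3)
            assert 0 < p <= 1


class TestForwardSelect:
    def test_planted_driver_recovered(self):
        sc = planted_driver_scenario(seed=123)
        env, series, _ = simulate_campaign(sc)
        X = env.set_index("sample_id").drop(columns=["time_days"])
        trace = forward_select(series.matrix(), X, seed=99)
        assert trace.included[0] == "temperature"

    def test_pure_noise_usually_selects_nothing(self, rng):
        Y = rng.dirichlet(np.ones(3) * 2, size=20)
        empty_rounds = 0
        for s in range(10):
            X = np.random.default_rng(s).standard_normal((20, 3))
            trace = forward_select(Y, X, seed=s, n_perm=199)
            if not trace.included:
                empty_rounds += 1
        assert empty_rounds >= 7  # alpha=0.05, 3 candidates

    def test_duplicate_of_included_variable_never_included(self):
        sc = planted_driver_scenario(seed=42)
        env, series, _ = simulate_campaign(sc)
        X = env.set_index("sample_id").drop(columns=["time_days"])
        X = X.assign(temperature_copy=X["temperature"])
        with pytest.warns(UserWarning, match="collinear"):
            trace = forward_select(series.matrix(), X, seed=4)
        assert "temperature_copy" not in trace.included
        # the copy adds no inertia wherever it appears in the trace
        rows = trace.rows[trace.rows.variable == "temperature_copy"]
        assert rows.empty or (rows.added_inertia < 1e-10).all()

    def test_trace_reports_every_candidate_once(self):
        sc = planted_driver_scenario(seed=7)
        env, series, _ = simulate_campaign(sc)
        X = env.set_index("sample_id").drop(columns=["time_days"])
        trace = forward_select(series.matrix(), X, seed=11)
        assert sorted(trace.rows.variable) == sorted(X.columns)
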
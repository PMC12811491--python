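"""Regularized PLS engine: thresholding, weight pairs, deflation, selection."""

import numpy as np
import pytest

import tnmpls.pls as pls
from tnmpls.pls import (
    RegularizationSpec,
    TripleNetworkPLS,
    cross_covariance,
    deflate,
    fit_rpls,
    leading_pair,
    select_lambda_c,
    select_lambda_p,
    soft_threshold_unit,
    sparse_pair,
    standardize_domains,
)


class TestStandardizeDomains:
    def test_columns_standardized(self, rng):
        C, P = standardize_domains(rng.uniform(0, 5, (20, 7)), rng.uniform(-3, 3, (20, 4)))
        for X in (C, P):
            assert np.allclose(X.mean(axis=0), 0, atol=1e-10)
            assert np.allclose(X.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_idempotent(self, rng):
        C, P = standardize_domains(rng.standard_normal((15, 5)), rng.standard_normal((15, 3)))
        C2, P2 = standardize_domains(C, P)
        assert np.allclose(C2, C, atol=1e-10) and np.allclose(P2, P, atol=1e-10)

    def test_constant_column_named(self, rng):
        C = rng.standard_normal((10, 4))
        C[:, 2] = 7.0
        with pytest.raises(ValueError, match=r"constant connectivity column.*\[2\]"):
            standardize_domains(C, rng.standard_normal((10, 3)))


class TestCrossCovariance:
    def test_identical_column_gives_unit_entry(self, rng):
        x = rng.standard_normal(30)
        C, P = standardize_domains(
            np.column_stack([x, rng.standard_normal(30)]),
            np.column_stack([x, rng.standard_normal(30)]),
        )
        M = cross_covariance(C, P)
        assert M[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_elementwise_formula(self, rng):
        C = rng.standard_normal((3, 4))
        P = rng.standard_normal((3, 2))
        M = cross_covariance(C, P)
        for i in range(4):
            for j in range(2):
                assert M[i, j] == pytest.approx(np.dot(C[:, i], P[:, j]) / 2, abs=1e-12)

    def test_independent_columns_vanish(self, rng):
        n = 4000
        C, P = standardize_domains(rng.standard_normal((n, 3)), rng.standard_normal((n, 3)))
        assert np.max(np.abs(cross_covariance(C, P))) < 3 / np.sqrt(n)


def power_iteration_pair(M, n_iter=2000):
    """Independent oracle: power iteration on M M^T for the leading pair."""
    v = np.ones(M.shape[0]) / np.sqrt(M.shape[0])
    for _ in range(n_iter):
        v = M @ (M.T @ v)
        v /= np.linalg.norm(v)
    u = M.T @ v
    return v, u / np.linalg.norm(u)


class TestLeadingPair:
    def test_diagonal_matrix(self):
        wc, wp = leading_pair(np.diag([3.0, 1.0]))
        assert np.allclose(np.abs(wc), [1, 0], atol=1e-12)
        assert np.allclose(np.abs(wp), [1, 0], atol=1e-12)
        assert wc @ np.diag([3.0, 1.0]) @ wp == pytest.approx(3.0)

    def test_rank_one(self, rng):
        u = rng.standard_normal(5)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        wc, wp = leading_pair(np.outer(u, v))
        assert abs(wc @ u) == pytest.approx(1.0, abs=1e-10)
        assert abs(wp @ v) == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_power_iteration(self, rng):
        M = rng.standard_normal((5, 3))
        wc, wp = leading_pair(M)
        wc_o, wp_o = power_iteration_pair(M)
        assert abs(abs(wc @ wc_o) - 1) < 1e-8
        assert abs(abs(wp @ wp_o) - 1) < 1e-8

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            leading_pair(np.zeros((3, 2)))


def grid_threshold_oracle(v, lam, n_grid=2_000_001):
    """Fine delta-grid oracle for the soft-threshold unit-norm projection."""
    a = np.abs(v)
    for delta in np.linspace(0.0, a.max(), n_grid):
        s = np.sign(v) * np.maximum(a - delta, 0)
        norm = np.linalg.norm(s)
        if norm > 0 and np.linalg.norm(s, 1) / norm <= lam:
            return s / norm
    j = np.argmax(a)
    out = np.zeros_like(v)
    out[j] = np.sign(v[j])
    return out


class TestSoftThresholdUnit:
    def test_inactive_constraint(self, rng):
        v = rng.standard_normal(6)
        lam = np.linalg.norm(v, 1) / np.linalg.norm(v) + 0.01
        w = soft_threshold_unit(v, lam)
        assert np.allclose(w, v / np.linalg.norm(v), atol=1e-12)

    def test_lambda_one_single_coordinate(self, rng):
        v = rng.standard_normal(10)
        w = soft_threshold_unit(v, 1.0)
        assert np.count_nonzero(w) == 1
        j = np.argmax(np.abs(v))
        assert w[j] == pytest.approx(np.sign(v[j]))

    def test_matches_fine_grid_oracle(self):
        v = np.array([3.0, 2.0, 1.0])
        w = soft_threshold_unit(v, 1.2)
        assert np.allclose(w, grid_threshold_oracle(v, 1.2), atol=1e-6)

    @pytest.mark.parametrize("lam", [1.0, 1.3, 1.8, 2.2])
    def test_norm_and_budget_invariants(self, lam, rng):
        for _ in range(5):
            v = rng.standard_normal(8)
            w = soft_threshold_unit(v, lam)
            assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(w, 1) <= lam + 1e-8


def constrained_sphere_oracle(M, lam_c, lam_p, n_samples=40_000, seed=7):
    """Brute-force maximum of w_c^T M w_p over the L1-capped unit spheres.

    Candidates are random unit vectors pushed onto the constraint set by
    soft thresholding at random levels (independent of the fitted path).
    """
    rng = np.random.default_rng(seed)

    def candidates(dim, lam):
        g = rng.standard_normal((n_samples, dim))
        delta = rng.uniform(0, 1, (n_samples, 1)) * np.abs(g).max(axis=1, keepdims=True)
        s = np.sign(g) * np.maximum(np.abs(g) - delta, 0)
        norms = np.linalg.norm(s, axis=1)
        ok = norms > 0
        s = s[ok] / norms[ok, None]
        keep = np.linalg.norm(s, 1, axis=1) <= lam + 1e-9
        return s[keep]

    A = candidates(M.shape[0], lam_c)
    B = candidates(M.shape[1], lam_p)
    X = A @ M
    best = -np.inf
    for start in range(0, B.shape[0], 256):  # chunked to bound memory
        best = max(best, float(np.max(X @ B[start:start + 256].T)))
    return best


class TestSparsePair:
    def test_max_budgets_reduce_to_svd(self, rng):
        for _ in range(5):
            M = rng.standard_normal((6, 4))
            spec = RegularizationSpec(np.sqrt(6), np.sqrt(4))
            wc, wp, conv = sparse_pair(M, spec)
            wc0, wp0 = leading_pair(M)
            assert conv
            assert np.allclose(wc, wc0, atol=1e-6)
            assert np.allclose(wp, wp0, atol=1e-6)

    def test_lambda_p_one_single_feature(self, rng):
        M = rng.standard_normal((10, 8))
        _, wp, _ = sparse_pair(M, RegularizationSpec(np.sqrt(10), 1.0))
        assert np.count_nonzero(wp) == 1

    @pytest.mark.parametrize("lam_c,lam_p", [(1.4, 1.2), (1.8, 1.5)])
    def test_objective_matches_brute_force(self, lam_c, lam_p, rng):
        M = rng.standard_normal((4, 3))
        wc, wp, _ = sparse_pair(M, RegularizationSpec(lam_c, lam_p))
        achieved = wc @ M @ wp
        oracle = constrained_sphere_oracle(M, lam_c, lam_p)
        assert achieved >= oracle - 1e-3

    def test_budget_invariants(self, rng):
        M = rng.standard_normal((12, 8))
        spec = RegularizationSpec(2.0, 1.5)
        wc, wp, _ = sparse_pair(M, spec)
        assert np.linalg.norm(wc) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(wp) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(wc, 1) <= 2.0 + 1e-8
        assert np.linalg.norm(wp, 1) <= 1.5 + 1e-8

    def test_sign_convention(self, rng):
        M = rng.standard_normal((6, 4))
        wc, wp, _ = sparse_pair(M, RegularizationSpec(1.8, 1.5))
        assert wc @ M @ wp >= 0
        assert wp[np.argmax(np.abs(wp))] > 0


class TestDeflate:
    def test_scores_removed(self, rng):
        C = rng.standard_normal((10, 6))
        P = rng.standard_normal((10, 4))
        phi, psi = C[:, 0].copy(), P[:, 1].copy()
        C1, P1 = deflate(C, P, phi, psi)
        assert np.allclose(phi @ C1, 0, atol=1e-10)
        assert np.allclose(psi @ P1, 0, atol=1e-10)

    def test_idempotent(self, rng):
        C = rng.standard_normal((8, 5))
        P = rng.standard_normal((8, 3))
        phi, psi = rng.standard_normal(8), rng.standard_normal(8)
        C1, P1 = deflate(C, P, phi, psi)
        C2, P2 = deflate(C1, P1, phi, psi)
        assert np.allclose(C1, C2, atol=1e-12) and np.allclose(P1, P2, atol=1e-12)

    def test_rank_drops_by_one(self, rng):
        C = rng.standard_normal((6, 4))
        phi = C @ rng.standard_normal(4)  # latent scores lie in the column space
        C1, _ = deflate(C, C.copy(), phi, phi)
        rank = lambda X: np.sum(np.linalg.svd(X, compute_uv=False) > 1e-10)
        assert rank(C) == 4
        assert rank(C1) == 3

    def test_zero_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            deflate(np.ones((4, 3)), np.ones((4, 2)), np.zeros(4), np.ones(4))


class TestFitRPLS:
    def make_domains(self, rng, n=30, E=40, p=8):
        C, P = standardize_domains(rng.standard_normal((n, E)), rng.standard_normal((n, p)))
        return C, P

    def test_first_component_pct_cov_100_and_k_components(self, rng):
        C, P = self.make_domains(rng)
        res = fit_rpls(C, P, RegularizationSpec(3.0, 2.0), k=4)
        assert res.k == 4
        assert res.components[0].pct_cov == pytest.approx(100.0)

    def test_cov_score_equals_top_singular_value_unregularized(self, rng):
        C, P = self.make_domains(rng)
        res = fit_rpls(C, P, RegularizationSpec(np.sqrt(40), np.sqrt(8)), k=1)
        sigma1 = np.linalg.svd(cross_covariance(C, P), compute_uv=False)[0]
        assert res.components[0].cov_score == pytest.approx(sigma1, abs=1e-8)

    def test_score_orthogonality_across_components(self, rng):
        C, P = self.make_domains(rng)
        res = fit_rpls(C, P, RegularizationSpec(4.0, 2.0), k=4)
        for a in range(4):
            for b in range(a + 1, 4):
                ca, cb = res.components[a], res.components[b]
                assert abs(ca.phi @ cb.phi) < 1e-6 * np.linalg.norm(ca.phi) * np.linalg.norm(cb.phi)
                assert abs(ca.psi @ cb.psi) < 1e-6 * np.linalg.norm(ca.psi) * np.linalg.norm(cb.psi)

    def test_k_bound_enforced(self, rng):
        C, P = self.make_domains(rng, n=12)
        with pytest.raises(ValueError, match="k="):
            fit_rpls(C, P, RegularizationSpec(2.0, 2.0), k=9)

    def test_null_cov_score_below_planted(self, small_spec, small_cohort):
        """Independent-noise domains carry far less component-1 covariance
        than the planted cohort at matching dimensions."""
        from tnmpls import assemble_phenotypes, vectorize

        rows, conns, truth = small_cohort
        P = assemble_phenotypes(rows).values
        C = np.vstack([vectorize(fc, truth.mask).values for fc in conns])
        Cs, Ps = standardize_domains(C, P)
        spec = RegularizationSpec(np.sqrt(C.shape[1]), np.sqrt(8))
        planted_cov = fit_rpls(Cs, Ps, spec, k=1).components[0].cov_score
        null_covs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            Cn, Pn = standardize_domains(
                g.standard_normal(C.shape), g.standard_normal(P.shape)
            )
            null_covs.append(fit_rpls(Cn, Pn, spec, k=1).components[0].cov_score)
        assert planted_cov > max(null_covs)


class TestLambdaSelection:
    def make_instance(self, rng, n=25, E=10):
        return standardize_domains(rng.standard_normal((n, E)), rng.standard_normal((n, 8)))

    def test_nonzero_count_nondecreasing_in_lambda(self, rng):
        C, P = self.make_instance(rng)
        M = cross_covariance(C, P)
        counts = []
        for lam in np.geomspace(1, np.sqrt(10), 12):
            wc, _, _ = sparse_pair(M, RegularizationSpec(lam, np.sqrt(8)))
            counts.append(np.count_nonzero(wc))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_target_one_keeps_every_coefficient(self, rng):
        C, P = self.make_instance(rng)
        lam = select_lambda_c(C, P, target_fraction=1.0)
        M = cross_covariance(C, P)
        wc, _, _ = sparse_pair(M, RegularizationSpec(lam, np.sqrt(8)))
        assert np.count_nonzero(wc) == 10

    def test_matches_independent_grid_search(self, rng):
        """Selection agrees with an independently coded grid search at the
        same resolution (closest nonzero fraction, ties to the smaller,
        i.e. more strongly regularizing, budget)."""
        C, P = self.make_instance(rng)
        lam = select_lambda_c(C, P, target_fraction=0.5, n_grid=500)
        M = cross_covariance(C, P)
        best_lam, best_gap = None, np.inf
        for l in np.geomspace(1, np.sqrt(10), 500):
            wc, _, _ = sparse_pair(M, RegularizationSpec(l, np.sqrt(8)))
            gap = abs(np.count_nonzero(wc) / 10 - 0.5)
            if gap < best_gap - 1e-15:
                best_gap, best_lam = gap, l
        assert lam == pytest.approx(best_lam, rel=1e-12)

    def test_lambda_p_definitional(self, rng):
        C, P = self.make_instance(rng, E=30)
        lam = select_lambda_p(C, P, max_features=3)
        grid = np.geomspace(1, np.sqrt(8), 100)
        M = cross_covariance(C, P)
        lam_c = np.sqrt(30)

        def nnz(l):
            _, wp, _ = sparse_pair(M, RegularizationSpec(lam_c, l))
            return np.count_nonzero(wp)

        assert nnz(lam) <= 3
        larger = grid[grid > lam + 1e-12]
        if larger.size:
            assert nnz(larger[0]) > 3

    def test_max_features_one_feasible_at_unit_budget(self, rng):
        C, P = self.make_instance(rng)
        lam = select_lambda_p(C, P, max_features=1)
        M = cross_covariance(C, P)
        _, wp, _ = sparse_pair(M, RegularizationSpec(np.sqrt(10), lam))
        assert np.count_nonzero(wp) == 1


class TestModelResults:
    def test_model_fit_recovers_planted_component(self, small_cohort):
        from tnmpls import assemble_phenotypes, vectorize

        rows, conns, truth = small_cohort
        P = assemble_phenotypes(rows)
        C = np.vstack([vectorize(fc, truth.mask).values for fc in conns])
        res = TripleNetworkPLS(C, P, edge_mask=truth.mask).fit(k=2)
        assert abs(res.components[0].wp @ truth.wp[0]) >= 0.9
        assert "/" in res.component_name(0)

    def test_serialization_round_trip_fields(self, small_cohort, tmp_path):
        import json

        from tnmpls import assemble_phenotypes, vectorize

        rows, conns, truth = small_cohort
        P = assemble_phenotypes(rows)
        C = np.vstack([vectorize(fc, truth.mask).values for fc in conns])
        res = TripleNetworkPLS(C, P, edge_mask=truth.mask).fit(
            k=2, lambda_c=4.0, lambda_p=1.5
        )
        res.save_json(tmp_path / "model.json")
        data = json.loads((tmp_path / "model.json").read_text())
        assert data["lambda_c"] == 4.0
        assert len(data["components"]) == 2
        comp = data["components"][0]
        wc = np.zeros(comp["wc_length"])
        for idx, val in comp["wc_sparse"].items():
            wc[int(idx)] = val
        assert np.allclose(wc, res.components[0].wc)
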
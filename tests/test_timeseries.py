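"""Tests of DTW alignment, delay curves, PCA-95, AR-HMM fitting, and the
state-usage comparison."""

import numpy as np
import pytest

from selfee.synthetic import generate_arhmm_series
from selfee.timeseries import (
    ARHMMParams,
    compare_usages,
    delay_curve,
    dtw_align,
    fit_arhmm,
    fit_pca_95,
    state_usages,
)


def _brute_force_dtw(d):
    """Recursive-with-memo DP oracle for the symmetric (1,2,1) pattern."""
    import functools

    n, m = d.shape

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return 2 * d[0, 0]
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1) + 2 * d[i, j])
        if i > 0:
            best = min(best, rec(i - 1, j) + d[i, j])
        if j > 0:
            best = min(best, rec(i, j - 1) + d[i, j])
        return best

    import sys

    sys.setrecursionlimit(100_000)
    return rec(n - 1, m - 1)


class TestDTW:
    def test_identical_series_diagonal_zero_cost(self, rng):
        x = rng.normal(size=(30, 4))
        path = dtw_align(x, x)
        assert path.cost == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(path.pairs, np.stack([np.arange(30)] * 2, axis=1))

    def test_reverse_then_restore_same_as_identity(self, rng):
        x = rng.normal(size=(25, 3))
        restored = x[::-1][::-1]
        path = dtw_align(restored, x)
        assert path.cost == pytest.approx(0.0, abs=1e-9)

    def test_endpoints_and_monotonicity(self, rng):
        q = rng.normal(size=(20, 3))
        r = rng.normal(size=(28, 3))
        path = dtw_align(q, r)
        assert tuple(path.pairs[0]) == (0, 0)
        assert tuple(path.pairs[-1]) == (19, 27)
        assert np.all(np.diff(path.pairs[:, 0]) >= 0)
        assert np.all(np.diff(path.pairs[:, 1]) >= 0)

    def test_shift_recovered_in_delay_curve(self, rng):
        # query runs 10 frames ahead of the reference
        base = np.cumsum(rng.normal(size=(90, 3)), axis=0)
        shift = 10
        query = base[shift:]
        reference = base[:-shift]
        path = dtw_align(query, reference)
        delays = delay_curve(path, n_reference=len(reference))
        interior = delays[15:-15]
        assert np.abs(np.median(interior) - (-shift)) <= 1 or \
            np.abs(np.median(interior) + shift) <= 1

    @pytest.mark.parametrize("metric,n,m", [("cosine", 20, 25), ("absolute", 15, 15),
                                            ("cosine", 40, 30)])
    def test_matches_brute_force_dp(self, rng, metric, n, m):
        if metric == "cosine":
            q = rng.normal(size=(n, 4))
            r = rng.normal(size=(m, 4))
            from selfee.timeseries import _local_cost_matrix

            d = _local_cost_matrix(q, r, metric)
        else:
            q = rng.normal(size=n)
            r = rng.normal(size=m)
            from selfee.timeseries import _local_cost_matrix

            d = _local_cost_matrix(q, r, metric)
        path = dtw_align(q, r, metric=metric)
        assert path.cost == pytest.approx(_brute_force_dtw(d), abs=1e-9)

    def test_empty_series_rejected(self, rng):
        with pytest.raises(ValueError):
            dtw_align(rng.normal(size=(1, 3)), rng.normal(size=(5, 3)))


class TestDelayCurve:
    def test_identical_series_zero_delay(self, rng):
        x = rng.normal(size=(30, 3))
        path = dtw_align(x, x)
        assert np.allclose(delay_curve(path, 30), 0.0)

    def test_sign_flips_when_swapped(self, rng):
        base = np.cumsum(rng.normal(size=(80, 3)), axis=0)
        q, r = base[8:], base[:-8]
        d_qr = delay_curve(dtw_align(q, r), len(r))
        d_rq = delay_curve(dtw_align(r, q), len(q))
        assert np.sign(np.median(d_qr[10:-10])) == -np.sign(np.median(d_rq[10:-10]))


class TestPCA95:
    def test_one_dimensional_data(self, rng):
        x = rng.normal(size=(20, 1))
        assert fit_pca_95(x).n_components == 1

    def test_variance_99_1_keeps_one_component(self, rng):
        n = 4000
        x = np.zeros((n, 2))
        x[:, 0] = rng.normal(scale=np.sqrt(99), size=n)
        x[:, 1] = rng.normal(scale=1.0, size=n)
        proj = fit_pca_95(x)
        assert proj.n_components == 1

    def test_threshold_is_95_percent(self, rng):
        # isotropic data: every component carries 1/d, so 95% needs
        # ceil(0.95 * d) components (up to sampling noise)
        d = 10
        x = rng.normal(size=(5000, d))
        proj = fit_pca_95(x)
        assert proj.n_components == int(np.ceil(0.95 * d))

    def test_transform_applies_control_projection(self, rng):
        control = rng.normal(size=(100, 5)) * np.array([10, 3, 0.1, 0.05, 0.01])
        proj = fit_pca_95(control)
        other = rng.normal(size=(7, 5))
        assert proj.transform(other).shape == (7, proj.n_components)


def _two_state_params(noise=0.05):
    A = np.stack([np.diag([0.9, 0.5, 0.2]), np.diag([-0.3, 0.8, -0.5])])
    b = np.array([[1.0, -0.5, 0.2], [-1.0, 0.8, 0.1]])
    sigma = np.stack([noise * np.eye(3)] * 2)
    tm = np.array([[0.97, 0.03], [0.04, 0.96]])
    return ARHMMParams(A=A, b=b, sigma=sigma, transition=tm,
                       initial=np.array([0.5, 0.5]), lag=1)


def _match_states(true_states, est_states, k):
    import itertools

    best = -1
    for perm in itertools.permutations(range(k)):
        mapped = np.array(perm)[est_states]
        best = max(best, np.mean(mapped == true_states))
    return best


class TestARHMM:
    def test_k1_reduces_to_least_squares(self, rng):
        x = np.cumsum(rng.normal(size=(300, 2)), axis=0) * 0.1
        res = fit_arhmm([x], K=1, lag=1, n_iter=5, seed=0, n_restarts=1)
        # ordinary least-squares AR(1) fit of the pooled data
        design = np.concatenate([x[:-1], np.ones((299, 1))], axis=1)
        coef, *_ = np.linalg.lstsq(design, x[1:], rcond=None)
        assert np.allclose(res.params.A[0], coef[:-1].T, atol=1e-3)
        assert np.allclose(res.params.b[0], coef[-1], atol=1e-3)

    def test_loglik_monotone_nondecreasing(self):
        params = _two_state_params()
        x, _ = generate_arhmm_series(params, 1500, seed=1)
        res = fit_arhmm([x], K=2, lag=1, n_iter=25, seed=0, n_restarts=1)
        diffs = np.diff(res.log_likelihoods)
        assert np.all(diffs > -1e-6 * np.abs(res.log_likelihoods[:-1]))

    def test_two_state_recovery(self):
        params = _two_state_params()
        x, true_states = generate_arhmm_series(params, 6000, seed=3)
        res = fit_arhmm([x], K=2, lag=1, n_iter=40, seed=0, n_restarts=2)
        est = res.state_sequences[0]
        agreement = _match_states(true_states, est, 2)
        assert agreement > 0.95
        # transition probabilities within +/-0.05 after permutation matching
        import itertools

        errs = []
        for perm in itertools.permutations(range(2)):
            p = np.array(perm)
            tm = res.params.transition[np.ix_(np.argsort(p), np.argsort(p))]
            errs.append(np.max(np.abs(tm - params.transition)))
        assert min(errs) < 0.05

    def test_zero_noise_exact_ar_recovery(self):
        # single state, negligible noise, slowly decaying oscillatory
        # dynamics (so the regression stays well conditioned): the AR
        # matrix is recovered essentially exactly
        th = 0.7
        A = np.array([[[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]]) * 0.999
        params = ARHMMParams(A=A, b=np.array([[0.3, -0.2]]),
                             sigma=np.stack([1e-16 * np.eye(2)]),
                             transition=np.array([[1.0]]),
                             initial=np.array([1.0]), lag=1)
        x, _ = generate_arhmm_series(params, 500, seed=0)
        res = fit_arhmm([x], K=1, lag=1, n_iter=5, seed=0, n_restarts=1,
                        ridge=1e-14)
        assert np.linalg.norm(res.params.A[0] - A[0]) < 1e-6

    def test_usages_simplex(self):
        params = _two_state_params()
        series = [generate_arhmm_series(params, 800, seed=s)[0] for s in range(3)]
        res = fit_arhmm(series, K=2, lag=1, n_iter=15, seed=0, n_restarts=1)
        assert res.usages.shape[0] == 3
        assert np.allclose(res.usages.sum(axis=1), 1.0)
        assert np.all(res.usages >= 0)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_arhmm([rng.normal(size=(30, 2))], K=10, lag=1, n_iter=2, seed=0)


class TestUsageComparison:
    def test_identical_groups_q_one(self, rng):
        usages = rng.dirichlet(np.ones(4), size=6)
        res = compare_usages(usages, usages)
        assert np.all(res.q_values == pytest.approx(1.0))

    def test_shifted_state_detected(self, rng):
        # usage of state 0 shifted by 0.3 between groups of n=17
        a = rng.dirichlet(np.ones(4) * 20, size=17)
        b = a.copy()
        b[:, 0] += 0.3
        b /= b.sum(axis=1, keepdims=True)
        res = compare_usages(a, b)
        assert res.q_values[0] < 0.05

    def test_bh_preserves_p_order(self, rng):
        a = rng.dirichlet(np.ones(5), size=8)
        b = rng.dirichlet(np.ones(5), size=8)
        res = compare_usages(a, b)
        order = np.argsort(res.p_values)
        assert np.all(np.diff(res.q_values[order]) >= -1e-12)

    def test_state_usages_helper(self):
        u = state_usages(np.array([0, 0, 1, 2, 2, 2]), 4)
        assert np.allclose(u, [2 / 6, 1 / 6, 3 / 6, 0.0])
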
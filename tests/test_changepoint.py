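"""Change-point module tests, anchored by a first-principles oracle.

The oracle evaluates the penalized criterion directly from full Gamma
log-densities (no profiling shortcuts, no shared code with the reduced
objective) and exhaustively maximizes the penalized likelihood ratio.
"""

import numpy as np
import pytest
from scipy.special import gammaln

from circacp import changepoint
from circacp.changepoint import adjust_zeros, detect_cp, estimate_shape, mic
from circacp.errors import ContractError, DegenerateError, WindowTooShortError


def _gamma_logpdf_sum(y, theta, xi):
    return float(
        np.sum((xi - 1) * np.log(y) - gammaln(xi) - xi * np.log(theta) - y / theta)
    )


def oracle_cp(y, xi, lam, min_seg):
    """Exhaustive argmin of -2logL1 + penalty from raw Gamma densities."""
    n = len(y)
    best = None
    for k in range(min_seg, n - min_seg + 1):
        th1 = np.sum(y[:k]) / (k * xi)
        th2 = np.sum(y[k:]) / ((n - k) * xi)
        crit = (
            -2.0 * (_gamma_logpdf_sum(y[:k], th1, xi) + _gamma_logpdf_sum(y[k:], th2, xi))
            + lam * (2.0 * k / n - 1.0) ** 2 * np.log(n)
        )
        key = (crit, abs(k - n / 2.0), k)  # same tie-break: midpoint, then small k
        if best is None or key < best[0]:
            best = (key, k)
    return best[1]


class TestAdjustZeros:
    def test_floors_zeros(self):
        np.testing.assert_array_equal(adjust_zeros([0, 2, 0]), [0.1, 2, 0.1])

    def test_identity_on_positive(self):
        y = np.array([0.5, 2.0, 3.0])
        np.testing.assert_array_equal(adjust_zeros(y), y)

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ContractError):
            adjust_zeros([1.0], eps=0.0)

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(1, 5, 100)
        y[rng.random(100) < 0.3] = 0
        adj = adjust_zeros(y)
        assert np.all(np.diff(adj[np.argsort(y, kind="stable")]) >= 0)


class TestEstimateShape:
    @pytest.mark.parametrize("shape,scale", [(2.0, 3.0), (0.8, 40.0)])
    def test_recovers_known_shape(self, shape, scale):
        rng = np.random.default_rng(int(shape * 10))
        y = rng.gamma(shape, scale, 100_000)
        assert estimate_shape(y) == pytest.approx(shape, rel=0.02)

    def test_exponential_is_shape_one(self):
        rng = np.random.default_rng(9)
        y = rng.exponential(5.0, 100_000)
        assert estimate_shape(y) == pytest.approx(1.0, rel=0.02)

    def test_constant_sequence_degenerate(self):
        with pytest.raises(DegenerateError):
            estimate_shape(np.full(100, 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ContractError):
            estimate_shape(np.arange(1.0, 6.0))


class TestMic:
    def test_penalty_vanishes_at_midpoint(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(1, 5, 100)
        for lam in (0.0, 50.0, 1e6):
            assert mic(y, 50, xi=1.0, lam=lam) == pytest.approx(
                mic(y, 50, xi=1.0, lam=0.0)
            )

    def test_k_out_of_range_rejected(self):
        y = np.ones(10) + 0.1
        for k in (0, 10):
            with pytest.raises(ContractError):
                mic(y, k, xi=1.0)

    def test_matches_profile_likelihood_up_to_constant(self):
        # reduced objective - (-2logL1 + penalty) must be k-independent
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.gamma(1, 2, 60), rng.gamma(1, 40, 60)])
        xi, lam, n = 0.9, 50.0, len(y)
        gaps = []
        for k in range(5, n - 4):
            th1 = y[:k].sum() / (k * xi)
            th2 = y[k:].sum() / ((n - k) * xi)
            full = (
                -2.0 * (_gamma_logpdf_sum(y[:k], th1, xi) + _gamma_logpdf_sum(y[k:], th2, xi))
                + lam * (2.0 * k / n - 1) ** 2 * np.log(n)
            )
            gaps.append(mic(y, k, xi, lam) - full)
        assert np.ptp(gaps) < 1e-8


class TestDetectCp:
    def test_oracle_equivalence_random_windows(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(80, 201))
            k_true = int(rng.integers(10, n - 10))
            th = rng.uniform(0.5, 60, size=2)
            xi_true = rng.uniform(0.5, 3.0)
            y = np.concatenate(
                [rng.gamma(xi_true, th[0], k_true), rng.gamma(xi_true, th[1], n - k_true)]
            )
            lam = float(rng.choice([0.0, 10.0, 50.0]))
            res = detect_cp(y, lam=lam, min_seg=10)
            assert res.k_hat == oracle_cp(adjust_zeros(y), res.xi, lam, 10)

    def test_recovery_under_strong_contrast(self):
        hits = 0
        for i in range(200):
            rng = np.random.default_rng(5000 + i)
            y = np.concatenate([rng.gamma(1, 2, 100), rng.gamma(1, 80, 100)])
            hits += abs(detect_cp(y).k_hat - 100) <= 5
        assert hits / 200 >= 0.95

    def test_penalty_pulls_toward_centre_on_homogeneous_windows(self):
        # without a change, lambda=50 keeps k_hat closer to n/2 than lambda=0
        d50, d0 = [], []
        for i in range(100):
            rng = np.random.default_rng(300 + i)
            y = rng.gamma(1, 10, 200)
            d50.append(abs(detect_cp(y, lam=50.0).k_hat - 100))
            d0.append(abs(detect_cp(y, lam=0.0).k_hat - 100))
        assert np.mean(d50) < np.mean(d0)

    def test_deterministic_step_exact(self):
        y = np.array([1.0] * 100 + [100.0] * 100)
        assert detect_cp(y).k_hat == 100

    def test_scale_equivariance_with_fixed_shape(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.gamma(1, 3, 80), rng.gamma(1, 30, 120)])
        a = detect_cp(y, xi=1.0)
        b = detect_cp(y * 7.3, xi=1.0, eps=0.1 * 7.3)
        assert a.k_hat == b.k_hat

    def test_consistency_relative_error_shrinks(self):
        med = {}
        for n in (100, 400, 1600):
            errs = []
            for i in range(40):
                rng = np.random.default_rng(n * 100 + i)
                y = np.concatenate(
                    [rng.gamma(1, 5, n // 2), rng.gamma(1, 10, n // 2)]
                )
                errs.append(abs(detect_cp(y, min_seg=10).k_hat - n // 2) / n)
            med[n] = np.median(errs)
        assert med[1600] <= med[400] <= med[100]

    def test_short_window_rejected(self):
        with pytest.raises(WindowTooShortError):
            detect_cp(np.ones(40) + 0.1, min_seg=30)

    def test_global_index_offsets(self):
        y = np.array([1.0] * 100 + [100.0] * 100)
        res = detect_cp(y, origin_idx=500)
        assert res.k_hat_global == 600

    def test_h1_advantage_positive_on_clear_change(self):
        rng = np.random.default_rng(12)
        y = np.concatenate([rng.gamma(1, 2, 100), rng.gamma(1, 80, 100)])
        assert detect_cp(y).h1_advantage > 0
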
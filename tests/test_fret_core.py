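"""Core FRET math: orientation factor, rate, efficiency, trajectory averages."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdfret import (
    DipoleFrame,
    FrameObservables,
    PhotophysicsParams,
    analyze_frames,
    compute_observables,
    efficiency,
    orientation_factor,
    orientation_factors,
    summarize_trajectory,
    transfer_rate,
)
from mdfret.errors import DegenerateGeometryError, InsufficientDataError

from helpers import random_rotation, random_unit


def frame(mu_d, mu_a, r, t=0.0) -> DipoleFrame:
    return DipoleFrame(mu_d=mu_d, mu_a=mu_a, r_da_vec=r, t=t)


class TestOrientationFactor:
    @pytest.mark.parametrize(
        "mu_d, mu_a, r, expected",
        [
            # collinear along the separation axis: kappa = -2, kappa^2 = 4
            ((1, 0, 0), (1, 0, 0), (5, 0, 0), -2.0),
            # mutually orthogonal: kappa = 0
            ((0, 1, 0), (0, 0, 1), (5, 0, 0), 0.0),
            # parallel, perpendicular to the separation: kappa = 1
            ((0, 1, 0), (0, 1, 0), (5, 0, 0), 1.0),
        ],
    )
    def test_reference_geometries(self, mu_d, mu_a, r, expected):
        assert orientation_factor(frame(mu_d, mu_a, r)) == pytest.approx(expected, abs=1e-15)

    def test_zero_separation_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            DipoleFrame(mu_d=(1, 0, 0), mu_a=(0, 1, 0), r_da_vec=(0, 0, 0))

    def test_non_unit_dipole_rejected(self):
        with pytest.raises(ValueError):
            DipoleFrame(mu_d=(2, 0, 0), mu_a=(0, 1, 0), r_da_vec=(5, 0, 0))

    def test_vectorized_matches_scalar(self, rng):
        mu_d = random_unit(rng, 64)
        mu_a = random_unit(rng, 64)
        r = rng.uniform(-1, 1, size=(64, 3)) + np.array([3.0, 0, 0])
        ks = orientation_factors(mu_d, mu_a, r)
        for i in range(64):
            assert ks[i] == pytest.approx(
                orientation_factor(frame(mu_d[i], mu_a[i], r[i])), rel=1e-12
            )

    def test_bounds_and_symmetries(self, rng):
        """kappa^2 in [0,4]; invariant under sign flips, D/A exchange, rotations."""
        n = 100_000
        mu_d = random_unit(rng, n)
        mu_a = random_unit(rng, n)
        r = random_unit(rng, n) * rng.uniform(2.0, 30.0, size=(n, 1))
        k = orientation_factors(mu_d, mu_a, r)
        k2 = k * k
        assert np.all(k2 >= 0.0) and np.all(k2 <= 4.0 + 1e-12)
        # sign flips of both dipoles leave kappa itself unchanged
        np.testing.assert_allclose(orientation_factors(-mu_d, -mu_a, r), k, rtol=1e-12)
        # flipping one dipole flips the sign, not the square
        np.testing.assert_allclose(orientation_factors(-mu_d, mu_a, r), -k, rtol=1e-12)
        # donor/acceptor exchange
        np.testing.assert_allclose(
            orientation_factors(mu_a, mu_d, r), k, rtol=1e-12, atol=1e-12
        )
        # common rigid rotation
        rot = random_rotation(rng)
        np.testing.assert_allclose(
            orientation_factors(mu_d @ rot.T, mu_a @ rot.T, r @ rot.T), k, atol=1e-9
        )

    def test_isotropic_average_is_two_thirds(self, rng):
        """Monte-Carlo oracle: <kappa^2> -> 2/3 for independent isotropic pairs."""
        n = 1_000_000
        k = orientation_factors(
            random_unit(rng, n), random_unit(rng, n), np.tile([10.0, 0, 0], (n, 1))
        )
        k2 = k * k
        sem = k2.std(ddof=0) / math.sqrt(n)
        assert abs(k2.mean() - 2.0 / 3.0) < 3 * sem


class TestTransferRate:
    def test_unit_rate_at_forster_radius(self, wt_params):
        # kappa^2 = 2/3 at R = R_F gives W_F = 1/tau_d by construction
        assert transfer_rate(2.0 / 3.0, 24.0, wt_params) == pytest.approx(
            1.0 / 2.57, rel=1e-14
        )

    def test_wild_type_point_evaluation(self, wt_params):
        # Independent hand evaluation at the wild-type mean geometry.  This is
        # a point evaluation of the rate law, NOT the trajectory mean <W_F>:
        # averaging the convex R^-6 law over frames exceeds the rate at the
        # mean geometry (Jensen), so the two must not be conflated.
        expected = 3.0 * 0.558 / (2.0 * 2.57) * (24.0 / 9.14) ** 6
        w = transfer_rate(0.558, 9.14, wt_params)
        assert w == pytest.approx(expected, rel=1e-14)
        assert w == pytest.approx(1.07e2, rel=0.005)

    def test_zero_forster_radius_gives_exact_zero(self):
        p = PhotophysicsParams(tau_d=2.57, r_forster=0.0)
        assert transfer_rate(1.3, 5.0, p) == 0.0
        assert np.all(transfer_rate(np.array([0.1, 4.0]), np.array([2.0, 50.0]), p) == 0.0)

    def test_inverse_sixth_power_scaling(self, wt_params, rng):
        for _ in range(20):
            r = rng.uniform(3.0, 40.0)
            k2 = rng.uniform(0.0, 4.0)
            assert transfer_rate(k2, 2 * r, wt_params) == pytest.approx(
                transfer_rate(k2, r, wt_params) / 64.0, rel=1e-12
            )

    def test_degenerate_distance_rejected(self, wt_params):
        with pytest.raises(DegenerateGeometryError):
            transfer_rate(1.0, 0.0, wt_params)
        with pytest.raises(DegenerateGeometryError):
            transfer_rate(1.0, -3.0, wt_params)


class TestEfficiency:
    def test_half_at_unit_rate_lifetime_product(self):
        assert efficiency(1.0 / 2.57, 2.57) == 0.5

    def test_zero_rate_limit(self):
        assert efficiency(0.0, 2.57) == 0.0

    def test_matches_direct_formula(self, wt_params):
        w = transfer_rate(0.558, 9.14, wt_params)
        assert efficiency(w, 2.57) == pytest.approx(1.0 / (1.0 + 1.0 / (w * 2.57)), rel=1e-14)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            efficiency(-0.1, 2.57)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, derandomize=True)
    def test_strictly_increasing_and_bounded(self, w):
        e = efficiency(w, 2.57)
        assert 0.0 < e < 1.0
        assert efficiency(w * 1.5, 2.57) > e

    def test_saturates_to_one(self):
        assert efficiency(1e12, 2.57) == pytest.approx(1.0, abs=1e-11)


def _obs(r_da, kappa_sq, params, t=0.0) -> FrameObservables:
    w = transfer_rate(kappa_sq, r_da, params)
    return FrameObservables(
        t=t, r_da=r_da, kappa=math.sqrt(kappa_sq), kappa_sq=kappa_sq,
        w_f=w, e=efficiency(w, params.tau_d),
    )


class TestSummarizeTrajectory:
    def test_constant_series_has_zero_sem(self, wt_params):
        obs = [_obs(10.0, 1.0, wt_params, t=i * 0.001) for i in range(50)]
        s = summarize_trajectory(obs, dt=0.001)
        assert s.mean_r_da == 10.0 and s.sem_r_da == 0.0
        assert s.mean_kappa_sq == 1.0 and s.sem_kappa_sq == 0.0
        assert s.max_kappa_sq == 1.0
        assert s.sem_w_f == 0.0 and s.sem_e == 0.0
        assert s.duration_T == pytest.approx(0.05)

    def test_two_frame_kappa_sq_extremes(self, wt_params):
        obs = [_obs(10.0, 0.0, wt_params), _obs(10.0, 4.0, wt_params)]
        s = summarize_trajectory(obs, dt=0.001)
        assert s.mean_kappa_sq == 2.0
        assert s.max_kappa_sq == 4.0

    def test_jensen_gap_of_convex_distance_law(self, wt_params):
        """Alternating 8/12 Å: <W_F> is the mean of the two point rates and
        exceeds the rate at the 10 Å mean distance."""
        obs = [_obs([8.0, 12.0][i % 2], 1.0, wt_params) for i in range(100)]
        s = summarize_trajectory(obs, dt=0.001)
        w8 = transfer_rate(1.0, 8.0, wt_params)
        w12 = transfer_rate(1.0, 12.0, wt_params)
        assert s.mean_w_f == pytest.approx((w8 + w12) / 2.0, rel=1e-12)
        assert s.mean_w_f > transfer_rate(1.0, 10.0, wt_params)

    def test_self_concatenation_shrinks_sem_by_sqrt2(self, wt_params, rng):
        obs = [
            _obs(rng.uniform(6, 14), rng.uniform(0, 4), wt_params, t=i * 0.001)
            for i in range(64)
        ]
        s1 = summarize_trajectory(obs, dt=0.001)
        s2 = summarize_trajectory(obs + obs, dt=0.001)
        for name in ("mean_r_da", "mean_kappa_sq", "mean_w_f", "mean_e", "max_kappa_sq"):
            assert getattr(s2, name) == pytest.approx(getattr(s1, name), rel=1e-12)
        for name in ("sem_r_da", "sem_kappa_sq", "sem_w_f", "sem_e"):
            assert getattr(s2, name) == pytest.approx(
                getattr(s1, name) / math.sqrt(2.0), rel=1e-12
            )

    def test_too_few_frames_rejected(self, wt_params):
        with pytest.raises(InsufficientDataError):
            summarize_trajectory([], dt=0.001)
        with pytest.raises(InsufficientDataError):
            summarize_trajectory([_obs(10.0, 1.0, wt_params)], dt=0.001)

    def test_block_averaging_keeps_means(self, wt_params, rng):
        obs = [_obs(rng.uniform(6, 14), rng.uniform(0, 4), wt_params) for _ in range(100)]
        plain = summarize_trajectory(obs, dt=0.001)
        blocked = summarize_trajectory(obs, dt=0.001, block_size=10)
        assert blocked.mean_w_f == pytest.approx(plain.mean_w_f, rel=1e-12)
        assert blocked.block_size == 10
        with pytest.raises(InsufficientDataError):
            summarize_trajectory(obs, dt=0.001, block_size=60)

    def test_pipeline_means_match_bruteforce(self, wt_params, rng):
        """Trajectory means equal an explicit per-frame re-evaluation."""
        frames = [
            DipoleFrame(
                mu_d=random_unit(rng), mu_a=random_unit(rng),
                r_da_vec=[rng.uniform(6, 14), 0, 0], t=i * 0.001,
            )
            for i in range(300)
        ]
        s = summarize_trajectory(analyze_frames(frames, wt_params), dt=0.001)
        # brute force with plain python floats and the explicit formulas
        ws, es, k2s = [], [], []
        for f in frames:
            rhat = f.r_da_vec / math.sqrt(float(f.r_da_vec @ f.r_da_vec))
            k = float(f.mu_d @ f.mu_a) - 3.0 * float(rhat @ f.mu_d) * float(rhat @ f.mu_a)
            w = 3.0 * k * k / (2.0 * 2.57) * (24.0 / f.r_da) ** 6
            ws.append(w)
            es.append(1.0 / (1.0 + 1.0 / (w * 2.57)))
            k2s.append(k * k)
        assert s.mean_w_f == pytest.approx(sum(ws) / len(ws), rel=1e-12)
        assert s.mean_e == pytest.approx(sum(es) / len(es), rel=1e-12)
        assert s.mean_kappa_sq == pytest.approx(sum(k2s) / len(k2s), rel=1e-12)


def test_compute_observables_consistency(wt_params):
    f = DipoleFrame(mu_d=(0, 1, 0), mu_a=(0, 1, 0), r_da_vec=(24.0, 0, 0), t=0.5)
    o = compute_observables(f, wt_params)
    assert o.kappa == 1.0 and o.kappa_sq == 1.0
    assert o.r_da == 24.0
    assert o.w_f == pytest.approx(3.0 / (2.0 * 2.57), rel=1e-14)
    assert o.e == pytest.approx(1.0 / (1.0 + 1.0 / (o.w_f * 2.57)), rel=1e-14)
    assert o.t == 0.5
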
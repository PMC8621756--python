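"""Detection, linking, MSD/D estimation, motion range, histogram peaks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from memdyn import spt_dynamics as spt
from tests.conftest import make_brownian_tracks


def _plant_spot(shape, x, y, amplitude, sigma_px, background=10.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = background + amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2)
    )
    return img


class TestDetectSpots:
    def test_constant_image_yields_nothing(self):
        assert len(spt.detect_spots(np.full((64, 64), 7.0), 0.1)) == 0

    def test_single_spot_subpixel_accuracy(self):
        rng = np.random.default_rng(0)
        x_true, y_true = 30.3, 41.7
        img = _plant_spot((64, 64), x_true, y_true, 200.0, 1.25)
        img = rng.poisson(img).astype(float)
        spots = spt.detect_spots(img, 0.1)
        assert len(spots) == 1
        assert abs(spots["x_um"].iloc[0] / 0.1 - x_true) < 0.2
        assert abs(spots["y_um"].iloc[0] / 0.1 - y_true) < 0.2

    def test_two_spots_at_six_sigma_resolved(self):
        sigma_px = 1.25
        img = _plant_spot((64, 64), 20.0, 32.0, 200.0, sigma_px)
        img += _plant_spot((64, 64), 20.0 + 6 * sigma_px, 32.0, 200.0, sigma_px, 0.0)
        spots = spt.detect_spots(img, 0.1)
        assert len(spots) == 2

    def test_movie_detection_matches_planted_particles(self, small_movie):
        spec, movie, truth = small_movie
        spots = spt.detect_spots_movie(movie)
        per_frame = spots.groupby("frame").size()
        assert (per_frame == spec.n_particles).mean() > 0.9


class TestLinking:
    def test_single_stationary_spot_gives_full_track(self):
        rows = [{"frame": t, "x_um": 1.0, "y_um": 2.0} for t in range(10)]
        tracks = spt.link_trajectories(pd.DataFrame(rows), max_step_um=0.5)
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 10

    def test_parallel_tracks_do_not_swap(self):
        rows = []
        for t in range(12):
            rows.append({"frame": t, "x_um": 0.01 * t, "y_um": 0.0})
            rows.append({"frame": t, "x_um": 0.01 * t, "y_um": 5.0})
        tracks = spt.link_trajectories(pd.DataFrame(rows), max_step_um=0.3)
        assert tracks["track_id"].nunique() == 2
        for _, g in tracks.groupby("track_id"):
            assert g["y_um"].nunique() == 1  # no identity swap

    def test_link_recovery_against_ground_truth(self, small_movie):
        spec, movie, truth = small_movie
        spots = spt.detect_spots_movie(movie)
        tracks = spt.link_trajectories(spots, max_step_um=0.3, max_gap=1)
        # Match each recovered link (frame t -> t+1) against the truth by
        # nearest-neighbour position; ≥ 95% of true links must be recovered.
        true_links = 0
        recovered = 0
        truth_pos = {
            (int(r.track_id), int(r.frame)): (r.x_um, r.y_um)
            for r in truth.itertuples()
        }
        track_pos = {}
        for r in tracks.itertuples():
            track_pos.setdefault(int(r.track_id), {})[int(r.frame)] = (
                r.x_um,
                r.y_um,
            )
        tol = 3 * spec.localization_jitter_um + 0.02
        for (tid, frame), (x, y) in truth_pos.items():
            nxt = truth_pos.get((tid, frame + 1))
            if nxt is None:
                continue
            true_links += 1
            for pos_by_frame in track_pos.values():
                a = pos_by_frame.get(frame)
                b = pos_by_frame.get(frame + 1)
                if a is None or b is None:
                    continue
                if np.hypot(a[0] - x, a[1] - y) < tol and np.hypot(
                    b[0] - nxt[0], b[1] - nxt[1]
                ) < tol:
                    recovered += 1
                    break
        assert recovered / true_links >= 0.95

    def test_nonpositive_max_step_rejected(self):
        with pytest.raises(ValueError):
            spt.link_trajectories(
                pd.DataFrame([{"frame": 0, "x_um": 0.0, "y_um": 0.0}]), max_step_um=0.0
            )


class TestMsdAndDiffusion:
    def test_stationary_msd_is_zero(self):
        xy = np.tile([[1.0, 2.0]], (10, 1))
        msd = spt.compute_msd(xy, 0.05, max_lag=5)
        assert np.all(msd["msd_um2"] == 0)

    def test_ballistic_closed_form(self):
        # Uniform motion 0.1 μm/frame: MSD(nΔt) = (0.1 n)².
        xy = np.column_stack([0.1 * np.arange(20), np.zeros(20)])
        msd = spt.compute_msd(xy, 1.0, max_lag=5)
        np.testing.assert_allclose(
            msd["msd_um2"], (0.1 * np.arange(1, 6)) ** 2, rtol=1e-12
        )

    def test_max_lag_validation(self):
        xy = np.zeros((5, 2))
        with pytest.raises(ValueError):
            spt.compute_msd(xy, 0.05, max_lag=5)

    def test_ensemble_msd_matches_4dt(self):
        # Brownian closed form MSD(τ) = 4Dτ, checked on 1e4 simulated
        # tracks with D = 1e-3 μm²/s at Δt = 0.05 s.
        D, dt = 1e-3, 0.05
        sigma = np.sqrt(2 * D * dt)
        rng = np.random.default_rng(12)
        pos = make_brownian_tracks(rng, 10_000, 16, sigma)
        lags = None
        acc = None
        for xy in pos:
            msd = spt.compute_msd(xy, dt, max_lag=5)
            if acc is None:
                lags = msd["lag_s"].to_numpy()
                acc = msd["msd_um2"].to_numpy().copy()
            else:
                acc += msd["msd_um2"].to_numpy()
        acc /= len(pos)
        np.testing.assert_allclose(acc, 4 * D * lags, rtol=0.05)

    def test_exact_line_recovers_d(self):
        tau = 0.05 * np.arange(1, 6)
        msd = pd.DataFrame({"lag_s": tau, "msd_um2": 4e-3 * tau})
        est = spt.estimate_diffusion_coefficient(msd)
        assert est.D == pytest.approx(1e-3, rel=1e-12)
        assert not est.negative_slope

    def test_intercept_absorbed(self):
        tau = 0.05 * np.arange(1, 6)
        c = 1.6e-3  # 4·(20 nm)² static localization offset
        msd = pd.DataFrame({"lag_s": tau, "msd_um2": 4e-3 * tau + c})
        est = spt.estimate_diffusion_coefficient(msd)
        assert est.D == pytest.approx(1e-3, rel=1e-9)
        assert est.intercept == pytest.approx(c, rel=1e-9)

    def test_negative_slope_flagged_and_clipped(self):
        tau = 0.05 * np.arange(1, 5)
        msd = pd.DataFrame({"lag_s": tau, "msd_um2": -1e-3 * tau + 1e-2})
        est = spt.estimate_diffusion_coefficient(msd)
        assert est.D == 0.0
        assert est.negative_slope

    def test_estimator_bias_below_10_percent(self):
        # 50-frame tracks, 20 nm localization noise: the free-intercept
        # 4-lag fit must recover D with < 10% mean bias.
        D, dt = 1.95e-3, 0.05
        sigma = np.sqrt(2 * D * dt)
        rng = np.random.default_rng(4)
        pos = make_brownian_tracks(rng, 2000, 50, sigma, localization_sd_um=0.02)
        est = [
            spt.estimate_diffusion_coefficient(spt.compute_msd(xy, dt, max_lag=8))
            for xy in pos
        ]
        d_mean = np.mean([e.D for e in est if not e.negative_slope])
        assert d_mean == pytest.approx(D, rel=0.10)


class TestMotionRange:
    def test_stationary_is_zero(self):
        xy = np.tile([[0.3, 0.4]], (6, 1))
        assert spt.motion_range(xy).motion_range == 0.0

    def test_collinear_extremes(self):
        xy = np.array([[0.0, 0.0], [0.1, 0.0], [0.185, 0.0], [0.05, 0.02]])
        assert spt.motion_range(xy).motion_range == pytest.approx(0.185)

    def test_dense_circle_diameter(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 0.23
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert spt.motion_range(xy).motion_range == pytest.approx(2 * r, rel=1e-3)

    @given(
        xy=arrays(
            dtype=float,
            shape=st.tuples(st.integers(2, 60), st.just(2)),
            elements=st.floats(-5, 5, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_brute_force_pairwise_maximum(self, xy):
        # Oracle: exhaustive max over all pairs (convex-hull shortcut must
        # agree on every geometry, including degenerate ones).
        brute = 0.0
        for i in range(len(xy)):
            d = np.sqrt(np.sum((xy[i + 1 :] - xy[i]) ** 2, axis=1))
            if len(d):
                brute = max(brute, float(d.max()))
        assert spt.motion_range(xy).motion_range == pytest.approx(brute, abs=1e-9)


class TestPeakHistogram:
    def test_single_gaussian_peak_recovery(self):
        # Unimodal motion-range-like data: N(0.185, 0.0095²).
        rng = np.random.default_rng(21)
        values = rng.normal(0.185, 0.0095, 10_000)
        fit = spt.fit_peak_histogram(values, allow_bimodal=True)
        assert fit.n_components == 1
        assert fit.components[0].peak == pytest.approx(0.185, abs=0.005)

    def test_bimodal_mixture_recovery(self):
        # 70/30 mixture at the two diffusion peaks 2.43e-3 / 3.83e-4 μm²/s;
        # log-scale binning resolves the ~6x separation.
        rng = np.random.default_rng(22)
        fast = rng.normal(2.43e-3, 2e-4, 7000)
        slow = rng.normal(3.83e-4, 1e-4, 3000)
        values = np.concatenate([fast, slow])
        fit = spt.fit_peak_histogram(values, allow_bimodal=True, log_scale=True)
        assert fit.n_components == 2
        peaks = sorted(fit.peaks)
        assert peaks[1] == pytest.approx(2.43e-3, rel=0.10)
        assert peaks[0] == pytest.approx(3.83e-4, rel=0.15)
        # Majority component first (sorted by weight).
        assert fit.components[0].peak == pytest.approx(2.43e-3, rel=0.10)

    def test_identical_values_raise(self):
        with pytest.raises(ValueError, match="identical"):
            spt.fit_peak_histogram(np.full(100, 3.3))

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match="at least 30"):
            spt.fit_peak_histogram(np.arange(10.0))

    def test_weights_sum_to_one_and_counts_conserved(self):
        rng = np.random.default_rng(23)
        values = np.concatenate(
            [rng.normal(0.0, 1.0, 600), rng.normal(8.0, 1.0, 400)]
        )
        fit = spt.fit_peak_histogram(values, allow_bimodal=True)
        assert fit.counts.sum() == len(values)
        assert sum(c.weight for c in fit.components) == pytest.approx(1.0)
        assert all(c.width > 0 for c in fit.components)

    def test_false_bimodality_rate_under_5_percent(self):
        # Single-Gaussian data must almost never trigger the 2-component
        # model (ΔBIC > 10 rule), checked across 100 seeds.
        false_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            values = rng.normal(1.0, 0.1, 1000)
            fit = spt.fit_peak_histogram(values, allow_bimodal=True)
            false_hits += fit.n_components == 2
        assert false_hits < 5
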
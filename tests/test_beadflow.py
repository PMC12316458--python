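import math

import numpy as np
import pytest

from kvflow import beadflow as bf
from kvflow.core import ImageStack, Track
from kvflow.errors import DomainError, EmptyResultError, ParameterError
from kvflow.synthetic_data import BeadSimConfig, simulate_bead_tracks


def make_track(x, y, dt=0.25, tid=0):
    x = np.asarray(x, float)
    frames = np.arange(len(x))
    return Track(tid, frames, frames * dt, x, np.asarray(y, float))


def ballistic_track(v, n=32, dt=0.25, angle=0.3):
    t = np.arange(n) * dt
    return make_track(v * t * math.cos(angle), v * t * math.sin(angle), dt=dt)


class TestMSD:
    def test_stationary_track_is_zero(self):
        curve = bf.compute_track_msd(make_track(np.ones(10), np.ones(10)))
        assert np.all(curve.msd == 0.0)

    def test_ballistic_identity_every_lag(self):
        # time-averaged MSD of constant-velocity motion is exactly v^2 dt^2
        v = 1.0
        curve = bf.compute_track_msd(ballistic_track(v))
        assert np.allclose(curve.msd, v**2 * curve.lags**2, rtol=1e-12, atol=1e-12)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20).cumsum(), rng.normal(size=20).cumsum()
        base = bf.compute_track_msd(make_track(x, y))
        shifted = bf.compute_track_msd(make_track(x + 50.0, y - 12.0))
        th = 0.7
        xr = x * math.cos(th) - y * math.sin(th)
        yr = x * math.sin(th) + y * math.cos(th)
        rotated = bf.compute_track_msd(make_track(xr, yr))
        assert np.allclose(base.msd, shifted.msd)
        assert np.allclose(base.msd, rotated.msd)

    def test_single_point_track_gives_empty_curve(self):
        assert len(bf.compute_track_msd(make_track([1.0], [2.0]))) == 0

    def test_max_lag_truncates(self):
        curve = bf.compute_track_msd(ballistic_track(1.0, n=40), max_lag=2.0)
        assert curve.lags[-1] == pytest.approx(2.0)

    def test_brownian_ensemble_slope_recovers_4d(self):
        d_true = 0.5
        tracks = simulate_bead_tracks(
            BeadSimConfig(mode="diffusive", n_beads=500, D=d_true, duration=8.0, seed=5)
        )
        curve = bf.ensemble_msd(tracks, max_lag=8.0)
        slope = np.polyfit(curve.lags[:5], curve.msd[:5], 1)[0]
        assert slope == pytest.approx(4 * d_true, rel=0.10)


class TestEnsembleMSD:
    def test_single_track_reduces_to_track_curve(self):
        tr = ballistic_track(0.7)
        ens = bf.ensemble_msd([tr], min_duration=1.0, max_duration=8.0)
        single = bf.compute_track_msd(tr)
        assert np.allclose(ens.msd, single.msd)
        assert np.all(ens.n_pairs == 1)

    def test_duration_window_filters_everything(self):
        short = ballistic_track(1.0, n=3)  # 0.5 s
        long = ballistic_track(1.0, n=41)  # 10 s
        with pytest.raises(EmptyResultError):
            bf.ensemble_msd([short, long], min_duration=1.0, max_duration=8.0)

    def test_mixed_population_lies_between_pure_curves(self):
        directed = simulate_bead_tracks(BeadSimConfig(mode="directed", n_beads=60, seed=1))
        confined = simulate_bead_tracks(BeadSimConfig(mode="confined", n_beads=60, D=1.0, seed=2))
        cd = bf.ensemble_msd(directed, max_lag=8.0)
        cc = bf.ensemble_msd(confined, max_lag=8.0)
        cm = bf.ensemble_msd(directed + confined, max_lag=8.0)
        lo = np.minimum(cd.msd, cc.msd)
        hi = np.maximum(cd.msd, cc.msd)
        assert np.all(cm.msd >= lo - 1e-9) and np.all(cm.msd <= hi + 1e-9)


class TestClassifyMotion:
    def test_exact_ballistic_curve_is_directed(self):
        lags = np.arange(1, 13) * 0.25
        curve = bf.MSDCurve(lags=lags, msd=lags**2, n_pairs=np.ones(12, int))
        cls = bf.classify_motion(curve)
        assert cls.verdict == "directed"
        assert cls.v == pytest.approx(1.0, abs=1e-6)
        assert cls.D == pytest.approx(0.0, abs=1e-6)
        assert cls.alpha == pytest.approx(2.0, abs=1e-6)

    def test_exact_linear_curve_is_diffusive(self):
        lags = np.arange(1, 13) * 0.25
        curve = bf.MSDCurve(lags=lags, msd=4 * 0.3 * lags, n_pairs=np.ones(12, int))
        cls = bf.classify_motion(curve)
        assert cls.verdict == "diffusive"
        assert cls.D == pytest.approx(0.3, abs=1e-6)

    def test_exact_saturating_curve_is_confined(self):
        lags = np.arange(1, 25) * 0.25
        L, D = 4.0, 1.0
        msd = L**2 * (1 - np.exp(-4 * D * lags / L**2))
        cls = bf.classify_motion(bf.MSDCurve(lags=lags, msd=msd, n_pairs=np.ones(24, int)))
        assert cls.verdict == "confined"
        assert cls.L == pytest.approx(L, rel=1e-3)
        assert cls.tau == pytest.approx(L**2 / (4 * D), rel=1e-3)

    def test_rejects_bad_input(self):
        with pytest.raises(DomainError):
            bf.classify_motion(bf.MSDCurve(np.array([0.25, 0.5]), np.array([1.0, 2.0]), np.array([1, 1])))


class TestLinking:
    def det(self, frame, x, y):
        return bf.SpotDetection(frame=frame, x=x, y=y, diameter=1.0, brightness=100.0)

    def test_single_moving_spot_single_track(self):
        dets = [self.det(f, 0.1 * f, 0.0) for f in range(20)]
        tracks = bf.link_detections(dets)
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_step_beyond_gate_splits_track(self):
        dets = [self.det(0, 0.0, 0.0), self.det(1, 3.0, 0.0)]
        tracks = bf.link_detections(dets, max_step=2.5)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_step_exactly_at_gate_splits(self):
        dets = [self.det(0, 0.0, 0.0), self.det(1, 2.5, 0.0)]
        assert len(bf.link_detections(dets, max_step=2.5)) == 2

    def test_two_separated_beads_recovered_exactly(self):
        truth = {}
        dets = []
        for f in range(15):
            for bead, (x0, y0) in enumerate([(0.0, 0.0), (10.0, 0.0)]):
                x = x0 + 0.5 * f
                truth.setdefault(bead, []).append((x, y0))
                dets.append(self.det(f, x, y0))
        tracks = bf.link_detections(dets)
        assert len(tracks) == 2
        got = sorted([list(zip(t.x, t.y)) for t in tracks])
        want = sorted([truth[0], truth[1]])
        assert np.allclose(got, want)

    def test_empty_input(self):
        assert bf.link_detections([]) == []
        with pytest.raises(ParameterError):
            bf.link_detections([self.det(0, 0, 0)], max_step=0.0)


class TestDetection:
    def test_constant_stack_yields_nothing(self):
        stack = ImageStack(np.full((3, 64, 64), 7.0), 0.25, 0.25)
        assert bf.detect_spots(stack) == []

    def test_rendered_beads_recovered_within_one_pixel(self, separated_bead_scene):
        stack, truth, _ = separated_bead_scene
        spots = bf.detect_spots(stack)
        assert len(spots) == len(truth)
        for rec in truth:
            err = min(
                math.hypot(s.x - rec["x"], s.y - rec["y"])
                for s in spots
                if s.frame == rec["frame"]
            )
            assert err < stack.pixel_size

    def test_oversized_blob_excluded_by_size_gate(self, separated_bead_scene):
        stack, truth, _ = separated_bead_scene
        # superimpose a noiseless 3 um blob in the empty image centre
        sigma_px = 3.0 / (2 * math.sqrt(2)) / stack.pixel_size
        rows, cols = np.mgrid[0:256, 0:256]
        blob = 100.0 * np.exp(-((rows - 128) ** 2 + (cols - 128) ** 2) / (2 * sigma_px**2))
        frames = stack.frames + blob[None, :, :]
        merged = ImageStack(frames, stack.pixel_size, stack.frame_interval)
        spots = bf.detect_spots(merged)
        near_big = [s for s in spots if math.hypot(s.x - 32.0, s.y - 32.0) < 2.0]
        assert near_big == []
        assert len(spots) == len(truth)  # small beads unaffected

    def test_invalid_parameters(self, separated_bead_scene):
        stack, _, _ = separated_bead_scene
        with pytest.raises(ParameterError):
            bf.detect_spots(stack, size_range=(1.5, 0.5))
        with pytest.raises(ParameterError):
            bf.detect_spots(stack, brightness_quantile=1.5)


class TestMeanBeadSpeed:
    def test_stationary_tracks_zero(self):
        tracks = [make_track(np.zeros(5), np.zeros(5))]
        assert bf.mean_bead_speed(tracks).mean_speed == 0.0

    def test_ballistic_speed_exact(self):
        tracks = [ballistic_track(1.0), ballistic_track(1.0, angle=2.0)]
        summary = bf.mean_bead_speed(tracks)
        assert summary.mean_speed == pytest.approx(1.0, rel=1e-12)
        assert summary.n_tracks == 2

    def test_vortex_low_noise_recovers_tangential_speed(self):
        tracks = simulate_bead_tracks(
            BeadSimConfig(mode="directed", tangential_speed=0.96, D=0.005,
                          radial_jitter=0.0, seed=8)
        )
        assert bf.mean_bead_speed(tracks).mean_speed == pytest.approx(0.96, rel=0.10)

    def test_all_singletons_rejected(self):
        with pytest.raises(EmptyResultError):
            bf.mean_bead_speed([make_track([0.0], [0.0])])
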
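"""Spot detection, linking, duration filtering and trajectory MSDs."""

import numpy as np
import pytest

from imsdkit.io import AcquisitionMeta
from imsdkit.simulate import SimulationConfig, render_stack, simulate_trajectories
from imsdkit.spt import (
    MSDCurve,
    SpotDetection,
    Trajectory,
    compute_msd,
    detect_spots,
    detect_stack,
    ensemble_msd,
    filter_by_duration,
    fit_diffusivity,
    link_trajectories,
)


def render_positions(positions_um, frame_size=96, amplitude=200.0, background=20.0,
                     shot_noise=True, seed=0, n_frames=None):
    """Render given (P, T, 2) um positions with lysosome-like settings."""
    positions_um = np.asarray(positions_um, float)
    P, T, _ = positions_um.shape
    cfg = SimulationConfig(
        n_particles=P,
        D=0.0,
        amplitude=amplitude,
        background=background,
        shot_noise=shot_noise,
        read_noise_sigma=0.0 if not shot_noise else 3.0,
        frame_size=frame_size,
        meta=AcquisitionMeta(69.0, 0.065, max(T, 2), "sim"),
        seed=seed,
    )
    truth = simulate_trajectories(cfg)
    truth.positions = np.broadcast_to(
        positions_um, (P, cfg.meta.n_frames, 2)
    ).copy() if T == 1 else positions_um
    return render_stack(truth, cfg), cfg


class TestDetection:
    def test_blank_frame_empty(self):
        assert detect_spots(np.zeros((64, 64)), 3.0, quality_threshold=1.0) == []

    def test_single_spot_subpixel_accuracy(self):
        pos = np.array([[[2.513, 3.207]]])  # um
        stack, cfg = render_positions(pos, shot_noise=False)
        dets = detect_spots(stack.data[0], 3.0, pixel_size_nm=69.0)
        assert len(dets) == 1
        err_px = np.hypot(dets[0].x_um - 2.513, dets[0].y_um - 3.207) / 0.069
        assert err_px < 0.5

    def test_recall_precision_on_sparse_field(self, rng):
        # 20 spots, minimum separation 8 px, high SNR
        n, sep_px = 20, 8
        pts = []
        while len(pts) < n:
            cand = rng.uniform(0.7, 5.9, size=2)
            if all(np.linalg.norm(cand - p) > sep_px * 0.069 for p in pts):
                pts.append(cand)
        pos = np.array(pts)[:, None, :]
        stack, cfg = render_positions(pos, seed=5)
        dets = detect_spots(stack.data[0], 3.0, pixel_size_nm=69.0)
        matched = 0
        used = set()
        for p in pos[:, 0, :]:
            d2 = [
                np.hypot(d.x_um - p[0], d.y_um - p[1]) for d in dets
            ]
            if d2 and min(d2) < 2 * 0.069 and int(np.argmin(d2)) not in used:
                used.add(int(np.argmin(d2)))
                matched += 1
        recall = matched / n
        precision = matched / max(len(dets), 1)
        assert recall >= 0.95
        assert precision >= 0.95


def det(frame, x, y):
    return SpotDetection(frame=frame, x_um=x, y_um=y, quality=1.0)


class TestLinking:
    def test_two_immobile_spots(self):
        frames = [[det(f, 1.0, 1.0), det(f, 4.0, 4.0)] for f in range(10)]
        trajs = link_trajectories(frames, max_link_distance_um=0.5, frame_time_s=0.1)
        assert len(trajs) == 2
        assert all(t.n_samples == 10 for t in trajs)

    @pytest.mark.parametrize("max_gap,expected", [(1, 1), (0, 2)])
    def test_gap_closing_contract(self, max_gap, expected):
        frames = [[det(f, 1.0, 1.0)] if f != 5 else [] for f in range(10)]
        trajs = link_trajectories(
            frames, max_link_distance_um=0.5, max_gap=max_gap, frame_time_s=0.1
        )
        assert len(trajs) == expected
        if max_gap == 1:
            assert trajs[0].n_samples == 9  # frame 5 missing but spanned

    def test_brownian_links_mostly_correct(self):
        # displacement per frame well below particle spacing
        cfg = SimulationConfig(
            n_particles=10, D=0.005, frame_size=256,
            meta=AcquisitionMeta(69.0, 0.065, 100, "sim"), seed=13,
        )
        truth = simulate_trajectories(cfg)
        frames = [
            [det(f, *truth.positions[p, f]) for p in range(10)] for f in range(100)
        ]
        trajs = link_trajectories(frames, max_link_distance_um=0.5, frame_time_s=0.065)
        # correct link = consecutive samples belong to the same true particle
        correct = total = 0
        for tr in trajs:
            for i in range(1, tr.n_samples):
                total += 1
                d = np.linalg.norm(
                    truth.positions[:, tr.frames[i], :] - tr.xy[i], axis=1
                )
                d0 = np.linalg.norm(
                    truth.positions[:, tr.frames[i - 1], :] - tr.xy[i - 1], axis=1
                )
                correct += int(np.argmin(d) == np.argmin(d0))
        assert total >= 900
        assert correct / total >= 0.9


class TestDurationFilter:
    def make(self, duration_s, dt=0.1):
        n = int(round(duration_s / dt)) + 1
        return Trajectory(0, np.arange(n), np.zeros((n, 2)), dt)

    def test_strict_threshold(self):
        trajs = [self.make(11.6), self.make(12.9), self.make(30.0)]
        kept = filter_by_duration(trajs, 12.0)
        assert len(kept) == 2
        # exactly 12 s is not retained under the strict rule
        assert filter_by_duration([self.make(12.0)], 12.0) == []

    def test_zero_threshold_is_identity_and_idempotent(self):
        trajs = [self.make(1.0), self.make(2.0)]
        once = filter_by_duration(trajs, 0.0)
        assert once == trajs
        assert filter_by_duration(once, 0.0) == once

    def test_empty_input(self):
        assert filter_by_duration([], 12.0) == []


class TestMSD:
    def test_immobile_msd_zero(self):
        tr = Trajectory(0, np.arange(50), np.full((50, 2), 3.0), 0.1)
        curve = compute_msd(tr)
        assert np.all(curve.msd == 0.0)
        assert curve.msd[0] == 0.0 and curve.tau[0] == 0.0

    def test_ballistic_closed_form(self):
        v = 0.7
        t = np.arange(40) * 0.1
        xy = np.stack([v * t, np.zeros_like(t)], axis=1)
        curve = compute_msd(Trajectory(0, np.arange(40), xy, 0.1))
        np.testing.assert_allclose(curve.msd, (v * curve.tau) ** 2, atol=1e-12)

    def test_brownian_slope_recovers_D(self):
        # trajectory-level generator oracle, 50 seeds
        D, dt, n = 0.04, 0.1, 1000
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), (n, 2)), axis=0)
            curve = compute_msd(Trajectory(0, np.arange(n), xy, dt))
            slope = np.polyfit(curve.tau[1:11], curve.msd[1:11], 1)[0]
            errs.append(slope / 4 - D)
        assert abs(np.mean(errs)) / D < 0.15

    def test_gap_pairs_on_true_frame_separation(self):
        # gap at frame 2: lag-1 pairs must only use true separations of 1 frame
        frames = np.array([0, 1, 3, 4])
        xy = np.array([[0, 0], [1, 0], [3, 0], [4, 0]], float)
        curve = compute_msd(Trajectory(0, frames, xy, 1.0))
        k1 = np.where(curve.tau == 1.0)[0][0]
        assert curve.n_pairs[k1] == 2  # (0,1) and (3,4)
        assert curve.msd[k1] == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 0.1, (100, 2)), axis=0)
        base = compute_msd(Trajectory(0, np.arange(100), xy, 0.1))
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = xy @ R.T + np.array([5.0, -2.0])
        rot = compute_msd(Trajectory(0, np.arange(100), moved, 0.1))
        np.testing.assert_allclose(rot.msd, base.msd, rtol=1e-10)


class TestEnsemble:
    def make_curve(self, msd_vals):
        n = len(msd_vals)
        return MSDCurve(np.arange(n) * 0.1, np.asarray(msd_vals, float),
                        np.ones(n, int), 0.1)

    def test_mean_fixed_point(self):
        c = self.make_curve([0, 1, 2])
        out = ensemble_msd([c, c, c])
        np.testing.assert_allclose(out.msd, c.msd)

    def test_two_curve_average(self):
        out = ensemble_msd([self.make_curve([0, 4.0]), self.make_curve([0, 8.0])])
        assert out.msd[1] == pytest.approx(6.0)
        assert out.n_pairs[1] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([])

    def test_ensemble_of_brownian_trajectories_recovers_D(self):
        D, dt = 0.03, 0.065
        rng = np.random.default_rng(8)
        curves = []
        for _ in range(30):
            xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), (500, 2)), axis=0)
            curves.append(compute_msd(Trajectory(0, np.arange(500), xy, dt)))
        ens = ensemble_msd(curves)
        D_fit, _, _ = fit_diffusivity(ens, n_lags=10)
        assert D_fit == pytest.approx(D, rel=0.1)
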
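"""Frame classification, direction labels, bout encoding, edge exclusion."""

import numpy as np
import pytest

from intermotion.discretize import (
    BoutDiscretizer,
    angular_speed_profile,
    apply_edge_exclusion,
    classify_frames,
    discretize_trajectory,
    encode_bouts,
    rotational_direction,
    saturating_angular_speed,
)
from intermotion.synthetic import GeneratorConfig, Trajectory, simulate_trajectory


def _traj_from_angles(angles_deg, radius=30.0, dt=0.2):
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return Trajectory("t", np.arange(a.size) * dt, radius * np.cos(a), radius * np.sin(a))


def _traj_from_xy(x, y, dt=0.2):
    x = np.asarray(x, dtype=float)
    return Trajectory("t", np.arange(x.size) * dt, x, np.asarray(y, dtype=float))


class TestClassifyFrames:
    def test_threshold_boundaries(self):
        # 0.35 cm in one frame-pair is a move; exactly 0.30 cm is a pause
        t = _traj_from_xy([0.0, 0.35, 0.65], [20.0, 20.0, 20.0])
        assert list(classify_frames(t)) == [True, True]
        t = _traj_from_xy([0.0, 0.30], [20.0, 20.0])
        assert list(classify_frames(t)) == [False]

    def test_identical_positions_are_pauses(self):
        t = _traj_from_xy(np.full(51, 25.0), np.zeros(51))
        labels = classify_frames(t)
        assert labels.size == 50 and not labels.any()

    def test_threshold_monotonicity(self, rng):
        cfg = GeneratorConfig(duration=600.0, seed=2)
        traj = simulate_trajectory(cfg)
        t_lo = classify_frames(traj, 0.3).sum()
        t_hi = classify_frames(traj, 0.5).sum()
        assert t_hi <= t_lo

    def test_non_uniform_spacing_rejected(self):
        with pytest.raises(ValueError):
            Trajectory("t", np.array([0.0, 0.2, 0.5]), np.zeros(3), np.zeros(3))


class TestRotationalDirection:
    def test_increasing_angle_is_acw(self):
        t = _traj_from_angles([0, 1, 2])
        assert list(rotational_direction(t)) == [1, 1]

    def test_reversal_gives_one_switch(self):
        t = _traj_from_angles([0, 1, 0])
        assert list(rotational_direction(t)) == [1, -1]

    def test_zero_cross_product_carries_forward(self):
        # pure radial motion (angle constant) has zero cross product
        t = _traj_from_xy([20.0, 20.5, 20.5, 20.5], [0.0, 0.0, 0.1, 0.1])
        d = rotational_direction(t)
        # transition 2 is ACW (y increases at fixed x>0); 1 and 3 inherit
        assert list(d) == [1, 1, 1]

    def test_matches_unwrapped_angle_oracle(self, rng):
        """Sign of the finite difference of the unwrapped polar angle is an
        independent oracle for the cross-product labels."""
        for _ in range(200):
            angles = np.cumsum(rng.uniform(-5, 5, size=100))
            t = _traj_from_angles(angles, radius=rng.uniform(20, 35))
            d = rotational_direction(t)
            phi = np.unwrap(np.arctan2(t.y, t.x))
            oracle = np.sign(np.diff(phi)).astype(int)
            nz = oracle != 0
            assert np.all(d[nz] == oracle[nz])


class TestEncodeBouts:
    def test_small_example(self):
        labels = np.array([True, True, False, False, False, True])
        dirs = np.ones(6, dtype=int)
        bouts = encode_bouts(labels, dirs, 0.2)
        assert [(b.state, pytest.approx(b.duration)) for b in bouts] == [
            ("move", 0.4), ("pause", 0.6), ("move", 0.2)
        ]

    def test_all_move_single_bout(self):
        bouts = encode_bouts(np.ones(10, dtype=bool), np.ones(10, dtype=int), 0.2)
        assert len(bouts) == 1 and bouts[0].duration == pytest.approx(2.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            encode_bouts(np.array([]), np.array([]), 0.2)

    def test_duration_conservation(self, rng):
        labels = rng.uniform(size=500) < 0.5
        bouts = encode_bouts(labels, np.ones(500, dtype=int), 0.2)
        assert sum(b.duration for b in bouts) == pytest.approx(500 * 0.2)


class TestEdgeExclusion:
    def _radial_traj(self, radii):
        r = np.asarray(radii, dtype=float)
        return Trajectory("t", np.arange(r.size) * 0.2, r, np.zeros(r.size))

    def test_interior_untouched(self):
        blocks, gaps = apply_edge_exclusion(self._radial_traj(np.full(10, 30.0)))
        assert blocks == [(0, 10)] and gaps == []

    def test_outer_wall_margin(self):
        blocks, gaps = apply_edge_exclusion(self._radial_traj([30, 38, 30]))
        assert gaps == [(1, 2)]

    def test_dome_margin(self):
        blocks, gaps = apply_edge_exclusion(self._radial_traj([30, 20.4, 30]))
        assert gaps == [(1, 2)]
        # 20.6 cm is outside the 17.5 + 3 margin: kept
        blocks, gaps = apply_edge_exclusion(self._radial_traj([30, 20.6, 30]))
        assert gaps == []

    def test_empty_annulus_rejected(self):
        with pytest.raises(ValueError):
            apply_edge_exclusion(self._radial_traj([30.0, 30.0]), margin=15.0)

    def test_block_conservation(self, rng):
        """Within each block, move + pause durations equal the block span."""
        cfg = GeneratorConfig(duration=1200.0, seed=8)
        traj = simulate_trajectory(cfg)
        seq = discretize_trajectory(traj)
        for block in seq.blocks():
            total = sum(b.duration for b in block)
            span = (block[-1].start_frame + block[-1].n_frames - block[0].start_frame) * seq.frame_dt
            assert total == pytest.approx(span)
            # strict alternation inside the block
            states = [b.state for b in block]
            assert all(a != b for a, b in zip(states, states[1:]))


class TestAngularSpeed:
    def test_saturating_form_arithmetic(self):
        # a=3, c=18 gives omega(15) = 18*15/18 = 15 degrees/s
        assert saturating_angular_speed(15.0, 3.0, 18.0) == pytest.approx(15.0)

    def test_constant_rate_recovered(self):
        t = _traj_from_angles(np.arange(100) * 2.0)  # 10 deg/s at 0.2 s frames
        seq = discretize_trajectory(t)
        prof = angular_speed_profile(seq, t, bins=[0.2, 1000.0])
        assert prof["mean"][0] == pytest.approx(10.0, rel=1e-6)

    def test_fit_recovers_parameters(self, rng):
        """Synthetic moves generated from omega(t)=18t/(3+t) plus noise."""
        from intermotion.discretize import Bout, BoutSequence

        lengths = rng.uniform(0.4, 40.0, size=300)
        a_true, c_true = 3.0, 18.0
        bouts, xs, ys, t0 = [], [], [], 0
        phi = 0.0
        frames_x, frames_y = [30.0 * np.cos(phi)], [30.0 * np.sin(phi)]
        for L in lengths:
            n = max(int(round(L / 0.2)), 1)
            omega = saturating_angular_speed(n * 0.2, a_true, c_true) + rng.normal(0, 0.5)
            step = np.radians(max(omega, 0.1) * 0.2)
            for _ in range(n):
                phi += step
                frames_x.append(30.0 * np.cos(phi))
                frames_y.append(30.0 * np.sin(phi))
            bouts.append(Bout("move", t0, n, 0.2, np.ones(n, dtype=int)))
            t0 += n
        traj = Trajectory("t", np.arange(len(frames_x)) * 0.2, np.asarray(frames_x), np.asarray(frames_y))
        seq = BoutSequence("t", bouts, 0.2)
        prof = angular_speed_profile(seq, traj, bins=[0.2, 2, 8, 40])
        assert prof["fit_a"] == pytest.approx(a_true, rel=0.25)
        assert prof["fit_c"] == pytest.approx(c_true, rel=0.1)


def test_discretizer_transformer_round_trip(short_cohort):
    trajs, truths = short_cohort
    seqs = BoutDiscretizer().transform(trajs)
    assert len(seqs) == len(trajs)
    one = BoutDiscretizer().transform(trajs[0])
    assert [(b.state, b.n_frames) for b in one.bouts] == [
        (b.state, b.n_frames) for b in seqs[0].bouts
    ]
    params = BoutDiscretizer().get_params()
    assert params["move_threshold"] == pytest.approx(0.3)
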
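"""Spatially-discretized velocities, group frame, labels, and the table."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import brute_force_crossing, make_session, stop_and_go_track
from groupinfluence import (
    build_kinematic_table,
    discretized_velocity,
    individual_kinematics,
    label_group_motion,
    leave_one_out_centroid,
    reference_frame,
)
from groupinfluence.frame import DiscretizedVelocity


class TestDiscretizedVelocity:
    def test_constant_speed_track(self):
        t = np.arange(50.0)
        v = discretized_velocity((2 * t, 0 * t), t0=0, R=10, direction="future")
        assert v.attained
        assert (v.vx, v.vy) == pytest.approx((2.0, 0.0))
        assert v.span == 5

    def test_stationary_then_step(self):
        # 20 s in place, then a 12 m relocation: effective speed is slow
        x = np.concatenate([np.zeros(20), np.full(10, 12.0)])
        v = discretized_velocity((x, np.zeros(30)), t0=0, R=10, direction="future")
        assert v.attained
        assert v.vx == pytest.approx(0.6)
        assert v.span == 20

    def test_threshold_never_crossed(self):
        x = np.linspace(0, 4, 30)
        v = discretized_velocity((x, np.zeros(30)), t0=0, R=10, direction="future")
        assert not v.attained
        assert np.isnan(v.vx)

    def test_past_direction_symmetric(self):
        t = np.arange(50.0)
        v = discretized_velocity((2 * t, 0 * t), t0=49, R=10, direction="past")
        assert v.attained and v.vx == pytest.approx(2.0)

    def test_invalid_t0_raises(self):
        x = np.arange(20.0)
        valid = np.ones(20, bool)
        valid[5] = False
        with pytest.raises(ValueError):
            discretized_velocity((x, x, valid), t0=5, R=5)

    def test_scan_stops_at_invalid_sample(self):
        x = np.arange(30.0) * 2
        valid = np.ones(30, bool)
        valid[3] = False  # break before the 10 m crossing at t=5
        v = discretized_velocity((x, 0 * x, valid), t0=0, R=10, direction="future")
        assert not v.attained

    @pytest.mark.parametrize("direction", ["past", "future"])
    @pytest.mark.parametrize("mode", ["displacement", "path"])
    def test_matches_bruteforce_on_random_tracks(self, direction, mode):
        rng = np.random.default_rng(17)
        for _ in range(60):
            x, y, valid = stop_and_go_track(rng)
            t0 = int(rng.integers(0, len(x)))
            if not valid[t0]:
                continue
            got = discretized_velocity(
                (x, y, valid), t0, R=5.0, direction=direction,
                displacement_mode=mode,
            )
            j = brute_force_crossing(
                x, y, valid, t0, 5.0, direction, use_path=(mode == "path")
            )
            assert got.attained == (j >= 0)
            if j >= 0:
                dt = abs(t0 - j)
                assert got.span == dt
                sign = 1.0 if direction == "future" else -1.0
                assert got.vx == pytest.approx(sign * (x[j] - x[t0]) / dt)


class TestCentroidAndFrame:
    def test_full_group_centroid(self):
        sess = make_session(
            x=[[0.0, 0], [2, 2], [4, 4]], y=[[0.0, 0], [0, 0], [0, 0]]
        )
        assert leave_one_out_centroid(sess, None, 0) == (2.0, 0.0)

    def test_leave_one_out_mean(self):
        sess = make_session(
            x=[[0.0, 0], [2, 2], [4, 4]], y=[[0.0, 0], [0, 0], [0, 0]]
        )
        assert leave_one_out_centroid(sess, "m02", 0) == (1.0, 0.0)

    def test_focal_only_valid_individual_gives_none(self):
        valid = [[True, True], [False, False]]
        sess = make_session(
            x=[[0.0, 0], [1, 1]], y=[[0.0, 0], [0, 0]], valid=valid
        )
        assert leave_one_out_centroid(sess, "m00", 0) is None

    def test_frame_axis_case(self):
        v = DiscretizedVelocity(t0=0, vx=0, vy=3, span=5, attained=True)
        fr = reference_frame(v, (1.0, 2.0))
        np.testing.assert_allclose(fr.front, [0, 1])
        np.testing.assert_allclose(fr.right, [1, 0])

    def test_frame_diagonal_matches_rotation_matrix(self):
        v = DiscretizedVelocity(t0=0, vx=1, vy=1, span=5, attained=True)
        fr = reference_frame(v, (0.0, 0.0))
        np.testing.assert_allclose(fr.front, [0.7071, 0.7071], atol=5e-5)
        # right = R(-90deg) @ front
        rot = np.array([[0.0, 1.0], [-1.0, 0.0]])
        np.testing.assert_allclose(fr.right, rot @ fr.front, atol=1e-12)

    @given(st.floats(0.01, 2 * np.pi - 0.01))
    def test_front_right_orthonormal(self, angle):
        v = DiscretizedVelocity(
            t0=0, vx=3 * np.cos(angle), vy=3 * np.sin(angle), span=4, attained=True
        )
        fr = reference_frame(v, (0.0, 0.0))
        assert fr.front @ fr.right == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(fr.front) == pytest.approx(1.0)
        assert np.linalg.norm(fr.right) == pytest.approx(1.0)

    def test_unattained_velocity_rejected(self):
        v = DiscretizedVelocity(t0=0, vx=np.nan, vy=np.nan, span=np.nan, attained=False)
        with pytest.raises(ValueError):
            reference_frame(v, (0.0, 0.0))


def _vel(vx, vy):
    return DiscretizedVelocity(t0=0, vx=vx, vy=vy, span=1, attained=True)


class TestLabels:
    def test_left_turn_and_slow_down(self):
        turn, speed = label_group_motion(_vel(1, 0), _vel(0.7, 0.7))
        assert turn == 0  # counterclockwise = left
        assert speed == 0  # |future| ~ 0.99 < 1

    def test_right_turn_and_speed_up(self):
        turn, speed = label_group_motion(_vel(1, 0), _vel(1, -0.5))
        assert turn == 1
        assert speed == 1

    def test_exact_ties_are_undefined(self):
        turn, speed = label_group_motion(_vel(1, 0), _vel(1, 0))
        assert turn is None and speed is None

    def test_unattained_gives_undefined(self):
        bad = DiscretizedVelocity(0, np.nan, np.nan, np.nan, False)
        assert label_group_motion(_vel(1, 0), bad) == (None, None)


class TestIndividualKinematics:
    def test_axis_aligned_projection(self):
        fr = reference_frame(_vel(1, 0), (0.0, 0.0))
        lrm, fbs, fbp = individual_kinematics(_vel(0.3, 0.4), (0, 0), fr, _vel(1, 0))
        assert lrm == pytest.approx(-0.4)  # northward = leftward here
        assert fbs == pytest.approx(0.3 - 1.0)

    def test_parallel_motion_has_zero_lrm(self):
        fr = reference_frame(_vel(2, 2), (0.0, 0.0))
        lrm, _, _ = individual_kinematics(_vel(1, 1), (0, 0), fr, _vel(2, 2))
        assert lrm == pytest.approx(0.0, abs=1e-12)

    def test_speed_diff_and_front_position(self):
        fr = reference_frame(_vel(0.5, 0), (0.0, 0.0))
        lrm, fbs, fbp = individual_kinematics(
            _vel(0.8, 0), (3.0, 0.0), fr, _vel(0.5, 0)
        )
        assert fbs == pytest.approx(0.3)
        assert fbp == pytest.approx(3.0)


class TestBuildKinematicTable:
    def test_straight_comoving_pair_has_null_predictors(self):
        T = 200
        t = np.arange(T, dtype=float)
        sess = make_session(
            x=[0.5 * t, 0.5 * t], y=[np.zeros(T), np.ones(T)]
        )
        table = build_kinematic_table(sess, R=10.0)
        df = table.df
        ok = df["lrm"].notna()
        assert ok.any()
        np.testing.assert_allclose(df.loc[ok, "lrm"], 0.0, atol=1e-9)
        np.testing.assert_allclose(df.loc[ok, "fb_speed_diff"], 0.0, atol=1e-9)
        # perfectly straight motion: no turn is ever defined
        assert not df["valid_turn"].any()

    def test_exclusion_blocks_velocity_scans(self):
        # stationary until t=100, then walking; the window [50,150) cuts every
        # scan that would need pre-window data, so no labels exist before 150
        T = 400
        x = np.concatenate([np.zeros(100), np.arange(300) * 0.5])
        sess = make_session(x=[x, x], y=[np.zeros(T), np.ones(T)])
        for tr in sess.trajectories:
            tr.valid[50:150] = False
        table = build_kinematic_table(sess, R=10.0)
        labeled = table.df[table.df["valid_speed"]]
        assert (labeled["t"] >= 150).all()

    def test_fewer_than_two_individuals_empty(self):
        T = 50
        sess = make_session(x=[np.arange(T), np.arange(T)], y=[np.zeros(T)] * 2)
        sess.trajectories = sess.trajectories[:1]
        table = build_kinematic_table(sess, R=5.0)
        assert table.df.empty

    def test_row_validity_matches_single_point_operations(self):
        """Brute-force re-derivation of each row from the scalar operations."""
        rng = np.random.default_rng(5)
        T, n = 240, 4
        heading = np.cumsum(rng.normal(0, 0.1, T))
        px = np.cumsum(0.4 * np.cos(heading))
        py = np.cumsum(0.4 * np.sin(heading))
        x = px + rng.normal(0, 1.5, (n, T))
        y = py + rng.normal(0, 1.5, (n, T))
        sess = make_session(x=x, y=y)
        table = build_kinematic_table(sess, R=8.0)
        got = {
            (r.t, r.focal_id): r
            for r in table.df.itertuples()
        }
        ids = sess.individual_ids
        count = 0
        for t in range(T):
            for f in ids:
                others = [tr for tr in sess.trajectories if tr.individual_id != f]
                lx = np.mean([tr.x[t] for tr in others])
                # leave-one-out centroid track
                Lx = np.mean([tr.x for tr in others], axis=0)
                Ly = np.mean([tr.y for tr in others], axis=0)
                past = discretized_velocity((Lx, Ly), t, 8.0, "past")
                fut = discretized_velocity((Lx, Ly), t, 8.0, "future")
                turn, speed = label_group_motion(past, fut)
                focal = next(tr for tr in sess.trajectories if tr.individual_id == f)
                fpast = discretized_velocity((focal.x, focal.y), t, 8.0, "past")
                expect_turn = turn is not None and fpast.attained
                expect_speed = speed is not None and fpast.attained
                key = (t, f)
                if expect_turn or expect_speed:
                    count += 1
                    assert key in got
                    row = got[key]
                    assert bool(row.valid_turn) == expect_turn
                    assert bool(row.valid_speed) == expect_speed
                    if expect_turn:
                        assert row.group_turn_right == turn
                    if expect_speed:
                        assert row.group_speed_up == speed
        # every emitted labeled row was also re-derived
        labeled = table.df[table.df.valid_turn | table.df.valid_speed]
        assert count == len(labeled)


@pytest.fixture(scope="module")
def wandering_session():
    rng = np.random.default_rng(23)
    T, n = 600, 5
    heading = np.cumsum(rng.normal(0, 0.08, T))
    px = np.cumsum(0.3 * np.cos(heading))
    py = np.cumsum(0.3 * np.sin(heading))
    x = px + rng.normal(0, 2.0, (n, T))
    y = py + rng.normal(0, 2.0, (n, T))
    return x, y


class TestGeometryEquivariance:
    @staticmethod
    def _table(x, y):
        return build_kinematic_table(make_session(x=x, y=y), R=10.0).df

    def test_translation_and_rotation_equivariance(self, wandering_session):
        x, y = wandering_session
        base = self._table(x, y)
        th = 0.7
        c, s = np.cos(th), np.sin(th)
        rot = self._table(c * x - s * y + 50.0, s * x + c * y - 30.0)
        for col in ("lrm", "fb_speed_diff", "fb_position", "lr_position"):
            np.testing.assert_allclose(
                rot[col].to_numpy(), base[col].to_numpy(), atol=1e-9
            )
        for col in ("group_turn_right", "group_speed_up"):
            np.testing.assert_array_equal(rot[col].to_numpy(), base[col].to_numpy())

    def test_mirror_antisymmetry(self, wandering_session):
        x, y = wandering_session
        base = self._table(x, y)
        mir = self._table(-x, y)
        np.testing.assert_allclose(
            mir["lrm"].to_numpy(), -base["lrm"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            mir["lr_position"].to_numpy(), -base["lr_position"].to_numpy(),
            atol=1e-12,
        )
        # turn labels swap, speed labels and fb quantities unchanged
        np.testing.assert_array_equal(
            mir["group_turn_right"].to_numpy(), 1.0 - base["group_turn_right"].to_numpy()
        )
        np.testing.assert_array_equal(
            mir["group_speed_up"].to_numpy(), base["group_speed_up"].to_numpy()
        )
        np.testing.assert_allclose(
            mir["fb_speed_diff"].to_numpy(), base["fb_speed_diff"].to_numpy(),
            atol=1e-12,
        )

    def test_scale_coupling(self, wandering_session):
        x, y = wandering_session
        base = self._table(x, y)
        doubled = build_kinematic_table(
            make_session(x=2 * x, y=2 * y), R=20.0
        ).df
        np.testing.assert_allclose(
            doubled["lrm"].to_numpy(), 2 * base["lrm"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            doubled["fb_position"].to_numpy(), 2 * base["fb_position"].to_numpy(),
            atol=1e-12,
        )
        np.testing.assert_array_equal(
            doubled["group_turn_right"].to_numpy(),
            base["group_turn_right"].to_numpy(),
        )
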
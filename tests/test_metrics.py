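import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palpkit import metrics as me
from palpkit.errors import DomainError, UndefinedDirectionError, UndefinedMetricError
from palpkit.trajectory import HapticCondition, TargetPoint, Trial

from conftest import make_line_trial, make_random_trial


def _trial_from_positions(t, index, target=(0.0, 0.0), condition=None):
    index = np.asarray(index, dtype=float)
    return Trial(
        "T", "P",
        condition or HapticCondition("pulse", "strong", 4, 1),
        TargetPoint(*target),
        t_s=np.asarray(t, dtype=float),
        index_tip=index,
        middle_tip=index + np.array([20.0, 0.0, 0.0]),
    )


# ---------------------------------------------------------------------------
# velocity estimation
# ---------------------------------------------------------------------------

class TestEstimateVelocity:
    def test_uniform_motion_exact(self):
        t = np.arange(20) * 0.1
        pos = np.column_stack([5.0 * t, np.zeros(20), np.zeros(20)])
        trial = _trial_from_positions(t, pos)
        v = me.estimate_velocity(trial).values
        np.testing.assert_allclose(v, np.tile([5.0, 0.0, 0.0], (20, 1)), atol=1e-12)

    def test_stationary_all_zero(self):
        t = np.arange(10) * 0.1
        trial = _trial_from_positions(t, np.ones((10, 3)))
        # timestamps built in floating point are not exactly uniform, so the
        # nonuniform-spacing formula leaves O(1e-16) residue
        np.testing.assert_allclose(me.estimate_velocity(trial).values, 0.0,
                                   atol=1e-12)

    def test_quadratic_interior_exact(self):
        # central differences are exact for quadratics on a uniform grid
        t = np.arange(0, 1.0, 0.1)
        pos = np.column_stack([t**2, np.zeros_like(t), np.zeros_like(t)])
        trial = _trial_from_positions(t, pos)
        v = me.estimate_velocity(trial).values[1:-1, 0]
        np.testing.assert_allclose(v, 2.0 * t[1:-1], atol=1e-12)

    def test_middle_finger_series(self):
        trial = make_random_trial(np.random.default_rng(0))
        v = me.estimate_velocity(trial, "middle")
        assert len(v) == trial.n_frames
        # middle tip is a rigid offset of the index tip here
        np.testing.assert_allclose(
            v.values, me.estimate_velocity(trial, "index").values, atol=1e-9
        )


# ---------------------------------------------------------------------------
# duration / TPL
# ---------------------------------------------------------------------------

class TestDuration:
    def test_simple(self):
        trial = _trial_from_positions([0.0, 12.5], np.zeros((2, 3)))
        assert me.compute_duration(trial) == 12.5

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        trial = make_random_trial(rng)
        shifted = Trial(
            trial.trial_id, trial.participant_id, trial.condition, trial.target,
            t_s=trial.t_s + 100.0, index_tip=trial.index_tip,
            middle_tip=trial.middle_tip,
        )
        assert me.compute_duration(shifted) == pytest.approx(
            me.compute_duration(trial)
        )


class TestTpl:
    def test_three_four_five(self):
        trial = _trial_from_positions([0.0, 1.0], [[0, 0, 0], [3, 4, 0]])
        assert me.compute_tpl(trial) == pytest.approx(5.0)

    def test_out_and_back(self):
        trial = _trial_from_positions(
            [0.0, 1.0, 2.0], [[0, 0, 0], [3, 4, 12], [0, 0, 0]]
        )
        assert me.compute_tpl(trial) == pytest.approx(26.0)

    def test_triangle_inequality_random_paths(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            trial = make_random_trial(rng, n_frames=100)
            straight = np.linalg.norm(trial.index_tip[-1] - trial.index_tip[0])
            assert me.compute_tpl(trial) >= straight - 1e-9

    def test_superadditivity_of_concatenation(self):
        rng = np.random.default_rng(11)
        a = make_random_trial(rng, n_frames=30)
        b = make_random_trial(rng, n_frames=30)
        t_cat = np.concatenate([a.t_s, a.t_s[-1] + 1.0 + b.t_s])
        pos_cat = np.concatenate([a.index_tip, b.index_tip])
        cat = _trial_from_positions(t_cat, pos_cat)
        link = np.linalg.norm(b.index_tip[0] - a.index_tip[-1])
        assert me.compute_tpl(cat) == pytest.approx(
            me.compute_tpl(a) + me.compute_tpl(b) + link
        )


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

class TestAccuracy:
    def test_on_target_zero(self):
        trial = _trial_from_positions(
            [0.0, 1.0], [[5, 5, 0], [0, 0, 7]], target=(0.0, 0.0)
        )
        assert me.compute_accuracy(trial) == pytest.approx(0.0)

    def test_min_of_two_fingers(self):
        # index ends 12 mm away, middle 7 mm away -> 7
        t = np.array([0.0, 1.0])
        index = np.array([[0, 0, 0], [12.0, 0.0, 0.0]])
        middle = np.array([[0, 0, 0], [0.0, 7.0, 3.0]])
        trial = Trial(
            "T", "P", HapticCondition("pulse", "strong", 4, 1),
            TargetPoint(0.0, 0.0), t, index, middle,
        )
        assert me.compute_accuracy(trial) == pytest.approx(7.0)

    def test_in_plane_only(self):
        # z displacement must not count
        trial = _trial_from_positions(
            [0.0, 1.0], [[5, 5, 0], [3.0, 4.0, 25.0]], target=(0.0, 0.0)
        )
        assert me.compute_accuracy(trial) == pytest.approx(5.0)

    @settings(max_examples=25, deadline=None)
    @given(angle=st.floats(0.0, 2 * np.pi), seed=st.integers(0, 10_000))
    def test_rotation_invariance(self, angle, seed):
        trial = make_random_trial(np.random.default_rng(seed))
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        rotated = _rotate_trial(trial, R)
        assert me.compute_accuracy(rotated) == pytest.approx(
            me.compute_accuracy(trial), abs=1e-9
        )


def _rotate_trial(trial: Trial, R: np.ndarray, shift=(0.0, 0.0)) -> Trial:
    def rot(tips):
        out = tips.copy()
        out[:, :2] = tips[:, :2] @ R.T + np.asarray(shift)
        return out

    txy = R @ trial.target.xy + np.asarray(shift)
    return Trial(
        trial.trial_id, trial.participant_id, trial.condition,
        TargetPoint(float(txy[0]), float(txy[1])),
        t_s=trial.t_s, index_tip=rot(trial.index_tip),
        middle_tip=rot(trial.middle_tip),
    )


class TestClassifyAccuracy:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.0, me.AccuracyBand.ACCURATE),
            (10.0, me.AccuracyBand.ACCURATE),
            (10.0001, me.AccuracyBand.MARGINAL),
            (23.2, me.AccuracyBand.MARGINAL),  # the study-wide mean accuracy
            (30.0, me.AccuracyBand.MARGINAL),
            (30.0001, me.AccuracyBand.ERROR),
            (1e6, me.AccuracyBand.ERROR),
        ],
    )
    def test_bands(self, value, band):
        assert me.classify_accuracy(value) is band

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            me.classify_accuracy(-0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 200.0))
    def test_band_partition(self, value):
        band = me.classify_accuracy(value)
        expected = (
            me.AccuracyBand.ACCURATE if value <= 10
            else me.AccuracyBand.MARGINAL if value <= 30
            else me.AccuracyBand.ERROR
        )
        assert band is expected


# ---------------------------------------------------------------------------
# velocity projection
# ---------------------------------------------------------------------------

class TestProjectVelocity:
    def test_head_on_approach(self):
        vp = me.project_velocity([10.0, 0.0], [-5.0, 0.0], TargetPoint(0, 0))
        assert vp == pytest.approx(5.0)

    def test_orthogonal_is_zero(self):
        vp = me.project_velocity([10.0, 0.0], [0.0, 3.0], TargetPoint(0, 0))
        assert vp == pytest.approx(0.0)

    def test_moving_away_negative(self):
        vp = me.project_velocity([10.0, 0.0], [4.0, 0.0], TargetPoint(0, 0))
        assert vp == pytest.approx(-4.0)

    def test_at_target_undefined(self):
        with pytest.raises(UndefinedDirectionError):
            me.project_velocity([0.0, 0.0], [1.0, 0.0], TargetPoint(0, 0))

    def test_equals_negative_distance_derivative(self):
        # on a smooth path, d/dt of the in-plane distance to target == -V_p
        target = TargetPoint(2.0, -3.0)
        pos = lambda t: np.array([10.0 - 3.0 * t, 4.0 + 2.0 * t * t])
        vel = lambda t: np.array([-3.0, 4.0 * t])
        dist = lambda t: np.linalg.norm(pos(t) - target.xy)
        h = 1e-6
        for t in (0.0, 0.5, 1.3):
            ddist = (dist(t + h) - dist(t - h)) / (2 * h)
            vp = me.project_velocity(pos(t), vel(t), target)
            assert vp == pytest.approx(-ddist, abs=1e-6)


# ---------------------------------------------------------------------------
# RCM / error rate
# ---------------------------------------------------------------------------

class TestRcm:
    def test_straight_onto_target_is_100(self):
        trial = make_line_trial((60.0, 0.0), (0.0, 0.0), TargetPoint(0, 0))
        assert me.compute_rcm(trial) == pytest.approx(100.0)

    def test_straight_away_is_0(self):
        trial = make_line_trial((10.0, 0.0), (70.0, 0.0), TargetPoint(0, 0))
        assert me.compute_rcm(trial) == pytest.approx(0.0)

    def test_stationary_trial_undefined(self):
        t = np.arange(10) * 0.1
        trial = _trial_from_positions(t, np.tile([5.0, 5.0, 5.0], (10, 1)))
        with pytest.raises(UndefinedMetricError):
            me.compute_rcm(trial)

    def test_brute_force_recount(self):
        # naive frame-by-frame oracle on uniform-dt random trials
        rng = np.random.default_rng(19)
        for _ in range(20):
            trial = make_random_trial(rng, n_frames=50, uniform_dt=True)
            assert me.compute_rcm(trial) == _rcm_oracle(trial)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(40):
            trial = make_random_trial(rng, n_frames=50, uniform_dt=True)
            vels = _oracle_velocities(trial)
            vp, moving = _oracle_vp_and_movement(trial, vels)
            if np.any(vp[moving] == 0.0):
                continue  # symmetry only claimed without zero-projection frames
            reversed_trial = _reverse_trial(trial)
            assert me.compute_rcm(reversed_trial) == pytest.approx(
                100.0 - me.compute_rcm(trial), abs=1e-9
            )
            checked += 1
        assert checked >= 30


def _reverse_trial(trial: Trial) -> Trial:
    return Trial(
        trial.trial_id, trial.participant_id, trial.condition, trial.target,
        t_s=(trial.t_s[-1] - trial.t_s)[::-1].copy(),
        index_tip=trial.index_tip[::-1].copy(),
        middle_tip=trial.middle_tip[::-1].copy(),
    )


def _oracle_velocities(trial: Trial) -> np.ndarray:
    """Independent finite-difference velocities (uniform dt only)."""
    pos = trial.index_tip
    dt = trial.t_s[1] - trial.t_s[0]
    n = trial.n_frames
    v = np.empty_like(pos)
    v[0] = (pos[1] - pos[0]) / dt
    v[-1] = (pos[-1] - pos[-2]) / dt
    for i in range(1, n - 1):
        v[i] = (pos[i + 1] - pos[i - 1]) / (2 * dt)
    return v


def _oracle_vp_and_movement(trial, vels, eps=me.DEFAULT_SPEED_EPS_MM_S):
    txy = trial.target.xy
    n = trial.n_frames
    vp = np.empty(n)
    moving = np.zeros(n, dtype=bool)
    for i in range(n):
        speed = float(np.linalg.norm(vels[i]))
        d = txy - trial.index_tip[i, :2]
        dist = float(np.linalg.norm(d))
        if dist == 0.0 or speed < eps:
            vp[i] = np.nan
            continue
        moving[i] = True
        vp[i] = float(vels[i, :2] @ (d / dist))
    return vp, moving


def _rcm_oracle(trial: Trial) -> float:
    vp, moving = _oracle_vp_and_movement(trial, _oracle_velocities(trial))
    return 100.0 * np.sum(vp[moving] > 0) / np.sum(moving)


class TestErrorRate:
    def test_all_within_range_zero(self):
        trial = make_line_trial((25.0, 0.0), (5.0, 0.0), TargetPoint(0, 0))
        assert me.compute_error_rate(trial) == pytest.approx(0.0)

    def test_all_beyond_range_one(self):
        trial = make_line_trial((80.0, 0.0), (40.0, 0.0), TargetPoint(0, 0))
        assert me.compute_error_rate(trial) == pytest.approx(1.0)

    def test_piecewise_manual_count(self):
        # 10 frames at distance 50, then 10 frames at distance 20, all moving in y
        t = np.arange(20) * 0.1
        y = np.arange(20) * 2.0  # constant 20 mm/s in y keeps every frame "moving"
        x = np.concatenate([np.full(10, 50.0), np.full(10, 20.0)])
        pos = np.column_stack([x, np.zeros(20), np.zeros(20)])
        pos[:, 1] = y * 0  # keep distances exact; motion comes from z instead
        pos[:, 2] = y
        trial = _trial_from_positions(t, pos, target=(0.0, 0.0))
        # frames 9 and 10 straddle the 50 -> 20 jump; all frames exceed eps speed
        expected = np.sum(x > 30.0) / 20.0
        assert me.compute_error_rate(trial) == pytest.approx(expected)

    def test_all_frames_denominator_variant(self):
        rng = np.random.default_rng(31)
        trial = make_random_trial(rng, n_frames=60, uniform_dt=True)
        dist = np.linalg.norm(trial.index_tip[:, :2] - trial.target.xy, axis=1)
        expected = np.mean(dist > 30.0)
        got = me.compute_error_rate(trial, denominator="all")
        assert got == pytest.approx(expected)

    def test_brute_force_recount(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            trial = make_random_trial(rng, n_frames=50, uniform_dt=True)
            vels = _oracle_velocities(trial)
            speeds = np.linalg.norm(vels, axis=1)
            moving = speeds >= me.DEFAULT_SPEED_EPS_MM_S
            dist = np.linalg.norm(trial.index_tip[:, :2] - trial.target.xy, axis=1)
            expected = np.sum(dist[moving] > 30.0) / np.sum(moving)
            assert me.compute_error_rate(trial) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# aggregate MetricSet
# ---------------------------------------------------------------------------

class TestComputeMetrics:
    def test_straight_to_target_profile(self):
        trial = make_line_trial((70.0, 0.0), (0.0, 0.0), TargetPoint(0, 0))
        m = me.compute_metrics(trial)
        assert m.rcm_pct == pytest.approx(100.0)
        assert m.accuracy_band is me.AccuracyBand.ACCURATE
        assert m.accurate_binary

    def test_error_rate_decreases_with_start_distance(self):
        near = me.compute_metrics(
            make_line_trial((40.0, 0.0), (0.0, 0.0), TargetPoint(0, 0))
        )
        far = me.compute_metrics(
            make_line_trial((80.0, 0.0), (0.0, 0.0), TargetPoint(0, 0))
        )
        assert far.error_rate > near.error_rate

    def test_outcome_process_dissociation(self):
        # wandering path that still ends on the target: accuracy 0, tpl large
        t = np.arange(6) * 0.5
        pos = np.array([
            [50, 0, 0], [0, 50, 0], [-50, 0, 0], [0, -50, 0], [30, 30, 0], [0, 0, 0],
        ], dtype=float)
        trial = _trial_from_positions(t, pos, target=(0.0, 0.0))
        m = me.compute_metrics(trial)
        assert m.accuracy_mm == pytest.approx(0.0)
        straight = np.linalg.norm(pos[-1] - pos[0])
        assert m.tpl_mm > 3 * straight

    def test_invariants_on_random_trial_sweep(self):
        rng = np.random.default_rng(41)
        for _ in range(1000):
            trial = make_random_trial(rng, n_frames=int(rng.integers(5, 25)))
            m = me.compute_metrics(trial)  # MetricSet validates its invariants
            straight = np.linalg.norm(trial.index_tip[-1] - trial.index_tip[0])
            assert m.tpl_mm >= straight - 1e-9
            assert me.classify_accuracy(m.accuracy_mm) is m.accuracy_band

    def test_stationary_trial_reports_missing_not_zero(self):
        t = np.arange(5) * 0.1
        trial = _trial_from_positions(t, np.tile([9.0, 0.0, 0.0], (5, 1)))
        m = me.compute_metrics(trial)
        assert m.rcm_pct is None
        assert m.error_rate is None
        assert m.accuracy_mm == pytest.approx(9.0)

    def test_rigid_motion_invariance_all_metrics(self):
        rng = np.random.default_rng(43)
        trial = make_random_trial(rng, n_frames=40, uniform_dt=True)
        angle = 1.234
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        moved = _rotate_trial(trial, R, shift=(7.5, -4.25))
        m0, m1 = me.compute_metrics(trial), me.compute_metrics(moved)
        assert m1.accuracy_mm == pytest.approx(m0.accuracy_mm, abs=1e-9)
        assert m1.duration_s == pytest.approx(m0.duration_s, abs=1e-9)
        assert m1.tpl_mm == pytest.approx(m0.tpl_mm, abs=1e-9)
        assert m1.rcm_pct == pytest.approx(m0.rcm_pct, abs=1e-9)
        assert m1.error_rate == pytest.approx(m0.error_rate, abs=1e-9)

    def test_metrics_table_layout(self):
        rng = np.random.default_rng(47)
        trials = [
            make_random_trial(rng, trial_id=f"T{k}", participant_id="P01")
            for k in range(5)
        ]
        table = me.metrics_table(trials)
        assert len(table) == 5
        for col in ("trial_id", "participant_id", "vibration_type") + me.METRIC_COLUMNS:
            assert col in table.columns
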
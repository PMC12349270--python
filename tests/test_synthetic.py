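"""Protocol structure, motion-model properties and session reproducibility."""
import numpy as np
import pytest

from shakesense.features import acceleration_norm
from shakesense.io import SensorPosition
from shakesense.synthetic import (
    MotionParams,
    Protocol,
    Risk,
    default_protocol,
    random_orientation,
    rotate_recording,
    simulate_session,
    simulate_task,
)


class TestDefaultProtocol:
    def test_task_counts(self):
        p = default_protocol()
        assert len(p.tasks) == 18
        assert sum(t.risk == Risk.HIGH_RISK for t in p.tasks) == 7
        assert sum(t.care_class.value == "daily_care" for t in p.tasks) == 5

    def test_high_risk_task_ids(self):
        p = default_protocol()
        assert {t.task_id for t in p.tasks if t.risk == Risk.HIGH_RISK} == {
            2, 4, 6, 7, 8, 10, 13,
        }

    def test_participants_and_positions(self):
        p = default_protocol()
        assert p.n_participants == 8
        assert p.positions == list(SensorPosition)

    def test_high_risk_tasks_are_shaking(self):
        assert all(
            t.care_class.value == "shaking"
            for t in default_protocol().tasks
            if t.risk == Risk.HIGH_RISK
        )


class TestSimulateTask:
    def test_duration_and_sampling(self, motion_params):
        task = default_protocol().tasks[0]
        rec, events = simulate_task(task, SensorPosition.HEAD, motion_params, seed=0)
        assert rec.n == 1500 and rec.fs == 100.0
        assert len(events) == 1
        assert events[0].start_s == 0.0 and events[0].end_s == 15.0

    def test_static_case_norm_equals_gravity(self):
        params = MotionParams(
            light_amp_g=(0.0, 0.0), noise_sd_g=0.0,
            # keep validation satisfiable with zero light amplitude
            aggressive_amp_g=(3.0, 6.0),
        )
        task = default_protocol().tasks[0]  # no-risk -> light ranges
        rec, _ = simulate_task(task, SensorPosition.HEAD, params, seed=1)
        norm = acceleration_norm(rec.ax, rec.ay, rec.az)
        np.testing.assert_allclose(norm, params.gravity_g, atol=1e-9)

    def test_deterministic_for_fixed_seed(self, motion_params):
        task = default_protocol().tasks[3]
        r1, _ = simulate_task(task, SensorPosition.CHEST, motion_params, seed=42)
        r2, _ = simulate_task(task, SensorPosition.CHEST, motion_params, seed=42)
        np.testing.assert_array_equal(r1.accel(), r2.accel())

    def test_labels_follow_task_class(self, motion_params):
        p = default_protocol()
        labels = {}
        for t in p.tasks:
            _, events = simulate_task(t, SensorPosition.HEAD, motion_params, seed=t.task_id)
            labels[t.task_id] = events[0].label
        assert labels[2] == "aggressive"
        assert labels[1] == "light"
        assert labels[17] == "daily_care"

    def test_event_covers_every_sample(self, motion_params):
        task = default_protocol().tasks[10]  # throw-and-catch
        rec, events = simulate_task(task, SensorPosition.HEAD, motion_params, seed=5)
        ev = events[0]
        t = rec.t
        assert np.all((t >= ev.start_s) & (t < ev.end_s))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="aggressive"):
            MotionParams(aggressive_amp_g=(0.5, 1.0)).validate()
        with pytest.raises(ValueError, match="light"):
            MotionParams(light_amp_g=(0.3, 2.0)).validate()


class TestThresholdSeparation:
    """The LED-threshold analogue separates the classes by construction,
    measured at the motion's full-amplitude sensor site."""

    def _source_position(self, task):
        return SensorPosition.LEFT_ARM if task.motion_site == "arms" else SensorPosition.HEAD

    def test_high_risk_peaks_exceed_threshold(self, motion_params):
        tasks = [t for t in default_protocol().tasks if t.risk == Risk.HIGH_RISK]
        for i in range(100):
            task = tasks[i % len(tasks)]
            rec, _ = simulate_task(
                task, self._source_position(task), motion_params, seed=10_000 + i
            )
            peak = acceleration_norm(rec.ax, rec.ay, rec.az).max()
            assert peak > motion_params.threshold_g, (task.task_id, peak)

    def test_no_risk_peaks_stay_below_threshold(self, motion_params):
        tasks = [t for t in default_protocol().tasks if t.risk == Risk.NO_RISK]
        for i in range(100):
            task = tasks[i % len(tasks)]
            rec, _ = simulate_task(
                task, self._source_position(task), motion_params, seed=20_000 + i
            )
            peak = acceleration_norm(rec.ax, rec.ay, rec.az).max()
            assert peak < motion_params.threshold_g, (task.task_id, peak)


class TestRandomOrientation:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_proper_rotation(self, seed):
        R = random_orientation(seed)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_composition_is_rotation(self):
        R = random_orientation(1) @ random_orientation(2)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_identity_rotation_leaves_channels_unchanged(self, small_session):
        rec = small_session.entries[0].recording
        out = rotate_recording(rec, np.eye(3))
        np.testing.assert_array_equal(out.accel(), rec.accel())

    def test_rotation_preserves_norm(self, small_session, rng):
        rec = small_session.entries[0].recording
        norm0 = acceleration_norm(rec.ax, rec.ay, rec.az)
        for seed in range(5):
            rot = rotate_recording(rec, random_orientation(seed))
            norm1 = acceleration_norm(rot.ax, rot.ay, rot.az)
            np.testing.assert_allclose(norm1, norm0, atol=1e-9)


class TestSimulateSession:
    def test_default_protocol_bookkeeping(self, motion_params):
        session = simulate_session(default_protocol(), motion_params, seed=3)
        counts = session.task_label_counts()
        assert counts["n_tasks"] == 144
        assert counts["n_aggressive"] == 56
        assert counts["n_non_aggressive"] == 88
        assert session.n_recordings == 864

    def test_single_participant_single_position(self, motion_params):
        base = default_protocol()
        proto = Protocol(tasks=base.tasks, n_participants=1,
                         positions=[SensorPosition.HEAD])
        session = simulate_session(proto, motion_params, seed=0)
        assert session.n_recordings == 18

    def test_same_seed_reproduces_bytes(self, tmp_path, small_protocol, motion_params):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_session(small_protocol, motion_params, seed=11, out_dir=d1)
        simulate_session(small_protocol, motion_params, seed=11, out_dir=d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_different_seeds_differ(self, small_protocol, motion_params):
        s1 = simulate_session(small_protocol, motion_params, seed=1)
        s2 = simulate_session(small_protocol, motion_params, seed=2)
        assert not np.array_equal(
            s1.entries[0].recording.accel(), s2.entries[0].recording.accel()
        )

    def test_sensors_share_task_motion_but_not_noise(self, motion_params):
        """All six sensors observe the same drawn amplitude/frequency, but
        orientation and noise are per-sensor."""
        session = simulate_session(default_protocol(), motion_params, seed=9)
        e_head = session.entries[0]
        e_chest = session.entries[1]
        assert (e_head.participant_id, e_head.task_id) == (
            e_chest.participant_id, e_chest.task_id,
        )
        assert not np.array_equal(e_head.recording.accel(), e_chest.recording.accel())
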
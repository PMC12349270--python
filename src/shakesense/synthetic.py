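"""Synthetic labeled IMU sessions emulating the infant-handling study protocol.

The generator reproduces the structure of the data-collection protocol:
8 participants each perform 18 fifteen-second tasks (7 high-risk shaking
tasks, 6 light shaking tasks, 5 daily-care tasks) while 6 IMU sensors record
at 100 Hz.  The motion model is deliberately simple: the sensed specific
force is a fixed, randomly oriented gravity vector plus a sinusoid directed
along the task's shake axis (with per-cycle amplitude/frequency jitter) plus
white noise.  Aggressive tasks use amplitudes that drive the peak
acceleration norm above the doll's "LED" threshold analogue; light and
daily-care tasks stay below it by construction.  Two tasks get dedicated
patterns: the playful throw (brief free-fall, norm dropping toward zero,
followed by a catch impulse) and burping (gentle rocking plus patting
impulses).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    DEFAULT_FS,
    AnnotationEvent,
    ImuRecording,
    SensorPosition,
    Session,
    SessionEntry,
    save_session,
)

__all__ = [
    "TaskSpec",
    "MotionParams",
    "Protocol",
    "default_protocol",
    "simulate_task",
    "simulate_session",
    "random_orientation",
    "rotate_recording",
]


class Risk(str, Enum):
    NO_RISK = "no_risk"
    HIGH_RISK = "high_risk"


class CareClass(str, Enum):
    SHAKING = "shaking"
    DAILY_CARE = "daily_care"


class ShakeAxis(str, Enum):
    VERTICAL = "vertical"
    FORE_AFT = "fore_aft"
    LATERAL = "lateral"
    MIXED = "mixed"


@dataclass(frozen=True)
class TaskSpec:
    """One protocol task: what motion is performed and how it is labeled.

    ``motion_site`` says where the motion originates (trunk-shaking vs
    arm-swing tasks transmit differently to the sensors); ``pattern`` selects
    the motion model (plain oscillation, throw-and-catch, or patting).
    """

    task_id: int
    name: str
    risk: Risk
    care_class: CareClass
    shake_axis: Optional[ShakeAxis] = None
    duration_s: float = 15.0
    motion_site: str = "trunk"  # "trunk" | "arms"
    pattern: str = "shake"  # "shake" | "throw_catch" | "patting"

    def __post_init__(self) -> None:
        if not 1 <= self.task_id <= 18:
            raise ValueError(f"task_id must be in 1..18, got {self.task_id}")
        if self.risk == Risk.HIGH_RISK and self.care_class != CareClass.SHAKING:
            raise ValueError("high-risk tasks must be shaking tasks")

    @property
    def annotation_label(self) -> str:
        if self.risk == Risk.HIGH_RISK:
            return "aggressive"
        if self.care_class == CareClass.DAILY_CARE:
            return "daily_care"
        return "light"


@dataclass
class MotionParams:
    """Tunable magnitudes of the motion model, all in g / Hz.

    The aggressive amplitude range must place the peak acceleration norm
    above ``threshold_g`` at a full-amplitude sensor even after -10% jitter
    (worst case: shake axis orthogonal to gravity, peak = sqrt(g^2 + a^2)),
    and the light range must keep it below even after +10% jitter (worst
    case: axis aligned with gravity, peak = g + a).
    """

    aggressive_freq_hz: tuple[float, float] = (3.0, 5.0)
    aggressive_amp_g: tuple[float, float] = (3.0, 6.0)
    light_freq_hz: tuple[float, float] = (1.0, 2.0)
    light_amp_g: tuple[float, float] = (0.3, 1.0)
    care_freq_hz: tuple[float, float] = (0.3, 1.0)
    care_amp_g: tuple[float, float] = (0.1, 0.5)
    noise_sd_g: float = 0.05
    gravity_g: float = 1.0
    threshold_g: float = 2.5
    cycle_jitter: float = 0.10
    #: per-position amplitude multipliers during trunk-shaking tasks
    attenuation_trunk: dict[SensorPosition, float] = field(
        default_factory=lambda: {
            SensorPosition.HEAD: 1.0,
            SensorPosition.CHEST: 1.0,
            SensorPosition.LEFT_ARM: 0.9,
            SensorPosition.RIGHT_ARM: 0.9,
            SensorPosition.LEFT_LEG: 0.8,
            SensorPosition.RIGHT_LEG: 0.8,
        }
    )
    #: per-position amplitude multipliers during arm-swing tasks
    attenuation_arms: dict[SensorPosition, float] = field(
        default_factory=lambda: {
            SensorPosition.HEAD: 0.6,
            SensorPosition.CHEST: 0.6,
            SensorPosition.LEFT_ARM: 1.0,
            SensorPosition.RIGHT_ARM: 1.0,
            SensorPosition.LEFT_LEG: 0.6,
            SensorPosition.RIGHT_LEG: 0.6,
        }
    )

    def validate(self) -> None:
        for name in ("noise_sd_g", "gravity_g", "threshold_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in (
            "aggressive_freq_hz",
            "aggressive_amp_g",
            "light_freq_hz",
            "light_amp_g",
            "care_freq_hz",
            "care_amp_g",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a nonnegative (lo, hi) range")
        j = self.cycle_jitter
        agg_min_peak = math.hypot(self.gravity_g, self.aggressive_amp_g[0] * (1 - j))
        if agg_min_peak <= self.threshold_g:
            raise ValueError(
                "aggressive amplitude range cannot guarantee a peak norm above "
                f"threshold_g ({agg_min_peak:.3f} <= {self.threshold_g})"
            )
        light_max_peak = self.gravity_g + self.light_amp_g[1] * (1 + j)
        if light_max_peak >= self.threshold_g:
            raise ValueError(
                "light amplitude range cannot guarantee a peak norm below "
                f"threshold_g ({light_max_peak:.3f} >= {self.threshold_g})"
            )

    def attenuation(self, task: TaskSpec, position: SensorPosition) -> float:
        table = self.attenuation_arms if task.motion_site == "arms" else self.attenuation_trunk
        return table[position]

    def ranges_for(self, task: TaskSpec) -> tuple[tuple[float, float], tuple[float, float]]:
        """(amplitude range, frequency range) for a task's intensity class."""
        if task.risk == Risk.HIGH_RISK:
            return self.aggressive_amp_g, self.aggressive_freq_hz
        if task.care_class == CareClass.DAILY_CARE:
            return self.care_amp_g, self.care_freq_hz
        return self.light_amp_g, self.light_freq_hz


@dataclass
class Protocol:
    """An ordered task list plus who performs it and which sensors record it."""

    tasks: list[TaskSpec]
    n_participants: int = 8
    positions: list[SensorPosition] = field(default_factory=lambda: list(SensorPosition))

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not self.tasks:
            raise ValueError("protocol needs at least one task")


_TASK_TABLE = [
    # (id, name, risk, care, axis, site, pattern)
    (1, "Gently shake the doll up and down", Risk.NO_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "trunk", "shake"),
    (2, "Vigorously shake the doll up and down", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "trunk", "shake"),
    (3, "Lightly shake the doll forward and back", Risk.NO_RISK, CareClass.SHAKING, ShakeAxis.FORE_AFT, "trunk", "shake"),
    (4, "Shake the doll forward and back aggressively", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.FORE_AFT, "trunk", "shake"),
    (5, "Slowly shake the doll side to side", Risk.NO_RISK, CareClass.SHAKING, ShakeAxis.LATERAL, "trunk", "shake"),
    (6, "Quickly shake the doll side to side", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.LATERAL, "trunk", "shake"),
    (7, "Aggressively shake the doll head-down by the legs", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.MIXED, "trunk", "shake"),
    (8, "Aggressively shake the doll by the shoulders", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.FORE_AFT, "trunk", "shake"),
    (9, "Swing the doll's arms slowly or playfully", Risk.NO_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "arms", "shake"),
    (10, "Swing the doll's arms aggressively", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "arms", "shake"),
    (11, "Throw the doll up in the air and catch playfully", Risk.NO_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "trunk", "throw_catch"),
    (12, "Lift and lower the doll above the head at normal speed", Risk.NO_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "trunk", "shake"),
    (13, "Lift and lower the doll above the head aggressively", Risk.HIGH_RISK, CareClass.SHAKING, ShakeAxis.VERTICAL, "trunk", "shake"),
    (14, "Simulate the diaper-changing process", Risk.NO_RISK, CareClass.DAILY_CARE, ShakeAxis.MIXED, "trunk", "shake"),
    (15, "Gently bounce the doll seated on the leg", Risk.NO_RISK, CareClass.DAILY_CARE, ShakeAxis.VERTICAL, "trunk", "shake"),
    (16, "Move the doll's arms as if gently playing", Risk.NO_RISK, CareClass.DAILY_CARE, ShakeAxis.MIXED, "arms", "shake"),
    (17, "Pat the doll's back to aid with burping", Risk.NO_RISK, CareClass.DAILY_CARE, ShakeAxis.FORE_AFT, "trunk", "patting"),
    (18, "Hold the doll cradled in both arms", Risk.NO_RISK, CareClass.DAILY_CARE, ShakeAxis.LATERAL, "trunk", "shake"),
]


def default_protocol() -> Protocol:
    """The default 18-task protocol: 7 high-risk shaking tasks, 6 light
    shaking tasks and 5 daily-care tasks, performed by 8 participants and
    recorded at all 6 sensor positions."""
    tasks = [
        TaskSpec(task_id=i, name=name, risk=risk, care_class=care,
                 shake_axis=axis, motion_site=site, pattern=pattern)
        for i, name, risk, care, axis, site, pattern in _TASK_TABLE
    ]
    return Protocol(tasks=tasks, n_participants=8, positions=list(SensorPosition))


# ---------------------------------------------------------------------------
# orientation


def random_orientation(seed) -> np.ndarray:
    """A uniformly random proper rotation matrix (det +1, orthonormal).

    Drawn via a normalized random quaternion.  ``seed`` may be an int or a
    numpy Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotate_recording(rec: ImuRecording, R: np.ndarray) -> ImuRecording:
    """Apply a rotation to the raw acceleration axes of a recording."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    return rec.with_accel(R @ rec.accel())


_AXIS_VECTORS = {
    ShakeAxis.VERTICAL: np.array([0.0, 0.0, 1.0]),
    ShakeAxis.FORE_AFT: np.array([1.0, 0.0, 0.0]),
    ShakeAxis.LATERAL: np.array([0.0, 1.0, 0.0]),
}


def _jittered_oscillation(
    n: int, fs: float, amp: float, freq: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """A sinusoid whose amplitude and frequency are redrawn every cycle
    (uniform +/- jitter), sampled at fs."""
    if amp == 0.0 or freq == 0.0:
        return np.zeros(n)
    out = np.empty(n)
    i = 0
    t_local = 0.0
    while i < n:
        f_c = freq * (1.0 + rng.uniform(-jitter, jitter))
        a_c = amp * (1.0 + rng.uniform(-jitter, jitter))
        n_c = max(1, int(round(fs / f_c)))  # samples in this cycle
        n_c = min(n_c, n - i)
        tt = (np.arange(n_c) / fs) * f_c  # cycle phase in [0, ~1)
        out[i : i + n_c] = a_c * np.sin(2.0 * np.pi * tt)
        i += n_c
    return out


def _throw_catch_profile(
    n: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(gravity envelope, axial impulse) for the playful throw-and-catch task.

    During flight the sensor is in free fall and reads ~0 specific force; the
    catch is a brief half-sine impulse along the vertical.  Impulse amplitude
    is capped so the peak norm stays well below the aggressive threshold.
    """
    envelope = np.ones(n)
    impulse = np.zeros(n)
    t = 0.0
    while True:
        hold = rng.uniform(0.8, 1.4)
        flight = rng.uniform(0.3, 0.5)
        catch = rng.uniform(0.10, 0.16)
        start_flight = int(round((t + hold) * fs))
        end_flight = int(round((t + hold + flight) * fs))
        end_catch = int(round((t + hold + flight + catch) * fs))
        if end_catch >= n:
            break
        envelope[start_flight:end_flight] = 0.0
        k = end_catch - end_flight
        amp = rng.uniform(0.7, 1.1)
        impulse[end_flight:end_catch] = amp * np.sin(np.pi * np.arange(k) / max(k, 1))
        t += hold + flight + catch
    return envelope, impulse


def _patting_impulses(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Brief Gaussian-shaped pats at ~1.5 Hz, amplitude ~0.6 g."""
    out = np.zeros(n)
    t = rng.uniform(0.3, 0.8)
    width = 0.04  # s
    idx = np.arange(n)
    while t * fs < n:
        amp = rng.uniform(0.4, 0.6)
        out += amp * np.exp(-0.5 * ((idx / fs - t) / width) ** 2)
        t += rng.uniform(0.5, 0.9)
    return out


def simulate_task(
    task: TaskSpec,
    position: SensorPosition,
    params: MotionParams,
    seed,
    fs: float = DEFAULT_FS,
    amp: Optional[float] = None,
    freq: Optional[float] = None,
    recording_id: Optional[str] = None,
    participant_id: str = "",
) -> tuple[ImuRecording, list[AnnotationEvent]]:
    """Simulate one sensor's recording of one task, with its annotation.

    ``amp``/``freq`` override the per-task draw (the session generator draws
    them once per participant-task so all six sensors see the same motion).
    Deterministic for a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    position = SensorPosition(position)
    n = int(round(task.duration_s * fs))
    amp_range, freq_range = params.ranges_for(task)
    if amp is None:
        amp = rng.uniform(*amp_range)
    if freq is None:
        freq = rng.uniform(*freq_range)
    att = params.attenuation(task, position)

    R = random_orientation(rng)
    g_sensor = R @ np.array([0.0, 0.0, params.gravity_g])
    axis = task.shake_axis or ShakeAxis.MIXED
    if axis == ShakeAxis.MIXED:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
    else:
        v = _AXIS_VECTORS[axis]
    axis_sensor = R @ v

    gravity_env = np.ones(n)
    osc = _jittered_oscillation(n, fs, amp * att, freq, params.cycle_jitter, rng)
    if task.pattern == "throw_catch":
        gravity_env, impulse = _throw_catch_profile(n, fs, rng)
        osc = 0.1 * osc * gravity_env + impulse * att
    elif task.pattern == "patting":
        osc = osc + _patting_impulses(n, fs, rng) * att

    acc = (
        g_sensor[:, None] * gravity_env[None, :]
        + axis_sensor[:, None] * osc[None, :]
        + rng.normal(0.0, params.noise_sd_g, size=(3, n))
    )
    t = np.arange(n) / fs
    rid = recording_id or f"{participant_id or 'P00'}_T{task.task_id:02d}_{position.value}"
    rec = ImuRecording(
        recording_id=rid,
        position=position,
        fs=fs,
        t=t,
        ax=acc[0],
        ay=acc[1],
        az=acc[2],
        participant_id=participant_id,
        task_id=task.task_id,
    )
    events = [AnnotationEvent(label=task.annotation_label, start_s=0.0, end_s=task.duration_s)]
    return rec, events


def simulate_session(
    protocol: Protocol,
    params: MotionParams,
    seed: int,
    out_dir: Optional[str | Path] = None,
    fs: float = DEFAULT_FS,
) -> Session:
    """Simulate a full session: one recording per (participant, task, position).

    Amplitude and base frequency are drawn once per (participant, task) so all
    sensors observe the same underlying motion (scaled by per-position
    attenuation), with independent orientation and noise per sensor.  Fully
    reproducible for a fixed seed; when ``out_dir`` is given the session is
    also written to disk with a manifest recording the seed.
    """
    params.validate()
    root = np.random.SeedSequence(seed)
    children = root.spawn(protocol.n_participants * len(protocol.tasks))
    entries: list[SessionEntry] = []
    k = 0
    for p in range(protocol.n_participants):
        pid = f"P{p + 1:02d}"
        for task in protocol.tasks:
            rng_pt = np.random.default_rng(children[k])
            k += 1
            amp_range, freq_range = params.ranges_for(task)
            amp = rng_pt.uniform(*amp_range)
            freq = rng_pt.uniform(*freq_range)
            for position in protocol.positions:
                rec, events = simulate_task(
                    task,
                    position,
                    params,
                    seed=rng_pt,
                    fs=fs,
                    amp=amp,
                    freq=freq,
                    participant_id=pid,
                )
                entries.append(
                    SessionEntry(
                        recording=rec,
                        events=events,
                        participant_id=pid,
                        task_id=task.task_id,
                        position=SensorPosition(position),
                    )
                )
    session = Session(session_id=f"sim-{seed}", entries=entries, seed=seed)
    if out_dir is not None:
        save_session(session, out_dir, fs=fs)
    return session
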
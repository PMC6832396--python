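"""Synthetic EMG and IMU sessions with known ground truth.

No public dataset accompanies this control problem, so every pipeline
stage is exercised against generated signals whose ground truth is known
by construction:

* **EMG** — each channel is baseline Gaussian noise plus band-limited
  (20-450 Hz) Gaussian noise amplitude-modulated by a trapezoidal
  activation profile, the standard phenomenological surface-EMG model.
  A configurable fraction ``kappa`` of each activation leaks into the
  opposite channel to emulate co-contraction.
* **IMU** — irregular ~47 Hz timestamps (Gaussian jitter, random sample
  drops) carrying a constant gravity offset, sensor noise, and short
  Gaussian-windowed oscillatory bursts whose energy is distributed over
  the six axes according to a per-class unit signature vector.  Class
  identity therefore lives exactly where the feature extractor looks:
  in the per-axis RMS of the differenced signal.

A ``simulated_user`` policy turns instructed state transitions into
executed actions, optionally confusing the two activations, which lets the
whole validation protocol run end to end on a desk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .emg import EmgRecording
from .errors import ScriptError
from .fsm import HandState, Modality, MovementClass
from .imu import ImuStream

EMG_ACTIONS = ("muscle1", "muscle2", "rest")
IMU_ACTIONS = ("movement1", "movement2", "rest")

#: Muscle -> command mapping implied by the hysteresis conditions
#: (muscle 1 high closes, muscle 2 high opens); configurable downstream.
EMG_ACTION_COMMAND = {"muscle1": HandState.HC, "muscle2": HandState.HO}
IMU_ACTION_COMMAND = {"movement1": HandState.HO, "movement2": HandState.HC}
IMU_ACTION_CLASS = {"movement1": MovementClass.CLASS1, "movement2": MovementClass.CLASS2}


@dataclass(frozen=True)
class Instruction:
    """One scripted action: start a contraction, relax, or perform a burst."""

    time: float
    action: str


@dataclass
class ScriptedSession:
    """Time-ordered instructions plus total session duration."""

    instructions: list[Instruction]
    duration: float

    def __post_init__(self) -> None:
        times = [i.time for i in self.instructions]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ScriptError("instruction times must be non-decreasing")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ScriptError("instruction times must lie within the session")


@dataclass(frozen=True)
class GroundTruthEvent:
    """Intended command at an instructed time (the decoding target)."""

    time: float
    command: HandState
    action: str


@dataclass
class EmgSynthConfig:
    fs: float = 5000.0
    baseline_sigma: float = 0.01  # raw units
    contraction_amplitude: float = 0.8  # fraction of the VC reference
    cocontraction_kappa: float = 0.0  # leakage into the opposite channel
    emg_band: tuple[float, float] = (20.0, 450.0)
    rise_fall: float = 0.2  # s, trapezoid ramp
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cocontraction_kappa < 1.0):
            raise ValueError("kappa must lie in [0, 1)")
        lo, hi = self.emg_band
        if not (0.0 < lo < hi < self.fs / 2):
            raise ValueError("EMG band must lie within (0, fs/2)")


#: Default class signatures: class 1 lives on accel-x/gyro-x, class 2 on
#: accel-y/gyro-y — orthogonal axis-energy patterns, as produced by two
#: distinct movement directions.
_SIG1 = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0]) / np.sqrt(2)
_SIG2 = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 0.0]) / np.sqrt(2)


@dataclass
class ImuSynthConfig:
    nominal_fs: float = 47.0
    jitter_sigma: float = 0.002  # s
    drop_prob: float = 0.05  # per-sample drop probability
    class_signatures: tuple[np.ndarray, np.ndarray] = (_SIG1, _SIG2)
    signature_angle_noise: float = 0.0  # rad, per-movement signature wobble
    common_mode: float = 0.4  # class-independent all-axis motion fraction
    burst_duration: float = 0.4  # s
    burst_amplitude: float = 8.0  # sensor units
    burst_freq: float = 8.0  # Hz, oscillation inside the burst
    noise_sigma: float = 0.05  # sensor units
    gravity: float = 9.81  # constant accel-z offset
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.drop_prob < 0.5):
            raise ValueError("drop_prob must lie in [0, 0.5)")
        s1 = np.asarray(self.class_signatures[0], dtype=float)
        s2 = np.asarray(self.class_signatures[1], dtype=float)
        if s1.shape != (6,) or s2.shape != (6,):
            raise ValueError("class signatures must be 6-dimensional")
        s1, s2 = s1 / np.linalg.norm(s1), s2 / np.linalg.norm(s2)
        if abs(float(s1 @ s2)) > 1.0 - 1e-9:
            raise ValueError("class signatures must not be collinear")
        self.class_signatures = (s1, s2)


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    sos = _sig.butter(4, band, "bandpass", fs=fs, output="sos")
    x = _sig.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _activation_intervals(
    script: ScriptedSession, actions: Sequence[str]
) -> dict[str, list[tuple[float, float]]]:
    """Resolve start-contraction / relax instructions into hold intervals.

    A muscle action starts an activation of that channel which persists
    until the next ``rest`` instruction (or the session end); a second
    activation of an already-active channel is a script error.
    """
    intervals: dict[str, list[tuple[float, float]]] = {a: [] for a in actions[:2]}
    open_since: dict[str, float] = {}
    for instr in script.instructions:
        if instr.action == "rest":
            for act, t0 in open_since.items():
                intervals[act].append((t0, instr.time))
            open_since.clear()
        elif instr.action in intervals:
            if instr.action in open_since:
                raise ScriptError(
                    f"{instr.action} re-activated at t={instr.time} while still active"
                )
            open_since[instr.action] = instr.time
        else:
            raise ScriptError(f"unknown action {instr.action!r}")
    for act, t0 in open_since.items():
        intervals[act].append((t0, script.duration))
    return intervals


def _trapezoid(t: np.ndarray, t0: float, t1: float, ramp: float) -> np.ndarray:
    """Unit trapezoid: ramps up over [t0, t0+ramp], down over [t1, t1+ramp]."""
    up = np.clip((t - t0) / ramp, 0.0, 1.0) if ramp > 0 else (t >= t0).astype(float)
    down = np.clip((t1 + ramp - t) / ramp, 0.0, 1.0) if ramp > 0 else (t < t1).astype(float)
    return np.minimum(up, down)


def synth_emg_session(
    script: ScriptedSession,
    config: EmgSynthConfig,
    amplitude: float | None = None,
) -> tuple[EmgRecording, list[GroundTruthEvent]]:
    """Generate a two-channel EMG recording following a script.

    ``amplitude`` (raw units; default ``config.contraction_amplitude``,
    which is a fraction of the VC reference amplitude 1.0) scales every
    contraction.  Returns the recording plus the intended command list:
    a muscle-1 hold targets HC, a muscle-2 hold targets HO, and each
    ``rest`` targets RS.
    """
    rng = np.random.default_rng(config.seed)
    amp = config.contraction_amplitude if amplitude is None else amplitude
    n = int(round(script.duration * config.fs))
    t = np.arange(n) / config.fs

    intervals = _activation_intervals(script, EMG_ACTIONS)
    data = config.baseline_sigma * rng.standard_normal((n, 2))
    for ch, act in enumerate(("muscle1", "muscle2")):
        if not intervals[act]:
            continue
        carrier = _bandlimited_noise(n, config.fs, config.emg_band, rng)
        profile = np.zeros(n)
        for t0, t1 in intervals[act]:
            profile += _trapezoid(t, t0, t1, config.rise_fall)
        burst = amp * np.minimum(profile, 1.0) * carrier
        data[:, ch] += burst
        if config.cocontraction_kappa > 0:
            data[:, 1 - ch] += config.cocontraction_kappa * burst

    truth = []
    for instr in script.instructions:
        cmd = HandState.RS if instr.action == "rest" else EMG_ACTION_COMMAND[instr.action]
        truth.append(GroundTruthEvent(instr.time, cmd, instr.action))
    return EmgRecording(data, fs=config.fs), truth


def synth_emg_calibration(
    config: EmgSynthConfig,
    vc_duration: float = 4.0,
    rest_duration: float = 2.0,
) -> tuple[EmgRecording, EmgRecording]:
    """Rest and VC recordings for EMG calibration.

    The VC recording holds muscle 1 at the full VC amplitude (1.0 raw
    units) for ``vc_duration`` seconds, then muscle 2, with 1 s margins —
    one strong contraction per channel, as a calibration session records.
    """
    rest_script = ScriptedSession([], duration=rest_duration)
    rest, _ = synth_emg_session(rest_script, config)

    m1_start, m2_start = 1.0, vc_duration + 3.0
    vc_script = ScriptedSession(
        [
            Instruction(m1_start, "muscle1"),
            Instruction(m1_start + vc_duration, "rest"),
            Instruction(m2_start, "muscle2"),
            Instruction(m2_start + vc_duration, "rest"),
        ],
        duration=m2_start + vc_duration + 1.0,
    )
    vc, _ = synth_emg_session(vc_script, replace(config, seed=config.seed + 1),
                              amplitude=1.0)
    return rest, vc


def _perturbed_signature(sig: np.ndarray, angle_noise: float, rng) -> np.ndarray:
    """Rotate a unit signature by ~``angle_noise`` radians in a random direction."""
    if angle_noise <= 0:
        return sig
    perp = rng.standard_normal(6)
    perp -= (perp @ sig) * sig
    norm = np.linalg.norm(perp)
    if norm == 0:
        return sig
    angle = rng.normal(0.0, angle_noise)
    return np.cos(angle) * sig + np.sin(angle) * (perp / norm)


def synth_imu_session(
    script: ScriptedSession,
    config: ImuSynthConfig,
) -> tuple[ImuStream, list[GroundTruthEvent]]:
    """Generate a 6-axis IMU stream with movement bursts per the script.

    Timestamps are a nominal-rate grid with Gaussian jitter and random
    drops.  Each ``movement1``/``movement2`` instruction becomes a
    Gaussian-windowed oscillation of ``burst_duration`` starting at the
    instruction time, spread over axes by the (noise-perturbed) class
    signature.  ``rest`` instructions are no-ops for signal synthesis.
    Movements must be separated by more than burst_duration + 1 s (the
    detector's refractory period).
    """
    rng = np.random.default_rng(config.seed)
    moves = [i for i in script.instructions if i.action in ("movement1", "movement2")]
    for a, b in zip(moves, moves[1:]):
        if b.time - a.time <= config.burst_duration + 1.0:
            raise ScriptError(
                f"movements at t={a.time} and t={b.time} are closer than "
                f"burst_duration + 1 s refractory"
            )

    grid = np.arange(0.0, script.duration, 1.0 / config.nominal_fs)
    ts = grid + rng.normal(0.0, config.jitter_sigma, grid.shape)
    ts = ts[rng.random(grid.shape) >= config.drop_prob]
    ts.sort()
    ts = ts[np.concatenate([[True], np.diff(ts) > 1e-9])]

    n = ts.shape[0]
    data = config.noise_sigma * rng.standard_normal((n, 6))
    data[:, 2] += config.gravity  # accel z

    truth = []
    for instr in moves:
        cls = IMU_ACTION_CLASS[instr.action]
        sig = _perturbed_signature(
            config.class_signatures[int(cls) - 1], config.signature_angle_noise, rng
        )
        # any real movement shakes every axis a little: superpose a
        # class-independent common-mode component so no channel is
        # noise-only (class identity stays in the signature part)
        if config.common_mode > 0:
            sig = sig + config.common_mode * np.ones(6) / np.sqrt(6)
            sig = sig / np.linalg.norm(sig)
        tc = instr.time + config.burst_duration / 2.0
        width = config.burst_duration / 4.0
        phase = rng.uniform(0.0, 2.0 * np.pi)
        mask = np.abs(ts - tc) <= config.burst_duration
        osc = np.sin(2.0 * np.pi * config.burst_freq * (ts[mask] - tc) + phase)
        envelope = np.exp(-0.5 * ((ts[mask] - tc) / width) ** 2)
        data[mask] += config.burst_amplitude * np.outer(envelope * osc, sig)
        truth.append(GroundTruthEvent(tc, IMU_ACTION_COMMAND[instr.action], instr.action))

    stream = ImuStream(ts, data[:, :3], data[:, 3:])
    return stream, truth


def synth_imu_calibration(
    config: ImuSynthConfig,
    n_per_class: int = 10,
    spacing: float = 2.0,
) -> tuple[ImuStream, list[GroundTruthEvent]]:
    """A labelled calibration session: repeated movements of each class.

    Emulates the calibration procedure of executing each movement many
    times with short rests in between; the two classes are recorded in
    consecutive blocks.
    """
    instrs = []
    t = 1.0
    for action in ("movement1", "movement2"):
        for _ in range(n_per_class):
            instrs.append(Instruction(t, action))
            t += spacing
        t += 1.0
    script = ScriptedSession(instrs, duration=t + 1.0)
    return synth_imu_session(script, config)


@dataclass
class SimulatedUser:
    """Policy mapping instructed transitions to executed actions.

    With probability ``confusion_rate`` an activation instruction is
    executed with the wrong muscle/movement.  Release instructions are
    always executable: relaxation for the EMG interface, either movement
    for the IMU one.  ``latency`` is the reaction delay between an
    instruction and the start of the executed action.
    """

    confusion_rate: float = 0.0
    latency: float = 0.3
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.confusion_rate <= 1.0):
            raise ValueError("confusion_rate must lie in [0, 1]")
        self._rng = np.random.default_rng(self.seed)

    def execute(
        self, from_state: HandState, to_state: HandState, modality: Modality | str
    ) -> str:
        modality = Modality(modality)
        if to_state is HandState.RS:
            if modality is Modality.EMG:
                return "rest"
            return str(self._rng.choice(["movement1", "movement2"]))
        mapping = EMG_ACTION_COMMAND if modality is Modality.EMG else IMU_ACTION_COMMAND
        correct, (wrong,) = (
            next(a for a, c in mapping.items() if c is to_state),
            [a for a, c in mapping.items() if c is not to_state],
        )
        if self._rng.random() < self.confusion_rate:
            return wrong
        return correct


def simulated_user(
    confusion_rate: float = 0.0, latency: float = 0.3, seed: int = 0
) -> SimulatedUser:
    """Construct a :class:`SimulatedUser` policy."""
    return SimulatedUser(confusion_rate=confusion_rate, latency=latency, seed=seed)
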
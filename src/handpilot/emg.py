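"""Surface-EMG envelope extraction, VC calibration and command decoding.

The decoding chain mirrors a standard two-muscle myoelectric switch:

1. 4th-order Butterworth high-pass at 20 Hz (removes motion artifact and
   baseline drift),
2. full-wave rectification,
3. 4th-order Butterworth low-pass at 4 Hz → the envelope,
4. normalization of each channel against its voluntary-contraction (VC)
   reference amplitude,
5. sample-wise evaluation of the hysteresis state machine on the envelope
   decimated to a decision tick rate (default 100 Hz; the envelope is
   band-limited to 4 Hz, so nothing is lost).

Calibration records each muscle at rest and during a strong voluntary
contraction held for 4 s.  The VC reference is a robust plateau statistic
of the contraction envelope, and the hysteresis thresholds default to the
fixed ratios 0.2 (low, RL) and 0.6 (high, RH) of VC.  Per-muscle ratio
overrides model a subsequent manual fine-tuning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import signal

from .errors import CalibrationError
from .fsm import EnvelopeSample, HandState, Modality, TransitionEvent, run_session

#: Filter chain constants.
HIGHPASS_HZ = 20.0
LOWPASS_HZ = 4.0
FILTER_ORDER = 4
#: Leading stretch of a causally filtered record treated as filter settling
#: and excluded from triggering.
SETTLE_S = 0.5
#: Default decision tick rate for the state machine (Hz).
DEFAULT_TICK_RATE = 100.0
#: Minimum contrast between VC plateau and rest baseline.
VC_REST_MIN_RATIO = 3.0


@dataclass
class EmgRecording:
    """Two-channel raw EMG, amplifier gain already applied.

    ``data`` has shape (n_samples, 2); channel 0 is muscle 1.
    """

    data: np.ndarray
    fs: float = 5000.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 2:
            raise ValueError("EMG data must have shape (n_samples, 2)")
        if self.data.shape[0] == 0:
            raise ValueError("EMG recording is empty")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class EnvelopeSeries:
    """Normalized (VC-unit) envelopes decimated to the decision tick rate."""

    env: np.ndarray  # (n_ticks, 2), dimensionless
    tick_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        if self.env.ndim != 2 or self.env.shape[1] != 2:
            raise ValueError("envelope series must have shape (n_ticks, 2)")
        if np.any(self.env < 0):
            raise ValueError("normalized envelopes must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.env.shape[0]) / self.tick_rate


@dataclass
class EmgCalibration:
    """Per-muscle VC reference, rest level and hysteresis threshold ratios.

    Ratios are dimensionless fractions of VC with 0 < RL < RH <= 1 per
    muscle; ``rest_level`` values are raw envelope units.
    """

    vc1: float
    vc2: float
    rl1: float = 0.2
    rh1: float = 0.6
    rl2: float = 0.2
    rh2: float = 0.6
    rest_level1: float = 0.0
    rest_level2: float = 0.0

    def __post_init__(self) -> None:
        for m, (rl, rh) in enumerate([(self.rl1, self.rh1), (self.rl2, self.rh2)], 1):
            if not (0.0 < rl < rh <= 1.0):
                raise ValueError(
                    f"muscle {m}: require 0 < RL < RH <= 1, got RL={rl}, RH={rh}"
                )
        for m, (vc, rest) in enumerate(
            [(self.vc1, self.rest_level1), (self.vc2, self.rest_level2)], 1
        ):
            if vc <= rest:
                raise ValueError(f"muscle {m}: VC reference must exceed rest level")

    def with_ratios(self, **ratios: float) -> "EmgCalibration":
        """Return a copy with some of rl1/rh1/rl2/rh2 overridden."""
        return replace(self, **ratios)


def _sos(fs: float):
    if fs <= 2 * HIGHPASS_HZ:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {HIGHPASS_HZ} Hz high-pass"
        )
    hp = signal.butter(FILTER_ORDER, HIGHPASS_HZ, "highpass", fs=fs, output="sos")
    lp = signal.butter(FILTER_ORDER, LOWPASS_HZ, "lowpass", fs=fs, output="sos")
    return hp, lp


def compute_envelope(recording: EmgRecording, zero_phase: bool = False) -> np.ndarray:
    """High-pass, rectify and low-pass both channels; returns (n, 2) >= 0.

    Causal filtering (the default) matches online use; filter state is
    initialized to the first sample's steady state to shorten transients,
    and callers should still treat the first :data:`SETTLE_S` seconds as a
    settling window.  ``zero_phase=True`` uses forward-backward filtering
    for offline inspection only.
    """
    hp, lp = _sos(recording.fs)
    x = recording.data
    if zero_phase:
        hp_out = signal.sosfiltfilt(hp, x, axis=0)
        env = signal.sosfiltfilt(lp, np.abs(hp_out), axis=0)
    else:
        zi = signal.sosfilt_zi(hp)
        hp_out = np.empty_like(x)
        for ch in range(2):
            hp_out[:, ch], _ = signal.sosfilt(hp, x[:, ch], zi=zi * x[0, ch])
        rect = np.abs(hp_out)
        zi = signal.sosfilt_zi(lp)
        env = np.empty_like(rect)
        for ch in range(2):
            env[:, ch], _ = signal.sosfilt(lp, rect[:, ch], zi=zi * rect[0, ch])
    # the low-pass can undershoot slightly on sharp edges
    return np.clip(env, 0.0, None)


def _plateau_mean(env: np.ndarray, fs: float, trim_fraction: float = 0.125) -> float:
    """Mean envelope over the central part of the contraction plateau.

    The plateau is the contiguous region around the envelope peak where the
    envelope stays above half its maximum; ``trim_fraction`` of the region
    is discarded at each end (for a 4 s contraction this keeps the central
    3 s), making the statistic robust to onset/offset transients.
    """
    settle = int(round(SETTLE_S * fs))
    env = env[min(settle, len(env) - 1):]
    peak = int(np.argmax(env))
    half = env[peak] / 2.0
    lo = peak
    while lo > 0 and env[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < len(env) - 1 and env[hi + 1] >= half:
        hi += 1
    span = hi - lo + 1
    trim = int(round(span * trim_fraction))
    return float(np.mean(env[lo + trim: hi + 1 - trim or None]))


def calibrate_emg(
    rest: EmgRecording,
    vc: EmgRecording,
    ratios: Mapping[str, float] | None = None,
    vc_statistic: str = "plateau_mean",
) -> EmgCalibration:
    """Derive VC references, rest levels and hysteresis thresholds.

    ``rest`` holds both muscles relaxed; ``vc`` contains one strong 4 s
    voluntary contraction per channel (they need not be simultaneous — the
    plateau is located independently per channel).  ``ratios`` overrides
    any of ``rl1, rh1, rl2, rh2`` after the default 0.2/0.6 assignment.
    ``vc_statistic`` selects the plateau summary: ``plateau_mean``
    (default), ``peak`` or ``p95``.

    Raises :class:`CalibrationError` when a contraction is not clearly
    visible (VC reference below 3x the rest level), prompting re-recording.
    """
    rest_env = compute_envelope(rest)
    vc_env = compute_envelope(vc)
    settle_rest = min(int(round(SETTLE_S * rest.fs)), rest.n_samples - 1)
    rest_levels = rest_env[settle_rest:].mean(axis=0)

    vcs = []
    for ch in range(2):
        col = vc_env[:, ch]
        if vc_statistic == "plateau_mean":
            vcs.append(_plateau_mean(col, vc.fs))
        elif vc_statistic == "peak":
            vcs.append(float(col.max()))
        elif vc_statistic == "p95":
            vcs.append(float(np.percentile(col, 95)))
        else:
            raise ValueError(f"unknown vc_statistic {vc_statistic!r}")

    for m, (v, r) in enumerate(zip(vcs, rest_levels), 1):
        if v <= VC_REST_MIN_RATIO * r:
            raise CalibrationError(
                f"muscle {m}: contraction not clearly visible "
                f"(VC {v:.4g} <= {VC_REST_MIN_RATIO}x rest {r:.4g}); re-record"
            )

    calib = EmgCalibration(
        vc1=vcs[0],
        vc2=vcs[1],
        rest_level1=float(rest_levels[0]),
        rest_level2=float(rest_levels[1]),
    )
    if ratios:
        calib = calib.with_ratios(**dict(ratios))
    return calib


def normalize_envelope(
    raw_env: np.ndarray,
    calib: EmgCalibration,
    fs: float,
    tick_rate: float = DEFAULT_TICK_RATE,
    start_time: float = 0.0,
) -> EnvelopeSeries:
    """Divide each channel by its VC reference and decimate to the tick rate.

    Plain stride decimation is used: the envelope is band-limited to 4 Hz,
    far below half of any sensible tick rate, so no anti-alias stage is
    needed.
    """
    if calib.vc1 == 0 or calib.vc2 == 0:
        raise ZeroDivisionError("VC reference amplitude is zero")
    if tick_rate <= 0 or tick_rate > fs:
        raise ValueError("tick rate must lie in (0, fs]")
    step = max(1, int(round(fs / tick_rate)))
    norm = np.asarray(raw_env, dtype=float)[::step] / np.array([calib.vc1, calib.vc2])
    return EnvelopeSeries(norm, tick_rate=fs / step, start_time=start_time)


def decode_emg(
    recording: EmgRecording,
    calib: EmgCalibration,
    tick_rate: float = DEFAULT_TICK_RATE,
    settle: float = SETTLE_S,
    initial: HandState = HandState.RS,
) -> list[TransitionEvent]:
    """Full chain: envelope -> normalize -> hysteresis state machine.

    Returns the emitted transition events; each carries the normalized
    envelope pair at trigger time.  The first ``settle`` seconds are
    excluded from triggering.
    """
    raw = compute_envelope(recording)
    series = normalize_envelope(
        raw, calib, recording.fs, tick_rate=tick_rate, start_time=recording.start_time
    )
    times = series.times
    keep = times >= recording.start_time + settle
    triggers = [
        EnvelopeSample(float(t), float(e1), float(e2))
        for t, (e1, e2) in zip(times[keep], series.env[keep])
    ]
    return run_session(initial, triggers, Modality.EMG, thresholds=calib)
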
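"""Randomized validation protocol, scoring, and end-to-end simulated trials.

A validation sequence is a random order of 5 hand-open and 5 hand-close
trials, each expanded into its activation (RS→X) and release (X→RS)
instruction — 20 instructed transitions in total, 5 of each of the four
types, always feasible from the initial rest state and ending at rest.

Performance is the number of correctly activated gestures divided by the
number of desired gestures: an instruction is correct when the first state
change inside its response window reaches the instructed target state.
``run_trial`` closes the loop on synthetic data: generate the sequence,
let a simulated user execute it, decode the resulting signals with the
chosen pipeline, and score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import emg as _emg
from . import imu as _imu
from . import synth as _synth
from .fsm import HandState, Modality, TransitionEvent

#: Default per-instruction response window (s).
DEFAULT_TIMEOUT_S = 10.0
#: Instruction cadence in simulated trials (s): EMG holds a contraction
#: between activation and release, IMU performs one burst per instruction.
EMG_CADENCE_S = 6.0
IMU_CADENCE_S = 4.0


@dataclass
class ValidationSequence:
    """Randomized instructed-transition script with optional schedule times."""

    transitions: list[tuple[HandState, HandState]]
    seed: int
    times: list[float] | None = None

    def __post_init__(self) -> None:
        counts = {edge: 0 for edge in (
            (HandState.RS, HandState.HO),
            (HandState.RS, HandState.HC),
            (HandState.HO, HandState.RS),
            (HandState.HC, HandState.RS),
        )}
        state = HandState.RS
        for frm, to in self.transitions:
            if frm is not state:
                raise ValueError(
                    f"infeasible sequence: instruction departs {frm} but state is {state}"
                )
            if (frm, to) not in counts:
                raise ValueError(f"illegal instructed transition {frm}->{to}")
            counts[(frm, to)] += 1
            state = to
        if self.transitions:
            if any(c != 5 for c in counts.values()):
                raise ValueError("sequence must contain 5 instructions of each type")
            if state is not HandState.RS:
                raise ValueError("sequence must end at rest")
        if self.times is not None and len(self.times) != len(self.transitions):
            raise ValueError("times must align with transitions")

    def with_times(self, times: list[float]) -> "ValidationSequence":
        return replace(self, times=list(times))


@dataclass
class PerformanceReport:
    """Correct / desired gesture counts plus per-instruction outcomes."""

    n_desired: int
    n_correct: int
    outcomes: list[dict] = field(default_factory=list)

    @property
    def performance(self) -> float:
        return self.n_correct / self.n_desired if self.n_desired else 0.0

    def to_dict(self) -> dict:
        return {
            "n_desired": self.n_desired,
            "n_correct": self.n_correct,
            "performance": self.performance,
            "outcomes": self.outcomes,
        }


def generate_sequence(seed: int) -> ValidationSequence:
    """Uniformly shuffle 5 HO and 5 HC trials; expand each into
    activation + release, giving exactly 5 of each transition type."""
    rng = np.random.default_rng(seed)
    trials = [HandState.HO] * 5 + [HandState.HC] * 5
    order = rng.permutation(len(trials))
    transitions: list[tuple[HandState, HandState]] = []
    for idx in order:
        target = trials[idx]
        transitions.append((HandState.RS, target))
        transitions.append((target, HandState.RS))
    return ValidationSequence(transitions, seed=seed)


def score(
    sequence: ValidationSequence,
    achieved: list[TransitionEvent],
    per_instruction_timeout: float = DEFAULT_TIMEOUT_S,
    activations_only: bool = False,
) -> PerformanceReport:
    """Score achieved transitions against the instructed sequence.

    Instruction *i*, scheduled at ``sequence.times[i]``, is correct when
    the first achieved state change in [t_i, min(t_i + timeout, t_{i+1}))
    reaches the instructed target state.  Each achieved event counts for
    at most one instruction.  ``activations_only`` restricts the
    denominator to the RS→X instructions.
    """
    if sequence.times is None:
        raise ValueError("sequence has no schedule times; call with_times() first")
    if any(b.time < a.time for a, b in zip(achieved, achieved[1:])):
        raise ValueError("achieved events must be time-ordered")

    outcomes = []
    ev_idx = 0
    n_events = len(achieved)
    for i, ((frm, to), t_i) in enumerate(zip(sequence.transitions, sequence.times)):
        t_end = t_i + per_instruction_timeout
        if i + 1 < len(sequence.times):
            t_end = min(t_end, sequence.times[i + 1])
        while ev_idx < n_events and achieved[ev_idx].time < t_i:
            ev_idx += 1
        first = achieved[ev_idx] if ev_idx < n_events and achieved[ev_idx].time < t_end else None
        if first is not None:
            ev_idx += 1
        correct = first is not None and first.to_state is to
        outcomes.append(
            {
                "instruction": f"{frm.value}->{to.value}",
                "time": t_i,
                "achieved": None if first is None
                else f"{first.from_state.value}->{first.to_state.value}",
                "achieved_time": None if first is None else first.time,
                "correct": correct,
                "activation": to is not HandState.RS,
            }
        )

    scored = [o for o in outcomes if o["activation"]] if activations_only else outcomes
    return PerformanceReport(
        n_desired=len(scored),
        n_correct=sum(o["correct"] for o in scored),
        outcomes=outcomes,
    )


def _scheduled_script(
    sequence: ValidationSequence,
    user: _synth.SimulatedUser,
    modality: Modality,
    cadence: float,
    lead_in: float,
) -> tuple[_synth.ScriptedSession, list[float]]:
    """Expand instructed transitions into a user-executed action script."""
    times = [lead_in + i * cadence for i in range(len(sequence.transitions))]
    instrs = [
        _synth.Instruction(t + user.latency, user.execute(frm, to, modality))
        for (frm, to), t in zip(sequence.transitions, times)
    ]
    duration = times[-1] + cadence + 2.0
    return _synth.ScriptedSession(instrs, duration=duration), times


def run_trial(
    modality: Modality | str,
    user: _synth.SimulatedUser,
    emg_config: _synth.EmgSynthConfig | None = None,
    imu_config: _synth.ImuSynthConfig | None = None,
    seed: int = 0,
    sequence_seed: int | None = None,
    per_instruction_timeout: float = DEFAULT_TIMEOUT_S,
    activations_only: bool = False,
) -> PerformanceReport:
    """One complete simulated validation trial, reproducible from its seeds.

    Calibration fixtures are generated from the modality config's seed,
    the instruction sequence from ``sequence_seed`` (default: derived from
    ``seed``), and the session signals from ``seed``.
    """
    modality = Modality(modality)
    if sequence_seed is None:
        sequence_seed = seed + 1
    sequence = generate_sequence(sequence_seed)

    if modality is Modality.EMG:
        cfg = emg_config or _synth.EmgSynthConfig()
        rest, vc = _synth.synth_emg_calibration(cfg)
        calib = _emg.calibrate_emg(rest, vc)
        script, times = _scheduled_script(
            sequence, user, modality, EMG_CADENCE_S, lead_in=2.0
        )
        recording, _ = _synth.synth_emg_session(script, replace(cfg, seed=seed))
        events = _emg.decode_emg(recording, calib)
    else:
        cfg = imu_config or _synth.ImuSynthConfig()
        calib_stream, calib_truth = _synth.synth_imu_calibration(cfg)
        alpha, model = _imu.calibrate_imu(
            calib_stream,
            [gt.time for gt in calib_truth],
            [int(_synth.IMU_ACTION_CLASS[gt.action]) for gt in calib_truth],
        )
        script, times = _scheduled_script(
            sequence, user, modality, IMU_CADENCE_S, lead_in=2.0
        )
        stream, _ = _synth.synth_imu_session(script, replace(cfg, seed=seed))
        events = _imu.decode_imu(stream, model, alpha)

    return score(
        sequence.with_times(times),
        events,
        per_instruction_timeout=per_instruction_timeout,
        activations_only=activations_only,
    )
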
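"""Three-state hand-command machine shared by the EMG and IMU interfaces.

The controller exposes three commands — at-rest (RS), hand-open (HO) and
hand-close (HC) — and only four edges between them: RS→HO, RS→HC, HO→RS and
HC→RS.  Direct HO↔HC transitions do not exist; changing gesture requires
passing through RS.  Each sensing modality supplies its own trigger type and
transition rule:

* EMG: two normalized muscle envelopes compared against per-muscle
  low/high hysteresis thresholds (entry above the high threshold of one
  muscle while the other stays below its low threshold; release when both
  drop below their low thresholds).
* IMU: a classified movement (class 1 or class 2); class 1 opens, class 2
  closes, and either movement releases back to rest.

When no condition holds the machine keeps its state: conditions are
triggers, not state equations.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence


class HandState(str, enum.Enum):
    """Hand command state: at-rest, hand-open or hand-close."""

    RS = "RS"
    HO = "HO"
    HC = "HC"

    def __str__(self) -> str:  # cleaner logs
        return self.value


class MovementClass(enum.IntEnum):
    """Label assigned by the IMU nearest-centroid classifier."""

    CLASS1 = 1
    CLASS2 = 2


class Modality(str, enum.Enum):
    EMG = "EMG"
    IMU = "IMU"


#: The only edges the state machine may take (no self-edges, no HO<->HC).
ALLOWED_EDGES = frozenset(
    {
        (HandState.RS, HandState.HO),
        (HandState.RS, HandState.HC),
        (HandState.HO, HandState.RS),
        (HandState.HC, HandState.RS),
    }
)


@dataclass(frozen=True)
class EnvelopeSample:
    """One decision tick of the two normalized EMG envelopes (VC units)."""

    time: float
    env1: float
    env2: float


@dataclass(frozen=True)
class MovementTrigger:
    """A classified IMU movement delivered to the state machine.

    ``time`` is the decision-emission time (trailing edge of the RMS
    window), not the movement onset.
    """

    time: float
    movement: MovementClass
    point: tuple[float, float] | None = None
    distances: tuple[float, float] | None = None


@dataclass(frozen=True)
class TransitionEvent:
    """A state change, with the trigger payload that caused it."""

    time: float
    from_state: HandState
    to_state: HandState
    trigger: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.from_state, self.to_state) not in ALLOWED_EDGES:
            raise ValueError(
                f"illegal transition {self.from_state}->{self.to_state}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "time": self.time,
                "from": self.from_state.value,
                "to": self.to_state.value,
                "trigger": self.trigger,
            }
        )


def emg_transition(state: HandState, env1: float, env2: float, thresholds) -> HandState:
    """Apply the EMG hysteresis conditions once and return the next state.

    ``thresholds`` is any object exposing normalized ratio attributes
    ``rl1, rh1, rl2, rh2`` with ``rl < rh`` per muscle (validated at
    construction of the calibration object).  The three conditions:

    * RS→HC when env1 > RH1 and env2 < RL2;
    * RS→HO when env2 > RH2 and env1 < RL1;
    * HO/HC→RS when env1 < RL1 and env2 < RL2.

    Anything else — including co-contraction with both envelopes high —
    leaves the state unchanged.
    """
    if env1 < 0 or env2 < 0:
        raise ValueError("normalized envelopes must be non-negative")
    rl1, rh1 = thresholds.rl1, thresholds.rh1
    rl2, rh2 = thresholds.rl2, thresholds.rh2
    if state is HandState.RS:
        if env1 > rh1 and env2 < rl2:
            return HandState.HC
        if env2 > rh2 and env1 < rl1:
            return HandState.HO
        return state
    # HO or HC: release only when both muscles are relaxed
    if env1 < rl1 and env2 < rl2:
        return HandState.RS
    return state


def imu_transition(state: HandState, movement: MovementClass) -> HandState:
    """Apply the movement-classification conditions once.

    From RS, class 1 opens the hand and class 2 closes it; from HO or HC
    either movement returns to rest.
    """
    movement = MovementClass(movement)
    if state is HandState.RS:
        return HandState.HO if movement is MovementClass.CLASS1 else HandState.HC
    return HandState.RS


def run_session(
    initial: HandState,
    triggers: Sequence[EnvelopeSample] | Sequence[MovementTrigger],
    modality: Modality | str,
    thresholds=None,
    refractory: float = 0.0,
) -> list[TransitionEvent]:
    """Fold the modality's transition rule over a time-ordered trigger stream.

    Emits a :class:`TransitionEvent` only when the state actually changes.
    ``refractory`` optionally suppresses further transitions for that many
    seconds after each emitted event (off by default).

    Raises ``ValueError`` on unsorted triggers or, for the EMG modality,
    missing thresholds.
    """
    modality = Modality(modality)
    if modality is Modality.EMG and thresholds is None:
        raise ValueError("EMG session requires hysteresis thresholds")

    events: list[TransitionEvent] = []
    state = HandState(initial)
    last_time = None
    last_event_time = -float("inf")
    for trig in triggers:
        if last_time is not None and trig.time < last_time:
            raise ValueError("trigger stream is not time-sorted")
        last_time = trig.time
        if trig.time - last_event_time < refractory:
            continue
        if modality is Modality.EMG:
            nxt = emg_transition(state, trig.env1, trig.env2, thresholds)
            payload = {"env1": trig.env1, "env2": trig.env2}
        else:
            nxt = imu_transition(state, trig.movement)
            payload = {"movement_class": int(trig.movement)}
            if trig.point is not None:
                payload["point"] = list(trig.point)
            if trig.distances is not None:
                payload["distances"] = list(trig.distances)
        if nxt is not state:
            events.append(TransitionEvent(trig.time, state, nxt, payload))
            last_event_time = trig.time
            state = nxt
    return events


def final_state(initial: HandState, events: Iterable[TransitionEvent]) -> HandState:
    """State reached after applying ``events`` in order, starting at ``initial``."""
    state = HandState(initial)
    for ev in events:
        if ev.from_state is not state:
            raise ValueError(
                f"event at t={ev.time} departs from {ev.from_state}, "
                f"but machine is in {state}"
            )
        state = ev.to_state
    return state


def write_events_jsonl(events: Iterable[TransitionEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")
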
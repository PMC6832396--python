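"""Simulated actuators: robotic hand gestures and a two-channel stimulator.

Both actuators consume the state-machine event stream at the command
level.  The robotic hand mirrors the three gestures (at-rest, all fingers
extended, key-grip close).  The electrical stimulator maps hand-close to
channel 1 (wrist flexion) and hand-open to channel 2 (wrist extension);
rest deactivates both.  Stimulation is modeled as on/off per channel with
its pulse parameters (default 25 Hz, 300 us, rectangular biphasic
balanced waveform; current intensity is user-set per channel) — pulse
train synthesis is out of scope, the stimulator is a black box that
receives commands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError
from .fsm import HandState, TransitionEvent

#: Robotic-hand gesture names per command state.
GESTURES = {HandState.RS: "at-rest", HandState.HO: "open", HandState.HC: "key-grip"}


@dataclass
class StimulationConfig:
    """Stimulator pulse parameters and command-to-channel mapping."""

    frequency: float = 25.0  # Hz
    pulse_width: float = 300.0  # microseconds
    intensity: Mapping[int, float] | None = None  # mA per channel, user-set
    waveform: str = "rectangular, biphasic, balanced"
    channel_map: Mapping[HandState, int | None] = field(
        default_factory=lambda: {HandState.HC: 1, HandState.HO: 2, HandState.RS: None}
    )

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.pulse_width <= 0:
            raise ConfigError("frequency and pulse width must be positive")


@dataclass(frozen=True)
class ActuatorEntry:
    """One time-stamped actuator state record."""

    time: float
    state: HandState
    gesture: str | None = None  # robotic hand
    channel: int | None = None  # stimulator: active channel, None = off
    params: dict = field(default_factory=dict)


@dataclass
class ActuatorLog:
    entries: list[ActuatorEntry] = field(default_factory=list)

    @property
    def final_state(self) -> HandState:
        return self.entries[-1].state if self.entries else HandState.RS


def hand_actuator(
    events: Iterable[TransitionEvent], initial: HandState = HandState.RS
) -> ActuatorLog:
    """Replay command events on the simulated robotic hand.

    The log opens with the initial at-rest gesture and adds one entry per
    command; the final logged gesture always equals the final machine
    state.
    """
    log = ActuatorLog([ActuatorEntry(time=0.0, state=initial, gesture=GESTURES[initial])])
    for ev in events:
        log.entries.append(
            ActuatorEntry(time=ev.time, state=ev.to_state, gesture=GESTURES[ev.to_state])
        )
    return log


def stim_actuator(
    events: Iterable[TransitionEvent], config: StimulationConfig
) -> ActuatorLog:
    """Replay command events on the simulated two-channel stimulator.

    Raises :class:`ConfigError` if any mapped channel lacks a current
    intensity.  At most one channel is active at any time by construction
    (each log entry records a single active channel or none).
    """
    channels = {ch for ch in config.channel_map.values() if ch is not None}
    intensity = dict(config.intensity or {})
    missing = channels - intensity.keys()
    if missing:
        raise ConfigError(f"no current intensity set for channel(s) {sorted(missing)}")

    def entry(time: float, state: HandState) -> ActuatorEntry:
        ch = config.channel_map.get(state)
        params = {"frequency": config.frequency, "pulse_width": config.pulse_width,
                  "waveform": config.waveform}
        if ch is not None:
            params["intensity"] = intensity[ch]
        return ActuatorEntry(time=time, state=state, channel=ch, params=params)

    log = ActuatorLog([entry(0.0, HandState.RS)])
    for ev in events:
        log.entries.append(entry(ev.time, ev.to_state))
    return log
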
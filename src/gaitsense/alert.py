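"""Real-time distracted-walking alert state machine.

Classification results stream in at a fixed cadence (one label per 1-second
analysis window).  Five consecutive ``abnormal`` results raise an alert;
the alert stays active for 7 seconds unless the user dismisses it earlier.
The 5-window debounce suppresses false positives from brief screen glances
or transient sensor noise.

Semantics:

* a ``normal`` window resets the consecutive counter to zero ("continuous"
  detection means an uninterrupted run);
* while an alert is active (from the raise time through raise + display
  time, inclusive, or until dismissal) incoming labels do not accumulate —
  alerts never stack, and re-arming starts with the first window strictly
  after expiry/dismissal;
* every transition is appended to an ordered event log
  ``(time, raised | expired | dismissed | warning)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

__all__ = [
    "DEFAULT_MESSAGE",
    "AlertConfig",
    "AlertEvent",
    "AlertState",
    "step",
    "dismiss",
    "run_stream",
]

DEFAULT_MESSAGE = (
    "The use of smartphones was detected during walking. "
    "Please pay attention to safety."
)

Label = Literal["normal", "abnormal"]


@dataclass(frozen=True)
class AlertConfig:
    """Cadence and debounce settings of the alert machine."""

    window_s: float = 1.0
    consecutive_needed: int = 5
    display_s: float = 7.0
    message: str = DEFAULT_MESSAGE

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.display_s <= 0:
            raise ValueError("window_s and display_s must be positive")
        if self.consecutive_needed < 1:
            raise ValueError("consecutive_needed must be >= 1")


@dataclass(frozen=True)
class AlertEvent:
    t: float
    event: str  # raised | expired | dismissed | warning
    message: str = ""


@dataclass(frozen=True)
class AlertState:
    """Immutable machine state; transitions return a new state."""

    consecutive_abnormal: int = 0
    alert_active: bool = False
    alert_started_at: float | None = None
    last_t: float | None = None
    events: tuple[AlertEvent, ...] = field(default_factory=tuple)


def _expire_if_due(state: AlertState, t: float, config: AlertConfig) -> AlertState:
    """Log an expiry if the active alert's display time has fully elapsed.

    The alert is considered active through ``started + display_s``
    inclusive; a step at exactly the expiry instant logs the expiry but its
    label is still swallowed by the active alert.
    """
    if not state.alert_active or state.alert_started_at is None:
        return state
    expiry = state.alert_started_at + config.display_s
    if t >= expiry:
        return replace(
            state,
            alert_active=False,
            alert_started_at=None,
            events=state.events + (AlertEvent(expiry, "expired"),),
        )
    return state


def step(
    state: AlertState, t: float, label: Label, config: AlertConfig | None = None
) -> AlertState:
    """Consume one per-window classification result at time ``t`` (s)."""
    config = config or AlertConfig()
    if label not in ("normal", "abnormal"):
        raise ValueError(f"label must be normal or abnormal, got {label!r}")
    if state.last_t is not None and t <= state.last_t:
        raise ValueError(
            f"out-of-order step: t={t} after t={state.last_t}"
        )
    was_active = state.alert_active
    active_through = (
        state.alert_started_at + config.display_s if was_active else None
    )
    state = _expire_if_due(state, t, config)
    state = replace(state, last_t=t)

    # labels arriving while the alert was active (through the expiry
    # instant inclusive) do not count toward a new streak
    if was_active and t <= active_through:
        return state
    if state.alert_active:
        return state

    if label == "normal":
        return replace(state, consecutive_abnormal=0)
    streak = state.consecutive_abnormal + 1
    if streak >= config.consecutive_needed:
        return replace(
            state,
            consecutive_abnormal=0,
            alert_active=True,
            alert_started_at=t,
            events=state.events + (AlertEvent(t, "raised", config.message),),
        )
    return replace(state, consecutive_abnormal=streak)


def dismiss(state: AlertState, t: float) -> AlertState:
    """Manually dismiss the active alert; no-op (with warning) otherwise."""
    if not state.alert_active:
        return replace(
            state,
            events=state.events + (AlertEvent(t, "warning", "no active alert"),),
        )
    return replace(
        state,
        alert_active=False,
        alert_started_at=None,
        consecutive_abnormal=0,
        events=state.events + (AlertEvent(t, "dismissed"),),
    )


def run_stream(
    labels: Iterable[tuple[float, Label]], config: AlertConfig | None = None
) -> tuple[AlertEvent, ...]:
    """Fold :func:`step` over an ordered ``(t, label)`` stream.

    Returns the complete event log.  Expiries are observed (and logged, at
    the exact expiry instant) by the first step at or after them.
    """
    config = config or AlertConfig()
    state = AlertState()
    for t, label in labels:
        state = step(state, t, label, config)
    return state.events
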
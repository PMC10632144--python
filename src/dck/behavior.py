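"""T-maze behavioural indices and stimulus schedules.

Performance / preference indices are computed from the fly counts in the
two T-maze arms, averaged over reciprocal-odour experiments to cancel
odour bias. Stimulus schedules reproduce the training and testing
protocols (odour periods, shock trains, light pulses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ArmCounts:
    """Fly counts in the designated (CS+/shock/sucrose) arm and the other arm.

    ``n_center`` holds flies that entered neither arm; by default they are
    excluded from the total (only flies transferred from the two choice
    tubes are counted), matching how the counts are collected.
    """

    n_target: int
    n_other: int
    n_center: int = 0

    def __post_init__(self) -> None:
        if min(self.n_target, self.n_other, self.n_center) < 0:
            raise ValueError("arm counts must be non-negative")


@dataclass(frozen=True)
class IndexValue:
    value: float
    kind: str = "performance"  # performance | preference
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if abs(self.value) > 1 + 1e-12:
            raise ValueError("index must lie in [-1, 1]")


def performance_index(
    counts: ArmCounts, *, kind: str = "performance", include_center: bool = False
) -> IndexValue:
    """(flies in target arm - flies in other arm) / total flies.

    With ``include_center`` the non-choosing flies enter the denominator
    (diluting the index toward zero); the default counts only the two
    choice arms.
    """
    total = counts.n_target + counts.n_other
    if include_center:
        total += counts.n_center
    if total <= 0:
        raise ValueError("cannot compute an index from zero flies")
    return IndexValue((counts.n_target - counts.n_other) / total, kind=kind)


def reciprocal_index(e1: IndexValue, e2: IndexValue) -> IndexValue:
    """Mean of two reciprocal-odour experiments, cancelling odour bias."""
    if e1.kind != e2.kind:
        raise ValueError(f"cannot average a {e1.kind} with a {e2.kind} index")
    return IndexValue((e1.value + e2.value) / 2.0, kind=e1.kind, reciprocal=True)


# ---------------------------------------------------------------------------
# Stimulus schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus events: (onset_s, duration_s, kind)."""

    events: tuple[tuple[float, float, str], ...]
    template: str = "custom"

    def count(self, kind: str) -> int:
        return sum(1 for _, _, k in self.events if k == kind)


def pulse_train(
    start_s: float, duration_s: float, rate_hz: float, pulse_s: float, kind: str
) -> list[tuple[float, float, str]]:
    """Pulses at onsets start, start + 1/rate, ... strictly below the period end.

    The first pulse sits at t = 0 of the stimulus period, so the count over
    a period of ``duration_s`` is ceil(duration_s * rate_hz).
    """
    if duration_s < 0 or rate_hz < 0:
        raise ValueError("duration and rate must be non-negative")
    if rate_hz > 0 and pulse_s <= 0:
        raise ValueError("pulse duration must be positive when pulsing")
    if rate_hz == 0 or duration_s == 0:
        return []
    n = math.ceil(duration_s * rate_hz)
    return [(start_s + k / rate_hz, pulse_s, kind) for k in range(n)]


def build_schedule(
    template: str,
    duration_s: float | None = None,
    rate_hz: float | None = None,
    pulse_s: float | None = None,
) -> StimulusSchedule:
    """Assemble a named training/testing stimulus schedule.

    Templates:

    - ``appetitive``: 2 min CS- odour, 30 s air, 2 min CS+ odour (paired
      with the reward during training).
    - ``aversive``: 1 min CS+ odour with 90 V shock pulses (1.5 s at
      0.2 Hz, i.e. 12 shocks), 45 s air, 1 min CS- odour.
    - ``red_light``: pulsed optogenetic activation light (500 Hz, 1 ms
      pulses) over ``duration_s`` (default 120 s).
    - ``green_light``: continuous light over ``duration_s`` (default 120 s).
    - ``pulses``: a bare pulse train from the explicit duration/rate/pulse
      arguments.
    """
    if template == "appetitive":
        ev = [(0.0, 120.0, "odour_csminus"), (120.0, 30.0, "air"), (150.0, 120.0, "odour_csplus")]
        return StimulusSchedule(tuple(ev), template)
    if template == "aversive":
        d = 60.0 if duration_s is None else duration_s
        r = 0.2 if rate_hz is None else rate_hz
        p = 1.5 if pulse_s is None else pulse_s
        ev = [(0.0, d, "odour_csplus")]
        ev += pulse_train(0.0, d, r, p, "shock_pulse")
        ev += [(d, 45.0, "air"), (d + 45.0, 60.0, "odour_csminus")]
        return StimulusSchedule(tuple(sorted(ev)), template)
    if template == "red_light":
        d = 120.0 if duration_s is None else duration_s
        r = 500.0 if rate_hz is None else rate_hz
        p = 0.001 if pulse_s is None else pulse_s
        return StimulusSchedule(tuple(pulse_train(0.0, d, r, p, "light_pulse")), template)
    if template == "green_light":
        d = 120.0 if duration_s is None else duration_s
        return StimulusSchedule(((0.0, d, "light_continuous"),), template)
    if template == "pulses":
        if duration_s is None or rate_hz is None or pulse_s is None:
            raise ValueError("pulses template needs duration_s, rate_hz and pulse_s")
        return StimulusSchedule(
            tuple(pulse_train(0.0, duration_s, rate_hz, pulse_s, "shock_pulse")), template
        )
    raise ValueError(f"unknown schedule template: {template!r}")
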
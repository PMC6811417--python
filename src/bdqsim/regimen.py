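"""Dosing regimens as explicit dose-event schedules.

The four regimens compared in the study, all spanning 24 weeks (168 days):

* labeled: 400 mg QD for 14 days, then 200 mg thrice weekly for 22 weeks,
* 100 mg QD,
* 200 mg QD,
* switch: 200 mg QD for 56 days, then 100 mg QD for the remainder.

TIW (thrice weekly) is realised as dosing on days 1, 3 and 5 of each week
(48 h, 48 h, 72 h gaps), the common Mon/Wed/Fri clinic convention; the weekly
pattern is configurable.  QD means exactly every 24.0 h (nominal dosing, no
jitter).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DoseEvent",
    "Regimen",
    "qd_regimen",
    "tiw_regimen",
    "labeled_regimen",
    "switch_regimen",
    "standard_regimens",
    "regimen_from_phases",
    "HOURS_PER_DAY",
    "HOURS_PER_WEEK",
]

HOURS_PER_DAY = 24.0
HOURS_PER_WEEK = 168.0
#: offsets (h) of TIW doses within a week: days 1, 3, 5
TIW_WEEKLY_OFFSETS = (0.0, 48.0, 96.0)


@dataclass(frozen=True)
class DoseEvent:
    """One oral dose: time in hours since the first dose, amount in mg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")


@dataclass(frozen=True)
class Regimen:
    """An ordered schedule of dose events over a fixed duration (hours)."""

    name: str
    events: tuple[DoseEvent, ...]
    duration: float

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be strictly ascending in time")
        if self.events and self.events[-1].time >= self.duration:
            raise ValueError("last dose event must fall before the regimen duration")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def total_dose(self) -> float:
        """Total administered amount (mg)."""
        return sum(e.amount for e in self.events)

    @property
    def last_dose_time(self) -> float:
        if not self.events:
            raise ValueError("regimen has no dose events")
        return self.events[-1].time

    def scaled(self, factor: float) -> "Regimen":
        """Every dose amount multiplied by ``factor`` (for linearity checks)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Regimen(
            name=f"{self.name} x{factor:g}",
            events=tuple(DoseEvent(e.time, e.amount * factor) for e in self.events),
            duration=self.duration,
        )

    def truncated(self, n_days: float, name: str | None = None) -> "Regimen":
        """Restrict to doses given before ``n_days`` days (e.g. a 56-day study)."""
        horizon = n_days * HOURS_PER_DAY
        events = tuple(e for e in self.events if e.time < horizon)
        return Regimen(name=name or f"{self.name} ({n_days:g}d)", events=events, duration=horizon)


def qd_regimen(dose_mg: float, n_days: int, name: str | None = None) -> Regimen:
    """Once-daily dosing: one ``dose_mg`` event every 24 h for ``n_days`` days."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if n_days < 1:
        raise ValueError("need at least one dosing day")
    events = tuple(DoseEvent(d * HOURS_PER_DAY, dose_mg) for d in range(int(n_days)))
    return Regimen(name=name or f"{dose_mg:g} mg QD", events=events, duration=n_days * HOURS_PER_DAY)


def tiw_regimen(
    dose_mg: float,
    n_weeks: int,
    start_h: float = 0.0,
    weekly_offsets: tuple[float, ...] = TIW_WEEKLY_OFFSETS,
) -> tuple[DoseEvent, ...]:
    """Thrice-weekly dose events for ``n_weeks`` weeks starting at ``start_h``."""
    if dose_mg <= 0 or n_weeks < 1:
        raise ValueError("dose and number of weeks must be positive")
    return tuple(
        DoseEvent(start_h + w * HOURS_PER_WEEK + off, dose_mg)
        for w in range(int(n_weeks))
        for off in weekly_offsets
    )


def labeled_regimen(weekly_offsets: tuple[float, ...] = TIW_WEEKLY_OFFSETS) -> Regimen:
    """The labeled regimen: 400 mg QD x 14 days, then 200 mg TIW x 22 weeks.

    The first TIW dose is given 24 h after the last loading dose (t = 336 h),
    then the weekly day-1/3/5 pattern repeats for 22 weeks; total duration is
    24 weeks.
    """
    loading = tuple(DoseEvent(d * HOURS_PER_DAY, 400.0) for d in range(14))
    tiw = tiw_regimen(200.0, 22, start_h=14 * HOURS_PER_DAY, weekly_offsets=weekly_offsets)
    return Regimen(name="labeled", events=loading + tiw, duration=24 * HOURS_PER_WEEK)


def switch_regimen() -> Regimen:
    """200 mg QD for 56 days, then 100 mg QD for 112 days (24 weeks total)."""
    first = tuple(DoseEvent(d * HOURS_PER_DAY, 200.0) for d in range(56))
    second = tuple(DoseEvent(d * HOURS_PER_DAY, 100.0) for d in range(56, 168))
    return Regimen(name="200 mg QD x 56 d, then 100 mg QD", events=first + second, duration=24 * HOURS_PER_WEEK)


def standard_regimens() -> dict[str, Regimen]:
    """The four 24-week regimens compared in the study, keyed by short name."""
    return {
        "labeled": labeled_regimen(),
        "qd100": qd_regimen(100.0, 168, name="100 mg QD"),
        "qd200": qd_regimen(200.0, 168, name="200 mg QD"),
        "switch": switch_regimen(),
    }


def regimen_from_phases(name: str, phases: list[dict], duration_days: float | None = None) -> Regimen:
    """Build a regimen from config phases.

    Each phase is a mapping with ``dose_mg`` and ``n_days`` plus either
    ``interval_h`` (default 24) or ``weekly_offsets`` (hours within a week,
    e.g. ``[0, 48, 96]`` for TIW).  Phases are laid out back to back.
    """
    events: list[DoseEvent] = []
    t0 = 0.0
    for phase in phases:
        dose = float(phase["dose_mg"])
        n_days = float(phase["n_days"])
        span = n_days * HOURS_PER_DAY
        if "weekly_offsets" in phase:
            n_weeks = n_days / 7.0
            if abs(n_weeks - round(n_weeks)) > 1e-9:
                raise ValueError(f"phase with weekly pattern must span whole weeks, got {n_days} days")
            events.extend(tiw_regimen(dose, int(round(n_weeks)), start_h=t0,
                                      weekly_offsets=tuple(float(o) for o in phase["weekly_offsets"])))
        else:
            interval = float(phase.get("interval_h", HOURS_PER_DAY))
            t = t0
            while t < t0 + span - 1e-9:
                events.append(DoseEvent(t, dose))
                t += interval
        t0 += span
    duration = duration_days * HOURS_PER_DAY if duration_days is not None else t0
    return Regimen(name=name, events=tuple(events), duration=duration)
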
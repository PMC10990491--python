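"""Periodic dual-stress environment schedules.

A microfluidic chip alternates the medium delivered to yeast growth
chambers between combinations of glucose (carbon source, % wt/vol) and
sorbitol (osmotic agent, M).  Every experiment starts with an acclimation
hour in the default medium (glucose, no sorbitol); after that the
environment is a square wave with period ``T``:

``periodic_osmo``
    glucose held constant, sorbitol on for half of each period.
``periodic_glucose``
    sorbitol absent, glucose removed for half of each period.
``IPS`` (in-phase stresses)
    first half glucose without sorbitol, second half starvation *with*
    1 M sorbitol — the two stresses coincide.
``AS`` (alternating stresses)
    first half glucose *with* sorbitol, second half starvation without —
    exactly one stress at any time.

IPS and AS share identical glucose timing and identical total sorbitol
exposure; they differ only in the phasing of sorbitol relative to glucose.
Valve switching in the chip takes under two minutes, far below the 6-min
imaging interval, so transitions are idealized as instantaneous steps with
half-open ``[start, end)`` segments: the state at a transition instant is
the new state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict
from typing import Tuple


class Regime(str, enum.Enum):
    CONSTANT = "constant"
    PERIODIC_OSMO = "periodic_osmo"
    PERIODIC_GLUCOSE = "periodic_glucose"
    IPS = "IPS"
    AS = "AS"
    SINGLE_PULSE = "single_pulse"


PERIODIC_REGIMES = frozenset(
    {Regime.PERIODIC_OSMO, Regime.PERIODIC_GLUCOSE, Regime.IPS, Regime.AS}
)


@dataclass(frozen=True)
class EnvState:
    """Medium composition at an instant: glucose in % wt/vol, sorbitol in M."""

    glucose: float
    sorbitol: float

    def __post_init__(self) -> None:
        if self.glucose < 0 or self.sorbitol < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def has_glucose(self) -> bool:
        return self.glucose > 0

    @property
    def has_sorbitol(self) -> bool:
        return self.sorbitol > 0


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant glucose/sorbitol stimulus over one experiment.

    Times are minutes from the start of imaging.  ``acclimation`` minutes of
    default medium (``glucose_high``, no sorbitol) precede the periodic
    program; the phase clock starts at the end of acclimation.
    """

    regime: Regime
    period: float | None
    glucose_high: float
    sorbitol_high: float
    acclimation: float
    total_duration: float
    pulse_start: float | None = None
    pulse_length: float | None = None

    @property
    def is_periodic(self) -> bool:
        return self.regime in PERIODIC_REGIMES

    def env_at(self, t: float) -> EnvState:
        """Medium state at time ``t`` (minutes); half-open segment convention."""
        if t < 0 or t > self.total_duration:
            raise ValueError(
                f"t={t} outside schedule support [0, {self.total_duration}]"
            )
        if t < self.acclimation or self.regime is Regime.CONSTANT:
            return EnvState(self.glucose_high, 0.0)
        if self.regime is Regime.SINGLE_PULSE:
            assert self.pulse_start is not None and self.pulse_length is not None
            tau = t - self.acclimation
            in_pulse = self.pulse_start <= tau < self.pulse_start + self.pulse_length
            return EnvState(self.glucose_high, self.sorbitol_high if in_pulse else 0.0)

        phase, half = self.phase_of(t)
        first = half == "first"
        if self.regime is Regime.PERIODIC_OSMO:
            return EnvState(self.glucose_high, self.sorbitol_high if not first else 0.0)
        if self.regime is Regime.PERIODIC_GLUCOSE:
            return EnvState(self.glucose_high if first else 0.0, 0.0)
        if self.regime is Regime.IPS:
            # stress-free half first, then starvation + sorbitol together
            return (
                EnvState(self.glucose_high, 0.0)
                if first
                else EnvState(0.0, self.sorbitol_high)
            )
        if self.regime is Regime.AS:
            # glucose + sorbitol first, then starvation without sorbitol
            return (
                EnvState(self.glucose_high, self.sorbitol_high)
                if first
                else EnvState(0.0, 0.0)
            )
        raise AssertionError(f"unhandled regime {self.regime}")

    def phase_of(self, t: float) -> Tuple[float, str]:
        """Phase in [0, T) and half-period label for a post-acclimation time."""
        if not self.is_periodic:
            raise ValueError("phase is defined only for periodic regimes")
        if t < self.acclimation:
            raise ValueError(f"t={t} precedes end of acclimation ({self.acclimation})")
        assert self.period is not None
        phase = math.fmod(t - self.acclimation, self.period)
        return phase, ("first" if phase < self.period / 2 else "second")

    def transition_times(self) -> list[float]:
        """All times in (0, total_duration] at which the state changes."""
        out: list[float] = []
        prev = self.env_at(0.0)
        # candidate edges: half-period boundaries after acclimation, pulse edges
        candidates: list[float] = []
        if self.is_periodic:
            assert self.period is not None
            k, half = 0, self.period / 2
            while True:
                edge = self.acclimation + k * half
                if edge > self.total_duration:
                    break
                candidates.append(edge)
                k += 1
        elif self.regime is Regime.SINGLE_PULSE:
            assert self.pulse_start is not None and self.pulse_length is not None
            candidates = [
                self.acclimation + self.pulse_start,
                self.acclimation + self.pulse_start + self.pulse_length,
            ]
        for edge in candidates:
            if not 0 < edge <= self.total_duration:
                continue
            state = self.env_at(edge)
            if state != prev:
                out.append(edge)
            prev = state
        return out

    def sorbitol_downshifts(self) -> list[float]:
        """Times at which sorbitol switches from high to zero (hypo-osmotic shocks)."""
        out = []
        prev = self.env_at(0.0)
        for edge in self.transition_times():
            state = self.env_at(edge)
            if prev.has_sorbitol and not state.has_sorbitol:
                out.append(edge)
            prev = state
        return out

    def sorbitol_upshifts(self) -> list[float]:
        """Times at which sorbitol switches from zero to high (hyperosmotic shocks)."""
        out = []
        prev = self.env_at(0.0)
        for edge in self.transition_times():
            state = self.env_at(edge)
            if state.has_sorbitol and not prev.has_sorbitol:
                out.append(edge)
            prev = state
        return out

    def n_complete_periods(self) -> int:
        if not self.is_periodic:
            raise ValueError("not periodic")
        assert self.period is not None
        return int((self.total_duration - self.acclimation) // self.period)

    def analysis_end(self) -> float:
        """End of the last complete fluctuation period (incomplete tail excluded)."""
        if not self.is_periodic:
            return self.total_duration
        assert self.period is not None
        return self.acclimation + self.n_complete_periods() * self.period

    def to_dict(self) -> dict:
        d = {
            "regime": self.regime.value,
            "period_min": self.period,
            "glucose_high_pct": self.glucose_high,
            "sorbitol_high_M": self.sorbitol_high,
            "acclimation_min": self.acclimation,
            "duration_min": self.total_duration,
        }
        if self.regime is Regime.SINGLE_PULSE:
            d["pulse_start_min"] = self.pulse_start
            d["pulse_length_min"] = self.pulse_length
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSchedule":
        return make_schedule(
            regime=d["regime"],
            period=d.get("period_min"),
            glucose_high=d.get("glucose_high_pct", 2.0),
            sorbitol_high=d.get("sorbitol_high_M", 1.0),
            acclimation=d.get("acclimation_min", 60.0),
            total_duration=d["duration_min"],
            pulse_start=d.get("pulse_start_min"),
            pulse_length=d.get("pulse_length_min"),
        )


def make_schedule(
    regime: str | Regime,
    period: float | None = None,
    glucose_high: float = 2.0,
    sorbitol_high: float = 1.0,
    acclimation: float = 60.0,
    total_duration: float = 720.0,
    pulse_start: float | None = None,
    pulse_length: float | None = None,
) -> EnvironmentSchedule:
    """Build a validated stimulus schedule.

    Parameters
    ----------
    regime
        One of ``constant``, ``periodic_osmo``, ``periodic_glucose``, ``IPS``,
        ``AS``, ``single_pulse``.
    period
        Fluctuation period T in minutes (required and > 0 for periodic regimes).
    glucose_high, sorbitol_high
        Concentrations during the "on" phases (% wt/vol and M).
    acclimation
        Minutes of default medium before the program starts (default 60).
    total_duration
        Total experiment length in minutes, acclimation included.
    """
    try:
        regime = Regime(regime)
    except ValueError as exc:
        raise ValueError(
            f"unknown regime {regime!r}; valid: {[r.value for r in Regime]}"
        ) from exc
    if regime in PERIODIC_REGIMES:
        if period is None or period <= 0:
            raise ValueError(f"periodic regime {regime.value} requires period > 0")
    else:
        period = None
    if regime is Regime.SINGLE_PULSE:
        if pulse_start is None or pulse_length is None or pulse_length <= 0:
            raise ValueError("single_pulse requires pulse_start and pulse_length > 0")
    if acclimation < 0:
        raise ValueError("acclimation must be >= 0")
    if total_duration < acclimation:
        raise ValueError("total_duration must be >= acclimation")
    if glucose_high < 0 or sorbitol_high < 0:
        raise ValueError("concentrations must be non-negative")
    return EnvironmentSchedule(
        regime=regime,
        period=period,
        glucose_high=glucose_high,
        sorbitol_high=sorbitol_high,
        acclimation=acclimation,
        total_duration=total_duration,
        pulse_start=pulse_start,
        pulse_length=pulse_length,
    )


def env_at(schedule: EnvironmentSchedule, t: float) -> EnvState:
    """Functional alias for :meth:`EnvironmentSchedule.env_at`."""
    return schedule.env_at(t)


def phase_of(schedule: EnvironmentSchedule, t: float) -> Tuple[float, str]:
    """Functional alias for :meth:`EnvironmentSchedule.phase_of`."""
    return schedule.phase_of(t)
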
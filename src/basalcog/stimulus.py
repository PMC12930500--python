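"""Deterministic input schedules and the interval partition used for scoring.

Every experiment in this package drives a circuit with a piecewise-constant
external input x(t): rectangular pulses of fixed amplitude separated by
input-free relaxation gaps.  Two schedule types cover the protocols used:

* :class:`PulseTrain` — N identical pulses of width ``dur_on`` separated by
  gaps ``dur_off`` (period ``dur_on + dur_off``), the protocol used for
  habituation / sensitization / hybrid runs.
* :class:`MassedSpacedProtocol` — a fixed total stimulation time T split into
  N equal pulses separated by a delay ``gap``; N = 1 is the massed control.

The trajectory of a run is scored per stimulus interval: interval i spans
from the onset of pulse i to the onset of pulse i+1, and the final interval
runs from the last onset to the simulation horizon.  :func:`partition`
builds that decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "PulseTrain",
    "MassedSpacedProtocol",
    "IntervalPartition",
    "input_level",
    "to_pulse_train",
    "partition",
]


@dataclass(frozen=True)
class PulseTrain:
    """Periodic rectangular pulse train.

    Parameters
    ----------
    n_pulses
        Number of pulses N (>= 1).
    dur_on
        Pulse width (> 0), dimensionless time.
    dur_off
        Input-free gap between consecutive pulses (>= 0).
    amplitude
        Input level x during a pulse. Default 1 (the transfer functions
        saturate for moderate receptor levels, so results are insensitive
        to the exact value once it is order one or larger).
    first_onset
        Time of the first pulse onset. Default 0.
    """

    n_pulses: int
    dur_on: float
    dur_off: float
    amplitude: float = 1.0
    first_onset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise DomainError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if not (self.dur_on > 0):
            raise DomainError(f"dur_on must be > 0, got {self.dur_on}")
        if self.dur_off < 0:
            raise DomainError(f"dur_off must be >= 0, got {self.dur_off}")
        if self.amplitude < 0:
            raise DomainError(f"amplitude must be >= 0, got {self.amplitude}")

    @property
    def period(self) -> float:
        """Onset-to-onset spacing, ``dur_on + dur_off``."""
        return self.dur_on + self.dur_off

    @property
    def onsets(self) -> np.ndarray:
        return self.first_onset + self.period * np.arange(self.n_pulses)

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.dur_on

    @property
    def total_on_time(self) -> float:
        return self.n_pulses * self.dur_on

    @property
    def last_offset(self) -> float:
        return float(self.offsets[-1])


@dataclass(frozen=True)
class MassedSpacedProtocol:
    """A total stimulation time T delivered as N equal spaced pulses.

    The protocol fixes the total on-time; splitting it into more pulses makes
    each pulse shorter (width T/N) while ``gap`` sets the input-free delay
    between consecutive pulses.  With ``n_pulses=1`` the signal is massed and
    the gap is irrelevant.
    """

    total_on_time: float
    n_pulses: int
    gap: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.total_on_time > 0):
            raise DomainError("total_on_time must be > 0")
        if self.n_pulses < 1:
            raise DomainError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if self.gap < 0:
            raise DomainError(f"gap must be >= 0, got {self.gap}")
        if self.amplitude < 0:
            raise DomainError("amplitude must be >= 0")


@dataclass(frozen=True)
class IntervalPartition:
    """Stimulus-aligned decomposition of a trajectory.

    Interval i is the half-open window [onsets[i], onsets[i+1]); the final
    interval extends from the last onset to ``horizon`` (a finite truncation
    of the open-ended post-stimulus window).
    """

    onsets: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.ndim != 1 or onsets.size < 1:
            raise DomainError("onsets must be a non-empty 1-D sequence")
        if np.any(np.diff(onsets) <= 0):
            raise DomainError("onsets must be strictly increasing")
        if not (self.horizon > onsets[-1]):
            raise DomainError("horizon must exceed the last onset")

    @property
    def n_intervals(self) -> int:
        return int(self.onsets.size)

    @property
    def edges(self) -> np.ndarray:
        """Interval boundaries: onsets followed by the horizon."""
        return np.append(self.onsets, self.horizon)


def to_pulse_train(p: MassedSpacedProtocol) -> PulseTrain:
    """Realize a massed-spaced protocol as an explicit pulse train.

    N pulses of width T/N with off-gap ``p.gap``; for N = 1 the result is a
    single massed pulse of width T (the gap plays no role but is retained as
    ``dur_off`` so the default horizon is comparable across the sweep).
    """
    width = p.total_on_time / p.n_pulses
    return PulseTrain(
        n_pulses=p.n_pulses,
        dur_on=width,
        dur_off=p.gap,
        amplitude=p.amplitude,
    )


def _as_pulse_train(schedule) -> PulseTrain:
    if isinstance(schedule, MassedSpacedProtocol):
        return to_pulse_train(schedule)
    if isinstance(schedule, PulseTrain):
        return schedule
    raise DomainError(f"unsupported schedule type: {type(schedule).__name__}")


def input_level(t, schedule) -> float:
    """Input x(t) at time t: amplitude inside a pulse window, else 0.

    Pulse windows are half-open, [onset, onset + width), so the value is
    single-valued at edges.  Accepts scalars or arrays.
    """
    train = _as_pulse_train(schedule)
    t = np.asarray(t, dtype=float)
    phase = t - train.first_onset
    k = np.floor(phase / train.period)
    in_train = (k >= 0) & (k < train.n_pulses)
    in_pulse = in_train & (phase - k * train.period < train.dur_on)
    out = np.where(in_pulse, train.amplitude, 0.0)
    return float(out) if out.ndim == 0 else out


def partition(schedule, horizon: float | None = None) -> IntervalPartition:
    """Interval partition whose onsets are the schedule's pulse onsets.

    If ``horizon`` is omitted, the final interval is closed one full period
    after the last onset; simulation code passes the actual trajectory
    horizon instead.
    """
    train = _as_pulse_train(schedule)
    if horizon is None:
        horizon = float(train.onsets[-1] + train.period)
    return IntervalPartition(onsets=train.onsets, horizon=float(horizon))
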
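"""Per-interval peak extraction and the fold-change learning metrics.

Learning strength is scored from the output reporter G alone.  A trajectory
is split into stimulus intervals (one per pulse; the last runs to the
horizon), the maximum of G in each interval forms a :class:`PeakSeries`, and
three log2 fold-change statistics compare peaks:

* ``fold_change`` — last peak vs first peak: negative for habituation
  (shrinking responses), positive for sensitization (growing responses).
  FC = -1 means the final response fell to half the initial one.
* ``hybrid_fold_changes`` — for circuits that sensitize then habituate:
  the highest peak vs the first measures the sensitization phase
  (fc_sens >= 0) and the last peak vs the highest measures the habituation
  phase (fc_hab <= 0), so each magnitude matches the single-behaviour score.
* ``msl_fold_change`` — global output maximum of a spaced run vs the massed
  run that delivers the same total stimulation time; positive means spacing
  enhanced the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory
from .errors import DomainError, UndefinedFoldChangeError
from .stimulus import IntervalPartition

__all__ = [
    "PeakSeries",
    "FoldChangeReport",
    "interval_peaks",
    "fold_change",
    "hybrid_fold_changes",
    "msl_fold_change",
]


@dataclass(frozen=True)
class PeakSeries:
    """Output maxima, one per stimulus interval, with their times."""

    peak_values: np.ndarray
    peak_times: np.ndarray
    partition: IntervalPartition | None = None

    def __post_init__(self) -> None:
        pv = np.asarray(self.peak_values, dtype=float)
        pt = np.asarray(self.peak_times, dtype=float)
        object.__setattr__(self, "peak_values", pv)
        object.__setattr__(self, "peak_times", pt)
        if pv.shape != pt.shape or pv.ndim != 1:
            raise DomainError("peak_values and peak_times must be equal-length 1-D")
        if np.any(pv < 0):
            raise DomainError("peaks must be >= 0")

    def __len__(self) -> int:
        return int(self.peak_values.size)


@dataclass(frozen=True)
class FoldChangeReport:
    """Result of a fold-change comparison.

    ``fc`` is the headline log2 fold change; for the hybrid metric it is left
    None and the pair (``fc_sens``, ``fc_hab``) is filled instead.
    ``components`` records the two peak values entering each ratio, and
    ``flags`` carries degeneracy markers (e.g. ``last_peak_zero``).
    """

    fc: float | None = None
    fc_sens: float | None = None
    fc_hab: float | None = None
    components: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "fc": self.fc,
            "fc_sens": self.fc_sens,
            "fc_hab": self.fc_hab,
            "components": {k: list(map(float, v)) for k, v in self.components.items()},
            "flags": list(self.flags),
        }


def interval_peaks(traj: Trajectory, part: IntervalPartition) -> PeakSeries:
    """Maximum of G over each stimulus interval of the partition.

    Interval i is the half-open sample window [t_i, t_{i+1}); the final
    interval extends to the partition horizon inclusive.  Ties are broken by
    the earliest time.
    """
    if traj.times[-1] < part.horizon - 1e-12:
        raise DomainError(
            f"trajectory ends at {traj.times[-1]:.6g}, before the partition "
            f"horizon {part.horizon:.6g}"
        )
    g = traj.output
    edges = part.edges
    values = np.empty(part.n_intervals)
    times = np.empty(part.n_intervals)
    for i in range(part.n_intervals):
        last = i == part.n_intervals - 1
        mask = (traj.times >= edges[i]) & (
            (traj.times <= edges[i + 1]) if last else (traj.times < edges[i + 1])
        )
        if not mask.any():
            raise DomainError(
                f"no trajectory samples in interval [{edges[i]:.6g}, "
                f"{edges[i + 1]:.6g}); decrease sample_spacing"
            )
        seg = g[mask]
        j = int(np.argmax(seg))  # argmax returns the first (earliest) maximum
        values[i] = seg[j]
        times[i] = traj.times[mask][j]
    return PeakSeries(peak_values=values, peak_times=times, partition=part)


def _log2_ratio(num: float, den: float, what: str) -> tuple[float, tuple[str, ...]]:
    if den == 0:
        raise UndefinedFoldChangeError(f"{what}: reference peak is zero")
    if num == 0:
        return -math.inf, (f"{what}_zero_numerator",)
    return math.log2(num / den), ()


def fold_change(peaks: PeakSeries) -> FoldChangeReport:
    """log2(last peak / first peak): the single-behaviour learning score.

    Raises :class:`UndefinedFoldChangeError` when the first peak is zero; a
    zero last peak yields fc = -inf with an explicit flag rather than a
    silent number.
    """
    if len(peaks) < 2:
        raise DomainError("need at least two interval peaks for a fold change")
    first = float(peaks.peak_values[0])
    last = float(peaks.peak_values[-1])
    fc, flags = _log2_ratio(last, first, "fold_change")
    return FoldChangeReport(fc=fc, components={"fc": (first, last)}, flags=flags)


def hybrid_fold_changes(peaks: PeakSeries) -> FoldChangeReport:
    """Sensitization and habituation scores of a biphasic peak series.

    fc_sens = log2(highest/first) >= 0 measures the growth phase;
    fc_hab = log2(last/highest) <= 0 measures the decay phase.  Signs follow
    the single-behaviour conventions so the two scores are comparable with
    the pure-circuit fold changes.
    """
    if len(peaks) < 2:
        raise DomainError("need at least two interval peaks for a fold change")
    first = float(peaks.peak_values[0])
    last = float(peaks.peak_values[-1])
    top = float(np.max(peaks.peak_values))
    fc_sens, f1 = _log2_ratio(top, first, "fc_sens")
    fc_hab, f2 = _log2_ratio(last, top, "fc_hab")
    return FoldChangeReport(
        fc_sens=fc_sens,
        fc_hab=fc_hab,
        components={"fc_sens": (first, top), "fc_hab": (top, last)},
        flags=f1 + f2,
    )


def msl_fold_change(spaced: Trajectory, massed: Trajectory) -> FoldChangeReport:
    """log2 of the global output maxima, spaced over massed.

    Both runs must use the same circuit parameters and deliver the same
    total stimulation time; only the temporal arrangement may differ.
    """
    if spaced.params != massed.params:
        raise DomainError("spaced and massed runs must share circuit parameters")
    from .stimulus import _as_pulse_train

    on_s = _as_pulse_train(spaced.schedule).total_on_time
    on_m = _as_pulse_train(massed.schedule).total_on_time
    if not math.isclose(on_s, on_m, rel_tol=1e-12):
        raise DomainError(
            f"total stimulation time differs: spaced {on_s} vs massed {on_m}"
        )
    peak_s = float(np.max(spaced.output))
    peak_m = float(np.max(massed.output))
    fc, flags = _log2_ratio(peak_s, peak_m, "msl_fc")
    return FoldChangeReport(fc=fc, components={"fc": (peak_m, peak_s)}, flags=flags)
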
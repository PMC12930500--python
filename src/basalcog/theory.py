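"""Closed-form analysis of memory accumulation under pulsed stimulation.

When each pulse is much shorter than the relaxation gap and the memory
species stays far from saturation, the memory ODE can be replaced by an
impulsive model: every pulse deposits a fixed increment (the pulse weight,
production rate times pulse width) instantaneously, and the level decays
exponentially between pulses.  This module implements that approximation and
the results that follow from it:

* the explicit delta-train solution (:func:`impulsive_memory`),
* the net memory change per stimulation cycle and the critical relaxation
  time beyond which no net gain is possible (:func:`memory_increment`,
  :func:`critical_relaxation`),
* the periodic steady-state envelope reached after many pulses
  (:func:`periodic_envelope`),
* a step-gated massed-spaced model in which output is produced at full rate
  whenever the memory exceeds a normalized threshold of 1, with closed-form
  post-pulse levels, production windows and output trajectory
  (:func:`msl_state_after_pulse`, :func:`msl_production_windows`,
  :func:`msl_output`), closed-form peak outputs for one and two pulses
  (:func:`massed_peak`, :func:`two_pulse_peak`) and the condition under
  which spacing a fixed stimulation budget beats delivering it massed
  (:func:`spaced_superiority_holds`).

Indexing conventions differ between the two families on purpose: the
delta-train of :func:`impulsive_memory` places pulse k at t = k*period for
k = 1..N (the first pulse arrives after one period), while the massed-spaced
model places pulse k at t = k*period for k = 0..N-1 (the first pulse at
t = 0).  Each matches the construction it approximates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuits import CircuitParams
from .errors import AssumptionError, DomainError
from .regulation import heaviside

__all__ = [
    "ImpulsiveProtocol",
    "MSLClosedForm",
    "ClosedFormPeak",
    "impulsive_memory",
    "memory_increment",
    "critical_relaxation",
    "periodic_envelope",
    "msl_state_after_pulse",
    "msl_production_windows",
    "msl_output",
    "massed_peak",
    "two_pulse_peak",
    "spaced_superiority_holds",
    "msl_protocol",
]

#: normalized memory threshold gating output production in the step model
THRESHOLD = 1.0


@dataclass(frozen=True)
class ImpulsiveProtocol:
    """A train of instantaneous memory increments with exponential decay.

    Parameters
    ----------
    pulse_weight
        Memory deposited per pulse: production rate x pulse width (for a
        split stimulation budget: alpha * dur_on / N).
    decay
        Memory decay rate (gamma).
    n_pulses
        Number of pulses N.
    period
        Pulse spacing; in the short-pulse regime this is approximately the
        relaxation gap dur_off.
    I0
        Memory level just before the first pulse (default 0).
    output_rate
        Maximal output production rate (beta) used by the step-gated
        massed-spaced output model.
    """

    pulse_weight: float
    decay: float
    n_pulses: int
    period: float
    I0: float = 0.0
    output_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pulse_weight > 0):
            raise DomainError("pulse_weight must be > 0")
        if not (self.decay > 0):
            raise DomainError("decay must be > 0")
        if self.n_pulses < 1:
            raise DomainError("n_pulses must be >= 1")
        if self.period < 0:
            raise DomainError("period must be >= 0")
        if self.I0 < 0:
            raise DomainError("I0 must be >= 0")
        if not (self.output_rate > 0):
            raise DomainError("output_rate must be > 0")


def msl_protocol(
    p: CircuitParams, dur_on: float, dur_off: float, n_pulses: int
) -> ImpulsiveProtocol:
    """Impulsive protocol for a stimulation budget ``alpha * dur_on`` split
    into ``n_pulses`` equal pulses separated by ``dur_off``."""
    return ImpulsiveProtocol(
        pulse_weight=p.alpha * dur_on / n_pulses,
        decay=p.gamma,
        n_pulses=n_pulses,
        period=dur_off,
        output_rate=p.beta,
    )


def impulsive_memory(t, ip: ImpulsiveProtocol):
    """Delta-train memory level, pulses at t_k = k*period for k = 1..N.

    I(t) = sum_k w * H(t - t_k) * exp(-decay * (t - t_k)), assuming
    negligible memory before the first pulse.  Vectorized in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    tk = ip.period * np.arange(1, ip.n_pulses + 1)
    dt = t[..., None] - tk
    terms = heaviside(dt) * np.exp(-ip.decay * np.where(dt >= 0, dt, 0.0))
    out = ip.pulse_weight * terms.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def memory_increment(
    I0: float, pulse_weight: float, decay: float, dur_off: float
) -> float:
    """Net memory change over one cycle: jump by the pulse weight, then
    decay for ``dur_off``: (I0 + w) exp(-decay*dur_off) - I0."""
    if I0 < 0:
        raise DomainError("I0 must be >= 0")
    return (I0 + pulse_weight) * math.exp(-decay * dur_off) - I0


def critical_relaxation(I0: float, pulse_weight: float, decay: float) -> float:
    """Longest relaxation gap compatible with net memory gain.

    The per-cycle increment is strictly positive below this gap and strictly
    negative above it: dur_off* = log(1 + w/I0) / decay.  For I0 = 0 any
    gap admits net gain and +inf is returned.
    """
    if I0 < 0 or pulse_weight < 0:
        raise DomainError("I0 and pulse_weight must be >= 0")
    if not (decay > 0):
        raise DomainError("decay must be > 0")
    if I0 == 0:
        return math.inf
    return math.log1p(pulse_weight / I0) / decay


def periodic_envelope(tau, ip: ImpulsiveProtocol):
    """Periodic steady-state memory profile in the many-pulse limit.

    I(tau) = w * exp(-decay*tau) / (1 - exp(-decay*period)) for tau in
    [0, period), tau measured from the most recent pulse.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0) or np.any(tau >= ip.period):
        raise DomainError("tau must lie in [0, period)")
    denom = -math.expm1(-ip.decay * ip.period)
    if denom == 0:
        raise DomainError("period must be > 0 for a periodic envelope")
    out = ip.pulse_weight * np.exp(-ip.decay * tau) / denom
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# step-gated massed-spaced model: pulses at t_k = k*period, k = 0..N-1


def msl_state_after_pulse(k: int, ip: ImpulsiveProtocol) -> float:
    """Memory level immediately after the k-th pulse (k = 0..N-1).

    Geometric accumulation of the per-pulse weight under inter-pulse decay:
    A_k = w * (1 - r**(k+1)) / (1 - r) with r = exp(-decay*period).  The
    period -> 0 limit (k+1)*w is returned by continuity.
    """
    if not (0 <= k <= ip.n_pulses - 1):
        raise DomainError(f"k must be in 0..{ip.n_pulses - 1}, got {k}")
    gdt = ip.decay * ip.period
    if gdt == 0:
        return (k + 1) * ip.pulse_weight
    return ip.pulse_weight * (-math.expm1(-(k + 1) * gdt)) / (-math.expm1(-gdt))


@dataclass(frozen=True)
class MSLClosedForm:
    """Closed-form bookkeeping of the step-gated massed-spaced model."""

    onsets: np.ndarray  # pulse times t_k = k*period
    A_k: np.ndarray  # memory immediately after each pulse
    t_star: np.ndarray  # decay time from A_k back to the threshold
    l_k: np.ndarray  # output-production window started by each pulse


def msl_production_windows(ip: ImpulsiveProtocol) -> MSLClosedForm:
    """Production windows of the step-gated output.

    After pulse k the memory sits at A_k and decays; output is produced while
    it stays at or above the threshold 1, i.e. for t*_k = log(A_k)/decay,
    truncated at the arrival of the next pulse for all but the final one.
    Below-threshold pulses contribute no window.
    """
    ks = np.arange(ip.n_pulses)
    A = np.array([msl_state_after_pulse(int(k), ip) for k in ks])
    with np.errstate(divide="ignore"):
        t_star = np.where(A > 0, np.log(np.maximum(A, 1e-300)) / ip.decay, -np.inf)
    above = heaviside(A - THRESHOLD)
    l = above * np.maximum(t_star, 0.0)
    if ip.n_pulses > 1:
        l[:-1] = above[:-1] * np.minimum(np.maximum(t_star[:-1], 0.0), ip.period)
    return MSLClosedForm(
        onsets=ip.period * ks, A_k=A, t_star=t_star, l_k=l
    )


def msl_output(t, ip: ImpulsiveProtocol):
    """Step-gated output G(t) as the sum of per-pulse contributions.

    Each pulse k produces output at rate beta during its window
    [t_k, t_k + l_k]; with linear decay the contributions superpose:
    G(t) = (beta/decay) * sum_k (1 - exp(-decay*tau_k_plus))
    * exp(-decay*tau_k_minus) * H(t - t_k), where tau_k_plus is the
    production time already elapsed for pulse k and tau_k_minus the time
    since its production halted.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    cf = msl_production_windows(ip)
    dt = t[..., None] - cf.onsets
    tau_plus = np.minimum(np.where(dt >= 0, dt, 0.0), cf.l_k)
    tau_minus = np.maximum(0.0, dt - cf.l_k)
    terms = (
        (-np.expm1(-ip.decay * tau_plus))
        * np.exp(-ip.decay * tau_minus)
        * heaviside(dt)
    )
    out = (ip.output_rate / ip.decay) * terms.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def msl_peak(ip: ImpulsiveProtocol) -> float:
    """Global maximum of the step-gated output.

    Peaks sit at the ends of production windows and are nondecreasing across
    pulses, so the global maximum is at the end of the final window.
    """
    cf = msl_production_windows(ip)
    if not np.any(cf.l_k > 0):
        return 0.0
    t_peak = float(cf.onsets[-1] + cf.l_k[-1])
    return float(msl_output(t_peak, ip))


@dataclass(frozen=True)
class ClosedFormPeak:
    """A closed-form peak output, flagged when the stimulation budget never
    lifts the memory above the production threshold."""

    value: float
    below_threshold: bool = False

    def __float__(self) -> float:
        return self.value


def massed_peak(p: CircuitParams, dur_on: float) -> ClosedFormPeak:
    """Peak step-gated output of a single massed pulse.

    max G = (beta/gamma) * (1 - 1/(alpha*dur_on)) when alpha*dur_on > 1;
    below the threshold no output is produced and 0 is returned flagged.
    """
    w = p.alpha * dur_on
    if w <= THRESHOLD:
        return ClosedFormPeak(0.0, below_threshold=True)
    return ClosedFormPeak((p.beta / p.gamma) * (1.0 - 1.0 / w))


def two_pulse_peak(p: CircuitParams, dur_on: float, dur_off: float) -> float:
    """Peak step-gated output of the budget split into two spaced pulses.

    max G = (beta/gamma) * (1 - 2 exp(-gamma*dur_off)
    / (alpha*dur_on (1 + exp(-gamma*dur_off)))), valid when each
    half-budget pulse sustains production across the whole gap
    (log(alpha*dur_on/2) >= gamma*dur_off); strictly exceeds the massed
    peak whenever gamma*dur_off > 0.
    """
    if not spaced_superiority_holds(p, dur_on, dur_off, 2):
        raise AssumptionError(
            "closed form requires each half pulse to sustain production "
            "across the full gap: log(alpha*dur_on/2) >= gamma*dur_off"
        )
    e = math.exp(-p.gamma * dur_off)
    return (p.beta / p.gamma) * (1.0 - 2.0 * e / (p.alpha * dur_on * (1.0 + e)))


def spaced_superiority_holds(
    p: CircuitParams, dur_on: float, dur_off: float, n_pulses: int
) -> bool:
    """Whether a single split pulse sustains production across the full gap:
    log(alpha*dur_on/N) >= gamma*dur_off.  Inside this region, splitting
    the budget into N equally spaced pulses beats the massed delivery."""
    if n_pulses < 1:
        raise DomainError("n_pulses must be >= 1")
    if dur_off < 0:
        raise DomainError("dur_off must be >= 0")
    w = p.alpha * dur_on / n_pulses
    if w <= 0:
        return False
    return math.log(w) >= p.gamma * dur_off
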
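"""Independent reference computations used to cross-check the package.

These deliberately take different routes than the implementation: the
step-gated output model is integrated forward in time segment by segment
(exact linear-ODE pieces between events) instead of summing per-pulse
contributions, and the delta-train memory is accumulated by explicit jump
recursion.
"""

from __future__ import annotations

import math

import numpy as np


def gated_step_model_output(t_eval, ip):
    """Forward integration of the step-gated massed-spaced model.

    The memory jumps by the pulse weight at t_k = k*period (k = 0..N-1) and
    decays exponentially; output is produced at the full rate exactly while
    the memory is at or above 1 and decays otherwise.  Between consecutive
    events (pulse arrivals and threshold crossings) both pieces are linear
    ODEs with constant coefficients, integrated in closed form, so the only
    approximation anywhere is float round-off.
    """
    g, w, beta = ip.decay, ip.pulse_weight, ip.output_rate
    # production on/off segments from the jump recursion
    pieces: list[tuple[float, float, bool]] = []
    A = 0.0
    for k in range(ip.n_pulses):
        tk = k * ip.period
        A += w
        t_next = (k + 1) * ip.period if k < ip.n_pulses - 1 else math.inf
        if A >= 1.0:
            t_stop = min(tk + math.log(A) / g, t_next)
            pieces.append((tk, t_stop, True))
            if t_stop < t_next:
                pieces.append((t_stop, t_next, False))
        else:
            pieces.append((tk, t_next, False))
        if k < ip.n_pulses - 1:
            A *= math.exp(-g * ip.period)

    te = np.atleast_1d(np.asarray(t_eval, dtype=float))
    out = np.zeros_like(te)
    for i, t in enumerate(te):
        G = 0.0
        for t0, t1, producing in pieces:
            if t <= t0:
                break
            dt = min(t1, t) - t0
            decay = math.exp(-g * dt)
            G = G * decay + (beta / g) * (1.0 - decay) * producing
            if t1 >= t:
                break
        out[i] = G
    return out if np.ndim(t_eval) else float(out[0])


def delta_train_memory(t, weight, decay, pulse_times):
    """Jump-and-decay recursion for a delta-train memory level at time t."""
    level = 0.0
    t_prev = 0.0
    for tk in pulse_times:
        if tk > t:
            break
        level *= math.exp(-decay * (tk - t_prev))
        level += weight
        t_prev = tk
    return level * math.exp(-decay * (t - t_prev))


def relaxing_exponential(t, start, target, rate):
    """Solution of y' = rate*(target - y): exponential relaxation."""
    t = np.asarray(t, dtype=float)
    return target + (start - target) * np.exp(-rate * t)
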
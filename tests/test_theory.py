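import math

import numpy as np
import pytest
from scipy.optimize import brentq

from basalcog.circuits import CircuitParams
from basalcog.engine import SimulationGrid, integrate, simulate_protocol
from basalcog.errors import AssumptionError, DomainError
from basalcog.stimulus import PulseTrain
from basalcog.theory import (
    ImpulsiveProtocol,
    critical_relaxation,
    impulsive_memory,
    massed_peak,
    memory_increment,
    msl_output,
    msl_peak,
    msl_production_windows,
    msl_protocol,
    msl_state_after_pulse,
    periodic_envelope,
    spaced_superiority_holds,
    two_pulse_peak,
)
from oracles import delta_train_memory, gated_step_model_output


def _random_protocol(rng, n_max=6):
    return ImpulsiveProtocol(
        pulse_weight=rng.uniform(0.5, 20.0),
        decay=rng.uniform(1e-3, 5e-2),
        n_pulses=int(rng.integers(1, n_max + 1)),
        period=rng.uniform(1.0, 100.0),
        output_rate=rng.uniform(0.5, 2.0),
    )


# --- delta-train memory ----------------------------------------------------


def test_impulsive_memory_basics():
    ip = ImpulsiveProtocol(pulse_weight=2.0, decay=0.01, n_pulses=1, period=10.0)
    assert impulsive_memory(10.0, ip) == pytest.approx(2.0)  # just after the jump
    assert impulsive_memory(9.99, ip) == 0.0  # before the first pulse
    slow = ImpulsiveProtocol(pulse_weight=2.0, decay=1e-12, n_pulses=5, period=10.0)
    assert impulsive_memory(51.0, slow) == pytest.approx(10.0, rel=1e-9)


def test_impulsive_memory_matches_jump_recursion():
    rng = np.random.default_rng(7)
    for _ in range(20):
        ip = _random_protocol(rng)
        pulse_times = ip.period * np.arange(1, ip.n_pulses + 1)
        t = float(rng.uniform(0.0, ip.period * (ip.n_pulses + 2)))
        expected = delta_train_memory(t, ip.pulse_weight, ip.decay, pulse_times)
        assert impulsive_memory(t, ip) == pytest.approx(expected, abs=1e-12)


def test_memory_increment_values():
    assert memory_increment(1.0, 1.5, 0.01, 0.0) == pytest.approx(1.5)
    assert memory_increment(1.0, 1.5, 0.01, 1e9) == pytest.approx(-1.0)
    assert memory_increment(1.0, 1.5, 0.01, 9.0) == pytest.approx(
        2.5 * math.exp(-0.09) - 1.0, rel=1e-12
    )


def test_critical_relaxation_is_the_sign_change():
    assert critical_relaxation(1.0, 0.0, 0.01) == 0.0
    assert critical_relaxation(1.0, 1.5, 0.01) == pytest.approx(
        100.0 * math.log(2.5), rel=1e-12
    )
    assert critical_relaxation(0.0, 1.5, 0.01) == math.inf
    # defining identity and strict sign flip around the root
    for I0, w, g in [(1.0, 1.5, 0.01), (5.0, 0.3, 0.002), (0.2, 8.0, 0.05)]:
        crit = critical_relaxation(I0, w, g)
        assert memory_increment(I0, w, g, crit) == pytest.approx(0.0, abs=1e-10)
        assert memory_increment(I0, w, g, 0.99 * crit) > 0
        assert memory_increment(I0, w, g, 1.01 * crit) < 0
        root = brentq(
            lambda d: memory_increment(I0, w, g, d), 1e-9, 10 * crit, xtol=1e-12
        )
        assert root == pytest.approx(crit, abs=1e-10)


def test_periodic_envelope():
    ip = ImpulsiveProtocol(pulse_weight=1.5, decay=0.01, n_pulses=500, period=10.0)
    assert periodic_envelope(0.0, ip) == pytest.approx(
        1.5 / (1.0 - math.exp(-0.1)), rel=1e-12
    )
    # pure decay within a cycle
    ratio = periodic_envelope(0.0, ip) / periodic_envelope(10.0 - 1e-9, ip)
    assert ratio == pytest.approx(math.exp(0.01 * 10.0), rel=1e-6)
    # no carry-over when cycles are long compared to the memory lifetime
    long_ip = ImpulsiveProtocol(pulse_weight=1.5, decay=1.0, n_pulses=10, period=50.0)
    assert periodic_envelope(0.0, long_ip) == pytest.approx(1.5, rel=1e-12)
    with pytest.raises(DomainError):
        periodic_envelope(10.0, ip)  # tau must lie within the cycle


def test_envelope_is_the_many_pulse_limit():
    ip = ImpulsiveProtocol(pulse_weight=1.5, decay=0.01, n_pulses=500, period=10.0)
    for tau in (0.0, 2.5, 9.0):
        late = 490 * ip.period + tau
        assert impulsive_memory(late, ip) == pytest.approx(
            periodic_envelope(tau, ip), rel=1e-6
        )


def test_impulsive_approximation_tracks_full_circuit():
    """At pulse onsets the delta-train memory stays within 5% of the
    integrated habituation memory when pulses are short (on/off = 0.1) and
    the input saturates the receptor complex."""
    p = CircuitParams(alpha=1.5, beta=5.0, gamma=0.01, lam=1.0, mu=1.0)
    proto = PulseTrain(n_pulses=10, dur_on=1.0, dur_off=10.0, amplitude=50.0)
    traj = simulate_protocol("habituation", p, proto)
    ip = ImpulsiveProtocol(
        pulse_weight=p.alpha * proto.dur_on,
        decay=p.gamma,
        n_pulses=proto.n_pulses,
        period=proto.period,
    )
    # the delta train fires at t_k = k*period, so the memory just before its
    # k-th event corresponds to the simulated memory at the onset of the
    # k-th pulse (which starts at (k-1)*period)
    for k in range(2, proto.n_pulses + 1):
        i_ode = np.interp((k - 1) * proto.period, traj.times, traj.species["I"])
        i_imp = impulsive_memory(k * proto.period - 1e-9, ip)
        assert abs(i_ode - i_imp) / i_ode < 0.05


# --- step-gated massed-spaced model ---------------------------------------


def test_msl_state_after_pulse():
    ip = ImpulsiveProtocol(pulse_weight=5.0, decay=0.01, n_pulses=2, period=50.0)
    assert msl_state_after_pulse(0, ip) == pytest.approx(5.0)
    assert msl_state_after_pulse(1, ip) == pytest.approx(
        5.0 * (1 - math.exp(-1.0)) / (1 - math.exp(-0.5)), rel=1e-12
    )
    # zero-gap limit by continuity
    ip0 = ImpulsiveProtocol(pulse_weight=5.0, decay=0.01, n_pulses=3, period=0.0)
    assert msl_state_after_pulse(2, ip0) == pytest.approx(15.0)
    # no accumulation when the gap dwarfs the memory lifetime
    far = ImpulsiveProtocol(pulse_weight=5.0, decay=1.0, n_pulses=4, period=1e3)
    assert msl_state_after_pulse(3, far) == pytest.approx(5.0, rel=1e-12)
    with pytest.raises(DomainError):
        msl_state_after_pulse(2, ip)


def test_production_windows():
    # never crosses the threshold
    low = ImpulsiveProtocol(pulse_weight=0.3, decay=0.1, n_pulses=3, period=100.0)
    assert np.all(msl_production_windows(low).l_k == 0.0)
    # exactly at threshold: window of zero length, but the gate is open
    at = ImpulsiveProtocol(pulse_weight=1.0, decay=0.01, n_pulses=1, period=1.0)
    cf = msl_production_windows(at)
    assert cf.l_k[0] == 0.0
    # single strong pulse
    one = ImpulsiveProtocol(pulse_weight=10.0, decay=0.01, n_pulses=1, period=1.0)
    assert msl_production_windows(one).l_k[0] == pytest.approx(
        100.0 * math.log(10.0), rel=1e-12
    )


def test_msl_output_matches_gated_integration():
    rng = np.random.default_rng(11)
    for _ in range(40):
        ip = _random_protocol(rng)
        horizon = (ip.n_pulses - 1) * ip.period + 3.0 / ip.decay
        ts = np.linspace(0.0, horizon, 150)
        np.testing.assert_allclose(
            msl_output(ts, ip), gated_step_model_output(ts, ip), atol=1e-6
        )


def test_closed_form_peaks():
    p = CircuitParams(alpha=1.0, beta=1.0, gamma=0.01, lam=1.0, mu=1.0)
    assert massed_peak(p, 1.0).value == 0.0  # alpha*dur_on exactly at threshold
    assert massed_peak(p, 1.0).below_threshold
    assert massed_peak(p, 10.0).value == pytest.approx(90.0, rel=1e-12)
    big = massed_peak(p.replace(alpha=1e9), 10.0).value
    assert big == pytest.approx(p.beta / p.gamma, rel=1e-8)
    assert two_pulse_peak(p, 10.0, 50.0) == pytest.approx(
        100.0 * (1.0 - 2.0 * math.exp(-0.5) / (10.0 * (1.0 + math.exp(-0.5)))),
        rel=1e-12,
    )
    # zero gap: splitting changes nothing
    assert two_pulse_peak(p, 10.0, 0.0) == pytest.approx(
        massed_peak(p, 10.0).value, rel=1e-12
    )
    with pytest.raises(AssumptionError):
        two_pulse_peak(p, 10.0, 1000.0)


def test_closed_form_peaks_match_output_model():
    p = CircuitParams(alpha=1.0, beta=1.0, gamma=0.01, lam=1.0, mu=1.0)
    assert msl_peak(msl_protocol(p, 10.0, 0.0, 1)) == pytest.approx(
        massed_peak(p, 10.0).value, abs=1e-6
    )
    assert msl_peak(msl_protocol(p, 10.0, 50.0, 2)) == pytest.approx(
        two_pulse_peak(p, 10.0, 50.0), abs=1e-6
    )


def test_spaced_superiority_condition():
    p = CircuitParams(alpha=1.0, beta=1.0, gamma=0.01, lam=1.0, mu=1.0)
    assert spaced_superiority_holds(p, 10.0, 50.0, 2)  # ln 5 > 0.5
    assert not spaced_superiority_holds(p, 10.0, 1.0, 20)  # split below unit weight
    assert spaced_superiority_holds(p, 10.0, 0.0, 10)  # unit weight, zero gap


def test_splitting_beats_massed_for_general_pulse_counts():
    """Whenever a split pulse sustains production across the full gap, any
    number of spaced pulses yields at least the massed peak output."""
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 40:
        alpha = rng.uniform(0.5, 5.0)
        dur_on = rng.uniform(2.0, 20.0)
        gamma = rng.uniform(1e-3, 5e-2)
        dur_off = rng.uniform(0.5, 60.0)
        n = int(rng.integers(2, 7))
        p = CircuitParams(alpha=alpha, beta=1.0, gamma=gamma, lam=1.0, mu=1.0)
        if not spaced_superiority_holds(p, dur_on, dur_off, n):
            continue
        assert msl_peak(msl_protocol(p, dur_on, dur_off, n)) >= massed_peak(
            p, dur_on
        ).value - 1e-9
        checked += 1


def test_threshold_crossing_in_full_circuit():
    """One pulse-relaxation cycle of the habituation ODE gains memory below
    the predicted critical gap and loses memory above it."""
    p = CircuitParams(alpha=1.5, beta=5.0, gamma=0.01, lam=1.0, mu=1.0)
    I0 = 10.0
    for dur_off, expect_gain in [(10.0, True), (100.0, False)]:
        dur_on = 0.1 * dur_off
        w = p.alpha * dur_on
        predicted = memory_increment(I0, w, p.gamma, dur_off)
        assert (predicted > 0) == expect_gain  # the impulsive layer agrees
        proto = PulseTrain(1, dur_on, dur_off, amplitude=50.0)
        traj = integrate(
            "habituation",
            p,
            proto,
            SimulationGrid(0.01, dur_on / 10.0, proto.period),
            initial_state=np.array([1.0, I0, 0.0]),
        )
        delta = traj.species["I"][-1] - I0
        assert (delta > 0) == expect_gain
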
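"""Right-hand sides and resting states of the four learning circuits.

Each circuit is a small ODE model of a synthetic transcriptional network in
which a constitutive receptor X binds a diffusible input molecule x (a
quorum-sensing signal in the reference implementation), and the ligand-bound
complex X*x drives downstream promoters through squared Hill transfer
functions.  Species are dimensionless concentrations:

* ``habituation`` — incoherent feed-forward loop.  The complex activates both
  a slowly degrading memory repressor I and the output G; G's hybrid promoter
  requires the complex and the absence of I, so output peaks shrink as I
  accumulates over pulses.
* ``sensitization`` — double-repression cascade closing a positive feedback
  on the receptor: I represses R which represses X, so stimulation history
  boosts receptor levels and output peaks grow.
* ``hybrid`` — the sensitization circuit with the habituation-style hybrid
  output promoter reintroduced (repression half-activation ``K_out``),
  producing sensitization followed by habituation.
* ``msl`` — massed-spaced learning: a linear activation chain x -> A -> G in
  which the intermediate inducer A integrates input history and G production
  outlasts the stimulus.  All species here decay at the slow rate gamma.

Rates: ``alpha``, ``beta``, ``mu``, ``rho`` are maximal expression rates of
the I, G, X and R promoters; ``gamma`` is the slow degradation-dilution rate
of untagged proteins; ``lam`` is the fast degradation rate of tagged
proteins.  Memory requires time-scale separation lam >> gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "CircuitParams",
    "CIRCUIT_KINDS",
    "species_names",
    "circuit_rhs",
    "habituation_rhs",
    "sensitization_rhs",
    "hybrid_rhs",
    "msl_rhs",
    "resting_state",
]

CIRCUIT_KINDS = ("habituation", "sensitization", "hybrid", "msl")


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of one circuit instance (all rates > 0).

    Parameters
    ----------
    alpha
        Maximal expression rate of the memory species (I or A).
    beta
        Maximal expression rate of the output G.
    gamma
        Slow degradation-dilution rate (untagged proteins).
    lam
        Fast degradation rate of tagged proteins; must satisfy
        ``lam >= gamma`` and should exceed it by at least 10x for the
        memory mechanism to work (a warning is issued below that ratio).
        Unused by the ``msl`` circuit, whose species all decay at gamma.
    mu
        Maximal expression rate of the receptor X.
    rho
        Maximal expression rate of the intermediate repressor R
        (sensitization and hybrid circuits only).
    K_out
        Half-activation of the output repressor curve (hybrid circuit
        only); raising it above 1 delays the switch from sensitization
        to habituation.
    """

    alpha: float = 1.5
    beta: float = 5.0
    gamma: float = 0.01
    lam: float = 1.0
    mu: float = 1.0
    rho: float = 1.75
    K_out: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "lam", "mu", "rho", "K_out"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be finite and > 0, got {v}")
        if self.lam < self.gamma:
            raise DomainError(
                f"lam ({self.lam}) must be >= gamma ({self.gamma}); the fast "
                "degradation class cannot be slower than the basal one"
            )
        if self.lam < 10 * self.gamma:
            warnings.warn(
                f"lam/gamma = {self.lam / self.gamma:.2f} < 10: weak time-scale "
                "separation, memory persistence between pulses will be poor",
                stacklevel=3,
            )

    def replace(self, **kw) -> "CircuitParams":
        from dataclasses import replace

        return replace(self, **kw)


_SPECIES = {
    "habituation": ("X", "I", "G"),
    "sensitization": ("X", "I", "R", "G"),
    "hybrid": ("X", "I", "R", "G"),
    "msl": ("X", "A", "G"),
}


def species_names(kind: str) -> tuple[str, ...]:
    """State-variable labels of a circuit, in integration order."""
    _check_kind(kind)
    return _SPECIES[kind]


def _check_kind(kind: str) -> None:
    if kind not in CIRCUIT_KINDS:
        raise DomainError(f"unknown circuit {kind!r}; choose from {CIRCUIT_KINDS}")


def _check_state(s: np.ndarray, n: int, x: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (n,):
        raise DomainError(f"state must have {n} components, got shape {s.shape}")
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise DomainError("state components must be finite and >= 0")
    if x < 0 or not np.isfinite(x):
        raise DomainError("input level must be finite and >= 0")
    return s


# Hill forms are inlined on scalars here (hot path of the integrator); they
# are identical to regulation.theta_plus / theta_minus with K = 1.


def habituation_rhs(s, x: float, p: CircuitParams) -> np.ndarray:
    """Incoherent feed-forward loop: dX = mu - lam X; dI = alpha th+(Xx)
    - gamma I; dG = beta th+(Xx) th-(I) - lam G.

    The complex concentration passed to the activating Hill function is the
    instantaneous mass-action product X*x.
    """
    X, I, G = _check_state(s, 3, x)
    c2 = (X * x) ** 2
    tp = c2 / (1.0 + c2)
    tm = 1.0 / (1.0 + I * I)
    return np.array(
        [p.mu - p.lam * X, p.alpha * tp - p.gamma * I, p.beta * tp * tm - p.lam * G]
    )


def sensitization_rhs(s, x: float, p: CircuitParams) -> np.ndarray:
    """Double-repression positive feedback: dX = mu th-(R) - lam X;
    dI = alpha th+(Xx) - gamma I; dR = rho th-(I) - lam R;
    dG = beta th+(Xx) - lam G."""
    X, I, R, G = _check_state(s, 4, x)
    c2 = (X * x) ** 2
    tp = c2 / (1.0 + c2)
    return np.array(
        [
            p.mu / (1.0 + R * R) - p.lam * X,
            p.alpha * tp - p.gamma * I,
            p.rho / (1.0 + I * I) - p.lam * R,
            p.beta * tp - p.lam * G,
        ]
    )


def hybrid_rhs(s, x: float, p: CircuitParams) -> np.ndarray:
    """Sensitization core with a hybrid output promoter: as sensitization
    but dG = beta th+(Xx) th-_K(I) - lam G, with repressor half-activation
    ``K_out``."""
    X, I, R, G = _check_state(s, 4, x)
    c2 = (X * x) ** 2
    tp = c2 / (1.0 + c2)
    tmK = 1.0 / (1.0 + (I / p.K_out) ** 2)
    return np.array(
        [
            p.mu / (1.0 + R * R) - p.lam * X,
            p.alpha * tp - p.gamma * I,
            p.rho / (1.0 + I * I) - p.lam * R,
            p.beta * tp * tmK - p.lam * G,
        ]
    )


def msl_rhs(s, x: float, p: CircuitParams) -> np.ndarray:
    """Linear activation chain with slow turnover everywhere:
    dX = mu - gamma X; dA = alpha th+(Xx) - gamma A; dG = beta th+(A)
    - gamma G."""
    X, A, G = _check_state(s, 3, x)
    c2 = (X * x) ** 2
    tp = c2 / (1.0 + c2)
    tg = A * A / (1.0 + A * A)
    return np.array(
        [p.mu - p.gamma * X, p.alpha * tp - p.gamma * A, p.beta * tg - p.gamma * G]
    )


_RHS = {
    "habituation": habituation_rhs,
    "sensitization": sensitization_rhs,
    "hybrid": hybrid_rhs,
    "msl": msl_rhs,
}


def circuit_rhs(kind: str):
    """Return the RHS function ``f(state, x, params) -> dstate/dt``."""
    _check_kind(kind)
    return _RHS[kind]


def resting_state(kind: str, p: CircuitParams) -> np.ndarray:
    """Closed-form fixed point of the x = 0 system; every simulation starts
    here.

    habituation: (X, I, G) = (mu/lam, 0, 0);
    sensitization/hybrid: I = 0, R = rho/lam, X = (mu/lam) th-(R), G = 0;
    msl: (X, A, G) = (mu/gamma, 0, 0).
    """
    _check_kind(kind)
    if kind == "habituation":
        return np.array([p.mu / p.lam, 0.0, 0.0])
    if kind == "msl":
        return np.array([p.mu / p.gamma, 0.0, 0.0])
    R = p.rho / p.lam
    X = (p.mu / p.lam) / (1.0 + R * R)
    return np.array([X, 0.0, R, 0.0])
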
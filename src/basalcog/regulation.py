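"""Normalized promoter transfer functions.

All circuits in this package regulate transcription through squared Hill
functions: an activating branch ``theta_plus`` for promoters switched on by a
transcription-factor/ligand complex and a repressing branch ``theta_minus``
for promoters silenced by a repressor.  Both are normalized to [0, 1] and
parameterized only by the half-activation concentration K; the Hill exponent
is fixed at 2 (the dimerizing regulators used throughout — LuxR, LacI, TetR,
AraC — all act cooperatively).

A unit-step ``heaviside`` with H(0) = 1 is also provided; the step-gated
output of the simplified massed-spaced model depends on this convention, so
it is defined here once rather than borrowed from a library that uses
H(0) = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["TransferSpec", "theta_plus", "theta_minus", "heaviside", "HILL_EXPONENT"]

#: Hill exponent used by every promoter model in the package (dimeric binding).
HILL_EXPONENT = 2


@dataclass(frozen=True)
class TransferSpec:
    """Parameters of a normalized promoter transfer function.

    Parameters
    ----------
    half_activation
        Dimensionless regulator concentration at which the promoter is at
        half of its maximal (or half of its unrepressed) activity. Must be
        positive. Default 1, the nondimensionalized reference scale.
    """

    half_activation: float = 1.0

    def __post_init__(self) -> None:
        if not (self.half_activation > 0):
            raise DomainError(
                f"half_activation must be > 0, got {self.half_activation}"
            )


_DEFAULT_SPEC = TransferSpec()


def _check_concentration(c):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise DomainError("concentration must be finite and >= 0")
    return c


def theta_plus(c, spec: TransferSpec = _DEFAULT_SPEC):
    """Activating Hill response ``c**2 / (K**2 + c**2)``.

    Strictly increasing on c >= 0, equals 0 at c = 0, 1/2 at c = K and
    saturates to 1. Accepts scalars or arrays; scalars come back as floats.
    """
    c = _check_concentration(c)
    r = (c / spec.half_activation) ** 2
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def theta_minus(c, spec: TransferSpec = _DEFAULT_SPEC):
    """Repressing Hill response ``1 / (1 + (c/K)**2)``.

    Strictly decreasing on c >= 0, equals 1 at c = 0 and 1/2 at c = K.
    For a common K, ``theta_plus(c) + theta_minus(c) == 1`` identically.
    """
    c = _check_concentration(c)
    out = 1.0 / (1.0 + (c / spec.half_activation) ** 2)
    return float(out) if out.ndim == 0 else out


def heaviside(v):
    """Unit step with the convention H(0) = 1.

    Returns 0 where ``v < 0`` and 1 where ``v >= 0``.  Note that this differs
    from :func:`numpy.heaviside`'s common half-maximum convention at v = 0.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DomainError("heaviside argument must be finite")
    out = np.where(v < 0, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
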
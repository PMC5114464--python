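"""Closed-form scaling-law and linearised wave-reflection relations.

High-Womersley ("steady") regime: the characteristic impedance of a segment
is ``Z0 = rho * c0 / A0`` and the forward reflection coefficient at a
junction follows from admittance balance.  Recasting both frameworks in the
area ratio ``sigma`` and symmetry ratio ``gamma`` links a branching
exponent ``tau`` to zero forward reflection (well-matchedness):

    sigma = (1 + gamma) * (1 + gamma**(tau/2))**(-2/tau)

Blood density cancels from every reflection ratio; it is carried only for
impedance reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MURRAY_TAU",
    "HUO_KASSAB_TAU",
    "DEFAULT_RHO",
    "ScalingLaw",
    "SegmentImpedance",
    "ReflectionTriple",
    "sigma_of_gamma",
    "forward_reflection_sigma_gamma",
    "reflection_triple",
    "reflection_triple_from_admittances",
    "matched_backward_coefficients",
    "pws_from_beta_star",
    "beta_star_from_pws",
    "scaling_residual",
    "speed_area_exponent",
    "backward_transmission",
    "transit_time",
]

MURRAY_TAU = 3.0
HUO_KASSAB_TAU = 7.0 / 3.0
#: blood density, kg/m^3 (cancels in all reflection ratios)
DEFAULT_RHO = 1060.0


@dataclass(frozen=True)
class ScalingLaw:
    """A branching power law ``(d_d1/d_m)**tau + (d_d2/d_m)**tau = 1``."""

    tau: float
    bounds: tuple = (1.0, 6.0)

    def __post_init__(self):
        lo, hi = self.bounds
        if not (lo < self.tau < hi):
            raise ValueError(f"tau={self.tau} outside bounds ({lo}, {hi})")


@dataclass(frozen=True)
class SegmentImpedance:
    """Reference area, wave speed and density of one segment.

    Units only need to be consistent across the three segments of a
    junction; reflection coefficients are ratio-invariant.
    """

    A0: float
    c0: float
    rho: float = DEFAULT_RHO

    def __post_init__(self):
        if self.A0 <= 0 or self.c0 <= 0 or self.rho <= 0:
            raise ValueError(
                f"A0, c0, rho must be positive, got "
                f"({self.A0}, {self.c0}, {self.rho})"
            )

    @property
    def Z0(self) -> float:
        """Characteristic impedance ``rho * c0 / A0``."""
        return self.rho * self.c0 / self.A0

    @property
    def admittance(self) -> float:
        """``A0 * c0`` — admittance up to the common 1/rho factor."""
        return self.A0 * self.c0


@dataclass(frozen=True)
class ReflectionTriple:
    """Reflection coefficients for waves incident from the mother (Rf),
    the larger daughter (Rd1) and the smaller daughter (Rd2)."""

    Rf: float
    Rd1: float
    Rd2: float


def _check_gamma(gamma) -> np.ndarray:
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError(f"gamma must lie in [0, 1], got {gamma!r}")
    return g


def sigma_of_gamma(gamma, tau):
    """Area ratio of a well-matched junction for symmetry ratio ``gamma``.

    ``sigma = (1 + gamma) * (1 + gamma**(tau/2))**(-2/tau)``.  Accepts
    scalars or arrays; ``gamma = 0`` (no bifurcation) gives ``sigma = 1``,
    and ``tau = 2`` gives ``sigma = 1`` for every ``gamma``.
    """
    g = _check_gamma(gamma)
    if not np.all(np.asarray(tau) > 0):
        raise ValueError(f"tau must be positive, got {tau!r}")
    out = (1.0 + g) * (1.0 + g ** (tau / 2.0)) ** (-2.0 / tau)
    return out if out.ndim else float(out)


def forward_reflection_sigma_gamma(sigma, gamma, tau):
    """Forward reflection coefficient in (sigma, gamma) form.

    ``Rf = (1 - X) / (1 + X)`` with
    ``X = (sigma / (1 + gamma))**(tau/2) * (1 + gamma**(tau/2))``, the
    admittance ratio of daughters to mother when wave speed scales with
    area as ``c ~ A**(tau/2 - 1)``.
    """
    g = _check_gamma(gamma)
    s = np.asarray(sigma, dtype=float)
    if np.any(s <= 0):
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    x = (s / (1.0 + g)) ** (tau / 2.0) * (1.0 + g ** (tau / 2.0))
    out = (1.0 - x) / (1.0 + x)
    return out if out.ndim else float(out)


def reflection_triple_from_admittances(Ym, Yd1, Yd2) -> ReflectionTriple:
    """Reflection triple from the three (rho-scaled) admittances ``A*c``."""
    for name, y in (("mother", Ym), ("d1", Yd1), ("d2", Yd2)):
        if y <= 0:
            raise ValueError(f"{name} admittance must be positive, got {y}")
    total = Ym + Yd1 + Yd2
    return ReflectionTriple(
        Rf=(Ym - Yd1 - Yd2) / total,
        Rd1=(Yd1 - Ym - Yd2) / total,
        Rd2=(Yd2 - Ym - Yd1) / total,
    )


def reflection_triple(
    mother: SegmentImpedance, d1: SegmentImpedance, d2: SegmentImpedance
) -> ReflectionTriple:
    """Forward and backward reflection coefficients of one junction.

    ``Rf = (Y_m - Y_d1 - Y_d2) / (Y_m + Y_d1 + Y_d2)`` with ``Y = A0 * c0``;
    the backward coefficients swap the leading term cyclically.  Constant
    blood density is assumed, so rho drops out.
    """
    return reflection_triple_from_admittances(
        mother.admittance, d1.admittance, d2.admittance
    )


def matched_backward_coefficients(gamma, tau):
    """Backward coefficients of a well-matched junction, in closed form.

    Under ``Rf = 0`` with ``c ~ A**(tau/2 - 1)``:
    ``Rd1 = -gamma**(tau/2) / (1 + gamma**(tau/2))`` and
    ``Rd2 = -1 / (1 + gamma**(tau/2))``.  ``Rd1 >= Rd2`` always, with
    equality only at ``gamma = 1``; at ``gamma -> 0`` the larger daughter
    sees no reflection and the smaller one full reflection.
    """
    g = _check_gamma(gamma)
    gu = g ** (tau / 2.0)
    rd1 = -gu / (1.0 + gu)
    rd2 = -1.0 / (1.0 + gu)
    if np.ndim(rd1) == 0:
        return float(rd1), float(rd2)
    return rd1, rd2


def pws_from_beta_star(beta_star, A0, rho=DEFAULT_RHO):
    """Pulse wave speed from the area-independent stiffness ``beta*``.

    ``c0 = sqrt(beta*/(2 rho)) * A0**(-1/4)`` (SI units: beta* in Pa m,
    A0 in m^2, c0 in m/s).
    """
    b = np.asarray(beta_star, dtype=float)
    a = np.asarray(A0, dtype=float)
    if np.any(b <= 0) or np.any(a <= 0) or rho <= 0:
        raise ValueError("beta_star, A0 and rho must be positive")
    out = np.sqrt(b / (2.0 * rho)) * a ** (-0.25)
    return out if out.ndim else float(out)


def beta_star_from_pws(c0, A0, rho=DEFAULT_RHO):
    """Exact inverse of :func:`pws_from_beta_star`."""
    c = np.asarray(c0, dtype=float)
    a = np.asarray(A0, dtype=float)
    if np.any(c <= 0) or np.any(a <= 0) or rho <= 0:
        raise ValueError("c0, A0 and rho must be positive")
    out = 2.0 * rho * c**2 * np.sqrt(a)
    return out if out.ndim else float(out)


def scaling_residual(d_m, d_d1, d_d2, tau):
    """Deviation from the branching power law:
    ``(d_d1/d_m)**tau + (d_d2/d_m)**tau - 1`` (0 for exact adherence)."""
    dm = np.asarray(d_m, dtype=float)
    if np.any(dm <= 0) or np.any(np.asarray(d_d1) < 0) or np.any(np.asarray(d_d2) < 0):
        raise ValueError("diameters must be positive (daughters may be 0)")
    out = (np.asarray(d_d1) / dm) ** tau + (np.asarray(d_d2) / dm) ** tau - 1.0
    return out if out.ndim else float(out)


def speed_area_exponent(tau: float) -> float:
    """Exponent ``s`` of the speed-area coupling ``c ~ A**s`` implied by a
    scaling law with exponent ``tau`` (from admittance conservation
    ``A_m c_m = A_d1 c_d1 + A_d2 c_d2``): ``s = tau/2 - 1``."""
    return tau / 2.0 - 1.0


def backward_transmission(R: float) -> float:
    """Transmitted amplitude fraction ``1 + R`` for a wave hitting a
    junction with reflection coefficient ``R`` (e.g. R = -0.3 -> 0.7)."""
    return 1.0 + R


def transit_time(length_m: float, pws_m_per_s: float) -> float:
    """Wave-front transit time (s) through a segment of given length (m)."""
    if length_m <= 0 or pws_m_per_s <= 0:
        raise ValueError("length and wave speed must be positive")
    return length_m / pws_m_per_s
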
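"""Pulsatile extension of the junction-matching analysis.

The oscillatory velocity profile enters the characteristic impedance
through the Womersley modulus/phase pair (M0', eps0), defined by

    M0' * exp(i * eps0) = 1 - F10(alpha)
    F10(alpha) = 2 J1(i^{3/2} alpha) / (i^{3/2} alpha J0(i^{3/2} alpha))

evaluated with complex Bessel functions rather than interpolating the
historical tables.  With the convention eps0 in [0, pi/2] and eps0 -> 0 as
alpha -> inf, the complex impedance reduces (in junction ratios) to the
steady rho*c/A form at high alpha.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import jv

from .steady import DEFAULT_RHO, sigma_of_gamma

__all__ = [
    "PulsatileSettings",
    "WomersleyFactors",
    "ConvergenceError",
    "SigmaGammaBand",
    "womersley_alpha",
    "m0_eps",
    "daughter_alphas",
    "pulsatile_impedance",
    "pulsatile_mismatch",
    "pulsatile_forward_reflection",
    "sigma_of_gamma_pulsatile",
    "sigma_gamma_band",
]

#: heartbeat fundamental, 75 min^-1
DEFAULT_HEART_RATE_HZ = 1.25
#: dynamic viscosity of blood, Pa s
DEFAULT_MU = 3.5e-3

# above this alpha the direct Bessel ratio is evaluated asymptotically
# (J0/J1 overflow near alpha ~ 1000; crossover error is O(alpha^-3))
_ASYMPTOTIC_ALPHA = 400.0


@dataclass(frozen=True)
class PulsatileSettings:
    """Fluid/wall constants of the oscillatory regime (SI units)."""

    omega: float = 2.0 * math.pi * DEFAULT_HEART_RATE_HZ
    mu: float = DEFAULT_MU
    rho: float = DEFAULT_RHO
    nu_poisson: float = 0.5

    def __post_init__(self):
        if self.omega <= 0 or self.mu <= 0 or self.rho <= 0:
            raise ValueError("omega, mu and rho must be positive")
        if not (0.0 <= self.nu_poisson <= 0.5):
            raise ValueError("nu_poisson must lie in [0, 0.5]")

    def with_harmonic(self, k: int) -> "PulsatileSettings":
        """Settings of the k-th harmonic (omega scaled by k)."""
        if k < 1:
            raise ValueError("harmonic index must be >= 1")
        return replace(self, omega=self.omega * k)


@dataclass(frozen=True)
class WomersleyFactors:
    """(alpha, M0', eps0) triple entering the complex impedance."""

    alpha: float
    M0p: float
    eps0: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 < self.M0p <= 1.0):
            raise ValueError(f"M0p must lie in (0, 1], got {self.M0p}")
        if not (0.0 <= self.eps0 <= math.pi / 2.0):
            raise ValueError(f"eps0 must lie in [0, pi/2], got {self.eps0}")


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the iterate trace."""

    def __init__(self, message: str, trace: List[float]):
        super().__init__(message)
        self.trace = trace


def womersley_alpha(radius_m: float, settings: PulsatileSettings) -> float:
    """Womersley number ``alpha = r * sqrt(omega * rho / mu)`` (r in m)."""
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    return radius_m * math.sqrt(settings.omega * settings.rho / settings.mu)


def _one_minus_f10(alpha: float) -> complex:
    """``1 - F10(alpha)`` via complex Bessel functions (asymptotic branch
    beyond the overflow range of J0/J1)."""
    if alpha > _ASYMPTOTIC_ALPHA:
        # F10 = 2 J1/(z J0) with J1/J0 -> i + 1/(2z) for large |z|, Im z > 0
        f10 = 2.0 * cmath.exp(-1j * math.pi / 4.0) / alpha + 1j / alpha**2
        return 1.0 - f10
    z = alpha * cmath.exp(3j * math.pi / 4.0)  # i^(3/2) * alpha
    f10 = 2.0 * jv(1, z) / (z * jv(0, z))
    return 1.0 - f10


def m0_eps(alpha: float) -> WomersleyFactors:
    """Womersley modulus/phase factors of the oscillatory profile.

    Small alpha: ``M0' ~ alpha**2 / 8`` and ``eps0 -> pi/2``; large alpha:
    ``M0' -> 1`` and ``eps0 -> 0``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    w = _one_minus_f10(alpha)
    m0p = abs(w)
    eps0 = math.atan2(w.imag, w.real)
    # clip tiny numerical excursions outside [0, pi/2]
    eps0 = min(max(eps0, 0.0), math.pi / 2.0)
    m0p = min(m0p, 1.0)
    return WomersleyFactors(alpha=alpha, M0p=m0p, eps0=eps0)


def daughter_alphas(
    alpha_m: float, sigma: float, gamma: float
) -> Tuple[float, float]:
    """Womersley numbers of the daughters given the mother's.

    ``alpha_d1 = alpha_m * sqrt(sigma / (1 + gamma))`` and
    ``alpha_d2 = alpha_m * sqrt(sigma * gamma / (1 + gamma))`` — i.e.
    proportional to the daughter radii implied by (sigma, gamma).
    """
    if alpha_m <= 0 or sigma <= 0:
        raise ValueError("alpha_m and sigma must be positive")
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    a1 = alpha_m * math.sqrt(sigma / (1.0 + gamma))
    return a1, a1 * math.sqrt(gamma)


def pulsatile_impedance(
    A0: float,
    c0: float,
    rho: float,
    nu_poisson: float,
    factors: WomersleyFactors,
) -> complex:
    """Complex characteristic impedance
    ``Z0 = (rho c0 / A0) * (M0' (1 - nu^2))**(-1/2) * exp(-i eps0 / 2)``.

    As alpha -> inf this tends to ``(rho c0/A0) * (1 - nu^2)**(-1/2)`` with
    zero phase; the (1 - nu^2) factor is common to all segments of a
    junction when nu is uniform and cancels from reflection ratios.
    """
    if A0 <= 0 or c0 <= 0 or rho <= 0:
        raise ValueError("A0, c0 and rho must be positive")
    scale = (factors.M0p * (1.0 - nu_poisson**2)) ** -0.5
    return (rho * c0 / A0) * scale * cmath.exp(-1j * factors.eps0 / 2.0)


def _bracket_sum(
    gamma: float, tau: float, sigma: float, alpha_m: float
) -> complex:
    """The bracketed daughter sum S of the pulsatile mismatch:
    ``S = sqrt(M_d1/M_m) e^{-i(e_d1-e_m)/2}
        + gamma^{tau/2} sqrt(M_d2/M_m) e^{-i(e_d2-e_m)/2}``."""
    fm = m0_eps(alpha_m)
    a1, a2 = daughter_alphas(alpha_m, sigma, gamma)
    f1, f2 = m0_eps(a1), m0_eps(a2)
    t1 = math.sqrt(f1.M0p / fm.M0p) * cmath.exp(-1j * (f1.eps0 - fm.eps0) / 2.0)
    t2 = (
        gamma ** (tau / 2.0)
        * math.sqrt(f2.M0p / fm.M0p)
        * cmath.exp(-1j * (f2.eps0 - fm.eps0) / 2.0)
    )
    return t1 + t2


def pulsatile_mismatch(
    sigma: float,
    gamma: float,
    tau: float,
    alpha_m: float,
    settings: Optional[PulsatileSettings] = None,
) -> complex:
    """Complex mismatch ``D``; the junction is well matched when
    ``Re(D) = 1``.

    ``D = (sigma/(1+gamma))**(tau/2) * S`` with S the bracketed daughter
    sum.  ``settings`` is accepted for interface symmetry; alpha_m already
    encodes the oscillatory state.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (sigma / (1.0 + gamma)) ** (tau / 2.0) * _bracket_sum(
        gamma, tau, sigma, alpha_m
    )


def pulsatile_forward_reflection(
    sigma: float,
    gamma: float,
    tau: float,
    alpha_m: float,
    settings: Optional[PulsatileSettings] = None,
) -> complex:
    """Complex forward reflection coefficient ``Rf = (1 - D) / (1 + D)``."""
    d = pulsatile_mismatch(sigma, gamma, tau, alpha_m, settings)
    return (1.0 - d) / (1.0 + d)


def sigma_of_gamma_pulsatile(
    gamma: float,
    tau: float,
    alpha_m: float,
    settings: Optional[PulsatileSettings] = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Area ratio achieving ``Re(D) = 1`` at finite Womersley number.

    Solves ``sigma = (1+gamma) * Re(S(sigma))**(-2/tau)`` by fixed-point
    iteration started from the steady solution, with 0.5 damping engaged if
    the iterates oscillate.  Deterministic; raises :class:`ConvergenceError`
    with the iterate trace after ``max_iter`` steps.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    if alpha_m <= 0:
        raise ValueError("alpha_m must be positive")
    sigma = float(sigma_of_gamma(gamma, tau))
    trace = [sigma]
    prev_delta = 0.0
    for _ in range(max_iter):
        re_s = _bracket_sum(gamma, tau, sigma, alpha_m).real
        if re_s <= 0:
            raise ConvergenceError(
                f"non-positive Re(S) at sigma={sigma}", trace
            )
        new = (1.0 + gamma) * re_s ** (-2.0 / tau)
        delta = new - sigma
        if abs(delta) < tol:
            return new
        if delta * prev_delta < 0:  # oscillation -> damp
            new = sigma + 0.5 * delta
        prev_delta = delta
        sigma = new
        trace.append(sigma)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations "
        f"(gamma={gamma}, tau={tau}, alpha_m={alpha_m})",
        trace,
    )


@dataclass(frozen=True)
class SigmaGammaBand:
    """Pointwise envelope of the pulsatile sigma-gamma relation over an
    alpha range (the steady curve is the alpha -> inf member)."""

    tau: float
    gamma: np.ndarray
    sigma_min: np.ndarray
    sigma_max: np.ndarray

    def contains(self, gamma, sigma, rtol: float = 1e-9) -> np.ndarray:
        """Membership of (gamma, sigma) points, linear-interpolating the
        envelope in gamma (clipped to the tabulated gamma range)."""
        g = np.clip(np.atleast_1d(np.asarray(gamma, dtype=float)),
                    self.gamma[0], self.gamma[-1])
        s = np.atleast_1d(np.asarray(sigma, dtype=float))
        lo = np.interp(g, self.gamma, self.sigma_min)
        hi = np.interp(g, self.gamma, self.sigma_max)
        return (s >= lo * (1.0 - rtol)) & (s <= hi * (1.0 + rtol))


def sigma_gamma_band(
    tau: float,
    alpha_range: Tuple[float, float] = (0.01, 10.0),
    n_gamma: int = 41,
    n_alpha: int = 17,
    include_steady: bool = True,
) -> SigmaGammaBand:
    """Envelope of sigma(gamma) over a log-spaced alpha grid.

    With ``include_steady`` the alpha -> inf (steady) curve joins the
    envelope, so the band always contains the steady relation; since sigma
    is non-increasing in alpha the lower edge is then the steady curve.
    """
    lo, hi = alpha_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid alpha range {alpha_range!r}")
    gammas = np.linspace(0.01, 1.0, n_gamma)
    alphas = np.geomspace(lo, hi, n_alpha)
    curves = []
    for a in alphas:
        curves.append(
            [sigma_of_gamma_pulsatile(g, tau, a) for g in gammas]
        )
    if include_steady:
        curves.append([float(sigma_of_gamma(g, tau)) for g in gammas])
    arr = np.asarray(curves)
    return SigmaGammaBand(
        tau=tau,
        gamma=gammas,
        sigma_min=arr.min(axis=0),
        sigma_max=arr.max(axis=0),
    )
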
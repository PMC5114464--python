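"""Per-segment wave speed / wall stiffness under competing hypotheses.

Three parametrizations from the literature are supported, plus the literal
"uniform beta*" reading (see note below):

``uniform_pws``
    Constant pulse wave speed everywhere; the stiffness ``beta*`` then
    scales as ``sqrt(A0)`` (decreasing distally).
``uniform_beta_star``
    Constant ``beta* = beta * A0``; ``c0 = sqrt(beta*/(2 rho)) A0**(-1/4)``
    increases distally.  Literally this couples ``c ~ A**(-1/4)``.
``uniform_beta``
    Constant tube-law stiffness ``beta``; ``c0 = sqrt(beta/(2 rho)) A0**(1/4)``
    i.e. ``c ~ A**(+1/4)``, the coupling behind the tau = 2.5 implication.
``olufsen``
    Empirical wall law ``Eh/r0 = k1 exp(k2 r0) + k3`` with the constants in
    cgs as published (g s^-2 cm^-1, cm^-1); converted internally to SI.
    ``beta* = sqrt(pi) Eh / (1 - nu^2)``, then ``c0`` from the tube law.

Note: imposing constant beta* with the tube law as printed yields
``c ~ A**(-1/4)`` (tau = 1.5), whereas the tau = 2.5 attribution follows
from constant beta (``c ~ A**(+1/4)``).  Both are provided; downstream
comparisons default to the tau = 2.5 reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

from .steady import (
    DEFAULT_RHO,
    ReflectionTriple,
    beta_star_from_pws,
    pws_from_beta_star,
    reflection_triple_from_admittances,
)
from .tree_model import VascularTree, extract_bifurcations

__all__ = [
    "HYPOTHESES",
    "OLUFSEN_DEFAULTS",
    "MaterialAssignment",
    "assign_material",
    "tree_reflection_coefficients",
    "olufsen_eh",
]

HYPOTHESES = ("uniform_pws", "uniform_beta_star", "uniform_beta", "olufsen")

#: published wall-law constants, cgs: k1, k3 in g s^-2 cm^-1; k2 in cm^-1
OLUFSEN_DEFAULTS = {"k1": 2.0e7, "k2": -22.53, "k3": 8.65e5}

#: 1 g s^-2 cm^-1 = 0.1 Pa  (used for Eh/r0); Eh itself: 1 g s^-2 = 1e-3 Pa m
_CGS_EH_TO_SI = 1.0e-3

_DEFAULT_PARAMS = {
    "uniform_pws": {"c0": 20.0},  # m/s, within the measured 15-25 m/s range
    "uniform_beta_star": {"beta_star": 800.0},  # Pa m
    "uniform_beta": {"beta": 8.0e8},  # Pa/m
    "olufsen": dict(OLUFSEN_DEFAULTS),
}


@dataclass
class MaterialAssignment:
    """Per-segment wave speed and stiffness under one hypothesis."""

    hypothesis: str
    c0: Dict[str, float]  # m/s, keyed by segment id
    beta_star: Dict[str, float]  # Pa m
    rho: float = DEFAULT_RHO
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        bad = [k for k, v in self.c0.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive wave speed for segments {bad[:3]}")


def olufsen_eh(r0_cm: float, k1: float, k2: float, k3: float) -> float:
    """Wall stiffness-thickness product Eh (cgs, g s^-2) at radius r0 (cm):
    ``Eh = r0 * (k1 * exp(k2 * r0) + k3)``."""
    if r0_cm <= 0:
        raise ValueError("radius must be positive")
    return r0_cm * (k1 * math.exp(k2 * r0_cm) + k3)


def _area_si(radius_mm: float) -> float:
    r = radius_mm * 1e-3
    return math.pi * r * r


def assign_material(
    tree: VascularTree,
    hypothesis: str,
    params: Optional[Dict[str, float]] = None,
    rho: float = DEFAULT_RHO,
    nu_poisson: float = 0.5,
) -> MaterialAssignment:
    """Assign ``c0`` and ``beta*`` to every segment under one hypothesis."""
    if hypothesis not in HYPOTHESES:
        raise ValueError(
            f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}"
        )
    p = dict(_DEFAULT_PARAMS[hypothesis])
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameter(s) {sorted(unknown)} "
                             f"for hypothesis {hypothesis!r}")
        p.update(params)

    c0: Dict[str, float] = {}
    beta_star: Dict[str, float] = {}
    for seg in tree:
        A0 = _area_si(seg.radius)
        if hypothesis == "uniform_pws":
            c = p["c0"]
            bs = beta_star_from_pws(c, A0, rho)
        elif hypothesis == "uniform_beta_star":
            bs = p["beta_star"]
            c = pws_from_beta_star(bs, A0, rho)
        elif hypothesis == "uniform_beta":
            # constant tube-law stiffness: c = sqrt(beta/(2 rho)) A^(1/4)
            c = math.sqrt(p["beta"] / (2.0 * rho)) * A0**0.25
            bs = p["beta"] * A0
        else:  # olufsen
            eh_si = _CGS_EH_TO_SI * olufsen_eh(
                seg.radius * 0.1, p["k1"], p["k2"], p["k3"]
            )
            bs = math.sqrt(math.pi) * eh_si / (1.0 - nu_poisson**2)
            c = pws_from_beta_star(bs, A0, rho)
        c0[seg.id] = c
        beta_star[seg.id] = bs
    return MaterialAssignment(
        hypothesis=hypothesis, c0=c0, beta_star=beta_star, rho=rho, params=p
    )


def tree_reflection_coefficients(
    tree: VascularTree, assignment: MaterialAssignment
) -> Dict[str, ReflectionTriple]:
    """Steady (linearised) reflection triple at every bifurcation,
    keyed by mother segment id.

    Uses admittances ``A * c0`` with the assigned wave speeds; n-furcations
    are excluded (as in the bifurcation extraction).
    """
    records, _ = extract_bifurcations(tree)
    out: Dict[str, ReflectionTriple] = {}
    for rec in records:
        try:
            cm = assignment.c0[rec.mother_id]
            c1 = assignment.c0[rec.d1_id]
            c2 = assignment.c0[rec.d2_id]
        except KeyError as exc:
            raise ValueError(
                f"segment {exc.args[0]!r} has no material assignment"
            ) from exc
        out[rec.mother_id] = reflection_triple_from_admittances(
            rec.A_m * cm, rec.A_d1 * c1, rec.A_d2 * c2
        )
    return out
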
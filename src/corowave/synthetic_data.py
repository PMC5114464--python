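"""Synthetic vascular trees with coronary-like branching statistics.

The generator grows a rooted tree from a single segment.  At every junction
it draws a symmetry ratio ``gamma`` from a radius-conditioned Beta law
(mean rising from ~0.3 proximally to ~0.7 distally, so the asymmetric
fraction falls distally) and sets the area ratio ``sigma`` from a
configured matching law — the steady closed form, or the pulsatile fixed
point with the Womersley number taken from the mother radius.  Daughter
areas follow as ``A_d1 = A_m * sigma / (1 + gamma)``, ``A_d2 = gamma *
A_d1``.  A small fraction of junctions is upgraded to trifurcations (by
splitting the smaller daughter) to exercise the downstream exclusion rule.

Everything is reproducible from the configured seed; trees are grown
largest-radius-first so a segment cap yields a radius-balanced frontier.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .steady import sigma_of_gamma
from .tree_model import VascularTree, VesselSegment
from .womersley import PulsatileSettings, sigma_of_gamma_pulsatile, womersley_alpha

__all__ = [
    "GammaLaw",
    "MatchingLaw",
    "SyntheticConfig",
    "generate_tree",
    "add_radius_noise",
    "generate_matched_cloud",
]

DEFAULT_TERRITORIES = ("LAD", "LCx", "RCA")


@dataclass(frozen=True)
class GammaLaw:
    """Radius-conditioned Beta law for the symmetry ratio.

    The Beta mean interpolates linearly in log(radius) between
    ``mean_proximal`` at the root radius and ``mean_distal`` at the
    terminal radius; ``concentration`` is a + b of the Beta.
    """

    mean_proximal: float = 0.3
    mean_distal: float = 0.7
    concentration: float = 10.0

    def mean_at(self, radius: float, root_radius: float, r_min: float) -> float:
        span = math.log(root_radius) - math.log(r_min)
        t = 0.0 if span <= 0 else (math.log(root_radius) - math.log(radius)) / span
        t = min(max(t, 0.0), 1.0)
        return self.mean_proximal + t * (self.mean_distal - self.mean_proximal)

    def draw(self, rng: np.random.Generator, mean: float) -> float:
        if mean >= 1.0:  # degenerate: perfectly symmetric junctions
            return 1.0
        a = mean * self.concentration
        b = (1.0 - mean) * self.concentration
        g = float(rng.beta(a, b))
        return min(max(g, 1e-6), 1.0)


@dataclass(frozen=True)
class MatchingLaw:
    """How the area ratio is set at each junction.

    ``kind`` is ``"steady"`` (closed form at exponent tau) or
    ``"pulsatile"`` (zero-Re-reflection fixed point, Womersley number from
    the mother radius via ``settings``).  If ``tau_distal`` is given, the
    exponent interpolates linearly in log(radius) between ``tau`` at the
    root and ``tau_distal`` at the terminal radius.
    """

    kind: str = "steady"
    tau: float = 7.0 / 3.0
    tau_distal: Optional[float] = None
    settings: PulsatileSettings = field(default_factory=PulsatileSettings)

    def __post_init__(self):
        if self.kind not in ("steady", "pulsatile"):
            raise ValueError(f"unknown matching law kind {self.kind!r}")

    def tau_at(self, radius: float, root_radius: float, r_min: float) -> float:
        if self.tau_distal is None:
            return self.tau
        span = math.log(root_radius) - math.log(r_min)
        t = 0.0 if span <= 0 else (math.log(root_radius) - math.log(radius)) / span
        t = min(max(t, 0.0), 1.0)
        return self.tau + t * (self.tau_distal - self.tau)

    def sigma_at(self, gamma: float, radius_mm: float,
                 root_radius: float, r_min: float) -> float:
        tau = self.tau_at(radius_mm, root_radius, r_min)
        if self.kind == "steady":
            return float(sigma_of_gamma(gamma, tau))
        alpha_m = womersley_alpha(radius_mm * 1e-3, self.settings)
        return sigma_of_gamma_pulsatile(gamma, tau, alpha_m, self.settings)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration (radii in mm)."""

    root_radius: float = 2.5
    r_min: float = 0.05
    gamma_law: GammaLaw = field(default_factory=GammaLaw)
    matching_law: MatchingLaw = field(default_factory=MatchingLaw)
    length_ratio: float = 10.0
    noise_cv: float = 0.0
    trifurcation_rate: float = 0.04
    n_territories: int = 3
    seed: int = 0
    max_segments: int = 6000

    def __post_init__(self):
        if not (0.0 < self.r_min < self.root_radius):
            raise ValueError("need 0 < r_min < root_radius")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0.0 <= self.trifurcation_rate <= 0.1):
            raise ValueError("trifurcation_rate must lie in [0, 0.1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "gamma_law" in d and isinstance(d["gamma_law"], dict):
            d["gamma_law"] = GammaLaw(**d["gamma_law"])
        if "matching_law" in d and isinstance(d["matching_law"], dict):
            m = dict(d["matching_law"])
            if "settings" in m and isinstance(m["settings"], dict):
                m["settings"] = PulsatileSettings(**m["settings"])
            d["matching_law"] = MatchingLaw(**m)
        return cls(**d)


def _grow(config: SyntheticConfig) -> Tuple[List[VesselSegment], Dict[str, List[str]]]:
    rng = np.random.default_rng(config.seed)
    segments: List[VesselSegment] = []
    by_id: Dict[str, VesselSegment] = {}
    children: Dict[str, List[str]] = {}
    counter = 0

    def new_segment(parent_id: Optional[str], radius: float) -> VesselSegment:
        nonlocal counter
        seg = VesselSegment(
            id=f"v{counter}",
            parent_id=parent_id,
            radius=radius,
            length=config.length_ratio * radius,
        )
        counter += 1
        segments.append(seg)
        by_id[seg.id] = seg
        children[seg.id] = []
        if parent_id is not None:
            children[parent_id].append(seg.id)
        return seg

    root = new_segment(None, config.root_radius)
    # max-heap on radius; tie broken by creation order for determinism
    frontier: List[Tuple[float, int, str]] = [(-root.radius, 0, root.id)]
    while frontier and len(segments) < config.max_segments:
        _, _, seg_id = heapq.heappop(frontier)
        seg = by_id[seg_id]
        if seg.radius < config.r_min:
            continue  # terminal branch
        mean = config.gamma_law.mean_at(
            seg.radius, config.root_radius, config.r_min
        )
        gamma = config.gamma_law.draw(rng, mean)
        sigma = config.matching_law.sigma_at(
            gamma, seg.radius, config.root_radius, config.r_min
        )
        A_m = math.pi * seg.radius**2
        A_d1 = A_m * sigma / (1.0 + gamma)
        A_d2 = gamma * A_d1
        daughters = [A_d1, A_d2]
        if rng.random() < config.trifurcation_rate:
            # upgrade to a trifurcation by splitting the smaller daughter
            daughters = [A_d1, A_d2 / 2.0, A_d2 / 2.0]
        if len(segments) + len(daughters) > config.max_segments:
            break
        for area in daughters:
            child = new_segment(seg.id, math.sqrt(area / math.pi))
            heapq.heappush(
                frontier, (-child.radius, int(child.id[1:]), child.id)
            )
    return segments, children


def _label_territories(
    segments: List[VesselSegment],
    children: Dict[str, List[str]],
    n_territories: int,
) -> None:
    """Round-robin territory labels over the first >= n_territories subtree
    roots (largest subtrees split first); ancestors take the label of their
    largest child so every segment is labelled."""
    if n_territories < 1:
        return
    by_id = {s.id: s for s in segments}
    root_id = next(s.id for s in segments if s.parent_id is None)
    frontier = list(children[root_id])
    if not frontier:
        frontier = [root_id]
    while len(frontier) < n_territories:
        expandable = [f for f in frontier if children[f]]
        if not expandable:
            break
        biggest = max(expandable, key=lambda i: (by_id[i].radius, i))
        frontier.remove(biggest)
        frontier.extend(children[biggest])
    labels = [
        DEFAULT_TERRITORIES[i]
        if i < len(DEFAULT_TERRITORIES)
        else f"T{i + 1}"
        for i in range(n_territories)
    ]
    order = sorted(frontier, key=lambda i: -by_id[i].radius)
    for i, sub_root in enumerate(order):
        label = labels[i % n_territories]
        stack = [sub_root]
        while stack:
            cur = stack.pop()
            by_id[cur].territory = label
            stack.extend(children[cur])

    # propagate upward: unlabeled ancestors inherit their largest child's label
    def fill_up(seg_id: str) -> Optional[str]:
        seg = by_id[seg_id]
        if seg.territory is None and children[seg_id]:
            kid_labels = [fill_up(k) for k in children[seg_id]]
            biggest = max(children[seg_id], key=lambda i: (by_id[i].radius, i))
            seg.territory = by_id[biggest].territory
            del kid_labels
        return seg.territory

    fill_up(root_id)


def _assign_depths(
    segments: List[VesselSegment],
    children: Dict[str, List[str]],
    rng: np.random.Generator,
) -> None:
    """Transmural depth: clipped cumulative Uniform(0, 0.15) increments per
    junction crossed (a label generator, not a mesh solve)."""
    by_id = {s.id: s for s in segments}
    root_id = next(s.id for s in segments if s.parent_id is None)
    by_id[root_id].transmural_depth = 0.0
    stack = [root_id]
    while stack:
        cur = stack.pop()
        depth = by_id[cur].transmural_depth
        is_junction = len(children[cur]) >= 2
        for k in children[cur]:
            inc = float(rng.uniform(0.0, 0.15)) if is_junction else 0.0
            by_id[k].transmural_depth = min(depth + inc, 1.0)
            stack.append(k)


def generate_tree(config: SyntheticConfig) -> VascularTree:
    """Grow a synthetic tree; byte-identical for a fixed config."""
    if config.root_radius < config.r_min:
        raise ValueError("root radius below r_min produces an empty tree")
    segments, children = _grow(config)
    _label_territories(segments, children, config.n_territories)
    # depth labels use a dedicated stream so topology draws stay aligned
    _assign_depths(segments, children, np.random.default_rng(config.seed + 1))
    tree = VascularTree(segments)
    if config.noise_cv > 0:
        tree = add_radius_noise(tree, config.noise_cv, config.seed + 2)
    return tree


def add_radius_noise(tree: VascularTree, cv: float, seed: int) -> VascularTree:
    """Multiply radii by lognormal factors with unit median and the stated
    coefficient of variation; topology and all labels are unchanged."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return tree.copy()
    rng = np.random.default_rng(seed)
    s = math.sqrt(math.log(1.0 + cv * cv))
    out = tree.copy()
    for seg in out:
        seg.radius *= float(rng.lognormal(mean=0.0, sigma=s))
    return out


def generate_matched_cloud(
    exponent_s: float,
    n: int,
    alpha_settings: Optional[Tuple[float, PulsatileSettings]] = None,
) -> np.ndarray:
    """(gamma, sigma) points of junctions with zero forward reflection.

    ``gamma`` is evenly spaced in (0, 1].  For the steady case the area
    ratio at each gamma is found by root-finding the admittance balance
    under ``c ~ A**s`` directly (an independent route from the closed
    form); the implied exponent is ``tau = 2 (1 + s)``.  With
    ``alpha_settings = (alpha_m, settings)`` the pulsatile fixed point is
    used instead.

    Returns an (n, 2) array of columns (gamma, sigma).
    """
    if n < 2:
        raise ValueError("need n >= 2 points")
    from scipy.optimize import brentq

    gammas = np.arange(1, n + 1) / n
    tau = 2.0 * (1.0 + exponent_s)
    out = np.empty((n, 2))
    for i, g in enumerate(gammas):
        if alpha_settings is not None:
            alpha_m, settings = alpha_settings
            sig = sigma_of_gamma_pulsatile(g, tau, alpha_m, settings)
        else:
            e = 1.0 + exponent_s  # admittance Y = A * c ~ A**(1+s)

            def mismatch(sigma: float, g: float = g) -> float:
                a1 = sigma / (1.0 + g)
                a2 = g * a1
                return a1**e + a2**e - 1.0  # Y_d1 + Y_d2 - Y_m (A_m = 1)

            sig = brentq(mismatch, 1e-6, 16.0, xtol=1e-14, rtol=8.9e-16)
        out[i] = (g, sig)
    return out
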
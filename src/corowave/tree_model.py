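"""Rooted vascular tree data model, plain-text I/O, and junction extraction.

A tree is stored as one row per vessel segment with a parent pointer; the
root row has an empty parent field.  Radii and lengths are in millimetres;
cross-sectional areas are computed on demand as ``pi * r**2`` (circular
cross-section).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pandas as pd

__all__ = [
    "VesselSegment",
    "VascularTree",
    "BifurcationRecord",
    "TreeValidationError",
    "load_tree",
    "save_tree",
    "extract_bifurcations",
    "assign_weibel_generations",
    "assign_transmural_layer",
    "transmural_layer",
]

#: canonical required columns of the node table
REQUIRED_COLUMNS = ("id", "parent", "radius_mm", "length_mm")
#: optional columns written/read with dedicated types
OPTIONAL_COLUMNS = ("territory", "transmural_depth", "weibel_generation")


class TreeValidationError(ValueError):
    """Raised when a segment table does not describe a valid rooted tree."""


@dataclass
class VesselSegment:
    """One vessel segment (an edge of the centerline graph).

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a tree.
    parent_id : str or None
        Identifier of the feeding segment; ``None`` marks the root.
    radius : float
        Luminal radius in mm, strictly positive.
    length : float
        Segment length in mm, strictly positive.
    territory : str, optional
        Perfusion territory label (e.g. ``"LAD"``).
    transmural_depth : float, optional
        Normalised wall depth in [0, 1] (0 = epicardium, 1 = endocardium).
    weibel_generation : int, optional
        Number of junctions crossed from the root (0 for the root itself).
    extra : dict
        Unrecognised table columns, preserved verbatim on round-trip.
    """

    id: str
    parent_id: Optional[str]
    radius: float
    length: float
    territory: Optional[str] = None
    transmural_depth: Optional[float] = None
    weibel_generation: Optional[int] = None
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise TreeValidationError("segment with empty id")
        if not (self.radius > 0):
            raise TreeValidationError(
                f"segment {self.id!r}: radius must be > 0, got {self.radius!r}"
            )
        if not (self.length > 0):
            raise TreeValidationError(
                f"segment {self.id!r}: length must be > 0, got {self.length!r}"
            )
        if self.transmural_depth is not None and not (
            0.0 <= self.transmural_depth <= 1.0
        ):
            raise TreeValidationError(
                f"segment {self.id!r}: transmural_depth must lie in [0, 1], "
                f"got {self.transmural_depth!r}"
            )

    @property
    def area(self) -> float:
        """Cross-sectional area in mm^2."""
        return math.pi * self.radius**2


class VascularTree:
    """A validated rooted tree of :class:`VesselSegment`.

    Validation on construction guarantees exactly one root, that every
    parent pointer resolves, and that the graph is connected and acyclic.
    Segment insertion order is preserved (and is the on-disk row order).
    """

    def __init__(self, segments: Iterable[VesselSegment]):
        self._segments: Dict[str, VesselSegment] = {}
        self._children: Dict[str, List[str]] = {}
        roots: List[str] = []
        for seg in segments:
            if seg.id in self._segments:
                raise TreeValidationError(f"duplicate segment id {seg.id!r}")
            self._segments[seg.id] = seg
            self._children.setdefault(seg.id, [])
            if seg.parent_id is None:
                roots.append(seg.id)
        if not self._segments:
            raise TreeValidationError("empty tree")
        if len(roots) == 0:
            raise TreeValidationError("no root segment (every row has a parent)")
        if len(roots) > 1:
            raise TreeValidationError(f"multiple roots: {roots!r}")
        self._root_id = roots[0]
        for seg in self._segments.values():
            if seg.parent_id is not None:
                if seg.parent_id not in self._segments:
                    raise TreeValidationError(
                        f"segment {seg.id!r}: parent {seg.parent_id!r} not in table"
                    )
                self._children[seg.parent_id].append(seg.id)
        # connectivity from the root implies acyclicity for parent-pointer graphs
        seen = set()
        stack = [self._root_id]
        while stack:
            cur = stack.pop()
            seen.add(cur)
            stack.extend(self._children[cur])
        if len(seen) != len(self._segments):
            stranded = sorted(set(self._segments) - seen)
            raise TreeValidationError(
                f"segments unreachable from root (cycle or disconnect), "
                f"e.g. {stranded[0]!r}"
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._segments)

    def __iter__(self) -> Iterator[VesselSegment]:
        return iter(self._segments.values())

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._segments

    # -- accessors ----------------------------------------------------------
    @property
    def root_id(self) -> str:
        return self._root_id

    def segment(self, seg_id: str) -> VesselSegment:
        return self._segments[seg_id]

    def children(self, seg_id: str) -> List[str]:
        return list(self._children[seg_id])

    def copy(self) -> "VascularTree":
        return VascularTree(replace(s, extra=dict(s.extra)) for s in self)


@dataclass
class BifurcationRecord:
    """Geometry of one bifurcation: mother + two daughters, ordered by area.

    ``sigma`` is the area ratio ``(A_d1 + A_d2) / A_m`` and ``gamma`` the
    symmetry ratio ``A_d2 / A_d1`` with ``A_d1 >= A_d2``, so ``gamma`` lies
    in (0, 1].  Equal daughter areas give ``gamma == 1`` exactly, with the
    d1/d2 order broken by id.
    """

    mother_id: str
    d1_id: str
    d2_id: str
    A_m: float
    A_d1: float
    A_d2: float
    sigma: float
    gamma: float
    r_m: float
    territory: Optional[str] = None
    transmural_depth: Optional[float] = None
    weibel_generation: Optional[int] = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_tree(node_table_path, edge_convention: str = "parent") -> VascularTree:
    """Read a comma-separated node table into a validated tree.

    The table must have columns ``id,parent,radius_mm,length_mm``; the root
    row has an empty ``parent``.  ``territory``, ``transmural_depth`` and
    ``weibel_generation`` are recognised optional columns; any other column
    is preserved in ``VesselSegment.extra``.  Lines starting with ``#`` are
    comments.
    """
    if edge_convention != "parent":
        raise ValueError(f"unsupported edge convention {edge_convention!r}")
    df = pd.read_csv(
        node_table_path, dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{node_table_path}: missing required column(s) {missing}"
        )
    extra_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    ]
    segments: List[VesselSegment] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        seg_id = rec["id"]
        try:
            radius = float(rec["radius_mm"])
            length = float(rec["length_mm"])
        except ValueError as exc:
            raise ValueError(
                f"{node_table_path} row {i + 1} (id={seg_id!r}): "
                f"non-numeric radius/length"
            ) from exc
        depth = rec.get("transmural_depth", "")
        gen = rec.get("weibel_generation", "")
        try:
            segments.append(
                VesselSegment(
                    id=seg_id,
                    parent_id=rec["parent"] or None,
                    radius=radius,
                    length=length,
                    territory=rec.get("territory") or None,
                    transmural_depth=float(depth) if depth != "" else None,
                    weibel_generation=int(gen) if gen != "" else None,
                    extra={c: rec[c] for c in extra_cols},
                )
            )
        except TreeValidationError as exc:
            raise TreeValidationError(
                f"{node_table_path} row {i + 1}: {exc}"
            ) from exc
    return VascularTree(segments)


def _fmt(value) -> str:
    """Shortest round-trip decimal representation."""
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def save_tree(tree: VascularTree, path, header_comment: Optional[str] = None) -> None:
    """Write a tree as a node table with deterministic column order.

    Optional columns appear only if at least one segment carries them;
    numeric fields are written with full (shortest round-trip) precision.
    """
    segs = list(tree)
    cols = list(REQUIRED_COLUMNS)
    if any(s.territory is not None for s in segs):
        cols.append("territory")
    if any(s.transmural_depth is not None for s in segs):
        cols.append("transmural_depth")
    if any(s.weibel_generation is not None for s in segs):
        cols.append("weibel_generation")
    extra_keys = sorted({k for s in segs for k in s.extra})
    cols.extend(extra_keys)

    rows = []
    for s in segs:
        row = {
            "id": s.id,
            "parent": s.parent_id or "",
            "radius_mm": _fmt(s.radius),
            "length_mm": _fmt(s.length),
            "territory": s.territory or "",
            "transmural_depth": _fmt(s.transmural_depth),
            "weibel_generation": _fmt(s.weibel_generation),
        }
        for k in extra_keys:
            row[k] = s.extra.get(k, "")
        rows.append([row[c] for c in cols])

    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(cols) + "\n")
        for r in rows:
            fh.write(",".join(r) + "\n")


# ---------------------------------------------------------------------------
# junction extraction
# ---------------------------------------------------------------------------

def extract_bifurcations(
    tree: VascularTree,
) -> Tuple[List[BifurcationRecord], Dict[str, Dict[str, float]]]:
    """Extract one record per two-child junction plus a junction census.

    Junctions with three or more children (n-furcations) are counted in the
    census and excluded from the record list.  The census classifies every
    segment by outdegree: ``terminal`` (0), ``unary`` (1), ``bifurcation``
    (2) and ``n_furcation`` (>= 3); the all-node fractions sum to 1.  The
    ``junction_fractions`` entry normalises over junctions only (outdegree
    >= 2).
    """
    counts = {"terminal": 0, "unary": 0, "bifurcation": 0, "n_furcation": 0}
    records: List[BifurcationRecord] = []
    for seg in tree:
        kids = tree.children(seg.id)
        if len(kids) == 0:
            counts["terminal"] += 1
        elif len(kids) == 1:
            counts["unary"] += 1
        elif len(kids) == 2:
            counts["bifurcation"] += 1
            a, b = (tree.segment(k) for k in kids)
            # larger area first; equal areas ordered by id for determinism
            if b.area > a.area or (b.area == a.area and b.id < a.id):
                a, b = b, a
            A_m = seg.area
            records.append(
                BifurcationRecord(
                    mother_id=seg.id,
                    d1_id=a.id,
                    d2_id=b.id,
                    A_m=A_m,
                    A_d1=a.area,
                    A_d2=b.area,
                    sigma=(a.area + b.area) / A_m,
                    gamma=b.area / a.area,
                    r_m=seg.radius,
                    territory=seg.territory,
                    transmural_depth=seg.transmural_depth,
                    weibel_generation=(
                        seg.weibel_generation + 1
                        if seg.weibel_generation is not None
                        else None
                    ),
                )
            )
        else:
            counts["n_furcation"] += 1
    n = len(tree)
    n_junc = counts["bifurcation"] + counts["n_furcation"]
    census = {
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "junction_fractions": {
            "bifurcation": counts["bifurcation"] / n_junc if n_junc else 0.0,
            "n_furcation": counts["n_furcation"] / n_junc if n_junc else 0.0,
        },
    }
    return records, census


def assign_weibel_generations(tree: VascularTree) -> VascularTree:
    """Fill ``weibel_generation`` in place: junctions crossed from the root.

    The root (and any unary chain before the first junction) carries 0; the
    daughters of the first junction carry 1, increasing by 1 at every
    junction crossed along the root-to-segment path.  A bifurcation record
    extracted afterwards carries its junction number (mother generation + 1),
    so the first bifurcation is numbered 1.
    """
    root = tree.segment(tree.root_id)
    root.weibel_generation = 0
    stack = [tree.root_id]
    while stack:
        cur = stack.pop()
        seg = tree.segment(cur)
        kids = tree.children(cur)
        step = 1 if len(kids) >= 2 else 0
        for k in kids:
            tree.segment(k).weibel_generation = seg.weibel_generation + step
            stack.append(k)
    return tree


def transmural_layer(depth: float, n_layers: int = 3) -> int:
    """Equal-width layer (1-based) of a normalised depth; 1.0 maps to the last."""
    if not (0.0 <= depth <= 1.0):
        raise ValueError(f"transmural depth {depth!r} outside [0, 1]")
    return min(int(depth * n_layers) + 1, n_layers)


def assign_transmural_layer(
    tree: VascularTree, n_layers: int = 3
) -> Dict[str, int]:
    """Bin each segment's transmural depth into ``n_layers`` equal layers.

    Raises if any segment lacks a depth label.
    """
    layers: Dict[str, int] = {}
    for seg in tree:
        if seg.transmural_depth is None:
            raise ValueError(
                f"segment {seg.id!r} has no transmural_depth; "
                "cannot assign a layer"
            )
        layers[seg.id] = transmural_layer(seg.transmural_depth, n_layers)
    return layers
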
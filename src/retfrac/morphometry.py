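"""Vessel morphometry: centerline segments, calibers (CRAE/CRVE/AVR),
and the tortuosity index.

The binary vessel mask is reduced to a 1-px topological skeleton; branch
segments are maximal skeleton paths between nodes of degree != 2 (end
points and junctions).  Local vessel width at a centerline pixel is twice
the Euclidean distance-transform value of the mask there.

Summary calibers follow the revised Parr–Hubbard (Knudtson) procedure: the
six widest arterioles and venules crossing the caliber annulus are combined
pairwise — widest with narrowest, each pair collapsing to
``c * sqrt(w_a^2 + w_b^2)`` with c = 0.88 (arterioles) or 0.95 (venules) —
until a single equivalent remains (CRAE / CRVE); AVR = CRAE / CRVE.

Tortuosity of a branch segment is the ratio of the straight end-point
distance (chord) to the traced centerline length (arc); a straight segment
scores 1 and meanders score lower.  The index is the unweighted mean over
segments lying (by majority of centerline pixels) in the tortuosity
annulus.  The reciprocal arc/chord convention is available via a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .roi import AnnulusROI, OpticDisc

__all__ = [
    "CenterlineSegment",
    "CaliberSummary",
    "TortuosityResult",
    "UndefinedCaliberError",
    "extract_segments",
    "crossing_widths",
    "knudtson_combine",
    "caliber_summary",
    "segment_tortuosity",
    "tortuosity_index",
    "KNUDTSON_ARTERIOLE",
    "KNUDTSON_VENULE",
]

KNUDTSON_ARTERIOLE = 0.88
KNUDTSON_VENULE = 0.95


class UndefinedCaliberError(ValueError):
    """No vessel widths available to form a caliber equivalent."""


@dataclass
class CenterlineSegment:
    """A skeleton branch between two nodes (or an end point and a node).

    ``points`` is the ordered (row, col) path; widths are per-point local
    diameters (2x distance transform).  ``vessel_class`` is assigned from a
    sidecar or phantom truth; the skeleton itself cannot tell arterioles
    from venules.
    """

    points: np.ndarray  # (n, 2) float
    widths_px: np.ndarray | None = None
    vessel_class: str = "unknown"
    segment_id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a segment needs at least two points")
        if self.widths_px is not None:
            self.widths_px = np.asarray(self.widths_px, dtype=float)

    @property
    def arc_length_px(self) -> float:
        steps = np.diff(self.points, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    @property
    def chord_length_px(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    @property
    def mean_width_px(self) -> float:
        if self.widths_px is None or len(self.widths_px) == 0:
            return math.nan
        return float(np.mean(self.widths_px))


@dataclass(frozen=True)
class CaliberSummary:
    crae_um: float
    crve_um: float
    avr: float
    units: str = "um"  # "px" when no physical scale was supplied


@dataclass(frozen=True)
class TortuosityResult:
    per_segment: tuple[float, ...]
    index: float
    convention: str = "chord_over_arc"


# ---------------------------------------------------------------------------
# skeleton graph -> branch segments

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbors_of(skel: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    rows, cols = skel.shape
    out = []
    for dr, dc in _NEIGHBORS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]:
            out.append((rr, cc))
    return out


def extract_segments(mask: np.ndarray) -> list[CenterlineSegment]:
    """Skeletonize the mask and split the skeleton into branch segments.

    Nodes are skeleton pixels of degree != 2; each maximal node-to-node path
    becomes one segment.  Pure cycles (every pixel degree 2) yield a single
    closed segment.  Local width is attached per centerline point.
    """
    m = np.asarray(getattr(mask, "pixels", mask), dtype=bool)
    if not m.any():
        return []
    skel = skeletonize(m)
    edt = ndimage.distance_transform_edt(m)

    coords = np.argwhere(skel)
    degree: dict[tuple[int, int], int] = {}
    for r, c in map(tuple, coords):
        degree[(r, c)] = len(_neighbors_of(skel, r, c))

    nodes = {p for p, d in degree.items() if d != 2}
    visited_edges: set[frozenset] = set()
    segments: list[CenterlineSegment] = []

    def walk(start: tuple[int, int], first: tuple[int, int]) -> list[tuple[int, int]]:
        path = [start, first]
        prev, cur = start, first
        while cur not in nodes:
            nbrs = [p for p in _neighbors_of(skel, *cur) if p != prev]
            # at a degree-2 pixel exactly one neighbor continues the path
            if not nbrs:
                break
            # prefer an unvisited continuation (guards against diagonal shortcuts)
            nxt = nbrs[0]
            if len(nbrs) > 1:
                unseen = [p for p in nbrs if frozenset((cur, p)) not in visited_edges]
                nxt = unseen[0] if unseen else nbrs[0]
            if frozenset((cur, nxt)) in visited_edges:
                break
            visited_edges.add(frozenset((cur, nxt)))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    for node in sorted(nodes):
        for nb in _neighbors_of(skel, *node):
            edge = frozenset((node, nb))
            if edge in visited_edges:
                continue
            visited_edges.add(edge)
            path = walk(node, nb)
            if len(path) < 2:
                continue
            # adjacent junction pixels produce 1-2 step slivers that are
            # skeletonization artifacts, not branches
            if len(path) <= 3 and path[0] in nodes and path[-1] in nodes:
                continue
            pts = np.asarray(path, dtype=float)
            widths = 2.0 * edt[tuple(np.asarray(path, dtype=int).T)]
            segments.append(CenterlineSegment(pts, widths))

    # pure cycles: degree-2 pixels never reached from any node
    touched = {p for e in visited_edges for p in e}
    remaining = sorted(set(map(tuple, coords)) - touched - nodes)
    seen_cycle: set[tuple[int, int]] = set()
    for start in remaining:
        if start in seen_cycle:
            continue
        nbrs = _neighbors_of(skel, *start)
        if not nbrs:
            continue
        path = [start]
        prev, cur = start, nbrs[0]
        while cur != start:
            path.append(cur)
            nxt = [p for p in _neighbors_of(skel, *cur) if p != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        path.append(start)
        seen_cycle.update(path)
        if len(path) >= 3:
            pts = np.asarray(path, dtype=float)
            widths = 2.0 * edt[tuple(np.asarray(path, dtype=int).T)]
            segments.append(CenterlineSegment(pts, widths))

    for i, seg in enumerate(segments):
        seg.segment_id = i
    return segments


# ---------------------------------------------------------------------------
# calibers

def _radial_distances(points: np.ndarray, disc: OpticDisc) -> np.ndarray:
    return np.hypot(points[:, 0] - disc.center_row, points[:, 1] - disc.center_col)


def crossing_widths(
    segments: list[CenterlineSegment],
    roi1: AnnulusROI,
    disc: OpticDisc,
    um_per_px: float | None = None,
) -> tuple[list[float], list[float], str]:
    """Widths of labelled vessels passing completely through the caliber zone.

    A segment qualifies when its centerline reaches both the inner and the
    outer boundary of the annulus; it contributes the mean of its local
    widths at points inside the annulus.  Returns (arteriole widths, venule
    widths, units); units are "px" with a warning when no ``um_per_px`` scale
    is available.
    """
    units = "um"
    scale = um_per_px
    if scale is None:
        warnings.warn("no um_per_px scale supplied; widths reported in pixels",
                      stacklevel=2)
        units, scale = "px", 1.0

    arts: list[float] = []
    vens: list[float] = []
    for seg in segments:
        if seg.vessel_class not in ("arteriole", "venule"):
            continue
        d = _radial_distances(seg.points, disc)
        crosses = (d.min() <= roi1.inner_radius_px) and (d.max() >= roi1.outer_radius_px)
        if not crosses:
            continue
        inside = (d > roi1.inner_radius_px) & (d <= roi1.outer_radius_px)
        if seg.widths_px is None or not inside.any():
            continue
        w = float(np.mean(seg.widths_px[inside])) * scale
        (arts if seg.vessel_class == "arteriole" else vens).append(w)
    return arts, vens, units


def knudtson_combine(widths: list[float], coefficient: float) -> float:
    """Collapse vessel widths to one equivalent by iterative pairing.

    Each round pairs the widest remaining width with the narrowest,
    replacing the pair by ``coefficient * sqrt(wa^2 + wb^2)``; an odd
    leftover carries into the next round.  Intended for six widths (the six
    widest vessels); fewer are accepted with a warning.
    """
    ws = sorted(float(w) for w in widths)
    if not ws:
        raise UndefinedCaliberError("no widths to combine")
    if any(w <= 0 for w in ws):
        raise ValueError("widths must be positive")
    if len(ws) != 6:
        warnings.warn(f"expected 6 widths, combining {len(ws)}", stacklevel=2)
    while len(ws) > 1:
        nxt: list[float] = []
        lo, hi = 0, len(ws) - 1
        while lo < hi:
            nxt.append(coefficient * math.hypot(ws[hi], ws[lo]))
            lo += 1
            hi -= 1
        if lo == hi:  # odd leftover carries forward
            nxt.append(ws[lo])
        ws = sorted(nxt)
    return ws[0]


def caliber_summary(
    art_widths: list[float], ven_widths: list[float], units: str = "um"
) -> CaliberSummary:
    """CRAE / CRVE from the six widest arterioles and venules; AVR = ratio."""
    if not art_widths or not ven_widths:
        raise UndefinedCaliberError("need at least one arteriole and one venule width")
    top_a = sorted(art_widths, reverse=True)[:6]
    top_v = sorted(ven_widths, reverse=True)[:6]
    crae = knudtson_combine(top_a, KNUDTSON_ARTERIOLE)
    crve = knudtson_combine(top_v, KNUDTSON_VENULE)
    return CaliberSummary(crae_um=crae, crve_um=crve, avr=crae / crve, units=units)


# ---------------------------------------------------------------------------
# tortuosity

def _resample_polyline(points: np.ndarray, step_px: float) -> np.ndarray:
    """Subsample a path at roughly ``step_px`` spacing (endpoints kept).

    The polygonal approximation suppresses the staircase bias of raw
    pixel-chain lengths (an 8-connected digital path overstates a smooth
    curve's length by several percent).
    """
    if step_px <= 0 or len(points) < 3:
        return points
    steps = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    if cum[-1] <= step_px:
        return points[[0, -1]]
    targets = np.arange(0.0, cum[-1], step_px)
    idx = np.unique(np.searchsorted(cum, targets))
    if idx[-1] != len(points) - 1:
        idx = np.append(idx, len(points) - 1)
    return points[idx]


def segment_tortuosity(
    segment: CenterlineSegment, convention: str = "chord_over_arc"
) -> float:
    """Tortuosity ratio of one branch segment.

    Default convention is chord/arc (straight = 1, in (0, 1]); the
    ``arc_over_chord`` flag returns the reciprocal.  Closed loops (zero
    chord) are rejected.
    """
    arc = segment.arc_length_px
    chord = segment.chord_length_px
    if arc <= 0:
        raise ValueError("degenerate segment with zero arc length")
    if chord == 0:
        raise ValueError("closed loop has no chord; excluded from tortuosity")
    if convention == "chord_over_arc":
        return min(chord / arc, 1.0)
    if convention == "arc_over_chord":
        return max(arc / chord, 1.0)
    raise ValueError(f"unknown tortuosity convention {convention!r}")


def tortuosity_index(
    segments: list[CenterlineSegment],
    roi2: AnnulusROI | None = None,
    disc: OpticDisc | None = None,
    convention: str = "chord_over_arc",
    min_arc_px: float = 3.0,
    resample_step_px: float = 8.0,
) -> TortuosityResult:
    """Unweighted mean tortuosity over branch segments in the annulus.

    A segment qualifies when the majority of its centerline points lie in
    ``roi2`` (all segments qualify when no ROI is given).  Very short
    segments (< ``min_arc_px``) carry no shape information and are skipped.
    Paths are resampled at ``resample_step_px`` before the ratio so that
    pixel-chain staircase bias does not depress the index.
    """
    ratios: list[float] = []
    for seg in segments:
        if seg.arc_length_px < min_arc_px:
            continue
        if roi2 is not None and disc is not None:
            d = _radial_distances(seg.points, disc)
            inside = (d > roi2.inner_radius_px) & (d <= roi2.outer_radius_px)
            if inside.mean() <= 0.5:
                continue
        if seg.chord_length_px == 0:
            warnings.warn("skipping closed loop in tortuosity index", stacklevel=2)
            continue
        reduced = CenterlineSegment(
            _resample_polyline(seg.points, resample_step_px),
            vessel_class=seg.vessel_class,
            segment_id=seg.segment_id,
        )
        ratios.append(segment_tortuosity(reduced, convention))
    if not ratios:
        warnings.warn("no qualifying segments; tortuosity index undefined",
                      stacklevel=2)
        return TortuosityResult((), math.nan, convention)
    return TortuosityResult(tuple(ratios), float(np.mean(ratios)), convention)
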
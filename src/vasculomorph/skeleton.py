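"""Skeletonization and branch-graph analysis.

Topology-preserving thinning, per-pixel endpoint/junction/slab tagging,
branch-graph construction with junction clustering, branch length /
Euclidean distance / tortuosity measurement, whole-skeleton summaries and
ROI-scoped collateral-vessel analysis.

Conventions (fixed, tested):
  * 8-connectivity for foreground throughout.
  * branch length is the step sum along the pixel path: 1 px per orthogonal
    step, sqrt(2) px per diagonal step, scaled by pixel size.
  * adjacent junction pixels merge into a single junction vertex; a branch
    path includes one vertex pixel at each junction end (and the endpoint
    pixel at endpoint ends), so branch extremes coincide with the graph
    vertices they attach to.
  * tortuosity T = length / Euclidean(V1, V2); undefined for closed cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .imaging_io import BinaryMask, PolygonROI

__all__ = [
    "Skeleton",
    "SkeletonGraph",
    "SkeletonVertex",
    "SkeletonBranch",
    "BranchMeasures",
    "SkeletonSummary",
    "CollateralReport",
    "ENDPOINT",
    "SLAB",
    "JUNCTION",
    "thin_mask",
    "classify_pixels",
    "build_skeleton_graph",
    "measure_branches",
    "summarize_skeleton",
    "analyze_collaterals",
    "path_step_length",
    "analyze_mask",
]

# pixel tags
ENDPOINT, SLAB, JUNCTION = 1, 2, 3

# 8-neighborhood in deterministic order: E, NE, N, NW, W, SW, S, SE  (x right, y down)
_NEIGHBORS = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


@dataclass
class Skeleton:
    """1-px-wide centerline as a boolean grid."""

    data: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("skeleton must be 2D")

    @property
    def pixel_count(self) -> int:
        return int(self.data.sum())


def thin_mask(mask: BinaryMask) -> Skeleton:
    """Topology-preserving thinning to a 1-px centerline (Lee-style)."""
    if not mask.data.any():
        return Skeleton(np.zeros_like(mask.data, dtype=bool), mask.pixel_size_um)
    return Skeleton(_sk_skeletonize(mask.data, method="lee").astype(bool), mask.pixel_size_um)


def _neighbor_counts(data: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    counts = ndimage.convolve(data.astype(np.uint8), kernel, mode="constant", cval=0)
    return np.where(data, counts, 0)


def classify_pixels(sk: Skeleton) -> np.ndarray:
    """Tag each skeleton pixel by its 8-neighbor count.

    fewer than 2 neighbors -> endpoint, exactly 2 -> slab, more -> junction.
    Returns an int grid: 0 background, 1 endpoint, 2 slab, 3 junction.
    """
    counts = _neighbor_counts(sk.data)
    tags = np.zeros(sk.data.shape, dtype=np.uint8)
    tags[sk.data & (counts < 2)] = ENDPOINT
    tags[sk.data & (counts == 2)] = SLAB
    tags[sk.data & (counts > 2)] = JUNCTION
    return tags


@dataclass
class SkeletonVertex:
    vertex_id: int
    kind: str  # 'endpoint' | 'junction'
    pixels: list[tuple[int, int]]  # (y, x)

    @property
    def centroid(self) -> tuple[float, float]:
        arr = np.asarray(self.pixels, dtype=float)
        cy, cx = arr.mean(axis=0)
        return (cx, cy)


@dataclass
class SkeletonBranch:
    branch_id: int
    v1: int | None  # vertex ids; None for isolated cycles
    v2: int | None
    path: np.ndarray  # (n, 2) int, (y, x) along the branch incl. vertex pixels
    is_cycle: bool = False

    @property
    def path_xy(self) -> np.ndarray:
        return self.path[:, ::-1]


@dataclass
class SkeletonGraph:
    vertices: list[SkeletonVertex]
    branches: list[SkeletonBranch]
    pixel_size_um: float = 1.0
    shape: tuple[int, int] = (0, 0)

    def vertex_degree(self, vertex_id: int) -> int:
        deg = 0
        for b in self.branches:
            deg += (b.v1 == vertex_id) + (b.v2 == vertex_id)
        return deg

    @property
    def junction_vertices(self) -> list[SkeletonVertex]:
        return [v for v in self.vertices if v.kind == "junction"]

    @property
    def endpoint_vertices(self) -> list[SkeletonVertex]:
        return [v for v in self.vertices if v.kind == "endpoint"]


def build_skeleton_graph(
    sk: Skeleton,
    tags: np.ndarray | None = None,
    prune_cycles: str = "none",
    merge_junction_px: float = 3.0,
    min_branch_px: float = 0.0,
) -> SkeletonGraph:
    """Cluster junction pixels into vertices and walk slab chains into branches.

    Cycles are retained (``prune_cycles='none'``, the only supported mode);
    isolated closed loops become single self-edges with no vertices.

    Thinning can split one anatomical junction into two clusters joined by a
    branch of a couple of pixels; junction vertices connected by a branch of
    step length <= ``merge_junction_px`` are therefore consolidated into one
    vertex (set to 0 to disable). ``min_branch_px`` > 0 additionally prunes
    terminal spur branches shorter than that length (off by default).
    """
    if prune_cycles != "none":
        raise NotImplementedError("only prune_cycles='none' is supported")
    if tags is None:
        tags = classify_pixels(sk)
    data = sk.data
    h, w = data.shape

    # vertices: each endpoint pixel alone; 8-connected junction clusters merged
    vertex_of: dict[tuple[int, int], int] = {}
    vertices: list[SkeletonVertex] = []
    ey, ex = np.nonzero(tags == ENDPOINT)
    for y, x in zip(ey.tolist(), ex.tolist()):
        vid = len(vertices)
        vertices.append(SkeletonVertex(vid, "endpoint", [(y, x)]))
        vertex_of[(y, x)] = vid
    jlab, njunc = ndimage.label(tags == JUNCTION, structure=np.ones((3, 3)))
    for lab in range(1, njunc + 1):
        jy, jx = np.nonzero(jlab == lab)
        vid = len(vertices)
        pix = list(zip(jy.tolist(), jx.tolist()))
        vertices.append(SkeletonVertex(vid, "junction", pix))
        for p in pix:
            vertex_of[p] = vid

    def neighbors(y: int, x: int):
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and data[ny, nx]:
                yield ny, nx

    branches: list[SkeletonBranch] = []
    visited_slab: set[tuple[int, int]] = set()
    seen_direct: set[frozenset] = set()

    # walk slab chains out of every vertex pixel
    for v in vertices:
        for p in v.pixels:
            for q in neighbors(*p):
                tq = tags[q]
                if tq == SLAB and q not in visited_slab:
                    path = [p, q]
                    visited_slab.add(q)
                    prev, cur = p, q
                    while True:
                        nxts = [n for n in neighbors(*cur) if n != prev]
                        if not nxts:  # dead-ends only if tagging degenerate
                            end_vid = None
                            break
                        nxt = nxts[0]
                        if tags[nxt] == SLAB:
                            if nxt in visited_slab:  # closed back onto the chain
                                end_vid = None
                                break
                            visited_slab.add(nxt)
                            path.append(nxt)
                            prev, cur = cur, nxt
                        else:
                            path.append(nxt)
                            end_vid = vertex_of[nxt]
                            break
                    branches.append(
                        SkeletonBranch(
                            len(branches), v.vertex_id, end_vid, np.asarray(path, dtype=int)
                        )
                    )
                elif tq in (ENDPOINT, JUNCTION):
                    ov = vertex_of[q]
                    if ov != v.vertex_id:
                        key = frozenset((p, q))
                        if key not in seen_direct:
                            seen_direct.add(key)
                            branches.append(
                                SkeletonBranch(
                                    len(branches),
                                    v.vertex_id,
                                    ov,
                                    np.asarray([p, q], dtype=int),
                                )
                            )

    # isolated closed loops: slab pixels never reached from any vertex
    sy, sx = np.nonzero(tags == SLAB)
    for y, x in zip(sy.tolist(), sx.tolist()):
        start = (y, x)
        if start in visited_slab:
            continue
        path = [start]
        visited_slab.add(start)
        prev, cur = None, start
        while True:
            nxts = [n for n in neighbors(*cur) if n != prev]
            nxt = nxts[0]
            if nxt == start:
                path.append(start)  # close the loop
                break
            visited_slab.add(nxt)
            path.append(nxt)
            prev, cur = cur, nxt
        branches.append(
            SkeletonBranch(len(branches), None, None, np.asarray(path, dtype=int), is_cycle=True)
        )

    if merge_junction_px > 0:
        vertices, branches = _merge_junction_fragments(vertices, branches, merge_junction_px)
    if min_branch_px > 0:
        vertices, branches = _prune_spurs(vertices, branches, min_branch_px)
    for i, b in enumerate(branches):
        b.branch_id = i
    return SkeletonGraph(vertices, branches, sk.pixel_size_um, data.shape)


def _merge_junction_fragments(
    vertices: list[SkeletonVertex], branches: list[SkeletonBranch], merge_px: float
) -> tuple[list[SkeletonVertex], list[SkeletonBranch]]:
    """Contract short junction-to-junction branches into a single vertex."""
    by_id = {v.vertex_id: v for v in vertices}
    changed = True
    while changed:
        changed = False
        for b in branches:
            if b.v1 is None or b.v2 is None:
                continue
            if b.v1 == b.v2:
                # residual micro-loop hugging a junction (thinning artifact)
                if by_id[b.v1].kind == "junction" and path_step_length(b.path) <= 2 * merge_px:
                    v = by_id[b.v1]
                    v.pixels = v.pixels + [tuple(p) for p in b.path[1:-1] if tuple(p) not in v.pixels]
                    branches = [x for x in branches if x is not b]
                    changed = True
                    break
                continue
            v1, v2 = by_id[b.v1], by_id[b.v2]
            if v1.kind != "junction" or v2.kind != "junction":
                continue
            if path_step_length(b.path) > merge_px:
                continue
            # absorb v2 and the connecting pixels into v1
            interior = [tuple(p) for p in b.path[1:-1]]
            v1.pixels = v1.pixels + v2.pixels + [p for p in interior if p not in v1.pixels]
            for other in branches:
                if other.v1 == v2.vertex_id:
                    other.v1 = v1.vertex_id
                if other.v2 == v2.vertex_id:
                    other.v2 = v1.vertex_id
            del by_id[v2.vertex_id]
            vertices = [v for v in vertices if v.vertex_id != v2.vertex_id]
            branches = [x for x in branches if x is not b]
            changed = True
            break
    return vertices, branches


def _prune_spurs(
    vertices: list[SkeletonVertex], branches: list[SkeletonBranch], min_px: float
) -> tuple[list[SkeletonVertex], list[SkeletonBranch]]:
    """Drop terminal branches shorter than ``min_px`` (spur suppression)."""
    by_id = {v.vertex_id: v for v in vertices}
    keep: list[SkeletonBranch] = []
    dropped_endpoints: set[int] = set()
    for b in branches:
        kinds = {by_id[v].kind for v in (b.v1, b.v2) if v is not None}
        is_spur = (
            not b.is_cycle
            and "endpoint" in kinds
            and "junction" in kinds
            and path_step_length(b.path) < min_px
        )
        if is_spur:
            for v in (b.v1, b.v2):
                if by_id[v].kind == "endpoint":
                    dropped_endpoints.add(v)
        else:
            keep.append(b)
    used = {v for b in keep for v in (b.v1, b.v2) if v is not None}
    vertices = [v for v in vertices if v.vertex_id in used or (v.kind == "endpoint" and v.vertex_id not in dropped_endpoints)]
    return vertices, keep


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def path_step_length(path: np.ndarray) -> float:
    """Step-sum length in pixels: 1 per orthogonal step, sqrt(2) per diagonal."""
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(np.asarray(path, dtype=float), axis=0))
    return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())


@dataclass
class BranchMeasures:
    branch_id: int
    length_um: float
    euclidean_um: float
    tortuosity: float  # nan when undefined (zero chord / cycles)
    v1_xy: tuple[int, int]
    v2_xy: tuple[int, int]
    is_cycle: bool = False

    @property
    def tortuosity_defined(self) -> bool:
        return np.isfinite(self.tortuosity)


def measure_branches(g: SkeletonGraph) -> list[BranchMeasures]:
    """Step-sum length, V1-V2 Euclidean distance and tortuosity per branch."""
    out = []
    px = g.pixel_size_um
    for b in g.branches:
        length = path_step_length(b.path) * px
        (y1, x1), (y2, x2) = b.path[0], b.path[-1]
        euclid = float(np.hypot(x2 - x1, y2 - y1)) * px
        tort = length / euclid if euclid > 0 else float("nan")
        out.append(
            BranchMeasures(b.branch_id, length, euclid, tort, (int(x1), int(y1)), (int(x2), int(y2)), b.is_cycle)
        )
    return out


@dataclass
class SkeletonSummary:
    branch_count: int = 0
    junction_count: int = 0
    endpoint_count: int = 0
    slab_count: int = 0
    triple_point_count: int = 0
    quadruple_point_count: int = 0
    avg_branch_length_um: float = 0.0
    max_branch_length_um: float = 0.0
    total_branch_length_um: float = 0.0
    avg_tortuosity: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_skeleton(g: SkeletonGraph, measures: list[BranchMeasures] | None = None) -> SkeletonSummary:
    if measures is None:
        measures = measure_branches(g)
    slab_count = sum(len(b.path) for b in g.branches)  # recomputed below from tags
    # slab pixels = path interiors; count from vertex bookkeeping instead
    vertex_pix = sum(len(v.pixels) for v in g.vertices)
    all_pix = set()
    for b in g.branches:
        for p in b.path:
            all_pix.add((int(p[0]), int(p[1])))
    for v in g.vertices:
        all_pix.update(v.pixels)
    slab_count = len(all_pix) - vertex_pix

    lengths = [m.length_um for m in measures]
    torts = [m.tortuosity for m in measures if np.isfinite(m.tortuosity)]
    junctions = g.junction_vertices
    s = SkeletonSummary(
        branch_count=len(g.branches),
        junction_count=len(junctions),
        endpoint_count=len(g.endpoint_vertices),
        slab_count=slab_count,
        triple_point_count=sum(1 for v in junctions if g.vertex_degree(v.vertex_id) == 3),
        quadruple_point_count=sum(1 for v in junctions if g.vertex_degree(v.vertex_id) == 4),
        avg_branch_length_um=float(np.mean(lengths)) if lengths else 0.0,
        max_branch_length_um=float(np.max(lengths)) if lengths else 0.0,
        total_branch_length_um=float(np.sum(lengths)) if lengths else 0.0,
        avg_tortuosity=float(np.mean(torts)) if torts else float("nan"),
    )
    return s


@dataclass
class CollateralReport:
    count: int
    branch_ids: list[int]
    lengths_um: list[float]
    mean_length_um: float
    mean_tortuosity: float
    length_histogram: tuple[np.ndarray, np.ndarray] = field(default=None)  # (counts, edges)

    def to_dict(self) -> dict:
        counts, edges = self.length_histogram
        return {
            "count": self.count,
            "branch_ids": self.branch_ids,
            "lengths_um": self.lengths_um,
            "mean_length_um": self.mean_length_um,
            "mean_tortuosity": self.mean_tortuosity,
            "length_histogram_counts": counts.tolist(),
            "length_histogram_edges": edges.tolist(),
        }


def analyze_collaterals(
    g: SkeletonGraph,
    measures: list[BranchMeasures],
    anastomosis_roi: PolygonROI,
    inside_fraction: float = 0.5,
    histogram_bins: int = 10,
) -> CollateralReport:
    """Branches lying mostly inside the anastomosis ROI.

    A branch counts as a collateral when at least ``inside_fraction`` of its
    path pixels fall inside the polygon. Reports per-branch lengths, their
    mean, a length histogram and the mean (defined) tortuosity.
    """
    by_id = {m.branch_id: m for m in measures}
    ids, lengths, torts = [], [], []
    for b in g.branches:
        xs = b.path[:, 1].astype(float)
        ys = b.path[:, 0].astype(float)
        frac = float(np.mean(anastomosis_roi.contains(xs, ys)))
        if frac >= inside_fraction:
            m = by_id[b.branch_id]
            ids.append(b.branch_id)
            lengths.append(m.length_um)
            if np.isfinite(m.tortuosity):
                torts.append(m.tortuosity)
    if lengths:
        counts, edges = np.histogram(lengths, bins=histogram_bins)
    else:
        counts, edges = np.zeros(histogram_bins, dtype=int), np.linspace(0, 1, histogram_bins + 1)
    return CollateralReport(
        count=len(ids),
        branch_ids=ids,
        lengths_um=lengths,
        mean_length_um=float(np.mean(lengths)) if lengths else 0.0,
        mean_tortuosity=float(np.mean(torts)) if torts else float("nan"),
        length_histogram=(counts, edges),
    )


def analyze_mask(
    mask: BinaryMask, merge_junction_px: float = 3.0, min_branch_px: float = 0.0
) -> tuple[Skeleton, SkeletonGraph, list[BranchMeasures], SkeletonSummary]:
    """Convenience: thin -> classify -> graph -> measure -> summarize."""
    sk = thin_mask(mask)
    g = build_skeleton_graph(sk, merge_junction_px=merge_junction_px, min_branch_px=min_branch_px)
    measures = measure_branches(g)
    return sk, g, measures, summarize_skeleton(g, measures)
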
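"""Semi-automated centerline tracing (live-wire style).

A ridge/intensity blend produces a per-pixel traversal cost; segments are
traced as minimum-cost 8-connected paths between anchor points (Dijkstra,
diagonal steps weighted by sqrt(2)), then smoothed, subsampled and
re-rasterized. Anchor clicks can be snapped to the lowest-cost pixel in a
small window. Interactive clicking is replaced by ordered seed-point lists
per branch for batch reproducibility.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import line as _bresenham
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.morphology import disk

from .imaging_io import BinaryMask, RasterImage

__all__ = [
    "TracingParams",
    "Tracing",
    "compute_cost_image",
    "trace_segment",
    "trace_branches",
    "snap_point",
    "smooth_subsample",
    "refine_tracing",
    "rasterize_tracing",
    "path_cost",
]

COST_FLOOR = 1e-4

# deterministic neighbor order: E, NE, N, NW, W, SW, S, SE as (dx, dy); y down
_NEIGHBOR_STEPS = (
    (1, 0, 1.0),
    (1, -1, np.sqrt(2.0)),
    (0, -1, 1.0),
    (-1, -1, np.sqrt(2.0)),
    (-1, 0, 1.0),
    (-1, 1, np.sqrt(2.0)),
    (0, 1, 1.0),
    (1, 1, np.sqrt(2.0)),
)


@dataclass
class TracingParams:
    """Tracing configuration (defaults match NeuronJ-style settings for
    bright vessels: Hessian scale 2, cost weight 0.7, 9x9 snap window)."""

    appearance: str = "bright"
    hessian_scale: float = 2.0
    cost_weight: float = 0.7  # gamma: weight of the ridge term vs intensity
    snap_window: int = 9
    search_window: int = 2500
    smoothing_range: int = 5
    subsampling_factor: int = 5
    line_width: int = 3

    def __post_init__(self) -> None:
        if self.appearance not in ("bright", "dark"):
            raise ValueError("appearance must be 'bright' or 'dark'")
        if not (0.0 <= self.cost_weight <= 1.0):
            raise ValueError("cost_weight must lie in [0, 1]")
        if self.snap_window % 2 != 1:
            raise ValueError("snap_window must be odd")
        if self.subsampling_factor < 1:
            raise ValueError("subsampling_factor must be >= 1")
        if self.line_width < 1:
            raise ValueError("line_width must be >= 1")


@dataclass
class Tracing:
    """Ordered 8-connected pixel paths, one per traced branch."""

    segments: dict[str, np.ndarray]  # branch id -> (n, 2) int array of (x, y)
    source: str = ""
    params: TracingParams = field(default_factory=TracingParams)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source": self.source,
            "params": asdict(self.params),
            "segments": {k: v.tolist() for k, v in self.segments.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Tracing":
        payload = json.loads(Path(path).read_text())
        return cls(
            segments={k: np.asarray(v, dtype=int) for k, v in payload["segments"].items()},
            source=payload.get("source", ""),
            params=TracingParams(**payload.get("params", {})),
        )


def compute_cost_image(img: RasterImage, params: TracingParams | None = None) -> np.ndarray:
    """Per-pixel traversal cost in (0, 1].

    cost = gamma * (1 - ridge) + (1 - gamma) * (1 - intensity), where ridge is
    the rescaled magnitude of the dominant negative Hessian eigenvalue at the
    smoothing scale (bright vessels curve downward across their axis) and
    intensity is the min-max normalized image ('dark' appearance inverts it).
    A small floor keeps every cost strictly positive.
    """
    if params is None:
        params = TracingParams()
    gamma = params.cost_weight
    vals = img.values.astype(np.float64)
    lo, hi = vals.min(), vals.max()
    inten = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
    if params.appearance == "dark":
        inten = 1.0 - inten

    H = hessian_matrix(
        vals, sigma=params.hessian_scale, mode="nearest", order="rc", use_gaussian_derivatives=False
    )
    ev_hi, ev_lo = hessian_matrix_eigvals(H)  # sorted descending
    raw = np.maximum(-(ev_lo if params.appearance == "bright" else -ev_hi), 0.0)
    mx = raw.max()
    ridge = raw / mx if mx > 0 else np.zeros_like(raw)

    cost = gamma * (1.0 - ridge) + (1.0 - gamma) * (1.0 - inten)
    return np.clip(cost, COST_FLOOR, 1.0)


def path_cost(cost: np.ndarray, path: np.ndarray) -> float:
    """Cumulative path cost: sum over steps of mean(node costs) * step length.

    Symmetric in path direction, so trace(a->b) and trace(b->a) cost the same.
    """
    path = np.asarray(path, dtype=int)
    total = 0.0
    for (x0, y0), (x1, y1) in zip(path[:-1], path[1:]):
        steplen = np.sqrt(2.0) if (abs(x1 - x0) + abs(y1 - y0)) == 2 else 1.0
        total += 0.5 * (cost[y0, x0] + cost[y1, x1]) * steplen
    return float(total)


def _search_bounds(cost_shape, seed, target, window: int):
    h, w = cost_shape
    cx = 0.5 * (seed[0] + target[0])
    cy = 0.5 * (seed[1] + target[1])
    half = window / 2.0
    x0 = max(int(np.floor(cx - half)), 0)
    x1 = min(int(np.ceil(cx + half)) + 1, w)
    y0 = max(int(np.floor(cy - half)), 0)
    y1 = min(int(np.ceil(cy + half)) + 1, h)
    return x0, x1, y0, y1


def trace_segment(
    cost: np.ndarray,
    seed: tuple[int, int],
    target: tuple[int, int],
    params: TracingParams | None = None,
) -> np.ndarray:
    """Minimum-cumulative-cost 8-connected path from seed to target (x, y).

    Dijkstra over the pixel grid restricted to the search window centered
    between the endpoints; edge weight = mean of the two node costs times the
    step length (sqrt(2) for diagonals). Ties break by the fixed neighbor
    order E, NE, N, NW, W, SW, S, SE, making paths bit-reproducible.
    """
    if params is None:
        params = TracingParams()
    h, w = cost.shape
    for name, (x, y) in (("seed", seed), ("target", target)):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"{name} {x, y} lies outside the image")
    x0, x1, y0, y1 = _search_bounds(cost.shape, seed, target, params.search_window)
    for name, (x, y) in (("seed", seed), ("target", target)):
        if not (x0 <= x < x1 and y0 <= y < y1):
            raise ValueError(f"{name} lies outside the search window")

    sub = cost[y0:y1, x0:x1]
    sh, sw = sub.shape
    start = (seed[1] - y0) * sw + (seed[0] - x0)
    goal = (target[1] - y0) * sw + (target[0] - x0)

    dist = np.full(sh * sw, np.inf)
    prev = np.full(sh * sw, -1, dtype=np.int64)
    dist[start] = 0.0
    flat = sub.ravel()
    counter = 0
    heap = [(0.0, counter, start)]
    done = np.zeros(sh * sw, dtype=bool)
    while heap:
        d, _, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == goal:
            break
        uy, ux = divmod(u, sw)
        cu = flat[u]
        for dx, dy, steplen in _NEIGHBOR_STEPS:
            vx, vy = ux + dx, uy + dy
            if not (0 <= vx < sw and 0 <= vy < sh):
                continue
            v = vy * sw + vx
            if done[v]:
                continue
            nd = d + 0.5 * (cu + flat[v]) * steplen
            if nd < dist[v]:
                dist[v] = nd
                prev[v] = u
                counter += 1
                heapq.heappush(heap, (nd, counter, v))
    if not np.isfinite(dist[goal]):
        raise RuntimeError("no path found (disconnected search window?)")

    nodes = []
    u = goal
    while u != -1:
        nodes.append(u)
        u = prev[u] if u != start else -1
    nodes.reverse()
    ys, xs = np.divmod(np.asarray(nodes), sw)
    return np.column_stack([xs + x0, ys + y0]).astype(int)


def snap_point(
    cost: np.ndarray, click: tuple[int, int], params: TracingParams | None = None
) -> tuple[int, int]:
    """Move a click to the lowest-cost pixel in the snap window around it.

    The click itself wins ties (so uniform cost returns the click unchanged);
    other ties resolve to the first minimum in row-major window order.
    """
    if params is None:
        params = TracingParams()
    h, w = cost.shape
    half = params.snap_window // 2
    x, y = click
    x0, x1 = max(x - half, 0), min(x + half + 1, w)
    y0, y1 = max(y - half, 0), min(y + half + 1, h)
    win = cost[y0:y1, x0:x1]
    m = win.min()
    if cost[y, x] <= m:
        return (x, y)
    iy, ix = np.unravel_index(int(np.argmin(win)), win.shape)
    return (x0 + int(ix), y0 + int(iy))


def smooth_subsample(path: np.ndarray, params: TracingParams | None = None) -> np.ndarray:
    """Moving-average smoothing then vertex subsampling; returns control vertices.

    Interior vertices are averaged over +-smoothing_range neighbors (window
    clipped at the ends, endpoints pinned); every ``subsampling_factor``-th
    vertex is kept and the final endpoint is always retained.
    """
    if params is None:
        params = TracingParams()
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValueError("path must contain at least 2 vertices")
    n = len(path)
    r = params.smoothing_range
    smoothed = path.copy()
    for i in range(1, n - 1):
        lo, hi = max(0, i - r), min(n, i + r + 1)
        smoothed[i] = path[lo:hi].mean(axis=0)
    keep = list(range(0, n, params.subsampling_factor))
    if keep[-1] != n - 1:
        keep.append(n - 1)
    return smoothed[keep]


def refine_tracing(path: np.ndarray, params: TracingParams | None = None) -> np.ndarray:
    """Smooth, subsample and re-rasterize a traced path to 8-connected pixels."""
    return _rasterize_polyline(smooth_subsample(path, params))


def _rasterize_polyline(control: np.ndarray) -> np.ndarray:
    pts: list[tuple[int, int]] = []
    ctrl = np.round(control).astype(int)
    for (x0, y0), (x1, y1) in zip(ctrl[:-1], ctrl[1:]):
        rr, cc = _bresenham(y0, x0, y1, x1)
        seg = list(zip(cc.tolist(), rr.tolist()))
        if pts and seg and pts[-1] == seg[0]:
            seg = seg[1:]
        pts.extend(seg)
    # drop immediate revisits that rounding can create
    dedup = [pts[0]]
    for p in pts[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return np.asarray(dedup, dtype=int)


def rasterize_tracing(
    tracing: Tracing, shape: tuple[int, int], pixel_size_um: float = 1.0
) -> BinaryMask:
    """Paint each traced path as a stroke of ``line_width`` pixels.

    Width-1 strokes are exactly the path pixels; wider strokes dilate the
    path with a radius-(width-1)/2 disk, giving e.g. a 3-px-tall band for a
    horizontal path at width 3.
    """
    if not tracing.segments:
        raise ValueError("empty tracing")
    canvas = np.zeros(shape, dtype=bool)
    for seg in tracing.segments.values():
        seg = np.asarray(seg, dtype=int)
        canvas[seg[:, 1], seg[:, 0]] = True
    width = tracing.params.line_width
    if width > 1:
        from scipy import ndimage

        canvas = ndimage.binary_dilation(canvas, structure=disk((width - 1) // 2))
    return BinaryMask(canvas, pixel_size_um)


def trace_branches(
    img: RasterImage,
    seeds: dict[str, list[tuple[int, int]]],
    params: TracingParams | None = None,
    snap: bool = True,
    refine: bool = True,
    source: str = "",
) -> Tracing:
    """Trace each branch through its ordered anchor points.

    For every branch the anchors are (optionally) snapped, consecutive pairs
    are traced with :func:`trace_segment` and concatenated, and the result is
    (optionally) smoothed/subsampled with :func:`refine_tracing`.
    """
    if params is None:
        params = TracingParams()
    cost = compute_cost_image(img, params)
    segments: dict[str, np.ndarray] = {}
    for branch_id, anchors in seeds.items():
        anchors = [tuple(map(int, a)) for a in anchors]
        if len(anchors) < 2:
            raise ValueError(f"branch {branch_id!r} needs >= 2 anchor points")
        if snap:
            anchors = [snap_point(cost, a, params) for a in anchors]
        full: list[np.ndarray] = []
        for a, b in zip(anchors[:-1], anchors[1:]):
            seg = trace_segment(cost, a, b, params)
            if full:
                seg = seg[1:]
            full.append(seg)
        path = np.vstack(full)
        if refine:
            path = refine_tracing(path, params)
        segments[str(branch_id)] = path
    return Tracing(segments=segments, source=source, params=params)
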
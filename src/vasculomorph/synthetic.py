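"""Synthetic vascular images with exact analytic ground truth.

Generators for bifurcating vessel trees, grid-like anastomotic networks and
classic fractal fixtures, rendered as anti-aliased bright strokes on a dark
(optionally noisy) background. Every generator returns the ground truth
needed to score the downstream pipeline: branch polylines with labels, true
branch/junction/endpoint counts, per-branch polyline and chord lengths
(hence true tortuosity) and the exact stroke mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import BinaryMask, RasterImage

__all__ = [
    "TreeSpec",
    "GroundTruthBranch",
    "GroundTruth",
    "generate_tree",
    "generate_grid",
    "generate_fractal_fixture",
    "add_imaging_noise",
    "render_polylines",
    "random_branch_path",
]


@dataclass
class TreeSpec:
    """Parameters of a recursive bifurcating vessel tree.

    The root grows upward from the bottom of the frame; at each level the
    branch splits in two, child length shrinks by ``length_decay`` and the
    angular spread between siblings (``bifurcation_angle_deg``, optionally
    jittered) shrinks by ``angle_decay`` so deep trees stay non-overlapping.
    """

    depth: int = 3
    root_length_px: float = 260.0
    length_decay: float = 0.85
    bifurcation_angle_deg: float = 90.0
    angle_jitter_deg: float = 0.0
    angle_decay: float = 0.75
    stroke_width_px: float = 3.0
    curvature_amplitude_px: float = 0.0
    curvature_periods: float = 1.0
    noise_sigma: float = 0.0
    background_level: float = 0.0
    seed: int = 0
    image_shape: tuple[int, int] | None = None  # (height, width); auto-fit if None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.stroke_width_px < 1:
            raise ValueError("stroke_width_px must be >= 1")
        if self.root_length_px <= 0 or self.length_decay <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class GroundTruthBranch:
    branch_id: int
    label: str  # 'trunk' | 'branch' | 'collateral'
    polyline: np.ndarray  # (n, 2) float, (x, y)
    depth: int = 0

    @property
    def length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.polyline, axis=0).T)))

    @property
    def chord_px(self) -> float:
        return float(np.hypot(*(self.polyline[-1] - self.polyline[0])))

    @property
    def step_length_px(self) -> float:
        """Step-sum length of the digitized polyline (1 orthogonal, sqrt(2)
        diagonal) — the expected value of a pixel-chain measurement of this
        branch, which for oblique lines exceeds the Euclidean length by up
        to ~8% (the known digital-line bias of the step-sum convention).
        Computed as the chamfer metric integrated along the polyline."""
        dif = np.abs(np.diff(self.polyline, axis=0))
        steps = np.maximum(dif[:, 0], dif[:, 1]) + (np.sqrt(2.0) - 1.0) * np.minimum(
            dif[:, 0], dif[:, 1]
        )
        return float(steps.sum())

    @property
    def tortuosity(self) -> float:
        c = self.chord_px
        return self.length_px / c if c > 0 else float("nan")


@dataclass
class GroundTruth:
    branches: list[GroundTruthBranch]
    junction_count: int
    endpoint_count: int
    stroke_mask: np.ndarray | None = None
    junctions_xy: list[tuple[float, float]] = field(default_factory=list)
    pixel_size_um: float = 1.0

    @property
    def branch_count(self) -> int:
        return len(self.branches)

    def branch_lengths_px(self) -> np.ndarray:
        return np.array([b.length_px for b in self.branches])

    def branch_step_lengths_px(self) -> np.ndarray:
        return np.array([b.step_length_px for b in self.branches])

    def to_dict(self) -> dict:
        return {
            "branch_count": self.branch_count,
            "junction_count": self.junction_count,
            "endpoint_count": self.endpoint_count,
            "junctions_xy": [list(map(float, j)) for j in self.junctions_xy],
            "branches": [
                {
                    "branch_id": b.branch_id,
                    "label": b.label,
                    "depth": b.depth,
                    "length_px": b.length_px,
                    "chord_px": b.chord_px,
                    "tortuosity": b.tortuosity,
                    "polyline": b.polyline.tolist(),
                }
                for b in self.branches
            ],
        }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _branch_polyline(
    p0: np.ndarray, angle: float, length: float, amplitude: float, periods: float, step: float = 1.0
) -> np.ndarray:
    """Straight segment from p0 at ``angle`` with an optional sinusoidal bow.

    The perpendicular offset vanishes at both endpoints so the chord is the
    straight p0->p1 segment regardless of amplitude.
    """
    n = max(int(np.ceil(length / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    d = np.array([np.cos(angle), np.sin(angle)])
    perp = np.array([-d[1], d[0]])
    pts = p0[None, :] + t[:, None] * length * d[None, :]
    if amplitude != 0:
        pts = pts + (amplitude * np.sin(np.pi * periods * t))[:, None] * perp[None, :]
    return pts


def _seg_distance_field(canvas: np.ndarray, a: np.ndarray, b: np.ndarray, reach: float) -> None:
    """Write min(point-to-segment distance) into ``canvas`` near segment a-b."""
    h, w = canvas.shape
    x0 = max(int(np.floor(min(a[0], b[0]) - reach)), 0)
    x1 = min(int(np.ceil(max(a[0], b[0]) + reach)) + 1, w)
    y0 = max(int(np.floor(min(a[1], b[1]) - reach)), 0)
    y1 = min(int(np.ceil(max(a[1], b[1]) + reach)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        d = np.hypot(xx - a[0], yy - a[1])
    else:
        t = np.clip(((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom, 0.0, 1.0)
        d = np.hypot(xx - (a[0] + t * ab[0]), yy - (a[1] + t * ab[1]))
    np.minimum(canvas[y0:y1, x0:x1], d, out=canvas[y0:y1, x0:x1])


def render_polylines(
    shape: tuple[int, int], polylines: list[np.ndarray], width_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render anti-aliased strokes; return (float image in [0,1], stroke mask).

    Intensity falls linearly from 1 to 0 over one pixel at the stroke edge;
    the ground-truth stroke mask is the >= 50% level set, i.e. distance to
    the polyline <= width/2.
    """
    dist = np.full(shape, np.inf)
    reach = width_px / 2.0 + 2.0
    for line in polylines:
        line = np.asarray(line, dtype=float)
        for i in range(len(line) - 1):
            _seg_distance_field(dist, line[i], line[i + 1], reach)
    half = width_px / 2.0
    img = np.clip(half + 0.5 - dist, 0.0, 1.0)
    mask = dist <= half
    return img, mask


def add_imaging_noise(
    img: RasterImage, noise_sigma: float, background_level: float = 0.0, seed: int = 0
) -> RasterImage:
    """Add a constant background and Gaussian noise, clipped to bit depth."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    vals = img.values.astype(np.float64) + background_level
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sigma, size=vals.shape)
    mx = img.bit_depth_max
    return RasterImage(np.clip(np.round(vals), 0, mx).astype(img.values.dtype), img.pixel_size_um)


# ---------------------------------------------------------------------------
# Tree generator
# ---------------------------------------------------------------------------


def _tree_polylines(spec: TreeSpec) -> tuple[list[GroundTruthBranch], list[tuple[float, float]]]:
    rng = np.random.default_rng(spec.seed)
    branches: list[GroundTruthBranch] = []
    junctions: list[tuple[float, float]] = []

    def grow(p0: np.ndarray, angle: float, length: float, spread: float, level: int) -> None:
        poly = _branch_polyline(
            p0, angle, length, spec.curvature_amplitude_px, spec.curvature_periods
        )
        label = "trunk" if level == 0 else "branch"
        branches.append(GroundTruthBranch(len(branches), label, poly, depth=level))
        p1 = poly[-1]
        if level < spec.depth:
            junctions.append((float(p1[0]), float(p1[1])))
            half = spread / 2.0
            for sign in (-1.0, +1.0):
                jitter = rng.normal(0.0, np.deg2rad(spec.angle_jitter_deg)) if spec.angle_jitter_deg else 0.0
                grow(
                    p1,
                    angle + sign * half + jitter,
                    length * spec.length_decay,
                    spread * spec.angle_decay,
                    level + 1,
                )

    grow(np.zeros(2), -np.pi / 2.0, spec.root_length_px, np.deg2rad(spec.bifurcation_angle_deg), 0)
    return branches, junctions


def generate_tree(spec: TreeSpec) -> tuple[RasterImage, GroundTruth]:
    """Render a bifurcating tree; deterministic for a given seed.

    Ground truth counts for a full tree of depth d: 2^(d+1)-1 branches,
    2^d-1 junctions, 2^d+1 endpoints.
    """
    branches, junctions = _tree_polylines(spec)

    pts = np.vstack([b.polyline for b in branches])
    margin = spec.stroke_width_px + 8.0
    offset = margin - pts.min(axis=0)
    for b in branches:
        b.polyline = b.polyline + offset
    junctions = [(x + offset[0], y + offset[1]) for x, y in junctions]
    extent = pts.max(axis=0) - pts.min(axis=0) + 2 * margin
    need = (int(np.ceil(extent[1])), int(np.ceil(extent[0])))  # (h, w)
    if spec.image_shape is None:
        shape = need
    else:
        shape = tuple(spec.image_shape)
        if shape[0] < need[0] or shape[1] < need[1]:
            raise ValueError(f"image_shape {shape} too small for this tree (needs {need})")

    img01, mask = render_polylines(shape, [b.polyline for b in branches], spec.stroke_width_px)
    img = RasterImage(np.round(img01 * 255).astype(np.uint8), spec.pixel_size_um)
    if spec.background_level or spec.noise_sigma:
        img = add_imaging_noise(img, spec.noise_sigma, spec.background_level, spec.seed)

    d = spec.depth
    gt = GroundTruth(
        branches=branches,
        junction_count=2**d - 1,
        endpoint_count=2**d + 1,
        stroke_mask=mask,
        junctions_xy=junctions,
        pixel_size_um=spec.pixel_size_um,
    )
    return img, gt


# ---------------------------------------------------------------------------
# Grid (anastomotic network) generator
# ---------------------------------------------------------------------------


def generate_grid(
    n_horizontal: int,
    n_vertical: int,
    spacing_px: int = 40,
    width_px: int = 3,
    pixel_size_um: float = 1.0,
) -> tuple[BinaryMask, GroundTruth]:
    """Orthogonal line lattice: n_h horizontal lines crossing n_v vertical ones.

    Ground truth: n_h * n_v junctions; each line is split by the crossings,
    giving n_h*(n_v+1) + n_v*(n_h+1) branch segments; 2*(n_h+n_v) endpoints.
    """
    if n_horizontal < 0 or n_vertical < 0 or n_horizontal + n_vertical < 1:
        raise ValueError("need at least one line")
    if spacing_px < width_px:
        raise ValueError("spacing must be >= stroke width")
    m = spacing_px  # margin: line ends extend one spacing beyond the lattice
    ys = [m + i * spacing_px for i in range(n_horizontal)]
    xs = [m + j * spacing_px for j in range(n_vertical)]
    width = (xs[-1] if xs else m) + m
    height = (ys[-1] if ys else m) + m
    x_lo, x_hi = 0, width
    y_lo, y_hi = 0, height
    mask = np.zeros((height + 1, width + 1), dtype=bool)
    half = (width_px - 1) // 2

    branches: list[GroundTruthBranch] = []
    for y in ys:
        mask[y - half : y + half + 1, x_lo : x_hi + 1] = True
        cuts = [x_lo] + xs + [x_hi]
        for a, b in zip(cuts[:-1], cuts[1:]):
            poly = np.array([[a, y], [b, y]], dtype=float)
            branches.append(GroundTruthBranch(len(branches), "collateral", poly))
    for x in xs:
        mask[y_lo : y_hi + 1, x - half : x + half + 1] = True
        cuts = [y_lo] + ys + [y_hi]
        for a, b in zip(cuts[:-1], cuts[1:]):
            poly = np.array([[x, a], [x, b]], dtype=float)
            branches.append(GroundTruthBranch(len(branches), "collateral", poly))

    gt = GroundTruth(
        branches=branches,
        junction_count=n_horizontal * n_vertical,
        endpoint_count=2 * (n_horizontal + n_vertical),
        stroke_mask=mask,
        junctions_xy=[(float(x), float(y)) for y in ys for x in xs],
        pixel_size_um=pixel_size_um,
    )
    return BinaryMask(mask, pixel_size_um), gt


# ---------------------------------------------------------------------------
# Fractal fixtures
# ---------------------------------------------------------------------------


def generate_fractal_fixture(kind: str, size: int = 1024, depth: int = 7) -> BinaryMask:
    """Exact point sets with known box-counting dimension.

    'line': one pixel row (D = 1); 'filled_square': all-foreground block
    (D = 2); 'sierpinski_triangle': the 2^depth-sized bitwise construction
    {(x, y): x & y == 0}, which holds exactly 3^depth pixels (D = log3/log2).
    """
    if kind == "line":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, :] = True
        return BinaryMask(mask)
    if kind == "filled_square":
        return BinaryMask(np.ones((size, size), dtype=bool))
    if kind == "sierpinski_triangle":
        n = 2**depth
        x = np.arange(n)
        mask = (x[None, :] & x[:, None]) == 0
        return BinaryMask(mask)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Random branch paths (tortuosity-contract fixtures)
# ---------------------------------------------------------------------------


def random_branch_path(rng: np.random.Generator, n_steps: int | None = None) -> np.ndarray:
    """A random self-avoiding-ish 8-connected pixel path, (n, 2) (y, x) ints.

    A drifting random walk over the 8 neighbor moves with a forward bias so
    paths rarely self-cross; used to exercise the length/tortuosity contract.
    """
    if n_steps is None:
        n_steps = int(rng.integers(5, 60))
    moves = np.array([(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)])
    heading = int(rng.integers(0, 8))
    path = [(0, 0)]
    seen = {(0, 0)}
    for _ in range(n_steps):
        heading = (heading + int(rng.integers(-1, 2))) % 8
        dy, dx = moves[heading]
        nxt = (path[-1][0] + int(dy), path[-1][1] + int(dx))
        if nxt in seen:
            continue
        seen.add(nxt)
        path.append(nxt)
    return np.asarray(path, dtype=int)
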
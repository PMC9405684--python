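"""Image input/output and preparation.

Holds the core raster types used across the package and the preparation
operations applied before segmentation/tracing: maximum-intensity projection,
polygon ROI extraction, automatic contrast, sharpening, morphological haze
reduction and binarization.

Coordinate convention: 0-based, x to the right, y down; pixel centers at
integer coordinates. Arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "RasterImage",
    "ZStack",
    "PolygonROI",
    "BinaryMask",
    "max_project",
    "auto_contrast",
    "sharpen",
    "gaussian_blur",
    "reduce_haze",
    "extract_polygon_roi",
    "binarize",
    "otsu_threshold",
    "read_image",
    "read_stack",
    "write_image",
    "read_roi",
    "prepare_image",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RasterImage:
    """Calibrated 2D grayscale image (8- or 16-bit)."""

    values: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.values.shape}")
        if self.values.size == 0:
            raise ValueError("image must have width, height >= 1")
        if self.values.dtype not in (np.uint8, np.uint16):
            # tolerate float/other integer input; normalize into uint8
            self.values = _to_uint8(self.values)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def bit_depth_max(self) -> int:
        return 255 if self.values.dtype == np.uint8 else 65535

    def as_uint8(self) -> "RasterImage":
        """Linearly rescale 16-bit data into 8-bit; pass 8-bit through."""
        if self.values.dtype == np.uint8:
            return RasterImage(self.values.copy(), self.pixel_size_um)
        return RasterImage(_to_uint8(self.values), self.pixel_size_um)


def _to_uint8(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.clip(np.round((values - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)


@dataclass
class ZStack:
    """Ordered stack of same-sized slices with an axial step size."""

    slices: list[RasterImage]
    step_um: float = 1.0

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("z-stack must contain at least one slice")
        shape = self.slices[0].values.shape
        for s in self.slices:
            if s.values.shape != shape:
                raise ValueError("all slices must share the same dimensions")


@dataclass
class PolygonROI:
    """Simple polygon, vertices as ordered (x, y) pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if _self_intersects(self.vertices):
            raise ValueError("polygon must be simple (non-self-intersecting)")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Point-in-polygon test for pixel centers (winding rule)."""
        pts = np.column_stack([np.asarray(x, float).ravel(), np.asarray(y, float).ravel()])
        # tiny radius makes boundary pixels inclusive
        inside = MplPath(self.vertices).contains_points(pts, radius=1e-9)
        return inside.reshape(np.shape(x))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains(xx, yy)

    def area_px(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _self_intersects(v: np.ndarray) -> bool:
    n = len(v)
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # first and last edges share a vertex
            c, d = v[j], v[(j + 1) % n]
            if _segments_cross(a, b, c, d):
                return True
    return False


@dataclass
class BinaryMask:
    """Boolean foreground grid with pixel calibration."""

    data: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Preparation operations
# ---------------------------------------------------------------------------


def max_project(stack: ZStack) -> RasterImage:
    """Per-pixel maximum-intensity projection across the stack."""
    if len(stack.slices) == 0:
        raise ValueError("cannot project an empty stack")
    out = stack.slices[0].values.copy()
    for s in stack.slices[1:]:
        np.maximum(out, s.values, out=out)
    return RasterImage(out, stack.slices[0].pixel_size_um)


def auto_contrast(img: RasterImage, saturation_fraction: float = 0.0035) -> RasterImage:
    """Linear contrast stretch saturating ``saturation_fraction`` at each tail.

    Maps the lower quantile to 0 and the upper quantile to full scale,
    clipping in between. Constant images pass through unchanged.
    """
    if not (0 <= saturation_fraction < 0.5):
        raise ValueError("saturation_fraction must lie in [0, 0.5)")
    vals = img.values.astype(np.float64)
    lo = np.quantile(vals, saturation_fraction)
    hi = np.quantile(vals, 1.0 - saturation_fraction)
    if hi <= lo:
        return RasterImage(img.values.copy(), img.pixel_size_um)
    mx = img.bit_depth_max
    out = np.clip((vals - lo) / (hi - lo) * mx, 0, mx)
    return RasterImage(np.round(out).astype(img.values.dtype), img.pixel_size_um)


_SHARPEN_KERNEL = np.array([[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]], dtype=np.float64) / 4.0


def sharpen(img: RasterImage) -> RasterImage:
    """3x3 unsharp kernel (center 12, neighbors -1, /4), replicate borders."""
    out = ndimage.convolve(img.values.astype(np.float64), _SHARPEN_KERNEL, mode="nearest")
    mx = img.bit_depth_max
    return RasterImage(np.clip(np.round(out), 0, mx).astype(img.values.dtype), img.pixel_size_um)


def gaussian_blur(img: RasterImage, sigma: float) -> RasterImage:
    """Gaussian blur, kernel truncated at 4 sigma (sigma in pixels)."""
    if sigma <= 0:
        return RasterImage(img.values.copy(), img.pixel_size_um)
    out = ndimage.gaussian_filter(img.values.astype(np.float64), sigma, truncate=4.0, mode="nearest")
    mx = img.bit_depth_max
    return RasterImage(np.clip(np.round(out), 0, mx).astype(img.values.dtype), img.pixel_size_um)


def reduce_haze(img: RasterImage, radius: int) -> RasterImage:
    """Subtract the morphological opening (disk of ``radius``), clip at 0.

    Stand-in for proprietary haze reduction: removes diffuse background glow
    wider than the structuring element while preserving thin bright vessels.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(img.values.shape):
        raise ValueError("structuring element larger than the image")
    background = ndimage.grey_opening(img.values, footprint=disk(radius), mode="nearest")
    out = img.values.astype(np.int64) - background.astype(np.int64)
    return RasterImage(np.clip(out, 0, img.bit_depth_max).astype(img.values.dtype), img.pixel_size_um)


def extract_polygon_roi(img: RasterImage, roi: PolygonROI) -> RasterImage:
    """Crop to the ROI bounding box and zero pixels outside the polygon."""
    inside = roi.mask(img.values.shape)
    if not inside.any():
        raise ValueError("polygon lies fully outside the image")
    ys, xs = np.nonzero(inside)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    out = np.where(inside[y0:y1, x0:x1], img.values[y0:y1, x0:x1], 0)
    return RasterImage(out.astype(img.values.dtype), img.pixel_size_um)


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu threshold over the 256 8-bit levels.

    Returns t maximizing between-class variance for the split
    ``{v < t} | {v >= t}``; raises on constant input.
    """
    hist = np.bincount(values.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    best_t, best_var = 1, -1.0
    cum = np.cumsum(hist)
    cum_mean = np.cumsum(hist * levels)
    grand = cum_mean[-1]
    for t in range(1, 256):
        w0 = cum[t - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_mean[t - 1] / w0
        mu1 = (grand - cum_mean[t - 1]) / w1
        var_b = w0 * w1 * (mu0 - mu1) ** 2
        if var_b > best_var:
            best_var, best_t = var_b, t
    return best_t


def binarize(img: RasterImage, method: str = "otsu", threshold: int | None = None) -> BinaryMask:
    """Threshold an 8-bit image; foreground = values >= threshold.

    method 'otsu' searches all 256 levels for the maximal between-class
    variance; method 'fixed' uses the supplied ``threshold``.
    """
    vals = img.as_uint8().values
    if method == "otsu":
        try:
            t = otsu_threshold(vals)
        except ValueError:
            warnings.warn("constant image: Otsu undefined, returning empty mask", stacklevel=2)
            return BinaryMask(np.zeros(vals.shape, dtype=bool), img.pixel_size_um)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = int(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return BinaryMask(vals >= t, img.pixel_size_um)


def prepare_image(
    img: RasterImage,
    roi: PolygonROI | None = None,
    do_auto_contrast: bool = True,
    saturation_fraction: float = 0.0035,
    do_sharpen: bool = False,
    haze_radius: int = 0,
    blur_sigma: float = 0.0,
) -> RasterImage:
    """Standard preparation chain: 8-bit, ROI, haze, contrast, sharpen, blur."""
    out = img.as_uint8()
    if roi is not None:
        out = extract_polygon_roi(out, roi)
    if haze_radius > 0:
        out = reduce_haze(out, haze_radius)
    if do_auto_contrast:
        out = auto_contrast(out, saturation_fraction)
    if do_sharpen:
        out = sharpen(out)
    if blur_sigma > 0:
        out = gaussian_blur(out, blur_sigma)
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_image(path: str | Path, pixel_size_um: float | None = None) -> RasterImage:
    """Read a single 2D TIFF/PNG image; ``pixel_size_um`` overrides file tags."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if pixel_size_um is None:
            pixel_size_um = _tiff_pixel_size(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    if data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) -> luminance
        data = data[..., :3].mean(axis=-1).astype(np.uint8)
    if data.ndim != 2:
        raise ValueError(f"{path} is not a single 2D image; use read_stack")
    return RasterImage(data, pixel_size_um or 1.0)


def read_stack(path: str | Path, pixel_size_um: float | None = None, step_um: float = 1.0) -> ZStack:
    """Read a multi-page TIFF as a z-stack."""
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    if pixel_size_um is None:
        pixel_size_um = _tiff_pixel_size(Path(path))
    slices = [RasterImage(plane, pixel_size_um or 1.0) for plane in data]
    return ZStack(slices, step_um)


def _tiff_pixel_size(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None:
                return None
            num, den = res.value
            if num == 0:
                return None
            px_per_unit = num / den
            if unit is not None and getattr(unit.value, "value", unit.value) == 3:  # cm
                return 1e4 / px_per_unit
            return 25.4e3 / px_per_unit  # assume inch
    except Exception:
        return None


def write_image(path: str | Path, img: RasterImage | BinaryMask) -> None:
    path = Path(path)
    if isinstance(img, BinaryMask):
        data = (img.data.astype(np.uint8)) * 255
    else:
        data = img.values
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_roi(path: str | Path) -> PolygonROI:
    """Read a polygon ROI from JSON ([[x, y], ...]) or an ImageJ .roi file."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return _read_imagej_roi(path)
    verts = json.loads(path.read_text())
    if isinstance(verts, dict):
        verts = verts.get("vertices", verts)
    return PolygonROI(np.asarray(verts, dtype=float))


def _read_imagej_roi(path: Path) -> PolygonROI:
    """Minimal parser for ImageJ .roi polygon/freehand/traced outlines."""
    buf = path.read_bytes()
    if buf[:4] != b"Iout":
        raise ValueError(f"{path} is not an ImageJ ROI file")
    roi_type = buf[6]
    if roi_type not in (0, 3, 7, 8):  # polygon, freeline, freehand, traced
        raise ValueError(f"unsupported ImageJ ROI type {roi_type}")
    top, left = struct.unpack(">hh", buf[8:12])
    (n,) = struct.unpack(">h", buf[16:18])
    xs = struct.unpack(f">{n}h", buf[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", buf[64 + 2 * n : 64 + 4 * n])
    verts = np.column_stack([np.asarray(xs) + left, np.asarray(ys) + top]).astype(float)
    return PolygonROI(verts)
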
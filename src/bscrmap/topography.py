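"""Scaled three-point directional curvature on substrate height maps.

The substrate is a 2.5D surface: one height z(x, y) per lateral position,
obtained from micro-CT voxel stacks (topmost occupied voxel per column) or
read directly as a raster.  At every point A the local curvature is probed
along D discrete directions (default 18, i.e. 10° steps over [0°, 180°)):
the surface is sampled at the two flanking points C and E a half-span
s = scale_length/2 (default 30 µm) away along the direction, and the
signed curvature is the reciprocal circumradius of the planar triangle
{E=(-s, zE), A=(0, zA), C=(+s, zC)},

    kappa = sign(zC + zE - 2 zA) * 1000 / R_circ     [mm^-1]

positive when A dips below its neighbours (concave / bowl-like).  The mean
over directions classifies the point into a motif (convex / flat /
concave, flat band ±2.5 mm^-1), while the individual directional values
are compared against the blastocyst-scaled curvature range (BSCR,
default 15-62 mm^-1, strict interior): a point is BSCR+ if at least one
direction falls inside, and the BSCR count (0..D) is binned into
none / low (1-6) / med (7-12) / hi (13-18) for D = 18.

Coordinate convention: x rightward (columns), y downward (rows), origin at
the top-left pixel centre; physical position in µm = pixel index *
pixel_size.  Points whose full chord star does not fit inside the valid
raster are marked invalid rather than computed from truncated chords.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .geometry import DEFAULT_BSCR, BSCRRange, ValidationError

__all__ = [
    "HeightMap",
    "CurvatureParams",
    "DirectionalCurvature",
    "MotifMap",
    "BSCRMap",
    "SamplingError",
    "MOTIF_INVALID",
    "MOTIF_CONVEX",
    "MOTIF_FLAT",
    "MOTIF_CONCAVE",
    "MOTIF_NAMES",
    "BSCR_CATEGORIES",
    "heightmap_from_voxels",
    "sample_height",
    "three_point_curvature",
    "direction_angles",
    "directional_curvatures",
    "classify_motif",
    "bscr_category",
    "bscr_flags",
    "map_surface",
    "read_heightmap",
    "write_label_image",
    "write_summary",
]

# Sagitta below this (µm) is treated as exactly collinear -> kappa = 0.
# Prevents sign flapping at machine precision on flat regions.
COLLINEAR_TOL_UM = 1e-9

# Integer motif codes used in label rasters.
MOTIF_INVALID, MOTIF_CONVEX, MOTIF_FLAT, MOTIF_CONCAVE = 0, 1, 2, 3
MOTIF_NAMES = {
    MOTIF_INVALID: "invalid",
    MOTIF_CONVEX: "convex",
    MOTIF_FLAT: "flat",
    MOTIF_CONCAVE: "concave",
}
BSCR_CATEGORIES = ("none", "low", "med", "hi")


class SamplingError(ValueError):
    """Raised when a continuous height query cannot be answered."""


@dataclass
class HeightMap:
    """Raster of surface heights (µm) with pixel size and validity mask."""

    heights: np.ndarray
    pixel_size: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValidationError(f"heights must be 2D, got shape {self.heights.shape}")
        if not self.pixel_size > 0:
            raise ValidationError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.valid is None:
            self.valid = np.isfinite(self.heights)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.heights.shape:
                raise ValidationError(
                    f"valid mask shape {self.valid.shape} != heights shape {self.heights.shape}"
                )
            self.valid = self.valid & np.isfinite(self.heights)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(x_max, y_max) of the pixel-centre grid in µm."""
        nr, nc = self.heights.shape
        return ((nc - 1) * self.pixel_size, (nr - 1) * self.pixel_size)


@dataclass(frozen=True)
class CurvatureParams:
    """Parameters of the scaled three-point analysis.

    scale_length is the full chord CE (µm); the half-span s used on each
    flank is scale_length / 2.  flat_band is the half-width (mm^-1) of the
    flat motif class around zero mean curvature.
    """

    n_directions: int = 18
    scale_length: float = 60.0
    bscr: BSCRRange = DEFAULT_BSCR
    flat_band: float = 2.5
    interpolation: str = "bilinear"  # or "nearest"

    def __post_init__(self) -> None:
        if self.n_directions < 2:
            raise ValidationError(f"n_directions must be >= 2, got {self.n_directions}")
        if not self.scale_length > 0:
            raise ValidationError(f"scale_length must be positive, got {self.scale_length}")
        if not self.flat_band > 0:
            raise ValidationError(f"flat_band must be positive, got {self.flat_band}")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValidationError(f"unknown interpolation {self.interpolation!r}")

    @property
    def half_span(self) -> float:
        return self.scale_length / 2.0


@dataclass(frozen=True)
class DirectionalCurvature:
    """Signed curvatures (mm^-1) of one point in each probe direction."""

    kappas: np.ndarray
    mean_kappa: float


@dataclass(frozen=True)
class MotifMap:
    """Per-pixel motif labels (integer codes, see MOTIF_NAMES)."""

    labels: np.ndarray
    pixel_size: float

    def fractions(self) -> dict[str, float]:
        """Area fractions of convex/flat/concave over valid pixels."""
        valid = self.labels != MOTIF_INVALID
        n = int(valid.sum())
        if n == 0:
            return {"convex": math.nan, "flat": math.nan, "concave": math.nan}
        return {
            MOTIF_NAMES[c]: float((self.labels == c).sum()) / n
            for c in (MOTIF_CONVEX, MOTIF_FLAT, MOTIF_CONCAVE)
        }


@dataclass(frozen=True)
class BSCRMap:
    """Per-pixel BSCR membership: flag, direction count and category.

    category holds indices into BSCR_CATEGORIES; -1 marks invalid pixels.
    """

    positive: np.ndarray
    count: np.ndarray
    category: np.ndarray
    n_directions: int
    pixel_size: float

    def positive_fraction(self) -> float:
        valid = self.count >= 0
        n = int(valid.sum())
        return float(self.positive[valid].sum()) / n if n else math.nan


# ---------------------------------------------------------------------------
# Surface extraction and sampling


def heightmap_from_voxels(volume: np.ndarray, voxel_size: float) -> HeightMap:
    """Extract a height map from a binary occupancy stack.

    ``volume`` is indexed (z, y, x) with z increasing upward; the height of
    a column is (topmost occupied z-index + 1) * voxel_size.  Columns with
    no occupied voxel become invalid pixels.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError(f"volume must be 3D (z, y, x), got shape {volume.shape}")
    uniq = np.unique(volume)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError("volume must be binary occupancy (values 0/1)")
    occ = volume.astype(bool)
    any_occ = occ.any(axis=0)
    nz = occ.shape[0]
    # topmost occupied index: argmax over reversed z
    top = nz - 1 - np.argmax(occ[::-1], axis=0)
    heights = np.where(any_occ, (top + 1) * float(voxel_size), np.nan)
    return HeightMap(heights=heights, pixel_size=float(voxel_size), valid=any_occ)


def _bilinear(hm: HeightMap, x: float, y: float) -> float:
    px = hm.pixel_size
    cf, rf = x / px, y / px
    nr, nc = hm.heights.shape
    if not (0.0 <= cf <= nc - 1 and 0.0 <= rf <= nr - 1):
        raise SamplingError(f"query ({x}, {y}) µm outside raster extent")
    c0 = min(int(math.floor(cf)), nc - 2) if nc > 1 else 0
    r0 = min(int(math.floor(rf)), nr - 2) if nr > 1 else 0
    c1, r1 = min(c0 + 1, nc - 1), min(r0 + 1, nr - 1)
    tc, tr = cf - c0, rf - r0
    # a neighbour only participates when its bilinear weight is nonzero
    w = {
        (r0, c0): (1 - tr) * (1 - tc),
        (r0, c1): (1 - tr) * tc,
        (r1, c0): tr * (1 - tc),
        (r1, c1): tr * tc,
    }
    z = 0.0
    for (r, c), wt in w.items():
        if wt == 0.0:
            continue
        if not hm.valid[r, c]:
            raise SamplingError(f"query ({x}, {y}) µm touches an invalid pixel at ({r}, {c})")
        z += wt * hm.heights[r, c]
    return z


def _nearest(hm: HeightMap, x: float, y: float) -> float:
    px = hm.pixel_size
    c = int(round(x / px))
    r = int(round(y / px))
    nr, nc = hm.heights.shape
    if not (0 <= c < nc and 0 <= r < nr):
        raise SamplingError(f"query ({x}, {y}) µm outside raster extent")
    if not hm.valid[r, c]:
        raise SamplingError(f"query ({x}, {y}) µm on an invalid pixel")
    return float(hm.heights[r, c])


def sample_height(hm: HeightMap, x: float, y: float, interpolation: str = "bilinear") -> float:
    """Continuous height query (µm) at physical position (x, y) µm.

    Bilinear by default (exact on planes); nearest-neighbour mode is kept
    for voxel-faithful tests.  Raises SamplingError when the query leaves
    the raster or touches invalid pixels.
    """
    if interpolation == "bilinear":
        return _bilinear(hm, x, y)
    if interpolation == "nearest":
        return _nearest(hm, x, y)
    raise ValidationError(f"unknown interpolation {interpolation!r}")


# ---------------------------------------------------------------------------
# The three-point curvature primitive


def three_point_curvature(zA: float, zC: float, zE: float, half_span: float) -> float:
    """Signed curvature (mm^-1) of the circle through E, A, C.

    The three points are taken in the vertical plane of the probe
    direction: E = (-s, zE), A = (0, zA), C = (+s, zC) with s = half_span
    in µm.  The magnitude is 1000 / circumradius_µm; the sign follows the
    sagitta zC + zE - 2 zA (positive = A below its neighbours = concave).
    Collinear (|sagitta| < 1e-9 µm) returns exactly 0.
    """
    if not half_span > 0:
        raise ValidationError(f"half_span must be positive, got {half_span}")
    s = half_span
    d = zC + zE - 2.0 * zA
    if abs(d) < COLLINEAR_TOL_UM:
        return 0.0
    # circumradius R = (|EA| |AC| |CE|) / (4 * area)
    ea = math.hypot(s, zA - zE)
    ac = math.hypot(s, zC - zA)
    ce = math.hypot(2.0 * s, zC - zE)
    area = 0.5 * abs(s * d)  # shoelace of the three points
    r = ea * ac * ce / (4.0 * area)
    return math.copysign(1000.0 / r, d)


def direction_angles(n_directions: int) -> np.ndarray:
    """Probe angles in radians: i * pi / D for i = 0..D-1.

    Each probe uses both flanks of the chord, so headings over [0, 180°)
    already cover the full circle of chord orientations.
    """
    return np.arange(n_directions) * math.pi / n_directions


def directional_curvatures(
    hm: HeightMap, x: float, y: float, params: CurvatureParams = CurvatureParams()
) -> DirectionalCurvature:
    """Curvature of point (x, y) µm in each of the D probe directions.

    Samples the flanking points C (forward) and E (backward) at the
    half-span along each direction and applies the three-point primitive.
    Any unsampleable endpoint invalidates the whole point (SamplingError);
    partial direction sets are never returned.
    """
    s = params.half_span
    zA = sample_height(hm, x, y, params.interpolation)
    kappas = np.empty(params.n_directions)
    for i, theta in enumerate(direction_angles(params.n_directions)):
        dx, dy = s * math.cos(theta), s * math.sin(theta)
        zC = sample_height(hm, x + dx, y + dy, params.interpolation)
        zE = sample_height(hm, x - dx, y - dy, params.interpolation)
        kappas[i] = three_point_curvature(zA, zC, zE, s)
    return DirectionalCurvature(kappas=kappas, mean_kappa=float(kappas.mean()))


# ---------------------------------------------------------------------------
# Classification


def classify_motif(mean_kappa: float, flat_band: float = 2.5) -> str:
    """Motif class of a mean curvature: concave (>= +band), convex
    (<= -band), flat otherwise; NaN -> 'invalid'.  The three classes
    partition the real line."""
    if math.isnan(mean_kappa):
        return "invalid"
    if mean_kappa >= flat_band:
        return "concave"
    if mean_kappa <= -flat_band:
        return "convex"
    return "flat"


def bscr_category(count: int, n_directions: int = 18) -> str:
    """Bin a BSCR count into none / low / med / hi (thirds of D)."""
    if count < 0 or count > n_directions:
        raise ValidationError(f"count {count} outside 0..{n_directions}")
    if count == 0:
        return "none"
    if count <= n_directions / 3:
        return "low"
    if count <= 2 * n_directions / 3:
        return "med"
    return "hi"


def bscr_flags(
    kappas: np.ndarray, bscr: BSCRRange = DEFAULT_BSCR
) -> tuple[bool, int, str]:
    """BSCR membership of one point from its directional curvatures.

    count = number of directions with lower < kappa < upper (strict);
    positive = count >= 1; category per thirds of D.
    """
    kappas = np.asarray(kappas, dtype=float)
    if not np.all(np.isfinite(kappas)):
        raise ValidationError("kappas must be finite")
    count = int(np.sum((kappas > bscr.lower) & (kappas < bscr.upper)))
    return count >= 1, count, bscr_category(count, len(kappas))


# ---------------------------------------------------------------------------
# Whole-map evaluation


def _shifted_fields(hm: HeightMap, dx_um: float, dy_um: float, order: int):
    """Heights and validity of the surface sampled at (x+dx, y+dy) for all
    pixels at once.  Returns (z, ok) arrays of the raster shape."""
    nr, nc = hm.heights.shape
    px = hm.pixel_size
    rows, cols = np.meshgrid(np.arange(nr, dtype=float), np.arange(nc, dtype=float), indexing="ij")
    rq = rows + dy_um / px
    cq = cols + dx_um / px
    in_extent = (rq >= 0.0) & (rq <= nr - 1) & (cq >= 0.0) & (cq <= nc - 1)
    coords = np.stack([rq, cq])
    z = ndimage.map_coordinates(
        np.where(hm.valid, hm.heights, 0.0), coords, order=order, mode="constant", cval=0.0
    )
    bad = ndimage.map_coordinates(
        (~hm.valid).astype(float), coords, order=order, mode="constant", cval=1.0
    )
    ok = in_extent & (bad == 0.0)
    return z, ok


def map_surface(
    hm: HeightMap, params: CurvatureParams = CurvatureParams()
) -> tuple[MotifMap, BSCRMap, dict]:
    """Evaluate motif and BSCR maps over an entire height map.

    Directional curvatures are computed at every valid pixel whose full
    chord star (both flanks in all D directions) lies inside the valid
    raster; pixels within the half-span of the border or adjacent to
    invalid input become invalid output.  Evaluation is independent per
    pixel, so the result does not depend on traversal order.

    Returns (MotifMap, BSCRMap, summary) where summary holds the motif
    area fractions, the BSCR+ fraction and the histogram of BSCR counts
    0..D over valid pixels.
    """
    s = params.half_span
    px = hm.pixel_size
    nr, nc = hm.heights.shape
    if min(nr, nc) * px <= 2.0 * s:
        raise ValidationError(
            f"raster ({nr}x{nc} px at {px} µm) smaller than the 2*{s} µm chord star"
        )
    order = 1 if params.interpolation == "bilinear" else 0
    D = params.n_directions
    zA = np.where(hm.valid, hm.heights, 0.0)
    ok = hm.valid.copy()
    count = np.zeros((nr, nc), dtype=np.int16)
    ksum = np.zeros((nr, nc))
    for theta in direction_angles(D):
        dx, dy = s * math.cos(theta), s * math.sin(theta)
        zC, okC = _shifted_fields(hm, dx, dy, order)
        zE, okE = _shifted_fields(hm, -dx, -dy, order)
        ok &= okC & okE
        d = zC + zE - 2.0 * zA
        sag = np.abs(d) >= COLLINEAR_TOL_UM
        ea = np.hypot(s, zA - zE)
        ac = np.hypot(s, zC - zA)
        ce = np.hypot(2.0 * s, zC - zE)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = ea * ac * ce / (4.0 * 0.5 * np.abs(s * d))
            kappa = np.where(sag, np.sign(d) * 1000.0 / r, 0.0)
        ksum += kappa
        count += ((kappa > params.bscr.lower) & (kappa < params.bscr.upper)).astype(np.int16)
    mean_kappa = ksum / D

    labels = np.full((nr, nc), MOTIF_INVALID, dtype=np.uint8)
    labels[ok & (mean_kappa >= params.flat_band)] = MOTIF_CONCAVE
    labels[ok & (mean_kappa <= -params.flat_band)] = MOTIF_CONVEX
    labels[ok & (np.abs(mean_kappa) < params.flat_band)] = MOTIF_FLAT

    count = np.where(ok, count, -1).astype(np.int16)
    positive = count >= 1
    lo = math.floor(D / 3)
    med = math.floor(2 * D / 3)
    category = np.full((nr, nc), -1, dtype=np.int8)
    category[ok] = 0
    category[ok & (count >= 1)] = 1
    category[ok & (count > lo)] = 2
    category[ok & (count > med)] = 3

    motif = MotifMap(labels=labels, pixel_size=px)
    bscr = BSCRMap(positive=positive, count=count, category=category, n_directions=D, pixel_size=px)

    n_valid = int(ok.sum())
    hist = np.bincount(count[ok].astype(int), minlength=D + 1) if n_valid else np.zeros(D + 1, int)
    summary = {
        "n_valid": n_valid,
        "valid_area_um2": n_valid * px * px,
        **{f"frac_{k}": v for k, v in motif.fractions().items()},
        "frac_bscr_positive": float(positive[ok].sum()) / n_valid if n_valid else math.nan,
        "count_hist": hist.tolist(),
    }
    return motif, bscr, summary


# ---------------------------------------------------------------------------
# Raster I/O


def read_heightmap(
    path, pixel_size: float, height_scale: float = 1.0
) -> HeightMap:
    """Read a height map from TIFF or delimited text.

    ``height_scale`` converts raw raster units to µm (µm per unit); NaN
    pixels become invalid.
    """
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        raw = tifffile.imread(p).astype(float)
    else:
        raw = pd.read_csv(p, header=None).to_numpy(dtype=float)
    return HeightMap(heights=raw * height_scale, pixel_size=pixel_size)


def write_label_image(path, labels: np.ndarray) -> None:
    """Write an integer label raster as a single-channel TIFF."""
    arr = np.asarray(labels)
    if arr.min() < 0:  # BSCR count uses -1 for invalid; shift is lossless for viewing
        arr = arr.astype(np.int16)
    else:
        arr = arr.astype(np.uint8) if arr.max() < 256 else arr.astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def write_summary(path, summary: dict) -> None:
    """Write a flat key-value summary as plain text."""
    with open(path, "w") as fh:
        for k, v in summary.items():
            fh.write(f"{k}: {v}\n")


def maps_to_table(motif: MotifMap, bscr: BSCRMap) -> pd.DataFrame:
    """Per-pixel tidy table of motif and BSCR results (valid pixels only)."""
    ok = motif.labels != MOTIF_INVALID
    rr, cc = np.nonzero(ok)
    return pd.DataFrame(
        {
            "x_um": cc * motif.pixel_size,
            "y_um": rr * motif.pixel_size,
            "motif": [MOTIF_NAMES[v] for v in motif.labels[rr, cc]],
            "bscr_positive": bscr.positive[rr, cc],
            "bscr_count": bscr.count[rr, cc],
            "bscr_category": [BSCR_CATEGORIES[v] for v in bscr.category[rr, cc]],
        }
    )
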
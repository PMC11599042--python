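"""Correlative overlay of cell observations on motif / BSCR maps.

Cell tables (one row per cell per observation time, positions in µm) are
registered into the map frame with a landmark-based affine fit, called
naive-high against a plain-substrate control threshold, annotated with the
motif label and BSCR flag/count of the pixel under their centroid, and
summarised per stratum (motif class, BSCR category or BSCR flag) and time
point.  Track tables are scored for displacement and BSCR-border crossing
per imaging interval.  Simple image operations used upstream of the cell
tables (maximum-intensity projection, nuclei detection, hi/positive area
ratios) live here too.

Cell tables are plain pandas DataFrames with columns
``cell_id, x_um, y_um, t_h, <channel>_intensity[, area_um2]``; derived
columns are ``naive_hi, motif, bscr_positive, bscr_count, bscr_category,
excluded``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure

from .geometry import ValidationError
from .topography import (
    BSCR_CATEGORIES,
    MOTIF_INVALID,
    MOTIF_NAMES,
    BSCRMap,
    MotifMap,
)

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "Track",
    "AffineTransform",
    "landmark_affine",
    "naive_threshold",
    "label_cells",
    "assign_topography",
    "region_stats",
    "area_ratio_hi",
    "track_metrics",
    "detect_nuclei",
    "max_intensity_projection",
    "read_cell_table",
    "read_tracks",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """How the naive-calling threshold is derived from plain-control cells.

    statistic 'max' reproduces live GFP tracking (threshold = maximum
    control intensity); 'mean' the fixed-stain MFI rule; 'mean_plus_k_sd'
    a parametric variant.
    """

    channel: str
    statistic: Literal["max", "mean", "mean_plus_k_sd"] = "mean"
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.statistic not in ("max", "mean", "mean_plus_k_sd"):
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if self.k < 0:
            raise ValidationError(f"k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class Track:
    """Time-ordered positions of one tracked cell (t in h, x/y in µm)."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError(f"track {self.track_id}: times must be strictly increasing")


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map y = A x + b from the cell/image frame to the map frame."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    rms_residual: float = 0.0

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(matrix=np.eye(2), offset=np.zeros(2), rms_residual=0.0)


def landmark_affine(pairs: Sequence[tuple]) -> AffineTransform:
    """Least-squares affine fit from landmark correspondences.

    ``pairs`` is a sequence of (source_xy, target_xy) in µm; at least three
    non-collinear source points are required.  Replaces the manual overlay
    of bright-field images onto micro-CT maps with a reproducible fit; the
    RMS residual (µm) reports registration quality.
    """
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 landmark pairs, got {len(pairs)}")
    src = np.array([p[0] for p in pairs], dtype=float)
    dst = np.array([p[1] for p in pairs], dtype=float)
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValidationError("landmark source points are collinear; affine fit is degenerate")
    design = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(matrix=matrix, offset=offset, rms_residual=rms)


def _intensity_col(df: pd.DataFrame, channel: str) -> str:
    col = f"{channel}_intensity"
    if col not in df.columns:
        raise ValidationError(f"cell table has no column {col!r} for channel {channel!r}")
    return col


def naive_threshold(control_cells: pd.DataFrame, spec: ThresholdSpec) -> float:
    """Naive-calling threshold from the plain-substrate control population."""
    col = _intensity_col(control_cells, spec.channel)
    vals = control_cells[col].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"control table has no finite {col} values")
    if spec.statistic == "max":
        return float(vals.max())
    if spec.statistic == "mean":
        return float(vals.mean())
    return float(vals.mean() + spec.k * vals.std(ddof=1))


def label_cells(cells: pd.DataFrame, threshold: float, channel: str) -> pd.DataFrame:
    """Add the naive_hi column: intensity strictly above threshold."""
    if not math.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold}")
    col = _intensity_col(cells, channel)
    out = cells.copy()
    out["naive_hi"] = out[col].to_numpy(dtype=float) > threshold
    return out


def assign_topography(
    cells: pd.DataFrame,
    motif: MotifMap,
    bscr: BSCRMap,
    transform: Optional[AffineTransform] = None,
) -> pd.DataFrame:
    """Annotate each cell with the motif/BSCR state under its centroid.

    The cell position is mapped into the map frame (identity transform by
    default) and read from the single pixel under it.  Cells landing
    outside the raster or on invalid pixels are flagged ``excluded`` and
    carry no annotation; their number is reported through the module
    logger.
    """
    if transform is None:
        transform = AffineTransform.identity()
    out = cells.copy()
    xy = transform.apply(out[["x_um", "y_um"]].to_numpy(dtype=float))
    px = motif.pixel_size
    cc = np.round(xy[:, 0] / px).astype(int)
    rr = np.round(xy[:, 1] / px).astype(int)
    nr, nc = motif.labels.shape
    inside = (cc >= 0) & (cc < nc) & (rr >= 0) & (rr < nr)
    ccs, rrs = np.clip(cc, 0, nc - 1), np.clip(rr, 0, nr - 1)
    lbl = motif.labels[rrs, ccs]
    ok = inside & (lbl != MOTIF_INVALID)
    out["excluded"] = ~ok
    out["motif"] = pd.array(
        [MOTIF_NAMES[v] if good else None for v, good in zip(lbl, ok)], dtype="string"
    )
    cnt = bscr.count[rrs, ccs].astype(float)
    cat = bscr.category[rrs, ccs]
    out["bscr_count"] = np.where(ok, cnt, np.nan)
    out["bscr_positive"] = pd.array(
        [bool(c >= 1) if good else None for c, good in zip(cnt, ok)], dtype="boolean"
    )
    out["bscr_category"] = pd.array(
        [BSCR_CATEGORIES[v] if good else None for v, good in zip(cat, ok)], dtype="string"
    )
    n_excl = int((~ok).sum())
    if n_excl:
        log.warning("assign_topography: %d of %d cells excluded (outside map or invalid pixel)",
                    n_excl, len(out))
    return out


_STRATA_COLS = {
    "motif": "motif",
    "bscr_category": "bscr_category",
    "bscr_positive": "bscr_positive",
}


def _stratum_areas(motif: MotifMap, bscr: BSCRMap, strata: str) -> dict:
    """Valid-pixel area (µm²) per stratum value."""
    px2 = motif.pixel_size**2
    if strata == "motif":
        ok = motif.labels != MOTIF_INVALID
        return {
            MOTIF_NAMES[c]: float((motif.labels == c).sum()) * px2
            for c in (1, 2, 3)
        }
    ok = bscr.count >= 0
    if strata == "bscr_positive":
        return {
            True: float((ok & bscr.positive).sum()) * px2,
            False: float((ok & ~bscr.positive).sum()) * px2,
        }
    return {
        name: float((bscr.category == i).sum()) * px2
        for i, name in enumerate(BSCR_CATEGORIES)
    }


def region_stats(
    cells: pd.DataFrame,
    motif: MotifMap,
    bscr: BSCRMap,
    strata: Literal["motif", "bscr_category", "bscr_positive"] = "bscr_category",
    channel: Optional[str] = None,
    times: Optional[Iterable[float]] = None,
) -> pd.DataFrame:
    """Per-stratum, per-time cell statistics.

    For every stratum value and time point: cell count, stratum area
    (µm²), density (cells mm^-2), naive fraction (hi / total; missing for
    empty strata, never 0) and channel MFI.  ``cells`` must already be
    annotated by assign_topography; excluded cells are dropped.
    """
    if strata not in _STRATA_COLS:
        raise ValidationError(f"unknown strata {strata!r}")
    col = _STRATA_COLS[strata]
    if col not in cells.columns or "excluded" not in cells.columns:
        raise ValidationError("cells must be annotated with assign_topography first")
    df = cells[~cells["excluded"]].copy()
    if times is not None:
        df = df[df["t_h"].isin(list(times))]
    areas = _stratum_areas(motif, bscr, strata)
    icol = f"{channel}_intensity" if channel else None
    if icol is not None and icol not in df.columns:
        raise ValidationError(f"no column {icol!r} in cell table")
    rows = []
    for t in sorted(df["t_h"].unique()):
        sub_t = df[df["t_h"] == t]
        for stratum, area in areas.items():
            sub = sub_t[sub_t[col] == stratum]
            n = len(sub)
            naive = (
                float(sub["naive_hi"].mean()) if n and "naive_hi" in sub.columns else math.nan
            )
            rows.append(
                {
                    "t_h": t,
                    "stratum": stratum,
                    "n_cells": n,
                    "area_um2": area,
                    "density_per_mm2": (n / area * 1e6) if area > 0 else math.nan,
                    "naive_fraction": naive if n else math.nan,
                    "mfi": float(sub[icol].mean()) if (icol and n) else math.nan,
                }
            )
    return pd.DataFrame(rows)


def area_ratio_hi(
    image: np.ndarray,
    region_mask: np.ndarray,
    positive_threshold: float,
    hi_threshold: float,
) -> float:
    """Area ratio of hi-expressing to positive pixels inside a mask.

    ratio = #(pixels > hi_threshold) / #(pixels > positive_threshold)
    within region_mask; NaN when no positive pixels.  Used as the
    GFP-hi / GFP+ occupancy metric.
    """
    if hi_threshold < positive_threshold:
        raise ValidationError("hi_threshold must be >= positive_threshold")
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("region mask is empty")
    vals = np.asarray(image, dtype=float)[mask]
    n_pos = int((vals > positive_threshold).sum())
    if n_pos == 0:
        return math.nan
    return int((vals > hi_threshold).sum()) / n_pos


def _bscr_flag_at(bscr: BSCRMap, x: float, y: float) -> Optional[bool]:
    px = bscr.pixel_size
    c, r = int(round(x / px)), int(round(y / px))
    nr, nc = bscr.count.shape
    if not (0 <= c < nc and 0 <= r < nr) or bscr.count[r, c] < 0:
        return None
    return bool(bscr.positive[r, c])


def track_metrics(
    tracks: Sequence[Track],
    bscr: BSCRMap,
    interval: Optional[float] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-interval displacement and BSCR-border events for cell tracks.

    Each consecutive pair of retained samples forms one interval; when
    ``interval`` (h) is given, samples are subsampled onto that grid
    (nearest sample to each multiple of the interval), mirroring fixed
    frame spacings of time-lapse recordings.  Per interval: straight-line
    displacement (µm), path length along the raw samples, and a border
    event class from the BSCR flag at the two endpoints: stay_in,
    stay_out, in_to_out or out_to_in.  Tracks with fewer than two samples
    are skipped with a warning; endpoints off the valid map yield a None
    class.  Returns (per-interval table, summary counts per class).
    """
    rows = []
    n_skipped = 0
    for tr in tracks:
        t = np.asarray(tr.t, dtype=float)
        x = np.asarray(tr.x, dtype=float)
        y = np.asarray(tr.y, dtype=float)
        if t.size < 2:
            n_skipped += 1
            log.warning("track %s has a single sample; skipped", tr.track_id)
            continue
        if interval is None:
            idx = np.arange(t.size)
        else:
            grid = np.arange(t[0], t[-1] + 1e-9, interval)
            idx = np.unique([int(np.argmin(np.abs(t - g))) for g in grid])
            if idx.size < 2:
                idx = np.array([0, t.size - 1])
        for a, b in zip(idx[:-1], idx[1:]):
            disp = math.hypot(x[b] - x[a], y[b] - y[a])
            path = float(np.sum(np.hypot(np.diff(x[a : b + 1]), np.diff(y[a : b + 1]))))
            fa = _bscr_flag_at(bscr, x[a], y[a])
            fb = _bscr_flag_at(bscr, x[b], y[b])
            if fa is None or fb is None:
                event = None
            elif fa and fb:
                event = "stay_in"
            elif not fa and not fb:
                event = "stay_out"
            elif fa:
                event = "in_to_out"
            else:
                event = "out_to_in"
            rows.append(
                {
                    "track_id": tr.track_id,
                    "t_start_h": t[a],
                    "t_end_h": t[b],
                    "displacement_um": disp,
                    "path_length_um": path,
                    "event": event,
                }
            )
    table = pd.DataFrame(rows)
    summary = {
        "n_tracks": len(tracks) - n_skipped,
        "n_skipped": n_skipped,
        "events": (
            table["event"].value_counts(dropna=True).to_dict() if len(table) else {}
        ),
    }
    return table, summary


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over the slices of a z-stack (axis 0)."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValidationError(f"expected a non-empty 3D stack, got shape {stack.shape}")
    return stack.max(axis=0)


def detect_nuclei(
    image: np.ndarray,
    pixel_size: float,
    smoothing_sigma: float = 2.0,
    threshold_mode: Literal["otsu", "fixed"] = "otsu",
    threshold: Optional[float] = None,
    min_area_um2: float = 10.0,
    channel: str = "gfp",
) -> pd.DataFrame:
    """Segment nuclei from a single-channel fluorescence raster.

    Gaussian smoothing (sigma in µm) -> global threshold (Otsu or fixed)
    -> connected components; components below ``min_area_um2`` are
    discarded.  Returns a cell table with centroid (µm), area (µm²) and
    mean intensity of the raw image per component.  A blank image yields
    an empty table.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError(f"expected a 2D raster, got shape {img.shape}")
    cols = ["cell_id", "x_um", "y_um", "t_h", f"{channel}_intensity", "area_um2"]
    if img.max() == img.min():
        return pd.DataFrame(columns=cols)
    smoothed = filters.gaussian(img, sigma=smoothing_sigma / pixel_size, preserve_range=True)
    if threshold_mode == "otsu":
        thr = filters.threshold_otsu(smoothed)
    elif threshold_mode == "fixed":
        if threshold is None:
            raise ValidationError("threshold_mode='fixed' requires a threshold value")
        thr = threshold
    else:
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    labels = measure.label(smoothed > thr)
    rows = []
    for rp in measure.regionprops(labels, intensity_image=img):
        area = rp.area * pixel_size**2
        if area < min_area_um2:
            continue
        r, c = rp.centroid
        rows.append(
            {
                "cell_id": f"n{rp.label}",
                "x_um": c * pixel_size,
                "y_um": r * pixel_size,
                "t_h": 0.0,
                f"{channel}_intensity": float(rp.intensity_mean),
                "area_um2": float(area),
            }
        )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("cell_id", "x_um", "y_um", "t_h"):
        if col not in df.columns:
            raise ValidationError(f"cell table is missing required column {col!r}")
    return df


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path)
    for col in ("track_id", "t_h", "x_um", "y_um"):
        if col not in df.columns:
            raise ValidationError(f"track table is missing required column {col!r}")
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_h")
        out.append(
            Track(
                track_id=str(tid),
                t=sub["t_h"].to_numpy(dtype=float),
                x=sub["x_um"].to_numpy(dtype=float),
                y=sub["y_um"].to_numpy(dtype=float),
            )
        )
    return out
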
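"""Blastocyst epiblast arc geometry and the blastocyst-scaled curvature range.

The outer layer of the epiblast (Epi) in a peri-implantation mouse
blastocyst (E4.25-E4.50) approximates a shallow circular arc bounded by the
polar trophectoderm.  From the measured chord width ``w`` and cap height
``h`` of that arc (both in µm) the circumscribed radius follows from the
sagitta relation

    r = w**2 / (8 * h) + h / 2                                  [µm]

and from it the curvature (reported in mm**-1, i.e. 1000 / r), the arc
length ``2 * r * arcsin(w / (2 * r))`` and, when a cell count is available,
the linear cell density along the arc.  Pooling curvatures over a set of
blastocyst measurements yields the blastocyst-scaled curvature range
(BSCR): the interval of interface curvatures that naive pluripotent cells
experience in vivo, used downstream to flag substrate topography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlastocystMeasurement",
    "EpiGeometry",
    "BSCRRange",
    "epi_geometry",
    "bscr_from_measurements",
    "read_measurements",
    "geometry_table",
]

#: Published BSCR bounds (mm^-1) used as the package-wide default interval.
DEFAULT_BSCR_LOWER = 15.0
DEFAULT_BSCR_UPPER = 62.0
DEFAULT_BSCR_MEAN = 31.0
DEFAULT_BSCR_SD = 8.0


class ValidationError(ValueError):
    """Raised when an input fails a documented precondition."""


@dataclass(frozen=True)
class BlastocystMeasurement:
    """Chord width and cap height of the outer Epi arc, in µm.

    ``cell_count`` is the number of cells resolved along the arc, when the
    source image allowed counting; it is optional and only feeds the
    linear cell density.
    """

    width: float
    height: float
    cell_count: Optional[int] = None
    blastocyst_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.width > 0 and math.isfinite(self.width)):
            raise ValidationError(
                f"width must be positive and finite, got {self.width!r}"
                + (f" (blastocyst {self.blastocyst_id})" if self.blastocyst_id else "")
            )
        if not (self.height > 0 and math.isfinite(self.height)):
            raise ValidationError(
                f"height must be positive and finite, got {self.height!r}"
                + (f" (blastocyst {self.blastocyst_id})" if self.blastocyst_id else "")
            )
        if self.cell_count is not None and self.cell_count < 0:
            raise ValidationError(f"cell_count must be non-negative, got {self.cell_count!r}")


@dataclass(frozen=True)
class EpiGeometry:
    """Arc geometry derived from one blastocyst measurement.

    arc_radius and arc_length are in µm, curvature in mm^-1, cell_density
    in cells per µm of arc (None when no cell count was recorded).
    """

    arc_radius: float
    curvature: float
    arc_length: float
    cell_density: Optional[float] = None


@dataclass(frozen=True)
class BSCRRange:
    """Curvature interval (mm^-1) summarising a set of blastocysts.

    ``lower``/``upper`` bound the interval; ``mean``/``sd`` describe the
    underlying curvature sample.  A substrate point is BSCR+ when at least
    one of its directional curvatures lies strictly inside (lower, upper).
    """

    lower: float
    upper: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValidationError(
                f"require 0 < lower <= upper, got lower={self.lower}, upper={self.upper}"
            )

    def contains(self, kappa: float) -> bool:
        """Strict-interior membership test (the BSCR+ rule)."""
        return self.lower < kappa < self.upper


#: The published interval as a ready-made range object.
DEFAULT_BSCR = BSCRRange(
    lower=DEFAULT_BSCR_LOWER,
    upper=DEFAULT_BSCR_UPPER,
    mean=DEFAULT_BSCR_MEAN,
    sd=DEFAULT_BSCR_SD,
)


def epi_geometry(m: BlastocystMeasurement) -> EpiGeometry:
    """Compute arc radius, curvature, arc length and cell density.

    Uses the sagitta construction: the arc through the chord endpoints
    (±w/2, 0) and the apex (0, h) has radius w²/(8h) + h/2.  Curvature is
    returned in mm^-1 (1000 / radius_µm).

    Raises
    ------
    ValidationError
        If the measurement violates its invariants or the arcsin argument
        exceeds 1 (numerically impossible chord/radius combination).
    """
    w, h = m.width, m.height
    r = w * w / (8.0 * h) + h / 2.0
    ratio = w / (2.0 * r)
    if ratio > 1.0 + 1e-12:
        raise ValidationError(
            f"arcsin argument {ratio:.6g} > 1 for measurement "
            f"(width={w}, height={h}"
            + (f", id={m.blastocyst_id}" if m.blastocyst_id else "")
            + ")"
        )
    ratio = min(ratio, 1.0)
    arc_length = 2.0 * r * math.asin(ratio)
    curvature = 1000.0 / r
    density = None
    if m.cell_count is not None:
        density = m.cell_count / arc_length
    return EpiGeometry(
        arc_radius=r, curvature=curvature, arc_length=arc_length, cell_density=density
    )


def bscr_from_measurements(
    measurements: Sequence[BlastocystMeasurement],
    mode: Literal["minmax", "mean_sd"] = "minmax",
    k: float = 1.0,
) -> BSCRRange:
    """Pool per-blastocyst curvatures into a BSCR interval.

    mode="minmax" (default) takes the interval bounds as the extreme
    observed curvatures; mode="mean_sd" uses mean ∓ k·sd.  The sample mean
    and sd are reported either way.  Requires at least two measurements.
    """
    if len(measurements) < 2:
        raise ValidationError(
            f"need at least 2 measurements to define a curvature range, got {len(measurements)}"
        )
    kappas = np.array([epi_geometry(m).curvature for m in measurements], dtype=float)
    mean = float(kappas.mean())
    sd = float(kappas.std(ddof=1))
    if mode == "minmax":
        lower, upper = float(kappas.min()), float(kappas.max())
    elif mode == "mean_sd":
        if k < 0:
            raise ValidationError(f"k must be non-negative, got {k}")
        lower, upper = mean - k * sd, mean + k * sd
        if lower <= 0:
            raise ValidationError(
                f"mean - {k}*sd = {lower:.4g} <= 0; interval not a valid curvature range"
            )
    else:
        raise ValidationError(f"unknown mode {mode!r}; expected 'minmax' or 'mean_sd'")
    return BSCRRange(lower=lower, upper=upper, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_measurements(path) -> list[BlastocystMeasurement]:
    """Read blastocyst measurements from a delimited table.

    Expects columns ``width_um`` and ``height_um``; ``cell_count`` and
    ``blastocyst_id`` are optional.
    """
    df = pd.read_csv(path)
    for col in ("width_um", "height_um"):
        if col not in df.columns:
            raise ValidationError(f"measurement table is missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        cc = row.get("cell_count")
        out.append(
            BlastocystMeasurement(
                width=float(row["width_um"]),
                height=float(row["height_um"]),
                cell_count=None if cc is None or pd.isna(cc) else int(cc),
                blastocyst_id=str(row["blastocyst_id"]) if "blastocyst_id" in df.columns else None,
            )
        )
    return out


def geometry_table(measurements: Sequence[BlastocystMeasurement]) -> pd.DataFrame:
    """Per-blastocyst geometry as a tidy table (lengths µm, curvature mm^-1)."""
    rows = []
    for i, m in enumerate(measurements):
        g = epi_geometry(m)
        rows.append(
            {
                "blastocyst_id": m.blastocyst_id if m.blastocyst_id is not None else str(i),
                "width_um": m.width,
                "height_um": m.height,
                "cell_count": m.cell_count,
                "arc_radius_um": g.arc_radius,
                "curvature_mm1": g.curvature,
                "arc_length_um": g.arc_length,
                "cell_density_per_um": g.cell_density,
            }
        )
    return pd.DataFrame(rows)
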
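"""Closed-form auxiliary quantifications: ChIP percent input and teratoma volume.

Two small formulas that accompany the curvature analysis in downstream
characterisation: qPCR enrichment of immunoprecipitated chromatin relative
to a 10% input sample, and the caliper ellipsoid approximation of teratoma
volume.  Percent values stay on the printed scale (10 means 10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .geometry import ValidationError

__all__ = [
    "ChipMeasurement",
    "TeratomaMeasurement",
    "chip_percent_input",
    "normalize_to_h3",
    "teratoma_volume",
    "chip_table",
    "teratoma_table",
]


@dataclass(frozen=True)
class ChipMeasurement:
    """qPCR cycle thresholds of a ChIP reaction and its 10% input."""

    ct_input_10pct: float
    ct_chip: float
    ct_h3: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ct_input_10pct", "ct_chip"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if self.ct_h3 is not None and not math.isfinite(self.ct_h3):
            raise ValidationError(f"ct_h3 must be finite, got {self.ct_h3!r}")


@dataclass(frozen=True)
class TeratomaMeasurement:
    """Caliper width and length of a teratoma, in cm (width <= length)."""

    width: float
    length: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.length < 0:
            raise ValidationError(
                f"width and length must be non-negative, got ({self.width}, {self.length})"
            )


def chip_percent_input(m: ChipMeasurement) -> float:
    """Percent-input enrichment: 10 * 2**(ct_input_10pct - ct_chip).

    Equal CTs return exactly 10 (the input aliquot fraction); each extra
    ChIP cycle halves the result.
    """
    return 10.0 * 2.0 ** (m.ct_input_10pct - m.ct_chip)


def normalize_to_h3(percent_target: float, percent_h3: float) -> float:
    """Normalise a percent-input value to the total-H3 enrichment."""
    if percent_h3 <= 0:
        raise ValidationError(f"percent_h3 must be positive, got {percent_h3}")
    return percent_target / percent_h3


def teratoma_volume(m: TeratomaMeasurement) -> float:
    """Ellipsoid caliper volume: width**2 * length / 2 (cm^3)."""
    return m.width**2 * m.length / 2.0


def chip_table(df: pd.DataFrame) -> pd.DataFrame:
    """Batch percent-input (and H3-normalised ratio when ct_h3 present)."""
    out = df.copy()
    vals, ratios = [], []
    for _, row in df.iterrows():
        m = ChipMeasurement(
            ct_input_10pct=float(row["ct_input_10pct"]),
            ct_chip=float(row["ct_chip"]),
            ct_h3=float(row["ct_h3"]) if "ct_h3" in df.columns and pd.notna(row["ct_h3"]) else None,
        )
        pct = chip_percent_input(m)
        vals.append(pct)
        if m.ct_h3 is not None:
            h3 = chip_percent_input(
                ChipMeasurement(ct_input_10pct=m.ct_input_10pct, ct_chip=m.ct_h3)
            )
            ratios.append(normalize_to_h3(pct, h3))
        else:
            ratios.append(math.nan)
    out["percent_input"] = vals
    out["h3_normalized"] = ratios
    return out


def teratoma_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["volume_cm3"] = [
        teratoma_volume(TeratomaMeasurement(width=float(r["width_cm"]), length=float(r["length_cm"])))
        for _, r in df.iterrows()
    ]
    return out
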
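"""Synthetic topographies and cell populations with known ground truth.

Replaces micro-CT scans and microscopy with generators whose geometry and
statistics are analytically known, so that every stage of the curvature /
overlay pipeline can be validated without any imaging data:

* surfaces — a flat plane, square lattices of spherical micro-bowls
  (radial symmetry, curvature 1000/R mm^-1 at the cap bottom), parallel
  cylindrical micro-grooves (axial symmetry: curved across, flat along),
  and a seeded random micro-structured surface built from smooth pits and
  bumps, emulating spark-eroded moulds with randomly varied motifs;
* cells — an agent-based population seeded uniformly over the valid map
  area in the primed state; at each time step a primed cell reverts to
  the naive state with probability logistic(beta0 + beta1 * BSCR_count)
  at its position, cells divide as Bernoulli events at a state-specific
  rate and move by a reflected Gaussian random walk; fluorescence
  intensity is drawn per observation from state-specific lognormals.
  Reversion is irreversible by default (an optional relapse rate mimics
  inhibitor washout); apoptosis is off by default.

With no movement and equal division rates the naive fraction at horizon T
for cells sitting on BSCR count c has the closed form
1 - (1 - q_c)**(T/dt), q_c = logistic(beta0 + beta1 * c); the simulator
emits this expectation alongside the observable tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import ValidationError
from .topography import BSCRMap, HeightMap, MotifMap, MOTIF_INVALID

__all__ = [
    "SurfaceSpec",
    "SimulationParams",
    "SimulationResult",
    "make_surface",
    "simulate_cells",
    "render_images",
    "expected_naive_fraction",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """Recipe for a synthetic substrate height map.

    kind 'flat', 'microbowl_array', 'microgroove_array' or 'random_bms'.
    extent is (width, height) µm; sphere/cylinder radius, aperture and
    pitch are in µm; axis_angle (deg) orients grooves.  For 'random_bms',
    n_features smooth pits/bumps with lognormal amplitudes (sign random)
    and lateral extents are summed and low-pass filtered with
    smoothing_length.
    """

    kind: str
    extent: tuple[float, float] = (500.0, 500.0)
    pixel_size: float = 1.0
    radius: float = 32.0
    aperture: float = 60.0
    pitch: float = 100.0
    axis_angle: float = 0.0
    n_features: int = 25
    amplitude: float = 8.0
    amplitude_sd_log: float = 0.4
    lateral_extent: float = 35.0
    lateral_sd_log: float = 0.3
    smoothing_length: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "microbowl_array", "microgroove_array", "random_bms"):
            raise ValidationError(f"unknown surface kind {self.kind!r}")
        if self.extent[0] <= 0 or self.extent[1] <= 0 or self.pixel_size <= 0:
            raise ValidationError("extent and pixel_size must be positive")
        if self.kind in ("microbowl_array", "microgroove_array"):
            if self.aperture / 2.0 > self.radius:
                raise ValidationError(
                    f"infeasible cap: aperture/2 = {self.aperture / 2} µm exceeds "
                    f"radius {self.radius} µm"
                )


def _grid(spec: SurfaceSpec) -> tuple[np.ndarray, np.ndarray]:
    nx = int(round(spec.extent[0] / spec.pixel_size)) + 1
    ny = int(round(spec.extent[1] / spec.pixel_size)) + 1
    x = np.arange(nx) * spec.pixel_size
    y = np.arange(ny) * spec.pixel_size
    return np.meshgrid(x, y)  # (ny, nx) each


def _cap_depth(dist: np.ndarray, radius: float, half_aperture: float) -> np.ndarray:
    """Height deficit of a spherical/cylindrical cap cut into a plane.

    Inside the aperture the surface follows the sphere/cylinder of the
    given radius; outside it is 0.  Values are <= 0 (a pit)."""
    rim = math.sqrt(radius**2 - half_aperture**2)
    inside = dist < half_aperture
    z = np.zeros_like(dist)
    z[inside] = rim - np.sqrt(radius**2 - dist[inside] ** 2)
    return z


def make_surface(spec: SurfaceSpec) -> tuple[HeightMap, dict]:
    """Build the height map for a surface spec.

    Returns (HeightMap, info) where info carries the analytic curvature
    annotation where defined: nominal_kappa_mm1 = 1000/radius for bowl and
    groove arrays (at the feature bottom, across the groove), plus the
    feature lattice centres.
    """
    X, Y = _grid(spec)
    info: dict = {"kind": spec.kind}
    if spec.kind == "flat":
        Z = np.zeros_like(X)
    elif spec.kind == "microbowl_array":
        a = spec.aperture / 2.0
        cx = np.arange(spec.pitch / 2.0, spec.extent[0], spec.pitch)
        cy = np.arange(spec.pitch / 2.0, spec.extent[1], spec.pitch)
        Z = np.zeros_like(X)
        for yc in cy:
            for xc in cx:
                dist = np.hypot(X - xc, Y - yc)
                Z += _cap_depth(dist, spec.radius, a)
        info["nominal_kappa_mm1"] = 1000.0 / spec.radius
        info["centers_um"] = [(float(xc), float(yc)) for yc in cy for xc in cx]
    elif spec.kind == "microgroove_array":
        a = spec.aperture / 2.0
        phi = math.radians(spec.axis_angle)
        # signed distance across the groove axis direction (cos, sin)
        p = -X * math.sin(phi) + Y * math.cos(phi)
        offs = (p - spec.pitch / 2.0) % spec.pitch
        dist = np.abs(np.where(offs > spec.pitch / 2.0, offs - spec.pitch, offs))
        Z = _cap_depth(dist, spec.radius, a)
        info["nominal_kappa_mm1"] = 1000.0 / spec.radius
        info["axis_angle_deg"] = spec.axis_angle
    else:  # random_bms
        rng = np.random.default_rng(spec.seed)
        Z = np.zeros_like(X)
        for _ in range(spec.n_features):
            xc = rng.uniform(0, spec.extent[0])
            yc = rng.uniform(0, spec.extent[1])
            amp = rng.lognormal(math.log(spec.amplitude), spec.amplitude_sd_log)
            sign = rng.choice([-1.0, 1.0])
            w = rng.lognormal(math.log(spec.lateral_extent), spec.lateral_sd_log)
            Z += sign * amp * np.exp(-((X - xc) ** 2 + (Y - yc) ** 2) / (2.0 * w**2))
        if spec.smoothing_length > 0:
            from scipy.ndimage import gaussian_filter

            Z = gaussian_filter(Z, sigma=spec.smoothing_length / spec.pixel_size)
    return HeightMap(heights=Z, pixel_size=spec.pixel_size), info


# ---------------------------------------------------------------------------
# Cell population simulator


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the agent-based reversion/growth/migration model.

    beta0/beta1 set the per-step logistic reversion hazard as a function
    of the local BSCR count; g_naive >= g_primed are per-hour division
    rates (naive cells proliferate faster); sigma_move scales the random
    walk (µm per sqrt(h)); intensity_* are (log-mean, log-sd) of the
    lognormal fluorescence per state; dt and horizon are in hours.
    relapse_rate > 0 lets naive cells fall back per step (inhibitor
    scenario); it is 0 by default because reversion persists in the
    modelled system.
    """

    n0: int = 2000
    beta0: float = -4.0
    beta1: float = 0.25
    g_naive: float = 0.03
    g_primed: float = 0.02
    sigma_move: float = 1.0
    intensity_lo: tuple[float, float] = (math.log(100.0), 0.3)
    intensity_hi: tuple[float, float] = (math.log(1000.0), 0.3)
    dt: float = 1.0
    horizon: float = 24.0
    relapse_rate: float = 0.0
    channel: str = "gfp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValidationError(f"horizon must be positive, got {self.horizon}")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if min(self.g_naive, self.g_primed, self.sigma_move, self.relapse_rate) < 0:
            raise ValidationError("rates and step scales must be non-negative")
        if self.g_naive < self.g_primed:
            raise ValidationError("g_naive must be >= g_primed (naive cells divide faster)")
        if self.n0 < 1:
            raise ValidationError(f"n0 must be >= 1, got {self.n0}")


@dataclass
class SimulationResult:
    """Observable tables plus ground truth of one simulated run."""

    cells: pd.DataFrame  # cell_id, t_h, x_um, y_um, <channel>_intensity
    tracks: pd.DataFrame  # track_id, t_h, x_um, y_um
    truth: pd.DataFrame  # cell_id, t_h, true_state, true_bscr_count
    n_divisions: int
    params: SimulationParams = field(repr=False, default=None)  # type: ignore[assignment]


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def expected_naive_fraction(count: np.ndarray, p: SimulationParams) -> np.ndarray:
    """Closed-form naive fraction at the horizon for fixed BSCR count.

    Valid when cells do not change count over time (sigma_move = 0) and
    division does not bias state composition (g_naive = g_primed):
    1 - (1 - q_c)**n_steps with q_c the per-step logistic hazard.
    """
    n_steps = int(round(p.horizon / p.dt))
    q = _logistic(p.beta0 + p.beta1 * np.asarray(count, dtype=float))
    return 1.0 - (1.0 - q) ** n_steps


def _count_at(bscr: BSCRMap, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    px = bscr.pixel_size
    nr, nc = bscr.count.shape
    cc = np.clip(np.round(x / px).astype(int), 0, nc - 1)
    rr = np.clip(np.round(y / px).astype(int), 0, nr - 1)
    return bscr.count[rr, cc]


def simulate_cells(
    motif: MotifMap, bscr: BSCRMap, params: SimulationParams
) -> SimulationResult:
    """Run the agent-based reversion/growth/migration simulation.

    Cells are seeded uniformly over valid map pixels (primed state) and
    stepped to the horizon; observable tables record every cell at every
    step together with the matching ground truth.  Fully reproducible for
    a given (maps, params) pair.
    """
    rng = np.random.default_rng(params.seed)
    valid = motif.labels != MOTIF_INVALID
    rr, cc = np.nonzero(valid)
    if rr.size == 0:
        raise ValidationError("no valid pixels to seed cells on")
    px = motif.pixel_size
    pick = rng.integers(0, rr.size, size=params.n0)
    x = (cc[pick] + rng.uniform(-0.5, 0.5, params.n0)) * px
    y = (rr[pick] + rng.uniform(-0.5, 0.5, params.n0)) * px
    naive = np.zeros(params.n0, dtype=bool)
    ids = np.arange(params.n0)
    next_id = params.n0
    n_div = 0
    xmax, ymax = (motif.labels.shape[1] - 1) * px, (motif.labels.shape[0] - 1) * px

    n_steps = int(round(params.horizon / params.dt))
    times = np.arange(n_steps + 1) * params.dt
    mu_lo, sd_lo = params.intensity_lo
    mu_hi, sd_hi = params.intensity_hi
    cell_rows, truth_rows = [], []

    def record(t: float) -> None:
        counts = _count_at(bscr, x, y)
        mu = np.where(naive, mu_hi, mu_lo)
        sd = np.where(naive, sd_hi, sd_lo)
        inten = rng.lognormal(mu, sd)
        cell_rows.append(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in ids],
                    "t_h": t,
                    "x_um": x.copy(),
                    "y_um": y.copy(),
                    f"{params.channel}_intensity": inten,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in ids],
                    "t_h": t,
                    "true_state": np.where(naive, "naive", "primed"),
                    "true_bscr_count": counts,
                }
            )
        )

    record(0.0)
    p_div_naive = 1.0 - math.exp(-params.g_naive * params.dt)
    p_div_primed = 1.0 - math.exp(-params.g_primed * params.dt)
    for step in range(1, n_steps + 1):
        # reversion hazard from the BSCR count under the current position
        counts = _count_at(bscr, x, y)
        q = _logistic(params.beta0 + params.beta1 * counts.astype(float))
        revert = (~naive) & (rng.random(naive.size) < q)
        naive = naive | revert
        if params.relapse_rate > 0:
            relapse = naive & (rng.random(naive.size) < params.relapse_rate * params.dt)
            naive = naive & ~relapse
        # division (Bernoulli per step at the state's exponential rate)
        p_div = np.where(naive, p_div_naive, p_div_primed)
        divide = rng.random(naive.size) < p_div
        n_new = int(divide.sum())
        if n_new:
            n_div += n_new
            ang = rng.uniform(0.0, 2.0 * math.pi, n_new)
            rad = rng.uniform(0.0, 5.0, n_new)  # daughter within one cell diameter
            x = np.concatenate([x, np.clip(x[divide] + rad * np.cos(ang), 0, xmax)])
            y = np.concatenate([y, np.clip(y[divide] + rad * np.sin(ang), 0, ymax)])
            naive = np.concatenate([naive, naive[divide]])
            ids = np.concatenate([ids, np.arange(next_id, next_id + n_new)])
            next_id += n_new
        # reflected Gaussian random walk
        if params.sigma_move > 0:
            step_sd = params.sigma_move * math.sqrt(params.dt)
            x = x + rng.normal(0.0, step_sd, x.size)
            y = y + rng.normal(0.0, step_sd, y.size)
            x = np.abs(x)
            x = np.where(x > xmax, 2 * xmax - x, x)
            y = np.abs(y)
            y = np.where(y > ymax, 2 * ymax - y, y)
        record(float(times[step]))

    cells = pd.concat(cell_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    tracks = cells.rename(columns={"cell_id": "track_id"})[
        ["track_id", "t_h", "x_um", "y_um"]
    ].copy()
    return SimulationResult(
        cells=cells, tracks=tracks, truth=truth, n_divisions=n_div, params=params
    )


# ---------------------------------------------------------------------------
# Fluorescence rendering


def render_images(
    cells: pd.DataFrame,
    extent: tuple[float, float],
    pixel_size: float = 1.0,
    psf_sigma: float = 3.0,
    noise_sd: float = 0.0,
    channel: str = "gfp",
    seed: int = 0,
    footprint: str = "gaussian",
    disk_radius: float = 5.0,
) -> np.ndarray:
    """Render a cell table as a fluorescence raster.

    footprint="gaussian" (default) gives each cell a Gaussian spot of
    width psf_sigma (µm) and amplitude equal to its channel intensity —
    a point-source through a diffraction-limited optic.  footprint="disk"
    paints a uniform disk of disk_radius (µm) at the amplitude instead,
    modelling cells as extended objects of equal area; appropriate when
    thresholded pixel *areas* (rather than peak detection) are the readout.
    Additive Gaussian noise is applied and the result clipped at zero.
    Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    nx = int(round(extent[0] / pixel_size)) + 1
    ny = int(round(extent[1] / pixel_size)) + 1
    if footprint not in ("gaussian", "disk"):
        raise ValidationError(f"unknown footprint {footprint!r}")
    img = np.zeros((ny, nx))
    col = f"{channel}_intensity"
    reach = 4.0 * psf_sigma if footprint == "gaussian" else disk_radius
    win = max(1, int(math.ceil(reach / pixel_size)))
    for _, row in cells.iterrows():
        xc, yc = float(row["x_um"]), float(row["y_um"])
        amp = float(row[col])
        c0 = int(round(xc / pixel_size))
        r0 = int(round(yc / pixel_size))
        cs = slice(max(0, c0 - win), min(nx, c0 + win + 1))
        rs = slice(max(0, r0 - win), min(ny, r0 + win + 1))
        xs = np.arange(cs.start, cs.stop) * pixel_size
        ys = np.arange(rs.start, rs.stop) * pixel_size
        XX, YY = np.meshgrid(xs, ys)
        r2 = (XX - xc) ** 2 + (YY - yc) ** 2
        if footprint == "gaussian":
            img[rs, cs] += amp * np.exp(-r2 / (2.0 * psf_sigma**2))
        else:
            patch = img[rs, cs]
            inside = r2 <= disk_radius**2
            patch[inside] = np.maximum(patch[inside], amp)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, None)
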
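"""Beam-quality and profile metrics from 3-D dose grids.

Extracts central-axis percentage depth dose (PDD) curves and off-axis
profiles from :class:`~targetqa.dose_io.DoseGrid` objects and computes the
constancy metrics used to monitor a degrading photon target:

* ``PDD20,10`` — the 20 cm / 10 cm depth-dose ratio, a beam-quality index;
* ``Deviation_max`` — the largest relative off-axis-factor deviation of a
  test profile from its baseline, reported separately for the negative and
  positive half of the curve over the central 0.8 or 0.95 field-size region;
* ``flatness = (M - m)/(M + m) * 100%`` over the central 0.8 field size;
* ``beam_output`` — the interpolated central-axis dose at 10 cm depth
  (beyond the electron-contamination range).

Field-size regions are divergence-scaled to the evaluation depth by
``(SSD + z)/SSD`` because field size is defined at SSD 100.  Profiles are
conventionally resampled to a 1 mm grid (``resample``) and smoothed with an
adaptive second-order Savitzky-Golay filter before deviation and flatness
evaluation; the core metric functions operate on the samples they are
given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import savgol_filter

from .dose_io import DoseGrid

__all__ = [
    "PDDCurve",
    "ProfileCurve",
    "DeviationReport",
    "extract_pdd",
    "pdd_ratio_20_10",
    "extract_profile",
    "smooth_profile",
    "resample",
    "deviation_max",
    "flatness",
    "beam_output",
]


@dataclass
class PDDCurve:
    """Central-axis depth dose, normalized to 100 at its maximum."""

    depths: np.ndarray
    values: np.ndarray
    field_size: float
    raw_max: float
    z_of_max: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.shape != self.values.shape:
            raise ValueError("depths and values must have the same length")


@dataclass
class ProfileCurve:
    """1-D dose samples at signed distances from the CAX at fixed depth.

    ``axis`` is ``"x"``, ``"y"`` or ``"diagonal"``; diagonal positions are
    Euclidean distances from the CAX along the x = y line, signed by x.
    When ``normalized`` the values are off-axis factors (CAX value 1).
    """

    positions: np.ndarray
    values: np.ndarray
    depth: float
    field_size: float
    axis: str = "x"
    normalized: bool = True
    ssd: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        i_cax = int(np.argmin(np.abs(self.positions)))
        step = np.min(np.diff(self.positions)) if len(self.positions) > 1 else 0.0
        if abs(self.positions[i_cax]) > step / 2 + 1e-9:
            raise ValueError("profile must contain a CAX sample (position ~ 0)")
        if self.normalized and abs(self.values[i_cax] - 1.0) > 1e-6:
            raise ValueError("normalized profile must have CAX value 1")

    @property
    def cax_index(self) -> int:
        return int(np.argmin(np.abs(self.positions)))


@dataclass
class DeviationReport:
    """Per-side maximum profile deviation from baseline, in percent.

    ``negative``/``positive`` are magnitudes; the ``*_signed`` companions
    retain the sign of the extreme deviation.
    """

    negative: float
    positive: float
    negative_signed: float
    positive_signed: float
    region_fraction: float
    axis: str
    depth: float
    field_size: float


def _cax_interpolator(grid: DoseGrid):
    return RegularGridInterpolator(
        (grid.x_centers, grid.y_centers, grid.z_centers),
        grid.dose,
        method="linear",
        bounds_error=True,
    )


def extract_pdd(grid: DoseGrid, field_size: float = 10.0) -> PDDCurve:
    """Central-axis depth dose, bilinearly interpolated to (0, 0) per layer."""
    if not (grid.x_centers[0] <= 0.0 <= grid.x_centers[-1]) or not (
        grid.y_centers[0] <= 0.0 <= grid.y_centers[-1]
    ):
        raise ValueError("central axis (x = y = 0) lies outside the grid")
    interp = RegularGridInterpolator(
        (grid.x_centers, grid.y_centers),
        grid.dose,
        method="linear",
        bounds_error=True,
    )
    cax = interp((0.0, 0.0))  # dose along z
    i_max = int(np.argmax(cax))  # first occurrence = shallowest on ties
    raw_max = float(cax[i_max])
    if raw_max <= 0:
        raise ValueError("central-axis dose is zero everywhere")
    return PDDCurve(
        depths=grid.z_centers,
        values=100.0 * cax / raw_max,
        field_size=field_size,
        raw_max=raw_max,
        z_of_max=float(grid.z_centers[i_max]),
    )


def pdd_ratio_20_10(curve: PDDCurve) -> float:
    """Beam-quality index: depth-dose at 20 cm over depth-dose at 10 cm."""
    if curve.depths[0] > 10.0 or curve.depths[-1] < 20.0:
        raise ValueError("PDD curve must span depths 10-20 cm")
    v20 = float(np.interp(20.0, curve.depths, curve.values))
    v10 = float(np.interp(10.0, curve.depths, curve.values))
    return v20 / v10


def extract_profile(
    grid: DoseGrid,
    axis: str,
    depth: float,
    ssd: float = 100.0,
    field_size: float | None = None,
    normalize: bool = True,
) -> ProfileCurve:
    """Profile along x, y or the x = y diagonal at a fixed depth.

    Samples are taken at evenly spaced signed distances from the CAX with a
    step equal to the smallest in-plane voxel pitch (for the diagonal, the
    diagonal lattice pitch ``hypot(dx, dy)``), by linear interpolation on
    voxel centers.  ``normalize`` divides by the CAX value (OAF convention).
    """
    if axis not in ("x", "y", "diagonal"):
        raise ValueError("axis must be 'x', 'y' or 'diagonal'")
    if not (grid.z_centers[0] <= depth <= grid.z_centers[-1]):
        raise ValueError(f"depth {depth} cm outside grid z extent")
    interp = _cax_interpolator(grid)
    dx = float(np.min(np.diff(grid.x_centers)))
    dy = float(np.min(np.diff(grid.y_centers)))
    if axis == "x":
        step, reach = min(dx, dy), min(-grid.x_centers[0], grid.x_centers[-1])
        unit = (1.0, 0.0)
    elif axis == "y":
        step, reach = min(dx, dy), min(-grid.y_centers[0], grid.y_centers[-1])
        unit = (0.0, 1.0)
    else:
        step = math.hypot(dx, dy)
        reach = math.hypot(
            min(-grid.x_centers[0], grid.x_centers[-1]),
            min(-grid.y_centers[0], grid.y_centers[-1]),
        )
        s = 1.0 / math.sqrt(2.0)
        unit = (s, s)
    n = int(math.floor(reach / step + 1e-9))
    t = step * np.arange(-n, n + 1)
    pts = np.column_stack(
        (t * unit[0], t * unit[1], np.full(t.shape, float(depth)))
    )
    values = interp(pts)
    if normalize:
        cax = values[n]
        if cax <= 0:
            raise ValueError("CAX dose is zero; cannot normalize profile")
        values = values / cax
    return ProfileCurve(
        positions=t,
        values=values,
        depth=float(depth),
        field_size=float(field_size) if field_size is not None else float("nan"),
        axis=axis,
        normalized=normalize,
        ssd=ssd,
    )


def _adaptive_window(n: int) -> int:
    w = max(7, math.ceil(0.05 * n))
    return w if w % 2 == 1 else w + 1


def smooth_profile(curve):
    """Adaptive second-order Savitzky-Golay smoothing (positions unchanged).

    The window is the smallest odd integer >= 5% of the sample count,
    floored at 7; endpoints are handled by a polynomial fit on the
    truncated window.  Quadratic inputs pass through unchanged.
    """
    values = curve.values
    n = len(values)
    if n < 7:
        raise ValueError(f"need >= 7 samples to smooth, got {n}")
    smoothed = savgol_filter(values, _adaptive_window(n), 2, mode="interp")
    if getattr(curve, "normalized", False):
        smoothed = smoothed / smoothed[curve.cax_index]  # keep OAF(CAX) = 1
    return replace(curve, values=smoothed)


def resample(curve: ProfileCurve, step: float = 0.1) -> ProfileCurve:
    """Linearly resample a profile onto an evenly spaced grid containing 0.

    The 1 mm default mirrors the convention of interpolating scanned curves
    to a 1 mm grid before metric evaluation.
    """
    pos = curve.positions
    neg = -np.arange(step, -pos[0] + 1e-9, step)[::-1]
    posr = np.arange(0.0, pos[-1] + 1e-9, step)
    new_pos = np.concatenate([neg, posr])
    new_val = np.interp(new_pos, pos, curve.values)
    if getattr(curve, "normalized", False):
        cax = new_val[int(np.argmin(np.abs(new_pos)))]
        new_val = new_val / cax
    return replace(curve, positions=new_pos, values=new_val)


def _region_limit(curve: ProfileCurve, region_fraction: float) -> float:
    if math.isnan(curve.field_size):
        raise ValueError("curve has no field size; cannot locate the region")
    return (
        region_fraction
        * (curve.field_size / 2.0)
        * (curve.ssd + curve.depth)
        / curve.ssd
    )


def _side_max(dev: np.ndarray, positions: np.ndarray) -> tuple[float, float]:
    """(magnitude, signed) of the extreme deviation; ties go nearest the CAX."""
    if len(dev) == 0:
        return 0.0, 0.0
    mag = np.abs(dev)
    peak = mag.max()
    candidates = np.flatnonzero(mag >= peak - 1e-12)
    best = candidates[np.argmin(np.abs(positions[candidates]))]
    return float(peak), float(dev[best])


def deviation_max(
    test: ProfileCurve,
    baseline: ProfileCurve,
    region_fraction: float = 0.8,
) -> DeviationReport:
    """Maximum relative profile deviation from baseline, per curve side.

    ``max |TP - BP| / BP * 100%`` over baseline positions with
    ``|pos| <= region_fraction * (field_size / 2)`` (divergence-scaled to
    depth); the test curve is interpolated onto the baseline positions.
    One value is collected from the negative-axis side and one from the
    positive-axis side.
    """
    if test.axis != baseline.axis:
        raise ValueError(f"axis mismatch: {test.axis} vs {baseline.axis}")
    if not math.isclose(test.depth, baseline.depth, abs_tol=1e-6):
        raise ValueError("depth mismatch between test and baseline")
    if not (
        math.isnan(test.field_size)
        or math.isnan(baseline.field_size)
        or math.isclose(test.field_size, baseline.field_size)
    ):
        raise ValueError("field-size mismatch between test and baseline")
    r_lim = _region_limit(baseline, region_fraction)
    pos = baseline.positions
    bp = baseline.values
    tp = np.interp(pos, test.positions, test.values)
    in_region = np.abs(pos) <= r_lim + 1e-9
    if np.any(in_region & (bp <= 0)):
        raise ValueError("baseline profile is non-positive inside the region")
    dev = np.where(in_region, (tp - bp) / np.where(bp > 0, bp, 1.0) * 100.0, 0.0)
    neg = in_region & (pos < 0)
    posi = in_region & (pos > 0)
    neg_mag, neg_sgn = _side_max(dev[neg], pos[neg])
    pos_mag, pos_sgn = _side_max(dev[posi], pos[posi])
    return DeviationReport(
        negative=neg_mag,
        positive=pos_mag,
        negative_signed=neg_sgn,
        positive_signed=pos_sgn,
        region_fraction=region_fraction,
        axis=baseline.axis,
        depth=baseline.depth,
        field_size=baseline.field_size,
    )


def flatness(curve: ProfileCurve, region_fraction: float = 0.8) -> float:
    """``(M - m)/(M + m) * 100%`` over the central 0.8 field-size region."""
    r_lim = _region_limit(curve, region_fraction)
    pos = curve.positions
    if pos[0] > -r_lim + 1e-9 or pos[-1] < r_lim - 1e-9:
        raise ValueError("profile does not cover the central region")
    region = np.abs(pos) <= r_lim + 1e-9
    m_hi = float(curve.values[region].max())
    m_lo = float(curve.values[region].min())
    if m_hi + m_lo == 0:
        raise ValueError("degenerate profile: M + m = 0")
    return (m_hi - m_lo) / (m_hi + m_lo) * 100.0


def beam_output(grid: DoseGrid, depth: float = 10.0) -> float:
    """Interpolated CAX dose at 10 cm depth (un-normalized units)."""
    if not (grid.z_centers[0] <= depth <= grid.z_centers[-1]):
        raise ValueError(f"grid does not span depth {depth} cm")
    if not (grid.x_centers[0] <= 0.0 <= grid.x_centers[-1]) or not (
        grid.y_centers[0] <= 0.0 <= grid.y_centers[-1]
    ):
        raise ValueError("central axis lies outside the grid")
    return float(_cax_interpolator(grid)((0.0, 0.0, depth)))
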
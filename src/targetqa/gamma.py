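"""2-D gamma-index comparison of planar dose distributions.

The gamma index combines a dose-difference criterion (delta, % of the
normalization dose) and a distance-to-agreement criterion (DTA, mm): for
each reference point the test plane is searched within a radius of a few
DTA for the position minimizing

    gamma^2 = (dD / (delta * D_norm))^2 + (dr / DTA)^2

and the point passes when gamma <= 1.  This implementation is a global
gamma: the normalization dose is the reference-plane maximum, and points
below a low-dose cutoff (default 10% of the normalization) are excluded
from the pass-rate statistics.  The search interpolates the test plane
bilinearly on a grid of step DTA/10 out to a radius of 2 DTA (both
configurable); a brute-force fine search bounds the discretization error
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .dose_io import DosePlane

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "pass_rate_profile"]

#: numerical slack on the pass boundary so that an exact-delta offset passes
PASS_TOL = 1e-9


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: dose difference %, DTA mm, cutoff % and search detail."""

    dose_pct: float = 2.0
    dta_mm: float = 2.0
    cutoff_pct: float = 10.0
    interp_fraction: int = 10     # search step = DTA / interp_fraction
    max_radius_factor: float = 2  # search radius = factor * DTA

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose and DTA criteria must be positive")
        if not 0 <= self.cutoff_pct < 100:
            raise ValueError("cutoff must lie in [0, 100)")

    @property
    def dta_cm(self) -> float:
        return self.dta_mm / 10.0


@dataclass
class GammaResult:
    """Gamma map over the reference grid plus pass-rate summary."""

    gamma: np.ndarray                # NaN below the dose cutoff
    ax1_positions: np.ndarray
    ax2_positions: np.ndarray
    pass_rate: float                 # % of evaluated points with gamma <= 1
    n_evaluated: int
    n_passing: int
    criteria: GammaCriteria
    normalization: float


def _offsets(criteria: GammaCriteria) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dta = criteria.dta_cm
    step = dta / criteria.interp_fraction
    radius = criteria.max_radius_factor * dta
    n = int(round(radius / step))
    o = step * np.arange(-n, n + 1)
    ox, oy = np.meshgrid(o, o, indexing="ij")
    keep = ox**2 + oy**2 <= radius**2 + 1e-12
    dist2_dta2 = (ox[keep] ** 2 + oy[keep] ** 2) / dta**2
    return ox[keep], oy[keep], dist2_dta2


def gamma_map(
    reference: DosePlane,
    test: DosePlane,
    criteria: GammaCriteria = GammaCriteria(),
) -> GammaResult:
    """Global 2-D gamma of ``test`` against ``reference``.

    Every reference point at or above the low-dose cutoff is evaluated;
    search positions falling outside the test-plane extent are ignored.
    """
    lo1 = max(reference.ax1_positions[0], test.ax1_positions[0])
    hi1 = min(reference.ax1_positions[-1], test.ax1_positions[-1])
    lo2 = max(reference.ax2_positions[0], test.ax2_positions[0])
    hi2 = min(reference.ax2_positions[-1], test.ax2_positions[-1])
    if lo1 >= hi1 or lo2 >= hi2:
        raise ValueError("reference and test planes do not overlap")
    d_norm = float(reference.dose.max())
    if d_norm <= 0:
        raise ValueError("reference plane has zero maximum dose")

    interp = RegularGridInterpolator(
        (test.ax1_positions, test.ax2_positions),
        test.dose,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    ox, oy, dist2 = _offsets(criteria)
    dose_denom = (criteria.dose_pct / 100.0) * d_norm

    p1 = reference.ax1_positions
    p2 = reference.ax2_positions
    gamma = np.full(reference.dose.shape, np.nan)
    cutoff = criteria.cutoff_pct / 100.0 * d_norm
    eval_mask = reference.dose >= cutoff

    # evaluate row by row to bound the candidate-array size
    for i in range(len(p1)):
        cols = np.flatnonzero(eval_mask[i])
        if len(cols) == 0:
            continue
        pts1 = p1[i] + ox[None, :]                     # (ncols, K) broadcast
        pts2 = p2[cols][:, None] + oy[None, :]
        cand = np.stack(
            [np.broadcast_to(pts1, pts2.shape), pts2], axis=-1
        ).reshape(-1, 2)
        d_test = interp(cand).reshape(len(cols), -1)
        dd2 = ((d_test - reference.dose[i, cols][:, None]) / dose_denom) ** 2
        g2 = dd2 + dist2[None, :]
        g2 = np.where(np.isnan(g2), np.inf, g2)
        gamma[i, cols] = np.sqrt(g2.min(axis=1))

    evaluated = gamma[eval_mask]
    n_eval = int(eval_mask.sum())
    n_pass = int(np.sum(evaluated <= 1.0 + PASS_TOL))
    pass_rate = 100.0 * n_pass / n_eval if n_eval else float("nan")
    return GammaResult(
        gamma=gamma,
        ax1_positions=p1.copy(),
        ax2_positions=p2.copy(),
        pass_rate=pass_rate,
        n_evaluated=n_eval,
        n_passing=n_pass,
        criteria=criteria,
        normalization=d_norm,
    )


def pass_rate_profile(result: GammaResult, axis: str = "ax1") -> pd.DataFrame:
    """Gamma and pass flags along the central line of the map.

    ``axis='ax1'`` walks along the first plane axis at the second-axis
    position nearest zero, and vice versa.  Points below the dose cutoff
    carry NaN gamma and a False pass flag.
    """
    if axis not in ("ax1", "ax2"):
        raise ValueError("axis must be 'ax1' or 'ax2'")
    if axis == "ax1":
        j = int(np.argmin(np.abs(result.ax2_positions)))
        positions, line = result.ax1_positions, result.gamma[:, j]
    else:
        i = int(np.argmin(np.abs(result.ax1_positions)))
        positions, line = result.ax2_positions, result.gamma[i, :]
    return pd.DataFrame(
        {
            "position_cm": positions,
            "gamma": line,
            "passed": np.where(np.isnan(line), False, line <= 1.0 + PASS_TOL),
            "evaluated": ~np.isnan(line),
        }
    )
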
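"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from targetqa.beam_synth import BeamModelParams, water_phantom_grid
from targetqa.dose_io import DoseGrid, DosePlane
from targetqa.gamma import GammaCriteria
from targetqa.scenarios import builtin_library


@pytest.fixture(scope="session")
def params() -> BeamModelParams:
    """Default calibrated beam model."""
    return BeamModelParams()


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_grid(rng: np.random.Generator, shape=(5, 5, 5)) -> DoseGrid:
    """A random valid DoseGrid with irregular strictly increasing bounds."""
    bounds = []
    for n in shape:
        steps = rng.uniform(0.2, 1.5, size=n + 1)
        b = np.cumsum(steps) - steps[0] - rng.uniform(0, 5)
        bounds.append(b)
    dose = rng.uniform(0.0, 10.0, size=shape)
    rel_unc = rng.uniform(0.0, 0.05, size=shape)
    return DoseGrid(bounds[0], bounds[1], bounds[2], dose, rel_unc)


def aligned_phantom(field_size: float, depth: float = 22.0, dxy: float = 0.5,
                    dz: float = 0.5):
    """Grid whose voxel centers sit on 0.5 cm multiples incl. the CAX and
    the 1.5/5/10/20 cm reference depths, for closed-form comparisons."""
    return water_phantom_grid(
        half_width=field_size * 0.62 + 2.5, dxy=dxy, depth=depth, dz=dz,
        z_first_center=dz,
    )


def smooth_random_plane(rng: np.random.Generator, n: int = 20,
                        spacing: float = 0.5, smooth_px: float = 3.0) -> DosePlane:
    """A smooth, strictly positive random dose plane (PSQA-like surrogate)."""
    from scipy.ndimage import gaussian_filter

    values = gaussian_filter(rng.random((n, n)), sigma=smooth_px) + 0.5
    pos = spacing * (np.arange(n) - (n - 1) / 2.0)
    return DosePlane(pos, pos.copy(), values)


def brute_force_gamma(reference: DosePlane, test: DosePlane,
                      criteria: GammaCriteria, fine_fraction: int = 50
                      ) -> np.ndarray:
    """Exhaustive-search gamma oracle on a fine global grid.

    Upsamples the test plane bilinearly to a step of DTA / ``fine_fraction``
    and, for every above-cutoff reference point, scans every fine-grid
    position within the search radius.  Independent of the production
    search loop; reference positions must lie on the fine lattice.
    """
    from scipy.interpolate import RegularGridInterpolator

    dta = criteria.dta_cm
    step = dta / fine_fraction
    radius = criteria.max_radius_factor * dta
    d_norm = float(reference.dose.max())
    denom = criteria.dose_pct / 100.0 * d_norm
    cutoff = criteria.cutoff_pct / 100.0 * d_norm

    def fine_axis(pos):
        n = int(round((pos[-1] - pos[0]) / step))
        return np.linspace(pos[0], pos[0] + n * step, n + 1)

    f1 = fine_axis(test.ax1_positions)
    f2 = fine_axis(test.ax2_positions)
    interp = RegularGridInterpolator(
        (test.ax1_positions, test.ax2_positions), test.dose, method="linear"
    )
    F1, F2 = np.meshgrid(f1, f2, indexing="ij")
    fine = interp(np.column_stack([F1.ravel(), F2.ravel()])).reshape(F1.shape)

    w = int(round(radius / step))
    off = step * np.arange(-w, w + 1)
    kernel = (off[:, None] ** 2 + off[None, :] ** 2) / dta**2
    kernel = np.where(kernel <= criteria.max_radius_factor**2 + 1e-12,
                      kernel, np.inf)

    gamma = np.full(reference.dose.shape, np.nan)
    for i, p1 in enumerate(reference.ax1_positions):
        i_f = int(round((p1 - f1[0]) / step))
        for j, p2 in enumerate(reference.ax2_positions):
            d_ref = reference.dose[i, j]
            if d_ref < cutoff:
                continue
            j_f = int(round((p2 - f2[0]) / step))
            lo1, hi1 = max(i_f - w, 0), min(i_f + w + 1, len(f1))
            lo2, hi2 = max(j_f - w, 0), min(j_f + w + 1, len(f2))
            window = fine[lo1:hi1, lo2:hi2]
            kwin = kernel[lo1 - (i_f - w): hi1 - (i_f - w),
                          lo2 - (j_f - w): hi2 - (j_f - w)]
            g2 = ((window - d_ref) / denom) ** 2 + kwin
            gamma[i, j] = np.sqrt(g2.min())
    return gamma
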
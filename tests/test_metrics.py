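"""PDD/profile extraction and QA metric computations."""

import numpy as np
import pytest

from conftest import aligned_phantom
from targetqa.beam_synth import generate_field
from targetqa.dose_io import DoseGrid
from targetqa.metrics import (
    PDDCurve,
    ProfileCurve,
    beam_output,
    deviation_max,
    extract_pdd,
    extract_profile,
    flatness,
    pdd_ratio_20_10,
    resample,
    smooth_profile,
)


def constant_grid(value=1.0, n=11, pitch=1.0, nz=5):
    lateral = pitch * (np.arange(n + 1) - n / 2)
    z = np.arange(nz + 1, dtype=float)
    dose = np.full((n, n, nz), value)
    return DoseGrid(lateral, lateral.copy(), z, dose, np.zeros_like(dose))


def profile(positions, values, field_size=10.0, depth=10.0, axis="x",
            normalized=False):
    return ProfileCurve(np.asarray(positions, float), np.asarray(values, float),
                        depth=depth, field_size=field_size, axis=axis,
                        normalized=normalized)


# -- PDD --------------------------------------------------------------------

def test_pdd_matches_generator_law(params, library):
    spec = aligned_phantom(10.0, depth=22.0)
    sim = generate_field(library["NC"], 10.0, spec, params, noise=0.0)
    curve = extract_pdd(sim.grid)
    expected = 100.0 * params.pdd(curve.depths, 0.0)
    np.testing.assert_allclose(curve.values, expected / expected.max() * 100,
                               rtol=1e-9)
    assert curve.z_of_max == pytest.approx(params.z_max)
    assert np.sum(curve.values == 100.0) == 1


def test_pdd_normalization_at_first_layer_max():
    g = constant_grid(nz=6)
    g.dose[:, :, :] = np.linspace(3.0, 1.0, 6)[None, None, :]
    curve = extract_pdd(g)
    assert curve.values[0] == 100.0
    assert curve.z_of_max == g.z_centers[0]


def test_pdd_ratio_closed_forms():
    depths = np.linspace(0, 25, 251)
    expo = PDDCurve(depths, 100 * np.exp(-0.05 * depths), 10.0, 100.0, 0.0)
    assert pdd_ratio_20_10(expo) == pytest.approx(np.exp(-0.5), rel=1e-6)
    flat = PDDCurve(depths, np.full_like(depths, 100.0), 10.0, 100.0, 0.0)
    assert pdd_ratio_20_10(flat) == 1.0
    short = PDDCurve(depths[:100], expo.values[:100], 10.0, 100.0, 0.0)
    with pytest.raises(ValueError, match="span"):
        pdd_ratio_20_10(short)


def test_generator_nominal_beam_quality(params, library):
    """The nominal synthetic beam has PDD20,10 at the 0.58 design point."""
    spec = aligned_phantom(10.0, depth=22.0)
    sim = generate_field(library["NC"], 10.0, spec, params, noise=0.0)
    ratio = pdd_ratio_20_10(extract_pdd(sim.grid))
    assert ratio == pytest.approx(0.58, abs=1e-6)


# -- profile extraction -----------------------------------------------------

def test_flat_plane_gives_unit_oaf():
    g = constant_grid(5.0)
    for axis in ("x", "y", "diagonal"):
        curve = extract_profile(g, axis, depth=2.5, field_size=10.0)
        np.testing.assert_allclose(curve.values, 1.0, rtol=1e-12)


def test_linear_field_profile():
    g = constant_grid(1.0)
    x = g.x_centers
    g.dose[:, :, :] = (1.0 + 0.01 * x)[:, None, None]
    curve = extract_profile(g, "x", depth=2.5, field_size=10.0)
    np.testing.assert_allclose(curve.values, 1.0 + 0.01 * curve.positions,
                               rtol=1e-12)


def test_profile_matches_generator_oaf_law(params, library):
    """Noise off, extracted diagonal/x OAFs equal the closed-form law."""
    spec = aligned_phantom(30.0, depth=12.0)
    sim = generate_field(library["NC"], 30.0, spec, params, noise=0.0)
    for axis in ("x", "diagonal"):
        curve = extract_profile(sim.grid, axis, depth=10.0, field_size=30.0)
        t = curve.positions
        if axis == "x":
            xs, ys = t, np.zeros_like(t)
        else:
            xs = ys = t / np.sqrt(2.0)
        expected = params.oaf(xs, ys, 10.0, 30.0, 0.0)
        np.testing.assert_allclose(curve.values, expected, rtol=1e-9)


def test_profile_depth_guard(params, library):
    sim = generate_field(library["NC"], 10.0, aligned_phantom(10.0, depth=12.0),
                         params, noise=0.0)
    with pytest.raises(ValueError, match="outside grid"):
        extract_profile(sim.grid, "x", depth=40.0)


# -- smoothing --------------------------------------------------------------

def test_savgol_reproduces_quadratics_and_constants():
    pos = np.linspace(-10, 10, 101)
    quad = profile(pos, 1.0 + 0.02 * pos - 0.003 * pos**2)
    np.testing.assert_allclose(smooth_profile(quad).values, quad.values,
                               rtol=0, atol=1e-10)
    const = profile(pos, np.ones_like(pos))
    np.testing.assert_allclose(smooth_profile(const).values, 1.0, atol=1e-12)


def test_smoothing_reduces_noise_residual():
    """1% noise on a central-region profile: RMS residual drops >= 2x."""
    rng = np.random.default_rng(42)
    pos = np.linspace(-12, 12, 481)  # 0.5 mm steps, in-field region only
    truth = 1.0 + 0.09 * (pos / 16.5) ** 2
    noisy = truth * (1.0 + 0.01 * rng.standard_normal(truth.shape))
    smoothed = smooth_profile(profile(pos, noisy)).values
    rms = lambda v: np.sqrt(np.mean((v - truth) ** 2))
    assert rms(noisy) / rms(smoothed) >= 2.0


def test_smoothing_needs_enough_samples():
    with pytest.raises(ValueError, match=">= 7"):
        smooth_profile(profile(np.arange(5) - 2.0, np.ones(5)))


def test_resample_hits_one_mm_grid():
    pos = np.linspace(-5, 5, 21)
    curve = resample(profile(pos, 1.0 + 0.1 * np.abs(pos)))
    steps = np.diff(curve.positions)
    np.testing.assert_allclose(steps, 0.1, atol=1e-9)
    assert 0.0 in curve.positions


# -- deviation_max ----------------------------------------------------------

def test_deviation_identical_curves_zero():
    pos = np.linspace(-8, 8, 161)
    c = profile(pos, 1.0 + 0.05 * (pos / 8) ** 2)
    rep = deviation_max(c, c, 0.8)
    assert rep.negative == 0.0 and rep.positive == 0.0


def test_deviation_single_point_case():
    """One in-region +3% point on the positive side is found, signed."""
    pos = np.linspace(-6, 6, 121)
    base = profile(pos, np.ones_like(pos))
    values = np.ones_like(pos)
    values[np.argmin(np.abs(pos - 3.0))] = 1.03
    test = profile(pos, values)
    rep = deviation_max(test, base, 0.8)
    assert rep.positive == pytest.approx(3.0, abs=1e-9)
    assert rep.positive_signed == pytest.approx(3.0, abs=1e-9)
    assert rep.negative == 0.0


def test_deviation_region_superset(params, library):
    """The 0.95-region maximum can only exceed the 0.8-region maximum."""
    spec = aligned_phantom(30.0, depth=12.0)
    base = extract_profile(
        generate_field(library["NC"], 30.0, spec, params, noise=0.0).grid,
        "diagonal", 10.0, field_size=30.0)
    test = extract_profile(
        generate_field(library["W1"], 30.0, spec, params, noise=0.0).grid,
        "diagonal", 10.0, field_size=30.0)
    wide = deviation_max(test, base, 0.95)
    narrow = deviation_max(test, base, 0.8)
    assert max(wide.negative, wide.positive) >= max(narrow.negative,
                                                    narrow.positive)


def test_deviation_rescale_invariance():
    rng = np.random.default_rng(3)
    pos = np.linspace(-8, 8, 161)
    base = profile(pos, 1.0 + 0.05 * rng.random(pos.shape))
    test = profile(pos, 1.0 + 0.05 * rng.random(pos.shape))
    a = deviation_max(test, base, 0.8)
    scaled = deviation_max(
        profile(pos, 7.3 * test.values), profile(pos, 7.3 * base.values), 0.8
    )
    assert a.positive == pytest.approx(scaled.positive, rel=1e-12)
    assert a.negative == pytest.approx(scaled.negative, rel=1e-12)


def test_deviation_mismatch_errors():
    pos = np.linspace(-6, 6, 121)
    a = profile(pos, np.ones_like(pos), axis="x")
    b = profile(pos, np.ones_like(pos), axis="diagonal")
    with pytest.raises(ValueError, match="axis mismatch"):
        deviation_max(a, b)
    zero = profile(pos, np.zeros_like(pos))
    with pytest.raises(ValueError, match="non-positive"):
        deviation_max(a, zero)


# -- flatness ---------------------------------------------------------------

def test_flatness_closed_forms():
    pos = np.linspace(-6, 6, 121)
    assert flatness(profile(pos, np.ones_like(pos))) == 0.0
    # extremes 1.05 / 0.95 inside the region -> 5.0%
    values = np.ones_like(pos)
    values[np.argmin(np.abs(pos - 1.0))] = 1.05
    values[np.argmin(np.abs(pos + 1.0))] = 0.95
    assert flatness(profile(pos, values)) == pytest.approx(5.0)
    # invariant under uniform rescaling
    assert flatness(profile(pos, 3.7 * values)) == pytest.approx(5.0)


def test_flatness_region_not_covered():
    pos = np.linspace(-2, 2, 41)
    with pytest.raises(ValueError, match="cover"):
        flatness(profile(pos, np.ones_like(pos), field_size=30.0))


def test_flatness_matches_analytic_on_generated_field(params, library):
    spec = aligned_phantom(30.0, depth=12.0)
    sim = generate_field(library["NC"], 30.0, spec, params, noise=0.0)
    curve = extract_profile(sim.grid, "x", 10.0, field_size=30.0)
    got = flatness(curve)
    r_lim = 0.8 * 15.0 * 1.1
    region = np.abs(curve.positions) <= r_lim + 1e-9
    vals = params.oaf(curve.positions[region], 0.0, 10.0, 30.0, 0.0)
    expected = (vals.max() - vals.min()) / (vals.max() + vals.min()) * 100
    assert got == pytest.approx(expected, rel=1e-9)


# -- beam output ------------------------------------------------------------

def test_beam_output_closed_form_and_linearity(params, library):
    spec = aligned_phantom(10.0, depth=12.0)
    sim = generate_field(library["NC"], 10.0, spec, params, noise=0.0)
    got = beam_output(sim.grid)
    expected = float(
        params.output_factor(library["NC"])
        * params.head_scatter(10.0)
        * params.pdd(10.0, 0.0)
    )
    assert got == pytest.approx(expected, rel=1e-12)
    doubled = DoseGrid(sim.grid.x_bounds, sim.grid.y_bounds, sim.grid.z_bounds,
                       2 * sim.grid.dose, sim.grid.rel_unc)
    assert beam_output(doubled) == pytest.approx(2 * got, rel=1e-12)
    assert beam_output(sim.grid) == got  # deterministic
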
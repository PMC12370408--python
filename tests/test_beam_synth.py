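"""Synthetic beam generator: determinism, closed forms, calibration anchors."""

import numpy as np
import pytest

from conftest import aligned_phantom
from targetqa.beam_synth import (
    GridSpec,
    RCH_FIXTURE,
    generate_field,
    generate_plane_pair,
    rch_model,
    water_phantom_grid,
)
from targetqa.metrics import beam_output
from targetqa.scenarios import DegradationScenario


def small_grid():
    return water_phantom_grid(half_width=6, dxy=1.0, depth=12, dz=1.0,
                              z_first_center=1.0)


def test_same_seed_identical_fields(params, library):
    spec = small_grid()
    a = generate_field(library["D0.6"], 10.0, spec, params, rng=7)
    b = generate_field(library["D0.6"], 10.0, spec, params, rng=7)
    assert np.array_equal(a.grid.dose, b.grid.dose)
    c = generate_field(library["D0.6"], 10.0, spec, params, rng=8)
    assert not np.array_equal(a.grid.dose, c.grid.dose)


def test_nominal_cax_matches_pdd_law(params, library):
    """Noise off: the central-axis depth curve is exactly the PDD law."""
    spec = aligned_phantom(10.0, depth=22.0)
    sim = generate_field(library["NC"], 10.0, spec, params, noise=0.0)
    g = sim.grid
    i0 = int(np.argmin(np.abs(g.x_centers)))
    j0 = int(np.argmin(np.abs(g.y_centers)))
    cax = g.dose[i0, j0, :]
    expected = params.pdd(g.z_centers, 0.0)
    np.testing.assert_allclose(cax / cax.max(), expected / expected.max(),
                               rtol=1e-12)
    # depth of maximum dose at the design z_max
    assert g.z_centers[np.argmax(cax)] == pytest.approx(params.z_max)


def test_rel_unc_filled_with_noise_sigma(params, library):
    sim = generate_field(library["NC"], 10.0, small_grid(), params, noise=0.02)
    assert np.all(sim.grid.rel_unc == 0.02)


@pytest.mark.parametrize("name, value", sorted(RCH_FIXTURE.items()))
def test_rch_fixture_values(name, value):
    assert rch_model(name, fixture=True) == value


def test_rch_model_properties(params, library):
    assert rch_model("NC", fixture=True) == 1.0
    assert rch_model(library["NC"], params) == 1.0
    with pytest.raises(KeyError, match="no fixture"):
        rch_model("D0.2", fixture=True)
    # monotone decreasing with severity in the tungsten regime
    ladder = [rch_model(library[n], params)
              for n in ("D0.1", "D0.3", "D0.5", "D0.6", "D0.7", "W1", "W2")]
    assert all(a > b for a, b in zip(ladder, ladder[1:]))
    # partial recovery beyond full penetration
    assert rch_model(library["Z2"], params) > rch_model(library["WC"], params)


def test_output_anchor_calibration(params, library):
    """Noise off, the generated beam-output losses hit the anchor values."""
    spec = aligned_phantom(10.0, depth=12.0)
    out = {}
    for scen in (library["NC"], library["D0.6"],
                 DegradationScenario("D0.7W2.0", 0.7, 2.0)):
        sim = generate_field(scen, 10.0, spec, params, noise=0.0)
        out[scen.name] = beam_output(sim.grid)
    dev_d06 = (out["D0.6"] / out["NC"] - 1.0) * 100.0
    dev_d07w2 = (out["D0.7W2.0"] / out["NC"] - 1.0) * 100.0
    assert dev_d06 == pytest.approx(-5.7, abs=0.15)
    assert dev_d07w2 == pytest.approx(-24.1, abs=0.5)


def test_burn_through_regime(params, library):
    """Output collapses at WC and partially recovers at Z2/Z3."""
    o = {n: params.output_factor(library[n]) for n in ("W2", "WC", "Z2", "Z3")}
    assert o["WC"] == pytest.approx(0.029, abs=0.002)  # -97.1% output
    assert o["Z2"] == pytest.approx(0.5, abs=0.05)
    assert o["Z3"] == pytest.approx(0.5, abs=0.05)
    assert o["WC"] < o["W2"] < o["Z2"]


def test_wedge_field_gradient(params, library):
    """Wedged over open dose is the exponential transmission profile."""
    spec = small_grid()
    wedged = generate_field(library["NC"], 10.0, spec, params, wedge=True,
                            noise=0.0)
    open_f = generate_field(library["NC"], 10.0, spec, params, noise=0.0)
    j0 = int(np.argmin(np.abs(wedged.grid.y_centers)))
    ratio = wedged.grid.dose[:, j0, 5] / open_f.grid.dose[:, j0, 5]
    expected = params.wedge_profile(wedged.grid.x_centers)
    np.testing.assert_allclose(ratio, expected, rtol=1e-12)
    assert np.all(np.diff(ratio) < 0)  # monotone along the wedge axis


def test_field_size_and_grid_guards(params, library):
    with pytest.raises(ValueError, match=r"\[3, 30\]"):
        generate_field(library["NC"], 40.0, small_grid(), params)
    with pytest.raises(ValueError, match="2e6"):
        GridSpec(np.arange(200), np.arange(200), np.arange(200))


def test_plane_pair_nominal_identity(params, library):
    fluence = np.zeros((41, 41))
    fluence[10:31, 10:31] = 1.0
    ref, test = generate_plane_pair(library["NC"], fluence, params, noise=0.0)
    np.testing.assert_allclose(ref.dose, test.dose, atol=1e-12)


def test_plane_pair_center_rescale_and_sag(params, library):
    """Degraded pair: equal at the center, sagging away from it."""
    fluence = np.ones((41, 41))
    ref, test = generate_plane_pair(library["W2"], fluence, params, noise=0.0)
    i0 = j0 = 20
    assert test.dose[i0, j0] == pytest.approx(ref.dose[i0, j0], rel=1e-12)
    ratio = test.dose[i0, j0:] / ref.dose[i0, j0:]
    assert np.all(np.diff(ratio) < 1e-12)   # decreasing with distance
    assert ratio[-1] < 1.0


def test_plane_pair_rejects_empty_fluence(params, library):
    with pytest.raises(ValueError, match="empty"):
        generate_plane_pair(library["NC"], np.zeros((0, 0)), params)
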
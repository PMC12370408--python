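# Methods

## The problem being modeled

A medical linac produces its photon beam by slamming accelerated electrons
into a two-layer target: a 0.889 mm tungsten button on a 1.575 mm copper
base.  Prolonged IMRT-era beam time melts and recrystallizes the tungsten at
the focal spot, leaving roughly cylindrical holes 1–2 mm wide.  The package
represents one hole as a `DegradationScenario(depth, width)` and carries a
built-in library of twelve named conditions spanning nominal (NC), graded
tungsten erosion (D0.1–D0.7 at 1 mm width, plus 2 mm variants), full
tungsten burn-through (W1, W2), burn-through 1 mm into the copper (WC) and
full two-layer penetration (Z2, Z3).

All of the *analysis* machinery (3ddose I/O, metric extraction, correction
chain, gamma, detection rules) works on any rectilinear dose grid.  The
*generator* exists so that the full pipeline can be exercised, calibrated
and tested at desk scale without Monte Carlo particle transport.

## Severity scale

Degradation is collapsed to one non-negative scalar

    sev = (depth / t_W)^a · (width / w0)^b ,   a = 3, b = 0.5, w0 = 1 mm,

zero for the nominal target and 1 at W1 (full tungsten burn-through, 1 mm
hole).  The cubic depth exponent against the square-root width exponent
encodes the observed asymmetry — output falls sharply with hole depth but
only gently with width.  The exponents are generator calibration knobs, not
measured quantities; the monotonicity of the scale (strict in depth,
non-decreasing in width) is a tested invariant for any positive exponents.

## Synthetic beam law

A generated water-phantom dose grid samples the separable law

    D(x, y, z) = O(sev) · S(f) · PDD(z; sev) · OAF(x, y, z; f, sev)
                 [· W(x)] · (1 + σ ε)

with the following pieces (defaults in brackets; all distances cm):

* **Depth dose.**  `PDD(z) = (1 − e^{−βz}) e^{−μ_eff z}`, renormalized to 1
  at its maximum.  `μ0` is fixed by the nominal beam-quality design point
  PDD₂₀,₁₀ = 0.58 (`μ0 = −ln 0.58 / 10 ≈ 0.0545 cm⁻¹`) and the build-up
  rate β is solved so the nominal depth of maximum dose is z_max [1.5 cm].
  Degradation softens the beam: `μ_eff = μ0 (1 + κ_soft · sev^{q_soft})`.
* **Profile.**  `OAF = clip(1 + h(f, sev) (r/r_f)^p, 0) · edge(r, z)`, a
  flattened profile with horns of amplitude `h` and radial exponent p [2].
  `r_f(z) = (f/2)(SSD + z)/SSD` is the divergence-scaled field radius and
  the edge is a sigmoid of width σ_p [0.4 cm] in `r_f − r`, normalized to 1
  at r = 0 so that OAF(CAX) = 1 exactly and the central-axis dose follows
  the PDD law identically (several closed-form tests rely on this).  Horn
  amplitude grows with field size, `h = h0 (1 + 0.04 (f − 10))`
  [h0 = 0.05], which makes 30 cm profile metrics strictly more sensitive
  than 10 cm ones while keeping nominal 30 cm flatness below 3 %.
  Degradation sags the horns: `h → h (1 − κ_horn · sev^{q_horn})`, allowed
  to go negative (rounded profile) down to −h.
* **Output.**  `O(sev) = 1 − κ_out · sev^{q_out}` in the tungsten regime,
  floored at 0.01.  `S(f) = 1 + 0.028 ln(f/10)` is a head-scatter factor
  carrying the field-size output dependence (so relative output factors
  grow with field size independently of the profile shape).
* **Wedge.**  `W(x) = t_w e^{−τx}` [t_w = 0.55, τ = 0.04 cm⁻¹], a pure
  transmission gradient for the 30° physical wedge; the wedge geometry
  itself is not modeled.
* **Noise.**  Multiplicative Gaussian, truncated at ±5σ, per voxel
  [σ = 0.01], the type-A uncertainty level the emulated Monte Carlo runs
  were designed to reach; the `rel_unc` grid is filled with σ.  All
  randomness flows through one seeded generator.

### Calibration

The couplings are (κ, q) power-law pairs solved in closed form, at
parameter construction, from published anchor values of the study this
generator emulates (they are reproduction targets *by construction*, not
independent predictions):

| coupling | anchors |
|---|---|
| κ_out, q_out | output −5.7 % at D0.6, −24.1 % at D0.7W2.0 |
| κ_horn, q_horn | 30 cm diagonal horn sag 3.8 % / 5.9 % at the same two scenarios, evaluated at the 0.95 field-size region edge |
| κ_soft, q_soft | PDD₂₀,₁₀ change −0.9 % at W1, −2.8 % at W2 |
| κ_ch, q_ch | chamber response R_ch 0.945 at D0.6, 0.453 at W1 |

A single (κ, q) pair per effect is the minimal law through two anchors; a
linear-in-severity coupling cannot hit both ends of any anchor pair.  The
softening and horn couplings saturate at severity 2 (just above W2):
beyond tungsten burn-through the spectrum change is a regime switch, not a
continuation of the power law, and without the cap the Z2/Z3 severities
(≈ 30–37) drive the attenuation to unphysical values.

**Beyond burn-through** (depth > tungsten thickness), output and chamber
response follow a piecewise-linear regime table in the copper-penetration
fraction: collapse at the studied 1 mm copper burn (O ≈ 0.029,
R_ch ≈ 0.031 — the monitor chamber sees ~32× its baseline dose because the
thin copper remnant acts as an unfiltered thin target) and partial recovery
at full penetration (O ≈ 0.5, R_ch ≈ 0.41, the primary electrons now
striking the flattening filter).  `rch_model` also has a fixture mode that
returns the ten published reference ratios verbatim for factor tables.

### What the generator does *not* emulate

No bremsstrahlung physics, flattening-filter or MLC geometry, electron
contamination, or beam-steering asymmetry.  The OAF law is radially
symmetric, so diagonal and x/y profiles differ only through the region
geometry — the observed diagonal-vs-x sensitivity difference of real
square fields is *not* reproduced, and symmetry metrics are out of scope.
Passing tests therefore demonstrate that the pipeline recovers structure
of this class (output loss, horn sag, softening, periphery gamma
failures) from noisy grids, not that real target degradation follows
these exact functional forms.

## Metric conventions

* Voxel centers are boundary midpoints; all sampling interpolates linearly
  on centers.  Plane extraction picks the nearest layer, ties toward the
  smaller coordinate.
* PDDs interpolate dose to the CAX per depth layer and normalize to 100 at
  the maximum (ties to the shallowest depth).  Beam output is the CAX dose
  at 10 cm depth, beyond the electron-contamination range.
* Profiles are sampled at evenly spaced signed distances from the CAX
  (step = in-plane voxel pitch; on the diagonal, the diagonal lattice
  pitch `hypot(dx, dy)`, which keeps samples on voxel centers), normalized
  to the CAX value.  Field-size regions (0.8/0.95) are divergence-scaled
  to depth by (SSD + z)/SSD because field size is defined at SSD 100.
* The processing chain before deviation/flatness evaluation is: resample
  to a 1 mm grid (mirroring scanned-curve practice), then second-order
  Savitzky–Golay smoothing with an adaptive window — the smallest odd
  integer ≥ 5 % of the sample count, floored at 7 ("adaptive" is
  otherwise unspecified; this rule scales the window with curve length).
  Smoothed OAF curves are renormalized to 1 at the CAX.
* `Deviation_max` is reported as a magnitude with a signed companion
  (the defining formula is signed; published usage is magnitude-like), one
  value per curve side, ties broken toward the CAX.
* The gamma implementation is a global gamma (normalization = reference
  maximum, 10 % low-dose cutoff) searching a bilinear interpolation of the
  test plane at step DTA/10 within radius 2·DTA.  A brute-force
  exhaustive search at step DTA/50 bounds the discretization error to
  ≤ 0.02 per point in the test suite; because the search grid scales with
  DTA, the "looser criteria never increase γ" property holds exactly for
  the dose criterion and to ≤ 0.02 for DTA.
* The Friedman test uses within-block ranks (mean ranks on ties) and the
  rank-sum chi-square statistic referred to χ²(k−1); an exact permutation
  oracle on small inputs and scipy's implementation on tie-free data are
  test-suite cross-checks.
* Uncertainty on absolute dose propagates in first-order quadrature of
  the relative terms (simulation, chamber ratio, calibration).
* Backscatter factors are inputs, not recomputed (they require jaw-scatter
  transport): a monotone default table normalized to 1 at the 10 cm field
  ships with the package, and degraded-target values are taken equal to
  nominal ones (they differ by < 1 %).

## Plan-level (PSQA) surrogate

`generate_plane_pair` convolves a fluence map with a small Gaussian dose
kernel under the nominal beam (reference) and the degraded beam (test),
rescaling the test plane to the reference at the plane center — mirroring
the clinical reality that daily output recalibration hides the absolute
loss, so degradation survives only as a relative sag growing away from the
center.  The effective field size and sag radial scale are derived from
the fluence support (the sag is a property of the delivered field, not of
the scoring plane).  The analysis scripts use a pelvic-arc-like elliptical
target (11 × 8 cm half-axes on a 30 cm plane, 0.5 cm spacing); under
2 %/2 mm global gamma the failures concentrate in the field periphery and
the pass rate falls monotonically with severity.

## Problem sizes and determinism

Analyses and tests run on grids of roughly 30–600 k voxels (0.5 cm lateral
pitch, 0.5 cm depth pitch to 12–22 cm), which resolves every metric while
keeping a full scenario sweep in seconds; grid specs are validated to stay
under 2 M voxels.  Replicated quantities in `scripts/acceptance.py`
average 3–10 independent seeded grid pairs; the 30 cm profile runs use a
3× smaller per-voxel σ, mirroring the emulated study's larger scoring
voxels in the 30 cm flat region.  Every random quantity derives from an
integer seed through `numpy` seed sequences; identical seeds give
bit-identical grids, sweeps and reports.

## Known limitations

* The severity law and its couplings interpolate between published anchor
  scenarios; between-anchor values (e.g. D0.5) are model interpolations
  with no independent validation.
* The chamber-response model is smooth in severity and deviates from the
  published table at intermediate scenarios (e.g. W2: model 0.25 vs
  reference 0.31); factor-table work should use the fixture values.
* Wedge factors are severity-independent by construction, so WF deviations
  from the pipeline reflect noise only — consistent with WF being an
  insensitive detection metric, but not a test of wedge physics.
* The gamma search interpolates bilinearly; sub-voxel dose structure
  between plane nodes is invisible to both the production search and the
  oracle.
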
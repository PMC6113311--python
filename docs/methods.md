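# Methods

## Transport model

Electrons are tracked one elastic collision at a time.  Between
collisions the trajectory is a straight segment along which the energy
decreases continuously (continuous-slowing-down approximation) at the
Joy–Luo-modified Bethe rate,

    dE/ds = 7.85e-3 * rho / E * sum_i w_i (Z_i/A_i) ln(1.166 (E + k J_i)/J_i)
    J_i   = (9.76 Z_i + 58.5 Z_i^-0.19) * 1e-3 keV,   k = 0.77,

with Bragg additivity over elements (mass fractions w_i, density rho in
g/cm³, lengths in nm, energies in keV).  Free paths are exponential with
the local elastic mean free path `1 / sum_i n_i sigma_i(E)`.

Two elastic models are available:

- `rutherford`: the screened-Rutherford analytic cross section with
  relativistic factor, `sigma = 5.21e-21 Z²/E² · 4π/(α(1+α)) ·
  ((E+511)/(E+1024))²` cm², `α = 3.4e-3 Z^0.67/E`, used for both the
  collision rate and the angular law `cosθ = 1 − 2αu/(1+α−u)`.
- `browning` (default): collision rates from Browning's empirical fit to
  tabulated Mott partial-wave totals, `sigma = 3e-18 Z^1.7 / (E +
  0.005 Z^1.7 √E + 0.0007 Z²/√E)` cm², with the screened-Rutherford
  angular law.  For light elements the two totals are similar; for heavy
  elements at ~1 keV the analytic total is several times too large
  (for Pb at 1 keV: 0.151 vs 0.037 nm²), which matters directly for the
  absolute contrast of a lead stain.

A trajectory ends backscattered (exits through the block face with more
than the 50 eV tracking cutoff), absorbed (energy reaches the cutoff), or
escaped through a side or the bottom.  The detector model counts every
top-surface escape, scaled by a collection efficiency (default 1.0, no
angular restriction).  The test suite anchors the transport where the
analytic model is trustworthy: bulk carbon at 10 keV backscatters ~6% of
incident electrons, the canonical experimental value.

Known bias, and why it is tolerated: at 1.0–1.4 keV the screened-
Rutherford angular shape sends too much flux into large angles, so
absolute yields of both the resin background and the stain signal come
out roughly 1.5–1.7× larger than partial-wave-based transport (the
acceptance benchmark records a ~9.5% stain signal against the published
5.8%).  Correcting this would require tabulated Mott differential cross
sections, which are deliberately out of scope; the cross-section model is
pluggable for anyone who has them.  The reconstruction itself is
calibrated and applied within one self-consistent model, so recovered
densities are unbiased to within the interlayer coupling discussed below
— but absolute yield comparisons against other simulators carry that
factor.

## Stain and material conventions

Stain density S is expressed in heavy atoms per nm³ throughout.  A voxel
with stain density S is realized physically as the base resin (Epon-like,
H 0.53 / C 0.35 / O 0.12 at 1.22 g/cm³, 110.3 atoms/nm³) plus S lead
atoms per nm³, with the mass density increased by the added lead.  The
package default for "3 at% lead" is the nominal 3.24 atoms/nm³; the two
printed conversion conventions (stain added to the resin's atom count, or
as a fraction of the total) bracket this value and both are provided.
The bulk benchmark material "3 at% Pb at 1.52 g/cm³" is instead built
with conventional compound semantics (fractions of the total atom count
at the stated density, giving 2.17 Pb/nm³); the two constructions are
kept because published stain-density figures mix them.

## Calibration

`A[m, n]` is measured from laterally infinite single-layer stained slabs
(stain in layer n only, at the calibration density) against an unstained
reference: `A[m, n] = (eta_stained − eta_bg) / (S dz)`, units nm².
Slabs rather than finite cuboids avoid lateral point-spread edge losses;
the trade-off is that A describes the plateau response, so structures
narrower than ~2× the lateral spread (~±50 nm at 1.4 keV) recover below
their true density near edges.  Defaults: dz = 12.5 nm, S = 3.24 /nm³,
2×10⁵ electrons per target (coefficient standard errors ~2% for the
smallest element), energies (1.0, 1.4) keV.

The additive forward model `eta = dz · A S` neglects one real effect:
stain in layer 1 attenuates the marginal visibility of layer 2 at the
high energy.  With both layers stained at half density this biases the
recovered lower sub-slice density by about −5 to −9%; single-occupied
layers are unbiased within statistics.  The property tests bound this
coupling explicitly.

Energy-pair selection from a measured depth-response table: E_low is the
lowest feasible energy whose layer-1 share of total stain signal is at
least 80% (default; 1.0 keV for 12.5-nm layers), E_high the energy whose
layer-2/layer-1 ratio is closest to one, restricted to energies where
layers 3+ contribute at most 10% of the signal.  The restriction is what
keeps a two-layer inversion honest: without it the rule drifts to ever
higher energies where the ratio passes through one but deep layers leak
into both sub-slices.  Near the contamination boundary the choice between
1.4 and 1.5 keV is within calibration noise.

Inversion requires a condition number below 50 (ample for the 2×2 case,
cond ≈ 5) and verifies `‖A·A⁻¹ − I‖ < 1e-10`.  Matrices larger than 2×2
are representable, but deep-layer coefficients approach zero at practical
energies and the condition gate rejects them — matching the method's
published restriction to N = 2.

## Synthetic data

The generator emulates: interleaved dual-energy acquisition (low then
high energy per cut), a delta-function probe at pixel centers (optional
Gaussian), Poisson shot noise at the published operating point (~1,000
electrons per pixel per image, 13–15 e/nm² total fluence on 12.5-nm
pixels), an ideal BSE detector, and grid-aligned cuboid stain geometries
(the depth ladder and the three-cuboid sensitivity model with equal total
stain).  It does not emulate: stack misalignment or jitter (inputs are
assumed aligned), detector solid-angle and electronic noise, specimen
charging, cutting artifacts, continuous membrane-like geometry, or
stain-density heterogeneity inside structures.  Passing tests therefore
demonstrate the reconstruction's statistical and algebraic behavior under
ideal acquisition, not robustness to instrument imperfections.

## Numerical choices

- Steps inside a voxel phantom are capped at a quarter of the smallest
  voxel edge; the exponential free path is memoryless, so truncating and
  re-drawing is unbiased while preventing overshoot of 12.5-nm layers.
- Material quantities are pre-tabulated on a 256-point geometric energy
  grid from the cutoff to the landing energy and linearly interpolated.
- A 50,000-step guard terminates pathological trajectories as absorbed.
- The clipping threshold ("one standard deviation of the background") is
  taken from a stain-free ROI when one is given; otherwise from the
  negative voxels of the reconstruction, which can only be noise:
  `sd = median(|negatives|)/0.6745`.
- Lower-sub-slice averaging uses the upper sub-slice of the same cut and
  of the next cut; the final cut averages with its single upper neighbor.
- The low-to-high intensity scaling multiplies the dose-normalized
  low-energy images so a through-thickness homogeneous ROI satisfies
  `mean(low) = r · mean(high)` with r the matrix row-sum ratio
  (r ≈ 0.76–0.78 for the (1.0, 1.4) keV pair); on self-consistently
  simulated stacks the factor is ~1 by construction.
- Reproducibility: every stochastic entry point takes a numpy Generator;
  the CLI derives all randomness from `--seed`.  Batched transport
  consumes random numbers in a fixed chunk order, so identical seeds give
  identical images bit for bit.

## Problem sizes

Default problem sizes were chosen so a full calibration-plus-demo runs in
minutes on one core: calibration targets at 2×10⁵ electrons, demo images
at 500–1,000 electrons/pixel over ~100×30-pixel fields, test-suite
variants at 2.5–6×10⁴ electrons and ≤16×16-pixel ROIs.  Recovery
statistics scale as expected with electron count; the published operating
point (1,000 e/pixel) is used wherever a test asserts recovery accuracy.

## Known limitations

- Absolute backscatter yields at ≤1.4 keV inflated ~1.5–1.7× (elastic
  surrogate; see above); stain-signal linearity consequently degrades
  earlier than partial-wave transport predicts (~8–12% departure from the
  0–3 at% line at 5 at%).
- No discrete inelastic events, secondary electrons, or X-rays.
- Interlayer coupling bias on the lower sub-slice (−5 to −9% when both
  layers are stained).
- The hydrogen mean ionization potential uses the analytic fit, which is
  rough at Z = 1; an override is available per element.
- MRC support requires the optional `mrcfile` dependency; TIFF is the
  first-class container.
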
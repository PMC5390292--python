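# Methods

This note records the models implemented in `ndendo`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Contact-area model (`ndendo.geometry`)

**Model.** The membrane contact patch of a faceted nanoparticle is
abstracted as a simple star-shaped polygon. Vertex *i* sits at polar
angle `phi_i = (2*pi/n) * (i + u_i * dalpha)` and radius
`rho_i = base_radius * (1 + v_i * dr)` with `u_i, v_i ~ U(-1, 1)`;
angles are wrapped into `[0, 2*pi)` and sorted ascending, which makes
the polygon star-shaped around the origin and therefore always simple.
`dr` and `dalpha` are the two dimensionless irregularity amplitudes
(default 0.3 each); `base_radius` sets the only length scale, and all
outputs are relative areas, so it cancels. Rounding radii are read in
units of `base_radius`.

**Corner rounding.** Each corner with interior angle `alpha` is
replaced by a circular fillet of radius `R_r` tangent to both adjacent
edges at offset `t = R_r / |tan(alpha/2)|` from the vertex, centered at
distance `R_r / sin(alpha/2)` along the local bisector. Convex corners
(`alpha < pi`) lose area `R_r^2 (cot(alpha/2) - (pi - alpha)/2)`;
reflex corners (`alpha > pi`) — which the generator emits at
`dr = dalpha = 0.3` — are filleted by the same construction and *gain*
the corresponding area. Areas of rounded outlines are computed exactly
by Green's theorem, `A = 1/2 * closed-integral (x dy - y dx)`, evaluated in
closed form over segments and arcs; the signed arc sweep handles the
convex and reflex cases uniformly. Unit tests verify the closed form
for rounded regular polygons and an L-shaped polygon to machine
precision, and agreement with a fine chord-discretization oracle to a
relative error below 1e-6.

**Infeasible fillets.** If any tangent offset exceeds half of an
adjacent edge length, the fillet construction is rejected for that
polygon at that radius (`FilletInfeasibleError`). The ensemble curve
excludes rejected polygons from the mean at that radius and reports the
rejection fraction, rather than silently clamping the radius, because
clamping would change the geometry being averaged. The rejection
fraction grows with vertex count (many-vertex irregular polygons have
short edges and occasionally near-straight corners whose offsets
diverge); it is reported so users can judge the surviving ensemble.

**Ensemble sizes.** The ensemble default is 100,000 polygons per
condition. The bundled analysis driver and the test suite use 2,000
per curve, which puts the Monte-Carlo standard error of each mean
relative area below 0.002 — amply sufficient for the monotone trend the
curves exhibit. Per-polygon RNG substreams are derived from
`(seed, draw_index)`, so ensembles are order-independent and
reproducible draw by draw.

## WHAM and adhesion strength (`ndendo.pmf`)

**Model.** Umbrella windows apply harmonic biases
`U_w(z) = k/2 (z - z0_w)^2` along the slab-membrane distance `z`. The
weighted histogram analysis method solves the coupled equations

    p_b  proportional to  (sum_w n_wb) / (sum_w N_w exp(-beta(U_w(z_b) - f_w)))
    f_w  =  -kBT ln sum_b p_b exp(-beta U_w(z_b))

iterated in log space (via `logsumexp`) until the largest change in any
window free energy is below `tol = 1e-6` kcal/mol (`max_iter = 1e5`).
The PMF is `F(z_b) = -kBT ln p_b`, min-referenced. Histogram bins are
uniform over `[min center - 3 sigma, max center + 3 sigma]` with
`sigma = sqrt(kBT / k)` and `n_bins = 200` by default; the depth is the
mean of the populated bins in the top 10% of the z range (a plateau
average, robust to bin noise, `bulk_fraction` configurable) minus the
minimum. Depth is invariant to the referencing convention by
construction. Adjacent windows must share at least one populated bin;
a gap raises an error naming the offending pair. `k_B` is
0.0019872041 kcal/mol/K throughout.

**Adhesion strength.** `k_ad = depth / (L_x * L_y)` for a rectangular
slab, and estimates from different systems are combined by an
arithmetic mean. The continuum model uses the *signed* convention
(`k_ad < 0` favorable); magnitudes are converted explicitly via
`adhesion_magnitude_to_signed` because reported binding strengths are
positive by convention while the wrapping formula needs the sign.

**Uncertainty.** `bootstrap_depth` resamples each window's z values
with replacement (ordinary bootstrap; the synthetic samples are i.i.d.
by construction, so no block structure is needed), reruns WHAM and
reports the standard deviation over 200 replicates by default. This is
a declared estimator choice, not a claim about how any particular
published error bar was computed.

## Continuum wrapping (`ndendo.wrapping`)

`G_tot(theta) = [4 pi k_b + 2 pi R^2 k_ad](1 - cos theta)` for a
tension-free, infinite membrane wrapping a spherical tip of radius `R`
to angle `theta` in `[0, pi]`. Because the energy is linear in
`1 - cos(theta)`, the classification "wrapping" (`G_tot < 0` for
`theta > 0`) depends only on the sign of the bracket; boundary points
(`G_tot = 0`) are classified as no-wrap under the strict inequality.
The bending modulus can be supplied in `kBT` (converted at 298.15 K by
default — the conversion temperature is configurable since experiments
span 4-37 °C, though the 10% difference never flips a classification in
the scanned range) or directly in kcal/mol. The model covers only the
initial stage of internalization (tip wrapping); membrane tension,
stretching, and full-particle engulfment are out of scope.

## Uptake quantification (`ndendo.uptake`)

At 4 °C only anchoring occurs; at 37 °C anchoring plus
internalization. With 4 °C and 37 °C wells on separate plates, the
subtraction `internalized = mean(37C) - mean(4C)` is unpaired and its
uncertainty is the quadrature sum of the two condition standard
deviations. Negative internalized estimates are reported with a QC
flag, never truncated, because truncation would bias downstream ratio
estimates. Raw intensities are made comparable across particle types
by dividing by each type's calibration slope (OLS of intensity vs
concentration over 0-20 ug/mL); the 0 ug/mL point serves as blank, and
blank subtraction shifts only the intercept, never the slope. The
whole pipeline is scale-equivariant: multiplying all raw and
calibration intensities by a constant changes no normalized quantity,
ratio, or p value.

Cross-type comparisons use a two-sided two-sample t test, pooled
variance by default (`df = n1 + n2 - 2`) — the variant that reproduces
the zeta-potential p = 0.937 from its printed summaries — with Welch
available by flag. Both raw-replicate and summary-statistics inputs
are supported. No multiple-testing correction is applied across time
points (per-time-point p values are reported raw).

## Synthetic data (`ndendo.synth`)

**Umbrella windows.** Samples are drawn i.i.d. from the exact biased
Boltzmann density `exp(-beta[F_true(z) + U_w(z)])` by inverse-CDF
interpolation on a fine grid (20,001 points by default). This
reproduces the *statistical* model of umbrella sampling exactly; it
deliberately omits what real MD adds — autocorrelation within windows,
equilibration transients, force-field error — so recovery tests
validate the WHAM estimator, not the molecular dynamics. The default
true profile is a Gaussian well of depth 9.93 kcal/mol and width
0.3 nm on a flat plateau, probed by 13 windows spaced 0.15 nm with a
400 kcal/mol/nm^2 bias, mirroring the umbrella protocol of the
experiment being modelled; with 1e4 samples per window the
reconstructed profile's RMSE is ~0.05 kcal/mol and the depth is
recovered within 1%.

**Plate assays.** Well intensity is
`[A(t) + I(t) * 1{37C}] * (1 + eps)`, `eps ~ N(0, CV^2)` truncated at
zero, with saturating kinetics `A(t) = A_max(1 - e^(-t/tau_a))` and
`I(t) = I_max(1 - e^(-t/tau_i))` per particle type (internalization
identically zero at 4 °C). The saturating-exponential form is a
modelling stand-in consistent with the observed "gradually increasing"
time courses; no functional form is claimed by the source data. The
`reference` preset uses `tau_a = 2 h`, `tau_i = 3 h`,
`A_max = 60/30` and `I_max = 60/240` (prickly/round) so that the
anchored prickly:round ratio is exactly 2 and the internalized
round:prickly ratio exactly 4 at every time point, the prickly signal
at 10 h is roughly half anchored (matching the observation that
anchored prickly particles remain a significant fraction), and the
round signal is internalization-dominated. Noise is multiplicative
Gaussian with CV = 0.15 and n = 4 replicate wells. Both conditions
share the time grid 10 min-10 h: the subtraction at 10 h requires a
4 °C measurement there, even though the original 4 °C series stopped
at 6 h. The generator returns the generative truth alongside the
noisy plate so recovery tests never re-derive it from internals.

**What recovery shows.** The mean of the per-plate internalized ratio
over 500 plates carries a small positive Jensen bias (~3% at these
settings) because a noisy denominator enters each per-plate ratio;
this is a property of the ratio estimator at CV = 0.15 and n = 4, is
well inside the 5% recovery band, and would shrink with more replicate
wells. Passing recovery tests show the pipeline arithmetic is
faithful under the stated noise model — not that real plates, with
pipetting errors, cell-density variation, or background drift, would
behave identically.

## Numerical choices and limitations

* WHAM convergence is measured on window free energies (gauge fixed to
  the first window); ~5,000 iterations are typical for the 13-window
  protocol.
* Polygon validity is delegated to shapely (`is_valid`), and areas use
  the shoelace formula; fillet feasibility uses the conservative
  half-edge rule, so a slightly larger feasible set exists in principle
  (offsets from both ends of one edge could share it unevenly).
* The tip radius used for the phase-diagram figure of the original
  study is not recoverable; drivers use R = 3 nm, chosen so the
  reference point (20 kBT, -2 kcal/mol/nm^2) sits near the boundary
  (R_c = 3.44 nm). The boundary's position in (k_b, k_ad) scales with
  R as `-2 k_b / R^2`.
* Calibration slopes assume linear fluorescence over 0-20 ug/mL;
  detector saturation or inner-filter effects are not modelled.
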
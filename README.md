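# ndendo — shape-dependent nanoparticle endocytosis modelling

Fluorescent nanodiamonds (NDs) enter cells in two stages: they first
**anchor** to the plasma membrane, then are **internalized** by an
energy-dependent wrapping process. Both stages turn out to depend on
particle shape — "prickly" particles with sharp corners anchor more but
internalize less than their chemically etched, "round" counterparts.
This package implements the quantitative analyses behind that finding,
for anyone who wants to rerun, probe, or extend them:

1. **Contact-area Monte Carlo** (`ndendo.geometry`) — the membrane
   contact patch is a random star-shaped polygon; etching is modelled by
   replacing each corner with a circular fillet of radius `R_r` tangent
   to both edges. Areas of the rounded outlines are exact (Green's
   theorem over segments and arcs), and ensemble curves of mean relative
   area vs `R_r` quantify how corner rounding shrinks the contact area.
2. **WHAM adhesion energetics** (`ndendo.pmf`) — umbrella-sampling
   windows (harmonic biases `U_w(z) = k/2 (z − z0_w)²`) are combined by a
   self-consistent weighted-histogram (WHAM) solver into a potential of
   mean force `F(z)`; the unit adhesion strength is the well depth per
   slab contact area, `k_ad = ΔF / (L_x·L_y)` in kcal/mol/nm².
3. **Continuum wrapping energetics** (`ndendo.wrapping`) — the energy of
   a membrane wrapping a spherical tip of radius `R` to angle `θ` is
   `G_tot = [4π k_b + 2π R² k_ad](1 − cos θ)`; wrapping is favorable iff
   the bracket is negative, giving the phase boundary
   `k_ad = −2 k_b / R²` and critical tip radius `R_c = √(2 k_b/|k_ad|)`.
4. **Uptake quantification** (`ndendo.uptake`) — plate-reader
   fluorescence at 4 °C (anchoring only) and 37 °C (anchoring +
   internalization) is normalized by calibration slopes and subtracted:
   `internalized = mean(37 °C) − mean(4 °C)`, with quadrature error
   propagation and two-sample t-tests between particle types.
5. **Synthetic data** (`ndendo.synth`) — exact i.i.d. samples from the
   biased Boltzmann density of a known PMF, and simulated plate assays
   with known kinetics, so every stage is testable against ground truth.

## Worked example

```python
import numpy as np
from ndendo import (SlabSpec, TruePMFSpec, k_ad_from_depth, pmf_depth,
                    sample_umbrella_windows, wham_solve)
from ndendo.synth import umbrella_ladder

truth = TruePMFSpec(form="well", depth=9.93, width=0.3, z_range=(-1, 3))
windows = sample_umbrella_windows(truth, umbrella_ladder(13, 0.15),
                                  force_constant=400.0, temperature=298.15,
                                  n_per_window=10_000, seed=7)
profile = wham_solve(windows)
depth = pmf_depth(profile)
print(round(depth, 3), round(k_ad_from_depth(depth, SlabSpec(2, 2)).k_ad, 4))
```

prints `9.875 2.4687`: thirteen windows of 10⁴ exact samples from a
9.93 kcal/mol Gaussian well are recombined by WHAM to a depth within
0.6% of truth, and the depth-per-area step gives the adhesion strength
of a 2 nm × 2 nm slab. The same arithmetic applied to the reported
molecular-dynamics depths gives `9.93/4 = 2.48` and
`37.39/16 = 2.34` (printed as 2.33) kcal/mol/nm², averaging with the
large-bilayer value 2.22 to **2.34 kcal/mol/nm²** — the adhesion
strength used in the wrapping model. At `k_b = 20 k_BT`
(11.85 kcal/mol) and `k_ad = −2 kcal/mol/nm²` the critical tip radius
is **3.44 nm**: a sharp corner of a prickly particle stays unwrapped
while a blunter round tip is engulfed.

The full analysis sequence lives in `analysis/`:

```sh
python analysis/01_contact_area.py           # mean relative area vs R_r
python analysis/02_pmf_adhesion.py           # WHAM round trip and k_ad table
python analysis/03_wrapping_phase_diagram.py # wrap/no-wrap phase diagram
python analysis/04_uptake_quant.py           # anchored/internalized recovery
```

Each script states what it finds and writes its tables under
`results/`. On the synthetic plates, the 37−4 °C pipeline recovers the
built-in effect sizes (anchored ratio 2.020 vs truth 2.0; internalized
ratio 4.130 vs truth 4.0 over 500 plates), and the pooled t-test on the
two particle types' zeta-potential summaries gives p = 0.937 (no
surface-charge difference, so shape is the operative variable).

A `ndendo` command-line tool exposes the same steps
(`area-curve`, `wham`, `kad`, `phase-diagram`, `quantify`,
`gen-umbrella`, `gen-assay`); see `ndendo --help`.

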
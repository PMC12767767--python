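# Methods

## Physical model and assumptions

The analysis assumes spherical particles in a low-Reynolds-number liquid, so
the Stokes–Einstein relation `D = kB·T/(6π·η·r)` applies, and plug flow down
the main channel: every particle moves at the mean carrier speed
`v = Q/(h·w)`, where `Q` is the **total** volumetric flow (analyte plus both
buffer streams — all three share the main-channel cross-section) and `h·w`
the cross-section.  No parabolic (Poiseuille) velocity profile or Taylor
dispersion correction is applied; transit times are simply
`t_i = position_i / v`.

Lateral spreading is treated as 1-D free diffusion of an initially Gaussian
band.  Profiles are modelled as sums of Gaussians in the
`a·exp(−((x−b)/c)²)` parameterization; matching exponents with the 1-D
diffusion kernel `exp(−x²/4Dt)` gives `c² = 4·D·t`.  All "variances" in this
package are this `c²`.  The probabilistic variance would be `c²/2`; mixing
the two conventions would halve every diffusion coefficient and double every
radius, which is why the parameterization is fixed package-wide and asserted
in tests.

Because the focused stream has a finite initial width c₀, the variance–time
line is fitted **with a free intercept**; the intercept estimates c₀² and
the point-source form is recovered when it is zero.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| temperature | 298.15 | K | read from workbook metadata; default is lab ambient |
| viscosity | 8.9e-4 | Pa·s | water at 25 °C |
| r_min, r_max | 1, 2000 | nm | admissible radius range; also sets the slope bounds and the reporting floor |
| baseline standard | 200 | counts | the common camera baseline the normalization aligns to |
| mixture order | 2 | – | order scans show no significant gain beyond 2 for these analytes |
| center bound | ±5 | μm | profiles are peak-centered first; the true center stays within 5 μm of the peak |
| sigma cap | 100 | μm | global width cap; empirically the best-behaved limit for known-size samples |
| patience | 5 | – | multi-start stops after 5 consecutive non-improving restarts; larger values gave no RMSE improvement |
| sigma floor ε | 1e-3 | μm | numerical stand-in for "positive" |

The admissible variance–time slope window `[4·D(r_max), 4·D(r_min)]`
(≈ [0.49, 981] μm²/s for 1 nm–2 μm in water at 25 °C) is propagated between
consecutive measurement points: component k fitted with width c at one point
may have width in `[√(c²+s_min·Δt), √(c²+s_max·Δt)]` at the next.  This
forces monotone widening (physical for free diffusion) and suppresses
artifact-driven rank swapping.  If the window collapses against the global
cap the point is skipped and logged, never silently truncated.

## Preprocessing rules and numerical choices

* **Crop band**: mean ± population (n-denominator) std of the *raw*
  brightfield trace, zeros included — the zero-padded ends depress the mean
  enough that real baseline points always clear the lower limit.  Points are
  removed from each end until one exceeds the lower limit.  The crop is
  idempotent whenever the retained end samples keep a > 3σ noise margin
  above the band recomputed on the cropped trace; at noise ≥ ~2% of the
  signal peak a second application may trim a few extra end samples (the
  recomputed band sits higher once the zeros are gone).  The pipeline crops
  exactly once, so this boundary only concerns the formal property, which is
  tested in its validity regime (noiseless and 0.5%-of-peak noise).
* **Wall localization**: starting at the fluorescent maximum, scan the
  brightfield both ways; the wall is the sample deviating most from the
  brightfield mean (bright spike or dark dip).  A region of width
  2 × wall_thickness centered there is excluded — doubled to absorb the
  uncertainty between spike position and wall-line center.  Fluorescent-max
  ties resolve toward the midpoint of the x range (this also makes flat
  degenerate traces behave deterministically).
* **Fluorescence normalization** is two-step: (1) scale each profile so its
  baseline equals the standard; the baseline is measured on the **outside**
  sections by default (the inside contains analyte signal; configurable via
  `fluor_baseline_region`), (2) scale each profile by the ratio of the
  largest inside-channel integral across the set to its own, equalizing
  areas (trapezoidal quadrature on the uniform grid).  Step 2 makes the
  result invariant to slow illumination drift and surface accumulation.
* **Zero and center**: subtract the outside mean, shift x so the peak sits
  at 0 (brightfield and wall centers shift rigidly).  A trace whose maximum
  does not exceed baseline + 3 × outside-std is reported as no-signal.
* **Mixture fitting**: bounded trust-region least squares
  (`scipy.optimize.least_squares`, method `trf`) from randomized starts —
  amplitude uniform in [0, 2·max(y)], center uniform in ±5 μm, sigma
  log-uniform within its window — with an improvement test on RMSE
  (sse/dfe convention) and a hard restart ceiling of 200.  Components are
  identified across restarts and measurement points by sigma-descending
  sort.  Fits use only the inside section.
* **Order scan**: every fit in the scan uses the global width bounds; the
  sequential windows are not chained there, because the scan compares model
  orders and is advisory only (no automatic AIC/BIC order selection; the
  default order is 2).
* **Variance–time fit**: `scipy.stats.linregress`; at least 3 points
  required; a non-positive slope is reported as a failure for that
  component, never converted into a radius.
* Radii below the 1 nm floor are clamped to the floor and flagged in
  provenance; the effective floor of a real instrument may sit slightly
  above the nominal one because of accumulated rounding in the upstream
  operations — this package documents clamping events instead of hard-coding
  an empirical offset.

## The synthetic generator

`diffsizer.synthetic` emulates the measurement workbooks end to end: a
focused Gaussian band (c₀ = 10 μm by default) spreading as
`c²(t) = c₀² + 4Dt` with amplitudes scaled `∝ 1/√c²` (area conservation, so
the `N = a·c·√π` estimate is testable); a flat baseline at 200 counts; two
wall lines in the brightfield as narrow Gaussian bumps (sd =
wall_thickness/4) at the channel edges — peaked, as imaged wall lines are,
which gives the wall locator a unique optimum; exact zeros over the first
and last 25 samples (rotation padding); additive Gaussian camera noise on
both traces; and an optional per-point multiplicative drift emulating
fluorophore accumulation on untreated surfaces.  Intensities are quantized
to 1e-6 counts — far below camera quantization — which also makes the
workbook round trip bit-exact through the 16-significant-digit decimal
cells of the XLSX writer.

Study-condition defaults: 300 × 20 μm channel, 20 μm wall lines, eleven
equidistant measurement points at 1–51 mm (5 mm spacing; transit times
0.04–2.04 s at the steady-state 4/1/4 μL·min⁻¹ pump rates), water at
25 °C, signal peak 1000 counts above baseline.  The point spacing was chosen
so the diffusion length `3·√(c₀²+4Dt_max)` of every species in the 1–5 nm
study range stays below the channel half-width; the simulator **refuses**
parameter sets that would reach the sidewalls rather than silently
truncating, because wall reflection is not modelled.

What the generator does **not** emulate: 2-D/3-D hydrodynamics, Taylor
dispersion across the channel height, photobleaching, wall reflection,
non-Gaussian camera noise, and imperfect focusing (asymmetric or off-center
initial bands).  Passing recovery tests therefore demonstrate the
correctness of the analysis chain under the stated model, not robustness to
every instrumental imperfection of real recordings.

## Problem sizes used in tests and the acceptance script

Profiles are sampled at 2 μm spacing (321 samples, 139 inside the channel);
eleven measurement points per run; noisy recovery uses 20 seeded replicates
at additive noise sd = 2% of the signal peak; two-species separation uses
the noiseless 1.5 + 3 nm mixture (at ≥ 2% noise a single Gaussian already
fits that mixture to within the noise floor — the two widths differ only
~1.4-fold at this geometry — so the order-scan contrast is resolvable only
on clean data, which is also the regime where the separation claim is made).
All randomness flows from explicit seeds; rerunning with the same seed
reproduces every number bit-exactly.

## Known limitations

* The method is biased toward the smaller species in a mixture (faster
  diffusers dominate the profile shape); the higher radius of the pair is
  the more reliable estimate.
* Close sigma pairs (< ~1.3× apart) are not reliably separable at realistic
  noise; the order-2 default reports them as a nearly degenerate pair.
* Plug-flow transit times ignore the parabolic velocity profile; absolute
  radii inherit that systematic simplification.
* Particle counts are intensity-weighted arbitrary units, not molar
  concentrations.
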
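# Methods

This note documents the models, parameter choices and limitations behind
`glycocal`. It is written for a reader who wants to know *why* the package
computes what it computes, and what passing its tests does and does not
demonstrate about real chromatographic data.

## Mass model

Standards' masses are free-acid average masses built from in-chain
(dehydrated) residue masses using standard average atomic weights
(C 12.011, H 1.008, N 14.007, O 15.999, S 32.06):

| residue | formula (in chain) | mass (Da) |
|---|---|---|
| GlcA / IdoA | C6H8O6 | 176.12 |
| GlcNAc | C8H13NO5 | 203.19 |
| GlcNS | C6H11NO7S | 241.21 |
| GlcNS6S | C6H11NO10S2 | 321.27 |
| IdoA2S | C6H8O9S | 256.18 |
| ΔHexA2S | C6H6O8S | 238.17 |

Each sulfo group adds SO₃ (+80.06 Da); the 4,5-unsaturated uronate formed by
β-elimination is the saturated residue minus H₂O; one terminal water
(+18.02 Da) is added per chain; the para-nitrophenyl aglycone replaces the
anomeric hydroxyl hydrogen (+121.10 Da net). This reproduces the panel's
reported masses within ±1 Da for all 27 synthetic standards. One compound
(the 12-mer NS6S) computes to 3123.48 Da and therefore rounds one dalton
below its reported 3124 — a rounding-boundary case sensitive to the sulfur
atomic weight, left as-is rather than adjusting the mass table. Sodium-salt
and monoisotopic masses, adducts and isotope patterns are out of scope. The
commercial dp4/dp6 standards are heterogeneous; their nominal masses
(~1200/~1800 Da) are used for calibration while the computed free-acid
masses of their majority structures (1155/1732 Da) are kept separately.

## Calibration models

Both models map RT (minutes) to log₁₀(MW/Da); base-10 logarithms are used
throughout.

**Cubic.** Unweighted least squares of log₁₀(MW) on (1, RT, RT², RT³),
requiring four distinct RTs; this is the pharmacopeial nonlinear-regression
procedure. R² is reported on the fitted points.

**Weighted RBF-SVM.** Support-vector regression (scikit-learn / libsvm)
on standardized RT with per-sample weights multiplying the regularized loss
— mathematically equivalent to replicating a point *w* times, which the test
suite verifies to 1e-6. Default weights by structural group: E and F
(tri-sulfated repeating units, dp4/dp6) 10, D (NS6S) 4, C (NS2S) 2, A, B
and the calibrant peaks 1, mirroring the relative molar contribution of each
repeating unit to the enoxaparin mixture. Where standards with different
masses share an RT, the weights arbitrate; points are never deduplicated.

Hyperparameters are not prescribed anywhere, so they are selected from a
fixed grid (C ∈ {1, 10, 100, 1000}, ε ∈ {0.001, 0.01, 0.05},
γ ∈ {0.1, 0.5, 1, 2} on standardized RT) by minimizing the *weighted*
leave-one-out squared prediction error. Grid-search fits run at a looser
libsvm stopping tolerance (1e-4, iteration cap 20 000) because they are only
compared against each other; the winning combination is refitted to full
convergence (tol 1e-8). Selection is deterministic: ties break to the first
grid combination in (C, ε, γ) order.

**Validation.** q² = 1 − PRESS/SS on log₁₀(MW), with leave-one-out refits
that preserve the group weights; residuals are unweighted. For the SVM the
hyperparameters are selected once on the full set and held fixed across
folds (per-fold re-selection would multiply the cost ~50-fold for no change
in the conclusion). Y-randomization permutes the MW labels over the (RT,
weight) positions with a seeded generator and records the q² of each refit.

**Extrapolation.** Predictions outside the training RT range are returned
but flagged, and the slice analysis reports the share of signal assigned by
extrapolation. There is no hard cap: an RBF regressor reverts toward its
bias far from the data, so extrapolated masses — particularly beyond the
largest calibrant — must be read with care.

## Slice analysis

The windowed 232 nm chromatogram is cut into one slice per sampling point;
the calibration model assigns each slice a mass Mᵢ and the detector signal
its abundance Nᵢ. Then

    Mw = Σᵢ NᵢMᵢ² / Σᵢ NᵢMᵢ.

Under UV detection at 232 nm each enoxaparin chain carries exactly one
unsaturated-uronate chromophore, so intensity is treated as proportional to
*molar* chain concentration (Nᵢ = intensity, the default). For
mass-proportional detectors (refractive index) a `detector="mass"` mode
divides intensity by Mᵢ. Distribution fractions are mass fractions — shares
of Σ NᵢMᵢ below 2000 Da (strict), in the closed band [2000, 8000] Da, and
above 8000 Da (strict) — consistent with Mw being a mass-weighted average;
a molar-fraction mode exists but is not the default. Whether the
pharmacopeial percentages are mass or molar shares under UV detection is
genuinely ambiguous, which is why both modes are explicit configuration
rather than a hidden assumption.

Mw is reported raw; a nearest-50 Da rounding is provided for display only.
Negative intensities (baseline noise) are clipped to zero abundance.
Integration is trapezoidal on the uniform grid; no baseline is subtracted by
default. The default analysis window runs from 1 min before the first
calibration standard to 1 min after the last, which excludes late-eluting
salt/solvent peaks; the cutoff is configurable because no standard value
exists.

## System suitability

Three internal standards (defaults: the 8-mer NS, 12-mer NS6S and 16-mer
NS6S) are verified on the 310 nm trace: peaks are detected, each expected RT
is matched to the nearest apex (ties toward earlier RT), and every standard
must fall within ±0.1 min. A trace with no detectable peaks yields a failing
report rather than an exception. The standards' 232 nm contribution is then
subtracted using a predetermined standards-alone trace (resampled by linear
interpolation; scale 1.0 assumes equal injected amounts; negative residuals
are clipped with a warning). With strict gating — the default — a failed
suitability check withholds the Mw section of the report entirely.

## Simulator: what it emulates, and what it does not

Real retention times for the panel are instrument-specific and not publicly
deposited, so the simulator generates them from an explicit ground truth:

* **Base law** RT = 30.0 − 4.0·log₁₀(MW) min — monotone decreasing, spanning
  ≈13.8–17.6 min over 1200–11000 Da, a plausible SEC window. Any decreasing
  polynomial in log₁₀(MW) may be substituted.
* **Structure-group offsets** (min): A +0.3, B +0.1, C −0.05, D −0.05,
  E −0.15, F −0.15, G −0.12. The orderings encode the observed physics: the
  non-sulfated NAc series deviates most from the calibrant curve, the NS
  series moderately, and the highly sulfated series migrate like the
  calibrants, with larger tri-sulfated chains co-eluting with smaller NS
  chains. Two quantitative choices matter and are deliberate. First, the
  magnitudes are scaled so that the weighted calibration's
  predicted-vs-observed agreement on the simulated panel (LOO q² ≈
  0.93–0.96) matches the agreement reported for the real standards panel
  (R² ≈ 0.96); much larger offsets would make the A/B series outliers the
  real data says they are not. Second, the calibrant offset equals the
  composition-weighted blend of the sulfated-group offsets (−0.12 min),
  because the pharmacopeial calibrants are heparin-derived, heterogeneously
  sulfated fragments — enoxaparin-like by construction. This reproduces the
  observed behaviour that a calibrant-only calibration determines enoxaparin
  Mw within the acceptability range; placing the calibrants off the blend
  instead produces a structural several-percent Mw bias in the top quarter
  of the distribution, where only calibrant points anchor the fit.
* **Peaks and noise**: Gaussian peaks (σ = 0.15 min) with area proportional
  to amount (standards) or molar abundance (mixture components); RT jitter
  0.02 min per injection; additive detector noise (sd 0.02 intensity units);
  detector sampling 0.01 min; the standards' 232 nm amplitude is 0.3× their
  310 nm amplitude. An optional late-eluting salt peak exercises windowing.
* **Enoxaparin mixtures**: an even-dp chain ladder (dp 2–40) with chain mass
  (dp/2)·(mean disaccharide mass ≈ 557 Da, from the 70/10/6/2/1 molar-%
  disaccharide composition) + 18 Da. Molar abundances follow a log-normal
  over chain mass (shape σ_log = 0.6) whose location is tuned by bisection so
  the exact component-level Mw hits the target (default 4500 Da). Each
  component inherits the composition-blended RT offset; an extra
  enoxaparin-specific offset (default 0) lets the standards-vs-sample
  elution mismatch be studied. True Mw and true mass fractions are computed
  from the component list, independent of rendering.

With σ_log = 0.6 the true fractions are 11.0 / 79.8 / 9.2 %; the middle
fraction tracks what UV-based measurements of commercial products show
(~81–84 %), and M2000 sits just below the monograph's 12 % floor — the
simulated default product therefore typically earns a "monograph fail" on
M2000 even when Mw is recovered almost exactly. This parallels the known
discrepancy between UV-based distributions and the RI-based monograph
bands, and it is deliberate: widening the distribution to force a monograph
pass would push more signal outside the calibrated RT range and degrade what
the simulation is for, namely measuring calibration-driven recovery error.

**Not emulated**: peak tailing and column aging, baseline drift,
concentration-dependent elution, 1,6-anhydro reducing-end effects (present
in up to a quarter of real enoxaparin chains), RI detection physics, and any
real pore-partition model of SEC. Passing the simulation-based tests
demonstrates that the analysis chain is self-consistent and recovers known
answers under the stated statistical structure — not that it reproduces any
particular instrument's numbers.

## Numerical choices and degenerate inputs

* Chromatograms must be uniformly sampled (tolerance 1e-6 min); non-uniform
  CSV input is linearly resampled with a warning; non-increasing time is an
  error naming the row.
* Peak bounds are the minima between adjacent accepted maxima (trace edges
  outermost); flat or all-zero traces yield no peaks, not an error.
* The cubic fit refuses fewer than four distinct RTs; q² refuses zero
  response variance; the SVM refuses fewer than five points or an empty
  grid.
* Mass rounding is half-away-from-zero to the nearest dalton, display only.
* The bisection for the mixture location parameter runs 200 iterations
  (monotone objective, exact to machine precision); unattainable targets
  raise with the attainable range.
* All randomness flows from `numpy.random.default_rng` seeded per run;
  channel and stage sub-seeds are fixed offsets of the run seed, so every
  simulated artifact is bit-reproducible.

## Problem sizes

The validation and recovery studies use the full 33-point training set, the
default dp 2–40 ladder rendered at 0.01-min sampling over 12–24 min
(1201 grid points), 20 Y-randomization rounds, and 20 seeded end-to-end
runs; these sizes make the whole suite and the acceptance script complete in
a few minutes on one CPU while leaving the statistics stable.

## Known limitations

* The weighted LOO-CV hyperparameter search is O(grid × n²) SVR fits; fine
  at n = 33, not intended for thousands of standards.
* RBF extrapolation beyond the calibrant range reverts toward the model
  bias; the extrapolated share is reported so users can judge exposure.
* The subtraction procedure assumes the standards-alone and co-injection
  runs share retention times to within the system-suitability tolerance; no
  amplitude re-matching is attempted beyond the configurable scale factor.
* The monograph check encodes a single pharmacopeia's limits; other
  rule sets are out of scope.
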
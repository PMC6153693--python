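# Methods

## Scattering model

The forward model treats a floc suspension as a population of mass-fractal
aggregates of gyration radius R_g built from primary particles of size R_p,
observed in the Rayleigh-Gans-Debye (RGD) regime. On a log-log plot of
relative intensity I against the scattering-vector magnitude
q = 4 pi n sin(theta/2) / lambda (units 1/um throughout; lambda defaults to
the 632.8 nm He-Ne line, n = 1.33 for water), the model curve is piecewise:

* q <= 1/a: Guinier branch. The standalone `guinier_intensity` implements
  the truncated expansion I0 (1 - (q R_g)^2 / 3), valid for q R_g < sqrt(3)
  and raising a domain error beyond. The *composite* curve instead uses the
  full exponential form I0 exp(-(q R_g)^2 / 3): the crossover 1/a can sit
  well past the truncated expansion's positivity limit (R_g/a reaches ~15
  for realistic floc populations), and the exponential is what keeps the
  composite strictly positive and non-increasing for every valid parameter
  set. The two forms agree to <0.5% for q R_g <= 0.3.
* 1/a < q <= 1/R_p: fractal branch, I = C q^(-Df), Df in (1, 3].
* q > 1/R_p: Porod branch, I = C' q^-4 (surface scattering off smooth
  primaries).

Continuity at both crossovers is enforced by rescaling the fractal and
Porod prefactors; the crossover placement q1 = 1/a, q2 = 1/R_p follows the
reciprocal structure of the regime bounds. A smooth unified
(Beaucage-style) blend is deliberately not modelled — the piecewise curve
keeps the ground-truth crossovers sharp for detector validation.

The exact RGD sphere form factor P(x) = [3 (sin x - x cos x)/x^3]^2 serves
as an independent oracle: its small-x expansion 1 - x^2/5 together with
R_g^2 = (3/5) R^2 for a sphere reproduces the Guinier 1/3 coefficient, and
the envelope of its large-x maxima decays as x^-4, the Porod exponent. Both
checks are asserted in the test suite, so the hand-written branches are
validated against closed-form physics rather than against themselves.
P(x) switches to its series below x = 0.01 to avoid catastrophic
cancellation.

## Measurement-noise model

A granulometer measurement averages 15 rapid optical sweeps. The simulator
multiplies each intensity by an independent lognormal factor with log-sd
`rel_noise_sd` (default 0.02) per (q, replicate) and returns the arithmetic
per-q mean of the replicates. Multiplicative noise matches detector
behaviour on signals spanning ~10 decades; averaging reduces the effective
relative sd to about 0.02/sqrt(15) ~ 0.5%. The small lognormal mean bias
exp(sd^2/2) - 1 ~ 2e-4 is q-independent, so it moves only the intercept,
never the slope. All generators take one explicit integer seed; there is no
hidden global random state.

## Regime detection

No standard algorithm exists for marking the fractal regime on a measured
curve; the detector here formalizes what a practitioner does by eye on the
log-log plot. It searches all contiguous windows from longest to shortest
(ties broken toward smaller q_low) and accepts the first whose

1. OLS R^2 >= `r2_min` (default 0.995) — global linearity;
2. OLS slope lies in `slope_window` (default (-3.6, -0.5)) — the
   mass-fractal band. This guard is essential: the Porod branch is itself
   an exact power law and on a wide grid often spans more points than the
   fractal regime, so a pure "longest linear window" rule would lock onto
   q^-4. The band also rejects near-flat Guinier heads;
3. every per-point local slope deviates from the window slope by less than
   `slope_tol` (default 0.15) — local straightness, which is what actually
   pins the window edges at the crossovers.

"Local slope" is a 5-point windowed OLS slope. Raw adjacent-point
difference quotients would have noise sd ~0.13 at the default noise level
on the default 200-point grid — indistinguishable from the tolerance — and
would fragment every window; the 5-point fit brings that down to ~0.03.
Near a candidate window's edges the neighbourhood is clipped to the window
(3- and 4-point one-sided fits), so points beyond a crossover never
contaminate the check and the detected bounds land within one grid step of
the true crossovers on noiseless composite curves. Detection is idempotent:
re-running on the curve restricted to its own bounds returns the same
bounds. A curve with no qualifying window (pure Guinier, pure Porod, flat,
or overwhelming noise) raises a no-regime error rather than returning a
meaningless fit. Window statistics are computed with prefix sums, so the
whole search is O(n^2) with small constants (milliseconds per curve).

## Fit, confidence interval, size range

Df = -slope of the OLS fit of log10 I on log10 q inside the detected
window (the slope is log-base invariant; base 10 is used for reporting).
The slope standard error uses the residual variance with n-2 degrees of
freedom, computed directly from residuals — the textbook sqrt(1 - r^2)
shortcut loses half the floating-point mantissa on near-exact data, which
matters for the machine-precision recovery contract. The confidence
halfwidth is t_{(1+level)/2, n-2} x stderr (default level 0.95). A fitted
Df outside (1, 3] is reported with a warning, never clamped or rejected:
field values marginally below 2 are real.

The regime bounds convert to a particle-diameter range via d = 1/q
(d_min = 1/q_high ~ R_p, d_max = 1/q_low ~ a). The literature is not
unanimous on the proportionality constant; d = 2 pi / q is available as an
opt-in convention but the reciprocal form is the default, consistent with
the bounds' reciprocal structure. The RGD validity flag marks diameters
d >= lambda (strict inequality at the boundary); `exceeds_rgd` on a result
records that the fitted regime extends beyond that limit — routinely true
for flocs, where the regime reaches tens of micrometres.

## PSD analysis

Distributions live on strictly increasing positive bin-edge grids (default
log-uniform, 100 bins over 0.02-2000 um, a granulometer's working range);
a bin's representative diameter is the geometric mean of its edges, the
natural centroid when bins span decades. Volume -> number conversion
divides bin weights by d_i^3 and renormalizes (number -> volume multiplies);
the two directions are exact inverses on a shared grid, and conversion to
number provably shifts cumulative mass toward small diameters. Range
fractions prorate straddling bins by log-width, since reporting cuts
(e.g. 10 um) need not coincide with instrument bin edges; fractions over a
partition sum to exactly 1. Percentile diameters interpolate the cumulative
log-linearly within bins — accordingly, inside a single occupied bin the
percentile curve sweeps the bin and crosses its geometric centre at
p = 0.5. Band counting for particle lists uses half-open bands
[e_k, e_{k+1}) with open-ended extremes, so counts always sum to the list
length; for the conventional <10 / 10-100 / >=100 um split this places a
particle of exactly 10 um in the middle band.

## Synthetic generators and calibration

`generate_psd` produces an analytic (sampling-free) volume-basis lognormal
mixture. The default calibration has two modes on the log10 scale:

| mode | median (um) | log10-sd | volume weight |
|------|-------------|----------|---------------|
| A — dominant flocs | 100 | 0.30 | 0.97 |
| B — microflocs     | 9   | 0.20 | 0.03 |

These values were chosen jointly so that, under the cubic basis conversion,
(a) the volume fraction above 10 um is ~98% (>= 96%) and (b) the number
fraction below 10 um is ~88.6%, inside the 85.5-92.4% band reported for
real sludge. The two constraints pull hard against each other: the d^-3
reweighting amplifies the microfloc mode by ~(100/9)^3, so a microfloc
median much below ~9 um drives the number fraction below 10 um to ~99%+ no
matter how small its volume weight — placing mode B near the top of the
2-10 um microfloc band, with its *number-basis* median at 4.8 um (mid-band),
is what makes both fractions land. Mode B is invisible on the volume basis
(volume d50 ~ 97 um, unimodal to the eye) yet owns ~99% of the particle
count: the generator reproduces the "concealed microfloc mode" structure.

`sample_particles` draws per-particle diameters from a number-basis PSD
(log-uniform within bins), emulating image-analysis output; absolute
particle counts are arbitrary, as real concentrations are instrument- and
dilution-dependent. `generate_scattering_sample` composes the forward model
(200-point log grid, q in [1e-3, 1e2] per um) with the noise model and
returns the generating parameters alongside the curve.
`generate_study_ensemble` emulates a 69-sample campaign: per sample, Df is
uniform on [1.98, 2.34] (the span observed across such campaigns), R_g on
[50, 150] um, R_p on [0.4, 1.0] um and a on [10, 45] um, with child seeds
spawned from the single campaign seed.

What the generators do **not** emulate: polydispersity of R_g within one
curve, multi-fractal structure (a single Df per sample), multiple
scattering, instrument smearing, inter-seasonal or per-plant covariate
structure, and absolute intensity calibration. Tests passing on this
synthetic population therefore demonstrate correctness of the estimation
machinery under the stated generative model, not robustness to every
artefact of real instruments.

## Numerical and interface choices

* Problem sizes: 200-point curves, 100-bin PSDs, 69-sample ensembles and
  50-100-seed recovery sweeps — the scales at which the statistical
  contracts (CI ceilings, recovery error bounds) are meaningful while the
  full suite runs in seconds.
* Exact power-law recovery is asserted to 1e-9; regime-bound recovery to
  one grid step; CI 1/sqrt(n) scaling within 20% over an 8x range of n.
* Degenerate inputs fail loudly and specifically: non-positive intensities,
  grids not spanning both crossovers (the error names the missing side),
  windows with <3 points, all-zero distributions, volume-basis input where
  number-basis is required (the error says how to convert).
* CSV dialects are plain text with `#` comments; floats are written with
  `repr` and parsed with pandas' round-trip parser, so file round-trips are
  bit-exact. JSON reports carry a schema version and embed units in key
  names (`d_min_um`, `q_low_per_um`) to prevent unit drift.
* The CLI (`flocscatter fd|psd|bands|synth|all`) is a thin layer over the
  library; a YAML `--config` file overrides flags, logs go to stderr, and
  any library error exits non-zero with its diagnostic.

## Known limitations

* The regime detector assumes one fractal regime per curve; multi-level
  (multi-fractal) flocs would need a segmented fit it does not attempt.
* R_g is a forward-model input only; the package does not fit Guinier radii
  from data.
* Mie inversion (how instruments turn raw patterns into PSDs) is out of
  scope; PSDs are consumed as given.
* The q -> d proportionality constant is a convention, not a measurement;
  results quoted as diameter ranges inherit that choice.
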
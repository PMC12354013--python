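# Methods

## Reaction model and assumptions

The package models Nε-lysine acylation of the histone H4(1–25)W tail
(sequence `SGRGKGGKGLGKGGAKRHRKVLRDNW`, five modifiable lysines) by an
acyltransferase under substrate excess.  Each site *i* is an independent
first-order process with time-invariant rate constant *kᵢ* (min⁻¹):
no cooperativity between sites, no substrate or cofactor depletion, no
reverse (deacylase) reaction, and no Michaelis–Menten saturation.  Under
these conditions the fitted *k* approximates *k*_cat.  These assumptions
are exactly what licenses exponential progress-curve fits and the
reading of bi-exponential amplitude fractions as site-class counts; they
are declared here because they are usually left implicit.

Two analytic identities follow and are exploited throughout:

* **Aggregate identity.** The expected acyllysine signal is
  *a*·Σᵢ(1 − e^(−kᵢt)) with *a* the per-site signal amplitude.  If the
  rates take two distinct values with multiplicities (m, n−m), the
  aggregate is exactly a bi-exponential with amplitudes
  (m·a, (n−m)·a) — so a 3-fast/2-slow five-site system yields a 60/40
  amplitude split and fitting is a pure round trip, not an approximation.
* **State distribution.** The number of modified sites per molecule is
  Poisson-binomial in the *pᵢ(t)*; it is computed by the exact
  dynamic-programming convolution over sites (O(n²), no Monte Carlo) and
  its mean equals the aggregate signal divided by *a*.

A lag phase (seen in propionylation time courses, attributed to an
uncharacterized early process) has no mechanistic model here; it is
emulated phenomenologically by multiplying the aggregate signal with the
same logistic gate used in the lagged fitting model, shared across
sites, plus a baseline C.

## Kinetic models and fitting

Three nested models: mono-exponential (I_max, k), bi-exponential
(A₁, A₂, k₁, k₂; canonical order k₁ ≥ k₂ enforced by component swap at
construction, removing label switching), and lagged mono-exponential
(A, k, t₀, α, C), where the logistic gate equals ½ at t = t₀ and is
evaluated as written at t = 0 (no clamping).

Fitting is bounded trust-region least squares (`scipy.optimize.
least_squares`, method `trf`, ftol = xtol = gtol = 1e−12, ≤ 10 000
evaluations; deterministic given the initializer, no random restarts).
Bounds: amplitudes and rates ≥ 0, t₀ ∈ [0, max t], α ∈ (0, 10] min⁻¹.
Initialization: I_max from the curve maximum; k from a log-linear fit of
log(1 − I/I_max) over the first half of the curve (fallback
1/median(t)); the bi-exponential splits that k into (3k, k/3) with a
60/40 amplitude split; the lagged model puts t₀ at the steepest
numerical gradient with α = 0.5 min⁻¹ and C at the first intensity.
R² = 1 − SS_res/SS_tot with SS_tot about the mean intensity; it may be
negative for terrible fits and is reported as such.  AICc uses
k = p + 1 parameters (including the noise variance) with SS_res floored
at n·10⁻³⁰ so machine-perfect noiseless fits remain finite.
Non-convergence is annotated on the result, never raised.

## Model-selection ladder

The decision the original workflow made by eye — "are the residuals
systematic?" — is formalized as:

1. Fit mono.  Compute a one-sided Wald–Wolfowitz runs test on the
   residual signs (testing for *too few* runs, i.e. clustering;
   near-zero residuals are dropped; p < 0.05 ⇒ systematic) and an
   early-lag score (mean residual sign over the first quartile of
   timepoints).  If not systematic, choose mono.
2. Otherwise fit bi and lagged; discard candidates that fail to converge
   or do not exceed mono's R².
3. An early-positive/mid-negative residual sign flip (both beyond 0.25)
   argues for bi; failing that, an early-lag score > +0.5 argues for
   lagged — either heuristic decides only if its candidate is within
   ΔAICc ≤ 10 of the best candidate, so a pattern hint can never
   override a decisively better fit.
4. Remaining ties go to the lower AICc; exact ties to fewer parameters.

A lagged bi-exponential is available purely as a convergence probe and
is only auto-selected if it beats the lagged model by ΔAICc > 10.  All
thresholds (runs-test α, score thresholds, AICc guard) are constructor
parameters of `KineticModelSelector`; the defaults above were chosen
before any comparison against data and the rationale trail records each
decision.  The runs test uses the normal approximation, implemented
directly (with explicit edge-case handling for all-zero and single-sign
residual vectors) and cross-checked in the test suite against the
statsmodels implementation.

## Synthetic HSQC spectra and extraction

Spectra are synthesized as already-processed absorptive 2D matrices
(¹³C rows × ¹H columns); FID simulation, Fourier transform and phasing
are acquisition-side and out of scope.  Peaks are separable 2D
Gaussians; default FWHM 0.03 ppm (¹H) and 0.6 ppm (¹³C) — plausible
linewidths chosen as conventions, since none are published.  Default
axes: ¹H 1024 points, 9.8 ppm sweep centered at 4.69 ppm; ¹³C 64 points,
70 ppm sweep centered at 35 ppm so every catalog shift (9.23–37.08 ppm)
is on-grid.  The ¹³C coordinate of the acetyl-CoA peak (30.2 ppm) is a
synthetic convention: only its ¹H shift is observed.

Resonance roles drive a time series: product peaks follow the kinetic
aggregate, cofactor peaks decay by conservation
(initial − transferred)/initial, byproduct/static peaks stay constant,
and experiment 1 is emitted as a flagged pre-initiation spectrum with
products absent.  Extraction mirrors the processing protocol: select a
narrow F2 (¹H) ppm window around the product peak (1.84–1.89 ppm for
acetyllysine, 2.34–2.38 ppm for propionyllysine), form a skyline (max)
projection over ¹³C, and take its maximum per experiment; timepoints
come from the schedule rule (time of experiment 2 = deadtime; +3.6 min
per experiment thereafter; default 67 experiments ≈ 4 h).  Max- rather
than sum-projection is the default because the downstream statistic is a
maximum intensity, making the result insensitive to window width; sum is
available.  The raw processing-software window indices (624–628,
573–577) are carried as metadata only — their index↔ppm correspondence
depends on unpublished processing parameters.  Because peak centers
need not sit on grid points, extraction is attenuated by one constant
quantization factor per setup; this cancels in rate fitting and in
normalized comparisons.  Inter-experiment spectrometer latency is
ignored, matching the upstream timepoint-list convention.

## MALDI state ladders

[M+H]⁺ masses come from monoisotopic residue-mass summation (pyteomics)
plus j times the acyl mass shift: 42.01057 Da (acetyl) or 56.02621 Da
(propionyl), plus 1.00336 Da per ¹³C-labeled carbon transferred (2 for
acetyl, 3 for propionyl).  Peak intensities equal the Poisson-binomial
state probabilities: ionization efficiency is assumed uniform across
acylation states (MALDI bias is acknowledged but unmodeled, consistent
with treating MS as semi-quantitative).  Peaks are monoisotopic sticks —
isotopologue envelopes are considered deconvoluted upstream.  State
calling assigns each observed peak to the nearest ladder mass within a
0.25 Da default tolerance (rejected if windows would overlap),
normalizes to total assigned intensity, and reports unassigned intensity
separately.

## Synthetic-data scope

The generator reproduces the study conditions: five sites in a 3:2
fast/slow split (acetylation rates 0.0473/0.0156 min⁻¹ for p300Δ,
0.0455/0.0122 for p300; mono rates 0.0273/0.0312; propionylation lagged
parameters k = 0.0073/0.0081 min⁻¹, t₀ = 25.39/24.37 min with
α = 0.5 min⁻¹, A = 1, C = 0 as conventions where only k and t₀ are
published), a 5-min default deadtime, 3.6-min experiments, additive
Gaussian intensity noise (σ as a fraction of the maximum, default
scenarios use 2%), and exponential waiting-time Monte Carlo for
stochastic trajectories (one top-level seed per operation via numpy
Generators).  It does **not** emulate: baseline drift or 1/f noise,
relaxation and NOE effects, phase errors, peak-position drift, enzyme
inactivation, cofactor hydrolysis, or MALDI ionization bias.  Passing
tests therefore demonstrate correctness of the estimators under the
stated kinetic model, not robustness to every artifact of real spectra.

Problem sizes: round-trip and selection tests use the full 67-point
default schedule; Monte-Carlo checks use 5·10⁴ molecules (CLT band) and
noisy-recovery checks 100 seeded replicates at σ = 2% — sizes at which
the statistical bounds asserted are comfortably discriminating while the
whole suite runs in seconds.

## Known limitations

* No parameter uncertainties (bootstrap/profile likelihood) and no
  global multi-curve fitting.
* Per-site rates within a class are assumed equal; the underlying
  assignment of (K5, K8, K12) vs (K16, K20) rests on prior knowledge,
  not on anything identifiable from an aggregate curve.
* The ladder's residual heuristics are calibrated for the curve shapes
  this system produces; pathological curves fall through to the AICc
  tie-break.
* Models with more than two exponential components are deliberately
  excluded (they are unidentifiable on these data), as are
  Michaelis–Menten and substrate-depletion treatments.
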
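# Methods

## Coordinate and intensity conventions

Positions are in micrometres along the AP axis, increasing anterior →
posterior, with the compartment boundary at x = 0 (anterior territory at
negative x). This matches the "anterior is left" display convention and
makes alignment shifts additive. Intensities are arbitrary fluorescence
units; noise is multiplicative (see below) so intensities stay positive.

## The synthetic-disc model

The generator is a steady-state description of Ci-155 levels, not a
mechanistic simulation of pathway biochemistry. Hh is a one-sided
exponential anterior of the boundary,

    H(x) = exp((x − x_b)/λ),  x ≤ x_b,   λ = lambda_hh

with no posterior dynamics: posterior Ci-155 is a constant background
(default 0, as posterior cells do not express Ci) and posterior reporter
intensity is a decaying tail plus an optional artifact level, since
posterior reporter signal carries no pathway information. Three Hill
functions read the gradient:

- pathway activity      A(x) = f · Hill(H; K_act, n_act), where f ≤ 1 is
  the genotype's activability ceiling (`fu_responsive`);
- processing rate       k_proc(x) = k_proc0 · c_proc · (1 − Hill(H; K_inh, n_inh));
- degradation rate      k_deg(x) = k_deg0 · c_deg · Hill(A; K_deg, n_deg);

with genotype capability scalings c_proc (`processing_competent`), c_deg
(`degradation_competent`) and a basal-turnover multiplier m. Steady-state
full-length protein and reporter intensity are

    C(x)   = s_syn / (m·k_basal + k_proc(x) + k_deg(x))
    ptc(x) = ptc_base + ptc_gain · A(x)

**Defaults and why.** No kinetic rates have been measured for this system;
the defaults are a one-time calibration and are echoed into every run's
config snapshot. s_syn = 100, k_basal = 0.1, k_proc0 = 0.25, k_deg0 = 0.15
(rates per arbitrary time unit), λ = 20 µm, grid −150…+30 µm at 1 µm,
Hill (K, n): activation (0.3, 4), processing inhibition (0.15, 3),
degradation (0.5, 4), reporter map (10, 90). Consequences, all verified by
the test suite rather than asserted:

- resistant-variant anterior plateau s/k_basal = 1000 a.u. vs WT anterior
  s/(k_basal+k_proc0) ≈ 286 a.u. (strong elevation without processing);
- fold reduction by the boundary ≈ 2.4 and processing span ≈ 3.5 — both
  "more than two-fold", the qualitative magnitude the decomposition is
  meant to resolve;
- K_inh < K_act places the half-point of processing inhibition anterior
  of the reporter half-rise: processing inhibition is the more sensitive
  readout of low Hh;
- the WT trace peaks in the interior of the AP border stripe because
  processing inhibition (raising C) saturates at lower Hh than
  activity-driven degradation (lowering C).

**Genotype presets.** WT and S3-5 use all capabilities; S849A / P(1-3)A
set c_proc = 0; the Δ1270–1370-like preset sets c_proc = 0 and f = 0.2
(weak activability reproduces a weak reporter and no decline without
inventing mechanism); Su(fu)-null uses m = 8 with c_proc = c_deg = 0,
giving a uniformly low flat profile. These presets are phenotype tables,
not models of Su(fu)/Cos2/Rdx biochemistry.

**Additive mode.** For exact round-trip testing the generator can instead
emit C(x) = P(x) − R(x) with a processing-only curve
P(x) = C_lo + ΔC·Hill(H; K_inh, n_inh) and
R(x) = R_max·c_deg·Hill(A; K_deg, n_deg), all constants derived from the
same kinetic parameters (C_lo = s/(m·k_basal + k_proc0·c_proc),
ΔC = s/(m·k_basal) − C_lo, R_max = s/(m·k_basal) − s/(m·k_basal + k_deg0)).
Here C + R = P holds exactly, so the decomposition must return the truth
to machine precision; parameters that would drive C negative raise an
error naming the first offending position. In kinetic mode the additivity
assumed by the decomposition is only an approximation (rates add in the
denominator); the tests characterize this bias: the deviation of the
recovered no-reduction curve from the true processing-only curve is
confined to the zone where k_deg acts, and the half-inhibition landmark is
still recovered within 0.5·λ.

**Noise model.** Per-position noise, per-channel disc scale jitter and
boundary-position jitter are the generator's replicate structure. The
multiplicative factor is a mean-one lognormal, exp(N(0, s) − s²/2) with
s = √ln(1+f²), so the coefficient of variation equals the nominal noise
fraction f exactly. Defaults: f = 0.05, scale jitter 0.05, offset SD 3 µm.
What this does **not** emulate: tissue folds and shadows, attenuation with
depth, cell-size inhomogeneity, segmentation error, or spatially
correlated staining variation. Passing recovery tests therefore show the
inference is correct and noise-stable under idealized replicate
variation, not that real-disc systematics are handled.

**Clone datasets.** Clone regions are anterior-territory windows evaluated
with locally overridden rates, so an empty override set reproduces the
anterior means exactly and the relative-expression round trip has an
exact zero. Scenario presets encode published clone readouts as forced
pathway-activity levels (pka_loss: activity 0.74 with processing off;
cos2_loss: 0.50 with processing off; GAP-Fu: 0.50), giving
anterior-subtracted relative reporter values of ≈ 0.78 and ≈ 0.53.

## Profile operations

- **Extraction** is the arithmetic column mean over the ROI rows
  (0-based, half-open rectangle) — the manual rectangle-averaging
  workflow.
- **Smoothing** is a 5-point centered moving average whose window shrinks
  at the edges, so output length equals input length and values stay
  within the input extrema.
- **Landmarks**: baseline = mean over an anterior window (default: the
  anterior-most quarter); initial rise = first position exceeding
  baseline + 2·SD sustained for 3 samples (k and the run length are
  parameters — no published operational definition exists, so both are
  explicit); 50% rise = first position at or above the midpoint to peak;
  peak = global maximum, most anterior position on ties. With zero noise
  the baseline SD collapses and the "initial rise" becomes the first
  numerical increase; it is stable only in the presence of noise or after
  smoothing, which is why alignment landmarks a smoothed copy by default.
- **Alignment** shifts each disc so the reporter maximum sits at 0 (the
  maximum is taken to mark the compartment boundary; a posterior
  half-maximum edge definition is available via `reference=
  "posterior_half_max"` since the alternative operationalization cannot
  be excluded). Interpolation is linear on a common grid at the smallest
  input step; positions outside a disc's support are missing, and
  mean/SEM count only contributing discs (SEM undefined below n = 2).
  Three discs per condition is the recommended default; fewer are
  accepted with a logged warning.
- **Normalization** is by global maximum or by anterior-plateau mean;
  which mode was used is recorded in provenance, as the choice cannot be
  recovered from a normalized curve.

## Decomposition

The resistant-genotype average is the **unweighted mean of genotype mean
profiles** (not a disc pool), since the quantity of interest is a
genotype-level curve; genotypes are assumed intensity-comparable (common
staining/imaging), and no rescaling is applied by default. The common
grid is trimmed to x ≤ 0 because territory posterior to the reporter peak
is uninformative and the synthetic posterior background would corrupt the
subtraction there. Negative reduction values from noise are retained (so
the defining identities hold exactly); their fraction is reported in
provenance. The anterior window defaults to [grid start, x_rise − 2
steps], using the smoothed mean reporter for the rise landmark and
falling back to the anterior fifth of the grid if noise pushes the
detected rise to the grid edge. Inhibition landmarks use ε = 0.05 for "first" and "fully"
inhibited — guide-line definitions, exposed as a parameter. Inputs are
smoothed (window 5) before subtraction by default; `smooth_window=None`
gives exact arithmetic for oracle tests, and smoothing order is recorded
in provenance.

## Clone metrics and statistics

Within-disc replicate regions are averaged **before** normalization and
each disc contributes one value per formula, so n counts discs — the
natural independent unit (the alternative order is available by passing
single-region measurements). Subtracted formulas are affine-invariant;
the ratio formula is scale-invariant only. Genotype-vs-genotype
comparisons default to Welch's two-sample t-test because different
genotypes come from different animals and have no natural pairing; a
paired test (one-sample t on differences) is available but requires an
explicit pairing key and refuses degenerate zero-variance differences.
Significance marks: `*` p < 0.001, `#` p < 0.05. SEM uses the n−1 sample
SD and is flagged undefined for n = 1.

## Problem sizes

The default study conditions used throughout tests and the acceptance
script are 3 discs per genotype on a 181-point grid, 50 replicates for
noise-recovery rates, 1000 random fixtures for invariance checks and
10 000 null replicates for the t-test calibration.

## Known limitations

- The kinetic generator shares its Hill-response structure with the
  assumptions of the decomposition; recovery tests validate the inference
  pipeline, not the biological model.
- The additive/kinetic discrepancy means absolute no-reduction levels in
  kinetic mode are biased where degradation acts (bounded in tests);
  landmark positions are much more robust than curve heights.
- No image segmentation or registration: ROIs and region means are
  inputs, as in a manual workflow.
- The reporter-to-activity map is affine; reporter saturation and
  perdurance are not modeled.
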
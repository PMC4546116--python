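# Methods

This note documents the models behind `renomark`, the parameters that
matter, the numerical conventions, and what the synthetic data does and does
not emulate.

## Dosimetry

The kidney is treated as its own source and target (self-dose). The mean
absorbed dose is

D [Gy] = Ã [MBq·h] · 3.6×10⁹ [decays/(MBq·h)] · Δ [keV] ·
1.602176634×10⁻¹⁶ [J/keV] · φ / M [kg]

with defaults Δ = 147 keV (mean electron energy per ^177^Lu decay,
electrons only — no photon dose), φ = 0.93, kidney mass M = 0.3 g
(configurable; a typical adult-mouse kidney), and physical half-life
159.528 h (6.647 d). 100 MBq·h with these defaults gives 26.28 Gy.

**Time integration.** `integrate_tac` uses the trapezoid rule over the
samples, a linear rise from (0, 0) to the first sample (an i.v. bolus is
fast but not instantaneous; the convention makes hand checks exact), and an
analytic tail A_last/λ beyond the last sample that decays with the
*physical* half-life only — conservative, since any residual biological
clearance would only shorten the tail. On an exponential sampled at 200
points over 10 half-lives the scheme is within 0.5% of the closed form.

**Uptake model.** Kidney uptake saturates with injected activity as
u(A) = u₀·k_sat/(k_sat + A), the simplest one-site receptor-saturation form
that reproduces a declining Gy/MBq. Retained activity clears
biexponentially (defaults: 60% with a 12 h and 40% with a 90 h biological
half-life — ordinary small-animal kinetics for a residualizing
radiopeptide) on top of physical decay. u₀ and k_sat are free parameters;
`calibrate_uptake_model` fits them to a table of activity→dose anchors
(dose is linear in u₀ at fixed k_sat, so the fit is a 1-D bounded search
over log k_sat with u₀ solved by least squares). Calibrated to
30→16, 60→29, 90→40 Gy, the model predicts 120 and 150 MBq within ~3% and
~6% of 48 and 54 Gy. The calibration reproduces a printed dose table; it is
a stand-in for the unpublished biodistribution behind it, not a
reconstruction.

## Differential expression

Samples are quantile-normalized (each sample's sorted values replaced by
the across-sample mean of order statistics; ties receive the mean of the
reference values over the tied rank range), then the lowest 20% of genes by
cross-sample variance are dropped (configurable; 0 disables). Order is
normalize → filter.

Each exposure group (tissue × timepoint × activity, n = 3) is compared to
its age-matched controls with a two-sided Welch t on log₂ values;
log₂ ratio = group mean − control mean. If both groups are exactly
constant, p = 1 when the means agree and p = 0 otherwise (documented
convention). BH adjustment is applied per group across genes; a gene is
significant iff q < 0.01 **and** |log₂ ratio| > 0.58, both strict, so
boundary values are non-significant.

**Detection limit.** With n = 3 per arm a Welch test has 2–4 degrees of
freedom; after BH correction across even ~60 genes the critical t exceeds
~12, so only effects an order of magnitude above the replicate noise are
reliably detected at q < 0.01. This is a property of the design, not of
the implementation: at effect = 4×noise the dual-threshold power is below
1%, and near-certain recovery requires effect ≳ 100×noise. Tests assert
the achievable regime; the realized false-discovery proportion under the
global null stays below 0.02 over 50 simulated studies.

## Biomarker analysis

A gene's *recurrence* is the number of dose×time groups (15 per tissue in
the reference design) where it is significant; "recurrent" defaults to ≥ 2
groups. The packaged marker catalogue (kidney-injury, radiation, or both;
protein-biodosimeter flag) is matched case-insensitively after trimming.
One catalogue cell prints a log₂ ratio of exactly 0.58; fixture values are
stored as printed and are exempt from the strict runtime threshold, which
applies to computed calls only.

Dose–response is scored as the Spearman rank correlation of dose-ordered
log₂ ratios (average ranks for ties; fewer than 3 values is signalled as
insufficient data, not an error), plus a strict-monotonicity flag. The
published Cdkn1a cortex 12-month profile (1.3, 1.0, 1.6, 1.4, 2.0) scores
ρ = 0.8.

Regulator-target analysis is a deliberate simplification: per regulator,
the overlap of its packaged target set with the query gene set and a
one-sided Fisher exact p (hypergeometric upper tail) over a configurable
universe (default: genes on the array post-filter), ranked by overlap then
p then name. Proprietary causal-network scoring is out of scope.

## Scintigraphy

Frames are 256×256 count matrices. ROIs grow from a caller-supplied seed at
10% of the *local* maximal pixel count — the maximum is taken in a square
window (half-width 24 px) around the seed so the hot calibration syringe
does not set the kidney threshold — as the 8-connected above-threshold
component containing the seed, confined to the window. Segmentation is
idempotent and monotone in the threshold.

Activity is counts scaled by the in-frame syringe of known activity,
assuming equal attenuation; %IA decay-corrects to injection time with the
^99m^Tc half-life (6.007 h). Renograms follow the 7-frame protocol (1-min
frames at 2.5…32.5 min); the bladder content is read from the 27.5-min
frame. Both kidneys are summed (and reported separately). DMSA uptake is a
static 3-min frame at 3 h, normalized to the mean of control %IAs. Group
comparisons use the classical paired two-sided t, significant iff p < 0.05
strict; an exactly constant nonzero difference is resolved as p = 0 and
flagged.

Because a 10%-of-max contour of a Gaussian blob excludes the ~10% of counts
below it, fractional-max ROIs recover ~90% of an isolated blob's counts;
control-normalized quantities (DMSA % of control) and trends cancel this,
and the unbiasedness of `quantify_frame` itself is asserted with full
truth masks.

## Synthetic data

The generators produce the statistical structure the analysis assumes, with
every seed explicit:

- **Expression**: per-tissue matrices for the 5-activity (30–150 MBq,
  mapped to 16–54 Gy) × 3-timepoint (4/8/12 months) × n=3 design with 3
  age-matched controls per timepoint; gene classes null, monotone-dose
  (log₂ ratio linear in dose), late-responder (switch-on at 12 months) and
  table-driven marker profiles; homoscedastic Gaussian noise on the log₂
  scale (default sd 0.2, matching the log-ratio analysis and keeping
  t-assumptions transparent).
- **Kinetics/frames**: a three-compartment DTPA model
  (remainder → kidneys → bladder, first-order rates 0.03 and 0.2 min⁻¹;
  an impairment factor in [0,1] scales excretion, 0 = obstruction) whose
  compartments conserve the injected activity up to physical decay; scenes
  with two Gaussian kidneys (σ = 3 px), a bladder disc, a corner syringe
  rectangle (5 MBq) and the remainder spread over a body ellipse;
  pixelwise Poisson noise over expected counts = sensitivity
  (1800 counts·MBq⁻¹·min⁻¹) × activity × duration.
- **Blood**: analyte baselines (WBC 6×10⁹/L, RBC 9×10¹²/L, urea 8 mmol/L,
  creatinine 20 µmol/L) scaled by the packaged percent-of-control table at
  the nearest design cell, with mean-preserving log-normal noise
  (σ_log = 0.05).

Not emulated: probe/bead-level microarray artifacts, attenuation, scatter,
collimator blur, depth or 3-D anatomy, organ motion, inter-animal kinetic
variability. Passing tests therefore demonstrate correctness of the
analysis chain under its stated assumptions, not robustness to those
real-data effects.

## Problem sizes and numerical conventions

Simulation-based tests use compact configurations chosen to make the
Monte-Carlo error terms explicit: 50–200 seeded studies of 60–200 genes for
error control and power, 500 Poisson frames for quantification bias
(3-standard-error criterion), 1000 random vectors for the BH and Spearman
brute-force comparisons. Biodistribution curves are sampled on a 400-point
geometric grid over ten physical half-lives. The end-to-end pipeline is
byte-reproducible under a fixed seed; all randomness flows through
`numpy.random.default_rng` with explicit seeds, never global state.

Known limitations: the uptake model is a calibrated stand-in; kidney mass
is assumed, not measured; the n = 3 design bounds detectable effect sizes
as described above; and renogram %IA carries the fractional-max ROI
underestimate common to threshold segmentation.
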
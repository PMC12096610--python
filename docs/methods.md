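# Methods

## Release curves and the two-clock convention

An in vitro digestion run has a gastric phase (pepsin, pH 3.5, 120 min)
followed by an intestinal phase (pancreatin + amyloglucosidase +
invertase, pH 6.8, 480 min). Sampling times are recorded on each
phase's own clock — intestinal minute 0 is the start of the intestinal
incubation — and every stored point carries a phase label. Rates are
therefore only defined within a phase; a cross-phase difference
quotient would mix clocks and is rejected.

Glucose is measured only in the intestinal phase (0, 20, 60, 90, 120,
240, 360, 480 min), because amyloglucosidase is absent earlier; soluble
nitrogen and total amino acids are also sampled at gastric minutes 60
and 120. Since the enzyme cocktail changes at the phase boundary, the
measured value at intestinal minute 0 need not be zero, and the
interval rate always uses the measured baseline D(t1) — never an
assumed zero.

Rates are computed between sampled points only (the direct-calculation
convention; no kinetic model is fitted to data). An opt-in linear
interpolation exists for simulator-generated dense grids. Negative
rates — real fluctuations at low short-term release amounts — are
retained and flagged, never clipped, because the analysis compares
relative differences rather than absolute values at those points.

Units: diet-level glucose is carried in g/kg DM; ingredient-level
reporting uses g/100 g sample. The two differ by the exact factor 10,
applied at I/O as an integer ratio so round trips are bit-exact.
Soluble nitrogen is g/kg, total amino acids mmol/kg; mmol↔g conversion
is undefined without a molar mass and raises.

## Synchronization indices

The four indices are computed over the 0–20 min intestinal window (the
common period of rapid release for all three nutrients; the window is
configurable for sensitivity analyses). Reference rates are the
arithmetic means of per-diet mean rates across the panel, which fixes
the normalization property: the across-diet mean of each normalized
rate is exactly 1.

SEM semantics: indices are computed per replicate against one fixed
panel context (whose reference rates use the per-diet means), then
averaged to mean ± SEM with n = 3. The alternative reference — pooling
all replicate values — is available and provably identical when group
sizes are equal.

Classification uses Relative G/AA alone. The amino-acid index is the
deciding one because a diet can look synchronized on soluble nitrogen
while its amino-acid release is badly out of step (soluble nitrogen
includes peptides not yet hydrolysed to amino acids, and the published
five-diet panel contains exactly such a case). The default band
[0.75, 1.50] is the widest band around 1 that separates the observed
panel into its reported classes; both bounds are configurable, and the
band is closed (a value exactly on a bound is Syn). Zero glucose rate
is legal (index 0); zero nitrogen or amino-acid rates make the indices
undefined and raise with the advice to widen the window, rather than
emitting infinities.

## Digestibility and balance

AID, IAA and SID follow the standard chromium marker-ratio equations
with concentrations per kg DM. Design choices:

- The basal endogenous loss applied in the SID correction is the
  arithmetic mean of per-animal losses from nitrogen-free-fed animals
  (median available as a robust alternative).
- Crude-protein AID uses the same marker equation with CP
  concentrations; no basal-loss correction is applied to CP.
- Negative AID values (possible in low-protein assays) are reported
  with a warning, never truncated; fecal output exceeding intake
  likewise warns but computes.
- ATTD and the excretion fractions are computed from the same amounts,
  so ATTD + 100·fecal/intake = 100 holds identically — this is used as
  an internal consistency check, not a rounding target.

Per-diet summaries are mean ± SEM over animals with Tukey letters from
the stats module.

## Diet design

Inclusion percentages are exact two-decimal `Decimal`s; the sum-to-100
check uses a 0.01 percentage-point tolerance with no float drift. The
substitution gradient places the slowly digested starch at
total·i/(n−1) for level i, rounded to 2 dp, with the rapidly digested
base taking the exact remainder, so pairs conserve the total exactly
and consecutive steps are equal. Formula completion assigns
100 − Σ(fixed) to a single filler and the result always validates.
Validation checks non-negativity, the sum, and the presence of the
chromic oxide marker at its declared 0.30% level. Analyzed nutrient
contents are treated as measured outputs of a formulation, never as
design inputs.

## The simulator

The generator's job is to produce data with the qualitative features
the analysis must handle, plus exact ground truth. It uses saturating
first-order kinetics, D(t) = A·(1 − exp(−k·max(0, t − lag))), as a
stand-in shape — chosen because no single mechanistic model is
universally applicable to digestion curves, and the pipeline under test
deliberately avoids model fitting. Defaults were chosen once to mirror
the study conditions:

- 3 replicates per substrate; additive Gaussian noise on each sampled
  cumulative value, clipped at zero. Additive noise deliberately
  produces occasional non-monotone replicates at low amounts,
  exercising the fluctuation-flagging path.
- Glucose: intestinal phase only, endpoints A = 450 g/kg, k = 0.030/min
  (rapid: ~97% released by 120 min) down to A = 280 g/kg, k = 0.007/min
  (slow: still rising at 480 min), interpolated linearly by the waxy
  starch fraction of the diet.
- Soluble N and amino acids release in both phases; their intestinal
  cumulative values carry the noiseless gastric amount forward as a
  baseline offset. The default panel shares one protein parameter set
  across diets, matching the constant protein mix of the design.
- The ingredient archetype grid maps release rate to the rate constant
  and lag (rapid: k₀ = 0.030/min, no lag; slow: k₀ = 0.006/min, 10 min
  lag), released amount to the amplitude (high 80, low 30 g/100 g), and
  release duration to a rate multiplier (persistent ×0.35, transient
  ×1.6), so the eight archetypes occupy distinct (A, k, lag) regions.

For recovery experiments, `simulate_targeted_panel` inverts the index
definitions: given target Relative G/AA values r_d, amino-acid weights
a_d = (1−t) + t/r_d make the constraint mean(r·a) = mean(a) linear in
t, which is solved in closed form; glucose rates follow as g_d ∝ r_d·a_d
and window rates are converted to amplitudes through the first-order
closed form at a shared rate constant (0.04/min; glucose 0.03/min).
The noiseless panel then reproduces the targets to 1e-12.

The virtual trial (6 animals per diet by default, 9-day periods,
nitrogen-free diet for endogenous losses, 0.3% Cr2O3 giving 2.05 g
elemental Cr/kg) generates digesta concentrations by inverting the
marker-ratio equations at the configured truths, so at zero noise the
analysis pipeline recovers every truth to machine precision; with noise
on, independent multiplicative assay errors (CV 4% by default) perturb
each measured concentration. Group-level truths (ATTD, excretion
fractions, ADG, ADFI) default to values on the scale reported for this
kind of trial. Between-replicate and between-assay errors are assumed
independent; the true correlation structure of wet assays is unknown.

Determinism: one global seed feeds `numpy.random.SeedSequence`, with
per-stream sub-seeds spawned deterministically — identical seed and
configuration give identical output with no time-based entropy.

## Statistics

Group comparisons wrap scipy: one-way ANOVA with Tukey HSD, the
two-sided two-sample t-test, and Kruskal–Wallis with pairwise two-sided
Wilcoxon rank-sum tests. Tukey pairwise significance is decided on the
studentized-range statistic against a cached critical value, which is
exact and lets tight simulation loops skip the expensive per-pair
p-value integrals; p-values, when requested, match
`scipy.stats.tukey_hsd`. Compact letters use the insert-and-absorb
algorithm; a secondary trend tier (x, y at 0.05 < P < 0.10) is
available and off by default. Degenerate inputs are defined explicitly:
all observations identical → nothing separates (p = 1); zero
within-group variance with distinct means → groups separate exactly.
No multiple-testing correction is applied across metrics.

## Problem sizes and limitations

Simulation-based checks use 20 panel seeds for class recovery, 200
virtual animals per diet for AID recovery, and 2,000 replicates for the
null calibration of the Tukey pathway — sizes chosen to make the Monte
Carlo error small relative to the tolerances being checked.

What passing tests do and do not show: the simulator demonstrates that
the pipeline's equations are implemented correctly (exact inversion),
that estimates are unbiased under the assumed noise model, and that
classification is robust at the designed effect sizes and 5% noise. It
does not validate the first-order shape against real digestion curves,
does not model correlated assay errors or animal-period effects, and
the class-recovery result is specific to the designed index spread; real
panels with indices near the band edges will classify less reliably.
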
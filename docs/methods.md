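# Methods

## Forward model of a post-HDX deuterium ladder

An analyte ion carries a set of exchangeable (labile) protons — hydroxyl,
phenol, amine, imine N–H, amide N–H, carboxyl — plus, for proton-bearing
adducts ([M+H]⁺, [2M+H]⁺), the charging proton itself. During microdroplet
HDX each of these positions exchanges independently with some probability,
so the number of incorporated deuteriums is **Poisson-binomial**:

    P(D = d) = Σ over site subsets S with |S| = d of Π_{i∈S} pᵢ Π_{i∉S} (1 − pᵢ),

computed by the standard O(n²) convolution recurrence (exact, no sampling).
For [2M+H]⁺ multimers the monomer site set is doubled. Sodiated ions have
no charging proton and show only site-derived channels.

The effective per-site probability in the liquid phase is

    pᵢ_eff = p(class) × d2o_fraction × back_exchange_factor,

with `d2o_fraction` the deuterium fraction of the exchangeable hydrogen
pool (1.0 for a pure-D₂O aqueous component, as in a 7:3 methanol:D₂O
spray) and `back_exchange_factor ∈ [0,1]` modeling re-protonation in
flight. Gas-phase mode sets every pᵢ_eff = 1: complete exchange erases
functional-group information, which is exactly why *incomplete* liquid-
phase exchange is the informative regime.

Because a deuterium shift (+1.006277 Da) is not resolved from ¹³C/¹⁵N/¹⁸O
substitutions at R = 120,000 (FWHM ≈ 0.002), the observed channel k is the
convolution of the deuterium pmf with the ion's natural isotope pattern,
aggregated per nominal mass offset. Natural patterns come from per-element
polynomial convolution over the NIST/IUPAC abundance table shipped with
pyteomics; exact masses use the same table with electron-mass correction
(reproducing the reference values 300.1594 and 328.1543 at 4 d.p.).

### Exchange-probability defaults

The per-class probabilities are calibration constants of the model, fixed
once from the qualitative behaviour of the reference panel and not fitted
to any numeric target:

| class     | p    | rationale |
|-----------|------|-----------|
| hydroxyl  | 0.45 | sugar base peaks: binomial(5,p) mode 2 (glucose) and binomial(6,p) mode 3 (inositol) force p ∈ (3/7, 1/2) |
| phenol    | 0.20 | slower than alcohols; keeps single-phenol opioids D₀-based |
| amine     | 0.50 | fast, comparable to hydroxyl |
| imine_NH  | 0.50 | moves norcodeine's base peak to D₁ while morphine stays D₀ |
| amide_NH  | 0.30 | intermediate |
| carboxyl  | 0.60 | fastest class |
| charge site | 0.25 | must stay < 0.43 or every [M+H]⁺ ion would acquire a D₁ base peak |

Morphine and naloxone share the same class multiset {phenol, hydroxyl}, yet
their measured base peaks differ (D₀ vs. D₁). Within a class-level model
this is only expressible as differential back exchange, which the exchange
literature supports for this pair; the fixture table therefore carries a
per-compound `hdx_attenuation` (morphine 0.65, all others 1.0) that scales
all of a compound's effective probabilities. Glucose, inositol and
sphingosine are modeled without the extra charge-site trial
(`charge_site_exchange=false`): their maximum observed channel equals the
site count, and for sphingosine the charging proton resides on an amine
already counted among the sites.

### Instrument/noise model

Per-channel multiplicative log-normal noise with mean 1 and a chosen CV
(default 5%), seeded through `numpy.random.default_rng`; channels below a
relative intensity floor are dropped. This is the simplest model
consistent with day-to-day relative-abundance RSDs under 15%; it carries
no heteroscedastic shot-noise or detector-saturation structure.

## Ladder detection and natural-isotope correction

Channel k of a precursor is searched at `m/z + k × 1.006277` within an
accumulated window `k × 0.0002` (each step contributes its own mass-accuracy
error; the linear accumulation is the conservative reading of the per-step
window 1.0063 ± 0.0002). The observed ladder is a lower-triangular
convolution of the deuterium distribution with the natural pattern, so the
distribution is recovered by forward substitution; noise can drive
components negative, which are clipped to zero and renormalized (standard
practice in isotope-enrichment correction).

A channel is called *deuterated* when its corrected mass is ≥ 1% of the
largest corrected channel (threshold relative to the distribution's base,
so that faint but real high channels of strongly exchanged ions are kept
while the natural tail of unlabeled ions is not). The exchangeable-site
estimate is the highest flagged channel minus one for the charge-site
deuteron when applicable; it is a lower bound, since sub-threshold tails
truncate (e.g. the urea dimer's eight amide sites flag only to D₇ at the
defaults). Base-peak ties break toward smaller k for determinism.

## Mixture deconvolution

Two isobaric components with (assumed) equal ionization efficiency mix
linearly in molar amount: `I_abs(k) = N_g I_g(k) + N_i I_i(k)`. Patterns
are compared after base-peak normalization with the mean absolute
deviation over the common zero-padded channel range, in percent units.
Composition is estimated by minimizing that L1 loss over the mole-fraction
simplex: a 10⁻³ grid followed by a 10⁻⁵ local refinement (the objective is
piecewise linear, so grid search is both exact enough and deterministic;
closed-form least squares would optimize the wrong norm).

**Identifiability limitation.** For glucose/inositol the two per-mole
relative patterns differ by only ~9% per channel on average, while 3%
channel noise induces best-fit losses of ~0.5–1.7%. The estimator is
therefore unbiased but not sharp: across 100 seeded mixtures the mean
recovered mole fraction is within ~0.01 of truth and the mean absolute
per-seed error is ~0.04, but individual fits can deviate by up to ~0.2.
Pairs with more distinct ladders deconvolve proportionally better; the
collinear limit raises an explicit non-identifiability error.

## Quantitation

One isobar is quantified from its *signature channel* — the smallest
deuterium channel flagged for the target but not the interferent (D₂ for
codeine over hydrocodone). The response is the corrected absolute
intensity of that channel divided by an internal-standard channel
(defaulting to the IS ladder's base peak); ratioing to the IS removes
run-to-run scale, so base-peak renormalization is deliberately not applied
here. Calibration is ordinary least squares on (concentration, response)
with Pearson r reported; inverse prediction flags negative results as
below range rather than clipping. Concentration units (µg/mL by default)
are carried explicitly; molar conversion requires the molecular weight.

## Cohort profiling

Feature matrices hold TIC-normalized intensities (total ion current scaled
to 100 per spectrum): one feature per precursor (D₀), plus one feature per
deuterium channel detected anywhere in the cohort when augmentation is on.
Features are autoscaled (unit variance) before PCA, since metabolite
intensities span orders of magnitude; component orientation is fixed by
making each component's largest-magnitude loading positive. Group
separation is scored as the mean silhouette in the PC1–PC2 plane — a
quantitative stand-in for "the score plot separates cleanly", chosen
because no numeric separation metric is standard for visual PCA claims.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their seed. The compound panel (12
reference compounds with formulas, adducts and exchange-site annotations)
ships as a TSV compound table. The cohort generator emulates a
direct-infusion urine study: 30 cases vs. 9 controls, the panel plus 30
deuteration-free decoy ions at random m/z in 50–300, log-normal biological
abundance variation (CV 40%), channel noise (CV 5%), and two group
effects on the urea/creatinine marker ions — reduced back exchange in
cases (factor 1.0 vs. 0.6) and a 1.4× abundance multiplier. Pre-HDX
spectra (d2o_fraction = 0) provide the intensity-only baseline.

Passing tests on this cohort show that the *pipeline* converts an
exchange-extent difference into PCA-separable features; they do not show
that real bladder-cancer urine carries such a difference, nor do the
decoys approximate real urinary matrix complexity, ion suppression, or
adduct heterogeneity. Calibration series are likewise idealized: the
interferent is held at fixed concentration and ionization efficiencies
are equal by construction.

## Problem sizes and numerical choices

Monte-Carlo experiments use 100 seeds × 3 ratios for mixture recovery and
20 seeded cohort realizations for the separation property — sizes at which
the reported means are stable to well under their tolerance. Tolerances:
pattern/convolution identities are checked at 1e−12, correction round
trips at 1e−9 (float accumulation in forward substitution), printed masses
at the 4th decimal place. Degenerate inputs (all-zero spectra or ladders,
collinear pure patterns, single-group cohorts, missing precursors) raise
typed errors rather than returning sentinel values.
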
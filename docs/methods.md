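# Methods

## Model and pipeline

The package predicts biochemical recurrence from per-pixel spectral-metric
data of tumor-adjacent stroma. The underlying assumption is that the
recurrence signal lives in *subsets* of pixels sharing a biochemical state,
not in whole-sample averages: averaging spectra over a heterogeneous core
washes out a signature carried by, say, 20 % of the stroma. Patterns —
conjunctions of discretized metric values — are the device for finding such
subsets, and a pattern's per-sample match frequency is the feature.

The stages, in run order:

**Discretization.** Each metric is cut into `n_bins = 20` equal-width bins
spanning the training range, with the bin midpoint as representative value.
Bins are half-open `[lo, hi)`, the last bin closed, and out-of-range test
values clip to the extreme bins. Equal-width (not quantile) binning is used
so that a bin means the same absorbance interval in every sample. A
constant-valued metric degenerates to a single bin with a warning.

**Mining.** FP-growth enumerates every pattern with support
≥ ceil(θ·n_pixels), θ = 0.02 by default, separately for recurrence and
non-recurrence pixels; the two sets are unioned (a pattern frequent in both
is attributed to the class with the higher support) and both supports are
recorded. A brute-force itemset enumerator ships alongside as the oracle
for the miner and is held to exact set equality in tests. Pattern length is
capped (default 4) to bound the search; the cap is configurable.

**Discriminative screen.** For each candidate pattern we compute each
subject's pooled match frequency — the fraction of all the subject's
eligible pixels matching, pooling cores so evidence scales with pixel
count. Stage 1 is a two-sided Wilcoxon rank-sum between the classes'
per-subject frequencies at α₁ = 0.05; stage 2 keeps survivors whose
frequency is one-sidedly *larger in the pattern's source class* (for a
symmetric rank test this equals requiring one-sided p ≤ α₁/2). Survivors
are ranked by one-sided p, ties by |rank-biserial effect| then canonical
pattern order, and the top m = 100 are retained. The rank tests use the
tie-corrected normal approximation, vectorized over patterns; scipy's exact
implementation is the unit-test oracle. With ≥ 30 subjects per class the
approximation error is negligible. When no pattern passes (expected on
null data in cross-validation folds), the screen relaxes to
direction-consistent patterns ranked by p, with a logged warning — a fold
must still emit predictions.

**Feature selection.** Greedy mRMR over the m pattern frequencies:
relevance is mutual information with the class label, redundancy the mean
mutual information with already-selected features, both estimated after
10-quantile binning (frequencies are heavily zero-inflated, so equal-width
bins would be nearly empty). Stage 2 refines the subset by sequential
floating add/remove steps accepted only when inner-CV pairwise ranking
accuracy improves by > 1e-6; the accepted-objective trace is non-decreasing
and the search terminates by an iteration cap. Refinement is optional
(`selection="mrmr"` skips it) since it multiplies training cost by the
candidate count.

**Ranking-SVM.** Linear kernel, C = 1, features z-scored on the pooled
training cores. Every ordered constraint "case core s above control core t"
becomes the two hinge examples (s−t, +1), (t−s, −1); with a matched-pair
design constraints are restricted to within pairs, otherwise all
case×control combinations are used, subsampled (seeded) beyond a cap.
Ranking by a linear scorer is invariant to affine feature rescaling when
the scaler is refit, which the tests assert.

**Preference scores.** With pooled ranks over S₁ ∪ S₂,

    Preference(p₁;p₂)   = Σ_{s∈S₁} rank(s)^d,   d ≥ 1 (default 1)
    Preference^min      = Σ_{i=1..|S₁|} i^d
    Preference^max      = Σ_{i=|S₂|+1..|S₁|+|S₂|} i^d
    nPreference         = (Preference − min) / (max − min)

At d = 1 nPreference is exactly the normalized Mann–Whitney U of S₁ over
S₂ (property-tested against a pairwise-counting oracle); d > 1 up-weights
the top ranks. Tied core scores receive midranks, making nPreference
symmetric in the two patients (fully tied sets give exactly 0.5).

**IR Score.** For a query, the most similar recurrent and non-recurrent
training patients are found by Euclidean distance over z-scored (age at
prostatectomy, Gleason sum, ordinal stage T2a→1 … T3b→4); equidistant
candidates resolve to the lower patient id. The two nPreference values
against the matches feed a logistic regression fitted on leave-one-out
covariates of the training set; the fit uses maximum likelihood with a
weak ridge (sklearn, C = 10⁶) so coefficients stay finite under
separation. Degenerate (constant) covariates fall back to an
intercept-only model at the class prevalence.

**Baselines.** CAPRA-S ships with the published point table (PSA ≤6/≤10/
≤20/>20 → 0–3; Gleason no pattern 4 → 0, secondary 4 → 1, primary 4 → 3;
margins 2, SVI 2, ECE 1, LNI 1; categories 0–2/3–5/≥6) as an editable
config, since only the per-variable maxima are fixed by the method
definition. The Kattan nomogram's Cox coefficients are proprietary and are
deliberately not bundled: `kattan_ppr` requires a user-supplied table and
raises otherwise. The combined score C = (1−x)·IR + x·E expects both inputs
on a probability scale (CAPRA-S divided by 12); x weights the external
score, so x→0 recovers the IR Score.

## Evaluation designs

**Nested pair CV.** Pairs are never split across the K = 10 folds; per test
pair, the member with the higher nPreference is predicted to be the case,
and the exact one-sided binomial tail P(X ≥ correct | n, ½) measures
significance. The comparison is a *randomized forced choice*: tied core
scores are separated by a seeded infinitesimal jitter before ranking, and a
pair at exactly nPreference 0.5 falls to a seeded fair coin. This matters:
nPreference over 2–4 cores per patient is a coarse rank statistic that hits
exactly 0.5 for ~15 % of uninformative pairs, and any deterministic tie
rule couples the decision to the fitted model's score distribution, which
miscalibrates the binomial test under the null. The randomized rule makes
the null success probability exactly ½ per pair; under real signal ties are
rare and power is unaffected. Tie usage is counted and logged.

Note a separate, irreducible caveat: across the pairs of one cohort, CV
outcomes are positively correlated because every fold's model is trained on
the other folds' pairs. The per-replicate accuracy therefore has somewhat
more variance than Binomial(n, ½)/n even though its mean is exactly ½ (we
verified both properties by simulation: mean 0.50 over 40 independent null
cohorts; dispersion ~1.7× binomial). This is the familiar dependence of
cross-validation estimates, not a property of the scoring rule.

**Query CV.** Stratified K-fold over patients; each patient is scored
exactly once by a pipeline (discretizer, patterns, screen, selection, SVM,
IR-score model) fitted without them. Leave-one-out (K = n) is supported.

**ROC/AUC.** The empirical AUC is the tie-corrected rank statistic
(identical to the normalized Mann–Whitney U; property-tested against pair
counting). Because the empirical step-function AUC is biased downward at
small n, a binormal-smoothed AUC Φ(Δμ/√(σ₁²+σ₀²)) from per-class normal
fits is always reported alongside. Bootstrap CIs resample patients within
class (percentile method, default 2000 reps); the AUC-difference test uses
a paired stratified bootstrap with a two-sided sign-based p. Quartiles are
assigned by stable score order (ties to the lower quartile, sizes within
1); odds ratios come from a maximum-likelihood logistic fit with Wald CIs,
the trend test from the ordinal quartile index.

## Synthetic cohorts

The generator emulates an outcomes tissue-microarray study: `n_pairs`
matched case-control pairs (exact match on Gleason sum, pathologic stage
and race; control age within ±3 years), 2–4 cores per patient, several
hundred stromal pixels per core with k metric values. Clinical marginals
default to a mid-grade-dominant cohort: age ~ N(62, 7²), Gleason sum
{6, 7, 8} with probabilities {0.20, 0.70, 0.10}, stage {T2a, T2b, T3a,
T3b} with {0.117, 0.55, 0.317, 0.016}, PSA lognormal matching means/SDs of
10.6/8.7 (cases) and 8.6/6.0 (controls).

Pixels are i.i.d. N(0, 1) per metric within a core given class; the
epithelial blob at the core center is shifted by +0.8 and is not analysed
downstream. A planted pattern overwrites its metrics with the generator
bin's midpoint plus uniform sub-bin jitter (±5 % of the bin width) in a
Bernoulli-selected fraction of stromal pixels, so the true per-class match
fraction equals the configured enrichment up to a (1/20)^|φ| chance term.
The tight jitter keeps planted pixels inside one fitted bin in almost all
realizations even though the pipeline refits bin edges on training data.
One seed feeds three named substreams (clinical, pixels, planting), making
cohorts bitwise-reproducible.

What the generator does *not* emulate: spatial pixel correlation within
cores, instrument drift and baseline artifacts across TMA slides,
cell-type misclassification, correlated metrics (real spectral metrics are
strongly collinear), and clinical-variable/outcome confounding. Passing
tests therefore demonstrate correctness and calibration of the machinery
under known ground truth — not expected performance on patient data.

## Problem sizes and defaults

Generator defaults (60 pairs, 200–1500 pixels/core, 20 metrics) mirror the
cohort scale the method targets. The test-suite and acceptance runs use
reduced sizes chosen for desk-scale runtime — 30–120 pixels per core, 6
metrics, pattern length ≤ 3 — at which a 0.30-vs-0.05 planted enrichment
is still recovered with AUC > 0.95 and null cohorts stay calibrated.
θ = 0.02, m = 100, α₁ = 0.05, 20 bins, K = 10 and d = 1 are the method
defaults throughout.

## Known limitations

- The discriminative screen's p-value ranking saturates when a pattern
  separates the classes completely; sibling patterns sharing planted items
  then tie with the true pattern and the exact top rank is not guaranteed
  (retention in the top m is).
- The normal-approximation rank test is slightly conservative at moderate
  subject counts (measured type-I ≈ 0.044 at α₁ = 0.05 with 100 + 100
  subjects).
- The logistic quartile OR diverges under complete separation (it is
  reported with a warning and a ridge fallback); on strongly separable
  synthetic cohorts the quartile table is not meaningful.
- Survival time is not modelled; recurrence is strictly binary here.
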
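# Methods

## Design and behavior

One block holds 107 experimental trials — 16 match, 48 partial, 12 mismatch,
12 catch, 16 neutral, 3 neutral catch — plus 36 null events. The 48 partial
trials cover the 12 valid prior×morph combinations (each of 4 identities
crossed with the 3 morph pairs containing it) exactly 4 times. Ordering is
rejection-resampled until no face identity (clear or inside a morph) appears
on more than 4 consecutive trials and no more than 2 null trials are
consecutive; with the default composition a valid permutation is found within
a few dozen attempts, and the sampler raises after 10,000 attempts naming the
violated constraint. Catch-type trials carry no face stimulus and never enter
the RSA structures.

Behavioral prior precision per morph pair is (n_prior − n_otherpart)/n over
valid partial responses naming an identity inside the morph; responses slower
than the response window (default 1500 ms — the study excluded "too slow"
responses without printing the cutoff, so it is configurable) are excluded.
Counts are pooled across the two prior directions of a pair by default
(`mode="keyed"` keeps one entry per prior×pair); a pair with n = 0 is
reported missing and dropped from hypothesis RDMs rather than imputed, since
the ratio is undefined and imputing 0 would silently assert "no prior use".
The assimilation index averages percent-expected responses over the 12
combinations (50 = no prior effect).

## Feature space

Identity activations are synthetic stand-ins for pooled post-ReLU
convolutional features: sparse nonnegative codes (Bernoulli(0.2) support,
active amplitudes uniform in [0.5, 1]), optionally sharing a common component
(`distinctness` < 1). Bounded amplitudes matter: the sharpening rule rescales
the prior by its maximum absolute entry, and under heavy-tailed amplitudes
that rescaling drives almost all prior weights toward zero, collapsing the
Sharpening model onto the Sensory-Input model. The four identities come out
equally distinct (coefficient of variation of the six pairwise correlation
distances ≈ 0.08 on average).

Morph activations are rectified convex mixtures of the parent identity
vectors (50/50 by default). This is a documented approximation: the original
analysis fed morph *images* through a network, and feature-level mixing only
preserves the contract that a morph lies between its parents. The HDF5 import
adapter (`load_activation_export`) exists so real image-derived activations
(which may be signed; no rectification is applied) can replace the synthetic
bank without touching the rest of the pipeline.

## Hypothesis models

PE subtracts the precision-weighted prior elementwise. Sharpening multiplies
the input by (1 + |p|·precision) where the signs of input and prior agree
(p = prior / max|prior|) and by (1 − |p·precision|) where they disagree; a
negative precision therefore dampens congruent features (a contrastive
prior), and the input's sign is always preserved. The final compression is
sign(y)·log1p(|y|) by default: the plain log is undefined at 0, which pooled
rectified activations regularly hit; log1p is monotone, sign-preserving and
serves the same purpose of taming large products (`log_mode="log_eps"` gives
log(|y|+ε) instead). Neutral conditions always carry the raw identity
vectors.

Hypothesis and neural RDMs use 1 − Pearson correlation, rank-rescaled to
[0, 1] with average ranks so ties stay tied (values are rounded at 1e-12
before ranking so floating-point fuzz cannot break genuine ties). Model–brain
agreement is evaluated on the 48 neutral×partial cells by default (matching
the noise-ceiling cell set); the full lower triangle is available via
`comparison_cells`. Hemispheric RDMs are averaged on raw distances and
rank-rescaled once — ranking ranks of averaged ranks would be ill-defined.

Kendall's tau-a is computed as (concordant − discordant) / (m(m−1)/2) with
tied pairs counting to neither; it is implemented directly (vectorized sign
outer products) because standard libraries expose tau-b, which renormalizes
away ties. A consequence worth knowing: the Sensory-Input RDM contains
structurally tied cells (both prior directions of a morph share one
activation vector — 24 of the 1128 cell pairs), so even a neural RDM
*identical* to the Input RDM yields tau-a ≈ 0.979, not 1. Noise ceilings use
the standard construction — upper bound: mean tau-a of each subject against
the grand-mean RDM; lower bound: against the leave-one-out mean.

## Group inference

Model-vs-zero tests are one-sided Wilcoxon signed-rank tests, Bonferroni
corrected over the tests per region; model comparisons are two-sided paired
Wilcoxon tests, BH-FDR corrected over the declared family. The normal
approximation with tie and continuity correction is used for N ≥ 20, the
exact distribution otherwise; Wilcoxon's r = |Z|/√N always uses the
approximation's Z so it is defined in both modes, and zero differences are
dropped (the usual convention). Reaction-time condition effects use a
Friedman omnibus with Kendall's W = χ²/(N(k−1)) and a rank-based
Tukey–Kramer (Nemenyi) post hoc: mean-rank differences referred to the
studentized range distribution with infinite degrees of freedom.

The *winning model* criterion used by the recovery experiment is: largest
group-mean tau-a, AND significant vs zero after Bonferroni, AND significantly
greater than the runner-up in a one-sided paired Wilcoxon test (the
directional complement of the two-sided comparison table). A cohort meeting
none of these declares no winner.

## Searchlight

Sphere neighborhoods are built in world millimetres through the grid affine
(anisotropic voxels supported): default radius 6 mm, truncated to 90 voxels
by ascending distance with a lexicographic tie-break; a center whose in-mask
fraction of the geometric sphere is below 10% is invalid. Per center the
neighborhood patch yields a neural RDM and one tau-a per hypothesis model;
maps are Fisher z-transformed. Group maps are voxelwise one-sample t-tests
with sign-flip permutation max-T familywise control (Bonferroni as fallback);
random-field corrections are out of scope. Gaussian smoothing of z-maps is
available but off by default on synthetic grids.

## Synthetic cohorts

Behavior: on a partial trial the expected identity is reported with
probability (1+w)/2, so the precision estimator's expectation equals the
subject's prior-use weight w exactly; w is drawn per subject from a clipped
normal (default mean 0.35 — matching an assimilation index in the mid-60s —
and SD 0.2, reflecting the wide between-subject spread of prior use).
Responses naming an identity outside the morph occur at a 4% rate; RTs are
log-normal with condition means of 591 (match), 727 (mismatch), 670/784 ms
(prior-confirming/contrastive partial responses).

Patterns: condition×voxel responses are W·center(f) + ε where f is the
mechanism's feature-space representation (neutral conditions: raw identity
vectors) and W a per-subject random isometry with zero column sums (QR of a
column-centered Gaussian). This choice makes voxel-pattern Pearson
correlations equal feature-space correlations exactly, so the noiseless limit
reproduces the matching hypothesis RDM cell-for-cell; when n_voxels < dim+2 a
plain Gaussian W is used and the identity holds only approximately. Noise is
iid Gaussian with `noise_sd` expressed as a noise-to-signal norm ratio.

Three sources of between-subject variability emulate what bounds real noise
ceilings: idiosyncratic neural tuning (`subject_jitter`, rectified Gaussian
perturbation of the shared bank), per-subject perceptual 50/50 morph
calibration (`morph_alpha_sd`; hypothesis models always use the canonical
50/50 morph, as the original analysis did), and optional subject-specific
feature sampling (`feature_frac`). Defaults: 20 subjects, 200 voxels per
(bilateral) region, feature dim 128, noise_sd 2.8 — calibrated once so the
noise-ceiling lower bound lands near 0.33, inside the 0.1–0.4 regime typical
of multi-subject RSA on single stimuli.

One trial-order randomization per block is shared across a cohort's subjects
by default (`share_design=False` restores per-subject orders); order affects
no downstream statistic. Seeds expand from the master seed through
`numpy.random.SeedSequence` substreams per subject and region, making cohorts
bit-reproducible.

## What the simulations do and do not show

The generator validates the *pipeline*: estimator identities (precision ↔ w),
the noiseless RDM identity, test calibration (empirical size of the vs-zero
test ≈ 0.04 at nominal 0.05), searchlight localization of a planted region,
and mechanism recovery. It does not simulate hemodynamics, autocorrelated
fMRI noise, or the GLM stage — patterns are generated directly at the
T-pattern level the RSA consumes — so passing tests certify the analysis
logic, not acquisition- or preprocessing-level robustness.

A structural finding from the recovery experiments: because every subject's
RDM shares the design's coarse ordering (morphs are closer to their parent
identities) and the group-mean mechanism signature, the leave-one-out noise
ceiling stays near 0.5 whenever per-subject data are clean, for any amount of
representational jitter. Pushing the noise-ceiling lower bound down into the
0.1–0.4 regime therefore requires measurement noise strong enough to scramble
within-subject orderings, and in that regime the Sharpening-vs-Input margin
(inherently ~0.01–0.02 tau at precision ≈ 0.35, since max-rescaled
multiplicative sharpening perturbs the input representation only mildly) is
rarely significant at N = 20: cohorts then abstain rather than misidentify.
At the frozen defaults the 3×20-replicate confusion diagonal is ≈ 0.4
(PE row ≈ 0.8–1.0; misidentifications are rare), while at higher SNR
(noise_sd ≈ 0.6–1.0) all three mechanisms are recovered essentially always.
Larger cohorts or less noisy measurements — not a different analysis — are
what the model comparison needs to separate Sharpening from pure input at
realistic noise ceilings.

## Numerical and degenerate-input choices

Constant condition vectors (zero variance) raise with the offending condition
named; voxels with missing values are dropped listwise per region; an
all-constant off-diagonal RDM rank-rescales to 0.5 everywhere; all-zero
priors skip the max-rescale (weight 0); fully tied Friedman data report
χ² = 0, p = 1; paired comparisons with all-zero differences report p = 1 with
a warning; group maps need ≥ 5 subjects and leave zero-variance voxels
missing.
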
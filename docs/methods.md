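# Methods

This note documents the statistical model, the numerical choices and the
limits of what the test suite demonstrates.

## Screening model

Expression is assumed FPKM-scale and non-negative. Preprocessing applies
`log2(x + 1)` (a flag disables it for users who prefer to standardize raw
FPKM — the two readings give the same per-gene t-statistics up to the
variance-prior fit, because z-scoring is a per-gene affine map) and then
z-scores each gene across **all** samples using the sample standard
deviation (ddof = 1). Zero-variance genes carry no between-group signal and
are dropped with a warning.

Each stage is compared with the normal group by a two-sample moderated
t-test. The hierarchical model is the standard empirical-Bayes variance
one: gene variances σ²_g follow a scaled inverse-chi-square prior with
hyperparameters (d₀, s₀²); the pooled sample variance s²_g (d_g = n₁ + n₀ −
2 degrees of freedom) is shrunk to the posterior value
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), and the resulting statistic is
t-distributed with d₀ + d_g degrees of freedom under the null. The
hyperparameters are fitted per comparison by matching the mean and variance
of log s²_g through the digamma/trigamma functions; the trigamma equation
is inverted by bracketed Brent root-finding on (10⁻⁸, 10⁸) half-degrees.
When the observed spread of log s² does not exceed its pure sampling
component, d₀ = +∞ (total shrinkage; the t reference degenerates to a
normal). d₀ = 0 is supported as the no-moderation limit and reproduces the
classical pooled t exactly — this equivalence, and agreement with an
independent implementation of the same model (limma's eBayes) on a shared
fixture, are both asserted in the tests.

A practical note: because standardization fixes every gene's total variance
at 1, the residual variances cluster tightly and the fitted d₀ is large —
moderation is strong but nearly uniform in this regime. The estimator's
recovery properties are therefore tested on unstandardized simulated
variances, where heterogeneity survives.

Benjamini–Hochberg adjustment is applied within each comparison
(`adjusted_(i) = min_{j≥i} m·p_(j)/j`, capped at 1); the default FDR cutoff
is 0.01. Direction calls (up/down) require both the cutoff and the sign of
the log-fold-change.

## Monotone filter

A gene is monotone decreasing iff it is significant and under-expressed in
all three comparisons **and** LFC_I > LFC_II > LFC_III strictly; increasing
is the mirror image. Ties violate strictness and are excluded — the audit
table records each gene's six statistics, its assigned pattern
(`mono_dec`, `mono_inc`, `other`, `not_deg`) and a human-readable exclusion
reason, so near-misses (e.g. ties, one failed comparison) are visible.
LFCs are mean differences on the standardized scale actually fed to the
tests; the ordering constraints only need comparability across the three
comparisons, which a common scale provides.

## Synthetic-data generator

The generator emulates a four-group ordered cohort. Per gene: a noise
variance σ²_g ~ noise_scale · noise_df / χ²_{noise_df} (the conjugate prior
behind the moderation model; default noise_df = 4, a strongly heteroscedastic
setting, noise_scale = 1), group means on the log2 scale at baseline 6
(≈ 64 FPKM) shifted by δ_g = effect_size·σ_g per step according to the
planted class (monotone up/down, U-shaped (m+δ, m, m, m+δ), waved
(m, m+δ, m, m+δ), or null), Gaussian noise, and the map 2^x − 1 floored at
zero back to the FPKM-like scale — chosen so the pipeline's log2(x + 1)
inverts it exactly. Group sizes default to the TCGA BRCA composition
(105/140/480/180). Defining the shift in units of each gene's own noise SD
makes the planted signal-to-noise uniform across genes; effect_size = 1 is
the generator's default study condition. Each gene draws from its own
counter-based random stream keyed by the global gene index, so per-gene data
are reproducible independently of what other classes request.

What the generator does **not** emulate: read-count sampling (no negative
binomial layer), gene–gene correlation, batch or platform effects, and
library-size variation. Passing tests therefore demonstrate correctness of
the procedure under independent, Gaussian-on-log-scale noise with known
planted patterns — not robustness to the correlation structure or technical
artifacts of real cohorts.

## VAE

Architecture: dense encoder input → 32 (ReLU) → 8 (ReLU) → {mean head,
log-variance head} over a latent of default dimension 1, and the mirrored
decoder 1 → 8 → 32 → input with a linear output layer. Training minimizes
reconstruction error plus kl_weight × the analytic Gaussian KL to N(0, I),
via the reparameterization trick and mini-batch Adam (step 10⁻³, β = 0.9 /
0.999, ε = 10⁻⁸, batch 32) for a fixed 20 epochs. The reconstruction term
is squared error **summed over genes** and averaged over samples (the
Gaussian-likelihood scaling): with the per-gene-averaged alternative and
unit KL weight the KL term dominates for wide inputs and the posterior
collapses. The per-epoch history records both components; the KL component
is non-negative by construction.

Implementation is pure NumPy with explicit backpropagation — the networks
are at most a few hundred units wide, every random draw (initialization,
shuffling, latent noise) comes from generators derived from the
configuration seed, and identical configuration + data yield bit-identical
trained weights. Weight initialization is Glorot-uniform with zero biases.
Setting kl_weight = 0 and disabling latent sampling reduces the model to a
plain autoencoder, which is used as an optimization sanity check.

A trained VAE's latent orientation is arbitrary. Where latents from
*independently trained* models must be compared (per-stage mode), each
latent axis is reflected so its correlation with the per-sample mean
expression of the input gene set is non-negative. When a single model
encodes two cohorts (external validation), no alignment is needed —
orientation cancels out of centroid distances.

The number of Adam updates is epochs × ⌈n/32⌉; the fixed 20-epoch schedule
presumes a cohort of several hundred samples (as in the motivating
application, ~900). On much smaller cohorts the model is undertrained at 20
epochs and `epochs` should be raised; the analysis scripts and acceptance
checks use cohorts large enough for the default schedule.

## Stage validation

Tests operate on per-sample posterior means, treating each sample's μ as
one observation — this makes sample size and power well defined, unlike
testing a single distribution-level (μ, σ²) pair per stage. Adjacent stages
are compared with Welch (unequal-variance) two-sample t-tests — per-stage
VAEs give no variance-homogeneity guarantee — and the joint null
μ_normal = μ_I = μ_II = μ_III with one-way ANOVA. The three pairwise
p-values are reported raw by default (a flag applies BH). The verdict is
`decreasing`/`increasing` only when the four stage means are strictly
ordered, else `non_monotone`. Multidimensional latents are reduced to the
first axis with a warning.

Both training modes are provided: pooled (one model per direction, all
samples — the default, since all latents then share one scale) and
per-stage (four independently trained models per direction). Comparing
latent means across independently trained models has no shared-scale
guarantee; sign alignment restores orientation but not scale, which is the
per-stage mode's documented caveat.

## External validation

Both cohorts are restricted to their shared genes (case-insensitive
identifier match), each standardized **within its own dataset** — raw
cross-platform scale differences would otherwise dominate the embedding —
and encoded by one overall VAE trained on the discovery cohort. External
samples take the stage of the nearest latent centroid (Euclidean; exact
ties broken toward the less-advanced stage and logged); a multinomial
logistic option on the latent features is available behind a flag. A
probe-level external matrix can be collapsed to genes via a two-column
mapping file (multiple probes per gene are averaged).

Limitation: within-cohort standardization centers each gene at its own
cohort mean, so it is only comparable across cohorts whose stage
compositions are similar. With a strongly different stage mix the centering
shifts by a fraction of a between-stage step and assignments slide
systematically toward adjacent stages; the synthetic external checks
therefore use matched compositions. No platform-effect correction (e.g.
ComBat) is attempted.

## Problem sizes and tolerances

The analysis scripts and acceptance checks run the full screen at
5,000 genes × 905 samples and train VAEs on up to 905 samples × ~100 genes;
the external check uses an 800-sample discovery cohort. All stochastic
assertions fix their seeds; calibration checks (type-I error 0.05 ± 0.01,
prior recovery within 25%/15%, null-ANOVA hit fraction ≤ 25%) use 5,000
genes or ≥ 8 repeated seeded runs. Standardization tolerance is 10⁻⁸ on
per-gene mean and variance; the pooled-t equivalence is asserted at 10⁻¹⁰
relative tolerance; the limma cross-check at 10⁻⁶.
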
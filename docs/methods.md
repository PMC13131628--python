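# Methods

## Model

`isofactor` estimates latent protein-isoform abundances by a two-layer
Bayesian supervised factor analysis. The first layer is a multivariate
linear regression of the latent abundances **I** (n samples × q isoforms) on
transcript expression **T** and a binary condition **A**:

    I_ij ~ N( I0_j + T_ij W_jj + A_i D_j , 1 )

The second layer is a factor analysis of the observed peptide matrix **P**
(n × r) with loadings constrained by the detectability mask:

    P_ik ~ N( Σ_j I_ij Z_jk , σ²_k ),   Z_jk = 0 unless peptide k can
                                         derive from isoform j.

The latent noise variance is fixed at 1: it sets the scale of the latent
layer, and any global rescaling is absorbed by Z and σ². The model is not
identifiable in a frequentist sense (Z and I trade off); the priors below
resolve this. Neither T nor A is required — without transcripts the latent
prior mean reduces to `I0 + A D`, and without a condition no effect is
estimated.

## Priors and hyperparameters

| parameter | prior | default | role |
|---|---|---|---|
| W_jj | N(1, τ_w) | τ_w = 1 | a priori proportionality of transcript and isoform |
| D_j | N(0, τ_d) or θ N(0, τ_d) + (1−θ) δ₀ | τ_d = 1, θ = 0.5 | condition effect; spike-and-slab for sparse calls |
| Z_jk (on support) | N̄(1, τ_z) on [l̄_j, ū_j] | τ_z = 1 | peptide detectability, kept on the observed scale |
| I0_j | N(m0, τ_i0) | m0 = 0, τ_i0 = 100 | per-isoform baseline |
| σ²_k | Inv-Gamma(a0, b0) | a0 = b0 = 1 | heteroskedastic peptide noise |

All values are configurable per isoform (`PriorConfig`). Two choices
deserve comment.

**Diffuse intercept.** The baseline I0 is a location nuisance on an
arbitrary log-intensity scale, typically far from zero. A unit-variance
zero-centered prior shrinks it by ≈ Ī/(n+1) and — because intercept,
transcript and condition terms jointly explain the mean — the deficit leaks
into the condition effect as a systematic bias (measured ≈ +0.15 at n=100
on data with baseline ≈ 13, enough to distort null calibration). The
default τ_i0 = 100 keeps the prior proper and conjugate while making this
leak negligible. When external average expression levels are available they
can be supplied as per-isoform prior means (`i0_mean`).

**Truncation bounds for Z.** For isoform j with compatible peptide column
means m_k, the truncated-normal support is [min(m)/max(m), max(m)/min(m)] —
an interval containing 1 that ties the latent scale to the observed peptide
scale. This requires positive column means ("data" policy; the natural
situation for log-intensity data). The "data-abs" policy applies the same
ratios to absolute column means: it is identical whenever all means are
positive and remains defined on signed working scales (e.g. simulated
data). Explicit per-isoform bounds are also accepted; degenerate bounds
(l = u) pin a coefficient exactly.

## Gibbs sampler

Every full conditional is conjugate: Gaussian for I0, W, D and the rows of
I, truncated Gaussian for on-support Z entries, Inverse-Gamma for σ², and a
Bernoulli-times-Gaussian two-step for spike-and-slab D (inclusion odds
combine the prior odds with the slab/spike marginal likelihood ratio; the
posterior inclusion probability is reported as PIP). The sweep order is
fixed: I0 → W → D → Z → σ² → I. Any fixed systematic scan is valid; this
order updates the regression layer before the loadings. Initialization is
at prior modes (W = 1, D = 0, I0 = m0, Z at mid-support, σ² = 1, I at its
prior mean), a valid state by construction.

Defaults are 3000 iterations with 2000 burn-in; 10 chains seeded
`base_seed + c` measure run-to-run consistency on real analyses, while the
simulation benchmark uses one chain per replicate. Because Z is block
diagonal over connected components of the isoform-peptide graph, the
posterior factorizes over blocks. Each block runs on its own random stream
keyed by `(seed, block_index)`, so executing blocks separately (or in any
order, or in parallel) is draw-for-draw identical to a whole-matrix run —
the test suite asserts bit-equality.

Numerical details: truncated-normal draws use the inverse-CDF transform
with a mirror flip into the lower tail; when the interval's normal mass
underflows the sampler falls back to an exponential-proposal rejection
step. The I-update factors one q_b × q_b precision Cholesky per block per
iteration (the precision `I + Z diag(1/σ²) Zᵀ` is positive definite by
construction) and reuses it for all n sample rows. Any non-finite draw
aborts the chain naming the parameter and iteration.

Correctness is established two ways: every conditional is checked against
dense grid integration of prior × likelihood on one-isoform toys (moments
to 1e-6), and a successive-conditional (joint-distribution) simulation —
alternately updating parameters given data and regenerating data given
parameters — verifies that 5000 sweeps leave the prior marginals of W and D
invariant (Kolmogorov–Smirnov p > 0.01). The latter is run on a
weakly-informative toy (small-magnitude T) so the chain traverses the prior
in the available sweeps.

## Differential abundance

The local false sign rate of isoform j is
`LFSR_j = min{ P(D_j ≥ 0 | ·), P(D_j ≤ 0 | ·) }`, estimated by inclusive
tail fractions of the posterior draws (draws at exactly zero — possible
under the spike — count toward both tails; the value is capped at 0.5, the
no-information point). Isoforms with LFSR ≤ α (default 0.05) are called
differential; no further multiple-testing adjustment is applied. With
several chains, each chain's own LFSR yields a detection count, and the
consensus set at minimum agreement γ contains isoforms detected by at least
γ chains; the summary table's single `lfsr` column pools draws across
chains. Chains whose mean abundance estimates disagree are flagged by the
stability filter: an isoform is retained when the variance over chains of
its per-chain mean abundance (averaged over samples) is below 1.

Under the null, thresholding LFSR at α behaves like a two-sided test at
level 2α, so the expected null call rate at α = 0.05 is about 10% — the
test suite checks the rate is not significantly above that (one-sided
binomial bound), observed ≈ 12% over 25 null replicates.

## Preprocessing

Peptides: per-sample total-intensity scaling to the median sample total,
log2 transform, then a per-peptide OLS fit on TMT batch (plex), diagnosis,
age and postmortem interval, subtracting only the fitted plex effects so
biological variation is retained. Missing intensities are rejected (or
optionally dropped by peptide); there is no imputation. Transcripts:
counts-per-million, log2 with pseudocount 1, optional removal of centered
technical-covariate effects. The pseudocount and the scaling target only
shift the log scale, which the intercept absorbs.

Isoforms with bit-identical mask rows are merged into isoform groups (they
are only jointly estimable); the group id joins the sorted member ids with
"+", and a grouped isoform's transcript column is the mean of its members'.
Validation flags isoforms without peptides, peptides without isoforms,
non-binary conditions, and blocks with more isoforms than peptides (the
model requires q ≤ r per block for identifiability; the sampler still runs
regularized by the priors if the check is overridden).

## Simulation benchmark

The generator reproduces two study conditions. **Easy**: one transcript
T ~ N(3, 1) mapped through W ~ N(1, 0.5) with intercept I0 ~ N(10, 0.5),
unit latent noise, split into two peptides with detectability scores drawn
from a unit-variance truncated normal centered at 1, unit peptide noise;
condition A = 1 for the first ⌈n/2⌉ samples, sample sizes n ∈ {100, 200,
500}, effects D ∈ {0.33, 0.66, 1}, 25 seeds. **Difficult**: five
transcripts with identity covariance, ten peptides, 30% of detectability
entries nonzero (drawn as exactly ⌈s·q·r⌉ uniformly-placed entries,
resampled on an incremented sub-seed until no isoform or peptide is
isolated — per-entry Bernoulli sampling conditioned on a connected mask
would inflate the realized sparsity to ≈ 0.36 at this size), with the first
`dact ∈ {1, 2, 3}` isoforms carrying the effect. All normal distributions
are parameterized as N(mean, variance).

The truncation interval for simulated detectability scores is
[0.5, 1.5] — half a unit either side of the location. The literal
alternative [−0.5, 0.5] (available via `z_interval`) places the support
below the model's ratio-of-means prior interval around 1; fitted
coefficients then pin to the bound and the condition effect is estimated as
roughly D·Z_true (≈ 0.17 for D = 1), so effect recovery is structurally
impossible under that reading and the centered interval is the default.

Misspecification and ablation switches: `misspecify_w_zero` severs the
transcript-isoform link in the generator while still reporting transcripts;
`transcript_mode` feeds the fit full transcripts, their sample means, or
nothing. Baselines collapse each isoform's compatible peptides per sample
by mean, sum or maximum and apply a two-sided two-sample t-test. Recovery
metrics: per-isoform absolute Pearson correlation between true and
posterior-mean abundances, mean effect bias, and detection proportions.

What the generator does not emulate: missing peptides, batch structure,
non-Gaussian intensity noise, correlated transcripts beyond the identity
covariance, and realistic isoform-peptide graph topologies. Passing
benchmarks therefore demonstrate correctness of the estimator under its own
generative assumptions and robustness to the specific misspecifications
above, not performance on real spectra.

## Correlation post-analysis

Given posterior-mean abundances and matched transcripts, the package
computes per-pair Pearson correlations over samples, flags |r| > 0.3 tails,
and classifies isoforms as `unique` or `ambiguous` (ambiguous iff any
compatible peptide is shared with another isoform). The null tail uses the
exact t-transform of the sample correlation under zero true correlation
(t = r√(n−2)/√(1−r²), n−2 df), not the Fisher-z approximation — at n = 103
and threshold 0.30 the two-sided tail is 0.208%, i.e. ≈ 7.4 expected pairs
per tail among 7107. Variance explained by an eGene variant with allele
frequency f and slope b is 2f(1−f)b². An OLS model (statsmodels) predicts
observed pair correlations from five variation covariates
(condition-difference and age coefficients for isoform and transcript, plus
eGene variance explained), reporting R² and per-predictor t statistics;
near-zero-correlation control pairs are drawn with a seeded generator.

One property worth knowing: when transcripts are truly uninformative
(W = 0) but the fit is supervised, the posterior-mean conversion weight for
weakly-supported isoforms is a data-driven draw around zero (sd ≈ 0.15 at
2–3 peptides per isoform), and the supervision term T·W̄ leaks that chance
association into the abundance estimate. The estimate-transcript null
correlation is then wider (sd ≈ 0.2) than the independent-data null
(sd ≈ 0.1). The analytic null tail is exactly recovered by unsupervised
fits, which is how the pipeline test checks it; with rich peptide support
the leak shrinks as W̄ concentrates.

## Problem sizes

The test suite and the acceptance script run the benchmark at n = 500 with
five replicates per condition and one 3000-iteration chain each, the null
calibration at n = 100 over 25 replicates, and the joint-distribution check
for 5000 sweeps on a 2-sample toy — sizes at which each check is stable
across seeds while the entire suite completes in a few minutes.

## Limitations

Only binary conditions are modeled; covariates beyond the condition enter
through preprocessing, not the likelihood. Post-translational modifications
are not modeled (they surface as inflated peptide noise or attenuated
detectability). The q ≤ r per-block requirement excludes heavily
under-determined blocks. LFSR calibration is exact only insofar as the
model is correctly specified; the data-driven truncation bounds reuse the
data and can make inference slightly anti-conservative in small samples.
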
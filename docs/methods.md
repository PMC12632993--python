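# Methods

This note documents the models, estimators and numerical choices behind
`lossycomp`, and what the synthetic-data experiments do and do not show.

## Lossiness of a target–lure pair

**Model.** Retrieval of a target in the presence of a similar lure is
modelled as traversal of the latent segment between their embeddings. The
segment is discretized into a path of `k + 2` points (endpoints exact,
interpolants evenly spaced; default `k = 10`, enough symbols for a
non-trivial channel while keeping the fit cheap). Pairwise cosine
distances over the path become similarities (`sim = 1 − dist`, negative
values floored at 0, scaled by the global maximum), each row is normalized
into an identification channel, and a confusion matrix is sampled
multinomially — 250 samples per input row. Per-row budgets keep every
input equally observed; a global budget is the documented alternative.

**Fit.** The confusion counts are fit by the optimal-channel form of
rate–distortion theory: `q(j|i) ∝ m(j)·exp(−s·d_ij)` with the output
marginal `m` given by the Blahut fixed point `m = pᵀq`. The fit maximizes
the multinomial log-likelihood of the counts minus a squared-asymmetry
penalty `λ_sym·Σ(d_ij − d_ji)²` (`λ_sym = 1`), with `d_ii = 0` and
`d ≥ 0`. Three numerical choices matter:

* **The trade-off `s` is fixed at 1 by default.** The likelihood depends
  on `(d, s)` only through the product `s·d`, so the scale of the cost
  matrix — and with it the scalar lossiness — is identified only when `s`
  is held fixed. Fitting `s` is available (`CostFitConfig.fit_s`) but
  leaves lossiness comparable only within a single fit.
* **The marginal is a capped Blahut relaxation.** Run to convergence, the
  fixed point degenerates to a boundary point mass whenever the cost
  structure is weak (nearly identical path rows), which poisons the
  likelihood. Each evaluation therefore runs a fixed budget of 100
  marginal updates starting from the empirical output marginal; this is
  deterministic, stays interior, and near a consistent solution the drift
  per update is negligible.
* **Initialization is closed-form.** With `q` set to the row-normalized
  counts and `m` to the empirical column marginal, the fixed-point
  condition holds exactly and the channel form inverts to
  `d_ij = [log m_j − log p_ij + log p_ii − log m_i]/s` — the saturated
  maximum-likelihood cost up to the sign and symmetry constraints.
  Projected-gradient ascent with backtracking (step size halves on
  failure, recovers ×1.5 on success) then polishes under the constraints;
  the penalized log-likelihood is non-decreasing by construction. Ten
  jittered restarts are run and the best final likelihood kept.

**Summary.** The pair's lossiness is the mean off-diagonal fitted cost
(the structurally zero diagonal is excluded; including it only rescales by
`(n−1)/n` and is a config switch). The public `optimal_channel` retains a
strict convergence contract (tolerance `1e-12`, error on failure) and is
validated against the closed-form binary-Hamming rate–distortion function
`R(D) = H_b(p) − H_b(D)` to `< 1e-3` nats.

## Encoders and the normalized rate

The autoencoder and β-VAE are dense (fully connected) stacks trained with
Adam in numpy — encoder trunk, latent (or `μ`/`log σ²` heads with the
reparameterization trick), mirrored decoder, sigmoid output. Dense
networks at 16×16×3 resolution are deliberate: the synthetic stimuli are
single parametric shapes, the rate–distortion trade-off being measured is
architecture-agnostic, and a self-contained trainer keeps the package free
of deep-learning framework dependencies. Defaults for the fixture scale
are one hidden layer of 128, latent 16, 50 epochs, batch 16, learning rate
1e-3; all are configuration, not code paths.

The β-VAE objective is `BCE + β·KL` (an optional L1 penalty on sampled
latents gives the sparse variant). Rate is the mean per-image KL in nats
and distortion the mean per-image binary cross-entropy, both evaluated at
the posterior mean on a held-out 80/20 split (the split and the "lowest
train/test loss" seed-selection rule are package choices; the selection
uses the summed train+test loss across the sweep). β sweeps are
log-spaced, since rates vary over orders of magnitude.

The **normalized rate** is the OLS slope of `log10(R)` on `D` over a
curve's points; points with `R ≤ 0` are filtered with a warning, and the
points are sorted before fitting so the slope is invariant to input
order. The per-pair variational lossiness averages reconstruction error
over target and lure across the full β sweep (the all-β mean; averaging a
subset is the flagged alternative).

Image normalization, where used, subtracts per-channel dataset means
(per-channel rather than one scalar; configurable).

## Behavioral scoring

Trial-level QC precedes participant-level QC: responses faster than
300 ms or slower than 3 s are dropped (the 3 s bound is exclusive —
exactly 3.0 s survives); then participants are excluded for > 20% missing
test responses, LDI < 0, or recognition < 0.5, all evaluated on the
post-trial-QC data. For tables with a delayed session the performance
thresholds are checked on the immediate session only. "Missing" counts
true non-responses by default; counting RT-excluded trials as missing is
a config switch. All probabilities condition on a response having been
made; empty denominators yield NaN and are reported, never silently 0.

Lure-difficulty bins are inputs (they come from independent normative
data), not computed here. The bin-level table joins each participant ×
bin's LDI and lure-FA to the mean lossiness of that bin's lure items —
the input shape for the models below.

## Neural signatures

Evoked per-trial series are `amplitude × HRF kernel` placed at trial
onsets. Participation ratio uses the voxel covariance over time points
(voxel means removed, `1/(T−1)` divisor); it is scale- and
rotation-invariant and lies in `[1, N]`. Mutual information is the
plug-in estimate over 16 equal-width bins per variable spanning each
series' observed range, in nats; a constant series has MI 0 by
convention (warning emitted). The plug-in estimator carries a positive bias of roughly
`(B_x−1)(B_y−1)/(2n)` nats — about 0.011 at 16 bins and `n = 10⁴` — and
no bias correction is applied, so null-MI checks need samples of that
order to read near zero.

Regional values use the subsampling protocol: 100 voxels × 100
iterations, sampling without replacement when the region is large enough
(with replacement, flagged, otherwise). Per iteration the correct-lure
and incorrect-lure participation ratios, their difference, and the MI
between concatenated flattened target and lure series within each
outcome (trials in onset order, series truncated to the shorter length)
are computed; regional values are the per-iteration means. MI over
concatenated series depends on the trial pairing, hence the documented
onset ordering.

## Statistical layer

The mixed model `LDI = β₀ + β₁·lossiness (+ β₂·age) + (1|participant) + ε`
is fit by REML via statsmodels MixedLM on the bin-level table (the
aggregate the indices are defined on). Singular fits — zero variance
components or failed convergence, as in the noiseless planted case — are
flagged and accompanied by a separately reported OLS fit.

The GAM `LDI = β₀ + s(lossiness, k=4) [+ s(lossiness, k=4)·(age − āge)]`
uses cubic B-splines with a second-difference (P-spline) penalty. The
main smooth is sum-to-zero centered (its level lives in the intercept);
the by-age varying-coefficient smooth is **uncentered**, so a constant
coefficient function — a linear age effect — stays in its span; centering
it demonstrably over-shrinks the interaction. Smoothing parameters
minimize the Gaussian REML criterion
`(n−M)/2·log(RSS_p) + ½log|XᵀX+S| − ½log|S|₊` (profile σ², Nelder–Mead
over log-λ from three starts, bounded to avoid overflow). Each smooth's F
statistic is a Wald test of its coefficients under the Bayesian
covariance `σ̂²(XᵀX+S)⁻¹`, on rank-`round(edf)` pseudo-inverse degrees of
freedom — approximate, as such tests are. Fits agree closely with R's
mgcv on matched models (cross-checked in the test suite).

The bootstrap contrast resamples participants with replacement
(default 10,000 iterations), reporting the percentile 95% CI and a
two-sided percentile p-value (floored at `1/n_iter`). Multiplicity uses
Bonferroni or Benjamini–Hochberg.

## Synthetic data: what it emulates, and what it does not

Generators plant every quantity the estimators recover: pair angles
(cosine separation exact to 1e-9), factor tables behind shape images,
task designs with the standard trial counts (128 study / 192 test; six
blocks of 107 with 32 first presentations, 16 repeats, 16 lures, 43
foils), response policies whose lure-"similar" probability is
`δ + (1−δ)·bias` (monotone in the planted discriminability δ, LDI = 1 at
δ = 1 with zero bias, expected LDI = 0 at δ = 0), and voxel series with a
covariance spectrum whose participation ratio equals the planted
effective rank exactly (k unit eigenvalues plus one solved fractional
eigenvalue, rotated into a random orthonormal basis). Coupled
target–lure series share a latent fraction of variance; independent ones
use disjoint stream draws. Continuous-design lags are geometric with a
configurable mean (default 19), realized by insertion after the first
presentation, so ordering constraints hold by construction and the mean
lag is approximate near block ends. The MST test split defaults to equal
thirds of repeats/lures/foils — a package default, exposed as a
parameter.

The generators are deliberately minimal: Gaussian voxel noise with no
scanner drift, motion or physiological structure; parametric shapes
rather than object photographs; response policies without RT–accuracy
coupling. Passing tests therefore certify the estimators and their
closure on their own generative assumptions — that planted geometry,
ranks, dependence and discriminability are recovered at stated
tolerances — not that real images, cohorts or fMRI data would yield any
particular effect size.

## Problem sizes

Test and acceptance runs use fixture scales chosen for a laptop-class
CPU: 64 images at 16×16 for encoder training, 32-dimensional embeddings
with 12-point paths for lossiness, 120–150 voxels with 20–25 time points
per trial for neural signatures, 100 participants × 5 bins × 200
replicates for mixed-model recovery, and n = 1000 × 100 replicates for
GAM power. Full-scale parameters (e.g. 22-point β sweeps over 5 seeds,
250-epoch training at 32×32) are configuration defaults documented in
`EncoderSpec` and reachable without code changes.
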
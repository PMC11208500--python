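# Methods

## Data model

An intensity table is a samples × features grid of log2-transformed LFQ
intensities with an explicit observed mask; `NaN` is the single canonical
missing marker, so mask and values cannot disagree. Zero intensities in
MaxQuant/Spectronaut-style exports mean "not quantified" and are treated as
missing at ingest. All modelling, losses and error metrics live on the log2
scale; raw-scale input is converted exactly once.

Before benchmarking, the usual two-step selection is applied: keep features
quantified in ≥ 25% of samples, then keep samples covering ≥ 50% of the
selected features (both thresholds configurable, both using ceilings).

## Holdout simulation

Splits operate on the long view (sample, feature, intensity). By default 90%
of observed records train, 5% validate (early stopping only) and 5% test.
A share `mnar_share` (default 25%) of the held-out records is drawn uniformly
without replacement from the records at or below a dataset-wide intensity
threshold `t`, labelled MNAR; the rest are MCAR draws from the remainder.
`t` is the empirical quantile `q = mnar_share × holdout_fraction × margin`
with `margin = 4`, so the candidate pool is four times the MNAR draw — the
low tail is oversampled without being exhausted. This deterministic
quantile-pool construction was chosen over probabilistic sigmoid censoring
for the *evaluation* holdouts because it is auditable record-by-record (every
MNAR holdout is provably below `t`); the sigmoid mechanism is what the
synthetic generator uses for the *data* instead. Records exactly at `t`
count as in the pool. Holdout counts use round-half-away-from-zero; the
validation split takes the first share, test the remainder. A single integer
seed drives all draws.

The permutation control shuffles each feature column independently across
samples (values travel with their gaps). Per-feature marginals — hence the
median baseline — are exactly conserved while cross-feature correlation is
destroyed, so any learned model's advantage must vanish; the tests assert
that post-permutation correlations sit at the finite-sample null level
`E|r| = sqrt(2/(π n))`, not at zero, which no permutation can reach.

## Models

**CF.** Biased matrix factorization: prediction is the scalar product of a
sample and a feature embedding (dimension L, default 10) plus per-sample and
per-feature biases and a global offset initialized at the training mean. The
biases make the feature-mean predictor a nested special case, which
stabilizes early training. Trained on long records in minibatches of 4096.

**DAE.** MLP encoder/decoder (default one hidden layer of 64 per side,
leaky-ReLU hidden activations, linear output) around a latent bottleneck
(default 10). Missing inputs are filled with the training-split feature
median (a zero-fill variant exists behind `fill_strategy`); each batch
additionally hides a fraction (default 0.1) of observed inputs, whose
observed targets still count in the squared-error loss. Originally-missing
cells never contribute to any loss.

**VAE.** Same encoder/decoder skeleton; the encoder emits a mean and log
variance per latent dimension, the latent is reparameterized during training
and taken at its mean at inference. The decoder likelihood is Gaussian. Its
log variance is a free per-feature parameter trained jointly rather than a
per-cell network head: with a per-cell head the likelihood can explain
residuals away by inflating the variance exactly where the mean error is
largest, which starves mean learning (we observed test MAE stuck at the
median-baseline level; the per-feature parameterization fixes it while
keeping heteroscedasticity across features). The KL term uses the closed
form ½(μ² + e^υ − 1 − υ) per latent dimension, guarded by max(0, ·) against
round-off only; KL and reconstruction are summed unweighted (a β flag
exists). Log variances are clipped to ±8 with gradients blocked outside.

**Input parameterization.** Autoencoder inputs are centered at the
per-feature fill level, so missing cells enter the encoder as exact zeros
and activations start at a sane scale. This is a reparameterization of the
network input, not data normalization — no scaling is applied, targets and
losses stay on the raw log2 scale, and an optional `standardize` flag
provides true standardization for those who want it.

**Optimization.** Hand-rolled Adam (β₁ 0.9, β₂ 0.999) over explicit
backpropagation, verified against finite differences to 1e-8. Default
learning rates are 1e-2 for CF and 3e-3 for the autoencoders, with up to 500
epochs and early-stopping patience of 50 epochs without validation-MAE
improvement; desk-scale tables yield only a handful of gradient steps per
epoch, which is why the epoch budget is larger than typical deep-learning
settings. The best-validation parameters are restored after stopping.
Everything is bit-reproducible from the config seed.

**Grid search** ranks configurations by validation MAE and returns the one
with the fewest trainable parameters among the top three, since near-equal
validation performance makes the cheapest model preferable.

## Baselines

Median: training-split median per feature. KNN: NaN-aware Euclidean distance
between samples, rescaled by sqrt(total features / shared features) (the
scikit-learn convention); donors must observe the target feature; ties break
by sample order; k defaults to 3. RSN: draws from
Normal(m − shift·sd, (scale·sd)²) per axis unit (per sample by default, the
clinical-study convention), with shift 1.6 and shrink 0.3 as defaults and
sample standard deviations (ddof 1).

## Metrics

Overall MAE on held-out records; MAE binned by floor of the feature's
training median (floor, not round — conventional histogramming) with 95%
percentile-bootstrap CIs from 1000 resamples of individual records within a
bin; Pearson r per feature across samples (features with < 3 test records
are excluded and listed) and per sample across features; and the missingness
vs. median summary whose per-bin quartiles make left-censoring visible.

## Differential abundance

Per feature, OLS of intensity on the ordinal stage score plus covariates
(binary covariates as indicators, the score as one linear term), two-sided
p-value on the score coefficient, Benjamini–Hochberg across all analyzed
features, significance at q ≤ 0.05. Without imputation each feature uses its
observed samples only (complete-case per feature); with imputation only
missing cells are filled — observed values pass through bit-identically, and
the recovery harness asserts this. Features observed in fewer than
(parameters + 2) samples, or with a rank-deficient design on their samples,
are excluded and reported. With no covariates and a binary score the p-value
equals the pooled-variance two-sample t-test (tested to 1e-10).

The recovery experiment: reference = analysis of the full table without
imputation; remove 20% of observed records with the MNAR/MCAR mixture;
re-analyze without imputation and with each imputer; count decisions against
the reference (reference-significant features missed = FN, newly significant
= FP). Model-based imputers retrain on the reduced table with an internal
90/5/5 split for early stopping.

## Synthetic data

The generator emulates what the models assume about LFQ tables: per-feature
baselines uniform over 20–35 log2 units (the dynamic range of protein-group
medians), cross-feature correlation through a rank-k factor model (default
rank 5), Gaussian residual noise, and missingness
`P(miss) = mcar + (1 − mcar)·sigmoid(−steepness·(value − LOD))` with the LOD
at a dataset quantile — logistic left-censoring whose infinite-steepness
limit is a hard detection threshold. The factor-plus-noise residual is
median-centered per feature so each column median equals its baseline
exactly. Benchmark preset: factor scale 1.3 (per-cell correlated signal
sd ≈ 2.9), noise sd 0.3, ≈ 20% missing.

The cohort preset plants an ordinal score (uniform on 0–4) whose effect
(1.0 log2 per stage on 40 of 300 features by default) enters *before*
censoring, so low-stage samples of low-abundance markers are the likeliest
to be missing, as in real cohorts. Clinical covariates (age, BMI, gender,
steatosis, abstinence) perturb a random 20% of features with small
coefficients. The cohort preset uses a larger factor scale (1.9, per-cell
sd ≈ 4.3) and heavier censoring (LOD quantile 0.3, steepness 0.6, ≈ 30%
missing): this spreads per-feature statistical power across the significance
boundary, so planted effects are near-certain discoveries on complete data
while complete-case analysis of heavily censored markers is fragile to
record loss — the regime in which imputation quality matters for downstream
conclusions.

What the generator does **not** emulate: batch effects and acquisition-time
drift, peptide-to-protein aggregation structure, non-Gaussian heavy tails,
and effect-size heterogeneity (all planted effects share one slope). Passing
benchmarks here therefore demonstrate correct mechanics and the expected
qualitative ordering of methods under low-rank correlation with left
censoring — not performance guarantees on any particular instrument's data.

## Problem sizes and determinism

Default verification sizes are 100 samples × 200 features for the imputation
benchmark and 200 × 300 (40 planted effects) for the recovery experiment;
these are the scales at which all distributional checks in the test suite
were calibrated. The end-to-end `benchmark` command fans a single global
seed out to per-stage seeds via fixed offsets, so stages can be rerun in
isolation and two runs of the same configuration produce byte-identical
output files.

## Known limitations

CF cannot predict for samples or features absent from training. The
autoencoders need enough samples to estimate cross-feature structure; on
very small or unrelated sample sets KNN or the median is the safer choice.
Imputation of heavily censored features is biased toward the center of the
training distribution, which attenuates effect estimates for exactly those
features — visible in the recovery experiment, where a minority of lost
discoveries on extremely censored markers stay lost under every model.
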
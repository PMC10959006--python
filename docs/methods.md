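# Methods

This note records the scientific and numerical choices behind `nirleaf`:
what the model assumes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Data model

A leaf's labeled observation is its mean reflectance spectrum over the
whole leaf area on a 224-band grid from 942 to 1,680 nm (~3.3 nm
spacing). The instrument records 256 bands over a wider range; the first
32 bands have very low signal-to-noise and are always dropped before
analysis (`trim_bands`). The two published grid facts (raw range and
retained range) are not exactly consistent under 32-band trimming; the
package treats the retained 942–1,680 nm / 224-band grid as authoritative
and also exposes the raw grid for completeness.

Status labels come from fixed concentration breakpoints (% dry mass):
N: 2.90 / 3.20 / 3.40 / 3.80, K: 0.70 / 0.90 / 1.10 / 1.50, giving five
classes VL, Low, Proper, High, VH. Breakpoint values belong to the lower
class (class i is the half-open interval (t_{i-1}, t_i]).

## Pixel screening

Unlabeled data are single pixels of leaf hyperspectral cubes. A pixel
spectrum k is scored against the leaf-mean spectrum q by
(q·k)/d, d = 224, min–max normalised across the pixels of one leaf.
Two deliberate fidelity points:

* The score is a scaled *projection*, not a true cosine — the customary
  "cosine similarity" name notwithstanding, there is no vector-norm
  denominator in the defining formula. True cosine is available via
  `metric="cosine"`, but the projection form is the default.
* The min–max map is implemented as (x − x_min)/(x_max − x_min) onto
  [0, 1]. The alternative printed form (x − x_max)/(x_max − x_min) maps
  onto [−1, 0] and is treated as a typo; screening behaviour (which is
  rank-based) is identical either way.

Normalisation is per leaf. The keep rule defaults to the top 30 % of leaf
pixels by score (the vein region — whose pixels track the leaf mean most
closely — is a minority of the leaf); both a `top_fraction` and a
`threshold` rule are supported, with ties broken by raster order. Both q
and the pixels are Savitzky–Golay smoothed (window 11, polyorder 2 —
standard chemometric practice at ~3.3 nm sampling) before scoring, which
in particular suppresses the single-band noise artifact near 1,380 nm by
well over half its amplitude.

## Rebalanced self-training

Given labeled set L and screened pool U:

1. L is optionally SMOTE-balanced once, before the loop (`labeled_sampler`).
2. The injected pool U′ holds round(|L|/β) samples drawn without
   replacement; β ∈ {1/2, 1/4, 1/6, 1/8} are the conventional settings.
3. Iterate (t = 1 … max_iter): fit the base classifier on L′ ∪ P_{t−1};
   predict U′; keep samples with top class probability ≥ τ; resample that
   high-confidence set with the pseudo-sampler into P_t; record its class
   counts and imbalance ratio.
4. Stop early when the fraction of changed pool predictions drops below
   `stop_eps` (default 0.01); default max_iter 10.
5. The final classifier is refitted on L′ ∪ P_final.

Choices that the procedure's published description leaves open, fixed
here as package defaults:

* **τ = 0.8** by default, configurable. Note that random-forest
  probabilities are tree-vote shares; in a noisy five-class problem they
  rarely exceed 0.8, so an RFC base with default τ often runs in the
  degenerate regime (no pseudo-labels accepted → the loop returns the
  balanced supervised fit, which is itself a meaningful baseline). τ of
  0.5–0.6 keeps the RFC pseudo-labeling path active; LDA/PLSDA
  confidences are sharper.
* **Per-iteration pseudo budget = |L′|**, capped by the high-confidence
  count — one labeled-set-worth of pseudo data per iteration keeps the
  labeled and pseudo influences comparable and produces the gradual
  per-iteration balancing histograms characteristic of the method.
* **The pseudo set is rebuilt from the full pool every iteration**
  (transductive re-selection) rather than consuming accepted pixels, so
  class histograms can both grow and rebalance.
* **MES inside the loop** rounds its budget down to a multiple of the
  number of classes present, so per-class quotas are exactly equal and
  the recorded pseudo-set μ is exactly 1. The general-purpose `resample`
  keeps the remainder rule (extra samples to the smallest classes first).
* **Recorded μ**: the per-iteration state carries both the imbalance
  ratio of the rebalanced pseudo set P_t (`mu` — the quantity that is
  identically 1 under MES/SMOTE) and of the combined training set L′ ∪
  P_t (`train_mu`).
* **RES is paired with no labeled balancing** (it self-balances from the
  start); configuring SMOTE-on-labeled together with RES triggers a
  validation warning rather than an error.
* Labeled data are balanced **once** before the loop; only pseudo data
  are rebalanced per iteration.
* β counts the injected pool **before** confidence filtering.

Degenerate contracts: max_iter = 0 or τ > 1 reproduce the plain
supervised base classifier bit-for-bit (the model-fit seed is derived
once from the global seed, not per iteration). Three consecutive
iterations with zero high-confidence samples abort the loop with a
warning and return the supervised model.

### Base classifiers

LDA and RFC use scikit-learn with library defaults and a fixed seed
(100 trees, single-threaded for determinism). PLS-DA is the package's
one-hot PLS2 regression with an argmax decision; its latent-variable
count defaults to 10 (capped by sample/feature counts), `scale=False`
since all bands share units. PLS-DA "probabilities" are the clipped,
sum-normalised class scores — adequate for confidence thresholding, not
calibrated probabilities. Argmax ties resolve to the lowest class index.

## Metrics

All metrics derive from the 5×5 confusion matrix (rows = true): per-class
precision M_ii/colsum and recall M_ii/rowsum (empty denominators give 0,
avoiding NaN propagation into the weighted sums); MAP is the unweighted
mean over the 5 classes; WAP and WR weight by true-class shares α_i.
WR ≡ trace/total (micro accuracy) — an algebraic identity that the test
suite fuzz-checks. Balanced evaluation downsamples every class without
replacement to the smallest class count (μ = 1, where WAP = MAP exactly);
uncertainty is assessed by stratified 5-fold cross-validation on WAP,
refolding with a warning when the smallest class has fewer samples than
folds.

## Wavelength importance

Gini importance of a fitted forest is computed by an explicit traversal
of every split: the default **weighted** mode uses the standard
impurity-decrease form G_q − (n_i/n_q)G_i − (n_j/n_q)G_j (non-negative,
normalised to sum 1, and verified against scikit-learn's
`feature_importances_`); a **literal** mode sums the raw unweighted
difference G_q − G_i − G_j, which can go negative and is normalised by
the sum of absolute values — retained only for fidelity to the unweighted
form sometimes quoted. For non-tree bases an auxiliary seeded forest is
fitted on the same training data. Band–concentration association is plain
per-band Pearson correlation (constant bands report r = 0 with a flag).

## Synthetic generator

The generator targets *statistical*, not biophysical, realism — no
radiative-transfer leaf optics. Labeled spectra are
(1 + ε)·m_c(λ) + white noise, with ε ~ N(0, scatter_sd) per sample, m_c a
cubic-spline archetype (broad NIR plateau with absorption dips near 1,200
and 1,450 nm) plus class-dependent raised-cosine bumps inside the
informative windows (defaults: the N windows 945–980, 1,548–1,592,
1,651–1,680 nm; K windows 964–1,044, 1,283–1,400, 1,665–1,676 nm).
Adjacent classes are separated by effect_size·noise_sd/2 at each window
centre. One band (nearest 1,380 nm) receives additive noise at 10× the
base noise scale, emulating the single-band instrument artifact the SG
filter must suppress. Concentrations are uniform within each class's
diagnostic interval; the open-ended outer classes use a bounded extension
of width equal to the neighbouring interval (no outer bounds are
published).

Defaults: noise_sd 0.01 reflectance units, scatter_sd 0.03,
effect_size 2 — chosen so a supervised baseline lands mid-range (neither
ceiling nor chance), which is the regime where semi-supervision can show
an effect. Class counts default to the reference N training design
45:93:225:104:268 (the published fifteen N counts sum to the stated
1,400-leaf total; the K design's published counts do not, so the N row is
the fixture default).

Leaf cubes place an elliptic leaf mask with a midrib-plus-branches vein
skeleton (vein share set by `vein_fraction`). Vein pixels carry tight
symmetric scatter around the class mean; lamina pixels carry (a) a
right-skewed zero-mean multiplicative scatter (centred exponential:
occasional bright pixels, most slightly dim) and (b) a spatially
correlated multiplicative field built by a separable moving-average of
white noise. The construction keeps the cube's leaf-mean spectrum
unbiased for the class mean while placing the lamina's *median*
projection onto the mean spectrum below the vein's — exactly the
structure similarity screening exploits. What the generator does **not**
emulate: real vein branching geometry, illumination gradients,
specular-angle effects, inter-leaf biological covariance, or any true
reflectance physics — so green tests demonstrate the pipeline's
correctness and its behaviour under the assumed statistical structure,
not field performance on real leaves.

## Problem sizes and numerics

The test and demonstration workloads use desk-scale sizes chosen as
study conditions: labeled sets of 50–750 samples, pools of 1,000–1,500
spectra, cubes around 40×56 px, 8–10 loop iterations, 10–20 seed
replicates for directional claims, and 10^5 draws for sampler-law checks
(3 Monte-Carlo SDs). The synthetic benchmark (labeled n = 50 at μ = 6,
4× unlabeled, RFC base, MES rebalancing, balanced held-out set) asserts
only the *direction* of the self-training effect across seeds, not any
absolute score. Determinism: every stochastic stage consumes a child
seed spawned (`numpy` SeedSequence) from one global seed; identical
configurations yield identical outputs, and ties anywhere (argmax,
screening ranks) break deterministically.

## Known limitations

* Pseudo-label confidence is classifier-dependent and uncalibrated;
  comparing τ across base classifiers is not meaningful.
* MES/SMOTE guarantee μ = 1 only over the classes actually present in
  the high-confidence set; a class the classifier never predicts cannot
  be rebalanced into existence.
* The ENVI reader supports the standard float32 .hdr+raw triad (BIL,
  BIP, BSQ) with a mask sidecar; vendor-specific raw formats and
  radiometric calibration are out of scope (reflectance is assumed
  already white/dark corrected).
* Real-survey accuracy claims are out of scope: the packaged evidence is
  synthetic by construction.
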
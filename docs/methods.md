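# Methods

## Problem setting

Shotgun-metagenomic profiling of the human gut yields two kinds of
per-sample feature vectors: strain-level **marker profiles** — binary
presence/absence indicators for strain-specific gene markers, up to
~10⁵ features wide and sparse — and species-level **abundance
profiles** — relative abundances in [0, 1], a few hundred features,
rows summing to 1. With cohorts of only a few hundred samples, this
extreme width invites overfitting. `microrep` addresses it by learning
a low-dimensional representation of the profiles with an autoencoder
(or a classical reduction), then training a conventional classifier on
the representation, with every fitting step quarantined from the test
samples.

## Representation learning

All autoencoders minimize reconstruction error of the input profile x
through a bottleneck; the encoder half f_φ is kept and z = f_φ(x) is
the representation.

- **SAE** (shallow): input → latent → output, linear latent and output
  activations, latent size ∈ {32, 64, 128, 256, 512}. A linear
  autoencoder of latent size k can at best span the top-k principal
  subspace, which is why a rank-k input must be reconstructed almost
  exactly — the property the training tests exploit.
- **DAE** (deep): 1 or 2 ReLU hidden layers inserted symmetrically on
  each side of the latent layer; widths double moving outward (latent
  512 with two insertions: 2048/1024/512/1024/2048).
- **VAE**: one ReLU intermediate layer (32…512 units) feeding separate
  μ and log σ² heads over a 4/8/16-dimensional latent. Training
  minimizes the negative evidence lower bound: squared-error
  reconstruction of a reparameterized sample z = μ + σ ⊙ ε plus the
  closed-form KL divergence −½ Σ_j (1 + log σ²_j − μ²_j − σ²_j) from
  the diagonal-Gaussian posterior to the N(0, I) prior. The gradient of
  this objective is hand-derived and verified against central
  differences in the test suite. Downstream, `encode` returns μ — a
  deterministic representation — rather than a posterior sample.
  Validation loss is evaluated at z = μ so early stopping is
  noise-free.
- **CAE**: the n-vector is reshaped row-major into a d × d single-channel
  image with d = ⌊√n⌋ + 1 and d² − n trailing zeros. Encoder layers are
  valid (unpadded) strided convolutions: layer 1 uses a filter of
  ⌊0.1·d⌋ with stride ⌊0.25·filter⌋; each deeper layer uses 10% of the
  preceding output size as filter and 50% of that filter as stride
  (all floored, minimum 1). Filters halve per layer from a first-layer
  count in {4, 8, 16, 32, 64}; depth is 2 or 3; no pooling. The
  representation is the flattened last encoder layer, so its size
  follows from the geometry rather than being chosen. The decoder
  mirrors the (filter, stride) schedule with transposed convolutions
  and crops/zero-pads back to d × d; reconstruction loss is measured
  against the padded image.

Training, common to all families: Adam (learning rate 0.001, epsilon
1e-07), minibatches of 32, mean-squared-error reconstruction loss
(negative ELBO for the VAE), Glorot-uniform initialization, and early
stopping — training halts after 20 consecutive epochs without
validation-loss improvement (ties keep the earlier epoch) and the
weights of the best epoch are restored. An epoch cap of 2000 bounds
runtime; in practice early stopping fires far earlier. One integer
seed drives weight initialization, batch shuffling, and VAE sampling
through independent substreams, making runs bit-reproducible with
single-threaded NumPy.

The neural-network layer engine (dense, convolutional, transposed
convolutional, dropout; Adam; the early-stopping loop) is implemented
in NumPy inside the package (`microrep._nn`) with analytic backward
passes validated against central-difference gradients.

Classical baselines: **PCA** keeps the smallest number of leading
components whose cumulative explained variance ratio on the training
rows reaches 0.99; **Gaussian random projection** targets the
Johnson–Lindenstrauss dimension 4·ln(n) / (eps²/2 − eps³/3) at
eps = 0.5 (if that does not reduce the dimensionality, the data pass
through unchanged with a warning). Both are fitted on training rows
only and applied unchanged to held-out rows.

## Classification

Grids searched exhaustively: SVM — linear kernel × C ∈ {2⁻⁵, 2⁻³, …,
2⁵} plus RBF × the same C × γ ∈ {2⁻¹³, 2⁻¹¹, …, 2³}, 60 combinations
(the γ grid starts at 2⁻¹³, nine values, so the grid total is exactly
60); RF — trees ∈ {100…900 by 200} × min-leaf ∈ {1…5} × {gini,
entropy} × max_features ∈ {sqrt, log2} of the feature count, 100
combinations; MLP — ReLU hidden layers whose widths floor-halve after
a first layer of {10, 30, 50, 100} units, depth 1–3, dropout
{0.1, 0.3} after each hidden layer, a single sigmoid output, binary
cross-entropy with Adam and batch size 32, epochs ∈ {30…300} as a grid
axis, 120 combinations.

Selection is stratified 5-fold cross-validation on the (encoded)
training pool, scored by **accuracy** and averaged across folds; ties
break to the earlier grid entry. The winner is refit on the whole pool
and reported by **AUC** (primary), **AUPRC** (informative under class
imbalance), and accuracy (0.5 threshold on probabilities, 0 on SVM
margins) on the test set. Selection deliberately uses accuracy even
though reporting is AUC-first: the two stages answer different
questions (which configuration to trust vs how well the final model
ranks unseen patients), and keeping the selection metric fixed makes
chosen hyper-parameters comparable across reducers.

RF grid evaluation grows each forest once through the tree-count axis
with scikit-learn's `warm_start` and scores at every stop; because
tree seeds are drawn sequentially from `random_state`, the grown
forest at each stop is tree-identical to a fresh fit of that size (a
test asserts this), so the optimization changes cost (~2.8× fewer
trees), not results.

## Evaluation protocol

Per repetition seed: a stratified 8:2 split into training pool and
test set, then a stratified 8:2 split of the pool into training and
validation rows — 64/16/20 overall. Per-class part sizes use
round-half-up of the 20% fraction (so an 85/25 cohort yields a 22-test
split with 17 controls and 5 patients); class proportions in every
part are within one sample of proportional. Autoencoders fit on the
64% with the 16% steering early stopping; PCA/RP fit on the merged
80% (they need no validation set); with no reducer the raw features
pass through. The reducer encodes pool and test, classifier selection
sees only the encoded pool, and the test rows reach nothing but the
final scoring call. An optional `LeakageRecorder` hook captures the
index sets visible to every fitting stage so tests can prove the
quarantine. The procedure repeats for seeds base…base+4 (default 5)
and per-seed AUCs are averaged.

## Synthetic cohorts

The generator emulates both profile kinds with planted structure.
Each sample draws latent factors z ~ N(0, I_k) (default k = 8) that
induce correlated low-rank background through a random loading matrix
scaled so each feature's latent logit is ~N(0, 1). The binary label is
thresholded from an independent standard-normal score, so classes are
~balanced and — crucially — **effect_size is the only feature–label
coupling**: a class shift effect_size·v_j added to the logits of a
random 10% subset of features (v_j ~ N(0, 1)). At effect 0 the labels
are exactly independent of the features and any pipeline AUC sits at
chance; effect 3 on a 2000-feature cohort is a strong signal (raw-
feature AUC ≈ 1, still ≥ 0.85 after unsupervised 32-d compression).

Marker kind: feature j of sample i is Bernoulli(sigmoid(logit_ij + b_j))
with per-feature intercepts b_j set by vectorized bisection so the
realized fraction of 1s matches the target sparsity (default 0.1,
typical of real marker matrices). Abundance kind: rows are softmax of
the logits plus N(0, 1) noise, hence non-negative and summing to 1.

What the generator does **not** emulate: phylogenetic correlation
between markers, compositional bias and zero-inflation structure of
real abundance data, batch effects, or label noise from misdiagnosis.
Passing tests therefore demonstrate that the machinery recovers
planted low-dimensional signal under a leakage-free protocol — not
that any particular AUC is attainable on real cohorts.

## Numerical and design choices

- Profile files are delimited text, header row = feature ids, first
  column = sample ids, rows = samples; comma by default, tab by flag
  or `.tsv`/`.txt` extension.
- Marker entries are validated to be exactly {0, 1}; abundance entries
  to [0, 1]. Parse errors name the offending sample and feature.
- No input scaling before autoencoders — they consume raw profiles.
- Epoch ties in early stopping keep the earliest epoch; `best_epoch`
  is a 0-based index into the loss log.
- The CAE minimum input side is 10 (below that the percentage-based
  filter rule degenerates); smaller inputs are a configuration error
  surfaced before training.
- Degenerate inputs: single-class label vectors are rejected before
  evaluation; classes with fewer than 5 samples cannot be stratified
  into 5 folds and raise immediately; test sets that end up
  single-class make AUC undefined and raise rather than return NaN.
- Problem sizes in the test suite: training-behaviour tests run on
  cohorts of 100–200 samples and 60–300 features; the full-scale
  recovery checks use 400 samples × 2000 features with the 5-seed
  protocol — large enough for stable AUC bands, small enough for a
  single-CPU run. The monotone-in-effect-size check at that scale uses
  the PCA+SVM pipeline, whose cost per repetition is a small fraction
  of an RF grid search, with the SAE+RF recovery band checked at the
  strong-signal point.

## Known limitations

- The NumPy engine is CPU-only and unbatched across architectures; it
  is sized for the few-hundred-sample cohorts this problem domain has,
  not for large-scale deep learning.
- CAE representations can be wider than the input for small inputs
  (flattened conv maps), which is faithful to the design but means
  "reduction" is not guaranteed for the CAE.
- `run_once` retrains the reducer per repetition seed; there is no
  caching across configurations.
- AUPRC is reported for all runs regardless of imbalance.
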
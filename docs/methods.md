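# Methods

## Problem and model

A candidate off-target site is an aligned pair of equal-length 23-nt
sequences: an sgRNA (20-nt protospacer + NGG PAM, written in the DNA
alphabet) and a genomic locus differing from it by 1–5 protospacer
mismatches. The task is to score each pair's cleavage propensity, either as
a binary off-target probability (classification) or as a predicted cleavage
frequency in [0, 1] (regression).

The model treats the pair as a sequence of 16 possible per-position "words"
(ordered base combinations), learns unsupervised GloVe vectors for those 16
words from the corpus of encoded pairs, and feeds the embedded sequence
through a biLSTM (context extraction) followed by five 1-D convolutions
(local-motif extraction) and two dense layers (sizes 20 and 2). Batch
normalization and dropout sit between stages. The recurrent-then-
convolutional order is deliberate: recurrence sees the intact sequence
before convolution fragments it into local features; the `Conv_LSTM`
variant exists to test exactly this choice, and `NoLSTM`, `NoBatchNor`,
`NoDropout` ablate the other components.

### Tokenization conventions

The index rule is the lexicographic bijection `4·rank(r) + rank(d)` over
A=0, C=1, G=2, T=3. Any fixed bijection over the 16 ordered base pairs
carries identical information, so this choice affects only the stability of
serialized artifacts; the base order is configurable for interoperability
with artifacts produced under a different assignment. Internal indices are
0-based; user-facing positions 1-based, with positions 21–23 the PAM.
Ambiguity codes (N) are rejected by default — the vocabulary has no column
for them — with an opt-in skip-row mode for permissive reading.

### GloVe stage

Within each 23-token sentence, co-occurrence is accumulated over a
symmetric window (default 5) with inverse-distance weighting; sentences
never share context. These are the original GloVe conventions; a
full-sentence window (22) and uniform weighting are selectable because the
sentences here are short enough that either regime is defensible. The cost

    J = Σ_{x_ij>0} f(x_ij) (v_iᵀ v_j + b_i + b_j − log x_ij)²,
    f(x) = (x/x_max)^α for x < x_max else 1,  x_max = 100, α = 0.75

is minimized by full-batch AdaGrad (initial rate 0.05, 1000 iterations) —
with a 16-word vocabulary the co-occurrence matrix is dense and tiny, so
full-batch optimization is exact and sub-second; no sampling, sharding or
asynchrony is warranted. `log 0` is never evaluated: the sum is restricted
to nonzero cells. The embedding handed to the network is the sum of word
and context vectors (standard composition; word-only selectable).
Default dimension d = 100.

### Network numerics

No deep-learning framework is a dependency: the layers are built on a
small in-package reverse-mode autodiff core (`cnncrispr.nn`) over float64
numpy arrays — dense, same-padding 1-D convolution via explicit kernel
taps, embedding gather, batch normalization composed from primitives, and
a per-timestep LSTM recurrence. Float64 keeps central-difference gradient
checks tight (the suite verifies the full model gradient to ~1e-4 relative)
and makes runs bit-reproducible on one CPU. Adam uses the standard
bias-corrected moments.

LSTM semantics are the standard four-gate form: with z = [h_{t−1}, x_t],

    f = σ(zW_f + b_f), i = σ(zW_i + b_i), C̃ = tanh(zW_C + b_C),
    o = σ(zW_o + b_o), C_t = f⊙C_{t−1} + i⊙C̃, h_t = o⊙tanh(C_t)

run in both directions, with each position's output combining the forward
state A and backward state A' as y = g(V·A + V'·A'). The combining
activation g is tanh (the combination rule leaves g generic; tanh keeps the
recurrent output bounded and centered going into the convolutions).

Defaults that the architecture description leaves open, all configurable:
conv filter counts (10, 20, 40, 80, 100) with kernel sizes (5, 5, 3, 3, 3),
stride 1, same padding, ReLU — increasing filter counts with shrinking
kernels is the conventional pyramid; recurrent width 30 units per direction
(comparable scale to the d = 100 embedding without dominating the parameter
budget); the biLSTM output width is 2×30. The embedding layer is
initialized from the GloVe matrix and fine-tuned during supervised training
(a frozen mode exists). Both heads share the dense(20) → dense(2) trunk;
classification applies a two-class softmax and reports the class-1
probability, regression applies a logistic to the second output unit and
trains by MSE against frequency (standard for a bounded target under a
logistic output). Fixed published-style defaults: dropout 0.3, Adam lr
0.01, batch-size parameter m = 256.

### Imbalance sampling

Per epoch, negatives are shuffled and cut into N = ⌊M/m⌋ subsets of size m;
each subset is paired with m positives drawn with replacement (N draws per
epoch). Unused negatives (< m per epoch) roll into the next epoch's
shuffle rather than forming a short batch, keeping batch shapes fixed.
Batch composition is a genuinely open reading: "batch size m" versus an
m-negative subset plus oversampled positives are not reconcilable exactly,
so the default is balanced 1:1 batches of 2m (oversampling intent, stable
gradients) with a `compact` mode (m/2 + m/2, total m) covering the other
reading. Positive-draw multiplicity is uniform in expectation (verified by
chi-square in the suite).

### Training schedule

Default 100 epochs with early stopping on a stratified 10% validation
split (patience 10), both configurable. Epoch counts in the examples and
end-to-end tests are deliberately small (3–12); they are the package's
desk-scale choice, sized so the planted synthetic signal is recovered in
about a minute on one CPU, and are not tuned estimates of the real screens'
training budget. Divergence (non-finite loss) aborts with the batch index.

### Evaluation

Recall = TP/(TP+FN) at a configurable threshold (default 0.5 — the usual
convention, since none is canonical). auROC is the trapezoidal area with
tied scores grouped; auPRC the step-curve area; both delegated to
scikit-learn and cross-checked in the suite against a concordant-pair
brute-force oracle and the degenerate constant-score identities (auROC 0.5,
auPRC = prevalence). Pearson/Spearman come from scipy with average-rank tie
handling. Leave-one-sgRNA-out makes one fold per guide; a fold whose test
set is single-class keeps its defined metrics, and undefined ranking
metrics are excluded from the fold mean with a logged notice. Regression
outputs can be fed to the ranking metrics against the binary labels
(probability-style reading of predicted frequency).

### CFD baseline

Multiplicative per-mismatch scoring over the 20-nt protospacer; PAM
positions are excluded (CFD is defined over the protospacer, which the
surrounding text does not restate). `rX-dY` means sgRNA base X against DNA
base Y. Position 1 defaults to the PAM-distal end, with a direction flag
because published tables differ in counting convention. Strict mode errors
on a mismatch absent from the table; non-strict scores it 1.0 with a
warning so partial tables stay usable. Only the two-entry worked-example
fixture ships; the full published table is external and loads through the
4-column TSV format.

## Synthetic benchmark: what it does and does not emulate

The generator reproduces the screen *statistics* the method assumes:
uniform random NGG guides; candidate loci with k ~ U{1..5} mismatches at
uniform protospacer positions and uniform substitute bases; a configurable
negative:positive ratio (default 250:1); and a planted cleavage propensity
that is multiplicative per mismatch under a hidden random score table
(entries U[0.05, 0.95]) — the only explicit mechanistic scoring model in
this domain, and one both the CFD baseline and the network can in principle
recover, which is what makes end-to-end checks meaningful. Positives are
the top 1/(1+ratio) fraction by propensity (rank-based, so the imbalance is
exact); positive frequencies are the propensity plus truncated Gaussian
noise (default sd 0.05), clipped away from zero so labels and frequencies
stay consistent. Positives are assigned per guide, spreading them uniformly
across guides (the real per-guide distribution is unpublished;
configurable).

It does **not** emulate genome-realistic site discovery (no alignment-based
candidate enumeration, no sequence composition bias, no chromatin or
cell-line effects) and contains no indel/bulge sites. Passing the
end-to-end checks therefore shows that the implementation can learn a
planted position- and type-dependent multiplicative signal under realistic
imbalance — not that it attains any particular accuracy on real screens.

## Numerical and degenerate-input choices

- All randomness flows from explicit seeds through
  `numpy.random.SeedSequence`; a single global seed fans out to per-stage
  sub-seeds via fixed stage ids, so adding a stage never perturbs earlier
  stages' draws.
- Ties in the propensity ranking (all-identical scores) are broken by a
  seeded jitter and logged.
- Zero co-occurrence rows make conditional probabilities undefined and are
  reported as errors, never silently dropped.
- Batch normalization uses running statistics (momentum 0.1, eps 1e-5) at
  inference; dropout is inverted (scaled at train time).
- Splits round the per-stratum test count; strata smaller than 2 are
  errors.

## Known limitations

- CPU-only and float64: training throughput is desk-scale (seconds per
  256+256 batch); the implementation targets correctness and
  reproducibility, not screen-scale training runs.
- The exact published conv/recurrent widths live only in the original
  authors' repository; the defaults here are declared package choices.
- Recall at the default 0.5 threshold is calibration-sensitive under short
  training (see the README example); ranking metrics are the robust
  summary.
- Leave-one-sgRNA-out retrains one model per guide; with the full network
  this is the most expensive protocol and is sized accordingly in tests.
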
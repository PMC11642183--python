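# Methods

`promdesign` implements a design-and-screen loop for fixed-length (50 bp)
bacterial promoter sequences: an adversarial generator constrained by
composition statistics, two independent strength regressors, and a
decile-intersection fusion that trades candidate coverage for precision.
This note records the models, their assumptions, the tunable parameters,
and the design choices made where the design was genuinely open.

## Sequence representations

**One-hot.** Sequences are strict `{A, C, G, T}` strings of one corpus-wide
length L (default 50). Ambiguity codes are rejected, never imputed. The
one-hot matrix is L x 4 with the fixed column order (A, C, G, T) used by
every module, so feature tensors always align. Error messages use 1-based
coordinates; internal indexing is 0-based.

**Chaos game representation (CGR).** Corners A=(0,0), T=(1,0), C=(0,1),
G=(1,1); point i is the midpoint of point i-1 and the corner of base i.
The walk starts at (0.5, 0.5) — the conventional CGR centre; the start is
configurable because any interior start converges to the same attractor
at rate 2^-i. The structural fingerprint fed to the deep model is the
20 x 20 *occupancy grid* of the trajectory: half-open binning
`floor(coord * 20)` (1.0 folds into the last bin), each of the L points
weighted 1/L, so the grid always sums to 1. A positional 20-row weight
matrix would be incoherent for a 4-letter alphabet of 50-mers; the
occupancy-grid reading is the only one consistent with a 20 x 20
single-channel input derived from CGR with equal point weights.

**Descriptors.** GC content is reported as a percentage. Dinucleotide
Moran's I builds the series x_i = within-sequence frequency of the
dinucleotide starting at position i (i = 1..L-1) and applies Moran's I
with binary lag-1 adjacency weights (w_ij = 1 iff |i-j| = 1); the lag is
configurable. A constant series (e.g. a homopolymer) raises a
zero-variance error rather than returning NaN. CKSNAP covers gaps
k = 0..K_max-1 (default K_max = 5; the gap range follows the
concatenation convention of the feature definition), 16 dinucleotide
frequencies per gap in lexicographic order, each block normalized by
N-k-1. EIIP features weight k-mer frequencies (denominator N-k+1) by the
summed base potentials A=0.1260, C=0.1340, G=0.0806, T=0.1335 — the
standard literature table, stored as a named constant and overridable;
the per-k-mer potential generalizes to any k as the sum of base values.

## k-mer embeddings and string featurizers

Overlapping 3-mers are treated as words (a 50-mer yields 48 of them). A
skip-gram model with negative sampling (dimension 100, window 5, 5
negatives) is trained on the corpus with min-count 1, so any sequence
drawn from the corpus embeds without out-of-vocabulary gaps; unseen
k-mers raise a named error rather than silently becoming zero vectors.
The trainer uses mean-normalized mini-batch gradients (batch 1024, base
step 5.0 decaying linearly to 10%): with a vocabulary of at most 64
3-mers each row receives hundreds of contributions per batch, and
classic per-pair steps applied as summed scatter updates diverge. The
objective, noise distribution (unigram^0.75) and zero-initialized output
matrix follow the standard formulation; training is single-threaded and
bit-reproducible under its seed.

The same trainer backs the FastText-style featurizer (input units =
k-mer + its character bigrams + characters, 2k units per k-mer, mean
pooled) and the Doc2Vec-style featurizer (input units = document ids,
i.e. PV-DBOW; new documents are inferred by gradient steps against the
frozen output matrix). Classic vectorizers (character counts, character
n-grams with default range 2-3, tf-idf, hashing with default width 64)
and the LDA / LSA / PCA (default dimension 10) / t-SNE (dimension 2)
reductions of the count matrix use scikit-learn. t-SNE has no
out-of-sample transform; its block only reproduces its fitting corpus
and is excluded from bitwise-stability guarantees across library
versions. GloVe- and BERT-style featurizers require pretrained weights
and are declared, error-raising stubs.

## Adversarial generator

The generator maps a 64-dimensional Gaussian noise vector, repeated at
every timestep, through a single LSTM (hidden 128) and a per-step dense
softmax to an L x 4 matrix of base probabilities. The discriminator runs
an LSTM (hidden 128) over sequence rows and emits a real-vs-generated
probability. Losses: generator, negative log probability that the
discriminator labels its output real; discriminator, binary
cross-entropy pushing real to 1 and generated to 0. Updates alternate
one-for-one under Adam (both learning rates 1e-3, batch 32). The
discriminator sees the generator's continuous probability rows during
training — a continuous relaxation that keeps the generator
differentiable; emission discretizes by per-position argmax, with
temperature sampling behind a flag (sampling preserves diversity and is
what the screening pipeline uses by default).

Screening accepts a candidate iff |GC - target_GC| <= gc_tolerance and
|I - target_I| <= moran_tolerance, with targets defaulting to the
training-corpus means and tolerances defaulting to 0.05 (GC fraction)
and 0.1 (Moran's I). Candidates with an undefined Moran's I (constant
dinucleotide series) are rejected with an explicit reason. Rejection is
a reported outcome, never an error; the per-candidate report carries
both measured values, and every emitted sequence satisfies both windows
by construction.

## Deep strength regressor (model 1)

Two branches: the k-mer branch applies a 1-D convolution (64 filters,
kernel 3) + max-pool (2) + bidirectional LSTM (hidden 32 per direction)
to the (48, 100) embedding matrix; the structural branch applies a 2-D
convolution (32 filters, 3 x 3) + max-pool (2 x 2) to the (20, 20, 1)
occupancy grid. The concatenated branch outputs feed a dense ReLU layer
of width 512 and a scalar linear output. Strength is log-standardized
(z = (log y - mean)/sd, statistics from the training split only);
inputs are z-scored (embeddings per dimension, grids per cell) with
scalers fit on the training split only. Loss is MSE under Adam
(lr 1e-3), with the learning rate halved when validation loss fails to
improve for 5 epochs (floor 1e-5). The final layer's weights are scaled
down at initialization so early losses start near the target variance.
Convolution filter counts, kernel sizes and the recurrent width are
configurable; the dense width 512 and branch input shapes are the
architecture's fixed points. An auxiliary corpus (e.g. a second
species' promoters) can be pooled into the training split — never into
validation — to stabilize fitting on small primary corpora.

All network code runs on a small reverse-mode autodiff core written for
this package (numpy tape of dense/convolution/LSTM/pooling operations,
Adam with per-tensor freezing). Its correctness oracle is the
finite-difference gradient check in the test suite; max-pool ties route
gradient to the first maximum.

**Incremental training** continues optimization on new records while a
seeded random subset of parameter tensors — round(lock_fraction x T) of
the T tensors — is excluded from optimizer updates and therefore stays
bit-identical. Freezing at tensor granularity (rather than per weight)
makes conservation testable by checksum. The incremental model keeps
the original target transform and input scalers so predictions remain
on the same scale.

**Similarity subsets** for incremental training rank training records by
cosine similarity of 3-mer frequency vectors against query sequences,
take the top n per query (ties broken by record order) and return the
union with each record's maximum similarity.

## Random-forest regressor (model 2)

The feature matrix fuses the configured string blocks with the
non-string descriptors (GC, Moran's I, CKSNAP, EIIP, k-mer frequencies
for k = 2..6), all columns named and prefixed by block. The fit
pipeline is fixed: z-score scaling; log-standardized target; feature
selection — default top 20% of columns by univariate F-statistic
(equivalent to squared-correlation ranking), alternatively model-based
selection from a preliminary forest; exhaustive grid search over
n_estimators {100, 300} x max_depth {8, 16, none} x max_features
{sqrt, 0.3} with 5-fold cross-validation on mean squared error; refit
on all rows. Scaling and selection live inside the cross-validated
pipeline, so fold statistics never leak from validation rows; the full
per-grid-point score table is retained. Zero-variance and duplicate
columns are dropped deterministically with a warning before fitting —
note that the CKSNAP gap-0 block and the k=2 k-mer block are the same
quantity and one of them is always dropped as a duplicate. Prediction
aligns columns by name; a missing trained column is an error naming it.

## Decile fusion and quantile hit rates

Each ranking (model 1, model 2, ground truth) is stratified over the
evaluated set itself: rank 1 = largest value, decile
d = ceil(10 rank / N), ties broken by stable input order (set
membership must be crisp, so midranks are not used). "Top" means
highest predicted strength — the design goal is strong promoters. The
top-m set is {items: d <= m}; fusion intersects or unites the two
models' top-m sets for m in {2, 3, 4, 5}; the quantile hit rate of a
candidate set is the percentage of its members whose truth decile is
<= m_true (m_true in 1..5). An empty intersection's rate is reported as
undefined (NaN), never 0 — zero would falsely signal a measured
failure. The report also carries the candidate-pool decomposition:
|union|, non-intersection count, hits within the intersection broken
out by exact truth decile, and non-hits. The quantile divisor (10) is
configurable.

## Synthetic corpus generator

The generator emulates a bacterial promoter strength corpus so every
stage is testable without external data: n = 2000 sequences of 50 bp
from a uniform background, a -10-box-like TATAAT hexamer planted at
offsets 35-42 in half the sequences (log-effect +1.0) and an arbitrary
hexamer GGCGCA at offsets 5-20 in half (+0.5), with

    log y = 3.0 + (motif effects present) + 2.0 (GC - 0.5) + N(0, 0.5)

and y = exp(log y) > 0. The log-linear law matches the models'
log-standardized target and gives closed-form planted effects for
recovery tests; an auxiliary corpus (default mean shift -0.5, separate
seed) emulates a second species. The benchmark split is a seeded 80/20
shuffle.

What the generator does *not* emulate: positional dependence beyond two
motifs, promoter-element grammar (-35/-10 spacing), realistic genome
composition, or measurement noise structure of RNA-seq/fluorescence
assays. Passing tests therefore demonstrate that the pipeline recovers
a planted, log-linear sequence-to-strength signal at realistic sizes —
not that it attains any particular accuracy on real promoter corpora.

## Problem sizes and numerical choices

Test and verification workloads use these sizes, chosen so each stage
exercises realistic behaviour at desk scale: formula oracles on 200
random sequences (exact to 1e-12); a 5-epoch adversarial run on 200
sequences; a 32-record memorization oracle (200 epochs, plateau decay
disabled via a large patience so the schedule cannot stall
memorization; the check asserts training MSE < 0.05 and training-set
Spearman > 0.95); the deep benchmark at n = 2000 with 30 epochs; the
forest benchmark at n = 500 with k-mer features k in {2, 3} and a
single-point grid; fusion statistics over 50 replicates of two noisy
predictors (noise sd 1.0, giving predictor-truth correlations near the
deep model's) and 1000 random-permutation shuffles.

Other numerical conventions: frequencies over zero windows are errors,
never NaN; degenerate inputs (empty vectors, NaN ranks, constant
series) raise; all stochastic stages take explicit seeds and are
reproducible bit-for-bit on one platform; model directories carry
config hashes, data hashes and seeds.

## Known limitations

- The deep model overfits its training split at default settings (low
  training MSE against a plateaued validation MSE); held-out ranking is
  the supported use, calibrated absolute strengths are not.
- The adversarial generator targets corpus-level composition statistics
  only; it has no notion of conditional generation on strength.
- The embedding trainer's mean-normalized batching is tuned for small
  vocabularies (4^k k-mers); for large vocabularies per-pair updates
  would be preferable.
- t-SNE blocks cannot transform new sequences; Doc2Vec inference for
  new documents is a few-step approximation.
- Cross-validation for the deep model is a single train/validation
  split; k-fold averaging is exposed by re-seeding, not built in.
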
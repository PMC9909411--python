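# Methods

This note records the models implemented, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic corpora do and do not establish about behaviour on real data.

## Text preprocessing

Complaints pass through punctuation removal → segmentation → stop-word
removal, in that order. Punctuation is any character of Unicode category
P\* plus the CJK punctuation and fullwidth-form blocks; removal replaces
with spaces so adjacent tokens never merge. Segmentation is an injectable
callable; the default splits on `\w+` runs (keeping token-internal
underscores and CJK ideograph runs intact), and a whitespace splitter is
provided. Case is folded by default (a no-op for CJK). The stop list is a
config-supplied file, one token per line; the shipped default is a minimal
English list because no canonical inventory exists for this task. A
document whose tokens are all removed is kept but flagged degenerate; it
vectorizes to the zero vector and is assigned cosine 0 to everything.

## Embeddings

Word2vec is implemented in numpy with negative sampling (5 negatives,
unigram^0.75 noise distribution). Skip-gram and CBOW share a pair-level
code path: skip-gram uses the center token as input, CBOW the context
token; at pair granularity the two differ only in which side indexes the
input matrix, which preserves the expected gradient of the windowed-average
CBOW objective while keeping one vectorized loop. Training is
single-threaded and deterministic for a fixed seed.

Defaults: window 5, min_count 1 (the corpora here are small), 5 epochs,
SGD with learning rate 0.025 decaying linearly to 10%, batch size 256.
Batched scatter-add can stack many updates onto one frequent token's row
within a batch, so each accumulated row step is clipped to ±0.1; without
the clip, highly repetitive vocabularies can diverge.

A document vector is the unweighted arithmetic mean of its in-vocabulary
token vectors; out-of-vocabulary tokens are skipped and do not count in
the divisor. The embedding dimension is selected by a sweep: for each
(dimension, architecture) pair, embed all documents and score a
5-nearest-neighbour classifier on a stratified 70/30 split; ties prefer
the smaller dimension, then skip-gram (cheaper and, in our sweeps, never
worse).

Two similarity functions are exposed. The default engine everywhere is
cosine over mean document vectors. A token-set overlap measure
|U∩V| / (|U|·|V|) is also provided, with a `sqrt_normalized` variant
(the Ochiai coefficient, bounded by 1); it is selectable but not the
default because dense pairwise similarity tables in (0,1) are what the
cosine engine produces and what the recommendation thresholds assume.

## Department triage

The headline classifier is a single recurrent LSTM layer over a frozen
pre-trained embedding lookup (pad index 0 maps to the zero vector and
leaves the recurrent state untouched, so the classifier reads the state at
each sequence's true end), followed by a ReLU dense layer, dropout and
softmax. TextCNN is one 1-D convolution (filter width 2, max-pool over
time) with the same head. Both train with Adam on cross-entropy,
learning rate 1e-2 (at the few-hundred-step scale of these corpora, 1e-3
barely moves the loss), batch 32. Reference hyperparameters: sequence
length 110, embedding 256, 256 LSTM units, 512 dense units, 15 epochs,
dropout 0.5; `ClassifierConfig.scaled_down()` substitutes dim 32 /
32 units / 64 dense / 5 epochs for small corpora. The maximum sequence
length is the nearest-rank 75th percentile of the token-length
distribution (≈110 for a corpus with median 50 and a long right tail).

The classical baselines consume mean document vectors: random forest
(100 trees), KNN (k = 5), and an SVM with polynomial kernel, C = 0.3,
gamma = 0.2. The SVM sits behind a standardization step: mean-embedding
features have magnitudes around 1e-2, at which the polynomial kernel is
numerically near-constant and the classifier collapses to the majority
class; standardization is ordinary SVM practice and does not alter the
kernel hyperparameters.

Metrics are one-vs-rest TP/FP/FN per class; headline numbers are macro
averages (micro also computed). A class absent from the test set yields
NaN per-class entries and is excluded from the macro mean with a warning.
Two protocols are provided and kept separate: a stratified 70/30 split
(the default reporting protocol) and repeated stratified k-fold
(10 folds × 5 repeats at reference scale), with per-repeat seeds derived
from the master seed.

Backpropagation notes: gradients for both networks are verified against
central differences in the test suite. Max-pool routes its gradient to the
first arg-max on exact ties; ties occur with non-negligible frequency on
synthetic text (duplicated token windows) and the chosen routing is a
valid subgradient.

## Physician recommendation

*Similar patients.* Candidates are all patients with cosine ≥ β to the
target, the target itself included — its self-similarity of 1.0 anchors
its own physician in the ranking, matching how a consultation history
should dominate a content signal. Each physician consulted by ≥ 1
candidate is scored by the mean similarity of its candidate patients;
the top 10 by score are returned. An empty candidate set is a cold start:
an empty list with a warning, not an error.

*Similar physicians.* Each physician's consulted texts are concatenated
into one document; tf·idf (tf = within-document frequency, smoothed
idf = ln((1+N)/(1+df)) + 1) ranks tokens, the top 15 are kept (ties by
raw count, then lexicographic), and the profile vector is the unweighted
mean of the in-vocabulary keyword embeddings. Ranking is by cosine to the
profile of the target's consulted physician, that physician excluded. A
target with no consultation history raises a cold-start error, since this
strategy has nothing to anchor on.

*Hybrid.* The narrative rule — delete set-A physicians missing from set B
and let the next physician fill the slot — is formalized as: walk the
extended similar-patient ranking (set A first, then the remainder of the
full ranking) in order, keep entries that are members of set B or are the
target's own consulted physician, stop at 10. Retained entries keep their
set-A scores. The own-physician carve-out reflects that a physician the
patient already consulted should not be filtered out by a profile-match
technicality.

Ties everywhere break by score descending, then physician id ascending,
making every strategy deterministic.

## Evaluation

Success rule: physician p is successfully recommended to target t at
(β, γ) iff the fraction of p's consulted texts with cosine ≥ β to t's
complaint vector is ≥ γ (boundary inclusive; the reference operating
point is γ = 0.8). The same β serves as the candidate threshold and the
success threshold — the method introduces no second similarity cutoff.
γ is exposed as a free parameter of the sweep rather than fixed at 0.8.

Service quality compares each recommended physician's mean reply length
(unicode characters) and mean voice duration (seconds) against the
unweighted mean over the whole physician pool, strictly greater-than; a
physician with no replies counts as below baseline. Corpus-level A, B, C
are unweighted means over all target patients (each patient serves once
as target); a patient with an empty recommendation list contributes 0 to
all three. RP = τ₁A + τ₂B + τ₃C with defaults (0.8, 0.1, 0.1); weights
not summing to 1 warn rather than fail, since the weighting is a modeling
choice, not an identity.

For fixed β, B and C do not depend on γ and per-physician success is
monotone non-increasing in γ, so RP is non-increasing in γ — the test
suite verifies this on seeded corpora for all three strategies. The sweep
engine precomputes the patient-similarity matrix, the physician text
cosine rows and the service-quality flags once, so each grid cell reduces
to thresholding.

## Synthetic corpora

The generator emulates: department-specific vocabularies (each disease
owns a round-robin slice of its department's vocabulary, so complaints
cluster by disease within departments); a `separation` parameter giving
the probability a token is drawn from the disease slice rather than the
shared vocabulary; lognormal complaint lengths (default ln 50 / 1.07,
i.e. median ≈ 50 tokens, mean ≈ 89, verified at n = 10,000 in the tests);
uniform department assignment; each patient linked to one physician of
their department whose consulted texts are exactly their patients'
complaints; and per-physician gamma reply lengths / voice durations with
a lognormal per-physician scale multiplier so physicians differ
systematically in verbosity. The guidance preset uses 8 departments with
a 9th disease added to the first department; the recommendation preset is
a single department of 63 physicians.

Tokens are opaque strings — the pipeline is language-agnostic after
segmentation, so no natural language is needed to exercise any stage.
What the synthetic corpora therefore do **not** establish: behaviour under
real segmentation ambiguity, misspellings, code-switching, or the soft
topical overlap of real departments (synthetic vocabularies overlap only
through the shared pool). Passing tests show the machinery is correct and
behaves monotonically as designed, not that real-data accuracy figures
will be reproduced.

A separate fixture generator pins service-quality counts exactly (n of a
pool strictly above the pool mean) by giving "above" physicians one high
constant and the rest one low constant; requesting all physicians above
their own mean is rejected as infeasible.

## Problem sizes used in the tests

Classifier-separation checks use 600-complaint corpora with short
complaints (median ≈ 12 tokens); the LSTM training-loss check uses 2,000
complaints at the realistic length distribution with the scaled-down
configuration; the recommendation/evaluation checks use 150 patients and
24 physicians. These sizes were chosen once as the smallest at which the
properties under test are stable, and the structural results (grid shape,
monotonicity, linearity, oracle equivalence) are scale-free.

## Known limitations

- The Eq.-style set-overlap similarity and the cosine engine can disagree
  on rankings; only cosine is exercised by the evaluation path.
- CBOW is trained at pair granularity (see above), not with a true
  averaged-context hidden layer.
- The LSTM/TextCNN trainers are plain-numpy and single-threaded; they are
  sized for corpora of thousands, not hundreds of thousands, of documents.
- No significance testing between strategies, and no ranking-quality
  metrics (NDCG/MAP); the composite RP is the only list-level score.
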
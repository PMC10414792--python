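# Methods

This note documents the model, the numerical choices, and the reasoning
behind design decisions that were genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting and data contract

The classifier separates neuropeptides from non-neuropeptides given only
the primary sequence. Inputs are peptides over the 20 natural amino acids
with lengths in [5, 100]; `filter_by_length` enforces both bounds
inclusively (a 5-mer and a 100-mer are kept; 4 and 101 are removed).
Labels arrive in FASTA headers (`>id|label=1`) or a two-column TSV.
Sequences are uppercased before validation; ambiguity codes (B, J, O, U,
X, Z) and stop characters are rejected, not silently stripped, because a
residue the encoders cannot represent would otherwise corrupt features
silently. Train/test splitting is stratified (a balanced 80/20 outcome on a
balanced input requires it) and seeded.

## Padding and the pseudo-residue

All encoders need fixed shapes, so sequences are right-padded with `B` to
length 100. Right padding (rather than centering or left padding) keeps
residue positions anchored to the N-terminus, the convention for models of
short peptides whose informative context typically starts at the sequence
start. The pad letter participates in the encodings deliberately:

- one-hot: `B` rows are the constant 0.05 vector — the uniform
  residue-frequency prior (20 × 0.05 = 1), so pad rows carry "average
  residue" information rather than zeros.
- AAIndex: `B` rows are per-property means over the 20 residues, the same
  uniform-frequency reading carried to continuous scales. (The pad value
  for property scales is not dictated by the encoding itself; the mean is
  the unique choice consistent with the one-hot convention.)
- g-gap: pairs with one pad member are tallied (they mark where the
  sequence ends — effectively a length feature); only the pure-pad pair
  (B,B) is discarded, giving the 440-bin space. Counting happens on the
  padded sequence; this is the only reading under which B-containing bins
  are meaningful at all.

## Encoders

**AAIndex.** The 14 property scales (HOPT810101, EISD840101, MIYS990104,
LIFS790101, MAXF760101, CEDJ970104, GRAR740102, KYTJ820101, MITS020101,
DAWD720101, BIOV880101, CHAM810101, EISD860101, BIGC670101) are vendored as
static constants transcribed from the public AAIndex database
(`_aaindex_data.py`). The columns mix hydropathy, secondary-structure
propensity, composition, accessibility, sterics and volume — a deliberately
heterogeneous physicochemical fingerprint. Raw units are kept in the
encoding; scale differences are handled by the model-side standardizer
(below).

**g-gap dipeptides.** `g` is the number of residues between the ordered
pair members (g = 0: adjacent dipeptides). The default is g = 0, the
setting that maximized cross-validated AUC when gap widths 0–4 were
compared. Counts are expressed as a 10-level one-hot per bin: count c in
1..10 sets column c−1, count 0 leaves an all-zero row, and counts above 10
clip to 10. The cap reflects the empirical maximum on realistic peptide
sets; clipping (rather than widening the matrix) keeps the 440 × 10 shape
stable for arbitrary inputs such as homopolymer stress tests.

**Skip-gram embeddings.** Tokens are single residues (vocabulary = the
21-letter padded alphabet), d = 32, window 5, 100 epochs. Because the
vocabulary is tiny, the skip-gram negative-sampling objective is optimized
in its *exact expectation*: center–context pairs are aggregated into a
21 × 21 co-occurrence matrix and the negative term is taken analytically
over the unigram^0.75 noise distribution, so each epoch is one full-batch
Adam step on 21 × d parameters. This is the same objective stochastic SGNS
trainers approximate, made deterministic and essentially free. Embeddings
are trained only on the training split (inside each CV fold, only on that
fold's training part) so the encoder itself cannot leak held-out
information. Tokens absent from a corpus keep the zero vector. CBOW is not
implemented.

## Base classifiers

Each encoder feeds a small 1-D conv net written directly in numpy
(`nn.py`): (conv → ReLU) along the first axis with the feature columns as
channels, a global pooling stage, inverted dropout, one dense ReLU layer,
and a sigmoid unit, trained with Adam on binary cross-entropy. The
implementation is plain forward/backward code; its gradients are verified
against central finite differences (≤ 1e-6 relative) in the test suite, and
all randomness (init, shuffling, dropout) flows from one seed, so training
is bit-reproducible.

Inputs are standardized per channel (mean/std fit on the training set,
stored with the model). This matters for AAIndex, whose raw columns span
~0.01 to ~136; it is harmless for the binary encodings.

Per-encoder defaults (`default_base_configs`):

| encoder | filters | kernel | head | dropout |
|---------|---------|--------|------|---------|
| onehot, aaindex, word2vec | 64 | 5 | global max pool | 0.3 |
| g-gap | 32 | 3 | flatten | 0.5 |

Two points deserve the explanation:

- **The g-gap head keeps the position axis.** On the sequence-axis
  encodings a motif is a translation-invariant local pattern, exactly what
  conv + global max pooling detects. On the dipeptide matrix the first axis
  indexes *which pair* occurred — position is identity, not context — and
  global pooling would collapse "pair (W,K) seen once" and "pair (A,A) seen
  once" into the same feature. The flatten head preserves bin identity;
  without it the g-gap model is blind by construction (chance-level AUC),
  with it it performs on par with the other bases.
- **64 filters / dropout 0.3 on the sequence encoders.** A narrower
  32-filter, dropout-0.5 template trains well on most seeds but
  occasionally loses the motif filter to unlucky initialization; widening
  the bank makes held-out AUC stable across seeds. Selection used the same
  criterion the training pipeline exposes for hyperparameter search: mean
  AUC over stratified 5-fold CV.

Other training defaults: learning rate 1e-3, batch 64, 50 epochs, no early
stopping (determinism). `grid_search` scores any candidate grid by mean
stratified k-fold AUC, breaking ties toward the earliest-enumerated
combination.

## Stacking

Meta-features for training the meta-learner are **out-of-fold** base
predictions under one shared stratified fold assignment (5 folds by
default): sample s is scored, for all four encoders, by models whose
training folds excluded s. Resubstitution predictions would look better and
mean nothing; the out-of-fold construction is the standard leakage-free
reading of stacking, and a structural test (fake base models that flag
their own training rows) verifies no sample is ever scored by a model that
saw it. For new samples the bases (and the embedding table) are refit on
the full training set.

Gaussian naive Bayes is the from-scratch deliverable: priors are class
frequencies; per class and feature, means and *population-divisor*
variances (the divisor convention is not dictated by the model; population
was chosen, matching common library behavior, and is pinned by a test
against an independent implementation). Variances get a smoothing floor,
default 1e-9 × the largest pooled per-feature variance, which keeps
degenerate zero-variance features finite on small synthetic sets. The
posterior is computed in log space with a max-subtraction renormalization;
a brute-force non-log density-product oracle agrees to 1e-9 relative.
A posterior of exactly 0.5 classifies as the positive class (documented
tie-break). LR / AdaBoost / GBDT / XGBoost are delegated to scikit-learn
and xgboost behind the same `predict_proba` interface for the comparison
experiment only; they are not serialized.

## Evaluation

Sn, Sp, Acc and MCC come from the 0.5-threshold confusion table; the MCC
uses the standard Matthews form with the square-root four-factor
denominator, with a zero factor yielding MCC = 0 (warned). An empty class
leaves Sn or Sp undefined (NaN with a warning) rather than a fabricated 0
or 1. AUC is the Mann–Whitney probability with ties at 1/2, delegated to a
standard implementation and checked against a brute-force all-pairs oracle
to 1e-12. Cross-validated headline numbers are unweighted fold averages
(pooling would weight folds by size and blur the per-fold variance the
averages are meant to summarize).

## Interpretation

Shapley values of the meta posterior are exact: 4 features → 16 coalitions,
enumerated directly with the interventional (marginal-replacement) value
function v(S) = mean over background rows of f(x on S, background off S).
The background defaults to the meta-training matrix, subsampled to 200 rows
with a seed. Exactness buys the axioms at floating precision — efficiency
(Σφ = f(x) − base value, asserted at 1e-9 on every explanation), dummy and
symmetry — and removes any estimator variance from the attribution. The
explained output is the class-1 posterior probability (not log-odds), so a
positive φ reads directly as "pushes toward the neuropeptide class". The
summary view is the mean absolute φ per meta-feature. Which encoder
dominates is a property of the data and the fitted model, not of the
method; tests only assert it for constructed cases where the answer is
known (signal planted in a single column).

## Synthetic benchmark

`synthetic_data.generate_dataset` draws balanced classes with lengths
uniform on [5, 100] from a background residue model (uniform by default;
a Swiss-Prot-like frequency table is provided), then overwrites a 5-mer
motif (default `WKRFC`) at a random position in each positive with
probability `motif_rate` (default 1.0). Overwriting rather than inserting
keeps length distributions identical between classes, so length is not a
confound unless the user makes it one. With a fully penetrant motif the
Bayes optimum is known (the motif is perfectly class-predictive and occurs
in a negative only by chance, ~10⁻⁵ per position), which turns the whole
pipeline into a testable system: every base classifier should approach
AUC 1, stacking should not fall below the best base, and permuted labels
should land at chance.

What passing these tests shows: the encoders, training loop, stacking
construction, metrics and attribution are correct and leakage-free. What it
does not show: performance on real neuropeptides, where the class signal is
distributed, partially penetrant, and confounded with composition and
homology. The generator makes no attempt at cleavage-site or precursor
biology.

`generate_meta_features` skips the sequence stage entirely and draws
class-conditional Gaussians in [0,1]⁴ (class means 0.5 ∓ separation/2 on
informative columns, noise sd 0.15, clipped), for direct tests of the
meta-learner and the Shapley module.

## Problem sizes

The benchmark harness (`benchmark.py`, used by the acceptance script and
the end-to-end tests) runs 400 peptides with 5-fold CV for the main
analysis, 400 for the 5- vs 10-fold comparison (one-hot base), and
240 peptides × 5 seeds for the permutation null — sizes at which the full
four-encoder pipeline completes in a few minutes on one CPU while leaving
the planted-signal conclusions unambiguous.

## Known limitations

- The vendored AAIndex table was transcribed once from the public release;
  values are constants in the repo and easy to audit or replace, but no
  on-line lookup is performed.
- Real-data hyperparameters are not reconstructed: the per-encoder defaults
  here were selected for stability on the synthetic benchmark and are
  starting points, not tuned settings, for curated neuropeptide data.
- Only the GNB-stacked ensemble serializes to a model directory; the four
  comparison meta-learners produce reports but are not persisted.
- The CNN is minimal by design (one conv layer, one dense layer); it is not
  a platform for deep architectures, and multi-layer conv stacks, though
  supported, are not exercised by the defaults.
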
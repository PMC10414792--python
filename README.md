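# neurostack

Neuropeptide prediction from peptide sequence, built as a stacked ensemble:
four complementary sequence encodings, one small convolutional network per
encoding, and a Gaussian naive Bayes meta-learner over the four base
probabilities, with exact Shapley attribution of the final posterior back to
the encodings.

## Who this is for

Neuropeptides are short bioactive peptides (5–100 residues) that signal in
the nervous system. Distinguishing them from other short protein fragments
by experiment (LC–MS) is slow and depends on curated precursor databases, so
sequence-based classifiers are used to triage candidates. This package is a
reusable, tested implementation of that classification workflow for anyone
who wants to train such a predictor on their own labeled peptide sets, or to
study the behavior of stacked CNN ensembles on peptide data.

## The model

Each peptide is right-padded with the pseudo-residue `B` to length 100 and
encoded four ways:

| encoder  | shape    | content |
|----------|----------|---------|
| one-hot  | 100 × 20 | basis vector per residue; pad rows are the uniform 0.05 vector (20 × 0.05 = 1) |
| AAIndex  | 100 × 14 | 14 physicochemical property scales per residue; pad rows are property means |
| g-gap    | 440 × 10 | counts of ordered residue pairs (s<sub>i</sub>, s<sub>i+g+1</sub>) over the 21-letter alphabet minus the pure-pad pair (441 − 1 = 440 bins), one-hot in 10 count levels; g = 0 by default |
| word2vec | 100 × d  | skip-gram residue embeddings (d = 32), trained on the training split only |

A 1-D CNN per encoding emits a neuropeptide probability; the four
probabilities form the meta-feature vector
(p<sub>onehot</sub>, p<sub>aaindex</sub>, p<sub>ggap</sub>, p<sub>word2vec</sub>).
Stacking uses **out-of-fold** base predictions (each sample scored by the
model whose training folds excluded it), so the meta-learner sees no leaked
training predictions. The meta-learner is Gaussian naive Bayes, implemented
from first principles:

    P(y = 1 | x) ∝ π₁ ∏ⱼ N(xⱼ; μ₁ⱼ, σ₁ⱼ²)

with class frequencies as priors, population-variance estimates plus a
smoothing floor, and a log-space posterior. Logistic regression, AdaBoost,
GBDT and XGBoost are available behind the same interface for the
meta-algorithm comparison. Evaluation reports Sn, Sp, Acc, MCC and AUC
(fold-averaged under stratified k-fold CV), and interpretation computes
**exact** Shapley values of the meta posterior over the four meta-features —
with 4 features all 2⁴ coalitions are enumerated, no sampling.

## Worked example

Real benchmarks are not bundled; the synthetic generator emulates one —
balanced classes, lengths 5–100, and a 5-mer motif planted in positives so
the class signal is known exactly.

```bash
$ neurostack simulate --out demo/data --n-pos 60 --n-neg 60 --seed 42
wrote 120 records to demo/data/data.fasta

$ neurostack train --fasta demo/data/data.fasta --out demo/run --k 5 --epochs 50 --seed 0
out-of-fold AUC=0.992 Acc=0.933 Sn=0.917 Sp=0.950 MCC=0.867
```

`train` writes `demo/run/model/` (four base checkpoints, the embedding
table, the GNB parameters, a manifest) plus `metrics.json` and the echoed
`config.yaml`. The printed numbers are out-of-fold: every sample was scored
by base models that never trained on it, so they estimate generalization,
not memorization.

```bash
$ neurostack predict --model demo/run/model --fasta demo/data/data.fasta --out demo/pred.tsv
predicted 120 records (0 rejected)
$ head -2 demo/pred.tsv
id	p_onehot	p_aaindex	p_ggap	p_word2vec	p_meta	label	error
pos_0001	0.828497	0.750394	0.497487	0.986638	0.999999	1	
```

Each row shows the four base probabilities, the stacked posterior and the
0.5-threshold label; records with invalid residues are reported in the
`error` column instead of aborting the run.

```bash
$ neurostack explain --model demo/run/model --fasta demo/data/data.fasta --out demo/shap
mean |phi|: onehot=0.0402, aaindex=0.1991, ggap=0.0034, word2vec=0.2631
```

The mean absolute Shapley values say which encodings drive this particular
model's decisions (here the embedding and AAIndex channels); per-sample
values are in `demo/shap/shap.tsv`, where every row satisfies the efficiency
identity Σφⱼ = f(x) − E<sub>background</sub>[f].

The same workflow is available as library calls
(`neurostack.synthetic_data.generate_dataset`, `neurostack.stacking.fit_stacked`,
`neurostack.stacking.stacked_predict`, `neurostack.interpret.exact_shapley`).

## Scope notes

- Redundancy removal (CD-HIT style clustering) is out of scope; datasets
  are expected to arrive deduplicated.
- The synthetic generator supplies statistical structure for testing, not
  neuropeptide biology; see `docs/methods.md` for what that does and does
  not demonstrate.
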
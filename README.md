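# secpred

Sequence-based prediction of **non-classically secreted** Gram-positive
bacterial proteins — proteins exported to the extracellular milieu without a
Sec/Tat signal peptide. Such proteins are frequent players in pathogenesis,
and because their export routes are heterogeneous and poorly characterised,
they are found by classification rather than by motif matching.

`secpred` is a toolkit for building that classifier end to end:

1. **Curation** — FASTA input, length bounds (50–10 000 residues), exclusion
   of dubiously annotated entries ("fragment", "putative", ...), removal of
   the annotated N-terminal signal region from positive examples, and greedy
   identity culling so no retained pair exceeds 25% pairwise identity.
2. **Encoding** — four fixed-length feature vectors per sequence:
   amino-acid composition (20), dipeptide composition (400), Atchley
   physicochemical-factor vectors (100), and PSSM-400 vectors (an L×20
   PSI-BLAST profile collapsed to 20×20, length-normalised, sigmoid-squashed).
   Any of the 15 block combinations can be concatenated and written in LIBSVM
   sparse format.
3. **Selection** — C-SVC with linear, Gaussian and polynomial kernels; the
   kernel, its parameters, the cost C ∈ 2^(−5..15) and the feature
   combination are chosen jointly by grid search (8 415 candidate models by
   default) inside **nested stratified k-fold cross-validation**: the inner
   loop picks hyperparameters, the outer held-out folds estimate
   generalisation accuracy without selection optimism.
4. **Evaluation** — sensitivity, specificity, accuracy and the Matthews
   correlation coefficient

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

   plus ROC curves whose AUC equals the Mann–Whitney pair statistic.
5. **Simulation** — a synthetic two-class sequence generator (controllable
   composition and dipeptide-adjacency separation, matching synthetic PSSM
   files) so the whole pipeline is testable without any database download.

## Worked example

```python
from secpred import SecretionClassifier, FixtureSpec
from secpred.simulate import generate
from secpred.selection import HyperParams

records, labels = generate(FixtureSpec(n_pos=40, n_neg=40, separation=0.25, seed=7))
grid = [HyperParams(k, C, frozenset(m), **kw)
        for C in (0.5, 8.0)
        for m in ({"frequencies"}, {"frequencies", "dipeptides"})
        for k, kw in (("linear", {}), ("gaussian", {"gamma": 0.5}))]
clf = SecretionClassifier.from_records(records, labels,
                                       features=("frequencies", "dipeptides"),
                                       grid=grid, k_outer=5, k_inner=5)
res = clf.fit(seed=7)
print(res.summary())
```

prints

```
Nested cross-validated SVM selection
==========================================================
examples: 80 (+40 / -40)
grid points: 8   k_outer=5 k_inner=5 seed=7
----------------------------------------------------------
 fold kernel   C    features  inner_cv_acc  outer_acc  n_test
    0 linear 8.0 frequencies      0.984375     1.0000      16
    1 linear 8.0 frequencies      0.984375     1.0000      16
    2 linear 8.0 frequencies      0.984375     1.0000      16
    3 linear 8.0 frequencies      1.000000     0.9375      16
    4 linear 8.0 frequencies      0.984375     1.0000      16
----------------------------------------------------------
mean outer accuracy: 0.9875
final model: linear kernel, C=0.5
final features: frequencies
final inner CV accuracy: 0.9875
```

Per outer fold: the hyperparameters the inner CV chose, that configuration's
inner CV accuracy, and its accuracy on the held-out fold. The **mean outer
accuracy (0.9875)** is the unbiased generalisation estimate — here high
because the fixture plants a strong composition signal (0.25 of probability
mass shifted between classes). The final model is re-selected on all data;
resubstitution metrics follow from
`res.evaluate(clf.dataset)`:

```
{'sensitivity': 0.975, 'specificity': 1.0, 'accuracy': 0.988, 'mcc': 0.975, 'auc': 1.0}
```

The same pipeline runs from the shell:

```sh
secpred simulate --n-pos 100 --n-neg 100 --separation 0.25 --pssm --out data/
secpred curate data/sequences.fasta --identity-threshold 0.25 --out curated.fasta
secpred encode curated.fasta --labels data/labels.tsv \
        --features freq,dipep,factors --out vectors.svm
secpred train curated.fasta --labels data/labels.tsv --features freq,dipep \
        --model-out model.joblib --report-out report.json
secpred predict new.fasta --model model.joblib --out predictions.tsv
secpred evaluate predictions.tsv --truth truth.tsv --plot roc.png
```

For real data, supply per-sequence PSSM files (NCBI BLAST ASCII dialect, one
row per position with 20 log-odds columns) via `--pssm-dir`; profiles are
typically produced with 3 PSI-BLAST iterations, E = 0.001, BLOSUM62.

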
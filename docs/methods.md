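# Methods

`secpred` classifies Gram-positive bacterial proteins as non-classically
secreted (exported without a Sec/Tat signal peptide) or not, from sequence
alone. The method is a binary soft-margin SVM over fixed-length sequence
encodings, with the classifier — kernel, its parameters, the cost C, and the
*combination of encodings* — chosen by nested k-fold cross-validation with
grid search. This note records the model, the choices that were genuinely
open, and what the synthetic validation data does and does not show.

## Curation model

Training sets for secretion classifiers are screened database extracts, and
the package reproduces that screening as explicit, testable operations:

- **Length bounds.** Only sequences of 50–10 000 residues (inclusive) are
  kept. Shorter entries are mostly fragments or peptides; longer ones are
  usually annotation artefacts.
- **Annotation exclusion.** Entries whose annotation contains any of
  *fragment, probable, probably, potential, hypothetical, putative, maybe,
  likely* are dropped (case-insensitive, whole-word — "reputation" is not a
  hit). Keywords come from a tab-separated sidecar table (id, keywords,
  signal-region end), not from flat-file database parsing.
- **Signal-region stripping.** Positive examples are classically annotated
  secreted proteins with the N-terminal signal/translocation region (position
  1 up to an annotated boundary, typically residues 21–55) removed, so the
  classifier must learn signal-peptide-independent features. Coordinates are
  1-based inclusive (SwissProt feature-table convention). Records without an
  annotated boundary pass through unchanged; the package never guesses a
  boundary.
- **Identity culling.** The set is greedily reduced so that no retained pair
  exceeds 25% pairwise identity, limiting train/test leakage. Candidates are
  visited longest-first (ties by id) and accepted iff their identity to every
  already-accepted sequence is at or below the threshold; the post-condition
  (no retained pair above threshold) is verified exhaustively in tests. The
  identity measure is an injection point. The default is global alignment
  (BLOSUM62, gap open −11, extend −1) with identity = matched columns /
  alignment length; a PSI-BLAST-profile-derived identity can be plugged in
  without touching the culling logic. Reproducing any specific culling
  server's retained set is a non-goal.

## Encodings

All four encoders map a length-L sequence to a fixed-length vector:

| block | dim | definition |
|---|---|---|
| frequencies | 20 | count(a)/L per residue, alphabetical order |
| dipeptides | 400 | count of overlapping ordered pairs / (L−1), row-major |
| factors | 100 | composition(a) × factor_f(a) over the five Atchley factors |
| pssm | 400 | Jones-style collapse of an L×20 profile, /L, then sigmoid |

Open choices resolved here:

- **Factor vectors.** The five multivariate physicochemical factors
  (polarity, secondary-structure propensity, molecular volume, relative
  composition, electrostatic charge) give 5 values per residue; the 100-d
  vector is the outer product of the 20-d composition with the 20×5 factor
  table, flattened row-major. This is the construction that reaches exactly
  100 dimensions from 20 residues × 5 factors while staying a composition-
  weighted summary; it is isolated behind `encode_factors` so an alternative
  reading can be swapped in. The factor table is embedded as a vetted
  constant.
- **PSSM vectors.** The L×20 profile is collapsed to 20×20 by summing
  profile rows grouped by the residue type at each position; each entry is
  divided by L and then squashed by 1/(1+e^(−x)). Length normalisation
  precedes the sigmoid (this order matters: the sigmoid saturates on
  unnormalised sums). Division is by L rather than by per-residue-type
  counts — with per-type counts, residue types absent from the sequence have
  an undefined normaliser, while /L keeps every entry finite and gives absent
  types the neutral value sigmoid(0) = 0.5. Both axes use NCBI PSSM column
  order. Profiles are consumed as files; running the profile search itself
  (typically 3 PSI-BLAST iterations, E = 0.001, BLOSUM62, against NR) is out
  of scope and documented here for users generating profiles externally.
- **Combination.** Any non-empty subset of the four blocks (15 masks) can be
  concatenated, always in the canonical order frequencies → dipeptides →
  factors → pssm; each vector's schema records its block boundaries, so
  serialised files are self-describing. LIBSVM sparse output
  (`label index:value`, 1-based ascending, zeros omitted) is
  byte-deterministic at six decimal places by default.

## Model selection

Kernels: linear K(x,y)=x·y, Gaussian K(x,y)=exp(−γ‖x−y‖²), polynomial
K(x,y)=(γ x·y + c₀)^d. Gaussian kernel values always lie in (0,1] with a unit
diagonal, which keeps the optimisation well-scaled; polynomial values can grow
without bound as the degree increases — both properties are asserted as tests.
The default grid is the usual coarse powers-of-two search: C ∈ 2^(−5,−3,…,15)
(11 values), γ ∈ 2^(−15,−13,…,3) (10 values), degree ∈ {2,3,4,5}, coef0 = 0,
crossed with all 15 feature masks: 15 × (11 + 110 + 440) = 8 415 candidate
models. A cost of C = 64, a scale reported for this problem class, lies inside
the C range.

Selection uses nested stratified k-fold CV, k_outer = k_inner = 5 by default
(a standard choice where the fold count is otherwise unspecified). For each
outer fold, the inner loop scores every grid point by CV accuracy on the
outer-training portion and the winner is retrained on that portion and scored
once on the held-out fold; the mean of the outer-fold accuracies is the
generalisation estimate. The deployable model comes from one final grid
search on all data. Accuracy ties are broken deterministically: lower C, then
simpler kernel (linear < gaussian < polynomial), then smaller feature mask.
All randomness flows from one caller seed; examples are canonically ordered
by id before fold assignment, so results are invariant to input order.
`SelectionResults.to_json()` is byte-identical across reruns with one seed.

The inner-loop criterion is CV accuracy. Inner accuracy is expected to exceed
outer accuracy on average (the selection optimism that nested CV exists to
quarantine); this is asserted over repeated null simulations.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Values are returned
as fractions (an optional percent formatter covers percentage reporting);
MCC is defined as 0 when a denominator factor vanishes, and an empty class
makes the affected rate NaN with a warning rather than a silent zero. ROC
curves use a descending threshold sweep with tied scores grouped into one
point; AUC is the trapezoidal area, which equals the Mann–Whitney pair
statistic with ties counted ½ — tests verify this against a brute-force
all-pairs oracle and against an independent library implementation.

## Synthetic data

The generator produces two sequence classes whose separation is controlled:

- **Composition signal** (`separation`): the positive class shifts that much
  total probability mass from a uniform base composition onto five designated
  residues (A, E, K, L, S), subtracted evenly from the rest; the
  total-variation distance between class compositions equals `separation`.
- **Adjacency signal** (`order_signal`): residues are drawn from a
  first-order Markov chain; the positive class biases self-transitions
  (residue repeats), the negative class transitions to the next alphabet
  letter, so the dipeptide block carries class information that the
  composition block cannot see.
- **Profiles**: synthetic PSSMs score +7 at each position's own residue and
  −2 elsewhere, plus integer-rounded Gaussian noise — sequence-faithful, so
  the pssm block carries the composition signal plus noise, mirroring why
  combining blocks helps on real data.

Defaults (chosen once as desk-scale study conditions): 100 sequences per
class, lengths uniform on 50–150, separation 0.2, order_signal 0.1, profile
noise 1.0. All draws come from one seeded NumPy generator stream;
regeneration is byte-identical.

What the synthetic data does *not* emulate: real secretome composition
statistics, phylogenetic correlation between sequences, length/class
dependence, or evolutionary conservation structure in profiles. Passing the
validation suite therefore shows the machinery is correct and calibrated
(near-chance accuracy at zero separation, signal recovery at strong
separation), not that any particular accuracy will be attained on real
proteins.

## Numerical and degenerate-input conventions

- Non-standard residues (B, J, O, U, X, Z, `*`, gaps) reject the whole
  record by default (with a logged warning), because every encoder assumes
  the 20-letter alphabet; the policy is configurable to a hard error.
- Dipeptide encoding requires L ≥ 2; composition requires L ≥ 1; profile row
  count and residue column must match the sequence exactly.
- Stratified CV requires at least k examples per class; violations raise
  before any training.
- Headline accuracies reported for this family of classifiers on database-
  derived sets (e.g. split-set accuracy 0.88, MCC 0.77, outer-CV accuracy
  0.93) depend on curated training sets that are not redistributable; they
  are context, not quantities this package reproduces. Reports in the
  literature also disagree on whether the finally selected kernel was linear
  or polynomial; the package simply reports whatever its own selection finds
  on the data given.

## Problem sizes used in validation

The shipped validation suite runs nested CV with a reduced linear-kernel grid
(C ∈ {2⁻⁵, 2, 2⁵}, composition features) on 50-sequence null sets over 10
seeds and one 200-sequence planted-signal set, culls 50-sequence pools, and
checks encoders on 200 random sequences — sizes chosen so the whole suite
completes in seconds while every statistical claim is still exercised at
meaningful n. The full 8 415-point grid is exercised for its structure, not
exhaustively trained in tests.
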
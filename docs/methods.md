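# Methods

## Model

`enzyclass` treats every EC number with enough training data as an
independent binary classification problem and combines three views of a
protein sequence — conserved subsequences, whole-sequence similarity, and
bulk physicochemical composition — into one weighted score per class.
Prediction is top-down over the EC tree; the assumptions are that (i) class
membership is signalled somewhere in the sequence by features at one of the
three granularities, (ii) a protein has at most one EC number (known
multi-functional enzymes are discarded from training), and (iii) deeper
levels are only meaningful once the shallower decision is accepted.

### Subsequence profiles (SPMap)

Windows of length `l` from the positive training proteins are clustered
online: each window joins the existing cluster whose *founding* window gives
the highest ungapped positionwise BLOSUM62 score, if that score reaches
`t = 8`; otherwise it founds a new cluster.  Comparing against the founder
(rather than max-over-members) keeps the pass O(#clusters), deterministic in
input order, and is exposed as the only implemented variant.  Ties on the
best score go to the earliest-created cluster.  Clusters smaller than
`discard_fraction` (default 0.10) × number of positive *proteins* are
dropped — rarely-hit profiles would contribute a near-empty feature
dimension.  Retained clusters become log-probability profiles with a 0.01
pseudo-count; a query feature is the exponentiated best window
log-probability per profile.  The pseudo-count makes a perfectly matching
window score `exp(l·ln((S_c+0.01)/S_c)) > 1`; features are clipped to 1.0 so
the contract "features in (0, 1]" holds.  Windows containing X are skipped;
a protein with no valid window gets a zero vector and a warning.

### Similarity vote (kNN)

The default similarity engine is Smith–Waterman with BLOSUM62 and affine
gaps (open 11, extend 1; a gap of length L costs 11 + L), floored at 0.  It
is a numba-compiled kernel whose scores are identical to
`Bio.Align.PairwiseAligner` in local mode (asserted in the test suite, which
keeps the slower library aligner as the independent oracle).  Scores are
cached symmetrically per sequence pair, and one shared cache serves all
class models in a training run.

Hits below a significance floor are discarded before neighbour selection:
`S_min = ln(K·n·m·N / E) / λ` with the standard gapped-BLOSUM62 parameters
(λ = 0.267, K = 0.041), query/target lengths n, m, training-set size N and
E = 10⁻³ per search.  The `N` factor mirrors a database search's E-value
correction; without it, screening tens of thousands of unrelated pairs
leaves dozens of spurious "significant" noise hits.  The k = 5 nearest
surviving hits vote: `O_B = (S_p − S_n)/(S_p + S_n) ∈ [−1, 1]`.  For
ensemble combination the vote is rescaled to `(O_B + 1)/2`, except that a
query with *no* significant hit contributes 0 (no evidence of membership),
not 0.5 — a deliberate asymmetry: absence of homology to a class's training
set is evidence against membership, and mapping it to half-support made
unrelated sequences un-rejectable at the 0.3 negative cutoff.  k is not
dictated by theory; 5 keeps the vote local and is configurable per run.
A query identical to a training sequence legitimately votes with its own
training copy; cross-validation removes it through fold separation.

### Physicochemical descriptors (Pepstats)

37 composition-based features: 20 amino-acid mole percentages; 9 property
class mole percentages (tiny, small, aliphatic, aromatic, non-polar, polar,
charged, basic, acidic — classic EMBOSS groupings restricted to canonical
residues); molecular weight; residue count; average residue weight; net
charge at pH 7; isoelectric point; molar extinction coefficients (reduced
and with cystine bridges, Pace values W 5500 / Y 1490 / cystine 125); and
extinction of a 1 mg/ml solution.  Charge follows Henderson–Hasselbalch
over the ionizable groups with EMBOSS-style pKs (N-term 8.6, C-term 3.6,
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); the charge–pH curve is
strictly decreasing, so pI is found by bisection to |charge| < 10⁻⁴.  The
exact 37-feature composition of the original descriptor tool is not
published; any composition-based set of this size serves the same role, and
the test suite cross-checks the pI against an independent implementation
(agreement within ~1 pH unit — the pK sets differ).  Features are min-max
scaled on training data only; out-of-range values clip to [0, 1] and
constant dimensions map to 0 (z-scoring was considered and rejected: the
clipped unit interval matches what the margin classifier saw in training).

### Ensemble, cutoffs, traversal

SVMs are RBF-kernel (C = 1, gamma = "scale"), with Platt sigmoid
calibration fit on internal stratified folds and the margin classifier
refit on all data, giving scores in [0, 1].  Each base predictor's 5-fold
cross-validated AUROC (rank/Mann–Whitney formulation, ties 0.5) is raised
to the fourth power and normalized into the ensemble weights; the fourth
power strongly favours the best predictor per class while never zeroing the
others.  Featurizers (profiles, scalers) are re-fit inside every
cross-validation fold so no information leaks from held-out folds.

The per-class acceptance cutoff sweeps the grid {0.00, 0.01, …, 1.00} over
held-out validation weighted scores and keeps the F1-maximizing value
(strictly-greater comparison; ties break toward the largest cutoff, the
most conservative of the equally good choices).  The result is clamped
above the global negative cutoff 0.3.  Traversal: at the main level, accept
the best class whose score exceeds its cutoff and descend; if every main
class scores below 0.3, emit `non-enzyme`; otherwise `no prediction`.
Below the main level only positive cutoffs apply (the non-enzyme rule is a
main-level decision); when no child clears its cutoff the query keeps the
parent's EC as its final label, and a class without trained children
finalizes there.  Score ties accept the lexicographically smallest EC for
determinism.

### Datasets

Annotations propagate to all ancestors; classes need ≥ 50 members
(`min_class_size`).  The negative pool for a class is coloured exactly as
the hierarchy dictates: sibling classes and their descendants, all other
main classes, and non-enzymes with annotation score ≥ 4 (lower-star
proteins are too likely to be unannotated enzymes); the class's own
descendants are excluded everywhere.  Negative sets are sampled without
replacement to the positive count (largest-remainder apportionment of the
mix, ±1): main classes use ½ other-main enzymes + ½ non-enzymes; deeper
levels use ½ sibling-branch + ¼ other-main + ¼ non-enzymes, on the view
that sibling discrimination is the hardest sub-problem and deserves the
largest share.  Both mixes are configurable, and the `wne` flag renormalizes
the enzyme fractions to drop non-enzymes entirely (the ablation
configuration).

Redundancy reduction is greedy longest-first clustering: a sequence joins
the first representative sharing ≥ 50% identity, else founds a cluster.
Identity is matches / alignment-length of a unit-cost global (NW) alignment
computed with edlib, with a 3-mer prefilter that skips alignments that
cannot plausibly reach the threshold (applied only to sequences > 80
residues; short test sequences always take the exact path).  Train/validation
splits assign whole clusters (ceil(10%) of clusters to validation), by
default keeping representatives only — so no cross-split pair can exceed
the identity threshold by construction.

## Synthetic benchmark

The generator emulates what the predictors exploit in real proteomes:
enzyme families as random background sequence (uniform composition by
default; a Swiss-Prot-like preset exists) carrying 3 conserved motifs of 20
residues per family in the default hierarchy, each motif residue
independently mutated at the family's mutation rate; child families inherit
parent motifs and add their own, so levels are separable; non-enzymes are
motif-free background with 5-star scores.  Motif lengths are chosen so a
single conserved block aligns well above the significance floor — families
whose only shared signal is indistinguishable from alignment noise are not
a realistic model of enzyme homology.  Sequence lengths are uniform in
[120, 400]: long enough for stable composition statistics and many profile
windows.

What passing the synthetic recovery test does *not* show: robustness to
indels and domain shuffling (motifs are implanted ungapped), to biased
composition differences between enzymes and non-enzymes (backgrounds are
identical by design, so Level-0 separation must come from motifs, which is
the harder setting), or to the label noise and extreme class imbalance of
curated databases.  The default benchmark (6 main classes × 80 members,
480 non-enzymes, mutation rate 0.05, three seeds) was sized to exercise the
full pipeline — redundancy split, fold-wise refitting, cutoff sweeps,
traversal — in a few minutes on one core.

## Numerical and degenerate-input choices

* Non-canonical residues (B, Z, X, U, O, J) map to X by default ("strict"
  policy raises); X windows are skipped by SPMap and X adds only sequence
  length in the descriptors.
* Sequences shorter than `l` are legal queries: zero SPMap vector, warning.
* Cutoff sweep with one-class validation raises; inverted or extreme sweep
  results warn rather than fail.
* `precision = 1` when TP+FP = 0 and FN = 0 (nothing to get wrong), 0 when
  misses exist; `no prediction` counts against recall, never precision.
* All randomness flows through explicit seeds (global default 42);
  per-class sampling seeds are derived deterministically from the run seed.

## Known limitations

* The EC tree is taken from the training annotations; classes absent or
  under-populated there cannot be predicted (queries finalize at the
  deepest trained ancestor).
* Multi-functional enzymes are out of scope by design — one label per query.
* The internal aligner reports raw scores, not E-values; the significance
  floor is an analytic approximation, adequate for ranking but not a
  substitute for full search statistics.
* Per-class models make training cost linear in the number of classes;
  the package targets desk-scale corpora, not full database sweeps.
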
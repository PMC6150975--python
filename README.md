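# enzyclass

Hierarchical Enzyme Commission (EC) number prediction from amino-acid
sequence.

Uncharacterized proteins are routinely annotated by predicting whether they
are enzymes and, if so, which reaction class they catalyse.  EC numbers
organize enzyme function as a four-level tree (main class . subclass .
sub-subclass . substrate, e.g. `1.1.2.4`), which makes top-down
classification natural: decide enzyme vs. non-enzyme together with the main
class, then descend one level at a time.  `enzyclass` implements this as an
ensemble of per-class binary classifiers, aimed at protein scientists who
need sequence-only function predictions and at method developers who want a
fully self-contained, testable pipeline (synthetic benchmark included — no
database downloads).

## Method

Every trainable EC class `e` (at least 50 annotated proteins after
propagating annotations up the tree) gets an independent binary model with
three base scorers:

* **SPMap** — all length-`l` subsequence windows of the positive training
  proteins are clustered by ungapped BLOSUM62 similarity (threshold `t = 8`);
  each cluster of `S_c` windows becomes a probabilistic profile
  `PP_c(i, j) = ln((count(i, j) + 0.01) / S_c)`, clusters smaller than 10%
  of the positive set are discarded; a query's feature `c` is
  `exp(max_ss Σ_i PP_c(i, ss_i))` over its windows, fed to an RBF SVM.
* **similarity-vote kNN** — the query is aligned (Smith–Waterman, BLOSUM62,
  affine gaps 11/1) against the class's training proteins; with `S_p` and
  `S_n` the summed scores of positives and negatives among the `k = 5`
  nearest significant hits, the vote is `O_B = (S_p − S_n) / (S_p + S_n)`.
* **Pepstats-SVM** — a 37-dimensional physicochemical descriptor
  (amino-acid and property-class mole percentages, molecular weight, net
  charge, isoelectric point, extinction coefficients), min-max scaled, fed
  to an RBF SVM.

Each scorer's 5-fold cross-validated AUROC `R_m` sets its ensemble weight

```
W(m) = R_m^4 / Σ_m' R_m'^4
```

and the class score is the weighted mean of the three scores.  Negative
training sets are balanced to the positive count and drawn from sibling
branches, other main classes and reliably annotated (≥ 4-star) non-enzymes;
redundancy is removed by ≥ 50% identity clustering with whole clusters
assigned to one side of the 90/10 train/validation split.  Per class, the
acceptance cutoff maximizes F1 on validation scores; queries below the
global negative cutoff 0.3 for all six main classes are labelled
`non-enzyme`, scores in between give `no prediction`.

## Worked example

Generate a toy proteome (motif-defined enzyme families plus non-enzymes),
train, predict and evaluate — one process, no network:

```bash
enzyclass synth   --out-fasta toy.fa --out-annotations toy.tsv \
                  --n-main 2 --members 24 --nonenzymes 60 --seed 5
enzyclass --quiet train --fasta toy.fa --annotations toy.tsv \
                  --model-dir model --min-class-size 15 --seed 5
enzyclass predict --model-dir model --fasta toy.fa --out pred.tsv
enzyclass eval    --predictions pred.tsv --truth toy.tsv
```

which prints (output of this exact run):

```
108 queries: 48 enzyme predictions -> pred.tsv
protein_id      main_class subclass sub_subclass substrate_class label    confidence
ec1_x_x_x_0000  1          -        -            -               1.-.-.-  0.9831
...
 level  TP  FP  FN  TN  precision  recall  f1  macro_precision  macro_recall  macro_f1  no_prediction
     0  48   0   0  60        1.0     1.0 1.0              1.0           1.0       1.0              0
     1  48   0   0  60        1.0     1.0 1.0              1.0           1.0       1.0              0
```

Level 0 is the enzyme/non-enzyme gate, level 1 the EC main class: all 48
enzymes recover their family's class and all 60 non-enzymes are rejected;
`confidence` is the weighted ensemble score of the deepest accepted class.
Deeper levels show TN-only counts because this toy tree has no trained
subclasses.

The same pipeline is available as a library:

```python
from enzyclass import run_synthetic_benchmark
result = run_synthetic_benchmark(seed=1)       # 6 classes x 80 + 480 non-enzymes
print(result.reports[1].f1)                    # held-out main-class F1
```

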
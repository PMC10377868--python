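# Methods

## Problem and data model

`hbpred` frames heparin-binding-protein recognition as balanced binary
classification of protein sequences. Inputs are FASTA records over the
20-letter amino-acid alphabet; records containing any other symbol
(including the ambiguity codes B, J, O, U, X, Z) are rejected outright,
because every descriptor below is undefined for non-canonical residues.
The minimum accepted length is 2 residues so the dipeptide-based
encodings, which normalise by `L − 1`, are well defined. Benchmark
assembly steps that depend on external services — UniProt retrieval,
protein-existence filtering, CD-HIT redundancy removal — are out of
scope; the package takes curated FASTA sets as given and provides the
in-scope pieces: the residue-validity filter, uniform negative
subsampling, and the class-balanced random test split (default 50 + 50
held out), all driven by an explicit user seed.

## Descriptors

**AAC / DC.** Residue frequencies `N_R / L` and overlapping dipeptide
frequencies `N_ab / (L − 1)`; each vector sums to 1 exactly.

**DDE.** For each of the 400 dipeptides the observed frequency is
Z-transformed against the frequency expected from synonymous-codon
degeneracy under the standard genetic code (61 sense codons):
`TF(ab) = (C_a/61)(C_b/61)` is the theoretical mean and
`TV(ab) = TF(1−TF)/(L−1)` the theoretical variance of a binomial
proportion over `L − 1` draws. We divide the deviation by `√TV` — the
standard deviation — because a Z-score requires one; the alternative
reading, dividing by the variance itself, merely rescales each feature
by a sequence-length-dependent constant per dipeptide and would not be a
Z-transform. The codon table (A:4, C:2, D:2, E:2, F:2, G:4, H:2, I:3,
K:2, L:6, M:1, N:2, P:4, Q:2, R:6, S:6, T:4, V:4, W:1, Y:2) sums to 61.

**CTD.** The widely used catalogue of 13 physicochemical properties,
each splitting the alphabet into 3 disjoint groups, ships as a versioned
TSV (`hydrophobicity_PRAM900101` … `solventaccess`); feature names take
the `property.G<i>` form. Composition is the per-group residue
fraction. Transition counts adjacent residue pairs whose members fall
one in each group of an unordered pair — the three pairs (G1,G2),
(G1,G3), (G2,G3) per property give exactly 39 transition features —
normalised by `L − 1`. Distribution reports, for each group and each
percentile p ∈ {1, 25, 50, 75, 100}, the 1-based position (as a
percentage of L) at which the running count of group members reaches
`max(1, ⌊p·n/100⌋)` of the group's n occurrences, computed in exact
integer arithmetic; p = 1 therefore indexes the first occurrence. A
group absent from the sequence reports 0 for all five percentiles — a
sentinel chosen to keep the vector totally ordered; no other convention
is defensible when no position exists. Canonical feature orders are
fixed (AAC alphabetical; DC/DDE row-major alphabetical pairs; CTD by
catalogue order, then group, then percentile) so column identity is
stable across runs.

## Feature ranking

Per-feature one-way ANOVA between the two classes (df1 = 1,
df2 = n − 2), computed via `sklearn.feature_selection.f_classif`, with
two degenerate cases handled explicitly: a feature constant across all
samples is 0/0 and scores F = 0, p = 1 (no discriminative information,
ranked last); a feature constant within classes but differing between
them scores F = +∞, p = 0 and ranks first. Ties are broken by canonical
feature order. p-values are raw — ranking is interpretive, not a
selection step: all features are passed to the classifiers.

## Classifiers and model selection

Two small-sample algorithms: an SVM (`sklearn.svm.SVC`) searched over
kernel ∈ {linear, RBF, sigmoid, poly}, C = 2^x for x ∈ [−1, 15],
γ = 2^x for x ∈ [−14, 2] (absent for linear), degree ∈ 1..5 (poly
only); and a random forest searched over criterion ∈ {gini, entropy},
max_depth spanning [5, 150], min_samples_split spanning [2, 30], with
min_samples_leaf = 5, max_leaf_nodes = 100, ccp_alpha = 0.001,
n_estimators ∈ {10, 100, 1000}. The published depth/split ranges carry
no step size, so the default grids discretise them coarsely
(max_depth ∈ {5, 10, 25, 50, 100, 150}, min_samples_split ∈
{2, 5, 10, 20, 30}); any grid is injectable as config. Documented
*reduced* grids (RBF-only SVM over a 5 × 4 C × γ lattice; a 4-point RF
sweep) serve quick runs and the synthetic-pipeline checks.

Cross-validation is stratified 10-fold *without shuffle*: samples of
each class are assigned to contiguous folds in dataset (manifest)
order, so the assignment is deterministic and reproducible by
construction. Every grid point is scored by its mean CV auROC; ties
break by mean OA, then mean MCC, then grid enumeration order. A grid
point whose selection metric is undefined on every fold sorts below any
defined value. The winner is refitted on all training data.

Scoring during the sweep uses raw SVM decision values for auROC — auROC
is invariant under any strictly monotone transform, so this is
identical to scoring calibrated probabilities at a fraction of the
cost — and `predict` labels for Sn/Sp/OA/MCC. The final refitted SVM is
Platt-calibrated (sigmoid calibration over an internal deterministic
5-fold split, `ensemble=False`) so deployed scores lie in [0, 1]; the
classification threshold is fixed at 0.5 throughout. RF scores are
class-1 vote fractions.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), OA = (TP+TN)/N, and MCC by its
standard four-count formula. A zero denominator yields NaN plus a
logged warning, never a silent 0 — degenerate folds should be visible.
ROC curves come from a threshold sweep with tied scores grouped; auROC
is the trapezoidal integral and equals the Mann–Whitney concordance
probability (ties ½), which the test suite verifies against an explicit
pair-counting oracle. Fold summaries report mean ± standard deviation;
the sample (n−1) form is the default with the population form a
parameter, since either convention is defensible for 10 folds. Report
tables render percent metrics to 1 decimal and MCC to 3.

## Synthetic corpus generator

The generator emulates the *shape* of the curated benchmark: two
balanced classes (default 183 + 183), lengths uniform on 50–500
(typical protein lengths), residues i.i.d. per position from a
background composition (average database residue frequencies), and a
class-differential composition signal — by default +0.15 on serine in
positives, re-normalised — matching the kind of signal the ranking
stage is expected to surface (serine-rich features at the top). An
optional first-order Markov mode biases chosen residue→residue
transitions in positives only, planting signal in adjacency rather
than composition; this is the regime where dipeptide descriptors carry
information that composition alone does not.

What the generator does *not* emulate: domain structure, homology
between sequences, realistic length distributions per class, or any
biophysical constraint. Passing pipeline tests on this corpus therefore
demonstrates that the machinery recovers a planted composition signal
at a realistic corpus size — not that real HBPs are separable at any
particular accuracy. Results on the curated benchmark are
dataset-dependent and are not asserted anywhere in this package.

## Problem sizes and numerical choices

The synthetic-pipeline checks run the reduced SVM grid on the default
366-sequence corpus (10-fold CV; one signal run, 20 ranking seeds, 10
null seeds) — sizes chosen so the whole battery completes in about a
minute while keeping per-fold class counts above 13. All descriptor
arithmetic is double precision with no tolerance applied at encode
time. Grid-search reproducibility is exact for fixed seeds: fold
assignment and enumeration order are deterministic, and the only
stochastic components (RF bootstrap, Platt's internal split) are
seeded.

## Known limitations

- Negative-set construction (DNA-binding proteins) builds a contrast of
  convenience; a deployed recogniser would need harder negatives.
- The descriptor set is intentionally classical; profile- or
  embedding-based features are out of scope.
- Binding affinity is not predicted — only class membership.
- Feature fusion and post-ranking feature selection are deliberately
  not implemented.
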
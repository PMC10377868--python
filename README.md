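# hbpred

Machine-learning recognition of heparin-binding proteins (HBPs) from
sequence alone. HBP (azurocidin / CAP-37) is a cationic antimicrobial
protein released by neutrophils and an early biomarker of severe bacterial
infection, so telling HBPs apart from other proteins computationally is a
useful screening step. `hbpred` implements the full recognition pipeline:
fixed-dimension sequence descriptors, ANOVA feature ranking, grid-searched
SVM / random-forest classifiers under stratified 10-fold cross-validation,
and a confusion-matrix + ROC evaluation battery — together with a synthetic
corpus generator so the whole pipeline is testable without any download.

## The descriptors

For a protein `P = R1 R2 … RL` over the 20-letter alphabet:

- **AAC** (20-dim): residue frequencies `F(R) = N_R / L`.
- **DC** (400-dim): overlapping dipeptide frequencies
  `F(ab) = N_ab / (L − 1)`.
- **DDE** (400-dim): *dipeptide deviation from expected mean*, a Z-score of
  the observed dipeptide frequency against the mean implied by
  synonymous-codon degeneracy (61 sense codons):
  `TF(ab) = (C_a/61)(C_b/61)`, `TV(ab) = TF(1 − TF)/(L − 1)`,
  `DDE(ab) = (F(ab) − TF(ab)) / √TV(ab)`.
- **CTD** (39 + 39 + 195 = 273-dim): composition, transition and
  distribution over 3-group partitions of the alphabet under 13
  physicochemical properties (seven hydrophobicity scales, van der Waals
  volume, polarity, polarizability, charge, secondary structure, solvent
  accessibility). The catalogue ships as
  `src/hbpred/data/ctd_groups.tsv` and is user-overridable.

Classifiers are scored per fold by sensitivity, specificity, overall
accuracy, Matthews correlation coefficient and auROC; grid points are
selected by mean CV auROC, ties broken by OA then MCC.

On the curated benchmark this protocol targets (183 UniProt HBPs vs. 183
human DNA-binding proteins, de-duplicated at 80% identity with CD-HIT —
not redistributable here), an RBF SVM on DDE features is the strongest
combination.

## Worked example

```python
import hbpred as hp
from hbpred.descriptors import encode_dataset, split_matrix

# synthetic study-shaped corpus: 183+183 sequences, +0.15 Ser shift in positives
ds = hp.generate(hp.GeneratorConfig(seed=1))
X, y, names = split_matrix(encode_dataset(ds, "dde"))

for f in hp.anova_rank(X, y, top_k=3, feature_names=names):
    print(f.rank, f.name, round(f.f_score, 1), f"{f.p_value:.3g}")

clf = hp.ProteinClassifier(algorithm="svm", param_grid="reduced",
                           n_folds=10, random_state=1).fit(X, y)
print(clf.best_params_)
print("CV auROC", clf.cv_result_.summary.formatted("auroc"))
```

prints

```
1 SS 641.3 2.62e-82
2 LS 278.4 7.9e-47
3 SA 173.7 1.06e-32
{'kernel': 'rbf', 'C': 2.0, 'gamma': 0.0078125}
CV auROC 1.000 ± 0.001
```

The serine-rich dipeptides dominate the ranking because the generator
plants a +0.15 serine composition shift in the positive class; the
grid-searched SVM separates the classes essentially perfectly at that
effect size (mean ± sd over the 10 folds).

The same stages are available from the shell:

```bash
hbpred simulate --out-dir corpus --seed 1
hbpred encode --fasta corpus/positives.fasta --negatives corpus/negatives.fasta \
              --descriptor dde --out dde.tsv
hbpred rank --matrix dde.tsv --top-k 5 --out ranked.tsv
hbpred train --matrix dde.tsv --algorithm svm --grid reduced --seed 1 \
             --model-out model.joblib --cv-out cv.json
hbpred predict --model model.joblib --matrix dde.tsv --out scores.tsv
hbpred evaluate --scores scores.tsv --truth dde.tsv --out-prefix eval
hbpred run --config pipeline.yaml   # all stages + run manifest
```

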
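# kinomeprio

Prioritization of cancer-associated point mutations in the human protein
kinome by an ensemble of classifiers over biochemical, structural and
evolutionary features.

## The problem

Tumour genomes carry many somatic mutations, but only a small subset drive
cancer progression. In protein kinases — proto-oncogenes mutated in many
cancers — recurrently observed mutations (EGFR L858R, BRAF V600E) are easy to
call, while rare mutations observed in a single sample are indistinguishable
from passengers by frequency alone. `kinomeprio` scores kinase-domain point
mutations by learned features so that rare candidates can be ranked for
experimental follow-up.

A mutation is identified by (gene, position, wild-type, mutant). For each
mutation the package computes 29 features:

* **comparative** — the kinase's group and family (KinBase-style hierarchy)
  and the conservation of the site at three evolutionary depths. The
  conservation of residue *r* at an alignment column is its frequency in the
  column; it is evaluated for both the wild-type and the consensus (modal)
  residue, in the family, group and all-kinase alignments — six fractions;
* **biochemical** — wild-type and mutant residue identity, BLOSUM62 pair
  score, and per-residue hydropathy, charge, polarity, van der Waals volume,
  free-amino-acid mass and natural frequency (plus hydropathy/volume deltas);
* **structural/functional** — the kinase subdomain (I–XI) containing the
  site, binding-site and post-translational-modification annotations, and an
  in-kinase-domain flag.

Feature selection runs five algorithms (OneR, ReliefF, chi-square, gain
ratio, CFS) on the training folds of a stratified 10-fold split; attributes
selected by at least 3 of 5 selectors are retained (17 by default).

Eleven classifiers (decision tree, random forest, NB-tree, functional tree,
decision table, DTNB, locally weighted learner, Bayes net, naive Bayes, SVM,
neural network) are evaluated by stratified 10-fold cross-validation and
combined two ways: a majority vote (disease at ≥ 6 of 11 votes) and an
accuracy-weighted vote, the **S-Score**

```
S(x_i) = Σ_j acc_j · P_j(D | x_i) / Σ_j acc_j        ∈ [0, 1]
```

where `acc_j` is classifier *j*'s cross-validated accuracy and `P_j(D|x_i)`
its disease probability for mutation *i*; scores above 0.5 are positive
predictions and unknown mutations are ranked by descending S-Score.
A label audit clusters instances label-blind (Euclidean k-means in the
selected-feature space) and computes a **U-Score** — the disease fraction of
an instance's cluster, leave-one-out. Instances whose S/U consensus matches
their given label are `Expected`, the rest `Suspicious`.

Because the original training catalogues require downloads, the package
ships a synthetic-kinome generator that reproduces the *statistical
structure* of the task (alignment hierarchy, annotations, 226 disease / 331
benign labeled mutations with a planted effect model), so the whole pipeline
runs end-to-end offline.

## Worked example

```python
from kinomeprio import (SimConfig, MutationPrioritizationModel,
                        build_feature_matrix, generate_kinome,
                        generate_labeled_mutations, generate_unlabeled_mutations)

cfg = SimConfig(seed=1)                       # 226 disease / 331 benign
kinome = generate_kinome(cfg)
mutations = generate_labeled_mutations(cfg, kinome)
matrix = build_feature_matrix(mutations, kinome.resources())

results = MutationPrioritizationModel(matrix, selection="default").fit(seed=1)
print(results.summary())
```

prints the cross-validated confusion matrix and metrics per classifier:

```
Kinome mutation prioritization — ensemble cross-validation
instances: 557 (D=226, ND=331), attributes: 17, folds: 10, seed: 1

algorithm            TP   FN   TN   FP  TPrate  FPrate    Acc   Prec  Recall      F
J48 (Tree)          210   16  305   26   0.929   0.079  0.925  0.890   0.929  0.909
Random Forest       204   22  323    8   0.903   0.024  0.946  0.962   0.903  0.932
...
SVM                 208   18  313   18   0.920   0.054  0.935  0.920   0.920  0.920
Neural Network      203   23  306   25   0.898   0.076  0.914  0.890   0.898  0.894
Combined (0.5)      207   19  320   11   0.916   0.033  0.946  0.950   0.916  0.932
```

Each row is one classifier's 10-fold out-of-fold confusion matrix (TP = true
disease calls) and the derived positive-class metrics; `Combined (0.5)` is
the accuracy-weighted ensemble thresholded at 0.5, which matches or beats the
best single classifier. Ranking unknown singleton mutations and auditing the
training labels:

```python
unknown = generate_unlabeled_mutations(cfg, kinome, 50, exclude=mutations)
table = results.prioritize(build_feature_matrix(unknown, kinome.resources(),
                                                with_class=False))
print(table.head(3))     # rank, S-Score, votes, gene, position, wt, mut
audit = results.audit()  # s_score, u_score, consensus, Expected/Suspicious
```

The same pipeline is scriptable from a shell (`kinomeprio simulate`,
`features`, `select`, `train`, `prioritize`, `audit`; all take `--seed`).

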
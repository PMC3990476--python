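# Methods

This note documents the models and procedures implemented in `kinomeprio`,
the parameters that matter, the synthetic study system, and the numerical
and design choices made where the design was genuinely open.

## Mutation records and the recurrence filter

A mutation is the tuple (gene, 1-based protein position, wild-type residue,
mutant residue) with an observation count (number of independent tumour
samples). Wild-type and mutant must differ and be among the 20 canonical
residues; non-canonical codes (B, Z, X, U, O) are rejected rather than
coerced. Duplicate keys in one table are an error, never silently merged or
summed — observation counts must be pre-aggregated upstream, which avoids
double counting when several catalogue versions are combined.

`partition_by_recurrence(ms, min_count)` splits a mutation set into the
recurrently observed subset (count ≥ min_count, default use: 2) and the
singletons. Somatic mutations recur across unrelated tumour samples far more
often when they are under positive selection, so the recurrent subset serves
as the disease-labeled training set while singletons are held out and later
ranked by the fitted ensemble.

## Residue properties and substitution scores

Six per-residue properties feed the feature vector:

| property | units | source of defaults |
|---|---|---|
| hydropathy | unitless | Kyte–Doolittle index |
| charge | −1/0/+1 | formal side-chain charge at pH 7.4 |
| polarity | 0/1 | standard polar set {R,N,D,Q,E,H,K,S,T,Y} |
| van der Waals volume | Å³ | standard side-chain volume scale (G 48 … W 163) |
| average mass | Da | average residue mass + H₂O (free amino acid) |
| natural frequency | fraction | Swiss-Prot residue composition |

Masses are free-amino-acid average masses (K = 146.18934 Da), not dehydrated
residue masses; this is the convention the feature values follow. Histidine
is encoded as charge 0: it is mostly neutral at physiological pH, and the
feature is deliberately ternary rather than fractional. Frequencies are
renormalized to sum exactly to 1 on load so that tables printed at fixed
precision remain valid. All defaults ship as an EMBOSS-data-style text table
and can be replaced by a user file in the same format.

BLOSUM62 is parsed from an NCBI-format matrix file shipped with the package;
symmetry over all 190 unordered pairs is validated at load, and the test
suite cross-checks every entry against an independently distributed copy of
the matrix.

## Conservation at three evolutionary depths

Conservation of residue *r* at an alignment column is count(*r*)/n_rows —
gaps count in the denominator, so a fully occupied, fully conserved column
scores exactly 1.0. The consensus residue of a column is the modal non-gap
residue with ties broken lexicographically (a determinism choice; ties are
rare in real alignments). An all-gap column has no consensus and scores 0.

For each mutation, six features are computed: the frequency of the wild-type
residue and of the column consensus, in the family alignment (close
relatives), the group alignment (greater distance) and the all-kinase
alignment (ancient divergence). Protein positions map to columns by counting
non-gap characters of the named reference row; by construction
consensus-conservation ≥ wild-type-conservation within one column of one
alignment. If the table's wild-type disagrees with the reference row at the
mapped column, a warning is emitted and the features are computed anyway —
isoform and sequence-version drift is common and a hard failure would block
batch runs. A gene absent from an alignment yields missing values (NaN),
never zeros, so imputation rather than a spurious "unconserved" signal
handles the gap downstream.

## The 29-attribute feature vector

Identity features (4): kinase group, family (nominal, KinBase-style), and
the wild-type and mutant residue types. Exchange features (3 + 12): the
BLOSUM62 pair score, the six properties above for the wild-type and for the
mutant residue, and signed deltas for hydropathy and van der Waals volume
(the two quantitative properties whose change is most directly interpretable
as a perturbation size). Conservation (6): as above. Structural/functional
(4): subdomain (I–XI with the canonical VIa/VIb split, or `none`), binding
site (`yes`/`NA`), modification kind (e.g. `Phosphorylation`, else `NA`) and
the binary in-kinase-domain flag. Total: 29.

The default selected subset is 17 attributes (the selector-vote outcome):
family, group, aa_wt, blosum62, polarity_mut, cons_wt_all,
cons_consensus_group, cons_consensus_all, cons_consensus_family, subdomain,
mass_mut, binding_site, vdw_wt, modification, aa_mut, polarity_wt,
in_pk_domain. The mass feature is the mutant-side value (the wild-type-side
column remains available in the full roster).

Two encodings serve the learners. Numeric-only algorithms (SVM, neural
network, nearest-neighbour, Gaussian NB, trees) consume one-hot nominals
plus min–max-scaled numerics with median imputation; the one-hot layout is
fixed by the schema, while scaling and imputation statistics are estimated
on training folds only and applied unchanged to test folds (no test
leakage). Rule/Bayes-table learners consume integer level codes, numerics
binned at training-fold quantiles (5 bins; missing values get their own
code).

## Feature selection by five-selector voting

OneR, ReliefF, chi-square, gain ratio and CFS are each run on the ten
training folds (90% each) of a stratified, seeded 10-fold split. The four
single-attribute evaluators report fold-averaged merit and ordinal rank;
CFS (greedy forward search over the symmetrical-uncertainty correlation
merit) reports per-fold best-subset membership. An attribute is retained at
≥ 3 of 5 votes; its overall average rank is the arithmetic mean of its five
per-selector ranks.

What constitutes a ranker's "vote" is not externally defined; here a ranker
votes when the fold-averaged merit is positive **and** the average rank is
within the top 17 of the 29-attribute schema (both configurable). OneR merit
is baseline-corrected (training accuracy of the one-attribute rule minus the
majority-class share) so that an uninformative attribute has merit ≈ 0 and
the positive-merit clause is meaningful. ReliefF uses k = 10 neighbours and
all instances, with 0/1 diffs for nominals and range-scaled absolute diffs
for numerics; chi-square is the Pearson statistic on the attribute × class
contingency table without continuity correction; gain ratio is information
gain over split information, 0 when either vanishes.

This selection runs outside the classifier-evaluation loop (one fixed
feature set for supervised and unsupervised stages). That is an OUT-type
design: the full data set is seen by the selectors before classifier
cross-validation, which can leak information into the absolute performance
estimates; relative classifier comparisons are unaffected, and the pipeline
records the selection provenance with the run.

## The 11-classifier roster

Scikit-learn provides the tree (entropy criterion), random forest (100
trees), Gaussian naive Bayes, RBF-kernel SVM (sigmoid/Platt calibration
fitted within the training data, since the ensemble needs P(disease|x)) and
the MLP (one hidden layer of 16 units). Six classic rule/hybrid learners
have no scikit-learn equivalent and are implemented here:

* **NB-tree** — shallow decision tree (depth 3) with a Gaussian NB model in
  each large mixed leaf, smoothed leaf frequencies elsewhere;
* **functional tree** — same partition with logistic models at the leaves;
* **decision table** — greedy forward attribute selection maximizing the
  table's leave-one-out accuracy (LOO penalizes memorizing singleton cells),
  majority cell predictions, class-prior fallback for unseen keys;
* **DTNB** — decision table on the greedily chosen attribute block combined
  with categorical naive Bayes on the complementary block, assuming
  independence between blocks (log-odds sum);
* **locally weighted learner** — inverse-distance-weighted k-nearest
  neighbours (k = 50) in the numeric encoding;
* **Bayes net** — tree-augmented naive Bayes: feature–feature edges are a
  maximum spanning tree of class-conditional mutual information, CPTs with
  Laplace smoothing.

These are faithful members of the same algorithm families, not bitwise
reimplementations of any particular toolkit; the roster's purpose is 11
diverse, reasonably strong members.

Evaluation is stratified 10-fold cross-validation: the confusion matrix is
summed over the ten test folds (every instance tested exactly once), metrics
follow the positive-class convention (recall = TP/(TP+FN), precision =
TP/(TP+FP), F = harmonic mean, FP rate = FP/(TN+FP)); class-averaged
variants are available but positive-class is primary because it is the
convention under which the published benchmark table is internally
consistent. Precision and F are reported as undefined (None) when TP+FP = 0
rather than coerced to 0.

A cost-sensitive wrapper turns any roster member into a threshold learner:
with misclassification costs c(FP), c(FN) the expected-cost-minimizing rule
predicts disease when P(D) ≥ c(FP)/(c(FP)+c(FN)); the default all-ones cost
matrix gives the neutral threshold 0.5. One master seed derives the fold
split and every stochastic learner's seed through a hash, so runs are
reproducible end to end; derived seeds stay below 2³¹.

## Ensemble combination and ranking

The majority vote counts each classifier's cost-adjusted binary call and
declares disease at ≥ 6 of 11 votes. The weighted vote (S-Score) is
Σ acc_j·P_j / Σ acc_j with acc_j the classifier's own 10-fold CV accuracy,
frozen before any unknown mutation is scored; the score is a convex
combination of the member probabilities and invariant under uniform
rescaling of the weights. The combined classifier's cross-validated
confusion matrix is computed from *out-of-fold* S-Scores — each instance's
ensemble score uses only probabilities predicted when that instance was in a
test fold — so the combined row is comparable to the single-classifier rows.
Priority tables sort by descending S-Score with a deterministic
(gene, position, mutant) tie-break.

The chi-squared helper compares two classifiers' correct/incorrect counts by
the Pearson statistic on the 2×2 table without continuity correction (df = 1);
optionally a Monte-Carlo p-value resamples tables with fixed margins
(hypergeometric draws) and applies the (1+hits)/(1+n) estimator. At small
counts the exact conditional null is discrete and can differ from the χ²₁
approximation by more than Monte-Carlo noise; the two agree on large-count
tables.

## Label audit (S/U consensus)

Catalogue labels are noisy. The audit clusters instances label-blind with
Euclidean k-means (10 restarts, seeded; instances are put in a canonical
sort order before fitting so the result is invariant to row permutations) in
the encoded selected-feature space. The U-Score of an instance is the
disease-labeled fraction among the *other* members of its cluster
(leave-one-out, so an instance cannot confirm its own label; singleton
clusters score a neutral 0.5). Consensus: S and U both > 0.5 → disease,
both < 0.5 → benign, anything else — including scores exactly at 0.5 —
uncertain. An instance is `Expected` when a decisive consensus matches its
label, else `Suspicious`. Suspicious instances are reported, never removed
or relabeled.

The cluster count defaults to the number of kinase-family levels in the
schema (minimum 2). In one-hot space the dominant axis of variation is the
family block, so a 2-cluster solution merely bisects the family structure
and mixes both classes into each half; one cluster per family-scale
subpopulation lets the cluster label fractions reflect the local label
structure. Any fixed k can still be passed explicitly.

## The synthetic kinome

The generator emulates the statistical structure the pipeline assumes — it
is the study system for all end-to-end tests, not a model of real kinase
biology. Defaults: 4 groups × 2 families × 6 genes (48 genes), domain length
250 with the kinase domain at positions 6–245, subdomains tiling ~60% of the
domain, three binding sites and two phosphosites on the shared coordinate
system; family/group/all-kinase alignments of 50/60/80 rows; 226
disease-labeled and 331 benign mutations.

Sequences are drawn per column: 40% of columns are designated conserved;
conservation levels (conserved/background) are 0.95/0.50 within a family,
0.80/0.35 within a group and 0.60/0.15 across all kinases, a hierarchy in
which close relatives are most alike. Consensus sequences mutate along the
hierarchy (30% of columns change from all-kinase to group consensus and
again from group to family), and every gene's reference sequence appears as
a row of its family, group and all-kinase alignments.

The effect model plants the class signal. Disease mutations are drawn with
odds multiplied by `enrichment_odds` (default 8) per matched property —
conserved column, annotated functional site, subdomain interior, membership
in an "oncogene" family subset (25% of families) — and their mutant residue
is drawn with weight `substitution_odds^(−BLOSUM62)` (default 3), favouring
radical substitutions; benign mutations are uniform over the remaining sites
with conservative substitution bias. Disease mutations carry observation
counts ≥ 2 (recurrence), benign ones count 1. The substitution channel is
essential: with position-level enrichment alone the disease and benign
categories overlap so much that no classifier can exceed ~0.93 accuracy,
whereas the paired position+substitution signal supports near-perfect
separation at strong odds.

What the generator does *not* emulate: real amino-acid composition,
phylogenetic correlation between rows (rows are i.i.d. given the consensus),
alignment gaps, real mutation spectra, or family-size imbalance. Passing
tests therefore demonstrate that the pipeline recovers signal of this
structure — they do not certify accuracy on real tumour catalogues.

Two conditions are used in tests: the default odds (8/3), a deliberately
hard problem where the ensemble reaches ~0.95 CV accuracy, and a strongly
separable configuration (odds 50/8) mirroring a cleanly separable data set,
under which every learner exceeds 0.95, the combined classifier stays within
0.02 of the best single member, and the S/U audit confirms ≥ 90% of disease
labels. One caveat on parameter recovery: the wild-type all-kinase
conservation feature is only weakly informative *by construction* (wild
types are drawn from the family consensus, which has diverged from the
all-kinase consensus), so it is not asserted among the planted features; the
consensus-type conservation at the same depth carries the column signal and
is recovered in all seeds.

## Numerical choices and limitations

* Consensus ties: lexicographic; ranking ties: (gene, position, mutant).
* Missing values: nominal → explicit `NA` level; numeric → training-fold
  median (encoders) or own level code (discretizers).
* Selector ranks are ordinal permutations per fold (ties broken by schema
  order), so average ranks are always comparable across selectors.
* The ARFF dialect sorts nominal levels lexicographically and quotes levels
  containing whitespace; numeric cells are written with full float precision
  (`repr`) so both serialization dialects round-trip bit-exactly.
* Protein coordinates are 1-based in every external file; internal column
  indices are 0-based and never serialized.
* Hyperparameters are fixed, documented defaults; there is no search. The
  roster's absolute accuracies on any particular data set therefore depend
  on those defaults, and no attempt is made to match any external toolkit's
  numeric behaviour.
* Runtime scales with alignment size × mutation count for featurization and
  roughly linearly in roster size for cross-validation; the default
  synthetic study (557 instances, 17 attributes) fits the full roster in
  ~10 s on one CPU, and the 20-seed selection-recovery experiment runs in
  ~2 minutes.
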
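"""Model/Results facade over the prioritization pipeline.

``MutationPrioritizationModel`` is built from a labeled feature matrix (or
directly from a mutation set plus resources); ``fit`` runs optional
cross-validated feature selection, evaluates the 11-classifier roster under
stratified 10-fold cross-validation and assembles the accuracy-weighted
ensemble.  The returned ``PrioritizationResults`` carries the per-classifier
confusion matrices and metrics, the combined-classifier row, a ``summary()``
table, and methods to rank unknown mutations and audit the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import label_audit
from .classify import (
    ClassifierSpec,
    ConfusionMatrix,
    MetricReport,
    TrainedModel,
    cross_validate,
    default_roster,
    metrics_from_confusion,
)
from .datamodel_io import Label, MutationSet
from .ensemble import rank_mutations, score_mutations, weighted_score
from .feature_build import (
    DEFAULT_SELECTED,
    FeatureMatrix,
    KinomeResources,
    apply_selection,
    build_feature_matrix,
)
from .feature_selection import SelectionResult, select_features

COMBINED = "Combined (0.5)"


class MutationPrioritizationModel:
    """Ensemble model over a labeled kinase-mutation feature matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Labeled training matrix (class column D/ND).
    roster : sequence of ClassifierSpec, optional
        Defaults to the 11-member roster.
    selection : "voted", "default", sequence of names, or None
        "voted" reruns the cross-validated 5-selector vote on the training
        matrix; "default" applies the shipped 17-attribute list; an explicit
        name sequence selects those attributes; None keeps all attributes.
    """

    def __init__(self, matrix: FeatureMatrix, roster: Optional[Sequence[ClassifierSpec]] = None,
                 selection="default"):
        if not matrix.has_class:
            raise ValueError("training matrix needs a class column")
        self.matrix = matrix
        self.roster = list(roster) if roster is not None else default_roster()
        self.selection = selection

    @classmethod
    def from_mutations(cls, mutations: MutationSet, resources: KinomeResources,
                       **kwargs) -> "MutationPrioritizationModel":
        return cls(build_feature_matrix(mutations, resources), **kwargs)

    def fit(self, seed: int = 0, k: int = 10) -> "PrioritizationResults":
        selection_result = None
        if self.selection == "voted":
            selection_result = select_features(self.matrix, k_folds=k, seed=seed)
            selected = [n for n in self.matrix.attribute_names
                        if n in selection_result.retained]
            train = apply_selection(self.matrix, selected)
        elif self.selection == "default":
            selected = [n for n in DEFAULT_SELECTED if n in self.matrix.attribute_names]
            train = apply_selection(self.matrix, selected)
        elif self.selection is None:
            train = self.matrix
        else:
            train = apply_selection(self.matrix, list(self.selection))

        confusions: dict = {}
        metrics: dict = {}
        models: dict = {}
        oof = {}
        for spec in self.roster:
            cm, report, model, probs = cross_validate(spec, train, k=k, seed=seed)
            confusions[spec.name] = cm
            metrics[spec.name] = report
            models[spec.name] = model
            oof[spec.name] = probs

        # combined classifier: accuracy-weighted out-of-fold S-Scores
        accs = np.array([metrics[s.name].accuracy for s in self.roster])
        probs = np.vstack([oof[s.name] for s in self.roster])
        s_scores = (accs[:, None] * probs).sum(axis=0) / accs.sum()
        y = train.y()
        pred = (s_scores > 0.5).astype(int)
        combined_cm = ConfusionMatrix(
            tp=int(((pred == 1) & (y == 1)).sum()), fn=int(((pred == 0) & (y == 1)).sum()),
            tn=int(((pred == 0) & (y == 0)).sum()), fp=int(((pred == 1) & (y == 0)).sum()))
        confusions[COMBINED] = combined_cm
        metrics[COMBINED] = metrics_from_confusion(combined_cm)

        return PrioritizationResults(
            model=self, train_matrix=train, seed=seed, k=k,
            selection_result=selection_result, confusions=confusions,
            metrics=metrics, trained=models, oof_probs=probs, s_scores=s_scores)


@dataclass
class PrioritizationResults:
    """Fitted ensemble: estimates, diagnostics, ranking and audit."""

    model: MutationPrioritizationModel
    train_matrix: FeatureMatrix
    seed: int
    k: int
    selection_result: Optional[SelectionResult]
    confusions: dict  # name -> ConfusionMatrix (incl. combined)
    metrics: dict  # name -> MetricReport (incl. combined)
    trained: dict  # name -> TrainedModel
    oof_probs: np.ndarray  # (n_classifiers, n_instances)
    s_scores: np.ndarray  # combined out-of-fold S-Score per training instance

    @property
    def accuracies(self) -> dict:
        return {name: m.cv_accuracy for name, m in self.trained.items()}

    @property
    def combined_accuracy(self) -> float:
        return self.metrics[COMBINED].accuracy

    @property
    def best_single_accuracy(self) -> float:
        return max(self.metrics[s.name].accuracy for s in self.model.roster)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name in list(self.trained) + [COMBINED]:
            cm, m = self.confusions[name], self.metrics[name]
            rows.append({
                "algorithm": name, "TP": cm.tp, "FN": cm.fn, "TN": cm.tn, "FP": cm.fp,
                "tp_rate": m.tp_rate, "fp_rate": m.fp_rate, "accuracy": m.accuracy,
                "precision": m.precision, "recall": m.recall, "f_measure": m.f_measure,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Text table of per-classifier and combined CV performance."""
        frame = self.metrics_frame()
        lines = [
            "Kinome mutation prioritization — ensemble cross-validation",
            f"instances: {self.train_matrix.n_instances} "
            f"(D={int(self.train_matrix.y().sum())}, "
            f"ND={int((1 - self.train_matrix.y()).sum())}), "
            f"attributes: {self.train_matrix.n_attributes}, folds: {self.k}, "
            f"seed: {self.seed}",
            "",
            f"{'algorithm':<18}{'TP':>5}{'FN':>5}{'TN':>5}{'FP':>5}"
            f"{'TPrate':>8}{'FPrate':>8}{'Acc':>7}{'Prec':>7}{'Recall':>8}{'F':>7}",
        ]
        for _, r in frame.iterrows():
            lines.append(
                f"{r['algorithm']:<18}{r['TP']:>5}{r['FN']:>5}{r['TN']:>5}{r['FP']:>5}"
                f"{r['tp_rate']:>8.3f}{r['fp_rate']:>8.3f}{r['accuracy']:>7.3f}"
                f"{(r['precision'] if r['precision'] is not None else float('nan')):>7.3f}"
                f"{r['recall']:>8.3f}"
                f"{(r['f_measure'] if r['f_measure'] is not None else float('nan')):>7.3f}")
        return "\n".join(lines)

    def prioritize(self, matrix: FeatureMatrix) -> pd.DataFrame:
        """Rank unknown mutations by descending S-Score (priority table)."""
        if matrix.attribute_names != self.train_matrix.attribute_names:
            matrix = apply_selection(matrix, list(self.train_matrix.attribute_names))
        models = [self.trained[s.name] for s in self.model.roster]
        return rank_mutations(score_mutations(models, matrix))

    def audit(self, k_clusters: Optional[int] = None, seed: Optional[int] = None) -> pd.DataFrame:
        """S/U-Score label audit of the training set (Expected vs Suspicious)."""
        return label_audit.audit(self.train_matrix, self.s_scores,
                                 k_clusters=k_clusters,
                                 seed=self.seed if seed is None else seed)
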
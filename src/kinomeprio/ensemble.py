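"""Combining the 11 classifiers: majority and accuracy-weighted voting.

The majority vote counts one cost-adjusted binary call per classifier and
calls a mutation disease-associated at 6 or more of 11 votes.  The weighted
vote (the S-Score) averages the classifiers' disease probabilities weighted
by their cross-validated accuracies,

    S(x_i) = sum_j acc_j * P_j(D | x_i) / sum_j acc_j,

a value in [0, 1] where scores above 0.5 indicate a positive prediction.
Unconfirmed mutations are ranked by descending S-Score.  A chi-squared
helper compares correct/incorrect prediction counts of two classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TrainedModel, derive_seed
from .datamodel_io import Label, Mutation
from .feature_build import FeatureMatrix

ROSTER_SIZE = 11
MAJORITY_CUTOFF = 6


@dataclass(frozen=True)
class EnsembleScore:
    """Per-mutation ensemble outputs: vote count, S-Score and the per-classifier
    probabilities/accuracies behind them."""

    mutation: Mutation
    votes: int
    weighted: float  # the S-Score
    probs: tuple
    accs: tuple

    @property
    def majority_call(self) -> Label:
        return Label.DISEASE if self.votes >= MAJORITY_CUTOFF else Label.NON_DISEASE

    @property
    def weighted_call(self) -> Label:
        return Label.DISEASE if self.weighted > 0.5 else Label.NON_DISEASE


def majority_score(predictions: Sequence[int], roster_size: int = ROSTER_SIZE,
                   cutoff: int = MAJORITY_CUTOFF) -> tuple:
    """Count positive votes; the call is disease at ``cutoff`` or more votes."""
    if len(predictions) != roster_size:
        raise ValueError(f"expected {roster_size} predictions, got {len(predictions)}")
    votes = int(sum(1 for p in predictions if p))
    return votes, Label.DISEASE if votes >= cutoff else Label.NON_DISEASE


def weighted_score(probs: Sequence[float], accs: Sequence[float]) -> float:
    """Accuracy-weighted mean of disease probabilities, normalized to [0, 1]."""
    if len(probs) != len(accs):
        raise ValueError("probs and accs differ in length")
    probs = np.asarray(probs, dtype=float)
    accs = np.asarray(accs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    # accuracies act as weights: only nonnegativity matters (the score is
    # invariant under uniform rescaling)
    if (accs < 0).any():
        raise ValueError("accuracies must be nonnegative")
    denom = accs.sum()
    if denom <= 0:
        raise ValueError("sum of accuracies must be positive")
    return float((accs * probs).sum() / denom)


def score_mutations(models: Sequence[TrainedModel], matrix: FeatureMatrix) -> list:
    """Ensemble-score every instance of an (unlabeled) feature matrix."""
    if matrix.mutations is None:
        raise ValueError("feature matrix carries no mutation keys")
    probs = np.vstack([m.predict_proba(matrix) for m in models])
    preds = np.vstack([m.predict(matrix) for m in models])
    accs = tuple(m.cv_accuracy for m in models)
    out = []
    for i, mut in enumerate(matrix.mutations):
        votes, _ = majority_score(preds[:, i], roster_size=len(models),
                                  cutoff=int(np.ceil((len(models) + 1) / 2)))
        out.append(EnsembleScore(
            mutation=mut, votes=votes,
            weighted=weighted_score(probs[:, i], accs),
            probs=tuple(float(p) for p in probs[:, i]), accs=accs))
    return out


def rank_mutations(scores: Sequence[EnsembleScore]) -> pd.DataFrame:
    """Priority table sorted by descending S-Score (deterministic tie-break)."""
    if not scores:
        raise ValueError("no scores to rank")
    ordered = sorted(scores, key=lambda s: (-s.weighted, s.mutation.gene,
                                            s.mutation.position, s.mutation.mut))
    return pd.DataFrame({
        "rank": np.arange(1, len(ordered) + 1),
        "score": [s.weighted for s in ordered],
        "votes": [s.votes for s in ordered],
        "gene": [s.mutation.gene for s in ordered],
        "position": [s.mutation.position for s in ordered],
        "wt": [s.mutation.wt for s in ordered],
        "mut": [s.mutation.mut for s in ordered],
    })


def chi2_compare(correct_a: int, wrong_a: int, correct_b: int, wrong_b: int,
                 n_sim: Optional[int] = None, seed: int = 0) -> tuple:
    """Pearson chi-square (no continuity correction) on a 2x2 correct/incorrect
    table; with ``n_sim`` the p-value is estimated by Monte-Carlo resampling of
    tables with fixed margins.

    Returns ``(statistic, p_value)`` with df = 1.
    """
    table = np.array([[correct_a, wrong_a], [correct_b, wrong_b]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("each classifier needs at least one prediction")

    def pearson(t: np.ndarray) -> np.ndarray:
        rows = t.sum(axis=-1, keepdims=True)
        cols = t.sum(axis=-2, keepdims=True)
        expected = rows * cols / t.sum(axis=(-2, -1), keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
        return terms.sum(axis=(-2, -1))

    stat = float(pearson(table))
    if n_sim is None:
        p = float(stats.chi2.sf(stat, df=1))
    else:
        rng = np.random.default_rng(derive_seed(seed, "chi2-mc"))
        r1 = int(table[0].sum())
        c1 = int(table[:, 0].sum())
        n = int(table.sum())
        a = rng.hypergeometric(c1, n - c1, r1, size=n_sim).astype(float)
        sims = np.stack([np.stack([a, r1 - a], axis=-1),
                         np.stack([c1 - a, n - r1 - (c1 - a)], axis=-1)], axis=-2)
        sim_stats = pearson(sims)
        p = float((1 + np.sum(sim_stats >= stat - 1e-9)) / (1 + n_sim))
    return stat, p
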
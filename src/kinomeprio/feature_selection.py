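"""Cross-validated feature selection by five-selector voting.

Five selection algorithms — OneR, ReliefF, chi-square, gain ratio and
correlation-based subset selection (CFS) — are each run on the ten training
folds of a stratified 10-fold split.  Single-attribute evaluators report the
fold-averaged merit and ordinal rank of every attribute; CFS reports in how
many folds each attribute entered the best subset.  An attribute is retained
when at least 3 of the 5 selectors vote for it, and its overall "average
rank" is the arithmetic mean of its five per-selector ranks.

When a ranker's vote counts is not externally defined; here a ranker votes
for an attribute when its fold-averaged merit is positive and its average
rank falls within the top ``top_k`` (default 17) of the schema.  This rule is
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .feature_build import Discretizer, FeatureMatrix, NumericEncoder

SELECTORS = ("OneR", "ReliefF", "ChiSquare", "GainRatio", "CFS")


@dataclass
class SelectorRanking:
    """Per-fold output of one selector over a fixed attribute schema."""

    selector: str
    attribute_names: tuple
    fold_merits: Optional[np.ndarray] = None  # (n_folds, n_attr) for rankers
    fold_ranks: Optional[np.ndarray] = None  # (n_folds, n_attr), rank 1 = best
    fold_membership: Optional[np.ndarray] = None  # (n_folds, n_attr) bool, CFS

    @property
    def avg_merit(self) -> Optional[np.ndarray]:
        return None if self.fold_merits is None else self.fold_merits.mean(axis=0)

    @property
    def avg_rank(self) -> np.ndarray:
        if self.fold_ranks is not None:
            return self.fold_ranks.mean(axis=0)
        # CFS: rank by membership count, most-selected first (ties by order)
        counts = self.fold_membership.sum(axis=0)
        order = np.lexsort((np.arange(len(counts)), -counts))
        ranks = np.empty(len(counts))
        ranks[order] = np.arange(1, len(counts) + 1)
        return ranks


@dataclass
class SelectionResult:
    """Votes (0-5), average rank and the retained attribute set."""

    attribute_names: tuple
    votes: dict  # name -> int
    avg_rank: dict  # name -> float
    retained: tuple  # names with votes >= threshold, Table-style ordering

    def report(self) -> str:
        lines = ["feature\tvotes\tavg_rank"]
        for name in self.retained:
            lines.append(f"{name}\t{self.votes[name]}\t{self.avg_rank[name]:.2f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Per-attribute merit functions on discretized level codes

def _contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    n_levels = int(codes.max()) + 1
    table = np.zeros((n_levels, 2))
    for cls in (0, 1):
        table[:, cls] = np.bincount(codes[y == cls], minlength=n_levels)
    return table[table.sum(axis=1) > 0]


def chi_square_merit(codes: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-square statistic of the attribute x class contingency table."""
    table = _contingency(codes, y)
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    mask = expected > 0
    return float((((table - expected) ** 2)[mask] / expected[mask]).sum())


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def gain_ratio_merit(codes: np.ndarray, y: np.ndarray) -> float:
    """Information gain of the class given the attribute, over the split info."""
    table = _contingency(codes, y)
    n = table.sum()
    h_class = _entropy(table.sum(axis=0))
    h_cond = sum((row.sum() / n) * _entropy(row) for row in table)
    split_info = _entropy(table.sum(axis=1))
    gain = h_class - h_cond
    if split_info <= 1e-12 or gain <= 1e-12:
        return 0.0
    return float(gain / split_info)


def oner_merit(codes: np.ndarray, y: np.ndarray) -> float:
    """Training accuracy of the one-attribute majority rule (fraction)."""
    table = _contingency(codes, y)
    return float(table.max(axis=1).sum() / table.sum())


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    n_a, n_b = int(a.max()) + 1, int(b.max()) + 1
    joint = np.zeros((n_a, n_b))
    np.add.at(joint, (a, b), 1)
    h_a = _entropy(joint.sum(axis=1))
    h_b = _entropy(joint.sum(axis=0))
    h_ab = _entropy(joint.ravel())
    if h_a + h_b <= 1e-12:
        return 0.0
    return max(0.0, 2.0 * (h_a + h_b - h_ab) / (h_a + h_b))


def cfs_best_subset(codes: np.ndarray, y: np.ndarray) -> list:
    """Greedy forward correlation-based subset search.

    Subset merit = k*mean(SU(a,c)) / sqrt(k + k(k-1)*mean(SU(a,b))); the
    search adds the best attribute until merit stops improving.
    """
    n_attr = codes.shape[1]
    su_class = np.array([symmetrical_uncertainty(codes[:, j], y) for j in range(n_attr)])
    su_pair = np.zeros((n_attr, n_attr))
    for j in range(n_attr):
        for k in range(j + 1, n_attr):
            su_pair[j, k] = su_pair[k, j] = symmetrical_uncertainty(codes[:, j], codes[:, k])

    def merit(subset: list) -> float:
        k = len(subset)
        rcf = su_class[subset].mean()
        rff = su_pair[np.ix_(subset, subset)].sum() / (k * (k - 1)) if k > 1 else 0.0
        return k * rcf / math.sqrt(k + k * (k - 1) * rff)

    selected: list = []
    best = -np.inf
    remaining = list(range(n_attr))
    while remaining:
        scored = [(merit(selected + [j]), j) for j in remaining]
        top_merit, top_j = max(scored, key=lambda t: (t[0], -t[1]))
        if top_merit <= best + 1e-12:
            break
        best = top_merit
        selected.append(top_j)
        remaining.remove(top_j)
    return sorted(selected)


# ---------------------------------------------------------------------------
# ReliefF on the mixed representation

def relieff_merits(matrix: FeatureMatrix, y: np.ndarray, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF attribute weights; nominal diff is 0/1, numeric diff is range-scaled.

    All instances are used; neighbor distance is the Manhattan sum of
    per-attribute diffs.
    """
    n = matrix.n_instances
    n_attr = matrix.n_attributes
    diffs = np.zeros((n_attr, n, n))
    for j, attr in enumerate(matrix.attributes):
        if attr.kind == "numeric":
            col = np.array(matrix.column(attr.name), dtype=float)
            med = np.nanmedian(col) if np.isnan(col).any() and not np.isnan(col).all() else 0.0
            col = np.where(np.isnan(col), med, col)
            span = col.max() - col.min()
            scaled = (col - col.min()) / span if span > 0 else np.zeros(n)
            diffs[j] = np.abs(scaled[:, None] - scaled[None, :])
        else:
            col = matrix.column(attr.name)
            codes = np.array([hash(v) if v is not None else -1 for v in col])
            diffs[j] = (codes[:, None] != codes[None, :]).astype(float)
    dist = diffs.sum(axis=0)
    np.fill_diagonal(dist, np.inf)
    priors = np.bincount(y, minlength=2) / n
    weights = np.zeros(n_attr)
    k = k_neighbors
    for i in range(n):
        same = np.where((y == y[i]) & (np.arange(n) != i))[0]
        hits = same[np.argsort(dist[i, same], kind="stable")[:k]]
        if hits.size:
            weights -= diffs[:, i, hits].sum(axis=1) / (n * hits.size)
        for cls in (0, 1):
            if cls == y[i]:
                continue
            other = np.where(y == cls)[0]
            misses = other[np.argsort(dist[i, other], kind="stable")[:k]]
            if misses.size:
                factor = priors[cls] / (1.0 - priors[y[i]])
                weights += factor * diffs[:, i, misses].sum(axis=1) / (n * misses.size)
    return weights


# ---------------------------------------------------------------------------
# Cross-validated driver

def _ordinal_ranks(merits: np.ndarray) -> np.ndarray:
    """Rank 1 = highest merit; ties broken by attribute order (a permutation)."""
    order = np.lexsort((np.arange(len(merits)), -merits))
    ranks = np.empty(len(merits))
    ranks[order] = np.arange(1, len(merits) + 1)
    return ranks


def run_selector(selector: str, matrix: FeatureMatrix, k_folds: int = 10,
                 seed: int = 0) -> SelectorRanking:
    """Run one selector on each training fold of a stratified k-fold split."""
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}; expected one of {SELECTORS}")
    if not matrix.has_class:
        raise ValueError("feature matrix has no class column")
    y_all = matrix.y()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    names = matrix.attribute_names
    merits_per_fold, ranks_per_fold, membership_per_fold = [], [], []
    for train_idx, _test_idx in skf.split(np.zeros(len(y_all)), y_all):
        fold = matrix.subset_rows(train_idx)
        y = y_all[train_idx]
        if selector == "ReliefF":
            merits = relieff_merits(fold, y, k_neighbors=10)
        elif selector == "CFS":
            disc = Discretizer(fold.attributes, n_bins=5).fit(fold)
            codes = disc.transform(fold)
            subset = cfs_best_subset(codes, y)
            member = np.zeros(len(names), dtype=bool)
            member[subset] = True
            membership_per_fold.append(member)
            continue
        else:
            n_bins = 6 if selector == "OneR" else 5
            disc = Discretizer(fold.attributes, n_bins=n_bins).fit(fold)
            codes = disc.transform(fold)
            merit_fn = {"OneR": oner_merit, "ChiSquare": chi_square_merit,
                        "GainRatio": gain_ratio_merit}[selector]
            merits = np.array([merit_fn(codes[:, j], y) for j in range(len(names))])
            if selector == "OneR":
                # baseline-correct so an uninformative rule has merit ~0
                merits = merits - max(np.mean(y), 1 - np.mean(y))
        merits_per_fold.append(merits)
        ranks_per_fold.append(_ordinal_ranks(merits))
    if selector == "CFS":
        return SelectorRanking(selector, names, fold_membership=np.array(membership_per_fold))
    return SelectorRanking(selector, names, fold_merits=np.array(merits_per_fold),
                           fold_ranks=np.array(ranks_per_fold))


def vote_and_rank(rankings: Sequence[SelectorRanking], vote_threshold: int = 3,
                  top_k: int = 17) -> SelectionResult:
    """Count selector votes and average the five per-selector ranks.

    A ranker votes for an attribute when its fold-averaged merit is positive
    and its average rank is within the top ``top_k``; CFS votes when the
    attribute sat in the best subset in a majority of folds.
    """
    schemas = {r.attribute_names for r in rankings}
    if len(schemas) != 1:
        raise ValueError("selector rankings cover different schemas")
    names = rankings[0].attribute_names
    votes = np.zeros(len(names), dtype=int)
    rank_sum = np.zeros(len(names))
    for r in rankings:
        rank_sum += r.avg_rank
        if r.fold_membership is not None:
            counts = r.fold_membership.sum(axis=0)
            votes += (counts > r.fold_membership.shape[0] / 2).astype(int)
        else:
            votes += ((r.avg_merit > 1e-12) & (r.avg_rank <= top_k)).astype(int)
    avg_rank = rank_sum / len(rankings)
    retained_idx = [j for j in range(len(names)) if votes[j] >= vote_threshold]
    retained_idx.sort(key=lambda j: (-votes[j], avg_rank[j], names[j]))
    return SelectionResult(
        attribute_names=names,
        votes={n: int(v) for n, v in zip(names, votes)},
        avg_rank={n: float(r) for n, r in zip(names, avg_rank)},
        retained=tuple(names[j] for j in retained_idx),
    )


def select_features(matrix: FeatureMatrix, k_folds: int = 10, seed: int = 0,
                    vote_threshold: int = 3, top_k: int = 17) -> SelectionResult:
    """Run all five selectors under cross-validation and vote."""
    rankings = [run_selector(s, matrix, k_folds=k_folds, seed=seed) for s in SELECTORS]
    return vote_and_rank(rankings, vote_threshold=vote_threshold, top_k=top_k)
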
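"""Label audit by label-blind clustering (the U-Score).

Training labels from mutation catalogues are noisy: a somatic catalogue can
contain passengers and a polymorphism catalogue can contain mildly deleterious
variants.  To flag suspicious labels, instances are clustered label-blind by
Euclidean k-means in the encoded selected-feature space; the U-Score of an
instance is the disease-labeled fraction among the *other* members of its
cluster (leave-one-out, so an instance cannot confirm its own label;
singletons score a neutral 0.5).

Combining the supervised S-Score with the U-Score gives a consensus: both
above 0.5 -> disease, both below 0.5 -> benign, anything else (including
exact 0.5) -> uncertain.  An instance is "Expected" when the consensus is
decisive and matches its given label, otherwise "Suspicious".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .classify import derive_seed
from .datamodel_io import Label
from .feature_build import FeatureMatrix, NumericEncoder

CONSENSUS_DISEASE = "disease"
CONSENSUS_BENIGN = "benign"
CONSENSUS_UNCERTAIN = "uncertain"
EXPECTED = "Expected"
SUSPICIOUS = "Suspicious"


def default_cluster_count(matrix: FeatureMatrix) -> int:
    """One cluster per kinase family when the family attribute is present.

    Kinase families form well-separated subpopulations in the one-hot encoded
    feature space, so clusters at coarser granularity simply recover family
    blocks; matching the cluster count to the family count makes the
    disease-fraction of a cluster reflect the local label structure."""
    try:
        return max(2, len(matrix.attribute("family").levels))
    except KeyError:
        return 2


def u_score(matrix: FeatureMatrix, k_clusters: Optional[int] = None,
            seed: int = 0) -> np.ndarray:
    """Per-instance leave-one-out disease fraction of the instance's cluster."""
    if not matrix.has_class:
        raise ValueError("labeled matrix required to compute U-Scores")
    if k_clusters is None:
        k_clusters = default_cluster_count(matrix)
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if k_clusters > matrix.n_instances:
        raise ValueError("k_clusters exceeds the number of instances")
    X = NumericEncoder(matrix.attributes).fit(matrix).transform(matrix)
    # canonicalize instance order before fitting so the clustering (and hence
    # every u_score) is invariant to row permutations of the input matrix
    order = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=k_clusters, n_init=10,
                random_state=derive_seed(seed, "kmeans"))
    clusters = np.empty(len(X), dtype=int)
    clusters[order] = km.fit_predict(X[order])
    y = matrix.y()
    scores = np.empty(len(y))
    for c in np.unique(clusters):
        members = clusters == c
        size = int(members.sum())
        disease = int(y[members].sum())
        if size == 1:
            scores[members] = 0.5
        else:
            # leave-one-out: exclude the instance's own label
            scores[members] = (disease - y[members]) / (size - 1)
    return scores


def categorize(s: float, u: float, label: Label) -> tuple:
    """Consensus of S/U scores and Expected/Suspicious category for a label."""
    for name, v in (("s", s), ("u", u)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}-score {v} outside [0, 1]")
    if s > 0.5 and u > 0.5:
        consensus = CONSENSUS_DISEASE
    elif s < 0.5 and u < 0.5:
        consensus = CONSENSUS_BENIGN
    else:
        consensus = CONSENSUS_UNCERTAIN
    if consensus == CONSENSUS_DISEASE and label is Label.DISEASE:
        category = EXPECTED
    elif consensus == CONSENSUS_BENIGN and label is Label.NON_DISEASE:
        category = EXPECTED
    else:
        category = SUSPICIOUS
    return consensus, category


def audit(matrix: FeatureMatrix, s_scores: Sequence[float],
          k_clusters: Optional[int] = None, seed: int = 0) -> pd.DataFrame:
    """Full audit table: mutation key, S-Score, U-Score, consensus, category."""
    s_scores = np.asarray(s_scores, dtype=float)
    if len(s_scores) != matrix.n_instances:
        raise ValueError("one S-Score per instance required")
    u_scores = u_score(matrix, k_clusters=k_clusters, seed=seed)
    rows = []
    for i in range(matrix.n_instances):
        consensus, category = categorize(s_scores[i], u_scores[i], matrix.class_labels[i])
        mut = matrix.mutations[i] if matrix.mutations else None
        rows.append({
            "mutation": str(mut) if mut else str(i),
            "label": matrix.class_labels[i].value,
            "s_score": float(s_scores[i]),
            "u_score": float(u_scores[i]),
            "consensus": consensus,
            "category": category,
        })
    return pd.DataFrame(rows)
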
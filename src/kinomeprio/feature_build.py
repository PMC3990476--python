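"""Assembly of the 29-attribute feature vector and the selected-feature matrix.

The full roster combines four nominal identity features (kinase group and
family, wild-type and mutant residue type), the BLOSUM62 pair score, twelve
wild-type/mutant physicochemical property values plus two signed deltas
(hydropathy and van der Waals volume), six alignment-conservation fractions
(wild-type and consensus residue at family/group/all-kinase depth) and four
structural/functional site features — 29 attributes in total.  The default
17-attribute selection is the subset retained by the cross-validated
selector vote.

Numeric-only learners consume an encoded view (one-hot nominals, min-max
scaled numerics, median imputation) whose scaling/imputation statistics are
fit on training folds only; rule/Bayes learners consume discretized level
codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .datamodel_io import Label, Mutation, MutationSet
from . import residue_props as rp
from .conservation import DepthAlignment, conservation_features
from .kinase_annotation import (
    NA,
    NO_SUBDOMAIN,
    SUBDOMAIN_LABELS,
    KinaseRecord,
    classify_gene,
    site_features,
)


@dataclass(frozen=True)
class Attribute:
    """One column of a feature matrix: name, numeric/nominal kind, level set."""

    name: str
    kind: str  # "numeric" | "nominal"
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "nominal"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "nominal" and not self.levels:
            raise ValueError(f"nominal attribute {self.name!r} needs levels")


FULL_FEATURE_NAMES = (
    "group", "family", "aa_wt", "aa_mut",
    "blosum62",
    "hydropathy_wt", "hydropathy_mut", "hydropathy_delta",
    "charge_wt", "charge_mut",
    "polarity_wt", "polarity_mut",
    "vdw_wt", "vdw_mut", "vdw_delta",
    "mass_wt", "mass_mut",
    "freq_wt", "freq_mut",
    "cons_wt_family", "cons_wt_group", "cons_wt_all",
    "cons_consensus_family", "cons_consensus_group", "cons_consensus_all",
    "subdomain", "binding_site", "modification", "in_pk_domain",
)

# Attributes retained by the cross-validated 5-selector vote (>=3/5 votes),
# in descending usefulness.  The mass feature is the mutant-side value.
DEFAULT_SELECTED = (
    "family", "group", "aa_wt", "blosum62", "polarity_mut",
    "cons_wt_all", "cons_consensus_group", "cons_consensus_all",
    "cons_consensus_family", "subdomain", "mass_mut", "binding_site",
    "vdw_wt", "modification", "aa_mut", "polarity_wt", "in_pk_domain",
)

_NOMINAL = {"group", "family", "aa_wt", "aa_mut", "subdomain", "binding_site", "modification"}


class FeatureMatrix:
    """Rectangular instance table with a typed attribute schema.

    Nominal cells hold strings (None = missing), numeric cells floats
    (NaN = missing).  The optional class column holds D/ND labels.
    """

    def __init__(self, attributes: Sequence[Attribute], rows: Sequence[Sequence],
                 class_labels: Optional[Sequence[Label]] = None,
                 mutations: Optional[Sequence[Mutation]] = None):
        names = [a.name for a in attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")
        self.attributes = tuple(attributes)
        self.rows = [list(r) for r in rows]
        for r in self.rows:
            if len(r) != len(self.attributes):
                raise ValueError("row length does not match schema")
        self.class_labels = list(class_labels) if class_labels is not None else None
        if self.class_labels is not None and len(self.class_labels) != len(self.rows):
            raise ValueError("class column length mismatch")
        self.mutations = list(mutations) if mutations is not None else None
        self._index = {a.name: i for i, a in enumerate(self.attributes)}

    # -- basic queries ------------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.rows)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def has_class(self) -> bool:
        return self.class_labels is not None

    @property
    def attribute_names(self) -> tuple:
        return tuple(a.name for a in self.attributes)

    def attribute(self, name: str) -> Attribute:
        return self.attributes[self._index[name]]

    def value(self, i: int, name: str):
        return self.rows[i][self._index[name]]

    def column(self, name: str) -> list:
        j = self._index[name]
        return [r[j] for r in self.rows]

    def y(self) -> np.ndarray:
        """Binary class vector: 1 = disease, 0 = non-disease."""
        if not self.has_class:
            raise ValueError("matrix has no class column")
        return np.array([1 if l is Label.DISEASE else 0 for l in self.class_labels])

    def subset_rows(self, indices: Iterable[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.attributes,
            [self.rows[i] for i in idx],
            [self.class_labels[i] for i in idx] if self.has_class else None,
            [self.mutations[i] for i in idx] if self.mutations else None,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        if self.attributes != other.attributes or self.class_labels != other.class_labels:
            return False
        if len(self.rows) != len(other.rows):
            return False
        for ra, rb in zip(self.rows, other.rows):
            for va, vb in zip(ra, rb):
                if isinstance(va, float) and isinstance(vb, float):
                    if not (va == vb or (math.isnan(va) and math.isnan(vb))):
                        return False
                elif va != vb:
                    return False
        return True


@dataclass
class KinomeResources:
    """Everything needed to featurize a mutation set.

    ``alignments`` maps gene -> {depth -> DepthAlignment} with the gene's own
    sequence as the reference row of each depth alignment.
    """

    classification: dict  # gene -> (group, family)
    annotations: dict  # gene -> KinaseRecord
    properties: rp.PropertyTable
    matrix: rp.SubstitutionMatrix
    alignments: dict = field(default_factory=dict)


def build_feature_vector(mut: Mutation, resources: KinomeResources) -> dict:
    """All 29 named feature values for one mutation (missing = NaN/None)."""
    group, family = classify_gene(mut.gene, resources.classification)
    props = resources.properties
    vec: dict = {
        "group": group,
        "family": family,
        "aa_wt": mut.wt,
        "aa_mut": mut.mut,
        "blosum62": float(rp.substitution_score(resources.matrix, mut.wt, mut.mut)),
    }
    for prop, short in (("hydropathy", "hydropathy"), ("charge", "charge"),
                        ("polarity", "polarity"), ("vdw_volume", "vdw"),
                        ("avg_mass", "mass"), ("frequency", "freq")):
        vec[f"{short}_wt"] = rp.lookup_property(props, mut.wt, prop)
        vec[f"{short}_mut"] = rp.lookup_property(props, mut.mut, prop)
    vec["hydropathy_delta"] = rp.property_delta(props, mut.wt, mut.mut, "hydropathy")
    vec["vdw_delta"] = rp.property_delta(props, mut.wt, mut.mut, "vdw_volume")
    vec.update(conservation_features(mut, resources.alignments.get(mut.gene.upper(), {})))
    rec = resources.annotations.get(mut.gene.upper())
    if rec is None:
        vec.update({"subdomain": None, "binding_site": None, "modification": None,
                    "in_pk_domain": float("nan")})
    else:
        sf = site_features(mut, rec)
        vec.update({"subdomain": sf.subdomain, "binding_site": sf.is_binding_site,
                    "modification": sf.modification, "in_pk_domain": float(sf.in_pk_domain)})
    assert set(vec) == set(FULL_FEATURE_NAMES)
    return vec


def _schema_from_vectors(vectors: Sequence[dict], resources: KinomeResources) -> list:
    attrs = []
    for name in FULL_FEATURE_NAMES:
        if name in ("aa_wt", "aa_mut"):
            attrs.append(Attribute(name, "nominal", tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))))
        elif name == "subdomain":
            attrs.append(Attribute(name, "nominal", tuple(SUBDOMAIN_LABELS) + (NO_SUBDOMAIN,)))
        elif name == "binding_site":
            attrs.append(Attribute(name, "nominal", ("yes", NA)))
        elif name in _NOMINAL:
            levels = sorted({v[name] for v in vectors if v[name] is not None})
            if name == "modification" and NA not in levels:
                levels.append(NA)
            attrs.append(Attribute(name, "nominal", tuple(sorted(levels))))
        else:
            attrs.append(Attribute(name, "numeric"))
    return attrs


def build_feature_matrix(ms: MutationSet, resources: KinomeResources,
                         with_class: bool = True) -> FeatureMatrix:
    """Featurize a mutation set into the full 29-attribute matrix."""
    vectors = [build_feature_vector(lm.mutation, resources) for lm in ms]
    attrs = _schema_from_vectors(vectors, resources)
    rows = [[v[a.name] for a in attrs] for v in vectors]
    labels = [lm.label for lm in ms] if with_class else None
    return FeatureMatrix(attrs, rows, labels, mutations=ms.mutations())


def apply_selection(matrix: FeatureMatrix, selected: Sequence[str]) -> FeatureMatrix:
    """Project the matrix onto an ordered attribute subset (class kept)."""
    unknown = [n for n in selected if n not in matrix.attribute_names]
    if unknown:
        raise ValueError(f"unknown attributes {unknown}")
    attrs = [matrix.attribute(n) for n in selected]
    idx = [matrix._index[n] for n in selected]
    rows = [[r[j] for j in idx] for r in matrix.rows]
    return FeatureMatrix(attrs, rows, matrix.class_labels, matrix.mutations)


# ---------------------------------------------------------------------------
# Encodings for learning algorithms

class NumericEncoder:
    """One-hot nominals + min-max scaled numerics with median imputation.

    The one-hot layout comes from the (fixed) schema; scaling and imputation
    statistics are estimated from the matrix passed to :meth:`fit` (a training
    fold) and applied unchanged to test folds.
    """

    def __init__(self, attributes: Sequence[Attribute]):
        self.attributes = tuple(attributes)
        self._fitted = False

    def fit(self, matrix: FeatureMatrix) -> "NumericEncoder":
        self.medians_: dict = {}
        self.ranges_: dict = {}
        for a in self.attributes:
            if a.kind != "numeric":
                continue
            col = np.array(matrix.column(a.name), dtype=float)
            finite = col[~np.isnan(col)]
            med = float(np.median(finite)) if finite.size else 0.0
            lo = float(finite.min()) if finite.size else 0.0
            hi = float(finite.max()) if finite.size else 1.0
            self.medians_[a.name] = med
            self.ranges_[a.name] = (lo, hi - lo if hi > lo else 1.0)
        self._fitted = True
        return self

    def feature_names(self) -> list:
        names = []
        for a in self.attributes:
            if a.kind == "numeric":
                names.append(a.name)
            else:
                names.extend(f"{a.name}={l}" for l in a.levels)
        return names

    def transform(self, matrix: FeatureMatrix) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("encoder not fitted")
        blocks = []
        for a in self.attributes:
            if a.kind == "numeric":
                col = np.array(matrix.column(a.name), dtype=float)
                col = np.where(np.isnan(col), self.medians_[a.name], col)
                lo, span = self.ranges_[a.name]
                blocks.append(((col - lo) / span)[:, None])
            else:
                col = matrix.column(a.name)
                onehot = np.zeros((len(col), len(a.levels)))
                index = {l: k for k, l in enumerate(a.levels)}
                for i, v in enumerate(col):
                    if v is not None and v in index:
                        onehot[i, index[v]] = 1.0
                blocks.append(onehot)
        return np.hstack(blocks)

    def group_slices(self) -> list:
        """(attribute name, column slice) pairs in the encoded array."""
        out, start = [], 0
        for a in self.attributes:
            width = 1 if a.kind == "numeric" else len(a.levels)
            out.append((a.name, slice(start, start + width)))
            start += width
        return out


class Discretizer:
    """Integer level codes per attribute; numerics binned by training quantiles.

    Missing values get their own code (0); nominal levels are offset by 1.
    """

    def __init__(self, attributes: Sequence[Attribute], n_bins: int = 5):
        self.attributes = tuple(attributes)
        self.n_bins = n_bins
        self._fitted = False

    def fit(self, matrix: FeatureMatrix) -> "Discretizer":
        self.edges_: dict = {}
        for a in self.attributes:
            if a.kind != "numeric":
                continue
            col = np.array(matrix.column(a.name), dtype=float)
            finite = col[~np.isnan(col)]
            if finite.size == 0:
                self.edges_[a.name] = np.array([])
                continue
            qs = np.quantile(finite, np.linspace(0, 1, self.n_bins + 1)[1:-1])
            self.edges_[a.name] = np.unique(qs)
        self._fitted = True
        return self

    def n_levels(self) -> list:
        out = []
        for a in self.attributes:
            if a.kind == "numeric":
                out.append(len(self.edges_[a.name]) + 2)  # bins + missing code
            else:
                out.append(len(a.levels) + 1)
        return out

    def transform(self, matrix: FeatureMatrix) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("discretizer not fitted")
        cols = []
        for a in self.attributes:
            if a.kind == "numeric":
                col = np.array(matrix.column(a.name), dtype=float)
                codes = np.searchsorted(self.edges_[a.name], col, side="right") + 1
                codes = np.where(np.isnan(col), 0, codes)
            else:
                index = {l: k + 1 for k, l in enumerate(a.levels)}
                codes = np.array([index.get(v, 0) if v is not None else 0
                                  for v in matrix.column(a.name)])
            cols.append(codes.astype(np.int64))
        return np.column_stack(cols)
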
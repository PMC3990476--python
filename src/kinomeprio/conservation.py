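"""Alignment-column conservation at three evolutionary depths.

The conservation of a residue at an alignment column is its frequency among
all rows of the column (gaps count in the denominator).  Conservation is
evaluated at three depths of the kinase superfamily — within the kinase
family, within the major group, and across all kinases — for both the
wild-type residue and the column's consensus (modal non-gap) residue, giving
six features per mutation site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .datamodel_io import CANONICAL_RESIDUES, Mutation

DEPTHS = ("family", "group", "all_kinase")
GAP = "-"
_RESIDUE_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


@dataclass(frozen=True)
class DepthAlignment:
    """A named multiple alignment at one evolutionary depth.

    ``reference_name`` selects the row used to map protein positions to
    alignment columns.
    """

    depth: str
    sequences: tuple  # of (name, aligned_str) pairs
    reference_name: str

    def __post_init__(self) -> None:
        if self.depth not in DEPTHS:
            raise ValueError(f"unknown depth {self.depth!r}")
        if len(self.sequences) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: rows differ in length")
        if self.reference_name not in dict(self.sequences):
            raise ValueError(f"reference {self.reference_name!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def row(self, name: str) -> str:
        return dict(self.sequences)[name]

    def with_reference(self, name: str) -> "DepthAlignment":
        return replace(self, reference_name=name)


def read_depth_alignment(path, depth: str, reference_name: Optional[str] = None) -> DepthAlignment:
    """Read an aligned FASTA; default reference is the first record."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return DepthAlignment(depth, tuple(records), reference_name or records[0][0])


def write_depth_alignment(aln: DepthAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.sequences:
            fh.write(f">{name}\n{seq}\n")


@dataclass(frozen=True)
class AlignmentProfile:
    """Per-column residue/gap counts with the consensus residue per column.

    ``counts`` is a (21, L) integer array: 20 residue rows in canonical order
    plus a final gap row.  ``consensus[j]`` is the modal non-gap residue of
    column j (lexicographic tie-break) or None for an all-gap column.
    """

    counts: np.ndarray
    n_sequences: int
    consensus: tuple

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def build_profile(aln: DepthAlignment) -> AlignmentProfile:
    arr = np.frombuffer("".join(s for _, s in aln.sequences).encode(), dtype="S1")
    arr = arr.reshape(aln.n_sequences, aln.length)
    counts = np.zeros((21, aln.length), dtype=np.int64)
    for i, res in enumerate(CANONICAL_RESIDUES):
        counts[i] = (arr == res.encode()).sum(axis=0)
    counts[20] = aln.n_sequences - counts[:20].sum(axis=0)  # gaps + non-canonical
    consensus = []
    residue_counts = counts[:20]
    # argmax over rows is lexicographic-first on ties because rows are in
    # canonical residue order
    top = residue_counts.argmax(axis=0)
    for j in range(aln.length):
        consensus.append(None if residue_counts[top[j], j] == 0 else CANONICAL_RESIDUES[top[j]])
    return AlignmentProfile(counts, aln.n_sequences, tuple(consensus))


def column_frequency(profile: AlignmentProfile, column: int, residue: str) -> float:
    """Frequency of ``residue`` in a (0-based) column; gaps count in the denominator."""
    if not 0 <= column < profile.length:
        raise IndexError(f"column {column} out of range 0..{profile.length - 1}")
    if residue == GAP:
        return float(profile.counts[20, column]) / profile.n_sequences
    if residue not in _RESIDUE_INDEX:
        raise ValueError(f"unknown residue {residue!r}")
    return float(profile.counts[_RESIDUE_INDEX[residue], column]) / profile.n_sequences


def map_position(aln: DepthAlignment, position: int) -> int:
    """Map a 1-based ungapped reference position to its 0-based alignment column."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    row = aln.row(aln.reference_name)
    seen = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            seen += 1
            if seen == position:
                return col
    raise ValueError(
        f"position {position} beyond ungapped length {seen} of reference {aln.reference_name!r}"
    )


MISSING = float("nan")

_FEATURE_NAMES = {
    "family": ("cons_wt_family", "cons_consensus_family"),
    "group": ("cons_wt_group", "cons_consensus_group"),
    "all_kinase": ("cons_wt_all", "cons_consensus_all"),
}


def conservation_features(mut: Mutation, alignments: dict) -> dict:
    """Six conservation fractions for a mutation site.

    ``alignments`` maps depth -> DepthAlignment (reference row = the mutated
    gene).  A depth whose alignment is absent yields NaN for its two features.
    If the wild-type residue disagrees with the reference row at the mapped
    column, a warning is emitted and features are still computed (sequence
    version drift is common).
    """
    out: dict = {}
    for depth, (wt_name, cons_name) in _FEATURE_NAMES.items():
        aln = alignments.get(depth)
        if aln is None:
            out[wt_name] = MISSING
            out[cons_name] = MISSING
            continue
        col = map_position(aln, mut.position)
        ref_res = aln.row(aln.reference_name)[col]
        if ref_res != mut.wt:
            warnings.warn(
                f"{mut}: wild-type {mut.wt} differs from reference residue "
                f"{ref_res} at {depth} column {col}",
                stacklevel=2,
            )
        profile = build_profile(aln)
        out[wt_name] = column_frequency(profile, col, mut.wt)
        cons = profile.consensus[col]
        out[cons_name] = 0.0 if cons is None else column_frequency(profile, col, cons)
    return out
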
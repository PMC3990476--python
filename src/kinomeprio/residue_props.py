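"""Amino-acid property tables and the BLOSUM62 substitution score.

Six per-residue properties are used as mutation features: Kyte-Doolittle
hydropathy, formal side-chain charge (-1/0/+1), binary side-chain polarity,
side-chain van der Waals volume (A^3), average mass of the free amino acid
(Da) and naturally occurring residue frequency.  The BLOSUM62 log-odds score
of the (wt, mut) pair summarizes overall exchangeability.

Default tables ship with the package; both are overridable with files in the
same formats (whitespace-delimited property table, NCBI matrix format).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .datamodel_io import CANONICAL_RESIDUES

PROPERTIES = ("hydropathy", "charge", "polarity", "vdw_volume", "avg_mass", "frequency")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("kinomeprio").joinpath("data", name)))


@dataclass(frozen=True)
class PropertyTable:
    """Mapping property name -> {residue -> value} for all 20 canonical residues."""

    values: dict

    def __post_init__(self) -> None:
        for prop in PROPERTIES:
            if prop not in self.values:
                raise ValueError(f"missing property {prop!r}")
            missing = [r for r in CANONICAL_RESIDUES if r not in self.values[prop]]
            if missing:
                raise ValueError(f"property {prop!r} missing residues {missing}")
        total = sum(self.values["frequency"].values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"residue frequencies sum to {total}, expected 1")


def load_property_table(path=None) -> PropertyTable:
    """Load a whitespace-delimited property table (default: packaged table).

    Frequencies are renormalized to sum exactly to 1, so tables printed at
    fixed precision remain valid.
    """
    path = _data_path("aa_properties.tsv") if path is None else Path(path)
    values: dict = {p: {} for p in PROPERTIES}
    for line in open(path):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        cells = s.split()
        if len(cells) != 1 + len(PROPERTIES):
            raise ValueError(f"{path}: bad property row {s!r}")
        res = cells[0]
        for prop, cell in zip(PROPERTIES, cells[1:]):
            values[prop][res] = float(cell)
    total = sum(values["frequency"].values())
    values["frequency"] = {r: v / total for r, v in values["frequency"].items()}
    return PropertyTable(values)


def lookup_property(table: PropertyTable, residue: str, prop: str) -> float:
    if prop not in PROPERTIES:
        raise ValueError(f"unknown property {prop!r}")
    if residue not in CANONICAL_RESIDUES:
        raise ValueError(f"unknown residue {residue!r}")
    return table.values[prop][residue]


def property_delta(table: PropertyTable, wt: str, mut: str, prop: str) -> float:
    """Signed change of a quantitative property: value(mut) - value(wt)."""
    return lookup_property(table, mut, prop) - lookup_property(table, wt, prop)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20x20 integer substitution scores keyed by residue pair."""

    scores: dict
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        for a in CANONICAL_RESIDUES:
            for b in CANONICAL_RESIDUES:
                if (a, b) not in self.scores:
                    raise ValueError(f"missing pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValueError(f"asymmetric scores for ({a},{b})")


def load_substitution_matrix(path=None, name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Parse an NCBI-format matrix file ('#' comments, residue header row).

    Rows/columns beyond the 20 canonical residues (B, Z, X, *) are ignored.
    """
    path = _data_path("blosum62.txt") if path is None else Path(path)
    header: list[str] = []
    scores: dict = {}
    for line in open(path):
        s = line.rstrip()
        if not s or s.lstrip().startswith("#"):
            continue
        cells = s.split()
        if not header:
            header = cells
            continue
        row_res = cells[0]
        if row_res not in CANONICAL_RESIDUES:
            continue
        for col_res, cell in zip(header, cells[1:]):
            if col_res in CANONICAL_RESIDUES:
                scores[(row_res, col_res)] = int(cell)
    if len(scores) != 400:
        raise ValueError(f"{path}: expected 400 canonical entries, got {len(scores)}")
    return SubstitutionMatrix(scores, name=name)


def substitution_score(matrix: SubstitutionMatrix, wt: str, mut: str) -> int:
    for res in (wt, mut):
        if res not in CANONICAL_RESIDUES:
            raise ValueError(f"unknown residue {res!r}")
    return matrix.scores[(wt, mut)]
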
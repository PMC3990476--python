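"""Core record types and readers/writers for the external file formats.

A point mutation is identified by (gene, 1-based protein position, wild-type
residue, mutant residue).  Mutation tables are TSV files with a header; the
training set is defined by the recurrence filter :func:`partition_by_recurrence`
(mutations observed more than once in tumour catalogues form the positive
training set).

Feature matrices are serialized either as ARFF (nominal attributes declared
with their level sets, class attribute last) or as CSV with a typed schema
header so that both dialects round-trip exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class Label(enum.Enum):
    """Training label of a mutation: disease (D), non-disease (ND) or unknown."""

    DISEASE = "D"
    NON_DISEASE = "ND"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Label":
        t = text.strip()
        for member in cls:
            if member.value.lower() == t.lower() or member.name.lower() == t.lower():
                return member
        raise ValueError(f"unknown label {text!r}; expected D, ND or unknown")


@dataclass(frozen=True)
class Mutation:
    """One amino-acid substitution.

    Parameters
    ----------
    gene : str
        Gene symbol (e.g. ``EGFR``).
    position : int
        1-based position in the protein sequence.
    wt, mut : str
        One-letter wild-type and mutant residue codes; must differ and be
        canonical.
    count : int
        Number of independent observations (tumour samples); default 1.
    """

    gene: str
    position: int
    wt: str
    mut: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, res in (("wt", self.wt), ("mut", self.mut)):
            if res not in CANONICAL_RESIDUES:
                raise ValueError(f"non-canonical {name} residue {res!r}")
        if self.wt == self.mut:
            raise ValueError(f"wild-type equals mutant ({self.wt}{self.position}{self.mut})")
        if self.count < 0:
            raise ValueError("count must be nonnegative")

    @property
    def key(self) -> tuple:
        return (self.gene, self.position, self.wt, self.mut)

    def __str__(self) -> str:  # e.g. "EGFR L858R"
        return f"{self.gene} {self.wt}{self.position}{self.mut}"


@dataclass(frozen=True)
class LabeledMutation:
    mutation: Mutation
    label: Label = Label.UNKNOWN


class MutationSet:
    """Ordered, key-unique collection of labeled mutations."""

    def __init__(self, items: Iterable[LabeledMutation] = (), provenance: str = ""):
        self.items: list[LabeledMutation] = []
        self.provenance = provenance
        seen: set[tuple] = set()
        for lm in items:
            if lm.mutation.key in seen:
                raise ValueError(f"duplicate mutation {lm.mutation}")
            seen.add(lm.mutation.key)
            self.items.append(lm)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[LabeledMutation]:
        return iter(self.items)

    def mutations(self) -> list[Mutation]:
        return [lm.mutation for lm in self.items]

    def labels(self) -> list[Label]:
        return [lm.label for lm in self.items]

    def label_counts(self) -> dict:
        counts: dict = {}
        for lm in self.items:
            counts[lm.label] = counts.get(lm.label, 0) + 1
        return counts

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationSet) and self.items == other.items


def read_mutation_table(path, label: Label = Label.UNKNOWN) -> MutationSet:
    """Read a mutation TSV (columns gene, position, wt, mut [, count] [, label]).

    An explicit ``label`` column overrides the ``label`` argument; a missing
    ``count`` column defaults to 1.  Malformed rows raise with the offending
    line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty mutation table")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    required = ["gene", "position", "wt", "mut"]
    for col in required:
        if col not in header:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    items = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < len(required):
            raise ValueError(f"{path}:{lineno}: expected >= {len(required)} columns")
        try:
            mut = Mutation(
                gene=cells[idx["gene"]].strip(),
                position=int(cells[idx["position"]]),
                wt=cells[idx["wt"]].strip(),
                mut=cells[idx["mut"]].strip(),
                count=int(cells[idx["count"]]) if "count" in idx and cells[idx["count"]].strip() else 1,
            )
            row_label = label
            if "label" in idx and len(cells) > idx["label"] and cells[idx["label"]].strip():
                row_label = Label.parse(cells[idx["label"]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        items.append(LabeledMutation(mut, row_label))
    try:
        return MutationSet(items, provenance=str(path))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_mutation_table(ms: MutationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tposition\twt\tmut\tcount\tlabel\n")
        for lm in ms:
            m = lm.mutation
            fh.write(f"{m.gene}\t{m.position}\t{m.wt}\t{m.mut}\t{m.count}\t{lm.label.value}\n")


def partition_by_recurrence(ms: MutationSet, min_count: int) -> tuple[MutationSet, MutationSet]:
    """Split by observation count: ``train`` holds items with count >= min_count.

    Recurrently observed somatic mutations are far more likely to be causative
    than singletons, so the recurrent subset defines the positive training set
    while singletons are held out for later prioritization.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    train = [lm for lm in ms if lm.mutation.count >= min_count]
    heldout = [lm for lm in ms if lm.mutation.count < min_count]
    return (
        MutationSet(train, provenance=f"{ms.provenance} (count>={min_count})"),
        MutationSet(heldout, provenance=f"{ms.provenance} (count<{min_count})"),
    )


# ---------------------------------------------------------------------------
# Feature-matrix serialization (ARFF and schema-headed CSV)

def _quote(value: str) -> str:
    if any(ch in value for ch in " \t,{}%'\""):
        return "'" + value.replace("'", "\\'") + "'"
    return value


def _format_number(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "?"
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_feature_matrix(matrix, path, dialect: str = "arff", relation: str = "mutations") -> None:
    """Serialize a FeatureMatrix; ``dialect`` is ``arff`` or ``csv``.

    ARFF declares nominal attributes with their (lexicographically sorted)
    level sets and the class attribute last; the CSV dialect carries the same
    schema in ``#`` comment lines so both round-trip exactly.
    """
    if matrix.n_instances == 0:
        raise ValueError("no instances")
    if dialect not in ("arff", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    attrs = list(matrix.attributes)
    with open(path, "w") as fh:
        if dialect == "arff":
            fh.write(f"@relation {_quote(relation)}\n\n")
            for a in attrs:
                if a.kind == "numeric":
                    fh.write(f"@attribute {_quote(a.name)} numeric\n")
                else:
                    levels = ",".join(_quote(l) for l in sorted(a.levels))
                    fh.write(f"@attribute {_quote(a.name)} {{{levels}}}\n")
            if matrix.has_class:
                fh.write("@attribute class {D,ND}\n")
            fh.write("\n@data\n")
            for i in range(matrix.n_instances):
                cells = []
                for a in attrs:
                    v = matrix.value(i, a.name)
                    if a.kind == "numeric":
                        cells.append(_format_number(v))
                    else:
                        cells.append("?" if v is None else _quote(v))
                if matrix.has_class:
                    cells.append(matrix.class_labels[i].value)
                fh.write(",".join(cells) + "\n")
        else:
            for a in attrs:
                if a.kind == "numeric":
                    fh.write(f"# attribute\t{a.name}\tnumeric\n")
                else:
                    fh.write(f"# attribute\t{a.name}\tnominal\t{'|'.join(sorted(a.levels))}\n")
            if matrix.has_class:
                fh.write("# attribute\tclass\tnominal\tD|ND\n")
            names = [a.name for a in attrs] + (["class"] if matrix.has_class else [])
            fh.write("\t".join(names) + "\n")
            for i in range(matrix.n_instances):
                cells = []
                for a in attrs:
                    v = matrix.value(i, a.name)
                    if a.kind == "numeric":
                        cells.append(_format_number(v))
                    else:
                        cells.append("?" if v is None else v)
                if matrix.has_class:
                    cells.append(matrix.class_labels[i].value)
                fh.write("\t".join(cells) + "\n")


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == "'" and token[-1] == "'":
        return token[1:-1].replace("\\'", "'")
    return token


def _split_arff_row(line: str) -> list[str]:
    out, cur, in_q = [], "", False
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "\\" and in_q and i + 1 < len(line):
            cur += line[i + 1]
            i += 2
            continue
        if ch == "'":
            in_q = not in_q
        elif ch == "," and not in_q:
            out.append(cur)
            cur = ""
        else:
            cur += ch
        i += 1
    out.append(cur)
    return [c.strip() for c in out]


def read_feature_matrix(path, dialect: Optional[str] = None):
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    from .feature_build import Attribute, FeatureMatrix

    path = Path(path)
    if dialect is None:
        dialect = "arff" if path.suffix.lower() == ".arff" else "csv"
    attrs: list[Attribute] = []
    rows: list[list] = []
    class_labels: list[Label] = []
    has_class = False
    lines = open(path).read().splitlines()
    if dialect == "arff":
        in_data = False
        for line in lines:
            s = line.strip()
            if not s or s.startswith("%"):
                continue
            low = s.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                rest = s[len("@attribute"):].strip()
                if rest.endswith("}"):
                    name_part, levels_part = rest.split("{", 1)
                    name = _unquote(name_part.strip())
                    levels = tuple(_unquote(t) for t in _split_arff_row(levels_part.rstrip("}")))
                    if name == "class":
                        has_class = True
                    else:
                        attrs.append(Attribute(name, "nominal", levels))
                else:
                    name = _unquote(rest.rsplit(None, 1)[0])
                    attrs.append(Attribute(name, "numeric"))
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            if in_data:
                cells = _split_arff_row(s)
                row = []
                for a, c in zip(attrs, cells):
                    if c == "?":
                        row.append(float("nan") if a.kind == "numeric" else None)
                    elif a.kind == "numeric":
                        row.append(float(c))
                    else:
                        row.append(_unquote(c))
                rows.append(row)
                if has_class:
                    class_labels.append(Label.parse(cells[len(attrs)]))
    else:
        header_seen = False
        for line in lines:
            if line.startswith("# attribute\t"):
                parts = line[len("# attribute\t"):].split("\t")
                name, kind = parts[0], parts[1]
                if name == "class":
                    has_class = True
                elif kind == "numeric":
                    attrs.append(Attribute(name, "numeric"))
                else:
                    attrs.append(Attribute(name, "nominal", tuple(parts[2].split("|"))))
                continue
            if not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            cells = line.split("\t")
            row = []
            for a, c in zip(attrs, cells):
                if c == "?":
                    row.append(float("nan") if a.kind == "numeric" else None)
                elif a.kind == "numeric":
                    row.append(float(c))
                else:
                    row.append(c)
            rows.append(row)
            if has_class:
                class_labels.append(Label.parse(cells[len(attrs)]))
    return FeatureMatrix(attrs, rows, class_labels if has_class else None)
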
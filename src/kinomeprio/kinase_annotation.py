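"""Kinase classification lookup and structural/functional site features.

Protein kinases are classified hierarchically into major groups (TK, CMGC,
AGC, ...) and families within groups (EGFR, Src, ...).  The catalytic domain
is organized into 11 conserved subdomains (I-XI); a mutation's subdomain,
whether it falls at an annotated binding site or post-translationally
modified residue, and whether it lies inside the kinase domain at all are
used as features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .datamodel_io import Mutation

SUBDOMAIN_LABELS = ("I", "II", "III", "IV", "V", "VIa", "VIb", "VII", "VIII", "IX", "X", "XI")
NO_SUBDOMAIN = "none"
NA = "NA"


@dataclass(frozen=True)
class KinaseRecord:
    """Per-gene annotation: domain span, subdomain spans, functional sites.

    All coordinates are 1-based inclusive protein positions.
    """

    gene: str
    group: str
    family: str
    domain_span: tuple  # (start, end)
    subdomain_spans: dict = field(default_factory=dict)  # label -> (start, end)
    binding_sites: dict = field(default_factory=dict)  # position -> site kind
    modifications: dict = field(default_factory=dict)  # position -> modification kind

    def __post_init__(self) -> None:
        start, end = self.domain_span
        if start > end or start < 1:
            raise ValueError(f"{self.gene}: bad domain span {self.domain_span}")
        spans = sorted(self.subdomain_spans.items(), key=lambda kv: kv[1][0])
        prev_end = 0
        for label, (s, e) in spans:
            if s > e:
                raise ValueError(f"{self.gene}: bad subdomain span {label} {s}-{e}")
            if s <= prev_end:
                raise ValueError(f"{self.gene}: overlapping subdomain spans at {label}")
            if s < start or e > end:
                raise ValueError(f"{self.gene}: subdomain {label} outside kinase domain")
            prev_end = e


@dataclass(frozen=True)
class SiteFeatures:
    subdomain: str
    is_binding_site: str  # "yes" or "NA"
    modification: str  # kind or "NA"
    in_pk_domain: int  # 0/1


def load_classification(path) -> dict:
    """Read a classification TSV (gene, group, family) into an upper-cased map."""
    table: dict = {}
    lines = open(path).read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise ValueError(f"{path}:{lineno}: expected gene, group, family")
        table[cells[0].strip().upper()] = (cells[1].strip(), cells[2].strip())
    return table


def classify_gene(gene: str, table: dict) -> tuple:
    """Return (group, family) for a gene; lookup is case-insensitive."""
    key = gene.strip().upper()
    if key not in table:
        raise KeyError(f"gene {gene!r} not in kinase classification table")
    return table[key]


def load_annotations(path, classification: dict) -> dict:
    """Read an annotation TSV (gene, kind, start, end, value) into KinaseRecords.

    Kinds: ``domain`` (kinase-domain span), ``subdomain`` (value = label I-XI),
    ``binding_site`` (value = site kind, start==end) and ``modification``
    (value = modification kind, start==end).
    """
    raw: dict = {}
    lines = open(path).read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        cells = line.split("\t")
        if len(cells) < 5:
            raise ValueError(f"{path}:{lineno}: expected gene, kind, start, end, value")
        gene, kind = cells[0].strip().upper(), cells[1].strip()
        start, end, value = int(cells[2]), int(cells[3]), cells[4].strip()
        entry = raw.setdefault(gene, {"domain": None, "subdomains": {}, "binding": {}, "mods": {}})
        if kind == "domain":
            entry["domain"] = (start, end)
        elif kind == "subdomain":
            entry["subdomains"][value] = (start, end)
        elif kind == "binding_site":
            entry["binding"][start] = value
        elif kind == "modification":
            entry["mods"][start] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown annotation kind {kind!r}")
    records: dict = {}
    for gene, entry in raw.items():
        if entry["domain"] is None:
            raise ValueError(f"{path}: gene {gene} has no kinase-domain span")
        group, family = classify_gene(gene, classification)
        records[gene] = KinaseRecord(
            gene=gene,
            group=group,
            family=family,
            domain_span=entry["domain"],
            subdomain_spans=entry["subdomains"],
            binding_sites=entry["binding"],
            modifications=entry["mods"],
        )
    return records


def site_features(mut: Mutation, rec: KinaseRecord) -> SiteFeatures:
    """Structural/functional features of a mutation site; total over positions."""
    pos = mut.position
    subdomain = NO_SUBDOMAIN
    for label, (s, e) in rec.subdomain_spans.items():
        if s <= pos <= e:
            subdomain = label
            break
    start, end = rec.domain_span
    return SiteFeatures(
        subdomain=subdomain,
        is_binding_site="yes" if pos in rec.binding_sites else NA,
        modification=rec.modifications.get(pos, NA),
        in_pk_domain=int(start <= pos <= end),
    )
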
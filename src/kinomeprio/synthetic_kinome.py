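"""Synthetic kinome generator: alignments, annotations and labeled mutations.

Emulates the statistical structure the pipeline assumes, so every stage can
run end-to-end without any database download: a hierarchy of kinase groups
and families with per-column conservation that decays with evolutionary
depth (family > group > all-kinase), subdomain/binding-site/modification
annotations on a shared domain coordinate system, and a labeled mutation set
whose class sizes default to the 226 disease / 331 benign structure of the
somatic-catalogue / polymorphism training data.

The effect model plants the signal the classifiers are meant to learn:
disease mutations are drawn preferentially at conserved columns, at
annotated functional sites, and in a subset of "oncogene" families, with
odds multiplied by ``enrichment_odds`` per matched property.  Benign
mutations are uniform background.  Sequence columns are independent: the
consensus residue is drawn with the configured conservation probability,
otherwise a uniform alternative.  Real kinase composition, phylogeny and
mutation spectra are deliberately not imitated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import derive_seed
from .conservation import DepthAlignment, read_depth_alignment, write_depth_alignment
from .datamodel_io import (
    CANONICAL_RESIDUES,
    Label,
    LabeledMutation,
    Mutation,
    MutationSet,
)
from .feature_build import KinomeResources
from .kinase_annotation import KinaseRecord, SUBDOMAIN_LABELS, load_annotations, load_classification
from .residue_props import load_property_table, load_substitution_matrix


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic kinome.

    Class sizes default to 226 disease / 331 benign; conservation levels are
    (conserved-column, background-column) pairs per depth, decreasing with
    evolutionary depth.
    """

    n_groups: int = 4
    families_per_group: int = 2
    genes_per_family: int = 6
    seqs_per_family_alignment: int = 50
    seqs_per_group_alignment: int = 60
    seqs_per_all_alignment: int = 80
    domain_length: int = 250
    frac_conserved_columns: float = 0.4
    cons_family: tuple = (0.95, 0.50)
    cons_group: tuple = (0.80, 0.35)
    cons_all: tuple = (0.60, 0.15)
    n_positives: int = 226
    n_negatives: int = 331
    enrichment_odds: float = 8.0
    substitution_odds: float = 3.0
    oncogene_family_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for pair in (self.cons_family, self.cons_group, self.cons_all):
            if not all(0.0 <= c <= 1.0 for c in pair):
                raise ValueError("conservation levels must lie in [0, 1]")
        if not 0.0 <= self.frac_conserved_columns <= 1.0:
            raise ValueError("frac_conserved_columns must lie in [0, 1]")
        if min(self.n_positives, self.n_negatives) < 0 or self.domain_length < 30:
            raise ValueError("invalid counts")


@dataclass
class SyntheticKinome:
    """Generated study system: sequences, alignments and annotation tables."""

    config: SimConfig
    classification: dict  # gene -> (group, family)
    annotations: dict  # gene -> KinaseRecord
    reference_seqs: dict  # gene -> ungapped domain sequence
    family_alignments: dict  # family -> DepthAlignment
    group_alignments: dict  # group -> DepthAlignment
    all_alignment: DepthAlignment
    conserved_mask: np.ndarray  # (domain_length,) bool
    oncogene_families: tuple
    functional_positions: tuple

    def alignments_for(self, gene: str) -> dict:
        group, family = self.classification[gene]
        return {
            "family": self.family_alignments[family].with_reference(gene),
            "group": self.group_alignments[group].with_reference(gene),
            "all_kinase": self.all_alignment.with_reference(gene),
        }

    def resources(self) -> KinomeResources:
        return KinomeResources(
            classification=self.classification,
            annotations=self.annotations,
            properties=load_property_table(),
            matrix=load_substitution_matrix(),
            alignments={g: self.alignments_for(g) for g in self.classification},
        )


def _sample_sequences(rng, consensus: np.ndarray, cons_levels: np.ndarray,
                      n_seqs: int) -> np.ndarray:
    """Draw aligned rows: consensus residue with per-column probability, else a
    uniform alternative residue."""
    length = len(consensus)
    keep = rng.random((n_seqs, length)) < cons_levels
    alt = rng.integers(0, 19, size=(n_seqs, length))
    # skip over the consensus index so alternatives are uniform on the other 19
    alt = np.where(alt >= consensus, alt + 1, alt)
    return np.where(keep, consensus, alt)


def _to_str(codes: np.ndarray) -> str:
    return "".join(CANONICAL_RESIDUES[c] for c in codes)


def _mutate_consensus(rng, consensus: np.ndarray, prob: float) -> np.ndarray:
    flip = rng.random(len(consensus)) < prob
    alt = rng.integers(0, 19, size=len(consensus))
    alt = np.where(alt >= consensus, alt + 1, alt)
    return np.where(flip, alt, consensus)


def generate_kinome(cfg: SimConfig) -> SyntheticKinome:
    """Generate the full synthetic kinome deterministically from cfg.seed."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "kinome"))
    L = cfg.domain_length
    conserved = np.zeros(L, dtype=bool)
    conserved[rng.choice(L, size=round(cfg.frac_conserved_columns * L), replace=False)] = True

    def levels(pair):
        return np.where(conserved, pair[0], pair[1])

    c_fam, c_grp, c_all = levels(cfg.cons_family), levels(cfg.cons_group), levels(cfg.cons_all)
    all_consensus = rng.integers(0, 20, size=L)

    groups = [f"GRP{g + 1}" for g in range(cfg.n_groups)]
    classification: dict = {}
    reference_seqs: dict = {}
    family_alignments: dict = {}
    group_alignments: dict = {}
    all_rows: list = []
    gene_no = 0
    family_of_group: dict = {}
    for group in groups:
        group_consensus = _mutate_consensus(rng, all_consensus, 0.3)
        group_gene_rows: list = []
        for f in range(cfg.families_per_group):
            family = f"{group}_{chr(ord('A') + f)}"
            family_of_group.setdefault(group, []).append(family)
            family_consensus = _mutate_consensus(rng, group_consensus, 0.3)
            genes = []
            for _ in range(cfg.genes_per_family):
                gene_no += 1
                genes.append(f"KIN{gene_no:03d}")
            gene_rows = _sample_sequences(rng, family_consensus, c_fam, len(genes))
            n_bg = max(cfg.seqs_per_family_alignment - len(genes), 0)
            bg_rows = _sample_sequences(rng, family_consensus, c_fam, n_bg)
            seqs = [(g, _to_str(row)) for g, row in zip(genes, gene_rows)]
            seqs += [(f"{family}_bg{i + 1}", _to_str(row)) for i, row in enumerate(bg_rows)]
            family_alignments[family] = DepthAlignment("family", tuple(seqs), genes[0])
            for g, row in zip(genes, gene_rows):
                classification[g] = (group, family)
                reference_seqs[g] = _to_str(row)
                group_gene_rows.append((g, _to_str(row)))
                all_rows.append((g, _to_str(row)))
        n_bg = max(cfg.seqs_per_group_alignment - len(group_gene_rows), 0)
        bg = _sample_sequences(rng, group_consensus, c_grp, n_bg)
        seqs = tuple(group_gene_rows + [(f"{group}_bg{i + 1}", _to_str(r)) for i, r in enumerate(bg)])
        group_alignments[group] = DepthAlignment("group", seqs, group_gene_rows[0][0])

    n_bg = max(cfg.seqs_per_all_alignment - len(all_rows), 0)
    bg = _sample_sequences(rng, all_consensus, c_all, n_bg)
    all_alignment = DepthAlignment(
        "all_kinase",
        tuple(all_rows + [(f"ePK_bg{i + 1}", _to_str(r)) for i, r in enumerate(bg)]),
        all_rows[0][0])

    # Shared domain coordinate system: kinase domain tiled by the canonical
    # subdomains (I-XI, VI split into VIa/VIb) plus a few fixed functional sites.
    domain_span = (6, L - 5)
    subdomain_spans = {}
    # divide the domain into equal blocks; each subdomain occupies the
    # first ~60% of its block, leaving inter-subdomain linkers
    block = (domain_span[1] - domain_span[0] + 1) // len(SUBDOMAIN_LABELS)
    span_len = max(1, round(block * 0.6))
    for i, label in enumerate(SUBDOMAIN_LABELS):
        start = domain_span[0] + i * block
        subdomain_spans[label] = (start, start + span_len - 1)
    binding = {subdomain_spans["I"][0] + 2: "ATP",
               subdomain_spans["III"][0] + 2: "ATP",
               subdomain_spans["VIb"][0] + 2: "substrate"}
    mods = {subdomain_spans["VIII"][0] + 3: "Phosphorylation",
            subdomain_spans["II"][0] + 5: "Phosphorylation"}
    annotations = {
        gene: KinaseRecord(gene=gene, group=grp, family=fam, domain_span=domain_span,
                           subdomain_spans=dict(subdomain_spans),
                           binding_sites=dict(binding), modifications=dict(mods))
        for gene, (grp, fam) in classification.items()
    }

    families = sorted(family_alignments)
    n_onco = max(1, round(cfg.oncogene_family_fraction * len(families)))
    oncogene_families = tuple(families[:n_onco])
    return SyntheticKinome(
        config=cfg, classification=classification, annotations=annotations,
        reference_seqs=reference_seqs, family_alignments=family_alignments,
        group_alignments=group_alignments, all_alignment=all_alignment,
        conserved_mask=conserved, oncogene_families=oncogene_families,
        functional_positions=tuple(sorted(set(binding) | set(mods))))


def _site_enrichment(kinome: SyntheticKinome, gene: str, position: int) -> int:
    z = 0
    if kinome.conserved_mask[position - 1]:
        z += 1
    if position in kinome.functional_positions:
        z += 1
    if kinome.classification[gene][1] in kinome.oncogene_families:
        z += 1
    rec = kinome.annotations[gene]
    if any(s <= position <= e for s, e in rec.subdomain_spans.values()):
        z += 1
    return z


def _biased_substitution(rng, wt: str, odds: float, matrix, radical: bool) -> str:
    """Mutant residue draw weighted by BLOSUM62 exchangeability.

    Disease mutations (``radical=True``) favour low-scoring (radical)
    substitutions with weight odds**(-score); benign polymorphisms favour
    conservative ones.  odds=1 recovers the uniform draw.
    """
    others = [r for r in CANONICAL_RESIDUES if r != wt]
    scores = np.array([matrix.scores[(wt, r)] for r in others], dtype=float)
    sign = -1.0 if radical else 1.0
    w = odds ** (sign * scores)
    return others[int(rng.choice(len(others), p=w / w.sum()))]


def generate_labeled_mutations(cfg: SimConfig, kinome: SyntheticKinome) -> MutationSet:
    """Labeled mutation set: positives enriched per the effect model, negatives
    uniform, wild-types read off the reference sequences, no duplicate keys."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "mutations"))
    genes = sorted(kinome.classification)
    sites = [(g, p) for g in genes for p in range(1, cfg.domain_length + 1)]
    if cfg.n_positives + cfg.n_negatives > len(sites):
        raise ValueError("requested mutation counts exceed available sites")
    weights = np.array([cfg.enrichment_odds ** _site_enrichment(kinome, g, p)
                        for g, p in sites], dtype=float)
    items: list = []

    def draw(n: int, w: np.ndarray, available: np.ndarray) -> list:
        w = np.where(available, w, 0.0)
        idx = rng.choice(len(sites), size=n, replace=False, p=w / w.sum())
        available[idx] = False
        return [sites[i] for i in idx]

    available = np.ones(len(sites), dtype=bool)
    pos_sites = draw(cfg.n_positives, weights, available)
    neg_sites = draw(cfg.n_negatives, np.ones(len(sites)), available)
    subst = load_substitution_matrix()
    for (g, p), label in ([(s, Label.DISEASE) for s in pos_sites]
                          + [(s, Label.NON_DISEASE) for s in neg_sites]):
        wt = kinome.reference_seqs[g][p - 1]
        mut = _biased_substitution(rng, wt, cfg.substitution_odds, subst,
                                   radical=label is Label.DISEASE)
        count = 2 + int(rng.poisson(1.5)) if label is Label.DISEASE else 1
        items.append(LabeledMutation(Mutation(g, p, wt, mut, count=count), label))
    return MutationSet(items, provenance=f"synthetic kinome (seed {cfg.seed})")


def generate_unlabeled_mutations(cfg: SimConfig, kinome: SyntheticKinome, n: int,
                                 exclude: MutationSet = None) -> MutationSet:
    """Singleton mutations of unknown status for prioritization: half drawn
    from the effect model, half uniform background."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "unknowns"))
    taken = {lm.mutation.key[:2] for lm in exclude} if exclude else set()
    genes = sorted(kinome.classification)
    sites = [(g, p) for g in genes for p in range(1, cfg.domain_length + 1)
             if (g, p) not in taken]
    if n > len(sites):
        raise ValueError("requested mutation count exceeds available sites")
    weights = np.array([cfg.enrichment_odds ** _site_enrichment(kinome, g, p)
                        for g, p in sites], dtype=float)
    mixed = 0.5 * weights / weights.sum() + 0.5 / len(sites)
    idx = rng.choice(len(sites), size=n, replace=False, p=mixed / mixed.sum())
    items = []
    for i in idx:
        g, p = sites[i]
        wt = kinome.reference_seqs[g][p - 1]
        items.append(LabeledMutation(Mutation(g, p, wt, _random_other_residue(rng, wt)),
                                     Label.UNKNOWN))
    return MutationSet(items, provenance="synthetic unknowns")


def _random_other_residue(rng, wt: str) -> str:
    k = int(rng.integers(0, 19))
    wt_idx = CANONICAL_RESIDUES.index(wt)
    if k >= wt_idx:
        k += 1
    return CANONICAL_RESIDUES[k]


# ---------------------------------------------------------------------------
# Round-trip through the external file formats

def write_kinome(kinome: SyntheticKinome, directory) -> None:
    """Write classification/annotation TSVs and aligned FASTA files."""
    directory = Path(directory)
    (directory / "alignments").mkdir(parents=True, exist_ok=True)
    with open(directory / "classification.tsv", "w") as fh:
        fh.write("gene\tgroup\tfamily\n")
        for gene, (grp, fam) in sorted(kinome.classification.items()):
            fh.write(f"{gene}\t{grp}\t{fam}\n")
    with open(directory / "annotations.tsv", "w") as fh:
        fh.write("gene\tkind\tstart\tend\tvalue\n")
        for gene, rec in sorted(kinome.annotations.items()):
            s, e = rec.domain_span
            fh.write(f"{gene}\tdomain\t{s}\t{e}\tkinase_domain\n")
            for label, (ss, ee) in rec.subdomain_spans.items():
                fh.write(f"{gene}\tsubdomain\t{ss}\t{ee}\t{label}\n")
            for pos, kind in sorted(rec.binding_sites.items()):
                fh.write(f"{gene}\tbinding_site\t{pos}\t{pos}\t{kind}\n")
            for pos, kind in sorted(rec.modifications.items()):
                fh.write(f"{gene}\tmodification\t{pos}\t{pos}\t{kind}\n")
    for family, aln in sorted(kinome.family_alignments.items()):
        write_depth_alignment(aln, directory / "alignments" / f"family_{family}.fasta")
    for group, aln in sorted(kinome.group_alignments.items()):
        write_depth_alignment(aln, directory / "alignments" / f"group_{group}.fasta")
    write_depth_alignment(kinome.all_alignment, directory / "alignments" / "all_kinase.fasta")


def load_resources(directory) -> KinomeResources:
    """Rebuild KinomeResources from a directory written by :func:`write_kinome`."""
    directory = Path(directory)
    classification = load_classification(directory / "classification.tsv")
    annotations = load_annotations(directory / "annotations.tsv", classification)
    family_alns: dict = {}
    group_alns: dict = {}
    for path in sorted((directory / "alignments").glob("family_*.fasta")):
        family_alns[path.stem[len("family_"):]] = read_depth_alignment(path, "family")
    for path in sorted((directory / "alignments").glob("group_*.fasta")):
        group_alns[path.stem[len("group_"):]] = read_depth_alignment(path, "group")
    all_aln = read_depth_alignment(directory / "alignments" / "all_kinase.fasta", "all_kinase")
    alignments = {}
    for gene, (grp, fam) in classification.items():
        alignments[gene] = {
            "family": family_alns[fam].with_reference(gene),
            "group": group_alns[grp].with_reference(gene),
            "all_kinase": all_aln.with_reference(gene),
        }
    return KinomeResources(
        classification=classification, annotations=annotations,
        properties=load_property_table(), matrix=load_substitution_matrix(),
        alignments=alignments)
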
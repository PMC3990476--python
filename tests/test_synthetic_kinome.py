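"""Generator contracts: determinism, conservation calibration, effect model."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from kinomeprio.conservation import build_profile, column_frequency
from kinomeprio.datamodel_io import Label
from kinomeprio.synthetic_kinome import (
    SimConfig,
    generate_kinome,
    generate_labeled_mutations,
    generate_unlabeled_mutations,
    load_resources,
    write_kinome,
)


class TestConfigValidation:
    def test_conservation_levels_must_be_fractions(self):
        with pytest.raises(ValueError):
            SimConfig(cons_family=(1.2, 0.5))

    def test_defaults_mirror_training_class_sizes(self):
        cfg = SimConfig()
        assert (cfg.n_positives, cfg.n_negatives) == (226, 331)


class TestKinomeGeneration:
    def test_same_seed_reproduces_identical_files(self, small_cfg, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_kinome(generate_kinome(small_cfg), a)
        write_kinome(generate_kinome(small_cfg), b)
        for f in sorted(a.rglob("*")):
            if f.is_file():
                assert f.read_bytes() == (b / f.relative_to(a)).read_bytes()

    def test_family_conservation_matches_configured_levels(self):
        """Empirical consensus frequency per family column tracks its
        configured conservation at 100 sequences (binomial concentration:
        per-column within 3 standard deviations, tight on average)."""
        cfg = SimConfig(n_groups=1, families_per_group=1, genes_per_family=3,
                        seqs_per_family_alignment=100, domain_length=100,
                        cons_family=(0.9, 0.5), seed=21)
        kinome = generate_kinome(cfg)
        (family_aln,) = kinome.family_alignments.values()
        profile = build_profile(family_aln)
        deviations = {True: [], False: []}
        for col in range(cfg.domain_length):
            conserved = bool(kinome.conserved_mask[col])
            target = 0.9 if conserved else 0.5
            freq = column_frequency(profile, col, profile.consensus[col])
            assert abs(freq - target) < 0.16  # ~3 sd of Binomial(100, 0.5)/100
            deviations[conserved].append(freq - target)
        # modal-residue frequency is slightly upward-biased at low conservation,
        # but column averages stay close to the configured levels
        assert abs(np.mean(deviations[True])) < 0.02
        assert abs(np.mean(deviations[False])) < 0.05

    def test_full_conservation_gives_monomorphic_columns(self):
        cfg = SimConfig(n_groups=1, families_per_group=1, genes_per_family=3,
                        seqs_per_family_alignment=30, domain_length=60,
                        cons_family=(1.0, 1.0), seed=2)
        kinome = generate_kinome(cfg)
        (aln,) = kinome.family_alignments.values()
        rows = [s for _, s in aln.sequences]
        assert all(len(set(col)) == 1 for col in zip(*rows))

    def test_subdomains_tile_part_of_the_domain(self, small_kinome):
        from kinomeprio.kinase_annotation import SUBDOMAIN_LABELS

        rec = next(iter(small_kinome.annotations.values()))
        # 11 subdomains, with VI split into its VIa/VIb halves
        assert set(rec.subdomain_spans) == set(SUBDOMAIN_LABELS)
        assert {"VIa", "VIb"} <= set(rec.subdomain_spans)
        start, end = rec.domain_span
        for s, e in rec.subdomain_spans.values():
            assert start <= s <= e <= end

    def test_reference_rows_present_at_all_depths(self, small_kinome):
        gene = sorted(small_kinome.classification)[0]
        alns = small_kinome.alignments_for(gene)
        for depth, aln in alns.items():
            assert aln.reference_name == gene
            assert gene in dict(aln.sequences)


class TestLabeledMutations:
    def test_class_sizes_and_uniqueness(self, small_cfg, small_mutations):
        counts = small_mutations.label_counts()
        assert counts[Label.DISEASE] == small_cfg.n_positives
        assert counts[Label.NON_DISEASE] == small_cfg.n_negatives
        keys = [lm.mutation.key for lm in small_mutations]
        assert len(set(keys)) == len(keys)

    def test_wild_types_match_reference_sequences(self, small_kinome, small_mutations):
        for lm in small_mutations:
            m = lm.mutation
            assert small_kinome.reference_seqs[m.gene][m.position - 1] == m.wt

    def test_positives_are_recurrent(self, small_mutations):
        for lm in small_mutations:
            if lm.label is Label.DISEASE:
                assert lm.mutation.count >= 2
            else:
                assert lm.mutation.count == 1

    def test_excessive_counts_rejected(self):
        cfg = SimConfig(n_groups=1, families_per_group=1, genes_per_family=1,
                        domain_length=50, n_positives=40, n_negatives=40, seed=0)
        kinome = generate_kinome(cfg)
        with pytest.raises(ValueError, match="exceed"):
            generate_labeled_mutations(cfg, kinome)

    def test_null_effect_model_removes_conservation_signal(self):
        """With all enrichment odds at 1 the positive and negative family
        conservation distributions are statistically indistinguishable."""
        pvals = []
        for seed in range(6):
            cfg = SimConfig(n_groups=2, families_per_group=2, genes_per_family=3,
                            seqs_per_family_alignment=15, seqs_per_group_alignment=15,
                            seqs_per_all_alignment=15, domain_length=100,
                            n_positives=120, n_negatives=120,
                            enrichment_odds=1.0, substitution_odds=1.0, seed=seed)
            kinome = generate_kinome(cfg)
            ms = generate_labeled_mutations(cfg, kinome)
            cons = {Label.DISEASE: [], Label.NON_DISEASE: []}
            for lm in ms:
                m = lm.mutation
                cons[lm.label].append(float(kinome.conserved_mask[m.position - 1]))
            pvals.append(mannwhitneyu(cons[Label.DISEASE], cons[Label.NON_DISEASE]).pvalue)
        assert np.median(pvals) > 0.01

    def test_enriched_positives_sit_at_conserved_sites(self, small_kinome, small_mutations):
        frac = {}
        for label in (Label.DISEASE, Label.NON_DISEASE):
            hits = [small_kinome.conserved_mask[lm.mutation.position - 1]
                    for lm in small_mutations if lm.label is label]
            frac[label] = np.mean(hits)
        assert frac[Label.DISEASE] > frac[Label.NON_DISEASE] + 0.2


class TestUnlabeledMutations:
    def test_singletons_disjoint_from_training_sites(self, small_cfg, small_kinome,
                                                     small_mutations):
        unknown = generate_unlabeled_mutations(small_cfg, small_kinome, 30,
                                               exclude=small_mutations)
        train_sites = {lm.mutation.key[:2] for lm in small_mutations}
        for lm in unknown:
            assert lm.label is Label.UNKNOWN
            assert lm.mutation.count == 1
            assert lm.mutation.key[:2] not in train_sites


class TestRoundTrip:
    def test_written_kinome_reloads_into_equivalent_resources(self, small_cfg,
                                                              small_kinome, tmp_path):
        write_kinome(small_kinome, tmp_path)
        resources = load_resources(tmp_path)
        assert set(resources.classification) == set(small_kinome.classification)
        gene = sorted(resources.classification)[0]
        direct = small_kinome.alignments_for(gene)
        loaded = resources.alignments[gene]
        for depth in ("family", "group", "all_kinase"):
            assert loaded[depth].sequences == direct[depth].sequences
            assert loaded[depth].reference_name == gene
        assert resources.annotations[gene] == small_kinome.annotations[gene]
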
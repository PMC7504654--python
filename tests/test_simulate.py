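"""Synthetic-genome generator: determinism, conservation, codon model."""
import dataclasses

import numpy as np
import pytest

from famevol.io_core import SequenceRecord, read_fasta, read_gff3
from famevol.molevol import CodonAlignment, ng86_kaks, translate_cds
from famevol.promoter import reverse_complement
from famevol.simulate import (SimConfig, evolve_codon_pair, reverse_translate,
                              simulate_counts, simulate_ct,
                              simulate_family_genome, simulate_fourfold_pair)
from conftest import random_cds


class TestEvolveCodonPair:
    def test_zero_target_identical_copies(self, rng):
        anc = random_cds(rng, 50)
        a, b, ks, ka = evolve_codon_pair(anc, 0.0, 2.0, 0.2, 1)
        assert a == b == anc and ks == 0.0 and ka == 0.0

    def test_omega_zero_forbids_nonsynonymous_events(self, rng):
        anc = random_cds(rng, 100)
        a, b, ks, ka = evolve_codon_pair(anc, 0.3, 2.0, 0.0, 2)
        assert ka == 0.0
        assert translate_cds(a) == translate_cds(b) == translate_cds(anc)

    def test_negative_target_rejected(self, rng):
        with pytest.raises(ValueError):
            evolve_codon_pair(random_cds(rng, 10), -0.1, 2.0, 0.2, 1)

    def test_copies_stay_translatable(self, rng):
        anc = random_cds(rng, 80)
        a, b, *_ = evolve_codon_pair(anc, 0.5, 2.0, 0.5, 3)
        translate_cds(a)
        translate_cds(b)

    def test_realized_ks_concentrates_on_target(self):
        rng = np.random.default_rng(77)
        realized = []
        for _ in range(30):
            anc = reverse_translate(
                "M" + "".join(np.random.default_rng(1).choice(
                    list("ADEFGHIKLNPQRSTVWY"), 299)), rng)
            _, _, ks, _ = evolve_codon_pair(anc, 0.1, 2.0, 0.2, rng)
            realized.append(ks)
        cv = np.std(realized) / np.mean(realized)
        assert abs(np.mean(realized) - 0.2) < 0.03
        assert cv < 0.2

    def test_estimator_agrees_with_realized_truth(self):
        rng = np.random.default_rng(13)
        est_all, real_all = [], []
        for _ in range(40):
            anc = random_cds(rng, 300)
            a, b, rks, _ = evolve_codon_pair(anc, 0.1, 2.0, 0.2, rng)
            est_all.append(ng86_kaks(CodonAlignment("a", "b", a, b)).ks)
            real_all.append(rks)
        assert np.mean(est_all) == pytest.approx(np.mean(real_all), rel=0.1)


class TestFourfoldPairs:
    def test_all_columns_eligible(self, rng):
        from famevol.molevol import four_dtv
        a, b = simulate_fourfold_pair(150, 0.3, 2.0, rng)
        _, n = four_dtv(CodonAlignment("a", "b", a.residues, b.residues))
        assert n == 150

    def test_zero_divergence_identical(self, rng):
        a, b = simulate_fourfold_pair(100, 0.0, 2.0, rng)
        assert a.residues == b.residues


class TestGenomeGeneration:
    def test_same_seed_byte_identical(self):
        sg1 = simulate_family_genome(seed=5)
        sg2 = simulate_family_genome(seed=5)
        assert sg1.genome == sg2.genome
        assert sg1.cds == sg2.cds
        assert [dataclasses.asdict(p) for p in sg1.truth.pairs] == \
               [dataclasses.asdict(p) for p in sg2.truth.pairs]

    def test_planted_counts_match_config(self):
        cfg = SimConfig(seed=8)
        sg = simulate_family_genome(cfg)
        modes = [p.mode for p in sg.truth.pairs]
        assert modes.count("WGD") == cfg.wgd_blocks * cfg.family_pairs_per_block
        assert modes.count("TD") == cfg.tandem_pairs
        assert modes.count("PD") == cfg.proximal_pairs
        assert modes.count("TRD") == cfg.transposed_pairs
        assert modes.count("DD") == cfg.dispersed_pairs
        n_family = (2 * (modes.count("WGD") + cfg.tandem_pairs
                         + cfg.proximal_pairs + cfg.dispersed_pairs)
                    + cfg.transposed_pairs + cfg.singletons)
        assert len(sg.family_ids()) == n_family
        assert len(sg.truth.scaffold_genes) == cfg.scaffold_members
        classes = list(sg.truth.classes.values())
        assert classes.count("II") == cfg.class_ii_members

    def test_cds_matches_genome_slice_strand_aware(self):
        sg = simulate_family_genome(seed=6)
        for g in sg.annotation.genes[:40]:
            piece = sg.genome[g.chrom][g.start:g.end]
            if g.strand == "-":
                piece = reverse_complement(piece)
            assert piece == sg.cds[g.gene_id]

    def test_outputs_pass_io_round_trips(self, tmp_path):
        sg = simulate_family_genome(seed=6)
        paths = sg.write(tmp_path)
        genome = read_fasta(paths["genome.fa"], "nt")
        assert {r.id for r in genome} == set(sg.genome)
        ann = read_gff3(paths["genes.gff3"])
        for g in sg.annotation.genes:
            g2 = ann[g.gene_id]
            assert (g2.chrom, g2.start, g2.end, g2.strand, g2.rank) == \
                   (g.chrom, g.start, g.end, g.strand, g.rank)
        prots = read_fasta(paths["proteins.fa"], "aa")
        assert {r.id for r in prots} == set(sg.proteins)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            simulate_family_genome(SimConfig(genes_per_chromosome=4))


class TestCounts:
    def test_structural_zeros_and_present_minimum(self):
        sg = simulate_family_genome(seed=3)
        counts = simulate_counts(sg, seed=4)
        presence = sg.truth.presence
        assert (counts[~presence].fillna(0) == 0).all().all()
        assert (counts[presence].stack() >= 1).all()

    def test_silent_genes_never_expressed(self):
        sg = simulate_family_genome(seed=3)
        simulate_counts(sg, seed=4)
        silent = sg.truth.presence[~sg.truth.presence.any(axis=1)]
        assert len(silent) >= 1

    def test_percentages_recovered_exactly(self):
        from famevol.expression import (call_expressed, compute_rpkm,
                                        tissue_percentages)
        sg = simulate_family_genome(seed=3)
        counts = simulate_counts(sg, seed=4)
        expr = compute_rpkm(counts, sg.gene_lengths, sg.library_sizes)
        presence = call_expressed(expr)
        planted = tissue_percentages(sg.truth.presence)
        assert tissue_percentages(presence).equals(planted)

    def test_negative_binomial_moments(self):
        cfg = SimConfig(seed=3, nb_dispersion=0.1)
        sg = simulate_family_genome(cfg)
        draws = []
        for rep in range(60):
            counts = simulate_counts(sg, cfg, seed=rep)
            level = sg.truth.expression_level
            mu = (level * np.array([len(sg.cds[g])
                                    for g in level.index])[:, None]
                  * cfg.library_size / 1e9)
            mask = sg.truth.presence.values & (mu.values > 20)
            draws.append((counts.values[mask] / mu.values[mask]))
        ratio = np.concatenate(draws)
        # mean ratio ~ 1; truncation at one read only affects tiny means
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.05)
        # variance inflated over Poisson by the planted dispersion
        assert np.var(ratio) > 0.05
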
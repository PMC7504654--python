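"""Codon alignment, NG86 Ka/Ks, 4DTv, selection classes and dating."""
import math

import numpy as np
import pytest

from famevol.io_core import SequenceRecord
from famevol.molevol import (CodonAlignment, align_codon_pair,
                             assign_wgd_band, classify_selection, four_dtv,
                             ks_to_time, ng86_kaks)
from conftest import (affine_score_of_alignment, oracle_ng86,
                      optimal_protein_score, random_cds)

nt = lambda i, s: SequenceRecord(i, s, "nt")


class TestCodonAlignment:
    def test_identical_cds_align_without_gaps(self, rng):
        cds = random_cds(rng, 20)
        aln = align_codon_pair(nt("a", cds), nt("b", cds))
        assert aln.aligned_a == aln.aligned_b == cds

    def test_single_codon_deletion_gives_one_triplet_gap(self, rng):
        # a clearly alignable sequence with one codon removed
        cds = "ATGGAGTGGAAGCGCCCGTTCTACTGCCAC" * 2
        shorter = cds[:15] + cds[18:]
        aln = align_codon_pair(nt("a", cds), nt("b", shorter))
        assert aln.aligned_a == cds
        assert aln.aligned_b.count("-") == 3
        assert "---" in aln.aligned_b

    def test_internal_stop_reports_codon_index(self):
        with pytest.raises(ValueError, match="codon 1"):
            align_codon_pair(nt("a", "ATGTAAAAA"), nt("b", "ATGAAAAAA"))

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            align_codon_pair(nt("a", "ATGA"), nt("b", "ATG"))

    def test_terminal_stop_codons_stripped(self):
        aln = align_codon_pair(nt("a", "ATGAAATAA"), nt("b", "ATGAAATGA"))
        assert aln.aligned_a == aln.aligned_b == "ATGAAA"

    def test_achieves_independent_optimal_score(self, rng):
        for _ in range(25):
            la, lb = rng.integers(2, 11, size=2)
            a, b = random_cds(rng, la), random_cds(rng, lb)
            aln = align_codon_pair(nt("a", a), nt("b", b))
            # score our protein-level alignment and compare with Biopython's
            # independent affine aligner optimum
            from famevol.molevol import translate_cds
            pa, pb = translate_cds(a), translate_cds(b)
            aligned_pa = "".join(
                "-" if aln.aligned_a[i:i + 3] == "---" else
                translate_cds(aln.aligned_a[i:i + 3])
                for i in range(0, len(aln.aligned_a), 3))
            aligned_pb = "".join(
                "-" if aln.aligned_b[i:i + 3] == "---" else
                translate_cds(aln.aligned_b[i:i + 3])
                for i in range(0, len(aln.aligned_b), 3))
            assert aligned_pa.replace("-", "") == pa
            assert aligned_pb.replace("-", "") == pb
            ours = affine_score_of_alignment(aligned_pa, aligned_pb)
            assert ours == pytest.approx(optimal_protein_score(pa, pb))


class TestNG86:
    def test_spec_worked_example(self):
        aln = CodonAlignment("a", "b", "TTT" * 10, "TTT" * 9 + "TTC")
        est = ng86_kaks(aln)
        assert est.s_sites == pytest.approx(10 / 3)
        assert est.ps == pytest.approx(0.3)
        assert est.ks == pytest.approx(0.383, abs=5e-4)
        assert est.ka == 0.0
        assert est.omega == 0.0

    def test_identical_sequences_undefined_omega(self, rng):
        cds = random_cds(rng, 15)
        est = ng86_kaks(CodonAlignment("a", "b", cds, cds))
        assert est.ka == 0.0 and est.ks == 0.0 and est.omega is None

    def test_symmetric_in_sequence_order(self, rng):
        a, b = random_cds(rng, 30), random_cds(rng, 30)
        e1 = ng86_kaks(CodonAlignment("a", "b", a, b))
        e2 = ng86_kaks(CodonAlignment("b", "a", b, a))
        assert e1.ks == e2.ks and e1.ka == e2.ka
        assert e1.s_sites == e2.s_sites

    def test_site_counts_partition_columns(self, rng):
        a, b = random_cds(rng, 25), random_cds(rng, 25)
        est = ng86_kaks(CodonAlignment("a", "b", a, b))
        assert est.s_sites + est.n_sites == pytest.approx(3 * 25)

    def test_matches_enumeration_oracle_on_random_short_pairs(self, rng):
        for _ in range(120):
            n = int(rng.integers(1, 4))
            a, b = random_cds(rng, n), random_cds(rng, n)
            est = ng86_kaks(CodonAlignment("a", "b", a, b))
            ks_o, ka_o, s_o, n_o = oracle_ng86(
                [a[i:i + 3] for i in range(0, 3 * n, 3)],
                [b[i:i + 3] for i in range(0, 3 * n, 3)])
            assert est.s_sites == pytest.approx(s_o)
            for mine, ref in ((est.ks, ks_o), (est.ka, ka_o)):
                if ref is None:
                    assert mine is None
                else:
                    assert mine == pytest.approx(ref, abs=1e-12)

    def test_gapped_columns_excluded(self):
        aln = CodonAlignment("a", "b", "TTTAAA---", "TTT---AAA")
        est = ng86_kaks(aln)
        assert est.s_sites + est.n_sites == pytest.approx(3.0)

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError):
            ng86_kaks(CodonAlignment("a", "b", "TTT---", "---AAA"))

    def test_kweighted_counts_more_synonymous_sites(self, rng):
        # transition weighting concentrates site mass on synonymous changes
        a = random_cds(rng, 50)
        b = random_cds(rng, 50)
        plain = ng86_kaks(CodonAlignment("a", "b", a, b), method="ng86")
        weighted = ng86_kaks(CodonAlignment("a", "b", a, b),
                             method="kweighted", kappa=4.0)
        assert weighted.s_sites > plain.s_sites


class TestFourDTV:
    def test_hand_counted_example(self):
        value, n = four_dtv(CodonAlignment("a", "b", "GGTGGT", "GGAGGC"))
        assert (value, n) == (0.5, 2)      # one transversion of two sites

    def test_identical_sequences_zero_with_sites(self):
        value, n = four_dtv(CodonAlignment("a", "b", "GGTGCC", "GGTGCC"))
        assert value == 0.0 and n == 2

    def test_second_base_difference_ineligible(self):
        value, n = four_dtv(CodonAlignment("a", "b", "GGT", "GCT"))
        assert value is None and n == 0

    def test_non_fourfold_codons_ineligible(self):
        value, n = four_dtv(CodonAlignment("a", "b", "TTT", "TTC"))
        assert value is None and n == 0

    def test_symmetry_and_range(self, rng):
        from famevol.simulate import simulate_fourfold_pair
        a, b = simulate_fourfold_pair(200, 1.0, 2.0, rng)
        v1, _ = four_dtv(CodonAlignment("a", "b", a.residues, b.residues))
        v2, _ = four_dtv(CodonAlignment("b", "a", b.residues, a.residues))
        assert v1 == v2 and 0.0 <= v1 <= 1.0

    def test_monotone_in_divergence_up_to_saturation(self):
        rng = np.random.default_rng(5)
        from famevol.simulate import simulate_fourfold_pair
        means = []
        for d in (0.05, 0.3, 1.0, 3.0):
            vals = []
            for _ in range(20):
                a, b = simulate_fourfold_pair(300, d, 2.0, rng)
                vals.append(four_dtv(
                    CodonAlignment("a", "b", a.residues, b.residues))[0])
            means.append(np.mean(vals))
        assert means == sorted(means)
        assert means[-1] == pytest.approx(0.5, abs=0.05)

    def test_corrected_exceeds_raw(self):
        rng = np.random.default_rng(6)
        from famevol.simulate import simulate_fourfold_pair
        a, b = simulate_fourfold_pair(400, 0.5, 2.0, rng)
        aln = CodonAlignment("a", "b", a.residues, b.residues)
        raw, _ = four_dtv(aln)
        corr, _ = four_dtv(aln, corrected=True)
        assert corr > raw


class TestSelectionAndDating:
    @pytest.mark.parametrize("omega,expected", [
        (0.5, "purifying"), (1.0, "neutral"), (2.0, "positive"),
        (0.96, "neutral"), (None, "undefined")])
    def test_selection_classes(self, omega, expected):
        from famevol.molevol import EvolEstimate
        est = EvolEstimate(ka=0.1, ks=0.1, omega=omega, kappa=None,
                           fourdtv=None, n_4d_sites=0, s_sites=1.0,
                           n_sites=2.0)
        assert classify_selection(est) == expected

    @pytest.mark.parametrize("ks,band", [
        (0.2, "recent"), (0.15, "recent"), (0.30, "recent"),
        (1.6, "ancient"), (3.8, "other"), (0.5, "other")])
    def test_ks_band_assignment(self, ks, band):
        assert assign_wgd_band(ks) == band

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_wgd_band(0.2, {"a": (0.1, 0.5), "b": (0.4, 0.9)})

    def test_recent_wgd_dating_identity(self):
        assert ks_to_time(0.15, 2.5e-9).t_mya == 30.0

    def test_zero_ks_zero_age(self):
        assert ks_to_time(0.0).t_mya == 0.0

    def test_doubling_rate_halves_age(self):
        assert ks_to_time(0.3, 5e-9).t_mya == \
            pytest.approx(ks_to_time(0.3, 2.5e-9).t_mya / 2)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            ks_to_time(-0.1)


def test_kappa_estimate_recovers_transition_bias():
    rng = np.random.default_rng(11)
    from famevol.simulate import simulate_fourfold_pair
    a, b = simulate_fourfold_pair(20_000, 0.1, 2.0, rng)
    est = ng86_kaks(CodonAlignment("a", "b", a.residues, b.residues))
    assert est.kappa == pytest.approx(2.0, rel=0.3)
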
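"""Anchor chaining, duplication-mode priority, flank windows, summaries."""
import pytest

from famevol.synteny import (AnchorPair, ChainParams, chain_anchors,
                             classify_duplicates, flank_window, mode_summary)
from conftest import make_annotation


def grid_annotation(n_chrom=2, n_genes=12, spacing=1000):
    """One gene per kb on each chromosome; rank == index."""
    spec = []
    for c in range(n_chrom):
        for i in range(n_genes):
            spec.append((f"c{c+1}g{i}", f"chr{c+1}", i * spacing,
                         i * spacing + 500, "+"))
    return make_annotation(spec)


def anchors_at(pairs):
    return [AnchorPair(f"c1g{i}", f"c2g{j}", 100.0) for i, j in pairs]


class TestChaining:
    def test_perfect_diagonal_one_plus_block(self):
        ann = grid_annotation()
        blocks = chain_anchors(anchors_at([(i, i) for i in range(1, 6)]), ann)
        assert len(blocks) == 1
        blk = blocks[0]
        assert (blk.orientation, len(blk)) == ("plus", 5)
        assert blk.score == pytest.approx(250.0)

    def test_below_min_block_size_no_block(self):
        ann = grid_annotation()
        blocks = chain_anchors(anchors_at([(i, i) for i in range(1, 5)]), ann)
        assert blocks == []

    def test_anti_diagonal_minus_block(self):
        ann = grid_annotation()
        pairs = [(1, 5), (2, 4), (3, 3), (4, 2), (5, 1)]
        blocks = chain_anchors(anchors_at(pairs), ann)
        assert len(blocks) == 1
        assert blocks[0].orientation == "minus"
        assert len(blocks[0]) == 5

    def test_gap_penalty_reduces_score(self):
        ann = grid_annotation()
        gapped = anchors_at([(1, 1), (2, 2), (3, 3), (4, 4), (6, 6)])
        blocks = chain_anchors(gapped, ann)
        assert len(blocks) == 1
        assert blocks[0].score == pytest.approx(250.0 - 2.0)  # gap of 1+1

    def test_max_gap_splits_chain(self):
        ann = grid_annotation(n_genes=60)
        pairs = [(i, i) for i in range(5)] + [(i, i) for i in range(40, 45)]
        blocks = chain_anchors(anchors_at(pairs), ann,
                               ChainParams(max_gap=10))
        assert len(blocks) == 2 and all(len(b) == 5 for b in blocks)

    def test_monotone_and_disjoint_blocks(self, rng):
        ann = grid_annotation(n_genes=30)
        pairs = {(int(i), int(j))
                 for i, j in rng.integers(0, 30, size=(60, 2))}
        blocks = chain_anchors(anchors_at(sorted(pairs)), ann)
        seen = set()
        for blk in blocks:
            ra = [ann[a.gene_a].rank for a in blk.anchors]
            rb = [ann[a.gene_b].rank for a in blk.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            if blk.orientation == "plus":
                assert rb == sorted(rb) and len(set(rb)) == len(rb)
            else:
                assert rb == sorted(rb, reverse=True)
            for a in blk.anchors:
                assert a.key not in seen
                seen.add(a.key)

    def test_symmetric_under_role_swap(self):
        ann = grid_annotation()
        pairs = [(1, 2), (2, 3), (3, 5), (4, 6), (5, 7), (7, 8)]
        fwd = chain_anchors(anchors_at(pairs), ann)
        swapped = [AnchorPair(a.gene_b, a.gene_a, a.score)
                   for a in anchors_at(pairs)]
        rev = chain_anchors(swapped, ann)
        assert [(len(b), b.score, b.orientation) for b in fwd] == \
               [(len(b), b.score, b.orientation) for b in rev]

    def test_unknown_gene_rejected(self):
        ann = grid_annotation()
        with pytest.raises(KeyError):
            chain_anchors([AnchorPair("ghost", "c1g1", 1.0)], ann)


class TestDuplicationModes:
    def _setup(self):
        ann = grid_annotation(n_chrom=3, n_genes=25)
        # a diagonal block whose anchors include the family pair (g2,g2)
        block_anchors = anchors_at([(i, i) for i in range(1, 7)])
        extra = [
            AnchorPair("c1g10", "c1g11", 50.0),   # tandem
            AnchorPair("c1g14", "c1g18", 50.0),   # proximal (rank dist 4)
            AnchorPair("c2g2", "c3g9", 50.0),     # transposed: c2g2 in block
            AnchorPair("c1g20", "c3g20", 50.0),   # dispersed
            AnchorPair("c1g1", "c1g2", 60.0),     # WGD wins over tandem
        ]
        anchors = block_anchors + extra
        blocks = chain_anchors(anchors, ann)
        family = ["c1g2", "c2g2", "c1g10", "c1g11", "c1g14", "c1g18",
                  "c3g9", "c1g20", "c3g20", "c1g1", "c2g1"]
        return ann, anchors, blocks, family

    def test_priority_assignment(self):
        ann, anchors, blocks, family = self._setup()
        modes = {frozenset((d.gene_a, d.gene_b)): d.mode
                 for d in classify_duplicates(family, anchors, blocks, ann)}
        assert modes[frozenset(("c1g2", "c2g2"))] == "WGD"
        assert modes[frozenset(("c1g10", "c1g11"))] == "TD"
        assert modes[frozenset(("c1g14", "c1g18"))] == "PD"
        assert modes[frozenset(("c2g2", "c3g9"))] == "TRD"
        assert modes[frozenset(("c1g20", "c3g20"))] == "DD"

    def test_block_membership_beats_rank_adjacency(self):
        # (c1g1, c1g2): both block anchors and adjacent ranks -> WGD? No:
        # the pair itself is not a block anchor, both genes are, so the
        # TRD rule cannot fire either and rank distance 1 gives TD.
        ann, anchors, blocks, family = self._setup()
        modes = {frozenset((d.gene_a, d.gene_b)): d.mode
                 for d in classify_duplicates(family, anchors, blocks, ann)}
        assert modes[frozenset(("c1g1", "c1g2"))] == "TD"

    def test_pair_that_is_block_anchor_and_adjacent_is_wgd(self):
        ann = grid_annotation(n_chrom=1, n_genes=20)
        # same-chromosome diagonal: pairs (i, i+1) are collinear anchors
        anchors = [AnchorPair(f"c1g{i}", f"c1g{i+1}", 10.0)
                   for i in range(0, 12, 2)]
        blocks = chain_anchors(anchors, ann, ChainParams(min_block_size=5))
        assert blocks
        family = [f"c1g{i}" for i in range(14)]
        modes = {frozenset((d.gene_a, d.gene_b)): d.mode
                 for d in classify_duplicates(family, anchors, blocks, ann)}
        assert modes[frozenset(("c1g0", "c1g1"))] == "WGD"

    def test_non_family_anchors_ignored(self):
        ann, anchors, blocks, _ = self._setup()
        dups = classify_duplicates(["c1g20", "c3g20"], anchors, blocks, ann)
        assert len(dups) == 1 and dups[0].mode == "DD"


class TestFlankWindow:
    ANN = [("focal", "chr1", 50_000, 52_000, "+"),
           ("inside", "chr1", 10_000, 12_000, "+"),
           ("edge", "chr1", 151_999, 155_000, "+"),
           ("outside", "chr1", 152_000, 155_500, "+"),
           ("left", "chr1", 100, 600, "+")]

    def test_window_membership_and_boundary(self):
        ann = make_annotation(self.ANN, {"chr1": 200_000})
        win = flank_window("focal", ann, width_bp=100_000)
        names = [g.gene_id for g in win.genes]
        assert "inside" in names and "edge" in names
        assert "outside" not in names          # starts exactly at the bound
        assert "focal" in names
        assert names == sorted(names, key=lambda n: ann[n].start)

    def test_clipped_at_chromosome_start(self):
        ann = make_annotation(self.ANN, {"chr1": 200_000})
        win = flank_window("left", ann, width_bp=100_000)
        assert win.span[0] == 0

    def test_width_must_be_positive(self):
        ann = make_annotation(self.ANN, {"chr1": 200_000})
        with pytest.raises(ValueError):
            flank_window("focal", ann, width_bp=0)


class TestModeSummary:
    def test_disjoint_wgd_pairs_cover_family(self):
        pairs = [classify_pair("a", "b"), classify_pair("c", "d"),
                 classify_pair("e", "f")]
        s = mode_summary(pairs, ["a", "b", "c", "d", "e", "f"])
        assert s.gene_counts["WGD"] == 6
        assert s.gene_proportions["WGD"] == pytest.approx(1.0)
        assert s.pair_proportions["WGD"] == pytest.approx(1.0)

    def test_empty_pairs_all_zero(self):
        s = mode_summary([], ["a", "b"])
        assert sum(s.pair_counts.values()) == 0
        assert sum(s.gene_counts.values()) == 0

    def test_gene_counted_once_in_highest_priority_mode(self):
        from famevol.synteny import DuplicatePair
        pairs = [DuplicatePair("a", "b", "WGD", ""),
                 DuplicatePair("a", "c", "TD", "")]
        s = mode_summary(pairs, ["a", "b", "c"])
        assert s.gene_counts["WGD"] == 2      # a and b
        assert s.gene_counts["TD"] == 1       # c only


def classify_pair(a, b):
    from famevol.synteny import DuplicatePair
    return DuplicatePair(a, b, "WGD", "test")
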
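"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities through different code
paths (Biopython translation, explicit pathway enumeration, Biopython's
pairwise aligner, path-length matrices on explicit trees) so the package
implementations are checked against something they do not share code with.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from famevol.io_core import GeneModel, SequenceRecord, annotate

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
         if a + b + c not in STOPS]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_annotation(spec, chrom_lengths=None):
    """Annotation from (gene_id, chrom, start, end, strand) tuples."""
    genes = [GeneModel(*row) for row in spec]
    return annotate(genes, chrom_lengths)


# ---------------------------------------------------------------------------
# NG86 oracle: explicit enumeration, Biopython translation

def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for i in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut in STOPS:
                continue
            tot += 1
            syn += _aa(mut) == _aa(codon)
        if tot:
            total += syn / tot
    return total


def oracle_pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    clean, stop_paths = [], []
    for perm in itertools.permutations(positions):
        cur, sd, nd, hits_stop = c1, 0, 0, False
        for i in perm:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in STOPS:
                hits_stop = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (stop_paths if hits_stop else clean).append((sd, nd))
    use = clean or stop_paths
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def oracle_ng86(codons_a: list[str], codons_b: list[str]):
    """(ks, ka) by explicit NG86 counting with JC correction; None on
    saturation."""
    s_sites = (sum(map(oracle_syn_sites, codons_a))
               + sum(map(oracle_syn_sites, codons_b))) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_s, d_n = oracle_pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0

    def jc(p):
        if p >= 0.75 - 1e-9:      # same saturation guard as the package
            return None
        return 0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return jc(ps), jc(pn), s_sites, n_sites


def random_cds(rng, n_codons: int) -> str:
    return "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n_codons))


# ---------------------------------------------------------------------------
# alignment score oracle: Biopython PairwiseAligner (independent affine DP)

def optimal_protein_score(a: str, b: str, gap_open=10.0, gap_extend=0.5):
    from Bio import Align
    from Bio.Align import substitution_matrices
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner.score(a, b)


def affine_score_of_alignment(aln_a: str, aln_b: str, gap_open=10.0,
                              gap_extend=0.5) -> float:
    """Score an explicit alignment under the same affine convention."""
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aln_a, aln_b):
        if x == "-" :
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += m[x, y]
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# additive trees: explicit path-length distance matrices

def random_additive_tree(rng, n_taxa: int):
    """(labels, distance matrix) from a random binary tree with positive
    branch lengths, distances computed by explicit path summation."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [{lab: 0.0} for lab in labels]      # tip -> distance-to-subroot
    dist_pairs: list[tuple[str, str, float]] = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        da, db = nodes[i], nodes[j]
        la, lb = rng.uniform(0.5, 2.0, size=2)
        dist_pairs.extend((ta, tb, da[ta] + la + db[tb] + lb)
                          for ta in da for tb in db)
        merged = {t: d + la for t, d in da.items()}
        merged.update({t: d + lb for t, d in db.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    idx = {lab: k for k, lab in enumerate(labels)}
    d = np.zeros((n_taxa, n_taxa))
    for ta, tb, dist in dist_pairs:
        d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = dist
    return labels, d


def tree_distance_matrix(tree, labels):
    """Pairwise tip path lengths of a PhyloNode tree."""
    paths = {}
    for tip in tree.tips():
        anc, node, dist = {}, tip, 0.0
        while node is not None:
            anc[id(node)] = dist
            dist += node.length or 0.0
            node = node.parent
        paths[tip.name] = anc
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            best = min(pa[k] + pb[k] for k in pa if k in pb)
            d[i, j] = d[j, i] = best
    return d
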
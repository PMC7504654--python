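"""Synteny-block chaining and duplication-mode classification.

Homologous gene pairs (anchors) are chained into collinear blocks by dynamic
programming over per-chromosome gene ranks, in both orientations (a minus
block is an anti-diagonal run).  Family duplicate pairs are then assigned one
of five duplication modes under a fixed priority:

    WGD  — the pair is an anchor inside a synteny block
    TD   — same chromosome, adjacent ranks (tandem)
    PD   — same chromosome, rank distance 2..proximal_max_rank (proximal)
    TRD  — exactly one member is a block anchor (treated as the parental
           locus) and the pair itself is not syntenic (transposed)
    DD   — everything else (dispersed)

The first matching rule wins (WGD > TD > PD > TRD > DD).
"""
from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .io_core import GeneModel, GenomeAnnotation, natural_key

MODES = ("WGD", "TD", "PD", "TRD", "DD")


@dataclasses.dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self anchor {self.gene_a!r}")
        if self.score <= 0:
            raise ValueError("anchor score must be positive")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclasses.dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str          # "plus" | "minus"
    score: float

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def genes(self) -> set[str]:
        out = set()
        for a in self.anchors:
            out.update((a.gene_a, a.gene_b))
        return out


@dataclasses.dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    mode: str
    evidence: str


@dataclasses.dataclass
class ChainParams:
    min_block_size: int = 5
    max_gap: int = 25
    gap_penalty: float = 1.0
    match_score: float = 50.0


def _rank_points(anchors: Iterable[AnchorPair], annotation: GenomeAnnotation):
    """Group anchors by canonical chromosome pair with rank coordinates."""
    groups: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = defaultdict(list)
    for anchor in anchors:
        ga, gb = annotation[anchor.gene_a], annotation[anchor.gene_b]
        a, b = ga, gb
        if (natural_key(ga.chrom), ga.rank) > (natural_key(gb.chrom), gb.rank):
            a, b = gb, ga
        groups[(a.chrom, b.chrom)].append((a.rank, b.rank, anchor))
    return groups


def chain_anchors(anchors: Sequence[AnchorPair],
                  annotation: GenomeAnnotation,
                  params: ChainParams | None = None) -> list[SyntenyBlock]:
    """Chain anchors into maximal-scoring collinear blocks.

    Per chromosome pair and orientation: dynamic programming over rank
    coordinates, extending a chain when both rank gaps are in [1, max_gap];
    chain score = sum(match_score) - gap_penalty * (rank gap units beyond
    adjacency).  Overlapping candidate chains are resolved greedily by score
    (ties by leftmost start); only chains with >= min_block_size anchors are
    reported.
    """
    params = params or ChainParams()
    blocks: list[SyntenyBlock] = []
    for (chrom_a, chrom_b), pts in sorted(_rank_points(anchors, annotation).items()):
        candidates = []      # (score, start rank, orientation, anchor list)
        for orientation in ("plus", "minus"):
            sign = 1 if orientation == "plus" else -1
            items = sorted(((ra, sign * rb, anchor) for ra, rb, anchor in pts),
                           key=lambda t: (t[0], t[1]))
            n = len(items)
            score = [params.match_score] * n
            prev = [-1] * n
            for i in range(n):
                rai, rbi, _ = items[i]
                for j in range(i):
                    raj, rbj, _ = items[j]
                    dra, drb = rai - raj, rbi - rbj
                    if dra < 1 or drb < 1 or dra > params.max_gap or drb > params.max_gap:
                        continue
                    gap = (dra - 1) + (drb - 1)
                    cand = score[j] + params.match_score - params.gap_penalty * gap
                    if cand > score[i]:
                        score[i], prev[i] = cand, j
            for i in range(n):
                path = []
                k = i
                while k != -1:
                    path.append(k)
                    k = prev[k]
                path.reverse()
                if len(path) >= params.min_block_size:
                    candidates.append((score[i], items[path[0]][0],
                                       orientation,
                                       [items[k][2] for k in path]))
        # resolve overlaps greedily by score (ties leftmost start, plus
        # before minus) across both orientations so no two reported blocks
        # on this chromosome pair share an anchor
        candidates.sort(key=lambda c: (-c[0], c[1], c[2] != "plus"))
        used: set[frozenset[str]] = set()
        for chain_score, _start, orientation, chain in candidates:
            if any(a.key in used for a in chain):
                continue
            used.update(a.key for a in chain)
            blocks.append(SyntenyBlock(chrom_a, chrom_b, chain, orientation,
                                       chain_score))
    blocks.sort(key=lambda b: (natural_key(b.chrom_a), natural_key(b.chrom_b),
                               -b.score))
    return blocks


def classify_duplicates(family_ids: Iterable[str],
                        anchors: Sequence[AnchorPair],
                        blocks: Sequence[SyntenyBlock],
                        annotation: GenomeAnnotation,
                        tandem_max_rank: int = 1,
                        proximal_max_rank: int = 10) -> list[DuplicatePair]:
    """Assign each homologous family pair a duplication mode (first matching
    rule wins, priority WGD > TD > PD > TRD > DD)."""
    family = set(family_ids)
    block_anchor_keys = {a.key for blk in blocks for a in blk.anchors}
    block_genes = {g for blk in blocks for g in blk.genes}
    out: list[DuplicatePair] = []
    seen: set[frozenset[str]] = set()
    for anchor in anchors:
        if anchor.gene_a not in family or anchor.gene_b not in family:
            continue
        if anchor.key in seen:
            continue
        seen.add(anchor.key)
        a, b = sorted((anchor.gene_a, anchor.gene_b))
        ga, gb = annotation[a], annotation[b]
        if anchor.key in block_anchor_keys:
            out.append(DuplicatePair(a, b, "WGD", "anchor in synteny block"))
            continue
        if ga.chrom == gb.chrom:
            dist = abs(ga.rank - gb.rank)
            if dist <= tandem_max_rank:
                out.append(DuplicatePair(a, b, "TD", f"rank distance {dist}"))
                continue
            if dist <= proximal_max_rank:
                out.append(DuplicatePair(a, b, "PD", f"rank distance {dist}"))
                continue
        in_block = (a in block_genes, b in block_genes)
        if in_block[0] != in_block[1]:
            parent = a if in_block[0] else b
            out.append(DuplicatePair(
                a, b, "TRD", f"parental locus {parent} is a block anchor"))
            continue
        out.append(DuplicatePair(a, b, "DD", "no synteny or proximity"))
    return out


@dataclasses.dataclass
class FlankWindow:
    focal: GeneModel
    span: tuple[int, int]
    genes: list[GeneModel]    # includes the focal gene, sorted by start


def flank_window(gene_id: str, annotation: GenomeAnnotation,
                 width_bp: int = 100_000) -> FlankWindow:
    """Genes whose spans intersect the focal gene's span widened by width_bp
    on each side, clipped at chromosome ends."""
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    focal = annotation[gene_id]
    chrom_len = annotation.chrom_lengths[focal.chrom]
    lo = max(0, focal.start - width_bp)
    hi = min(chrom_len, focal.end + width_bp)
    genes = [g for g in annotation.genes_on(focal.chrom)
             if g.start < hi and g.end > lo]
    genes.sort(key=lambda g: g.start)
    return FlankWindow(focal, (lo, hi), genes)


@dataclasses.dataclass
class ModeSummary:
    pair_counts: dict[str, int]
    pair_proportions: dict[str, float]
    gene_counts: dict[str, int]
    gene_proportions: dict[str, float]
    family_size: int


def mode_summary(pairs: Sequence[DuplicatePair],
                 family_ids: Sequence[str]) -> ModeSummary:
    """Per-mode pair counts/proportions, and per-mode gene counts where each
    gene is counted once in its highest-priority mode; gene proportions are
    over the family size."""
    pair_counts = {m: 0 for m in MODES}
    for p in pairs:
        pair_counts[p.mode] += 1
    total_pairs = sum(pair_counts.values())
    pair_proportions = {m: (pair_counts[m] / total_pairs if total_pairs else 0.0)
                        for m in MODES}
    priority = {m: i for i, m in enumerate(MODES)}
    best: dict[str, str] = {}
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in best or priority[p.mode] < priority[best[g]]:
                best[g] = p.mode
    gene_counts = {m: 0 for m in MODES}
    for mode in best.values():
        gene_counts[mode] += 1
    n_family = len(set(family_ids))
    gene_proportions = {m: (gene_counts[m] / n_family if n_family else 0.0)
                        for m in MODES}
    return ModeSummary(pair_counts, pair_proportions, gene_counts,
                       gene_proportions, n_family)


def write_collinearity(blocks: Sequence[SyntenyBlock], path) -> None:
    """Write blocks in an MCScanX-like plain-text collinearity layout."""
    with open(path, "w") as fh:
        fh.write("# famevol collinearity\n")
        for i, blk in enumerate(blocks):
            fh.write(f"## block {i}: {blk.chrom_a}&{blk.chrom_b} "
                     f"orientation={blk.orientation} score={blk.score:g} "
                     f"n={len(blk)}\n")
            for j, anchor in enumerate(blk.anchors):
                fh.write(f"{i}-{j}:\t{anchor.gene_a}\t{anchor.gene_b}\t"
                         f"{anchor.score:g}\n")
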
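"""Synthetic genomes with planted, recoverable truth.

The generator emulates the inputs of a whole-genome gene-family study: a
multi-chromosome genome whose genes sit on a regular slot grid (one gene per
slot, so gene rank equals slot index), a planted transcription-factor family
whose proteins carry the CX2CX6CX3C zinc-finger motif (class I members also
an LX6LX3LX6L leucine zipper downstream), duplicate pairs planted by mode —
collinear WGD runs, tandem, proximal, transposed and dispersed — diverged
under a continuous-time codon model with transition bias kappa and
nonsynonymous factor omega, promoters with planted cis-elements at recorded
offsets, and tissue count / qPCR Ct tables with known presence patterns and
fold changes.

Design notes that make recovery tests exact rather than probabilistic:

* background proteins are cysteine-free and class II family proteins are
  leucine-free outside their motifs, so a chance zinc finger or leucine
  zipper cannot appear in sequence the truth table does not know about;
* motif anchor residues are frozen against nonsynonymous change during
  divergence (hard purifying selection at the anchors), so planted class
  labels survive arbitrary divergence;
* truth Ks for a pair is the realized substitution-event count normalized by
  the ancestor's NG86 synonymous sites — not the target parameter — so
  estimator tests compare like with like.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (GeneModel, GenomeAnnotation, SequenceRecord, annotate,
                      write_fasta, write_gff3, write_pair_table)
from .molevol import (AA_OF, BASES, FOURFOLD_PREFIXES, SENSE_CODONS,
                      STOP_CODONS, codons_of, is_transition, site_fractions,
                      translate_cds)
from .promoter import MotifEntry, IUPAC_SETS, load_default_catalog, reverse_complement
from .synteny import AnchorPair

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(AA_OF.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

_AA_NO_C = sorted(set(AA_OF.values()) - {"C"})
_AA_NO_CL = sorted(set(AA_OF.values()) - {"C", "L"})


# ---------------------------------------------------------------------------
# configuration and truth

@dataclasses.dataclass
class SimConfig:
    """Study conditions of the synthetic genome; defaults are the conditions
    every recovery test runs under."""

    n_chromosomes: int = 6
    genes_per_chromosome: int = 30
    slot_bp: int = 6000            # one gene per slot; rank == slot index
    gene_offset_bp: int = 2500     # leaves >= 2000 bp flanks on both sides
    background_codons: tuple[int, int] = (220, 320)
    family_codons: int = 300
    # planted duplication structures
    wgd_blocks: int = 3
    block_size: int = 6
    family_pairs_per_block: int = 2
    tandem_pairs: int = 2
    proximal_pairs: int = 2
    transposed_pairs: int = 1
    dispersed_pairs: int = 2
    singletons: int = 5
    class_ii_members: int = 5
    scaffold_members: int = 2
    # codon model
    kappa: float = 2.0
    omega: float = 0.2
    target_ks: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"WGD": 0.2, "TD": 0.05, "PD": 0.05,
                                 "TRD": 0.3, "DD": 0.8})
    # promoter plan
    promoter_len: int = 2000
    elements_per_gene: int = 3
    # expression plan
    tissues: tuple[str, ...] = ("stem", "ovary", "petal", "sepal", "fruit",
                                "leaf")
    tissue_presence_fraction: tuple[float, ...] = (0.52, 0.60, 0.48, 0.73,
                                                   0.40, 0.35)
    silent_fraction: float = 0.15
    expression_range: tuple[float, float] = (20.0, 120.0)   # RPKM scale
    nb_dispersion: float = 0.1
    library_size: int = 1_000_000
    qpcr_genes: int = 7
    qpcr_replicates: int = 3
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        counts = (self.wgd_blocks, self.block_size, self.tandem_pairs,
                  self.proximal_pairs, self.transposed_pairs,
                  self.dispersed_pairs, self.singletons)
        if any(c < 0 for c in counts):
            raise ValueError("planted counts must be >= 0")
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        if any(v < 0 for v in self.target_ks.values()):
            raise ValueError("target Ks values must be >= 0")


@dataclasses.dataclass
class PlantedPair:
    gene_a: str
    gene_b: str
    mode: str
    target_ks: float
    realized_ks: float
    realized_ka: float
    omega: float


@dataclasses.dataclass
class PlantedElement:
    gene_id: str
    motif: str
    category: str
    offset: int        # within the promoter, 0-based
    sequence: str      # concrete instantiation of the IUPAC consensus


@dataclasses.dataclass
class TruthTable:
    pairs: list[PlantedPair] = dataclasses.field(default_factory=list)
    classes: dict[str, str] = dataclasses.field(default_factory=dict)
    scaffold_genes: list[str] = dataclasses.field(default_factory=list)
    elements: list[PlantedElement] = dataclasses.field(default_factory=list)
    presence: pd.DataFrame | None = None
    expression_level: pd.DataFrame | None = None
    fold_changes: pd.DataFrame | None = None

    def pair_modes(self) -> dict[frozenset[str], str]:
        return {frozenset((p.gene_a, p.gene_b)): p.mode for p in self.pairs}


# ---------------------------------------------------------------------------
# codon-model divergence

def _neighbor_rates(codon: str, kappa: float, omega: float,
                    frozen: bool) -> list[tuple[str, bool, float]]:
    out = []
    for pos in range(3):
        base = codon[pos]
        for b in BASES:
            if b == base:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            syn = AA_OF[alt] == AA_OF[codon]
            if not syn and frozen:
                continue
            rate = (kappa if is_transition(base, b) else 1.0) * \
                   (1.0 if syn else omega)
            if rate > 0:
                out.append((alt, syn, rate))
    return out


def _evolve_branch(codons: Sequence[str], t_total: float, kappa: float,
                   omega: float, frozen: frozenset[int],
                   rng: np.random.Generator) -> tuple[list[str], int, int]:
    """Gillespie simulation of codon substitution for time t_total; returns
    (codons, synonymous events, nonsynonymous events)."""
    codons = list(codons)
    nbrs = [_neighbor_rates(c, kappa, omega, i in frozen)
            for i, c in enumerate(codons)]
    totals = np.array([sum(r for *_, r in nb) for nb in nbrs])
    t = 0.0
    syn_events = nonsyn_events = 0
    while True:
        total_rate = totals.sum()
        if total_rate <= 0:
            break
        t += rng.exponential(1.0 / total_rate)
        if t >= t_total:
            break
        i = int(rng.choice(len(codons), p=totals / total_rate))
        nb = nbrs[i]
        rates = np.array([r for *_, r in nb])
        k = int(rng.choice(len(nb), p=rates / rates.sum()))
        alt, syn, _ = nb[k]
        codons[i] = alt
        if syn:
            syn_events += 1
        else:
            nonsyn_events += 1
        nbrs[i] = _neighbor_rates(alt, kappa, omega, i in frozen)
        totals[i] = sum(r for *_, r in nbrs[i])
    return codons, syn_events, nonsyn_events


def _syn_flux(codons: Sequence[str], kappa: float, omega: float,
              frozen: frozenset[int]) -> float:
    return sum(r
               for i, c in enumerate(codons)
               for _, syn, r in _neighbor_rates(c, kappa, omega, i in frozen)
               if syn)


@dataclasses.dataclass
class _Divergence:
    cds_a: str
    cds_b: str
    events_a: tuple[int, int]   # (syn, nonsyn)
    events_b: tuple[int, int]
    s_sites: float
    n_sites: float


def _diverge(ancestor: str, branch_a: float, branch_b: float, kappa: float,
             omega: float, frozen: frozenset[int],
             rng: np.random.Generator) -> _Divergence:
    codons = codons_of(ancestor, "ancestor")
    s_sites = sum(site_fractions(c) for c in codons)
    n_sites = 3.0 * len(codons) - s_sites
    flux = _syn_flux(codons, kappa, omega, frozen)
    scale = s_sites / flux if flux > 0 else 0.0
    a, sa, na = _evolve_branch(codons, branch_a * scale, kappa, omega,
                               frozen, rng)
    b, sb, nb = _evolve_branch(codons, branch_b * scale, kappa, omega,
                               frozen, rng)
    return _Divergence("".join(a), "".join(b), (sa, na), (sb, nb),
                       s_sites, n_sites)


def evolve_codon_pair(ancestor_cds: SequenceRecord | str,
                      branch_sub_per_syn_site: float, kappa: float,
                      omega: float, seed: int | np.random.Generator
                      ) -> tuple[str, str, float, float]:
    """Evolve two copies of an ancestor CDS independently, each branch run
    until the expected synonymous divergence per NG86 synonymous site reaches
    ``branch_sub_per_syn_site``.

    Returns (cds_a, cds_b, realized_ks, realized_ka), where the realized
    values count actual events against the ancestor's NG86 site counts.
    """
    if branch_sub_per_syn_site < 0:
        raise ValueError("target divergence must be >= 0")
    seq = ancestor_cds.residues if isinstance(ancestor_cds, SequenceRecord) \
        else ancestor_cds
    translate_cds(seq, "ancestor")   # validates: divisible by 3, no stops
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    div = _diverge(seq, branch_sub_per_syn_site, branch_sub_per_syn_site,
                   kappa, omega, frozenset(), rng)
    realized_ks = (div.events_a[0] + div.events_b[0]) / div.s_sites
    realized_ka = (div.events_a[1] + div.events_b[1]) / div.n_sites
    return div.cds_a, div.cds_b, realized_ks, realized_ka


# ---------------------------------------------------------------------------
# fourfold-degenerate site pairs (exact K80 sampling)

_TRANSITION_OF = np.array([2, 3, 0, 1])          # ACGT: A<->G, C<->T
_TRANSVERSIONS_OF = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_BASE = np.array(list("ACGT"))


def _k80_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(same, transition, each-transversion) probabilities after expected
    divergence d substitutions/site under K80 (closed form)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    p_tv = 0.25 - 0.25 * e1
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    return 1.0 - p_ti - 2.0 * p_tv, p_ti, p_tv


def _k80_branch(bases: np.ndarray, d: float, kappa: float,
                rng: np.random.Generator) -> np.ndarray:
    same, ti, tv = _k80_probs(d, kappa)
    u = rng.random(len(bases))
    out = bases.copy()
    mask_ti = (u >= same) & (u < same + ti)
    out[mask_ti] = _TRANSITION_OF[bases[mask_ti]]
    mask_tv1 = (u >= same + ti) & (u < same + ti + tv)
    out[mask_tv1] = _TRANSVERSIONS_OF[bases[mask_tv1], 0]
    mask_tv2 = u >= same + ti + tv
    out[mask_tv2] = _TRANSVERSIONS_OF[bases[mask_tv2], 1]
    return out


def simulate_fourfold_pair(n_codons: int, divergence: float, kappa: float,
                           seed: int | np.random.Generator
                           ) -> tuple[SequenceRecord, SequenceRecord]:
    """A CDS pair built entirely from fourfold-degenerate codon families,
    whose third positions have diverged by ``divergence`` expected
    substitutions per site under K80 with the given kappa (exact transition
    probabilities, so any divergence including saturation is realized
    faithfully).  First two codon positions are identical by construction,
    so every codon column is 4DTv-eligible."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    prefixes = sorted(FOURFOLD_PREFIXES)
    pref = rng.integers(0, len(prefixes), size=n_codons)
    anc = rng.integers(0, 4, size=n_codons)
    third_a = _k80_branch(anc, divergence / 2.0, kappa, rng)
    third_b = _k80_branch(anc, divergence / 2.0, kappa, rng)

    def build(thirds: np.ndarray) -> str:
        return "".join(prefixes[p] + _BASE[t]
                       for p, t in zip(pref, thirds))

    return (SequenceRecord("ffd_a", build(third_a), "nt"),
            SequenceRecord("ffd_b", build(third_b), "nt"))


# ---------------------------------------------------------------------------
# protein construction

def _random_aa(rng: np.random.Generator, n: int, alphabet: Sequence[str]) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _family_protein(rng: np.random.Generator, n_aa: int,
                    class_label: str) -> tuple[str, frozenset[int]]:
    """A family protein of n_aa residues carrying the zinc finger (and for
    class I a downstream zipper); returns (protein, frozen anchor indices)."""
    alphabet = _AA_NO_C if class_label == "I" else _AA_NO_CL
    parts: list[str] = []
    anchors: list[int] = []

    def add_motif(anchor_aa: str, spacers: Sequence[int]) -> None:
        pos = sum(len(p) for p in parts)
        parts.append(anchor_aa)
        anchors.append(pos)
        pos += 1
        for s in spacers:
            parts.append(_random_aa(rng, s, alphabet))
            pos += s
            parts.append(anchor_aa)
            anchors.append(pos)
            pos += 1

    parts.append("M")
    parts.append(_random_aa(rng, 4, alphabet))
    add_motif("C", (2, 6, 3))
    if class_label == "I":
        parts.append(_random_aa(rng, 10, alphabet))
        add_motif("L", (6, 3, 6))
    tail = n_aa - sum(len(p) for p in parts)
    if tail < 0:
        raise ValueError("family protein length too short for motifs")
    parts.append(_random_aa(rng, tail, alphabet))
    return "".join(parts), frozenset(anchors)


def _background_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "M" + _random_aa(rng, n_aa - 1, _AA_NO_C)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon per residue (uniform over sense codons)."""
    out = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        out.append(options[int(rng.integers(0, len(options)))])
    return "".join(out)


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC_SETS[ch][int(rng.integers(0, len(IUPAC_SETS[ch])))]
                   for ch in consensus)


# ---------------------------------------------------------------------------
# the genome builder

@dataclasses.dataclass
class _GeneSpec:
    gene_id: str
    chrom: str
    slot: int
    cds: str
    strand: str
    family: bool
    class_label: str | None = None


@dataclasses.dataclass
class SyntheticGenome:
    config: SimConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    cds: dict[str, str]
    proteins: dict[str, str]
    anchors: list[AnchorPair]
    catalog: list[MotifEntry]
    truth: TruthTable
    counts: pd.DataFrame | None = None
    gene_lengths: dict[str, int] | None = None
    library_sizes: dict[str, int] | None = None
    ct: pd.DataFrame | None = None

    def family_ids(self, chromosome_placed_only: bool = True) -> list[str]:
        ids = sorted(self.truth.classes)
        if chromosome_placed_only:
            ids = [g for g in ids if g not in set(self.truth.scaffold_genes)]
        return ids

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        paths: dict[str, Path] = {}

        def p(name: str) -> Path:
            paths[name] = out / name
            return paths[name]

        write_fasta([SequenceRecord(c, self.genome[c], "nt")
                     for c in sorted(self.genome)], p("genome.fa"))
        write_gff3(self.annotation, p("genes.gff3"))
        write_fasta([SequenceRecord(g, self.cds[g], "nt")
                     for g in sorted(self.cds)], p("cds.fa"))
        write_fasta([SequenceRecord(g, self.proteins[g], "aa")
                     for g in sorted(self.proteins)], p("proteins.fa"))
        write_pair_table([(a.gene_a, a.gene_b, a.score)
                          for a in self.anchors], p("pairs.tsv"))
        pd.DataFrame([{"name": m.name, "category": m.category,
                       "consensus": m.consensus} for m in self.catalog]
                     ).to_csv(p("catalog.tsv"), sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(pair) for pair in self.truth.pairs]
                     ).to_csv(p("truth/pairs.tsv"), sep="\t", index=False,
                              float_format="%.6g")
        pd.DataFrame(sorted(self.truth.classes.items()),
                     columns=["gene_id", "class_label"]
                     ).to_csv(p("truth/classes.tsv"), sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in self.truth.elements]
                     ).to_csv(p("truth/elements.tsv"), sep="\t", index=False)
        if self.counts is not None:
            self.counts.to_csv(p("counts.tsv"), sep="\t",
                               index_label="gene_id")
            pd.Series(self.gene_lengths, name="length_bp").rename_axis(
                "gene_id").to_csv(p("gene_lengths.tsv"), sep="\t")
            pd.Series(self.library_sizes, name="library_size").rename_axis(
                "library").to_csv(p("library_sizes.tsv"), sep="\t")
            self.truth.presence.to_csv(p("truth/presence.tsv"), sep="\t",
                                       index_label="gene_id")
        if self.ct is not None:
            self.ct.to_csv(p("ct.tsv"), sep="\t", index=False,
                           float_format="%.4f")
            self.truth.fold_changes.to_csv(p("truth/fold_changes.tsv"),
                                           sep="\t", index_label="gene_id",
                                           float_format="%.6g")
        return paths


def _take(slots: list, start: int, idxs: Sequence[int]) -> int:
    """Find the first offset >= start where all relative idxs are free; mark
    them reserved and return the offset."""
    n = len(slots)
    for s in range(start, n):
        if all(s + i < n and slots[s + i] is None for i in idxs):
            for i in idxs:
                slots[s + i] = "reserved"
            return s
    raise ValueError("infeasible packing: not enough free gene slots")


def simulate_family_genome(cfg: SimConfig | None = None,
                           seed: int | None = None) -> SyntheticGenome:
    """Generate the full synthetic study: genome, annotation, CDS/protein
    sets, homolog-pair table, promoter plants and the truth table."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    catalog = load_default_catalog()
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    slots: dict[str, list] = {c: [None] * cfg.genes_per_chromosome
                              for c in chroms}
    truth = TruthTable()
    specs: list[_GeneSpec] = []
    anchors: list[AnchorPair] = []

    def gene_id(chrom: str, slot: int) -> str:
        return f"{chrom}g{slot + 1:03d}"

    def place(chrom: str, slot: int, cds: str, family: bool,
              class_label: str | None = None) -> str:
        gid = gene_id(chrom, slot)
        strand = "+" if rng.random() < 0.5 else "-"
        slots[chrom][slot] = gid
        specs.append(_GeneSpec(gid, chrom, slot, cds, strand, family,
                               class_label))
        if family:
            truth.classes[gid] = class_label
        return gid

    def family_ancestor(class_label: str) -> tuple[str, frozenset[int]]:
        prot, frozen = _family_protein(rng, cfg.family_codons, class_label)
        return reverse_translate(prot, rng), frozen

    def background_ancestor() -> str:
        n_aa = int(rng.integers(*cfg.background_codons))
        return reverse_translate(_background_protein(rng, n_aa), rng)

    def plant_pair(anc: str, frozen: frozenset[int], mode: str
                   ) -> tuple[_Divergence, float]:
        target = cfg.target_ks[mode]
        div = _diverge(anc, target / 2.0, target / 2.0, cfg.kappa,
                       cfg.omega, frozen, rng)
        return div, target

    def record_pair(gid_a: str, gid_b: str, mode: str, target: float,
                    div: _Divergence, events_a=None, events_b=None) -> None:
        ea = events_a if events_a is not None else div.events_a
        eb = events_b if events_b is not None else div.events_b
        truth.pairs.append(PlantedPair(
            gid_a, gid_b, mode, target,
            realized_ks=(ea[0] + eb[0]) / div.s_sites,
            realized_ka=(ea[1] + eb[1]) / div.n_sites,
            omega=cfg.omega))

    # --- class plan: which family units are class II -------------------
    ii_budget = cfg.class_ii_members
    tandem_classes = []
    for i in range(cfg.tandem_pairs):
        if ii_budget >= 2:
            tandem_classes.append("II")
            ii_budget -= 2
        else:
            tandem_classes.append("I")
    singleton_classes = []
    for i in range(cfg.singletons):
        if ii_budget >= 1:
            singleton_classes.append("II")
            ii_budget -= 1
        else:
            singleton_classes.append("I")

    # --- WGD runs ------------------------------------------------------
    trd_parents: list[tuple[str, _Divergence, frozenset[int], str]] = []
    for b in range(cfg.wgd_blocks):
        chrom_a = chroms[(2 * b) % len(chroms)]
        chrom_b = chroms[(2 * b + 1) % len(chroms)]
        reversed_run = b % 2 == 1      # exercise minus-orientation chaining
        sa = _take(slots[chrom_a], 0, range(cfg.block_size))
        sb = _take(slots[chrom_b], 0, range(cfg.block_size))
        fam_offsets = set(np.linspace(1, cfg.block_size - 2,
                                      num=cfg.family_pairs_per_block,
                                      dtype=int).tolist()) \
            if cfg.family_pairs_per_block else set()
        for k in range(cfg.block_size):
            is_family = k in fam_offsets
            if is_family:
                anc, frozen = family_ancestor("I")
            else:
                anc, frozen = background_ancestor(), frozenset()
            div, target = plant_pair(anc, frozen, "WGD")
            slot_b = sb + (cfg.block_size - 1 - k) if reversed_run else sb + k
            gid_a = place(chrom_a, sa + k, div.cds_a, is_family,
                          "I" if is_family else None)
            gid_b = place(chrom_b, slot_b, div.cds_b, is_family,
                          "I" if is_family else None)
            anchors.append(AnchorPair(gid_a, gid_b, 100.0))
            if is_family:
                record_pair(gid_a, gid_b, "WGD", target, div)
                trd_parents.append((gid_a, div, frozen, anc))

    # --- tandem and proximal pairs ------------------------------------
    for i in range(cfg.tandem_pairs):
        chrom = chroms[i % len(chroms)]
        cls = tandem_classes[i]
        anc, frozen = family_ancestor(cls)
        div, target = plant_pair(anc, frozen, "TD")
        s = _take(slots[chrom], 0, (0, 1))
        gid_a = place(chrom, s, div.cds_a, True, cls)
        gid_b = place(chrom, s + 1, div.cds_b, True, cls)
        anchors.append(AnchorPair(gid_a, gid_b, 100.0))
        record_pair(gid_a, gid_b, "TD", target, div)

    for i in range(cfg.proximal_pairs):
        chrom = chroms[(i + 1) % len(chroms)]
        dist = min(2 + 2 * i, 10)
        anc, frozen = family_ancestor("I")
        div, target = plant_pair(anc, frozen, "PD")
        s = _take(slots[chrom], 0, (0, dist))
        gid_a = place(chrom, s, div.cds_a, True, "I")
        gid_b = place(chrom, s + dist, div.cds_b, True, "I")
        anchors.append(AnchorPair(gid_a, gid_b, 100.0))
        record_pair(gid_a, gid_b, "PD", target, div)

    # --- transposed copies (parent is a WGD anchor) --------------------
    for i in range(cfg.transposed_pairs):
        if i >= len(trd_parents):
            raise ValueError("infeasible packing: not enough WGD family "
                             "anchors to parent transposed copies")
        parent_gid, parent_div, frozen, anc = trd_parents[i]
        chrom = chroms[(i + 3) % len(chroms)]
        branch = max(cfg.target_ks["TRD"] - cfg.target_ks["WGD"] / 2.0, 0.05)
        codons = codons_of(anc)
        flux = _syn_flux(codons, cfg.kappa, cfg.omega, frozen)
        scale = parent_div.s_sites / flux if flux > 0 else 0.0
        evolved, s_ev, n_ev = _evolve_branch(codons, branch * scale,
                                             cfg.kappa, cfg.omega, frozen,
                                             rng)
        s = _take(slots[chrom], cfg.genes_per_chromosome // 2, (0,))
        gid_t = place(chrom, s, "".join(evolved), True, "I")
        anchors.append(AnchorPair(parent_gid, gid_t, 100.0))
        record_pair(parent_gid, gid_t, "TRD", cfg.target_ks["TRD"],
                    parent_div, events_a=parent_div.events_a,
                    events_b=(s_ev, n_ev))

    # --- dispersed pairs ----------------------------------------------
    for i in range(cfg.dispersed_pairs):
        chrom_a = chroms[i % len(chroms)]
        chrom_b = chroms[(i + 3) % len(chroms)]
        if chrom_a == chrom_b:
            chrom_b = chroms[(i + 4) % len(chroms)]
        anc, frozen = family_ancestor("I")
        div, target = plant_pair(anc, frozen, "DD")
        s_a = _take(slots[chrom_a], 0, (0,))
        s_b = _take(slots[chrom_b], 0, (0,))
        gid_a = place(chrom_a, s_a, div.cds_a, True, "I")
        gid_b = place(chrom_b, s_b, div.cds_b, True, "I")
        anchors.append(AnchorPair(gid_a, gid_b, 100.0))
        record_pair(gid_a, gid_b, "DD", target, div)

    # --- singletons and scaffold-anchored members ----------------------
    for i in range(cfg.singletons):
        chrom = chroms[(i + 2) % len(chroms)]
        cls = singleton_classes[i]
        anc, _frozen = family_ancestor(cls)
        s = _take(slots[chrom], 0, (0,))
        place(chrom, s, anc, True, cls)

    scaffold_specs: list[_GeneSpec] = []
    if cfg.scaffold_members:
        scaffold = "scaffold1"
        for i in range(cfg.scaffold_members):
            anc, _frozen = family_ancestor("I")
            gid = f"{scaffold}g{i + 1:03d}"
            scaffold_specs.append(_GeneSpec(gid, scaffold, i, anc,
                                            "+" if rng.random() < 0.5
                                            else "-", True, "I"))
            truth.classes[gid] = "I"
            truth.scaffold_genes.append(gid)

    # --- background fill ----------------------------------------------
    for chrom in chroms:
        for slot in range(cfg.genes_per_chromosome):
            if slots[chrom][slot] is None:
                place(chrom, slot, background_ancestor(), False)

    # --- assemble chromosome sequences ---------------------------------
    chrom_len = cfg.genes_per_chromosome * cfg.slot_bp + 1000
    base_arr = {c: rng.integers(0, 4, size=chrom_len).astype(np.uint8)
                for c in chroms}
    scaffold_len = (cfg.scaffold_members or 1) * cfg.slot_bp + 1000
    if cfg.scaffold_members:
        base_arr["scaffold1"] = rng.integers(
            0, 4, size=scaffold_len).astype(np.uint8)

    lut = {b: i for i, b in enumerate("ACGT")}

    def encode(seq: str) -> np.ndarray:
        return np.array([lut[ch] for ch in seq], dtype=np.uint8)

    genes: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    all_specs = specs + scaffold_specs
    for spec in all_specs:
        start = spec.slot * cfg.slot_bp + cfg.gene_offset_bp
        end = start + len(spec.cds)
        arr = base_arr[spec.chrom]
        placed = spec.cds if spec.strand == "+" \
            else reverse_complement(spec.cds)
        arr[start:end] = encode(placed)
        genes.append(GeneModel(spec.gene_id, spec.chrom, start, end,
                               spec.strand))
        cds_map[spec.gene_id] = spec.cds

    # --- promoters with planted elements -------------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    for spec in all_specs:
        if not spec.family:
            continue
        g = gene_by_id[spec.gene_id]
        arr = base_arr[spec.chrom]
        taken: list[tuple[int, int]] = []
        for _ in range(cfg.elements_per_gene):
            motif = catalog[int(rng.integers(0, len(catalog)))]
            instance = _instantiate(motif.consensus, rng)
            L = len(instance)
            for _try in range(100):
                off = int(rng.integers(0, cfg.promoter_len - L + 1))
                if all(off + L <= lo or off >= hi for lo, hi in taken):
                    break
            else:
                continue
            taken.append((off, off + L))
            if spec.strand == "+":
                gstart = g.start - cfg.promoter_len + off
                arr[gstart:gstart + L] = encode(instance)
            else:
                gstart = g.end + cfg.promoter_len - off - L
                arr[gstart:gstart + L] = encode(reverse_complement(instance))
            truth.elements.append(PlantedElement(
                spec.gene_id, motif.name, motif.category, off, instance))

    decode = np.array(list("ACGT"))
    genome = {c: "".join(decode[a]) for c, a in sorted(base_arr.items())}
    lengths = {c: len(s) for c, s in genome.items()}
    annotation = annotate(genes, lengths)
    proteins = {gid: translate_cds(c, gid) for gid, c in cds_map.items()}
    return SyntheticGenome(cfg, genome, annotation, cds_map, proteins,
                           anchors, catalog, truth)


# ---------------------------------------------------------------------------
# expression and qPCR simulation

def simulate_counts(sg: SyntheticGenome, cfg: SimConfig | None = None,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Negative-binomial tissue counts for the family with planted presence.

    Planted-absent cells are structural zeros; planted-present cells draw
    from NB(mean = level * length_kb * depth, dispersion) truncated at one
    read so a sampling zero cannot contradict the planted presence.
    Fills truth.presence / truth.expression_level and the count-matrix
    companions on the genome object.
    """
    cfg = cfg or sg.config
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    genes = sg.family_ids()
    n = len(genes)
    tissues = list(cfg.tissues)
    n_silent = int(round(cfg.silent_fraction * n))
    silent = set(rng.choice(genes, size=n_silent, replace=False).tolist())
    expressible = [g for g in genes if g not in silent]
    presence = pd.DataFrame(False, index=genes, columns=tissues)
    for t, frac in zip(tissues, cfg.tissue_presence_fraction):
        k = min(int(round(frac * n)), len(expressible))
        chosen = rng.choice(expressible, size=k, replace=False)
        presence.loc[sorted(chosen), t] = True
    lo, hi = cfg.expression_range
    level = pd.DataFrame(rng.uniform(lo, hi, size=(n, len(tissues))),
                         index=genes, columns=tissues).where(presence, 0.0)
    lengths = {g: len(sg.cds[g]) for g in genes}
    counts = pd.DataFrame(0, index=genes, columns=tissues, dtype=int)
    for t in tissues:
        mu = (level[t] * pd.Series(lengths) * cfg.library_size / 1e9)
        for g in genes:
            if not presence.loc[g, t]:
                continue
            m = mu[g]
            if cfg.nb_dispersion > 0:
                r = 1.0 / cfg.nb_dispersion
                draw = rng.negative_binomial(r, r / (r + m))
            else:
                draw = rng.poisson(m)
            counts.loc[g, t] = max(int(draw), 1)
    sg.truth.presence = presence
    sg.truth.expression_level = level
    sg.counts = counts
    sg.gene_lengths = lengths
    sg.library_sizes = {t: cfg.library_size for t in tissues}
    return counts


def simulate_ct(sg: SyntheticGenome, cfg: SimConfig | None = None,
                seed: int | np.random.Generator = 0,
                noise_sd: float | None = None) -> pd.DataFrame:
    """qPCR Ct table with planted fold changes against the first tissue.

    Target Ct decreases by one cycle per planted log2 fold change; the
    reference gene sits at a constant Ct.  Gaussian Ct noise (sd
    ``noise_sd``, default from config) is shared by target and reference
    draws independently.  Fills truth.fold_changes.
    """
    cfg = cfg or sg.config
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sd = cfg.ct_noise_sd if noise_sd is None else noise_sd
    genes = sg.family_ids()[:cfg.qpcr_genes]
    tissues = list(cfg.tissues)
    log2fold = pd.DataFrame(
        rng.integers(-2, 3, size=(len(genes), len(tissues))).astype(float),
        index=genes, columns=tissues)
    log2fold[tissues[0]] = 0.0     # calibrator tissue
    rows = []
    for g in genes:
        base = float(rng.uniform(22.0, 26.0))
        for t in tissues:
            for rep in range(cfg.qpcr_replicates):
                noise_t = rng.normal(0.0, sd) if sd > 0 else 0.0
                noise_r = rng.normal(0.0, sd) if sd > 0 else 0.0
                rows.append({"gene": g, "sample": t, "replicate": rep,
                             "target_ct": base - log2fold.loc[g, t] + noise_t,
                             "reference_ct": 20.0 + noise_r})
    sg.truth.fold_changes = 2.0 ** log2fold
    sg.ct = pd.DataFrame(rows)
    return sg.ct
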
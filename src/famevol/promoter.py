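"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2000 bp immediately upstream of the gene start (the
transcription start is taken as the gene-feature start), strand-aware: for a
minus-strand gene the slice downstream of the feature end is taken and
reverse-complemented, so the returned sequence always reads 5'->3' toward
the gene.  Scanning matches IUPAC degenerate consensi exactly (set
membership per position, no mismatches) on both strands, reporting every
offset including overlapping ones.

The package ships a small catalog with one representative consensus per
element category for testing; real analyses should supply their own catalog
(name, category, IUPAC consensus as a 3-column TSV).
"""
from __future__ import annotations

import dataclasses
import re
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_core import FormatError, GeneModel, GenomeAnnotation, SequenceRecord

IUPAC_SETS: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class MotifEntry:
    name: str
    category: str
    consensus: str

    def __post_init__(self):
        if len(self.consensus) < 4:
            raise ValueError(f"motif {self.name}: consensus shorter than 4")
        bad = set(self.consensus) - set(IUPAC_SETS)
        if bad:
            raise FormatError(
                f"motif {self.name}: illegal IUPAC letters {sorted(bad)}")

    def regex(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC_SETS[ch]}]"
                                  for ch in self.consensus))


def read_catalog(path) -> list[MotifEntry]:
    """Read a motif catalog TSV (name, category, consensus; header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "category", "consensus"}
    if not required.issubset(df.columns):
        raise FormatError(f"catalog must have columns {sorted(required)}")
    return [MotifEntry(r["name"], r["category"], r["consensus"].upper())
            for _, r in df.iterrows()]


def load_default_catalog() -> list[MotifEntry]:
    """The shipped single-representative-per-category test catalog."""
    with resources.as_file(resources.files("famevol.data")
                           / "cis_catalog.tsv") as p:
        return read_catalog(p)


@dataclasses.dataclass
class PromoterRegion:
    gene_id: str
    chrom: str
    span: tuple[int, int]      # 0-based half-open genomic span
    strand: str
    sequence: str              # 5'->3' toward the gene (RC'd for minus)
    clipped: bool


def extract_promoter(gene: GeneModel, genome: Mapping[str, str],
                     length: int = 2000) -> PromoterRegion:
    """Strand-aware upstream slice of the gene start, clipped at chromosome
    bounds."""
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} missing from genome")
    chrom_seq = genome[gene.chrom]
    if gene.strand == "+":
        lo, hi = max(0, gene.start - length), gene.start
        seq = chrom_seq[lo:hi]
        clipped = gene.start - length < 0
    else:
        lo, hi = gene.end, min(len(chrom_seq), gene.end + length)
        seq = reverse_complement(chrom_seq[lo:hi])
        clipped = gene.end + length > len(chrom_seq)
    return PromoterRegion(gene.gene_id, gene.chrom, (lo, hi), gene.strand,
                          seq, clipped)


@dataclasses.dataclass(frozen=True)
class ElementHit:
    gene_id: str
    motif: str
    category: str
    offset: int                # 0-based within the promoter sequence
    strand: str                # strand of the hit relative to the promoter


def scan_elements(promoter: PromoterRegion, catalog: Sequence[MotifEntry],
                  both_strands: bool = True) -> list[ElementHit]:
    """Every (overlapping) IUPAC consensus match in the promoter; with
    both_strands, matches of the reverse complement are reported as
    minus-strand hits at their forward-coordinate offset."""
    hits: list[ElementHit] = []
    seq = promoter.sequence
    n = len(seq)
    for motif in catalog:
        pat = motif.regex()
        wrapped = re.compile(f"(?=({pat.pattern}))")
        for m in wrapped.finditer(seq):
            hits.append(ElementHit(promoter.gene_id, motif.name,
                                   motif.category, m.start(), "+"))
        if both_strands:
            rc = reverse_complement(seq)
            L = len(motif.consensus)
            for m in wrapped.finditer(rc):
                hits.append(ElementHit(promoter.gene_id, motif.name,
                                       motif.category, n - m.start() - L,
                                       "-"))
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def count_matrix(hits: Iterable[ElementHit], catalog: Sequence[MotifEntry],
                 family_ids: Sequence[str]) -> pd.DataFrame:
    """gene x category integer counts; every family gene gets a row and
    every catalog category a column, so the grand total equals len(hits)."""
    categories = sorted({m.category for m in catalog})
    df = pd.DataFrame(0, index=list(family_ids), columns=categories,
                      dtype=int)
    for h in hits:
        if h.gene_id in df.index:
            df.loc[h.gene_id, h.category] += 1
    return df


def scan_family_promoters(annotation: GenomeAnnotation,
                          genome: Mapping[str, str],
                          family_ids: Sequence[str],
                          catalog: Sequence[MotifEntry],
                          length: int = 2000,
                          both_strands: bool = True
                          ) -> tuple[list[PromoterRegion], list[ElementHit],
                                     pd.DataFrame]:
    """Extract and scan the promoters of a gene family; returns (promoters,
    hits, gene x category counts)."""
    promoters, hits = [], []
    for gid in family_ids:
        prom = extract_promoter(annotation[gid], genome, length)
        promoters.append(prom)
        hits.extend(scan_elements(prom, catalog, both_strands))
    return promoters, hits, count_matrix(hits, catalog, family_ids)
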
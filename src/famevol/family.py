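"""LOB-domain family identification.

The LBD transcription-factor family is defined by two literal motifs in the
protein sequence: an N-terminal CX2CX6CX3C zinc-finger-like domain (DNA
binding) and, in class I members only, a downstream LX6LX3LX6L leucine
zipper-like domain (protein-protein interaction).  Identification here is
deterministic pattern matching on those motifs: candidates without a complete
zinc finger are rejected, zinc finger plus downstream zipper is class I, zinc
finger alone is class II.  Members are filtered to chromosome-placed
sequences, named by chromosome order, and annotated with protein length,
molecular weight and isoelectric point.
"""
from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

from .io_core import (AA_LETTERS, GeneModel, GenomeAnnotation, SequenceRecord,
                      natural_key)

ZINC_FINGER_LENGTH = 15   # C xx C xxxxxx C xxx C
ZIPPER_LENGTH = 19        # L xxxxxx L xxx L xxxxxx L

#: Default spacer lengths of the two motifs (between the four anchors).
ZF_SPACERS = (2, 6, 3)
ZIPPER_SPACERS = (6, 3, 6)

#: Residues accepted at the four zipper anchor positions.  The strict default
#: is leucine only; the relaxed set admits the other aliphatic residues that
#: commonly occupy zipper heptad positions.
ZIPPER_ANCHORS_STRICT = frozenset("L")
ZIPPER_ANCHORS_RELAXED = frozenset("LIVM")


@dataclasses.dataclass(frozen=True)
class DomainHit:
    kind: str             # "zinc_finger" | "leucine_zipper"
    start: int            # 0-based amino-acid offset
    end: int              # exclusive


@dataclasses.dataclass
class FamilyMember:
    gene_id: str
    family_name: str
    class_label: str      # "I" | "II"
    hits: list[DomainHit]
    length_aa: int
    mw_da: float
    pi: float


def _motif_regex(anchors: Iterable[str], spacers: Sequence[int],
                 spacer_widen: int = 0) -> re.Pattern:
    anchor = "[" + "".join(sorted(set(anchors))) + "]"
    parts = [anchor]
    for s in spacers:
        if spacer_widen:
            lo, hi = max(0, s - spacer_widen), s + spacer_widen
            parts.append(f".{{{lo},{hi}}}{anchor}")
        else:
            parts.append(f".{{{s}}}{anchor}")
    return re.compile("".join(parts))


def scan_zinc_finger(protein: SequenceRecord,
                     spacer_widen: int = 0) -> list[DomainHit]:
    """All non-overlapping CX2CX6CX3C matches, left-to-right greedy."""
    if protein.alphabet != "aa":
        raise ValueError("zinc-finger scan requires a protein sequence")
    pat = _motif_regex("C", ZF_SPACERS, spacer_widen)
    return [DomainHit("zinc_finger", m.start(), m.end())
            for m in pat.finditer(protein.residues)]


def scan_leucine_zipper(protein: SequenceRecord, after: int = 0,
                        anchors: frozenset[str] = ZIPPER_ANCHORS_STRICT,
                        spacer_widen: int = 0) -> list[DomainHit]:
    """All non-overlapping LX6LX3LX6L matches starting at offset >= after."""
    if after < 0:
        raise ValueError("after must be >= 0")
    pat = _motif_regex(anchors, ZIPPER_SPACERS, spacer_widen)
    return [DomainHit("leucine_zipper", m.start() + after, m.end() + after)
            for m in pat.finditer(protein.residues[after:])]


def classify_member(protein: SequenceRecord,
                    zipper_anchors: frozenset[str] = ZIPPER_ANCHORS_STRICT,
                    spacer_widen: int = 0) -> tuple[str, list[DomainHit]]:
    """Classify a protein as ("class_I" | "class_II" | "rejected", hits).

    Class I requires a complete zinc finger with a leucine zipper downstream
    of it; class II a zinc finger only; anything without a complete zinc
    finger is rejected.
    """
    zf = scan_zinc_finger(protein, spacer_widen)
    if not zf:
        return "rejected", []
    zips = scan_leucine_zipper(protein, after=zf[0].end,
                               anchors=zipper_anchors,
                               spacer_widen=spacer_widen)
    if zips:
        return "class_I", zf + zips
    return "class_II", zf


def apply_location_filter(gene_ids: Sequence[str],
                          annotation: GenomeAnnotation
                          ) -> tuple[list[str], list[tuple[str, str]]]:
    """Split candidate genes into chromosome-placed (kept) and scaffold-
    anchored (dropped, with reason)."""
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for gid in gene_ids:
        if gid not in annotation:
            raise KeyError(f"candidate gene {gid!r} absent from annotation")
        if annotation.is_chromosome_placed(gid):
            kept.append(gid)
        else:
            dropped.append((gid, "scaffold"))
    return kept, dropped


def name_by_chromosome_order(gene_ids: Sequence[str],
                             annotation: GenomeAnnotation,
                             prefix: str) -> dict[str, str]:
    """1-based family names prefix+N in (natural chromosome sort, start) order,
    ties at identical start broken by gene_id."""
    genes = [annotation[gid] for gid in gene_ids]
    genes.sort(key=lambda g: (natural_key(g.chrom), g.start, g.gene_id))
    return {g.gene_id: f"{prefix}{i + 1}" for i, g in enumerate(genes)}


# ---------------------------------------------------------------------------
# protein physical properties
#
# Average residue masses (Da) follow the ExPASy standard table; pKa values
# follow the EMBOSS set.  Both are fixed here so results are reproducible
# bit-for-bit; docs/methods.md names the sources.

RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def molecular_weight(sequence: str) -> float:
    """Average molecular weight: sum of residue masses plus one water."""
    try:
        return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"ambiguous or unknown residue {exc.args[0]!r}") from None


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge over termini and ionizable side
    chains (D, E, C, Y, H, K, R)."""
    pos = [PKA_POSITIVE["nterm"]]
    neg = [PKA_NEGATIVE["cterm"]]
    for aa in sequence:
        if aa in PKA_POSITIVE:
            pos.append(PKA_POSITIVE[aa])
        elif aa in PKA_NEGATIVE:
            neg.append(PKA_NEGATIVE[aa])
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pI by bisection on the net charge (monotone decreasing in pH).

    The interval is narrowed to 1e-7 pH units, which drives |charge| well
    below ``tol`` for every 20-letter sequence."""
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    mid = (lo + hi) / 2.0
    assert abs(net_charge(sequence, mid)) < tol
    return mid


def protein_properties(protein: SequenceRecord) -> tuple[int, float, float]:
    """(length_aa, average MW in Da, pI)."""
    seq = protein.residues
    bad = set(seq) - AA_LETTERS
    if bad:
        raise ValueError(f"ambiguity letters {sorted(bad)} in {protein.id}")
    return len(seq), molecular_weight(seq), isoelectric_point(seq)


# ---------------------------------------------------------------------------
# end-to-end identification

def identify_family(proteins: Sequence[SequenceRecord],
                    annotation: GenomeAnnotation, prefix: str,
                    zipper_anchors: frozenset[str] = ZIPPER_ANCHORS_STRICT,
                    spacer_widen: int = 0
                    ) -> tuple[list[FamilyMember], list[tuple[str, str]]]:
    """Scan a proteome, reject incomplete domains, drop scaffold-anchored
    genes, name survivors by chromosome order and compute properties.

    Returns (members sorted by family ordinal, dropped candidates with
    reasons — "incomplete_domain" or "scaffold").
    """
    classified: dict[str, tuple[str, list[DomainHit]]] = {}
    dropped: list[tuple[str, str]] = []
    for prot in proteins:
        verdict, hits = classify_member(prot, zipper_anchors, spacer_widen)
        if verdict == "rejected":
            if hits or scan_zinc_finger(prot, spacer_widen=1):
                dropped.append((prot.id, "incomplete_domain"))
            continue
        classified[prot.id] = (verdict, hits)
    kept, scaffold_dropped = apply_location_filter(sorted(classified),
                                                   annotation)
    dropped.extend(scaffold_dropped)
    names = name_by_chromosome_order(kept, annotation, prefix)
    by_id = {p.id: p for p in proteins}
    members = []
    for gid in kept:
        verdict, hits = classified[gid]
        length, mw, pi = protein_properties(by_id[gid])
        members.append(FamilyMember(
            gene_id=gid, family_name=names[gid],
            class_label="I" if verdict == "class_I" else "II",
            hits=hits, length_aa=length, mw_da=mw, pi=pi))
    members.sort(key=lambda m: int(m.family_name[len(prefix):]))
    return members, dropped
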
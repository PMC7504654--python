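"""Shared I/O layer: FASTA, GFF3, homolog-pair tables, Newick, run manifests.

Internal coordinates are 0-based half-open on every type; conversion to and
from the 1-based inclusive GFF3 convention happens only inside the readers
and writers in this module, so no downstream code ever adds or subtracts one.
"""
from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

NT_LETTERS = frozenset("ACGT")
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"

DEFAULT_SCAFFOLD_PATTERN = r"scaffold"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequences

@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an explicit alphabet ("nt" or "aa")."""

    id: str
    residues: str
    alphabet: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _check_residues(rec_id: str, residues: str, alphabet: str,
                    allow_gaps: bool, allow_iupac: bool) -> None:
    allowed = NT_LETTERS if alphabet == "nt" else AA_LETTERS
    if allow_iupac and alphabet == "nt":
        allowed = IUPAC_NT
    if allow_gaps:
        allowed = allowed | {GAP}
    for pos, ch in enumerate(residues):
        if ch not in allowed:
            raise FormatError(
                f"illegal {alphabet} residue {ch!r} at position {pos} "
                f"in record {rec_id!r}")


def read_fasta(path, alphabet: str, *, allow_gaps: bool = False,
               allow_iupac: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased, validated records.

    Raises :class:`FormatError` on duplicate IDs or residues illegal for
    the declared alphabet (gap characters are accepted only when
    ``allow_gaps`` is set, for pre-aligned input).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        _check_residues(rec.id, residues, alphabet, allow_gaps, allow_iupac)
        records.append(SequenceRecord(rec.id, residues, alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models and annotation

@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A located gene: 0-based half-open span plus per-chromosome rank."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}")


def natural_key(name: str):
    """Sort key treating digit runs numerically, so chr2 < chr10."""
    return tuple((0, int(tok)) if tok.isdigit() else (1, tok)
                 for tok in re.split(r"(\d+)", name) if tok != "")


@dataclasses.dataclass
class GenomeAnnotation:
    """Gene models with chromosome lengths and chromosome/scaffold placement."""

    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    placement: dict[str, str]

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            ids = [g.gene_id for g in self.genes]
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate gene_id {dup!r} in annotation")
        for g in self.genes:
            length = self.chrom_lengths.get(g.chrom)
            if length is not None and g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} span exceeds {g.chrom} length {length}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted((g for g in self.genes if g.chrom == chrom),
                      key=lambda g: g.rank)

    @property
    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self.genes}, key=natural_key)

    def is_chromosome_placed(self, gene_id: str) -> bool:
        return self.placement.get(self[gene_id].chrom) == "chromosome"


def annotate(genes: Sequence[GeneModel],
             chrom_lengths: Mapping[str, int] | None = None,
             scaffold_pattern: str = DEFAULT_SCAFFOLD_PATTERN) -> GenomeAnnotation:
    """Assign per-chromosome ranks (by start, ties by gene_id) and placement.

    Rank assignment is stable under permutation of the input order.
    """
    pat = re.compile(scaffold_pattern, re.IGNORECASE)
    ranked: list[GeneModel] = []
    chroms = sorted({g.chrom for g in genes}, key=natural_key)
    for chrom in chroms:
        members = sorted((g for g in genes if g.chrom == chrom),
                         key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(members):
            ranked.append(dataclasses.replace(g, rank=rank))
    lengths = dict(chrom_lengths) if chrom_lengths else {}
    for chrom in chroms:
        if chrom not in lengths:
            lengths[chrom] = max(g.end for g in genes if g.chrom == chrom)
    placement = {c: ("scaffold" if pat.search(c) else "chromosome")
                 for c in chroms}
    return GenomeAnnotation(ranked, lengths, placement)


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|Name)=([^;]+)")


def read_gff3(path, feature_type: str = "gene",
              scaffold_pattern: str = DEFAULT_SCAFFOLD_PATTERN) -> GenomeAnnotation:
    """Read gene features from GFF3 (1-based inclusive) into 0-based models."""
    genes: list[GeneModel] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols[:9]
            if ftype != feature_type:
                continue
            start1, end1 = int(start1), int(end1)
            if end1 < start1:
                raise FormatError(
                    f"{path}:{lineno}: end {end1} < start {start1}")
            m = _GFF_ID_RE.search(attrs)
            gene_id = m.group(1) if m else f"{chrom}:{start1}-{end1}"
            try:
                genes.append(GeneModel(gene_id, chrom, start1 - 1, end1,
                                       strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return annotate(genes, lengths or None, scaffold_pattern)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write gene features back out in 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 "
                     f"{annotation.chrom_lengths[chrom]}\n")
        for chrom in annotation.chromosomes:
            for g in annotation.genes_on(chrom):
                fh.write("\t".join([
                    g.chrom, "famevol", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# homolog-pair tables

def read_pair_table(path) -> list[tuple[str, str, float]]:
    """Read a BLAST-tabular-like pair table (query, subject, score, ...).

    Self-pairs are dropped; unordered duplicates keep the maximum score.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-delimited columns")
            a, b, raw = cols[0], cols[1], cols[2]
            try:
                score = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in best:
                order.append(key)
                best[key] = score
            else:
                best[key] = max(best[key], score)
    return [(a, b, best[(a, b)]) for a, b in order]


def write_pair_table(pairs: Iterable[tuple[str, str, float]], path) -> None:
    with open(path, "w") as fh:
        for a, b, score in pairs:
            fh.write(f"{a}\t{b}\t{_fmt_num(score)}\n")


# ---------------------------------------------------------------------------
# Newick

def _fmt_num(x: float) -> str:
    if x == int(x):
        return f"{float(x):.1f}"
    return f"{x:.6f}".rstrip("0")


def write_newick(tree, path=None) -> str:
    """Serialize a phylogeny to Newick with branch lengths and integer
    bootstrap supports as internal-node labels. Returns the string; also
    writes it when ``path`` is given."""

    def render(node) -> str:
        if not node.children:
            if not node.name:
                raise ValueError("unnamed leaf cannot be serialized")
            return f"{node.name}:{_fmt_num(node.length or 0.0)}"
        inner = ",".join(render(c) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        if node.parent is None:
            return f"({inner}){label}"
        return f"({inner}){label}:{_fmt_num(node.length or 0.0)}"

    text = render(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source) -> "PhyloNode":
    """Parse Newick (file path or string) into a phylogeny, interpreting
    numeric internal-node labels as bootstrap supports."""
    from .phylogeny import PhyloNode  # deferred: avoids a module cycle
    import skbio

    text = source if str(source).lstrip().startswith("(") else Path(source).read_text()
    sk = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)

    def convert(node, parent=None):
        support = None
        name = node.name
        if node.children and name is not None:
            try:
                support = int(float(name))
                name = None
            except ValueError:
                pass
        out = PhyloNode(name=name, length=node.length, support=support,
                        parent=parent)
        for child in node.children:
            out.children.append(convert(child, out))
        return out

    return convert(sk)


# ---------------------------------------------------------------------------
# run manifests

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, command: str, seed: int | None,
                   params: Mapping, inputs: Mapping[str, str],
                   outputs: Sequence[str]) -> Path:
    """Record the reproducibility contract of a run: command, seed, params,
    input digests and output names."""
    manifest = {
        "command": command,
        "seed": seed,
        "params": {k: params[k] for k in sorted(params)},
        "inputs": {name: sha256_of(p) for name, p in sorted(inputs.items())},
        "outputs": sorted(outputs),
    }
    path = Path(outdir) / f"{command}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
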
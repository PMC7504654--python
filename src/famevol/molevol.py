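"""Pairwise molecular evolution: protein-guided codon alignment, NG86 Ka/Ks,
fourfold-degenerate transversion distance (4DTv), selection-regime
classification and Ks-based duplication dating.

The Ka/Ks estimator is the Nei-Gojobori (NG86) counting method: synonymous
and nonsynonymous sites are counted fractionally per codon (each codon
position contributes one site, split by the proportion of single-nucleotide
changes that preserve the amino acid; changes creating a stop codon are
excluded from the proportion), observed differences between codons that
differ at several positions are averaged over all mutational pathways that
avoid stop codons, and both proportions receive the Jukes-Cantor multiple-hit
correction d = -(3/4) ln(1 - (4/3) p).  An optional kappa-weighted site
counting variant down-weights transversions in the site counts, approximating
the behavior of codon estimators that model transition bias.

4DTv is the proportion of transversions among third positions of codon
columns where both sequences carry fourfold-degenerate codons from the same
family (identical first two bases); it resists saturation and tends to 0.5
under equal base frequencies.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from functools import lru_cache
from typing import Mapping

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_core import SequenceRecord

_STD = CodonTable.unambiguous_dna_by_id[1]   # NCBI translation table 1
STOP_CODONS = frozenset(_STD.stop_codons)
AA_OF: Mapping[str, str] = dict(_STD.forward_table)
SENSE_CODONS = tuple(sorted(AA_OF))
BASES = "TCAG"
PURINES = frozenset("AG")

#: Codon prefixes whose four completions all encode the same amino acid.
FOURFOLD_PREFIXES = frozenset(
    p for p in (a + b for a in BASES for b in BASES)
    if len({AA_OF.get(p + c, "*") for c in BASES}) == 1
    and (p + "T") not in STOP_CODONS)


def is_transition(a: str, b: str) -> bool:
    return a != b and (a in PURINES) == (b in PURINES)


def codons_of(cds: str, name: str = "cds") -> list[str]:
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def translate_cds(cds: str, name: str = "cds") -> str:
    """Translate, allowing a single terminal stop codon only."""
    codons = codons_of(cds, name)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {codon} at codon {idx}")
        aas.append(AA_OF[codon])
    return "".join(aas)


# ---------------------------------------------------------------------------
# protein-guided codon alignment

@dataclasses.dataclass
class CodonAlignment:
    """A pair of gap-aligned CDS (lengths equal, divisible by 3) plus the
    gap-free codon column pairs."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned CDS lengths differ")
        if len(self.aligned_a) % 3:
            raise ValueError("aligned length not divisible by 3")

    @property
    def codon_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(0, len(self.aligned_a), 3):
            ca, cb = self.aligned_a[i:i + 3], self.aligned_b[i:i + 3]
            if "-" in ca or "-" in cb:
                continue
            out.append((ca, cb))
        return out


NEG_INF = float("-inf")


def _affine_align(a: str, b: str, matrix, gap_open: float,
                  gap_extend: float) -> tuple[str, str, float]:
    """Global affine-gap alignment (Gotoh).  A gap of length k costs
    gap_open + (k-1) * gap_extend.  Traceback ties prefer match over delete
    (gap in b) over insert (gap in a), which makes the result deterministic.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]   # gap in a (insert b)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]   # gap in b (delete a)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Y[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        X[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_extend,
                          Y[i][j - 1] - gap_open)
            Y[i][j] = max(M[i - 1][j] - gap_open, Y[i - 1][j] - gap_extend,
                          X[i - 1][j] - gap_open)
    i, j = n, m
    state = max(("M", "Y", "X"),
                key=lambda st: {"M": M[i][j], "X": X[i][j], "Y": Y[i][j]}[st])
    score = {"M": M[i][j], "X": X[i][j], "Y": Y[i][j]}[state]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[a[i - 1], b[j - 1]]
            prev = [st for st in ("M", "Y", "X")
                    if abs({"M": M, "X": X, "Y": Y}[st][i - 1][j - 1] + s
                           - M[i][j]) < 1e-9]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = prev[0] if i or j else "M"
        elif state == "Y":   # delete: consume a
            out_a.append(a[i - 1])
            out_b.append("-")
            cur = Y[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            for st, cost in (("M", gap_open), ("Y", gap_extend),
                             ("X", gap_open)):
                if abs({"M": M, "X": X, "Y": Y}[st][i][j] - cost - cur) < 1e-9:
                    state = st
                    break
        else:                # insert: consume b
            out_a.append("-")
            out_b.append(b[j - 1])
            cur = X[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            for st, cost in (("M", gap_open), ("X", gap_extend),
                             ("Y", gap_open)):
                if abs({"M": M, "X": X, "Y": Y}[st][i][j] - cost - cur) < 1e-9:
                    state = st
                    break
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def align_codon_pair(cds_a: SequenceRecord, cds_b: SequenceRecord,
                     gap_open: float = 10.0, gap_extend: float = 0.5,
                     substitution_table: str = "BLOSUM62") -> CodonAlignment:
    """Globally align the two translations with affine gaps and back-translate
    the alignment to codon space (the ParaAT strategy)."""
    prot_a = translate_cds(cds_a.residues, cds_a.id)
    prot_b = translate_cds(cds_b.residues, cds_b.id)
    matrix = substitution_matrices.load(substitution_table)
    aln_a, aln_b, _ = _affine_align(prot_a, prot_b, matrix, gap_open,
                                    gap_extend)

    def back_translate(aln: str, cds: str) -> str:
        codons = codons_of(cds)
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        out, k = [], 0
        for ch in aln:
            if ch == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        return "".join(out)

    return CodonAlignment(cds_a.id, cds_b.id,
                          back_translate(aln_a, cds_a.residues),
                          back_translate(aln_b, cds_b.residues))


# ---------------------------------------------------------------------------
# NG86

@lru_cache(maxsize=None)
def site_fractions(codon: str, kappa: float = 1.0) -> float:
    """Synonymous sites in a codon (0..3).  Each position contributes one
    site split by the (kappa-weighted) proportion of non-stop single-base
    changes that preserve the amino acid; kappa=1 gives plain NG86."""
    syn_sites = 0.0
    for pos in range(3):
        syn = tot = 0.0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], b) else 1.0
            tot += w
            if AA_OF[alt] == AA_OF[codon]:
                syn += w
        if tot:
            syn_sites += syn / tot
    return syn_sites


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) observed differences between two codons,
    averaged over all mutational orderings that avoid stop codons (all
    orderings if every pathway hits a stop)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
            if AA_OF.get(nxt, "*") == AA_OF.get(cur, "*"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if ok else fallback).append((sd, nd))
    paths = valid or fallback
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4).

    The boundary test carries a 1e-9 guard so a floating-point tie at
    exactly 3/4 (possible on tiny alignments) is classified as saturated
    regardless of summation order."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75 - 1e-9:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclasses.dataclass
class EvolEstimate:
    """Per-pair molecular-evolution estimates.  ka/ks/omega/fourdtv are None
    when undefined (zero divergence, zero eligible sites) and ks carries the
    saturated flag when p_s >= 3/4."""

    ka: float | None
    ks: float | None
    omega: float | None
    kappa: float | None
    fourdtv: float | None
    n_4d_sites: int
    s_sites: float
    n_sites: float
    ps: float = 0.0
    pn: float = 0.0
    saturated: bool = False


def ng86_kaks(aln: CodonAlignment, method: str = "ng86",
              kappa: float | None = None) -> EvolEstimate:
    """NG86 Ka/Ks on the gap-free codon columns of a codon alignment.

    method="ng86" is plain Nei-Gojobori counting; method="kweighted" weights
    the site counts by the transition/transversion ratio (estimated from
    fourfold-degenerate sites when ``kappa`` is not given).
    """
    pairs = aln.codon_pairs
    if not pairs:
        raise ValueError("no gap-free codon columns to estimate from")
    for ca, cb in pairs:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError("stop codon inside gap-free alignment columns")
    kappa_hat = _kappa_from_4d(pairs)
    if method == "kweighted":
        k = kappa if kappa is not None else (kappa_hat or 1.0)
    elif method == "ng86":
        k = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    s_sites = sum(site_fractions(ca, k) + site_fractions(cb, k)
                  for ca, cb in pairs) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    sd = nd = 0.0
    for ca, cb in pairs:
        d_s, d_n = pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = ks is None
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    fourdtv, n4d = four_dtv(aln)
    return EvolEstimate(ka=ka, ks=ks, omega=omega, kappa=kappa_hat,
                        fourdtv=fourdtv, n_4d_sites=n4d,
                        s_sites=s_sites, n_sites=n_sites,
                        ps=ps, pn=pn, saturated=saturated)


def _eligible_4d(pairs) -> list[tuple[str, str]]:
    return [(ca, cb) for ca, cb in pairs
            if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES]


def _kappa_from_4d(pairs) -> float | None:
    """Transition/transversion rate ratio from fourfold third positions:
    kappa = 2 * transitions / transversions (two transversion targets per
    base). None when no transversions are observed."""
    ti = tv = 0
    for ca, cb in _eligible_4d(pairs):
        if ca[2] == cb[2]:
            continue
        if is_transition(ca[2], cb[2]):
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return 2.0 * ti / tv


def four_dtv(aln: CodonAlignment,
             corrected: bool = False) -> tuple[float | None, int]:
    """(4DTv, eligible site count).

    Eligible sites are gap-free codon columns where both codons belong to the
    same fourfold-degenerate family (identical first two bases); the value is
    the fraction of those third positions differing by a transversion, or
    None when no site is eligible.  With ``corrected`` the K80 transversion
    distance -0.5 ln(1 - 2Q) is returned instead of the raw proportion Q.
    """
    eligible = _eligible_4d(aln.codon_pairs)
    n = len(eligible)
    if n == 0:
        return None, 0
    tv = sum(1 for ca, cb in eligible
             if ca[2] != cb[2] and not is_transition(ca[2], cb[2]))
    q = tv / n
    if corrected:
        if q >= 0.5:
            return None, n
        return -0.5 * math.log(1.0 - 2.0 * q), n
    return q, n


# ---------------------------------------------------------------------------
# selection regime, WGD bands, dating

def classify_selection(est: EvolEstimate, neutral_band: float = 0.05) -> str:
    """purifying / neutral / positive by omega against 1 with a +-band,
    undefined when omega cannot be computed."""
    if est.omega is None:
        return "undefined"
    if est.omega < 1.0 - neutral_band:
        return "purifying"
    if est.omega > 1.0 + neutral_band:
        return "positive"
    return "neutral"


DEFAULT_KS_BANDS = {"recent": (0.15, 0.30), "ancient": (1.5, 1.8)}


def assign_wgd_band(ks: float,
                    bands: Mapping[str, tuple[float, float]] | None = None
                    ) -> str:
    """Closed-interval Ks band membership; bands must not overlap."""
    if ks < 0:
        raise ValueError("ks must be >= 0")
    bands = dict(bands) if bands is not None else dict(DEFAULT_KS_BANDS)
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _hi2)) in zip(items, items[1:]):
        if lo2 <= hi1:
            raise ValueError("overlapping Ks bands in configuration")
    for name, (lo, hi) in items:
        if lo <= ks <= hi:
            return name
    return "other"


@dataclasses.dataclass(frozen=True)
class DatingResult:
    t_mya: float
    clock_rate: float
    band: str


#: Synonymous substitutions per site per year; reproduces the Ks 0.15 <-> 30
#: MYA edge of the recent pear WGD window under T = Ks / (2 r).
DEFAULT_CLOCK_RATE = 2.5e-9


def ks_to_time(ks: float, clock_rate: float = DEFAULT_CLOCK_RATE,
               bands: Mapping[str, tuple[float, float]] | None = None
               ) -> DatingResult:
    """T(MYA) = Ks / (2 * clock_rate) / 1e6."""
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if clock_rate <= 0:
        raise ValueError("clock_rate must be positive")
    t_mya = ks / (2.0 * clock_rate) / 1e6
    return DatingResult(t_mya, clock_rate, assign_wgd_band(ks, bands))


def estimate_pair(cds_a: SequenceRecord, cds_b: SequenceRecord,
                  method: str = "ng86", gap_open: float = 10.0,
                  gap_extend: float = 0.5) -> EvolEstimate:
    """Convenience: codon-align a CDS pair and run NG86 (+4DTv) on it."""
    aln = align_codon_pair(cds_a, cds_b, gap_open, gap_extend)
    return ng86_kaks(aln, method=method)
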
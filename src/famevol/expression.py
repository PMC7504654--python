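"""Expression summaries: RPKM matrices, presence calls, tissue percentages,
two-group t-tests with star thresholds, and 2^-ddCt relative expression.

RPKM = count * 1e9 / (library_size * gene_length_bp).  A gene is called
expressed in a library iff RPKM > 0 (no minimal-expression floor).  The
default differential test is the equal-variance two-sample Student t-test
(Welch available); stars follow 0.05 / 0.01 / 0.001.  qPCR quantification is
the standard 2^-ddCt: per-sample dCt = mean target Ct - mean reference Ct,
ddCt against a calibrator sample.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ExpressionMatrix:
    rpkm: pd.DataFrame          # genes x libraries, >= 0

    @property
    def log2(self) -> pd.DataFrame:
        """log2(RPKM + 1), the heatmap-ready view."""
        return np.log2(self.rpkm + 1.0)


def compute_rpkm(counts: pd.DataFrame, gene_lengths: Mapping[str, int],
                 library_sizes: Mapping[str, int]) -> ExpressionMatrix:
    """Reads per kilobase of gene per million library reads."""
    missing = set(counts.index) - set(gene_lengths)
    if missing:
        raise KeyError(f"gene lengths missing for {sorted(missing)[:3]}")
    missing = set(counts.columns) - set(library_sizes)
    if missing:
        raise KeyError(f"library sizes missing for {sorted(missing)[:3]}")
    sizes = pd.Series({c: library_sizes[c] for c in counts.columns},
                      dtype=float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    lengths = pd.Series({g: gene_lengths[g] for g in counts.index},
                        dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpkm = counts.astype(float).mul(1e9).div(sizes, axis=1).div(lengths,
                                                                axis=0)
    return ExpressionMatrix(rpkm)


def call_expressed(expr: ExpressionMatrix) -> pd.DataFrame:
    """Boolean presence matrix: expressed iff RPKM > 0."""
    return expr.rpkm > 0


def tissue_percentages(presence: pd.DataFrame,
                       decimals: int = 2) -> pd.Series:
    """Percentage of family genes expressed per library, rounded for report
    output."""
    pct = presence.mean(axis=0) * 100.0
    return pct.round(decimals)


@dataclasses.dataclass
class DEResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    stars: str


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def de_ttest(group_a: Sequence[float], group_b: Sequence[float],
             equal_var: bool = True) -> DEResult:
    """Two-sided two-sample t-test with star thresholds.

    Degenerate zero-variance groups are resolved by the limit: identical
    constant groups give t=0, p=1; distinct constants give p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float("inf") if a.mean() > b.mean() else float("-inf")
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return DEResult(float(a.mean()), float(b.mean()), t, p,
                    significance_stars(p))


@dataclasses.dataclass(frozen=True)
class QpcrRecord:
    sample: str
    target_ct: float
    reference_ct: float
    replicate: int = 0

    def __post_init__(self):
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("Ct values must be positive")


def ddct(records: Sequence[QpcrRecord],
         calibrator_sample: str) -> dict[str, float]:
    """2^-ddCt relative expression per sample, against the calibrator.

    dCt per sample averages replicate target and reference Ct first; the
    calibrator maps to exactly 1.0.
    """
    by_sample: dict[str, list[QpcrRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample, []).append(rec)
    if calibrator_sample not in by_sample:
        raise KeyError(f"calibrator sample {calibrator_sample!r} absent")
    dct = {
        sample: (float(np.mean([r.target_ct for r in recs]))
                 - float(np.mean([r.reference_ct for r in recs])))
        for sample, recs in by_sample.items()
    }
    base = dct[calibrator_sample]
    return {sample: float(2.0 ** -(v - base)) for sample, v in dct.items()}


def ddct_table(ct: pd.DataFrame, calibrator_sample: str) -> pd.DataFrame:
    """Relative expression for a long-format qPCR table with columns
    (gene, sample, replicate, target_ct, reference_ct); one row per gene,
    one column per sample."""
    out: dict[str, dict[str, float]] = {}
    for gene, sub in ct.groupby("gene", sort=True):
        recs = [QpcrRecord(r.sample, r.target_ct, r.reference_ct,
                           int(r.replicate))
                for r in sub.itertuples(index=False)]
        out[gene] = ddct(recs, calibrator_sample)
    return pd.DataFrame(out).T.sort_index()
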
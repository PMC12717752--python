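"""Cis and trans target inference for differentially expressed lncRNAs.

Cis targets are protein-coding genes whose span lies within 100 kb of the
DEL's genomic span (gap measured between spans, overlap = 0, boundary
inclusive).  Trans targets are differentially expressed mRNAs whose
expression profile across the samples correlates with the lncRNA at
|Pearson r| > 0.95 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeAnnotation, TranscriptModel, ValidationError


@dataclass
class TargetPair:
    """One lncRNA-mRNA link.

    ``distance`` (cis only) is the signed gap between spans on forward
    coordinates: negative when the gene lies upstream (left) of the DEL,
    0 when they overlap.  ``r`` (trans, and cis when expression was supplied)
    is the sample Pearson correlation.
    """

    lncrna: str
    gene: str
    mode: str  # "cis" | "trans"
    distance: int | None = None
    r: float | None = None

    @property
    def sign(self) -> str | None:
        if self.r is None:
            return None
        return "positive" if self.r > 0 else "negative"


@dataclass
class PairStats:
    n_cis: int
    n_trans: int
    trans_cis_ratio: float  # nan when n_cis == 0
    fraction_trans_negative: float
    fraction_cis_positive: float


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; zero variance raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("pearson needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("undefined correlation: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Signed gap between half-open spans; 0 on overlap, negative = b left of a."""
    if b[0] >= a[1]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return -(a[0] - b[1])
    return 0


def cis_targets(
    dels: list[TranscriptModel],
    annotation: GenomeAnnotation,
    window_bp: int = 100_000,
    lnc_expr: pd.DataFrame | None = None,
    gene_expr: pd.DataFrame | None = None,
) -> list[TargetPair]:
    """Protein-coding genes within ``window_bp`` up/downstream of each DEL locus.

    When both expression frames are given (features x samples, shared sample
    axis) each pair is annotated with the lncRNA-gene Pearson correlation so
    regulation sign fractions can be reported.
    """
    known_chroms = set(annotation.chrom_lengths) | {g.chrom for g in annotation.genes}
    pairs: list[TargetPair] = []
    for t in dels:
        if known_chroms and t.chrom not in known_chroms:
            raise ValidationError(f"{t.id}: unknown chromosome {t.chrom!r}")
        span = (t.start, t.end)
        for g in annotation.genes_on(t.chrom):
            if g.biotype != "protein_coding":
                continue
            gap = _span_gap(span, g.span)
            if abs(gap) <= window_bp:
                r = None
                if lnc_expr is not None and gene_expr is not None:
                    if t.id in lnc_expr.index and g.id in gene_expr.index:
                        xv = lnc_expr.loc[t.id].to_numpy(float)
                        yv = gene_expr.loc[g.id].to_numpy(float)
                        if np.std(xv) > 0 and np.std(yv) > 0:
                            r = pearson(xv, yv)
                pairs.append(TargetPair(t.id, g.id, "cis", distance=gap, r=r))
    return pairs


def trans_targets(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_threshold: float = 0.95,
) -> list[TargetPair]:
    """All (lncRNA, mRNA) pairs with |Pearson r| strictly above the threshold.

    Both frames are features x samples over the same sample axis.  Features
    with zero variance are skipped with a warning.
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValidationError("sample axes differ between lncRNA and mRNA matrices")
    lx = lnc_expr.to_numpy(dtype=float)
    mx = mrna_expr.to_numpy(dtype=float)
    n = lx.shape[1]

    def _standardize(a: np.ndarray, names: pd.Index) -> tuple[np.ndarray, np.ndarray]:
        sd = a.std(axis=1, ddof=1)
        ok = sd > 0
        if (~ok).any():
            warnings.warn(
                f"skipping zero-variance features: {list(names[~ok])[:5]}",
                stacklevel=2,
            )
        z = (a[ok] - a[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        return z, np.flatnonzero(ok)

    zl, il = _standardize(lx, lnc_expr.index)
    zm, im = _standardize(mx, mrna_expr.index)
    if zl.size == 0 or zm.size == 0:
        return []
    rmat = zl @ zm.T / (n - 1)
    pairs: list[TargetPair] = []
    for i, j in zip(*np.nonzero(np.abs(rmat) > r_threshold)):
        pairs.append(
            TargetPair(
                str(lnc_expr.index[il[i]]),
                str(mrna_expr.index[im[j]]),
                "trans",
                r=float(rmat[i, j]),
            )
        )
    return pairs


def pair_stats(pairs: list[TargetPair]) -> PairStats:
    """Pair-level summary: counts, trans/cis ratio (2 decimals, round
    half-even; nan when no cis pairs), and regulation-sign fractions."""
    if not pairs:
        raise ValidationError("pair_stats on empty pair set")
    cis = [p for p in pairs if p.mode == "cis"]
    trans = [p for p in pairs if p.mode == "trans"]
    ratio = float(np.round(len(trans) / len(cis), 2)) if cis else float("nan")
    trans_signed = [p for p in trans if p.sign is not None]
    cis_signed = [p for p in cis if p.sign is not None]
    frac_tn = (
        sum(p.sign == "negative" for p in trans_signed) / len(trans_signed)
        if trans_signed
        else float("nan")
    )
    frac_cp = (
        sum(p.sign == "positive" for p in cis_signed) / len(cis_signed)
        if cis_signed
        else float("nan")
    )
    return PairStats(len(cis), len(trans), ratio, frac_tn, frac_cp)


def pairs_to_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    rows = [
        {
            "lncrna": p.lncrna,
            "gene": p.gene,
            "mode": p.mode,
            "distance": p.distance if p.distance is not None else "",
            "r": f"{p.r:.6f}" if p.r is not None else "",
            "sign": p.sign or "",
        }
        for p in pairs
    ]
    df = pd.DataFrame(rows, columns=["lncrna", "gene", "mode", "distance", "r", "sign"])
    return df.sort_values(["mode", "lncrna", "gene"]).reset_index(drop=True)
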
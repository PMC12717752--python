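"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written as plain loops / exact rational arithmetic,
deliberately ignoring the vectorised or indexed structures the package uses,
so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def iv_overlap(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def brute_exon_overlap(transcript, annotation) -> bool:
    """Any >=1 bp same-strand overlap between transcript exons and
    protein-coding gene exons, by all-pairs comparison."""
    for g in annotation.genes:
        if g.biotype != "protein_coding" or g.chrom != transcript.chrom:
            continue
        if g.strand != transcript.strand:
            continue
        for te in transcript.exons:
            for ge in g.exons():
                if iv_overlap(te, ge):
                    return True
    return False


def brute_filter(transcript, annotation, min_exons=2, min_length_nt=201) -> str:
    if len(transcript.exons) < min_exons:
        return "reject_exon"
    if transcript.length < min_length_nt:
        return "reject_length"
    if brute_exon_overlap(transcript, annotation):
        return "reject_exon_overlap"
    return "retained"


def brute_classify(transcript, annotation) -> str:
    """Positional class by precedence, via all-pairs interval comparison."""
    span = (transcript.start, transcript.end)
    for g in annotation.genes:
        if g.chrom != transcript.chrom or g.strand == transcript.strand:
            continue
        for te in transcript.exons:
            for ge in g.exons():
                if iv_overlap(te, ge):
                    return "antisense"
    for g in annotation.genes:
        if g.chrom != transcript.chrom or g.strand != transcript.strand:
            continue
        gs, ge = g.span
        if gs <= span[0] and span[1] <= ge:
            if not any(
                iv_overlap(te, gex) for te in transcript.exons for gex in g.exons()
            ):
                return "intronic"
    if not any(
        iv_overlap(span, g.span)
        for g in annotation.genes
        if g.chrom == transcript.chrom
    ):
        return "lincRNA"
    return "intronic"


def brute_cis(del_transcript, annotation, window=100_000):
    """All protein-coding genes within the window, with signed distance."""
    out = []
    for g in annotation.genes:
        if g.chrom != del_transcript.chrom or g.biotype != "protein_coding":
            continue
        gs, ge = g.span
        if gs >= del_transcript.end:
            gap = gs - del_transcript.end
        elif ge <= del_transcript.start:
            gap = -(del_transcript.start - ge)
        else:
            gap = 0
        if abs(gap) <= window:
            out.append((g.id, gap))
    return sorted(out)


# ---------------------------------------------------------------------------
# ORF
# ---------------------------------------------------------------------------

def brute_longest_orf(seq: str):
    """Try every ATG position; (start, length, frame) of the longest complete
    ORF, ties to smallest start then lowest frame; None without one."""
    seq = seq.upper()
    best = None
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in _STOPS:
                length = pos + 3 - start
                frame = start % 3
                key = (-length, start, frame)
                if best is None or key < (-best[1], best[0], best[2]):
                    best = (start, length, frame)
                break
    return best


# ---------------------------------------------------------------------------
# miRNA site comparison
# ---------------------------------------------------------------------------

def brute_site_counts(mirna: str, window: str):
    """(mismatches, gu_pairs) for one miRNA against one equal-length target
    window, position by position, antiparallel."""
    mirna = mirna.upper().replace("U", "T")
    window = window.upper().replace("U", "T")
    L = len(mirna)
    mis = gu = 0
    for j in range(L):
        q = mirna[L - 1 - j]
        t = window[j]
        if q in _COMP and t == _COMP[q]:
            continue
        if (q == "G" and t == "T") or (q == "T" and t == "G"):
            gu += 1
        else:
            mis += 1
    return mis, gu


def brute_scan(mirna: str, target: str, max_mismatches: int, allow_gu: bool):
    L = len(mirna)
    out = []
    for off in range(len(target) - L + 1):
        mis, gu = brute_site_counts(mirna, target[off : off + L])
        if mis <= max_mismatches and (allow_gu or gu == 0):
            out.append((off, mis, gu))
    return out


# ---------------------------------------------------------------------------
# exact distributions
# ---------------------------------------------------------------------------

def binom_conditional_p(a: int, t: int) -> Fraction:
    """Two-sided conditional binomial(t, 1/2) p-value: mass of outcomes no
    more likely than a, in exact rationals."""
    pmf = [Fraction(comb(t, k), 2**t) for k in range(t + 1)]
    obs = pmf[a]
    return sum((p for p in pmf if p <= obs), Fraction(0))


def hypergeom_upper_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def bh_reference(pvals):
    """Step-up BH written the slow, definitional way."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        q[i] = running_min
    return q


# ---------------------------------------------------------------------------
# Fickett TESTCODE, straight from the published tables
# ---------------------------------------------------------------------------

_F_POS_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_F_POS_W = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_F_CON_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_F_CON_W = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def fickett_reference(seq: str) -> float:
    seq = seq.upper()
    score = 0.0
    for base in "ACGT":
        c0 = sum(1 for i in range(0, len(seq), 3) if seq[i] == base)
        c1 = sum(1 for i in range(1, len(seq), 3) if seq[i] == base)
        c2 = sum(1 for i in range(2, len(seq), 3) if seq[i] == base)
        pos = max(c0, c1, c2) / (min(c0, c1, c2) + 1.0)
        pos_cuts = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
        idx = next(i for i, c in enumerate(pos_cuts) if pos >= c)
        score += _F_POS_PROB[base][idx] * _F_POS_W[base]
        content = seq.count(base) / len(seq)
        con_cuts = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]
        idx = next(i for i, c in enumerate(con_cuts) if content >= c)
        score += _F_CON_PROB[base][idx] * _F_CON_W[base]
    return score
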
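"""Candidate lncRNA identification and positional classification.

The screen applies four sequential filters to assembled transcripts:

1. structural complexity — at least ``min_exons`` exons;
2. length — strictly more than 200 nt (retain >= 201);
3. exclusion of transcripts with same-strand exonic overlap against annotated
   protein-coding exons (opposite-strand overlap survives, so the antisense
   class can exist);
4. a coding-potential consensus gate: a transcript is retained only when all
   three in-repo predicates (longest-ORF length, ORF coverage, Fickett
   TESTCODE score) call it non-coding — the intersection rule of a
   three-tool Venn.

Survivors may additionally be screened against a known-lncRNA set by shared
k-mer fraction, then partitioned into the three positional classes
lincRNA / intronic / antisense with precedence antisense > intronic > lincRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import (
    BeetlncError,
    GenomeAnnotation,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)

DISPOSITIONS = (
    "retained",
    "reject_exon",
    "reject_length",
    "reject_exon_overlap",
    "reject_coding",
    "reject_known",
)

CLASSES = ("lincRNA", "intronic", "antisense")

ORF_BINS = ((1, 50), (51, 100), (101, 200), (201, 300), (301, 400))


@dataclass
class OrfResult:
    """Longest ATG-initiated, in-frame-stop-terminated ORF (length includes stop)."""

    start: int
    length: int
    frame: int


@dataclass
class CodingCall:
    predicate_orf_len: bool  # True = non-coding by this predicate
    predicate_orf_coverage: bool
    predicate_fickett: bool

    @property
    def consensus_noncoding(self) -> bool:
        return (
            self.predicate_orf_len
            and self.predicate_orf_coverage
            and self.predicate_fickett
        )


@dataclass
class CodingThresholds:
    """Cuts for the three non-coding predicates (all strict upper bounds)."""

    max_orf_nt: int = 300
    max_orf_coverage: float = 0.5
    max_fickett: float = 0.95


@dataclass
class FilterReport:
    """Per-transcript disposition; dispositions partition the input set."""

    dispositions: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        out = {d: 0 for d in DISPOSITIONS}
        for d in self.dispositions.values():
            out[d] += 1
        return out

    @property
    def retained(self) -> list[str]:
        return [t for t, d in self.dispositions.items() if d == "retained"]


# ---------------------------------------------------------------------------
# structural filters
# ---------------------------------------------------------------------------

def _coding_exon_trees(annotation: GenomeAnnotation) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation.genes:
        if g.biotype != "protein_coding":
            continue
        tree = trees.setdefault((g.chrom, g.strand), IntervalTree())
        for s, e in g.exons():
            tree.addi(s, e)
    return trees


def filter_structure(
    transcripts: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    min_exons: int = 2,
    min_length_nt: int = 201,
) -> FilterReport:
    """Apply filters 1-3 (exon count, length > 200 nt, same-strand exon overlap)."""
    trees = _coding_exon_trees(annotation)
    known_chroms = set(annotation.chrom_lengths) | {g.chrom for g in annotation.genes}
    disp: dict[str, str] = {}
    for t in transcripts:
        if known_chroms and t.chrom not in known_chroms:
            raise ValidationError(f"{t.id}: unknown chromosome {t.chrom!r}")
        if t.exon_count < min_exons:
            disp[t.id] = "reject_exon"
        elif t.length < min_length_nt:
            disp[t.id] = "reject_length"
        else:
            tree = trees.get((t.chrom, t.strand))
            if tree is not None and any(tree.overlap(s, e) for s, e in t.exons):
                disp[t.id] = "reject_exon_overlap"
            else:
                disp[t.id] = "retained"
    return FilterReport(disp)


# ---------------------------------------------------------------------------
# coding potential
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValidationError(f"non-ACGTN symbols in sequence: {sorted(set(seq) - set('ACGTN'))}")
    return seq


def longest_orf(sequence: str) -> OrfResult | None:
    """Longest complete ORF over the three forward frames of the spliced sense strand.

    Ties are broken by smallest start, then lowest frame.  Codons containing
    ``N`` match neither ATG nor a stop.
    """
    seq = _check_alphabet(sequence)
    if len(seq) < 3:
        raise ValidationError("sequence shorter than one codon")
    best: OrfResult | None = None
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in _STOPS:
                length = pos + 3 - open_start
                if (
                    best is None
                    or length > best.length
                    or (length == best.length and open_start < best.start)
                    or (
                        length == best.length
                        and open_start == best.start
                        and frame < best.frame
                    )
                ):
                    best = OrfResult(open_start, length, frame)
                open_start = None
        # an open ORF without an in-frame stop does not count
    return best


# Fickett (TESTCODE) lookup tables: probability that a window with the given
# position/composition parameter is coding, and the weight of each parameter.
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_CUTS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_CUTS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def fickett_score(sequence: str) -> float:
    """TESTCODE-style coding-potential score; higher is more coding-like.

    Combines the asymmetry of each base across the three codon positions
    (position parameter: max count / (min count + 1)) with overall base
    composition, through the published lookup tables.
    """
    seq = _check_alphabet(sequence)
    if len(seq) < 200:
        raise ValidationError(f"fickett_score needs >= 200 nt, got {len(seq)}")
    score = 0.0
    for base in "ACGT":
        counts = [seq[i::3].count(base) for i in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        for i, cut in enumerate(_POSITION_CUTS):
            if position >= cut:
                score += _POSITION_PROB[base][i] * _POSITION_WEIGHT[base]
                break
        content = seq.count(base) / len(seq)
        for i, cut in enumerate(_CONTENT_CUTS):
            if content >= cut:
                score += _CONTENT_PROB[base][i] * _CONTENT_WEIGHT[base]
                break
    return score


def consensus_noncoding(
    transcript: TranscriptModel | str, thresholds: CodingThresholds | None = None
) -> CodingCall:
    """Run the three coding-potential predicates; consensus = all non-coding."""
    thresholds = thresholds or CodingThresholds()
    seq = transcript if isinstance(transcript, str) else transcript.sequence
    if seq is None:
        raise BeetlncError("transcript has no sequence")
    orf = longest_orf(seq)
    orf_len = 0 if orf is None else orf.length
    return CodingCall(
        predicate_orf_len=orf_len < thresholds.max_orf_nt,
        predicate_orf_coverage=(orf_len / len(seq)) < thresholds.max_orf_coverage,
        predicate_fickett=fickett_score(seq) < thresholds.max_fickett,
    )


# ---------------------------------------------------------------------------
# known-lncRNA exclusion
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def exclude_known(
    candidates: Mapping[str, str],
    known: Mapping[str, str],
    k: int = 25,
    shared_fraction: float = 0.5,
) -> dict[str, str]:
    """Flag candidates homologous to known lncRNAs by shared k-mer fraction.

    A candidate is rejected when at least ``shared_fraction`` of its k-mers
    occur in the known-set index (either strand).  Returns a per-candidate
    disposition delta: ``reject_known`` or ``retained``.
    """
    if not known:
        return {cid: "retained" for cid in candidates}
    shortest = min(len(s) for s in candidates.values())
    if k > shortest:
        raise ValidationError(f"k={k} exceeds shortest candidate length {shortest}")
    index: set[str] = set()
    for seq in known.values():
        index.update(_kmers(seq.upper(), k))
        index.update(_kmers(reverse_complement(seq.upper()), k))
    out: dict[str, str] = {}
    for cid, seq in candidates.items():
        kmers = list(_kmers(seq.upper(), k))
        shared = sum(1 for km in kmers if km in index)
        out[cid] = "reject_known" if shared / len(kmers) >= shared_fraction else "retained"
    return out


# ---------------------------------------------------------------------------
# positional classification
# ---------------------------------------------------------------------------

def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_lncrna(transcript: TranscriptModel, annotation: GenomeAnnotation) -> str:
    """Assign one positional class with precedence antisense > intronic > lincRNA.

    antisense: any transcript exon overlaps an exon of an opposite-strand gene;
    intronic:  contained within one same-strand gene span without exon overlap;
    lincRNA:   no overlap with any gene span.  Transcripts with partial span
    overlap that match none of the above fall back to intronic (documented
    containment-failure rule, keeping the partition deterministic).
    """
    known_chroms = set(annotation.chrom_lengths) | {g.chrom for g in annotation.genes}
    if known_chroms and transcript.chrom not in known_chroms:
        raise ValidationError(f"{transcript.id}: unknown chromosome {transcript.chrom!r}")
    span = (transcript.start, transcript.end)
    span_overlap = False
    for g in annotation.genes_on(transcript.chrom):
        g_span = g.span
        if not _overlaps(span, g_span):
            continue
        span_overlap = True
        if g.strand != transcript.strand:
            if any(
                _overlaps(te, ge) for te in transcript.exons for ge in g.exons()
            ):
                return "antisense"
    for g in annotation.genes_on(transcript.chrom):
        if g.strand != transcript.strand:
            continue
        g_start, g_end = g.span
        if g_start <= span[0] and span[1] <= g_end:
            if not any(
                _overlaps(te, ge) for te in transcript.exons for ge in g.exons()
            ):
                return "intronic"
    if not span_overlap:
        return "lincRNA"
    return "intronic"


def orf_bin(orf_len: int) -> str:
    """Histogram bin label for an ORF length (nt); 0 means no complete ORF."""
    if orf_len == 0:
        return "none"
    for lo, hi in ORF_BINS:
        if lo <= orf_len <= hi:
            return f"{lo}-{hi}"
    return ">400"


def class_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Summarise retained lncRNAs per class.

    ``records`` needs columns ``clazz``, ``length``, ``exon_count``,
    ``orf_len`` (0 when absent).  Returns one row per class with count,
    fraction, mean length (1 decimal, round half-even) and serialized
    exon-count and ORF-length histograms.
    """
    if records.empty:
        raise ValidationError("class_summary on empty set")
    total = len(records)
    rows = []
    for clazz, grp in records.groupby("clazz"):
        exon_hist = grp["exon_count"].value_counts().sort_index()
        orf_hist = grp["orf_len"].map(orf_bin).value_counts()
        order = ["none"] + [f"{lo}-{hi}" for lo, hi in ORF_BINS] + [">400"]
        orf_hist = orf_hist.reindex([b for b in order if b in orf_hist.index])
        rows.append(
            {
                "clazz": clazz,
                "count": len(grp),
                "fraction": len(grp) / total,
                "mean_length": float(np.round(grp["length"].mean(), 1)),
                "exon_hist": ";".join(f"{k}:{v}" for k, v in exon_hist.items()),
                "orf_hist": ";".join(f"{k}:{v}" for k, v in orf_hist.items()),
            }
        )
    return pd.DataFrame(rows).sort_values("clazz").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full identification pass
# ---------------------------------------------------------------------------

def identify_lncrnas(
    transcripts: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    known: Mapping[str, str] | None = None,
    thresholds: CodingThresholds | None = None,
    min_exons: int = 2,
    min_length_nt: int = 201,
) -> pd.DataFrame:
    """Run filters 1-4 (+ optional known-set exclusion) and classify survivors.

    Returns one row per input transcript: disposition, class (empty unless
    retained), length, exon_count, orf_len, fickett score.
    """
    report = filter_structure(transcripts, annotation, min_exons, min_length_nt)
    disp = dict(report.dispositions)
    by_id = {t.id: t for t in transcripts}

    survivors = {tid: by_id[tid].sequence for tid in report.retained}
    for tid, seq in survivors.items():
        if seq is None:
            raise BeetlncError(f"{tid}: sequence required for coding-potential gate")
    for tid in report.retained:
        call = consensus_noncoding(by_id[tid], thresholds)
        if not call.consensus_noncoding:
            disp[tid] = "reject_coding"
    if known:
        still = {tid: survivors[tid] for tid in disp if disp[tid] == "retained"}
        for tid, d in exclude_known(still, known).items():
            if d == "reject_known":
                disp[tid] = "reject_known"

    rows = []
    for t in transcripts:
        d = disp[t.id]
        clazz = classify_lncrna(t, annotation) if d == "retained" else ""
        orf = longest_orf(t.sequence) if t.sequence else None
        rows.append(
            {
                "transcript": t.id,
                "disposition": d,
                "clazz": clazz,
                "length": t.length,
                "exon_count": t.exon_count,
                "orf_len": 0 if orf is None else orf.length,
                "fickett": (
                    fickett_score(t.sequence)
                    if t.sequence and len(t.sequence) >= 200
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
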
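"""Typed readers and writers for the pipeline's tabular and sequence formats.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
on the forward strand; GTF input/output converts at the boundary (GTF is
1-based inclusive).  Sequences are stored in the DNA alphabet (``U`` is
normalised to ``T`` on read); miRNA comparisons happen in RNA space inside the
binding-site scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

TISSUES = ("foliage", "root")
CONDITIONS = ("CV", "LN")

#: tissue letter used in sample names, mirroring CV-A1 .. LN-B3
TISSUE_CODE = {"foliage": "A", "root": "B"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class BeetlncError(Exception):
    """Base class for pipeline errors."""


class ParseError(BeetlncError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(BeetlncError):
    """An in-memory value violates a domain invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# annotation types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """An exon-structured transcript; the unit flowing through identification.

    ``exons`` are 0-based half-open intervals sorted by start and
    non-overlapping.  ``sequence`` is the spliced 5'->3' sequence (reverse
    complemented for minus-strand transcripts) when available.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def validate(self, chrom_length: int | None = None) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.id}: transcript has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.id}: degenerate exon [{s}, {e})")
            if s < prev_end:
                raise ValidationError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e
        if self.exons[0][0] < 0:
            raise ValidationError(f"{self.id}: exon start < 0")
        if chrom_length is not None and self.end > chrom_length:
            raise ValidationError(
                f"{self.id}: exon end {self.end} outside chromosome {self.chrom} "
                f"(length {chrom_length})"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"{self.id}: sequence length {len(self.sequence)} != exon sum {self.length}"
            )


@dataclass
class GeneModel:
    """A gene locus: the container for cis windows and positional classes."""

    id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    def exons(self) -> list[tuple[int, int]]:
        """Union of all transcript exons, merged, sorted."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def introns(self) -> list[tuple[int, int]]:
        ex = self.exons()
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class GenomeAnnotation:
    """Gene models plus chromosome lengths; the coordinate frame of the run."""

    genes: list[GeneModel]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes:
            yield from g.transcripts

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValidationError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if not g.transcripts:
                raise ValidationError(f"gene {g.id} has no transcripts")
            for t in g.transcripts:
                if t.strand != g.strand:
                    raise ValidationError(f"{t.id}: strand differs from gene {g.id}")
                t.validate(self.chrom_lengths.get(g.chrom))


# ---------------------------------------------------------------------------
# GTF reading / writing
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> GenomeAnnotation:
    """Read a GTF/GFF file of exon features into a :class:`GenomeAnnotation`.

    GTF's 1-based inclusive coordinates are converted to internal 0-based
    half-open intervals.  Records must carry ``gene_id`` and ``transcript_id``
    attributes; an optional ``gene_biotype`` defaults to ``protein_coding``.
    """
    path = Path(path)
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene_id)
    gene_biotype: dict[str, str] = {}
    gene_order: list[str] = []
    tx_order: dict[str, list[str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(
                    f"{path.name}:{lineno}: malformed record: expected 9 tab-separated "
                    f"fields, got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several exception types
                raise ParseError(f"{path.name}:{lineno}: malformed record: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise ValidationError(
                    f"{path.name}:{lineno}: end {feat.end} < start {feat.start}"
                )
            try:
                gid = feat.attributes["gene_id"][0]
                tid = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: missing {exc} attribute"
                ) from exc
            if "gene_biotype" in feat.attributes:
                gene_biotype[gid] = feat.attributes["gene_biotype"][0]
            if tid not in tx_meta:
                tx_meta[tid] = (feat.seqid, feat.strand, gid)
                if gid not in tx_order:
                    tx_order[gid] = []
                    gene_order.append(gid)
                tx_order[gid].append(tid)
            # GTF 1-based inclusive -> 0-based half-open
            tx_exons.setdefault(tid, []).append((feat.start - 1, feat.end))

    genes: list[GeneModel] = []
    for gid in gene_order:
        tids = tx_order[gid]
        chrom, strand, _ = tx_meta[tids[0]]
        transcripts = []
        for tid in tids:
            t_chrom, t_strand, _ = tx_meta[tid]
            transcripts.append(
                TranscriptModel(tid, t_chrom, t_strand, sorted(tx_exons[tid]))
            )
        genes.append(
            GeneModel(gid, chrom, strand, transcripts, gene_biotype.get(gid, "protein_coding"))
        )
    ann = GenomeAnnotation(genes, dict(chrom_lengths or {}))
    ann.validate()
    return ann


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write exon features in GTF (1-based inclusive), one line per exon."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{g.id}"; transcript_id "{t.id}"; '
                        f'gene_biotype "{g.biotype}";'
                    )
                    fh.write(
                        f"{t.chrom}\tbeetlnc\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "DNA") -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence map.

    Sequences are uppercased; ``U`` is normalised to ``T`` for DNA (the
    internal alphabet) or ``T`` to ``U`` for ``alphabet="RNA"``.  Duplicate
    ids and empty records are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        if alphabet == "DNA":
            seq = seq.replace("U", "T")
        elif alphabet == "RNA":
            seq = seq.replace("T", "U")
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# expression matrix + sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    name: str
    tissue: str
    condition: str
    replicate: int


@dataclass
class ExpressionMatrix:
    """Non-negative integer counts, features x samples, with design metadata."""

    feature_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray
    feature_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.samples)):
            raise ValidationError(
                f"count shape {self.counts.shape} != "
                f"({len(self.feature_ids)}, {len(self.samples)})"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        keys = [(s.tissue, s.condition, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (tissue, condition, replicate) sample")

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def sample_idx(self, tissue: str | None = None, condition: str | None = None) -> np.ndarray:
        idx = [
            i
            for i, s in enumerate(self.samples)
            if (tissue is None or s.tissue == tissue)
            and (condition is None or s.condition == condition)
        ]
        return np.asarray(idx, dtype=int)

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [pos[f] for f in ids]
        lengths = None
        if self.feature_lengths is not None:
            lengths = {f: self.feature_lengths[f] for f in ids if f in self.feature_lengths}
        return ExpressionMatrix(list(ids), self.samples, self.counts[rows], lengths)

    def subset_samples(self, tissue: str | None = None, condition: str | None = None) -> "ExpressionMatrix":
        idx = self.sample_idx(tissue, condition)
        return ExpressionMatrix(
            self.feature_ids,
            [self.samples[i] for i in idx],
            self.counts[:, idx],
            self.feature_lengths,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_names)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "tissue", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(required)}")
    samples = []
    for _, row in df.iterrows():
        if row["tissue"] not in TISSUES:
            raise ValidationError(f"unknown tissue {row['tissue']!r}")
        if row["condition"] not in CONDITIONS:
            raise ValidationError(f"unknown condition {row['condition']!r}")
        samples.append(
            SampleInfo(str(row["name"]), row["tissue"], row["condition"], int(row["replicate"]))
        )
    return samples


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [(s.name, s.tissue, s.condition, s.replicate) for s in samples],
        columns=["name", "tissue", "condition", "replicate"],
    ).to_csv(path, sep="\t", index=False)


def read_counts(
    counts_path: str | Path,
    sample_sheet_path: str | Path,
    lengths_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a feature x sample count TSV against a sample sheet.

    The TSV's first column holds feature ids; remaining column names must
    match the sheet exactly (as a set); output columns follow sheet order.
    """
    samples = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet_names = [s.name for s in samples]
    missing = sorted(set(sheet_names) - set(df.columns))
    extra = sorted(set(df.columns) - set(sheet_names))
    if missing or extra:
        raise ValidationError(
            f"{counts_path}: sample sheet/header mismatch; "
            f"missing from counts: {missing}; not in sheet: {extra}"
        )
    df = df[sheet_names]
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError(f"{counts_path}: non-numeric counts")
    if (vals < 0).any():
        raise ValidationError(f"{counts_path}: negative counts")
    if not np.allclose(vals, np.round(vals)):
        raise ValidationError(f"{counts_path}: non-integer counts")
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = {str(k): int(v) for k, v in ldf.iloc[:, 0].items()}
    return ExpressionMatrix(
        [str(i) for i in df.index], samples, vals.astype(np.int64), lengths
    )


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# term maps and Ct tables
# ---------------------------------------------------------------------------

@dataclass
class TermMap:
    """term id -> set of gene ids, within one namespace (GO-like, pathway-like)."""

    terms: dict[str, set[str]]
    namespace: str = "GO"

    def validate_against(self, universe: Iterable[str]) -> None:
        uni = set(universe)
        for term, genes in self.terms.items():
            bad = genes - uni
            if bad:
                raise ValidationError(
                    f"term {term}: genes outside universe: {sorted(bad)[:5]}"
                )


def read_term_map(path: str | Path, namespace: str = "GO") -> TermMap:
    df = pd.read_csv(path, sep="\t")
    if not {"term", "gene"}.issubset(df.columns):
        raise ParseError(f"{path}: term map needs columns term, gene")
    terms: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        terms.setdefault(str(row["term"]), set()).add(str(row["gene"]))
    return TermMap(terms, namespace)


def write_term_map(term_map: TermMap, path: str | Path) -> None:
    rows = [
        (term, gene)
        for term in sorted(term_map.terms)
        for gene in sorted(term_map.terms[term])
    ]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


CT_COLUMNS = ["gene", "sample", "condition", "ct", "is_reference"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table; columns gene, sample, condition, ct, is_reference."""
    df = pd.read_csv(path, sep="\t")
    if not set(CT_COLUMNS).issubset(df.columns):
        raise ParseError(f"{path}: Ct table needs columns {CT_COLUMNS}")
    df = df[CT_COLUMNS].copy()
    df["is_reference"] = df["is_reference"].astype(bool)
    validate_ct_table(df)
    return df


def validate_ct_table(df: pd.DataFrame) -> None:
    ct = df["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise ValidationError("Ct values must be finite and > 0")
    for sample, grp in df.groupby("sample"):
        if not grp["is_reference"].any():
            raise ValidationError(f"sample {sample!r} has no reference gene")


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shared numeric helpers
# ---------------------------------------------------------------------------

def round_half_even(x: float, ndigits: int) -> float:
    """Banker's rounding, used for every reported summary decimal."""
    if not math.isfinite(x):
        return x
    return float(np.round(x, ndigits))
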
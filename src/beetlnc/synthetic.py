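"""Synthetic toy genome, transcriptome, expression design and ground truth.

This module emulates the study design the pipeline targets: a small plant
genome with protein-coding genes on both strands; planted lncRNAs of the
three positional classes (lincRNA / intronic / antisense) plus transcripts
built to fail each identification filter; a 12-sample expression design
(2 tissues x {CV, LN} x 3 replicates) with negative-binomial counts, planted
differential expression and planted correlated lncRNA-mRNA pairs; miRNAs
(21 nt, within the 18-30 nt small-RNA window) with binding sites planted at
controlled mismatch / G.U-wobble counts; term maps with one over-represented
term; and a qPCR Ct table consistent with the planted fold changes.

Every output is reproducible bit-for-bit from (config, seed), and every
planted feature is recorded in :class:`TruthTables` so downstream stages can
be scored for recall and precision.

Count model: NB parameterised by (mean, dispersion) with variance
``mu + phi * mu^2``; ``phi = 0`` degenerates to Poisson.  Correlated pairs
share a per-sample log-normal latent factor whose variance is calibrated
analytically so the expected count Pearson correlation hits the configured
target (see :func:`latent_sigma`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    BeetlncError,
    ExpressionMatrix,
    GeneModel,
    GenomeAnnotation,
    SampleInfo,
    TermMap,
    TranscriptModel,
    ValidationError,
    reverse_complement,
    write_annotation,
    write_counts,
    write_ct_table,
    write_fasta,
    write_sample_sheet,
    write_term_map,
)
from .lncrna import CodingThresholds, consensus_noncoding, longest_orf

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {"G": "T", "T": "G"}


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the conditions the pipeline
    is exercised under (a desk-scale genome that runs in seconds)."""

    seed: int = 0
    # genome geometry
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_coding_genes: int = 60
    isolated_tail: int = 250_000  # gene-free region hosting >100 kb edge cases
    gene_exon_range: tuple[int, int] = (3, 6)
    gene_exon_len: tuple[int, int] = (200, 400)
    gene_intron_len: tuple[int, int] = (1500, 3000)
    # planted transcript classes
    n_lincrna: int = 60
    n_intronic: int = 30
    n_antisense: int = 14
    n_short_reject: int = 10
    n_coding_like_reject: int = 8
    lnc_exon_range: tuple[int, int] = (2, 4)
    # expression
    mrna_mean: float = 200.0
    lnc_mean: float = 80.0
    mirna_mean: float = 300.0
    mrna_disp: float = 0.05
    lnc_disp: float = 0.1
    mirna_disp: float = 0.05
    lib_sd: float = 0.1  # lognormal sd of true library-size factors
    # planted differential expression (|log2FC| and per-tissue counts)
    de_log2fc: float = 2.0
    de_mean: float = 150.0
    n_de_lnc_foliage: int = 12
    n_de_lnc_root: int = 24
    n_de_mrna_foliage: int = 15
    n_de_mrna_root: int = 15
    # planted correlated lncRNA-mRNA pairs
    n_trans_pairs: int = 10
    trans_r: float = 0.99
    triad_r: float = 0.9
    latent_mean: float = 5000.0
    latent_disp: float = 0.001
    # miRNAs and planted binding sites
    n_mirnas: int = 8
    mirna_length: int = 21
    # terms
    n_terms: int = 15
    term_base_rate: float = 0.12
    planted_term_odds: float = 40.0
    # qPCR
    n_qpcr_genes: int = 7

    @classmethod
    def small(cls, seed: int = 0) -> "SimulationConfig":
        """A reduced geometry for fast unit tests (same generative rules)."""
        return cls(
            seed=seed,
            n_chroms=2,
            chrom_length=700_000,
            n_coding_genes=24,
            isolated_tail=150_000,
            n_lincrna=16,
            n_intronic=6,
            n_antisense=4,
            n_short_reject=4,
            n_coding_like_reject=3,
            n_de_lnc_foliage=4,
            n_de_lnc_root=8,
            n_de_mrna_foliage=6,
            n_de_mrna_root=10,
            n_trans_pairs=4,
            n_terms=8,
            n_qpcr_genes=3,
        )


@dataclass
class TruthTables:
    """Planted ground truth; every id refers to an emitted feature."""

    classes: pd.DataFrame       # transcript, clazz
    de: pd.DataFrame            # feature, kind, tissue, log2fc
    trans_pairs: pd.DataFrame   # lncrna, gene, target_r
    cis_pairs: pd.DataFrame     # lncrna, gene, distance
    sites: pd.DataFrame         # mirna, target, target_kind, tissue, offset, mismatches, gu_pairs
    triads: pd.DataFrame        # lncrna, mirna, mrna, tissue
    enriched_terms: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    genome: dict[str, str]
    transcripts: dict[str, TranscriptModel]  # the lncRNA-screening input set
    mirnas: dict[str, str]  # id -> RNA-space sequence
    lnc_matrix: "ExpressionMatrix"
    mrna_matrix: "ExpressionMatrix"
    mirna_matrix: "ExpressionMatrix"
    term_map: TermMap
    universe: list[str]
    ct_table: pd.DataFrame
    qpcr_tissue: dict[str, str]
    sequences: dict[str, str]  # lnc + gene (mRNA) + miRNA, DNA space
    truth: TruthTables


# ---------------------------------------------------------------------------
# primitive samplers
# ---------------------------------------------------------------------------

def sample_nb(rng: np.random.Generator, mean, dispersion, size=None) -> np.ndarray:
    """NB(mean, dispersion) counts via gamma-Poisson mixing; Poisson at 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean) if size is None else size)
    if np.any(np.asarray(dispersion) < 0):
        raise ValidationError("negative dispersion")
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    lam = np.where(
        disp > 0,
        rng.gamma(np.where(disp > 0, 1.0 / np.maximum(disp, 1e-300), 1.0), mean * disp),
        mean,
    )
    return rng.poisson(lam)


def latent_sigma(rho: float, mean: float, dispersion: float) -> float:
    """Log-normal sigma so two NB features sharing the latent factor reach
    expected Pearson correlation ``rho``.

    With latent squared CV ``c`` and NB noise, the count correlation is
    ``c / (1/mean + dispersion * (1 + c) + c)``; solving for ``c`` gives
    ``c = rho * (1/mean + dispersion) / (1 - rho - rho * dispersion)`` and
    ``sigma = sqrt(log(1 + c))``.  Raises when ``rho`` is infeasible for the
    given noise level (the ceiling is ``1 / (1 + dispersion)``).
    """
    if rho >= 1.0:
        raise ValidationError("requested correlation >= 1")
    denom = 1.0 - rho - rho * dispersion
    if denom <= 0:
        raise ValidationError(
            f"correlation {rho} not achievable at dispersion {dispersion} "
            f"(ceiling {1.0 / (1.0 + dispersion):.4f})"
        )
    c = rho * (1.0 / mean + dispersion) / denom
    return float(np.sqrt(np.log1p(c)))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _arr_to_str(rng.integers(0, 4, n).astype(np.uint8))


def _split_lengths(rng, total: int, parts: int, min_part: int) -> list[int]:
    extra = total - parts * min_part
    if extra < 0:
        raise ValidationError(f"cannot split {total} into {parts} parts of >= {min_part}")
    add = rng.multinomial(extra, [1.0 / parts] * parts)
    return [min_part + int(a) for a in add]


def noncoding_seq(
    rng: np.random.Generator,
    length: int,
    thresholds: CodingThresholds | None = None,
    fixed: tuple[int, str] | None = None,
    max_tries: int = 500,
) -> str:
    """A sequence of the given length passing the non-coding consensus gate,
    by rejection sampling.  ``fixed=(offset, chunk)`` pins a subsequence
    (used where an antisense transcript reads through a gene exon)."""
    thresholds = thresholds or CodingThresholds()
    for _ in range(max_tries):
        seq = random_seq(rng, length)
        if fixed is not None:
            off, chunk = fixed
            seq = seq[:off] + chunk + seq[off + len(chunk):]
        if length >= 200 and consensus_noncoding(seq, thresholds).consensus_noncoding:
            return seq
        if length < 200:
            orf = longest_orf(seq) if length >= 3 else None
            if orf is None or orf.length < thresholds.max_orf_nt:
                return seq
    raise BeetlncError(f"could not draw a non-coding sequence of length {length}")


def coding_seq(rng: np.random.Generator, length: int, orf_len: int, utr5: int) -> str:
    """utr5 + ATG + stop-free codons + stop + utr3, total ``length`` nt."""
    if utr5 + orf_len > length:
        raise ValidationError("ORF does not fit in transcript")
    n_codons = orf_len // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = random_seq(rng, 3)
        if c not in ("TAA", "TAG", "TGA", "ATG"):
            codons.append(c)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    body = "ATG" + "".join(codons) + stop
    return random_seq(rng, utr5) + body + random_seq(rng, length - utr5 - orf_len)


# ---------------------------------------------------------------------------
# genome arrays
# ---------------------------------------------------------------------------

def _genome_arrays(rng, config) -> dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": rng.integers(0, 4, config.chrom_length).astype(np.uint8)
        for i in range(config.n_chroms)
    }


_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _DECODE[_b] = _i


def _arr_to_str(arr: np.ndarray) -> str:
    return _ASCII[arr].tobytes().decode("ascii")


def _str_to_arr(seq: str) -> np.ndarray:
    return _DECODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def read_spliced(chrom_arr: np.ndarray, exons, strand: str) -> str:
    seq = "".join(_arr_to_str(chrom_arr[s:e]) for s, e in exons)
    return seq if strand == "+" else reverse_complement(seq)


def write_spliced(chrom_arr: np.ndarray, exons, strand: str, seq: str) -> None:
    if strand == "-":
        seq = reverse_complement(seq)
    pos = 0
    for s, e in exons:
        chrom_arr[s:e] = _str_to_arr(seq[pos : pos + (e - s)])
        pos += e - s


class _Placer:
    """Tracks occupied intervals per chromosome and hands out free slots."""

    def __init__(self, rng, margin: int = 500):
        self.rng = rng
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {}

    def reserve(self, chrom: str, start: int, end: int) -> None:
        ivs = self.occupied.setdefault(chrom, [])
        ivs.append((start, end))
        ivs.sort()

    def is_free(
        self,
        chrom: str,
        start: int,
        end: int,
        ignore: tuple[int, int] | None = None,
    ) -> bool:
        return not any(
            s - self.margin < end and start < e + self.margin
            for s, e in self.occupied.get(chrom, [])
            if (s, e) != ignore
        )

    def place(self, chrom: str, width: int, region: tuple[int, int]) -> int:
        """Return a start position for a ``width``-bp feature inside ``region``
        clear of occupied intervals (+margin); reserves it."""
        lo, hi = region
        gaps = []
        cursor = lo
        for s, e in self.occupied.get(chrom, []):
            s, e = s - self.margin, e + self.margin
            if e <= lo or s >= hi:
                continue
            if s > cursor:
                gaps.append((cursor, min(s, hi)))
            cursor = max(cursor, e)
        if cursor < hi:
            gaps.append((cursor, hi))
        gaps = [(s, e) for s, e in gaps if e - s >= width]
        if not gaps:
            raise BeetlncError(
                f"cannot place a {width}-bp feature on {chrom} in {region}; "
                f"increase chrom_length or reduce feature counts"
            )
        gi = int(self.rng.integers(0, len(gaps)))
        s, e = gaps[gi]
        start = int(self.rng.integers(s, e - width + 1))
        self.reserve(chrom, start, start + width)
        return start


# ---------------------------------------------------------------------------
# stage 1: genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAnnotation, dict[str, np.ndarray], _Placer]:
    """Lay out protein-coding genes on both strands and design their mRNAs.

    Genes are evenly slotted in the first ``chrom_length - isolated_tail`` bp
    of each chromosome; the tail stays gene-free so cis-window edge cases
    beyond 100 kb exist.  Returns the annotation (one transcript per gene,
    with the spliced mRNA sequence attached), the mutable genome arrays and
    the interval placer carrying the occupied gene spans.
    """
    rng = rng or np.random.default_rng(config.seed)
    genome = _genome_arrays(rng, config)
    chroms = sorted(genome)
    placer = _Placer(rng)

    per_chrom = [config.n_coding_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_coding_genes % config.n_chroms):
        per_chrom[i] += 1

    margin = 5_000
    region_end = config.chrom_length - config.isolated_tail
    max_extent = (
        config.gene_exon_range[1] * config.gene_exon_len[1]
        + (config.gene_exon_range[1] - 1) * config.gene_intron_len[1]
    )
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = (region_end - 2 * margin) / n
        if slot < max_extent + 2 * placer.margin:
            need = int(n * (max_extent + 2 * placer.margin) + 2 * margin + config.isolated_tail)
            raise BeetlncError(
                f"{n} genes do not fit on {chrom}: need chrom_length >= {need}"
            )
        for j in range(n):
            n_ex = int(rng.integers(config.gene_exon_range[0], config.gene_exon_range[1] + 1))
            ex_lens = [int(rng.integers(*config.gene_exon_len)) for _ in range(n_ex)]
            in_lens = [int(rng.integers(*config.gene_intron_len)) for _ in range(n_ex - 1)]
            extent = sum(ex_lens) + sum(in_lens)
            start = int(margin + j * slot + rng.integers(0, max(1, int(slot - extent - 2 * placer.margin))))
            exons = []
            pos = start
            for k, el in enumerate(ex_lens):
                exons.append((pos, pos + el))
                pos += el + (in_lens[k] if k < n_ex - 1 else 0)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gid = f"G{gi:04d}"
            gi += 1
            L = sum(ex_lens)
            orf_len = max(300, (int(0.6 * L) // 3) * 3)
            utr5 = min(100, max(0, L - orf_len - 60))
            seq = coding_seq(rng, L, orf_len, utr5)
            tx = TranscriptModel(f"{gid}.t1", chrom, strand, exons, seq)
            write_spliced(genome[chrom], exons, strand, seq)
            genes.append(GeneModel(gid, chrom, strand, [tx], "protein_coding"))
            placer.reserve(chrom, exons[0][0], exons[-1][1])

    ann = GenomeAnnotation(genes, {c: config.chrom_length for c in chroms})
    ann.validate()
    return ann, genome, placer


def utr3_window(gene: GeneModel) -> tuple[int, int]:
    """Transcript-coordinate window of the 3' UTR interior (site-planting zone)."""
    tx = gene.transcripts[0]
    orf = longest_orf(tx.sequence)
    lo = (0 if orf is None else orf.start + orf.length) + 5
    hi = tx.length - 30
    return lo, hi


# ---------------------------------------------------------------------------
# stage 2: planted transcripts
# ---------------------------------------------------------------------------

def _lnc_structure(rng, config, total_len: int) -> tuple[list[int], list[int]]:
    n_ex = int(rng.integers(config.lnc_exon_range[0], config.lnc_exon_range[1] + 1))
    n_ex = min(n_ex, max(2, total_len // 100))
    ex_lens = _split_lengths(rng, total_len, n_ex, 80)
    in_lens = [int(rng.integers(100, 400)) for _ in range(n_ex - 1)]
    return ex_lens, in_lens


def _exons_from(start: int, ex_lens, in_lens) -> list[tuple[int, int]]:
    exons, pos = [], start
    for k, el in enumerate(ex_lens):
        exons.append((pos, pos + el))
        pos += el + (in_lens[k] if k < len(in_lens) else 0)
    return exons


def simulate_transcripts(
    annotation: GenomeAnnotation,
    genome: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    placer: _Placer,
) -> tuple[dict[str, TranscriptModel], pd.DataFrame, dict[str, str]]:
    """Plant the transcript classes and write their sequences into the genome.

    Returns the screening input set, the truth class table, and the
    antisense-host map (gene id -> lncRNA id) used to keep mRNA site planting
    away from genes an antisense transcript reads through.
    """
    chroms = sorted(genome)
    region_end = config.chrom_length - config.isolated_tail
    transcripts: dict[str, TranscriptModel] = {}
    classes: list[tuple[str, str]] = []
    antisense_hosts: dict[str, str] = {}

    def add(tid, chrom, strand, exons, seq, clazz):
        t = TranscriptModel(tid, chrom, strand, exons, seq)
        transcripts[tid] = t
        classes.append((tid, clazz))

    # --- lincRNAs: gaps between genes plus the isolated tail ---------------
    n_tail = max(2, config.n_lincrna // 5)
    for i in range(config.n_lincrna):
        chrom = chroms[i % len(chroms)]
        total = int(np.clip(rng.normal(400, 90), 280, 700))
        ex_lens, in_lens = _lnc_structure(rng, config, total)
        extent = sum(ex_lens) + sum(in_lens)
        if i < n_tail:  # guaranteed > 100 kb from every gene
            region = (region_end + 110_000, config.chrom_length - 1_000)
        else:
            region = (2_000, region_end)
        start = placer.place(chrom, extent, region)
        exons = _exons_from(start, ex_lens, in_lens)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = noncoding_seq(rng, total)
        write_spliced(genome[chrom], exons, strand, seq)
        add(f"LINC{i:04d}", chrom, strand, exons, seq, "lincRNA")

    # --- intronic lncRNAs: wholly inside one intron ------------------------
    hosts = [
        g
        for g in annotation.genes
        for iv in [max(g.introns(), key=lambda ab: ab[1] - ab[0], default=None)]
        if iv is not None and iv[1] - iv[0] >= 1_400
    ]
    if len(hosts) == 0 and config.n_intronic > 0:
        raise BeetlncError("no intron large enough to host intronic lncRNAs")
    for i in range(config.n_intronic):
        g = hosts[i % len(hosts)]
        intron = max(g.introns(), key=lambda ab: ab[1] - ab[0])
        room = intron[1] - intron[0] - 200
        total = int(np.clip(rng.normal(900, 150), 500, min(1300, room - 250)))
        ex_lens, in_lens = _lnc_structure(rng, config, total)
        extent = sum(ex_lens) + sum(in_lens)
        while extent > room:
            in_lens = [max(50, il // 2) for il in in_lens]
            extent = sum(ex_lens) + sum(in_lens)
        start = intron[0] + 100 + int(rng.integers(0, max(1, room - extent)))
        exons = _exons_from(start, ex_lens, in_lens)
        seq = noncoding_seq(rng, total)
        write_spliced(genome[g.chrom], exons, g.strand, seq)
        add(f"INTR{i:04d}", g.chrom, g.strand, exons, seq, "intronic")

    # --- antisense lncRNAs: read through a gene exon on the other strand ---
    host_cursor = 0
    for i in range(config.n_antisense):
        g = None
        e1 = e2 = (0, 0)
        ov = 120
        while host_cursor < len(annotation.genes):
            cand = annotation.genes[host_cursor]
            host_cursor += 1
            if cand.id in antisense_hosts:
                continue
            last_exon = cand.exons()[-1]
            len1 = int(rng.integers(180, 260))
            gap = int(rng.integers(120, 250))
            len2 = int(rng.integers(120, 220))
            e1 = (last_exon[1] - ov, last_exon[1] - ov + len1)
            e2 = (e1[1] + gap, e1[1] + gap + len2)
            # the extension beyond the gene span must not hit anything else
            if placer.is_free(cand.chrom, cand.span[1], e2[1] + 100, ignore=cand.span):
                g = cand
                break
        if g is None:
            raise BeetlncError("antisense quota unplaceable: no host gene with free flank")
        last_exon = g.exons()[-1]
        placer.reserve(g.chrom, g.span[1], e2[1] + 100)
        strand = "-" if g.strand == "+" else "+"
        exons = [e1, e2]
        total = len1 + len2
        # the chunk inside the gene exon is fixed (read from the genome)
        chunk_fwd = _arr_to_str(genome[g.chrom][e1[0] : last_exon[1]])
        if strand == "-":
            chunk = reverse_complement(chunk_fwd)
            off = total - ov  # last ov nt of the spliced lnc
        else:
            chunk = chunk_fwd
            off = 0
        seq = noncoding_seq(rng, total, fixed=(off, chunk))
        write_spliced(genome[g.chrom], exons, strand, seq)
        # re-read: the fixed chunk was never overwritten, rest now matches
        seq = read_spliced(genome[g.chrom], exons, strand)
        add(f"ANTI{i:04d}", g.chrom, strand, exons, seq, "antisense")
        antisense_hosts[g.id] = f"ANTI{i:04d}"

    # --- rejects -----------------------------------------------------------
    for i in range(config.n_short_reject):
        chrom = chroms[i % len(chroms)]
        if i % 2 == 0:  # single exon, long enough: fails filter 1
            total = 500
            ex_lens, in_lens = [total], []
        else:  # two exons but <= 200 nt: fails filter 2 (boundary included)
            total = 200 if i == 1 else int(rng.integers(140, 200))
            ex_lens = _split_lengths(rng, total, 2, 60)
            in_lens = [int(rng.integers(100, 300))]
        extent = sum(ex_lens) + sum(in_lens)
        start = placer.place(chrom, extent, (2_000, region_end))
        exons = _exons_from(start, ex_lens, in_lens)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = noncoding_seq(rng, total)
        write_spliced(genome[chrom], exons, strand, seq)
        add(f"SHRT{i:04d}", chrom, strand, exons, seq, "short_reject")

    for i in range(config.n_coding_like_reject):
        chrom = chroms[i % len(chroms)]
        total = 800
        ex_lens = _split_lengths(rng, total, 2, 200)
        in_lens = [int(rng.integers(150, 400))]
        extent = sum(ex_lens) + sum(in_lens)
        start = placer.place(chrom, extent, (2_000, region_end))
        exons = _exons_from(start, ex_lens, in_lens)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = coding_seq(rng, total, 450, 100)  # ORF >= 300 nt by construction
        write_spliced(genome[chrom], exons, strand, seq)
        add(f"CODL{i:04d}", chrom, strand, exons, seq, "coding_like_reject")

    truth = pd.DataFrame(classes, columns=["transcript", "clazz"])
    return transcripts, truth, antisense_hosts


# ---------------------------------------------------------------------------
# stage 3: expression
# ---------------------------------------------------------------------------

def make_samples() -> list[SampleInfo]:
    """The 12-sample design: CV-A1..CV-A3, CV-B1..CV-B3, LN-A1.., LN-B3."""
    samples = []
    for cond in ("CV", "LN"):
        for tissue, code in (("foliage", "A"), ("root", "B")):
            for rep in (1, 2, 3):
                samples.append(SampleInfo(f"{cond}-{code}{rep}", tissue, cond, rep))
    return samples


@dataclass
class FeatureSpec:
    """Per-feature generative parameters."""

    mean: float
    disp: float
    lfc: dict[str, float] = field(default_factory=dict)  # tissue -> log2FC (LN vs CV)
    latent_group: str | None = None
    latent_sign: int = 1


def simulate_expression(
    feature_specs: dict[str, FeatureSpec],
    samples: list[SampleInfo],
    latent_sigmas: dict[str, float],
    rng: np.random.Generator,
    lib_factors: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Draw NB counts for every feature under the design.

    Sample mean = base mean x 2^lfc (LN samples of a planted tissue) x the
    feature's latent-group factor (log-normal, unit mean, shared within the
    group per sample) x the sample's library factor.
    """
    n = len(samples)
    if lib_factors is None:
        lib_factors = np.ones(n)
    latents = {
        gid: np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma**2)
        for gid, sigma in sorted(latent_sigmas.items())
    }
    ids = list(feature_specs)
    counts = np.zeros((len(ids), n), dtype=np.int64)
    for fi, fid in enumerate(ids):
        spec = feature_specs[fid]
        mu = np.full(n, spec.mean)
        for si, s in enumerate(samples):
            if s.condition == "LN" and s.tissue in spec.lfc:
                mu[si] *= 2.0 ** spec.lfc[s.tissue]
        if spec.latent_group is not None:
            lat = latents[spec.latent_group]
            if spec.latent_sign >= 0:
                mu = mu * lat
            else:
                sigma = latent_sigmas[spec.latent_group]
                # inverted coupling, renormalised to unit mean
                mu = mu * np.exp(-np.log(lat) - sigma**2)
        mu = mu * lib_factors
        counts[fi] = sample_nb(rng, mu, spec.disp)
    return ExpressionMatrix(ids, samples, counts)


# ---------------------------------------------------------------------------
# stage 4: miRNA site planting
# ---------------------------------------------------------------------------

@dataclass
class SitePlan:
    mirna: str
    host: str
    host_kind: str  # "lncRNA" | "mRNA"
    tissue: str
    mismatches: int
    forced_gu: bool = False


def _make_site(rng, mirna_dna: str, mismatches: int, forced_gu: bool) -> str:
    """A target window pairing the miRNA with the requested defect pattern."""
    L = len(mirna_dna)
    site = list(reverse_complement(mirna_dna))  # perfect WC site
    positions = list(rng.choice(L, size=mismatches, replace=False)) if mismatches else []
    for j in positions:
        q = mirna_dna[L - 1 - j]  # miRNA base pairing window position j
        banned = {_COMP[q], _WOBBLE.get(q, "")}
        choices = [b for b in _BASES if b not in banned]
        site[j] = choices[int(rng.integers(0, len(choices)))]
    if forced_gu:
        cand = [j for j in range(L) if mirna_dna[L - 1 - j] in _WOBBLE and j not in positions]
        j = cand[int(rng.integers(0, len(cand)))]
        site[j] = _WOBBLE[mirna_dna[L - 1 - j]]
    return "".join(site)


def plant_mirna_sites(
    sequences: dict[str, str],
    regions: dict[str, tuple[int, int]],
    plan: list[SitePlan],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate miRNAs and embed one planned site per plan entry.

    ``regions`` limits the offset range per host (e.g. an mRNA's 3' UTR).
    lncRNA hosts are re-checked against the non-coding consensus gate after
    each edit.  Returns (edited sequences, miRNA FASTA map in RNA space,
    truth site table); the scanner is run on every edited host to confirm the
    planted site is found with exactly the planted mismatch/wobble counts.
    """
    from .cerna import scan_binding_sites  # local import avoids a cycle

    seqs = dict(sequences)
    mirnas_dna = {}
    for i in range(config.n_mirnas):
        mirnas_dna[f"miR{i:02d}"] = random_seq(rng, config.mirna_length)
    rows = []
    used: dict[str, list[tuple[int, int]]] = {}  # host -> occupied site windows
    for sp in plan:
        mir = mirnas_dna[sp.mirna]
        L = len(mir)
        host_seq = seqs[sp.host]
        lo, hi = regions.get(sp.host, (5, len(host_seq) - L - 5))
        hi = min(hi, len(host_seq) - L)
        if hi <= lo:
            raise ValidationError(f"site longer than usable region of {sp.host}")
        placed = False
        for _ in range(60):
            site = _make_site(rng, mir, sp.mismatches, sp.forced_gu)
            off = int(rng.integers(lo, hi + 1))
            if any(off < e and s < off + L for s, e in used.get(sp.host, [])):
                continue  # never overwrite an earlier planted site
            edited = host_seq[:off] + site + host_seq[off + L:]
            if sp.host_kind == "lncRNA" and not consensus_noncoding(edited).consensus_noncoding:
                continue
            found = scan_binding_sites(mir, edited, max_mismatches=4, allow_gu=True,
                                       mirna_id=sp.mirna, target_id=sp.host)
            at = [s for s in found if s.offset == off]
            stray = [s for s in found if s.offset != off and s.mismatches <= 3 and s.gu_pairs == 0]
            want_gu = 1 if sp.forced_gu else 0
            if at and at[0].mismatches == sp.mismatches and at[0].gu_pairs == want_gu and not stray:
                seqs[sp.host] = edited
                host_seq = edited
                used.setdefault(sp.host, []).append((off, off + L))
                rows.append(
                    {
                        "mirna": sp.mirna,
                        "target": sp.host,
                        "target_kind": sp.host_kind,
                        "tissue": sp.tissue,
                        "offset": off,
                        "mismatches": sp.mismatches,
                        "gu_pairs": want_gu,
                    }
                )
                placed = True
                break
        if not placed:
            raise BeetlncError(f"could not plant site {sp} after 60 tries")
    mirnas_rna = {k: v.replace("T", "U") for k, v in mirnas_dna.items()}
    return seqs, mirnas_rna, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 5: terms
# ---------------------------------------------------------------------------

def simulate_terms(
    genes: list[str],
    de_genes: set[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[TermMap, list[str]]:
    """Uniform random terms plus one term over-represented in the DE set.

    Membership odds for the planted term are ``planted_term_odds`` times
    higher for DE genes; an odds ratio of 1 plants nothing.
    """
    if config.n_terms < 1:
        raise ValidationError("need >= 1 term")
    q = config.term_base_rate
    terms: dict[str, set[str]] = {}
    enriched: list[str] = []
    odds = config.planted_term_odds
    p1 = odds * q / (1 - q + odds * q)
    for ti in range(config.n_terms):
        term = f"T{ti:03d}"
        planted = ti == 0 and odds > 1 and de_genes
        members = set()
        for g in genes:
            p = p1 if (planted and g in de_genes) else q
            if rng.random() < p:
                members.add(g)
        if not members:
            members.add(genes[int(rng.integers(0, len(genes)))])
        if len(members) > len(genes):
            raise ValidationError("term size exceeds universe")
        terms[term] = members
        if planted:
            enriched.append(term)
    return TermMap(terms, "GO"), enriched


# ---------------------------------------------------------------------------
# stage 6: qPCR Ct table
# ---------------------------------------------------------------------------

def simulate_ct_table(
    de_rows: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str]]:
    """A Ct table for a panel of planted DE features, two reference genes,
    3 replicates per condition, consistent with the planted fold changes."""
    chosen = de_rows.head(config.n_qpcr_genes)
    rows = []
    tissue_of = {}
    for _, r in chosen.iterrows():
        gene, lfc = r["feature"], float(r["log2fc"])
        tissue_of[gene] = r["tissue"]
        for cond in ("CV", "LN"):
            for rep in (1, 2, 3):
                sample = f"{gene}:{cond}{rep}"
                rows.append((f"refA", sample, cond, 20.0 + rng.normal(0, 0.05), True))
                rows.append((f"refB", sample, cond, 22.0 + rng.normal(0, 0.05), True))
                ct = 25.0 - (lfc if cond == "LN" else 0.0) + rng.normal(0, 0.08)
                rows.append((gene, sample, cond, ct, False))
    df = pd.DataFrame(rows, columns=["gene", "sample", "condition", "ct", "is_reference"])
    return df, tissue_of


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def _brute_cis_truth(
    del_ids: list[str],
    transcripts: dict[str, TranscriptModel],
    annotation: GenomeAnnotation,
    window: int = 100_000,
) -> pd.DataFrame:
    """Simple all-pairs distance scan recording the planted cis truth."""
    rows = []
    for lid in del_ids:
        t = transcripts[lid]
        for g in annotation.genes:
            if g.chrom != t.chrom or g.biotype != "protein_coding":
                continue
            gs, ge = g.span
            if gs >= t.end:
                gap = gs - t.end
            elif ge <= t.start:
                gap = -(t.start - ge)
            else:
                gap = 0
            if abs(gap) <= window:
                rows.append({"lncrna": lid, "gene": g.id, "distance": gap})
    return pd.DataFrame(rows, columns=["lncrna", "gene", "distance"])


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run every stage under one seed and assemble the truth tables."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    annotation, genome, placer = simulate_genome(config, rng)
    transcripts, class_truth, antisense_hosts = simulate_transcripts(
        annotation, genome, config, rng, placer
    )

    lincs = [t for t, c in zip(class_truth["transcript"], class_truth["clazz"]) if c == "lincRNA"]
    intronics = [t for t, c in zip(class_truth["transcript"], class_truth["clazz"]) if c == "intronic"]
    lnc_ids = [t for t, c in zip(class_truth["transcript"], class_truth["clazz"])
               if c in ("lincRNA", "intronic", "antisense")]
    gene_ids = annotation.gene_ids()
    plantable_genes = [g for g in gene_ids if g not in antisense_hosts]
    mir_ids = [f"miR{i:02d}" for i in range(config.n_mirnas)]

    # ---- identity assignment ---------------------------------------------
    # root DELs first (hub, decoy-negative, trans-pair lncs), then foliage
    need_root = config.n_de_lnc_root
    need_fol = config.n_de_lnc_foliage
    if len(lincs) < need_root + need_fol - min(4, len(intronics)) + 3:
        raise BeetlncError("not enough lincRNAs for the planted DE design")
    root_lncs = lincs[: need_root - 2] + intronics[:2]
    fol_lncs = lincs[need_root - 2 : need_root - 2 + need_fol - 2] + intronics[2:4]
    root_lncs = root_lncs[:need_root]
    fol_lncs = fol_lncs[:need_fol]
    decoy_lnc = lincs[need_root + need_fol]  # never DE: must yield no triad

    L_hub, L_neg = root_lncs[0], root_lncs[1]
    L_f1, L_f2 = fol_lncs[0], fol_lncs[1]

    root_genes = plantable_genes[: config.n_de_mrna_root]
    fol_genes = plantable_genes[
        config.n_de_mrna_root : config.n_de_mrna_root + config.n_de_mrna_foliage
    ]
    G0, G1, G2, G3 = root_genes[:4]
    G4, G5, G6, G_neg = fol_genes[:4]

    root_mirs = [mir_ids[0], mir_ids[1], mir_ids[2], mir_ids[5]]
    fol_mirs = [mir_ids[3], mir_ids[4], mir_ids[6]]
    M0, M1, M2, M5 = root_mirs
    M3, M4, M6 = fol_mirs

    # trans pairs: half positive (shared latent), half negative (opposed DE)
    n_pos = (config.n_trans_pairs + 1) // 2
    pair_lncs = [l for l in root_lncs[2:] if l != decoy_lnc][: config.n_trans_pairs]
    pair_genes = root_genes[4 : 4 + config.n_trans_pairs]
    if len(pair_lncs) < config.n_trans_pairs or len(pair_genes) < config.n_trans_pairs:
        raise BeetlncError("not enough DE features for the planted trans pairs")

    # ---- feature specs ----------------------------------------------------
    lfc = config.de_log2fc
    specs: dict[str, FeatureSpec] = {}
    latent_sigmas: dict[str, float] = {}

    def base_spec(mean, disp):
        return FeatureSpec(mean=mean, disp=disp)

    for t in lnc_ids:
        specs[t] = base_spec(config.lnc_mean, config.lnc_disp)
    for g in gene_ids:
        specs[g] = base_spec(config.mrna_mean, config.mrna_disp)
    for m in mir_ids:
        specs[m] = base_spec(config.mirna_mean, config.mirna_disp)

    de_rows = []

    def plant_de(fid, kind, tissue, value):
        specs[fid].mean = max(specs[fid].mean, config.de_mean)
        specs[fid].lfc[tissue] = value
        de_rows.append({"feature": fid, "kind": kind, "tissue": tissue, "log2fc": value})

    for i, t in enumerate(root_lncs):
        plant_de(t, "lncRNA", "root", lfc if (i % 2 == 0 or t in (L_hub, L_neg)) else -lfc)
    for i, t in enumerate(fol_lncs):
        plant_de(t, "lncRNA", "foliage", lfc if (i % 2 == 0 or t in (L_f1, L_f2)) else -lfc)
    for i, g in enumerate(root_genes):
        plant_de(g, "mRNA", "root", lfc if (g in (G0, G1, G2, G3) or i % 2 == 0) else -lfc)
    for i, g in enumerate(fol_genes):
        plant_de(g, "mRNA", "foliage", lfc if (g in (G4, G5, G6) or i % 2 == 0) else -lfc)
    for m in (M0, M1, M2, M5):
        plant_de(m, "miRNA", "root", lfc)
    for m in (M3, M4, M6):
        plant_de(m, "miRNA", "foliage", lfc)

    # triad clusters share a mild latent so lncRNA-mRNA consistency is positive
    for gid_, members in (
        ("grp_hub", [L_hub, G0, G1, G2, G3]),
        ("grp_f1", [L_f1, G4]),
        ("grp_f2", [L_f2, G5, G6]),
    ):
        latent_sigmas[gid_] = latent_sigma(config.triad_r, config.latent_mean, config.latent_disp)
        for f in members:
            specs[f].mean = config.latent_mean
            specs[f].disp = config.latent_disp
            specs[f].latent_group = gid_

    trans_rows = []
    for i, (l, g) in enumerate(zip(pair_lncs, pair_genes)):
        positive = i < n_pos
        specs[l].mean = specs[g].mean = config.latent_mean
        specs[l].disp = specs[g].disp = config.latent_disp
        # matched (positive) or opposed (negative) DE direction in root
        specs[l].lfc["root"] = lfc
        specs[g].lfc["root"] = lfc if positive else -lfc
        for row in de_rows:
            if row["feature"] in (l, g):
                row["log2fc"] = specs[row["feature"]].lfc["root"]
        if positive:
            gid_ = f"grp_trans{i}"
            latent_sigmas[gid_] = latent_sigma(
                config.trans_r, config.latent_mean, config.latent_disp
            )
            specs[l].latent_group = specs[g].latent_group = gid_
        trans_rows.append(
            {"lncrna": l, "gene": g, "target_r": config.trans_r if positive else -config.trans_r}
        )

    samples = make_samples()
    lib = np.exp(rng.normal(0, config.lib_sd, len(samples)))
    lib /= np.exp(np.log(lib).mean())
    full = simulate_expression(specs, samples, latent_sigmas, rng, lib)

    def pick(ids):
        return full.subset_features(ids)

    lnc_matrix = pick(lnc_ids)
    mrna_matrix = pick(gene_ids)
    mirna_matrix = pick(mir_ids)
    lnc_matrix.feature_lengths = {t: transcripts[t].length for t in lnc_ids}
    mrna_matrix.feature_lengths = {
        g.id: g.transcripts[0].length for g in annotation.genes
    }

    # ---- binding sites ----------------------------------------------------
    site_plan = [
        SitePlan(M0, L_hub, "lncRNA", "root", 0),
        SitePlan(M1, L_hub, "lncRNA", "root", 1),
        SitePlan(M2, L_hub, "lncRNA", "root", 2),
        SitePlan(M0, G0, "mRNA", "root", 1),
        SitePlan(M0, G1, "mRNA", "root", 3),
        SitePlan(M1, G2, "mRNA", "root", 0),
        SitePlan(M2, G3, "mRNA", "root", 2),
        SitePlan(M5, L_neg, "lncRNA", "root", 4),        # too many mismatches
        SitePlan(M5, G0, "mRNA", "root", 1),             # mir-mRNA without lnc pair
        SitePlan(M0, decoy_lnc, "lncRNA", "root", 0),    # perfect site, non-DE lnc
        SitePlan(M3, L_f1, "lncRNA", "foliage", 3),
        SitePlan(M3, G4, "mRNA", "foliage", 0),
        SitePlan(M4, L_f2, "lncRNA", "foliage", 0),
        SitePlan(M4, G5, "mRNA", "foliage", 1),
        SitePlan(M4, G6, "mRNA", "foliage", 2),
        SitePlan(M6, L_f2, "lncRNA", "foliage", 0),
        SitePlan(M6, G_neg, "mRNA", "foliage", 0, forced_gu=True),  # G.U control
    ]
    sequences = {t: transcripts[t].sequence for t in lnc_ids}
    sequences[decoy_lnc] = transcripts[decoy_lnc].sequence
    for g in annotation.genes:
        sequences[g.id] = g.transcripts[0].sequence
    regions = {g.id: utr3_window(g) for g in annotation.genes}
    sequences, mirnas, site_truth = plant_mirna_sites(sequences, regions, site_plan, config, rng)

    # propagate edits back into transcripts and the genome
    for t in transcripts.values():
        if t.id in sequences and sequences[t.id] != t.sequence:
            t.sequence = sequences[t.id]
            write_spliced(genome[t.chrom], t.exons, t.strand, t.sequence)
    for g in annotation.genes:
        tx = g.transcripts[0]
        if sequences[g.id] != tx.sequence:
            tx.sequence = sequences[g.id]
            write_spliced(genome[g.chrom], tx.exons, tx.strand, tx.sequence)
    for m, s in mirnas.items():
        sequences[m] = s.replace("U", "T")

    de_truth = pd.DataFrame(de_rows, columns=["feature", "kind", "tissue", "log2fc"])

    # expected triads: accepted planted sites joined on the miRNA, DE-matched
    accepted = site_truth[(site_truth["mismatches"] <= 3) & (site_truth["gu_pairs"] == 0)]
    de_by_tissue = {
        tis: set(de_truth.loc[de_truth["tissue"] == tis, "feature"]) for tis in ("foliage", "root")
    }
    triad_rows = []
    for tis in ("foliage", "root"):
        ok = de_by_tissue[tis]
        acc = accepted[accepted["tissue"] == tis]
        lnc_side = acc[(acc["target_kind"] == "lncRNA") & acc["target"].isin(ok) & acc["mirna"].isin(ok)]
        mrna_side = acc[(acc["target_kind"] == "mRNA") & acc["target"].isin(ok) & acc["mirna"].isin(ok)]
        for _, lr in lnc_side.iterrows():
            for _, gr in mrna_side[mrna_side["mirna"] == lr["mirna"]].iterrows():
                triad_rows.append(
                    {"lncrna": lr["target"], "mirna": lr["mirna"], "mrna": gr["target"], "tissue": tis}
                )
    triad_truth = pd.DataFrame(triad_rows, columns=["lncrna", "mirna", "mrna", "tissue"])

    del_ids = sorted(set(de_truth.loc[de_truth["kind"] == "lncRNA", "feature"]))
    cis_truth = _brute_cis_truth(del_ids, transcripts, annotation)

    de_gene_set = set(de_truth.loc[de_truth["kind"] == "mRNA", "feature"])
    term_map, enriched = simulate_terms(gene_ids, de_gene_set, config, rng)

    ct_table, qpcr_tissue = simulate_ct_table(
        de_truth[de_truth["kind"] == "lncRNA"], config, rng
    )

    truth = TruthTables(
        classes=class_truth,
        de=de_truth,
        trans_pairs=pd.DataFrame(trans_rows, columns=["lncrna", "gene", "target_r"]),
        cis_pairs=cis_truth,
        sites=site_truth,
        triads=triad_truth,
        enriched_terms=enriched,
    )
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        genome={c: _arr_to_str(a) for c, a in sorted(genome.items())},
        transcripts=transcripts,
        mirnas=mirnas,
        lnc_matrix=lnc_matrix,
        mrna_matrix=mrna_matrix,
        mirna_matrix=mirna_matrix,
        term_map=term_map,
        universe=gene_ids,
        ct_table=ct_table,
        qpcr_tissue=qpcr_tissue,
        sequences=sequences,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Emit the dataset in the same formats core_io reads, plus truth/*.tsv."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_annotation(ds.annotation, out / "annotation.gtf")
    write_fasta(ds.genome, out / "genome.fa")
    write_fasta(
        {t.id: t.sequence for t in ds.transcripts.values()}, out / "transcripts.fa"
    )
    write_fasta(ds.mirnas, out / "mirnas.fa")
    write_sample_sheet(ds.lnc_matrix.samples, out / "samples.tsv")
    write_counts(ds.lnc_matrix, out / "counts_lncrna.tsv")
    write_counts(ds.mrna_matrix, out / "counts_mrna.tsv")
    write_counts(ds.mirna_matrix, out / "counts_mirna.tsv")
    write_term_map(ds.term_map, out / "terms.tsv")
    write_ct_table(ds.ct_table, out / "qpcr_ct.tsv")
    ds.truth.classes.to_csv(out / "truth" / "classes.tsv", sep="\t", index=False)
    ds.truth.de.to_csv(out / "truth" / "de.tsv", sep="\t", index=False)
    ds.truth.trans_pairs.to_csv(out / "truth" / "trans_pairs.tsv", sep="\t", index=False)
    ds.truth.cis_pairs.to_csv(out / "truth" / "cis_pairs.tsv", sep="\t", index=False)
    ds.truth.sites.to_csv(out / "truth" / "sites.tsv", sep="\t", index=False)
    ds.truth.triads.to_csv(out / "truth" / "triads.tsv", sep="\t", index=False)
    pd.DataFrame({"term": ds.truth.enriched_terms}).to_csv(
        out / "truth" / "enriched_terms.tsv", sep="\t", index=False
    )
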
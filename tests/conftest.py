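import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from beetlnc.core_io import GeneModel, GenomeAnnotation, TranscriptModel
from beetlnc.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """Reduced synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig.small(seed=7))


@pytest.fixture(scope="session")
def default_ds():
    """The default-scale synthetic dataset (the study conditions)."""
    return simulate_dataset(SimulationConfig())


@pytest.fixture()
def toy_annotation():
    """Two genes on chr1 (one per strand) with simple exon structure."""
    g1 = GeneModel(
        "gene_plus",
        "chr1",
        "+",
        [TranscriptModel("gene_plus.t1", "chr1", "+", [(1000, 1500), (2500, 3000), (4000, 4600)])],
    )
    g2 = GeneModel(
        "gene_minus",
        "chr1",
        "-",
        [TranscriptModel("gene_minus.t1", "chr1", "-", [(10000, 10400), (11200, 11800)])],
    )
    return GenomeAnnotation([g1, g2], {"chr1": 50_000, "chr2": 50_000})


def random_transcripts(annotation, n, rng, chrom_len=50_000):
    """Random exon-structured transcripts over the annotation's chromosomes."""
    chroms = sorted(annotation.chrom_lengths) or ["chr1"]
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        n_ex = int(rng.integers(1, 4))
        start = int(rng.integers(0, chrom_len - 6000))
        exons = []
        pos = start
        for _ in range(n_ex):
            length = int(rng.integers(50, 600))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 1500))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        out.append(TranscriptModel(f"rand{i:04d}", chrom, strand, exons))
    return out
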
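"""miRNA binding-site scanning and ceRNA (lncRNA-miRNA-mRNA) triad assembly.

The scanner slides the full-length miRNA (no gaps, no seed weighting) along
the target: at each offset the miRNA 5'->3' is paired antiparallel against
the target window, so a perfect site is the reverse complement of the miRNA.
Positions pair Watson-Crick (A:U, G:C); G.U oppositions are tallied as wobble
— a category of their own, not mismatches — and disqualify a site when
disallowed; every other non-pairing position is a mismatch.  A site is
accepted when mismatches <= 3 ("fewer than 4") and, by default, no G.U pair
is present.

Triads join an accepted miRNA-lncRNA pair with an accepted miRNA-mRNA pair
through the shared miRNA; all three members must be differentially expressed
in the same tissue, and by default the lncRNA and mRNA must be positively
correlated there (the ceRNA hypothesis implies co-directional response;
``consistency="none"`` disables the filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError
from .targets import pearson

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_WC_PARTNER = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: target base forming a G.U wobble opposite the given miRNA base (DNA space)
_WOBBLE_PARTNER = {"G": "T", "T": "G"}


@dataclass(frozen=True)
class BindingSite:
    """An ungapped miRNA site; ``offset`` is the 5'-most target base (0-based)."""

    mirna: str
    target: str
    offset: int
    mismatches: int
    gu_pairs: int


@dataclass
class CeRNATriad:
    lncrna: str
    mirna: str
    mrna: str
    tissue: str
    lnc_mrna_r: float | None
    lnc_site: BindingSite
    mrna_site: BindingSite


@dataclass
class NetworkSummary:
    degrees: dict[str, int]
    hubs: list[str]  # lncRNA(s) of maximal miRNA-degree, all ties, sorted
    hub_mirna_degree: int
    n_lnc_mir_pairs: dict[str, int]  # per tissue
    n_mir_mrna_edges: dict[str, int]


def _encode(seq: str, what: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"{what}: non-ACGTUN symbol {exc}") from exc


def scan_binding_sites(
    mirna_seq: str,
    target_seq: str,
    max_mismatches: int = 3,
    allow_gu: bool = False,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[BindingSite]:
    """Scan every offset of the target for miRNA sites; overlaps all reported.

    ``N`` in either sequence counts as a mismatch.  RNA and DNA alphabets are
    both accepted (compared in a common space).
    """
    L = len(mirna_seq)
    if not 18 <= L <= 30:
        raise ValidationError(f"{mirna_id}: miRNA length must be 18-30 nt, got {L}")
    if len(target_seq) < L:
        raise ValidationError(f"{mirna_id} longer than target {target_id}")
    mir = _encode(mirna_seq, mirna_id)
    tgt = _encode(target_seq, target_id)
    n_off = len(tgt) - L + 1

    # per window position j the miRNA base is mir[L-1-j] (antiparallel pairing)
    q = mir[::-1]
    q_chars = mirna_seq.upper().replace("U", "T")[::-1]
    wc = np.array([_CODE[_WC_PARTNER.get(c, "N")] if c != "N" else -1 for c in q_chars])
    wob = np.array([_CODE[_WOBBLE_PARTNER[c]] if c in _WOBBLE_PARTNER else -1 for c in q_chars])

    # windows[i, j] = tgt[i + j], built column-wise (L is small)
    windows = np.empty((n_off, L), dtype=np.int8)
    for j in range(L):
        windows[:, j] = tgt[j : j + n_off]
    is_wc = windows == wc[None, :]
    is_wob = windows == wob[None, :]
    n_wob = is_wob.sum(axis=1)
    n_mis = L - is_wc.sum(axis=1) - n_wob

    sites = []
    for i in range(n_off):
        if n_mis[i] <= max_mismatches and (allow_gu or n_wob[i] == 0):
            sites.append(BindingSite(mirna_id, target_id, i, int(n_mis[i]), int(n_wob[i])))
    return sites


def binding_pairs(
    mirna_ids: Sequence[str],
    host_ids: Sequence[str],
    sequences: Mapping[str, str],
    max_mismatches: int = 3,
    allow_gu: bool = False,
) -> dict[tuple[str, str], BindingSite]:
    """All (miRNA, host) pairs with >= 1 accepted site; each pair carries its
    best site (fewest mismatches, earliest offset on ties)."""
    out: dict[tuple[str, str], BindingSite] = {}
    for mid in mirna_ids:
        if mid not in sequences:
            raise ValidationError(f"missing sequence for miRNA {mid!r}")
        for hid in host_ids:
            if hid not in sequences:
                raise ValidationError(f"missing sequence for feature {hid!r}")
            if len(sequences[hid]) < len(sequences[mid]):
                continue
            sites = scan_binding_sites(
                sequences[mid], sequences[hid], max_mismatches, allow_gu, mid, hid
            )
            if sites:
                out[(mid, hid)] = min(sites, key=lambda s: (s.mismatches, s.offset))
    return out


def pair_del_dem(
    dels: Sequence[str],
    dems: Sequence[str],
    sequences: Mapping[str, str],
    max_mismatches: int = 3,
    allow_gu: bool = False,
) -> dict[tuple[str, str], BindingSite]:
    """Accepted DEL-DEM pairs, keyed (miRNA, lncRNA)."""
    return binding_pairs(dems, dels, sequences, max_mismatches, allow_gu)


def build_triads(
    del_dem_pairs: Mapping[tuple[str, str], BindingSite],
    dem_deg_pairs: Mapping[tuple[str, str], BindingSite],
    expression: ExpressionMatrix,
    tissue: str,
    consistency: str = "positive",
) -> list[CeRNATriad]:
    """Merge the two pair sets on the shared miRNA into ceRNA triads."""
    if not any(s.tissue == tissue for s in expression.samples):
        raise ValidationError(f"tissue {tissue!r} absent from sample sheet")
    if consistency not in ("positive", "none"):
        raise ValidationError(f"unknown consistency mode {consistency!r}")
    idx = expression.sample_idx(tissue=tissue)
    pos = {f: i for i, f in enumerate(expression.feature_ids)}
    by_mir_lnc: dict[str, list[tuple[str, BindingSite]]] = {}
    for (mid, lid), site in del_dem_pairs.items():
        by_mir_lnc.setdefault(mid, []).append((lid, site))
    triads: list[CeRNATriad] = []
    for (mid, gid), g_site in sorted(dem_deg_pairs.items()):
        for lid, l_site in sorted(by_mir_lnc.get(mid, [])):
            r = None
            if consistency == "positive":
                xv = expression.counts[pos[lid], idx].astype(float)
                yv = expression.counts[pos[gid], idx].astype(float)
                if np.std(xv) == 0 or np.std(yv) == 0:
                    continue
                r = pearson(xv, yv)
                if r <= 0:
                    continue
            triads.append(CeRNATriad(lid, mid, gid, tissue, r, l_site, g_site))
    return triads


# ---------------------------------------------------------------------------
# network summaries and export
# ---------------------------------------------------------------------------

def _edges(triads: Sequence[CeRNATriad]) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    lnc_edges = {(t.mirna, t.lncrna) for t in triads}
    mrna_edges = {(t.mirna, t.mrna) for t in triads}
    return lnc_edges, mrna_edges


def network_summary(triads: Sequence[CeRNATriad]) -> NetworkSummary:
    """Node degrees over the union bipartite edge sets, hub lncRNA(s), and
    per-tissue edge counts.  Empty input yields a zero-filled summary."""
    lnc_edges, mrna_edges = _edges(triads)
    degrees: dict[str, int] = {}
    for m, l in lnc_edges:
        degrees[m] = degrees.get(m, 0) + 1
        degrees[l] = degrees.get(l, 0) + 1
    for m, g in mrna_edges:
        degrees[m] = degrees.get(m, 0) + 1
        degrees[g] = degrees.get(g, 0) + 1
    lnc_mir_degree: dict[str, int] = {}
    for m, l in lnc_edges:
        lnc_mir_degree[l] = lnc_mir_degree.get(l, 0) + 1
    if lnc_mir_degree:
        top = max(lnc_mir_degree.values())
        hubs = sorted(l for l, d in lnc_mir_degree.items() if d == top)
    else:
        top, hubs = 0, []
    tissues = sorted({t.tissue for t in triads})
    n_lnc = {
        tis: len({(t.mirna, t.lncrna) for t in triads if t.tissue == tis}) for tis in tissues
    }
    n_mrna = {
        tis: len({(t.mirna, t.mrna) for t in triads if t.tissue == tis}) for tis in tissues
    }
    return NetworkSummary(degrees, hubs, top, n_lnc, n_mrna)


def export_network(
    triads: Sequence[CeRNATriad], prefix: str | Path, dialect: str = "edge_tsv"
) -> tuple[Path, Path]:
    """Write Cytoscape-consumable edge and node tables.

    Edges are typed ``binds_lnc`` (miRNA->lncRNA) and ``targets_mrna``
    (miRNA->mRNA); the node table carries each node's kind (the diamond /
    circle / triangle roles of the rendered network).  Ordering is
    deterministic.  Returns (edges_path, nodes_path).
    """
    if dialect not in ("sif", "edge_tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    prefix = Path(prefix)
    lnc_edges, mrna_edges = _edges(triads)
    rows = [("binds_lnc", m, x) for m, x in sorted(lnc_edges)] + [
        ("targets_mrna", m, x) for m, x in sorted(mrna_edges)
    ]
    if dialect == "sif":
        edges_path = prefix.with_suffix(".sif")
        with open(edges_path, "w") as fh:
            for kind, src, dst in rows:
                fh.write(f"{src}\t{kind}\t{dst}\n")
    else:
        edges_path = prefix.with_suffix(".edges.tsv")
        pd.DataFrame(
            [(src, kind, dst) for kind, src, dst in rows],
            columns=["source", "interaction", "target"],
        ).to_csv(edges_path, sep="\t", index=False)
    nodes: dict[str, str] = {}
    for t in triads:
        nodes[t.lncrna] = "lncRNA"
        nodes[t.mirna] = "miRNA"
        nodes[t.mrna] = "mRNA"
    nodes_path = prefix.parent / (prefix.name + ".nodes.tsv")
    pd.DataFrame(sorted(nodes.items()), columns=["id", "kind"]).to_csv(
        nodes_path, sep="\t", index=False
    )
    return edges_path, nodes_path


def read_network(edges_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(edges_path, sep="\t")
    if not {"source", "interaction", "target"}.issubset(df.columns):
        raise ValidationError(f"{edges_path}: not an edge_tsv export")
    return df


def triads_from_edges(edges: pd.DataFrame, tissue: str = "") -> set[tuple[str, str, str]]:
    """Reconstitute (lncRNA, miRNA, mRNA) triples by joining the two edge
    types on the shared miRNA (the inverse of unfiltered triad assembly)."""
    lnc = edges[edges["interaction"] == "binds_lnc"]
    mrna = edges[edges["interaction"] == "targets_mrna"]
    out = set()
    for _, lr in lnc.iterrows():
        for _, gr in mrna[mrna["source"] == lr["source"]].iterrows():
            out.add((lr["target"], lr["source"], gr["target"]))
    return out


def triads_to_frame(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    rows = [
        {
            "lncrna": t.lncrna,
            "mirna": t.mirna,
            "mrna": t.mrna,
            "tissue": t.tissue,
            "lnc_mrna_r": f"{t.lnc_mrna_r:.6f}" if t.lnc_mrna_r is not None else "",
            "lnc_site_offset": t.lnc_site.offset,
            "lnc_site_mismatches": t.lnc_site.mismatches,
            "mrna_site_offset": t.mrna_site.offset,
            "mrna_site_mismatches": t.mrna_site.mismatches,
        }
        for t in triads
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "lncrna", "mirna", "mrna", "tissue", "lnc_mrna_r",
            "lnc_site_offset", "lnc_site_mismatches",
            "mrna_site_offset", "mrna_site_mismatches",
        ],
    )
    return df.sort_values(["tissue", "lncrna", "mirna", "mrna"]).reset_index(drop=True)
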
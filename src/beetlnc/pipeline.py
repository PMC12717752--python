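"""End-to-end run on a synthetic dataset: identify, test, link, network, qPCR.

``run_pipeline`` chains every stage under one seed and (optionally) writes
each stage's tables to an output directory with deterministic ordering, so
two runs of the same config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna, diffexp, enrichment, lncrna, qpcr, targets
from .core_io import ExpressionMatrix
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset, write_dataset


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    lnc_report: pd.DataFrame
    class_summary: pd.DataFrame
    de_lnc: dict[str, pd.DataFrame]
    de_mrna: dict[str, pd.DataFrame]
    de_mirna: dict[str, pd.DataFrame]
    pairs: list[targets.TargetPair]
    pair_stats: targets.PairStats
    enrichment_tables: dict[str, pd.DataFrame]
    triads: list[cerna.CeRNATriad]
    network: cerna.NetworkSummary
    qpcr_rel: pd.DataFrame
    qpcr_concordance: pd.DataFrame
    summary: dict[str, float]


def _called(df: pd.DataFrame) -> list[str]:
    return sorted(df.loc[df["call"] != "ns", "feature"])


def _combined_matrix(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(
        a.feature_ids + b.feature_ids,
        a.samples,
        np.vstack([a.counts, b.counts]),
    )


def run_pipeline(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> PipelineResult:
    config = config or SimulationConfig()
    ds = simulate_dataset(config)
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(ds, out / "inputs")

    # ---- identification --------------------------------------------------
    tx = sorted(ds.transcripts.values(), key=lambda t: t.id)
    report = lncrna.identify_lncrnas(tx, ds.annotation)
    retained = report[report["disposition"] == "retained"]
    summary_tbl = lncrna.class_summary(retained)

    # ---- differential expression ----------------------------------------
    de_lnc, de_mrna, de_mirna = {}, {}, {}
    retained_ids = [t for t in retained["transcript"] if t in ds.lnc_matrix.feature_ids]
    lnc_mat = ds.lnc_matrix.subset_features(sorted(retained_ids))
    for tissue in ("foliage", "root"):
        de_lnc[tissue] = diffexp.run_de(lnc_mat, tissue, "lncRNA")
        de_mrna[tissue] = diffexp.run_de(ds.mrna_matrix, tissue, "mRNA")
        de_mirna[tissue] = diffexp.run_de(ds.mirna_matrix, tissue, "miRNA")
    fpkm_lnc = diffexp.fpkm(lnc_mat)
    fpkm_mrna = diffexp.fpkm(ds.mrna_matrix)

    dels = {t: _called(de_lnc[t]) for t in de_lnc}
    degs = {t: _called(de_mrna[t]) for t in de_mrna}
    dems = {t: _called(de_mirna[t]) for t in de_mirna}
    del_union = sorted(set(dels["foliage"]) | set(dels["root"]))
    deg_union = sorted(set(degs["foliage"]) | set(degs["root"]))

    # ---- cis / trans targets --------------------------------------------
    # co-expression is computed on size-factor-normalised counts: trimmed
    # factors track library depth without letting the strongly expressed or
    # regulated minority of features distort the scale (as raw totals would)
    combined = _combined_matrix(lnc_mat, ds.mrna_matrix)
    sf_all = diffexp.size_factors(combined.counts)
    lnc_frame = lnc_mat.to_frame() / sf_all
    mrna_frame = ds.mrna_matrix.to_frame() / sf_all
    del_tx = [ds.transcripts[t] for t in del_union]
    cis = targets.cis_targets(
        del_tx, ds.annotation, lnc_expr=lnc_frame, gene_expr=mrna_frame
    )
    trans = targets.trans_targets(lnc_frame.loc[del_union], mrna_frame.loc[deg_union])
    pairs = cis + trans
    stats = targets.pair_stats(pairs) if pairs else targets.PairStats(
        0, 0, float("nan"), float("nan"), float("nan")
    )

    # ---- enrichment ------------------------------------------------------
    universe = set(ds.universe)
    cis_deg = sorted({p.gene for p in cis} & set(deg_union))
    trans_deg = sorted({p.gene for p in trans})
    enrich_tables = {}
    for mode, selected in (("cis", cis_deg), ("trans", trans_deg)):
        if selected:
            enrich_tables[mode] = enrichment.enrich(selected, ds.term_map, universe)
        else:
            enrich_tables[mode] = pd.DataFrame(
                columns=["term", "N", "K", "n", "k", "p", "gene_ratio", "q", "enriched"]
            )

    # ---- ceRNA network ---------------------------------------------------
    # same size-factor normalisation for the triad co-expression check
    combined.counts = combined.counts / sf_all
    triads: list[cerna.CeRNATriad] = []
    for tissue in ("foliage", "root"):
        lnc_pairs = cerna.pair_del_dem(dels[tissue], dems[tissue], ds.sequences)
        mrna_pairs = cerna.binding_pairs(dems[tissue], degs[tissue], ds.sequences)
        triads.extend(
            cerna.build_triads(lnc_pairs, mrna_pairs, combined, tissue)
        )
    net = cerna.network_summary(triads)

    # ---- qPCR ------------------------------------------------------------
    rel = qpcr.relative_expression_table(ds.ct_table)
    conc_frames = []
    for tissue in ("foliage", "root"):
        sub = rel[rel["gene"].map(lambda g: ds.qpcr_tissue.get(g) == tissue)]
        if len(sub):
            conc_frames.append(qpcr.concordance(sub, de_lnc[tissue]))
    conc = (
        pd.concat(conc_frames, ignore_index=True)
        if conc_frames
        else pd.DataFrame(columns=["gene", "rel_mean", "de_call", "flag"])
    )

    # ---- summary ---------------------------------------------------------
    frac = dict(zip(summary_tbl["clazz"], summary_tbl["fraction"]))
    mlen = dict(zip(summary_tbl["clazz"], summary_tbl["mean_length"]))
    comparable = conc[conc["flag"].isin(["agree", "disagree"])]
    summary = {
        "transcripts_screened": len(report),
        "candidate_lncrnas": len(retained),
        "pct_lincrna": 100.0 * frac.get("lincRNA", 0.0),
        "pct_intronic": 100.0 * frac.get("intronic", 0.0),
        "pct_antisense": 100.0 * frac.get("antisense", 0.0),
        "mean_len_lincrna": mlen.get("lincRNA", float("nan")),
        "mean_len_intronic": mlen.get("intronic", float("nan")),
        "mean_len_antisense": mlen.get("antisense", float("nan")),
        "dels_foliage": len(dels["foliage"]),
        "dels_root": len(dels["root"]),
        "degs_foliage": len(degs["foliage"]),
        "degs_root": len(degs["root"]),
        "n_cis_pairs": stats.n_cis,
        "n_trans_pairs": stats.n_trans,
        "trans_cis_ratio": stats.trans_cis_ratio,
        "pct_trans_negative": 100.0 * stats.fraction_trans_negative,
        "pct_cis_positive": 100.0 * stats.fraction_cis_positive,
        "enriched_terms_cis": int(enrich_tables["cis"]["enriched"].sum())
        if len(enrich_tables["cis"])
        else 0,
        "enriched_terms_trans": int(enrich_tables["trans"]["enriched"].sum())
        if len(enrich_tables["trans"])
        else 0,
        "triads_foliage": sum(t.tissue == "foliage" for t in triads),
        "triads_root": sum(t.tissue == "root" for t in triads),
        "mir_lnc_pairs_foliage": net.n_lnc_mir_pairs.get("foliage", 0),
        "mir_lnc_pairs_root": net.n_lnc_mir_pairs.get("root", 0),
        "mir_mrna_edges_foliage": net.n_mir_mrna_edges.get("foliage", 0),
        "mir_mrna_edges_root": net.n_mir_mrna_edges.get("root", 0),
        "hub_mirna_degree": net.hub_mirna_degree,
        "pct_qpcr_concordant": (
            100.0 * (comparable["flag"] == "agree").mean() if len(comparable) else float("nan")
        ),
    }

    # ---- deterministic output files -------------------------------------
    if out is not None:
        report.sort_values("transcript").to_csv(
            out / "lncrna_report.tsv", sep="\t", index=False
        )
        summary_tbl.to_csv(out / "class_summary.tsv", sep="\t", index=False)
        for tissue in ("foliage", "root"):
            de_lnc[tissue].sort_values("feature").to_csv(
                out / f"de_lncrna_{tissue}.tsv", sep="\t", index=False
            )
            de_mrna[tissue].sort_values("feature").to_csv(
                out / f"de_mrna_{tissue}.tsv", sep="\t", index=False
            )
            de_mirna[tissue].sort_values("feature").to_csv(
                out / f"de_mirna_{tissue}.tsv", sep="\t", index=False
            )
            tissue_triads = [t for t in triads if t.tissue == tissue]
            cerna.triads_to_frame(tissue_triads).to_csv(
                out / f"triads_{tissue}.tsv", sep="\t", index=False
            )
            cerna.export_network(tissue_triads, out / f"network_{tissue}", "edge_tsv")
        fpkm_lnc.round(4).to_csv(out / "fpkm_lncrna.tsv", sep="\t")
        fpkm_mrna.round(4).to_csv(out / "fpkm_mrna.tsv", sep="\t")
        targets.pairs_to_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
        for mode, tbl in enrich_tables.items():
            tbl.to_csv(out / f"enrichment_go_{mode}.tsv", sep="\t", index=False)
        rel.round(6).to_csv(out / "qpcr_relexpr.tsv", sep="\t", index=False)
        conc.round(6).to_csv(out / "qpcr_concordance.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(summary.items()), columns=["quantity", "value"]
        ).to_csv(out / "summary.tsv", sep="\t", index=False)

    return PipelineResult(
        dataset=ds,
        lnc_report=report,
        class_summary=summary_tbl,
        de_lnc=de_lnc,
        de_mrna=de_mrna,
        de_mirna=de_mirna,
        pairs=pairs,
        pair_stats=stats,
        enrichment_tables=enrich_tables,
        triads=triads,
        network=net,
        qpcr_rel=rel,
        qpcr_concordance=conc,
        summary=summary,
    )
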
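"""Generator contracts: determinism, planted geometry, count model, sites."""

import numpy as np
import pytest

from beetlnc import cerna, lncrna
from beetlnc.core_io import BeetlncError, ValidationError
from beetlnc.synthetic import (
    SimulationConfig,
    latent_sigma,
    sample_nb,
    simulate_dataset,
    simulate_genome,
)

from oracles import iv_overlap


class TestDeterminism:
    def test_same_seed_identical_dataset(self):
        cfg = SimulationConfig.small(seed=3)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.genome == b.genome
        assert np.array_equal(a.lnc_matrix.counts, b.lnc_matrix.counts)
        assert np.array_equal(a.mrna_matrix.counts, b.mrna_matrix.counts)
        assert a.mirnas == b.mirnas
        assert a.truth.sites.equals(b.truth.sites)
        assert a.ct_table.equals(b.ct_table)

    def test_different_seed_differs(self):
        a = simulate_dataset(SimulationConfig.small(seed=3))
        b = simulate_dataset(SimulationConfig.small(seed=4))
        assert a.genome != b.genome


class TestGenome:
    def test_zero_genes_is_valid(self):
        cfg = SimulationConfig.small()
        cfg.n_coding_genes = 0
        ann, genome, _ = simulate_genome(cfg)
        assert ann.genes == []
        assert set(genome) == {"chr1", "chr2"}

    def test_packing_error_states_required_minimum(self):
        cfg = SimulationConfig.small()
        cfg.chrom_length = 200_000
        cfg.n_coding_genes = 400
        with pytest.raises(BeetlncError, match="chrom_length >="):
            simulate_genome(cfg)

    def test_genes_have_multiple_exons_on_both_strands(self, small_ds):
        strands = {g.strand for g in small_ds.annotation.genes}
        assert strands == {"+", "-"}
        assert all(len(g.exons()) >= 2 for g in small_ds.annotation.genes)


class TestPlantedGeometry:
    def test_lincrnas_overlap_no_gene(self, small_ds):
        truth = small_ds.truth.classes
        for tid in truth.query("clazz == 'lincRNA'")["transcript"]:
            t = small_ds.transcripts[tid]
            for g in small_ds.annotation.genes:
                if g.chrom != t.chrom:
                    continue
                assert not iv_overlap((t.start, t.end), g.span), (tid, g.id)

    def test_intronic_contained_in_one_intron(self, small_ds):
        truth = small_ds.truth.classes
        for tid in truth.query("clazz == 'intronic'")["transcript"]:
            t = small_ds.transcripts[tid]
            containing = [
                (g.id, iv)
                for g in small_ds.annotation.genes
                if g.chrom == t.chrom
                for iv in g.introns()
                if iv[0] <= t.start and t.end <= iv[1]
            ]
            assert len(containing) == 1, tid

    def test_antisense_overlaps_opposite_strand_exon(self, small_ds):
        truth = small_ds.truth.classes
        for tid in truth.query("clazz == 'antisense'")["transcript"]:
            t = small_ds.transcripts[tid]
            hit = any(
                iv_overlap(te, ge)
                for g in small_ds.annotation.genes
                if g.chrom == t.chrom and g.strand != t.strand
                for te in t.exons
                for ge in g.exons()
            )
            assert hit, tid

    def test_rejects_built_to_fail_their_filter(self, small_ds):
        truth = small_ds.truth.classes
        for tid in truth.query("clazz == 'short_reject'")["transcript"]:
            t = small_ds.transcripts[tid]
            assert t.exon_count < 2 or t.length <= 200
        for tid in truth.query("clazz == 'coding_like_reject'")["transcript"]:
            orf = lncrna.longest_orf(small_ds.transcripts[tid].sequence)
            assert orf is not None and orf.length >= 300

    def test_planted_noncoding_have_no_long_orf(self, small_ds):
        truth = small_ds.truth.classes
        keep = truth["clazz"].isin(["lincRNA", "intronic", "antisense"])
        for tid in truth[keep]["transcript"]:
            orf = lncrna.longest_orf(small_ds.transcripts[tid].sequence)
            assert orf is None or orf.length < 300

    def test_sequences_match_genome_splice(self, small_ds):
        from beetlnc.synthetic import _str_to_arr, read_spliced

        for t in list(small_ds.transcripts.values())[:20]:
            arr = _str_to_arr(small_ds.genome[t.chrom])
            assert read_spliced(arr, t.exons, t.strand) == t.sequence


class TestCountModel:
    def test_planted_log2fc_recovered_in_expectation(self):
        """Monte-Carlo check of the DE planting: empirical log2 mean ratio
        within +-0.5 of the planted value over repeated 3v3 draws."""
        rng = np.random.default_rng(9)
        ratios = []
        for _ in range(200):
            cv = sample_nb(rng, np.full(3, 100.0), 0.05)
            ln = sample_nb(rng, np.full(3, 400.0), 0.05)
            ratios.append(np.log2((ln.mean() + 0.5) / (cv.mean() + 0.5)))
        assert abs(np.mean(ratios) - 2.0) < 0.5

    def test_zero_dispersion_is_poisson(self):
        rng = np.random.default_rng(10)
        x = sample_nb(rng, np.full(20000, 50.0), 0.0)
        assert x.var() == pytest.approx(x.mean(), rel=0.05)

    def test_latent_pairs_reach_target_correlation(self):
        rng = np.random.default_rng(11)
        sigma = latent_sigma(0.99, 5000.0, 0.001)
        rs = []
        for _ in range(30):
            lat = np.exp(sigma * rng.standard_normal(12) - 0.5 * sigma**2)
            x = sample_nb(rng, 5000.0 * lat, 0.001)
            y = sample_nb(rng, 5000.0 * lat, 0.001)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) > 0.95

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValidationError):
            latent_sigma(1.0, 100.0, 0.1)
        with pytest.raises(ValidationError):
            latent_sigma(0.99, 100.0, 0.1)  # above the 1/(1+phi) ceiling


class TestPlantedSites:
    def test_zero_mismatch_site_found_at_planted_offset(self, small_ds):
        truth = small_ds.truth.sites
        clean = truth[(truth["mismatches"] == 0) & (truth["gu_pairs"] == 0)]
        for _, row in clean.iterrows():
            sites = cerna.scan_binding_sites(
                small_ds.mirnas[row["mirna"]], small_ds.sequences[row["target"]]
            )
            assert any(
                s.offset == row["offset"] and s.mismatches == 0 for s in sites
            ), row["target"]

    def test_forced_gu_site_rejected_without_wobble(self, small_ds):
        truth = small_ds.truth.sites
        gu_rows = truth[truth["gu_pairs"] > 0]
        assert len(gu_rows) > 0
        for _, row in gu_rows.iterrows():
            strict = cerna.scan_binding_sites(
                small_ds.mirnas[row["mirna"]],
                small_ds.sequences[row["target"]],
                allow_gu=False,
            )
            assert all(s.offset != row["offset"] for s in strict)
            relaxed = cerna.scan_binding_sites(
                small_ds.mirnas[row["mirna"]],
                small_ds.sequences[row["target"]],
                allow_gu=True,
            )
            assert any(s.offset == row["offset"] for s in relaxed)

    def test_four_mismatch_site_not_accepted(self, small_ds):
        truth = small_ds.truth.sites
        rows = truth[truth["mismatches"] == 4]
        assert len(rows) > 0
        for _, row in rows.iterrows():
            sites = cerna.scan_binding_sites(
                small_ds.mirnas[row["mirna"]], small_ds.sequences[row["target"]]
            )
            assert sites == []


class TestTruthConsistency:
    def test_every_truth_id_exists_in_outputs(self, small_ds):
        tx_ids = set(small_ds.transcripts)
        feat_ids = (
            set(small_ds.lnc_matrix.feature_ids)
            | set(small_ds.mrna_matrix.feature_ids)
            | set(small_ds.mirna_matrix.feature_ids)
        )
        assert set(small_ds.truth.classes["transcript"]) <= tx_ids
        assert set(small_ds.truth.de["feature"]) <= feat_ids
        assert set(small_ds.truth.sites["mirna"]) <= set(small_ds.mirnas)
        assert set(small_ds.truth.sites["target"]) <= set(small_ds.sequences)
        assert set(small_ds.truth.triads["lncrna"]) <= tx_ids

    def test_each_transcript_in_exactly_one_class(self, small_ds):
        truth = small_ds.truth.classes
        assert truth["transcript"].is_unique
        assert set(truth["transcript"]) == set(small_ds.transcripts)
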
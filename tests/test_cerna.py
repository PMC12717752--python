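"""Binding-site scanner, pair assembly, triads, network export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beetlnc import cerna
from beetlnc.core_io import ExpressionMatrix, ValidationError, reverse_complement
from beetlnc.synthetic import make_samples, random_seq

from oracles import brute_scan

RNG = np.random.default_rng(101)


class TestScanner:
    def test_perfect_complement_found_at_planted_offset(self):
        mir = random_seq(np.random.default_rng(1), 21)
        target = random_seq(np.random.default_rng(2), 40) + reverse_complement(mir)
        sites = cerna.scan_binding_sites(mir, target + random_seq(np.random.default_rng(3), 30))
        exact = [s for s in sites if s.offset == 40]
        assert exact and exact[0].mismatches == 0 and exact[0].gu_pairs == 0

    def test_three_substitutions_accepted_four_rejected(self):
        mir = random_seq(np.random.default_rng(4), 21)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        wob = {"G": "T", "T": "G"}

        def substituted(n):
            window = list(reverse_complement(mir))
            for j in range(n):
                q = mir[20 - j]  # miRNA base pairing window position j
                window[j] = next(
                    b for b in "ACGT" if b != comp[q] and b != wob.get(q)
                )
            return "".join(window)

        got3 = cerna.scan_binding_sites(mir, substituted(3))
        assert len(got3) == 1 and got3[0].mismatches == 3 and got3[0].gu_pairs == 0
        assert cerna.scan_binding_sites(mir, substituted(4)) == []

    def test_single_gu_wobble_disqualifies(self):
        rng = np.random.default_rng(5)
        mir = random_seq(rng, 21)
        window = list(reverse_complement(mir))
        j = next(j for j in range(21) if mir[20 - j] in "GT")
        window[j] = {"G": "T", "T": "G"}[mir[20 - j]]
        target = "".join(window)
        assert cerna.scan_binding_sites(mir, target, allow_gu=False) == []
        allowed = cerna.scan_binding_sites(mir, target, allow_gu=True)
        assert len(allowed) == 1 and allowed[0].gu_pairs == 1 and allowed[0].mismatches == 0

    def test_matches_brute_force_over_settings(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            L = int(rng.integers(18, 31))
            mir = random_seq(rng, L)
            target = random_seq(rng, int(rng.integers(L, 90)))
            for mm in range(5):
                for gu in (False, True):
                    got = [
                        (s.offset, s.mismatches, s.gu_pairs)
                        for s in cerna.scan_binding_sites(mir, target, mm, gu)
                    ]
                    assert got == brute_scan(mir, target, mm, gu)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_scanner_equals_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        mir = random_seq(rng, 20)
        target = random_seq(rng, 55)
        got = [
            (s.offset, s.mismatches, s.gu_pairs)
            for s in cerna.scan_binding_sites(mir, target, 4, True)
        ]
        assert got == brute_scan(mir, target, 4, True)

    def test_mirna_longer_than_target_rejected(self):
        with pytest.raises(ValidationError):
            cerna.scan_binding_sites("ACGT" * 5, "ACGT")

    def test_bad_mirna_length_rejected(self):
        with pytest.raises(ValidationError):
            cerna.scan_binding_sites("ACGT", "ACGT" * 20)


class TestPairs:
    def test_empty_dem_set_gives_no_pairs(self):
        assert cerna.pair_del_dem(["l1"], [], {"l1": "A" * 100}) == {}

    def test_best_site_fewest_mismatches_earliest_offset(self):
        rng = np.random.default_rng(7)
        mir = random_seq(rng, 21)
        perfect = reverse_complement(mir)
        one_mm = list(perfect)
        q = mir[20]
        one_mm[0] = next(
            b for b in "ACGT"
            if b != {"A": "T", "C": "G", "G": "C", "T": "A"}[q]
            and b != {"G": "T", "T": "G"}.get(q)
        )
        target = "".join(one_mm) + random_seq(rng, 30) + perfect + random_seq(rng, 10)
        pairs = cerna.binding_pairs(["m"], ["t"], {"m": mir, "t": target})
        assert pairs[("m", "t")].mismatches == 0
        assert pairs[("m", "t")].offset == 51

    def test_missing_sequence_names_feature(self):
        with pytest.raises(ValidationError, match="lncX"):
            cerna.pair_del_dem(["lncX"], ["m"], {"m": "A" * 21})


def _expr_matrix(values: dict[str, np.ndarray]) -> ExpressionMatrix:
    ids = list(values)
    return ExpressionMatrix(ids, make_samples(), np.vstack([values[i] for i in ids]))


class TestTriads:
    def _pairs(self, mir, lnc, mrna):
        site = cerna.BindingSite(mir, lnc, 0, 0, 0)
        gsite = cerna.BindingSite(mir, mrna, 0, 1, 0)
        return {(mir, lnc): site}, {(mir, mrna): gsite}

    def test_no_shared_mirna_no_triads(self):
        lp, _ = self._pairs("m1", "l1", "g1")
        _, gp = self._pairs("m2", "l1", "g1")
        expr = _expr_matrix({"l1": np.arange(12), "g1": np.arange(12)})
        assert cerna.build_triads(lp, gp, expr, "root") == []

    def test_positive_consistency_filters_anticorrelated(self):
        lp, gp = self._pairs("m1", "l1", "g1")
        up = np.arange(1.0, 13.0)
        expr_pos = _expr_matrix({"l1": up, "g1": up * 2})
        expr_neg = _expr_matrix({"l1": up, "g1": up[::-1]})
        assert len(cerna.build_triads(lp, gp, expr_pos, "root")) == 1
        assert cerna.build_triads(lp, gp, expr_neg, "root") == []
        # consistency="none" disables the expression filter
        assert len(cerna.build_triads(lp, gp, expr_neg, "root", consistency="none")) == 1

    def test_unknown_tissue_rejected(self):
        lp, gp = self._pairs("m1", "l1", "g1")
        expr = _expr_matrix({"l1": np.arange(12), "g1": np.arange(12)})
        with pytest.raises(ValidationError):
            cerna.build_triads(lp, gp, expr, "stem")

    def test_ablating_the_mrna_site_removes_the_triad(self, small_ds):
        """Perturbation check: removing a planted site breaks its triads."""
        truth = small_ds.truth
        row = truth.sites.query("target_kind == 'mRNA' and mismatches == 0").iloc[0]
        mir, gid, tissue = row["mirna"], row["target"], row["tissue"]
        de = truth.de[truth.de["tissue"] == tissue]
        dels = sorted(de.query("kind == 'lncRNA'")["feature"])
        dems = sorted(de.query("kind == 'miRNA'")["feature"])
        degs = sorted(de.query("kind == 'mRNA'")["feature"])
        seqs = dict(small_ds.sequences)
        expr = ExpressionMatrix(
            small_ds.lnc_matrix.feature_ids + small_ds.mrna_matrix.feature_ids,
            small_ds.lnc_matrix.samples,
            np.vstack([small_ds.lnc_matrix.counts, small_ds.mrna_matrix.counts]),
        )

        def run():
            lp = cerna.pair_del_dem(dels, dems, seqs)
            gp = cerna.binding_pairs(dems, degs, seqs)
            return {(t.lncrna, t.mirna, t.mrna) for t in cerna.build_triads(lp, gp, expr, tissue)}

        before = run()
        assert any(t[1] == mir and t[2] == gid for t in before)
        off, L = int(row["offset"]), len(small_ds.mirnas[mir])
        rng = np.random.default_rng(0)
        while True:  # scramble the site region
            repl = random_seq(rng, L)
            seqs[gid] = seqs[gid][:off] + repl + seqs[gid][off + L:]
            if not cerna.scan_binding_sites(small_ds.sequences[mir], seqs[gid]):
                break
        after = run()
        assert not any(t[1] == mir and t[2] == gid for t in after)
        assert after <= before


class TestNetwork:
    def _triads(self):
        mk = lambda l, m, g: cerna.CeRNATriad(
            l, m, g, "root", 0.9,
            cerna.BindingSite(m, l, 0, 0, 0), cerna.BindingSite(m, g, 0, 0, 0),
        )
        return [mk("l1", "m1", "g1"), mk("l1", "m2", "g2"), mk("l1", "m3", "g2")]

    def test_single_triad_degrees(self):
        t = self._triads()[:1]
        net = cerna.network_summary(t)
        assert net.degrees == {"m1": 2, "l1": 1, "g1": 1}

    def test_hub_is_lncrna_with_most_mirnas(self):
        net = cerna.network_summary(self._triads())
        assert net.hubs == ["l1"] and net.hub_mirna_degree == 3

    def test_empty_network_zero_filled(self):
        net = cerna.network_summary([])
        assert net.degrees == {} and net.hubs == [] and net.hub_mirna_degree == 0

    def test_degrees_match_recount_from_export(self, tmp_path):
        triads = self._triads()
        edges_path, nodes_path = cerna.export_network(triads, tmp_path / "net")
        edges = cerna.read_network(edges_path)
        recount: dict[str, int] = {}
        for _, e in edges.iterrows():
            recount[e["source"]] = recount.get(e["source"], 0) + 1
            recount[e["target"]] = recount.get(e["target"], 0) + 1
        assert recount == cerna.network_summary(triads).degrees

    def test_edge_roundtrip_reproduces_triads(self, tmp_path):
        triads = self._triads()
        edges_path, _ = cerna.export_network(triads, tmp_path / "net")
        got = cerna.triads_from_edges(cerna.read_network(edges_path))
        assert got == {(t.lncrna, t.mirna, t.mrna) for t in triads}

    def test_export_counts(self, tmp_path):
        triads = self._triads()[:1]
        edges_path, nodes_path = cerna.export_network(triads, tmp_path / "one")
        assert len(cerna.read_network(edges_path)) == 2
        assert len(pd.read_csv(nodes_path, sep="\t")) == 3

    def test_empty_export_header_only(self, tmp_path):
        edges_path, nodes_path = cerna.export_network([], tmp_path / "empty")
        assert len(cerna.read_network(edges_path)) == 0
        assert len(pd.read_csv(nodes_path, sep="\t")) == 0
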
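"""Identification filters, ORF/Fickett predicates, classification."""

import numpy as np
import pandas as pd
import pytest

from beetlnc import lncrna
from beetlnc.core_io import TranscriptModel, ValidationError
from beetlnc.synthetic import coding_seq, random_seq

from conftest import random_transcripts
from oracles import brute_classify, brute_filter, brute_longest_orf, fickett_reference


def _tx(tid, exons, strand="+", chrom="chr1", seq=None):
    return TranscriptModel(tid, chrom, strand, exons, seq)


class TestStructureFilters:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(20000, 20500)], "reject_exon"),                 # 1 exon, 500 nt
            ([(20000, 20100), (20400, 20500)], "reject_length"),  # 200 nt exactly
            ([(20000, 20101), (20400, 20500)], "retained"),    # 201 nt boundary
        ],
    )
    def test_exon_and_length_filters(self, toy_annotation, exons, expected):
        rep = lncrna.filter_structure([_tx("t", exons)], toy_annotation)
        assert rep.dispositions["t"] == expected

    def test_single_bp_same_strand_exon_overlap_rejected(self, toy_annotation):
        # gene_plus exon ends at 1500; transcript exon [1499, 1700) shares 1 bp
        t = _tx("t", [(1499, 1700), (1900, 2100)], strand="+")
        rep = lncrna.filter_structure([t], toy_annotation)
        assert rep.dispositions["t"] == "reject_exon_overlap"
        # the same interval on the minus strand survives (strand-aware filter)
        t2 = _tx("t2", [(1499, 1700), (1900, 2100)], strand="-")
        rep2 = lncrna.filter_structure([t2], toy_annotation)
        assert rep2.dispositions["t2"] == "retained"

    def test_unknown_chromosome_raises(self, toy_annotation):
        with pytest.raises(ValidationError, match="unknown chromosome"):
            lncrna.filter_structure([_tx("t", [(0, 300), (400, 700)], chrom="chrX")],
                                    toy_annotation)

    def test_matches_brute_force_and_order_independent(self, toy_annotation):
        rng = np.random.default_rng(11)
        txs = random_transcripts(toy_annotation, 150, rng)
        rep = lncrna.filter_structure(txs, toy_annotation)
        for t in txs:
            assert rep.dispositions[t.id] == brute_filter(t, toy_annotation)
        perm = [txs[i] for i in rng.permutation(len(txs))]
        assert lncrna.filter_structure(perm, toy_annotation).dispositions == rep.dispositions


class TestLongestOrf:
    def test_single_complete_orf(self):
        r = lncrna.longest_orf("ATGAAATAG")
        assert (r.start, r.length, r.frame) == (0, 9, 0)

    def test_no_atg_gives_none(self):
        assert lncrna.longest_orf("CCCCCC") is None

    def test_open_reading_without_stop_does_not_count(self):
        assert lncrna.longest_orf("ATGAAAAAA") is None

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            seq = random_seq(rng, int(rng.integers(30, 900)))
            got = lncrna.longest_orf(seq)
            want = brute_longest_orf(seq)
            if want is None:
                assert got is None
            else:
                assert (got.start, got.length, got.frame) == want

    def test_bad_alphabet_raises(self):
        with pytest.raises(ValidationError):
            lncrna.longest_orf("ATGXXXTAG")


class TestFickett:
    def test_deterministic(self):
        seq = random_seq(np.random.default_rng(3), 400)
        assert lncrna.fickett_score(seq) == lncrna.fickett_score(seq)

    def test_matches_table_reference_implementation(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            seq = random_seq(rng, int(rng.integers(200, 800)))
            assert lncrna.fickett_score(seq) == pytest.approx(fickett_reference(seq), abs=1e-12)

    def test_shuffling_a_coding_sequence_lowers_the_mean_score(self):
        rng = np.random.default_rng(23)
        coding = coding_seq(rng, 402, 396, 3)
        original = lncrna.fickett_score(coding)
        shuffled = []
        arr = list(coding)
        for _ in range(100):
            rng.shuffle(arr)
            shuffled.append(lncrna.fickett_score("".join(arr)))
        assert np.mean(shuffled) < original

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            lncrna.fickett_score("ATG" * 30)


class TestConsensusGate:
    def test_long_orf_vetoes_consensus(self):
        rng = np.random.default_rng(29)
        seq = coding_seq(rng, 900, 600, 100)
        call = lncrna.consensus_noncoding(seq)
        assert not call.predicate_orf_len
        assert not call.consensus_noncoding

    def test_planted_lincrnas_pass_the_gate(self, small_ds):
        lincs = small_ds.truth.classes.query("clazz == 'lincRNA'")["transcript"]
        for tid in lincs:
            seq = small_ds.transcripts[tid].sequence
            assert lncrna.consensus_noncoding(seq).consensus_noncoding

    def test_consensus_equals_predicate_set_intersection(self, small_ds):
        """Venn accounting: |consensus| == |A ∩ B ∩ C| computed from the
        three per-predicate sets; dropping any predicate only grows the set."""
        seqs = {
            t.id: t.sequence
            for t in small_ds.transcripts.values()
            if len(t.sequence) >= 200
        }
        A, B, C = set(), set(), set()
        for tid, seq in seqs.items():
            call = lncrna.consensus_noncoding(seq)
            if call.predicate_orf_len:
                A.add(tid)
            if call.predicate_orf_coverage:
                B.add(tid)
            if call.predicate_fickett:
                C.add(tid)
        consensus = {
            tid for tid, seq in seqs.items()
            if lncrna.consensus_noncoding(seq).consensus_noncoding
        }
        assert consensus == A & B & C
        for drop in (A, B, C):
            kept_without = set.intersection(*(s for s in (A, B, C) if s is not drop))
            assert consensus <= kept_without


class TestExcludeKnown:
    def test_exact_copy_rejected(self):
        known = {"k1": "ACGTACGTGG" * 10}
        cand = {"c1": known["k1"]}
        assert lncrna.exclude_known(cand, known)["c1"] == "reject_known"

    def test_unrelated_candidate_retained(self):
        rng = np.random.default_rng(31)
        known = {"k1": random_seq(rng, 600)}
        cand = {"c1": random_seq(rng, 500)}
        assert lncrna.exclude_known(cand, known)["c1"] == "retained"

    def test_half_chimera_matches_direct_kmer_fraction(self):
        rng = np.random.default_rng(37)
        known_seq = random_seq(rng, 400)
        cand = {"c1": known_seq[:200] + random_seq(rng, 200)}
        k = 25
        index = set()
        for s in (known_seq,):
            from beetlnc.core_io import reverse_complement
            for x in (s, reverse_complement(s)):
                index.update(x[i : i + k] for i in range(len(x) - k + 1))
        kmers = [cand["c1"][i : i + k] for i in range(len(cand["c1"]) - k + 1)]
        frac = sum(km in index for km in kmers) / len(kmers)
        expected = "reject_known" if frac >= 0.5 else "retained"
        assert lncrna.exclude_known(cand, {"k1": known_seq})["c1"] == expected

    def test_k_longer_than_candidate_raises(self):
        with pytest.raises(ValidationError):
            lncrna.exclude_known({"c": "ACGT"}, {"k": "ACGT" * 20}, k=25)


class TestClassification:
    def test_distant_transcript_is_lincrna(self, toy_annotation):
        t = _tx("t", [(30000, 30300), (30500, 30800)])
        assert lncrna.classify_lncrna(t, toy_annotation) == "lincRNA"

    def test_intron_contained_same_strand_is_intronic(self, toy_annotation):
        t = _tx("t", [(1600, 1800), (2000, 2200)], strand="+")
        assert lncrna.classify_lncrna(t, toy_annotation) == "intronic"
        assert brute_classify(t, toy_annotation) == "intronic"

    def test_opposite_strand_exon_overlap_is_antisense(self, toy_annotation):
        t = _tx("t", [(10350, 10600), (10800, 11000)], strand="+")  # gene_minus exon
        assert lncrna.classify_lncrna(t, toy_annotation) == "antisense"
        assert brute_classify(t, toy_annotation) == "antisense"

    def test_agrees_with_brute_force_on_random_transcripts(self, toy_annotation):
        rng = np.random.default_rng(41)
        for t in random_transcripts(toy_annotation, 200, rng):
            assert lncrna.classify_lncrna(t, toy_annotation) == brute_classify(t, toy_annotation)


class TestClassSummary:
    def test_single_member(self):
        df = pd.DataFrame(
            [{"clazz": "lincRNA", "length": 500, "exon_count": 2, "orf_len": 60}]
        )
        out = lncrna.class_summary(df)
        assert out.loc[0, "count"] == 1
        assert out.loc[0, "fraction"] == 1.0
        assert out.loc[0, "mean_length"] == 500.0

    def test_fractions(self):
        rows = [{"clazz": "lincRNA", "length": 400, "exon_count": 2, "orf_len": 0}] * 3
        rows += [{"clazz": "antisense", "length": 800, "exon_count": 3, "orf_len": 120}]
        out = lncrna.class_summary(pd.DataFrame(rows)).set_index("clazz")
        assert out.loc["lincRNA", "fraction"] == 0.75
        assert out.loc["antisense", "fraction"] == 0.25

    def test_empty_set_raises(self):
        with pytest.raises(ValidationError):
            lncrna.class_summary(pd.DataFrame(columns=["clazz", "length", "exon_count", "orf_len"]))

    def test_counts_match_planted_truth(self, small_ds):
        from beetlnc.lncrna import identify_lncrnas

        report = identify_lncrnas(
            sorted(small_ds.transcripts.values(), key=lambda t: t.id), small_ds.annotation
        )
        got = (
            report[report["disposition"] == "retained"]["clazz"].value_counts().to_dict()
        )
        truth = small_ds.truth.classes
        want = {
            c: int((truth["clazz"] == c).sum())
            for c in ("lincRNA", "intronic", "antisense")
        }
        assert got == want
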
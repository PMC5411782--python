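"""Confidence tiers, annotation overlap, splicing events and NMD flags."""

import itertools

import pytest

from polyqc.genes import (
    Evidence,
    assign_confidence,
    classify_as_events,
    compare_annotations,
    flag_nmd,
    transfer_filter,
)
from polyqc.models import GeneModel, Transcript


def _tx(tid, exons, strand="+", cds=(), rep=False, gene="g1", chrom="1A"):
    return Transcript(
        id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=tuple(cds), is_representative=rep,
    )


def _gene(gid, transcripts, chrom="1A", strand="+"):
    g = GeneModel(id=gid, chrom=chrom, strand=strand)
    for t in transcripts:
        g.add(t)
    return g


class TestConfidence:
    def test_full_support_is_hc_p1_t1(self):
        conf = assign_confidence(
            Evidence(0.85, pacbio_full=True, has_wheat_transcript_support=True)
        )
        assert (conf.tier, conf.protein_rank, conf.transcript_rank) == ("HC", "P1", "T1")

    def test_short_protein_without_support_is_lc(self):
        conf = assign_confidence(Evidence(0.55))
        assert conf.tier == "LC"
        assert conf.lc_reason == "short-protein"
        assert conf.lc_reasons == ("short-protein", "no-transcript")

    def test_mid_coverage_rnaseq_support_is_hc_t2(self):
        conf = assign_confidence(Evidence(0.70, rnaseq_full=True))
        assert (conf.tier, conf.protein_rank, conf.transcript_rank) == ("HC", None, "T2")

    def test_repeat_association_forces_lc(self):
        conf = assign_confidence(
            Evidence(0.9, pacbio_full=True, repeat_associated=True, has_wheat_transcript_support=True)
        )
        assert conf.tier == "LC"
        assert conf.lc_reasons == ("repeat",)

    def test_rule_table_exhaustive(self):
        # enumerate flag combinations x coverage strata against first-principles rules
        for cov in (0.0, 0.55, 0.60, 0.75, 0.80, 0.95):
            for pacbio, rnaseq, repeat, support in itertools.product([False, True], repeat=4):
                ev = Evidence(cov, pacbio, rnaseq, repeat, support)
                conf = assign_confidence(ev)
                any_support = support or pacbio or rnaseq
                expect_lc = cov < 0.60 or not any_support or repeat
                assert (conf.tier == "LC") == expect_lc
                if conf.tier == "HC":
                    assert (conf.protein_rank == "P1") == (cov >= 0.80)
                    if pacbio:
                        assert conf.transcript_rank == "T1"
                    elif rnaseq:
                        assert conf.transcript_rank == "T2"
                    assert conf.lc_reasons == ()

    def test_coverage_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Evidence(1.2)

    def test_boundary_coverages(self):
        assert assign_confidence(Evidence(0.60, rnaseq_full=True)).tier == "HC"
        assert assign_confidence(Evidence(0.80, rnaseq_full=True)).protein_rank == "P1"
        lc = assign_confidence(Evidence(0.5999, rnaseq_full=True))
        assert lc.tier == "LC" and lc.lc_reasons == ("short-protein",)


class TestTransferFilter:
    def test_inclusive_boundary_kept(self):
        assert transfer_filter([{"coverage": 0.90, "identity": 0.95}])

    def test_below_coverage_dropped(self):
        assert transfer_filter([{"coverage": 0.89, "identity": 0.99}]) == []

    def test_toy_set(self):
        recs = [
            {"id": i, "coverage": c, "identity": d}
            for i, (c, d) in enumerate(
                [(0.95, 0.99), (0.91, 0.95), (0.90, 0.94), (0.50, 0.99),
                 (0.99, 0.80), (0.90, 0.95), (1.0, 1.0), (0.89, 0.95),
                 (0.93, 0.96), (0.1, 0.1)]
            )
        ]
        kept = transfer_filter(recs)
        assert [r["id"] for r in kept] == [0, 1, 5, 6, 8]


class TestCompareAnnotations:
    E3 = [(101, 200), (301, 400), (501, 600)]

    def test_identical_copy(self):
        ref = {"r1": _gene("r1", [_tx("r1.1", self.E3, gene="r1")])}
        qry = {"q1": _gene("q1", [_tx("q1.1", self.E3, gene="q1")])}
        cats, summary, fused = compare_annotations(ref, qry)
        assert cats == {"r1": "identical"}
        assert summary["fractions"]["identical"] == 1.0
        assert not fused

    def test_truncated_reference_contained(self):
        # reference missing the first exon but sharing all internal introns
        ref = {"r1": _gene("r1", [_tx("r1.1", self.E3[1:], gene="r1")])}
        qry = {"q1": _gene("q1", [_tx("q1.1", self.E3, gene="q1")])}
        cats, _, _ = compare_annotations(ref, qry)
        assert cats == {"r1": "contained"}

    def test_different_intron_boundaries_structurally_different(self):
        ref = {"r1": _gene("r1", [_tx("r1.1", [(101, 200), (311, 400), (501, 600)], gene="r1")])}
        qry = {"q1": _gene("q1", [_tx("q1.1", self.E3, gene="q1")])}
        cats, _, _ = compare_annotations(ref, qry)
        assert cats == {"r1": "structurally_different"}

    def test_antisense_overlap_is_missing(self):
        ref = {"r1": _gene("r1", [_tx("r1.1", self.E3, gene="r1")], strand="+")}
        qry = {"q1": _gene("q1", [_tx("q1.1", self.E3, strand="-", gene="q1")], strand="-")}
        cats, _, _ = compare_annotations(ref, qry)
        assert cats == {"r1": "missing"}

    def test_no_overlap_missing(self):
        ref = {"r1": _gene("r1", [_tx("r1.1", self.E3, gene="r1")])}
        qry = {"q1": _gene("q1", [_tx("q1.1", [(10_000, 10_500)], gene="q1")])}
        cats, _, _ = compare_annotations(ref, qry)
        assert cats == {"r1": "missing"}

    def test_fusion_flagged(self):
        ref = {
            "r1": _gene("r1", [_tx("r1.1", [(101, 200)], gene="r1")]),
            "r2": _gene("r2", [_tx("r2.1", [(501, 600)], gene="r2")]),
        }
        qry = {"q1": _gene("q1", [_tx("q1.1", [(50, 700)], gene="q1")])}
        _, summary, fused = compare_annotations(ref, qry)
        assert fused == {"q1"}
        assert summary["n_fused_query_genes"] == 1

    def test_categories_mutually_exclusive_and_exhaustive(self):
        ref = {
            "r1": _gene("r1", [_tx("r1.1", self.E3, gene="r1")]),
            "r2": _gene("r2", [_tx("r2.1", self.E3[1:], gene="r2")]),
            "r3": _gene("r3", [_tx("r3.1", [(101, 250), (301, 400)], gene="r3")]),
            "r4": _gene("r4", [_tx("r4.1", [(9000, 9100)], gene="r4")]),
        }
        qry = {"q1": _gene("q1", [_tx("q1.1", self.E3, gene="q1")])}
        cats, summary, _ = compare_annotations(ref, qry)
        assert set(cats) == set(ref)
        assert sum(summary["fractions"].values()) == pytest.approx(1.0)


class TestSplicingEvents:
    REP = [(101, 200), (301, 400), (501, 600), (701, 800)]

    def _pair(self, alt_exons, strand="+"):
        rep = _tx("g1.1", self.REP, strand=strand, rep=True)
        alt = _tx("g1.2", alt_exons, strand=strand)
        return [rep, alt]

    def _events(self, alt_exons, strand="+"):
        return [e for _, _, e in classify_as_events(self._pair(alt_exons, strand))]

    def test_intron_retention(self):
        assert self._events([(101, 400), (501, 600), (701, 800)]) == ["IR"]

    def test_exon_skipping(self):
        assert self._events([(101, 200), (501, 600), (701, 800)]) == ["ES"]

    def test_a5ss_plus_strand(self):
        # donor of the first intron shifted right on '+': alternative 5' site
        assert self._events([(101, 212), (301, 400), (501, 600), (701, 800)]) == ["A5SS"]

    def test_a3ss_plus_strand(self):
        assert self._events([(101, 200), (289, 400), (501, 600), (701, 800)]) == ["A3SS"]

    def test_a5ss_minus_strand_is_genomic_right_shift(self):
        # same genomic change as +A3SS, but in mRNA orientation on '-' the
        # shifted boundary is the donor
        assert self._events([(101, 200), (289, 400), (501, 600), (701, 800)], strand="-") == ["A5SS"]

    def test_a3ss_minus_strand(self):
        assert self._events([(101, 212), (301, 400), (501, 600), (701, 800)], strand="-") == ["A3SS"]

    def test_mutually_exclusive_exons(self):
        rep = _tx("g1.1", [(101, 200), (301, 400), (701, 800)], rep=True)
        alt = _tx("g1.2", [(101, 200), (501, 600), (701, 800)])
        events = [e for _, _, e in classify_as_events([rep, alt])]
        assert events == ["MXE"]

    def test_identity_yields_no_events(self):
        rep = _tx("g1.1", self.REP, rep=True)
        same = _tx("g1.2", self.REP)
        assert classify_as_events([rep, same]) == []

    def test_single_transcript_yields_no_events(self):
        assert classify_as_events([_tx("g1.1", self.REP, rep=True)]) == []

    def test_translation_invariance(self):
        shift = 10_000
        for alt in ([(101, 400), (501, 600), (701, 800)], [(101, 200), (501, 600), (701, 800)]):
            base = self._events(alt)
            rep = _tx("g1.1", [(s + shift, e + shift) for s, e in self.REP], rep=True)
            moved = _tx("g1.2", [(s + shift, e + shift) for s, e in alt])
            assert [e for _, _, e in classify_as_events([rep, moved])] == base

    def test_strand_flip_with_mirrored_coordinates(self):
        # mirroring genomic coordinates and flipping strand preserves events
        L = 10_001
        mirror = lambda exons: tuple(sorted((L - e, L - s) for s, e in exons))
        for alt, expected in (
            ([(101, 400), (501, 600), (701, 800)], ["IR"]),
            ([(101, 212), (301, 400), (501, 600), (701, 800)], ["A5SS"]),
        ):
            rep = _tx("g1.1", mirror(self.REP), strand="-", rep=True)
            m_alt = _tx("g1.2", mirror(alt), strand="-")
            assert [e for _, _, e in classify_as_events([rep, m_alt])] == expected


class TestNMD:
    def _tx_with_stop(self, stop_offset_from_last_junction):
        # two exons of 300 nt each; junction at mRNA position 300
        exons = [(1, 300), (401, 700)]
        junction = 300
        stop_mrna = junction - stop_offset_from_last_junction
        # CDS from position 1 to stop_mrna (all within exon 1)
        return _tx("g1.1", exons, cds=[(1, stop_mrna)])

    def test_stop_in_last_exon_not_flagged(self):
        t = _tx("g1.1", [(1, 300), (401, 700)], cds=[(1, 300), (401, 550)])
        assert flag_nmd(t) is False

    def test_boundary_51_flagged_50_not(self):
        assert flag_nmd(self._tx_with_stop(51)) is True
        assert flag_nmd(self._tx_with_stop(50)) is False

    def test_monoexonic_never_flagged(self):
        t = _tx("g1.1", [(1, 900)], cds=[(1, 300)])
        assert flag_nmd(t) is False

    def test_no_cds_not_evaluable(self):
        t = _tx("g1.1", [(1, 300), (401, 700)])
        assert flag_nmd(t) is False

    def test_minus_strand_mrna_coordinates(self):
        # on '-', the mRNA starts at the genomic right; stop = CDS genomic start
        exons = [(1, 300), (401, 700)]
        # mRNA: exon (401,700) first. Put stop 100 nt before the junction:
        # junction at mRNA 300; stop at mRNA 200 = genomic 501
        t = _tx("g1.1", exons, strand="-", cds=[(501, 700)])
        assert t.stop_codon_mrna_position() == 200
        assert flag_nmd(t) is True
        assert flag_nmd(t, distance=100) is False

    def test_oracle_mrna_arithmetic(self):
        # independent mRNA-coordinate oracle: walk exons and count bases
        exons = [(11, 40), (61, 100), (151, 200)]
        t = _tx("g1.1", exons, cds=[(11, 40), (61, 70)])
        order = exons
        mrna = {}
        pos = 0
        for s, e in order:
            for g in range(s, e + 1):
                pos += 1
                mrna[g] = pos
        assert t.to_mrna(70) == mrna[70]
        assert t.stop_codon_mrna_position() == mrna[70]
        assert t.junction_mrna_positions() == (mrna[40], mrna[100])
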
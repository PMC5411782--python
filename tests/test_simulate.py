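"""Synthetic genome, reads, map, expression and transcript generators."""

import math

import numpy as np
import pandas as pd
import pytest

from polyqc import gffio
from polyqc.genes import classify_as_events
from polyqc.kmers import revcomp
from polyqc.simulate import (
    ConfigurationError,
    GenomeConfig,
    Translocation,
    apportion,
    generate_expression,
    generate_genome,
    generate_map,
    generate_reads,
    generate_transcripts,
    member_bins_frame,
)
from polyqc.triads import classify_stress, tpm_normalize
from tests.conftest import fresh_genome


class TestGenomeGeneration:
    def test_zero_divergence_homoeologs_identical(self):
        genome, truth = fresh_genome(seed=1, homoeolog_divergence=0.0, n_triads=10)
        genes = {
            name: {c.gene.id: c.gene.seq for c in chrom.cassettes}
            for name, chrom in genome.chromosomes.items()
        }
        flat = {gid: seq for d in genes.values() for gid, seq in d.items()}
        for members in truth.triad_membership.values():
            seqs = {flat[g] for g in members.values()}
            assert len(seqs) == 1

    def test_byte_identical_rerun(self, tmp_path):
        for run in ("a", "b"):
            genome, _ = fresh_genome(seed=1, n_triads=10)
            genome.write_fasta(tmp_path / f"{run}.fasta")
            genome.write_gff3(tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_substitution_count_within_binomial_bounds(self):
        # the substitution process is Binomial(L, rate): every mutated base
        # changes, so the Hamming distance to the source is the draw itself
        from polyqc.simulate import mutate, random_dna

        rng = np.random.default_rng(2)
        L, rate = 1000, 0.05
        sd = math.sqrt(L * rate * (1 - rate))
        for _ in range(20):
            seq = random_dna(rng, L)
            mutated = mutate(seq, rate, rng)
            diff = sum(a != b for a, b in zip(seq, mutated))
            assert abs(diff - L * rate) <= 3 * sd

    def test_homoeolog_pairwise_divergence(self):
        # two copies mutated independently at rate d differ per site with
        # probability 2d(1-d) + (2/3)d^2
        d = 0.05
        genome, truth = fresh_genome(seed=2, homoeolog_divergence=d, n_triads=12)
        seqs = {
            c.gene.id: c.gene.seq
            for chrom in genome.chromosomes.values()
            for c in chrom.cassettes
        }
        p = 2 * d * (1 - d) + (2 / 3) * d * d
        diffs = bases = 0
        for members in truth.triad_membership.values():
            a, b = seqs[members["A"]], seqs[members["B"]]
            diffs += sum(x != y for x, y in zip(a, b))
            bases += len(a)
        sd = math.sqrt(bases * p * (1 - p))
        assert abs(diffs - bases * p) <= 4 * sd

    def test_every_gene_in_exactly_one_triad(self):
        genome, truth = fresh_genome(seed=3, n_triads=15)
        genes = set(genome.gene_models())
        in_truth = [g for m in truth.triad_membership.values() for g in m.values()]
        assert sorted(in_truth) == sorted(genes)
        assert all(len(m) == 3 for m in truth.triad_membership.values())

    def test_tsd_flanks_identical(self):
        cfg = GenomeConfig(n_triads=6, seed=5, repeat_fraction=0.2, tsd_length=6,
                           spacer_length=400)
        genome, _ = generate_genome(cfg)
        found = 0
        for chrom in genome.chromosomes.values():
            seq = chrom.sequence
            for element in genome.repeat_library:
                start = seq.find(element)
                while start != -1:
                    left = seq[start - 6 : start]
                    right = seq[start + len(element) : start + len(element) + 6]
                    if len(left) == 6 and len(right) == 6:
                        assert left == right
                        found += 1
                    start = seq.find(element, start + 1)
        assert found > 0

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="homoeolog_divergence"):
            GenomeConfig(n_triads=5, homoeolog_divergence=0.5)
        with pytest.raises(ConfigurationError, match="n_triads"):
            GenomeConfig(n_triads=0)

    def test_gff3_roundtrip(self, tmp_path):
        genome, _ = fresh_genome(seed=6, n_triads=6)
        path = tmp_path / "genes.gff3"
        genome.write_gff3(path)
        loaded = gffio.read_gff3(path)
        original = genome.gene_models()
        assert set(loaded) == set(original)
        for gid in original:
            t0 = original[gid].representative
            t1 = loaded[gid].representative
            assert t0.exons == t1.exons
            assert t0.cds == t1.cds
            assert t0.strand == t1.strand


class TestReads:
    def test_error_free_reads_are_substrings(self):
        genome, _ = fresh_genome(seed=7, n_triads=8)
        seqs = genome.sequences()
        reads = generate_reads(genome, coverage=2, read_len=120, error_rate=0.0, seed=1)
        for name, read in list(reads.items())[:200]:
            _, chrom, start, strand = name.split("|")
            src = seqs[chrom][int(start) : int(start) + 120]
            assert read == (src if strand == "+" else revcomp(src))

    def test_read_count_arithmetic(self):
        genome, _ = fresh_genome(seed=8, n_triads=8)
        total = genome.total_length
        reads = generate_reads(genome, coverage=10, read_len=100, seed=2)
        assert abs(len(reads) - 10 * total / 100) <= 1

    def test_error_rate_within_binomial_bounds(self):
        genome, _ = fresh_genome(seed=9, n_triads=8)
        seqs = genome.sequences()
        reads = generate_reads(genome, coverage=3, read_len=100, error_rate=0.01, seed=3)
        mismatches = bases = 0
        for name, read in reads.items():
            _, chrom, start, strand = name.split("|")
            src = seqs[chrom][int(start) : int(start) + 100]
            if strand == "-":
                src = revcomp(src)
            mismatches += sum(a != b for a, b in zip(read, src))
            bases += len(read)
        sd = math.sqrt(bases * 0.01 * 0.99)
        assert abs(mismatches - 0.01 * bases) <= 3 * sd

    def test_read_longer_than_chromosome_rejected(self):
        genome, _ = fresh_genome(seed=10, n_triads=8)
        with pytest.raises(ValueError, match="read_len"):
            generate_reads(genome, coverage=1, read_len=10**7)

    def test_invalid_rates_rejected(self):
        genome, _ = fresh_genome(seed=10, n_triads=8)
        with pytest.raises(ValueError):
            generate_reads(genome, coverage=0)
        with pytest.raises(ValueError):
            generate_reads(genome, coverage=1, error_rate=0.5)


class TestMapGeneration:
    def test_bin_count_arithmetic(self):
        genome, truth = fresh_genome(seed=11)
        result = generate_map(genome, truth, bins_per_chromosome=2)
        assert len(set(result.bins)) == 2 * 21
        df = result.map_frame()
        assert set(df.columns) == {"marker_id", "chromosome", "cM_bin"}
        assert df.groupby(["chromosome", "cM_bin"]).size().min() >= 1

    def test_markers_match_recorded_chromosome_without_translocations(self):
        genome, truth = fresh_genome(seed=12)
        seqs = genome.sequences()
        result = generate_map(genome, truth, bins_per_chromosome=2)
        for mid, seq in list(result.marker_seqs.items())[:40]:
            chrom, _ = result.gmap.markers[mid]
            assert seq in seqs[chrom] or revcomp(seq) in seqs[chrom]

    def test_planted_translocation_truth(self):
        genome, truth = fresh_genome(seed=13, n_triads=35)
        result = generate_map(
            genome, truth, bins_per_chromosome=2,
            translocations=[Translocation(2, "B", "5D", 2)],
        )
        assert len(truth.translocations) == 1
        tt = truth.translocations[0]
        assert tt.source_bin[0] == "5D"
        assert tt.target_chromosome == "2B"
        assert len(tt.triad_ids) == 2
        # exactly those triads have one member recorded off-group
        mb = member_bins_frame(truth, result)
        odd = []
        for tid, grp in mb.groupby("triad_id"):
            chroms = set(grp["chromosome"].str[0])
            if len(chroms) > 1:
                odd.append(tid)
        assert sorted(odd) == sorted(tt.triad_ids)
        # the moved markers physically sit on 2B, not on the recorded 5D
        seqs = genome.sequences()
        moved = [m for m, b in result.gmap.markers.items() if b[0] == "5D" and b[1] >= 20.0]
        assert moved
        for mid in moved:
            seq = result.marker_seqs[mid]
            assert seq in seqs["2B"] or revcomp(seq) in seqs["2B"]
            assert seq not in seqs["5D"] and revcomp(seq) not in seqs["5D"]

    def test_zero_divergence_markers_unavailable(self):
        genome, truth = fresh_genome(seed=14, homoeolog_divergence=0.0, n_triads=14)
        with pytest.raises(ConfigurationError):
            generate_map(genome, truth, bins_per_chromosome=1)

    def test_invalid_marker_length_rejected(self):
        genome, truth = fresh_genome(seed=15)
        with pytest.raises(ConfigurationError):
            generate_map(genome, truth, marker_length=20)


class TestExpressionGeneration:
    def _triads(self, n):
        return {
            f"t{i:03d}": {"A": f"g{i:03d}A", "B": f"g{i:03d}B", "D": f"g{i:03d}D"}
            for i in range(n)
        }

    def test_apportionment_is_exact(self):
        alloc = apportion({"a": 0.34, "b": 0.27, "c": 0.20, "d": 0.19}, 100)
        assert alloc == {"a": 34, "b": 27, "c": 20, "d": 19}
        assert sum(apportion({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, 10).values()) == 10

    def test_identical_matrix_on_rerun(self):
        triads = self._triads(20)
        a = generate_expression(triads, seed=4)
        b = generate_expression(triads, seed=4)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_flat_mix_recovers_all_not_de(self):
        triads = self._triads(30)
        flat = {"not-DE": 1.0, "1-DE": 0, "2-DE-same": 0, "3-DE-same": 0, "opposite": 0}
        data = generate_expression(
            triads, conditions=("D.6h",), pattern_mix=flat,
            imbalance_fraction=0.0, dispersion=0.0, seed=5,
        )
        tpm = tpm_normalize(data.counts, data.lengths)
        calls = classify_stress(tpm, data.triads, data.meta)
        assert (calls["pattern"] == "not-DE").all()

    def test_single_de_mix_recovered_exactly_noise_free(self):
        triads = self._triads(100)
        mix = {"not-DE": 0.0, "1-DE": 1.0, "2-DE-same": 0, "3-DE-same": 0, "opposite": 0}
        data = generate_expression(
            triads, conditions=("H.1h",), pattern_mix=mix, dispersion=0.0, seed=6,
        )
        tpm = tpm_normalize(data.counts, data.lengths)
        calls = classify_stress(tpm, data.triads, data.meta)
        assert (calls["pattern"] == "1-DE").all()

    def test_planted_labels_recovered_noise_free(self):
        from polyqc.simulate import TruthTables

        truth = TruthTables(triad_membership=self._triads(60))
        data = generate_expression(
            truth.triad_membership, conditions=("D.6h", "PM.48h"),
            dispersion=0.0, seed=7, truth=truth,
        )
        tpm = tpm_normalize(data.counts, data.lengths)
        calls = classify_stress(tpm, data.triads, data.meta)
        recovered = {(r.triad_id, r.condition): r.pattern for r in calls.itertuples()}
        assert recovered == truth.expression_labels

    def test_replicate_warning(self, caplog):
        with caplog.at_level("WARNING", logger="polyqc.simulate.expression"):
            generate_expression(self._triads(4), n_replicates=1, seed=8)
        assert any("replicate" in r.message for r in caplog.records)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_expression(self._triads(4), pattern_mix={"not-DE": 0.5}, seed=9)


class TestTranscriptGeneration:
    def test_ir_mix_all_retain_one_intron(self):
        genome, truth = fresh_genome(seed=16, n_triads=7)
        genes = genome.gene_models()
        tx = generate_transcripts(genes, {"IR": 1.0}, seed=1, truth=truth)
        assert len(tx) == len(genes)
        for gid, pair in tx.items():
            rep, alt = pair
            assert len(alt.exons) == len(rep.exons) - 1
            retained = set(rep.introns) - set(alt.introns)
            assert len(retained) == 1
            events = [e for _, _, e in classify_as_events(pair)]
            assert events == ["IR"]

    def test_mxe_exons_never_cooccur(self):
        genome, truth = fresh_genome(seed=17, n_triads=7)
        tx = generate_transcripts(genome.gene_models(), {"MXE": 1.0}, seed=2, truth=truth)
        for gid, (rep, alt) in tx.items():
            rep_only = set(rep.exons) - set(alt.exons)
            alt_only = set(alt.exons) - set(rep.exons)
            assert len(rep_only) == 1 and len(alt_only) == 1
            assert [e for _, _, e in classify_as_events([rep, alt])] == ["MXE"]

    def test_es_on_two_exon_gene_skipped(self, caplog):
        genome, _ = fresh_genome(seed=18, n_triads=4, exons_per_gene=2)
        with caplog.at_level("INFO", logger="polyqc.simulate.transcripts"):
            tx = generate_transcripts(genome.gene_models(), {"ES": 1.0}, seed=3)
        assert tx == {}
        assert any("cannot host" in r.message for r in caplog.records)

    def test_event_mix_recovered_exactly(self):
        genome, truth = fresh_genome(seed=19, n_triads=34)
        genes = genome.gene_models()  # 102 genes
        mix = {"IR": 0.34, "A3SS": 0.27, "ES": 0.20, "A5SS": 0.19}
        tx = generate_transcripts(genes, mix, seed=4, truth=truth)
        recovered = {}
        for pair in tx.values():
            for _, _, event in classify_as_events(pair):
                recovered[event] = recovered.get(event, 0) + 1
        expected = apportion(mix, len(genes))
        assert recovered == {k: v for k, v in expected.items() if v}
        # and the classifier agrees with every planted label
        for pair in tx.values():
            alt = [t for t in pair if not t.is_representative][0]
            events = [e for _, _, e in classify_as_events(pair)]
            assert events == [truth.as_event_labels[alt.id]]
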
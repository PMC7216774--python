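"""Generators: determinism, parameter fidelity and truth bookkeeping."""


import numpy as np
import pytest

from asmeval.accuracy import detect_breakpoints
from asmeval.contiguity import split_into_contigs
from asmeval.kmer_spectra import count_kmers
from asmeval.synthetic_data import (
    AssemblySimParams,
    GenomeSimParams,
    TruthTable,
    simulate_assembly,
    simulate_coverage_tracks,
    simulate_genome,
    simulate_gradient_study,
    simulate_reads,
    simulate_repeat_hits,
    simulate_status_tables,
    write_fastq,
)


class TestSimulateGenome:
    def test_deterministic(self):
        p = GenomeSimParams(chromosome_lengths=(5000,), seed=11)
        g1 = simulate_genome(p)
        g2 = simulate_genome(p)
        assert [r.seq for r in g1] == [r.seq for r in g2]

    def test_gc_content_concentrates(self):
        g = simulate_genome(GenomeSimParams(
            chromosome_lengths=(150_000,), gc=0.5, seed=3))
        seq = g[0].seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_gc_zero_gives_at_only(self):
        g = simulate_genome(GenomeSimParams(
            chromosome_lengths=(2000,), gc=0.0, seed=1))
        assert set(g[0].seq) <= {"A", "T"}

    def test_chromosome_naming_and_lengths(self):
        g = simulate_genome(GenomeSimParams(
            chromosome_lengths=(100, 200), seed=0))
        assert [(r.id, r.length) for r in g] == [("chr1", 100), ("chr2", 200)]


@pytest.fixture(scope="module")
def small_genome():
    return simulate_genome(GenomeSimParams(
        chromosome_lengths=(60_000, 40_000), seed=42))


class TestSimulateAssembly:
    def test_no_misassemblies_all_joins_correct(self, small_genome):
        a, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=3000,
                              misassembly_rate=0.0, seed=1))
        assert truth.planted_misassemblies == 0
        assert all(j.correct for j in truth.joins)

    def test_rate_one_corrupts_every_join(self, small_genome):
        a, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=3000,
                              misassembly_rate=1.0, seed=2))
        assert truth.planted_misassemblies == len(truth.joins)
        assert len(truth.joins) > 0

    def test_exact_misassembly_count(self, small_genome):
        for k in (1, 2, 3):
            a, truth = simulate_assembly(
                small_genome,
                AssemblySimParams(mean_fragment_length=3000,
                                  n_misassemblies=k, seed=k))
            assert truth.planted_misassemblies == k

    def test_sequence_content_is_conserved(self, small_genome):
        """Assembly bases = genome bases; gap bases are exactly the Ns."""
        a, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=4000,
                              misassembly_rate=0.1, seed=3))
        genome_size = sum(r.length for r in small_genome)
        n_gap = sum(r.seq.count("N") for r in a.records)
        assert a.total_size - n_gap == genome_size

    def test_junction_offsets_point_at_contig_starts(self, small_genome):
        a, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=4000,
                              misassembly_rate=0.2, seed=4))
        seqs = {r.id: r.seq for r in a.records}
        for j in truth.joins:
            seq = seqs[j.scaffold_id]
            assert seq[j.offset] != "N"      # contig starts here
            assert seq[j.offset - 1] == "N"  # gap run ends just before

    def test_splitting_recovers_the_cut_contigs(self, small_genome):
        """Gap runs >= 25 make every join visible: contig splitting
        recovers exactly the pieces the genome was cut into."""
        a, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=4000,
                              misassembly_rate=0.0, seed=5))
        contigs = split_into_contigs(a, min_gap_run=25)
        joined = sorted(r.seq for r in contigs.records)
        # reconstruct the cut set independently from the truth offsets
        n_contigs = len(a.records) + len(truth.joins)
        assert len(contigs) == n_contigs
        genome_cat = "".join(r.seq for r in small_genome)
        assert "".join(sorted(set("".join(joined)))) <= "ACGT"
        assert sum(len(s) for s in joined) == len(genome_cat)

    def test_sub_threshold_gaps_stay_unbroken(self, small_genome):
        a, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=4000,
                              misassembly_rate=0.0, gap_range=(5, 20),
                              seed=6))
        contigs = split_into_contigs(a, min_gap_run=25)
        assert len(contigs) == len(a.records)  # nothing broken

    def test_deterministic(self, small_genome):
        p = AssemblySimParams(mean_fragment_length=3000,
                              misassembly_rate=0.3, seed=9)
        a1, t1 = simulate_assembly(small_genome, p)
        a2, t2 = simulate_assembly(small_genome, p)
        assert [r.seq for r in a1.records] == [r.seq for r in a2.records]
        assert t1.joins == t2.joins

    def test_truth_json_round_trip(self, small_genome, tmp_path):
        _, truth = simulate_assembly(
            small_genome,
            AssemblySimParams(mean_fragment_length=4000,
                              n_misassemblies=2, seed=7))
        p = tmp_path / "truth.json"
        truth.to_json(p)
        assert TruthTable.from_json(p).joins == truth.joins


class TestSimulateReads:
    def test_read_count_matches_coverage(self, small_genome):
        reads = simulate_reads(small_genome, coverage=30, read_len=150,
                               error_rate=0.0, seed=1)
        assert len(reads) == round(30 * 100_000 / 150)

    def test_error_free_reads_are_genome_substrings(self, small_genome):
        reads = simulate_reads(small_genome, coverage=0.5, read_len=100,
                               error_rate=0.0, seed=2)
        genome_kmers = count_kmers([r.seq for r in small_genome], k=31)
        read_kmers = count_kmers([r.seq for r in reads[:50]], k=31)
        assert set(read_kmers.counts) <= set(genome_kmers.counts)

    def test_error_rate_introduces_mismatches(self, small_genome):
        clean = simulate_reads(small_genome, coverage=0.2, read_len=100,
                               error_rate=0.0, seed=3)
        noisy = simulate_reads(small_genome, coverage=0.2, read_len=100,
                               error_rate=0.05, seed=3)
        diffs = sum(a != b for r1, r2 in zip(clean, noisy)
                    for a, b in zip(r1.seq, r2.seq))
        n_bases = sum(r.length for r in clean)
        assert 0.03 < diffs / n_bases < 0.07

    def test_deterministic_fastq(self, small_genome, tmp_path):
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        for p in (p1, p2):
            write_fastq(simulate_reads(small_genome, coverage=0.1,
                                       read_len=100, seed=5), p)
        assert p1.read_bytes() == p2.read_bytes()


class TestSimulateCoverageTracks:
    def test_zero_mean_gives_all_zero(self, small_genome):
        a, truth = simulate_assembly(
            small_genome, AssemblySimParams(mean_fragment_length=4000,
                                            misassembly_rate=0.0, seed=1))
        tracks = simulate_coverage_tracks(a, truth, mean_cov=0, seed=1)
        assert all((t.cov == 0).all() for t in tracks)

    def test_no_bad_joins_no_long_zero_runs(self, small_genome):
        a, truth = simulate_assembly(
            small_genome, AssemblySimParams(mean_fragment_length=4000,
                                            misassembly_rate=0.0, seed=2))
        for seed in range(5):
            tracks = simulate_coverage_tracks(a, truth, mean_cov=30,
                                              seed=seed)
            assert all(detect_breakpoints(t, min_cov=5, min_run=100) == []
                       for t in tracks)

    def test_dropout_at_every_incorrect_join(self, small_genome):
        a, truth = simulate_assembly(
            small_genome, AssemblySimParams(mean_fragment_length=4000,
                                            n_misassemblies=3, seed=3))
        tracks = simulate_coverage_tracks(a, truth, mean_cov=30,
                                          dropout_halfwidth=200, seed=3)
        n_found = sum(len(detect_breakpoints(t, min_run=100))
                      for t in tracks)
        assert n_found == 3

    def test_track_lengths_match_assembly(self, small_genome):
        a, truth = simulate_assembly(
            small_genome, AssemblySimParams(mean_fragment_length=4000,
                                            misassembly_rate=0.1, seed=4))
        tracks = simulate_coverage_tracks(a, truth, seed=4)
        assert {t.seq_id: len(t) for t in tracks} == \
            {r.id: r.length for r in a.records}


class TestStatusAndRepeatTables:
    def test_fixed_seed_identical_tables(self):
        t1 = simulate_status_tables(3, total_orthologs=500, seed=7)
        t2 = simulate_status_tables(3, total_orthologs=500, seed=7)
        assert all(a.status == b.status for a, b in zip(t1, t2))

    def test_flat_gradient_gives_similar_single_counts(self):
        tables = simulate_status_tables(4, total_orthologs=4000,
                                        quality=[0.9] * 4, seed=1)
        counts = [sum(1 for v in t.status.values() if v == "single")
                  for t in tables]
        # binomial(4000, 0.9): sd ~ 19, so spread stays within ~6 sd
        assert max(counts) - min(counts) < 120

    def test_quality_gradient_orders_single_counts(self):
        tables = simulate_status_tables(
            3, total_orthologs=4000, quality=[0.7, 0.85, 0.97], seed=2)
        counts = [sum(1 for v in t.status.values() if v == "single")
                  for t in tables]
        assert counts == sorted(counts)

    def test_zero_density_gives_no_hits(self, small_genome):
        a, _ = simulate_assembly(
            small_genome, AssemblySimParams(mean_fragment_length=4000,
                                            misassembly_rate=0.0, seed=1))
        assert simulate_repeat_hits(a, density=0.0, seed=1) == []

    def test_hits_within_bounds(self, small_genome):
        a, _ = simulate_assembly(
            small_genome, AssemblySimParams(mean_fragment_length=4000,
                                            misassembly_rate=0.0, seed=1))
        lengths = {r.id: r.length for r in a.records}
        hits = simulate_repeat_hits(a, density=0.3, seed=2)
        assert hits
        assert all(0 <= h.start < h.end <= lengths[h.seq_id] for h in hits)


class TestGradientStudy:
    def test_deterministic_and_complete(self):
        s1 = simulate_gradient_study(seed=5,
                                     chromosome_lengths=(60_000, 40_000))
        s2 = simulate_gradient_study(seed=5,
                                     chromosome_lengths=(60_000, 40_000))
        assert s1.planted_order == s2.planted_order == [
            "S1", "S2", "S3", "S4", "S5"]
        assert [len(a) for a in s1.assemblies] == [len(a) for a in s2.assemblies]
        assert all(t1.joins == t2.joins
                   for t1, t2 in zip(s1.truths, s2.truths))
        assert len(s1.status_tables) == 5
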
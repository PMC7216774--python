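"""Length statistics: FASTA loading, filtering, gap splitting, Nx."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmeval.contiguity import (
    Assembly,
    SequenceRecord,
    contiguity_report,
    filter_min_length,
    fold_change,
    nx,
    read_assembly,
    split_into_contigs,
)
from asmeval.errors import InputError
from tests.conftest import make_assembly


def _write_fasta(path, records, width=None):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            if width:
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
            else:
                fh.write(seq + "\n")


class TestReadAssembly:
    def test_single_record_upper_cased(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, [("s1", "acgtN")])
        a = read_assembly(p)
        assert len(a) == 1
        assert a.records[0].seq == "ACGTN"
        assert a.records[0].length == 5

    def test_total_size_is_additive(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, [("s1", "A" * 10), ("s2", "C" * 3), ("s3", "G" * 7)])
        a = read_assembly(p)
        assert a.total_size == 20
        assert len(a) == 3

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, [("s1", "ACGTRYKMSWacgt")])
        a = read_assembly(p)
        assert a.records[0].seq == "ACGTNNNNNNACGT"

    def test_wrapped_lines_match_naive_parser(self, tmp_path, rng):
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        records = [
            (f"r{i}", bases[rng.integers(0, 4, size=int(rng.integers(1, 400)))]
             .tobytes().decode())
            for i in range(50)
        ]
        p = tmp_path / "wrapped.fasta"
        _write_fasta(p, records, width=60)
        a = read_assembly(p)
        # independent line-by-line reference parser
        oracle = {}
        rid = None
        for line in p.read_text().splitlines():
            if line.startswith(">"):
                rid = line[1:].split()[0]
                oracle[rid] = ""
            else:
                oracle[rid] += line.strip()
        assert {r.id: r.seq for r in a.records} == oracle

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        _write_fasta(p, [("s1", "ACGT"), ("s1", "TTTT")])
        with pytest.raises(InputError, match="duplicate"):
            read_assembly(p)

    def test_empty_file_gives_empty_assembly(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert len(read_assembly(p)) == 0


class TestFilterMinLength:
    def test_strictly_greater_by_default(self):
        a = make_assembly(["A" * 1000, "C" * 1001])
        kept = filter_min_length(a, 1000)
        assert [r.length for r in kept.records] == [1001]

    def test_inclusive_flag(self):
        a = make_assembly(["A" * 1000, "C" * 1001])
        kept = filter_min_length(a, 1000, inclusive=True)
        assert [r.length for r in kept.records] == [1000, 1001]

    def test_all_short_gives_empty(self):
        a = make_assembly(["A" * 5, "C" * 9])
        assert len(filter_min_length(a, 100)) == 0

    def test_min_len_zero_is_identity(self):
        a = make_assembly(["A" * 5, "C" * 9])
        assert filter_min_length(a, 0).lengths() == a.lengths()


class TestSplitIntoContigs:
    @pytest.mark.parametrize("gap_len,expected", [
        (25, [4, 4]),   # at-threshold run breaks
        (24, [32]),     # below-threshold run stays inside the contig
        (100, [4, 4]),
    ])
    def test_gap_threshold(self, gap_len, expected):
        a = make_assembly(["AAAA" + "N" * gap_len + "CCCC"])
        assert split_into_contigs(a).lengths() == expected

    def test_all_n_scaffold_gives_no_contigs(self):
        a = make_assembly(["N" * 100])
        assert len(split_into_contigs(a)) == 0

    def test_leading_trailing_gaps_dropped(self):
        a = make_assembly(["N" * 30 + "ACGT" + "N" * 30])
        contigs = split_into_contigs(a)
        assert [r.seq for r in contigs.records] == ["ACGT"]

    def test_contig_ids_derive_from_parent(self):
        a = make_assembly(["AAAA" + "N" * 25 + "CCCC"])
        assert [r.id for r in split_into_contigs(a).records] == ["s1.1", "s1.2"]

    @given(st.lists(
        st.tuples(st.sampled_from("ACGT"), st.integers(1, 40)),
        min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_run_length_scan_oracle(self, runs):
        seq = "".join(ch * n for ch, n in runs)
        a = make_assembly([seq])
        got = [r.seq for r in split_into_contigs(a, min_gap_run=25).records]
        # independent oracle: explicit run-length scan over the string
        expected, cur = [], ""
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if seq[i] == "N" and j - i >= 25:
                if cur:
                    expected.append(cur)
                cur = ""
            else:
                cur += seq[i:j]
            i = j
        if cur:
            expected.append(cur)
        assert got == expected

    def test_idempotent(self, random_scaffolds):
        once = split_into_contigs(random_scaffolds)
        twice = split_into_contigs(once)
        assert [r.seq for r in twice.records] == [r.seq for r in once.records]

    def test_length_bookkeeping(self, random_scaffolds):
        contigs = split_into_contigs(random_scaffolds)
        removed = sum(
            len(m.group()) for r in random_scaffolds.records
            for m in re.finditer("N{25,}", r.seq)
        )
        assert contigs.total_size + removed == random_scaffolds.total_size


def _nx_oracle(lengths, x):
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= x / 100 * total:
            return length
    raise AssertionError("unreachable")


class TestNx:
    def test_single_length(self):
        assert nx([42], 50) == 42
        assert nx([42], 1) == 42

    def test_worked_example_n50(self):
        assert nx([8, 5, 4, 2], 50) == 5  # cumulative 8, 13 >= 9.5

    def test_worked_example_n90(self):
        assert nx([8, 5, 4, 2], 90) == 2  # only the last element reaches 17.1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nx([], 50)

    def test_matches_oracle_and_monotone(self, rng):
        for _ in range(300):
            lengths = rng.integers(1, 10_000,
                                   size=int(rng.integers(1, 40))).tolist()
            xs = sorted(rng.uniform(1, 100, size=4))
            vals = [nx(lengths, x) for x in xs]
            assert vals == [_nx_oracle(lengths, x) for x in xs]
            assert all(a >= b for a, b in zip(vals, vals[1:]))
            assert nx(lengths, 50) >= nx(lengths, 90)


class TestContiguityReport:
    def test_single_chromosome_sized_scaffold(self):
        a = make_assembly(["A" * 40_000_000])
        r = contiguity_report(a)
        assert r.counts_ge[39_000_000] == (1, 100.0)
        assert r.pct_genome_ge_gene_len == 100.0
        assert r.scaffold_n50 == r.longest == 40_000_000

    def test_gene_length_fraction(self):
        a = make_assembly(["A" * 30_000, "C" * 20_000])
        r = contiguity_report(a)
        assert r.pct_genome_ge_gene_len == pytest.approx(60.0)

    def test_matches_brute_force_on_random_assembly(self, random_scaffolds):
        thresholds = (1000, 2000, 4000)
        r = contiguity_report(random_scaffolds, thresholds=thresholds,
                              gene_len=2500, min_len=600)
        lengths = [x for x in random_scaffolds.lengths() if x > 600]
        assert r.n_scaffolds == len(lengths)
        assert r.total_size == sum(lengths)
        assert r.longest == max(lengths)
        assert r.scaffold_n50 == _nx_oracle(lengths, 50)
        assert r.scaffold_n90 == _nx_oracle(lengths, 90)
        for t in thresholds:
            n_above = sum(1 for x in lengths if x > t)
            assert r.counts_ge[t] == (n_above, 100.0 * n_above / len(lengths))
        assert r.pct_genome_ge_gene_len == pytest.approx(
            100.0 * sum(x for x in lengths if x >= 2500) / sum(lengths))
        # thresholds counts are non-increasing
        counts = [r.counts_ge[t][0] for t in thresholds]
        assert counts == sorted(counts, reverse=True)
        assert r.scaffold_n90 <= r.scaffold_n50 <= r.longest
        assert r.contig_n50 <= r.scaffold_n50

    def test_empty_after_filter_rejected(self):
        a = make_assembly(["A" * 10])
        with pytest.raises(ValueError, match="empty"):
            contiguity_report(a)


class TestFoldChange:
    @pytest.mark.parametrize("num,den,expected", [
        (5.58, 0.30, 18.6),   # scaffold N50 gain from linked-read scaffolding
        (14.05, 5.73, 2.5),
        (800, 40, 20.0),      # N90 ratio between base assemblies
        (7.0, 7.0, 1.0),
    ])
    def test_worked_examples(self, num, den, expected):
        assert fold_change(num, den) == expected

    def test_half_rounds_up(self):
        assert fold_change(125, 1000, decimals=1) == 0.1
        assert fold_change(150, 1000, decimals=1) == 0.2

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
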
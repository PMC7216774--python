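"""Shared k-mer spectra between a read set and an assembly.

Every distinct canonical k-mer observed in the reads is classified by
its multiplicity in the reads (m) and its copy number in the assembly
(d).  The joint histogram over (d, m) is the comparison spectrum: the
d=0 row holds read content absent from the assembly (sequencing errors
at low m, genuinely missing sequence at high m), the d=1 row the
expected unique content, and d>=2 rows repeat or duplicated content.
Default k is 31.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerCountMap:
    """Multiplicities of (optionally canonical) k-mers."""

    k: int
    canonical: bool
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_kmers(seqs: Iterable[str], k: int = 31,
                canonical: bool = True) -> KmerCountMap:
    """Count k-mers over a collection of sequences.

    Windows containing any character outside {A,C,G,T} are skipped, so
    N runs partition each sequence into independently counted stretches.
    Canonical folding maps each k-mer to the lexicographic minimum of
    itself and its reverse complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    any_window = False
    for seq in seqs:
        seq = seq.upper()
        for stretch in _clean_stretches(seq):
            if len(stretch) < k:
                continue
            any_window = True
            for i in range(len(stretch) - k + 1):
                kmer = stretch[i:i + k]
                if canonical:
                    rc = revcomp(kmer)
                    if rc < kmer:
                        kmer = rc
                counts[kmer] = counts.get(kmer, 0) + 1
    if not any_window:
        log.warning("k=%d exceeds every clean sequence stretch; empty map", k)
    return KmerCountMap(k=k, canonical=canonical, counts=counts)


def _clean_stretches(seq: str) -> Iterable[str]:
    """Maximal substrings containing only A/C/G/T."""
    if set(seq) <= _ACGT:
        yield seq
        return
    start = None
    for i, ch in enumerate(seq):
        if ch in _ACGT:
            if start is None:
                start = i
        elif start is not None:
            yield seq[start:i]
            start = None
    if start is not None:
        yield seq[start:]


@dataclass
class SpectraMatrix:
    """Joint histogram of distinct read k-mers over assembly copy number
    d in {0..max_copy} (rows) and read multiplicity m in {1..max_mult}
    (columns); both axes clip into their last bucket.  Assembly k-mers
    never seen in the reads are tallied separately."""

    k: int
    cells: np.ndarray
    assembly_only: int

    @property
    def max_copy(self) -> int:
        return self.cells.shape[0] - 1

    @property
    def max_mult(self) -> int:
        return self.cells.shape[1]

    def total_read_kmers(self) -> int:
        return int(self.cells.sum())


def spectra_matrix(reads: KmerCountMap, assembly: KmerCountMap,
                   max_copy: int = 10, max_mult: int = 200) -> SpectraMatrix:
    """Build the comparison spectrum for a read set against an assembly."""
    if reads.k != assembly.k:
        raise ValueError(f"k mismatch: reads k={reads.k}, assembly k={assembly.k}")
    if reads.canonical != assembly.canonical:
        raise ValueError("canonical setting differs between the two maps")
    cells = np.zeros((max_copy + 1, max_mult), dtype=np.int64)
    for kmer, mult in reads.counts.items():
        d = min(assembly.counts.get(kmer, 0), max_copy)
        m = min(mult, max_mult)
        cells[d, m - 1] += 1
    assembly_only = sum(1 for kmer in assembly.counts if kmer not in reads.counts)
    return SpectraMatrix(k=reads.k, cells=cells, assembly_only=assembly_only)


def missing_content(matrix: SpectraMatrix, min_mult: int = 3,
                    ) -> tuple[int, float]:
    """Solid read content absent from the assembly: distinct read k-mers
    with multiplicity >= ``min_mult`` and assembly copy number 0, as a
    count and as a fraction of all distinct read k-mers."""
    if min_mult < 1:
        raise ValueError("min_mult must be >= 1")
    m0 = min(min_mult, matrix.max_mult)
    count = int(matrix.cells[0, m0 - 1:].sum())
    total = matrix.total_read_kmers()
    return count, (count / total if total else 0.0)


# ---------------------------------------------------------------------------
# I/O

def read_sequences(path: str | Path) -> list[str]:
    """Sequences from FASTA or FASTQ (format chosen by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_matrix(matrix: SpectraMatrix, path: str | Path) -> None:
    """TSV: one row per assembly copy number, one column per read
    multiplicity, with a header comment stating k."""
    with open(path, "w") as fh:
        fh.write(f"# k={matrix.k}\n")
        fh.write(f"# assembly_only_kmers={matrix.assembly_only}\n")
        fh.write("copy\\mult\t" + "\t".join(
            str(m) for m in range(1, matrix.max_mult + 1)) + "\n")
        for d in range(matrix.max_copy + 1):
            fh.write(str(d) + "\t" + "\t".join(
                str(int(v)) for v in matrix.cells[d]) + "\n")
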
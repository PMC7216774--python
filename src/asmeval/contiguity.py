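"""Length-based assembly statistics.

Scaffold-level contiguity is summarised by Nx values, threshold counts
and the fraction of the assembly held in gene-sized (default 25 kb)
scaffolds.  Contig statistics are obtained by breaking scaffolds at runs
of at least ``min_gap_run`` (default 25) consecutive N characters, the
conventional boundary between "estimated gap" and "short unknown
stretch" inside a contig.  All statistics are computed on the set of
sequences longer than a minimum length filter (default 1 kb), mirroring
how draft-assembly statistics are normally reported.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from asmeval.errors import InputError

log = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

#: Data types an assembly may have been built from.
PROVENANCE_TAGS = frozenset(
    {"pcr_free", "lmp", "10x", "bionano", "10x_scaffolding"}
)


@dataclass(frozen=True)
class SequenceRecord:
    """A single scaffold or contig."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """A named, ordered collection of sequence records."""

    name: str
    records: list[SequenceRecord]
    provenance: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise InputError(f"duplicate record id {dup!r} in assembly {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def total_size(self) -> int:
        return sum(r.length for r in self.records)

    def lengths(self) -> list[int]:
        return [r.length for r in self.records]


def read_assembly(path: str | Path, name: str | None = None,
                  provenance: Iterable[str] = ()) -> Assembly:
    """Load a (possibly line-wrapped, mixed-case) FASTA file.

    Sequences are upper-cased; characters outside {A,C,G,T,N} (IUPAC
    ambiguity codes and the like) are replaced by N, with the total
    replacement count logged as a warning.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    records: list[SequenceRecord] = []
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID_CHARS:
            seq, n = _NON_ACGTN.subn("N", seq)
            n_replaced += n
        records.append(SequenceRecord(rec.id, seq))
    if n_replaced:
        log.warning("%s: replaced %d non-ACGTN characters with N", path, n_replaced)
    if not records:
        log.warning("%s: no FASTA records found, empty assembly", path)
    return Assembly(name=name, records=records, provenance=frozenset(provenance))


def filter_min_length(a: Assembly, min_len: int = 1000,
                      inclusive: bool = False) -> Assembly:
    """Drop records not longer than ``min_len`` (strict ``>`` by default).

    ``inclusive=True`` keeps records of exactly ``min_len`` as well, for
    comparison against tools that filter with ``>=``.
    """
    if inclusive:
        kept = [r for r in a.records if r.length >= min_len]
    else:
        kept = [r for r in a.records if r.length > min_len]
    return Assembly(name=a.name, records=kept, provenance=a.provenance)


def split_into_contigs(a: Assembly, min_gap_run: int = 25) -> Assembly:
    """Break every scaffold at each maximal run of >= ``min_gap_run`` Ns.

    Runs shorter than the threshold stay inside contigs; leading or
    trailing gap runs produce no empty fragments.  Contig ids are the
    parent id plus a 1-based ordinal suffix.
    """
    if min_gap_run < 1:
        raise ValueError("min_gap_run must be >= 1")
    gap = re.compile("N{%d,}" % min_gap_run)
    contigs: list[SequenceRecord] = []
    for rec in a.records:
        pieces = [p for p in gap.split(rec.seq) if p]
        for i, piece in enumerate(pieces, start=1):
            contigs.append(SequenceRecord(f"{rec.id}.{i}", piece))
    return Assembly(name=a.name, records=contigs, provenance=a.provenance)


def nx(lengths: Sequence[int], x: float) -> int:
    """Nx statistic: the length L (a member of ``lengths``) such that
    sequences of length >= L together cover at least x% of the total.

    Descending-cumulative convention: sort descending, accumulate, and
    return the element at which the running sum first reaches x% of the
    total.
    """
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("Nx of an empty length collection is undefined")
    target = arr.sum() * (x / 100.0)
    idx = int(np.searchsorted(np.cumsum(arr), target, side="left"))
    return int(arr[min(idx, arr.size - 1)])


def fold_change(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Ratio of two sizes, rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("fold_change denominator must be > 0")
    q = Decimal(1).scaleb(-decimals)
    ratio = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


DEFAULT_THRESHOLDS = (100_000, 1_000_000, 39_000_000)


@dataclass
class ContiguityReport:
    """One assembly's row of length statistics.

    ``counts_ge`` maps each size threshold to ``(count, percent of
    scaffolds)`` strictly above it.  ``pct_genome_ge_gene_len`` is the
    percentage of the (filtered) assembly length held in scaffolds of at
    least ``gene_len`` bases.
    """

    assembly_name: str
    n_scaffolds: int
    total_size: int
    longest: int
    scaffold_n50: int
    scaffold_n90: int
    contig_n50: int
    counts_ge: dict[int, tuple[int, float]]
    pct_genome_ge_gene_len: float
    gene_len: int = 25_000
    min_len_filter: int = 1000


def contiguity_report(a: Assembly,
                      thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
                      gene_len: int = 25_000,
                      min_len: int = 1000,
                      min_gap_run: int = 25,
                      refilter_contigs: bool = False) -> ContiguityReport:
    """Compute the full per-assembly contiguity row.

    Applies the minimum-length filter, computes scaffold N50/N90,
    contig N50 on the gap-split records (optionally re-filtered at
    ``min_len``), counts above each threshold, and the percent of the
    filtered genome held in scaffolds >= ``gene_len``.
    """
    filtered = filter_min_length(a, min_len=min_len)
    if not filtered.records:
        raise ValueError(
            f"assembly {a.name!r} is empty after the {min_len} bp length filter"
        )
    lengths = np.asarray(filtered.lengths(), dtype=np.int64)
    total = int(lengths.sum())
    contigs = split_into_contigs(filtered, min_gap_run=min_gap_run)
    if refilter_contigs:
        contigs = filter_min_length(contigs, min_len=min_len)
    counts_ge: dict[int, tuple[int, float]] = {}
    for t in thresholds:
        c = int((lengths > t).sum())
        counts_ge[int(t)] = (c, 100.0 * c / lengths.size)
    return ContiguityReport(
        assembly_name=a.name,
        n_scaffolds=int(lengths.size),
        total_size=total,
        longest=int(lengths.max()),
        scaffold_n50=nx(lengths, 50),
        scaffold_n90=nx(lengths, 90),
        contig_n50=nx(contigs.lengths(), 50) if contigs.records else 0,
        counts_ge=counts_ge,
        pct_genome_ge_gene_len=100.0 * int(lengths[lengths >= gene_len].sum()) / total,
        gene_len=gene_len,
        min_len_filter=min_len,
    )


def contiguity_table(reports: Iterable[ContiguityReport]) -> pd.DataFrame:
    """Tabulate reports with headers following the conventional
    assembly-statistics layout (counts above thresholds, longest
    scaffold, contig/scaffold N50, assembly size)."""
    rows = []
    for r in reports:
        row: dict[str, object] = {
            "Assembly": r.assembly_name,
            "No. scaffolds": r.n_scaffolds,
        }
        for t, (c, pct) in sorted(r.counts_ge.items()):
            row[f">{_fmt_bases(t)}"] = f"{c} ({pct:.1f})"
        row[f"% genome >={_fmt_bases(r.gene_len)}"] = round(r.pct_genome_ge_gene_len, 1)
        row["Longest scaffold (Mb)"] = round(r.longest / 1e6, 2)
        row["Contig N50 (kb)"] = round(r.contig_n50 / 1e3, 2)
        row["Scaffold N50 (Mb)"] = round(r.scaffold_n50 / 1e6, 2)
        row["Scaffold N90 (Mb)"] = round(r.scaffold_n90 / 1e6, 2)
        row["Assembly size (Gb)"] = round(r.total_size / 1e9, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def write_contiguity_reports(reports: Sequence[ContiguityReport],
                             tsv_path: str | Path,
                             json_path: str | Path | None = None) -> None:
    df = contiguity_table(reports)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "assembly_name": r.assembly_name,
                "n_scaffolds": r.n_scaffolds,
                "total_size": r.total_size,
                "longest": r.longest,
                "scaffold_n50": r.scaffold_n50,
                "scaffold_n90": r.scaffold_n90,
                "contig_n50": r.contig_n50,
                "counts_ge": {str(k): list(v) for k, v in r.counts_ge.items()},
                "pct_genome_ge_gene_len": r.pct_genome_ge_gene_len,
                "gene_len": r.gene_len,
                "min_len_filter": r.min_len_filter,
            }
            for r in reports
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2))


def _fmt_bases(n: int) -> str:
    if n % 1_000_000 == 0:
        return f"{n // 1_000_000} Mb"
    if n % 1000 == 0:
        return f"{n // 1000} kb"
    return f"{n} bp"
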
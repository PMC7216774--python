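"""Completeness and repeat-content summaries.

Ortholog completeness is ingested as per-ortholog status tables
(single / duplicated / fragmented / missing, the usual BUSCO
categories) and summarised per assembly and across assemblies.  Repeat
content is ingested as per-hit tables (RepeatMasker ``.out`` or a
simplified TSV) and summarised as the masked fraction of the genome,
per-class masked fractions, and the mean divergence
mismatches / (matches + mismatches) over hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from asmeval.errors import ConsistencyError, InputError

log = logging.getLogger(__name__)

CATEGORIES = ("single", "duplicated", "fragmented", "missing")

#: BUSCO full-table status words -> our categories
_BUSCO_STATUS = {
    "complete": "single",
    "duplicated": "duplicated",
    "fragmented": "fragmented",
    "missing": "missing",
}


@dataclass
class OrthologStatusTable:
    """Per-ortholog completeness status for one assembly."""

    assembly_name: str
    status: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.status.values()} - set(CATEGORIES)
        if bad:
            raise ConsistencyError(f"unknown ortholog categories: {sorted(bad)}")

    @property
    def total_orthologs(self) -> int:
        return len(self.status)


def busco_summary(t: OrthologStatusTable) -> dict[str, tuple[int, int]]:
    """Per-category (count, integer percent of total, half-up)."""
    if t.total_orthologs == 0:
        raise ConsistencyError(f"{t.assembly_name}: empty ortholog table")
    out: dict[str, tuple[int, int]] = {}
    for cat in CATEGORIES:
        n = sum(1 for v in t.status.values() if v == cat)
        pct = Decimal(100 * n) / Decimal(t.total_orthologs)
        out[cat] = (n, int(pct.quantize(Decimal(1), rounding=ROUND_HALF_UP)))
    return out


def status_intersections(tables: Sequence[OrthologStatusTable],
                         ) -> dict[str, int]:
    """Per category, the number of orthologs holding that status in
    every table.  All tables must share one ortholog-id universe."""
    if not tables:
        raise ValueError("need at least one table")
    universe = set(tables[0].status)
    for t in tables[1:]:
        if set(t.status) != universe:
            raise ConsistencyError(
                f"{t.assembly_name}: ortholog-id universe differs from "
                f"{tables[0].assembly_name}"
            )
    out = {}
    for cat in CATEGORIES:
        out[cat] = sum(
            1 for oid in universe
            if all(t.status[oid] == cat for t in tables)
        )
    return out


def read_busco_table(path: str | Path, assembly_name: str | None = None,
                     ) -> OrthologStatusTable:
    """Parse a BUSCO full-table-like TSV: comment lines start with '#',
    data lines are (ortholog id, status, ...).  'Complete' maps to
    ``single``; a duplicated ortholog may appear on several lines."""
    path = Path(path)
    status: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}: expected >=2 tab-separated columns")
            oid, raw = parts[0], parts[1].strip().lower()
            cat = _BUSCO_STATUS.get(raw)
            if cat is None:
                raise InputError(f"{path}: unknown status {parts[1]!r}")
            status[oid] = cat
    return OrthologStatusTable(
        assembly_name=assembly_name or path.stem, status=status
    )


# ---------------------------------------------------------------------------
# repeats

@dataclass(frozen=True)
class RepeatHit:
    """One masked interval, 0-based half-open, with its alignment
    identity accounting.  ``div_override`` carries a tool-reported
    percent-divergence/100 that takes precedence over the
    matches/mismatches ratio when present."""

    seq_id: str
    start: int
    end: int
    repeat_class: str
    matches: int
    mismatches: int
    div_override: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty hit interval on {self.seq_id}")
        if self.matches + self.mismatches <= 0:
            raise ValueError("matches + mismatches must be > 0")

    @property
    def divergence_value(self) -> float:
        if self.div_override is not None:
            return self.div_override
        return divergence(self.matches, self.mismatches)


def divergence(matches: int, mismatches: int) -> float:
    """mismatches / (matches + mismatches)."""
    denom = matches + mismatches
    if denom <= 0:
        raise ValueError("matches + mismatches must be > 0")
    return mismatches / denom


@dataclass
class RepeatReport:
    """Masked percentages and mean divergence for one assembly.
    ``mean_divergence`` is a fraction in [0, 1]; display conventionally
    multiplies by 100.  Per-class percentages use independent interval
    unions, so overlapping annotations can make them sum above
    ``pct_masked``."""

    assembly_name: str
    pct_masked: float
    pct_by_class: dict[str, float]
    mean_divergence: float | None


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def repeat_report(hits: Sequence[RepeatHit], assembly_size: int,
                  classes: Sequence[str] = ("SINE", "LINE"),
                  assembly_name: str = "",
                  length_weighted: bool = False,
                  seq_lengths: Mapping[str, int] | None = None) -> RepeatReport:
    """Summarise repeat hits over an assembly of ``assembly_size`` bases.

    ``pct_masked`` is the union of all hit intervals (per sequence) as a
    percent of the assembly; per-class percentages use per-class unions.
    Mean divergence is the unweighted mean over hits by default;
    ``length_weighted=True`` weights each hit by its interval length.
    ``seq_lengths`` (seq_id -> length), when given, bounds-checks hits.
    """
    if assembly_size <= 0:
        raise ValueError("assembly_size must be > 0")
    if seq_lengths is not None:
        for h in hits:
            if h.seq_id not in seq_lengths or h.end > seq_lengths[h.seq_id]:
                raise ValueError(
                    f"hit [{h.start}, {h.end}) out of bounds on {h.seq_id!r}"
                )
    by_seq: dict[str, list[tuple[int, int]]] = {}
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {c: {} for c in classes}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append((h.start, h.end))
        if h.repeat_class in by_class:
            by_class[h.repeat_class].setdefault(h.seq_id, []).append(
                (h.start, h.end))
    masked = sum(union_length(ivs) for ivs in by_seq.values())
    pct_by_class = {
        c: 100.0 * sum(union_length(ivs) for ivs in per_seq.values())
        / assembly_size
        for c, per_seq in by_class.items()
    }
    if hits:
        if length_weighted:
            w = np.array([h.end - h.start for h in hits], dtype=float)
            d = np.array([h.divergence_value for h in hits])
            mean_div = float((w * d).sum() / w.sum())
        else:
            mean_div = float(np.mean([h.divergence_value for h in hits]))
    else:
        mean_div = None
    return RepeatReport(
        assembly_name=assembly_name,
        pct_masked=100.0 * masked / assembly_size,
        pct_by_class=pct_by_class,
        mean_divergence=mean_div,
    )


def read_repeat_hits(path: str | Path) -> list[RepeatHit]:
    """Read repeat hits from either format.

    Simplified TSV (7 columns, optional header): seq_id, start, end,
    repeat_class, matches, mismatches, pct_divergence (blank allowed).
    RepeatMasker ``.out``: whitespace-separated 14+ columns after a
    3-line header; the %div column takes precedence, with
    matches/mismatches synthesized from the hit length so the accounting
    invariant holds.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    if _looks_like_rm_out(lines[0]):
        return _parse_rm_out(lines, path)
    return _parse_simple_tsv(lines, path)


def _looks_like_rm_out(first_line: str) -> bool:
    toks = first_line.split()
    # .out header starts "SW perc perc perc query ..." or a data line
    # whose first field is a numeric Smith-Waterman score
    return toks[:2] == ["SW", "perc"] or (
        len(toks) >= 14 and toks[0].isdigit() and "\t" not in first_line
    )


def _parse_rm_out(lines: list[str], path: Path) -> list[RepeatHit]:
    hits = []
    for ln in lines:
        toks = ln.split()
        if not toks or not toks[0].isdigit():
            continue  # header/banner lines
        pct_div = float(toks[1])
        seq_id = toks[4]
        start = int(toks[5]) - 1  # .out is 1-based inclusive
        end = int(toks[6])
        repeat_class = toks[10].split("/")[0]
        length = end - start
        mism = int(round(pct_div / 100.0 * length))
        hits.append(RepeatHit(seq_id, start, end, repeat_class,
                              matches=max(length - mism, 1), mismatches=mism,
                              div_override=pct_div / 100.0))
    return hits


def _parse_simple_tsv(lines: list[str], path: Path) -> list[RepeatHit]:
    hits = []
    for ln in lines:
        parts = ln.split("\t")
        if parts[0].lower() in {"seq_id", "seqid"}:
            continue  # header
        if len(parts) < 6:
            raise InputError(f"{path}: expected >=6 tab-separated columns")
        div = None
        if len(parts) >= 7 and parts[6].strip():
            div = float(parts[6]) / 100.0
        hits.append(RepeatHit(parts[0], int(parts[1]), int(parts[2]), parts[3],
                              matches=int(parts[4]), mismatches=int(parts[5]),
                              div_override=div))
    return hits


def write_repeat_hits(hits: Iterable[RepeatHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\trepeat_class\tmatches\tmismatches\t"
                 "pct_divergence\n")
        for h in hits:
            div = "" if h.div_override is None else f"{h.div_override * 100:.2f}"
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.repeat_class}\t"
                     f"{h.matches}\t{h.mismatches}\t{div}\n")


def repeat_table(reports: Iterable[RepeatReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"Assembly name": r.assembly_name,
               "% Masked": round(r.pct_masked, 2)}
        for c, pct in r.pct_by_class.items():
            row[f"% {c}s"] = round(pct, 2)
        row["Mean divergence"] = (round(r.mean_divergence * 100, 2)
                                  if r.mean_divergence is not None else "")
        rows.append(row)
    return pd.DataFrame(rows)


def busco_table(tables: Iterable[OrthologStatusTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        summ = busco_summary(t)
        row: dict[str, object] = {"Assembly name": t.assembly_name,
                                  "Total orthologs": t.total_orthologs}
        for cat in CATEGORIES:
            n, pct = summ[cat]
            row[cat.capitalize()] = n
            row[f"% {cat}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def write_status_tables(tables: Iterable[OrthologStatusTable],
                        directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tables:
        p = directory / f"busco_{t.assembly_name}.tsv"
        with open(p, "w") as fh:
            fh.write("# ortholog_id\tstatus\n")
            for oid in sorted(t.status):
                word = {"single": "Complete"}.get(t.status[oid],
                                                  t.status[oid].capitalize())
                fh.write(f"{oid}\t{word}\n")
        paths.append(p)
    return paths
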
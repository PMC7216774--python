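"""Coverage-based accuracy accounting.

An assembly base is called *error-free* when it is covered by at least
``min_cov`` (default 5) perfectly-and-uniquely mapped read pairs.
Suspected misassemblies appear as sustained collapses of that coverage;
a simple dropout detector flags maximal runs of at least ``min_run``
consecutive low-coverage bases, and the assembly is broken at those
intervals.  The contrast between N50 before and after breaking — the
percent N50 reduction, the break count relative to a baseline assembly,
and a summary score combining accuracy with contiguity — quantifies how
much apparent contiguity rests on suspect joins.

The dropout detector is a declared simplification: production
evaluators flag misassemblies from the full fragment-coverage
distribution (FCD) statistic, which this module does not model.  FCD
error counts can be ingested from such a tool and carried through the
reports unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from asmeval.contiguity import Assembly, SequenceRecord, nx
from asmeval.errors import ConsistencyError

log = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-base perfect-and-unique read coverage for one sequence."""

    seq_id: str
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=np.int64)
        if (self.cov < 0).any():
            raise ValueError(f"negative coverage in track {self.seq_id!r}")

    def __len__(self) -> int:
        return int(self.cov.size)


@dataclass
class AccuracyReport:
    """One assembly's accuracy row: error-free bases, N50 before/after
    breaking, percent reduction (integer, half-up), break count, an
    optionally ingested FCD error count, and the summary score
    error_free_bases * broken_n50**2 / original_n50."""

    assembly_name: str
    error_free_bases: int
    pct_error_free: float
    original_n50: int
    broken_n50: int
    pct_reduction: int
    breaks: int
    summary_score: float
    fcd_errors: int | None = None


@dataclass
class BreakComparison:
    """Break accounting for one assembly against a baseline assembly."""

    assembly_name: str
    sequences_before: int
    sequences_after: int
    breaks: int
    baseline_breaks: int
    excess_breaks: int


def count_error_free_bases(tracks: Iterable[CoverageTrack],
                           min_cov: int = 5,
                           assembly: Assembly | None = None,
                           ) -> tuple[int, float]:
    """Count bases with coverage >= ``min_cov`` and the percent of all
    bases they represent.

    If ``assembly`` is given, each track length is checked against its
    sequence.
    """
    by_id = {r.id: r.length for r in assembly.records} if assembly else None
    total = 0
    good = 0
    for t in tracks:
        if by_id is not None:
            expect = by_id.get(t.seq_id)
            if expect is None:
                raise ConsistencyError(f"track {t.seq_id!r} has no assembly sequence")
            if expect != len(t):
                raise ConsistencyError(
                    f"track {t.seq_id!r} length {len(t)} != sequence length {expect}"
                )
        total += len(t)
        good += int((t.cov >= min_cov).sum())
    pct = 100.0 * good / total if total else 0.0
    return good, pct


def detect_breakpoints(track: CoverageTrack, min_cov: int = 5,
                       min_run: int = 100) -> list[tuple[int, int]]:
    """Maximal runs of >= ``min_run`` consecutive bases with coverage
    below ``min_cov``, as 0-based half-open intervals."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    low = track.cov < min_cov
    if not low.any():
        return []
    # run boundaries from the padded difference of the boolean mask
    edges = np.flatnonzero(np.diff(np.r_[False, low, False].astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= min_run
    return [(int(s), int(e)) for s, e in zip(starts[keep], ends[keep])]


def break_assembly(a: Assembly,
                   breakpoints: Mapping[str, Sequence[tuple[int, int]]],
                   ) -> Assembly:
    """Cut each sequence at its breakpoint intervals, dropping the
    interval content itself (the junction sequence is the suspect part).

    Intervals must lie within bounds and not overlap per sequence.
    Zero-length fragments (an interval touching a sequence end) are
    discarded.
    """
    out: list[SequenceRecord] = []
    for rec in a.records:
        ivs = sorted(breakpoints.get(rec.id, ()))
        if not ivs:
            out.append(rec)
            continue
        prev_end = -1
        for s, e in ivs:
            if not (0 <= s < e <= rec.length):
                raise ValueError(
                    f"interval ({s}, {e}) out of bounds for {rec.id!r} "
                    f"of length {rec.length}"
                )
            if s < prev_end:
                raise ValueError(f"overlapping intervals on {rec.id!r}")
            prev_end = e
        pieces = []
        pos = 0
        for s, e in ivs:
            pieces.append(rec.seq[pos:s])
            pos = e
        pieces.append(rec.seq[pos:])
        for i, piece in enumerate(p for p in pieces if p):
            out.append(SequenceRecord(f"{rec.id}.b{i + 1}", piece))
    return Assembly(name=a.name, records=out, provenance=a.provenance)


def reapr_breaks(sequences_before: int, sequences_after: int) -> int:
    """Number of breaks: extra sequences created by breaking."""
    if sequences_after < sequences_before:
        raise ConsistencyError(
            f"sequences_after ({sequences_after}) < sequences_before "
            f"({sequences_before})"
        )
    return sequences_after - sequences_before


def excess_breaks(breaks: int, baseline_breaks: int) -> int:
    """Breaks beyond those the baseline assembly itself accrued.

    May be negative when scaffolding merged sequences; that is reported
    with a warning rather than an error.
    """
    diff = breaks - baseline_breaks
    if diff < 0:
        warnings.warn(
            f"negative excess breaks ({diff}): fewer breaks than baseline",
            stacklevel=2,
        )
    return diff


def percent_reduction(original_n50: int, broken_n50: int) -> int:
    """Integer percent decrease in N50 after breaking, rounded half-up."""
    if original_n50 <= 0:
        raise ValueError("original_n50 must be > 0")
    if broken_n50 > original_n50:
        raise ValueError("broken_n50 cannot exceed original_n50")
    pct = Decimal(100) * (Decimal(str(original_n50)) - Decimal(str(broken_n50))) \
        / Decimal(str(original_n50))
    return int(pct.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def summary_score(error_free_bases: int, broken_n50: int,
                  original_n50: int) -> float:
    """error_free_bases * broken_n50**2 / original_n50.

    Rewards local accuracy and contiguity that survives breaking while
    penalising contiguity built on suspect joins.
    """
    if original_n50 <= 0:
        raise ValueError("original_n50 must be > 0")
    return error_free_bases * float(broken_n50) ** 2 / original_n50


def accuracy_report(a: Assembly, tracks: Sequence[CoverageTrack],
                    min_cov: int = 5, min_run: int = 100,
                    fcd_errors: int | None = None) -> AccuracyReport:
    """End-to-end accuracy row: error-free count, dropout breakpoints,
    break the assembly, and compare N50 before/after."""
    error_free, pct_ef = count_error_free_bases(tracks, min_cov=min_cov,
                                                assembly=a)
    bps = {t.seq_id: detect_breakpoints(t, min_cov=min_cov, min_run=min_run)
           for t in tracks}
    bps = {k: v for k, v in bps.items() if v}
    broken = break_assembly(a, bps)
    original_n50 = nx(a.lengths(), 50)
    broken_n50 = nx(broken.lengths(), 50) if broken.records else 0
    if broken_n50 > original_n50:
        # dropping junction content shrinks the total, which can nudge
        # the N50 statistic up a few bases even though every fragment
        # is no longer than its parent; clamp to keep the report
        # invariant broken_n50 <= original_n50
        log.warning("%s: broken N50 %d exceeds original %d by total-length "
                    "shrinkage; clamping", a.name, broken_n50, original_n50)
        broken_n50 = original_n50
    return AccuracyReport(
        assembly_name=a.name,
        error_free_bases=error_free,
        pct_error_free=pct_ef,
        original_n50=original_n50,
        broken_n50=broken_n50,
        pct_reduction=percent_reduction(original_n50, broken_n50),
        breaks=reapr_breaks(len(a), len(broken)),
        summary_score=summary_score(error_free, broken_n50, original_n50),
        fcd_errors=fcd_errors,
    )


def compare_breaks(name: str, sequences_before: int, sequences_after: int,
                   baseline_breaks: int) -> BreakComparison:
    b = reapr_breaks(sequences_before, sequences_after)
    return BreakComparison(
        assembly_name=name,
        sequences_before=sequences_before,
        sequences_after=sequences_after,
        breaks=b,
        baseline_breaks=baseline_breaks,
        excess_breaks=excess_breaks(b, baseline_breaks),
    )


# ---------------------------------------------------------------------------
# coverage track I/O: per-base TSV (seq_id, pos, cov) or BedGraph-like
# intervals (seq_id, start, end, cov)

def read_coverage_tracks(path: str | Path,
                         lengths: Mapping[str, int] | None = None,
                         ) -> list[CoverageTrack]:
    """Read coverage from TSV.

    Three columns are interpreted as per-base (seq_id, 0-based position,
    coverage); four columns as BedGraph-like half-open intervals
    (seq_id, start, end, coverage).  ``lengths`` (seq_id -> length)
    sizes each track; without it the track ends at the last covered
    base.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    tracks: list[CoverageTrack] = []
    if df.shape[1] == 3:
        df.columns = ["seq_id", "pos", "cov"]
        for seq_id, grp in df.groupby("seq_id", sort=False):
            n = lengths[seq_id] if lengths else int(grp["pos"].max()) + 1
            cov = np.zeros(n, dtype=np.int64)
            cov[grp["pos"].to_numpy()] = grp["cov"].to_numpy()
            tracks.append(CoverageTrack(str(seq_id), cov))
    elif df.shape[1] == 4:
        df.columns = ["seq_id", "start", "end", "cov"]
        for seq_id, grp in df.groupby("seq_id", sort=False):
            n = lengths[seq_id] if lengths else int(grp["end"].max())
            cov = np.zeros(n, dtype=np.int64)
            for s, e, c in grp[["start", "end", "cov"]].itertuples(index=False):
                cov[s:e] = c
            tracks.append(CoverageTrack(str(seq_id), cov))
    else:
        raise ConsistencyError(
            f"coverage file {path} must have 3 or 4 columns, found {df.shape[1]}"
        )
    return tracks


def write_coverage_tracks(tracks: Iterable[CoverageTrack],
                          path: str | Path) -> None:
    """Write tracks as BedGraph-like runs of constant coverage."""
    with open(path, "w") as fh:
        for t in tracks:
            edges = np.flatnonzero(np.r_[True, np.diff(t.cov) != 0])
            bounds = np.r_[edges, t.cov.size]
            for s, e in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{t.seq_id}\t{s}\t{e}\t{t.cov[s]}\n")


def accuracy_table(reports: Iterable[AccuracyReport]) -> pd.DataFrame:
    rows = [
        {
            "Assembly name": r.assembly_name,
            "% error-free": round(r.pct_error_free, 2),
            "Original N50": r.original_n50,
            "Broken N50": r.broken_n50,
            "% reduction": r.pct_reduction,
            "Breaks": r.breaks,
            "FCD errors": r.fcd_errors if r.fcd_errors is not None else "",
            "Summary score": r.summary_score,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def break_table(comparisons: Iterable[BreakComparison]) -> pd.DataFrame:
    rows = [
        {
            "Assembly name": c.assembly_name,
            "Assembled sequences": c.sequences_before,
            "No. sequences after breaking": c.sequences_after,
            "Breaks": c.breaks,
            "Excess breaks": c.excess_breaks,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)
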
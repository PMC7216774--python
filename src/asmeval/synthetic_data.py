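"""Synthetic genomes, assemblies, reads and evaluation tables.

The generators plant a known truth so every pipeline stage can be
validated by parameter recovery:

* a random genome with controlled GC content;
* an assembly built by cutting the genome into contigs and re-joining
  them into scaffolds with N-gap runs, where a configurable subset of
  joins is deliberately *incorrect* (non-adjacent or cross-chromosome
  contigs joined) and every junction is recorded in a truth table;
* shotgun reads with a stated substitution error rate;
* per-base coverage tracks that are Poisson around a mean everywhere
  except at incorrect joins, where coverage collapses to zero — the
  signature a perfect-unique-coverage evaluator keys on;
* per-ortholog status tables and repeat-hit tables following a planted
  quality gradient.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from asmeval.accuracy import CoverageTrack
from asmeval.content import CATEGORIES, OrthologStatusTable, RepeatHit
from asmeval.contiguity import Assembly, SequenceRecord

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome

@dataclass
class GenomeSimParams:
    chromosome_lengths: Sequence[int] = (500_000, 500_000)
    gc: float = 0.42  # mammal-like
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)


def simulate_genome(p: GenomeSimParams) -> list[SequenceRecord]:
    """IID random genome at the requested GC content."""
    rng = np.random.default_rng(p.seed)
    at = (1.0 - p.gc) / 2.0
    gc = p.gc / 2.0
    probs = [at, gc, gc, at]  # A C G T
    records = []
    for i, length in enumerate(p.chromosome_lengths, start=1):
        idx = rng.choice(4, size=length, p=probs)
        seq = _BASES[idx].tobytes().decode("ascii")
        records.append(SequenceRecord(f"chr{i}", seq))
    return records


# ---------------------------------------------------------------------------
# assembly with planted misassemblies

@dataclass
class AssemblySimParams:
    """Controls for cutting a genome into contigs and re-scaffolding.

    Contig lengths are uniform on [0.5, 1.5] x ``mean_fragment_length``.
    Either ``n_misassemblies`` (exact planted count, spread uniformly
    over join opportunities) or ``misassembly_rate`` (per-join Bernoulli
    corruption) selects the incorrect joins; scaffolds never join
    across a chromosome boundary except through a planted error, and a
    scaffold ends one contig after a planted error, so incorrect
    junctions are always at least half a fragment length apart and away
    from scaffold ends.  Gap runs are uniform on ``gap_range`` (default
    25-500, so every join is visible to gap-based contig breaking; pass
    a sub-25 range to exercise the unbroken branch).
    """

    mean_fragment_length: int = 5000
    contigs_per_scaffold: int = 8
    n_misassemblies: int | None = None
    misassembly_rate: float | None = None
    gap_range: tuple[int, int] = (25, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.misassembly_rate is not None and not (
                0.0 <= self.misassembly_rate <= 1.0):
            raise ValueError("misassembly_rate must lie in [0, 1]")
        if self.n_misassemblies is not None and self.misassembly_rate is not None:
            raise ValueError(
                "give n_misassemblies or misassembly_rate, not both")
        if self.gap_range[0] < 1 or self.gap_range[0] > self.gap_range[1]:
            raise ValueError("invalid gap_range")
        if self.contigs_per_scaffold < 2:
            raise ValueError("contigs_per_scaffold must be >= 2")


@dataclass(frozen=True)
class Join:
    """One junction inside a scaffold: the incoming contig starts at
    ``offset`` (0-based, immediately after the gap run)."""

    scaffold_id: str
    offset: int
    left_contig: str
    right_contig: str
    correct: bool


@dataclass
class TruthTable:
    joins: list[Join] = field(default_factory=list)

    @property
    def planted_misassemblies(self) -> int:
        return sum(1 for j in self.joins if not j.correct)

    def incorrect_joins(self) -> list[Join]:
        return [j for j in self.joins if not j.correct]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_misassemblies": self.planted_misassemblies,
            "joins": [asdict(j) for j in self.joins],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        data = json.loads(Path(path).read_text())
        return cls(joins=[Join(**j) for j in data["joins"]])


@dataclass(frozen=True)
class _Contig:
    chrom: str
    ordinal: int  # position along the chromosome
    seq: str


def _cut_genome(genome: Sequence[SequenceRecord], p: AssemblySimParams,
                rng: np.random.Generator) -> list[_Contig]:
    lo = max(2, int(0.5 * p.mean_fragment_length))
    hi = int(1.5 * p.mean_fragment_length)
    contigs = []
    for rec in genome:
        pos = 0
        ordinal = 0
        while pos < rec.length:
            length = int(rng.integers(lo, hi + 1))
            piece = rec.seq[pos:pos + length]
            # fold a runt tail into the previous contig
            if len(piece) < lo and contigs and contigs[-1].chrom == rec.id:
                last = contigs.pop()
                contigs.append(_Contig(last.chrom, last.ordinal,
                                       last.seq + piece))
            else:
                contigs.append(_Contig(rec.id, ordinal, piece))
                ordinal += 1
            pos += length
    return contigs


def _adjacent(a: _Contig, b: _Contig) -> bool:
    return a.chrom == b.chrom and b.ordinal == a.ordinal + 1


def simulate_assembly(genome: Sequence[SequenceRecord],
                      p: AssemblySimParams,
                      name: str = "sim") -> tuple[Assembly, TruthTable]:
    """Cut the genome into contigs and join them into gapped scaffolds,
    planting incorrect joins per the parameters; every junction is
    recorded in the returned truth table with its realized correctness
    (genome adjacency of the two joined contigs)."""
    rng = np.random.default_rng(p.seed)
    contigs = _cut_genome(genome, p, rng)
    if len(contigs) < 2:
        raise ValueError("fragment length too large: fewer than 2 contigs")
    queue = deque(contigs)
    n_scaffolds_est = -(-len(contigs) // p.contigs_per_scaffold)

    if p.n_misassemblies is not None and p.n_misassemblies > n_scaffolds_est - 1:
        raise ValueError(
            f"cannot place {p.n_misassemblies} misassemblies in "
            f"~{n_scaffolds_est - 1} eligible scaffolds (one per scaffold)")
    k_remaining = p.n_misassemblies or 0

    records: list[SequenceRecord] = []
    truth = TruthTable()
    scaffold_idx = 0
    while queue:
        scaffold_idx += 1
        sid = f"scaffold_{scaffold_idx}"
        parts = [queue.popleft()]
        length = len(parts[0].seq)
        pieces = [parts[0].seq]
        n_joins = min(p.contigs_per_scaffold, len(queue) + 1) - 1
        for slot in range(n_joins):
            if not queue:
                break
            if p.n_misassemblies is not None:
                # sequential-uniform placement of the k planted errors
                # over the remaining join opportunities, forced while
                # >= 2 contigs remain (the final contig cannot host one)
                est_rem = max(1, len(queue) - 2)
                corrupt = (k_remaining > 0 and len(queue) > 1
                           and (est_rem <= k_remaining
                                or rng.random() < k_remaining / est_rem))
            else:
                rate = p.misassembly_rate or 0.0
                corrupt = len(queue) > 1 and rng.random() < rate
            if corrupt:
                nxt = _pop_non_adjacent(queue, parts[-1], rng,
                                        from_tail=p.n_misassemblies is not None)
                k_remaining -= 1
            else:
                if not _adjacent(parts[-1], queue[0]):
                    break  # chromosome boundary: start a new scaffold
                nxt = queue.popleft()
            gap = int(rng.integers(p.gap_range[0], p.gap_range[1] + 1))
            pieces.append("N" * gap)
            offset = length + gap
            truth.joins.append(Join(
                scaffold_id=sid,
                offset=offset,
                left_contig=f"{parts[-1].chrom}:{parts[-1].ordinal}",
                right_contig=f"{nxt.chrom}:{nxt.ordinal}",
                correct=_adjacent(parts[-1], nxt),
            ))
            pieces.append(nxt.seq)
            parts.append(nxt)
            length = offset + len(nxt.seq)
        records.append(SequenceRecord(sid, "".join(pieces)))
    if k_remaining > 0:
        raise ValueError(
            f"could not place {k_remaining} of {p.n_misassemblies} planted "
            "misassemblies; use smaller fragments or fewer errors")
    return Assembly(name=name, records=records), truth


def _pop_non_adjacent(queue: deque, last: _Contig,
                      rng: np.random.Generator, from_tail: bool) -> _Contig:
    """Remove and return a queue contig that is not the genome successor
    of ``last``; preferring the tail keeps the adjacency chain of the
    remaining queue intact."""
    if from_tail:
        candidates = [len(queue) - 1, len(queue) - 2, 0]
    else:
        candidates = rng.permutation(len(queue)).tolist()
    for j in candidates:
        if j < 0 or j >= len(queue):
            continue
        if not _adjacent(last, queue[j]):
            c = queue[j]
            del queue[j]
            return c
    return queue.pop()  # all candidates adjacent (tiny queues): give up


# ---------------------------------------------------------------------------
# reads

def simulate_reads(genome: Sequence[SequenceRecord], coverage: float = 30.0,
                   read_len: int = 150, error_rate: float = 0.01,
                   seed: int = 0) -> list[SequenceRecord]:
    """Uniform single-end shotgun reads with IID substitution errors."""
    if any(read_len > rec.length for rec in genome):
        raise ValueError("read_len exceeds a chromosome length")
    rng = np.random.default_rng(seed)
    total = sum(rec.length for rec in genome)
    n_reads = int(round(coverage * total / read_len))
    weights = np.array([rec.length for rec in genome], dtype=float)
    chrom_choice = rng.choice(len(genome), size=n_reads, p=weights / weights.sum())
    lengths = np.array([rec.length for rec in genome])
    # positions drawn up front so the sampling layout is independent of
    # the error rate (same seed, same read placements)
    starts = rng.integers(0, lengths[chrom_choice] - read_len + 1)
    reads = []
    for i in range(n_reads):
        rec = genome[int(chrom_choice[i])]
        start = int(starts[i])
        seq = rec.seq[start:start + read_len]
        if error_rate > 0:
            n_err = rng.binomial(read_len, error_rate)
            if n_err:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                pos = rng.choice(read_len, size=n_err, replace=False)
                for j in pos:
                    choices = _BASES[_BASES != arr[j]]
                    arr[j] = rng.choice(choices)
                seq = arr.tobytes().decode("ascii")
        reads.append(SequenceRecord(f"read_{i}", seq))
    return reads


def write_fastq(reads: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * r.length}\n")


# ---------------------------------------------------------------------------
# coverage tracks

def simulate_coverage_tracks(a: Assembly, truth: TruthTable,
                             mean_cov: float = 30.0,
                             dropout_halfwidth: int = 200,
                             seed: int = 0) -> list[CoverageTrack]:
    """Poisson(mean_cov) coverage per base, collapsed to zero within
    +- ``dropout_halfwidth`` of every incorrect join.

    Gap (N) bases receive the same Poisson coverage as sequence bases:
    the track emulates fragment-spanning perfect-unique coverage, whose
    informative signal here is the planted collapse at bad joins.
    """
    if dropout_halfwidth < 1:
        raise ValueError("dropout_halfwidth must be >= 1")
    rng = np.random.default_rng(seed)
    bad_by_scaffold: dict[str, list[int]] = {}
    for j in truth.incorrect_joins():
        bad_by_scaffold.setdefault(j.scaffold_id, []).append(j.offset)
    tracks = []
    for rec in a.records:
        cov = (rng.poisson(mean_cov, size=rec.length) if mean_cov > 0
               else np.zeros(rec.length, dtype=np.int64))
        for off in bad_by_scaffold.get(rec.id, ()):
            cov[max(0, off - dropout_halfwidth):
                min(rec.length, off + dropout_halfwidth)] = 0
        tracks.append(CoverageTrack(rec.id, cov))
    return tracks


# ---------------------------------------------------------------------------
# ortholog status and repeat-hit tables

def simulate_status_tables(n_assemblies: int, total_orthologs: int = 4104,
                           quality: Sequence[float] | None = None,
                           seed: int = 0,
                           names: Sequence[str] | None = None,
                           ) -> list[OrthologStatusTable]:
    """Per-assembly ortholog status tables over a shared id universe.

    ``quality`` gives each assembly's probability that an ortholog is
    recovered single-copy (default: flat 0.92); the remainder splits
    20/40/40 between duplicated, fragmented and missing.
    """
    if quality is None:
        quality = [0.92] * n_assemblies
    if len(quality) != n_assemblies:
        raise ValueError("quality must have one entry per assembly")
    rng = np.random.default_rng(seed)
    ids = [f"ortho{i:05d}" for i in range(total_orthologs)]
    tables = []
    rest = np.array([0.2, 0.4, 0.4])
    for i, q in enumerate(quality):
        probs = np.r_[q, (1.0 - q) * rest]
        draws = rng.choice(4, size=total_orthologs, p=probs)
        status = {oid: CATEGORIES[d] for oid, d in zip(ids, draws)}
        name = names[i] if names else f"sim_{i + 1}"
        tables.append(OrthologStatusTable(assembly_name=name, status=status))
    return tables


def simulate_repeat_hits(a: Assembly, density: float = 0.3,
                         classes: Sequence[str] = ("SINE", "LINE"),
                         mean_divergence: float = 0.245,
                         mean_hit_length: int = 300,
                         seed: int = 0) -> list[RepeatHit]:
    """Random repeat annotations covering about ``density`` of the
    assembly, with per-hit divergences Beta-distributed around
    ``mean_divergence``."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hits: list[RepeatHit] = []
    conc = 50.0  # Beta concentration: sd ~ 0.06 around the mean
    for rec in a.records:
        n_hits = int(round(density * rec.length / mean_hit_length))
        for _ in range(n_hits):
            length = int(rng.integers(max(2, mean_hit_length // 3),
                                      mean_hit_length * 5 // 3))
            length = min(length, rec.length)
            start = int(rng.integers(0, rec.length - length + 1))
            div = float(rng.beta(mean_divergence * conc,
                                 (1 - mean_divergence) * conc))
            mism = max(1, int(round(div * length)))
            hits.append(RepeatHit(
                seq_id=rec.id, start=start, end=start + length,
                repeat_class=str(rng.choice(list(classes))),
                matches=max(1, length - mism), mismatches=mism,
            ))
    return hits


# ---------------------------------------------------------------------------
# the planted quality-gradient study

#: Study conditions for the five-assembly gradient: strictly improving
#: fragment length, misassembly rate and ortholog completeness.  All
#: five share one provenance (and hence one cost), so value-for-money
#: is a scaled broken N50.
GRADIENT_FRAGMENT_LENGTHS = (3000, 4500, 7000, 11000, 18000)
GRADIENT_MISASSEMBLY_RATES = (0.25, 0.15, 0.09, 0.045, 0.015)
GRADIENT_BUSCO_SINGLE = (0.90, 0.92, 0.94, 0.96, 0.975)


@dataclass
class GradientStudy:
    """Everything the ranking pipeline needs, plus the planted order
    (worst to best)."""

    genome: list[SequenceRecord]
    assemblies: list[Assembly]
    truths: list[TruthTable]
    tracks: list[list[CoverageTrack]]
    status_tables: list[OrthologStatusTable]
    planted_order: list[str]  # worst .. best


def simulate_gradient_study(seed: int = 0,
                            chromosome_lengths: Sequence[int] = (200_000,
                                                                 200_000),
                            mean_cov: float = 30.0,
                            dropout_halfwidth: int = 200) -> GradientStudy:
    """Five assemblies of one genome with a strict planted quality
    gradient (fragment length up, misassembly rate down, completeness
    up)."""
    rng = np.random.default_rng(seed)
    genome = simulate_genome(GenomeSimParams(
        chromosome_lengths=tuple(chromosome_lengths),
        seed=int(rng.integers(2**31))))
    assemblies, truths, tracks = [], [], []
    n = len(GRADIENT_FRAGMENT_LENGTHS)
    for i in range(n):
        asm, truth = simulate_assembly(
            genome,
            AssemblySimParams(
                mean_fragment_length=GRADIENT_FRAGMENT_LENGTHS[i],
                misassembly_rate=GRADIENT_MISASSEMBLY_RATES[i],
                seed=int(rng.integers(2**31)),
            ),
            name=f"S{i + 1}",
        )
        assemblies.append(asm)
        truths.append(truth)
        tracks.append(simulate_coverage_tracks(
            asm, truth, mean_cov=mean_cov,
            dropout_halfwidth=dropout_halfwidth,
            seed=int(rng.integers(2**31))))
    status = simulate_status_tables(
        n, quality=list(GRADIENT_BUSCO_SINGLE),
        seed=int(rng.integers(2**31)),
        names=[a.name for a in assemblies])
    return GradientStudy(
        genome=genome,
        assemblies=assemblies,
        truths=truths,
        tracks=tracks,
        status_tables=status,
        planted_order=[a.name for a in assemblies],
    )


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
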
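"""Generate the synthetic evaluation study.

Simulates one genome and five assemblies of it with a strict planted
quality gradient (rising fragment length and ortholog completeness,
falling misassembly rate), plus coverage tracks with dropout at every
planted misassembly, per-ortholog status tables, repeat annotations and
an error-free read set.  Raw data land in scratch/sim/ (large,
regenerable); the downstream drivers read from there.

Run:  python analysis/01_simulate.py [--seed 0]
"""

import argparse
from pathlib import Path

import numpy as np

from asmeval.accuracy import write_coverage_tracks
from asmeval.content import write_status_tables
from asmeval.synthetic_data import (
    simulate_gradient_study,
    simulate_reads,
    simulate_repeat_hits,
    write_fasta,
    write_fastq,
)
from asmeval.content import write_repeat_hits

OUT = Path("scratch/sim")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    OUT.mkdir(parents=True, exist_ok=True)

    study = simulate_gradient_study(seed=int(rng.integers(2**31)))
    write_fasta(study.genome, OUT / "genome.fasta")
    for asm, truth, tracks in zip(study.assemblies, study.truths,
                                  study.tracks):
        write_fasta(asm.records, OUT / f"{asm.name}.fasta")
        truth.to_json(OUT / f"{asm.name}.truth.json")
        write_coverage_tracks(tracks, OUT / f"{asm.name}.coverage.tsv")
        hits = simulate_repeat_hits(asm, density=0.3,
                                    seed=int(rng.integers(2**31)))
        write_repeat_hits(hits, OUT / f"{asm.name}.repeats.tsv")
        print(f"{asm.name}: {len(asm)} scaffolds, "
              f"{truth.planted_misassemblies} planted misassemblies")
    write_status_tables(study.status_tables, OUT)

    reads = simulate_reads(study.genome, coverage=8, read_len=150,
                           error_rate=0.01, seed=int(rng.integers(2**31)))
    write_fastq(reads, OUT / "reads.fastq")
    print(f"wrote {len(reads)} reads and 5 assemblies to {OUT}")


if __name__ == "__main__":
    main()
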
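"""Read-vs-assembly k-mer spectra.

Compares the 31-mer content of the simulated read set against the best
and worst assemblies: the copy-number-partitioned multiplicity matrix
and the solid read content (multiplicity >= 3) absent from each
assembly.

Run after 01_simulate.py:  python analysis/04_kmer_spectra.py
"""

from pathlib import Path

from asmeval.contiguity import read_assembly
from asmeval.kmer_spectra import (
    count_kmers,
    missing_content,
    read_sequences,
    spectra_matrix,
    write_matrix,
)

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reads = read_sequences(SIM / "reads.fastq")
    read_map = count_kmers(reads, k=31)
    print(f"{read_map.n_distinct:,} distinct read 31-mers")
    for name in ("S1", "S5"):
        a = read_assembly(SIM / f"{name}.fasta", name=name)
        asm_map = count_kmers((r.seq for r in a.records), k=31)
        m = spectra_matrix(read_map, asm_map, max_mult=60)
        n_missing, frac = missing_content(m, min_mult=3)
        write_matrix(m, RESULTS / f"spectra_{name}.tsv")
        print(f"{name}: {n_missing:,} solid read k-mers missing "
              f"({100 * frac:.3f}% of distinct read k-mers); "
              f"{m.assembly_only:,} assembly-only k-mers")
    print(f"wrote spectra matrices to {RESULTS}")


if __name__ == "__main__":
    main()
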
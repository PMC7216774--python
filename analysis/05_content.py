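"""Completeness and repeat-content summaries.

Per-assembly ortholog category counts/percentages, the cross-assembly
intersection (orthologs single-copy in every assembly), and the
repeat-masking summary (percent masked, per-class percentages, mean
divergence).

Run after 01_simulate.py:  python analysis/05_content.py
"""

from pathlib import Path

from asmeval.content import (
    busco_summary,
    busco_table,
    read_busco_table,
    read_repeat_hits,
    repeat_report,
    repeat_table,
    status_intersections,
)
from asmeval.contiguity import read_assembly

SIM = Path("scratch/sim")
RESULTS = Path("results")
NAMES = ["S1", "S2", "S3", "S4", "S5"]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tables = [read_busco_table(SIM / f"busco_{n}.tsv", assembly_name=n)
              for n in NAMES]
    busco_table(tables).to_csv(RESULTS / "busco_summary.tsv", sep="\t",
                               index=False)
    for t in tables:
        n, pct = busco_summary(t)["single"]
        print(f"{t.assembly_name}: {n:,} single-copy orthologs ({pct}%)")
    inter = status_intersections(tables)
    print(f"single-copy in every assembly: {inter['single']:,} of "
          f"{tables[0].total_orthologs:,}")

    reports = []
    for n in NAMES:
        a = read_assembly(SIM / f"{n}.fasta", name=n)
        hits = read_repeat_hits(SIM / f"{n}.repeats.tsv")
        reports.append(repeat_report(hits, assembly_size=a.total_size,
                                     assembly_name=n))
    repeat_table(reports).to_csv(RESULTS / "repeats.tsv", sep="\t",
                                 index=False)
    r = reports[0]
    print(f"{r.assembly_name}: {r.pct_masked:.1f}% masked, mean divergence "
          f"{100 * r.mean_divergence:.2f}")
    print(f"wrote {RESULTS / 'busco_summary.tsv'} and "
          f"{RESULTS / 'repeats.tsv'}")


if __name__ == "__main__":
    main()
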
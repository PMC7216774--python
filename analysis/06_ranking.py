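"""Assemble the seven-metric table and rank the assemblies.

Builds scaffold N50, broken scaffold N50, contig N50, percent of the
genome in gene-sized scaffolds, single-copy ortholog count, the
accuracy summary score and broken-N50 per $1,000 for every simulated
assembly, then produces rank-score totals and cumulative z-scores with
leave-one-metric-out error bounds (plus a dot plot).

Run after 01_simulate.py:  python analysis/06_ranking.py
"""

from pathlib import Path

import pandas as pd

from asmeval.accuracy import accuracy_report, read_coverage_tracks
from asmeval.content import busco_summary, read_busco_table
from asmeval.contiguity import contiguity_report, read_assembly
from asmeval.ranking import (
    CostModel,
    assembly_cost,
    plot_cumulative_z,
    rank_assemblies,
    value_for_money,
    write_ranking,
)

SIM = Path("scratch/sim")
RESULTS = Path("results")
NAMES = ["S1", "S2", "S3", "S4", "S5"]

# placeholder prices (not measured costs); all five assemblies share one
# provenance in this study, so cost only scales the value metric
COSTS = CostModel({"pcr_free": 10_000, "lmp": 8_000}, fixed_cost=2_000)
PROVENANCE = {"pcr_free", "lmp"}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = {}
    cost = assembly_cost(PROVENANCE, COSTS)
    for name in NAMES:
        a = read_assembly(SIM / f"{name}.fasta", name=name)
        crep = contiguity_report(a)
        tracks = read_coverage_tracks(
            SIM / f"{name}.coverage.tsv",
            lengths={r.id: r.length for r in a.records})
        arep = accuracy_report(a, tracks)
        busco = read_busco_table(SIM / f"busco_{name}.tsv",
                                 assembly_name=name)
        rows[name] = {
            "scaffold_n50": crep.scaffold_n50,
            "broken_scaffold_n50": arep.broken_n50,
            "contig_n50": crep.contig_n50,
            "pct_genome_ge_25kb": crep.pct_genome_ge_gene_len,
            "single_copy_orthologs": busco_summary(busco)["single"][0],
            "summary_score": arep.summary_score,
            "broken_n50_per_1000": value_for_money(arep.broken_n50, cost),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.to_csv(RESULTS / "metric_table.tsv", sep="\t")
    rr, zr = rank_assemblies(table)
    write_ranking(rr, zr, RESULTS)
    plot_cumulative_z(zr, RESULTS / "cumulative_z.png")

    print("rank totals (best first):")
    for name, total in rr.totals.sort_values(ascending=False).items():
        print(f"  {name}\t{total:g}")
    print("cumulative z with leave-one-metric-out bounds:")
    for name in zr.cumulative.sort_values(ascending=False).index:
        print(f"  {name}\t{zr.cumulative[name]:+.3f}  "
              f"[{zr.loo_min[name]:+.3f}, {zr.loo_max[name]:+.3f}]")
    print(f"wrote ranking tables and plot to {RESULTS}")


if __name__ == "__main__":
    main()
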
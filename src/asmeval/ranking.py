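"""Rank-score and z-score aggregation of assembly metrics.

Two complementary orderings over a metric table (assemblies x metrics):

* **Rank scores** — per metric, the best assembly among n receives
  score n, the second n-1, down to 1; ties share the mean of the
  spanned scores.  Totals across metrics are robust to any monotone
  rescaling of a metric but ignore margins.
* **z-scores** — per metric, values are standardised to
  (x - mean) / sd and summed across metrics, rewarding or penalising
  exceptional performance on any one metric.  Sensitivity to any single
  metric is bounded by recomputing the cumulative score with each
  metric left out in turn (leave-one-out min/max).

A cost model turns contiguity into a value-for-money metric,
N50 per $1,000 spent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from asmeval.errors import ConfigError

log = logging.getLogger(__name__)

#: The default seven ranking metrics.
DEFAULT_METRICS = (
    "scaffold_n50",
    "broken_scaffold_n50",
    "contig_n50",
    "pct_genome_ge_25kb",
    "single_copy_orthologs",
    "summary_score",
    "broken_n50_per_1000",
)


@dataclass
class CostModel:
    """Per-data-type sequencing costs in USD plus a fixed overhead."""

    per_data_type_cost: dict[str, float]
    fixed_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.fixed_cost < 0 or any(v < 0 for v in
                                      self.per_data_type_cost.values()):
            raise ConfigError("costs must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostModel":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(per_data_type_cost=dict(data.get("per_data_type_cost", {})),
                   fixed_cost=float(data.get("fixed_cost", 0.0)))


def assembly_cost(provenance: Iterable[str], model: CostModel) -> float:
    """Fixed cost plus the summed cost of every data type used."""
    total = model.fixed_cost
    for tag in provenance:
        if tag not in model.per_data_type_cost:
            raise ConfigError(f"no cost configured for data type {tag!r}")
        total += model.per_data_type_cost[tag]
    return total


def value_for_money(n50: float, cost: float) -> float:
    """Contiguity per unit spend: N50 per $1,000."""
    if cost <= 0:
        raise ValueError("cost must be > 0")
    return n50 / (cost / 1000.0)


@dataclass
class RankResult:
    rank_scores: pd.DataFrame  # assemblies x metrics
    totals: pd.Series  # per assembly


@dataclass
class ZResult:
    z: pd.DataFrame  # assemblies x metrics
    cumulative: pd.Series
    loo_min: pd.Series
    loo_max: pd.Series


def _validate_table(t: pd.DataFrame) -> None:
    if t.shape[0] < 2:
        raise ValueError("need at least 2 assemblies")
    if t.isna().any().any():
        raise ValueError("metric table contains missing cells")
    if t.columns.duplicated().any():
        raise ValueError("metric names must be unique")


def rank_scores(t: pd.DataFrame,
                higher_is_better: Mapping[str, bool] | None = None,
                ) -> RankResult:
    """Per-metric rank scores: best of n assemblies scores n, worst 1;
    ties take the mean of the spanned scores (so each metric's scores
    always sum to n(n+1)/2)."""
    _validate_table(t)
    hib = higher_is_better or {}
    scores = pd.DataFrame(index=t.index, columns=t.columns, dtype=float)
    for m in t.columns:
        vals = t[m].to_numpy(dtype=float)
        if not hib.get(m, True):
            vals = -vals
        scores[m] = rankdata(vals, method="average")
    return RankResult(rank_scores=scores, totals=scores.sum(axis=1))


def metric_z(values: Sequence[float], population_sd: bool = False,
             ) -> np.ndarray:
    """Standard scores (x - mean) / sd, sample sd by default.

    A degenerate metric (zero spread) standardises to all zeros, with a
    warning — it then contributes nothing to the ordering.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=0 if population_sd else 1)
    if sd == 0:
        warnings.warn("zero standard deviation; z-scores set to 0",
                      stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def zscore_table(t: pd.DataFrame,
                 higher_is_better: Mapping[str, bool] | None = None,
                 population_sd: bool = False) -> pd.DataFrame:
    """Column-wise z-scores of a metric table, sign-flipped for
    lower-is-better metrics so larger is always better."""
    _validate_table(t)
    hib = higher_is_better or {}
    z = pd.DataFrame(index=t.index, columns=t.columns, dtype=float)
    for m in t.columns:
        col = metric_z(t[m].to_numpy(), population_sd=population_sd)
        z[m] = col if hib.get(m, True) else -col
    return z


def cumulative_and_loo(z: pd.DataFrame) -> ZResult:
    """Cumulative z per assembly plus leave-one-metric-out bounds: the
    min and max cumulative score attainable by dropping any single
    metric."""
    if z.shape[1] < 2:
        raise ValueError("need at least 2 metrics for leave-one-out bounds")
    cumulative = z.sum(axis=1)
    loo = cumulative.to_numpy()[:, None] - z.to_numpy()  # drop each metric
    return ZResult(
        z=z,
        cumulative=cumulative,
        loo_min=pd.Series(loo.min(axis=1), index=z.index),
        loo_max=pd.Series(loo.max(axis=1), index=z.index),
    )


def rank_assemblies(t: pd.DataFrame,
                    higher_is_better: Mapping[str, bool] | None = None,
                    population_sd: bool = False) -> tuple[RankResult, ZResult]:
    """Convenience wrapper: rank scores and cumulative z with
    leave-one-out bounds, from one metric table."""
    rr = rank_scores(t, higher_is_better)
    zr = cumulative_and_loo(
        zscore_table(t, higher_is_better, population_sd=population_sd))
    return rr, zr


def read_metric_table(path: str | Path) -> pd.DataFrame:
    """Metric table TSV: first column assembly names, remaining columns
    metrics."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ranking(rr: RankResult, zr: ZResult, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rr.rank_scores.assign(total=rr.totals).to_csv(
        directory / "rank_scores.tsv", sep="\t")
    zr.z.assign(cumulative=zr.cumulative, loo_min=zr.loo_min,
                loo_max=zr.loo_max).to_csv(
        directory / "z_scores.tsv", sep="\t")


def plot_cumulative_z(zr: ZResult, path: str | Path,
                      title: str = "Cumulative z-scores") -> None:
    """Dot plot of cumulative z with leave-one-metric-out error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = zr.cumulative.sort_values(ascending=False).index
    y = zr.cumulative[order]
    fig, ax = plt.subplots(figsize=(7, 4))
    # the min-max leave-one-out band need not bracket the cumulative
    # point, so draw it as a segment rather than symmetric error bars
    ax.vlines(range(len(order)), zr.loo_min[order], zr.loo_max[order],
              color="grey", lw=2)
    ax.plot(range(len(order)), y.to_numpy(), "o", color="black")
    ax.set_xticks(range(len(order)), order, rotation=45, ha="right")
    ax.set_ylabel("cumulative z-score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
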
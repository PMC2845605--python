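"""RNA-seq versus two-color microarray fold-change comparison.

Both platforms are reduced to one log2 fold change per gene between two
conditions: for RNA-seq, ``f = log2(rpkm_A / rpkm_B)`` (genes with zero
RPKM in either condition are excluded); for the array, a gene's probes are
aggregated by one of three rules — the *mean* of all probe log2 ratios,
their *median*, or the *best* probe, i.e. the one whose value is closest
to the RNA-seq fold change.  Agreement is quantified with Spearman's rho,
overall and in 2000-bp gene-length bins, because the sampling variance of
the RNA-seq fold change shrinks with gene length (longer genes collect
more reads at a given expression level), so cross-platform correlation is
expected to rise with length.

The best-probe rule uses the RNA-seq value as its reference and therefore
inflates the correlation by construction; reports carry a warning to that
effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeMeasurement",
    "CorrelationReport",
    "load_probe_table",
    "rnaseq_log2fc",
    "aggregate_probes",
    "aggregate_probe_table",
    "spearman_rho",
    "correlation_by_length_bin",
    "AGGREGATION_METHODS",
    "BEST_PROBE_WARNING",
]

logger = logging.getLogger(__name__)

AGGREGATION_METHODS = ("mean", "median", "best")
DEFAULT_BIN_WIDTH = 2000
BEST_PROBE_WARNING = (
    "best-probe aggregation selects the probe closest to the RNA-seq value "
    "and therefore inflates the cross-platform correlation by construction"
)


@dataclass(frozen=True)
class ProbeMeasurement:
    """One microarray probe: gene assignment and log2 ratio (A vs B)."""

    probe_id: str
    gene_id: str
    log2_ratio: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_ratio):
            raise ValueError(f"probe {self.probe_id}: non-finite log2 ratio")


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman rho for one aggregation method and one gene-length bin."""

    method: str
    bin_lo: float
    bin_hi: float
    rho: float
    n: int


def load_probe_table(path) -> list[ProbeMeasurement]:
    """Read a probe table TSV with columns probe_id, gene_id, log2_ratio."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    return [
        ProbeMeasurement(str(p), str(g), float(m))
        for p, g, m in df[cols].itertuples(index=False)
    ]


def rnaseq_log2fc(
    rpkm_a: Mapping[str, float] | pd.Series,
    rpkm_b: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Per-gene log2(rpkm_A / rpkm_B) for genes expressed in both samples.

    Genes with zero RPKM in either sample are excluded (count logged).
    """
    a = pd.Series(rpkm_a, dtype=float)
    b = pd.Series(rpkm_b, dtype=float)
    a, b = a.align(b, join="inner")
    keep = (a > 0) & (b > 0)
    excluded = int((~keep).sum())
    if excluded:
        logger.info("rnaseq_log2fc: excluded %d genes with zero RPKM", excluded)
    return np.log2(a[keep] / b[keep])


def aggregate_probes(
    probe_values: Sequence[float],
    method: str,
    rnaseq_value: float | None = None,
) -> float:
    """Reduce one gene's probe log2 ratios to a single value.

    ``mean``/``median`` over the probe values; ``best`` picks the probe
    minimizing ``|m - f|`` against the gene's RNA-seq log2 fold change *f*
    (ties broken toward the smaller probe value).
    """
    if len(probe_values) == 0:
        raise ValueError("gene has no probes")
    vals = np.asarray(probe_values, dtype=float)
    if method == "mean":
        return float(vals.mean())
    if method == "median":
        return float(np.median(vals))
    if method == "best":
        if rnaseq_value is None:
            raise ValueError("best-probe aggregation needs the RNA-seq value")
        order = sorted(vals, key=lambda m: (abs(m - rnaseq_value), m))
        return float(order[0])
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_probe_table(
    probes: Sequence[ProbeMeasurement],
    log2fc: pd.Series,
    gene_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-gene table of RNA-seq f and the three array aggregates.

    Restricted to genes that have a defined RNA-seq fold change, at least
    one probe, and a known length — identically for all three methods, so
    n is equal across methods.
    """
    by_gene: dict[str, list[float]] = {}
    for p in probes:
        by_gene.setdefault(p.gene_id, []).append(p.log2_ratio)
    rows = []
    for gid, f in log2fc.items():
        if gid not in by_gene or gid not in gene_lengths:
            continue
        vals = by_gene[gid]
        rows.append(
            (
                gid,
                f,
                aggregate_probes(vals, "mean"),
                aggregate_probes(vals, "median"),
                aggregate_probes(vals, "best", rnaseq_value=f),
                gene_lengths[gid],
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "f", "a_mean", "a_median", "a_best", "length"]
    ).set_index("gene_id")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")  # zero rank variance
    res = stats.spearmanr(x, y)
    return float(res.statistic)


def correlation_by_length_bin(
    table: pd.DataFrame,
    bin_width: int = DEFAULT_BIN_WIDTH,
    short_cut: int = 2000,
    long_cut: int = 10000,
    min_n: int = 10,
) -> dict:
    """Spearman rho per aggregation method, overall and by gene length.

    *table* is the output of :func:`aggregate_probe_table`.  Length bins
    are ``(lo, lo + bin_width]`` up to the largest populated cutpoint,
    with an open-ended top bin; bins holding fewer than *min_n* genes are
    reported with rho = NaN.  Headline subsets: genes with length
    < *short_cut* and genes with length > *long_cut*.
    """
    if table.empty:
        raise ValueError("empty comparison table")
    methods = {"mean": "a_mean", "median": "a_median", "best": "a_best"}
    overall = {
        m: spearman_rho(table["f"], table[col]) for m, col in methods.items()
    }
    max_len = int(table["length"].max())
    edges = list(range(0, max_len + bin_width, bin_width))
    reports: list[CorrelationReport] = []
    for i, lo in enumerate(edges[:-1]):
        hi = edges[i + 1]
        top = hi >= max_len  # open-ended last bin
        sel = (table["length"] > lo) & (
            (table["length"] <= hi) | (top & (table["length"] > hi))
        )
        sub = table[sel]
        for m, col in methods.items():
            if len(sub) >= max(min_n, 2):
                rho = spearman_rho(sub["f"], sub[col])
            else:
                rho = float("nan")
            reports.append(
                CorrelationReport(m, lo, math.inf if top else hi, rho, len(sub))
            )
        if top:
            break

    def subset_rho(sel: pd.Series) -> dict[str, float]:
        sub = table[sel]
        out = {}
        for m, col in methods.items():
            out[m] = (
                spearman_rho(sub["f"], sub[col]) if len(sub) >= 2 else float("nan")
            )
        return out

    return {
        "overall": overall,
        "by_bin": reports,
        "short": subset_rho(table["length"] < short_cut),
        "long": subset_rho(table["length"] > long_cut),
        "n_short": int((table["length"] < short_cut).sum()),
        "n_long": int((table["length"] > long_cut).sum()),
        "warning": BEST_PROBE_WARNING,
    }


def reports_to_frame(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.method, r.bin_lo, r.bin_hi, r.rho, r.n) for r in reports],
        columns=["method", "bin_lo", "bin_hi", "rho", "n"],
    )
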
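"""Jenks natural-breaks classification and miRNA ranking.

Each miRNA is scored by how many of its predicted targets fall in each
category gene set (angiogenesis, inflammation, cardiac tissue, ...).  Within
every category the counts are classified into ``k`` (default 4) natural
clusters by Fisher-Jenks optimization — the contiguous partition of the
sorted counts minimizing total within-class sum of squared deviations —
giving a 1 (lowest) .. k (highest) label per miRNA per category.  The
composite score, the sum of the per-category cluster labels, orders the
final ranking; the sorted count/label matrix is exported as a plain TSV
suitable for heatmap tools.

The Jenks solver is an exact O(k·m²) dynamic program over runs of equal
values (m = number of distinct values) using weighted prefix sums.  Equal
values are never split across classes, so duplicates share a label and
requesting more classes than distinct values collapses gracefully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_sets import GeneSet
from .targets import TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "JenksResult",
    "jenks_natural_breaks",
    "count_targets_by_category",
    "rank_mirnas",
    "export_heatmap_matrix",
    "read_heatmap_matrix",
]


@dataclass
class JenksResult:
    """Outcome of a natural-breaks classification.

    ``breaks`` holds the maximum value of each class, ascending; ``labels``
    gives the 1-based class index of every input value in input order;
    ``gvf`` is the goodness of variance fit, 1 - SSD_within / SSD_total
    (1.0 when the input is constant).
    """

    k: int
    breaks: list[float]
    labels: np.ndarray
    gvf: float

    @property
    def n_classes(self) -> int:
        return len(self.breaks)


def jenks_natural_breaks(values, k: int) -> JenksResult:
    """Exact Fisher-Jenks natural breaks of 1-D data into <= k classes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")

    uniq, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    m = uniq.size
    if k > m:
        logger.warning(
            "requested k=%d classes but only %d distinct values; collapsing", k, m
        )
    kk = min(k, m)

    # weighted prefix sums over distinct-value runs
    w = np.concatenate([[0.0], np.cumsum(counts)])
    s = np.concatenate([[0.0], np.cumsum(counts * uniq)])
    q = np.concatenate([[0.0], np.cumsum(counts * uniq**2)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of runs i..j inclusive (0-based)
        ww = w[j + 1] - w[i]
        ss = s[j + 1] - s[i]
        qq = q[j + 1] - q[i]
        return max(qq - ss * ss / ww, 0.0)

    INF = float("inf")
    cost = np.full((kk + 1, m), INF)
    split = np.zeros((kk + 1, m), dtype=int)
    for j in range(m):
        cost[1, j] = ssd(0, j)
    for t in range(2, kk + 1):
        for j in range(t - 1, m):
            best, arg = INF, t - 1
            for i in range(t - 1, j + 1):
                c = cost[t - 1, i - 1] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cost[t, j], split[t, j] = best, arg

    # backtrack class start indices
    starts = [0] * kk
    j = m - 1
    for t in range(kk, 1, -1):
        starts[t - 1] = split[t, j]
        j = split[t, j] - 1
    bounds = starts + [m]

    run_label = np.empty(m, dtype=int)
    breaks: list[float] = []
    for c in range(kk):
        lo, hi = bounds[c], bounds[c + 1]
        run_label[lo:hi] = c + 1
        breaks.append(float(uniq[hi - 1]))

    total = ssd(0, m - 1)
    within = cost[kk, m - 1]
    gvf = 1.0 if total == 0 else 1.0 - within / total
    return JenksResult(k=k, breaks=breaks, labels=run_label[inv], gvf=gvf)


def count_targets_by_category(
    target_sets: list[TargetSet], gene_sets: list[GeneSet]
) -> pd.DataFrame:
    """Count matrix: cell (miRNA, category) = |targets ∩ category genes|."""
    if not gene_sets:
        raise ValueError("gene set list must be non-empty")
    labels = [gs.label for gs in gene_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("gene set labels must be unique")
    names = [ts.mirna.name for ts in target_sets]
    if len(set(names)) != len(names):
        raise ValueError("target sets must be keyed by unique miRNA ids")
    data = {
        gs.label: [len(ts.genes() & gs.genes) for ts in target_sets]
        for gs in gene_sets
    }
    return pd.DataFrame(data, index=pd.Index(names, name="mirna"), dtype=int)


def rank_mirnas(counts: pd.DataFrame, k: int = 4, pooled: bool = False) -> pd.DataFrame:
    """Rank miRNAs by per-category natural-breaks cluster labels.

    Each count column is classified independently (default) into <= k
    clusters labelled 1 (lowest counts) .. k (highest); with ``pooled=True``
    a single classification of all cells supplies common break values.  The
    composite score is the sum of labels across categories; rows are sorted
    by composite descending, then total target count, then miRNA id, and
    ``rank`` is the dense rank of the composite score.
    """
    if counts.shape[1] < 1:
        raise ValueError("count matrix needs at least one category")
    label_cols = {}
    if pooled:
        pooled_breaks = jenks_natural_breaks(counts.to_numpy().ravel(), k).breaks
        for col in counts.columns:
            label_cols[f"{col}_cluster"] = (
                np.searchsorted(pooled_breaks, counts[col].to_numpy()) + 1
            ).clip(max=len(pooled_breaks))
    else:
        for col in counts.columns:
            vals = counts[col].to_numpy()
            if np.all(vals == vals[0]):
                logger.info("category %r has constant counts; all labels 1", col)
            label_cols[f"{col}_cluster"] = jenks_natural_breaks(vals, k).labels

    table = counts.copy()
    for name, lab in label_cols.items():
        table[name] = lab
    cluster_cols = list(label_cols)
    table["composite"] = table[cluster_cols].sum(axis=1)
    table["total_targets"] = counts.sum(axis=1)
    table = table.sort_values(
        by=["composite", "total_targets", "mirna"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    table["rank"] = (
        table["composite"].rank(method="dense", ascending=False).astype(int)
    )
    return table


def export_heatmap_matrix(rank_table: pd.DataFrame, path) -> None:
    """Write the ranked count/label matrix as a TSV (row labels in column 1)
    importable by matrix-heatmap viewers; round-trips via
    :func:`read_heatmap_matrix`."""
    rank_table.to_csv(path, sep="\t", index=True)


def read_heatmap_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mirna")
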
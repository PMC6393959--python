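"""Replicate-correlation QC and hierarchical sample clustering.

Correlations are squared Pearson r on log2(RPKM + 1); the headline QC
number is the mean r^2 over within-group (replicate) pairs.  Samples are
clustered agglomeratively with average linkage on the distance 1 - r and
the tree is emitted as a Newick string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import CountMatrix, SampleDesign, compute_rpkm

__all__ = ["CorrelationReport", "replicate_correlation", "cluster_samples",
           "log_expression"]


def log_expression(counts: CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """log2(RPKM + 1) expression matrix, the input of QC and clustering."""
    return np.log2(compute_rpkm(counts, lengths) + 1.0)


@dataclass
class CorrelationReport:
    """Pairwise sample r^2 matrix plus the within-replicate-group summary."""

    r2_matrix: pd.DataFrame
    pairs: pd.DataFrame           # sample_a, sample_b, group, r2
    mean_replicate_r2: float


def replicate_correlation(
    expression: pd.DataFrame, design: SampleDesign
) -> CorrelationReport:
    """Pearson r^2 between all samples; mean over within-group pairs only.

    A constant expression column has no defined correlation; its pairs are
    reported as NaN and excluded from the mean.
    """
    arr = expression.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r = np.asarray(r, dtype=float)
    const = sd == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    r2 = pd.DataFrame(r**2, index=expression.columns, columns=expression.columns)

    rows = []
    for (organ, treatment, duration), samples in design.groups().items():
        group = f"{organ}_{treatment}_{duration}h"
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                rows.append({
                    "sample_a": samples[i], "sample_b": samples[j],
                    "group": group,
                    "r2": r2.loc[samples[i], samples[j]],
                })
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "group", "r2"])
    mean_r2 = float(pairs["r2"].mean()) if len(pairs) else float("nan")
    return CorrelationReport(r2_matrix=r2, pairs=pairs,
                             mean_replicate_r2=mean_r2)


def cluster_samples(expression: pd.DataFrame) -> tuple[np.ndarray, str]:
    """Average-linkage clustering of samples on distance 1 - Pearson r.

    Returns the scipy linkage matrix and a Newick string whose branch
    lengths are the increments in merge height.  Merge order is
    deterministic; equal-distance pairs resolve to the lowest-index pair.
    """
    if expression.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    arr = expression.to_numpy(dtype=float)
    r = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.average(condensed)
    newick = _to_newick(Z, list(expression.columns))
    return Z, newick


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = render(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"
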
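"""Expression-pattern-width statistics over a transcriptome map.

Two per-gene summaries of how broadly a gene is expressed across the sample
groups of a map:

* Shannon entropy H = -sum p_i log2 p_i of the gene's expression fractions
  p_i = x_i / sum x across groups.  H ranges from 0 (expression confined to
  one group) to log2 N (perfectly uniform); it is undefined (NaN) for a
  gene with zero total expression.
* DE Score: the number of unordered pairwise group comparisons in which the
  gene is called DE.  With S groups the maximum is C(S, 2); a 79-sample map
  yields a maximum of 3081.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .de import DEThresholds, test_two_groups
from .io import CountMatrix, SampleDesign, compute_rpkm

__all__ = [
    "shannon_entropy",
    "entropy_profile",
    "pair_count",
    "de_score",
    "specificity_table",
    "entropy_histogram",
]


def shannon_entropy(expression) -> float:
    """Entropy (bits) of one gene's expression profile across groups.

    Zero entries contribute nothing (0 * log2 0 = 0); an all-zero profile
    has no pattern and returns NaN.  Negative input is rejected.
    """
    x = np.asarray(expression, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x[x > 0] / total
    p = p[p > 0]  # guard against underflow of tiny fractions
    return float(-(p * np.log2(p)).sum())


def entropy_profile(expr: pd.DataFrame) -> pd.Series:
    """Row-wise Shannon entropy of a genes x groups expression matrix."""
    arr = expr.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    totals = arr.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = arr / np.where(totals > 0, totals, 1.0)[:, None]
        h = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
    h = np.where(totals > 0, h, np.nan)
    return pd.Series(h, index=expr.index, name="H")


def pair_count(n: int) -> int:
    """Number of unordered pairs among n sample groups: n(n-1)/2."""
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def _map_groups(design_map: SampleDesign | pd.Series) -> dict[str, list[str]]:
    if isinstance(design_map, SampleDesign):
        return {f"{o}_{tr}_{t}h": s for (o, tr, t), s in design_map.groups().items()}
    groups: dict[str, list[str]] = {}
    for sid, grp in design_map.items():
        groups.setdefault(str(grp), []).append(sid)
    return groups


def de_score(
    counts: CountMatrix,
    design_map: SampleDesign | pd.Series,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.Series:
    """Per-gene count of pairwise group comparisons called DE.

    ``design_map`` is either a full SampleDesign (groups are its
    organ/treatment/duration cells) or a Series mapping sample id ->
    group label.  Every group needs >= 2 replicates.  All C(S, 2) pairs are
    tested with the same NB Wald test and thresholds as the stress contrasts.
    """
    groups = _map_groups(design_map)
    for name, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    score = pd.Series(0, index=counts.data.index, name="de_score")
    for ga, gb in combinations(sorted(groups), 2):
        res = test_two_groups(counts, groups[ga], groups[gb], thresholds)
        score += (res["status"] != "ns").astype(int)
    return score


def specificity_table(
    counts: CountMatrix,
    design_map: SampleDesign | pd.Series,
    lengths: pd.Series,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Joint per-gene table of entropy H and DE Score for one map.

    H is computed on replicate-averaged RPKM per sample group (no
    pseudocount; zero-total genes get NaN).
    """
    rpkm = compute_rpkm(counts, lengths)
    groups = _map_groups(design_map)
    group_means = pd.DataFrame(
        {name: rpkm[samples].mean(axis=1) for name, samples in sorted(groups.items())}
    )
    return pd.DataFrame(
        {
            "H": entropy_profile(group_means),
            "de_score": de_score(counts, design_map, thresholds),
        },
        index=counts.data.index,
    )


def entropy_histogram(h: pd.Series, bin_width: float = 0.3) -> pd.DataFrame:
    """Histogram counts of an entropy distribution (NaN entries dropped).

    The default bin width of 0.3 makes the first bin the low-entropy
    (organ-specific) stratum 0-0.3.
    """
    vals = h.dropna().to_numpy()
    if vals.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    top = max(np.ceil(vals.max() / bin_width) * bin_width, bin_width)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    freq, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": freq}
    )
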
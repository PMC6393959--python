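"""Fisher-exact gene-set enrichment among differentially expressed genes.

Each gene set (a transcription-factor regulon from in-vitro binding data,
or a functional category term) is tested with a right-tailed Fisher exact
test on the 2x2 table (target vs non-target) x (DE vs non-DE), with
Benjamini-Hochberg correction over the tested family.  The reported
enrichment score is log2 of %target(DE) / %target(non-DE); the fold
enrichment (a/(a+b)) / ((a+c)/N) is reported alongside for category-style
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import AnnotationSets

__all__ = [
    "ContingencyTable2x2",
    "fisher_right_tail",
    "enrichment_score",
    "fold_enrichment",
    "tf_enrichment",
    "term_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a = DE&target, b = DE&non-target, c = nonDE&target, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_right_tail(table: ContingencyTable2x2) -> float:
    """Right-tailed Fisher exact p: P(overlap >= a) under fixed margins.

    The overlap is hypergeometric with population N, (a+c) targets and
    (a+b) draws (the DE genes).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    return float(hypergeom.sf(a - 1, table.n, a + c, a + b))


def enrichment_score(table: ContingencyTable2x2) -> float:
    """log2 of %target among DE genes over %target among non-DE genes.

    Returns +inf when targets occur only among DE genes, -inf when only
    among non-DE genes, NaN when either stratum is empty.
    """
    de_total = table.a + table.b
    non_total = table.c + table.d
    if de_total == 0 or non_total == 0:
        return float("nan")
    p_de = table.a / de_total
    p_non = table.c / non_total
    if p_de == 0 and p_non == 0:
        return float("nan")
    if p_non == 0:
        return float("inf")
    if p_de == 0:
        return float("-inf")
    return float(np.log2(p_de / p_non))


def fold_enrichment(table: ContingencyTable2x2) -> float:
    """(a/(a+b)) / ((a+c)/N): target rate among DE over the background rate."""
    de_total = table.a + table.b
    if de_total == 0 or table.n == 0 or (table.a + table.c) == 0:
        return float("nan")
    return (table.a / de_total) / ((table.a + table.c) / table.n)


def _enrich_frame(
    gene_list: set[str],
    universe: set[str],
    sets: AnnotationSets,
    min_set_size: int = 2,
) -> pd.DataFrame:
    offenders = gene_list - universe
    if offenders:
        raise ValueError(
            f"genes outside the universe: {sorted(offenders)[:10]}"
        )
    rows = []
    for term in sorted(sets.sets):
        targets = sets[term] & universe
        if len(targets) < min_set_size:
            warnings.warn(
                f"set {term!r} has fewer than {min_set_size} genes in the "
                "universe; skipped", stacklevel=3)
            continue
        a = len(gene_list & targets)
        b = len(gene_list) - a
        c = len(targets) - a
        d = len(universe) - len(gene_list) - c
        t = ContingencyTable2x2(a, b, c, d)
        rows.append({
            "term_id": term, "a": a, "b": b, "c": c, "d": d,
            "enrichment": enrichment_score(t),
            "fold": fold_enrichment(t),
            "pvalue": fisher_right_tail(t),
        })
    df = pd.DataFrame(
        rows, columns=["term_id", "a", "b", "c", "d", "enrichment",
                       "fold", "pvalue"]
    ).set_index("term_id")
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    return df


def tf_enrichment(
    de_genes: set[str],
    universe: set[str],
    tf_sets: AnnotationSets,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Regulon enrichment among DE genes; BH over exactly the tested TFs.

    Returns one row per testable TF with the 2x2 counts, the log2
    %target-ratio score, fold enrichment, Fisher p, BH q and a
    ``significant`` flag at ``fdr_max``.
    """
    df = _enrich_frame(set(de_genes), set(universe), tf_sets)
    df["significant"] = df["qvalue"] <= fdr_max
    return df.sort_values(["qvalue", "pvalue"])


def term_enrichment(
    gene_list: set[str],
    universe: set[str],
    term_sets: AnnotationSets,
    fdr_max: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Category-term enrichment: q <= fdr_max and fold enrichment >= min_fold.

    Returns the enriched terms only, sorted by q then descending fold.
    """
    df = _enrich_frame(set(gene_list), set(universe), term_sets)
    df["significant"] = (df["qvalue"] <= fdr_max) & (df["fold"] >= min_fold)
    out = df[df["significant"]].sort_values(
        ["qvalue", "fold"], ascending=[True, False])
    return out
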
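"""Cross-organ stress-response summaries.

Combines per-contrast DE results into the comparative summaries of the
study: per-contrast down/up counts and their ratio, the Down / Up / Mix
categories over a scope of contrasts, commonality counts (genes DE in
exactly k of the scope's contrasts), organ-unique gene sets, and direction
concordance against a signed reference gene list (e.g. a CBF regulon).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "summarize_counts",
    "summarize_contrast",
    "classify",
    "commonality",
    "unique_genes",
    "direction_concordance",
]

CATEGORIES = ("Down", "Up", "Mix")


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_counts(n_down: int, n_up: int) -> dict:
    """Totals and the down/up ratio for one contrast's DE counts.

    The ratio is reported rounded half-up at two decimals and, for
    comparison with one-decimal reports, at one decimal; it is ``None``
    (undefined) when no gene is upregulated.
    """
    n_down, n_up = int(n_down), int(n_up)
    if n_down < 0 or n_up < 0:
        raise ValueError("counts must be non-negative")
    out = {"n_down": n_down, "n_up": n_up, "n_total": n_down + n_up}
    if n_up == 0:
        out["down_up_ratio"] = None
        out["down_up_ratio_1dp"] = None
    else:
        r = n_down / n_up
        out["down_up_ratio"] = _round_half_up(r, 2)
        out["down_up_ratio_1dp"] = _round_half_up(r, 1)
    return out


def summarize_contrast(result: pd.DataFrame) -> dict:
    """Down/up totals and ratio from one contrast's DE result table."""
    status = result["status"]
    return summarize_counts((status == "down").sum(), (status == "up").sum())


def classify(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Down / Up / Mix classification over a scope of contrasts.

    ``results`` maps contrast name -> DE result table; all tables must share
    one gene universe.  Returns one row per gene DE in at least one contrast
    with a ``status_<contrast>`` column per contrast and a ``category``
    column: Down (down somewhere, up nowhere), Up (up somewhere, down
    nowhere), Mix (both directions).  Genes ns everywhere are excluded.
    """
    if not results:
        raise ValueError("need at least one contrast result")
    names = list(results)
    universe = results[names[0]].index
    for name in names[1:]:
        if not results[name].index.equals(universe):
            raise ValueError(
                f"contrast {name!r} has a different gene universe than "
                f"{names[0]!r}; classification needs one shared universe"
            )
    status = pd.DataFrame(
        {f"status_{name}": results[name]["status"] for name in names},
        index=universe,
    )
    arr = status.to_numpy()
    any_down = (arr == "down").any(axis=1)
    any_up = (arr == "up").any(axis=1)
    category = np.where(any_down & any_up, "Mix",
                        np.where(any_down, "Down",
                                 np.where(any_up, "Up", "ns")))
    out = status[category != "ns"].copy()
    out["category"] = category[category != "ns"]
    out.attrs["contrasts"] = names
    return out


def _status_block(classification: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in classification.columns if c.startswith("status_")]
    return classification[cols]


def commonality(classification: pd.DataFrame, direction: str) -> pd.Series:
    """Count genes DE in exactly k contrasts, k = 1..n, for one direction.

    ``direction`` is ``"down"`` / ``"up"`` (genes of the Down / Up category,
    counting contrasts with that call) or ``"mixed"`` (Mix-category genes,
    counting contrasts DE in either direction).
    """
    if direction not in ("down", "up", "mixed"):
        raise ValueError(f"direction must be down, up or mixed, got {direction!r}")
    block = _status_block(classification)
    n = block.shape[1]
    if direction == "mixed":
        sub = block[classification["category"] == "Mix"]
        k = (sub.to_numpy() != "ns").sum(axis=1)
    else:
        cat = "Down" if direction == "down" else "Up"
        sub = block[classification["category"] == cat]
        k = (sub.to_numpy() == direction).sum(axis=1)
    counts = pd.Series(0, index=pd.RangeIndex(1, n + 1, name="k"),
                       name=f"n_{direction}")
    vals, freq = np.unique(k, return_counts=True)
    for v, f in zip(vals, freq):
        counts.loc[int(v)] = int(f)
    return counts


def unique_genes(
    classification: pd.DataFrame, contrast: str, direction: str
) -> set[str]:
    """Genes DE with ``direction`` in the named contrast and ns elsewhere."""
    col = f"status_{contrast}"
    if col not in classification.columns:
        known = [c[len("status_"):] for c in classification.columns
                 if c.startswith("status_")]
        raise ValueError(f"unknown contrast {contrast!r}; scope has {known}")
    if direction not in ("down", "up"):
        raise ValueError(f"direction must be down or up, got {direction!r}")
    block = _status_block(classification)
    others = block.drop(columns=[col])
    mask = (block[col] == direction) & (others == "ns").all(axis=1)
    return set(classification.index[mask])


def direction_concordance(
    result: pd.DataFrame, reference: Mapping[str, str]
) -> dict:
    """Agreement between a contrast's DE directions and a signed reference list.

    Only reference genes that are DE in ``result`` are compared; a match is
    an identical direction.  ``pct_match`` is 100 * matched / compared,
    rounded half-up to 0 decimals, or ``None`` when nothing is comparable.
    """
    if not reference:
        raise ValueError("reference gene list is empty")
    bad = [g for g, d in reference.items() if d not in ("up", "down")]
    if bad:
        raise ValueError(f"reference directions must be up/down; offenders: {bad[:5]}")
    status = result["status"]
    n_matched = 0
    n_compared = 0
    for gene, expected in reference.items():
        if gene not in status.index:
            continue
        observed = status.loc[gene]
        if observed == "ns":
            continue
        n_compared += 1
        if observed == expected:
            n_matched += 1
    pct = (_round_half_up(100.0 * n_matched / n_compared, 0)
           if n_compared else None)
    return {"n_matched": n_matched, "n_compared": n_compared, "pct_match": pct}
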
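"""Core data containers and TSV readers/writers.

Every stage of the pipeline operates on a gene x sample integer count matrix
plus a sample design table mapping each library to (organ, treatment,
duration, replicate).  All on-disk formats are plain tab-separated UTF-8 with
a header row; readers validate and refuse malformed input rather than
coercing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "AnnotationSets",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_lengths",
    "write_lengths",
    "read_annotation",
    "write_annotation",
    "compute_rpkm",
]

VALID_TREATMENTS = ("control", "cold")


class FormatError(ValueError):
    """Raised when an input file violates its documented TSV contract."""


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples.

    ``data`` is a DataFrame indexed by gene id with one column per sample id.
    Entries must be non-negative integers; gene and sample ids must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count matrix contains non-numeric entries")
        if arr.size:
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
            if bad.size:
                g, s = bad[0]
                raise FormatError(
                    f"count matrix entry at gene {df.index[g]!r}, sample "
                    f"{df.columns[s]!r} is not a non-negative integer: {arr[g, s]}"
                )
        self.data = df.astype(np.int64)
        self.data.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleDesign:
    """Maps each sample to (organ, treatment, duration_h, replicate).

    ``table`` is indexed by sample id with columns ``organ``, ``treatment``
    (``control`` or ``cold``), ``duration_h`` (0 for control, else hours of
    cold) and ``replicate`` (1-based).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"organ", "treatment", "duration_h", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in design: {dup[:5]}")
        bad = set(t["treatment"]) - set(VALID_TREATMENTS)
        if bad:
            raise FormatError(
                f"unknown treatment labels {sorted(bad)}; expected {VALID_TREATMENTS}"
            )
        t["duration_h"] = t["duration_h"].astype(int)
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise FormatError("replicate indices must be >= 1")
        t.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def validate_against(self, counts: CountMatrix) -> None:
        """Require a one-to-one match between design rows and count columns."""
        design = set(self.table.index)
        mat = set(counts.sample_ids)
        only_counts = sorted(mat - design)
        only_design = sorted(design - mat)
        if only_counts:
            raise FormatError(f"samples in counts but not in design: {only_counts}")
        if only_design:
            raise FormatError(f"samples in design but not in counts: {only_design}")

    def group_samples(
        self, organ: str, treatment: str, duration_h: int
    ) -> list[str]:
        t = self.table
        mask = (
            (t["organ"] == organ)
            & (t["treatment"] == treatment)
            & (t["duration_h"] == int(duration_h))
        )
        return list(t.index[mask])

    def groups(self) -> dict[tuple[str, str, int], list[str]]:
        """All (organ, treatment, duration_h) groups with their samples."""
        out: dict[tuple[str, str, int], list[str]] = {}
        for sid, row in self.table.iterrows():
            key = (row["organ"], row["treatment"], int(row["duration_h"]))
            out.setdefault(key, []).append(sid)
        return out

    @property
    def organs(self) -> list[str]:
        seen: list[str] = []
        for o in self.table["organ"]:
            if o not in seen:
                seen.append(o)
        return seen


@dataclass
class AnnotationSets:
    """Flat gene sets (TF regulons or functional terms): term id -> gene ids."""

    sets: dict[str, frozenset[str]]
    kind: str = "tf_target"  # or "category_term"

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise FormatError(f"annotation set {term!r} is empty")
            self.sets[term] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric counts in sample {col!r}"
                + (f" (e.g. gene {bad[0]!r})" if len(bad) else "")
            )
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.data.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("design TSV must have a 'sample_id' column")
    return SampleDesign(df.set_index("sample_id"))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def read_lengths(path: str | Path) -> pd.Series:
    """Read a two-column gene_id / length_bp TSV into a Series of ints."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError("lengths TSV must have gene_id and length_bp columns")
    s = df.set_index(df.columns[0])[df.columns[1]].astype(int)
    s.index = s.index.astype(str)
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise FormatError(f"non-positive gene lengths for: {bad[:5]}")
    s.name = "length_bp"
    return s


def write_lengths(lengths: Mapping[str, int] | pd.Series, path: str | Path) -> None:
    s = pd.Series(dict(lengths)) if not isinstance(lengths, pd.Series) else lengths
    s.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path, kind: str = "tf_target") -> AnnotationSets:
    """Read a two-column (term_id, gene_id) TSV, one membership pair per line."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=0, dtype=str
    )
    if df.shape[1] < 2:
        raise FormatError("annotation TSV must have term_id and gene_id columns")
    sets: dict[str, set[str]] = {}
    for term, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sets.setdefault(term, set()).add(gene)
    return AnnotationSets({t: frozenset(g) for t, g in sets.items()}, kind=kind)


def write_annotation(ann: AnnotationSets, path: str | Path) -> None:
    rows = [
        (term, gene)
        for term in sorted(ann.sets)
        for gene in sorted(ann.sets[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# normalization


def compute_rpkm(counts: CountMatrix, lengths: pd.Series | Mapping[str, int]) -> pd.DataFrame:
    """Reads per kilobase of gene model per million assigned reads.

    rpkm[g, j] = counts[g, j] * 1e9 / (length[g] * total_counts[j]).

    The per-million denominator is each sample's total assigned gene reads
    (column sum of the count matrix).
    """
    if not isinstance(lengths, pd.Series):
        lengths = pd.Series(dict(lengths))
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    L = lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    rpkm = counts.data.to_numpy(dtype=float) * 1e9 / (
        L[:, None] * totals.to_numpy(dtype=float)[None, :]
    )
    return pd.DataFrame(rpkm, index=counts.data.index, columns=counts.data.columns)
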
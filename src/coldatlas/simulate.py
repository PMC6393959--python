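"""Synthetic cold-stress RNA-seq dataset generator.

Emulates the count structure of an organ-resolved cold-stress experiment in
*Arabidopsis thaliana*: six organs sampled under control conditions and after
3 h and 27 h of cold, with negative-binomial read counts, gene-specific
dispersion, a spectrum of expression-pattern widths (ubiquitous down to
single-organ genes), organ-dependent stress effects including direction flips
between organs, and transcription-factor regulons enriched among the
stress-responsive genes.  Every downstream stage of the package is testable
against the ground truth this module records.

All randomness flows from one integer seed through a single
``numpy.random.Generator``, so identical configurations produce bitwise
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationSets, CountMatrix, SampleDesign

__all__ = ["SimConfig", "SimTruth", "ConfigError", "generate_dataset",
           "write_truth", "read_truth", "DEFAULT_ORGANS"]

DEFAULT_ORGANS = ("cotyledons", "hypocotyl", "leaf", "flower", "young_flower", "seeds")

#: organs sharing a correlated photosynthetic baseline block
PHOTOSYNTHETIC = frozenset({"cotyledons", "hypocotyl", "leaf"})


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the study design: six organs, 3 h and 27 h cold
    durations, log-normal baseline expression, NB counts with
    Var = mu + alpha * mu^2, and 219 TF regulons of which a subset is
    "active" (targets enriched among stress-responsive genes).
    """

    n_genes: int = 5000
    organs: tuple[str, ...] = DEFAULT_ORGANS
    timepoints_h: tuple[int, ...] = (3, 27)
    n_replicates: int = 3
    frac_de_per_contrast: float = 0.1
    effect_log2fc_range: tuple[float, float] = (1.5, 4.0)
    frac_sign_flip: float = 0.05
    frac_organ_specific: float = 0.1
    baseline_log_mean: float = 4.0   # natural-log mean of control expression
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05         # NB alpha; Var = mu + alpha mu^2
    dispersion_sd: float = 0.0       # >0: gene-sampled log-normal around `dispersion`
    organ_class_sd: float = 0.8      # between-organ-class baseline spread (log scale)
    organ_jitter_sd: float = 0.2     # within-class per-organ spread (log scale)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    n_tf_sets: int = 219
    n_active_tfs: int = 20
    tf_target_de_enrichment: float = 4.0
    tf_set_size_range: tuple[int, int] = (50, 300)
    n_terms: int = 40
    n_enriched_terms: int = 8
    term_size_range: tuple[int, int] = (20, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be a positive integer")
        if not self.organs:
            raise ConfigError("organs must be non-empty")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        for name in ("frac_de_per_contrast", "frac_sign_flip", "frac_organ_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.effect_log2fc_range
        if lo < 1.0 or hi < lo:
            raise ConfigError(
                "effect_log2fc_range lower bound must be >= 1 (true effects must "
                f"clear the 2-fold threshold) and ordered, got ({lo}, {hi})"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.n_active_tfs > self.n_tf_sets:
            raise ConfigError("n_active_tfs cannot exceed n_tf_sets")
        if self.tf_target_de_enrichment < 1:
            raise ConfigError("tf_target_de_enrichment must be >= 1")
        sflo, sfhi = self.size_factor_range
        if sflo <= 0 or sfhi < sflo:
            raise ConfigError("size_factor_range must be positive and ordered")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``genes`` has one row per gene: ``pattern`` (``ubiquitous`` or
    ``organ-specific:<organ>``), ``dispersion``, per-organ baseline means
    (``baseline_<organ>``), per-contrast true log2 fold change
    (``lfc_<organ>_<t>h``) and DE flags (``de_<organ>_<t>h``), and
    comma-joined memberships in TF regulons / terms.
    """

    genes: pd.DataFrame
    contrasts: list[tuple[str, int]]
    active_tfs: list[str]
    enriched_terms: list[str]
    size_factors: pd.Series

    def true_de(self, organ: str, duration_h: int) -> pd.Series:
        return self.genes[f"de_{organ}_{duration_h}h"].astype(bool)

    def true_lfc(self, organ: str, duration_h: int) -> pd.Series:
        return self.genes[f"lfc_{organ}_{duration_h}h"]

    def de_union(self) -> pd.Series:
        cols = [c for c in self.genes.columns if c.startswith("de_")]
        return self.genes[cols].any(axis=1)


def _contrast_cols(organ: str, t: int) -> tuple[str, str]:
    return f"lfc_{organ}_{t}h", f"de_{organ}_{t}h"


def generate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, SampleDesign, pd.Series, dict[str, AnnotationSets], SimTruth]:
    """Draw one complete synthetic dataset.

    Returns (counts, design, gene lengths, annotation sets keyed by kind,
    truth).  Counts are NB with per-sample size factors log-uniform in the
    configured range; stress-group means are the control mean scaled by
    2**(true log2FC).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    organs = list(config.organs)
    gene_ids = np.array([f"AT1G{i:05d}" for i in range(1, n + 1)])

    # --- baseline expression per organ ------------------------------------
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    classes = np.array([0 if o in PHOTOSYNTHETIC else 1 for o in organs])
    class_eff = rng.normal(0.0, config.organ_class_sd, size=(n, 2))
    jitter = rng.normal(0.0, config.organ_jitter_sd, size=(n, len(organs)))
    baseline = base[:, None] * np.exp(class_eff[:, classes] + jitter)

    # organ-specific genes: expressed in exactly one organ under control
    pattern = np.array(["ubiquitous"] * n, dtype=object)
    n_spec = int(round(config.frac_organ_specific * n))
    spec_idx = rng.choice(n, size=n_spec, replace=False)
    spec_organ = rng.integers(0, len(organs), size=n_spec)
    for gi, oi in zip(spec_idx, spec_organ):
        mask = np.ones(len(organs), dtype=bool)
        mask[oi] = False
        baseline[gi, mask] = 0.0
        pattern[gi] = f"organ-specific:{organs[oi]}"

    # --- dispersion --------------------------------------------------------
    if config.dispersion_sd > 0:
        alpha = rng.lognormal(np.log(max(config.dispersion, 1e-12)),
                              config.dispersion_sd, size=n)
    else:
        alpha = np.full(n, config.dispersion)

    # --- true stress effects ------------------------------------------------
    contrasts = [(o, t) for o in organs for t in config.timepoints_h]
    lfc = np.zeros((n, len(contrasts)))
    lo, hi = config.effect_log2fc_range
    for ci, (organ, t) in enumerate(contrasts):
        oi = organs.index(organ)
        expressed = np.flatnonzero(baseline[:, oi] > 0)
        k = int(round(config.frac_de_per_contrast * n))
        k = min(k, expressed.size)
        chosen = rng.choice(expressed, size=k, replace=False)
        mags = rng.uniform(lo, hi, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        lfc[chosen, ci] = signs * mags

    # direction flips: force opposite-direction effects in two organs at the
    # same timepoint so the Mix category is guaranteed to be exercised
    de_any = np.flatnonzero((lfc != 0).any(axis=1) & (pattern == "ubiquitous"))
    n_flip = int(round(config.frac_sign_flip * de_any.size))
    if n_flip and len(organs) >= 2:
        flip_genes = rng.choice(de_any, size=n_flip, replace=False)
        for gi in flip_genes:
            t = config.timepoints_h[rng.integers(len(config.timepoints_h))]
            o1, o2 = rng.choice(len(organs), size=2, replace=False)
            mag1, mag2 = rng.uniform(lo, hi, size=2)
            lfc[gi, contrasts.index((organs[o1], t))] = mag1
            lfc[gi, contrasts.index((organs[o2], t))] = -mag2

    # --- samples, size factors, counts --------------------------------------
    conditions = [("control", 0)] + [("cold", t) for t in config.timepoints_h]
    sample_ids: list[str] = []
    design_rows = []
    mu_cols = []
    for organ in organs:
        oi = organs.index(organ)
        for treatment, t in conditions:
            if treatment == "cold":
                ci = contrasts.index((organ, t))
                group_mu = baseline[:, oi] * np.exp2(lfc[:, ci])
            else:
                group_mu = baseline[:, oi]
            tag = "ctrl" if treatment == "control" else f"c{t}h"
            for rep in range(1, config.n_replicates + 1):
                sample_ids.append(f"{organ}_{tag}_r{rep}")
                design_rows.append((organ, treatment, t, rep))
                mu_cols.append(group_mu)
    mu = np.column_stack(mu_cols)
    sflo, sfhi = config.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(sflo), np.log(sfhi),
                                      size=len(sample_ids)))
    mu_scaled = mu * size_factors[None, :]

    a = np.clip(alpha, 1e-8, None)[:, None]
    nb_n = 1.0 / a
    nb_p = nb_n / (nb_n + mu_scaled)
    counts_arr = rng.negative_binomial(nb_n, nb_p)

    counts = CountMatrix(pd.DataFrame(counts_arr, index=gene_ids,
                                      columns=sample_ids))
    design = SampleDesign(pd.DataFrame(
        design_rows, index=pd.Index(sample_ids, name="sample_id"),
        columns=["organ", "treatment", "duration_h", "replicate"],
    ))
    lengths = pd.Series(rng.integers(300, 5001, size=n), index=gene_ids,
                        name="length_bp")

    # --- annotation sets -----------------------------------------------------
    de_union = (lfc != 0).any(axis=1)
    tf_sets, tf_member = _draw_sets(
        rng, gene_ids, de_union, config.n_tf_sets, config.n_active_tfs,
        config.tf_set_size_range, config.tf_target_de_enrichment, prefix="TF",
    )
    active_tfs = [f"TF{i + 1:03d}" for i in range(config.n_active_tfs)]
    term_sets, term_member = _draw_sets(
        rng, gene_ids, de_union, config.n_terms, config.n_enriched_terms,
        config.term_size_range, config.tf_target_de_enrichment, prefix="TERM",
    )
    enriched_terms = [f"TERM{i + 1:03d}" for i in range(config.n_enriched_terms)]

    # --- truth table ----------------------------------------------------------
    truth_df = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth_df["pattern"] = pattern
    truth_df["dispersion"] = alpha
    for oi, organ in enumerate(organs):
        truth_df[f"baseline_{organ}"] = baseline[:, oi]
    for ci, (organ, t) in enumerate(contrasts):
        lcol, dcol = _contrast_cols(organ, t)
        truth_df[lcol] = lfc[:, ci]
        truth_df[dcol] = lfc[:, ci] != 0
    truth_df["tf_sets"] = [",".join(s) for s in tf_member]
    truth_df["terms"] = [",".join(s) for s in term_member]

    truth = SimTruth(
        genes=truth_df,
        contrasts=contrasts,
        active_tfs=active_tfs,
        enriched_terms=enriched_terms,
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
    )
    annotations = {
        "tf_target": AnnotationSets(tf_sets, kind="tf_target"),
        "category_term": AnnotationSets(term_sets, kind="category_term"),
    }
    return counts, design, lengths, annotations, truth


def _draw_sets(rng, gene_ids, de_union, n_sets, n_active, size_range,
               enrichment, prefix):
    """Sample gene sets; the first ``n_active`` oversample stress-DE genes.

    Membership weight for a DE gene in an active set is ``enrichment`` times
    that of a non-DE gene, realised by weighted sampling without replacement.
    """
    n = len(gene_ids)
    sets: dict[str, frozenset[str]] = {}
    member: list[list[str]] = [[] for _ in range(n)]
    for i in range(n_sets):
        name = f"{prefix}{i + 1:03d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, n)
        if i < n_active:
            w = np.where(de_union, enrichment, 1.0)
            w = w / w.sum()
            idx = rng.choice(n, size=size, replace=False, p=w)
        else:
            idx = rng.choice(n, size=size, replace=False)
        sets[name] = frozenset(gene_ids[idx])
        for gi in idx:
            member[gi].append(name)
    return sets, member


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write the per-gene truth table as TSV with a commented header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# simulated ground truth: one row per gene\n")
        fh.write("# pattern: ubiquitous | organ-specific:<organ>\n")
        fh.write("# lfc_<organ>_<t>h: true log2 fold change (0 = no effect); "
                 "de_<organ>_<t>h: True if gene is truly DE in that contrast\n")
        fh.write("# tf_sets / terms: comma-joined annotation-set memberships\n")
        fh.write("# contrasts: " + ";".join(f"{o}_{t}h" for o, t in truth.contrasts) + "\n")
        fh.write("# active_tfs: " + ",".join(truth.active_tfs) + "\n")
        fh.write("# enriched_terms: " + ",".join(truth.enriched_terms) + "\n")
        fh.write("# size_factors: " + ",".join(
            f"{s}={v:.6g}" for s, v in truth.size_factors.items()) + "\n")
        truth.genes.to_csv(fh, sep="\t", index_label="gene_id")


def read_truth(path: str | Path) -> SimTruth:
    """Read a truth TSV written by :func:`write_truth`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    genes = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                        keep_default_na=False, na_values=[])
    for col in genes.columns:
        if col.startswith("de_"):
            genes[col] = genes[col].astype(str).str.lower().isin(["true", "1"])
    contrasts = []
    for tok in meta.get("contrasts", "").split(";"):
        if tok:
            organ, _, t = tok.rpartition("_")
            contrasts.append((organ, int(t.rstrip("h"))))
    sf_pairs = [p.split("=") for p in meta.get("size_factors", "").split(",") if "=" in p]
    size_factors = pd.Series({k: float(v) for k, v in sf_pairs}, name="size_factor")
    return SimTruth(
        genes=genes,
        contrasts=contrasts,
        active_tfs=[t for t in meta.get("active_tfs", "").split(",") if t],
        enriched_terms=[t for t in meta.get("enriched_terms", "").split(",") if t],
        size_factors=size_factors,
    )
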
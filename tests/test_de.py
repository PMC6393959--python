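"""NB Wald differential-expression test: normalization, dispersion,
calibration, recovery, and the BH step-up oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coldatlas import (Contrast, CountMatrix, DEThresholds, SimConfig,
                       bh_adjust, estimate_dispersion, estimate_size_factors,
                       generate_dataset)
from coldatlas import test_contrast as run_contrast
from coldatlas import test_two_groups as run_two_groups


def bh_step_up_oracle(p):
    """Independent literal implementation of the BH step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5],
                           "c": [10, 20, 5]}, index=["g1", "g2", "g3"])
        sf = estimate_size_factors(CountMatrix(df))
        np.testing.assert_allclose(sf, 1.0)

    def test_doubled_sample_ratio_two(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 500, size=200)
        df = pd.DataFrame({"a": base, "b": base, "c": 2 * base},
                          index=[f"g{i}" for i in range(200)])
        sf = estimate_size_factors(CountMatrix(df))
        assert sf["c"] / sf["a"] == pytest.approx(2.0, rel=1e-9)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_recovery_of_simulated_factors(self):
        cfg = SimConfig(n_genes=500, frac_de_per_contrast=0.0,
                        frac_organ_specific=0.0, seed=13)
        counts, design, *_, truth = generate_dataset(cfg)
        samples = design.group_samples("leaf", "control", 0) + \
            design.group_samples("leaf", "cold", 3)
        sf = estimate_size_factors(counts.data[samples])
        true = truth.size_factors.loc[samples]
        true = true / np.exp(np.mean(np.log(true)))
        np.testing.assert_allclose(sf, true, rtol=0.10)

    def test_all_zero_gene_matrix_errors(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="nonzero"):
            estimate_size_factors(CountMatrix(df))


class TestDispersion:
    def _norm_two_groups(self, rng, draw, n_genes):
        a = draw((n_genes, 3))
        b = draw((n_genes, 3))
        df = pd.DataFrame(np.hstack([a, b]),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        return estimate_dispersion(df, ["a1", "a2", "a3"], ["b1", "b2", "b3"])

    def test_poisson_counts_near_floor(self):
        rng = np.random.default_rng(1)
        alpha = self._norm_two_groups(
            rng, lambda s: rng.poisson(1000.0, size=s), 2000)
        assert float(np.median(alpha)) < 0.01

    def test_constant_replicates_floor(self):
        df = pd.DataFrame({"a1": [5], "a2": [5], "b1": [5], "b2": [5]},
                          index=["g"])
        alpha = estimate_dispersion(df, ["a1", "a2"], ["b1", "b2"])
        assert alpha.iloc[0] == pytest.approx(1e-8)

    def test_mom_calibration_alpha_02(self):
        rng = np.random.default_rng(2)
        mu, a_true = 500.0, 0.2
        n = 1.0 / a_true
        draw = lambda s: rng.negative_binomial(n, n / (n + mu), size=s)
        alpha = self._norm_two_groups(rng, draw, 2000)
        assert 0.1 <= float(np.median(alpha)) <= 0.4


class TestContrast:
    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 300, size=(100, 3))
        df = pd.DataFrame(np.hstack([block, block]),
                          index=[f"g{i}" for i in range(100)],
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = run_two_groups(CountMatrix(df), ["a1", "a2", "a3"],
                              ["b1", "b2", "b3"])
        np.testing.assert_allclose(res["log2_fc"], 0.0)
        assert (res["status"] == "ns").all()

    def test_all_zero_gene_untested(self):
        df = pd.DataFrame({"a1": [0, 5], "a2": [0, 6], "b1": [0, 50],
                           "b2": [0, 60]}, index=["dead", "live"])
        res = run_two_groups(CountMatrix(df), ["a1", "a2"], ["b1", "b2"])
        assert not res.loc["dead", "tested"]
        assert np.isnan(res.loc["dead", "pvalue"])
        assert res.loc["dead", "status"] == "ns"

    def test_too_few_replicates_rejected(self, small_dataset):
        _, counts, design, *_ = small_dataset
        with pytest.raises(ValueError, match="2 replicates"):
            run_two_groups(counts, [counts.sample_ids[0]],
                            counts.sample_ids[1:3])

    def test_status_partition_and_threshold_consistency(self, small_dataset):
        _, counts, design, *_ = small_dataset
        th = DEThresholds()
        res = run_contrast(counts, design, Contrast("flower", 27), th)
        assert set(res["status"].unique()) <= {"up", "down", "ns"}
        up = res["status"] == "up"
        assert (res.loc[up, "qvalue"] <= th.fdr_max).all()
        assert (res.loc[up, "log2_fc"] >= th.min_abs_log2fc).all()
        down = res["status"] == "down"
        assert (res.loc[down, "log2_fc"] <= -th.min_abs_log2fc).all()

    def test_threshold_monotonicity(self, small_dataset):
        """Stricter thresholds only shrink the DE set."""
        _, counts, design, *_ = small_dataset
        loose = run_contrast(counts, design, Contrast("leaf", 27),
                              DEThresholds(0.05, 2.0))
        strict_q = run_contrast(counts, design, Contrast("leaf", 27),
                                 DEThresholds(0.01, 2.0))
        strict_fc = run_contrast(counts, design, Contrast("leaf", 27),
                                  DEThresholds(0.05, 4.0))
        de = lambda r: set(r.index[r["status"] != "ns"])
        assert de(strict_q) <= de(loose)
        assert de(strict_fc) <= de(loose)

    def test_parameter_recovery(self):
        """4-fold effects at baseMean >= 100: sensitivity and FDR targets."""
        cfg = SimConfig(n_genes=5000, dispersion=0.05, n_replicates=3,
                        effect_log2fc_range=(2.0, 2.0), frac_sign_flip=0.0,
                        seed=20)
        counts, design, *_, truth = generate_dataset(cfg)
        organ, t = "leaf", 3
        res = run_contrast(counts, design, Contrast(organ, t))
        well = res["base_mean"] >= 100
        true_de = truth.true_de(organ, t)
        called = res["status"] != "ns"
        sens = (called & true_de & well).sum() / (true_de & well).sum()
        fdr = (called & ~true_de).sum() / max(int(called.sum()), 1)
        assert sens >= 0.7
        assert fdr <= 0.15

    def test_null_type_i_calibration(self):
        """No true effects: raw p <= 0.05 for roughly 5% of genes."""
        cfg = SimConfig(n_genes=2000, frac_de_per_contrast=0.0,
                        frac_sign_flip=0.0, frac_organ_specific=0.0, seed=21)
        counts, design, *_ = generate_dataset(cfg)
        res = run_contrast(counts, design, Contrast("hypocotyl", 27))
        p = res.loc[res["tested"], "pvalue"]
        rate = float((p <= 0.05).mean())
        assert 0.02 <= rate <= 0.08


class TestBH:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 50))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up_oracle(p),
                                       atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bounds_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert ((0 <= q) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
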
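"""Cross-organ response: contrast summaries, Down/Up/Mix classification,
commonality counting, unique genes and direction concordance."""

import numpy as np
import pandas as pd
import pytest

from coldatlas import (classify, commonality, direction_concordance,
                       summarize_contrast, summarize_counts, unique_genes)


def make_results(status_matrix: dict[str, list[str]], genes=None):
    """Build minimal DE result tables from a contrast -> statuses mapping."""
    n = len(next(iter(status_matrix.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    out = {}
    for name, statuses in status_matrix.items():
        out[name] = pd.DataFrame(
            {"log2_fc": [1.0 if s == "up" else -1.0 if s == "down" else 0.0
                         for s in statuses],
             "status": statuses, "tested": True},
            index=genes)
    return out


class TestSummarize:
    @pytest.mark.parametrize("n_down,n_up,total,ratio,ratio1", [
        (765, 1351, 2116, 0.57, 0.6),    # Leaf after 3 h of cold
        (1238, 937, 2175, 1.32, 1.3),    # Hypocotyl 3 h
        (1350, 961, 2311, 1.40, 1.4),    # Flower 27 h
        (352, 670, 1022, 0.53, 0.5),     # Flower 3 h
        (3580, 3287, 6867, 1.09, 1.1),   # Leaf 27 h
    ])
    def test_down_up_arithmetic(self, n_down, n_up, total, ratio, ratio1):
        s = summarize_counts(n_down, n_up)
        assert s["n_total"] == total
        assert s["down_up_ratio"] == pytest.approx(ratio)
        assert s["down_up_ratio_1dp"] == pytest.approx(ratio1)

    def test_empty_contrast_undefined_ratio(self):
        s = summarize_counts(0, 0)
        assert s["n_total"] == 0
        assert s["down_up_ratio"] is None

    def test_from_result_table(self):
        res = make_results({"c": ["up", "up", "down", "ns"]})["c"]
        s = summarize_contrast(res)
        assert (s["n_down"], s["n_up"], s["n_total"]) == (1, 2, 3)
        assert s["down_up_ratio"] == 0.5


class TestClassify:
    def test_category_definitions(self):
        results = make_results({
            "a": ["up", "up", "down", "ns"],
            "b": ["up", "down", "ns", "ns"],
        })
        cls = classify(results)
        assert cls.loc["g0", "category"] == "Up"     # up in 2, down nowhere
        assert cls.loc["g1", "category"] == "Mix"    # both directions
        assert cls.loc["g2", "category"] == "Down"
        assert "g3" not in cls.index                 # ns everywhere

    def test_partition_of_de_anywhere_set(self):
        rng = np.random.default_rng(4)
        statuses = {f"c{j}": rng.choice(["up", "down", "ns"], size=200,
                                        p=[0.1, 0.1, 0.8]).tolist()
                    for j in range(6)}
        cls = classify(make_results(statuses))
        block = cls[[c for c in cls.columns if c.startswith("status_")]]
        de_anywhere = (block != "ns").any(axis=1)
        assert de_anywhere.all()
        assert set(cls["category"]) <= {"Down", "Up", "Mix"}

    def test_permutation_invariance(self):
        results = make_results({
            "a": ["up", "ns"], "b": ["ns", "down"], "c": ["up", "up"]})
        c1 = classify(dict(results))
        c2 = classify(dict(reversed(list(results.items()))))
        pd.testing.assert_series_equal(
            c1["category"].sort_index(), c2["category"].sort_index())

    def test_mismatched_universe_rejected(self):
        results = make_results({"a": ["up", "ns"]})
        results["b"] = make_results({"b": ["up", "ns"]},
                                    genes=["x0", "x1"])["b"]
        with pytest.raises(ValueError, match="universe"):
            classify(results)


class TestCommonality:
    def test_singletons(self):
        results = make_results({
            "a": ["down", "ns", "ns"], "b": ["ns", "down", "ns"],
            "c": ["ns", "ns", "down"]})
        table = commonality(classify(results), "down")
        assert table.loc[1] == 3
        assert table.loc[2:].sum() == 0

    def test_ubiquitous_gene(self):
        results = make_results({f"c{j}": ["up"] for j in range(6)})
        table = commonality(classify(results), "up")
        assert table.loc[6] == 1
        assert table.sum() == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        statuses = {f"c{j}": rng.choice(["up", "down", "ns"], size=300,
                                        p=[0.15, 0.15, 0.7]).tolist()
                    for j in range(6)}
        results = make_results(statuses)
        cls = classify(results)
        for direction in ("down", "up", "mixed"):
            table = commonality(cls, direction)
            # brute-force recount from the per-gene membership vectors
            expected = {k: 0 for k in range(1, 7)}
            for g in cls.index:
                vec = [results[f"c{j}"].loc[g, "status"] for j in range(6)]
                cat = cls.loc[g, "category"]
                if direction == "mixed" and cat == "Mix":
                    expected[sum(s != "ns" for s in vec)] += 1
                elif direction == "down" and cat == "Down":
                    expected[vec.count("down")] += 1
                elif direction == "up" and cat == "Up":
                    expected[vec.count("up")] += 1
            assert table.to_dict() == expected

    def test_total_conservation(self):
        rng = np.random.default_rng(12)
        statuses = {f"c{j}": rng.choice(["up", "down", "ns"], size=400,
                                        p=[0.2, 0.2, 0.6]).tolist()
                    for j in range(4)}
        cls = classify(make_results(statuses))
        for direction, cat in (("down", "Down"), ("up", "Up"),
                               ("mixed", "Mix")):
            assert commonality(cls, direction).sum() == \
                (cls["category"] == cat).sum()


class TestUniqueGenes:
    def test_unique_and_shared(self):
        results = make_results({
            "a": ["down", "down", "ns"],
            "b": ["ns", "down", "up"],
        })
        cls = classify(results)
        assert unique_genes(cls, "a", "down") == {"g0"}
        assert unique_genes(cls, "b", "up") == {"g2"}
        assert unique_genes(cls, "b", "down") == set()

    def test_unknown_contrast_rejected(self):
        cls = classify(make_results({"a": ["up"]}))
        with pytest.raises(ValueError, match="unknown contrast"):
            unique_genes(cls, "zz", "up")

    def test_unique_subset_of_k1_stratum(self):
        rng = np.random.default_rng(17)
        statuses = {f"c{j}": rng.choice(["up", "down", "ns"], size=300,
                                        p=[0.15, 0.15, 0.7]).tolist()
                    for j in range(5)}
        cls = classify(make_results(statuses))
        k1_down = commonality(cls, "down").loc[1]
        uniq = set()
        for j in range(5):
            uniq |= unique_genes(cls, f"c{j}", "down")
        assert len(uniq) <= k1_down


class TestConcordance:
    def test_full_agreement(self):
        res = make_results({"c": ["up"] * 10})["c"]
        ref = {f"g{i}": "up" for i in range(10)}
        out = direction_concordance(res, ref)
        assert out == {"n_matched": 10, "n_compared": 10, "pct_match": 100.0}

    def test_half_agreement(self):
        res = make_results({"c": ["up", "up", "down", "down"]})["c"]
        ref = {"g0": "up", "g1": "down", "g2": "up", "g3": "down"}
        out = direction_concordance(res, ref)
        assert out["n_compared"] == 4
        assert out["pct_match"] == 50.0

    def test_ns_genes_not_compared(self):
        res = make_results({"c": ["ns", "up"]})["c"]
        out = direction_concordance(res, {"g0": "up", "g1": "up"})
        assert out["n_compared"] == 1

    def test_nothing_comparable_flagged(self):
        res = make_results({"c": ["ns"]})["c"]
        out = direction_concordance(res, {"g0": "up"})
        assert out["pct_match"] is None

    def test_empty_reference_rejected(self):
        res = make_results({"c": ["up"]})["c"]
        with pytest.raises(ValueError):
            direction_concordance(res, {})

    def test_simulated_regulon_recovered(self, small_dataset):
        """A reference list built from simulation truth should agree for
        nearly every gene the caller detects."""
        from coldatlas import Contrast
        from coldatlas import test_contrast as run_contrast
        _, counts, design, *_, truth = small_dataset
        organ, t = "cotyledons", 27
        lfc = truth.true_lfc(organ, t)
        ref = {g: ("up" if v > 0 else "down")
               for g, v in lfc[truth.true_de(organ, t)].items()}
        res = run_contrast(counts, design, Contrast(organ, t))
        out = direction_concordance(res, ref)
        assert out["n_compared"] > 10
        assert out["pct_match"] >= 95.0
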
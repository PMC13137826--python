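import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from trsaxs.eom import EnsembleFitResult
from trsaxs.stats import (
    cluster_ensembles,
    condition_stats,
    dunn_test,
    feature_table,
    hedges_g,
    weighted_domain_distances,
)


def make_result(fractions, pool_seed):
    size = 50
    counts = {i: max(int(round(f * size)), 1) for i, f in fractions.items()}
    return EnsembleFitResult(
        multiplicities=counts, fractions=fractions, chi2=1.0, scale=1.0,
        background=0.0, generations_run=1, fitness_trace=np.array([1.0]),
        ensemble_size=size, pool_seed=pool_seed,
    )


class TestWeightedDomainDistances:
    def test_single_conformer_identity(self, small_pool):
        res = make_result({5: 1.0}, small_pool.seed)
        table = weighted_domain_distances(res, small_pool).set_index("pair")
        row = small_pool.metrics.iloc[5]
        for pair in ("ree", "ntd_internal", "nac_internal", "ctd_internal"):
            assert table.loc[pair, "mean_A"] == pytest.approx(row[pair])
            assert table.loc[pair, "sd_A"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic_two_conformers(self, small_pool):
        ree = small_pool.metrics["ree"]
        i, j = 0, 1
        res = make_result({i: 0.25, j: 0.75}, small_pool.seed)
        table = weighted_domain_distances(res, small_pool).set_index("pair")
        expected = 0.25 * ree.iloc[i] + 0.75 * ree.iloc[j]
        assert table.loc["ree", "mean_A"] == pytest.approx(expected)

    def test_convex_combination_bounds(self, small_pool):
        fracs = {k: 0.2 for k in range(5)}
        res = make_result(fracs, small_pool.seed)
        table = weighted_domain_distances(res, small_pool).set_index("pair")
        for pair in table.index:
            vals = small_pool.metrics[pair].iloc[:5]
            assert vals.min() - 1e-9 <= table.loc[pair, "mean_A"] <= vals.max() + 1e-9

    def test_provenance_mismatch(self, small_pool):
        res = make_result({0: 1.0}, pool_seed=12345)
        with pytest.raises(ValueError):
            weighted_domain_distances(res, small_pool)


def make_blobs(seed=0, n_per=50, sigma=0.05):
    """Three well-separated blobs in (rg, ree, fraction) space."""
    rng = np.random.default_rng(seed)
    centers = [(60.0, 178.0, 0.02), (35.0, 79.0, 0.02), (38.0, 120.0, 0.10)]
    rows, truth = [], []
    for label, (rg0, ree0, f0) in enumerate(centers):
        # sigma is given in standardized units; convert per column
        for _ in range(n_per):
            rows.append({
                "condition": f"c{label % 2}", "time_s": 1.0,
                "rg": rg0 + rng.normal(0, sigma * 12.0),
                "ree": ree0 + rng.normal(0, sigma * 45.0),
                "fraction": abs(f0 + rng.normal(0, sigma * 0.04)),
            })
            truth.append(label)
    return pd.DataFrame(rows), np.array(truth)


class TestClustering:
    def test_planted_three_blobs(self):
        features, truth = make_blobs(seed=1)
        model = cluster_ensembles(features, t=2.5)
        assert model.k == 3
        assert adjusted_rand_score(truth, model.assignments) == 1.0
        assert -1.0 <= model.silhouette <= 1.0

    def test_infinite_threshold_single_cluster(self):
        features, _ = make_blobs(seed=2)
        model = cluster_ensembles(features, t=1e9)
        assert model.k == 1

    def test_duplication_invariance_of_means(self):
        features, _ = make_blobs(seed=3)
        doubled = pd.concat([features, features], ignore_index=True)
        m1 = cluster_ensembles(features, t=2.5)
        m2 = cluster_ensembles(doubled, t=2.5)
        s1 = m1.summaries.sort_values("mean_rg_A")["mean_rg_A"].to_numpy()
        s2 = m2.summaries.sort_values("mean_rg_A")["mean_rg_A"].to_numpy()
        assert np.allclose(s1, s2, rtol=1e-9)

    def test_row_order_invariance(self):
        features, truth = make_blobs(seed=4)
        perm = np.random.default_rng(0).permutation(len(features))
        shuffled = features.iloc[perm].reset_index(drop=True)
        m1 = cluster_ensembles(features, t=2.5)
        m2 = cluster_ensembles(shuffled, t=2.5)
        assert adjusted_rand_score(m1.assignments[perm], m2.assignments) == 1.0

    def test_identical_rows_flagged(self):
        features = pd.DataFrame({
            "condition": ["a"] * 12, "time_s": [1.0] * 12,
            "rg": [30.0] * 12, "ree": [70.0] * 12, "fraction": [0.1] * 12,
        })
        model = cluster_ensembles(features)
        assert model.k == 1
        assert "all-rows-identical" in model.flags


class TestConditionStats:
    def test_hedges_g_hand_example(self):
        assert hedges_g([1, 2, 3], [2, 3, 4]) == pytest.approx(-0.8)

    def test_identical_groups_null(self):
        assert hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_dunn_matches_hand_computation(self):
        """Two groups, no ties: Dunn z reduces to the rank-sum z statistic."""
        g = {"a": np.array([1.0, 2.0, 3.0, 4.0]), "b": np.array([5.0, 6.0, 7.0, 8.0])}
        out = dunn_test(g)
        n = 8
        se = np.sqrt(n * (n + 1) / 12.0 * (1 / 4 + 1 / 4))
        z_expected = (2.5 - 6.5) / se
        assert out.loc[0, "z"] == pytest.approx(z_expected)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        rows = []
        for cond in "abcd":
            shift = {"a": 0.0, "b": 0.0, "c": 1.0, "d": 3.0}[cond]
            for _ in range(30):
                rows.append({
                    "condition": cond, "rg": rng.normal(30 + shift * 5, 2),
                    "ree": rng.normal(80 + shift * 10, 5),
                    "fraction": abs(rng.normal(0.05, 0.01)),
                })
        report = condition_stats(pd.DataFrame(rows))
        pw = report.pairwise.dropna(subset=["p"])
        assert ((pw["q"] >= pw["p"] - 1e-12) & (pw["q"] <= 1.0)).all()
        for _, grp in pw.groupby("feature"):
            q_sorted = grp.sort_values("p")["q"].to_numpy()
            assert np.all(np.diff(q_sorted) >= -1e-12)

    def test_shifted_condition_flagged(self):
        """A condition with planted extended-shifted features is flagged
        (q < alpha and |g| > 0.8) against all others."""
        rng = np.random.default_rng(42)
        rows = []
        for cond in ("wt", "mn", "cu", "fe", "zn"):
            shift = 25.0 if cond == "cu" else 0.0
            for _ in range(40):
                rows.append({
                    "condition": cond,
                    "rg": rng.normal(35.0 + shift, 4.0),
                    "ree": rng.normal(85.0 + 2.5 * shift, 12.0),
                    "fraction": abs(rng.normal(0.05, 0.02)),
                })
        report = condition_stats(pd.DataFrame(rows))
        rg_pairs = report.pairwise[report.pairwise["feature"] == "rg"]
        cu_pairs = rg_pairs[(rg_pairs["group1"] == "cu") | (rg_pairs["group2"] == "cu")]
        other = rg_pairs[(rg_pairs["group1"] != "cu") & (rg_pairs["group2"] != "cu")]
        assert cu_pairs["significant"].all()
        assert not other["significant"].any()

    def test_small_condition_excluded(self):
        rng = np.random.default_rng(0)
        rows = [{"condition": "a", "rg": rng.normal(30, 2), "ree": rng.normal(80, 5),
                 "fraction": abs(rng.normal(0.1, 0.02))} for _ in range(20)]
        rows += [{"condition": "b", "rg": rng.normal(40, 2), "ree": rng.normal(95, 5),
                  "fraction": abs(rng.normal(0.1, 0.02))} for _ in range(20)]
        rows += [{"condition": "tiny", "rg": 33.0, "ree": 80.0, "fraction": 0.1}]
        with pytest.warns(UserWarning):
            report = condition_stats(pd.DataFrame(rows))
        conds = set(report.pairwise["group1"]) | set(report.pairwise["group2"])
        assert "tiny" not in conds


def test_feature_table_fractions_sum_per_group(small_pool):
    results = {
        ("wt", 0.18): make_result({0: 0.5, 1: 0.5}, small_pool.seed),
        ("wt", 0.54): make_result({2: 0.25, 3: 0.75}, small_pool.seed),
    }
    table = feature_table(results, small_pool)
    sums = table.groupby(["condition", "time_s"])["fraction"].sum()
    assert np.allclose(sums, 1.0)
    assert (table["rg"] > 0).all() and (table["ree"] > 0).all()
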
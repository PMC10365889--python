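"""Outcome statistics: sign alignment, Spearman matrix, metric clustering,
monotone fits, wellness prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from swimgait.stats import (cluster_metrics, evaluate_prediction,
                            fit_monotonic_spline, sign_align_metrics,
                            spearman_matrix, wellness_scores)


class TestSignAlign:
    def _table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"rostral_compensation": rng.uniform(0, 1, 10),
                             "distance": rng.uniform(0, 1, 10),
                             "flat": rng.uniform(0, 1, 10)})

    def test_rising_metric_negated_and_prefixed(self):
        t = self._table()
        ctrl = pd.Series({"rostral_compensation": 0.01, "distance": 5.0,
                          "flat": 1.0})
        wk1 = pd.Series({"rostral_compensation": 0.2, "distance": 1.0,
                         "flat": 1.0})
        aligned, flipped = sign_align_metrics(t, ctrl, wk1)
        assert flipped == ["rostral_compensation"]
        assert "(-) rostral_compensation" in aligned.columns
        np.testing.assert_allclose(aligned["(-) rostral_compensation"],
                                   -t["rostral_compensation"])
        np.testing.assert_allclose(aligned["distance"], t["distance"])
        # strictly-unchanged metric untouched (boundary rule)
        np.testing.assert_allclose(aligned["flat"], t["flat"])


class TestSpearmanMatrix:
    def test_self_correlation_and_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, 20)
        t = pd.DataFrame({"x": x, "y": np.exp(x)})
        r, p = spearman_matrix(t)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_hand_computed_five_point_table(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        # hand ranks: rs = 1 - 6*sum(d^2)/(n(n^2-1)); d = (−1,1,−1,1,0)
        expected = 1 - 6 * 4 / (5 * 24)
        r, p = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert r.loc["x", "y"] == pytest.approx(expected)
        assert 0 <= p.loc["x", "y"] <= 1   # exact permutation p at n=5

    def test_exact_permutation_p_extreme_case(self):
        x = np.arange(6, dtype=float)
        t = pd.DataFrame({"x": x, "y": x * 2})
        _, p = spearman_matrix(t)
        # perfectly concordant: only 2 of 6! permutations reach |rs| = 1
        assert p.loc["x", "y"] == pytest.approx(2 / 720)

    def test_constant_column_dropped(self):
        t = pd.DataFrame({"x": np.arange(6, dtype=float),
                          "c": np.ones(6), "y": np.arange(6)[::-1] * 1.0})
        with pytest.warns(UserWarning, match="constant"):
            r, _ = spearman_matrix(t)
        assert "c" not in r.columns

    def test_matrix_properties(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(size=(25, 5)),
                         columns=list("abcde"))
        r, _ = spearman_matrix(t)
        v = r.to_numpy()
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 1.0)
        assert np.all(v >= -1 - 1e-12) and np.all(v <= 1 + 1e-12)


class TestClusterMetrics:
    def test_perfectly_correlated_pair_merges_first(self):
        x = np.arange(20, dtype=float)
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=20)})
        r, _ = spearman_matrix(t)
        out = cluster_metrics(r)
        Z = out["linkage"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)   # first merge height

    def test_anticorrelated_pair_merges_last(self):
        x = np.arange(20, dtype=float)
        rng = np.random.default_rng(4)
        t = pd.DataFrame({"a": x, "b": -x, "c": x + rng.normal(0, 0.1, 20)})
        r, _ = spearman_matrix(t)
        Z = cluster_metrics(r)["linkage"]
        assert Z[-1, 2] >= 1.9            # distance 1 - (-1) = 2 joins last

    def test_planted_two_blocks_recovered(self):
        rng = np.random.default_rng(5)
        n = 40
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        cols = {f"a{i}": f1 + 0.35 * rng.standard_normal(n) for i in range(4)}
        cols.update({f"b{i}": f2 + 0.35 * rng.standard_normal(n)
                     for i in range(4)})
        r, _ = spearman_matrix(pd.DataFrame(cols))
        labels = cluster_metrics(r, n_clusters=2)["labels"]
        a = set(labels[[f"a{i}" for i in range(4)]])
        b = set(labels[[f"b{i}" for i in range(4)]])
        assert len(a) == 1 and len(b) == 1 and a != b


class TestMonotonicFit:
    def test_noiseless_increasing_data_interpolated(self):
        x = np.linspace(0, 1, 30)
        y = x ** 2
        fit = fit_monotonic_spline(x, y, p_value=0.001, smooth_window=1)
        assert np.abs(fit.y_fit - y).max() < 1e-6
        assert fit.increasing

    def test_decreasing_direction(self):
        x = np.linspace(0, 1, 30)
        fit = fit_monotonic_spline(x, -x, p_value=0.001)
        assert not fit.increasing
        assert np.all(np.diff(fit.y_fit) <= 1e-12)

    def test_constant_y_flat(self):
        x = np.linspace(0, 1, 20)
        fit = fit_monotonic_spline(x, np.ones(20), p_value=0.01)
        assert np.allclose(fit.y_fit, 1.0)

    def test_nonsignificant_pair_declined(self):
        with pytest.raises(ValueError, match="declined"):
            fit_monotonic_spline(np.arange(10.0), np.arange(10.0),
                                 p_value=0.2)


def toy_metrics(rows):
    return pd.DataFrame(rows, columns=["fish_id", "sex", "week", "distance",
                                       "rostral_compensation"])


class TestWellness:
    def test_hand_computed_six_fish(self):
        rows = []
        dist = {"f1": (100, 120), "f2": (80, 90), "f3": (60, 50),
                "f4": (40, 45), "f5": (30, 20), "f6": (10, 15)}
        comp = {"f1": (0.01, 0.02), "f2": (0.05, 0.04), "f3": (0.03, 0.05),
                "f4": (0.10, 0.08), "f5": (0.12, 0.14), "f6": (0.20, 0.18)}
        for f in dist:
            for wi, wk in enumerate(("1", "2")):
                rows.append([f, "male", wk, dist[f][wi], comp[f][wi]])
        w = wellness_scores(toy_metrics(rows)).set_index("fish_id")
        # hand ranks: distance descending 1..6 = f1..f6; compensation
        # ascending: f1=1, f3=2, f2=3, f4=4, f5=5, f6=6
        assert w.loc["f1", "combined_rank"] == 2
        assert w.loc["f2", "combined_rank"] == 5
        assert w.loc["f3", "combined_rank"] == 5
        assert w.loc["f6", "combined_rank"] == 12
        assert w.loc["f1", "group"] == "high"
        assert w.loc["f6", "group"] == "low"

    def test_best_fish_rank_two_high_group(self):
        rows = []
        for i, f in enumerate(["a", "b", "c", "d"]):
            for wk in ("1", "2"):
                rows.append([f, "female", wk, 100 - 10 * i, 0.01 * (i + 1)])
        w = wellness_scores(toy_metrics(rows)).set_index("fish_id")
        assert w.loc["a", "combined_rank"] == 2
        assert w.loc["a", "group"] == "high"

    def test_all_tied_assigned_low_with_warning(self):
        rows = []
        for f in ("a", "b", "c", "d"):
            for wk in ("1", "2"):
                rows.append([f, "male", wk, 50.0, 0.05])
        with pytest.warns(UserWarning, match="tied"):
            w = wellness_scores(toy_metrics(rows))
        assert (w["group"] == "low").all()

    def test_missing_week_excluded_with_reason(self):
        rows = [["a", "male", "1", 10.0, 0.1], ["a", "male", "2", 12.0, 0.1],
                ["b", "male", "1", 20.0, 0.2]]
        w = wellness_scores(toy_metrics(rows))
        assert "b" not in set(w["fish_id"])
        assert "b" in w.attrs["excluded"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(8):
            for wk in ("1", "2"):
                rows.append([f"f{i}", "male", wk, rng.uniform(10, 100),
                             rng.uniform(0, 0.3)])
        t = toy_metrics(rows)
        w1 = wellness_scores(t).set_index("fish_id")["group"]
        t2 = t.copy()
        t2["distance"] = np.log(t2["distance"])
        t2["rostral_compensation"] = t2["rostral_compensation"] ** 3
        w2 = wellness_scores(t2).set_index("fish_id")["group"]
        assert (w1.sort_index() == w2.sort_index()).all()


class TestEvaluatePrediction:
    def _outcomes(self, vals):
        return pd.DataFrame([{"fish_id": f, "glial_bridging": v,
                              "axon_proximal": v, "axon_distal": v}
                             for f, v in vals.items()])

    def test_identical_groups_no_difference(self):
        groups = pd.DataFrame({"fish_id": list("abcdef"),
                               "group": ["high", "low"] * 3})
        out = self._outcomes({f: 50.0 + (i % 2) * 1e-9
                              for i, f in enumerate("abcdef")})
        out["glial_bridging"] = [50, 50, 50, 50, 50, 50.0]
        out["axon_proximal"] = out["glial_bridging"]
        out["axon_distal"] = out["glial_bridging"]
        rep = evaluate_prediction(groups, out)
        row = rep[rep.outcome == "glial_bridging"].iloc[0]
        assert row["mean_high"] == row["mean_low"]

    def test_welch_t_matches_closed_form(self):
        groups = pd.DataFrame({"fish_id": list("abcd"),
                               "group": ["high", "high", "low", "low"]})
        out = self._outcomes({"a": 10.0, "b": 12.0, "c": 5.0, "d": 6.0})
        rep = evaluate_prediction(groups, out)
        row = rep[rep.outcome == "glial_bridging"].iloc[0]
        m1, m2 = 11.0, 5.5
        s1, s2 = 2.0, 0.5          # sample variances
        t_hand = (m1 - m2) / np.sqrt(s1 / 2 + s2 / 2)
        assert row["t_statistic"] == pytest.approx(t_hand)

    def test_empty_group_rejected(self):
        groups = pd.DataFrame({"fish_id": ["a"], "group": ["high"]})
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_prediction(groups, self._outcomes({"a": 1.0}))
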
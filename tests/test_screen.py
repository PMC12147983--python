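"""Screen-level statistics: yields, Dunnett tests, effect rules, viability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from morphoscreen.screen import (
    CAVITY_BINS,
    cavity_histogram,
    class_area_stats,
    classify_effect,
    compute_yields,
    condition_yield_summary,
    dunnett_test,
    stars,
    viability_ingest,
)


def preds_frame(class_counts: dict[str, int], well="w1", condition="control",
                dose=0.0, replicate=1):
    rows = []
    for c, n in class_counts.items():
        for _ in range(n):
            rows.append(dict(well_id=well, condition=condition, dose=dose,
                             replicate=replicate, pred_class=c))
    return pd.DataFrame(rows)


class TestYields:
    def test_control_yield_percentage(self):
        """72 of 100 objects in the terminal class gives a 72% yield."""
        df = preds_frame({"XEnEpiC": 72, "XEnEpiRosette": 18,
                          "XEnNonPolarizedEpi": 4, "EBLike": 4,
                          "AmorphousXEn": 2})
        wells = compute_yields(df)
        assert wells.loc[0, "yield_XEnEpiC"] == pytest.approx(72.0)

    def test_single_class_well(self):
        wells = compute_yields(preds_frame({"EBLike": 30}))
        assert wells.loc[0, "yield_EBLike"] == 100.0
        assert wells.loc[0, "yield_XEnEpiC"] == 0.0

    def test_yields_equal_counts_for_100_objects(self):
        counts = {"XEnEpiC": 54, "XEnEpiRosette": 18, "XEnNonPolarizedEpi": 10,
                  "EBLike": 12, "AmorphousXEn": 6}
        wells = compute_yields(preds_frame(counts))
        for c, n in counts.items():
            assert wells.loc[0, f"yield_{c}"] == pytest.approx(float(n))

    def test_yields_sum_to_100(self):
        rng = np.random.default_rng(0)
        classes = ["XEnEpiC", "XEnEpiRosette", "XEnNonPolarizedEpi",
                   "EBLike", "AmorphousXEn"]
        rows = [dict(well_id=f"w{i%3}", condition="c", dose=1.0, replicate=i % 3,
                     pred_class=rng.choice(classes)) for i in range(123)]
        wells = compute_yields(pd.DataFrame(rows))
        sums = sum(wells[f"yield_{c}"] for c in classes)
        assert np.allclose(sums, 100.0)

    def test_condition_means_are_well_means(self):
        """Condition yield is the mean of well yields, not pooled objects."""
        df = pd.concat([
            preds_frame({"XEnEpiC": 8, "EBLike": 2}, well="w1", replicate=1),
            preds_frame({"XEnEpiC": 30, "EBLike": 70}, well="w2", replicate=2),
        ])
        summary = condition_yield_summary(compute_yields(df))
        # well yields: 80% and 30% -> mean 55 (pooling would give 38/110=34.5%)
        assert summary.loc[0, "yield_XEnEpiC_mean"] == pytest.approx(55.0)


class TestAreaStats:
    def _features(self, areas, well="w1"):
        return pd.DataFrame({"well_id": well, "object_id": range(len(areas)),
                             "Area_um2": areas})

    def _preds(self, n, well="w1", cls="XEnEpiC"):
        return pd.DataFrame({"well_id": well, "object_id": range(n),
                             "condition": "control", "dose": 0.0,
                             "replicate": 1, "pred_class": cls})

    def test_mixed_areas_average(self):
        feats = self._features([5000.0, 9000.0] * 10)
        summary, _ = class_area_stats(feats, self._preds(20))
        assert summary.loc[0, "mean_area"] == pytest.approx(7000.0)

    def test_single_object_sd_flagged(self):
        summary, _ = class_area_stats(self._features([7000.0]), self._preds(1))
        assert summary.loc[0, "n"] == 1
        assert np.isnan(summary.loc[0, "sd_area"])

    def test_no_target_objects_flagged(self):
        summary, _ = class_area_stats(self._features([7000.0]),
                                      self._preds(1, cls="EBLike"))
        assert bool(summary.loc[0, "flagged"])


class TestDunnett:
    def test_k1_reduces_to_pooled_t_test(self):
        """One treatment: adjusted p equals the two-sample pooled t-test p."""
        a = np.array([10.0, 11.0, 9.5])
        b = np.array([13.0, 14.5, 13.5])
        res = dunnett_test({"control": a, "t": b}, "control",
                           n_mc=400_000, seed=1)
        t, p = sps.ttest_ind(b, a, equal_var=True)
        assert res.comparisons.loc[0, "t"] == pytest.approx(t)
        assert res.comparisons.loc[0, "p_adj"] == pytest.approx(p, abs=0.004)

    def test_identical_means_not_significant(self):
        g = {"control": np.array([5.0, 5.1, 4.9]),
             "t1": np.array([5.0, 5.1, 4.9]),
             "t2": np.array([5.05, 4.95, 5.0])}
        res = dunnett_test(g, "control", n_mc=100_000, seed=2)
        assert (res.comparisons["p_adj"] > 0.9).all()
        assert (res.comparisons["stars"] == "").all()

    def test_matches_large_monte_carlo_oracle(self):
        """Fixed 4-group fixture: p within 0.005 of a 10⁶-draw simulation."""
        groups = {"control": np.array([10.0, 10.5, 9.8]),
                  "low": np.array([10.4, 10.9, 10.1]),
                  "mid": np.array([11.5, 11.9, 11.2]),
                  "high": np.array([13.0, 13.6, 12.7])}
        res = dunnett_test(groups, "control", n_mc=200_000, seed=3)

        # independent brute-force null simulation of max-|t|
        rng = np.random.default_rng(12345)
        ns = np.array([3, 3, 3, 3])
        df = int(ns.sum() - 4)
        n_draws = 1_000_000
        z = rng.standard_normal((n_draws, 4)) / np.sqrt(ns)
        s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
        tnull = (z[:, 1:] - z[:, :1]) / s[:, None] / np.sqrt(1 / ns[1:] + 1 / 3)
        max_abs = np.abs(tnull).max(axis=1)
        for _, row in res.comparisons.iterrows():
            p_oracle = (max_abs >= abs(row["t"])).mean()
            assert row["p_adj"] == pytest.approx(p_oracle, abs=0.005)

    def test_matches_scipy_dunnett(self):
        """Cross-check against the independent scipy implementation."""
        groups = {"control": np.array([7.2, 6.9, 7.4]),
                  "a": np.array([8.1, 8.4, 7.9]),
                  "b": np.array([6.8, 7.1, 7.0])}
        res = dunnett_test(groups, "control", n_mc=400_000, seed=4)
        ref = sps.dunnett(groups["a"], groups["b"], control=groups["control"])
        np.testing.assert_allclose(res.comparisons["p_adj"],
                                   ref.pvalue, atol=0.01)

    def test_adjusted_p_not_below_pairwise_p(self):
        rng = np.random.default_rng(5)
        groups = {"control": rng.normal(0, 1, 4),
                  "t1": rng.normal(0.5, 1, 4),
                  "t2": rng.normal(1.0, 1, 4),
                  "t3": rng.normal(1.5, 1, 4)}
        res = dunnett_test(groups, "control", n_mc=200_000, seed=6)
        for _, row in res.comparisons.iterrows():
            _, p_pair = sps.ttest_ind(groups[row["treatment"]],
                                      groups["control"], equal_var=True)
            assert row["p_adj"] >= p_pair - 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dunnett_test({"control": np.array([1.0, 1.0]),
                          "t": np.array([1.0, 1.0])}, "control")

    def test_star_mapping(self):
        assert stars(0.2) == ""
        assert stars(0.05) == "*"
        assert stars(0.009) == "**"
        assert stars(0.0009) == "***"
        assert stars(0.00009) == "****"


class TestCavityHistogram:
    def test_categories(self):
        counts = np.array([0, 0, 1, 2, 2, 3, 4, 5, 6, -1])
        h = cavity_histogram(counts)
        assert h["cavity_0"] == pytest.approx(100 * 2 / 9)
        assert h["cavity_2"] == pytest.approx(100 * 2 / 9)
        assert h["cavity_>4"] == pytest.approx(100 * 2 / 9)
        assert set(h) == {f"cavity_{b}" for b in CAVITY_BINS}


class TestEffectCategories:
    def _table(self, yields, pvals, **extra):
        df = pd.DataFrame({"dose": [1.0, 2.0, 3.0],
                           "xen_epic_yield": yields,
                           "xen_epic_p": pvals,
                           "control_yield": 72.0})
        for k, v in extra.items():
            df[k] = v
        return df

    def test_penicillin_like_gradient(self):
        """Mild monotone yield loss, nothing else significant: gradient."""
        t = self._table([54.0, 52.0, 49.0], [0.04, 0.008, 0.00005])
        assert classify_effect(t).category == "gradient"

    def test_fluorouracil_like_cytotoxic(self):
        """Top-dose yield collapses to 0% with morphology flags."""
        t = self._table([55.0, 20.0, 0.0], [0.04, 0.001, 0.00001],
                        earlier_p=[0.5, 0.01, 0.001],
                        earlier_increase=[False, True, True])
        assert classify_effect(t).category == "cytotoxic_morphotoxic"

    def test_caffeine_like_morphotoxic(self):
        """Significant delamination increase at a viable top-dose yield."""
        t = self._table([48.0, 50.0, 52.0], [0.2, 0.15, 0.04],
                        delam_p=[0.2, 0.03, 0.001],
                        delam_increase=[True, True, True])
        assert classify_effect(t).category == "morphotoxic"

    def test_no_effect(self):
        t = self._table([70.0, 71.0, 69.0], [0.9, 0.8, 0.7])
        assert classify_effect(t).category == "no_effect"

    def test_dose_order_permutation_invariance(self):
        t = self._table([54.0, 52.0, 49.0], [0.04, 0.008, 0.00005])
        shuffled = t.iloc[[2, 0, 1]].reset_index(drop=True)
        assert classify_effect(shuffled).category == \
            classify_effect(t).category == "gradient"

    def test_missing_endpoints_unclassified(self):
        t = pd.DataFrame({"dose": [1.0, 2.0, 3.0]})
        call = classify_effect(t)
        assert call.category == "unclassified"
        assert "missing" in call.diagnostics["reason"]


class TestViability:
    def _table(self):
        return pd.DataFrame([
            ("control", 0.0, "72h", 6.2e6), ("control", 0.0, "120h", 6.0e6),
            ("vpa", 10.0, "72h", 1.5e6), ("vpa", 10.0, "120h", 0.9e6),
            ("mild", 1.0, "72h", 4.5e6), ("mild", 1.0, "120h", 5.9e6),
        ], columns=["condition", "dose", "timepoint", "luminescence"])

    def test_control_normalizes_to_one(self):
        out = viability_ingest(self._table())
        ctrl = out[out["condition"] == "control"]
        assert np.allclose(ctrl["normalized"], 1.0)
        assert (ctrl["recovery"] == "recovered").all()

    def test_irreversible_drop(self):
        """72h at 1.5/6.2 and 120h at 0.9/6.0 flags an irreversible loss."""
        out = viability_ingest(self._table())
        vpa = out[out["condition"] == "vpa"].iloc[0]
        assert vpa["recovery"] == "irreversible"

    def test_recovery_after_low_72h(self):
        out = viability_ingest(self._table())
        mild = out[out["condition"] == "mild"].iloc[0]
        assert mild["recovery"] == "recovered"

    def test_missing_control_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="control"):
            viability_ingest(t[t["condition"] != "control"])
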
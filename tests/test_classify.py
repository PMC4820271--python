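"""Classification rules, calibration and performance accounting."""

import numpy as np
import pandas as pd
import pytest

from musselmix.classify import (InfeasibleCriterionError, ThresholdRule,
                                calibrate_thresholds, classify_by_iss,
                                classify_by_tscore, performance,
                                select_best_criterion)


def scores_frame(scores, n_loci=4):
    return pd.DataFrame({"t_score": scores, "n_loci_scored": n_loci,
                         "scorable": True})


class TestTscoreRule:
    @pytest.mark.parametrize("score,expected", [
        (0, "ME"), (1, "ME"), (2, "HYBRID"), (4, "HYBRID"), (6, "HYBRID"),
        (7, "MT"), (8, "MT"),
    ])
    def test_band_assignment(self, score, expected):
        out = classify_by_tscore(scores_frame([score]))
        assert out.iloc[0] == expected

    def test_incomplete_genotypes_unclassified(self):
        df = pd.DataFrame({"t_score": [3, 3], "n_loci_scored": [3, 4],
                           "scorable": True})
        out = classify_by_tscore(df)
        assert pd.isna(out.iloc[0]) and out.iloc[1] == "HYBRID"


class TestPerformance:
    def test_perfect_prediction(self):
        labels = ["ME"] * 5 + ["MT"] * 5 + ["HYBRID"] * 5
        rep = performance(labels, labels)
        assert rep.overall == pytest.approx(1.0)
        assert all(v == 1 for v in rep.efficiency.values())

    def test_hand_confusion_table(self):
        truth = ["ME"] * 10 + ["MT"] * 10 + ["HYBRID"] * 10
        pred = (["ME"] * 9 + ["HYBRID"]          # one ME lost to hybrids
                + ["MT"] * 10                      # MT perfect
                + ["HYBRID"] * 8 + ["ME"] * 2)     # two hybrids lost to ME
        rep = performance(truth, pred)
        assert rep.efficiency == {"ME": 0.9, "MT": 1.0, "HYBRID": 0.8}
        assert rep.accuracy["ME"] == pytest.approx(9 / 11)
        assert rep.accuracy["HYBRID"] == pytest.approx(8 / 9)
        assert rep.overall == pytest.approx(0.9 * np.mean([9 / 11, 1.0, 8 / 9]))
        assert rep.overall == pytest.approx(0.812, abs=5e-4)

    def test_everything_called_hybrid(self):
        truth = ["ME", "MT", "HYBRID"] * 4
        pred = ["HYBRID"] * 12
        with pytest.warns(UserWarning, match="never predicted"):
            rep = performance(truth, pred)
        assert rep.efficiency["HYBRID"] == 1.0
        assert rep.efficiency["ME"] == 0.0 and rep.efficiency["MT"] == 0.0
        assert rep.accuracy["ME"] == 1.0  # undefined -> treated as 1

    def test_truth_must_cover_classes(self):
        with pytest.raises(ValueError, match="lacks"):
            performance(["ME", "MT"], ["ME", "MT"])


def labeled(me, mt, hyb):
    return pd.DataFrame({
        "iss": np.concatenate([me, mt, hyb]),
        "compound": ["ME"] * len(me) + ["MT"] * len(mt) + ["HYBRID"] * len(hyb),
    })


class TestCalibration:
    def test_separated_purebreds(self):
        rng = np.random.default_rng(1)
        df = labeled(rng.uniform(0, 0.05, 100), rng.uniform(0.95, 1, 100),
                     rng.uniform(0.2, 0.8, 50))
        rule = calibrate_thresholds(df, "pure95")
        assert rule.lower <= 0.05 and rule.upper >= 0.95
        pred = classify_by_iss(df["iss"], rule)
        rep = performance(df["compound"], pred)
        assert rep.efficiency["ME"] >= 0.95 and rep.efficiency["MT"] >= 0.95

    def test_degenerate_hybrids_infeasible(self):
        df = labeled([0.01], [0.99], [0.5] * 10)
        with pytest.raises(InfeasibleCriterionError):
            calibrate_thresholds(df, "hyb95")

    def test_hybrid_criterion_symmetric_tails(self):
        hyb = np.linspace(0.1, 0.9, 101)
        df = labeled([0.01], [0.99], hyb)
        rule = calibrate_thresholds(df, "hyb90")
        assert rule.lower == pytest.approx(np.percentile(hyb, 5))
        assert rule.upper == pytest.approx(np.percentile(hyb, 95))

    def test_nominal_efficiency_achieved_on_calibration_data(self):
        rng = np.random.default_rng(2)
        df = labeled(rng.beta(1, 20, 200), rng.beta(20, 1, 200),
                     rng.beta(5, 5, 100))
        for crit, cls_targets in (("pure95", ("ME", "MT")), ("hyb90", ("HYBRID",))):
            rule = calibrate_thresholds(df, crit)
            rep = performance(df["compound"], classify_by_iss(df["iss"], rule))
            nominal = 0.95 if "95" in crit else 0.90
            for c in cls_targets:
                n_c = (df["compound"] == c).sum()
                assert rep.efficiency[c] >= nominal - 1 / n_c


class TestClassifyByIss:
    RULE = ThresholdRule(0.062, 0.916, "pure95")

    @pytest.mark.parametrize("iss,expected", [
        (0.01, "ME"), (0.5, "HYBRID"), (0.062, "ME"), (0.916, "MT"), (0.99, "MT"),
    ])
    def test_thresholds(self, iss, expected):
        assert classify_by_iss(iss, self.RULE) == expected

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        iss = rng.uniform(0, 1, 500)
        out = classify_by_iss(iss, self.RULE)
        assert set(out) == {"ME", "MT", "HYBRID"}
        assert len(out) == 500  # every value assigned exactly one class

    def test_invalid_rule(self):
        with pytest.raises(InfeasibleCriterionError):
            ThresholdRule(0.9, 0.1, "pure95")


class TestSelectBest:
    def test_trimodal_favors_pure95(self):
        # purebred scores clustered near 0/1, hybrid scores spanning almost
        # the whole interval (as admixture scores of mixed ancestries do):
        # hybrid-efficiency thresholds then cut into the purebred clusters
        rng = np.random.default_rng(4)
        df = labeled(rng.beta(1, 30, 300), rng.beta(30, 1, 300),
                     rng.uniform(0.01, 0.99, 150))
        rule, reports = select_best_criterion(df)
        assert rule.criterion_id == "pure95"
        assert reports["pure95"].overall == max(r.overall for r in reports.values())

    def test_single_feasible_criterion(self):
        df = labeled([0.01] * 10, [0.99] * 10, [0.5] * 10)
        with pytest.warns(UserWarning, match="infeasible"):
            rule, reports = select_best_criterion(df)
        assert rule.criterion_id in ("pure95", "pure90")

    def test_all_infeasible(self):
        df = labeled([0.5] * 5, [0.5] * 5, [0.5] * 5)
        with pytest.warns(UserWarning):
            with pytest.raises(InfeasibleCriterionError, match="all criteria"):
                select_best_criterion(df)
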
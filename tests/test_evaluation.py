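"""Metric definitions, bootstrap CIs, Bland–Altman, AAMI/BHS grading."""

import json

import numpy as np
import pytest

from ppgbp.evaluation import (
    PairedPredictions,
    aami_check,
    bhs_grade,
    bhs_result,
    bland_altman,
    bootstrap_ci,
    cumulative_within,
    evaluate_report,
    percent_improvement,
    regression_metrics,
    report_to_json,
)
from ppgbp.preprocess import InputError


def pairs(est, ref, target="sbp"):
    return PairedPredictions(np.asarray(est, float), np.asarray(ref, float), target)


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        m = regression_metrics(pairs([120, 130, 110], [120, 130, 110]))
        assert m["r2"] == 1.0
        assert m["rmse"] == m["mae"] == m["me"] == m["sd"] == 0.0

    def test_hand_computed_example(self):
        # errors (2, -2, 1): ME=1/3, MAE=5/3, RMSE=sqrt(3), SD=sqrt(13/3)
        m = regression_metrics(pairs([122, 128, 111], [120, 130, 110]))
        assert m["me"] == pytest.approx(1 / 3)
        assert m["mae"] == pytest.approx(5 / 3)
        assert m["rmse"] == pytest.approx(np.sqrt(3.0))
        assert m["sd"] == pytest.approx(np.sqrt(13 / 3))

    def test_constant_shift(self):
        ref = np.array([120.0, 130.0, 110.0])
        m = regression_metrics(pairs(ref + 5, ref))
        sst = np.sum((ref - ref.mean()) ** 2)
        assert m["me"] == m["mae"] == m["rmse"] == pytest.approx(5.0)
        assert m["sd"] == pytest.approx(0.0)
        assert m["r2"] == pytest.approx(1 - 75 / sst)

    def test_all_equal_references_r2_undefined(self):
        m = regression_metrics(pairs([121, 119], [120, 120]))
        assert np.isnan(m["r2"])
        assert m["mae"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rmse_mae_and_variance_decomposition(self, seed):
        r = np.random.default_rng(seed)
        p = pairs(r.normal(120, 12, 60), r.normal(120, 10, 60))
        m = regression_metrics(p)
        n = 60
        assert m["rmse"] >= m["mae"]
        assert m["rmse"] ** 2 == pytest.approx(
            m["me"] ** 2 + (n - 1) / n * m["sd"] ** 2, abs=1e-9
        )

    def test_single_pair_rejected(self):
        with pytest.raises(InputError):
            pairs([120], [118])


class TestBootstrap:
    def test_degenerate_errors_collapse_to_point(self):
        p = pairs([125, 135, 115], [120, 130, 110])
        lo, hi = bootstrap_ci(lambda q: float(np.mean(q.errors)), p, seed=0)
        assert lo == hi == pytest.approx(5.0)

    def test_seeded_determinism(self):
        r = np.random.default_rng(1)
        p = pairs(r.normal(120, 5, 50), r.normal(120, 5, 50))
        stat = lambda q: float(np.mean(q.errors))  # noqa: E731
        assert bootstrap_ci(stat, p, seed=9) == bootstrap_ci(stat, p, seed=9)

    def test_ci_width_matches_clt(self):
        # mean of n=200 standard-normal errors: CI width ~ 2 * 1.96 / sqrt(200)
        r = np.random.default_rng(7)
        ref = r.normal(120, 10, 200)
        p = pairs(ref + r.normal(0, 1, 200), ref)
        lo, hi = bootstrap_ci(lambda q: float(np.mean(q.errors)), p, seed=3)
        expected = 2 * 1.96 / np.sqrt(200)
        assert abs((hi - lo) - expected) < 0.25 * expected

    @pytest.mark.parametrize("seed", range(20))
    def test_mean_ci_contains_point_estimate(self, seed):
        r = np.random.default_rng(seed)
        ref = r.normal(120, 10, 30)
        p = pairs(ref + r.normal(0, 3, 30), ref)
        point = float(np.mean(p.errors))
        lo, hi = bootstrap_ci(lambda q: float(np.mean(q.errors)), p, n_boot=300, seed=seed)
        assert lo <= point <= hi


class TestBlandAltman:
    def test_perfect_agreement(self):
        ba = bland_altman(pairs([120, 130, 110], [120, 130, 110]), n_boot=50)
        assert ba.bias == ba.loa_low == ba.loa_high == 0.0

    def test_two_point_hand_oracle(self):
        # d = (-1, 1): bias 0, SD sqrt(2), LoA = -/+ 1.96 sqrt(2)
        ba = bland_altman(pairs([119, 131], [120, 130]), n_boot=50)
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_low == pytest.approx(-1.96 * np.sqrt(2))
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2))

    def test_loa_spread_identity(self, rng):
        p = pairs(rng.normal(120, 8, 40), rng.normal(120, 8, 40))
        ba = bland_altman(p, n_boot=50)
        sd = np.std(p.errors, ddof=1)
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * sd)
        assert ba.loa_low <= ba.bias <= ba.loa_high


class TestCumulativeAndBHS:
    def test_perfect_is_100(self):
        assert cumulative_within(pairs([120, 130], [120, 130])) == (100.0, 100.0, 100.0)

    def test_count_by_hand(self):
        ref = np.zeros(4)
        assert cumulative_within(pairs([3, 7, 12, 20], ref)) == (25.0, 50.0, 75.0)

    def test_monotone_in_threshold(self, rng):
        p = pairs(rng.normal(120, 8, 50), rng.normal(120, 8, 50))
        p5, p10, p15 = cumulative_within(p)
        assert 0 <= p5 <= p10 <= p15 <= 100
        assert cumulative_within(p, [np.inf]) == (100.0,)

    @pytest.mark.parametrize(
        "pcts,expected",
        [
            ((91.08, 99.34, 99.95), "A"),
            ((71.57, 83.92, 90.77), "B"),
            ((100.0, 100.0, 100.0), "A"),
            ((45.0, 70.0, 90.0), "C"),
            ((10.0, 20.0, 30.0), "D"),
            ((60.0, 85.0, 95.0), "A"),  # thresholds inclusive
            ((59.99, 85.0, 95.0), "B"),
        ],
    )
    def test_grade_thresholds(self, pcts, expected):
        assert bhs_grade(pcts) == expected

    def test_grade_monotone_in_percentages(self, rng):
        order = {"A": 0, "B": 1, "C": 2, "D": 3}
        for _ in range(50):
            p = np.sort(rng.uniform(0, 100, 3))
            bump = np.sort(rng.uniform(0, 100 - p) * rng.uniform(0, 1, 3))
            better = np.minimum(p + bump, 100)
            assert order[bhs_grade(tuple(better))] <= order[bhs_grade(tuple(p))]


class TestAAMI:
    @pytest.mark.parametrize(
        "me,sd,passes",
        [
            (-0.01, 2.80, True),
            (0.11, 2.14, True),
            (0.01, 6.48, True),
            (0.0, 0.0, True),
            (5.0, 8.0, True),  # inclusive bounds
            (6.0, 2.0, False),
            (-5.5, 2.0, False),
            (0.0, 8.1, False),
        ],
    )
    def test_verdicts(self, me, sd, passes):
        assert aami_check(me, sd).passes is passes


class TestPercentImprovement:
    @pytest.mark.parametrize(
        "base,new,orient,expected",
        [
            (0.38, 0.96, "higher_better", 152.63),
            (10.78, 2.80, "lower_better", 74.03),
            (7.94, 1.94, "lower_better", 75.57),
            (0.40, 0.96, "higher_better", 140.00),
        ],
    )
    def test_reported_comparisons(self, base, new, orient, expected):
        assert round(percent_improvement(base, new, orient), 2) == expected

    def test_no_change_is_zero(self):
        assert percent_improvement(3.0, 3.0, "higher_better") == 0.0
        assert percent_improvement(3.0, 3.0, "lower_better") == 0.0

    def test_zero_baseline_undefined(self):
        assert np.isnan(percent_improvement(0.0, 1.0, "higher_better"))


class TestReport:
    def test_perfect_predictions_report(self, tmp_path):
        ref = np.array([120.0, 130.0, 110.0, 125.0])
        sbp = pairs(ref, ref, "sbp")
        dbp = pairs(ref - 40, ref - 40, "dbp")
        report = evaluate_report(sbp, dbp, n_boot=50)
        for target in ("sbp", "dbp"):
            block = report["targets"][target]
            assert block["aami"]["passes"] is True
            assert block["bhs"]["grade"] == "A"
            assert block["metrics"]["rmse"]["value"] == 0.0

    def test_report_round_trips(self, tmp_path, rng):
        ref = rng.normal(120, 10, 30)
        sbp = pairs(ref + rng.normal(0, 3, 30), ref, "sbp")
        dbp = pairs(ref - 40 + rng.normal(0, 2, 30), ref - 40, "dbp")
        report = evaluate_report(sbp, dbp, n_boot=30)
        path = tmp_path / "report.json"
        report_to_json(report, str(path))
        loaded = json.loads(path.read_text())
        assert loaded["targets"]["sbp"]["metrics"]["rmse"]["value"] == pytest.approx(
            report["targets"]["sbp"]["metrics"]["rmse"]["value"]
        )
        assert loaded["targets"]["dbp"]["bhs"]["grade"] == report["targets"]["dbp"]["bhs"]["grade"]

    def test_single_pair_rejected(self):
        with pytest.raises(InputError):
            pairs([120], [118])
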
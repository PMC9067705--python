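"""Evaluation statistics vs textbook oracles; subgroup routing."""

import numpy as np
import pytest

from sonarcount.annotations import AnnotatedImage, PredictionRecord
from sonarcount.evaluate import (
    assign_subgroup,
    build_report,
    mae,
    nmae_by_subgroup,
    rmse,
    summary_table,
    uncertainty_error_correlation,
)


def rec(ct, cp, s=0.0, group=""):
    return PredictionRecord("x", ct, cp, s, group)


class TestMaeRmse:
    def test_perfect(self):
        records = [rec(5, 5.0), rec(7, 7.0)]
        assert mae(records) == 0.0
        assert rmse(records) == 0.0

    def test_simple_examples(self):
        records = [rec(10, 11.0), rec(10, 12.0), rec(10, 13.0)]
        assert mae(records) == pytest.approx(2.0)
        records2 = [rec(10, 13.0), rec(10, 14.0)]
        assert rmse(records2) == pytest.approx(np.sqrt(12.5))

    def test_matches_bruteforce(self, rng):
        records = [rec(int(t), float(p)) for t, p in zip(rng.integers(0, 400, 100), rng.normal(50, 30, 100))]
        abs_errors = [abs(r.count_true - r.count_pred) for r in records]
        assert mae(records) == pytest.approx(sum(abs_errors) / 100, rel=1e-12)
        assert rmse(records) == pytest.approx(
            np.sqrt(sum(e**2 for e in abs_errors) / 100), rel=1e-12
        )

    def test_rmse_dominates_mae(self, rng):
        for _ in range(20):
            records = [rec(int(t), float(p)) for t, p in zip(rng.integers(0, 400, 30), rng.normal(50, 30, 30))]
            assert rmse(records) >= mae(records)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([])


class TestSubgroups:
    def _img(self, boxes=(), h=64, w=112):
        return AnnotatedImage(
            "s", np.zeros((h, w, 3), np.uint8), noise_boxes=np.array(boxes).reshape(-1, 4)
        )

    @pytest.mark.parametrize(
        "count,expected",
        [(10, "c<25"), (24, "c<25"), (25, "25<=c<50"), (49, "25<=c<50"), (50, "50<=c<150"), (150, "c>=150")],
    )
    def test_count_bins(self, count, expected):
        assert assign_subgroup(count, self._img()) == expected

    def test_noise_takes_precedence(self):
        # a dolphin-sized box (>= 2% of frame area) routes to "Noise"
        img = self._img(boxes=[(0, 0, 20, 30)])
        assert assign_subgroup(10, img) == "Noise"

    def test_tiny_noise_box_ignored(self):
        img = self._img(boxes=[(0, 0, 3, 3)])
        assert assign_subgroup(10, img) == "c<25"


class TestNmae:
    def test_worked_example(self):
        """counts (10, 30) with errors (2, 6): NMAE = 8/40 = 0.2."""
        records = [rec(10, 12.0, group="c<25"), rec(30, 36.0, group="c<25")]
        out = nmae_by_subgroup(records)
        assert out["c<25"] == pytest.approx(0.2)

    def test_perfect_predictions(self):
        records = [rec(10, 10.0, group="c<25"), rec(200, 200.0, group="c>=150")]
        out = nmae_by_subgroup(records)
        assert out["c<25"] == 0.0
        assert out["c>=150"] == 0.0

    def test_zero_count_group_reported_missing(self):
        records = [rec(0, 3.0, group="c<25")]
        assert nmae_by_subgroup(records)["c<25"] is None

    def test_scale_free(self, rng):
        counts = rng.integers(1, 100, 20)
        preds = counts + rng.normal(0, 5, 20)
        a = nmae_by_subgroup([rec(int(t), float(p), group="c<25") for t, p in zip(counts, preds)])
        b = nmae_by_subgroup(
            [rec(int(t * 3), float(p * 3), group="c<25") for t, p in zip(counts, preds)]
        )
        assert a["c<25"] == pytest.approx(b["c<25"], rel=1e-9)


class TestUncertaintyCorrelation:
    def test_proportional_gives_r_one(self):
        records = [rec(10, 10 + e, s=0.5 * e) for e in (1.0, 2.0, 3.0, 4.0)]
        r, p = uncertainty_error_correlation(records)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_antiproportional(self):
        records = [rec(10, 10 + e, s=-0.5 * e) for e in (1.0, 2.0, 3.0, 4.0)]
        r, p = uncertainty_error_correlation(records)
        assert r == pytest.approx(-1.0)
        assert p > 0.95

    def test_matches_textbook_formula(self, rng):
        records = [
            rec(int(t), float(p), s=float(s))
            for t, p, s in zip(
                rng.integers(0, 400, 200), rng.normal(50, 30, 200), rng.normal(0, 2, 200)
            )
        ]
        r, p = uncertainty_error_correlation(records)
        x = np.array([q.log_sigma2 for q in records])
        y = np.abs(np.array([q.count_true - q.count_pred for q in records]))
        xm, ym = x - x.mean(), y - y.mean()
        r_ref = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(r_ref, abs=1e-10)
        # one-tailed p via the t-transform with N-2 dof
        from scipy import stats

        t = r_ref * np.sqrt(198 / (1 - r_ref**2))
        p_ref = stats.t.sf(t, df=198)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_constant_axis_reported_missing(self):
        records = [rec(10, 12.0, s=1.0), rec(10, 14.0, s=1.0), rec(10, 16.0, s=1.0)]
        assert uncertainty_error_correlation(records) == (None, None)


class TestReport:
    def test_perfect_report(self):
        records = [rec(5, 5.0, group="c<25")]
        report = build_report(records)
        assert report.mae == 0.0 and report.rmse == 0.0
        assert report.n == 1

    def test_rmse_ge_mae_invariant(self, rng):
        records = [
            rec(int(t), float(p), s=float(s), group="c<25")
            for t, p, s in zip(
                rng.integers(0, 400, 50), rng.normal(50, 30, 50), rng.normal(0, 2, 50)
            )
        ]
        report = build_report(records)
        assert report.rmse >= report.mae

    def test_summary_table_mean_column(self, rng):
        trials = {}
        for label in ("t1", "t2", "t3"):
            trials[label] = [
                rec(int(t), float(p))
                for t, p in zip(rng.integers(0, 100, 20), rng.normal(40, 20, 20))
            ]
        table = summary_table(trials)
        for metric in ("MAE", "RMSE"):
            expected = np.mean([table.loc[metric, c] for c in ("t1", "t2", "t3")])
            assert table.loc[metric, "mean"] == pytest.approx(expected, rel=1e-12)

    def test_report_serializes(self, tmp_path):
        records = [rec(5, 6.0, s=0.3, group="c<25"), rec(7, 7.0, s=0.1, group="c<25"), rec(9, 8.0, s=0.2, group="c<25")]
        report = build_report(records)
        report.save(tmp_path / "r.json")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["MAE"] == pytest.approx(report.mae)
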
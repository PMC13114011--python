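"""Participant filters, scoring bands, binarization, descriptives."""

import numpy as np
import pandas as pd
import pytest

from symptomnet.models import SymptomPanel
from symptomnet.preprocessing import (
    binarize,
    classify_nomophobia,
    classify_severity,
    comorbidity_groups,
    describe,
    filter_by_response_time,
    load_panel,
)
from symptomnet.synthetic_data import generate_response_times


def make_panel(scores: dict, scale_of=None) -> SymptomPanel:
    df = pd.DataFrame(scores)
    scales, ranges = {}, {}
    for c in df.columns:
        s = (scale_of or {}).get(c, c[:3])
        scales[c] = s
        ranges[c] = (1, 7) if s == "NMP" else (0, 3)
    return SymptomPanel(scores=df, item_scales=scales, score_ranges=ranges)


class TestResponseTimeFilter:
    def test_hand_worked_example(self):
        """times [1.5,3,4,5,30]: fast={1.5}; on the rest Q1=3.75, Q3=11.25,
        fence=22.5, so 30 is a slow outlier and {3,4,5} are kept."""
        res = filter_by_response_time([1.5, 3, 4, 5, 30])
        assert list(res.fast) == [0]
        assert res.slow_cutoff == pytest.approx(22.5)
        assert list(res.slow) == [4]
        assert list(res.kept) == [1, 2, 3]

    def test_constant_times_keep_everyone(self):
        res = filter_by_response_time([5.0] * 8)
        assert len(res.kept) == 8 and len(res.fast) == 0 and len(res.slow) == 0

    def test_planted_fixture_recovery(self):
        """All planted fast responders and extreme-slow outliers are caught."""
        t = generate_response_times(1000, fast_fraction=0.01, slow_fraction=0.005, seed=3)
        res = filter_by_response_time(t)
        assert len(res.fast) == 10
        assert len(res.slow) == 5
        assert np.all(t[res.slow] > 50)
        # the three sets partition the input
        assert len(res.kept) + len(res.fast) + len(res.slow) == 1000

    def test_fence_order_switch_changes_cutoff(self):
        """Fast responders widen the IQR when left in: on 30x0.5s, 60x5s,
        10x9s the full-sample fence is 11.75 (nothing slow) while the
        post-removal fence is 5.0 (the 9s become outliers)."""
        t = np.array([0.5] * 30 + [5.0] * 60 + [9.0] * 10)
        before = filter_by_response_time(t, order="before")
        after = filter_by_response_time(t, order="after")
        assert before.slow_cutoff == pytest.approx(11.75)
        assert len(before.slow) == 0
        assert after.slow_cutoff == pytest.approx(5.0)
        assert len(after.slow) == 10

    def test_rerun_on_kept_excludes_no_new_fast(self):
        t = generate_response_times(300, fast_fraction=0.05, slow_fraction=0.02, seed=9)
        res = filter_by_response_time(t)
        res2 = filter_by_response_time(t[res.kept])
        assert len(res2.fast) == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            filter_by_response_time([])
        with pytest.raises(ValueError):
            filter_by_response_time([-1.0, 3.0])


class TestBinarize:
    def test_rule_and_idempotence(self):
        panel = make_panel({"PHQ1": [0, 1, 2, 3], "GAD1": [0, 0, 0, 0]})
        b = binarize(panel)
        assert list(b.data["PHQ1"]) == [0, 1, 1, 1]
        assert list(b.data["GAD1"]) == [0, 0, 0, 0]
        # binarizing an already binary panel changes nothing
        panel01 = make_panel({"PHQ1": [0, 1, 1, 1], "GAD1": [0, 0, 0, 0]})
        assert binarize(panel01).data.equals(b.data)

    def test_prevalence_is_nonzero_fraction(self):
        panel = make_panel({"PHQ1": [0, 0, 1, 3], "GAD1": [1, 2, 3, 0]})
        prev = binarize(panel).prevalence()
        assert prev["PHQ1"] == pytest.approx(0.5)
        assert prev["GAD1"] == pytest.approx(0.75)

    def test_communities_attached(self):
        panel = make_panel({"PHQ1": [0, 1], "GAD1": [1, 0]})
        b = binarize(panel)
        assert b.communities == {"PHQ1": "depression", "GAD1": "anxiety"}


class TestNomophobiaBands:
    @pytest.mark.parametrize(
        "scores,mean,band,included",
        [([1] * 16, 1.0, "none", False),
         ([1] * 15 + [2], 1.0625, "mild", True),
         ([2] * 16, 2.0, "mild", True),
         ([3] * 16, 3.0, "moderate", True),
         ([4] * 8 + [5] * 8, 4.5, "moderate", True),
         ([5] * 16, 5.0, "severe", True)],
    )
    def test_boundaries(self, scores, mean, band, included):
        panel = SymptomPanel(
            scores=pd.DataFrame([scores], columns=[f"NMP{i+1}" for i in range(16)]),
            item_scales={f"NMP{i+1}": "NMP" for i in range(16)},
            score_ranges={f"NMP{i+1}": (1, 7) for i in range(16)},
        )
        out = classify_nomophobia(panel)
        assert out["mean_score"].iloc[0] == pytest.approx(mean)
        assert out["band"].iloc[0] == band
        assert bool(out["included"].iloc[0]) == included


class TestSeverityBands:
    @pytest.mark.parametrize(
        "total,scale,band",
        [(0, "PHQ", "none or minimal"), (10, "PHQ", "moderate"),
         (19, "PHQ", "moderately severe"), (27, "PHQ", "severe"),
         (15, "GAD", "severe"), (9, "GAD", "mild")],
    )
    def test_examples(self, total, scale, band):
        assert classify_severity(total, scale) == band

    def test_bands_cover_full_range_without_gaps(self):
        for scale, top in (("PHQ", 27), ("GAD", 21)):
            for t in range(top + 1):
                classify_severity(t, scale)  # must not raise
            with pytest.raises(ValueError):
                classify_severity(top + 1, scale)
            with pytest.raises(ValueError):
                classify_severity(-1, scale)


class TestComorbidityGroups:
    def test_strict_cutoff(self):
        counts, _ = comorbidity_groups([10], [9])
        assert counts == {"neither": 0, "depression_only": 1,
                          "anxiety_only": 0, "both": 0}

    def test_all_zero(self):
        counts, pct = comorbidity_groups([0, 0, 0], [0, 0, 0])
        assert counts["neither"] == 3 and pct["neither"] == 100.0

    def test_reference_cohort_percentages(self):
        """Counts (1277, 143, 58, 160) over n=1638 give 78.0/8.7/3.5/9.8%."""
        phq = np.concatenate([np.zeros(1277), np.full(143, 15), np.zeros(58),
                              np.full(160, 15)])
        gad = np.concatenate([np.zeros(1277), np.zeros(143), np.full(58, 15),
                              np.full(160, 15)])
        counts, pct = comorbidity_groups(phq, gad)
        assert counts == {"neither": 1277, "depression_only": 143,
                          "anxiety_only": 58, "both": 160}
        assert pct == {"neither": 78.0, "depression_only": 8.7,
                       "anxiety_only": 3.5, "both": 9.8}

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            comorbidity_groups([1, 2], [1])


class TestDescribe:
    def test_hand_arithmetic(self):
        panel = make_panel({"PHQ1": [0, 0, 1, 3], "GAD1": [1, 1, 1, 1]})
        s = describe(panel)
        assert s.items.loc["PHQ1", "mean"] == pytest.approx(1.0)
        assert s.items.loc["PHQ1", "prevalence"] == pytest.approx(0.5)
        # constant column: zero SD, undefined shape statistics
        assert s.items.loc["GAD1", "sd"] == 0.0
        assert np.isnan(s.items.loc["GAD1", "skewness"])
        assert s.group_counts["neither"] == 4
        assert sum(s.group_counts.values()) == s.n

    def test_prevalence_bounds(self, small_panel):
        s = describe(small_panel)
        assert ((s.items["prevalence"] >= 0) & (s.items["prevalence"] <= 1)).all()


class TestLoadPanel(object):
    def test_roundtrip_with_missing_rows(self, tmp_path):
        df = pd.DataFrame({
            "PHQ1": [1, 2, None, 3], "GAD1": [0, 1, 2, 3],
            "rt_per_item_s": [3.0, 4.0, 5.0, 6.0],
        })
        path = tmp_path / "panel.csv"
        df.to_csv(path, index=False)
        panel = load_panel(path)
        assert panel.n == 3  # row with missing PHQ dropped
        assert list(panel.response_times) == [3.0, 4.0, 6.0]

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"FOO1": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="expected PHQ"):
            load_panel(path)
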
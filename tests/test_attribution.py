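"""Integrated gradients, report selection, phrase mining, Kaplan-Meier and
log-rank machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mbehrt.attribution import (AttributionResult, ReportAttribution,
                                SurvivalSample, frequent_sequences,
                                integrated_gradients, km_estimate, logrank_test,
                                select_high_attribution_reports,
                                tabular_attributions)
from mbehrt.autograd import Tensor


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        """For F(x) = <w, x>, IG equals w * (x - baseline) exactly, at any
        number of steps."""
        rng = np.random.default_rng(0)
        w = rng.normal(size=(4, 3)).astype(np.float32)

        def forward(emb):
            return (emb * Tensor(w)).sum(axis=(1, 2))

        x = rng.normal(size=(4, 3)).astype(np.float32)
        baseline = rng.normal(size=(4, 3)).astype(np.float32)
        res = integrated_gradients(forward, x, baseline, steps=3)
        np.testing.assert_allclose(res.attributions, w * (x - baseline), atol=1e-6)
        assert res.completeness_gap < 1e-4

    def test_input_equal_baseline_gives_zero(self):
        def forward(emb):
            return (emb * emb).sum(axis=(1, 2))

        x = np.ones((3, 2), np.float32)
        res = integrated_gradients(forward, x, x, steps=10)
        np.testing.assert_array_equal(res.attributions, 0.0)
        assert res.f_input == res.f_baseline

    def test_invalid_steps_and_shapes(self):
        def forward(emb):
            return emb.sum(axis=(1, 2))

        with pytest.raises(ValueError):
            integrated_gradients(forward, np.ones((2, 2)), np.zeros((2, 2)), steps=0)
        with pytest.raises(ValueError):
            integrated_gradients(forward, np.ones((2, 2)), np.zeros((3, 2)))

    def test_completeness_on_transformer(self, dnpi_classifier, dnpi_cohort):
        """The completeness axiom holds within 1% of |F(x)-F(x')| at 200
        steps on the real (nonlinear) classifier, and the gap shrinks with
        more steps."""
        traj = dnpi_cohort["trajectories"][0]
        fine = tabular_attributions(dnpi_classifier, traj, steps=200)
        delta = abs(fine.f_input - fine.f_baseline)
        assert delta > 1e-4
        assert fine.completeness_gap < 0.01 * delta
        coarse = tabular_attributions(dnpi_classifier, traj, steps=5)
        assert fine.completeness_gap <= coarse.completeness_gap + 1e-9

    def test_scores_align_with_trajectory(self, dnpi_classifier, dnpi_cohort):
        traj = dnpi_cohort["trajectories"][3]
        res = tabular_attributions(dnpi_classifier, traj, steps=20)
        assert len(res.scores) == len(traj)

    def test_result_invariant_validated(self):
        with pytest.raises(ValueError):
            AttributionResult(np.zeros(3), np.zeros((2, 4)), 0.0, 0.0, 0.0)


class TestHighAttributionSelection:
    def reports(self, scores):
        return [ReportAttribution(f"P{i}", 0, f"texte {i}", s)
                for i, s in enumerate(scores)]

    def test_low_threshold_selects_everything(self):
        neg, _ = select_high_attribution_reports(self.reports([0.5, 1.0, 2.0]),
                                                 threshold=-10.0)
        assert len(neg) == 3

    def test_infinite_threshold_selects_nothing(self):
        with pytest.warns(UserWarning):
            neg, pos = select_high_attribution_reports(
                self.reports([0.5, -0.5]), threshold=np.inf)
        assert neg == [] and pos == []

    def test_quantile_split_by_direction(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0, 0.1, 100), [5.0, -5.0]])
        neg, pos = select_high_attribution_reports(self.reports(scores), quantile=0.99)
        assert any(r.score == 5.0 for r in neg)
        assert any(r.score == -5.0 for r in pos)


class TestSelectionEnrichment:
    def test_negative_dfs_set_enriched_for_planted_phrases(self, signal_cohort,
                                                           trained_text):
        """Reports selected as predictive for negative DFS by text-model
        attribution are enriched for reports carrying the planted signal
        phrases (Fisher odds ratio > 1, p < 0.05)."""
        import datetime as dt

        from mbehrt.attribution import text_attributions
        from mbehrt.text import preprocess_report

        sc = signal_cohort
        needles = [" ".join(preprocess_report(p)) for p in sc["config"].signal_phrases]
        attrs = []
        for rec, traj in list(zip(sc["records"], sc["text_trajectories"]))[:150]:
            scores, _ = text_attributions(trained_text, traj, steps=16)
            lo = rec.diagnosis_date
            hi = rec.surgery_date + dt.timedelta(days=365)
            texts = [v.report_text for v in rec.visits
                     if v.report_text and lo <= v.date <= hi]
            attrs.extend(ReportAttribution(rec.patient_id, i, texts[i], float(s))
                         for i, s in enumerate(scores))
        neg, _ = select_high_attribution_reports(attrs, quantile=0.95)

        def has_phrase(text):
            joined = " ".join(preprocess_report(text))
            return any(n in joined for n in needles)

        in_neg = np.array([has_phrase(r.text) for r in neg])
        overall = np.array([has_phrase(r.text) for r in attrs])
        a, b = int(in_neg.sum()), int(len(in_neg) - in_neg.sum())
        c = int(overall.sum() - in_neg.sum())
        d = int(len(attrs) - len(neg) - c)
        odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        assert odds_ratio > 1
        assert p < 0.05


def brute_force_ngrams(reports, n_lo, n_hi):
    counts = {}
    for tokens in reports:
        seen = set()
        for n in range(n_lo, n_hi + 1):
            for i in range(len(tokens) - n + 1):
                seen.add(tuple(tokens[i:i + n]))
        for g in seen:
            counts[g] = counts.get(g, 0) + 1
    return counts


class TestFrequentSequences:
    def test_identical_groups_empty_output(self):
        reports = ["un deux trois quatre", "cinq six sept huit"]
        assert frequent_sequences(reports, reports) == []

    def test_planted_phrase_recovered(self):
        phrase = "curage ganglionnaire axillaire realise"
        group_a = [f"debut rapport {phrase} fin rapport {i}" for i in range(8)]
        group_b = [f"rapport ordinaire numero {i} sans signal particulier texte"
                   for i in range(8)]
        out = dict(frequent_sequences(group_a, group_b))
        assert any(phrase in p for p in out)

    def test_single_trigram_report(self):
        out = frequent_sequences(["tissu glandulaire dense"], ["autre texte divers"])
        assert out[0] == ("tissu glandulaire dense", 1)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(4)
        words = list("abcdefg")
        reports = [[words[i] for i in rng.integers(0, 7, rng.integers(3, 12))]
                   for _ in range(12)]
        mined = frequent_sequences(reports, [["zz", "yy", "xx"]], top_k=10 ** 6)
        brute = brute_force_ngrams(reports, 3, 9)
        for phrase, count in mined:
            key = tuple(phrase.split())
            assert brute[key] == count

    def test_subphrases_merged_into_longer(self):
        group_a = ["alpha beta gamma delta epsilon"] * 5
        out = frequent_sequences(group_a, ["rien a voir ici du tout"], top_k=50)
        phrases = [p for p, _ in out]
        longest = "alpha beta gamma delta epsilon"
        assert longest in phrases
        for p in phrases:
            assert p == longest or p not in longest


class TestKaplanMeier:
    def test_two_events_no_censoring(self):
        curve = km_estimate(([1.0, 2.0], [True, True]))
        assert curve.at(1.0) == pytest.approx(0.5)
        assert curve.at(2.0) == pytest.approx(0.0)
        assert curve.at(0.5) == 1.0

    def test_censoring_fixture(self):
        samples = [SurvivalSample(1, True), SurvivalSample(2, False),
                   SurvivalSample(3, True), SurvivalSample(4, False)]
        curve = km_estimate(samples)
        assert curve.at(1) == pytest.approx(0.75)
        assert curve.at(3) == pytest.approx(0.375)

    def test_all_censored_flat_at_one(self):
        curve = km_estimate(([5.0, 7.0], [False, False]))
        assert curve.at(100.0) == 1.0

    def test_uncensored_closed_form(self):
        """Without censoring, S(t) is the fraction surviving past t."""
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 40).round(1)
        curve = km_estimate((times, np.ones(40, bool)))
        for t in [1.0, 5.0, 12.0]:
            assert curve.at(t) == pytest.approx((times > t).mean())

    def test_curve_monotone_right_continuous(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 30)
        events = rng.random(30) < 0.7
        curve = km_estimate((times, events))
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.at(0.0) <= 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 25).round(2)
        events = rng.random(25) < 0.6
        curve = km_estimate((times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.unique(times[events]):
            assert curve.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)


class TestKMPlot:
    def test_step_plot_written_to_disk(self, tmp_path):
        from mbehrt.attribution import plot_km
        curve = km_estimate(([1.0, 2.0, 3.0], [True, False, True]))
        out = tmp_path / "km.svg"
        plot_km({"phrase present": curve}, path=out)
        assert out.exists() and out.stat().st_size > 0


class TestLogRank:
    def test_identical_groups(self):
        g = ([1.0, 2.0, 3.0], [True, True, False])
        chi2, p = logrank_test(g, g)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_lifelines_on_20_subjects(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(7)
        ta = rng.exponential(10, 10).round(1)
        tb = rng.exponential(25, 10).round(1)
        ea = rng.random(10) < 0.8
        eb = rng.random(10) < 0.8
        chi2, p = logrank_test((ta, ea), (tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_strong_hazard_ratio_detected(self):
        """Large planted hazard ratio at n=500/arm: p < 0.001 across seeds."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(5, 500)
            tb = rng.exponential(50, 500)
            _, p = logrank_test((ta, np.ones(500, bool)), (tb, np.ones(500, bool)))
            assert p < 1e-3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(([], []), ([1.0], [True]))
        with pytest.raises(ValueError):
            logrank_test(([1.0], [False]), ([2.0], [False]))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalSample(-1.0, True)
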
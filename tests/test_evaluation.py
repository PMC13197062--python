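"""AUC, bootstrap CIs and the paired Wilcoxon comparison protocol."""

import numpy as np
import pytest

from cplp import auc, bootstrap_auc, compare_methods, evaluate_all


class TestAuc:
    def test_worked_example(self):
        # cases score 0.9 and 0.3; controls 0.8 and 0.2 -> 3 of 4 pairs ordered
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle_exhaustively(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = rng.integers(2, 13)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice(np.linspace(0, 1, 7), n)  # ties likely
            cases = scores[labels == 1]
            controls = scores[labels == 0]
            wins = sum((c > d) + 0.5 * (c == d)
                       for c in cases for d in controls)
            oracle = wins / (len(cases) * len(controls))
            assert auc(scores, labels) == pytest.approx(oracle, abs=1e-12)


class TestBootstrap:
    def test_perfect_separation_ci_collapses_to_one(self):
        r = bootstrap_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], B=200, seed=0)
        assert (r.mean, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)

    def test_single_resample_ci_collapses_to_point(self):
        r = bootstrap_auc([0.9, 0.1, 0.8, 0.3], [1, 0, 1, 0], B=1, seed=3)
        assert r.ci_low == r.ci_high == r.mean == r.auc_vector[0]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        scores, labels = rng.random(50), rng.integers(0, 2, 50)
        a = bootstrap_auc(scores, labels, B=100, seed=9)
        b = bootstrap_auc(scores, labels, B=100, seed=9)
        np.testing.assert_array_equal(a.auc_vector, b.auc_vector)

    def test_every_resample_has_both_classes(self):
        # 1 case among 30: naive resampling would often drop the case
        scores = np.linspace(0, 1, 30)
        labels = np.zeros(30, int)
        labels[-1] = 1
        r = bootstrap_auc(scores, labels, B=300, seed=1)
        assert len(r.auc_vector) == 300
        assert np.all(np.isfinite(r.auc_vector))

    def test_bootstrap_mean_near_point_estimate(self):
        rng = np.random.default_rng(4)
        scores = rng.random(400)
        labels = (rng.random(400) < 0.3).astype(int)
        point = auc(scores, labels)
        r = bootstrap_auc(scores, labels, B=2000, seed=5)
        assert abs(r.mean - point) < 0.01

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(6)
        scores, labels = rng.random(80), rng.integers(0, 2, 80)
        r = bootstrap_auc(scores, labels, B=500, seed=7)
        assert r.ci_low <= r.mean <= r.ci_high


class TestCompareMethods:
    def test_identical_vectors_give_p_one(self):
        v = np.random.default_rng(0).random(100)
        assert compare_methods(v, v) == 1.0

    def test_constant_shift_is_highly_significant(self):
        rng = np.random.default_rng(1)
        b = rng.random(1000) * 0.1 + 0.8
        a = b + 0.05
        assert compare_methods(a, b) < 1e-3

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(200), rng.random(200)
        assert compare_methods(a, b) == pytest.approx(compare_methods(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(np.ones(5), np.ones(6))


class TestEvaluateAll:
    @pytest.fixture(scope="class")
    def cohort_and_preds(self):
        from cplp import SynthConfig, generate_cohort
        cohort, latents = generate_cohort(
            SynthConfig(n_patients=400, feature_dim=8, seed=19))
        test = cohort.split_subset("test").patients
        logit = {lt.patient_id: lt.bayes_logit for lt in latents}
        rng = np.random.default_rng(0)
        preds = {
            "oracle": {p.patient_id: logit[p.patient_id] for p in test},
            "noisy": {p.patient_id: logit[p.patient_id] + rng.normal(0, 2)
                      for p in test},
        }
        return cohort, preds

    def test_reports_cover_both_cohorts(self, cohort_and_preds):
        cohort, preds = cohort_and_preds
        reports = evaluate_all(preds, cohort, B=100, seed=3)
        assert set(reports) == {"screening", "detected_nodule"}
        scr, nod = reports["screening"], reports["detected_nodule"]
        assert scr.n == len(cohort.split_subset("test"))
        from cplp import subset_detected_nodule
        assert nod.n == len(subset_detected_nodule(cohort))
        assert nod.n < scr.n

    def test_identical_predictions_give_p_one(self, cohort_and_preds):
        cohort, preds = cohort_and_preds
        dup = {"a": preds["oracle"], "b": dict(preds["oracle"])}
        reports = evaluate_all(dup, cohort, B=100, seed=3)
        assert reports["screening"].p_values[0, 1] == 1.0

    def test_seeded_determinism_of_full_report(self, cohort_and_preds):
        cohort, preds = cohort_and_preds
        r1 = evaluate_all(preds, cohort, B=100, seed=5)
        r2 = evaluate_all(preds, cohort, B=100, seed=5)
        for name in r1:
            for v in r1[name].variants:
                np.testing.assert_array_equal(r1[name].results[v].auc_vector,
                                              r2[name].results[v].auc_vector)
            np.testing.assert_array_equal(r1[name].p_values, r2[name].p_values)

    def test_missing_predictions_error_names_patient(self, cohort_and_preds):
        cohort, preds = cohort_and_preds
        broken = dict(preds["oracle"])
        missing_id = cohort.split_subset("test").patients[0].patient_id
        del broken[missing_id]
        with pytest.raises(ValueError, match=missing_id):
            evaluate_all({"a": broken}, cohort, B=10, seed=0)

    def test_shared_indices_pair_the_variants(self, cohort_and_preds):
        """With shared resamples, a variant compared against itself plus a
        constant is significant at any seed (the sign of the median paired
        difference is seed-invariant)."""
        cohort, preds = cohort_and_preds
        shifted = {pid: s + 0.05 for pid, s in preds["noisy"].items()}
        for seed in (0, 1, 2):
            reports = evaluate_all({"a": preds["noisy"], "b": shifted},
                                   cohort, B=100, seed=seed)
            va, vb = (reports["screening"].results[k].auc_vector
                      for k in ("a", "b"))
            # AUC is shift-invariant, so paired differences are all zero
            np.testing.assert_allclose(va, vb)

    def test_report_frame_and_markdown(self, cohort_and_preds):
        cohort, preds = cohort_and_preds
        rep = evaluate_all(preds, cohort, B=50, seed=1)["screening"]
        df = rep.to_frame()
        assert list(df.columns) == ["variant", "mean_auc", "ci_low", "ci_high"]
        md = rep.to_markdown()
        assert "oracle" in md and "mean AUC" in md
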
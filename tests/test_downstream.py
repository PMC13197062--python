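"""Zero-shot scoring, imputation, finetune contracts and baseline variants."""

import numpy as np
import pandas as pd
import pytest

from cplp import (FinetuneConfig, HashedTextEmbedder, ModelVariant,
                  impute_tabular, train_variant, zero_shot_score,
                  zero_shot_scores)
from cplp.cohort import MISSING, Cohort, PatientRecord, ScanFeature
from cplp.downstream import _MLP, tabular_matrix
from cplp.autodiff import Tensor


class TestZeroShot:
    def test_score_antisymmetric_under_candidate_swap(self, small_cohort,
                                                      tiny_encoders):
        cohort, _ = small_cohort
        enc, head = tiny_encoders
        provider = HashedTextEmbedder(16)
        pts = cohort.split_subset("test").patients[:10]
        scores = zero_shot_scores(pts, enc, head, provider)
        # swapping the candidate texts is exactly negation by construction;
        # verify via the swapped-template registry route
        from cplp.textser import TemplateRegistry
        swapped = TemplateRegistry(
            outcome_positive=TemplateRegistry().outcome_negative,
            outcome_negative=TemplateRegistry().outcome_positive)
        neg = zero_shot_scores(pts, enc, head, provider, registry=swapped)
        np.testing.assert_allclose(scores, -neg, atol=1e-6)

    def test_identical_candidates_score_zero_predict_negative(
            self, small_cohort, tiny_encoders):
        cohort, _ = small_cohort
        enc, head = tiny_encoders
        provider = HashedTextEmbedder(16)
        from cplp.textser import TemplateRegistry
        tied = TemplateRegistry(
            outcome_negative=TemplateRegistry().outcome_positive)
        p = cohort.patients[0]
        s = zero_shot_score(p, enc, head, provider, registry=tied)
        assert s == pytest.approx(0.0, abs=1e-6)
        assert not (s > 0)  # tie predicts the negative class

    def test_ranking_consistent_with_threshold_rule(self, small_cohort,
                                                    tiny_encoders):
        cohort, _ = small_cohort
        enc, head = tiny_encoders
        scores = zero_shot_scores(cohort.patients[:20], enc, head,
                                  HashedTextEmbedder(16))
        preds = scores > 0
        order = np.argsort(scores)
        # predictions are a threshold of the continuous score
        assert np.all(np.diff(preds[order].astype(int)) >= 0)


class TestImputation:
    def test_complete_table_is_identity(self):
        df = pd.DataFrame({"age": [60.0, 70.0], "bmi": [25.0, 30.0],
                           "sex": ["male", "female"]})
        out = impute_tabular(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_collinear_variable_recovered_exactly(self):
        """bmi = 2 * (age - 50): linear imputation must recover the
        relation on the missing rows."""
        rng = np.random.default_rng(3)
        age = rng.uniform(55, 75, 60).round(1)
        bmi = 2 * (age - 50)
        df = pd.DataFrame({"age": age, "bmi": bmi})
        missing_rows = [3, 10, 25, 40, 55]
        df.loc[missing_rows, "bmi"] = np.nan
        out = impute_tabular(df, seed=0)
        np.testing.assert_allclose(out.loc[missing_rows, "bmi"],
                                   2 * (age[missing_rows] - 50), atol=1e-6)

    def test_imputed_values_clamped_to_observed_range(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "age": rng.uniform(55, 75, 80).round(1),
            "pack_years": rng.uniform(30, 90, 80).round(1),
            "copd": rng.choice(["yes", "no"], 80),
        })
        df.loc[rng.choice(80, 12, replace=False), "pack_years"] = np.nan
        out = impute_tabular(df, seed=0)
        observed = df["pack_years"].dropna()
        assert out["pack_years"].min() >= observed.min() - 1e-9
        assert out["pack_years"].max() <= observed.max() + 1e-9
        assert set(out["copd"]) <= {"yes", "no"}

    def test_fully_missing_variable_rejected(self):
        df = pd.DataFrame({"age": [np.nan, np.nan], "bmi": [25.0, 30.0]})
        with pytest.raises(ValueError, match="age"):
            impute_tabular(df, seed=0)

    def test_deterministic_given_seed(self, small_cohort):
        cohort, _ = small_cohort
        a = tabular_matrix(cohort.patients, seed=1)
        b = tabular_matrix(cohort.patients, seed=1)
        np.testing.assert_array_equal(a, b)


class TestClassifierDegenerate:
    def test_zeroed_mlp_outputs_constant_bias(self):
        mlp = _MLP((8, 4, 1), np.random.default_rng(0))
        for k, p in mlp.params.items():
            p.data[:] = 0.0
        mlp.params["b1"].data[:] = 0.7
        out = mlp.forward(Tensor(np.random.default_rng(1)
                                 .standard_normal((5, 8)))).data
        np.testing.assert_allclose(out, 0.7, atol=1e-7)


def _strip_to_latest(p: PatientRecord) -> PatientRecord:
    from dataclasses import replace
    return replace(p, scans=p.scans[-1:])


class TestVariants:
    @pytest.fixture(scope="class")
    def cohort(self):
        from cplp import SynthConfig, generate_cohort
        return generate_cohort(SynthConfig(n_patients=120, feature_dim=16,
                                           seed=42))[0]

    @pytest.fixture(scope="class")
    def ft_cfg(self):
        return FinetuneConfig(max_epochs=8, patience=8, batch_size=32, seed=3)

    def test_probabilities_in_unit_interval(self, cohort, ft_cfg):
        model = train_variant(cohort, ModelVariant.SYBIL_CS, ft_cfg)
        s = model.predict_scores(cohort.split_subset("test").patients)
        assert np.all((s > 0) & (s < 1))

    def test_sybil_cs_ignores_earlier_scans(self, cohort, ft_cfg):
        model = train_variant(cohort, ModelVariant.SYBIL_CS, ft_cfg)
        pts = [p for p in cohort.split_subset("test").patients
               if len(p.scans) > 1]
        full = model.predict_scores(pts)
        latest_only = model.predict_scores([_strip_to_latest(p) for p in pts])
        np.testing.assert_allclose(full, latest_only, atol=1e-7)

    def test_mm_lang_and_clip_finetune_share_architecture(self, cohort, ft_cfg):
        from cplp import ClipConfig, ImageEncoderConfig
        from cplp.encoders import TextHeadConfig
        img_cfg = ImageEncoderConfig(model_dim=16, heads=4, feedforward_dim=32,
                                     projection_dim=16)
        txt_cfg = TextHeadConfig(input_dim=16, hidden=(32,), projection_dim=16)
        provider = HashedTextEmbedder(16)
        from cplp.encoders import ImageEncoder, TextHead
        rng = np.random.default_rng(1)
        enc, head = ImageEncoder(img_cfg, rng), TextHead(txt_cfg, rng)
        from cplp import pretrain
        pre = pretrain(cohort, enc, head,
                       ClipConfig(batch_size=40, max_epochs=5, seed=2),
                       provider=provider)
        a = train_variant(cohort, ModelVariant.CLIP_FINETUNE, ft_cfg,
                          pretrained=pre, image_cfg=img_cfg, text_cfg=txt_cfg,
                          provider=provider)
        b = train_variant(cohort, ModelVariant.MM_LANG, ft_cfg,
                          image_cfg=img_cfg, text_cfg=txt_cfg,
                          provider=provider)
        assert set(a.modules) == set(b.modules)
        for name in a.modules:
            for k in a.modules[name].params:
                assert a.modules[name].params[k].data.shape == \
                    b.modules[name].params[k].data.shape

    def test_clip_tabular_pretraining_converges(self, cohort, ft_cfg):
        from cplp import ClipConfig
        model = train_variant(cohort, ModelVariant.CLIP_TABULAR, ft_cfg,
                              clip_cfg=ClipConfig(batch_size=40, max_epochs=8,
                                                  seed=2))
        s = model.predict_scores(cohort.split_subset("test").patients)
        assert np.all((s > 0) & (s < 1))

    def test_mm_tabular_trains(self, cohort, ft_cfg):
        model = train_variant(cohort, ModelVariant.MM_TABULAR, ft_cfg)
        s = model.predict_scores(cohort.split_subset("test").patients)
        assert len(s) == len(cohort.split_subset("test").patients)

    def test_unknown_variant_rejected(self, cohort, ft_cfg):
        with pytest.raises(ValueError):
            train_variant(cohort, "magic", ft_cfg)

    def test_clip_finetune_requires_pretrained(self, cohort, ft_cfg):
        with pytest.raises(ValueError, match="PretrainResult"):
            train_variant(cohort, ModelVariant.CLIP_FINETUNE, ft_cfg)
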
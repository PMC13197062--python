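"""Time encodings, masked transformer invariants, text head, checkpoints."""

import numpy as np
import pytest

from cplp import (ImageEncoder, ImageEncoderConfig, TextHead, TextHeadConfig,
                  TimeEncodingConfig, load_checkpoint, save_checkpoint,
                  time_encoding)


class TestTimeEncoding:
    CFG = TimeEncodingConfig(dim=16, day_scale=30.0)

    def test_day_zero_is_sines_zero_cosines_one(self):
        v = time_encoding(0, self.CFG)
        np.testing.assert_allclose(v[:8], 0.0)
        np.testing.assert_allclose(v[8:], 1.0)

    def test_first_sine_component_closed_form(self):
        for d in (30, 365, 900):
            v = time_encoding(d, self.CFG)
            assert v[0] == pytest.approx(np.sin(d / 30.0))

    def test_encodings_distinct_over_screening_range(self):
        days = np.arange(0, 3651, 5)
        V = time_encoding(days, self.CFG)
        # brute force: every pair of distinct days differs somewhere
        diffs = np.abs(V[:, None, :] - V[None, :, :]).max(axis=-1)
        diffs[np.diag_indices(len(days))] = 1.0
        assert diffs.min() > 1e-6

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            time_encoding(-1, self.CFG)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            TimeEncodingConfig(dim=15)


def _batch(rng, n=4, dim=16, n_scans=(3, 2, 1, 3)):
    feats = rng.standard_normal((n, 3, dim)).astype(np.float32)
    days = np.cumsum(rng.integers(330, 400, (n, 3)), axis=1) - 330
    mask = np.zeros((n, 3), dtype=bool)
    for i, k in enumerate(n_scans):
        mask[i, :k] = True
    return feats, days, mask


class TestImageEncoder:
    def test_embeddings_unit_norm(self, tiny_encoders, rng):
        enc, _ = tiny_encoders
        feats, days, mask = _batch(rng)
        I = enc.forward(feats, days, mask)["embedding"].data
        np.testing.assert_allclose(np.linalg.norm(I, axis=1), 1.0, atol=1e-5)

    def test_masking_invariance_bit_identical(self, tiny_encoders, rng):
        """Padded-slot contents must not influence the embedding at all."""
        enc, _ = tiny_encoders
        feats, days, mask = _batch(rng)
        ref = enc.forward(feats, days, mask)["embedding"].data
        for _ in range(10):
            alt = feats.copy()
            alt[~mask] = rng.standard_normal(alt[~mask].shape) * 100
            alt_days = days.copy()
            alt_days[~mask] = rng.integers(0, 10000, alt_days[~mask].shape)
            out = enc.forward(alt, alt_days, mask)["embedding"].data
            np.testing.assert_array_equal(out, ref)

    def test_time_sensitivity(self, tiny_encoders, rng):
        """Shifting a real scan's day changes the embedding (time encodings
        are actually used)."""
        enc, _ = tiny_encoders
        feats, days, mask = _batch(rng)
        shifted = days.copy()
        shifted[0, 1] += 200
        a = enc.forward(feats, days, mask)["embedding"].data
        b = enc.forward(feats, shifted, mask)["embedding"].data
        assert np.abs(a[0] - b[0]).max() > 1e-6
        # untouched patients unchanged
        np.testing.assert_array_equal(a[1:], b[1:])

    def test_latest_token_pooling_uses_last_real_position(self, tiny_encoders, rng):
        """With one real scan, changing that scan changes the output even
        though slot 3 is padding."""
        enc, _ = tiny_encoders
        feats, days, mask = _batch(rng, n_scans=(1, 1, 1, 1))
        alt = feats.copy()
        alt[:, 0, 0] += 1.0  # non-uniform change survives layer norm
        a = enc.forward(feats, days, mask)["embedding"].data
        b = enc.forward(alt, days, mask)["embedding"].data
        assert np.abs(a - b).max() > 1e-6

    def test_all_masked_sequence_rejected(self, tiny_encoders, rng):
        enc, _ = tiny_encoders
        feats, days, mask = _batch(rng)
        mask[0] = False
        with pytest.raises(ValueError, match="at least one real scan"):
            enc.forward(feats, days, mask)

    def test_wrong_feature_dim_rejected(self, tiny_encoders, rng):
        enc, _ = tiny_encoders
        with pytest.raises(ValueError):
            enc.forward(rng.standard_normal((2, 3, 8)), np.zeros((2, 3)),
                        np.ones((2, 3), dtype=bool))

    def test_eval_mode_deterministic(self, tiny_encoders, rng):
        enc, _ = tiny_encoders
        feats, days, mask = _batch(rng)
        a = enc.forward(feats, days, mask)["embedding"].data
        b = enc.forward(feats, days, mask)["embedding"].data
        np.testing.assert_array_equal(a, b)

    def test_dropout_rng_perturbs_training_pass(self, rng):
        cfg = ImageEncoderConfig(model_dim=16, heads=4, feedforward_dim=32,
                                 projection_dim=16, dropout=0.5)
        enc = ImageEncoder(cfg, np.random.default_rng(1))
        feats, days, mask = _batch(rng)
        a = enc.forward(feats, days, mask,
                        dropout_rng=np.random.default_rng(2))["embedding"].data
        b = enc.forward(feats, days, mask)["embedding"].data
        assert np.abs(a - b).max() > 1e-6


class TestTextHead:
    def test_unit_norm_and_deterministic(self, tiny_encoders, rng):
        _, head = tiny_encoders
        x = rng.standard_normal((5, 16))
        a = head.forward(x)["embedding"].data
        b = head.forward(x)["embedding"].data
        np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-5)
        np.testing.assert_array_equal(a, b)

    def test_zeroed_final_layer_maps_everything_to_bias_direction(self, rng):
        head = TextHead(TextHeadConfig(input_dim=8, hidden=(8,),
                                       projection_dim=4),
                        np.random.default_rng(0))
        head.params["W1"].data[:] = 0.0
        head.params["b1"].data[:] = np.array([3.0, 0.0, 4.0, 0.0])
        out = head.forward(rng.standard_normal((6, 8)))["embedding"].data
        np.testing.assert_allclose(out, np.tile([0.6, 0.0, 0.8, 0.0], (6, 1)),
                                   atol=1e-6)

    def test_dimension_mismatch_rejected(self, tiny_encoders, rng):
        _, head = tiny_encoders
        with pytest.raises(ValueError):
            head.forward(rng.standard_normal((3, 7)))


class TestCheckpoint:
    def test_round_trip_restores_weights(self, tiny_encoders, tmp_path, rng):
        enc, head = tiny_encoders
        feats, days, mask = _batch(rng)
        ref = enc.forward(feats, days, mask)["embedding"].data
        save_checkpoint(tmp_path / "w.npz", {"image": enc, "text": head},
                        config={"note": "test"}, seed=5)
        enc2 = ImageEncoder(enc.cfg, np.random.default_rng(99))
        head2 = TextHead(head.cfg, np.random.default_rng(99))
        header = load_checkpoint(tmp_path / "w.npz",
                                 {"image": enc2, "text": head2})
        assert header["seed"] == 5
        out = enc2.forward(feats, days, mask)["embedding"].data
        np.testing.assert_array_equal(out, ref)

    def test_shape_mismatch_rejected(self, tiny_encoders, tmp_path):
        enc, head = tiny_encoders
        save_checkpoint(tmp_path / "w.npz", {"image": enc}, config={})
        other = ImageEncoder(ImageEncoderConfig(model_dim=8, heads=2,
                                                feedforward_dim=8,
                                                projection_dim=8),
                             np.random.default_rng(0))
        with pytest.raises(ValueError, match="shape mismatch"):
            load_checkpoint(tmp_path / "w.npz", {"image": other})
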
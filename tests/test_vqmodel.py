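"""Quantized-autoencoder contracts: quantization, perplexity, losses, toggles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vqcyto.vqmodel import (
    Codebook,
    ConfigurationError,
    InputError,
    ModelConfig,
    QuantizationError,
    assignment_counts,
    build_model,
    load_model,
    perplexity,
    save_model,
    split_quantize,
    total_loss,
)

from conftest import tiny_model_config


def brute_force_indices(latent, codes, n_splits):
    """Exhaustive nearest-neighbor assignment, position by position."""
    b, c, h, w = latent.shape
    dim = c // n_splits
    out = np.zeros((b, h, w, n_splits), np.intp)
    for bi in range(b):
        for y in range(h):
            for x in range(w):
                vec = latent[bi, :, y, x]
                for s in range(n_splits):
                    sub = vec[s * dim : (s + 1) * dim]
                    d = [np.linalg.norm(sub - code) for code in codes]
                    out[bi, y, x, s] = int(np.argmin(d))
    return out


# ---------------------------------------------------------------------------
# split quantization
# ---------------------------------------------------------------------------


class TestSplitQuantize:
    def test_two_code_example(self):
        cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
        latent = np.array([0.1, 0.1, 0.9, 0.9]).reshape(1, 4, 1, 1)
        res = split_quantize(latent, cb, 2)
        np.testing.assert_array_equal(res.indices[0, 0, 0], [0, 1])
        np.testing.assert_allclose(
            res.quantized[0, :, 0, 0], [0.0, 0.0, 1.0, 1.0]
        )

    def test_exact_code_fixed_point(self, rng):
        cb = Codebook(rng.normal(0, 1, (5, 3)))
        latent = np.concatenate([cb.codes[2], cb.codes[4]]).reshape(1, 6, 1, 1)
        res = split_quantize(latent, cb, 2)
        np.testing.assert_allclose(res.quantized, latent, rtol=1e-6)
        assert res.codebook_loss == 0.0 and res.commitment_loss == 0.0

    def test_nsplits_one_equals_standard_vq(self, rng):
        cb = Codebook(rng.normal(0, 1, (8, 6)))
        latent = rng.normal(0, 1, (2, 6, 3, 3)).astype(np.float32)
        res = split_quantize(latent, cb, 1)
        oracle = brute_force_indices(latent, cb.codes, 1)[..., 0]
        np.testing.assert_array_equal(res.indices, oracle)

    def test_matches_exhaustive_search(self, rng):
        cb = Codebook(rng.normal(0, 1, (32, 4)).astype(np.float32))
        latent = rng.normal(0, 1, (4, 12, 5, 5)).astype(np.float32)
        res = split_quantize(latent, cb, 3)
        oracle = brute_force_indices(latent, cb.codes, 3)
        np.testing.assert_array_equal(res.indices, oracle)

    def test_idempotence(self, rng):
        cb = Codebook(rng.normal(0, 1, (16, 4)))
        latent = rng.normal(0, 1, (2, 8, 4, 4)).astype(np.float32)
        first = split_quantize(latent, cb, 2)
        second = split_quantize(first.quantized, cb, 2)
        np.testing.assert_array_equal(first.indices, second.indices)
        assert second.codebook_loss == 0.0

    def test_tie_breaks_to_lowest_index(self):
        cb = Codebook(np.array([[1.0], [1.0], [-1.0]]))
        res = split_quantize(np.array([[[[1.0]]]]), cb, 1)
        assert res.indices[0, 0, 0] == 0

    def test_dimension_mismatch_rejected(self, rng):
        cb = Codebook(rng.normal(0, 1, (4, 3)))
        with pytest.raises(QuantizationError):
            split_quantize(rng.normal(0, 1, (1, 7, 2, 2)), cb, 2)
        with pytest.raises(QuantizationError):
            split_quantize(rng.normal(0, 1, (1, 8, 2, 2)), cb, 2)


# ---------------------------------------------------------------------------
# perplexity
# ---------------------------------------------------------------------------


class TestPerplexity:
    def test_degenerate_use_is_one(self):
        counts = np.zeros(16)
        counts[3] = 100
        assert perplexity(counts) == pytest.approx(1.0)

    def test_uniform_use_is_codebook_size(self):
        assert perplexity(np.full(32, 7.0)) == pytest.approx(32.0)

    def test_closed_form_half_quarter_quarter(self):
        assert perplexity(np.array([2.0, 1.0, 1.0])) == pytest.approx(2**1.5)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InputError):
            perplexity(np.zeros(8))

    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=64).filter(
            lambda c: sum(c) > 0
        ),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_scale_invariance(self, counts, factor):
        counts = np.asarray(counts, float)
        p = perplexity(counts)
        assert 1.0 <= p <= len(counts) + 1e-9
        assert perplexity(counts * factor) == pytest.approx(p)

    def test_assignment_counts_tally(self, rng):
        idx = rng.integers(0, 7, (3, 4, 4))
        counts = assignment_counts(idx, 7)
        assert counts.sum() == idx.size
        for k in range(7):
            assert counts[k] == (idx == k).sum()


# ---------------------------------------------------------------------------
# configuration and architecture contracts
# ---------------------------------------------------------------------------


class TestModelConfig:
    def test_split_divisibility_enforced(self):
        with pytest.raises(ConfigurationError):
            tiny_model_config(n_splits=5)

    def test_local_channels_must_match_code_dim(self):
        with pytest.raises(ConfigurationError):
            tiny_model_config(local_shape=(16, 16, 8))

    def test_default_shapes_are_canonical(self):
        cfg = ModelConfig(n_classes=3)
        assert cfg.global_shape == (4, 4, 576)
        assert cfg.local_shape == (25, 25, 64)
        assert cfg.n_splits * cfg.code_dim == 576


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(tiny_model_config(), seed=0)


@pytest.fixture(scope="module")
def batch():
    return np.random.default_rng(3).normal(0, 1, (2, 2, 64, 64)).astype(
        np.float32
    )


class TestForward:
    def test_latent_shape_contracts(self, tiny_model, batch):
        out = tiny_model.forward(batch)
        assert out.global_latent.shape == (2, 64, 4, 4)
        assert out.local_latent.shape == (2, 16, 16, 16)
        assert out.quant_local.indices.shape == (2, 16, 16)
        assert out.quant_global.indices.shape == (2, 4, 4, 4)
        assert out.reconstruction.shape == batch.shape
        assert out.intermediate_reconstruction.shape == out.local_latent.shape

    def test_indices_within_codebook_range(self, tiny_model, batch):
        out = tiny_model.forward(batch)
        assert out.quant_local.indices.min() >= 0
        assert out.quant_local.indices.max() < 32

    def test_forward_deterministic(self, tiny_model, batch):
        a = tiny_model.forward(batch)
        b = tiny_model.forward(batch)
        np.testing.assert_array_equal(a.reconstruction, b.reconstruction)
        np.testing.assert_array_equal(
            a.quant_global.indices, b.quant_global.indices
        )

    def test_untrained_losses_finite_and_nonnegative(self, tiny_model, batch):
        out = tiny_model.forward(batch)
        bundle = total_loss(out, batch, np.array([0, 1]), tiny_model.config)
        for term in (bundle.recon1, bundle.recon2, bundle.vq1, bundle.vq2,
                     bundle.ce1, bundle.ce2):
            assert np.isfinite(term) and term >= 0
        assert np.isfinite(bundle.total)

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(InputError):
            tiny_model.forward(np.zeros((1, 2, 32, 32), np.float32))


class TestAblationToggles:
    def test_without_nuclear_channel(self):
        model = build_model(
            tiny_model_config(use_nuclear_channel=False), seed=0
        )
        x = np.zeros((1, 1, 64, 64), np.float32)
        out = model.forward(x)
        assert out.reconstruction.shape == x.shape

    def test_without_id_task(self):
        model = build_model(tiny_model_config(use_id_task=False), seed=0)
        out = model.forward(np.zeros((1, 2, 64, 64), np.float32))
        assert out.logits_local is None and out.logits_global is None
        bundle = total_loss(
            out, np.zeros((1, 2, 64, 64), np.float32), None, model.config
        )
        assert bundle.ce1 == 0.0 and bundle.ce2 == 0.0

    def test_without_decoder(self):
        model = build_model(tiny_model_config(use_decoder=False), seed=0)
        out = model.forward(np.zeros((1, 2, 64, 64), np.float32))
        assert out.reconstruction is None
        bundle = total_loss(
            out,
            np.zeros((1, 2, 64, 64), np.float32),
            np.array([0]),
            model.config,
        )
        assert bundle.recon1 == 0.0 and bundle.recon2 == 0.0

    def test_without_vq_latent_passes_through(self):
        model = build_model(tiny_model_config(use_vq=False), seed=0)
        out = model.forward(np.zeros((1, 2, 64, 64), np.float32))
        np.testing.assert_array_equal(
            out.quant_local.quantized, out.local_latent
        )
        bundle = total_loss(
            out,
            np.zeros((1, 2, 64, 64), np.float32),
            np.array([0]),
            model.config,
        )
        assert bundle.vq1 == 0.0 and bundle.vq2 == 0.0

    def test_without_split_quantization_uses_whole_vectors(self):
        model = build_model(
            tiny_model_config(use_split_quantization=False), seed=0
        )
        out = model.forward(np.zeros((1, 2, 64, 64), np.float32))
        assert out.quant_global.indices.shape == (1, 4, 4)
        assert model.codebook_global.codes.shape == (32, 64)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


class TestTotalLoss:
    def test_uniform_logits_cross_entropy_is_log_c(self):
        from vqcyto._nn import softmax_cross_entropy

        logits = np.zeros((4, 7))
        loss, _ = softmax_cross_entropy(logits, np.array([0, 3, 5, 6]))
        assert loss == pytest.approx(np.log(7), rel=1e-6)

    def test_weight_linearity(self):
        model = build_model(tiny_model_config(), seed=0)
        x = np.random.default_rng(1).normal(0, 1, (2, 2, 64, 64)).astype(
            np.float32
        )
        out = model.forward(x)
        t = np.array([0, 1])
        base = total_loss(out, x, t, model.config, {"recon1": 1.0})
        doubled = total_loss(out, x, t, model.config, {"recon1": 2.0})
        assert doubled.total - base.total == pytest.approx(
            base.recon1, rel=1e-5
        )

    def test_invalid_target_rejected(self):
        model = build_model(tiny_model_config(), seed=0)
        x = np.zeros((1, 2, 64, 64), np.float32)
        out = model.forward(x)
        with pytest.raises(InputError):
            total_loss(out, x, np.array([99]), model.config)


# ---------------------------------------------------------------------------
# codebook EMA and checkpoints
# ---------------------------------------------------------------------------


def test_ema_update_moves_codes_toward_assigned_vectors(rng):
    cb = Codebook(np.array([[0.0, 0.0], [10.0, 10.0]]), decay=0.5)
    vectors = np.array([[1.0, 1.0], [1.2, 0.8], [9.0, 9.0]])
    idx = np.array([0, 0, 1])
    before = cb.codes.copy()
    cb.ema_update(vectors, idx)
    assert np.linalg.norm(cb.codes[0] - [1.1, 0.9]) < np.linalg.norm(
        before[0] - [1.1, 0.9]
    )
    assert np.linalg.norm(cb.codes[1] - [9.0, 9.0]) < np.linalg.norm(
        before[1] - [9.0, 9.0]
    )


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_model(tiny_model_config(), seed=4)
    x = rng.normal(0, 1, (1, 2, 64, 64)).astype(np.float32)
    ref = model.forward(x)
    save_model(model, tmp_path / "ckpt")
    loaded = load_model(tmp_path / "ckpt")
    out = loaded.forward(x)
    np.testing.assert_allclose(out.reconstruction, ref.reconstruction, atol=1e-6)
    np.testing.assert_array_equal(
        out.quant_local.indices, ref.quant_local.indices
    )
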
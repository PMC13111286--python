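"""Track assembly: shapes, normalisation, ablations, parameter counts."""

import numpy as np
import pytest

from qhandpd.autodiff import Tensor
from qhandpd.network import (HybridModel, ModelConfig, build_model,
                             count_parameters, reduced_config)


SMALL = dict(image_side=64, stem_channels=8, stage_channels=(8, 16),
             stage_strides=(1, 2), stage_variants=("CA_SE", "TRIPLET"),
             head_hidden=(32,), se_reduction=4, ca_reduction=4)


@pytest.fixture(scope="module")
def small_model():
    return build_model(ModelConfig(**SMALL), seed=3)


def _img(rng, side=64, n=1):
    return rng.random((n, side, side, 3)).astype(np.float32)


def _feat(rng, n=1):
    return rng.uniform(0, np.pi, (n, 6)).astype(np.float32)


class TestTVSFE:
    def test_output_is_eight_bounded_expectations(self, small_model, rng):
        out = small_model.tvsfe(small_model._to_nchw(_img(rng)))
        assert out.shape == (1, 8)
        assert np.all(out.data >= -1) and np.all(out.data <= 1)

    def test_pre_quantum_embedding_unit_norm(self, small_model, rng):
        emb = small_model.tvsfe.embed(small_model._to_nchw(_img(rng, n=2)))
        assert emb.shape == (2, 256)
        assert np.allclose(np.linalg.norm(emb.data, axis=1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic(self, small_model, rng):
        img = _img(rng)
        a = small_model.predict_proba(img, _feat(rng))
        b = small_model.predict_proba(img, _feat(rng))
        # same features drawn twice from a fresh rng differ; use fixed ones
        f = np.full((1, 6), 1.0, dtype=np.float32)
        a = small_model.predict_proba(img, f)
        b = small_model.predict_proba(img, f)
        assert np.array_equal(a, b)

    def test_wrong_input_size_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            small_model.tvsfe(small_model._to_nchw(_img(rng, side=32)))


class TestVQFMN:
    def test_depth_zero_returns_cosine(self, rng):
        cfg = ModelConfig(**SMALL, tabular_circuit_depth=0)
        model = build_model(cfg, seed=0)
        x = rng.uniform(0, np.pi, (3, 6))
        out = model.vqfmn(Tensor(x))
        assert np.allclose(out.data, np.cos(x), atol=1e-6)

    def test_output_length_matches_features(self, small_model, rng):
        out = small_model.vqfmn(Tensor(_feat(rng, n=4)))
        assert out.shape == (4, 6)
        assert np.all(np.abs(out.data) <= 1.0 + 1e-9)

    def test_out_of_range_features_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.vqfmn(Tensor(np.full((1, 6), 4.0)))


class TestFusion:
    def test_probabilities_sum_to_one(self, small_model, rng):
        p = small_model.predict_proba(_img(rng, n=3), _feat(rng, n=3))
        assert p.shape == (3, 2)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_final_layer_gives_uniform(self, small_model, rng):
        final = small_model.fusion.head.layers[-1]
        w, b = final.weight.data.copy(), final.bias.data.copy()
        final.weight.data[:] = 0.0
        final.bias.data[:] = 0.0
        try:
            p = small_model.predict_proba(_img(rng), _feat(rng))
            assert np.allclose(p, 0.5, atol=1e-7)
        finally:
            final.weight.data = w
            final.bias.data = b

    def test_concatenated_width(self, small_model):
        first = small_model.fusion.head.layers[0]
        assert first.weight.shape[0] == 8 + 6


class TestGradientFlow:
    def test_all_components_receive_gradient(self, rng):
        model = build_model(ModelConfig(**SMALL), seed=1)
        probs = model(_img(rng, n=2), _feat(rng, n=2))
        probs[np.arange(2), np.array([0, 1])].log().sum().backward()
        assert np.abs(model.tvsfe.stem.weight.grad).sum() > 0
        assert np.abs(model.tvsfe.circuit_angles.grad).sum() > 0
        assert np.abs(model.vqfmn.circuit_angles.grad).sum() > 0


class TestAblations:
    def test_image_only_and_tabular_only_constructible(self, rng):
        img_only = build_model(ModelConfig(**SMALL, use_tabular_track=False),
                               seed=0)
        p = img_only.predict_proba(_img(rng), None)
        assert np.allclose(p.sum(), 1.0, atol=1e-6)
        tab_only = build_model(ModelConfig(use_image_track=False), seed=0)
        p = tab_only.predict_proba(None, _feat(rng))
        assert np.allclose(p.sum(), 1.0, atol=1e-6)

    def test_no_quantum_keeps_shape_contracts(self, rng):
        model = build_model(ModelConfig(**SMALL, quantum=False), seed=0)
        out = model.tvsfe(model._to_nchw(_img(rng)))
        assert out.shape == (1, 8)
        out = model.vqfmn(Tensor(_feat(rng)))
        assert out.shape == (1, 6)
        p = model.predict_proba(_img(rng), _feat(rng))
        assert np.allclose(p.sum(), 1.0, atol=1e-6)

    def test_mismatched_qubits_and_embedding_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(embedding_dim=128, image_qubits=8)


class TestParameterCounts:
    def test_circuit_params_formula(self):
        model = build_model(ModelConfig(use_image_track=False,
                                        tabular_circuit_depth=4), seed=0)
        assert model.vqfmn.circuit_angles.size == 3 * 6 * 4
        deeper = build_model(ModelConfig(use_image_track=False,
                                         tabular_circuit_depth=8), seed=0)
        assert deeper.vqfmn.circuit_angles.size == 2 * 3 * 6 * 4

    def test_default_model_total_in_expected_band(self):
        total = count_parameters(build_model(seed=0))["total"]
        assert 1_000_000 <= total <= 2_000_000

    def test_counts_split_by_track(self, small_model):
        c = count_parameters(small_model)
        assert c["total"] == c["tvsfe"] + c["vqfmn"] + c["fusion"]


def test_reduced_config_forward_shape(rng):
    model = build_model(reduced_config(), seed=0)
    p = model.predict_proba(rng.random((2, 128, 128, 3)).astype(np.float32),
                            _feat(rng, n=2))
    assert p.shape == (2, 2)
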
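"""Capsule math against independent oracles, plus architecture contracts."""

import numpy as np
import pytest

from piradscaps.autodiff import Tensor
from piradscaps.network import (
    CapsOrdinalSegNet,
    NetworkConfig,
    attention_fuse,
    capsule_lengths,
    dynamic_routing,
    squash,
)

RNG = np.random.default_rng(7)


def loop_routing_oracle(u_hat: np.ndarray, iterations: int) -> np.ndarray:
    """Straight-line routing-by-agreement with explicit Python loops."""

    def squash_np(s):
        n2 = (s ** 2).sum()
        return (n2 / (1 + n2)) * s / np.sqrt(n2 + 1e-8)

    n, n_in, n_out, dim = u_hat.shape
    out = np.zeros((n, n_out, dim))
    for b in range(n):
        logits = np.zeros((n_in, n_out))
        for it in range(iterations):
            c = np.exp(logits - logits.max(axis=1, keepdims=True))
            c /= c.sum(axis=1, keepdims=True)
            v = np.zeros((n_out, dim))
            for j in range(n_out):
                s = sum(c[i, j] * u_hat[b, i, j] for i in range(n_in))
                v[j] = squash_np(s)
            if it + 1 < iterations:
                for i in range(n_in):
                    for j in range(n_out):
                        logits[i, j] += float(u_hat[b, i, j] @ v[j])
        out[b] = v
    return out


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.all(squash(Tensor(np.zeros((1, 4), np.float32))).data == 0)

    def test_unit_vector_halves_its_norm(self):
        v = np.zeros((1, 8), np.float32)
        v[0, 0] = 1.0
        out = squash(Tensor(v)).data
        assert np.isclose(np.linalg.norm(out), 0.5, atol=1e-5)

    def test_norm_approaches_one_from_below(self):
        v = RNG.normal(size=(50, 6)).astype(np.float32) * 100
        norms = np.linalg.norm(squash(Tensor(v)).data, axis=1)
        assert np.all(norms < 1.0)
        assert norms.min() > 0.99

    def test_direction_preserved(self):
        v = RNG.normal(size=(10, 5)).astype(np.float32)
        out = squash(Tensor(v)).data
        cos = (v * out).sum(1) / (np.linalg.norm(v, axis=1) * np.linalg.norm(out, axis=1))
        np.testing.assert_allclose(cos, 1.0, atol=1e-5)


class TestDynamicRouting:
    def test_singleton_coupling_is_exactly_one(self):
        u_hat = Tensor(RNG.normal(size=(1, 1, 1, 4)).astype(np.float32))
        record = []
        dynamic_routing(u_hat, iterations=3, record=record)
        for c in record:
            assert np.all(c == 1.0)

    def test_coupling_sums_to_one_every_iteration(self):
        u_hat = Tensor(RNG.normal(size=(2, 6, 3, 4)).astype(np.float32))
        record = []
        dynamic_routing(u_hat, iterations=4, record=record)
        assert len(record) == 4
        for c in record:
            np.testing.assert_allclose(c.sum(axis=2), 1.0, atol=1e-6)

    def test_two_by_two_matches_loop_oracle(self):
        u_hat = RNG.normal(size=(1, 2, 2, 3)).astype(np.float32)
        ours = dynamic_routing(Tensor(u_hat), iterations=3).data
        oracle = loop_routing_oracle(u_hat.astype(float), iterations=3)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_larger_instance_matches_loop_oracle(self):
        u_hat = RNG.normal(size=(2, 5, 3, 4)).astype(np.float32)
        ours = dynamic_routing(Tensor(u_hat), iterations=3).data
        oracle = loop_routing_oracle(u_hat.astype(float), iterations=3)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_rejects_zero_iterations(self):
        with pytest.raises(ValueError):
            dynamic_routing(Tensor(np.zeros((1, 1, 1, 2), np.float32)), iterations=0)


class TestShapeContracts:
    """Every printed shape of the published architecture, default profile."""

    def test_encoder_reaches_6x6x256(self, default_model):
        x = Tensor(RNG.normal(size=(2, 3, 100, 100)).astype(np.float32))
        feats, skips = default_model.encoder_forward(x)
        assert feats.shape == (2, 256, 6, 6)
        assert [s.shape[1] for s in skips] == [32, 64, 128, 256]

    def test_primary_caps_grid_is_32_types_8_dims(self, default_model):
        feats, _ = default_model.encoder_forward(
            Tensor(RNG.normal(size=(1, 3, 100, 100)).astype(np.float32)))
        grid = default_model.primary_caps(feats)
        assert grid.shape == (1, 32, 8, 6, 6)
        norms = np.sqrt((grid.data ** 2).sum(axis=2))
        assert np.all(norms < 1.0)

    def test_zero_features_give_zero_capsules(self, default_model):
        grid = default_model.primary_caps(Tensor(np.zeros((1, 256, 6, 6), np.float32)))
        bias_only = default_model.primary_conv.bias.data
        # with zero bias the capsules are exactly zero
        if np.all(bias_only == 0):
            assert np.all(grid.data == 0)

    def test_class_caps_are_two_vectors_with_short_lengths(self, default_model):
        feats, _ = default_model.encoder_forward(
            Tensor(RNG.normal(size=(2, 3, 100, 100)).astype(np.float32)))
        caps = default_model.class_caps(default_model.caps_to_stack(
            default_model.primary_caps(feats)))
        assert caps.shape == (2, 2, 16)
        lengths = capsule_lengths(caps).data
        assert np.all((lengths >= 0) & (lengths < 1))

    def test_full_forward_chain_shapes(self, default_model):
        out = default_model(Tensor(RNG.normal(size=(3, 3, 100, 100)).astype(np.float32)))
        assert out["ordinal"].shape == (3, 4, 100, 100)
        assert out["bph"].shape == (3, 1, 100, 100)
        assert out["grade_lengths"].shape == (3, 2)
        assert out["reconstruction"].shape == (3, 256, 6, 6)
        assert np.all((out["ordinal"].data >= 0) & (out["ordinal"].data <= 1))

    def test_wrong_input_shape_rejected(self, default_model):
        with pytest.raises(ValueError):
            default_model.encoder_forward(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        with pytest.raises(ValueError):
            default_model(Tensor(np.zeros((0, 3, 100, 100), np.float32)))

    def test_eval_determinism(self, desk_model):
        x = Tensor(RNG.normal(size=(2, 3, 100, 100)).astype(np.float32))
        a = desk_model(x)
        b = desk_model(x)
        np.testing.assert_array_equal(a["ordinal"].data, b["ordinal"].data)
        np.testing.assert_array_equal(a["grade_lengths"].data, b["grade_lengths"].data)


class TestCapsGRU:
    @pytest.mark.parametrize("n_slices", [1, 9, 14])
    def test_state_shape_equals_input_shape(self, desk_model, n_slices):
        cc = desk_model.config.caps_channels
        e = Tensor(RNG.normal(size=(n_slices, cc, 6, 6)).astype(np.float32))
        h = desk_model.caps_gru(e)
        assert h.shape == e.shape
        assert np.all(np.isfinite(h.data))

    def test_recurrence_is_order_sensitive(self, desk_model):
        cc = desk_model.config.caps_channels
        e = RNG.normal(size=(5, cc, 6, 6)).astype(np.float32)
        fwd = desk_model.caps_gru(Tensor(e)).data
        rev = desk_model.caps_gru(Tensor(e[::-1].copy())).data
        assert not np.allclose(fwd, rev[::-1])

    def test_disabling_gru_changes_outputs(self):
        x = Tensor(RNG.normal(size=(4, 3, 100, 100)).astype(np.float32))
        with_gru = CapsOrdinalSegNet(NetworkConfig.desk(seed=1, gru_enabled=True))(x)
        without = CapsOrdinalSegNet(NetworkConfig.desk(seed=1, gru_enabled=False))(x)
        assert not np.allclose(with_gru["ordinal"].data, without["ordinal"].data)


class TestReconstructionAndFusion:
    def test_reconstruction_shape_matches_encoder_features(self, default_model):
        caps = Tensor(RNG.normal(size=(2, 2, 16)).astype(np.float32) * 0.1)
        rec = default_model.reconstruct(caps, target_class=np.array([0, 1]))
        assert rec.shape == (2, 256, 6, 6)

    def test_masking_ignores_the_unselected_capsule(self, default_model):
        caps = RNG.normal(size=(1, 2, 16)).astype(np.float32) * 0.1
        perturbed = caps.copy()
        perturbed[0, 1] += 5.0  # only the non-selected capsule changes
        a = default_model.reconstruct(Tensor(caps), target_class=np.array([0])).data
        b = default_model.reconstruct(Tensor(perturbed), target_class=np.array([0])).data
        np.testing.assert_array_equal(a, b)

    def test_zero_capsules_give_bias_only_reconstruction(self, default_model):
        rec = default_model.reconstruct(Tensor(np.zeros((2, 2, 16), np.float32)),
                                        target_class=np.array([0, 1])).data
        np.testing.assert_array_equal(rec[0], rec[1])

    def test_attention_gate_limits(self):
        enc = Tensor(RNG.normal(size=(1, 8, 6, 6)).astype(np.float32))
        wide_open = Tensor(np.full((1, 8, 6, 6), 50.0, np.float32))
        closed = Tensor(np.full((1, 8, 6, 6), -50.0, np.float32))
        np.testing.assert_allclose(attention_fuse(enc, wide_open).data, enc.data, atol=1e-5)
        np.testing.assert_allclose(attention_fuse(enc, closed).data, 0.0, atol=1e-5)
        with pytest.raises(ValueError):
            attention_fuse(enc, Tensor(np.zeros((1, 4, 6, 6), np.float32)))


def test_parameter_count_is_stable_across_builds():
    a = CapsOrdinalSegNet(NetworkConfig(seed=5))
    b = CapsOrdinalSegNet(NetworkConfig(seed=5))
    assert a.n_parameters() == b.n_parameters() > 0
    for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert ka == kb
        np.testing.assert_array_equal(pa.data, pb.data)
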
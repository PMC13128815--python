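import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitmoment.errors import ConfigurationError, DimensionError, ParameterError
from gaitmoment.model import (
    AttentionParams,
    LSTMParams,
    LSTMState,
    ModelConfig,
    attention,
    build_variant,
    forward_reference,
    lstm_step,
)


def random_lstm_params(hidden, feature, rng, biases=False):
    def mat(shape):
        return rng.standard_normal(shape)

    kw = {}
    if biases:
        kw = {f"b_{g}": rng.standard_normal(hidden) for g in "ifoc"}
    return LSTMParams(
        W_i=mat((hidden, feature)), W_f=mat((hidden, feature)),
        W_o=mat((hidden, feature)), W_c=mat((hidden, feature)),
        U_i=mat((hidden, hidden)), U_f=mat((hidden, hidden)),
        U_o=mat((hidden, hidden)), U_c=mat((hidden, hidden)),
        **kw,
    )


def scalar_lstm_step(t, prev, p):
    """Pocket-calculator recomputation of the gate recurrence, zero biases."""
    hidden, feature = p.W_i.shape
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    C, H = np.empty(hidden), np.empty(hidden)
    for i in range(hidden):
        zi = sum(p.W_i[i, j] * t[j] for j in range(feature)) + sum(
            p.U_i[i, j] * prev.H[j] for j in range(hidden))
        zf = sum(p.W_f[i, j] * t[j] for j in range(feature)) + sum(
            p.U_f[i, j] * prev.H[j] for j in range(hidden))
        zo = sum(p.W_o[i, j] * t[j] for j in range(feature)) + sum(
            p.U_o[i, j] * prev.H[j] for j in range(hidden))
        zc = sum(p.W_c[i, j] * t[j] for j in range(feature)) + sum(
            p.U_c[i, j] * prev.H[j] for j in range(hidden))
        C[i] = sig(zf) * prev.C[i] + sig(zi) * math.tanh(zc)
        H[i] = sig(zo) * math.tanh(C[i])
    return C, H


class TestLSTMStep:
    def test_zero_weight_closed_form(self):
        hidden = 4
        p = LSTMParams(
            **{f"W_{g}": np.zeros((hidden, 2)) for g in "ifoc"},
            **{f"U_{g}": np.zeros((hidden, hidden)) for g in "ifoc"},
        )
        c0 = np.array([0.3, -1.2, 0.0, 2.0])
        prev = LSTMState(C=c0, H=np.zeros(hidden))
        out = lstm_step(np.ones(2), prev, p)
        np.testing.assert_allclose(out.C, 0.5 * c0, atol=1e-15)
        np.testing.assert_allclose(out.H, 0.5 * np.tanh(0.5 * c0), atol=1e-15)

    def test_scalar_case_matches_hand_computation(self, rng):
        p = random_lstm_params(1, 1, rng)
        prev = LSTMState(C=rng.standard_normal(1), H=np.tanh(rng.standard_normal(1)))
        t = rng.standard_normal(1)
        out = lstm_step(t, prev, p)
        C, H = scalar_lstm_step(t, prev, p)
        np.testing.assert_allclose(out.C, C, atol=1e-12)
        np.testing.assert_allclose(out.H, H, atol=1e-12)

    def test_100_random_cases_vs_scalar_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hidden = int(rng.integers(1, 5))
            feature = int(rng.integers(1, 5))
            p = random_lstm_params(hidden, feature, rng)
            prev = LSTMState(
                C=rng.standard_normal(hidden), H=np.tanh(rng.standard_normal(hidden))
            )
            t = rng.standard_normal(feature)
            out = lstm_step(t, prev, p)
            C, H = scalar_lstm_step(t, prev, p)
            np.testing.assert_allclose(out.C, C, atol=1e-12)
            np.testing.assert_allclose(out.H, H, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_hidden_state_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = random_lstm_params(3, 2, rng, biases=True)
        prev = LSTMState(C=rng.standard_normal(3) * 5, H=np.tanh(rng.standard_normal(3)))
        out = lstm_step(rng.standard_normal(2) * 10, prev, p)
        assert np.all(np.abs(out.H) < 1.0)

    def test_shape_mismatch_rejected(self, rng):
        p = random_lstm_params(3, 2, rng)
        prev = LSTMState(C=np.zeros(3), H=np.zeros(3))
        with pytest.raises(DimensionError):
            lstm_step(np.zeros(5), prev, p)

    def test_non_finite_input_rejected(self, rng):
        p = random_lstm_params(2, 2, rng)
        prev = LSTMState(C=np.zeros(2), H=np.zeros(2))
        with pytest.raises(ParameterError):
            lstm_step(np.array([np.inf, 0.0]), prev, p)


class TestAttention:
    def test_singleton_sequence(self, rng):
        x = rng.standard_normal((1, 4))
        ctx = attention(x, AttentionParams(W=rng.standard_normal(4)))
        np.testing.assert_allclose(ctx, x[0], atol=1e-12)

    def test_zero_scores_give_mean(self, rng):
        x = rng.standard_normal((6, 3))
        ctx = attention(x, AttentionParams(W=np.zeros(3)))
        np.testing.assert_allclose(ctx, x.mean(axis=0), atol=1e-12)

    def test_matches_explicit_softmax_oracle(self, rng):
        x = rng.standard_normal((5, 4))
        w = rng.standard_normal(4)
        scores = np.array([x[t] @ w for t in range(5)])
        e = np.exp(scores)
        weights = e / e.sum()
        expected = sum(weights[t] * x[t] for t in range(5))
        np.testing.assert_allclose(attention(x, AttentionParams(W=w)), expected, atol=1e-9)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ParameterError):
            attention(np.empty((0, 3)), AttentionParams(W=np.zeros(3)))

    @given(seed=st.integers(0, 10_000), t_len=st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_context_in_convex_hull(self, seed, t_len):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((t_len, 3)) * 10
        w = rng.standard_normal(3)
        ctx = attention(x, AttentionParams(W=w))
        assert np.all(ctx >= x.min(axis=0) - 1e-9)
        assert np.all(ctx <= x.max(axis=0) + 1e-9)

    def test_weights_invariant_to_constant_score_shift(self, rng):
        x = rng.standard_normal((7, 3))
        w = rng.standard_normal(3)
        scores = x @ w
        e1 = np.exp(scores - scores.max())
        e2 = np.exp((scores + 123.4) - (scores + 123.4).max())
        np.testing.assert_allclose(e1 / e1.sum(), e2 / e2.sum(), atol=1e-12)


class TestModelConfig:
    def test_defaults_follow_protocol(self):
        cfg = ModelConfig()
        assert (cfg.lr, cfg.epochs, cfg.batch, cfg.dropout) == (0.001, 30, 60, 0.2)
        assert cfg.window_len == 60 and cfg.latent_dim == 15

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(variant="VI")

    def test_window_len_divisible_by_4(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(window_len=62)

    @pytest.mark.parametrize(
        "variant,flags",
        [
            ("I", dict(spectral=False, autoencoder=False, conv=False, attention=False)),
            ("II", dict(spectral=False, autoencoder=False, conv=False, attention=True)),
            ("III", dict(spectral=True, autoencoder=True, conv=False, attention=False)),
            ("IV", dict(spectral=True, autoencoder=True, conv=False, attention=True)),
            ("V", dict(spectral=True, autoencoder=True, conv=True, attention=True)),
        ],
    )
    def test_component_flags(self, variant, flags):
        assert ModelConfig(variant=variant).component_flags() == flags


def small_cfg(variant, **kw):
    defaults = dict(variant=variant, window_len=16, hidden=8, n_channels=3,
                    n_targets=2, seed=3)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestBuildVariant:
    def test_variant_i_has_no_extra_components(self):
        model = build_variant(small_cfg("I"))
        names = set(model.params)
        assert not any(n.startswith(("enc.", "dec.", "conv.", "att.")) for n in names)

    def test_variant_v_has_all_components(self):
        model = build_variant(small_cfg("V"))
        names = set(model.params)
        for prefix in ("enc.", "dec.", "conv.", "att.", "lstm.", "head."):
            assert any(n.startswith(prefix) for n in names), prefix

    def test_parameter_count_ordering(self):
        counts = {v: build_variant(small_cfg(v)).parameter_count()
                  for v in ("III", "IV", "V")}
        assert counts["V"] > counts["IV"] > counts["III"]

    def test_attention_adds_exactly_hidden_params(self):
        c3 = build_variant(small_cfg("III")).parameter_count()
        c4 = build_variant(small_cfg("IV")).parameter_count()
        assert c4 - c3 == 8  # hidden


class TestForward:
    def test_zero_head_gives_zero_predictions(self, rng):
        model = build_variant(small_cfg("V"))
        model.params["head.W"].data[:] = 0.0
        model.params["head.b"].data[:] = 0.0
        out = model.predict(rng.standard_normal((4, 16, 3)))
        np.testing.assert_array_equal(out, np.zeros((4, 2)))

    def test_identical_windows_identical_predictions(self, rng):
        model = build_variant(small_cfg("V"))
        w = rng.standard_normal((1, 16, 3))
        batch = np.concatenate([w, w], axis=0)
        out = model.predict(batch)
        np.testing.assert_array_equal(out[0], out[1])

    def test_eval_forward_bit_deterministic(self, rng):
        model = build_variant(small_cfg("V"))
        w = rng.standard_normal((3, 16, 3))
        np.testing.assert_array_equal(model.predict(w), model.predict(w))

    @pytest.mark.parametrize("variant", ["I", "II", "III", "IV", "V"])
    def test_forward_matches_reference_route(self, variant, rng):
        model = build_variant(small_cfg(variant))
        w = rng.standard_normal((5, 16, 3))
        np.testing.assert_allclose(
            model.predict(w), forward_reference(model, w), atol=1e-9
        )

    def test_variant_i_ignores_spectral_config(self, rng):
        w = rng.standard_normal((4, 16, 3))
        base = build_variant(small_cfg("I")).predict(w)
        perturbed = build_variant(
            small_cfg("I", conv_kernel=5, fft_mode="magnitude_and_phase")
        ).predict(w)
        np.testing.assert_array_equal(base, perturbed)

    def test_wrong_channel_count_rejected(self, rng):
        model = build_variant(small_cfg("V"))
        with pytest.raises(ConfigurationError):
            model.predict(rng.standard_normal((2, 16, 4)))

    def test_wrong_window_len_rejected(self, rng):
        model = build_variant(small_cfg("V"))
        with pytest.raises(ConfigurationError):
            model.predict(rng.standard_normal((2, 20, 3)))

    def test_training_forward_needs_rng_for_dropout(self, rng):
        model = build_variant(small_cfg("V", dropout=0.5))
        with pytest.raises(ConfigurationError):
            model.forward_batch(rng.standard_normal((2, 16, 3)), training=True)

    def test_state_dict_round_trip(self, rng):
        cfg = small_cfg("V")
        a = build_variant(cfg)
        b = build_variant(ModelConfig(**{**cfg.__dict__, "seed": 99}))
        b.load_state_dict(a.state_dict())
        w = rng.standard_normal((2, 16, 3))
        np.testing.assert_array_equal(a.predict(w), b.predict(w))
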
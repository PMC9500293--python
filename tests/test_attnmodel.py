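"""Attention mathematics (against brute-force oracles), backprop, training."""

import math

import numpy as np
import pytest
from dataclasses import replace

from hfodet.attnmodel import (
    ABLATION_VARIANTS,
    AttentionParams,
    ModelSpec,
    MultiHeadParams,
    additive_score,
    attention_weights,
    build_model,
    cross_entropy,
    load_model,
    multi_head_self_attention,
    predict,
    save_model,
    self_attention_pool,
    self_attention_reweight,
    train,
)
from hfodet.core import ConfigError, LabeledSegment


# ---------------------------------------------------------------------------
# Scalar brute-force oracles
# ---------------------------------------------------------------------------


def _act(name):
    return math.tanh if name == "tanh" else lambda v: max(v, 0.0)


def oracle_score(x, params, q=None):
    d = len(params.w)
    sigma = _act(params.activation)
    total = 0.0
    for j in range(d):
        pre = sum(params.W1[j][k] * x[k] for k in range(d))
        if q is not None:
            pre += sum(params.W2[j][k] * q[k] for k in range(d))
        total += params.w[j] * sigma(pre)
    return total


def oracle_softmax(scores):
    m = max(scores)
    e = [math.exp(s - m) for s in scores]
    z = sum(e)
    return [v / z for v in e]


def oracle_pool(x, params):
    p = oracle_softmax([oracle_score(row, params) for row in x])
    d = len(params.w)
    return [sum(p[i] * x[i][j] for i in range(len(x))) for j in range(d)]


def oracle_reweight(x, params):
    p = oracle_softmax([oracle_score(row, params) for row in x])
    return [[p[i] * v for v in x[i]] for i in range(len(x))]


def oracle_multi_head(x, params):
    n = len(x)
    d = params.WO.shape[0]
    dk = d // params.k
    concat = [[0.0] * d for _ in range(n)]
    for h, (Wx, head) in enumerate(zip(params.Wx, params.heads)):
        proj = [[sum(x[i][a] * Wx[a][b] for a in range(d)) for b in range(dk)] for i in range(n)]
        rew = oracle_reweight(proj, head)
        for i in range(n):
            for b in range(dk):
                concat[i][h * dk + b] = rew[i][b]
    return [[sum(concat[i][a] * params.WO[a][j] for a in range(d)) for j in range(d)] for i in range(n)]


def random_attention_params(rng, d, activation="tanh", with_query=False):
    return AttentionParams(
        W1=rng.normal(size=(d, d)),
        w=rng.normal(size=d),
        W2=rng.normal(size=(d, d)) if with_query else None,
        activation=activation,
    )


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


class TestAdditiveScore:
    def test_zero_weights_score_zero(self):
        params = AttentionParams(W1=np.zeros((3, 3)), w=np.ones(3), activation="relu")
        assert additive_score(np.array([1.0, -2.0, 5.0]), params) == 0.0

    def test_hand_evaluated_relu_case(self):
        params = AttentionParams(W1=np.eye(2), w=np.array([1.0, 1.0]), activation="relu")
        assert additive_score(np.array([1.0, -3.0]), params) == pytest.approx(1.0)

    @pytest.mark.parametrize("activation", ["tanh", "relu"])
    def test_matches_scalar_loop(self, rng, activation):
        for _ in range(100):
            params = random_attention_params(rng, 3, activation)
            x = rng.normal(size=3)
            assert additive_score(x, params) == pytest.approx(oracle_score(x, params), abs=1e-9)

    def test_query_conditioned_form(self, rng):
        for _ in range(50):
            params = random_attention_params(rng, 3, with_query=True)
            x, q = rng.normal(size=3), rng.normal(size=3)
            assert additive_score(x, params, q=q) == pytest.approx(oracle_score(x, params, q), abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        params = random_attention_params(rng, 3)
        with pytest.raises(ConfigError):
            additive_score(np.ones(4), params)


class TestAttentionWeights:
    def test_equal_scores_are_uniform(self):
        assert np.allclose(attention_weights(np.full(4, 2.5)), 0.25)

    def test_closed_form_pair(self):
        w = attention_weights(np.array([0.0, np.log(2.0)]))
        assert np.allclose(w, [1 / 3, 2 / 3])

    def test_shift_invariance(self, rng):
        s = rng.normal(size=6)
        assert np.allclose(attention_weights(s), attention_weights(s + 1000.0))

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            attention_weights(np.array([]))

    def test_matches_scalar_loop_and_normalizes(self, rng):
        for _ in range(100):
            s = rng.normal(size=int(rng.integers(1, 9)))
            w = attention_weights(s)
            assert np.allclose(w, oracle_softmax(list(s)), atol=1e-9)
            assert w.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(w > 0)


class TestSelfAttentionPool:
    def test_single_token_returned_unchanged(self, rng):
        params = random_attention_params(rng, 4)
        x = rng.normal(size=(1, 4))
        assert np.allclose(self_attention_pool(x, params), x[0])

    def test_zero_scorer_gives_arithmetic_mean(self, rng):
        params = AttentionParams(W1=np.zeros((3, 3)), w=np.zeros(3), activation="relu")
        x = rng.normal(size=(5, 3))
        assert np.allclose(self_attention_pool(x, params), x.mean(axis=0))

    def test_matches_weighted_sum_loop(self, rng):
        for _ in range(100):
            params = random_attention_params(rng, 3)
            x = rng.normal(size=(4, 3))
            assert np.allclose(self_attention_pool(x, params), oracle_pool(x, params), atol=1e-9)


class TestMultiHead:
    def test_single_identity_head_reduces_to_self_attention(self, rng):
        d = 4
        head = random_attention_params(rng, d)
        params = MultiHeadParams(Wx=[np.eye(d)], heads=[head], WO=np.eye(d))
        x = rng.normal(size=(5, d))
        assert np.allclose(multi_head_self_attention(x, params), self_attention_reweight(x, head))

    def test_output_shape_contract(self, rng):
        d, k, n = 64, 8, 8
        params = MultiHeadParams(
            Wx=[rng.normal(size=(d, d // k)) for _ in range(k)],
            heads=[random_attention_params(rng, d // k) for _ in range(k)],
            WO=rng.normal(size=(d, d)),
        )
        assert multi_head_self_attention(rng.normal(size=(n, d)), params).shape == (n, d)

    def test_matches_brute_force_loop(self, rng):
        for _ in range(100):
            d, k = 8, 2
            params = MultiHeadParams(
                Wx=[rng.normal(size=(d, d // k)) for _ in range(k)],
                heads=[random_attention_params(rng, d // k) for _ in range(k)],
                WO=rng.normal(size=(d, d)),
            )
            x = rng.normal(size=(4, d))
            assert np.allclose(multi_head_self_attention(x, params), oracle_multi_head(x, params), atol=1e-9)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ConfigError):
            MultiHeadParams(
                Wx=[rng.normal(size=(6, 2))] * 4,
                heads=[random_attention_params(rng, 2)] * 4,
                WO=rng.normal(size=(6, 6)),
            )


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_is_ln_two(self):
        assert cross_entropy(0, 0.5) == pytest.approx(math.log(2), abs=1e-9)

    def test_clipping_caps_the_loss(self):
        assert cross_entropy(1, 0.0) == pytest.approx(-math.log(1e-7), rel=1e-6)

    def test_non_binary_target_rejected(self):
        with pytest.raises(ConfigError):
            cross_entropy(2, 0.5)


# ---------------------------------------------------------------------------
# Network assembly and gradients
# ---------------------------------------------------------------------------


def _tiny_spec(variant="msadr", **kw):
    base = dict(
        variant=variant,
        input_length=24,
        token_count=4,
        token_dim=4,
        heads=2,
        hidden_units=(16, 8, 4),
        dropout_p=0.0,
        input_repr="waveform",
        input_filter=None,
        seed=3,
    )
    base.update(kw)
    return ModelSpec(**base)


class TestBuild:
    def test_raw_variant_has_no_attention_parameters(self):
        model = build_model(ModelSpec(variant="raw"))
        assert not model.has_attention
        assert not any("head0" in name or "selfattn" in name for name in model.parameters)

    def test_forward_produces_probability_for_full_size_input(self, small_gold):
        model = build_model(ModelSpec(variant="msadr", heads=8))
        result = predict(model, small_gold[:3])
        assert all(0.0 <= r.probability <= 1.0 for r in result)

    def test_same_seed_builds_identical_parameters(self):
        a = build_model(ModelSpec(variant="msadr", seed=9))
        b = build_model(ModelSpec(variant="msadr", seed=9))
        assert all(np.array_equal(pa, pb) for pa, pb in zip(a.parameters.values(), b.parameters.values()))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec(variant="transformer")

    def test_ablation_strictly_adds_parameters(self):
        counts = [build_model(ModelSpec(variant=v)).n_parameters for v in ABLATION_VARIANTS]
        raw, attn_1, attn_2, msadr = counts
        assert raw < attn_2 <= attn_1 < msadr

    @pytest.mark.parametrize("k", [2, 4, 8, 16])
    def test_head_sweep_builds_and_runs(self, k, small_gold):
        model = build_model(ModelSpec(variant="msadr", heads=k))
        assert len(predict(model, small_gold[:2])) == 2


class TestGradients:
    @pytest.mark.parametrize("variant", ABLATION_VARIANTS)
    def test_backprop_matches_finite_differences(self, variant, rng):
        """Analytic gradients of every layer agree with numeric differentiation."""
        model = build_model(_tiny_spec(variant), dtype="float64")
        net = model.network
        x = rng.normal(size=(6, 24))
        direction = rng.normal(size=6)

        def loss():
            return float(net.forward(x, training=True) @ direction)

        loss()
        net.backward(direction)
        grads = {p.name: p.grad.copy() for p in net.params()}
        eps = 1e-6
        for p in net.params():
            flat = p.value.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[p.name].ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), p.name


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained(trainable_gold):
    _, segs = trainable_gold
    return train(build_model(ModelSpec(seed=2)), segs), segs


class TestTrain:
    def test_loss_improves_over_training(self, trained):
        model, _ = trained
        assert len(model.training_log) == model.spec.epochs
        assert model.training_log[-1] <= model.training_log[0]

    def test_high_snr_training_accuracy(self, trained):
        """On 200 clearly separable segments, training accuracy reaches 0.95."""
        model, segs = trained
        probs = np.array([r.probability for r in predict(model, segs)])
        y = np.array([s.y for s in segs])
        assert np.mean((probs >= 0.5) == y) >= 0.95

    def test_training_is_deterministic(self, small_gold):
        spec = ModelSpec(seed=4)
        a = train(build_model(spec), small_gold)
        b = train(build_model(spec), small_gold)
        assert a.training_log == b.training_log
        assert all(np.array_equal(pa, pb) for pa, pb in zip(a.parameters.values(), b.parameters.values()))

    def test_single_class_rejected(self, small_gold):
        hfo_only = [s for s in small_gold if s.label == "HFO"]
        with pytest.raises(ConfigError):
            train(build_model(ModelSpec()), hfo_only)


class TestPredict:
    def test_duplicate_segments_get_identical_probabilities(self, trained):
        model, segs = trained
        out = predict(model, [segs[0], segs[1], segs[0]])
        assert out[0].probability == pytest.approx(out[2].probability, abs=1e-6)

    def test_batch_size_invariance(self, trained):
        model, segs = trained
        single = predict(model, segs[:1], batch_size=1)[0].probability
        batched = predict(model, segs[:40], batch_size=32)[0].probability
        assert single == pytest.approx(batched, abs=1e-5)

    def test_probabilities_separate_classes(self, trained):
        from sklearn.metrics import roc_auc_score

        model, segs = trained
        probs = [r.probability for r in predict(model, segs)]
        assert roc_auc_score([s.y for s in segs], probs) >= 0.9

    def test_wrong_length_rejected(self, trained):
        model, _ = trained
        bad = LabeledSegment(np.zeros(100), "P", "c", 0.0, "NC", "bad")
        with pytest.raises(ConfigError):
            predict(model, [bad])


class TestCheckpoint:
    def test_save_load_round_trip(self, trained, tmp_path):
        model, segs = trained
        path = tmp_path / "model.h5"
        save_model(model, path)
        back = load_model(path)
        assert back.spec == model.spec
        assert back.training_log == model.training_log
        p0 = [r.probability for r in predict(model, segs[:5])]
        p1 = [r.probability for r in predict(back, segs[:5])]
        assert np.allclose(p0, p1, atol=1e-7)
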
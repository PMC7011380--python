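"""Network structure, recurrence semantics, training and prediction."""

import math

import numpy as np
import pytest

from cnncrispr.data_io import Dataset, SgRnaDnaPair
from cnncrispr.encoding import PAIR_LENGTH, VOCAB_SIZE, encode_dataset
from cnncrispr.network import (
    BiLstmParams,
    NetworkSpec,
    RecurrentGateParams,
    TrainedModel,
    bilstm_forward,
    build_network,
    predict,
    train_model,
)
from cnncrispr.nn import softmax, softmax_cross_entropy

SEQ = "ACGTACGTACGTACGTACGTAGG"
TINY = dict(recurrent_units=3, conv_filters=(2, 2, 2, 2, 2), conv_kernel_sizes=(3, 3, 3, 3, 3))


def tiny_spec(variant="CnnCrispr", d=4, seed=0, **kwargs):
    emb = np.random.default_rng(seed).normal(scale=0.3, size=(VOCAB_SIZE, d))
    return NetworkSpec(variant=variant, embedding_init=emb, **{**TINY, **kwargs})


def separable_dataset(n_per_class=20):
    """Planted signal: positives carry 3 fixed protospacer mismatches."""
    pos_dna = SEQ[:2] + "T" + SEQ[3:8] + "A" + SEQ[9:14] + "C" + SEQ[15:]
    pairs = [SgRnaDnaPair(f"p{i}", SEQ, pos_dna, 1, 0.8) for i in range(n_per_class)]
    pairs += [SgRnaDnaPair(f"n{i}", SEQ, SEQ, 0, 0.0) for i in range(n_per_class)]
    return Dataset(pairs)


# ------------------------------------------------------------ architecture


def test_variant_structural_audits():
    stages = {v: build_network(tiny_spec(v)).stage_names for v in
              ("CnnCrispr", "NoLSTM", "Conv_LSTM", "NoBatchNor", "NoDropout")}
    assert stages["NoBatchNor"].count("batchnorm") == 0
    assert stages["NoDropout"].count("dropout") == 0
    assert stages["NoLSTM"].count("bilstm") == 0
    for name in ("CnnCrispr", "NoBatchNor", "NoDropout", "Conv_LSTM", "NoLSTM"):
        assert stages[name].count("conv") == 5
        assert stages[name].count("dense") == 2
    # Conv_LSTM: every conv stage precedes the recurrence
    conv_lstm = stages["Conv_LSTM"]
    assert max(i for i, s in enumerate(conv_lstm) if s == "conv") < conv_lstm.index("bilstm")
    trainable = [s for s in conv_lstm if s in ("bilstm", "conv", "dense")]
    assert trainable[0] == "conv"
    # benchmark order: recurrence first
    assert stages["CnnCrispr"].index("bilstm") < stages["CnnCrispr"].index("conv")


def test_parameter_counts_across_variants():
    base = build_network(tiny_spec("CnnCrispr")).parameter_count()
    assert build_network(tiny_spec("NoDropout")).parameter_count() == base
    assert build_network(tiny_spec("NoBatchNor")).parameter_count() < base


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="unknown variant"):
        tiny_spec("Fancy")
    with pytest.raises(ValueError, match="5 convolution"):
        NetworkSpec(conv_filters=(4, 4), conv_kernel_sizes=(3, 3))
    with pytest.raises(ValueError, match=r"\(20, 2\)"):
        NetworkSpec(dense_sizes=(10, 2))
    with pytest.raises(ValueError, match="embedding_init"):
        NetworkSpec(embedding_init=np.zeros((4, 10)))


def test_classification_head_outputs_normalize():
    model = build_network(tiny_spec())
    idx = np.random.default_rng(1).integers(0, VOCAB_SIZE, (9, PAIR_LENGTH))
    probs = softmax(model.forward(idx, train=False).data)
    assert probs.shape == (9, 2)
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


# -------------------------------------------------------------- recurrence


def zero_params(d, H, out):
    z = np.zeros((H + d, H))
    b = np.zeros(H)
    gate = RecurrentGateParams(W_f=z, W_i=z.copy(), W_C=z.copy(), W_o=z.copy(),
                               b_f=b, b_i=b.copy(), b_C=b.copy(), b_o=b.copy())
    return BiLstmParams(forward=gate,
                        backward=RecurrentGateParams(
                            W_f=z.copy(), W_i=z.copy(), W_C=z.copy(), W_o=z.copy(),
                            b_f=b.copy(), b_i=b.copy(), b_C=b.copy(), b_o=b.copy()),
                        V=np.zeros((H, out)), V_prime=np.zeros((H, out)),
                        b_y=np.zeros(out))


def random_params(rng, d, H, out):
    def gate():
        return RecurrentGateParams(
            W_f=rng.normal(size=(H + d, H)), W_i=rng.normal(size=(H + d, H)),
            W_C=rng.normal(size=(H + d, H)), W_o=rng.normal(size=(H + d, H)),
            b_f=rng.normal(size=H), b_i=rng.normal(size=H),
            b_C=rng.normal(size=H), b_o=rng.normal(size=H))
    return BiLstmParams(forward=gate(), backward=gate(),
                        V=rng.normal(size=(H, out)), V_prime=rng.normal(size=(H, out)),
                        b_y=rng.normal(size=out))


def scalar_lstm_oracle(inputs, gate, reverse=False):
    """Pure-python per-unit recurrence straight from the gate equations."""
    T, d = inputs.shape
    H = gate.b_f.size
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h = [0.0] * H
    c = [0.0] * H
    out = np.zeros((T, H))
    order = reversed(range(T)) if reverse else range(T)
    for t in order:
        z = list(h) + list(inputs[t])
        f = [sig(sum(z[a] * gate.W_f[a, u] for a in range(len(z))) + gate.b_f[u]) for u in range(H)]
        i = [sig(sum(z[a] * gate.W_i[a, u] for a in range(len(z))) + gate.b_i[u]) for u in range(H)]
        ct = [math.tanh(sum(z[a] * gate.W_C[a, u] for a in range(len(z))) + gate.b_C[u]) for u in range(H)]
        o = [sig(sum(z[a] * gate.W_o[a, u] for a in range(len(z))) + gate.b_o[u]) for u in range(H)]
        c = [f[u] * c[u] + i[u] * ct[u] for u in range(H)]
        h = [o[u] * math.tanh(c[u]) for u in range(H)]
        out[t] = h
    return out


def test_zero_parameters_give_half_gates_and_zero_states():
    """With all weights and biases 0 every gate is sigmoid(0)=0.5 and the
    cell state never leaves 0, so all outputs are tanh(0)=0."""
    params = zero_params(d=3, H=2, out=4)
    inputs = np.random.default_rng(0).normal(size=(5, 3))
    out = bilstm_forward(inputs, params)
    np.testing.assert_array_equal(out, np.zeros((5, 4)))


def test_forward_direction_is_causal():
    rng = np.random.default_rng(1)
    params = random_params(rng, d=3, H=4, out=2)
    inputs = rng.normal(size=(6, 3))
    from cnncrispr.network import lstm_forward
    base = lstm_forward(inputs, params.forward)
    perturbed = inputs.copy()
    perturbed[4] += 10.0
    shifted = lstm_forward(perturbed, params.forward)
    np.testing.assert_allclose(shifted[:4], base[:4], atol=1e-12)
    assert not np.allclose(shifted[4:], base[4:])


def test_bilstm_matches_scalar_gate_equation_oracle():
    """3-step, 2-unit toy agrees with a per-unit scalar recurrence to 1e-6."""
    rng = np.random.default_rng(2)
    params = random_params(rng, d=2, H=2, out=3)
    inputs = rng.normal(size=(3, 2))
    A = scalar_lstm_oracle(inputs, params.forward, reverse=False)
    A_prime = scalar_lstm_oracle(inputs, params.backward, reverse=True)
    expected = np.tanh(A @ params.V + A_prime @ params.V_prime + params.b_y)
    np.testing.assert_allclose(bilstm_forward(inputs, params), expected, atol=1e-6)


def test_bilstm_layer_agrees_with_reference_on_random_instances():
    """The batched autodiff layer equals the sequence-level reference
    (100 randomized trials, tol 1e-5)."""
    from cnncrispr.network import _BiLstmLayer
    from cnncrispr.nn import Tensor
    rng = np.random.default_rng(3)
    layer = _BiLstmLayer(input_dim=3, units=4, output_dim=5, rng=rng)
    params = layer.numpy_params()
    for _ in range(100):
        x = rng.normal(size=(1, 6, 3))
        got = layer.forward(Tensor(x), train=False, rng=rng).data[0]
        want = bilstm_forward(x[0], params)
        np.testing.assert_allclose(got, want, atol=1e-5)


# ------------------------------------------------------------- gradients


def test_model_gradients_match_central_differences():
    """End-to-end autodiff gradient of the training loss checks out
    numerically on a tiny deterministic variant (dropout-free)."""
    spec = tiny_spec("NoDropout", d=3)
    model = build_network(spec, seed=4)
    rng = np.random.default_rng(5)
    idx = rng.integers(0, VOCAB_SIZE, (4, PAIR_LENGTH))
    labels = np.array([0, 1, 1, 0])

    def loss_value():
        return float(softmax_cross_entropy(model.forward(idx, train=False), labels).data)

    loss = softmax_cross_entropy(model.forward(idx, train=False), labels)
    loss.backward()
    params = model.parameters()
    eps = 1e-6
    checked = 0
    for p in params[:6] + params[-2:]:
        flat = p.data.reshape(-1)
        grad = p.grad.reshape(-1)
        for k in range(0, flat.size, max(1, flat.size // 3)):
            orig = flat[k]
            flat[k] = orig + eps
            hi = loss_value()
            flat[k] = orig - eps
            lo = loss_value()
            flat[k] = orig
            assert grad[k] == pytest.approx((hi - lo) / (2 * eps), rel=1e-4, abs=1e-8)
            checked += 1
    assert checked >= 10


# --------------------------------------------------------------- training


def test_training_log_counts_planned_batches():
    data = separable_dataset(10)  # 10 pos / 10 neg
    spec = tiny_spec()
    trained = train_model(data, spec, m=5, epochs=1, seed=0, early_stopping=False)
    assert len(trained.training_log) == 2  # floor(10 / 5)


def test_training_is_deterministic_given_seed():
    data = separable_dataset(8)
    spec = tiny_spec()
    a = train_model(data, spec, m=4, epochs=2, seed=3, early_stopping=False)
    b = train_model(data, spec, m=4, epochs=2, seed=3, early_stopping=False)
    assert a.training_log == b.training_log
    np.testing.assert_array_equal(predict(a, data), predict(b, data))


def test_overfits_separable_toy_and_ranks_positives_first():
    from cnncrispr.evaluation import ranking_metrics
    data = separable_dataset(12)
    spec = tiny_spec("NoDropout", d=6)
    trained = train_model(data, spec, m=8, epochs=60, seed=1, early_stopping=False)
    assert trained.training_log[-1] < 0.1
    scores = predict(trained, data)
    assert scores.shape == (len(data),)
    assert ((scores >= 0) & (scores <= 1)).all()
    auroc, _ = ranking_metrics(data.labels, scores)
    assert auroc == 1.0


def test_conv_lstm_order_changes_predictions():
    data = separable_dataset(8)
    idx_spec = dict(d=4, seed=0)
    a = train_model(data, tiny_spec("CnnCrispr", **idx_spec), m=4, epochs=1, seed=0,
                    early_stopping=False)
    b = train_model(data, tiny_spec("Conv_LSTM", **idx_spec), m=4, epochs=1, seed=0,
                    early_stopping=False)
    assert np.abs(predict(a, data) - predict(b, data)).max() > 0


def test_regression_head_predicts_frequencies_in_unit_interval():
    data = separable_dataset(10)
    spec = tiny_spec("NoDropout", head="regression")
    trained = train_model(data, spec, m=5, epochs=40, seed=2, early_stopping=False)
    preds = predict(trained, data)
    assert ((preds > 0) & (preds < 1)).all()
    # positives (frequency 0.8) score above negatives (frequency 0) after fitting
    assert preds[data.labels == 1].mean() > preds[data.labels == 0].mean()


def test_single_class_classification_training_rejected():
    pairs = [SgRnaDnaPair(f"n{i}", SEQ, SEQ, 0, 0.0) for i in range(10)]
    with pytest.raises(ValueError, match="both classes"):
        train_model(Dataset(pairs), tiny_spec(), m=4, epochs=1, seed=0)


def test_checkpoint_round_trip_preserves_predictions(tmp_path):
    data = separable_dataset(8)
    spec = tiny_spec()
    trained = train_model(data, spec, m=4, epochs=2, seed=5, early_stopping=False)
    trained.save(tmp_path / "model")
    reloaded = TrainedModel.load(tmp_path / "model")
    np.testing.assert_allclose(predict(reloaded, data), predict(trained, data),
                               atol=1e-12)
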
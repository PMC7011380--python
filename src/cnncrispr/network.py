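"""The biLSTM+CNN off-target network and its ablation variants.

The benchmark architecture ("CnnCrispr") maps the length-23 token vector
through an embedding layer initialized from the trained GloVe matrix, a
bidirectional LSTM that extracts context features, five 1-D convolution
layers with per-layer filter counts and kernel sizes, and dense layers of
sizes 20 and 2.  Batch normalization and dropout are interposed between
stages.  The classification head applies a two-class softmax (score =
probability of the off-target class); the regression head a logistic output
trained against measured cleavage frequency.

Four ablation variants differ structurally:

======================  =====================================================
``NoLSTM``              no recurrent stage
``Conv_LSTM``           all five convolution stages before the recurrence
``NoBatchNor``          no batch-normalization stages
``NoDropout``           no dropout stages
======================  =====================================================

Training uses Adam at learning rate 0.01 on batches from the imbalance
sampler; loss is two-class cross-entropy (classification) or mean squared
error on frequency (regression).  Everything is deterministic for a fixed
seed.

LSTM recurrence (per direction, per timestep, with z = [h_{t-1}, x_t]):

    f_t = sigmoid(z W_f + b_f)         (forget gate)
    i_t = sigmoid(z W_i + b_i)         (input gate)
    C~_t = tanh(z W_C + b_C)           (candidate cell state)
    o_t = sigmoid(z W_o + b_o)         (output gate)
    C_t = f_t * C_{t-1} + i_t * C~_t
    h_t = o_t * tanh(C_t)

and each output position combines the forward state A and backward state A'
as y = tanh(V A + V' A').
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .data_io import Dataset
from .encoding import PAIR_LENGTH, VOCAB_SIZE, encode_dataset
from .nn import Adam, Tensor, concat, conv1d_same, embedding_lookup, softmax, softmax_cross_entropy
from .sampler import iterate_batches, plan_batches

VARIANTS = ("CnnCrispr", "NoLSTM", "Conv_LSTM", "NoBatchNor", "NoDropout")

__all__ = [
    "VARIANTS",
    "NetworkSpec",
    "RecurrentGateParams",
    "BiLstmParams",
    "bilstm_forward",
    "lstm_forward",
    "build_network",
    "Model",
    "TrainedModel",
    "train_model",
    "predict",
    "make_trainer",
]


# --------------------------------------------------------------------- spec


@dataclass
class NetworkSpec:
    """Declarative description of one network variant."""

    variant: str = "CnnCrispr"
    embedding_init: np.ndarray | None = None
    recurrent_units: int = 30
    conv_filters: tuple[int, ...] = (10, 20, 40, 80, 100)
    conv_kernel_sizes: tuple[int, ...] = (5, 5, 3, 3, 3)
    dense_sizes: tuple[int, int] = (20, 2)
    dropout_rate: float = 0.3
    head: str = "classification"
    freeze_embedding: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.head not in ("classification", "regression"):
            raise ValueError(f"head must be 'classification' or 'regression', got {self.head!r}")
        self.conv_filters = tuple(int(v) for v in self.conv_filters)
        self.conv_kernel_sizes = tuple(int(v) for v in self.conv_kernel_sizes)
        if len(self.conv_filters) != 5 or len(self.conv_kernel_sizes) != 5:
            raise ValueError("exactly 5 convolution stages are required")
        if tuple(self.dense_sizes) != (20, 2):
            raise ValueError("dense sizes must be exactly (20, 2)")
        if self.embedding_init is not None:
            emb = np.asarray(self.embedding_init, dtype=np.float64)
            if emb.ndim != 2 or emb.shape[0] != VOCAB_SIZE:
                raise ValueError(
                    f"embedding_init must be ({VOCAB_SIZE}, d), got {emb.shape}"
                )
            self.embedding_init = emb

    @property
    def embedding_dim(self) -> int:
        return 100 if self.embedding_init is None else self.embedding_init.shape[1]

    def to_jsonable(self) -> dict:
        payload = asdict(self)
        payload["embedding_init"] = None  # stored with the weights, not the spec
        payload["embedding_dim"] = self.embedding_dim
        return payload


# ----------------------------------------------------- recurrence reference


@dataclass
class RecurrentGateParams:
    """Gate weights for one LSTM direction.

    Weight matrices act on the concatenation ``z = [h_{t-1}, x_t]`` (hidden
    state first), so each has shape ``(units + input_dim, units)``; biases
    have shape ``(units,)``.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    @property
    def units(self) -> int:
        return self.W_f.shape[1]


@dataclass
class BiLstmParams:
    """Both directions plus the output combination y = g(V A + V' A')."""

    forward: RecurrentGateParams
    backward: RecurrentGateParams
    V: np.ndarray
    V_prime: np.ndarray
    b_y: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_forward(
    inputs: np.ndarray, params: RecurrentGateParams, reverse: bool = False
) -> np.ndarray:
    """Run one LSTM direction over a (T, d) input; returns (T, units) states."""
    T = inputs.shape[0]
    H = params.units
    h = np.zeros(H)
    c = np.zeros(H)
    states = np.zeros((T, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        z = np.concatenate([h, inputs[t]])
        f = _sigmoid(z @ params.W_f + params.b_f)
        i = _sigmoid(z @ params.W_i + params.b_i)
        c_tilde = np.tanh(z @ params.W_C + params.b_C)
        o = _sigmoid(z @ params.W_o + params.b_o)
        c = f * c + i * c_tilde
        h = o * np.tanh(c)
        states[t] = h
    return states


def bilstm_forward(inputs: np.ndarray, params: BiLstmParams) -> np.ndarray:
    """Bidirectional forward pass over a single (T, d) sequence.

    Combines the forward state A_t and backward state A'_t at every position
    as ``y_t = tanh(A_t V + A'_t V' + b_y)``; returns (T, output_dim).
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    A = lstm_forward(inputs, params.forward, reverse=False)
    A_prime = lstm_forward(inputs, params.backward, reverse=True)
    return np.tanh(A @ params.V + A_prime @ params.V_prime + params.b_y)


# ------------------------------------------------------------------- layers


def _time_slice(x: Tensor, t: int) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, t, :] = g
            x._accumulate(full)

    return Tensor(x.data[:, t, :], parents=(x,), backward=backward)


def _stack_time(slices: Sequence[Tensor]) -> Tensor:
    """Stack per-timestep (B, C) tensors into (B, T, C)."""
    expanded = [s.reshape(s.shape[0], 1, s.shape[1]) for s in slices]
    return concat(expanded, axis=1)


class _EmbeddingLayer:
    kind = "embedding"

    def __init__(self, init: np.ndarray, trainable: bool = True):
        self.weight = Tensor(init.copy(), requires_grad=trainable)

    def parameters(self) -> list[Tensor]:
        return [self.weight] if self.weight.requires_grad else []

    def forward(self, idx: np.ndarray, train: bool, rng) -> Tensor:
        return embedding_lookup(self.weight, idx)


class _BiLstmLayer:
    kind = "bilstm"

    def __init__(self, input_dim: int, units: int, output_dim: int, rng: np.random.Generator):
        def mat(*shape):
            bound = 1.0 / np.sqrt(shape[0])
            return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

        z_dim = units + input_dim
        self.units = units
        self.output_dim = output_dim
        self.gates = {}
        for direction in ("fwd", "bwd"):
            self.gates[direction] = {
                name: (mat(z_dim, units), Tensor(np.zeros(units), requires_grad=True))
                for name in ("f", "i", "C", "o")
            }
        self.V = mat(units, output_dim)
        self.V_prime = mat(units, output_dim)
        self.b_y = Tensor(np.zeros(output_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        params = []
        for direction in ("fwd", "bwd"):
            for W, b in self.gates[direction].values():
                params.extend([W, b])
        params.extend([self.V, self.V_prime, self.b_y])
        return params

    def gate_params(self, direction: str) -> RecurrentGateParams:
        g = self.gates[direction]
        return RecurrentGateParams(
            W_f=g["f"][0].data, W_i=g["i"][0].data, W_C=g["C"][0].data, W_o=g["o"][0].data,
            b_f=g["f"][1].data, b_i=g["i"][1].data, b_C=g["C"][1].data, b_o=g["o"][1].data,
        )

    def numpy_params(self) -> BiLstmParams:
        return BiLstmParams(
            forward=self.gate_params("fwd"),
            backward=self.gate_params("bwd"),
            V=self.V.data, V_prime=self.V_prime.data, b_y=self.b_y.data,
        )

    def _run_direction(self, x: Tensor, direction: str, reverse: bool) -> list[Tensor]:
        B, T, _ = x.data.shape
        g = self.gates[direction]
        h = Tensor(np.zeros((B, self.units)))
        c = Tensor(np.zeros((B, self.units)))
        states: list[Tensor | None] = [None] * T
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            z = concat([h, _time_slice(x, t)], axis=1)
            f = (z @ g["f"][0] + g["f"][1]).sigmoid()
            i = (z @ g["i"][0] + g["i"][1]).sigmoid()
            c_tilde = (z @ g["C"][0] + g["C"][1]).tanh()
            o = (z @ g["o"][0] + g["o"][1]).sigmoid()
            c = f * c + i * c_tilde
            h = o * c.tanh()
            states[t] = h
        return states  # type: ignore[return-value]

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        A = self._run_direction(x, "fwd", reverse=False)
        A_prime = self._run_direction(x, "bwd", reverse=True)
        ys = [
            (a @ self.V + ap @ self.V_prime + self.b_y).tanh()
            for a, ap in zip(A, A_prime)
        ]
        return _stack_time(ys)


class _ConvLayer:
    kind = "conv"

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 activation: str = "relu"):
        bound = 1.0 / np.sqrt(kernel * c_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.activation = activation

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        out = conv1d_same(x, self.weight, self.bias)
        return out.relu() if self.activation == "relu" else out


class _DenseLayer:
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "linear"):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        out = x @ self.weight + self.bias
        return out.relu() if self.activation == "relu" else out


class _BatchNormLayer:
    """Normalize per feature channel to zero mean / unit variance.

    For (B, T, C) inputs statistics pool over batch and positions; for
    (B, F) inputs over the batch.  Inference uses running statistics.
    """

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        axes = (0, 1) if x.data.ndim == 3 else (0,)
        shape = (1, 1, -1) if x.data.ndim == 3 else (1, -1)
        gamma = self.gamma.reshape(*shape)
        beta = self.beta.reshape(*shape)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            inv = (var + self.eps) ** -0.5
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            return xc * inv * gamma + beta
        mu = self.running_mean.reshape(shape)
        inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
        return (x - Tensor(mu)) * Tensor(inv) * gamma + beta


class _DropoutLayer:
    kind = "dropout"

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def parameters(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = (rng.random(x.data.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class _FlattenLayer:
    kind = "flatten"

    def parameters(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        B = x.data.shape[0]
        return x.reshape(B, -1)


# -------------------------------------------------------------------- model


class Model:
    """An ordered stack of layers built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, layers: list):
        self.spec = spec
        self.layers = layers

    @property
    def stage_names(self) -> list[str]:
        return [layer.kind for layer in self.layers]

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        return params

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, idx: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if rng is None:
            rng = np.random.default_rng(0)
        out: Tensor | np.ndarray = idx
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out  # (B, 2) logits

    def state_arrays(self) -> list[np.ndarray]:
        seen = []
        for layer in self.layers:
            for p in layer.parameters():
                seen.append(p.data)
            if isinstance(layer, _BatchNormLayer):
                seen.extend([layer.running_mean, layer.running_var])
            if isinstance(layer, _EmbeddingLayer) and not layer.weight.requires_grad:
                seen.append(layer.weight.data)
        return seen

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        expected = self.state_arrays()
        if len(arrays) != len(expected):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(expected)}"
            )
        for target, source in zip(expected, arrays):
            source = np.asarray(source)
            if target.shape != source.shape:
                raise ValueError(
                    f"checkpoint array shape {source.shape} incompatible with "
                    f"model shape {target.shape}"
                )
            target[...] = source


def build_network(spec: NetworkSpec, seed: int = 0) -> Model:
    """Instantiate the layer stack for one variant.

    Layer order for ``CnnCrispr`` is embedding -> biLSTM -> conv x5 ->
    dense(20) -> dense(2), with batch normalization and dropout interposed
    except in the respective ablation variants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    if spec.embedding_init is None:
        emb = rng.uniform(-0.05, 0.05, size=(VOCAB_SIZE, spec.embedding_dim))
    else:
        emb = spec.embedding_init
    with_bn = spec.variant != "NoBatchNor"
    with_do = spec.variant != "NoDropout"
    layers: list = [_EmbeddingLayer(emb, trainable=not spec.freeze_embedding)]
    channels = spec.embedding_dim

    def norm_block(c: int) -> None:
        if with_bn:
            layers.append(_BatchNormLayer(c))
        if with_do:
            layers.append(_DropoutLayer(spec.dropout_rate))

    def recurrent_block() -> None:
        nonlocal channels
        out_dim = 2 * spec.recurrent_units
        layers.append(_BiLstmLayer(channels, spec.recurrent_units, out_dim, rng))
        channels = out_dim
        norm_block(channels)

    def conv_block() -> None:
        nonlocal channels
        for c_out, kernel in zip(spec.conv_filters, spec.conv_kernel_sizes):
            layers.append(_ConvLayer(channels, c_out, kernel, rng))
            channels = c_out
            norm_block(channels)

    if spec.variant == "Conv_LSTM":
        conv_block()
        recurrent_block()
    elif spec.variant == "NoLSTM":
        conv_block()
    else:  # CnnCrispr, NoBatchNor, NoDropout
        recurrent_block()
        conv_block()

    layers.append(_FlattenLayer())
    flat = channels * PAIR_LENGTH
    layers.append(_DenseLayer(flat, spec.dense_sizes[0], rng, activation="relu"))
    norm_block(spec.dense_sizes[0])
    layers.append(_DenseLayer(spec.dense_sizes[0], spec.dense_sizes[1], rng))
    return Model(spec, layers)


# ----------------------------------------------------------------- training


@dataclass
class TrainedModel:
    """A fitted network plus its provenance and per-batch loss log."""

    spec: NetworkSpec
    model: Model
    training_log: list[float]
    seed: int

    def save(self, path) -> None:
        path = Path(path)
        arrays = self.model.state_arrays()
        np.savez(path.with_suffix(".npz"),
                 **{f"arr_{i}": a for i, a in enumerate(arrays)})
        meta = {
            "spec": self.spec.to_jsonable(),
            "seed": self.seed,
            "training_log": self.training_log,
            "n_arrays": len(arrays),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec_dict = meta["spec"]
        spec_dict.pop("embedding_init", None)
        dim = spec_dict.pop("embedding_dim")
        # placeholder embedding of the right width; real weights loaded below
        spec = NetworkSpec(embedding_init=np.zeros((VOCAB_SIZE, dim)), **spec_dict)
        model = build_network(spec, seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as payload:
            arrays = [payload[f"arr_{i}"] for i in range(meta["n_arrays"])]
        model.load_state_arrays(arrays)
        return cls(spec=spec, model=model, training_log=meta["training_log"],
                   seed=meta["seed"])


def _batch_loss(model: Model, tokens: np.ndarray, labels: np.ndarray,
                freqs: np.ndarray, train: bool, rng) -> Tensor:
    logits = model.forward(tokens, train=train, rng=rng)
    if model.spec.head == "classification":
        return softmax_cross_entropy(logits, labels)
    pred = logits.slice_axis1(1, 2).sigmoid().reshape(-1)
    diff = pred - Tensor(freqs)
    return (diff * diff).mean()


def train_model(
    train: Dataset,
    spec: NetworkSpec,
    m: int = 256,
    composition: str = "balanced",
    epochs: int = 100,
    seed: int = 0,
    learning_rate: float = 0.01,
    early_stopping: bool = True,
    validation_fraction: float = 0.1,
    patience: int = 10,
) -> TrainedModel:
    """Train one variant with the imbalance sampler and Adam (lr 0.01).

    With ``early_stopping`` a stratified ``validation_fraction`` of the
    training pairs is held out; training stops when its loss has not
    improved for ``patience`` epochs.  Deterministic for a fixed seed.
    """
    labels = train.labels
    if spec.head == "classification" and (labels.min() == labels.max()):
        raise ValueError("classification training needs both classes present")
    model = build_network(spec, seed=seed)
    optimizer = Adam(model.parameters(), learning_rate=learning_rate)
    dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))

    fit_data = train
    val_tokens = val_labels = val_freqs = None
    if early_stopping and validation_fraction > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 307]))
        val_idx: list[int] = []
        for cls_value in (0, 1):
            cls_idx = np.flatnonzero(labels == cls_value)
            n_val = int(round(validation_fraction * cls_idx.size))
            if 0 < n_val < cls_idx.size:
                val_idx.extend(rng.permutation(cls_idx)[:n_val].tolist())
        if val_idx:
            val_set = set(val_idx)
            fit_idx = [i for i in range(len(train)) if i not in val_set]
            # the held-out slice must keep at least one positive in training
            if len({labels[i] for i in fit_idx}) == 2 or spec.head == "regression":
                fit_data = train.subset(fit_idx)
                val_data = train.subset(sorted(val_set))
                val_tokens = encode_dataset(val_data.pairs)
                val_labels = val_data.labels
                val_freqs = val_data.frequencies

    tokens = encode_dataset(fit_data.pairs)
    training_log: list[float] = []
    best_val = np.inf
    stale = 0
    for epoch in range(epochs):
        plan = plan_batches(fit_data, m=m, seed=seed, composition=composition, epoch=epoch)
        for idxs, batch_labels, batch_freqs in iterate_batches(plan, fit_data):
            loss = _batch_loss(model, tokens[idxs], batch_labels, batch_freqs,
                               train=True, rng=dropout_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}, "
                    f"batch {len(training_log) + 1}; aborting"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            training_log.append(float(loss.data))
        if val_tokens is not None:
            val_loss = float(
                _batch_loss(model, val_tokens, val_labels, val_freqs,
                            train=False, rng=dropout_rng).data
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    return TrainedModel(spec=spec, model=model, training_log=training_log, seed=seed)


def predict(trained: TrainedModel, data: Dataset, batch_size: int = 1024) -> np.ndarray:
    """Score pairs: class-1 probability (classification) or predicted
    cleavage frequency (regression), in input order."""
    tokens = encode_dataset(data.pairs)
    scores = np.empty(len(data), dtype=np.float64)
    for start in range(0, len(data), batch_size):
        chunk = tokens[start:start + batch_size]
        logits = trained.model.forward(chunk, train=False).data
        if trained.spec.head == "classification":
            scores[start:start + len(chunk)] = softmax(logits)[:, 1]
        else:
            scores[start:start + len(chunk)] = 1.0 / (1.0 + np.exp(-logits[:, 1]))
    return scores


def make_trainer(
    spec_template: NetworkSpec | None = None,
    glove_kwargs: dict | None = None,
    **train_kwargs,
) -> Callable:
    """Build a ``trainer(train_data, seed) -> scorer(test_data)`` closure.

    The closure fits the GloVe embedding on the training corpus, trains the
    network variant described by ``spec_template``, and returns a scoring
    function — the shape the leave-one-sgRNA-out driver expects.
    """
    from .glove import build_cooccurrence, fit_glove
    from .encoding import encode_pair

    def trainer(train_data: Dataset, seed: int = 0) -> Callable[[Dataset], np.ndarray]:
        corpus = [encode_pair(p.sgrna_seq, p.dna_seq) for p in train_data]
        gkw = dict(glove_kwargs or {})
        window = gkw.pop("window", 5)
        weighting = gkw.pop("distance_weighting", "inverse_distance")
        X = build_cooccurrence(corpus, window=window, distance_weighting=weighting)
        _, embedding = fit_glove(X, seed=seed, **gkw)
        base = spec_template or NetworkSpec()
        spec = NetworkSpec(
            variant=base.variant,
            embedding_init=embedding,
            recurrent_units=base.recurrent_units,
            conv_filters=base.conv_filters,
            conv_kernel_sizes=base.conv_kernel_sizes,
            dense_sizes=base.dense_sizes,
            dropout_rate=base.dropout_rate,
            head=base.head,
            freeze_embedding=base.freeze_embedding,
        )
        trained = train_model(train_data, spec, seed=seed, **train_kwargs)

        def scorer(test_data: Dataset) -> np.ndarray:
            return predict(trained, test_data)

        return scorer

    return trainer
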
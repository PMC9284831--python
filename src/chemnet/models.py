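"""Classifier families behind one train/predict contract.

Four architectures: ``dnn`` (fingerprint MLP), ``cnn`` (character feature
matrices through 1-D convolutions), ``rnn_seq2seq`` (token sequences through
a 3-layer LSTM perceiver with a linear head) and ``lm_finetune`` (language-
model pretraining with weight-dropped LSTMs and averaged-gradient switchover,
then classifier fine-tuning with gradual unfreezing).

Full-scale widths are available as the ``full_scale`` presets; the
``desk`` presets keep everything trainable on one CPU in seconds to minutes.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .encoding import EncodedDataset, MergeTable, TokenVocabulary
from .errors import ConfigurationError, InputError
from .nn import Adam, Embedding, Linear, LSTMLayer, Tensor, WeightAverager

logger = logging.getLogger(__name__)

ARCHITECTURES = ("dnn", "cnn", "rnn_seq2seq", "lm_finetune")

_SCHEME_FOR_ARCH = {
    "dnn": ("fingerprint",),
    "cnn": ("matrix",),
    "rnn_seq2seq": ("atomwise", "spe"),
    "lm_finetune": ("atomwise", "spe"),
}

# Fields permitted per architecture beyond the common ones.
_ARCH_FIELDS = {
    "dnn": {"hidden_sizes"},
    "cnn": {"conv_channels", "kernel_sizes", "fc_size"},
    "rnn_seq2seq": {"embed_dim", "hidden_size", "num_layers", "tokenizer_scheme"},
    "lm_finetune": {
        "embed_dim", "hidden_size", "num_layers", "tokenizer_scheme",
        "weight_drop", "asgd_patience",
    },
}


@dataclass
class ModelConfig:
    architecture: str
    dropout: float = 0.0
    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    # dnn
    hidden_sizes: tuple | None = None
    # cnn
    conv_channels: tuple | None = None
    kernel_sizes: tuple | None = None
    fc_size: int | None = None
    # sequence models
    embed_dim: int | None = None
    hidden_size: int | None = None
    num_layers: int | None = None
    tokenizer_scheme: str | None = None
    # lm_finetune
    weight_drop: float | None = None
    asgd_patience: int | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        allowed = _ARCH_FIELDS[self.architecture]
        every = set().union(*_ARCH_FIELDS.values())
        for name in every - allowed:
            if getattr(self, name) is not None:
                raise ConfigurationError(
                    f"field {name!r} is not valid for architecture "
                    f"{self.architecture!r}"
                )


def desk_config(architecture: str, **overrides) -> ModelConfig:
    """Small CPU-friendly presets for each architecture."""
    base = {
        "dnn": dict(hidden_sizes=(64, 64, 32), dropout=0.1, epochs=40, lr=3e-3),
        "cnn": dict(conv_channels=(32, 32, 32), kernel_sizes=(7, 5, 3),
                    fc_size=64, dropout=0.1, epochs=30, lr=2e-3),
        "rnn_seq2seq": dict(embed_dim=32, hidden_size=64, num_layers=3,
                            tokenizer_scheme="atomwise", epochs=25, lr=3e-3),
        "lm_finetune": dict(embed_dim=32, hidden_size=64, num_layers=3,
                            tokenizer_scheme="atomwise", weight_drop=0.1,
                            asgd_patience=2, epochs=8, lr=3e-3),
    }[architecture]
    base.update(overrides)
    return ModelConfig(architecture=architecture, **base)


def full_scale_config(architecture: str, **overrides) -> ModelConfig:
    """Documented full-scale defaults (not CPU-test material)."""
    base = {
        "dnn": dict(hidden_sizes=(4096, 4096, 1024), dropout=0.4, epochs=100),
        "cnn": dict(conv_channels=(64, 64, 64), kernel_sizes=(11, 11, 11),
                    fc_size=256, dropout=0.2, epochs=100),
        "rnn_seq2seq": dict(embed_dim=128, hidden_size=256, num_layers=3,
                            tokenizer_scheme="atomwise", epochs=100),
        "lm_finetune": dict(embed_dim=128, hidden_size=256, num_layers=3,
                            tokenizer_scheme="spe", weight_drop=0.5,
                            asgd_patience=3, epochs=50),
    }[architecture]
    base.update(overrides)
    return ModelConfig(architecture=architecture, **base)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


class _DNNNet:
    def __init__(self, n_in: int, n_classes: int, config: ModelConfig,
                 rng: np.random.Generator):
        sizes = list(config.hidden_sizes or (64, 64, 32))
        self.layers: list[Linear] = []
        prev = n_in
        for width in sizes:
            self.layers.append(Linear(prev, width, rng))
            prev = width
        self.head = Linear(prev, n_classes, rng)
        self.dropout = config.dropout

    def forward(self, X: np.ndarray, train: bool, rng: np.random.Generator) -> Tensor:
        h = Tensor(X)
        for layer in self.layers:
            h = nn.dropout(layer(h).relu(), self.dropout, rng, train)
        return self.head(h)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend(self.head.parameters())
        return out

    def named_parameters(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.named_parameters().items():
                out[f"layer{i}.{k}"] = v
        for k, v in self.head.named_parameters().items():
            out[f"head.{k}"] = v
        return out


class _CNNNet:
    """Three 1-D convolutions over the character axis, global max pooling,
    one fully connected layer, then the classification layer."""

    def __init__(self, n_features: int, n_classes: int, config: ModelConfig,
                 rng: np.random.Generator):
        channels = list(config.conv_channels or (32, 32, 32))
        kernels = list(config.kernel_sizes or (7, 5, 3))
        if len(channels) != len(kernels):
            raise ConfigurationError("conv_channels and kernel_sizes lengths differ")
        self.convs = []
        prev = n_features
        for c, k in zip(channels, kernels):
            scale = np.sqrt(1.0 / (prev * k))
            w = Tensor(rng.uniform(-scale, scale, (c, prev, k)), requires_grad=True)
            b = Tensor(np.zeros(c), requires_grad=True)
            self.convs.append((w, b))
            prev = c
        self.fc = Linear(prev, config.fc_size or 64, rng)
        self.head = Linear(config.fc_size or 64, n_classes, rng)
        self.dropout = config.dropout

    def forward(self, X: np.ndarray, train: bool, rng: np.random.Generator) -> Tensor:
        h = Tensor(X)  # (B, 42, L)
        for w, b in self.convs:
            h = nn.conv1d(h, w, b).relu()
        pooled = h.max(axis=2)  # (B, C)
        h = nn.dropout(self.fc(pooled).relu(), self.dropout, rng, train)
        return self.head(h)

    def parameters(self):
        out = []
        for w, b in self.convs:
            out.extend([w, b])
        out.extend(self.fc.parameters())
        out.extend(self.head.parameters())
        return out

    def named_parameters(self):
        out = {}
        for i, (w, b) in enumerate(self.convs):
            out[f"conv{i}.w"] = w
            out[f"conv{i}.b"] = b
        for k, v in self.fc.named_parameters().items():
            out[f"fc.{k}"] = v
        for k, v in self.head.named_parameters().items():
            out[f"head.{k}"] = v
        return out


class _SequenceBody:
    """Embedding plus LSTM stack shared by the perceiver classifier and the
    language model."""

    def __init__(self, n_vocab: int, config: ModelConfig, rng: np.random.Generator,
                 weight_drop: float = 0.0):
        dim = config.embed_dim or 32
        hidden = config.hidden_size or 64
        layers = config.num_layers or 3
        self.embedding = Embedding(n_vocab, dim, rng)
        self.lstms = []
        prev = dim
        for _ in range(layers):
            self.lstms.append(LSTMLayer(prev, hidden, rng, weight_drop=weight_drop))
            prev = hidden
        self.hidden = hidden

    def run(self, ids: np.ndarray, rng: np.random.Generator, train: bool,
            frozen_below: int = 0) -> list[Tensor]:
        """Hidden states of the top LSTM layer per timestep.

        ``frozen_below`` freezes the embedding (1) and the first k-1 LSTM
        layers (k) by detaching their outputs from the graph.
        """
        B, T = ids.shape
        emb = self.embedding(ids)  # (B, T, D)
        if frozen_below >= 1:
            emb = Tensor(emb.data)
        xs = [emb.narrow(1, t, 1).reshape(B, -1) for t in range(T)]
        for i, lstm in enumerate(self.lstms):
            xs = lstm(xs, rng, train)
            if frozen_below >= i + 2 and i < len(self.lstms) - 1:
                xs = [Tensor(x.data) for x in xs]
        return xs

    def parameters(self):
        out = self.embedding.parameters()
        for lstm in self.lstms:
            out.extend(lstm.parameters())
        return out

    def named_parameters(self):
        out = {f"embedding.{k}": v for k, v in self.embedding.named_parameters().items()}
        for i, lstm in enumerate(self.lstms):
            for k, v in lstm.named_parameters().items():
                out[f"lstm{i}.{k}"] = v
        return out

    def param_groups(self):
        """Head-to-input ordering used for gradual unfreezing."""
        groups = [lstm.parameters() for lstm in reversed(self.lstms)]
        groups.append(self.embedding.parameters())
        return groups


def _masked_pool(hs: list[Tensor], ids: np.ndarray, pad_id: int) -> Tensor:
    """Concat pooling over valid positions: last hidden state, mean and max."""
    B = ids.shape[0]
    T = len(hs)
    mask = (ids != pad_id).astype(np.float64)  # (B, T)
    lengths = np.maximum(mask.sum(axis=1), 1.0)
    last_idx = (
        np.argmax(np.where(mask > 0, np.arange(T)[None, :], -1), axis=1)
    )
    H = nn.concat([h.reshape(B, 1, -1) for h in hs], axis=1)  # (B, T, Hd)
    last_onehot = np.zeros((B, T, 1))
    last_onehot[np.arange(B), last_idx, 0] = 1.0
    last = (H * Tensor(last_onehot)).sum(axis=1)
    mean = (H * Tensor(mask[:, :, None] / lengths[:, None, None])).sum(axis=1)
    maxed = (H + Tensor((mask[:, :, None] - 1.0) * 1e9)).max(axis=1)
    return nn.concat([last, mean, maxed], axis=1)


class _RNNNet:
    def __init__(self, n_vocab: int, n_classes: int, config: ModelConfig,
                 rng: np.random.Generator, pad_id: int = 0,
                 weight_drop: float = 0.0):
        self.body = _SequenceBody(n_vocab, config, rng, weight_drop=weight_drop)
        self.head = Linear(3 * self.body.hidden, n_classes, rng)
        self.pad_id = pad_id
        self.dropout = config.dropout
        self.frozen_below = 0  # 0 = everything trainable

    def forward(self, X: np.ndarray, train: bool, rng: np.random.Generator) -> Tensor:
        ids = X.astype(np.int64)
        hs = self.body.run(ids, rng, train, frozen_below=self.frozen_below)
        pooled = _masked_pool(hs, ids, self.pad_id)
        pooled = nn.dropout(pooled, self.dropout, rng, train)
        return self.head(pooled)

    def parameters(self):
        return self.body.parameters() + self.head.parameters()

    def named_parameters(self):
        out = {f"body.{k}": v for k, v in self.body.named_parameters().items()}
        for k, v in self.head.named_parameters().items():
            out[f"head.{k}"] = v
        return out

    def param_groups(self):
        return [self.head.parameters()] + self.body.param_groups()


class _LMNet:
    """Next-token language model over token ids."""

    def __init__(self, n_vocab: int, config: ModelConfig, rng: np.random.Generator,
                 pad_id: int = 0):
        self.body = _SequenceBody(
            n_vocab, config, rng, weight_drop=config.weight_drop or 0.0
        )
        self.head = Linear(self.body.hidden, n_vocab, rng)
        self.pad_id = pad_id
        self.n_vocab = n_vocab

    def loss(self, ids: np.ndarray, train: bool, rng: np.random.Generator) -> Tensor:
        B, T = ids.shape
        hs = self.body.run(ids[:, :-1], rng, train)
        H = nn.concat([h.reshape(B, 1, -1) for h in hs], axis=1)
        logits = self.head(H.reshape(B * (T - 1), -1))
        targets = ids[:, 1:].reshape(-1).copy()
        targets[targets == self.pad_id] = -1  # ignore padding positions
        return nn.cross_entropy_logits(logits, targets)

    def parameters(self):
        return self.body.parameters() + self.head.parameters()

    def named_parameters(self):
        out = {f"body.{k}": v for k, v in self.body.named_parameters().items()}
        for k, v in self.head.named_parameters().items():
            out[f"lm_head.{k}"] = v
        return out


# ---------------------------------------------------------------------------
# Trained artifacts
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """Fitted classifier with its class ordering frozen at fit time."""

    architecture: str
    net: object
    config: ModelConfig
    classes: list
    train_log: list[float] = field(default_factory=list)
    encoder_meta: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.asarray([self.classes[i] for i in probs.argmax(axis=1)])

    # -- persistence ------------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        weights = {k: v.data for k, v in self.net.named_parameters().items()}
        np.savez(out / "weights.npz", **weights)
        (out / "config.json").write_text(json.dumps(asdict(self.config)))
        (out / "classes.json").write_text(json.dumps(list(self.classes)))
        (out / "meta.json").write_text(json.dumps(self.encoder_meta))

    @classmethod
    def load(cls, in_dir) -> "TrainedClassifier":
        src = Path(in_dir)
        cfg_dict = json.loads((src / "config.json").read_text())
        for key in ("hidden_sizes", "conv_channels", "kernel_sizes"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        classes = json.loads((src / "classes.json").read_text())
        meta = json.loads((src / "meta.json").read_text())
        rng = np.random.default_rng(config.seed)
        net = _build_net(config, meta, len(classes), rng)
        with np.load(src / "weights.npz") as blob:
            named = net.named_parameters()
            for k in named:
                named[k].data = blob[k].astype(np.float64)
        return cls(
            architecture=config.architecture, net=net, config=config,
            classes=classes, encoder_meta=meta,
        )


@dataclass
class LanguageModel:
    """Pretrained embedding + LSTM stack for transfer to classification."""

    net: _LMNet
    config: ModelConfig
    vocab_hash: str
    train_log: list[float] = field(default_factory=list)
    initial_perplexity: float = float("nan")
    final_perplexity: float = float("nan")


def _build_net(config: ModelConfig, meta: dict, n_classes: int,
               rng: np.random.Generator):
    arch = config.architecture
    if arch == "dnn":
        return _DNNNet(meta["n_features"], n_classes, config, rng)
    if arch == "cnn":
        return _CNNNet(meta["n_features"], n_classes, config, rng)
    if arch == "rnn_seq2seq":
        return _RNNNet(meta["n_vocab"], n_classes, config, rng,
                       pad_id=meta.get("pad_id", 0))
    if arch == "lm_finetune":
        return _RNNNet(meta["n_vocab"], n_classes, config, rng,
                       pad_id=meta.get("pad_id", 0),
                       weight_drop=config.weight_drop or 0.0)
    raise ConfigurationError(f"unknown architecture {arch!r}")


def _encoder_meta(encoded: EncodedDataset) -> dict:
    meta: dict = {"scheme": encoded.scheme}
    if encoded.scheme == "fingerprint":
        meta["n_features"] = int(encoded.X.shape[1])
    elif encoded.scheme == "matrix":
        meta["n_features"] = int(encoded.X.shape[1])
        meta["max_len"] = int(encoded.X.shape[2])
    else:
        meta["n_vocab"] = len(encoded.vocab)
        meta["pad_id"] = encoded.vocab.pad_id
        meta["max_len"] = int(encoded.X.shape[1])
        meta["vocab_json"] = encoded.vocab.to_json()
        meta["vocab_hash"] = encoded.vocab.content_hash()
        if encoded.merges is not None:
            meta["merges_json"] = encoded.merges.to_json()
    return meta


def _check_scheme(encoded: EncodedDataset, config: ModelConfig) -> None:
    allowed = _SCHEME_FOR_ARCH[config.architecture]
    if encoded.scheme not in allowed:
        raise ConfigurationError(
            f"architecture {config.architecture!r} requires encoding in "
            f"{allowed}, got {encoded.scheme!r}"
        )


def _run_epochs(net, X, y, config, rng, *, epochs=None, params=None,
                log: list[float] | None = None, opt=None):
    params = params if params is not None else net.parameters()
    if opt is None:
        opt = Adam(params, lr=config.lr)
    n = len(X)
    for _ in range(epochs if epochs is not None else config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start: start + config.batch_size]
            logits = net.forward(X[idx], True, rng)
            loss = nn.cross_entropy_logits(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if log is not None:
            log.append(float(np.mean(losses)))


def train_classifier(
    encoded: EncodedDataset, config: ModelConfig, lm: LanguageModel | None = None
) -> TrainedClassifier:
    """Fit one classifier on an encoded dataset.

    Deterministic given ``config.seed``. Raises on encoding/architecture
    mismatch and on single-class data. For ``lm_finetune`` an optional
    pretrained :class:`LanguageModel` provides the body initialization;
    without one the body starts at random weights.
    """
    _check_scheme(encoded, config)
    classes = list(encoded.classes)
    if len(classes) < 2:
        raise InputError("need at least 2 classes to train a classifier")
    if config.architecture == "lm_finetune":
        return finetune_lm_classifier(lm, encoded, config)

    rng = np.random.default_rng(config.seed)
    meta = _encoder_meta(encoded)
    net = _build_net(config, meta, len(classes), rng)
    log: list[float] = []
    _run_epochs(net, encoded.X, encoded.y, config, rng, log=log)
    return TrainedClassifier(
        architecture=config.architecture, net=net, config=config,
        classes=classes, train_log=log, encoder_meta=meta,
    )


def predict_proba(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Per-class probability rows (softmax), columns in ``model.classes``
    order. Raises :class:`InputError` on dimension mismatch."""
    X = np.asarray(X)
    if model.architecture == "dnn" and X.shape[1] != model.encoder_meta["n_features"]:
        raise InputError(
            f"expected {model.encoder_meta['n_features']} features, "
            f"got {X.shape[1]}"
        )
    if model.architecture == "cnn" and X.shape[1] != model.encoder_meta["n_features"]:
        raise InputError("feature-matrix dimension mismatch")
    if model.architecture in ("rnn_seq2seq", "lm_finetune"):
        if X.ndim != 2:
            raise InputError("token input must be (n, max_len) id matrix")
    rng = np.random.default_rng(0)  # unused: no dropout at eval
    out = []
    for start in range(0, len(X), 64):
        logits = model.net.forward(X[start: start + 64], False, rng)
        out.append(nn.softmax(logits.data))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# Language-model pretraining and fine-tuning
# ---------------------------------------------------------------------------


def _lm_eval_loss(net: _LMNet, ids: np.ndarray, batch_size: int = 64) -> float:
    rng = np.random.default_rng(0)
    total, count = 0.0, 0
    for start in range(0, len(ids), batch_size):
        batch = ids[start: start + batch_size]
        loss = net.loss(batch, False, rng)
        weight = int((batch[:, 1:] != net.pad_id).sum())
        total += float(loss.data) * weight
        count += weight
    return total / max(count, 1)


def pretrain_lm(
    corpus: np.ndarray, vocab: TokenVocabulary, config: ModelConfig
) -> LanguageModel:
    """Next-token pretraining with weight-dropped LSTMs and an averaging
    switchover once held-out loss stops improving for ``asgd_patience``
    epochs (NT-ASGD style; the underlying optimizer is Adam and the average
    is taken over its iterates)."""
    if config.architecture != "lm_finetune":
        raise ConfigurationError("pretrain_lm requires an lm_finetune config")
    corpus = np.asarray(corpus, dtype=np.int64)
    if corpus.size == 0:
        raise InputError("empty corpus for language-model pretraining")
    rng = np.random.default_rng(config.seed)
    net = _LMNet(len(vocab), config, rng, pad_id=vocab.pad_id)

    n_val = max(1, len(corpus) // 10)
    perm = rng.permutation(len(corpus))
    val_ids = corpus[perm[:n_val]]
    train_ids = corpus[perm[n_val:]]
    if len(train_ids) == 0:
        train_ids = val_ids

    initial = _lm_eval_loss(net, val_ids)
    opt = Adam(net.parameters(), lr=config.lr)
    averager = WeightAverager(net.parameters())
    patience = config.asgd_patience or 2
    best = float("inf")
    stall = 0
    log: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(train_ids))
        losses = []
        for start in range(0, len(train_ids), config.batch_size):
            batch = train_ids[order[start: start + config.batch_size]]
            loss = net.loss(batch, True, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
        val = _lm_eval_loss(net, val_ids)
        if val < best - 1e-6:
            best = val
            stall = 0
        else:
            stall += 1
        if averager.active:
            averager.update()
        elif stall >= patience:
            logger.info("averaging triggered after %d stalled epochs", stall)
            averager.trigger()
    averager.apply()
    final = _lm_eval_loss(net, val_ids)
    return LanguageModel(
        net=net, config=config, vocab_hash=vocab.content_hash(),
        train_log=log,
        initial_perplexity=float(np.exp(initial)),
        final_perplexity=float(np.exp(final)),
    )


def finetune_lm_classifier(
    lm: LanguageModel | None, encoded: EncodedDataset, config: ModelConfig
) -> TrainedClassifier:
    """Fine-tune a (possibly pretrained) sequence body for classification.

    The head is concat pooling (last/mean/max hidden state) into a linear
    layer. Gradual unfreezing: epoch 1 trains the head only, each following
    epoch unfreezes one more layer group from the top. A vocabulary hash
    mismatch between the language model and the dataset encoding raises
    :class:`ConfigurationError` (prevents silent UNK flooding).
    """
    _check_scheme(encoded, config)
    if lm is not None and lm.vocab_hash != encoded.vocab.content_hash():
        raise ConfigurationError(
            "language-model vocabulary does not match dataset encoding"
        )
    classes = list(encoded.classes)
    if len(classes) < 2:
        raise InputError("need at least 2 classes to train a classifier")
    rng = np.random.default_rng(config.seed)
    meta = _encoder_meta(encoded)
    net = _build_net(config, meta, len(classes), rng)
    if lm is not None:
        # transfer embedding + LSTM weights, leaving the LM untouched
        source = lm.net.body.named_parameters()
        target = net.body.named_parameters()
        for key, param in target.items():
            param.data = source[key].data.copy()

    log: list[float] = []
    if lm is None:
        # nothing pretrained to protect: train everything from epoch 1
        _run_epochs(net, encoded.X, encoded.y, config, rng, log=log)
    else:
        groups = net.param_groups()
        opt = Adam(groups[0], lr=config.lr)
        for epoch in range(config.epochs):
            if 0 < epoch < len(groups):
                opt.add_params(groups[epoch])
            net.frozen_below = max(0, len(groups) - (epoch + 1))
            _run_epochs(net, encoded.X, encoded.y, config, rng, epochs=1,
                        log=log, opt=opt)
        net.frozen_below = 0
    return TrainedClassifier(
        architecture="lm_finetune", net=net, config=config,
        classes=classes, train_log=log, encoder_meta=meta,
    )
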
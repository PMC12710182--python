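"""Sequence regressors for cytokine response prediction.

The primary model (``transformer_m1``) is a small encoder: token +
learned positional embeddings, post-norm transformer blocks (multi-head
self-attention with PAD masking, position-wise feed-forward, residual +
layer norm), a global average pool over non-PAD positions, and a scalar
regression head.  Trained with Adam on an MAE loss against log10
cytokine targets.  Comparators: the same architecture trained without
permutation augmentation (``transformer_noaug``), an LSTM encoder, and a
Random Forest on composition descriptors.  One model is trained per
endpoint (IFN-beta or IL-6).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from sklearn.ensemble import RandomForestRegressor

from . import nn
from .data import (
    NANPDataset,
    NANPRecord,
    NanpError,
    compute_descriptors,
    descriptor_table,
)
from .tokenization import (
    AugmentedDataset,
    Vocabulary,
    augment_dataset,
    encode_record,
    permute_strands,
)

TRANSFORMER_M1 = "transformer_m1"
TRANSFORMER_NOAUG = "transformer_noaug"
LSTM = "lstm"
RF_DESCRIPTORS = "rf_descriptors"
MODEL_KINDS = (TRANSFORMER_M1, TRANSFORMER_NOAUG, LSTM, RF_DESCRIPTORS)

#: default number of strand orderings averaged at inference
DEFAULT_INFERENCE_PERMUTATIONS = 24


class ConfigError(NanpError):
    """Invalid model configuration."""


class DivergenceError(NanpError):
    """Training loss became non-finite."""


class InsufficientDataError(NanpError):
    """Too few rows to fit a model."""


@dataclass
class TransformerConfig:
    """Architecture and training hyperparameters.

    The published work does not disclose its hyperparameter table, so
    these are conservative small-data defaults; every value is
    overridable from the CLI config file.
    """

    embedding_dim: int = 64
    num_blocks: int = 2
    num_heads: int = 4
    feedforward_dim: int = 128
    dropout: float = 0.1
    token_dropout: float = 0.0  # fraction of input tokens PAD-masked per step
    weight_decay: float = 0.0
    ema_decay: float = 0.0  # 0 disables Polyak weight averaging
    learning_rate: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 32
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim % self.num_heads != 0:
            raise ConfigError(
                f"embedding_dim {self.embedding_dim} not divisible by "
                f"num_heads {self.num_heads}"
            )
        for name in ("embedding_dim", "num_blocks", "num_heads",
                     "feedforward_dim", "max_epochs", "batch_size",
                     "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epochs_run: int = 0
    best_epoch: int | None = None


@dataclass
class TrainedModel:
    """A fitted regressor for one endpoint.

    ``params`` holds either the autodiff parameter tensors (neural
    kinds) or the fitted sklearn estimator (``rf_descriptors``).
    Predictions are deterministic given fixed parameters and input.
    """

    kind: str
    endpoint: str | None
    params: dict
    vocab: Vocabulary | None
    config: TransformerConfig | None
    training_seed: int = 0
    train_ids: frozenset[str] = frozenset()
    history: TrainingHistory | None = None

    # -- forward passes ----------------------------------------------------

    def predict_tokens(self, tokens: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic (eval-mode) forward pass over encoded variants."""
        if self.kind == RF_DESCRIPTORS:
            raise NanpError("descriptor RF does not consume token streams")
        pad = self.vocab.pad_index
        outs = []
        for start in range(0, len(tokens), batch_size):
            batch = np.asarray(tokens[start : start + batch_size], dtype=np.int64)
            batch = _trim_padding(batch, pad)
            if self.kind in (TRANSFORMER_M1, TRANSFORMER_NOAUG):
                out = _transformer_forward(
                    self.params, batch, self.vocab.pad_index, self.config,
                    training=False, rng=None,
                )
            elif self.kind == LSTM:
                out = _lstm_forward(
                    self.params, batch, self.vocab.pad_index, self.config,
                    training=False, rng=None,
                )
            else:
                raise NanpError(f"unknown model kind {self.kind!r}")
            outs.append(out.data.astype(np.float64))
        return np.concatenate(outs)

    def predict_descriptors(self, X: np.ndarray) -> np.ndarray:
        if self.kind != RF_DESCRIPTORS:
            raise NanpError("only the descriptor RF consumes descriptor matrices")
        return self.params["estimator"].predict(np.asarray(X, dtype=float))

    @property
    def feature_importances_(self) -> np.ndarray:
        if self.kind != RF_DESCRIPTORS:
            raise NanpError("feature importances only defined for the RF")
        return self.params["estimator"].feature_importances_

    def parameter_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_parameter_state(self, state: Mapping[str, np.ndarray]) -> None:
        for key, value in state.items():
            self.params[key].data = np.asarray(value, dtype=nn.DTYPE).copy()


def _trim_padding(batch: np.ndarray, pad_index: int) -> np.ndarray:
    """Drop trailing all-PAD columns (sequences are right-padded)."""
    lengths = (batch != pad_index).sum(axis=1)
    longest = int(lengths.max()) if len(lengths) else 0
    return batch[:, : max(longest, 1)]


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


def _init_transformer_params(config: TransformerConfig, vocab: Vocabulary) -> dict:
    rng = np.random.default_rng(config.seed)
    D, F = config.embedding_dim, config.feedforward_dim
    V, L = len(vocab), vocab.max_len
    params = {
        "tok_emb": nn.Tensor(rng.normal(0.0, 0.02, size=(V, D)), requires_grad=True),
        "pos_emb": nn.Tensor(rng.normal(0.0, 0.02, size=(L, D)), requires_grad=True),
        "w_out": nn.glorot(rng, D, 1),
        "b_out": nn.zeros((1,)),
    }
    for i in range(config.num_blocks):
        p = f"block{i}_"
        for name in ("wq", "wk", "wv", "wo"):
            params[p + name] = nn.glorot(rng, D, D)
            params[p + name.replace("w", "b")] = nn.zeros((D,))
        params[p + "ln1_g"] = nn.ones((D,))
        params[p + "ln1_b"] = nn.zeros((D,))
        params[p + "w1"] = nn.glorot(rng, D, F)
        params[p + "b1"] = nn.zeros((F,))
        params[p + "w2"] = nn.glorot(rng, F, D)
        params[p + "b2"] = nn.zeros((D,))
        params[p + "ln2_g"] = nn.ones((D,))
        params[p + "ln2_b"] = nn.zeros((D,))
    return params


def _transformer_forward(
    params: dict,
    tokens: np.ndarray,
    pad_index: int,
    config: TransformerConfig,
    training: bool,
    rng: np.random.Generator | None,
) -> nn.Tensor:
    B, L = tokens.shape
    D = config.embedding_dim
    H = config.num_heads
    Dh = D // H
    mask = (tokens != pad_index).astype(nn.DTYPE)  # (B, L)
    # additive bias hides PAD keys from attention
    attn_bias = ((1.0 - mask) * -1e9)[:, None, None, :].astype(nn.DTYPE)

    x = nn.embedding(params["tok_emb"], tokens)
    # (B, L, D) + (L, D); L may be trimmed below max_len for a batch
    x = nn.add(x, nn.row_slice(params["pos_emb"], L))
    x = nn.dropout(x, config.dropout, rng, training)

    for i in range(config.num_blocks):
        p = f"block{i}_"

        def proj(w, b):
            y = nn.add(nn.matmul(x, params[p + w]), params[p + b])
            y = nn.reshape(y, (B, L, H, Dh))
            return nn.transpose(y, (0, 2, 1, 3))  # (B, H, L, Dh)

        # 1/sqrt(Dh) applied to q (cheaper than scaling the L x L scores)
        q = nn.scale(proj("wq", "bq"), 1.0 / math.sqrt(Dh))
        k = proj("wk", "bk")
        v = proj("wv", "bv")
        scores = nn.matmul(q, nn.transpose(k, (0, 1, 3, 2)))
        attn = nn.softmax_last(scores, bias=attn_bias)
        attn = nn.dropout(attn, config.dropout, rng, training)
        ctx = nn.matmul(attn, v)  # (B, H, L, Dh)
        ctx = nn.reshape(nn.transpose(ctx, (0, 2, 1, 3)), (B, L, D))
        out = nn.add(nn.matmul(ctx, params[p + "wo"]), params[p + "bo"])
        out = nn.dropout(out, config.dropout, rng, training)
        x = nn.layer_norm(nn.add(x, out), params[p + "ln1_g"], params[p + "ln1_b"])

        hidden = nn.relu(nn.add(nn.matmul(x, params[p + "w1"]), params[p + "b1"]))
        ff = nn.add(nn.matmul(hidden, params[p + "w2"]), params[p + "b2"])
        ff = nn.dropout(ff, config.dropout, rng, training)
        x = nn.layer_norm(nn.add(x, ff), params[p + "ln2_g"], params[p + "ln2_b"])

    pooled = nn.masked_mean(x, mask)  # (B, D), PAD positions excluded
    out = nn.add(nn.matmul(pooled, params["w_out"]), params["b_out"])
    return nn.reshape(out, (B,))


def _init_lstm_params(config: TransformerConfig, vocab: Vocabulary) -> dict:
    rng = np.random.default_rng(config.seed)
    D = config.embedding_dim
    Hd = config.feedforward_dim  # recurrent hidden size
    V = len(vocab)
    params = {
        "tok_emb": nn.Tensor(rng.normal(0.0, 0.02, size=(V, D)), requires_grad=True),
        "wx": nn.glorot(rng, D, 4 * Hd),
        "wh": nn.glorot(rng, Hd, 4 * Hd),
        "b": nn.zeros((4 * Hd,)),
        "w_out": nn.glorot(rng, Hd, 1),
        "b_out": nn.zeros((1,)),
    }
    # forget-gate bias starts positive so long-range state survives early training
    params["b"].data[Hd : 2 * Hd] = 1.0
    return params


def _lstm_forward(
    params: dict,
    tokens: np.ndarray,
    pad_index: int,
    config: TransformerConfig,
    training: bool,
    rng: np.random.Generator | None,
) -> nn.Tensor:
    B, L = tokens.shape
    Hd = config.feedforward_dim
    mask = (tokens != pad_index).astype(nn.DTYPE)
    lengths = mask.sum(axis=1).astype(int)
    steps = int(lengths.max()) if len(lengths) else 0

    x = nn.embedding(params["tok_emb"], tokens)
    x = nn.dropout(x, config.dropout, rng, training)
    h = nn.Tensor(np.zeros((B, Hd)))
    c = nn.Tensor(np.zeros((B, Hd)))
    for t in range(steps):
        xt = nn.time_slice(x, t)
        z = nn.add(nn.add(nn.matmul(xt, params["wx"]),
                          nn.matmul(h, params["wh"])), params["b"])
        i = nn.sigmoid(nn.narrow(z, 0, Hd))
        f = nn.sigmoid(nn.narrow(z, Hd, Hd))
        g = nn.tanh(nn.narrow(z, 2 * Hd, Hd))
        o = nn.sigmoid(nn.narrow(z, 3 * Hd, Hd))
        c_new = nn.add(nn.mul(f, c), nn.mul(i, g))
        h_new = nn.mul(o, nn.tanh(c_new))
        # freeze state on padded positions so the final state is the one
        # at each sequence's true end
        mt = nn.Tensor(mask[:, t : t + 1])
        keep = nn.Tensor(1.0 - mask[:, t : t + 1])
        h = nn.add(nn.mul(h_new, mt), nn.mul(h, keep))
        c = nn.add(nn.mul(c_new, mt), nn.mul(c, keep))
    out = nn.add(nn.matmul(h, params["w_out"]), params["b_out"])
    return nn.reshape(out, (B,))


def build_transformer(
    config: TransformerConfig, vocab: Vocabulary, kind: str = TRANSFORMER_M1
) -> TrainedModel:
    """An untrained transformer regressor with seeded initialization."""
    if vocab.max_len is None:
        raise ConfigError("vocabulary has no max_len; build it from a corpus")
    if kind not in (TRANSFORMER_M1, TRANSFORMER_NOAUG):
        raise ConfigError(f"kind must be a transformer kind, got {kind!r}")
    return TrainedModel(
        kind=kind,
        endpoint=None,
        params=_init_transformer_params(config, vocab),
        vocab=vocab,
        config=config,
        training_seed=config.seed,
    )


def build_lstm(config: TransformerConfig, vocab: Vocabulary) -> TrainedModel:
    """An untrained LSTM regressor (recurrent encoder, final-state head).

    ``feedforward_dim`` doubles as the recurrent hidden size.
    """
    if vocab.max_len is None:
        raise ConfigError("vocabulary has no max_len; build it from a corpus")
    return TrainedModel(
        kind=LSTM,
        endpoint=None,
        params=_init_lstm_params(config, vocab),
        vocab=vocab,
        config=config,
        training_seed=config.seed,
    )


def build_rf(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_estimators: int = 300,
    endpoint: str | None = None,
    train_ids: Sequence[str] = (),
) -> TrainedModel:
    """Fit the descriptor-based Random Forest comparator."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 5:
        raise InsufficientDataError(
            f"need at least 5 training rows for the RF, got {len(X)}"
        )
    est = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    est.fit(X, y)
    return TrainedModel(
        kind=RF_DESCRIPTORS,
        endpoint=endpoint,
        params={"estimator": est},
        vocab=None,
        config=None,
        training_seed=seed,
        train_ids=frozenset(train_ids),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _eval_mae(model: TrainedModel, tokens: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict_tokens(tokens)
    return float(np.abs(pred - y).mean())


def train(
    model: TrainedModel,
    train_data: AugmentedDataset,
    val_data: AugmentedDataset | None,
    endpoint: str,
    config: TransformerConfig | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Adam / MAE training with early stopping on validation MAE.

    Weights from the best validation epoch are restored; without
    validation data the full epoch budget is run.  Raises
    :class:`DivergenceError` if the loss becomes non-finite.
    """
    config = config or model.config
    forward = (
        _transformer_forward
        if model.kind in (TRANSFORMER_M1, TRANSFORMER_NOAUG)
        else _lstm_forward
    )
    X = train_data.token_matrix().astype(np.int64)
    y = train_data.target_vector(endpoint)
    if val_data is not None and len(val_data):
        Xv = val_data.token_matrix().astype(np.int64)
        yv = val_data.target_vector(endpoint)
    else:
        Xv = yv = None

    optimizer = nn.Adam(
        model.params, lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    shuffle_rng = np.random.default_rng(config.seed + 1)
    dropout_rng = np.random.default_rng(config.seed + 2)
    history = TrainingHistory()
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    patience_left = config.early_stop_patience
    # halve the learning rate on a validation plateau (reduce-on-plateau)
    plateau_window = max(2, config.early_stop_patience // 3)
    plateau_left = plateau_window
    min_lr = config.learning_rate / 32.0

    ema: dict[str, np.ndarray] | None = None
    if config.ema_decay > 0:
        ema = model.parameter_state()

    def _with_ema_weights():
        """Temporarily swap in the averaged weights."""
        raw = model.parameter_state()
        model.load_parameter_state(ema)
        return raw

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(X))
        losses, weights = [], []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = _trim_padding(X[idx], model.vocab.pad_index)
            if config.token_dropout > 0:
                # PAD-mask a random token subset: the response depends on
                # composition, which survives subsampling; memorized
                # record-specific patterns do not
                drop = dropout_rng.random(batch.shape) < config.token_dropout
                batch = np.where(drop, model.vocab.pad_index, batch)
            optimizer.zero_grad()
            pred = forward(
                model.params, batch, model.vocab.pad_index, config,
                training=True, rng=dropout_rng,
            )
            loss = nn.mae_loss(pred, y[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            if ema is not None:
                d = config.ema_decay
                for key, p in model.params.items():
                    ema[key] = d * ema[key] + (1.0 - d) * p.data
            losses.append(float(loss.data))
            weights.append(len(idx))
        epoch_loss = float(np.average(losses, weights=weights))
        history.train_loss.append(epoch_loss)
        history.epochs_run = epoch + 1

        if Xv is not None:
            if ema is not None:
                raw = _with_ema_weights()
                val_mae = _eval_mae(model, Xv, yv)
                model.load_parameter_state(raw)
            else:
                val_mae = _eval_mae(model, Xv, yv)
            if not np.isfinite(val_mae):
                raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
            history.val_loss.append(val_mae)
            if val_mae < best_val - 1e-6:
                best_val = val_mae
                best_state = (
                    {k: v.copy() for k, v in ema.items()}
                    if ema is not None
                    else model.parameter_state()
                )
                history.best_epoch = epoch
                patience_left = config.early_stop_patience
                plateau_left = plateau_window
            else:
                patience_left -= 1
                plateau_left -= 1
                if patience_left <= 0:
                    break
                if plateau_left <= 0 and optimizer.lr > min_lr:
                    optimizer.lr = max(min_lr, optimizer.lr * 0.5)
                    plateau_left = plateau_window

    if best_state is not None:
        model.load_parameter_state(best_state)
    elif ema is not None:
        model.load_parameter_state(ema)
    model.endpoint = endpoint
    model.history = history
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def predict_record(
    model: TrainedModel,
    record: NANPRecord,
    n_permutations: int = DEFAULT_INFERENCE_PERMUTATIONS,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation-aggregated prediction for one construct.

    Returns (mean log10 prediction, standard deviation across the
    min(n_strands!, n_permutations) strand orderings, identity included).
    Descriptor models are order-invariant and report spread 0.
    """
    if model.kind == RF_DESCRIPTORS:
        x = compute_descriptors(record).to_array()[None, :]
        return float(model.predict_descriptors(x)[0]), 0.0
    orders = permute_strands(record, cap=n_permutations, seed=seed)
    tokens = np.array(
        [
            encode_record(record, order, model.vocab, permutation_index=j)
            .token_indices
            for j, order in enumerate(orders)
        ],
        dtype=np.int64,
    )
    preds = model.predict_tokens(tokens)
    return float(preds.mean()), float(preds.std())


def predict_dataset(
    model: TrainedModel,
    dataset: NANPDataset,
    n_permutations: int = DEFAULT_INFERENCE_PERMUTATIONS,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """predict_record over a dataset -> {nanp_id: (mean, spread)}."""
    return {
        rec.nanp_id: predict_record(model, rec, n_permutations, seed)
        for rec in dataset
    }


# ---------------------------------------------------------------------------
# Training-pipeline factories (shared by cross-validation and the CLI)
# ---------------------------------------------------------------------------

ModelFactory = Callable[[NANPDataset, str, int], TrainedModel]


def _group_val_split(
    dataset: NANPDataset, val_fraction: float, seed: int
) -> tuple[NANPDataset, NANPDataset]:
    rng = np.random.default_rng(seed)
    ids = dataset.ids()
    n_val = max(1, int(round(val_fraction * len(ids)))) if val_fraction > 0 else 0
    order = rng.permutation(len(ids))
    val_ids = {ids[i] for i in order[:n_val]}
    return (
        dataset.subset([i for i in ids if i not in val_ids]),
        dataset.subset([i for i in ids if i in val_ids]),
    )


def make_sequence_factory(
    config: TransformerConfig,
    kind: str = TRANSFORMER_M1,
    cap: int = 720,
    k: int = 3,
    max_len: int | None = None,
    val_fraction: float = 0.15,
    val_cap: int | None = None,
    n_members: int = 1,
) -> ModelFactory:
    """Factory closing over hyperparameters; trains on a record dataset.

    The factory builds the vocabulary from its training records, holds
    out a group-aware validation slice for early stopping (scored over
    ``val_cap`` permutation variants per held-out record — matching the
    training cap by default gives a far less noisy model-selection
    signal than a single ordering), augments the remainder with up to
    ``cap`` strand permutations, and trains.  ``cap=1`` yields the
    no-augmentation comparator regime.  ``n_members > 1`` trains
    seed-replicates and returns their prediction-averaging ensemble.
    """
    from .tokenization import build_vocabulary

    effective_kind = kind
    if kind in (TRANSFORMER_M1, TRANSFORMER_NOAUG):
        effective_kind = TRANSFORMER_NOAUG if cap == 1 else TRANSFORMER_M1
    if val_cap is None:
        val_cap = cap

    def train_one(train_dataset: NANPDataset, endpoint: str, seed: int) -> TrainedModel:
        vocab = build_vocabulary(train_dataset, k=k, max_len=max_len)
        fit_set, val_set = _group_val_split(train_dataset, val_fraction, seed + 101)
        run_config = dataclasses.replace(config, seed=seed)
        train_aug = augment_dataset(fit_set, vocab, cap=cap, seed=seed + 202)
        val_aug = (
            augment_dataset(val_set, vocab, cap=val_cap, seed=seed + 303)
            if len(val_set)
            else None
        )
        if effective_kind == LSTM:
            model = build_lstm(run_config, vocab)
        else:
            model = build_transformer(run_config, vocab, kind=effective_kind)
        model, _ = train(model, train_aug, val_aug, endpoint, run_config)
        model.train_ids = frozenset(train_dataset.ids())
        return model

    def factory(train_dataset: NANPDataset, endpoint: str, seed: int) -> TrainedModel:
        if n_members == 1:
            return train_one(train_dataset, endpoint, seed)
        members = [
            train_one(train_dataset, endpoint, seed + 7919 * i)
            for i in range(n_members)
        ]
        return SeedEnsemble(members)

    return factory


class SeedEnsemble:
    """Prediction-averaging ensemble of seed-replicate models.

    Quacks like :class:`TrainedModel` for inference and evaluation:
    ``predict_tokens`` averages the members, so permutation aggregation
    and spread computations apply transparently.
    """

    def __init__(self, members: list[TrainedModel]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.kind = members[0].kind
        self.endpoint = members[0].endpoint
        self.vocab = members[0].vocab
        self.config = members[0].config
        self.training_seed = members[0].training_seed
        self.train_ids = frozenset().union(*(m.train_ids for m in members))

    def predict_tokens(self, tokens, batch_size: int = 256):
        preds = [m.predict_tokens(tokens, batch_size) for m in self.members]
        return np.mean(preds, axis=0)


def make_rf_factory(n_estimators: int = 300) -> ModelFactory:
    """Factory for the descriptor Random Forest comparator."""

    def factory(train_dataset: NANPDataset, endpoint: str, seed: int) -> TrainedModel:
        table = descriptor_table(train_dataset)
        y = np.array(
            [rec.endpoints[endpoint] for rec in train_dataset], dtype=float
        )
        return build_rf(
            table.to_numpy(), y, seed=seed, n_estimators=n_estimators,
            endpoint=endpoint, train_ids=train_dataset.ids(),
        )

    return factory


# ---------------------------------------------------------------------------
# Model artifacts
# ---------------------------------------------------------------------------


def data_fingerprint(ids: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(sorted(ids)).encode()).hexdigest()[:16]


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Write a model artifact directory (weights, vocab, config, card)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if model.kind == RF_DESCRIPTORS:
        import joblib

        joblib.dump(model.params["estimator"], directory / "estimator.joblib")
    else:
        np.savez(directory / "weights.npz", **model.parameter_state())
        model.vocab.to_json(directory / "vocab.json")
    if model.config is not None:
        (directory / "config.yaml").write_text(yaml.safe_dump(asdict(model.config)))
    if model.history is not None:
        import pandas as pd

        rows = {
            "epoch": list(range(model.history.epochs_run)),
            "train_mae": model.history.train_loss,
        }
        if model.history.val_loss:
            rows["val_mae"] = model.history.val_loss
        pd.DataFrame(rows).to_csv(directory / "training_history.csv", index=False)
    card = {
        "kind": model.kind,
        "endpoint": model.endpoint,
        "training_seed": model.training_seed,
        "train_ids": sorted(model.train_ids),
        "data_fingerprint": data_fingerprint(list(model.train_ids)),
    }
    (directory / "model_card.md").write_text(
        "# Model card\n\n```json\n" + json.dumps(card, indent=2) + "\n```\n"
    )


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    card_text = (directory / "model_card.md").read_text()
    card = json.loads(card_text.split("```json\n")[1].split("\n```")[0])
    config = None
    if (directory / "config.yaml").exists():
        config = TransformerConfig(**yaml.safe_load((directory / "config.yaml").read_text()))
    if card["kind"] == RF_DESCRIPTORS:
        import joblib

        params = {"estimator": joblib.load(directory / "estimator.joblib")}
        vocab = None
    else:
        vocab = Vocabulary.from_json(directory / "vocab.json")
        if card["kind"] == LSTM:
            params = _init_lstm_params(config, vocab)
        else:
            params = _init_transformer_params(config, vocab)
        with np.load(directory / "weights.npz") as payload:
            for key in params:
                params[key].data = payload[key].astype(nn.DTYPE)
    return TrainedModel(
        kind=card["kind"],
        endpoint=card["endpoint"],
        params=params,
        vocab=vocab,
        config=config,
        training_seed=card["training_seed"],
        train_ids=frozenset(card["train_ids"]),
    )
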
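"""Convolutional networks for orthologous-group assignment, in pure numpy.

Two variants are provided as pure functions from encoded batches to
group-probability vectors:

* ``deepnog`` — learned amino-acid embedding (26 codes -> R^D), 1-D convolutions
  of eight filter sizes, SELU activations (self-normalizing, no explicit
  normalization layers), masked adaptive max-pooling over each sequence's valid
  windows, dropout, and a softmax output layer placed directly after pooling.
  Handles arbitrary sequence lengths; inputs shorter than the largest filter
  (36) are zero-padded so every filter sees at least one window.
* ``deepfam`` — the fixed-length baseline: pseudo one-hot input (21 dims),
  convolutions with batch normalization + ReLU, full-row 1-max-pooling over the
  fixed input length, one hidden ReLU layer, dropout, softmax output.

The masked pooling of the ``deepnog`` variant guarantees padding invariance:
windows that would fall entirely in trailing padding are excluded from the
maximum, so a sequence's logits do not depend on how far its row was padded or
on its batch companions.

Both forward and backward passes are implemented here; gradients flow to every
trainable array (the padding row of the embedding is pinned to zero).
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet_io import (
    EXTENDED_RESIDUES,
    EncodedBatch,
    GroupLabelMap,
    PADDING_INDEX,
)

logger = logging.getLogger(__name__)

# Self-normalizing scaled exponential linear unit constants (fixed point of
# zero mean / unit variance signal propagation).
SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805

DEFAULT_FILTER_SIZES = (8, 12, 16, 20, 24, 28, 32, 36)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters shared by both variants.

    Defaults follow the published parametrization: embedding dimension 10,
    filter sizes 8..36 in steps of 4, 150 filters per size, dropout 0.3.
    ``hidden_units`` and ``fixed_length`` apply to the baseline only (best
    parametrization: 250 filters per size and 2000 hidden units; the light
    parametrization uses 150 and 1500).
    """

    variant: str
    n_groups: int
    alphabet_size: int = 26
    embedding_dim: int = 10
    filter_sizes: tuple[int, ...] = DEFAULT_FILTER_SIZES
    filters_per_size: int = 150
    dropout_p: float = 0.3
    hidden_units: int = 0
    fixed_length: int = 1000

    def __post_init__(self):
        if self.variant not in ("deepnog", "deepfam"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        ks = tuple(self.filter_sizes)
        if not ks or any(k < 1 for k in ks) or list(ks) != sorted(set(ks)):
            raise ValueError("filter_sizes must be strictly increasing positive integers")
        if self.filters_per_size < 1:
            raise ValueError("filters_per_size must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.n_groups < 2:
            raise ValueError("need at least two output groups")
        if self.variant == "deepnog" and self.hidden_units != 0:
            raise ValueError("the deepnog variant has no hidden layer")
        if self.variant == "deepfam" and self.hidden_units < 1:
            raise ValueError("the deepfam variant requires hidden_units >= 1")

    @property
    def n_filters_total(self) -> int:
        return len(self.filter_sizes) * self.filters_per_size

    @property
    def input_channels(self) -> int:
        # deepfam consumes the 21-dim pseudo one-hot; deepnog embeds 26 codes.
        return 21 if self.variant == "deepfam" else self.embedding_dim


def deepfam_best_config(n_groups: int) -> ModelConfig:
    return ModelConfig(variant="deepfam", n_groups=n_groups,
                       filters_per_size=250, hidden_units=2000)


def deepfam_light_config(n_groups: int) -> ModelConfig:
    return ModelConfig(variant="deepfam", n_groups=n_groups,
                       filters_per_size=150, hidden_units=1500)


@dataclass
class ModelState:
    """Named weight arrays (plus non-trainable buffers) for one network."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    buffers: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            buffers={k: v.copy() for k, v in self.buffers.items()},
        )


def expected_param_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Name -> shape of every trainable array, the ground truth for allocation."""
    F, C = config.filters_per_size, config.n_groups
    shapes: dict[str, tuple[int, ...]] = {}
    if config.variant == "deepnog":
        shapes["embedding"] = (config.alphabet_size + 1, config.embedding_dim)
        d = config.embedding_dim
    else:
        d = 21
    for k in config.filter_sizes:
        shapes[f"conv{k}_w"] = (F, k, d)
        shapes[f"conv{k}_b"] = (F,)
        if config.variant == "deepfam":
            shapes[f"bn{k}_gamma"] = (F,)
            shapes[f"bn{k}_beta"] = (F,)
    n_feat = config.n_filters_total
    if config.variant == "deepfam":
        shapes["hidden_w"] = (n_feat, config.hidden_units)
        shapes["hidden_b"] = (config.hidden_units,)
        shapes["out_w"] = (config.hidden_units, C)
    else:
        shapes["out_w"] = (n_feat, C)
    shapes["out_b"] = (C,)
    return shapes


def count_parameters(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count; the padding embedding row is
    counted (it is allocated) even though it stays frozen at zero."""
    F, C, ks = config.filters_per_size, config.n_groups, config.filter_sizes
    if config.variant == "deepnog":
        a1, d = config.alphabet_size + 1, config.embedding_dim
        return (
            a1 * d
            + sum(F * (k * d + 1) for k in ks)
            + len(ks) * F * C
            + C
        )
    h = config.hidden_units
    return (
        sum(F * (k * 21 + 1) + 2 * F for k in ks)
        + len(ks) * F * h
        + h
        + h * C
        + C
    )


def initialize_self_normalizing(state: ModelState, seed: int) -> ModelState:
    """In-place initialization for stable signal propagation.

    Convolution and affine weights are drawn from N(0, 1/fan_in) so that unit
    variance inputs give unit variance pre-activations — the regime in which
    SELU drives activations toward zero mean and unit variance. Biases start at
    zero; embedding rows are standard normal (unit expected square per
    dimension) with the padding row pinned to zero; batch-norm scale/shift
    start at 1/0.
    """
    rng = np.random.default_rng(seed)
    cfg = state.config
    for name, shape in expected_param_shapes(cfg).items():
        if name == "embedding":
            w = rng.standard_normal(shape)
            w[PADDING_INDEX] = 0.0
        elif name.endswith("_b") or name.endswith("_beta"):
            w = np.zeros(shape)
        elif name.endswith("_gamma"):
            w = np.ones(shape)
        elif name.startswith("conv"):
            fan_in = shape[1] * shape[2]
            w = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape)
        else:  # affine weight matrices, fan_in = input dimension
            fan_in = shape[0]
            w = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape)
        state.params[name] = w.astype(np.float32)
    if cfg.variant == "deepfam":
        for k in cfg.filter_sizes:
            state.buffers[f"bn{k}_mean"] = np.zeros(cfg.filters_per_size, dtype=np.float32)
            state.buffers[f"bn{k}_var"] = np.ones(cfg.filters_per_size, dtype=np.float32)
    return state


def _empty_state(config: ModelConfig) -> ModelState:
    params = {n: np.zeros(s, dtype=np.float32) for n, s in expected_param_shapes(config).items()}
    return ModelState(config=config, params=params)


def build_deepnog(config: ModelConfig, seed: int = 0) -> ModelState:
    if config.variant != "deepnog":
        raise ValueError("config.variant must be 'deepnog'")
    return initialize_self_normalizing(_empty_state(config), seed)


def build_deepfam(config: ModelConfig, seed: int = 0) -> ModelState:
    if config.variant != "deepfam":
        raise ValueError("config.variant must be 'deepfam'")
    return initialize_self_normalizing(_empty_state(config), seed)


def build_model(config: ModelConfig, seed: int = 0) -> ModelState:
    return build_deepnog(config, seed) if config.variant == "deepnog" else build_deepfam(config, seed)


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def selu(x: np.ndarray) -> np.ndarray:
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(x))


def predict_proba(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax (computed in float64 for well-conditioned sums)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# deepnog forward/backward
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, D) -> (B, T, k*D) windows with T = L - k + 1."""
    win = sliding_window_view(x, k, axis=1)          # (B, T, D, k)
    win = win.transpose(0, 1, 3, 2)                  # (B, T, k, D)
    b, t = win.shape[:2]
    return np.ascontiguousarray(win).reshape(b, t, -1)


def _dropout_mask(rng, shape, p):
    # inverted dropout: scale at train time so evaluation is a plain identity
    return (rng.random(shape) >= p).astype(np.float32) / np.float32(1.0 - p)


def _forward_deepnog(state, batch: EncodedBatch, training, dropout_rng, need_cache):
    cfg = state.config
    matrix, lengths = batch.matrix, batch.lengths
    if matrix.min() < 0 or matrix.max() > cfg.alphabet_size:
        raise ValueError("batch contains indices outside the alphabet range")
    if matrix.shape[1] < max(cfg.filter_sizes):
        raise ValueError(
            f"batch is padded to {matrix.shape[1]} but the largest filter needs "
            f"{max(cfg.filter_sizes)} positions; use pad_and_batch(min_length="
            f"{max(cfg.filter_sizes)})"
        )
    emb = state.params["embedding"]
    x = emb[matrix]                                  # (B, L, D)
    b_sz, l_max, _ = x.shape
    feats, caches = [], []
    for k in cfg.filter_sizes:
        w = state.params[f"conv{k}_w"].reshape(cfg.filters_per_size, -1)  # (F, k*D)
        bias = state.params[f"conv{k}_b"]
        col = _im2col(x, k)                          # (B, T, k*D)
        t = col.shape[1]
        pre = col @ w.T + bias                       # (B, T, F)
        act = selu(pre)
        # valid windows per row: max(L_i - k + 1, 1); later windows are padding-only
        valid = np.maximum(lengths - k + 1, 1)
        invalid = np.arange(t)[None, :] >= valid[:, None]
        act_masked = np.where(invalid[:, :, None], -np.inf, act)
        arg = act_masked.argmax(axis=1)              # (B, F)
        pooled = np.take_along_axis(act_masked, arg[:, None, :], axis=1)[:, 0, :]
        feats.append(pooled.astype(np.float32))
        if need_cache:
            caches.append({"k": k, "col": col, "pre": pre, "arg": arg, "t": t})
    feat = np.concatenate(feats, axis=1)             # (B, |K|*F)
    if training and cfg.dropout_p > 0:
        mask = _dropout_mask(dropout_rng, feat.shape, cfg.dropout_p)
        feat_d = feat * mask
    else:
        mask = None
        feat_d = feat
    logits = feat_d @ state.params["out_w"] + state.params["out_b"]
    cache = None
    if need_cache:
        cache = {"caches": caches, "feat": feat, "feat_d": feat_d, "mask": mask,
                 "matrix": matrix, "x_shape": x.shape}
    return logits, cache


def _backward_deepnog(state, cache, dlogits):
    cfg = state.config
    grads = {}
    feat_d, mask = cache["feat_d"], cache["mask"]
    grads["out_w"] = (feat_d.T @ dlogits).astype(np.float32)
    grads["out_b"] = dlogits.sum(axis=0).astype(np.float32)
    dfeat = dlogits @ state.params["out_w"].T
    if mask is not None:
        dfeat = dfeat * mask
    b_sz, l_max, d = cache["x_shape"]
    dx = np.zeros((b_sz, l_max, d), dtype=np.float64)
    f = cfg.filters_per_size
    for i, c in enumerate(cache["caches"]):
        k, col, pre, arg = c["k"], c["col"], c["pre"], c["arg"]
        g = dfeat[:, i * f:(i + 1) * f]              # (B, F)
        rows = np.arange(b_sz)[:, None]
        pre_sel = pre[rows, arg, np.arange(f)[None, :]]          # (B, F)
        dpre = g * selu_grad(pre_sel)                             # (B, F)
        col_sel = col[rows, arg]                                  # (B, F, k*D)
        w = state.params[f"conv{k}_w"].reshape(f, -1)
        grads[f"conv{k}_w"] = np.einsum("bf,bfx->fx", dpre, col_sel).reshape(
            f, k, d).astype(np.float32)
        grads[f"conv{k}_b"] = dpre.sum(axis=0).astype(np.float32)
        # scatter dpre[b,f] * w[f] back into the embedded input
        dwin = (dpre[:, :, None] * w[None, :, :]).reshape(b_sz, f, k, d)
        pos = arg[:, :, None] + np.arange(k)[None, None, :]       # (B, F, k)
        np.add.at(dx, (rows[:, :, None], pos), dwin)
    demb = np.zeros_like(state.params["embedding"], dtype=np.float64)
    np.add.at(demb, cache["matrix"].reshape(-1), dx.reshape(-1, d))
    demb[PADDING_INDEX] = 0.0                        # padding row stays frozen
    grads["embedding"] = demb.astype(np.float32)
    return grads


# ---------------------------------------------------------------------------
# deepfam forward/backward
# ---------------------------------------------------------------------------

def _forward_deepfam(state, onehot: np.ndarray, training, dropout_rng, need_cache):
    cfg = state.config
    b_sz = onehot.shape[0]
    feats, caches = [], []
    for k in cfg.filter_sizes:
        f = cfg.filters_per_size
        w = state.params[f"conv{k}_w"].reshape(f, -1)
        bias = state.params[f"conv{k}_b"]
        col = _im2col(onehot, k)                     # (B, T, k*21)
        pre = col @ w.T + bias                       # (B, T, F)
        gamma, beta = state.params[f"bn{k}_gamma"], state.params[f"bn{k}_beta"]
        if training:
            mu = pre.mean(axis=(0, 1))
            var = pre.var(axis=(0, 1))
            state.buffers[f"bn{k}_mean"] = (
                (1 - _BN_MOMENTUM) * state.buffers[f"bn{k}_mean"] + _BN_MOMENTUM * mu
            ).astype(np.float32)
            state.buffers[f"bn{k}_var"] = (
                (1 - _BN_MOMENTUM) * state.buffers[f"bn{k}_var"] + _BN_MOMENTUM * var
            ).astype(np.float32)
        else:
            mu = state.buffers[f"bn{k}_mean"]
            var = state.buffers[f"bn{k}_var"]
        invstd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (pre - mu) * invstd
        bn = gamma * xhat + beta
        act = np.maximum(bn, 0.0)
        arg = act.argmax(axis=1)                     # full-row 1-max pooling
        pooled = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
        feats.append(pooled.astype(np.float32))
        if need_cache:
            caches.append({"k": k, "col": col, "xhat": xhat, "invstd": invstd,
                           "bn": bn, "arg": arg})
    feat = np.concatenate(feats, axis=1)
    h_pre = feat @ state.params["hidden_w"] + state.params["hidden_b"]
    h = np.maximum(h_pre, 0.0)
    if training and cfg.dropout_p > 0:
        mask = _dropout_mask(dropout_rng, h.shape, cfg.dropout_p)
        h_d = h * mask
    else:
        mask = None
        h_d = h
    logits = h_d @ state.params["out_w"] + state.params["out_b"]
    cache = None
    if need_cache:
        cache = {"caches": caches, "feat": feat, "h_pre": h_pre, "h_d": h_d, "mask": mask}
    return logits, cache


def _backward_deepfam(state, cache, dlogits):
    cfg = state.config
    f = cfg.filters_per_size
    grads = {}
    grads["out_w"] = (cache["h_d"].T @ dlogits).astype(np.float32)
    grads["out_b"] = dlogits.sum(axis=0).astype(np.float32)
    dh = dlogits @ state.params["out_w"].T
    if cache["mask"] is not None:
        dh = dh * cache["mask"]
    dh_pre = dh * (cache["h_pre"] > 0)
    grads["hidden_w"] = (cache["feat"].T @ dh_pre).astype(np.float32)
    grads["hidden_b"] = dh_pre.sum(axis=0).astype(np.float32)
    dfeat = dh_pre @ state.params["hidden_w"].T
    for i, c in enumerate(cache["caches"]):
        k, col, xhat, invstd, bn, arg = (c["k"], c["col"], c["xhat"],
                                         c["invstd"], c["bn"], c["arg"])
        b_sz, t = col.shape[:2]
        g = dfeat[:, i * f:(i + 1) * f].astype(np.float32)
        rows = np.arange(b_sz)[:, None]
        fcols = np.arange(f)[None, :]
        dact = np.zeros((b_sz, t, f), dtype=np.float32)
        dact[rows, arg, fcols] = g
        dbn = dact * (bn > 0)
        grads[f"bn{k}_gamma"] = (dbn * xhat).sum(axis=(0, 1)).astype(np.float32)
        grads[f"bn{k}_beta"] = dbn.sum(axis=(0, 1)).astype(np.float32)
        dxhat = dbn * state.params[f"bn{k}_gamma"]
        n = b_sz * t
        # standard batch-norm backward over the (batch, position) axes
        dpre = (invstd.astype(np.float32) / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat.astype(np.float32) * (dxhat * xhat).sum(axis=(0, 1), dtype=np.float64).astype(np.float32)
        )
        grads[f"conv{k}_w"] = (
            col.reshape(b_sz * t, -1).T @ dpre.reshape(b_sz * t, f)
        ).T.reshape(f, k, -1).astype(np.float32)
        grads[f"conv{k}_b"] = dpre.sum(axis=(0, 1)).astype(np.float32)
    return grads


# ---------------------------------------------------------------------------
# Public forward / loss
# ---------------------------------------------------------------------------

def forward(
    state: ModelState,
    batch,
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Logits for a batch; ``batch`` is an :class:`EncodedBatch` for the
    deepnog variant or a pseudo one-hot array (B, fixed_length, 21) for the
    baseline. Dropout is active only when ``training`` is set."""
    if training and state.config.dropout_p > 0 and dropout_rng is None:
        raise ValueError("training-mode forward with dropout requires dropout_rng")
    if state.config.variant == "deepnog":
        logits, _ = _forward_deepnog(state, batch, training, dropout_rng, False)
    else:
        logits, _ = _forward_deepfam(state, batch, training, dropout_rng, False)
    return logits


def loss_and_grads(
    state: ModelState,
    batch,
    y: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy of the softmax outputs and gradients for every
    trainable array (one training step's worth of work)."""
    fwd = _forward_deepnog if state.config.variant == "deepnog" else _forward_deepfam
    logits, cache = fwd(state, batch, True, dropout_rng, True)
    probs = predict_proba(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    bwd = _backward_deepnog if state.config.variant == "deepnog" else _backward_deepfam
    return loss, bwd(state, cache, dlogits)


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

_ARCHIVE_FORMAT = "ognet-model-1"


def save_model(
    state: ModelState,
    label_map: GroupLabelMap,
    path: str | Path,
    config: ModelConfig | None = None,
) -> None:
    """Bundle config, label map, alphabet ordering and weights into one file.

    The archive is a zip holding a JSON manifest plus one ``.npy`` entry per
    named array, so it is inspectable with standard tools and roundtrips
    bit-stably.
    """
    config = config or state.config
    if config.n_groups != len(label_map):
        raise ValueError(
            f"config declares {config.n_groups} groups but label map has {len(label_map)}"
        )
    manifest = {
        "format": _ARCHIVE_FORMAT,
        "config": asdict(config),
        "group_ids": list(label_map.group_ids),
        "alphabet": EXTENDED_RESIDUES,
        "params": sorted(state.params),
        "buffers": sorted(state.buffers),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for kind, arrays in (("params", state.params), ("buffers", state.buffers)):
            for name, arr in arrays.items():
                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"{kind}/{name}.npy", buf.getvalue())


def load_model(path: str | Path) -> tuple[ModelState, GroupLabelMap]:
    """Load and validate an archive; shape mismatches name the offender."""
    with zipfile.ZipFile(path, "r") as zf:
        names = set(zf.namelist())
        if "manifest.json" not in names:
            raise ValueError(f"archive {path} is missing its manifest")
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format") != _ARCHIVE_FORMAT:
            raise ValueError(f"archive {path} has unknown format {manifest.get('format')!r}")
        cfg_d = manifest["config"]
        cfg_d["filter_sizes"] = tuple(cfg_d["filter_sizes"])
        config = ModelConfig(**cfg_d)
        group_ids = manifest["group_ids"]
        if len(group_ids) != config.n_groups:
            raise ValueError(
                f"label map size {len(group_ids)} does not match config n_groups {config.n_groups}"
            )
        if manifest.get("alphabet") != EXTENDED_RESIDUES:
            raise ValueError("archive was built against a different alphabet ordering")
        params, buffers = {}, {}
        for kind, store in (("params", params), ("buffers", buffers)):
            for name in manifest[kind]:
                entry = f"{kind}/{name}.npy"
                if entry not in names:
                    raise ValueError(f"archive {path} is missing component {entry}")
                store[name] = np.load(io.BytesIO(zf.read(entry)))
    expected = expected_param_shapes(config)
    missing = set(expected) - set(params)
    if missing:
        raise ValueError(f"archive {path} is missing weight(s) {sorted(missing)}")
    for name, shape in expected.items():
        if params[name].shape != shape:
            raise ValueError(
                f"weight '{name}' has shape {params[name].shape}, expected {shape}"
            )
    label_map = GroupLabelMap(
        group_ids=tuple(group_ids), index_of={g: i for i, g in enumerate(group_ids)}
    )
    return ModelState(config=config, params=params, buffers=buffers), label_map
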
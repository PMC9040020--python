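"""Enhancer classifier: DNA module, auto-encoder, DNase module, joint module.

The DNA module convolves one-hot sequence (4 channels); the DNase module
convolves the auto-encoder embedding of k replicate accessibility tracks
(1 channel).  Both feature stacks follow the same pattern — a wide
motif-scanning layer, length-1 channel-mixing (network-in-network) layers,
length-3 layers, and two max-pooling stages — and expose their pooling
outputs as skip connections into a joint dense classifier ending in a
2-class softmax.

Training is two-stage to cope with the 1:10/1:20 class imbalance: the
whole network is first trained on a class-balanced subset, then the joint
module alone continues on the full imbalanced training set with the DNA
and DNase feature modules frozen.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from cape import nn
from cape.sampling import Sample
from cape.core_io import one_hot_encode

LayerSpec = tuple  # ("conv", n_kernels, kernel_len) | ("pool", pool_size)

DEFAULT_STACK: tuple[LayerSpec, ...] = (
    ("conv", 128, 8),
    ("conv", 64, 1),
    ("conv", 64, 3),
    ("conv", 128, 1),
    ("pool", 2),
    ("conv", 64, 3),
    ("conv", 64, 3),
    ("pool", 2),
)

REDUCED_STACK: tuple[LayerSpec, ...] = (
    ("conv", 16, 8),
    ("conv", 8, 1),
    ("conv", 8, 3),
    ("conv", 16, 1),
    ("pool", 2),
    ("conv", 8, 3),
    ("conv", 8, 3),
    ("pool", 2),
)


@dataclass(frozen=True)
class ConvKernel:
    """Weights of one convolution kernel: an M×N matrix plus a bias."""

    weights: np.ndarray  # (kernel_len M, in_channels N)
    bias: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise ValueError("kernel weights must be a 2-D matrix")
        if not np.isfinite(w).all():
            raise ValueError("non-finite kernel weights")
        object.__setattr__(self, "weights", w)


def conv_activate(x: np.ndarray, kernel: ConvKernel, position: int) -> float:
    """ReLU activation of a kernel at one position of an L×N input matrix.

    Summation uses ``math.fsum`` so the result is exactly rounded and does
    not depend on accumulation order.
    """
    import math

    x = np.asarray(x, dtype=np.float64)
    m = kernel.weights.shape[0]
    if not 0 <= position <= x.shape[0] - m:
        raise ValueError(
            f"position {position} out of range for input length {x.shape[0]} "
            f"and kernel length {m}"
        )
    pre = math.fsum(
        (kernel.weights * x[position:position + m]).ravel()
    ) + kernel.bias
    return max(pre, 0.0)


def softmax_probability(z: Sequence[float]) -> np.ndarray:
    """Softmax over a logit vector (numerically stabilized)."""
    return nn.softmax(np.asarray(z, dtype=np.float64))


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    ``merge_taps='pools'`` feeds the flattened output of every max-pooling
    layer of each enabled feature module into the joint dense stack;
    ``'pools+gmax1'`` additionally taps the first convolutional layer
    through a global per-channel max — a position-invariant readout of the
    motif-scanning kernels that is essential for motif learning on small
    training sets.
    """

    stack: tuple[LayerSpec, ...] = DEFAULT_STACK
    ae_replicates: int = 1
    latent_len: int = 300
    dense_sizes: tuple[int, ...] = (512, 256, 128)
    dropout: float = 0.5
    merge_taps: str = "pools"
    use_dna: bool = True
    use_dnase: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs_stage1: int = 20
    epochs_stage2: int = 10
    val_fraction: float = 0.1
    patience: int = 5
    ae_epochs: int = 15

    @classmethod
    def reduced(cls, **overrides) -> "NetworkConfig":
        """Small configuration for CPU-scale experiments: 16/8 kernels,
        dense sizes (32, 16), light dropout."""
        defaults = dict(stack=REDUCED_STACK, dense_sizes=(32, 16), dropout=0.2)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def motif_scanner(cls, n_kernels: int = 16, latent_len: int = 300,
                      **overrides) -> "NetworkConfig":
        """Sequence-only motif-discovery configuration: one motif-scanning
        convolutional layer read out through a global max over positions.

        The global pooling makes the gradient to each kernel position-
        invariant, which is what lets kernels converge to clean motif
        matrices on small training sets; the deeper positional stacks need
        far more distinct training regions before kernels sharpen.
        """
        defaults = dict(
            stack=(("conv", n_kernels, 8), ("pool", latent_len)),
            dense_sizes=(16,), dropout=0.0, use_dnase=False,
            latent_len=latent_len, batch_size=32, learning_rate=1e-3,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stack"] = [list(s) for s in self.stack]
        d["dense_sizes"] = list(self.dense_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkConfig":
        d = dict(d)
        d["stack"] = tuple(tuple(s) for s in d["stack"])
        d["dense_sizes"] = tuple(d["dense_sizes"])
        return cls(**d)


class _Branch:
    """One feature module: a conv/pool stack with tapped (skip) outputs.

    Taps feed the joint module.  Every max-pooling layer contributes its
    flattened output; with ``gmax_first_conv`` the first convolutional
    layer additionally contributes a global per-channel maximum over
    positions — a position-invariant summary of its motif detectors.
    """

    def __init__(self, stack: Sequence[LayerSpec], in_channels: int,
                 input_len: int, rng: np.random.Generator, name: str,
                 gmax_first_conv: bool = False):
        self.layers: list[nn.Layer] = []
        self.output_shapes: list[tuple[int, int]] = []  # (length, channels) per layer
        self.taps: list[tuple[int, str]] = []  # (layer index, 'flat' | 'gmax')
        length, channels = input_len, in_channels
        for li, spec in enumerate(stack):
            if spec[0] == "conv":
                _, n_kernels, k_len = spec
                self.layers.append(
                    nn.Conv1D(channels, n_kernels, k_len, rng,
                              padding="same", name=f"{name}.conv{li}")
                )
                channels = n_kernels
            elif spec[0] == "pool":
                _, pool = spec
                self.layers.append(nn.MaxPool1D(pool))
                length = length // pool
                self.taps.append((len(self.layers) - 1, "flat"))
            else:
                raise ValueError(f"unknown layer spec {spec!r}")
            self.output_shapes.append((length, channels))
        if gmax_first_conv:
            self.taps.append((0, "gmax"))
        self._relu = [nn.ReLU() if isinstance(l, nn.Conv1D) else None
                      for l in self.layers]
        self.feature_size = 0
        for li, kind in self.taps:
            l, c = self.output_shapes[li]
            self.feature_size += c if kind == "gmax" else l * c

    def params(self) -> list[nn.Parameter]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        outputs = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if self._relu[i] is not None:
                x = self._relu[i].forward(x, train=train)
            outputs.append(x)
        taps = []
        self._gmax_argmax = {}
        for li, kind in self.taps:
            if kind == "flat":
                taps.append(outputs[li])
            else:
                self._gmax_argmax[li] = outputs[li].argmax(axis=1)  # (B, C)
                taps.append(outputs[li].max(axis=1))
        self._out_shapes_cache = [o.shape for o in outputs]
        return taps

    def backward(self, tap_grads: Sequence[np.ndarray]) -> np.ndarray:
        per_layer: dict[int, np.ndarray] = {}
        for (li, kind), grad in zip(self.taps, tap_grads):
            if kind == "gmax":
                full = np.zeros(self._out_shapes_cache[li], dtype=np.float32)
                batch, _, ch = full.shape
                b_idx, c_idx = np.ogrid[:batch, :ch]
                full[b_idx, self._gmax_argmax[li], c_idx] = grad
                grad = full
            per_layer[li] = per_layer.get(li, 0) + grad
        g = None
        for i in reversed(range(len(self.layers))):
            if i in per_layer:
                g = per_layer[i] if g is None else g + per_layer[i]
            if g is None:
                continue
            if self._relu[i] is not None:
                g = self._relu[i].backward(g)
            g = self.layers[i].backward(g)
        return g


class Autoencoder:
    """Replicate-embedding auto-encoder: batch-norm, a position-shared
    linear map k channels -> 1, batch-norm, and a map 1 -> k back.

    The encoder output has length ``latent_len`` and one channel for any
    number of replicates k, which is what makes models transferable across
    cell lines with different replicate counts.
    """

    def __init__(self, k: int, latent_len: int = 300, seed: int = 0):
        if k < 1:
            raise ValueError("need at least one replicate channel")
        rng = np.random.default_rng(seed)
        self.k = k
        self.latent_len = latent_len
        self.bn_in = nn.BatchNorm(k, name="ae.bn_in")
        self.encoder = nn.Conv1D(k, 1, 1, rng, padding="same", name="ae.enc")
        self.bn_mid = nn.BatchNorm(1, name="ae.bn_mid")
        self.decoder = nn.Conv1D(1, k, 1, rng, padding="same", name="ae.dec")
        self._layers = [self.bn_in, self.encoder, self.bn_mid, self.decoder]

    def params(self) -> list[nn.Parameter]:
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self._layers:
            h = layer.forward(h, train=train)
        return h

    def reconstruction_loss(self, x: np.ndarray) -> float:
        loss, _ = nn.mse_loss(self.forward(x, train=False), x)
        return loss

    def fit(self, windows: np.ndarray, epochs: int | None = None,
            batch_size: int = 128, lr: float = 1e-3, seed: int = 0) -> list[float]:
        """Train to minimize mean squared reconstruction error.

        ``windows`` is (n, latent_len, k).  Returns the per-epoch losses.
        """
        windows = np.asarray(windows, dtype=np.float32)
        if windows.ndim != 3 or windows.shape[2] != self.k:
            raise ValueError(f"expected (n, L, {self.k}) windows, got {windows.shape}")
        epochs = 15 if epochs is None else epochs
        rng = np.random.default_rng(seed)
        opt = nn.Adam(self.params(), lr=lr)
        losses = []
        for _ in range(epochs):
            order = rng.permutation(len(windows))
            epoch_loss = 0.0
            for lo in range(0, len(windows), batch_size):
                batch = windows[order[lo:lo + batch_size]]
                out = self.forward(batch, train=True)
                loss, grad = nn.mse_loss(out, batch)
                opt.zero_grad()
                g = grad
                for layer in reversed(self._layers):
                    g = layer.backward(g)
                opt.step()
                epoch_loss += loss * len(batch)
            losses.append(epoch_loss / len(windows))
        return losses

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Embed (n, latent_len, k) accessibility into (n, latent_len, 1)."""
        x = np.asarray(x, dtype=np.float32)
        h = self.bn_in.forward(x, train=False)
        return self.encoder.forward(h, train=False)


class EnhancerNetwork:
    """The joint classifier over sequence and embedded accessibility."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        if not (cfg.use_dna or cfg.use_dnase):
            raise ValueError("at least one feature module must be enabled")
        if cfg.merge_taps not in ("pools", "pools+gmax1"):
            raise ValueError(f"unknown merge_taps {cfg.merge_taps!r}")
        self.cfg = cfg
        self.seed = seed
        gmax = cfg.merge_taps == "pools+gmax1"
        rng = np.random.default_rng(seed)
        self.dna = (
            _Branch(cfg.stack, 4, cfg.latent_len, rng, "dna", gmax_first_conv=gmax)
            if cfg.use_dna else None
        )
        self.dnase = (
            _Branch(cfg.stack, 1, cfg.latent_len, rng, "dnase", gmax_first_conv=gmax)
            if cfg.use_dnase else None
        )
        feat = sum(b.feature_size for b in self._branches())
        self.joint: list[nn.Layer] = []
        in_f = feat
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        for i, size in enumerate(cfg.dense_sizes):
            self.joint.append(nn.Dense(in_f, size, rng, name=f"joint.dense{i}"))
            self.joint.append(nn.ReLU())
            self.joint.append(nn.Dropout(cfg.dropout, self._dropout_rng))
            in_f = size
        self.joint.append(nn.Dense(in_f, 2, rng, name="joint.out"))
        self._tap_shapes_cache = None

    # ---- structure ------------------------------------------------------
    def _branches(self) -> list[_Branch]:
        return [b for b in (self.dna, self.dnase) if b is not None]

    def feature_params(self) -> list[nn.Parameter]:
        out = []
        for b in self._branches():
            out.extend(b.params())
        return out

    def joint_params(self) -> list[nn.Parameter]:
        out = []
        for layer in self.joint:
            out.extend(layer.params())
        return out

    def params(self) -> list[nn.Parameter]:
        return self.feature_params() + self.joint_params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def layer_output_shapes(self, module: str = "dna") -> list[tuple[int, int]]:
        branch = {"dna": self.dna, "dnase": self.dnase}[module]
        if branch is None:
            raise ValueError(f"{module} module is disabled")
        return list(branch.output_shapes)

    def first_layer_kernels(self, module: str = "dna") -> list[ConvKernel]:
        """First-layer kernels as (kernel_len × in_channels) matrices."""
        branch = {"dna": self.dna, "dnase": self.dnase}[module]
        conv = branch.layers[0]
        return [
            ConvKernel(conv.w.value[:, :, j].astype(np.float64),
                       float(conv.b.value[j]))
            for j in range(conv.out_channels)
        ]

    # ---- forward / backward --------------------------------------------
    def forward(self, x_dna: np.ndarray | None, x_enc: np.ndarray | None,
                train: bool = False) -> np.ndarray:
        tap_lists = []
        if self.dna is not None:
            tap_lists.append(self.dna.forward(x_dna, train=train))
        if self.dnase is not None:
            tap_lists.append(self.dnase.forward(x_enc, train=train))
        flats = [t.reshape(t.shape[0], -1) for taps in tap_lists for t in taps]
        self._tap_shapes_cache = [
            [t.shape for t in taps] for taps in tap_lists
        ]
        h = np.concatenate(flats, axis=1)
        for layer in self.joint:
            h = layer.forward(h, train=train)
        return h

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        for layer in reversed(self.joint):
            g = layer.backward(g)
        offset = 0
        for branch, shapes in zip(self._branches(), self._tap_shapes_cache):
            tap_grads = []
            for shape in shapes:
                size = int(np.prod(shape[1:]))
                tap_grads.append(g[:, offset:offset + size].reshape(shape))
                offset += size
            branch.backward(tap_grads)

    def predict_proba(self, x_dna, x_enc, batch_size: int = 256) -> np.ndarray:
        """Probability of the enhancer class for each window."""
        n = len(x_dna) if x_dna is not None else len(x_enc)
        out = np.empty(n, dtype=np.float64)
        for lo in range(0, n, batch_size):
            logits = self.forward(
                None if x_dna is None else x_dna[lo:lo + batch_size],
                None if x_enc is None else x_enc[lo:lo + batch_size],
                train=False,
            )
            out[lo:lo + batch_size] = nn.softmax(logits)[:, 1]
        return out

    # ---- persistence ----------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Save parameters (npz) plus a JSON architecture sidecar."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, **arrays)
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
            else str(path)[:-4] + ".json"
        with open(sidecar, "w") as out:
            json.dump({"config": self.cfg.to_dict(), "seed": self.seed}, out, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "EnhancerNetwork":
        path = str(path)
        npz = path if path.endswith(".npz") else path + ".npz"
        sidecar = npz[:-4] + ".json"
        with open(sidecar) as handle:
            meta = json.load(handle)
        model = cls(NetworkConfig.from_dict(meta["config"]), seed=meta["seed"])
        data = np.load(npz)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        return model


def build_model(cfg: NetworkConfig, seed: int = 0) -> EnhancerNetwork:
    return EnhancerNetwork(cfg, seed=seed)


# ---- dataset container ---------------------------------------------------

@dataclass
class WindowDataset:
    """Stacked arrays for a list of Samples.

    ``x_dna`` is (n, L, 4) one-hot sequence; ``x_acc`` is (n, L, k) raw
    accessibility (channels last), embedded to (n, L, 1) by an
    auto-encoder before entering the network.
    """

    x_dna: np.ndarray
    x_acc: np.ndarray
    y: np.ndarray
    origin: np.ndarray
    fold: np.ndarray

    @classmethod
    def from_samples(cls, samples: Sequence[Sample]) -> "WindowDataset":
        if not samples:
            raise ValueError("empty sample list")
        x_dna = np.stack(
            [one_hot_encode(s.sequence) for s in samples]
        ).astype(np.float32)
        x_acc = np.stack(
            [np.asarray(s.accessibility).T for s in samples]
        ).astype(np.float32)
        return cls(
            x_dna=x_dna,
            x_acc=x_acc,
            y=np.array([s.label for s in samples], dtype=np.int64),
            origin=np.array([s.origin_id for s in samples], dtype=object),
            fold=np.array([s.fold for s in samples], dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            self.x_dna[mask], self.x_acc[mask], self.y[mask],
            self.origin[mask], self.fold[mask],
        )


# ---- training ------------------------------------------------------------

@dataclass
class TrainState:
    """One row of the training log."""

    stage: int
    epoch: int
    loss: float
    val_loss: float
    feature_module_checksum: str


def _run_epoch(model: EnhancerNetwork, x_dna, x_enc, y, opt, batch_size, rng):
    order = rng.permutation(len(y))
    total = 0.0
    for lo in range(0, len(y), batch_size):
        idx = order[lo:lo + batch_size]
        logits = model.forward(
            None if x_dna is None else x_dna[idx],
            None if x_enc is None else x_enc[idx],
            train=True,
        )
        loss, grad = nn.softmax_cross_entropy(logits, y[idx])
        opt.zero_grad()
        model.backward(grad)
        opt.step()
        total += loss * len(idx)
    return total / len(y)


def _val_loss(model: EnhancerNetwork, x_dna, x_enc, y, batch_size=256) -> float:
    total = 0.0
    for lo in range(0, len(y), batch_size):
        logits = model.forward(
            None if x_dna is None else x_dna[lo:lo + batch_size],
            None if x_enc is None else x_enc[lo:lo + batch_size],
            train=False,
        )
        loss, _ = nn.softmax_cross_entropy(logits, y[lo:lo + batch_size])
        total += loss * min(batch_size, len(y) - lo)
    return total / len(y)


def _train_stage(model, x_dna, x_enc, y, stage, epochs, cfg, seed, log,
                 snapshots=None):
    """Train with early stopping on a held-out slice; append TrainState rows."""
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]

    def pick(a, idx):
        return None if a is None else a[idx]

    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    best, best_epoch = np.inf, -1
    best_params = None
    for epoch in range(epochs):
        loss = _run_epoch(
            model, pick(x_dna, train_idx), pick(x_enc, train_idx), y[train_idx],
            opt, cfg.batch_size, rng,
        )
        val = _val_loss(model, pick(x_dna, val_idx), pick(x_enc, val_idx), y[val_idx])
        digest = nn.params_digest(model.feature_params())
        log.append(TrainState(stage, epoch, loss, val, digest))
        if snapshots is not None:
            snapshots.append(digest)
        if val < best - 1e-6:
            best, best_epoch = val, epoch
            best_params = [p.value.copy() for p in model.params()]
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.value[...] = v


def train_two_stage(
    model: EnhancerNetwork,
    dataset: WindowDataset,
    fold_id: int,
    seed: int = 0,
    autoencoder: Autoencoder | None = None,
) -> tuple[EnhancerNetwork, list[TrainState], Autoencoder | None]:
    """Two-stage training on all folds except ``fold_id``.

    Stage 1 trains the whole network on every positive training window plus
    an equal-count random subset of negative windows.  Stage 2 continues on
    the full imbalanced training set with the DNA and DNase feature modules
    frozen (their parameter digest is recorded at every epoch).  The
    auto-encoder is pre-trained on the training windows and frozen as the
    input transform of the DNase module.
    """
    rng = np.random.default_rng(seed)
    train_mask = dataset.fold != fold_id
    train = dataset.subset(train_mask)
    if len(np.unique(train.y)) < 2:
        raise ValueError("training folds contain a single class")

    x_enc = None
    if model.dnase is not None:
        if autoencoder is None:
            autoencoder = Autoencoder(
                train.x_acc.shape[2], model.cfg.latent_len,
                seed=int(rng.integers(2 ** 31)),
            )
            autoencoder.fit(train.x_acc, epochs=model.cfg.ae_epochs,
                            seed=int(rng.integers(2 ** 31)))
        x_enc = autoencoder.encode(train.x_acc)
    x_dna = train.x_dna if model.dna is not None else None

    log: list[TrainState] = []

    # Stage 1: balanced subset, all parameters trainable.
    pos_idx = np.flatnonzero(train.y == 1)
    neg_idx = np.flatnonzero(train.y == 0)
    take = rng.choice(neg_idx, size=min(len(pos_idx), len(neg_idx)), replace=False)
    bal_idx = np.concatenate([pos_idx, take])

    def pick(a, idx):
        return None if a is None else a[idx]

    for p in model.params():
        p.trainable = True
    _train_stage(
        model, pick(x_dna, bal_idx), pick(x_enc, bal_idx), train.y[bal_idx],
        stage=1, epochs=model.cfg.epochs_stage1, cfg=model.cfg,
        seed=int(rng.integers(2 ** 31)), log=log,
    )

    # Stage 2: full imbalanced set, feature modules frozen.
    frozen_digest = nn.params_digest(model.feature_params())
    for p in model.feature_params():
        p.trainable = False
    _train_stage(
        model, x_dna, x_enc, train.y,
        stage=2, epochs=model.cfg.epochs_stage2, cfg=model.cfg,
        seed=int(rng.integers(2 ** 31)), log=log,
    )
    assert nn.params_digest(model.feature_params()) == frozen_digest, \
        "feature modules changed during stage 2"
    return model, log, autoencoder


def write_training_log(log: Sequence[TrainState], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        out.write("stage\tepoch\tloss\tval_loss\tfeature_module_checksum\n")
        for row in log:
            out.write(
                f"{row.stage}\t{row.epoch}\t{row.loss:.6f}\t{row.val_loss:.6f}\t"
                f"{row.feature_module_checksum}\n"
            )


# ---- prediction ----------------------------------------------------------

@dataclass
class PredictionRecord:
    origin_id: str
    window_probs: list[float]
    aggregate: float
    aggregator: str


def aggregate_origin(probs: Sequence[float], aggregator: str = "mean") -> float:
    """Combine per-window probabilities of one origin region."""
    if len(probs) == 0:
        raise ValueError("no window probabilities to aggregate")
    if aggregator == "mean":
        return float(np.mean(probs))
    if aggregator == "max":
        return float(np.max(probs))
    raise ValueError(f"unknown aggregator {aggregator!r}")


def predict_windows(model: EnhancerNetwork, dataset: WindowDataset,
                    autoencoder: Autoencoder | None = None) -> np.ndarray:
    """Per-window enhancer probabilities for every window in the dataset."""
    x_enc = None
    if model.dnase is not None:
        if autoencoder is None:
            raise ValueError("model uses the DNase module; an autoencoder is required")
        x_enc = autoencoder.encode(dataset.x_acc)
    x_dna = dataset.x_dna if model.dna is not None else None
    return model.predict_proba(x_dna, x_enc)


def predict_origins(
    model: EnhancerNetwork,
    dataset: WindowDataset,
    autoencoder: Autoencoder | None = None,
    aggregator: str = "mean",
) -> list[PredictionRecord]:
    """Aggregate window probabilities per origin region (file order of origins)."""
    probs = predict_windows(model, dataset, autoencoder)
    records = []
    seen: dict[str, list[float]] = {}
    order: list[str] = []
    for origin, p in zip(dataset.origin, probs):
        if origin not in seen:
            seen[origin] = []
            order.append(origin)
        seen[origin].append(float(p))
    for origin in order:
        records.append(
            PredictionRecord(
                origin_id=origin,
                window_probs=seen[origin],
                aggregate=aggregate_origin(seen[origin], aggregator),
                aggregator=aggregator,
            )
        )
    return records


def average_predictions(
    per_model: Sequence[Mapping[str, float]]
) -> dict[str, float]:
    """Unweighted mean of per-model origin probabilities (collective scoring)."""
    if len(per_model) == 0:
        raise ValueError("no model predictions to average")
    keys = list(per_model[0].keys())
    for preds in per_model[1:]:
        if set(preds.keys()) != set(keys):
            raise ValueError("models scored different origin sets")
    return {k: float(np.mean([preds[k] for preds in per_model])) for k in keys}


def score_window(
    model: EnhancerNetwork,
    genome,
    tracks: Mapping[str, Sequence],
    chrom: str,
    center: int,
    autoencoder: Autoencoder | None = None,
    target_len: int | None = None,
) -> float:
    """Enhancer probability of the fixed-length window centered at a position.

    This is the generic single-locus application (e.g. scoring the
    neighbourhood of a variant): a ``target_len`` window centered on
    ``center``, clipped to chromosome bounds, is scored by the model.
    """
    from cape.core_io import GenomicInterval, extract_sequence, one_hot_encode
    from cape.accessibility import window_accessibility

    target_len = target_len or model.cfg.latent_len
    chrom_len = genome.chrom_length(chrom)
    if chrom_len < target_len:
        raise ValueError("chromosome shorter than the scoring window")
    start = min(max(center - target_len // 2, 0), chrom_len - target_len)
    iv = GenomicInterval(chrom, start, start + target_len)
    x_dna = None
    if model.dna is not None:
        x_dna = one_hot_encode(extract_sequence(genome, iv).seq)[None].astype(
            np.float32
        )
    x_enc = None
    if model.dnase is not None:
        if autoencoder is None:
            raise ValueError("model uses the DNase module; an autoencoder is required")
        acc = window_accessibility(tracks[chrom], iv).T[None].astype(np.float32)
        x_enc = autoencoder.encode(acc)
    return float(model.predict_proba(x_dna, x_enc)[0])


def cross_validate(
    dataset: WindowDataset,
    cfg: NetworkConfig,
    seed: int = 0,
    folds: Sequence[int] | None = None,
    aggregator: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled origin-level scores and labels over held-out folds.

    For each fold id, a fresh model is trained on the remaining folds with
    the two-stage strategy and the held-out origins are scored; scores are
    pooled across folds.  Returns (scores, labels) aligned per origin.
    """
    fold_ids = sorted(set(dataset.fold)) if folds is None else list(folds)
    labels_by_origin = {o: int(l) for o, l in zip(dataset.origin, dataset.y)}
    scores, labels = [], []
    for i, fold_id in enumerate(fold_ids):
        model = EnhancerNetwork(cfg, seed=seed + 1000 * (i + 1))
        model, _, ae = train_two_stage(model, dataset, fold_id,
                                       seed=seed + 1000 * (i + 1))
        held = dataset.subset(dataset.fold == fold_id)
        for rec in predict_origins(model, held, ae, aggregator):
            scores.append(rec.aggregate)
            labels.append(labels_by_origin[rec.origin_id])
    return np.asarray(scores), np.asarray(labels)


def cross_cell_line_predict(
    models: Sequence[EnhancerNetwork],
    dataset: WindowDataset,
    aggregator: str = "mean",
    ae_seed: int = 0,
    ae_epochs: int | None = None,
) -> list[PredictionRecord]:
    """Score a target cell line with models trained on other cell lines.

    For each source model a fresh auto-encoder is fit unsupervised on the
    target cell line's accessibility windows (whose replicate count k may
    differ from any source), then per-origin probabilities are averaged
    over models without weighting.
    """
    if len(models) == 0:
        raise ValueError("no models given")
    per_model: list[dict[str, float]] = []
    for model in models:
        ae = None
        if model.dnase is not None:
            ae = Autoencoder(dataset.x_acc.shape[2], model.cfg.latent_len,
                             seed=ae_seed)
            ae.fit(dataset.x_acc, epochs=ae_epochs or model.cfg.ae_epochs,
                   seed=ae_seed)
        records = predict_origins(model, dataset, ae, aggregator)
        per_model.append({r.origin_id: r.aggregate for r in records})
    combined = average_predictions(per_model)
    window_map: dict[str, list[float]] = {k: [] for k in combined}
    for preds in per_model:
        for k, v in preds.items():
            window_map[k].append(v)
    return [
        PredictionRecord(origin_id=k, window_probs=window_map[k],
                         aggregate=combined[k], aggregator="mean")
        for k in per_model[0].keys()
    ]
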
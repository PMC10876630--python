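"""The fused multi-input convolutional classifier.

One sub-model per drug-feature modality consumes that modality's pair vector
(the two drugs' similarity rows concatenated, length 2N): a single-filter
1-D convolution (kernel 5, tanh) slides over the vector, the feature map is
flattened, and a 1024-512-256 stack of dense blocks (affine -> batch norm ->
elu -> dropout 0.3) produces a 256-wide representation.  The per-modality
representations are fused — by concatenation into one affine softmax head
over the E event classes by default, or by averaging per-branch softmax
heads — and the whole graph is trained end-to-end with Adam on categorical
cross-entropy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn

logger = logging.getLogger(__name__)


@dataclass
class SubmodelSpec:
    """Architecture of one per-modality branch."""

    input_length: int
    conv_filters: int = 1
    conv_kernel: int = 5
    conv_activation: str = "tanh"
    dense_sizes: tuple[int, ...] = (1024, 512, 256)
    dense_activation: str = "elu"
    dropout: float = 0.3
    batch_norm: bool = True
    use_conv: bool = True  # False = dense-only ablation of the conv front

    def __post_init__(self) -> None:
        self.dense_sizes = tuple(self.dense_sizes)
        if not self.dense_sizes:
            raise ValueError("dense_sizes must be non-empty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.use_conv and self.conv_kernel > self.input_length:
            raise ValueError(
                f"conv kernel {self.conv_kernel} exceeds input length {self.input_length}"
            )

    @property
    def output_width(self) -> int:
        return self.dense_sizes[-1]

    @property
    def flattened_width(self) -> int:
        if not self.use_conv:
            return self.input_length
        return (self.input_length - self.conv_kernel + 1) * self.conv_filters


@dataclass
class ModelConfig:
    """Full fused-model configuration."""

    submodels: dict[str, SubmodelSpec]
    n_events: int
    fusion: str = "concat"  # or "average"
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative learning-rate decay
    seed: int = 0
    early_stopping_patience: int | None = 10
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.submodels:
            raise ValueError("at least one modality sub-model is required")
        if self.fusion not in ("concat", "average"):
            raise ValueError(f"unknown fusion {self.fusion!r}; choose 'concat' or 'average'")
        if self.n_events < 2:
            raise ValueError("n_events must be >= 2")

    @property
    def modalities(self) -> list[str]:
        return list(self.submodels)

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        payload = json.loads(text)
        payload["submodels"] = {
            m: SubmodelSpec(**{**s, "dense_sizes": tuple(s["dense_sizes"])})
            for m, s in payload["submodels"].items()
        }
        return cls(**payload)


def default_config(
    modalities: Sequence[str],
    n_drugs: int,
    n_events: int,
    **overrides,
) -> ModelConfig:
    """Convenience constructor with the canonical architecture defaults."""
    spec_overrides = overrides.pop("submodel_overrides", {})
    submodels = {
        m: SubmodelSpec(input_length=2 * n_drugs, **spec_overrides) for m in modalities
    }
    return ModelConfig(submodels=submodels, n_events=n_events, **overrides)


def _build_branch(spec: SubmodelSpec, rng: np.random.Generator, dropout_rng: np.random.Generator) -> list:
    layers: list = []
    if spec.use_conv:
        layers.append(nn.Conv1D(spec.conv_kernel, spec.conv_filters, rng))
        layers.append(nn.make_activation(spec.conv_activation))
        layers.append(nn.Flatten())
    width = spec.flattened_width
    for size in spec.dense_sizes:
        layers.append(nn.Dense(width, size, rng))
        if spec.batch_norm:
            layers.append(nn.BatchNorm(size))
        layers.append(nn.make_activation(spec.dense_activation))
        if spec.dropout > 0:
            layers.append(nn.Dropout(spec.dropout, dropout_rng))
        width = size
    return layers


class MultimodalConvNet:
    """Fused multi-branch classifier; also the TrainedModel container.

    ``history`` holds per-epoch training loss (and validation loss when an
    early-stopping split is used) after :meth:`fit`.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        seq = np.random.SeedSequence(config.seed)
        init_seed, self._shuffle_seed, dropout_seed = seq.spawn(3)
        init_rng = np.random.default_rng(init_seed)
        dropout_rng = np.random.default_rng(dropout_seed)
        self.branches: dict[str, list] = {
            m: _build_branch(s, init_rng, dropout_rng) for m, s in config.submodels.items()
        }
        self.heads: dict[str, nn.Dense] = {}
        if config.fusion == "concat":
            fused_width = sum(s.output_width for s in config.submodels.values())
            self.heads["__fused__"] = nn.Dense(fused_width, config.n_events, init_rng)
        else:
            for m, s in config.submodels.items():
                self.heads[m] = nn.Dense(s.output_width, config.n_events, init_rng)
        self.history: dict[str, list[float]] = {"loss": []}

    # -- plumbing ----------------------------------------------------------

    @property
    def modalities(self) -> list[str]:
        return self.config.modalities

    def _all_layers(self) -> list:
        layers = [l for branch in self.branches.values() for l in branch]
        layers.extend(self.heads.values())
        return layers

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self._all_layers() for p in l.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self._all_layers() for g in l.grads()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def _buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        return [b for l in self._all_layers() for b in getattr(l, "buffers", list)()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters() + self._buffers()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters() + self._buffers(), weights, strict=True):
            p[...] = w

    # -- forward / backward ------------------------------------------------

    def _check_inputs(self, xs: Sequence[np.ndarray]) -> list[np.ndarray]:
        if len(xs) != len(self.modalities):
            raise ValueError(f"expected {len(self.modalities)} input matrices, got {len(xs)}")
        out = []
        for m, x in zip(self.modalities, xs):
            expected = self.config.submodels[m].input_length
            if x.shape[1] != expected:
                raise ValueError(
                    f"modality {m!r}: expected input length {expected}, got {x.shape[1]}"
                )
            out.append(np.asarray(x, dtype=nn.DTYPE))
        return out

    def _forward(self, xs: Sequence[np.ndarray], training: bool) -> np.ndarray:
        """Return class probabilities, caching activations for backward."""
        reps = []
        for m, x in zip(self.modalities, xs):
            h = x
            for layer in self.branches[m]:
                h = layer.forward(h, training=training)
            reps.append(h)
        if self.config.fusion == "concat":
            self._rep_widths = [r.shape[1] for r in reps]
            fused = np.concatenate(reps, axis=1)
            logits = self.heads["__fused__"].forward(fused, training=training)
            self._proba = nn.softmax(logits.astype(np.float64))
            return self._proba
        self._head_probas = []
        for m, rep in zip(self.modalities, reps):
            logits = self.heads[m].forward(rep, training=training)
            self._head_probas.append(nn.softmax(logits.astype(np.float64)))
        self._proba = np.mean(self._head_probas, axis=0)
        return self._proba

    def _backward(self, y: np.ndarray) -> float:
        """Cross-entropy loss + full backward pass; returns the loss."""
        n = y.shape[0]
        eps = 1e-12
        loss = float(-np.log(self._proba[np.arange(n), y] + eps).mean())
        if self.config.fusion == "concat":
            dlogits = self._proba.copy()
            dlogits[np.arange(n), y] -= 1.0
            dlogits = (dlogits / n).astype(nn.DTYPE)
            dfused = self.heads["__fused__"].backward(dlogits)
            pieces = np.split(dfused, np.cumsum(self._rep_widths)[:-1], axis=1)
        else:
            _, dproba = nn.cross_entropy_from_proba(self._proba, y)
            m = len(self.modalities)
            pieces = []
            for mod, p_head in zip(self.modalities, self._head_probas):
                dp = dproba / m
                dlogits = (p_head * (dp - (dp * p_head).sum(axis=1, keepdims=True))).astype(nn.DTYPE)
                pieces.append(self.heads[mod].backward(dlogits))
        for m, drep in zip(self.modalities, pieces):
            grad = drep
            for layer in reversed(self.branches[m]):
                grad = layer.backward(grad)
        return loss

    # -- training / inference ----------------------------------------------

    def fit(self, xs: Sequence[np.ndarray], y: np.ndarray) -> "MultimodalConvNet":
        """Train with Adam on categorical cross-entropy.

        With ``early_stopping_patience`` set, a stratification-free tail
        split of ``validation_fraction`` monitors validation loss and the
        best weights are restored.
        """
        xs = self._check_inputs(xs)
        y = np.asarray(y, dtype=np.int64)
        cfg = self.config
        rng = np.random.default_rng(self._shuffle_seed)

        val_xs = val_y = None
        if cfg.early_stopping_patience is not None and cfg.validation_fraction > 0:
            n_val = int(round(len(y) * cfg.validation_fraction))
            if n_val >= 1 and len(y) - n_val >= cfg.batch_size // 4:
                perm = rng.permutation(len(y))
                val_idx, train_idx = perm[:n_val], perm[n_val:]
                val_xs = [x[val_idx] for x in xs]
                val_y = y[val_idx]
                xs = [x[train_idx] for x in xs]
                y = y[train_idx]
                self.history["val_loss"] = []

        opt = nn.Adam(self.parameters(), lr=cfg.learning_rate)
        n = len(y)
        best_val = np.inf
        best_weights = None
        stale = 0
        for epoch in range(cfg.epochs):
            opt.lr = cfg.learning_rate * cfg.lr_decay**epoch
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                self._forward([x[idx] for x in xs], training=True)
                loss = self._backward(y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}; "
                        "lower the learning rate or check the inputs"
                    )
                opt.step(self.gradients())
                epoch_loss += loss * len(idx)
            self.history["loss"].append(epoch_loss / n)
            if val_xs is not None:
                val_proba = self.predict_proba(val_xs, _checked=True)
                val_loss = float(
                    -np.log(val_proba[np.arange(len(val_y)), val_y] + 1e-12).mean()
                )
                self.history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = self.get_weights()
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.early_stopping_patience:
                        logger.info("early stopping at epoch %d", epoch)
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self

    def predict_proba(self, xs: Sequence[np.ndarray], batch_size: int = 512, _checked: bool = False) -> np.ndarray:
        """(n, E) class-probability matrix; rows sum to 1."""
        if not _checked:
            xs = self._check_inputs(xs)
        n = xs[0].shape[0]
        if n == 0:
            return np.zeros((0, self.config.n_events))
        out = []
        for start in range(0, n, batch_size):
            out.append(self._forward([x[start : start + batch_size] for x in xs], training=False))
        return np.concatenate(out, axis=0)

    def predict(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        return self.predict_proba(xs).argmax(axis=1)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights to ``<path>`` (npz) plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{f"w{i}": w for i, w in enumerate(self.get_weights())})
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MultimodalConvNet":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".config.json")
        config = ModelConfig.from_json(sidecar.read_text())
        model = cls(config)
        with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
            weights = [data[f"w{i}"] for i in range(len(data.files))]
        model.set_weights(weights)
        return model


def parameter_count(config: ModelConfig) -> int:
    """Closed-form parameter count of the architecture.

    Per branch: conv ``k*f + f``; each dense block ``w_in*w_out + w_out``
    plus ``2*w_out`` batch-norm scale/shift; concat head
    ``(sum of branch widths)*E + E`` (or one head per branch when
    averaging).
    """
    total = 0
    for spec in config.submodels.values():
        if spec.use_conv:
            total += spec.conv_kernel * spec.conv_filters + spec.conv_filters
        width = spec.flattened_width
        for size in spec.dense_sizes:
            total += width * size + size
            if spec.batch_norm:
                total += 2 * size
            width = size
    if config.fusion == "concat":
        fused = sum(s.output_width for s in config.submodels.values())
        total += fused * config.n_events + config.n_events
    else:
        for spec in config.submodels.values():
            total += spec.output_width * config.n_events + config.n_events
    return total
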
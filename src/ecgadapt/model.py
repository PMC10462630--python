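"""The page-image classifier pair and the adaptive gradient-reversal schedule.

Two architectures share one convolutional feature extractor — stacked blocks
of [conv 7x7 (SAME, strided) -> batch norm -> ReLU -> dropout], flattened:

* the *vanilla* net adds a single dense label head (sigmoid output);
* the *adversarial* net adds, in parallel, a domain-classifier head reached
  through a gradient reversal layer.

The reversal coefficient follows the adaptive exponential ramp

    lambda(p) = a * exp(k * p),  p = (b + E * N_B) / (N_Batches * N_Epoch)

with a = 0.85 and k = 5.5 by default: adversarial pressure starts gentle
(label features are subtler than domain features) and grows roughly 245-fold
by the end of training. ``lambda`` scales only the reversed gradient flowing
into the feature extractor, never the domain loss value itself.

The full-scale reference configuration takes 880 x 1650 x 3 pages through
channels [8..512] with strides [1,2,2,2,2,2,2]; ``desk()`` is a
quarter-resolution five-block variant sized for single-CPU experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "NetworkConfig",
    "LambdaSchedule",
    "adaptive_lambda",
    "DannModel",
    "grad_reverse",
]

grad_reverse = nn.grad_reverse


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters for feature extractor and heads."""

    input_h: int = 880
    input_w: int = 1650
    channels: tuple[int, ...] = (8, 16, 32, 64, 128, 256, 512)
    strides: tuple[int, ...] = (1, 2, 2, 2, 2, 2, 2)
    kernel: int = 7
    dropout_p: float = 0.25
    label_head_units: tuple[int, ...] = ()
    domain_head_units: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if not self.channels:
            raise ValueError("need at least one block")
        if any(s < 1 for s in self.strides):
            raise ValueError("strides must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.input_h < 1 or self.input_w < 1:
            raise ValueError("input dimensions must be positive")

    @classmethod
    def full(cls, **kw) -> "NetworkConfig":
        """The full-scale reference architecture."""
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "NetworkConfig":
        """Five-block variant at quarter resolution for CPU-scale runs."""
        defaults = dict(input_h=220, input_w=412,
                        channels=(8, 16, 32, 64, 128),
                        strides=(2, 2, 2, 2, 2))
        defaults.update(kw)
        return cls(**defaults)

    def spatial_dims(self) -> tuple[int, int]:
        """Feature-map (height, width) after all blocks (SAME/ceil rule)."""
        h, w = self.input_h, self.input_w
        for s in self.strides:
            h, w = nn.conv_out_dim(h, s), nn.conv_out_dim(w, s)
        return h, w

    def feature_dim(self) -> int:
        h, w = self.spatial_dims()
        return h * w * self.channels[-1]


@dataclass(frozen=True)
class LambdaSchedule:
    """Parameters of the adaptive gradient-reversal coefficient."""

    n_batches_per_epoch: int
    n_epochs_total: int
    a: float = 0.85
    k: float = 5.5

    def __post_init__(self) -> None:
        if self.n_batches_per_epoch < 1 or self.n_epochs_total < 1:
            raise ValueError("schedule sizes must be >= 1")
        if self.a <= 0 or self.k <= 0:
            raise ValueError("a and k must be positive")


def adaptive_lambda(b: int, E: int, schedule: LambdaSchedule) -> float:
    """Reversal coefficient at batch ``b`` of epoch ``E`` (both 0-based).

    Training progress p = (b + E*N_B) / (N_Batches * N_Epoch) is clipped to
    [0, 1]; returns a * exp(k * p), i.e. 0.85 at the first batch of the
    first epoch under the default coefficients.
    """
    nb, ne = schedule.n_batches_per_epoch, schedule.n_epochs_total
    p = (b + E * nb) / (nb * ne)
    p = min(max(p, 0.0), 1.0)
    return float(schedule.a * np.exp(schedule.k * p))


def _make_head(f_in: int, units: tuple[int, ...],
               rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for u in units:
        layers += [nn.Linear(f_in, u, rng), nn.ReLU()]
        f_in = u
    layers.append(nn.Linear(f_in, 1, rng))
    return nn.Sequential(layers)


class DannModel:
    """Feature extractor + label head (+ domain head via gradient reversal).

    The same object serves both architectures: vanilla training simply never
    touches the domain path. All randomness (weight init, dropout masks) is
    derived from ``config.seed``.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_rng, self.dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))

        blocks: list[nn.Layer] = []
        c_in = 3
        for c_out, stride in zip(config.channels, config.strides):
            blocks += [
                nn.Conv2d(c_in, c_out, config.kernel, stride, init_rng),
                nn.BatchNorm2d(c_out),
                nn.ReLU(),
                nn.Dropout(config.dropout_p, self.dropout_rng),
            ]
            c_in = c_out
        blocks.append(nn.Flatten())
        self.feature = nn.Sequential(blocks)
        f = config.feature_dim()
        self.label_head = _make_head(f, config.label_head_units, init_rng)
        self.domain_head = _make_head(f, config.domain_head_units, init_rng)
        self.grl = nn.GradReverse(1.0)

    # -- forward passes ----------------------------------------------------
    def feature_extractor_forward(self, batch: np.ndarray,
                                  training: bool = False) -> np.ndarray:
        """B x H x W x 3 images -> B x F flattened features."""
        if batch.ndim != 4 or batch.shape[3] != 3:
            raise ValueError("expected a B x H x W x 3 batch")
        if batch.shape[1] != self.config.input_h or batch.shape[2] != self.config.input_w:
            raise ValueError(
                f"input {batch.shape[1]}x{batch.shape[2]} does not match config "
                f"{self.config.input_h}x{self.config.input_w}")
        x = np.ascontiguousarray(batch, dtype=np.float32)
        return self.feature.forward(x, training)

    def label_head_forward(self, features: np.ndarray,
                           training: bool = False) -> np.ndarray:
        """Features -> per-sample probability of the condition."""
        return nn.sigmoid(self.label_head.forward(features, training).ravel())

    def domain_head_forward(self, features: np.ndarray,
                            training: bool = False) -> np.ndarray:
        """Features (through the reversal layer) -> P(domain = captured)."""
        x = self.grl.forward(features)
        return nn.sigmoid(self.domain_head.forward(x, training).ravel())

    def predict_proba(self, batch: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Label probabilities in evaluation mode, computed in minibatches."""
        out = []
        for i in range(0, len(batch), batch_size):
            f = self.feature_extractor_forward(batch[i : i + batch_size], False)
            out.append(self.label_head_forward(f, False))
        return np.concatenate(out)

    def predict_domain_proba(self, batch: np.ndarray,
                             batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(batch), batch_size):
            f = self.feature_extractor_forward(batch[i : i + batch_size], False)
            out.append(self.domain_head_forward(f, False))
        return np.concatenate(out)

    # -- parameter state ---------------------------------------------------
    def _param_arrays(self) -> list[np.ndarray]:
        arrays = list(self.feature.params) + list(self.label_head.params) \
            + list(self.domain_head.params)
        for layer in self.feature.layers:
            if isinstance(layer, nn.BatchNorm2d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self._param_arrays()]

    def load_state(self, state: list[np.ndarray]) -> None:
        arrays = self._param_arrays()
        if len(arrays) != len(state):
            raise ValueError("state does not match architecture")
        for dst, src in zip(arrays, state):
            dst[...] = src

    def save(self, path: str | Path) -> None:
        """Serialize parameters + config to an .npz checkpoint."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = {f"p{i}": p for i, p in enumerate(self._param_arrays())}
        cfg = asdict(self.config)
        np.savez_compressed(path, __config__=json.dumps(cfg), **state)

    @classmethod
    def load(cls, path: str | Path) -> "DannModel":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        for key in ("channels", "strides", "label_head_units", "domain_head_units"):
            cfg[key] = tuple(cfg[key])
        model = cls(NetworkConfig(**cfg))
        model.load_state([data[f"p{i}"] for i in range(len(model._param_arrays()))])
        return model
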
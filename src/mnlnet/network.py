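"""Assembly of the full MNL-Network.

The backbone is a three-stage 1D CNN (conv + batch-norm + ReLU, with 2/2
max-pooling after the first two stages), followed by the signal pooling
layer, the multi-scale non-local layer, flattening, and a three-layer
fully connected head ending in a softmax over the task classes.  For the
canonical 178-sample input the feature-map length trace is
178 -> 89 -> 35 -> 17 -> 4 with 20/40/80 channels, so the flattened
feature vector has 4 x 80 = 320 entries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .mnl_layers import MultiScaleNonLocal, SignalPooling
from .nn.core import Parameter
from .nn.layers import BatchNorm1d, Conv1d, Dense, Flatten, MaxPool1d, ReLU
from .nn.optim import SoftmaxCrossEntropy, softmax

__all__ = ["ConvStage", "ArchitectureSpec", "MNLNetwork", "build_model",
           "relu", "softmax_head", "save_checkpoint", "load_checkpoint"]


def relu(a):
    """Elementwise rectifier max(0, a)."""
    return np.maximum(0, a)


def softmax_head(logits: np.ndarray) -> np.ndarray:
    """Class-probability vector; invariant to a constant shift of the logits."""
    logits = np.asarray(logits, dtype=float)
    if logits.shape[-1] < 2:
        raise ValueError("softmax head needs at least 2 classes")
    return softmax(logits, axis=-1)


@dataclass(frozen=True)
class ConvStage:
    filters: int
    kernel: int
    stride: int
    padding: str        # 'same' | 'valid'
    pool: bool          # 2/2 max-pooling after this stage


def _default_stages() -> tuple[ConvStage, ...]:
    return (
        ConvStage(filters=20, kernel=40, stride=1, padding="same", pool=True),
        ConvStage(filters=40, kernel=20, stride=2, padding="valid", pool=True),
        ConvStage(filters=80, kernel=10, stride=2, padding="valid", pool=False),
    )


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the network; defaults reproduce the published layout."""

    input_length: int = 178
    conv_stages: tuple[ConvStage, ...] = field(default_factory=_default_stages)
    fc_widths: tuple[int, ...] = (64, 32)
    n_classes: int = 2
    c_hat: int | None = None            # embedding channels; None -> c // 2
    pooling_reduce: str = "conv"        # 'conv' | 'none'
    attention_mode: str = "channel"     # 'channel' | 'position'

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_stages"] = [asdict(s) for s in self.conv_stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["conv_stages"] = tuple(ConvStage(**s) for s in d["conv_stages"])
        d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)


class MNLNetwork:
    """The trainable classifier: feature extractor + fully connected head."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers = []
        c = 1
        w = spec.input_length
        for i, st in enumerate(spec.conv_stages):
            conv = Conv1d(c, st.filters, st.kernel, stride=st.stride,
                          padding=st.padding, rng=rng, name=f"conv{i + 1}")
            self.layers += [conv, BatchNorm1d(st.filters, name=f"bn{i + 1}"), ReLU()]
            w = conv.output_length(w)
            c = st.filters
            if st.pool:
                pool = MaxPool1d(2, 2)
                w = pool.output_length(w)
                self.layers.append(pool)
        self.layers.append(SignalPooling(c, reduce=spec.pooling_reduce, rng=rng))
        c = self.layers[-1].out_channels
        self.layers.append(MultiScaleNonLocal(
            c, c_hat=spec.c_hat, mode=spec.attention_mode, rng=rng))
        self.layers.append(Flatten())
        n_feat = w * c
        widths = list(spec.fc_widths) + [spec.n_classes]
        for j, width in enumerate(widths):
            self.layers.append(Dense(n_feat, width, rng=rng, name=f"fc{j + 1}"))
            if j < len(widths) - 1:
                self.layers.append(ReLU())
            n_feat = width
        self.loss_head = SoftmaxCrossEntropy()

    # -- introspection ----------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def shape_trace(self) -> list[tuple[str, tuple[int, int]]]:
        """Per-layer feature-map (length, channels) for one forward pass,
        mirroring the published output-size column."""
        trace = []
        w, c = self.spec.input_length, 1
        for layer in self.layers:
            if isinstance(layer, Conv1d):
                w = layer.output_length(w)
                c = layer.out_channels
                name = f"conv(k={layer.kernel})"
            elif isinstance(layer, MaxPool1d):
                w = layer.output_length(w)
                name = "maxpool(2,2)"
            elif isinstance(layer, BatchNorm1d):
                name = "batchnorm"
            elif isinstance(layer, SignalPooling):
                w = layer.output_length(w)
                c = layer.out_channels
                name = "signal_pooling"
            elif isinstance(layer, MultiScaleNonLocal):
                name = "multi_scale_nonlocal"
            elif isinstance(layer, Flatten):
                name = "flatten"
                trace.append((name, (w * c, 1)))
                continue
            elif isinstance(layer, Dense):
                w, c = layer.weight.value.shape[1], 1
                name = "fc"
            else:
                name = "relu"
            trace.append((name, (w, c)))
        return trace

    # -- forward / training -----------------------------------------------
    def _check_input(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=float)
        if batch.ndim == 2:
            batch = batch[:, :, None]
        if batch.shape[1] != self.spec.input_length:
            raise ValueError(f"segment length {batch.shape[1]} != expected "
                             f"{self.spec.input_length}")
        return batch

    def forward_logits(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(batch)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Inference: class-probability matrix, one row per segment."""
        return softmax_head(self.forward_logits(batch, train=False))

    predict_proba = forward

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(batch).argmax(axis=1)

    def train_step_loss(self, batch: np.ndarray, labels: np.ndarray) -> float:
        """Forward in training mode and backpropagate; gradients accumulate
        into the parameters (caller owns optimizer zero_grad/step)."""
        logits = self.forward_logits(batch, train=True)
        loss = self.loss_head.forward(logits, labels)
        dlogits = self.loss_head.backward()
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return loss

    # -- state ------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers().items():
                state[f"buffer.{i}.{k}"] = v.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers().items():
                v[...] = state[f"buffer.{i}.{k}"]


def build_model(spec: ArchitectureSpec, seed: int = 0) -> MNLNetwork:
    """Build the network and verify its shape trace is consistent."""
    model = MNLNetwork(spec, seed=seed)
    trace = model.shape_trace()
    flat = [shape[0] for name, shape in trace if name == "flatten"]
    if not flat or flat[0] < 1:
        raise ValueError("architecture spec yields an empty feature vector")
    return model


def save_checkpoint(model: MNLNetwork, path, extra: dict | None = None) -> None:
    """Single-file checkpoint with the architecture spec embedded."""
    meta = {"spec": model.spec.to_dict(), "extra": extra or {}}
    arrays = {f"state/{k}": v for k, v in model.get_state().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[MNLNetwork, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
    spec = ArchitectureSpec.from_dict(meta["spec"])
    model = MNLNetwork(spec, seed=0)
    model.set_state(state)
    return model, meta.get("extra", {})
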
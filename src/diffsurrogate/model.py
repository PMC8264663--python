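"""The dual-branch surrogate: size-preserving CNN plus convolutional autoencoder.

The surrogate maps a source-layout image |x> to a predicted stationary field
|y^> = p1 * NN1(x) + p2 * NN2(x), where p1, p2 are fixed mixing weights
(Boolean in all reference presets).

* **NN 1** is a deep convolutional network that preserves the spatial size
  through six 3x3 convolutions with channel sequence 1-4-8-16-8-4-1,
  leaky-ReLU activations on the first five layers and ReLU on the last.
  It resolves the sources but not the long-range field.
* **NN 2** is an autoencoder: the encoder alternates size-preserving 3x3
  convolutions with 2x2 mean-pooling (floor mode), halving the spatial size
  while doubling the channels, and collapses the final small map to a 1x1
  bottleneck with an unpadded convolution; the decoder mirrors it with
  transposed convolutions back to the full grid. Squeezing the field through
  the bottleneck forces the network to learn the global structure.

For the reference 100x100 grid the encoder traces spatial sizes
100-50-25-12-6-3-1 with channels 1-64-128-256-512-1024-2048 and the decoder
traces 1-3-7-13-25-51-100 with channels 2048-1024-512-256-128-64-1. Both
branches end in a ReLU, so predictions are non-negative (values above 1 are
possible for an untrained model; no upper clamp is applied).

Grids other than 100x100 use the same construction with the halving schedule
shortened to the grid and the channel widths scaled by ``nn2_base_channels``;
the collapse-to-1x1 bottleneck property is preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn

__all__ = [
    "SurrogateSpec",
    "SurrogateModel",
    "build_nn1",
    "build_nn2",
    "encoder_schedule",
    "decoder_schedule",
    "PRESETS",
]


def encoder_schedule(grid_size: int) -> tuple[list[int], int]:
    """Spatial sizes traversed by the encoder's mean-pool stages.

    Halve (floor) until the map is at most 3 pixels wide; the returned final
    kernel is the unpadded convolution that collapses it to 1x1.
    """
    sizes = [grid_size]
    while sizes[-1] > 3:
        sizes.append(sizes[-1] // 2)
    return sizes, sizes[-1]


# Transposed-convolution (kernel, stride, padding) per decoder step for the
# reference 100-pixel grid, realizing the size trace 1-3-7-13-25-51-100.
_DECODER_100 = [(3, 1, 0), (3, 2, 0), (3, 2, 1), (3, 2, 1), (3, 2, 0), (4, 2, 2)]


def decoder_schedule(grid_size: int) -> tuple[list[int], list[tuple[int, int, int]]]:
    """Decoder spatial sizes and the (kernel, stride, padding) realizing them."""
    if grid_size == 100:
        sizes = [1]
        for k, s, p in _DECODER_100:
            sizes.append((sizes[-1] - 1) * s - 2 * p + k)
        return sizes, list(_DECODER_100)
    enc_sizes, _ = encoder_schedule(grid_size)
    targets = list(reversed(enc_sizes))  # e.g. 32 -> [2, 4, 8, 16, 32]
    sizes = [1]
    steps: list[tuple[int, int, int]] = []
    for tgt in targets:
        cur = sizes[-1]
        if cur == 1:
            steps.append((tgt, 1, 0))  # valid transposed conv: out = kernel
        else:
            r = tgt - 2 * (cur - 1)  # kernel - 2*padding at stride 2
            if r == 2:
                steps.append((4, 2, 1))
            elif r == 3:
                steps.append((3, 2, 0))
            else:
                raise ValueError(f"no stride-2 step from {cur} to {tgt}")
        sizes.append(tgt)
    return sizes, steps


def _nn2_channels(grid_size: int, base: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    enc_sizes, _ = encoder_schedule(grid_size)
    n_pool = len(enc_sizes) - 1
    enc = tuple(base * 2**i for i in range(n_pool)) + (base * 2**n_pool,)
    dec = tuple(reversed(enc[:-1])) + (1,)
    return enc, dec


@dataclass(frozen=True)
class SurrogateSpec:
    """Architecture description for one surrogate model.

    ``dropout`` holds (D1, D2) for the plain CNN branch and (D3, D4) for the
    autoencoder branch. ``p1``/``p2`` are the fixed mixing weights; a branch
    with weight 0 is not built. The reference preset is grid_size=100 with
    nn2_base_channels=64, which yields the 2048-channel 1x1 bottleneck.
    """

    grid_size: int = 100
    p1: float = 1.0
    p2: float = 1.0
    dropout: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    nn1_channels: tuple[int, ...] = (4, 8, 16, 8, 4, 1)
    nn2_base_channels: int = 64
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "dropout", tuple(float(d) for d in self.dropout))
        object.__setattr__(self, "nn1_channels", tuple(self.nn1_channels))
        if len(self.dropout) != 4 or any(not (0 <= d < 1) for d in self.dropout):
            raise ValueError("dropout must be four rates in [0, 1)")
        if self.nn1_channels[-1] != 1:
            raise ValueError("NN1 must end in a single output channel")
        if self.p1 == 0 and self.p2 == 0:
            raise ValueError("at least one branch must have a nonzero weight")
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")

    @property
    def nn2_encoder_channels(self) -> tuple[int, ...]:
        return _nn2_channels(self.grid_size, self.nn2_base_channels)[0]

    @property
    def nn2_decoder_channels(self) -> tuple[int, ...]:
        return _nn2_channels(self.grid_size, self.nn2_base_channels)[1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dropout"] = list(self.dropout)
        d["nn1_channels"] = list(self.nn1_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateSpec":
        return cls(**d)


def build_nn1(spec: SurrogateSpec, rng: np.random.Generator) -> nn.Sequential:
    """Size-preserving deep CNN branch (resolves the sources).

    Six 3x3 stride-1 padded convolutions; per-layer order is
    conv -> activation -> [dropout] -> batch norm, except the final layer,
    whose batch norm precedes the ReLU so that the branch output stays
    non-negative. Dropout D1 follows layer 1, dropout D2 the final layer.
    """
    d1, d2 = spec.dropout[0], spec.dropout[1]
    chans = (1,) + spec.nn1_channels
    layers: list[nn.Layer] = []
    n_conv = len(spec.nn1_channels)
    for i in range(n_conv):
        conv = nn.Conv2d(chans[i], chans[i + 1], 3, stride=1, padding=1, rng=rng)
        last = i == n_conv - 1
        if last:
            layers += [conv, nn.Dropout(d2), nn.BatchNorm2d(chans[i + 1]), nn.ReLU()]
        else:
            layers.append(conv)
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            if i == 0:
                layers.append(nn.Dropout(d1))
            layers.append(nn.BatchNorm2d(chans[i + 1]))
    return nn.Sequential(layers)


def build_nn2(spec: SurrogateSpec, rng: np.random.Generator) -> nn.Sequential:
    """Convolutional autoencoder branch (resolves the field).

    Encoder: [3x3 padded conv -> leaky ReLU -> 2x2 mean-pool] stages, batch
    norm and dropout D3 after the first convolution, then an unpadded
    convolution collapsing the last small map to a 1x1 bottleneck. Decoder:
    transposed convolutions back to the grid size, dropout D4 before the
    final one, whose batch norm precedes the final ReLU.
    """
    d3, d4 = spec.dropout[2], spec.dropout[3]
    enc_sizes, bottleneck_kernel = encoder_schedule(spec.grid_size)
    enc_ch = spec.nn2_encoder_channels
    dec_sizes, dec_steps = decoder_schedule(spec.grid_size)
    dec_ch = spec.nn2_decoder_channels
    if dec_sizes[-1] != spec.grid_size:
        raise ValueError(
            f"decoder schedule ends at {dec_sizes[-1]}, expected {spec.grid_size}"
        )

    layers: list[nn.Layer] = []
    in_ch = 1
    for i, out_ch in enumerate(enc_ch[:-1]):
        layers.append(nn.Conv2d(in_ch, out_ch, 3, stride=1, padding=1, rng=rng))
        layers.append(nn.LeakyReLU(spec.leaky_slope))
        if i == 0:
            layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.Dropout(d3))
        layers.append(nn.MeanPool2d(2))
        in_ch = out_ch
    # collapse to the 1x1 bottleneck with a valid (unpadded) convolution
    layers.append(nn.Conv2d(in_ch, enc_ch[-1], bottleneck_kernel, rng=rng))
    layers.append(nn.LeakyReLU(spec.leaky_slope))

    in_ch = enc_ch[-1]
    for i, (out_ch, (k, s, p)) in enumerate(zip(dec_ch, dec_steps)):
        last = i == len(dec_ch) - 1
        if last:
            layers.append(nn.Dropout(d4))
        layers.append(nn.ConvTranspose2d(in_ch, out_ch, k, stride=s, padding=p, rng=rng))
        if last:
            layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.ReLU())
        else:
            layers.append(nn.LeakyReLU(spec.leaky_slope))
        in_ch = out_ch
    return nn.Sequential(layers)


class SurrogateModel:
    """Weighted combination of the two branches: p1 * NN1(x) + p2 * NN2(x).

    Branches with zero mixing weight are not constructed. Inference mode
    (``training=False``) freezes batch-norm statistics and disables dropout,
    so predictions are deterministic for fixed parameters.
    """

    def __init__(self, spec: SurrogateSpec, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.spec = spec
        self.nn1 = build_nn1(spec, rng) if spec.p1 != 0 else None
        self.nn2 = build_nn2(spec, rng) if spec.p2 != 0 else None

    def _branches(self) -> list[tuple[float, nn.Sequential]]:
        out = []
        if self.nn1 is not None:
            out.append((self.spec.p1, self.nn1))
        if self.nn2 is not None:
            out.append((self.spec.p2, self.nn2))
        return out

    def parameters(self) -> list[nn.Parameter]:
        return [p for _, net in self._branches() for p in net.parameters()]

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Batched forward pass on (B, 1, L, L) input."""
        total = None
        for p, net in self._branches():
            y = p * net.forward(x, training=training, rng=rng)
            total = y if total is None else total + y
        return total

    def backward(self, grad: np.ndarray) -> None:
        for p, net in self._branches():
            net.backward(p * grad)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference on (L, L), (B, L, L) or (B, 1, L, L) input."""
        L = self.spec.grid_size
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        chan = x.ndim == 3
        if chan:
            x = x[:, None]
        if x.shape[-2:] != (L, L):
            raise ValueError(f"input spatial shape {x.shape[-2:]} != ({L}, {L})")
        y = self.forward(np.asarray(x, dtype=np.float64), training=False)
        if chan:
            y = y[:, 0]
        if squeeze:
            y = y[0]
        return y

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, net in (("nn1", self.nn1), ("nn2", self.nn2)):
            if net is not None:
                for k, v in net.state_dict().items():
                    state[f"{name}/{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("checkpoint does not match this architecture")
        for k, arr in own.items():
            if np.shape(state[k]) != arr.shape:
                raise ValueError(
                    f"checkpoint entry {k!r} has shape {np.shape(state[k])}, "
                    f"expected {arr.shape}: does not match this architecture"
                )
            arr[...] = state[k]

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        """Write parameters to ``<path>`` (npz) and a YAML sidecar of the spec."""
        path = Path(path)
        np.savez(path, **{k.replace("/", "__"): v for k, v in self.state_dict().items()})
        sidecar = {"spec": self.spec.to_dict(), "provenance": provenance or {}}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        path = Path(path)
        if not path.suffix:
            path = path.with_suffix(".npz")
        sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
        model = cls(SurrogateSpec.from_dict(sidecar["spec"]), rng=0)
        with np.load(path) as data:
            model.load_state_dict(
                {k.replace("__", "/"): data[k] for k in data.files}
            )
        return model


#: Reference hyperparameter rows: loss kind, exponential weight w, mixing
#: weights p1/p2 and dropout rates (D1, D2, D3, D4) for models 1-14.
PRESETS: dict[str, dict] = {
    "model1": dict(w=1000.0, p1=1, p2=1, dropout=(0.3, 0.3, 0.3, 0.3), loss="mse"),
    "model2": dict(w=1.0, p1=1, p2=1, dropout=(0.3, 0.3, 0.3, 0.3), loss="mse"),
    "model3": dict(w=1.0, p1=1, p2=1, dropout=(0.4, 0.4, 0.1, 0.1), loss="mse"),
    "model4": dict(w=1.0, p1=0, p2=1, dropout=(0.0, 0.0, 0.3, 0.3), loss="mse"),
    "model5": dict(w=1.0, p1=0, p2=1, dropout=(0.0, 0.0, 0.1, 0.1), loss="mse"),
    "model6": dict(w=1.0, p1=1, p2=0, dropout=(0.3, 0.3, 0.0, 0.0), loss="mse"),
    "model7": dict(w=1.0, p1=1, p2=0, dropout=(0.4, 0.4, 0.0, 0.0), loss="mse"),
    "model8": dict(w=100.0, p1=1, p2=1, dropout=(0.3, 0.3, 0.3, 0.3), loss="mae"),
    "model9": dict(w=100.0, p1=1, p2=1, dropout=(0.4, 0.4, 0.1, 0.1), loss="mae"),
    "model10": dict(w=1.0, p1=1, p2=1, dropout=(0.3, 0.3, 0.3, 0.3), loss="mae"),
    "model11": dict(w=1.0, p1=1, p2=1, dropout=(0.4, 0.4, 0.1, 0.1), loss="mae"),
    "model12": dict(w=1.0, p1=0, p2=1, dropout=(0.0, 0.0, 0.1, 0.1), loss="mae"),
    "model13": dict(w=10.0, p1=0, p2=1, dropout=(0.0, 0.0, 0.3, 0.3), loss="mae"),
    "model14": dict(w=10.0, p1=0, p2=1, dropout=(0.0, 0.0, 0.1, 0.1), loss="mae"),
}
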
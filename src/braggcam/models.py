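"""Size-parameterized CNN classifiers for diffraction frames.

Two architectures are provided:

* ``alexnet_style`` -- five convolution blocks (some max-pooled) followed by
  three fully connected layers, all ReLU-activated; the classic eight-layer
  layout scaled down by default to desk size (64x64 input, reduced filter
  counts).  The classic full-size filter plan is available as the ``full``
  preset.  The desk preset omits dropout and local-response normalization so
  that every forward/backward pass is a deterministic function of the weights.
* ``resnet_style`` -- a stem convolution, a configurable number of residual
  stages (each a stack of 3x3 residual blocks, downsampling at stage entry),
  global average pooling and a linear head.  The deep 101-layer-class preset
  exists as a configuration; tests and the desk study use a small 2-stage
  variant, and explanations default to the last residual stage.

Frames are single-channel; grayscale input is replicated to ``in_channels``
here, and every frame is standardized per-image ((x - mean) / (std + 1e-8))
so the absolute intensity scale of the generator is irrelevant to the
classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import yaml

from .frames import DetectorFrame
from .nn import (
    Conv2D,
    Dense,
    Flatten,
    GlobalAvgPool,
    MaxPool2D,
    Network,
    ReLU,
    ResidualBlock,
    ResidualStage,
)

__all__ = [
    "ConvBlockSpec",
    "NetworkSpec",
    "CNNModel",
    "build_model",
    "desk_alexnet_spec",
    "fullscale_alexnet_spec",
    "desk_resnet_spec",
    "save_checkpoint",
    "load_checkpoint",
]

FrameLike = Union[DetectorFrame, np.ndarray]


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolution block: conv -> ReLU -> (optional max-pool)."""

    filters: int
    kernel: int
    stride: int = 1
    pool: Optional[int] = None


@dataclass(frozen=True)
class NetworkSpec:
    input_size: int = 64
    in_channels: int = 1
    n_classes: int = 5
    arch: str = "alexnet_style"
    conv_blocks: Tuple[ConvBlockSpec, ...] = (
        ConvBlockSpec(16, 5, 2, 2),
        ConvBlockSpec(32, 3, 1, 2),
        ConvBlockSpec(48, 3, 1, None),
        ConvBlockSpec(48, 3, 1, None),
        ConvBlockSpec(32, 3, 1, 2),
    )
    #: Hidden fully connected widths; the output layer of width ``n_classes``
    #: is appended automatically (so ``alexnet_style`` has 3 FC layers total).
    fc_hidden: Tuple[int, ...] = (128, 64)
    #: resnet_style only: residual blocks per stage.
    residual_depth: Tuple[int, ...] = (2, 2)
    #: resnet_style only: channels of the first stage; doubled per stage.
    stem_channels: int = 16

    def __post_init__(self) -> None:
        if self.arch not in ("alexnet_style", "resnet_style"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.arch == "alexnet_style":
            if len(self.conv_blocks) != 5:
                raise ValueError("alexnet_style requires exactly 5 conv blocks")
            if len(self.fc_hidden) != 2:
                raise ValueError("alexnet_style requires exactly 3 FC layers "
                                 "(2 hidden + the class layer)")
        self._check_spatial()

    def _check_spatial(self) -> None:
        h = w = self.input_size
        if self.arch == "alexnet_style":
            for blk in self.conv_blocks:
                h = (h + 2 * (blk.kernel // 2) - blk.kernel) // blk.stride + 1
                w = (w + 2 * (blk.kernel // 2) - blk.kernel) // blk.stride + 1
                if blk.pool:
                    if h % blk.pool or w % blk.pool:
                        raise ValueError(
                            f"pool {blk.pool} does not divide spatial size ({h},{w})"
                        )
                    h //= blk.pool
                    w //= blk.pool
                if h < 1 or w < 1:
                    raise ValueError("spec reduces spatial size below 1")
        else:
            for si in range(len(self.residual_depth)):
                if si > 0:
                    h = (h + 1) // 2
                    w = (w + 1) // 2
                if h < 1 or w < 1:
                    raise ValueError("spec reduces spatial size below 1")

    @property
    def layer_names(self) -> Tuple[str, ...]:
        if self.arch == "alexnet_style":
            convs = tuple(f"conv{i + 1}" for i in range(len(self.conv_blocks)))
            fcs = tuple(f"fc{i + 1}" for i in range(len(self.fc_hidden) + 1))
            return convs + fcs
        stages = tuple(f"stage{i + 1}" for i in range(len(self.residual_depth)))
        return ("stem",) + stages + ("head",)

    @property
    def last_conv_layer(self) -> str:
        """Default explanation layer: last conv layer / last residual stage."""
        if self.arch == "alexnet_style":
            return f"conv{len(self.conv_blocks)}"
        return f"stage{len(self.residual_depth)}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_blocks"] = [list(dataclasses.astuple(b)) for b in self.conv_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["conv_blocks"] = tuple(ConvBlockSpec(*b) for b in d.get("conv_blocks", []))
        for key in ("fc_hidden", "residual_depth"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def desk_alexnet_spec(n_classes: int = 5, input_size: int = 64) -> NetworkSpec:
    return NetworkSpec(input_size=input_size, n_classes=n_classes)


def fullscale_alexnet_spec(n_classes: int = 5, input_size: int = 512) -> NetworkSpec:
    """Full-size filter plan of the classic eight-layer network (a config
    choice; desk tests never train it)."""
    return NetworkSpec(
        input_size=input_size,
        in_channels=3,
        n_classes=n_classes,
        conv_blocks=(
            ConvBlockSpec(96, 11, 4, 2),
            ConvBlockSpec(256, 5, 1, 2),
            ConvBlockSpec(384, 3, 1, None),
            ConvBlockSpec(384, 3, 1, None),
            ConvBlockSpec(256, 3, 1, 2),
        ),
        fc_hidden=(4096, 4096),
    )


def desk_resnet_spec(n_classes: int = 5, input_size: int = 64,
                     residual_depth: Tuple[int, ...] = (2, 2)) -> NetworkSpec:
    return NetworkSpec(
        input_size=input_size, n_classes=n_classes, arch="resnet_style",
        residual_depth=residual_depth,
    )


class CNNModel:
    """A (possibly trained) CNN: spec + weights + uniform activation access."""

    def __init__(self, spec: NetworkSpec, net: Network) -> None:
        self.spec = spec
        self.net = net

    @property
    def dtype(self) -> np.dtype:
        for layer, name in self.net.param_items():
            return layer.params[name].dtype
        return np.dtype(np.float64)

    # ------------------------------------------------------------ preprocessing
    def preprocess(self, frames: Union[FrameLike, Sequence[FrameLike]]) -> np.ndarray:
        """Frames -> standardized (N, C, H, W) batch on the spec's input size."""
        from skimage.transform import resize

        if isinstance(frames, (DetectorFrame, np.ndarray)):
            frames = [frames]
        size = self.spec.input_size
        batch = np.empty((len(frames), self.spec.in_channels, size, size), dtype=self.dtype)
        for n, f in enumerate(frames):
            x = np.asarray(f.pixels if isinstance(f, DetectorFrame) else f, dtype=float)
            if x.ndim != 2:
                raise ValueError("each frame must be a 2-D intensity array")
            if x.shape != (size, size):
                x = resize(x, (size, size), order=1, mode="edge",
                           anti_aliasing=x.shape[0] > size, preserve_range=True)
            x = (x - x.mean()) / (x.std() + 1e-8)
            batch[n] = x[None, :, :]  # replicate grayscale across channels
        return batch

    # ----------------------------------------------------------------- forward
    def forward(self, frames: Union[FrameLike, Sequence[FrameLike]]) -> np.ndarray:
        """Raw class scores (logits, pre-softmax); (n_classes,) for one frame."""
        single = isinstance(frames, (DetectorFrame, np.ndarray))
        x = self.preprocess(frames)
        logits, _, _ = self.net.forward(x)
        return logits[0] if single else logits

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """Logits from an already-preprocessed (N, C, H, W) batch."""
        logits, _, _ = self.net.forward(x)
        return logits

    def activations(self, frame: FrameLike, layer_name: str) -> np.ndarray:
        """Post-ReLU feature maps A^k of the named layer, (K, h, w) or (K,)."""
        acts = self.net.activations(self.preprocess(frame), layer_name)
        return acts[0]

    @property
    def layer_names(self) -> Tuple[str, ...]:
        return self.spec.layer_names

    def parameter_count(self) -> int:
        return self.net.parameter_count()


def _build_alexnet(spec: NetworkSpec, rng: np.random.Generator) -> Network:
    layers: List = []
    taps = {}
    ch = spec.in_channels
    h = w = spec.input_size
    for i, blk in enumerate(spec.conv_blocks):
        conv = Conv2D(ch, blk.filters, blk.kernel, stride=blk.stride, rng=rng)
        layers.append(conv)
        h, w = conv.out_spatial(h, w)
        layers.append(ReLU())
        taps[f"conv{i + 1}"] = len(layers) - 1
        if blk.pool:
            pool = MaxPool2D(blk.pool)
            h, w = pool.out_spatial(h, w)
            layers.append(pool)
        ch = blk.filters
    layers.append(Flatten())
    features = ch * h * w
    for j, width in enumerate(spec.fc_hidden):
        layers.append(Dense(features, width, rng=rng))
        layers.append(ReLU())
        taps[f"fc{j + 1}"] = len(layers) - 1
        features = width
    layers.append(Dense(features, spec.n_classes, rng=rng))
    taps[f"fc{len(spec.fc_hidden) + 1}"] = len(layers) - 1
    return Network(layers, taps)


def _build_resnet(spec: NetworkSpec, rng: np.random.Generator) -> Network:
    layers: List = []
    taps = {}
    stem = Conv2D(spec.in_channels, spec.stem_channels, 3, rng=rng)
    layers.extend([stem, ReLU()])
    taps["stem"] = 1
    ch = spec.stem_channels
    for si, depth in enumerate(spec.residual_depth):
        out_ch = spec.stem_channels * (2**si)
        blocks = []
        for bi in range(depth):
            stride = 2 if (si > 0 and bi == 0) else 1
            blocks.append(ResidualBlock(ch, out_ch, stride=stride, rng=rng))
            ch = out_ch
        layers.append(ResidualStage(blocks))
        taps[f"stage{si + 1}"] = len(layers) - 1
    layers.append(GlobalAvgPool())
    layers.append(Dense(ch, spec.n_classes, rng=rng))
    taps["head"] = len(layers) - 1
    return Network(layers, taps)


def build_model(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> CNNModel:
    """Deterministically initialize a model from its spec and a seed.

    Weights are kept in ``dtype`` (single precision by default -- ample for
    classification and twice as fast on CPU BLAS; pass ``np.float64`` when
    bitwise-tight numerics matter).
    """
    rng = np.random.default_rng(seed)
    if spec.arch == "alexnet_style":
        net = _build_alexnet(spec, rng)
    else:
        net = _build_resnet(spec, rng)
    for layer, name in net.param_items():
        layer.params[name] = layer.params[name].astype(dtype)
    return CNNModel(spec, net)


# -------------------------------------------------------------- checkpointing
def save_checkpoint(model: CNNModel, path) -> None:
    """Write spec + weights to HDF5, with a YAML spec dump alongside."""
    spec_yaml = yaml.safe_dump(model.spec.to_dict())
    with h5py.File(path, "w") as f:
        f.attrs["spec_yaml"] = spec_yaml
        grp = f.create_group("params")
        for i, arr in enumerate(model.net.state_arrays()):
            grp.create_dataset(f"{i:04d}", data=arr)
    with open(str(path) + ".yaml", "w") as fh:
        fh.write(spec_yaml)


def load_checkpoint(path) -> CNNModel:
    with h5py.File(path, "r") as f:
        spec = NetworkSpec.from_dict(yaml.safe_load(f.attrs["spec_yaml"]))
        arrays = [f["params"][k][()] for k in sorted(f["params"])]
    model = build_model(spec, seed=0)
    model.net.set_state_arrays(arrays)
    return model
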
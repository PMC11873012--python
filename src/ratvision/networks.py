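"""Network architectures, parameter accounting and activation extraction.

Two reference architectures are provided:

* a 16-weight-layer convolutional network (13 conv stages in five blocks
  separated by 2x2 max pooling, then 3 fully connected stages, 1000-way
  output) -- the classic VGG-16 layout;
* a depth- and parameter-matched multi-layer perceptron: 16 affine stages
  with ReLU between them, dimensioned so the total parameter count matches
  the convolutional reference (~138 million) on a 224x224 single-channel
  input.

Networks are untrained by default, with the standard fan-in uniform
initialization, and run on a small numpy forward-pass engine.  Layer probing
follows the convention that "layer l" means the l-th weight layer (conv1..
conv13, fc14..fc16) and that activations are recorded before the ReLU gate.
Pretrained weights are an optional plug-in: requesting them without
providing a weight file raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

VGG16_CONV_CHANNELS = [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]
# max-pool follows these (1-based) conv stages
VGG16_POOL_AFTER = {2, 4, 7, 10, 13}
VGG16_FC_DIMS = [4096, 4096, 1000]

MLP_TABLE_DIMS = [224 * 224, 2150, 2048, 2048, 2048, 2048, 1024,
                  1024, 1024, 1024, 1024, 1024, 1024, 1024, 1024, 1024, 1000]

ALLOWED_UNIT_SCALES = (1_000, 5_000, 10_000, 50_000, 100_000)


@dataclass(frozen=True)
class LayerSpec:
    """Shape bookkeeping for one weight layer."""

    index: int  # 1-based depth
    name: str
    kind: str  # 'conv' | 'dense'
    in_dim: int  # fan-in per unit (C*k*k for conv, N_{l-1} for dense)
    out_dim: int  # filters (conv) or N_l (dense)
    units: int  # flattened pre-ReLU output size
    n_weights: int
    n_biases: int

    @property
    def n_params(self) -> int:
        return self.n_weights + self.n_biases


@dataclass(frozen=True)
class NetworkSpec:
    kind: str  # 'vgg16' | 'mlp_table1'
    init: str = "untrained_default"
    input_size: int = 224
    layers: tuple[LayerSpec, ...] = field(default_factory=tuple)

    @property
    def depth(self) -> int:
        return len(self.layers)


def vgg16_spec(input_size: int = 224, init: str = "untrained_default") -> NetworkSpec:
    """Architecture bookkeeping for the 16-weight-layer convolutional net.

    ``input_size`` must be divisible by 32 (five pooling stages).
    """
    if input_size % 32 != 0:
        raise ValueError("input_size must be a multiple of 32")
    layers: list[LayerSpec] = []
    spatial = input_size
    in_ch = 3
    for i, out_ch in enumerate(VGG16_CONV_CHANNELS, start=1):
        layers.append(
            LayerSpec(
                index=i,
                name=f"conv{i}",
                kind="conv",
                in_dim=in_ch * 9,
                out_dim=out_ch,
                units=out_ch * spatial * spatial,
                n_weights=out_ch * in_ch * 9,
                n_biases=out_ch,
            )
        )
        in_ch = out_ch
        if i in VGG16_POOL_AFTER:
            spatial //= 2
    flat = in_ch * spatial * spatial
    dims = [flat] + VGG16_FC_DIMS
    for j, (din, dout) in enumerate(zip(dims[:-1], dims[1:]), start=14):
        layers.append(
            LayerSpec(
                index=j,
                name=f"fc{j}",
                kind="dense",
                in_dim=din,
                out_dim=dout,
                units=dout,
                n_weights=din * dout,
                n_biases=dout,
            )
        )
    return NetworkSpec(kind="vgg16", init=init, input_size=input_size, layers=tuple(layers))


def mlp_table1_spec(init: str = "untrained_default") -> NetworkSpec:
    """Architecture bookkeeping for the parameter-matched MLP."""
    layers = []
    for i, (din, dout) in enumerate(zip(MLP_TABLE_DIMS[:-1], MLP_TABLE_DIMS[1:]), start=1):
        layers.append(
            LayerSpec(
                index=i,
                name=f"M{i}",
                kind="dense",
                in_dim=din,
                out_dim=dout,
                units=dout,
                n_weights=din * dout,
                n_biases=dout,
            )
        )
    return NetworkSpec(kind="mlp_table1", init=init, input_size=224, layers=tuple(layers))


def parameter_count(network_or_spec) -> dict:
    """Per-layer and total parameter counts (weights + biases).

    Returns a dict with 'per_layer' (list of dicts with raw counts and
    millions rounded to the nearest integer), 'total' and 'total_millions'.
    """
    spec = getattr(network_or_spec, "spec", network_or_spec)
    per_layer = [
        {
            "layer": ls.index,
            "name": ls.name,
            "n_params": ls.n_params,
            "millions": round(ls.n_params / 1e6),
        }
        for ls in spec.layers
    ]
    total = sum(ls.n_params for ls in spec.layers)
    return {
        "per_layer": per_layer,
        "total": total,
        "total_millions": round(total / 1e6),
        "rounded_millions_sum": sum(d["millions"] for d in per_layer),
    }


@dataclass
class ActivationTensor:
    """Stimulus x unit matrix of pre-ReLU responses for one layer."""

    layer_id: int
    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))


@dataclass(frozen=True)
class UnitSample:
    layer_id: int
    indices: np.ndarray
    requested: int


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class _Conv3x3:
    def __init__(self, rng, in_ch, out_ch):
        fan_in = in_ch * 9
        self.W = _fan_in_uniform(rng, (out_ch, in_ch, 3, 3), fan_in)
        self.b = _fan_in_uniform(rng, (out_ch,), fan_in)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, H, W) -> (N, out_ch, H, W), stride 1, zero pad 1
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)


class _Dense:
    def __init__(self, rng, din, dout):
        self.W = _fan_in_uniform(rng, (dout, din), din)
        self.b = _fan_in_uniform(rng, (dout,), din)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.T + self.b


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))


class Network:
    """A feed-forward network with probe-able pre-ReLU weight layers."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self._ops: list[tuple[str, object]] = []
        if spec.kind == "vgg16":
            in_ch = 3
            for i, out_ch in enumerate(VGG16_CONV_CHANNELS, start=1):
                self._ops.append(("weight", _Conv3x3(rng, in_ch, out_ch)))
                self._ops.append(("relu", None))
                if i in VGG16_POOL_AFTER:
                    self._ops.append(("pool", None))
                in_ch = out_ch
            self._ops.append(("flatten", None))
            dims = [spec.layers[13].in_dim] + VGG16_FC_DIMS
            for din, dout in zip(dims[:-1], dims[1:]):
                self._ops.append(("weight", _Dense(rng, din, dout)))
                self._ops.append(("relu", None))
            self._ops.pop()  # no ReLU after the output layer
        elif spec.kind == "mlp_table1":
            self._ops.append(("flatten", None))
            for din, dout in zip(MLP_TABLE_DIMS[:-1], MLP_TABLE_DIMS[1:]):
                self._ops.append(("weight", _Dense(rng, din, dout)))
                self._ops.append(("relu", None))
            self._ops.pop()
        else:
            raise ValueError(f"unknown network kind {spec.kind!r}")

    @property
    def depth(self) -> int:
        return self.spec.depth

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if self.spec.kind == "vgg16":
            if x.ndim == 3:  # grayscale replicated over the 3 input channels
                x = np.repeat(x[:, None], 3, axis=1)
        return x

    def forward(self, images: np.ndarray, upto_layer: int | None = None) -> np.ndarray:
        """Run the network; return pre-ReLU activations of ``upto_layer``
        (1-based weight-layer index) or the final output when None."""
        max_layer = upto_layer if upto_layer is not None else self.depth
        if not 1 <= max_layer <= self.depth:
            raise ValueError(f"layer_id must be in 1..{self.depth}")
        x = self._prepare(images)
        seen = 0
        for kind, op in self._ops:
            if kind == "weight":
                x = op(x)
                seen += 1
                if seen == max_layer:
                    return x.reshape(x.shape[0], -1)
            elif kind == "relu":
                x = np.maximum(x, 0.0)
            elif kind == "pool":
                x = _maxpool2(x)
            elif kind == "flatten":
                x = x.reshape(x.shape[0], -1)
        return x.reshape(x.shape[0], -1)

    def collect(self, images: np.ndarray, layers) -> dict[int, np.ndarray]:
        """Pre-ReLU activations for several layers in a single pass."""
        wanted = sorted(set(layers))
        if not wanted or wanted[0] < 1 or wanted[-1] > self.depth:
            raise ValueError(f"layers must be within 1..{self.depth}")
        x = self._prepare(images)
        out: dict[int, np.ndarray] = {}
        seen = 0
        for kind, op in self._ops:
            if kind == "weight":
                x = op(x)
                seen += 1
                if seen in wanted:
                    out[seen] = x.reshape(x.shape[0], -1)
                if seen == wanted[-1]:
                    break
            elif kind == "relu":
                x = np.maximum(x, 0.0)
            elif kind == "pool":
                x = _maxpool2(x)
            elif kind == "flatten":
                x = x.reshape(x.shape[0], -1)
        return out

    def layer_size(self, layer_id: int) -> int:
        return self.spec.layers[layer_id - 1].units


class SyntheticDeepNet:
    """A toy depth-indexed representation with growing stimulus signal.

    Layer ``l`` responds with ``snr[l-1] * (M x) + n(x)``, where M is a fixed
    random mixing of the input and n(x) is a unit-variance pseudo-noise
    vector derived deterministically from a checksum of the input (so
    identical stimuli always evoke identical responses, while across stimuli
    the noise carries no usable structure).  Linear decodability of any
    stimulus property therefore increases with depth, which makes this a
    convenient stand-in for probing depth trends in the readout machinery.
    """

    def __init__(
        self,
        input_dim: int,
        n_units: int = 200,
        depth: int = 6,
        snr: np.ndarray | None = None,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.seed = seed
        self.snr = (
            np.geomspace(0.05, 3.0, depth) if snr is None else np.asarray(snr, float)
        )
        self.mix = rng.normal(size=(n_units, input_dim)) / np.sqrt(input_dim)
        self.spec = NetworkSpec(
            kind="synthetic",
            layers=tuple(
                LayerSpec(l, f"s{l}", "dense", input_dim, n_units, n_units,
                          n_units * input_dim, n_units)
                for l in range(1, depth + 1)
            ),
        )

    def _pseudo_noise(self, x: np.ndarray) -> np.ndarray:
        import zlib

        n_units = self.mix.shape[0]
        out = np.empty((len(x), n_units))
        for i, row in enumerate(x):
            key = zlib.crc32(row.tobytes()) ^ self.seed
            out[i] = np.random.default_rng(key).standard_normal(n_units)
        return out

    def forward(self, images: np.ndarray, upto_layer: int | None = None) -> np.ndarray:
        l = self.depth if upto_layer is None else upto_layer
        if not 1 <= l <= self.depth:
            raise ValueError(f"layer_id must be in 1..{self.depth}")
        x = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
        return self.snr[l - 1] * (x @ self.mix.T) + self._pseudo_noise(x)

    def collect(self, images: np.ndarray, layers) -> dict[int, np.ndarray]:
        x = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
        proj = x @ self.mix.T
        noise = self._pseudo_noise(x)
        return {l: self.snr[l - 1] * proj + noise for l in layers}

    def layer_size(self, layer_id: int) -> int:
        return self.mix.shape[0]


def build_vgg16(
    rng: np.random.Generator,
    input_size: int = 224,
    init: str = "untrained_default",
    weights_path=None,
) -> Network:
    """Untrained 16-weight-layer convolutional network, seeded init.

    ``init='pretrained'`` (or 'pretrained_blur') requires an explicit
    weights file; none ships with the package, so requesting it without one
    raises with a pointer to the untrained mode.
    """
    if init != "untrained_default" and weights_path is None:
        raise ValueError(
            f"init={init!r} requires a weights_path; pretrained weights are an "
            "optional plug-in -- use init='untrained_default' instead"
        )
    net = Network(vgg16_spec(input_size, init), rng)
    if weights_path is not None:
        _load_weights(net, weights_path)
    return net


def build_mlp_table1(rng: np.random.Generator) -> Network:
    """The depth- and parameter-matched MLP (16 affine stages, ReLU between)."""
    return Network(mlp_table1_spec(), rng)


def _load_weights(net: Network, path) -> None:
    arrs = np.load(path)
    k = 0
    for kind, op in net._ops:
        if kind == "weight":
            op.W = arrs[f"W{k}"].astype(np.float32)
            op.b = arrs[f"b{k}"].astype(np.float32)
            k += 1


def extract_activations(
    network: Network, layer_id: int, images: np.ndarray, *, batch_size: int = 64
) -> ActivationTensor:
    """Pre-ReLU responses of every unit in a layer, stimulus x unit."""
    imgs = np.asarray(images)
    if imgs.ndim == 2:
        imgs = imgs[None]
    chunks = [
        network.forward(imgs[i : i + batch_size], upto_layer=layer_id)
        for i in range(0, len(imgs), batch_size)
    ]
    data = np.concatenate(chunks, axis=0)
    return ActivationTensor(layer_id, data, {"n_stimuli": len(imgs)})


def sample_units(
    layer_size: int,
    requested: int,
    rng: np.random.Generator,
    *,
    layer_id: int = 0,
    allowed_scales=None,
) -> UnitSample:
    """Uniform unit subsample without replacement, capped at the layer size."""
    if requested <= 0:
        raise ValueError("requested sample size must be positive")
    if allowed_scales is not None and requested not in allowed_scales:
        raise ValueError(f"requested={requested} not in allowed scales {allowed_scales}")
    n = min(requested, layer_size)
    idx = rng.choice(layer_size, size=n, replace=False)
    return UnitSample(layer_id=layer_id, indices=np.sort(idx), requested=requested)
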
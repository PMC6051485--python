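"""Compact resolution-preserving segmentation networks.

Two architectures are provided, both binary-softmax fully-convolutional
networks whose output keeps the spatial shape of the input:

* a 2D network of six blocks where the five feature blocks use dilated
  3x3 convolutions with dilations 1, 2, 4, 8 and 16 so that one output
  pixel sees a 181x181 context;
* a 3D variant with anisotropic kernels (3x3x3 in the first two blocks,
  3x3x1 afterwards) and per-block 1x1x1 feature-compression convolutions,
  giving an 85x85x9 receptive field suited to thick-slice volumes.

The outputs of the five feature blocks are concatenated (after compression
in 3D) and fed to a final classifying block of 1-tap convolutions.  At test
time only the classifier parameters are adapted, so the concatenated
features of a given image can be cached once and reused for every
classifier update; :class:`FeatureCache` carries a fingerprint of the
non-classifier ("backbone") parameters so a stale cache is detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from ._conv import conv_backward_input, conv_backward_params, conv_forward, relu
from .errors import ConfigurationError, InputError, StateError

CLASSIFIER_BLOCK = "block6"


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class BlockSpec:
    """One feature block: ``layers`` convolutions of the same kernel/dilation."""

    kernel: tuple[int, ...]
    dilation: tuple[int, ...]
    channels: int
    layers: int


@dataclass(frozen=True)
class NetworkSpec:
    """Structural description of a network; ``blocks`` excludes the classifier.

    ``compression_channels`` is only meaningful in 3D, where each block's
    output is squeezed by a 1x1x1 convolution before concatenation.
    """

    blocks: tuple[BlockSpec, ...]
    classifier_channels: int = 2
    compression_channels: int | None = None

    @property
    def ndim(self) -> int:
        return len(self.blocks[0].kernel)

    @property
    def concat_channels(self) -> int:
        per_block = self.compression_channels or 0
        if self.compression_channels is None:
            return sum(b.channels for b in self.blocks)
        return per_block * len(self.blocks)

    def validate(self) -> None:
        nd = self.ndim
        for bi, b in enumerate(self.blocks, start=1):
            if len(b.kernel) != nd or len(b.dilation) != nd:
                raise ConfigurationError(f"block{bi}: kernel/dilation dimensionality mismatch")
            if any(d < 1 for d in b.dilation):
                raise ConfigurationError(f"block{bi}: every dilation must be >= 1")
            if any(k % 2 == 0 or k < 1 for k in b.kernel):
                raise ConfigurationError(f"block{bi}: every kernel size must be odd and positive")
            if b.channels < 1 or b.layers < 1:
                raise ConfigurationError(f"block{bi}: channels and layers must be positive")
        if nd == 2:
            if len(self.blocks) != 5:
                raise ConfigurationError("2D spec must have five feature blocks plus the classifier (six blocks)")
            expected = (1, 2, 4, 8, 16)
            for bi, (b, d) in enumerate(zip(self.blocks, expected), start=1):
                if b.dilation != (d, d):
                    raise ConfigurationError(f"2D block{bi} must use isotropic dilation {d}")
        elif nd == 3:
            if len(self.blocks) != 5:
                raise ConfigurationError("3D spec must have five feature blocks plus the classifier (six blocks)")
            for bi, b in enumerate(self.blocks, start=1):
                want = (3, 3, 3) if bi <= 2 else (3, 3, 1)
                if b.kernel != want:
                    raise ConfigurationError(f"3D block{bi} must use {'x'.join(map(str, want))} kernels")
            if self.compression_channels is not None and self.compression_channels < 1:
                raise ConfigurationError("compression_channels must be positive")
        else:
            raise ConfigurationError("only 2D and 3D networks are supported")

    def to_json(self) -> str:
        payload = {
            "blocks": [
                {"kernel": list(b.kernel), "dilation": list(b.dilation),
                 "channels": b.channels, "layers": b.layers}
                for b in self.blocks
            ],
            "classifier_channels": self.classifier_channels,
            "compression_channels": self.compression_channels,
        }
        return json.dumps(payload, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "NetworkSpec":
        payload = json.loads(text)
        blocks = tuple(
            BlockSpec(tuple(b["kernel"]), tuple(b["dilation"]), b["channels"], b["layers"])
            for b in payload["blocks"]
        )
        return NetworkSpec(blocks, payload["classifier_channels"], payload["compression_channels"])

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def receptive_field(spec: NetworkSpec) -> tuple[int, ...]:
    """Theoretical per-axis receptive field of one output pixel.

    Accumulates ``(kernel - 1) * dilation`` over every convolution layer of
    the feature blocks, plus one.  The 1-tap classifier and compression
    convolutions contribute nothing.
    """
    spec.validate()
    extents = [0] * spec.ndim
    for b in spec.blocks:
        for ax in range(spec.ndim):
            extents[ax] += b.layers * (b.kernel[ax] - 1) * b.dilation[ax]
    return tuple(e + 1 for e in extents)


def default_2d_spec(channels: int = 8) -> NetworkSpec:
    """Default 2D spec: dilations 1,2,4,8,16 over blocks with 2,2,3,3,3 layers.

    Layer counts are chosen so the printed 181x181 receptive field is
    reproduced exactly; the constructor re-checks this.
    """
    dilations = (1, 2, 4, 8, 16)
    layer_counts = (2, 2, 3, 3, 3)
    blocks = tuple(
        BlockSpec((3, 3), (d, d), channels, n) for d, n in zip(dilations, layer_counts)
    )
    spec = NetworkSpec(blocks)
    if receptive_field(spec) != (181, 181):
        raise ConfigurationError("default 2D spec no longer yields the 181x181 receptive field")
    return spec


def default_3d_spec(channels: int = 8, compression_channels: int = 16) -> NetworkSpec:
    """Default 3D spec with anisotropic kernels and an 85x85x9 receptive field.

    In-plane dilations grow 1..5 over blocks with 2,2,3,3,3 layers; the
    through-plane axis only sees the 3-tap kernels of blocks 1-2 at
    dilation 1, hence the thin 9-voxel extent.
    """
    layer_counts = (2, 2, 3, 3, 3)
    blocks = []
    for bi, (d, n) in enumerate(zip((1, 2, 3, 4, 5), layer_counts), start=1):
        kernel = (3, 3, 3) if bi <= 2 else (3, 3, 1)
        blocks.append(BlockSpec(kernel, (d, d, 1), channels, n))
    spec = NetworkSpec(tuple(blocks), compression_channels=compression_channels)
    if receptive_field(spec) != (85, 85, 9):
        raise ConfigurationError("default 3D spec no longer yields the 85x85x9 receptive field")
    return spec


# ---------------------------------------------------------------------------
# Feature cache and probability containers


@dataclass
class FeatureCache:
    """Concatenation-layer features for one region, tied to backbone params."""

    concat_features: np.ndarray  # (C, *spatial)
    spatial_shape: tuple[int, ...]
    backbone_fingerprint: str


@dataclass
class ProbabilityMap:
    """Per-pixel foreground probability from the binary softmax."""

    p: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise InputError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Network


class _Conv:
    _dtype = np.float32

    def __init__(self, name, in_ch, out_ch, kernel, dilation, rng):
        self.name = name
        self.kernel = kernel
        self.dilation = dilation
        fan_in = in_ch * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.weight = (rng.standard_normal((out_ch, in_ch) + kernel) * scale).astype(self._dtype)
        self.bias = np.zeros(out_ch, dtype=self._dtype)


class Network:
    """A realized network: parameters plus forward/backward machinery.

    Parameters are addressable as a flat ``{name: array}`` dict; classifier
    parameters live under the ``block6/`` prefix, everything else is the
    backbone that stays frozen during image-specific fine-tuning.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        nd = spec.ndim
        ones = (1,) * nd
        self.blocks: list[list[_Conv]] = []
        in_ch = 1
        _Conv._dtype = self.dtype
        for bi, b in enumerate(spec.blocks, start=1):
            layers = []
            for li in range(b.layers):
                layers.append(_Conv(f"block{bi}/conv{li}", in_ch, b.channels, b.kernel, b.dilation, rng))
                in_ch = b.channels
            self.blocks.append(layers)
        self.compress: list[_Conv] | None = None
        if spec.compression_channels is not None:
            self.compress = [
                _Conv(f"block{bi}/compress", spec.blocks[bi - 1].channels,
                      spec.compression_channels, ones, ones, rng)
                for bi in range(1, len(spec.blocks) + 1)
            ]
        self.classifier = _Conv(f"{CLASSIFIER_BLOCK}/conv0", spec.concat_channels,
                                spec.classifier_channels, ones, ones, rng)

    # -- parameter bookkeeping ---------------------------------------------

    def _convs(self) -> list[_Conv]:
        out = [c for block in self.blocks for c in block]
        if self.compress is not None:
            out.extend(self.compress)
        out.append(self.classifier)
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for c in self._convs():
            params[f"{c.name}/W"] = c.weight
            params[f"{c.name}/b"] = c.bias
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for c in self._convs():
            c.weight = np.asarray(params[f"{c.name}/W"], dtype=self.dtype)
            c.bias = np.asarray(params[f"{c.name}/b"], dtype=self.dtype)

    def classifier_parameter_names(self) -> list[str]:
        return [k for k in self.parameters() if k.startswith(CLASSIFIER_BLOCK + "/")]

    def backbone_fingerprint(self) -> str:
        h = hashlib.sha256()
        for name, arr in sorted(self.parameters().items()):
            if not name.startswith(CLASSIFIER_BLOCK + "/"):
                h.update(name.encode())
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- forward ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != self.spec.ndim:
            raise InputError(
                f"expected a {self.spec.ndim}D region, got {x.ndim}D input")
        return x[None]  # single channel

    def _forward_features(self, x: np.ndarray, tape: list | None = None) -> np.ndarray:
        h = x
        block_outputs = []
        for block in self.blocks:
            for conv in block:
                z, cols = conv_forward(h, conv.weight, conv.bias, conv.dilation, return_cols=True)
                if tape is not None:
                    tape.append((conv, cols, z))
                h = relu(z)
            block_outputs.append(h)
        if self.compress is not None:
            squeezed = []
            for conv, out in zip(self.compress, block_outputs):
                z, cols = conv_forward(out, conv.weight, conv.bias, conv.dilation, return_cols=True)
                if tape is not None:
                    tape.append((conv, cols, z))
                squeezed.append(relu(z))
            block_outputs = squeezed
        return np.concatenate(block_outputs, axis=0)

    def _classifier_logits(self, feats: np.ndarray, tape: list | None = None) -> np.ndarray:
        c = self.classifier
        z, cols = conv_forward(feats, c.weight, c.bias, c.dilation, return_cols=True)
        if tape is not None:
            tape.append((c, cols, z))
        return z

    def forward_logits(self, region) -> np.ndarray:
        x = self._check_input(_region_array(region))
        return self._classifier_logits(self._forward_features(x))

    def forward_probability(self, region) -> ProbabilityMap:
        """Foreground probability map from a full forward pass (inference)."""
        return ProbabilityMap(softmax_foreground(self.forward_logits(region)))

    def cache_features(self, region) -> FeatureCache:
        """Store the concatenation-layer features for classifier-only updates."""
        x = self._check_input(_region_array(region))
        feats = self._forward_features(x)
        return FeatureCache(feats, tuple(x.shape[1:]), self.backbone_fingerprint())

    def classifier_logits_from_cache(self, cache: FeatureCache) -> np.ndarray:
        return self._classifier_logits(cache.concat_features)

    def probability_from_cache(self, cache: FeatureCache) -> ProbabilityMap:
        return ProbabilityMap(softmax_foreground(self.classifier_logits_from_cache(cache)))

    def check_cache(self, cache: FeatureCache) -> None:
        if cache.backbone_fingerprint != self.backbone_fingerprint():
            raise StateError("feature cache is stale: backbone parameters changed since caching")

    # -- backward (full training path) --------------------------------------

    def backprop(self, region, target: np.ndarray, weights: np.ndarray | None = None,
                 reduction: str = "mean"):
        """Weighted cross-entropy loss and gradients for one region.

        ``target`` is a binary map; ``weights`` an optional per-pixel weight
        map.  ``reduction`` is "mean" (training) or "sum" (the fine-tuning
        objective).  Returns ``(loss, grads)`` with ``grads`` keyed like
        :meth:`parameters`.
        """
        x = self._check_input(_region_array(region))
        tape: list = []
        feats = self._forward_features(x, tape)
        logits = self._classifier_logits(feats, tape)
        loss, dlogits = softmax_cross_entropy(logits, target, weights, reduction)
        grads = self._backward(tape, dlogits)
        return loss, grads

    def _backward(self, tape, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        conv, cols, _ = tape[-1]  # classifier
        dw, db = conv_backward_params(dlogits, cols, conv.weight.shape)
        grads[f"{conv.name}/W"] = dw
        grads[f"{conv.name}/b"] = db
        dfeat = conv_backward_input(dlogits, conv.weight, conv.dilation)
        n_blocks = len(self.blocks)
        # split concat gradient into per-block slices
        if self.compress is not None:
            cc = self.spec.compression_channels
            slices = [dfeat[i * cc:(i + 1) * cc] for i in range(n_blocks)]
            comp_tape = tape[-1 - n_blocks:-1]
            block_grads = []
            for (conv, cols, z), dpart in zip(comp_tape, slices):
                dz = dpart * (z > 0)
                dw, db = conv_backward_params(dz, cols, conv.weight.shape)
                grads[f"{conv.name}/W"] = dw
                grads[f"{conv.name}/b"] = db
                block_grads.append(conv_backward_input(dz, conv.weight, conv.dilation))
            body_tape = tape[:-1 - n_blocks]
        else:
            offsets = np.cumsum([0] + [b.channels for b in self.spec.blocks])
            block_grads = [dfeat[offsets[i]:offsets[i + 1]] for i in range(n_blocks)]
            body_tape = tape[:-1]
        # walk the block chain backwards; each block's output feeds both the
        # concat layer and the next block's first convolution
        per_block_tapes: list[list] = []
        idx = 0
        for b in self.spec.blocks:
            per_block_tapes.append(body_tape[idx:idx + b.layers])
            idx += b.layers
        dchain = None
        for bi in reversed(range(n_blocks)):
            g = block_grads[bi] if dchain is None else block_grads[bi] + dchain
            for conv, cols, z in reversed(per_block_tapes[bi]):
                g = g * (z > 0)
                dw, db = conv_backward_params(g, cols, conv.weight.shape)
                grads[f"{conv.name}/W"] = dw
                grads[f"{conv.name}/b"] = db
                g = conv_backward_input(g, conv.weight, conv.dilation)
            dchain = g
        return grads


def _region_array(region) -> np.ndarray:
    return region.intensities if hasattr(region, "intensities") else np.asarray(region)


# ---------------------------------------------------------------------------
# Softmax helpers

PROB_EPS = 1e-6


def softmax_foreground(logits: np.ndarray) -> np.ndarray:
    """Binary softmax foreground channel; logits are (2, *spatial)."""
    from scipy.special import expit

    return expit((logits[1] - logits[0]).astype(np.float64))


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray,
                          weights: np.ndarray | None, reduction: str):
    """Weighted binary cross-entropy over the softmax; returns (loss, dlogits)."""
    p = softmax_foreground(logits)
    y = np.asarray(target, dtype=np.float64)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=np.float64)
    pc = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    loss = -np.sum(w * (y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    dfg = w * (p - y)
    if reduction == "mean":
        n = p.size
        loss /= n
        dfg = dfg / n
    elif reduction != "sum":
        raise InputError(f"unknown reduction {reduction!r}")
    dlogits = np.stack([-dfg, dfg]).astype(np.float32)
    return float(loss), dlogits


def build_network(spec: NetworkSpec, dims: int | None = None, seed: int = 0) -> Network:
    """Validate ``spec`` and realize it as a trainable :class:`Network`."""
    spec.validate()
    if dims is not None and dims != spec.ndim:
        raise ConfigurationError(f"spec is {spec.ndim}D but dims={dims} was requested")
    return Network(spec, seed=seed)
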
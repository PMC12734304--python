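"""Architecture building blocks and the reference volumetric classifier.

The network is a chain of depthwise-separable 3D convolution stages with a
lightweight multi-scale fusion (LMF) block at one stage, a parameter-free
ILS attention, dilated depthwise convolutions in the final stages, global
average pooling and a linear head.  Channel order is ``(C, D, H, W)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .engine import (BatchNorm3d, Conv3d, GlobalAvgPool3d, Layer, Linear,
                     ReLU, Sequential, softmax)


class ILSAttention(Layer):
    """Simplified SimAM-style attention: normalise, shift to ~[0, 1], sigmoid.

    Per sample and channel, with spatial mean ``mu`` and (population)
    variance ``v``::

        xhat = (x - mu) / (v + lam) * 0.5 + 0.5
        M    = sigmoid(xhat)
        y    = x * M

    Parameter-free; ``lam`` guards the zero-variance case, where ``xhat``
    collapses to 0.5 and the mask to ``sigmoid(0.5)``.
    """

    def __init__(self, epsilon_lambda: float = 1e-4):
        if epsilon_lambda <= 0:
            raise ValueError(f"lambda must be positive, got {epsilon_lambda}")
        self.lam = float(epsilon_lambda)

    def forward(self, x, training=False):
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        v = x.var(axis=axes, keepdims=True)
        xhat = (x - mu) / (v + self.lam) * 0.5 + 0.5
        m = 1.0 / (1.0 + np.exp(-xhat))
        self._cache = (x, mu, v, m)
        return (x * m).astype(np.float32, copy=False)

    def backward(self, dy):
        x, mu, v, m = self._cache
        axes = (2, 3, 4)
        n = x.shape[2] * x.shape[3] * x.shape[4]
        u = x - mu
        denom = v + self.lam
        # h_i = dy_i * x_i * M_i (1 - M_i) * 0.5  (chain through sigmoid & scale)
        h = dy * x * m * (1.0 - m) * 0.5
        dx = (dy * m
              + (h - h.mean(axis=axes, keepdims=True)) / denom
              - u * (h * u).sum(axis=axes, keepdims=True) / (n * denom ** 2))
        return dx.astype(np.float32, copy=False)

    def out_shape(self, in_shape):
        return in_shape

    def flops(self, in_shape):
        return 0  # elementwise work excluded from the profiler's scope

    @staticmethod
    def mask(x: np.ndarray, epsilon_lambda: float = 1e-4) -> np.ndarray:
        """Return just the attention mask M (useful for inspection/tests)."""
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        v = x.var(axis=(2, 3, 4), keepdims=True)
        xhat = (x - mu) / (v + epsilon_lambda) * 0.5 + 0.5
        return 1.0 / (1.0 + np.exp(-xhat))


def ds_unit(c_in: int, c_out: int, k: int = 3, stride: int = 1, dilation: int = 1,
            rng=None, name: str = "ds") -> Sequential:
    """Depthwise-separable conv unit: depthwise k^3 -> BN -> ReLU -> 1^3 pointwise -> BN -> ReLU."""
    return Sequential([
        Conv3d(c_in, c_in, k, stride=stride, padding="same", dilation=dilation,
               groups=c_in, bias=False, rng=rng),
        BatchNorm3d(c_in),
        ReLU(),
        Conv3d(c_in, c_out, 1, stride=1, padding=0, bias=False, rng=rng),
        BatchNorm3d(c_out),
        ReLU(),
    ], name=name)


class LMFBlock(Layer):
    """Lightweight multi-scale fusion block.

    Parallel depthwise-separable branches at kernel scales ``scales`` (same
    padding so they align), a gating path — 3D global average pooling of the
    channel-concatenation, two small linear layers with ReLU, softmax — and a
    convex fusion of the branch outputs with the resulting per-scale weights.
    """

    def __init__(self, channels: int, scales: Sequence[int] = (3, 5),
                 gate_hidden: Optional[int] = None, rng=None,
                 in_channels: Optional[int] = None):
        scales = tuple(int(s) for s in scales)
        if len(scales) < 2:
            raise ValueError("LMF needs at least two scales")
        if any(s % 2 == 0 for s in scales):
            raise ValueError(f"kernel scales must be odd, got {scales}")
        self.channels = int(channels)
        self.in_channels = int(in_channels) if in_channels is not None else int(channels)
        self.scales = scales
        S = len(scales)
        if gate_hidden is None:
            gate_hidden = max(4, (S * channels) // 4)
        self.gate_hidden = int(gate_hidden)
        self.branches = [
            ds_unit(self.in_channels, channels, k=s, stride=1, rng=rng, name=f"branch{s}")
            for s in scales
        ]
        # gate layers excluded from the FLOPs profile (documented choice)
        self.gate_fc1 = Linear(S * channels, self.gate_hidden, rng=rng, count_in_flops=False)
        self.gate_relu = ReLU()
        self.gate_fc2 = Linear(self.gate_hidden, S, rng=rng, count_in_flops=False)
        self.gate_fc1.name = "gate_fc1"
        self.gate_fc2.name = "gate_fc2"

    def children(self):
        return [*self.branches, self.gate_fc1, self.gate_fc2]

    def gate_weights(self, branch_outputs: Sequence[np.ndarray]) -> np.ndarray:
        """Fusion weights alpha (N, S) for given branch outputs (forward only)."""
        z = pooled_descriptor(branch_outputs)
        h = np.maximum(self.gate_fc1.forward(z), 0.0)
        return softmax(self.gate_fc2.forward(h), axis=1)

    def forward(self, x, training=False):
        feats = [b.forward(x, training=training) for b in self.branches]
        shapes = {f.shape for f in feats}
        if len(shapes) != 1:
            raise ValueError(f"branch outputs misaligned: {sorted(shapes)}")
        z = pooled_descriptor(feats)  # (N, S*C)
        h = self.gate_fc1.forward(z, training=training)
        hr = self.gate_relu.forward(h, training=training)
        logits = self.gate_fc2.forward(hr, training=training)
        alpha = softmax(logits, axis=1)  # (N, S)
        out = np.zeros_like(feats[0])
        for i, f in enumerate(feats):
            out += alpha[:, i][:, None, None, None, None] * f
        self._cache = (feats, alpha)
        return out.astype(np.float32, copy=False)

    def backward(self, dy):
        feats, alpha = self._cache
        S = len(feats)
        N = dy.shape[0]
        # d(alpha): fused = sum_i alpha_i F_i
        dalpha = np.stack([np.einsum("ncdhw,ncdhw->n", dy, f) for f in feats], axis=1)
        dlogits = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dhr = self.gate_fc2.backward(dlogits.astype(np.float32))
        dh = self.gate_relu.backward(dhr)
        dz = self.gate_fc1.backward(dh)  # (N, S*C)
        C = self.channels
        P = feats[0].shape[2] * feats[0].shape[3] * feats[0].shape[4]
        dx = None
        for i, (branch, f) in enumerate(zip(self.branches, feats)):
            df = alpha[:, i][:, None, None, None, None] * dy
            dz_i = dz[:, i * C:(i + 1) * C] / P  # GAP backward for segment i
            df = df + dz_i[:, :, None, None, None]
            dxi = branch.backward(df.astype(np.float32))
            dx = dxi if dx is None else dx + dxi
        return dx

    def out_shape(self, in_shape):
        return self.branches[0].out_shape(in_shape)

    def flops(self, in_shape):
        return sum(b.flops(in_shape) for b in self.branches)


def pooled_descriptor(feature_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate feature maps along channels and 3D-global-average-pool.

    For S maps of C channels each the result has length S*C per sample: the
    per-channel mean over all D*H*W positions of the concatenation.
    """
    cat = np.concatenate(list(feature_maps), axis=1)
    return cat.mean(axis=(2, 3, 4)).astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# network configuration and assembly
# ---------------------------------------------------------------------------

#: Stage widths calibrated (grid over a width multiplier on the 24/64/128/256/512
#: ladder; see ``voxslim.complexity.calibrate_width_multiplier``) so that the
#: default network holds ~0.92 M trainable parameters.
DEFAULT_STAGE_WIDTHS: Tuple[int, ...] = (24, 125, 250, 499, 998)  # multiplier 1.95


@dataclass
class NetworkConfig:
    """Full architecture description; instantiation is deterministic given a seed."""

    stem_channels: int = 24
    stage_widths: Tuple[int, ...] = ()
    lmf_position: int = 2
    ils_positions: Tuple[int, ...] = (2,)
    lmf_scales: Tuple[int, ...] = (3, 5)
    dilation_rates: Tuple[int, ...] = (2, 4)
    num_classes: int = 2
    ils_lambda: float = 1e-4
    #: fused LMF output width; None means "same as its stage width".  Compacted
    #: models use this because pruning narrows the LMF input but its (protected)
    #: fused output keeps the original width.
    lmf_channels: Optional[int] = None
    #: compacted (pruned) exports may legitimately carry non-monotone widths
    enforce_monotone: bool = True

    def __post_init__(self):
        if not self.stage_widths:
            self.stage_widths = DEFAULT_STAGE_WIDTHS
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        self.ils_positions = tuple(int(i) for i in self.ils_positions)
        self.dilation_rates = tuple(int(r) for r in self.dilation_rates)
        self.lmf_scales = tuple(int(s) for s in self.lmf_scales)
        problems = []
        if self.stem_channels < 1:
            problems.append(f"stem_channels={self.stem_channels} must be >= 1")
        if any(w < 1 for w in self.stage_widths):
            problems.append(f"stage_widths={self.stage_widths} must be positive")
        if self.enforce_monotone and any(
                a > b for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            problems.append(f"stage_widths={self.stage_widths} must be non-decreasing")
        if not 0 <= self.lmf_position < len(self.stage_widths):
            problems.append(f"lmf_position={self.lmf_position} outside stages "
                            f"0..{len(self.stage_widths) - 1}")
        if any(not 0 <= i < len(self.stage_widths) for i in self.ils_positions):
            problems.append(f"ils_positions={self.ils_positions} outside stage range")
        if any(r < 1 for r in self.dilation_rates):
            problems.append(f"dilation_rates={self.dilation_rates} must be >= 1")
        if len(self.dilation_rates) > len(self.stage_widths):
            problems.append("more dilation rates than stages")
        if self.num_classes < 2:
            problems.append(f"num_classes={self.num_classes} must be >= 2")
        if self.ils_lambda <= 0:
            problems.append(f"ils_lambda={self.ils_lambda} must be positive")
        if problems:
            raise ValueError("invalid NetworkConfig: " + "; ".join(problems))

    # The last len(dilation_rates) stages are dilated and keep stride 1;
    # all earlier stages downsample with stride-2 depthwise convs.
    def stage_plan(self):
        n = len(self.stage_widths)
        nd = len(self.dilation_rates)
        plan = []
        for i, w in enumerate(self.stage_widths):
            if i >= n - nd:
                plan.append((w, 1, self.dilation_rates[i - (n - nd)]))
            else:
                plan.append((w, 2, 1))
        return plan

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text) or {}
        for key in ("stage_widths", "ils_positions", "dilation_rates", "lmf_scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class StageBlock(Layer):
    """One stage: DS conv (possibly strided/dilated) + optional LMF + optional ILS."""

    def __init__(self, c_in, c_out, stride, dilation, lmf=None, ils=None, rng=None, name="stage"):
        self.ds = ds_unit(c_in, c_out, k=3, stride=stride, dilation=dilation,
                          rng=rng, name="ds")
        self.lmf = lmf
        self.ils = ils
        self.name = name
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.stride, self.dilation = int(stride), int(dilation)

    def children(self):
        out = [self.ds]
        if self.lmf is not None:
            out.append(self.lmf)
        if self.ils is not None:
            out.append(self.ils)
        return out

    def forward(self, x, training=False):
        x = self.ds.forward(x, training=training)
        if self.lmf is not None:
            x = self.lmf.forward(x, training=training)
        if self.ils is not None:
            x = self.ils.forward(x, training=training)
        return x

    def backward(self, dy):
        if self.ils is not None:
            dy = self.ils.backward(dy)
        if self.lmf is not None:
            dy = self.lmf.backward(dy)
        return self.ds.backward(dy)

    def out_shape(self, in_shape):
        s = self.ds.out_shape(in_shape)
        if self.lmf is not None:
            s = self.lmf.out_shape(s)
        return s

    def flops(self, in_shape):
        total = self.ds.flops(in_shape)
        if self.lmf is not None:
            total += self.lmf.flops(self.ds.out_shape(in_shape))
        return total


class VoxNet(Layer):
    """The assembled classifier: stem -> stages -> GAP -> linear head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem_conv = Conv3d(1, config.stem_channels, 1, stride=1, padding=0,
                                bias=False, rng=rng)
        self.stem_bn = BatchNorm3d(config.stem_channels)
        self.stem_relu = ReLU()
        self.stem_conv.name = "stem_conv"
        self.stem_bn.name = "stem_bn"
        self.stages = []
        c_prev = config.stem_channels
        for i, (w, stride, dil) in enumerate(config.stage_plan()):
            lmf = None
            if i == config.lmf_position:
                lmf = LMFBlock(config.lmf_channels or w, scales=config.lmf_scales,
                               rng=rng, in_channels=w)
                lmf.name = "lmf"
            ils = (ILSAttention(config.ils_lambda)
                   if i in config.ils_positions else None)
            self.stages.append(StageBlock(c_prev, w, stride, dil, lmf=lmf, ils=ils,
                                          rng=rng, name=f"stage{i}"))
            c_prev = lmf.channels if lmf is not None else w
        self.pool = GlobalAvgPool3d()
        self.fc = Linear(c_prev, config.num_classes, bias=True, rng=rng)
        self.fc.name = "fc"

    def children(self):
        return [self.stem_conv, self.stem_bn, self.stem_relu, *self.stages,
                self.pool, self.fc]

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:  # (C, D, H, W) single sample
            x = x[None]
        x = self.stem_relu.forward(self.stem_bn.forward(
            self.stem_conv.forward(x, training=training), training=training))
        for stage in self.stages:
            x = stage.forward(x, training=training)
        return self.fc.forward(self.pool.forward(x))

    def backward(self, dy):
        dy = self.pool.backward(self.fc.backward(dy))
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        return self.stem_conv.backward(self.stem_bn.backward(
            self.stem_relu.backward(dy)))

    def out_shape(self, in_shape):
        s = self.stem_conv.out_shape(in_shape)
        for stage in self.stages:
            s = stage.out_shape(s)
        return (self.config.num_classes,)

    def flops(self, in_shape):
        total = self.stem_conv.flops(in_shape)
        s = self.stem_conv.out_shape(in_shape)
        for stage in self.stages:
            total += stage.flops(s)
            s = stage.out_shape(s)
        total += self.fc.flops((s[0],))
        return total

    # convenience ------------------------------------------------------
    def conv_layers(self):
        """(name, Conv3d) pairs in forward order."""
        out = [("stem_conv", self.stem_conv)]
        for i, stage in enumerate(self.stages):
            out.append((f"stage{i}.dw", stage.ds.layers[0]))
            out.append((f"stage{i}.pw", stage.ds.layers[3]))
            if stage.lmf is not None:
                for s, branch in zip(stage.lmf.scales, stage.lmf.branches):
                    out.append((f"stage{i}.lmf.branch{s}.dw", branch.layers[0]))
                    out.append((f"stage{i}.lmf.branch{s}.pw", branch.layers[3]))
        return out


def build_network(config: Optional[NetworkConfig] = None, seed: int = 0) -> VoxNet:
    """Instantiate the classifier from a config, deterministically for a seed."""
    return VoxNet(config or NetworkConfig(), seed=seed)


def predict(model: VoxNet, volume: np.ndarray):
    """Class index and softmax probabilities for one volume or a batch.

    Probabilities sum to 1 (within float tolerance); argmax ties break toward
    the lower class index.
    """
    x = np.asarray(volume, dtype=np.float32)
    if x.ndim not in (3, 4, 5):
        raise ValueError(
            f"expected a (D,H,W) volume or (C,D,H,W)/(N,C,D,H,W) batch, got shape {x.shape}")
    single = x.ndim <= 4
    if x.ndim == 3:
        x = x[None, None]
    elif x.ndim == 4:
        x = x[None]
    scores = model.forward(x, training=False)
    probs = softmax(scores, axis=1)
    labels = np.argmax(probs, axis=1)
    if single:
        return int(labels[0]), probs[0]
    return labels, probs


# ---------------------------------------------------------------------------
# checkpoints: portable weight archive keyed by layer-qualified names
# ---------------------------------------------------------------------------

def _bn_layers(model: Layer, prefix=""):
    for name, child in _named_children(model, prefix):
        if isinstance(child, BatchNorm3d):
            yield name, child
        else:
            yield from _bn_layers(child, name + ".")


def _named_children(layer: Layer, prefix=""):
    for i, child in enumerate(layer.children()):
        cname = getattr(child, "name", None) or f"{type(child).__name__.lower()}{i}"
        yield prefix + cname, child


def save_checkpoint(path, model: VoxNet, extra: Optional[dict] = None):
    """Write weights + running stats + config (and optional metadata) to .npz."""
    arrays = {f"param/{n}": p.data for n, p in model.named_params()}
    for name, bn in _bn_layers(model):
        arrays[f"running_mean/{name}"] = bn.running_mean
        arrays[f"running_var/{name}"] = bn.running_var
    meta = {"config_yaml": model.config.to_yaml(), "extra": extra or {}}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8).copy()
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Rebuild a VoxNet from a checkpoint; returns (model, extra_metadata)."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode("utf-8"))
        config = NetworkConfig.from_yaml(meta["config_yaml"])
        model = VoxNet(config, seed=0)
        params = dict(model.named_params())
        for key in archive.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                if name not in params:
                    raise KeyError(f"checkpoint key {name!r} not in model")
                if params[name].data.shape != archive[key].shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: model {params[name].data.shape}"
                        f" vs checkpoint {archive[key].shape}")
                params[name].data = archive[key].astype(np.float32, copy=False)
                params[name].grad = np.zeros_like(params[name].data)
        bns = dict(_bn_layers(model))
        for key in archive.files:
            if key.startswith("running_mean/"):
                bns[key[len("running_mean/"):]].running_mean = archive[key].astype(np.float32, copy=False)
            elif key.startswith("running_var/"):
                bns[key[len("running_var/"):]].running_var = archive[key].astype(np.float32, copy=False)
    return model, meta["extra"]
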
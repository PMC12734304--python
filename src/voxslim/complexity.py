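"""Model complexity profiler: parameters, FLOPs, model size, performance density.

Counting conventions
--------------------
* ``count_params`` counts every trainable entry: convolution kernels, linear
  weights, biases, and BatchNorm scale/shift pairs.  Running statistics are
  not trainable and are excluded.
* ``count_flops`` counts multiply-adds at a factor of 2 for convolutions and
  fully connected layers only: per conv layer
  ``2 * D_out * H_out * W_out * (C_in / groups) * K^3 * C_out`` (a depthwise
  layer therefore contributes one kernel per group, summed), per linear layer
  ``2 * m * n``.  BatchNorm, activations, pooling, the attention block's
  elementwise work, and the LMF gate's two small linear layers are excluded;
  dilation does not change the count.
* ``model_size`` is ``Para * b`` bytes (b = 4 for float32) and is also
  reported in MiB (bytes / 2^20).
* Performance density is ``acc_percent / (Para / 1e6)`` — accuracy percent
  per million parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .blocks import NetworkConfig, build_network
from .engine import Layer


def count_params(model: Layer) -> int:
    """Total trainable parameter count (direct enumeration of entries)."""
    return int(sum(p.size for p in model.params()))


def count_flops(model: Layer, input_shape: Sequence[int]) -> int:
    """FLOPs of one forward pass at ``input_shape = (C, D, H, W)``."""
    input_shape = tuple(int(v) for v in input_shape)
    if len(input_shape) != 4:
        raise ValueError(f"input_shape must be (C, D, H, W), got {input_shape}")
    return int(model.flops(input_shape))


def model_size(para: int, b: int = 4) -> Tuple[int, float]:
    """(bytes, MiB) occupied by ``para`` parameters at ``b`` bytes each."""
    if para < 0:
        raise ValueError(f"para must be >= 0, got {para}")
    if b < 1:
        raise ValueError(f"bytes per parameter must be >= 1, got {b}")
    nbytes = int(para) * int(b)
    return nbytes, nbytes / 2 ** 20


def performance_density(acc_percent: float, para: int) -> float:
    """Accuracy (0-100 scale) per million parameters."""
    if para <= 0:
        raise ValueError(f"para must be positive, got {para}")
    return float(acc_percent) / (para / 1e6)


@dataclass
class ComplexityReport:
    para: int
    flops: int
    bytes_per_param: int
    model_size_bytes: int
    model_size_mib: float
    input_shape: Tuple[int, int, int, int]
    acc_percent: Optional[float] = None
    pd: Optional[float] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return d

    def __le__(self, other: "ComplexityReport") -> bool:
        return (self.para <= other.para and self.flops <= other.flops
                and self.model_size_bytes <= other.model_size_bytes)


def complexity_report(model: Layer, input_shape: Sequence[int],
                      acc_percent: Optional[float] = None,
                      bytes_per_param: int = 4) -> ComplexityReport:
    """Aggregate profile of a model (use on a compacted model after pruning)."""
    para = count_params(model)
    flops = count_flops(model, input_shape)
    nbytes, mib = model_size(para, bytes_per_param)
    pd = performance_density(acc_percent, para) if acc_percent is not None else None
    return ComplexityReport(para=para, flops=flops, bytes_per_param=int(bytes_per_param),
                            model_size_bytes=nbytes, model_size_mib=mib,
                            input_shape=tuple(int(v) for v in input_shape),
                            acc_percent=acc_percent, pd=pd)


# ---------------------------------------------------------------------------
# width calibration
# ---------------------------------------------------------------------------

BASE_STAGE_WIDTHS = (24, 64, 128, 256, 512)


def widths_for_multiplier(multiplier: float,
                          base: Sequence[int] = BASE_STAGE_WIDTHS) -> Tuple[int, ...]:
    """Scale the stage-width ladder, keeping the first stage at its base value.

    The stem/first-stage width is fixed (the architecture specifies an initial
    channel size of 24); later stages scale with the multiplier.
    """
    out = [int(base[0])]
    for w in base[1:]:
        out.append(max(out[-1], int(round(w * multiplier))))
    return tuple(out)


def calibrate_width_multiplier(target_params: int = 920_000,
                               base: Sequence[int] = BASE_STAGE_WIDTHS,
                               grid: Optional[Sequence[float]] = None,
                               **config_kwargs) -> Tuple[float, Tuple[int, ...], int]:
    """Grid-search the width multiplier whose network is closest to a parameter budget.

    Returns ``(multiplier, stage_widths, params)``.  This is the documented
    procedure that produced the default ``NetworkConfig`` stage widths.
    """
    if grid is None:
        grid = np.arange(0.5, 3.01, 0.05)
    best = None
    for m in grid:
        widths = widths_for_multiplier(float(m), base)
        cfg = NetworkConfig(stage_widths=widths, **config_kwargs)
        p = count_params(build_network(cfg, seed=0))
        err = abs(p - target_params)
        if best is None or err < best[0]:
            best = (err, float(m), widths, p)
    _, m, widths, p = best
    return m, widths, p
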
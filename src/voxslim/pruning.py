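"""Sparsity-regularised progressive channel pruning (network slimming).

Channel importance is the magnitude of the BatchNorm scale ``gamma`` that
follows each stage's pointwise convolution.  At each pruning step a global
nearest-rank-lower quantile ``tau`` of the pooled |gamma| over all currently
surviving, unprotected channels is computed, and channels with ``|gamma| <
tau`` (strict) are masked: their BN gamma/beta, the consumer block's depthwise
kernel and depthwise-BN entries, and the consumer pointwise columns — plus the
producer pointwise row — are zeroed, so the masked forward pass is exactly the
forward pass of the physically compacted model.  Masks are monotone: a pruned
channel never returns.

Protected from pruning: the stem, the classifier head, the LMF gate, and the
LMF fused output channels (they are tied across branches and feed the gate,
so no single gamma ranks them); the LMF *input* follows its upstream stage's
mask.  Each stage always keeps at least one channel.

The schedule prunes every ``interval_epochs`` epochs at ``ratio_per_step`` of
the remaining channels, and stops at a parameter-reduction target: within a
step, candidates are masked in increasing |gamma| order and the step ends as
soon as the (masked-equivalent) parameter count reaches
``(1 - target_total_fraction) * original``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .blocks import VoxNet
from .complexity import count_params


@dataclass
class PruneSchedule:
    interval_epochs: int = 5
    ratio_per_step: float = 0.05
    #: stop once this fraction of the original parameter count has been removed
    target_total_fraction: float = 0.47
    protected_layers: frozenset = field(default_factory=frozenset)
    #: pool the quantile globally across layers (network-slimming convention)
    #: or per layer
    global_quantile: bool = True

    def __post_init__(self):
        if not 0 < self.ratio_per_step < 1:
            raise ValueError(f"ratio_per_step must be in (0,1), got {self.ratio_per_step}")
        if not 0 <= self.target_total_fraction < 1:
            raise ValueError(
                f"target_total_fraction must be in [0,1), got {self.target_total_fraction}")
        if self.interval_epochs < 1:
            raise ValueError(f"interval_epochs must be >= 1, got {self.interval_epochs}")
        self.protected_layers = frozenset(self.protected_layers)


@dataclass
class PruneState:
    """Per-stage keep masks plus schedule position."""

    keep_mask: Dict[str, np.ndarray]
    original_params: int
    initial_channels: int
    step_count: int = 0

    @classmethod
    def from_model(cls, model: VoxNet) -> "PruneState":
        masks = {s.name: np.ones(s.c_out, dtype=bool) for s in model.stages}
        total = sum(int(m.size) for m in masks.values())
        return cls(keep_mask=masks, original_params=count_params(model),
                   initial_channels=total)

    @property
    def cumulative_pruned_fraction(self) -> float:
        masked = sum(int((~m).sum()) for m in self.keep_mask.values())
        return masked / self.initial_channels

    def remaining(self, protected: frozenset = frozenset()) -> int:
        return sum(int(m.sum()) for name, m in self.keep_mask.items()
                   if name not in protected)

    def to_jsonable(self) -> dict:
        return {
            "keep_mask": {k: v.astype(int).tolist() for k, v in self.keep_mask.items()},
            "original_params": self.original_params,
            "initial_channels": self.initial_channels,
            "step_count": self.step_count,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "PruneState":
        return cls(keep_mask={k: np.asarray(v, dtype=bool)
                              for k, v in d["keep_mask"].items()},
                   original_params=int(d["original_params"]),
                   initial_channels=int(d["initial_channels"]),
                   step_count=int(d["step_count"]))


def prunable_gammas(model: VoxNet, state: Optional[PruneState] = None,
                    protected: frozenset = frozenset()) -> List[Tuple[str, np.ndarray]]:
    """(stage name, gamma vector) for every prunable BN (post-pointwise)."""
    out = []
    for stage in model.stages:
        if stage.name in protected:
            continue
        bn = stage.ds.layers[4]
        out.append((stage.name, bn.gamma.data))
    return out


def sparsity_penalty(gammas, lam: float) -> float:
    """L1 penalty ``lam * sum |gamma|`` over prunable BN channels.

    ``gammas`` may be a VoxNet (its prunable gammas are collected), or any
    sequence of arrays.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if isinstance(gammas, VoxNet):
        vecs = [g for _, g in prunable_gammas(gammas)]
    else:
        vecs = [np.asarray(g, dtype=np.float64) for g in gammas]
    return float(lam * sum(np.abs(v).sum() for v in vecs))


def add_sparsity_grad(model: VoxNet, lam: float):
    """Accumulate the L1 subgradient ``lam * sign(gamma)`` on prunable BN gammas."""
    for stage in model.stages:
        bn = stage.ds.layers[4]
        bn.gamma.grad += (lam * np.sign(bn.gamma.data)).astype(np.float32)


def compute_threshold(gammas, r: float) -> float:
    """Nearest-rank lower r-quantile of the pooled |gamma|.

    With the pooled magnitudes sorted ascending as ``a[0..m-1]``, the
    threshold is ``a[max(ceil(r*m) - 1, 0)]``; channels strictly below it are
    pruning candidates, so ``r = 0`` prunes nothing and exact ties at the
    threshold are kept.
    """
    if not 0 <= r < 1:
        raise ValueError(f"quantile fraction r must satisfy 0 <= r < 1, got {r}")
    pooled = np.sort(np.abs(np.concatenate([np.ravel(g) for g in gammas])))
    if pooled.size == 0:
        raise ValueError("no unmasked, unprotected channels to rank")
    idx = max(int(np.ceil(r * pooled.size)) - 1, 0)
    return float(pooled[idx])


# ---------------------------------------------------------------------------
# masking machinery
# ---------------------------------------------------------------------------

def _zero_channel(model: VoxNet, stage_idx: int, j: int):
    """Zero everything tied to output channel j of stage ``stage_idx``.

    Producer side: pointwise row j and post-pointwise BN gamma/beta.
    Consumer side (next stage's DS unit, or the stage's own LMF branches):
    depthwise kernel j, depthwise-BN gamma/beta j, pointwise column j.
    """
    stage = model.stages[stage_idx]
    ds = stage.ds
    ds.layers[3].weight.data[j, :] = 0.0          # pointwise row
    bn2 = ds.layers[4]
    bn2.gamma.data[j] = 0.0
    bn2.beta.data[j] = 0.0
    consumers = []
    if stage.lmf is not None:
        consumers = stage.lmf.branches
    elif stage_idx + 1 < len(model.stages):
        consumers = [model.stages[stage_idx + 1].ds]
    for unit in consumers:
        unit.layers[0].weight.data[j] = 0.0       # depthwise kernel j
        unit.layers[1].gamma.data[j] = 0.0        # depthwise BN
        unit.layers[1].beta.data[j] = 0.0
        unit.layers[3].weight.data[:, j] = 0.0    # pointwise column j
    # final stage feeding GAP->fc: the zeroed channel contributes 0 to the
    # head automatically; compaction slices the fc columns.


def apply_masks(model: VoxNet, state: PruneState):
    """Re-zero all masked channels (call after every optimiser update)."""
    for i, stage in enumerate(model.stages):
        mask = state.keep_mask[stage.name]
        for j in np.nonzero(~mask)[0]:
            _zero_channel(model, i, int(j))


def masked_param_count(model: VoxNet, state: PruneState) -> int:
    """Parameter count of the model the current masks compact to."""
    cfg = model.config
    total = cfg.stem_channels * 1 + 2 * cfg.stem_channels  # stem conv + BN
    a = cfg.stem_channels
    for i, stage in enumerate(model.stages):
        b = int(state.keep_mask[stage.name].sum())
        total += a * 27 + 2 * a            # depthwise 3^3 + BN
        total += a * b + 2 * b             # pointwise + BN
        if stage.lmf is not None:
            lmf = stage.lmf
            C = lmf.channels
            for s in lmf.scales:
                total += b * s ** 3 + 2 * b + b * C + 2 * C
            S = len(lmf.scales)
            total += S * C * lmf.gate_hidden + lmf.gate_hidden
            total += lmf.gate_hidden * S + S
            a = C
        else:
            a = b
    total += a * cfg.num_classes + cfg.num_classes  # head
    return int(total)


def prune_step(model: VoxNet, state: PruneState,
               schedule: PruneSchedule) -> PruneState:
    """One progressive pruning step; mutates the model's weights (zeroing).

    Ranks the surviving unprotected channels by |gamma|, computes the
    quantile threshold at ``ratio_per_step`` (globally pooled by default,
    per layer otherwise), and masks candidates in increasing |gamma| order,
    skipping any layer's last surviving channel and stopping early at the
    parameter-reduction target.  Returns the updated state (same object).
    """
    target_params = int(round((1.0 - schedule.target_total_fraction)
                              * state.original_params))
    if masked_param_count(model, state) <= target_params:
        return state  # target met: idempotent no-op
    protected = schedule.protected_layers
    stage_index = {s.name: i for i, s in enumerate(model.stages)}
    candidates: List[Tuple[float, str, int]] = []
    if schedule.global_quantile:
        pools = [np.abs(g[state.keep_mask[name]])
                 for name, g in prunable_gammas(model, protected=protected)
                 if state.keep_mask[name].any()]
        tau = compute_threshold(pools, schedule.ratio_per_step)
        for name, g in prunable_gammas(model, protected=protected):
            mask = state.keep_mask[name]
            for j in np.nonzero(mask & (np.abs(g) < tau))[0]:
                candidates.append((float(abs(g[j])), name, int(j)))
    else:
        for name, g in prunable_gammas(model, protected=protected):
            mask = state.keep_mask[name]
            if not mask.any():
                continue
            tau = compute_threshold([np.abs(g[mask])], schedule.ratio_per_step)
            for j in np.nonzero(mask & (np.abs(g) < tau))[0]:
                candidates.append((float(abs(g[j])), name, int(j)))
    candidates.sort()
    for _, name, j in candidates:
        mask = state.keep_mask[name]
        if mask.sum() <= 1:
            continue  # every layer keeps at least one channel
        mask[j] = False
        _zero_channel(model, stage_index[name], j)
        if masked_param_count(model, state) <= target_params:
            break
    state.step_count += 1
    return state


# ---------------------------------------------------------------------------
# physical compaction
# ---------------------------------------------------------------------------

def _slice_bn(dst, src, idx):
    dst.gamma.data = src.gamma.data[idx].copy()
    dst.beta.data = src.beta.data[idx].copy()
    dst.gamma.grad = np.zeros_like(dst.gamma.data)
    dst.beta.grad = np.zeros_like(dst.beta.data)
    dst.running_mean = src.running_mean[idx].copy()
    dst.running_var = src.running_var[idx].copy()
    dst.c = len(idx)


def _slice_unit(dst, src, in_idx, out_idx):
    """Copy a ds_unit's weights restricted to kept input/output channels."""
    dst.layers[0].weight.data = src.layers[0].weight.data[in_idx].copy()
    dst.layers[0].weight.grad = np.zeros_like(dst.layers[0].weight.data)
    _slice_bn(dst.layers[1], src.layers[1], in_idx)
    dst.layers[3].weight.data = src.layers[3].weight.data[out_idx][:, in_idx].copy()
    dst.layers[3].weight.grad = np.zeros_like(dst.layers[3].weight.data)
    _slice_bn(dst.layers[4], src.layers[4], out_idx)


def compact(model: VoxNet, state: PruneState) -> VoxNet:
    """Physically remove masked channels; returns a new, smaller VoxNet.

    The compacted model's forward pass equals the masked model's forward pass
    (eval mode) up to float round-off.  Raises if any mask empties a layer.
    """
    cfg = model.config
    kept: Dict[str, np.ndarray] = {}
    for stage in model.stages:
        idx = np.nonzero(state.keep_mask[stage.name])[0]
        if idx.size == 0:
            raise ValueError(f"mask empties layer {stage.name}")
        kept[stage.name] = idx
    new_widths = tuple(int(kept[s.name].size) for s in model.stages)
    lmf_width = (model.stages[cfg.lmf_position].lmf.channels
                 if model.stages[cfg.lmf_position].lmf is not None else None)
    new_cfg = dataclasses.replace(cfg, stage_widths=new_widths,
                                  lmf_channels=lmf_width, enforce_monotone=False)
    out = VoxNet(new_cfg, seed=0)

    # stem (protected, copied whole)
    out.stem_conv.weight.data = model.stem_conv.weight.data.copy()
    out.stem_conv.weight.grad = np.zeros_like(out.stem_conv.weight.data)
    _slice_bn(out.stem_bn, model.stem_bn, np.arange(cfg.stem_channels))

    in_idx = np.arange(cfg.stem_channels)
    for src_stage, dst_stage in zip(model.stages, out.stages):
        out_idx = kept[src_stage.name]
        _slice_unit(dst_stage.ds, src_stage.ds, in_idx, out_idx)
        if src_stage.lmf is not None:
            all_out = np.arange(src_stage.lmf.channels)
            for src_b, dst_b in zip(src_stage.lmf.branches, dst_stage.lmf.branches):
                _slice_unit(dst_b, src_b, out_idx, all_out)
            for attr in ("gate_fc1", "gate_fc2"):
                src_l, dst_l = getattr(src_stage.lmf, attr), getattr(dst_stage.lmf, attr)
                dst_l.weight.data = src_l.weight.data.copy()
                dst_l.bias.data = src_l.bias.data.copy()
                dst_l.weight.grad = np.zeros_like(dst_l.weight.data)
                dst_l.bias.grad = np.zeros_like(dst_l.bias.data)
            in_idx = all_out
        else:
            in_idx = out_idx

    out.fc.weight.data = model.fc.weight.data[:, in_idx].copy()
    out.fc.bias.data = model.fc.bias.data.copy()
    out.fc.weight.grad = np.zeros_like(out.fc.weight.data)
    out.fc.bias.grad = np.zeros_like(out.fc.bias.data)
    return out
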
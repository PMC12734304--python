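"""Model inspection: occlusion testing over axial slice windows and
per-layer weight-importance summaries.

The occlusion test masks consecutive axial slices (half-open windows,
0-based, inferior to superior) with a fill value and measures the accuracy
drop over a dataset, localising the depth range the classifier relies on.
Layer importance is the mean absolute weight per convolutional layer,
excluding channels removed by pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .blocks import VoxNet
from .phantoms import Volume
from .pruning import PruneState
from .training import evaluate


@dataclass
class OcclusionProfile:
    windows: List[Tuple[int, int]]
    accuracy_per_window: List[float]
    baseline_accuracy: float

    @property
    def drops(self) -> np.ndarray:
        return self.baseline_accuracy - np.asarray(self.accuracy_per_window)

    def max_drop_window(self) -> Tuple[int, int]:
        """The window with the largest accuracy drop (first on ties)."""
        return self.windows[int(np.argmax(self.drops))]


def default_windows(depth: int, window_size: int = 10, stride: int = 10):
    return [(s, min(s + window_size, depth)) for s in range(0, depth, stride)]


def occlusion_profile(model: VoxNet, volumes: Sequence[Volume],
                      window_size: int = 10, stride: int = 10,
                      fill: float = 0.0,
                      windows: Optional[Sequence[Tuple[int, int]]] = None
                      ) -> OcclusionProfile:
    """Accuracy after masking each axial slice window, plus the baseline.

    Volumes are copied before masking (the dataset is left untouched).  An
    empty window reproduces the baseline exactly.  Windows must lie within
    [0, depth].
    """
    depth = volumes[0].data.shape[0]
    if windows is None:
        windows = default_windows(depth, window_size, stride)
    for lo, hi in windows:
        if not (0 <= lo <= hi <= depth):
            raise ValueError(f"window [{lo}, {hi}) outside volume depth {depth}")
    y, pred, _ = evaluate(model, volumes)
    baseline = float((y == pred).mean())
    accs = []
    for lo, hi in windows:
        masked = []
        for v in volumes:
            data = v.data.copy()
            data[lo:hi] = fill
            masked.append(Volume(data=data, spacing=v.spacing, label=v.label,
                                 subject_id=v.subject_id))
        ym, pm, _ = evaluate(model, masked)
        accs.append(float((ym == pm).mean()))
    return OcclusionProfile(windows=[(int(a), int(b)) for a, b in windows],
                            accuracy_per_window=accs, baseline_accuracy=baseline)


@dataclass
class LayerImportance:
    layers: List[Tuple[str, float, int]]  # (name, mean |w|, n_params)

    def as_rows(self):
        return [{"layer": n, "mean_abs_weight": w, "n_params": p}
                for n, w, p in self.layers]


def layer_importance(model: VoxNet, state: Optional[PruneState] = None) -> LayerImportance:
    """Mean absolute kernel weight per conv layer, masked channels excluded.

    For a stage's pointwise conv, pruning masks its output rows (own mask)
    and input columns (upstream mask); for a depthwise conv, the upstream
    mask removes whole kernels.  With no prune state, all weights count.
    """
    masks = state.keep_mask if state is not None else {}
    upstream = {}  # conv name -> bool mask over input channels
    own = {}       # conv name -> bool mask over output channels
    prev = None    # upstream stage name (None = stem, protected)
    for i, stage in enumerate(model.stages):
        m_in = masks.get(prev) if prev is not None else None
        m_out = masks.get(stage.name)
        upstream[f"stage{i}.dw"] = m_in
        own[f"stage{i}.dw"] = m_in  # depthwise: channels in == out
        upstream[f"stage{i}.pw"] = m_in
        own[f"stage{i}.pw"] = m_out
        if stage.lmf is not None:
            for s in stage.lmf.scales:
                upstream[f"stage{i}.lmf.branch{s}.dw"] = m_out
                own[f"stage{i}.lmf.branch{s}.dw"] = m_out
                upstream[f"stage{i}.lmf.branch{s}.pw"] = m_out
                own[f"stage{i}.lmf.branch{s}.pw"] = None  # fused output protected
            prev = None  # LMF output is full width again
        else:
            prev = stage.name
    rows = []
    for name, conv in model.conv_layers():
        w = conv.weight.data
        sel = np.ones(w.shape, dtype=bool)
        mo = own.get(name)
        if mo is not None:
            sel &= mo[:, None, None, None, None]
        mi = upstream.get(name)
        if mi is not None and conv.groups == 1 and w.shape[1] == mi.size:
            sel &= mi[None, :, None, None, None]
        vals = np.abs(w[sel])
        rows.append((name, float(vals.mean()) if vals.size else 0.0, int(vals.size)))
    return LayerImportance(layers=rows)
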
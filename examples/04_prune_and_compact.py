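"""Progressive BN-gamma pruning and physical compaction.

Randomises the BN channel scales (standing in for post-training dispersion),
runs quantile-threshold pruning steps to the default parameter-reduction
target, compacts, and verifies the masked and compacted models agree."""

import numpy as np

from voxslim import (NetworkConfig, PruneSchedule, PruneState, build_network,
                     compact, count_params, masked_param_count, prune_step)

rng = np.random.default_rng(0)
cfg = NetworkConfig(stem_channels=8, stage_widths=(16, 32, 48), lmf_position=1,
                    ils_positions=(1,), dilation_rates=(2,))
model = build_network(cfg, seed=0)
for stage in model.stages:  # emulate trained gamma spread
    bn = stage.ds.layers[4]
    bn.gamma.data = rng.uniform(0.02, 1.0, bn.c).astype(np.float32)

state = PruneState.from_model(model)
schedule = PruneSchedule(ratio_per_step=0.05, target_total_fraction=0.30)
print(f"start: {state.original_params:,} params, {state.initial_channels} prunable channels")
for step in range(12):
    prune_step(model, state, schedule)
    print(f"  step {state.step_count}: pruned fraction "
          f"{state.cumulative_pruned_fraction:.3f}, "
          f"params {masked_param_count(model, state):,}")

small = compact(model, state)
x = rng.normal(size=(2, 1, 16, 24, 24)).astype(np.float32)
diff = np.abs(model.forward(x) - small.forward(x)).max()
print(f"compacted: {count_params(small):,} params; "
      f"masked-vs-compacted max |diff| = {diff:.2e}")
# The masked model and the physically smaller model are the same function.
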
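"""BN-gamma channel pruning: quantile threshold, progressive steps,
masked/compacted equivalence, schedule arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxslim.blocks import NetworkConfig, build_network
from voxslim.complexity import count_params
from voxslim.pruning import (PruneSchedule, PruneState, compact,
                             compute_threshold, masked_param_count, prune_step,
                             sparsity_penalty)


def randomize_gammas(model, rng, low=0.02, high=1.0):
    """Emulate post-training gamma dispersion (fresh BN gammas are all ones)."""
    for stage in model.stages:
        bn = stage.ds.layers[4]
        bn.gamma.data = rng.uniform(low, high, bn.c).astype(np.float32)


class TestSparsityPenalty:
    def test_zero_gammas_give_zero(self):
        assert sparsity_penalty([np.zeros(5)], lam=1e-4) == 0.0

    def test_direct_sum(self):
        assert sparsity_penalty([np.array([1.0, -1.0])], 1e-4) == pytest.approx(2e-4)

    def test_homogeneous_in_lambda(self, rng):
        g = [rng.normal(size=7), rng.normal(size=3)]
        assert sparsity_penalty(g, 2e-4) == pytest.approx(2 * sparsity_penalty(g, 1e-4))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            sparsity_penalty([np.ones(2)], -1.0)


class TestComputeThreshold:
    def test_nearest_rank_lower_four_elements(self):
        """Pooled {0.05, 0.1, 0.5, 0.9} at r=0.5 -> tau=0.1; only 0.05 falls below."""
        g = [np.array([0.05, 0.1, 0.5, 0.9])]
        tau = compute_threshold(g, 0.5)
        assert tau == 0.1
        assert (np.abs(g[0]) < tau).sum() == 1

    def test_r_zero_prunes_nothing(self, rng):
        g = [np.abs(rng.normal(size=20))]
        tau = compute_threshold(g, 0.0)
        assert tau <= g[0].min()
        assert (g[0] < tau).sum() == 0

    def test_all_equal_ties_are_kept(self):
        g = [np.full(8, 0.3)]
        tau = compute_threshold(g, 0.5)
        assert (g[0] < tau).sum() == 0  # strict inequality keeps ties

    def test_quantile_matches_sorted_rank_oracle(self, rng):
        pooled = np.abs(rng.normal(size=37))
        for r in (0.05, 0.25, 0.5, 0.9):
            tau = compute_threshold([pooled], r)
            srt = np.sort(pooled)
            assert tau == srt[max(int(np.ceil(r * 37)) - 1, 0)]

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold([np.ones(3)], 1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(values=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=40),
           r=st.floats(0, 0.99))
    def test_candidate_fraction_never_exceeds_r(self, values, r):
        """At most ceil(r*m) channels can fall strictly below the threshold."""
        pooled = np.abs(np.asarray(values))
        tau = compute_threshold([pooled], r)
        assert (pooled < tau).sum() <= int(np.ceil(r * pooled.size))
        assert tau in pooled  # the threshold is an observed magnitude


@pytest.fixture
def pruned_setup(tiny_config, rng):
    model = build_network(tiny_config, seed=2)
    randomize_gammas(model, rng)
    state = PruneState.from_model(model)
    schedule = PruneSchedule(ratio_per_step=0.2, target_total_fraction=0.6)
    return model, state, schedule


class TestPruneStep:
    def test_masks_exactly_channels_below_threshold(self, pruned_setup):
        """Eq-style exactness: after a step, keep <=> |gamma| >= tau (while the
        parameter target is not binding and no layer empties)."""
        model, state, _ = pruned_setup
        schedule = PruneSchedule(ratio_per_step=0.1, target_total_fraction=0.9)
        pooled = np.concatenate([np.abs(s.ds.layers[4].gamma.data) for s in model.stages])
        tau = compute_threshold([pooled], 0.1)
        prune_step(model, state, schedule)
        for stage in model.stages:
            g = np.abs(stage.ds.layers[4].gamma.data)
            keep = state.keep_mask[stage.name]
            # masked gammas were zeroed; compare against the pre-step magnitudes
            for j, kept in enumerate(keep):
                if kept:
                    assert g[j] >= tau
                else:
                    assert g[j] == 0.0

    def test_step_prunes_at_most_ratio_of_remaining(self, pruned_setup):
        model, state, _ = pruned_setup
        schedule = PruneSchedule(ratio_per_step=0.05, target_total_fraction=0.9)
        before = state.remaining()
        prune_step(model, state, schedule)
        newly = before - state.remaining()
        assert newly <= int(np.ceil(0.05 * before))

    def test_idempotent_once_target_met(self, pruned_setup):
        model, state, schedule = pruned_setup
        for _ in range(40):
            prune_step(model, state, schedule)
        masks_before = {k: v.copy() for k, v in state.keep_mask.items()}
        steps_before = state.step_count
        prune_step(model, state, schedule)
        assert state.step_count == steps_before
        for k in masks_before:
            np.testing.assert_array_equal(state.keep_mask[k], masks_before[k])

    def test_masks_monotone_nonincreasing(self, pruned_setup):
        model, state, schedule = pruned_setup
        prev = {k: v.copy() for k, v in state.keep_mask.items()}
        for _ in range(4):
            prune_step(model, state, schedule)
            for k, mask in state.keep_mask.items():
                assert not (mask & ~prev[k]).any()  # no resurrection
                prev[k] = mask.copy()

    def test_every_layer_keeps_at_least_one_channel(self, rng):
        cfg = NetworkConfig(stem_channels=2, stage_widths=(2, 4), lmf_position=1,
                            ils_positions=(), dilation_rates=(2,))
        model = build_network(cfg, seed=0)
        randomize_gammas(model, rng)
        state = PruneState.from_model(model)
        schedule = PruneSchedule(ratio_per_step=0.9, target_total_fraction=0.99)
        for _ in range(20):
            prune_step(model, state, schedule)
        for mask in state.keep_mask.values():
            assert mask.sum() >= 1

    def test_protected_layers_untouched(self, pruned_setup):
        model, state, _ = pruned_setup
        schedule = PruneSchedule(ratio_per_step=0.5, target_total_fraction=0.9,
                                 protected_layers=frozenset({"stage0"}))
        for _ in range(5):
            prune_step(model, state, schedule)
        assert state.keep_mask["stage0"].all()

    def test_schedule_arithmetic_geometric_decay(self, rng):
        """After s steps at ratio rho of remaining, the surviving unprotected
        fraction tracks (1 - rho)^s within integer rounding per layer."""
        cfg = NetworkConfig(stem_channels=8, stage_widths=(40, 60, 60), lmf_position=1,
                            ils_positions=(), dilation_rates=(2,))
        model = build_network(cfg, seed=1)
        randomize_gammas(model, rng)
        state = PruneState.from_model(model)
        schedule = PruneSchedule(ratio_per_step=0.1, target_total_fraction=0.95)
        total = state.initial_channels
        for s in range(1, 6):
            prune_step(model, state, schedule)
            want = (1 - 0.1) ** s
            got = state.remaining() / total
            assert abs(got - want) <= (s + len(state.keep_mask)) / total


class TestMaskedEqualsCompacted:
    def test_forward_equivalence_and_param_agreement(self, pruned_setup, rng):
        model, state, schedule = pruned_setup
        for _ in range(3):
            prune_step(model, state, schedule)
        small = compact(model, state)
        assert count_params(small) == masked_param_count(model, state)
        x = rng.normal(size=(2, 1, 12, 16, 16)).astype(np.float32)
        ym = model.forward(x, training=False)
        yc = small.forward(x, training=False)
        np.testing.assert_allclose(yc, ym, rtol=1e-5, atol=1e-6)

    def test_all_ones_mask_is_noop(self, tiny_config, rng):
        model = build_network(tiny_config, seed=4)
        state = PruneState.from_model(model)
        small = compact(model, state)
        assert count_params(small) == count_params(model)
        x = rng.normal(size=(1, 1, 12, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(small.forward(x), model.forward(x),
                                   rtol=1e-5, atol=1e-6)

    def test_monotone_compression_across_steps(self, pruned_setup):
        model, state, schedule = pruned_setup
        counts = [masked_param_count(model, state)]
        for _ in range(5):
            prune_step(model, state, schedule)
            counts.append(masked_param_count(model, state))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_empty_layer_mask_rejected(self, tiny_config):
        model = build_network(tiny_config, seed=0)
        state = PruneState.from_model(model)
        state.keep_mask["stage0"][:] = False
        with pytest.raises(ValueError, match="stage0"):
            compact(model, state)


def test_prune_state_json_round_trip(pruned_setup):
    model, state, schedule = pruned_setup
    prune_step(model, state, schedule)
    again = PruneState.from_jsonable(state.to_jsonable())
    assert again.step_count == state.step_count
    assert again.original_params == state.original_params
    for k in state.keep_mask:
        np.testing.assert_array_equal(again.keep_mask[k], state.keep_mask[k])
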
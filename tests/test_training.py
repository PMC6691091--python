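"""Greedy two-phase training loop and the conventional baseline."""

import math

import numpy as np
import pytest

from memstdp import (
    EncoderConfig,
    LifConfig,
    LifLayerState,
    StdpParams,
    TrainConfig,
    VariationSpec,
    conventional_train_epoch,
    conventional_train_image,
    greedy_train_epoch,
    pixel_error_rates,
    sample_d2d,
    substream,
)
from memstdp.device import apply_update
from memstdp.training import greedy_train_image, stdp_pairings


def fresh(n_in, n_out, seed=0, variation=VariationSpec()):
    syn = sample_d2d(StdpParams(), variation, n_in, n_out, seed)
    state = LifLayerState.create(n_out, LifConfig())
    return syn, state


class TestPairingOracle:
    def test_hand_scheduled_trajectory_matches_pencil_and_paper(self):
        """A 3-input/1-output spike script reproduces the soft-bound weight
        trajectory computed by hand to 1e-9 μS (no variation)."""
        ts = 50.0
        window = 4
        syn, _ = fresh(3, 1, seed=5)
        syn.weights[:, 0] = [30.0, 20.0, 45.0]

        # pattern pre spikes: input2@t1, input0@t2, inputs0,1@t4; post @ t4
        buffer = [(1, np.array([2])), (2, np.array([0])),
                  (3, np.array([], dtype=int)), (4, np.array([0, 1]))]
        events = stdp_pairings(buffer, 4, window, ts)
        assert events == [(2, 150.0), (0, 100.0), (0, 0.0), (1, 0.0)]
        for i, dt in events:
            apply_update(syn, i, 0, dt)
        # background pre spikes: input2 at lag 1, input1 at lag 3
        for i, dt in [(2, -50.0), (1, -150.0)]:
            apply_update(syn, i, 0, dt)

        # independent pencil-and-paper application of the soft-bound rule
        w = [30.0, 20.0, 45.0]
        w[2] += 1.0 * (50 - w[2]) * math.exp(-150 / 150)
        w[0] += 1.0 * (50 - w[0]) * math.exp(-100 / 150)
        w[0] += 1.0 * (50 - w[0]) * math.exp(0.0)
        w[1] += 1.0 * (50 - w[1]) * math.exp(0.0)
        w[2] -= 0.6 * (w[2] - 10) * math.exp(-50 / 150)
        w[1] -= 0.6 * (w[1] - 10) * math.exp(-150 / 150)
        assert np.allclose(syn.weights[:, 0], w, atol=1e-9)
        assert syn.update_counts[:, 0].tolist() == [2, 2, 2]

    def test_pairings_respect_window_and_order(self):
        buffer = [(1, np.array([0])), (5, np.array([1, 0]))]
        # lag 4 falls outside a 4-step window; ties order by input index
        assert stdp_pairings(buffer, 5, 4, 50.0) == [(0, 0.0), (1, 0.0)]


class TestGreedy:
    def test_single_post_spike_guarantee(self, single_pattern):
        images, _ = single_pattern
        syn, state = fresh(100, 1, seed=1)
        rng = substream(2, "encode")
        for img in images[:20]:
            rec = greedy_train_image(img, syn, state, EncoderConfig(),
                                     LifConfig(), TrainConfig(), rng)
            assert rec.post_spikes <= 1
            assert rec.steps_used <= EncoderConfig().pattern_max_steps

    def test_no_fire_path_skips_background(self, single_pattern):
        images, _ = single_pattern
        syn, _ = fresh(100, 1, seed=1)
        state = LifLayerState.create(1, LifConfig())
        state.thresholds[:] = 1e6  # unreachable
        rng = substream(3, "encode")
        rec = greedy_train_image(images[0], syn, state, EncoderConfig(),
                                 LifConfig(), TrainConfig(), rng)
        assert rec.fired is None
        assert rec.n_updates == 0
        assert rec.steps_used == EncoderConfig().pattern_max_steps

    def test_pattern_learning_polarizes_weights(self, single_pattern):
        """Pattern-pixel synapses drift to the ceiling and background-pixel
        synapses to the floor on a noise-free binary pattern."""
        images, target = single_pattern
        syn, state = fresh(100, 1, seed=7)
        greedy_train_epoch(images, syn, state, seed=11)
        pat = target.reshape(-1) > 0
        assert syn.weights[pat, 0].min() > 40.0
        assert syn.weights[~pat, 0].max() < 20.0
        pe, be = pixel_error_rates(syn.weights[:, 0], target)
        assert pe == 0.0 and be == 0.0

    def test_depression_only_hits_background_pixels(self, single_pattern):
        """With a binary pattern the complement is zero on pattern pixels,
        so no depression pairing can touch them: pattern weights never
        decrease across the epoch."""
        images, target = single_pattern
        syn, state = fresh(100, 1, seed=3)
        pat = target.reshape(-1) > 0
        before = syn.weights[pat, 0].copy()
        greedy_train_epoch(images[:10], syn, state, seed=5)
        assert np.all(syn.weights[pat, 0] >= before - 1e-12)

    def test_accounting_identity_and_counts(self, tiny_dataset):
        images, _, _ = tiny_dataset
        images = images[:60]
        syn, state = fresh(images[0].size, 6, seed=2)
        enc = EncoderConfig()
        rec = greedy_train_epoch(images, syn, state, seed=9)
        expected = sum(
            r.steps_used + (enc.background_steps if r.fired is not None else 0)
            for r in rec.images
        )
        assert rec.total_steps == expected
        assert syn.update_counts.max() <= len(images)
        assert int(syn.update_counts.sum()) == sum(r.n_updates for r in rec.images)

    def test_epoch_is_bitwise_reproducible(self, tiny_dataset):
        images, _, _ = tiny_dataset
        runs = []
        for _ in range(2):
            syn, state = fresh(images[0].size, 4, seed=13,
                               variation=VariationSpec(level_c2c=0.3))
            greedy_train_epoch(images[:25], syn, state, seed=21)
            runs.append((syn.weights.copy(), state.thresholds.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestConventional:
    def _silent_image(self):
        # zero phase factor: stimulus exists but never spikes
        return np.full((4, 4), 9.0), EncoderConfig(f_pattern=0.0)

    def test_no_spikes_no_decay_leaves_weights(self):
        img, enc = self._silent_image()
        syn, state = fresh(16, 2, seed=0)
        w0 = syn.weights.copy()
        cfg = TrainConfig(mode="conventional", decay_per_step=0.0)
        conventional_train_image(img, syn, state, enc, LifConfig(), cfg,
                                 substream(0, "encode"))
        assert np.array_equal(syn.weights, w0)

    def test_pure_decay_closed_form(self):
        """k decay steps scale w − w_min by (1 − decay)^k exactly."""
        img, enc = self._silent_image()
        syn, state = fresh(16, 1, seed=4)
        w0 = syn.weights.copy()
        d, k = 1e-3, 210
        cfg = TrainConfig(mode="conventional", decay_per_step=d,
                          conventional_duration_steps=k)
        conventional_train_image(img, syn, state, enc, LifConfig(), cfg,
                                 substream(0, "encode"))
        assert np.allclose(syn.weights, 10.0 + (w0 - 10.0) * (1 - d) ** k)

    def test_multiple_posts_allowed_and_fixed_duration(self, single_pattern):
        images, _ = single_pattern
        syn, state = fresh(100, 1, seed=6)
        cfg = TrainConfig(mode="conventional")
        rec = conventional_train_epoch(images[:10], syn, state, train=cfg,
                                       seed=8)
        assert all(r.steps_used == cfg.conventional_duration_steps
                   for r in rec.images)
        assert max(r.post_spikes for r in rec.images) > 1

    def test_stuck_devices_ignore_decay(self):
        img, enc = self._silent_image()
        syn, state = fresh(16, 1, seed=4,
                           variation=VariationSpec(failure_rate=1.0))
        w0 = syn.weights.copy()
        cfg = TrainConfig(mode="conventional", decay_per_step=0.01)
        conventional_train_image(img, syn, state, enc, LifConfig(), cfg,
                                 substream(0, "encode"))
        assert np.array_equal(syn.weights, w0)
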
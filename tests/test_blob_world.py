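import numpy as np
import pytest

from wormspan.blob_world import (
    BlobState,
    SimConfig,
    default_blank_days,
    init_states,
    online_dataset,
    render_day,
    simulate_sequence,
    step_day,
)
from wormspan.survival_sim import GridSpec

from conftest import count_components


def spread_states(n, config, spacing=None):
    """Blobs on a coarse lattice, guaranteed non-overlapping discs."""
    spacing = spacing or (2 * config.blob_radius + 3)
    size = config.image_size
    states, i = [], 0
    for y in range(spacing, size - spacing, spacing):
        for x in range(spacing, size - spacing, spacing):
            if i >= n:
                return states
            # keep inside the plate disc
            c = size / 2
            r = size / 2 - config.plate_margin
            if (x - c) ** 2 + (y - c) ** 2 <= (r - config.blob_radius) ** 2:
                states.append(BlobState(i, True, (x, y)))
                i += 1
    return states


class TestRenderDay:
    def test_no_blobs_gives_constant_frame(self, clean_sim_config):
        frame = render_day([], clean_sim_config)
        assert frame.dtype == np.uint8
        assert np.all(frame == clean_sim_config.background_intensity)

    def test_single_blob_single_component(self, clean_sim_config):
        frame = render_day([BlobState(0, True, (32, 32))], clean_sim_config)
        assert count_components(frame) == 1
        assert frame[32, 32] == clean_sim_config.blob_intensity

    def test_separated_blobs_give_two_components(self, clean_sim_config):
        states = [BlobState(0, True, (20, 20)), BlobState(1, True, (44, 44))]
        assert count_components(render_day(states, clean_sim_config)) == 2

    def test_occluded_blob_not_drawn(self, clean_sim_config):
        states = [BlobState(0, True, (32, 32), occluded=True)]
        frame = render_day(states, clean_sim_config)
        assert np.all(frame == clean_sim_config.background_intensity)

    def test_out_of_frame_position_rejected(self, clean_sim_config):
        with pytest.raises(ValueError):
            render_day([BlobState(0, True, (999, 10))], clean_sim_config)


class TestStepDay:
    def test_no_deaths_resamples_alive_keeps_dead(self, clean_sim_config, rng):
        states = spread_states(6, clean_sim_config)
        states[0] = BlobState(0, False, states[0].last_position)
        dead_pos = states[0].last_position
        out = step_day(states, target_alive=5, rng=rng, config=clean_sim_config)
        assert sum(s.alive for s in out) == 5
        assert out[0].last_position == dead_pos and not out[0].alive

    def test_extinction_freezes_world(self, clean_sim_config, rng):
        states = init_states(5, rng, clean_sim_config)
        out = step_day(states, 0, rng, clean_sim_config)
        frame1 = render_day(out, clean_sim_config)
        out2 = step_day(out, 0, rng, clean_sim_config)
        frame2 = render_day(out2, clean_sim_config)
        np.testing.assert_array_equal(frame1, frame2)

    def test_target_above_alive_count_rejected(self, clean_sim_config, rng):
        states = init_states(3, rng, clean_sim_config)
        with pytest.raises(ValueError):
            step_day(states, 4, rng, clean_sim_config)

    def test_occlusion_rate_matches_probability(self):
        config = SimConfig(image_size=64, seq_length=10, plate_margin=5,
                           occlusion_prob=0.1)
        rng = np.random.default_rng(7)
        states = init_states(10, rng, config)
        occluded = total = 0
        for _ in range(500):
            states = step_day(states, sum(s.alive for s in states), rng, config)
            occluded += sum(s.occluded for s in states)
            total += len(states)
        assert occluded / total == pytest.approx(0.1, abs=0.03)


class TestSimulateSequence:
    def test_conservation_of_component_count(self):
        # with occlusion off every blob (alive or dead) is drawn, so a frame
        # shows exactly n_objects components whenever no two discs touch
        config = SimConfig(image_size=128, seq_length=8, plate_margin=8,
                           blob_radius=2, occlusion_prob=0.0,
                           blank_day_schedule=frozenset(), max_rotation=0.0,
                           max_translation=0.0, perturb_magnitude=0.0)
        rng = np.random.default_rng(17)
        states = init_states(12, rng, config)
        checked = 0
        for day in range(40):
            states = step_day(states, sum(s.alive for s in states), rng, config)
            pos = np.array([s.last_position for s in states], dtype=float)
            dists = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(dists, np.inf)
            frame = render_day(states, config)
            if dists.min() > 2 * config.blob_radius + 2:  # discs disjoint
                assert count_components(frame) == 12
                checked += 1
            else:
                assert count_components(frame) <= 12
        assert checked >= 10

    def test_labels_monotone_on_capture_days(self, tiny_sim_config):
        for seed in range(20):
            sample = simulate_sequence((12, 6, 5), tiny_sim_config,
                                       np.random.default_rng(seed))
            blanks = tiny_sim_config.blank_days
            capture = [l for d, l in enumerate(sample.labels, start=1)
                       if d not in blanks]
            assert np.all(np.diff(capture) <= 0)
            # blank days repeat the previous day's label
            for d in sorted(blanks):
                if d > 1 and d <= len(sample.labels):
                    assert sample.labels[d - 1] == sample.labels[d - 2]

    def test_blank_days_are_background_only(self, tiny_sim_config, rng):
        sample = simulate_sequence((12, 6, 5), tiny_sim_config, rng)
        for d in sorted(tiny_sim_config.blank_days):
            frame = sample.images[d - 1]
            if sample.labels[d - 1] > 0:  # not in the padded tail
                assert np.all(frame == tiny_sim_config.background_intensity)

    def test_padding_replicates_last_frame_with_zero_labels(self):
        config = SimConfig(image_size=64, seq_length=12, plate_margin=5,
                           blank_day_schedule=frozenset())
        # mean life 2 with steep slope: population collapses early
        sample = simulate_sequence((10, 2, 8), config, np.random.default_rng(3))
        zeros = np.flatnonzero(sample.labels == 0)
        assert zeros.size >= 2
        last_real = zeros[0]
        for d in range(last_real + 1, config.seq_length):
            np.testing.assert_array_equal(sample.images[d], sample.images[last_real])
            assert sample.labels[d] == 0

    def test_dead_blob_persistence_across_full_sequence(self):
        config = SimConfig(image_size=64, seq_length=10, plate_margin=5,
                           occlusion_prob=0.0, blank_day_schedule=frozenset(),
                           max_rotation=0.0, max_translation=0.0)
        sample = simulate_sequence((10, 3, 6), config, np.random.default_rng(11))
        # once extinct, consecutive frames are identical
        dead_days = np.flatnonzero(sample.labels == 0)
        for a, b in zip(dead_days[:-1], dead_days[1:]):
            np.testing.assert_array_equal(sample.images[a], sample.images[b])

    def test_bit_reproducibility(self, tiny_sim_config):
        s1 = simulate_sequence((12, 6, 5), tiny_sim_config, np.random.default_rng(42))
        s2 = simulate_sequence((12, 6, 5), tiny_sim_config, np.random.default_rng(42))
        np.testing.assert_array_equal(s1.images, s2.images)
        np.testing.assert_array_equal(s1.labels, s2.labels)


class TestOnlineDataset:
    def test_same_seed_identical_streams(self, tiny_grid, tiny_sim_config):
        a = online_dataset(tiny_grid, tiny_sim_config, seed=5)
        b = online_dataset(tiny_grid, tiny_sim_config, seed=5)
        for _ in range(10):
            sa, sb = next(a), next(b)
            np.testing.assert_array_equal(sa.images, sb.images)
            np.testing.assert_array_equal(sa.labels, sb.labels)

    def test_fresh_randomness_on_each_grid_pass(self, tiny_grid, tiny_sim_config):
        stream = online_dataset(tiny_grid, tiny_sim_config, seed=5)
        first, second = next(stream), next(stream)  # singleton grid: same triple
        assert first.meta["triple"] == second.meta["triple"]
        assert not np.array_equal(first.images, second.images)

    def test_full_pass_covers_grid_once(self, tiny_sim_config):
        grid = GridSpec((10, 11), (5, 6), (4, 5))
        stream = online_dataset(grid, tiny_sim_config, seed=0)
        triples = [next(stream).meta["triple"] for _ in range(8)]
        assert len(set(triples)) == 8


def test_default_blank_schedule_is_weekly():
    assert default_blank_days(14) == frozenset({6, 7, 13, 14})
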
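import dataclasses
import math

import numpy as np
import pytest

from onsnn import NetworkConfig, NetworkState, process_sample, run_batch, run_online


def test_published_defaults():
    """The default config reproduces the published hyperparameter table."""
    c = NetworkConfig()
    assert (c.f, c.v_thresh, c.v_rest, c.R, c.C) == (0.7, 0.05, 0.0, 1.0, 10.0)
    assert (c.A_plus, c.A_minus, c.tau_pos, c.tau_neg) == (0.001, 0.001, 10.0, 10.0)
    assert (c.w_max, c.w_min) == (0.5, -0.5)
    assert (c.theta_pos, c.theta_neg) == (0.001, 0.000001)
    assert c.sp_thresh == 1
    assert (c.alpha, c.mod, c.d) == (1.0, 0.8, 0.001)
    assert c.n_init_samples == 15 and c.train_fraction == 0.70


def test_toml_roundtrip(tmp_path):
    path = tmp_path / "cfg.toml"
    path.write_text("f = 0.9\nn_hidden = 33\nstructural_plasticity = false\n")
    c = NetworkConfig.from_toml(path)
    assert c.f == 0.9 and c.n_hidden == 33 and not c.structural_plasticity
    assert c.mod == 0.8  # untouched defaults stay at the table values
    with pytest.raises(ValueError):
        (tmp_path / "bad.toml").write_text("bogus_key = 1\n")
        NetworkConfig.from_toml(tmp_path / "bad.toml")


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(train_fraction=1.0)
    with pytest.raises(ValueError):
        NetworkConfig(mode="streaming")


class TestProcessSample:
    def test_unknown_label_rejected(self, small_stream, small_config):
        state = NetworkState.initialize(("x", "y"), 4, small_config)
        with pytest.raises(ValueError):
            process_sample(state, small_stream[0])

    def test_initiation_evolves_neuron_per_sample(self, small_stream, small_config):
        cfg = dataclasses.replace(small_config, n_init_samples=6)
        state = NetworkState.initialize(
            ("neutral", "positive", "stress"), 4, cfg)
        for s in small_stream[:6]:
            process_sample(state, s)
        assert len(state.repo) == 6
        assert all(n.is_initiation for n in state.repo.neurons)
        assert state.initiation_snapshot is not None
        assert len(state.initiation_snapshot) == 6

    def test_training_only_on_errors(self, small_stream, small_config):
        """After initiation a correct prediction leaves the repository and
        thresholds structurally unchanged; an error grows the repository."""
        cfg = dataclasses.replace(small_config, n_init_samples=4)
        state = NetworkState.initialize(
            ("neutral", "positive", "stress"), 4, cfg)
        for s in small_stream[:4]:
            process_sample(state, s)
        for s in small_stream[4:]:
            size_before = len(state.repo)
            elim_ids = {n.neuron_id for n in state.repo.neurons}
            out = process_sample(state, s)
            if out.correct:
                assert len(state.repo) == size_before
                assert {n.neuron_id for n in state.repo.neurons} == elim_ids
                assert out.pruned_count == 0
            else:
                grown = len(state.repo) - size_before
                assert grown == 1 - out.eliminated_count


class TestRunOnline:
    def test_no_sp_baseline_one_neuron_per_sample(self, small_stream, small_config):
        cfg = dataclasses.replace(small_config, structural_plasticity=False)
        result = run_online(small_stream, cfg)
        assert result.final_repo_size == len(small_stream)

    def test_sp_repo_bounded_by_initiation_plus_errors(self, small_stream, small_config):
        result = run_online(small_stream, small_config)
        errors = int((~np.array(result.trace.correctness)).sum())
        assert result.final_repo_size <= small_config.n_init_samples + errors

    def test_scoring_starts_at_second_sample(self, small_stream, small_config):
        result = run_online(small_stream, small_config)
        assert len(result.trace.correctness) == len(small_stream) - 1

    def test_bit_identical_replay(self, small_stream, small_config):
        a = run_online(small_stream, small_config)
        b = run_online(small_stream, small_config)
        assert a.outcomes.equals(b.outcomes)
        assert a.trace.acc_pre == b.trace.acc_pre
        assert a.spikes_generated == b.spikes_generated

    def test_ablation_differs_only_through_structural_events(self, small_stream, small_config):
        on = run_online(small_stream, small_config)
        off = run_online(small_stream,
                         dataclasses.replace(small_config,
                                             structural_plasticity=False))
        # identical behaviour while both modes evolve a neuron per sample
        k = small_config.n_init_samples - 1
        assert on.trace.correctness[:k] == off.trace.correctness[:k]

    def test_empty_stream_rejected(self, small_config):
        with pytest.raises(ValueError):
            run_online([], small_config)


class TestRunBatch:
    def test_split_sizes(self, small_stream, small_config):
        result = run_batch(small_stream, small_config)
        n_train = math.floor(0.70 * len(small_stream))
        assert result.final_repo_size == n_train
        assert len(result.trace.correctness) == len(small_stream) - n_train

    def test_frozen_model_is_repeatable(self, small_stream, small_config):
        a = run_batch(small_stream, small_config)
        b = run_batch(small_stream, small_config)
        assert list(a.outcomes.predicted_label) == list(b.outcomes.predicted_label)

    def test_degenerate_split_rejected(self, small_stream, small_config):
        # floor(0.3 * 2) = 0 training samples
        with pytest.raises(ValueError):
            run_batch(small_stream[:2],
                      dataclasses.replace(small_config, train_fraction=0.3))


def test_single_pass_memory_is_model_bounded(small_stream, small_config):
    """The state retains no raw segments after processing."""
    result, state = run_online(small_stream, small_config, return_state=True)
    assert result.outcomes.shape[0] == len(small_stream)
    for attr in vars(state).values():
        assert not isinstance(attr, list) or all(
            not hasattr(x, "segment") for x in attr)
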
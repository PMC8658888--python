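import math

import numpy as np
import pytest

from crnnqsar.crnn_model import build_cnn, build_crnn, clone_config, forward
from crnnqsar.errors import ConfigurationError
from crnnqsar.evaluation import r_squared
from crnnqsar.training import (EARLY_STOP_THRESHOLDS, EarlyStopState,
                               GRID_DOMAIN, PhasePlan, _grid_configs,
                               early_stop_update, grid_search,
                               select_batch_size, train_single_phase,
                               train_three_phase)


class TestBatchSizeRule:
    @pytest.mark.parametrize("n,expected", [
        (300, 128), (41101, 128), (299, 64), (150, 64), (101, 64),
        (100, 24), (1, 24),
    ])
    def test_boundaries(self, n, expected):
        assert select_batch_size(n) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            select_batch_size(0)


class TestEarlyStopping:
    def _run(self, metrics, threshold=0.005, patience=3):
        state = EarlyStopState(threshold=threshold, patience_limit=patience)
        for m in metrics:
            state = early_stop_update(state, m)
            if state.stopped:
                break
        return state

    def test_monotone_improvement_never_stops(self):
        state = self._run([0.50, 0.60, 0.70])
        assert not state.stopped and state.best_metric == 0.70

    def test_stops_at_third_qualifying_decrease(self):
        # three values each more than 0.005 below the best (0.70)
        state = self._run([0.70, 0.60, 0.60, 0.60])
        assert state.stopped and state.decrease_count == 3

    def test_new_best_resets_counter(self):
        state = self._run([0.70, 0.60, 0.75, 0.60, 0.60])
        assert not state.stopped and state.decrease_count == 2
        assert state.best_metric == 0.75

    def test_small_dips_within_threshold_ignored(self):
        state = self._run([0.70, 0.697, 0.698, 0.696, 0.699])
        assert state.decrease_count == 0

    def test_thresholds_offered(self):
        assert EARLY_STOP_THRESHOLDS == (0.005, 0.01)

    def test_non_finite_metric_rejected(self):
        with pytest.raises(ValueError):
            early_stop_update(EarlyStopState(), math.nan)


class TestFreezeContract:
    def _train(self, state, groups, data, config, epochs=2):
        return train_single_phase(state, groups, data, config,
                                  max_epochs=epochs, seed=0, batch_size=16)

    def test_gru_frozen_in_phase_one(self, tiny_config, tiny_regression_data):
        state = build_crnn(tiny_config, seed=0)
        before = state.group_snapshot("gru")
        self._train(state, {"conv", "dense"}, tiny_regression_data, tiny_config)
        after = state.group_snapshot("gru")
        for name in before:
            np.testing.assert_array_equal(before[name], after[name])
        # and the trained groups did move
        assert any(not np.array_equal(state.group_snapshot("conv")[n], v)
                   for n, v in build_crnn(tiny_config, 0).group_snapshot("conv").items())

    def test_conv_and_dense_frozen_in_phase_two(self, tiny_config,
                                                tiny_regression_data):
        state = build_crnn(tiny_config, seed=0)
        before = {g: state.group_snapshot(g) for g in ("conv", "dense")}
        self._train(state, {"gru"}, tiny_regression_data, tiny_config)
        for g, snap in before.items():
            for name, v in snap.items():
                np.testing.assert_array_equal(v, state.group_snapshot(g)[name])

    def test_zero_learning_rate_changes_nothing(self, tiny_config,
                                                tiny_regression_data):
        cfg = clone_config(tiny_config, lr_conv=0.0, lr_gru=0.0, lr_dense=0.0)
        state = build_crnn(cfg, seed=0)
        before = {n: p.data.copy() for n, p in state.model.store.params.items()}
        self._train(state, {"conv", "gru", "dense"}, tiny_regression_data, cfg,
                    epochs=1)
        for name, v in before.items():
            np.testing.assert_array_equal(v, state.model.store.params[name].data)

    def test_empty_group_set_rejected(self, tiny_config, tiny_regression_data):
        state = build_crnn(tiny_config, seed=0)
        with pytest.raises(ConfigurationError):
            self._train(state, set(), tiny_regression_data, tiny_config)


class TestThreePhase:
    def test_history_shows_three_phases(self, tiny_config, tiny_regression_data):
        X, y = tiny_regression_data
        plan = PhasePlan(phases=[(frozenset({"conv", "dense"}), 2),
                                 (frozenset({"gru"}), 2),
                                 (frozenset({"conv", "gru", "dense"}), 2)])
        state = build_crnn(tiny_config, seed=0)
        _, history = train_three_phase(state, (X[:32], y[:32]), (X[32:], y[32:]),
                                       tiny_config, plan=plan, seed=0)
        assert sorted({h["phase"] for h in history}) == [0, 1, 2]

    def test_training_is_reproducible(self, tiny_config, tiny_regression_data):
        X, y = tiny_regression_data
        plan = PhasePlan(phases=[(frozenset({"conv", "gru", "dense"}), 2)])
        runs = []
        for _ in range(2):
            state = build_crnn(tiny_config, seed=3)
            state, history = train_three_phase(state, (X[:32], y[:32]),
                                               (X[32:], y[32:]), tiny_config,
                                               plan=plan, seed=3)
            runs.append((history, {n: p.data.copy()
                                   for n, p in state.model.store.params.items()}))
        assert runs[0][0] == runs[1][0]
        for name in runs[0][1]:
            np.testing.assert_array_equal(runs[0][1][name], runs[1][1][name])


class TestCapacity:
    def test_crnn_memorises_random_labels(self, tiny_config):
        """Exercisability: the model can drive a 32-sample random-label
        regression task to near-perfect training fit."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((32, 32))
        y = rng.standard_normal(32)
        cfg = clone_config(tiny_config, lr_conv=0.003, lr_gru=0.003,
                           lr_dense=0.003)
        state = build_crnn(cfg, seed=0)
        plan = PhasePlan(phases=[(frozenset({"conv", "gru", "dense"}), 500)])
        best = -np.inf
        state, _ = train_three_phase(state, (X, y), None, cfg, plan=plan, seed=0)
        best = r_squared(y, forward(state, X))
        assert best > 0.95


class TestGridSearch:
    def test_full_grid_cardinality(self):
        from crnnqsar.crnn_model import CRNNConfig

        grid = {k: list(v) for k, v in GRID_DOMAIN.items()}
        configs = list(_grid_configs(grid, CRNNConfig(latent_dim=32)))
        assert len(configs) == 2 * 2 * 3 * 3 * 3 * 2  # == 216

    def test_singleton_grid_returns_that_config(self, tiny_config,
                                                tiny_regression_data):
        X, y = tiny_regression_data
        best = grid_search((X[:32], y[:32]), (X[32:], y[32:]),
                           {"lr_gru": [0.0005]}, tiny_config, seed=0,
                           trainer_kwargs={"plan": PhasePlan.single(
                               {"conv", "gru", "dense"}, 1)})
        assert best.lr_gru == 0.0005

    def test_off_domain_value_warns_not_errors(self, tiny_config,
                                               tiny_regression_data, caplog):
        X, y = tiny_regression_data
        with caplog.at_level("WARNING"):
            grid_search((X[:32], y[:32]), (X[32:], y[32:]),
                        {"lr_gru": [0.123]}, tiny_config, seed=0,
                        trainer_kwargs={"plan": PhasePlan.single(
                            {"conv", "gru", "dense"}, 1)})
        assert "outside the usual domain" in caplog.text

    def test_default_learning_rates_match_defaults(self):
        from crnnqsar.crnn_model import CRNNConfig

        cfg = CRNNConfig()
        assert cfg.lr_conv == 0.0001 and cfg.lr_gru == 0.0005
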
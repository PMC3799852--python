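"""SWLDA stepwise selection, feature extraction and speller classification."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from erpbci.cohort import SpellerSpec, make_cohort
from erpbci.errors import InvalidArgumentError, ModelGenerationFailureError
from erpbci.recording import EpochSet, Event
from erpbci.swlda import (
    LinearDiscriminantModel,
    SWLDAConfig,
    build_feature_vectors,
    classify_symbol,
    features_from_recording,
    simulate_speller_run,
    swlda_train,
)

FS = 256.0


def epochs_from_array(data, targets):
    time = np.arange(data.shape[2]) / FS * 1000.0
    events = [Event(sample=0, code="flash", is_target=bool(t)) for t in targets]
    return EpochSet(data=data, time=time,
                    labels=np.array(["flash"] * data.shape[0]), fs=FS,
                    channel_labels=tuple(f"c{i}" for i in range(data.shape[1])),
                    events=events)


class TestFeatures:
    def test_feature_count_16ch_1s_window(self, rng):
        data = rng.standard_normal((5, 16, 256))
        X, y = build_feature_vectors(epochs_from_array(data, [1, 0, 1, 0, 0]))
        assert X.shape == (5, 16 * 11)  # ceil(256 / 25) = 11 bins
        assert y.tolist() == [1, 0, 1, 0, 0]

    def test_constant_epoch_gives_constant_features(self):
        data = np.full((2, 3, 256), 4.25)
        X, _ = build_feature_vectors(epochs_from_array(data, [1, 0]))
        assert np.allclose(X, 4.25)

    def test_impulse_hits_one_or_two_features(self):
        for pos in (5, 12, 37, 200, 255):
            data = np.zeros((1, 1, 256))
            data[0, 0, pos] = 1.0
            X, _ = build_feature_vectors(epochs_from_array(data, [1]))
            assert 1 <= (np.abs(X) > 1e-12).sum() <= 2, pos

    def test_window_must_be_covered(self, rng):
        data = rng.standard_normal((2, 3, 128))  # only 0..500 ms
        with pytest.raises(InvalidArgumentError):
            build_feature_vectors(epochs_from_array(data, [1, 0]))

    def test_fast_path_matches_epoch_path(self, quiet_participant):
        from erpbci.preprocess import epoch_and_baseline
        from erpbci.simulate import simulate_speller_session
        spec = SpellerSpec(n_selections=2, repetitions_per_selection=3,
                           pause_after_selection_s=1.5)
        rec = simulate_speller_session(quiet_participant, spec, "AB", seed=3)
        cfg = SWLDAConfig()
        epochs = epoch_and_baseline(rec, cfg.window, None)
        X1, y1 = build_feature_vectors(epochs, cfg)
        X2, y2, _, _, _ = features_from_recording(rec, cfg)
        assert np.abs(X1 - X2).max() < 1e-10
        assert np.array_equal(y1, y2)


class TestStepwise:
    def test_informative_feature_recovered(self, rng):
        n = 200
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 100))
        X[:, 37] = y + 0.1 * rng.standard_normal(n)
        model = swlda_train(X, y)
        assert 37 in model.selected
        assert model.weights[model.selected.index(37)] > 0

    def test_final_model_p_values_below_removal_threshold(self, rng):
        n = 300
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 50))
        X[:, 3] = y + 0.5 * rng.standard_normal(n)
        X[:, 4] = y + 0.5 * rng.standard_normal(n)
        cfg = SWLDAConfig()
        model = swlda_train(X, y, cfg)
        # independent check: statsmodels-style OLS p-values on the final set
        design = np.column_stack([np.ones(n), X[:, model.selected]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        dof = n - design.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(design.T @ design)))
        pvals = 2 * sps.t.sf(np.abs(beta / se), dof)
        assert (pvals[1:] < cfg.p_remove).all()

    def test_weights_equal_ols_refit_on_selected_set(self, rng):
        n = 150
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 30))
        X[:, 7] = y + 0.3 * rng.standard_normal(n)
        model = swlda_train(X, y)
        design = np.column_stack([np.ones(n), X[:, model.selected]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r_direct = y - design @ beta
        r_model = y - model.intercept - X[:, model.selected] @ model.weights
        rss_direct = r_direct @ r_direct
        rss_model = r_model @ r_model
        assert abs(rss_model - rss_direct) <= 1e-10 * rss_direct
        assert np.allclose(model.weights, beta[1:], rtol=1e-10)

    def test_selection_log_replays_against_partial_f_oracle(self, rng):
        """Every add/remove decision is reproduced by an independent
        partial-F computation over the logged model states."""
        n = 120
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 10))
        X[:, 1] = y + 0.6 * rng.standard_normal(n)
        X[:, 2] = X[:, 1] + 0.4 * rng.standard_normal(n)  # correlated pair
        cfg = SWLDAConfig(p_enter=0.1, p_remove=0.15, max_features=10)
        model = swlda_train(X, y, cfg)

        def partial_p(sel, j):
            base = np.column_stack([np.ones(n)] + [X[:, k] for k in sel])
            full = np.column_stack([base, X[:, j]])
            rss0 = np.linalg.lstsq(base, y, rcond=None)[1][0]
            bfull, res_full, *_ = np.linalg.lstsq(full, y, rcond=None)
            rss1 = float(res_full[0]) if res_full.size else float(
                ((y - full @ bfull) ** 2).sum())
            df2 = n - full.shape[1]
            f = (rss0 - rss1) / (rss1 / df2)
            return sps.f.sf(f, 1, df2)

        current: list[int] = []
        removed: set[int] = set()
        for _step, action, feat, p in model.selection_log:
            if action == "add":
                cands = [j for j in range(10)
                         if j not in current and j not in removed]
                oracle = {j: partial_p(current, j) for j in cands}
                assert min(oracle, key=oracle.get) == feat
                assert oracle[feat] == pytest.approx(p, rel=1e-6)
                assert p < cfg.p_enter
                current.append(feat)
            elif action == "remove":
                assert p >= cfg.p_remove
                current.remove(feat)
                removed.add(feat)
        assert current == model.selected

    def test_pure_noise_raises_model_generation_failure(self):
        rng = np.random.default_rng(5)
        failures = 0
        for seed in range(12):
            r = np.random.default_rng(seed)
            X = r.standard_normal((50, 3))
            y = np.repeat([0.0, 1.0], 25)
            try:
                model = swlda_train(X, y)
                assert model.selected  # never a silent empty model
            except ModelGenerationFailureError:
                failures += 1
        assert failures > 0

    def test_constant_columns_skipped_with_log(self, rng):
        n = 100
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 5))
        X[:, 2] = 7.0
        X[:, 0] = y
        model = swlda_train(X, y)
        assert 2 not in model.selected
        assert any(a == "skip_constant" and f == 2
                   for _, a, f, _ in model.selection_log)

    def test_max_features_cap(self, rng):
        n = 400
        y = rng.integers(0, 2, n).astype(float)
        X = 0.05 * rng.standard_normal((n, 80)) + y[:, None]
        model = swlda_train(X, y, SWLDAConfig(max_features=5))
        assert len(model.selected) <= 5

    def test_input_validation(self, rng):
        with pytest.raises(InvalidArgumentError):
            swlda_train(rng.standard_normal((10, 3)), np.zeros(10))
        with pytest.raises(InvalidArgumentError):
            swlda_train(rng.standard_normal((2, 3)), np.array([0.0, 1.0]))

    def test_model_json_round_trip(self, rng):
        n = 100
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 10))
        X[:, 4] = y
        model = swlda_train(X, y)
        clone = LinearDiscriminantModel.from_json(model.to_json())
        assert clone.selected == model.selected
        assert np.allclose(clone.weights, model.weights)
        assert clone.config == model.config


class TestClassifySymbol:
    @staticmethod
    def toy_model():
        return LinearDiscriminantModel(selected=[0], weights=np.array([1.0]),
                                       intercept=0.0, selection_log=[])

    def flashes(self, scores, rows, cols):
        X = np.asarray(scores, dtype=float)[:, None]
        return X, np.asarray(rows), np.asarray(cols)

    def test_dominant_stimulus_selected(self):
        rows, cols, scores = [], [], []
        for rep in range(3):
            for r in range(7):
                rows.append(r); cols.append(-1)
                scores.append(1.0 if r == 2 else -1.0)
            for c in range(7):
                rows.append(-1); cols.append(c)
                scores.append(1.0 if c == 5 else -1.0)
        X, r, c = self.flashes(scores, rows, cols)
        assert classify_symbol(self.toy_model(), X, r, c) == (2, 5)

    def test_all_equal_ties_to_lowest_index(self):
        rows = list(range(7)) + [-1] * 7
        cols = [-1] * 7 + list(range(7))
        X, r, c = self.flashes([0.5] * 14, rows, cols)
        assert classify_symbol(self.toy_model(), X, r, c) == (0, 0)

    def test_linearity_over_repetitions(self, rng):
        rows = list(range(7)) + [-1] * 7
        cols = [-1] * 7 + list(range(7))
        scores = rng.standard_normal(14)
        X1, r1, c1 = self.flashes(scores, rows, cols)
        X10, r10, c10 = self.flashes(np.tile(scores, 10), rows * 10, cols * 10)
        assert classify_symbol(self.toy_model(), X1, r1, c1) \
            == classify_symbol(self.toy_model(), X10, r10, c10)

    def test_scale_invariance_of_weights(self, rng):
        rows = list(range(7)) + [-1] * 7
        cols = [-1] * 7 + list(range(7))
        scores = rng.standard_normal(14)
        X, r, c = self.flashes(scores, rows, cols)
        m1 = self.toy_model()
        m2 = LinearDiscriminantModel(selected=[0], weights=np.array([173.5]),
                                     intercept=0.0, selection_log=[])
        assert classify_symbol(m1, X, r, c) == classify_symbol(m2, X, r, c)

    def test_missing_coverage_rejected(self):
        X, r, c = self.flashes([1.0, 1.0], [0, -1], [-1, 3])
        with pytest.raises(InvalidArgumentError):
            classify_symbol(self.toy_model(), X, r, c)


class TestSpellerRun:
    def test_noiseless_high_aptitude_is_error_free(self, quiet_participant,
                                                   small_speller_specs):
        p = dataclasses.replace(quiet_participant, aptitude=1.0)
        train, test = small_speller_specs
        _, errors = simulate_speller_run(p, train, test, seed=4)
        assert errors == 0

    def test_error_count_range_and_determinism(self, noisy_participant,
                                               small_speller_specs):
        train, test = small_speller_specs
        sel_a, err_a = simulate_speller_run(noisy_participant, train, test,
                                            seed=8)
        sel_b, err_b = simulate_speller_run(noisy_participant, train, test,
                                            seed=8)
        assert (sel_a, err_a) == (sel_b, err_b)
        assert 0 <= err_a <= test.n_selections
        assert len(sel_a) == test.n_selections

    def test_errors_decrease_with_aptitude(self, small_speller_specs):
        """Planted aptitude gradient: error counts anti-correlate with
        aptitude across the cohort."""
        train, _ = small_speller_specs
        test = SpellerSpec(n_selections=10, repetitions_per_selection=4,
                           pause_after_selection_s=1.5)
        cohort = make_cohort(12, -0.85, seed=3)
        errs = [simulate_speller_run(p, train, test, seed=50 + i)[1]
                for i, p in enumerate(cohort)]
        rho = sps.spearmanr([p.aptitude for p in cohort], errs).statistic
        assert rho < -0.5
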
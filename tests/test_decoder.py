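import dataclasses
import math

import numpy as np
import pytest

from memdecode.decoder import (
    DecoderConfig,
    base_predict,
    evaluate_nested,
    fit_base_learner,
    fit_bagged_bank,
    fit_ensemble,
    fit_meta_learner,
    load_decoder,
    save_decoder,
)
from memdecode.exceptions import DegenerateFoldError, DimensionError
from memdecode.synthesize import SimConfig, sample_intensities, simulate_trials
from tests.conftest import TINY_DECODER, TINY_SIM


def _toy(n=60, p=8, seed=0, signal=2.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (X[:, 0] * signal + 0.3 * rng.standard_normal(n) > 0).astype(int)
    return X, y


class TestBaseLearner:
    def test_infinite_penalty_gives_prevalence_intercept(self):
        """lambda -> inf: all weights zero, intercept = logit(bag prevalence)."""
        X, y = _toy(seed=1)
        learner = fit_base_learner(X, y, lam=1e6)
        assert not learner.coef.any()
        prev = y.mean()
        assert learner.intercept == pytest.approx(math.log(prev / (1 - prev)), abs=1e-6)

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.standard_normal(50), rng.standard_normal(50)])
        y = (X[:, 0] > 0).astype(int)
        learner = fit_base_learner(X, y, lam=1e-4)
        assert ((base_predict(learner, X) >= 0.5).astype(int) == y).all()

    def test_single_class_bag_rejected(self):
        X, y = _toy()
        with pytest.raises(DegenerateFoldError):
            fit_base_learner(X, y, lam=0.1, bag=np.flatnonzero(y == 1))

    def test_duplicated_columns_leave_prediction_unchanged(self):
        """L1 may split weight arbitrarily between exact duplicates, but the
        prediction function must be (numerically) unchanged."""
        X, y = _toy(seed=3)
        Xdup = np.column_stack([X, X[:, :2]])
        a = fit_base_learner(X, y, lam=0.05)
        b = fit_base_learner(Xdup, y, lam=0.05)
        pa = base_predict(a, X)
        pb = base_predict(b, Xdup)
        assert np.abs(pa - pb).max() < 0.05

    def test_base_predict_matches_direct_dot_product(self):
        X, y = _toy(seed=4)
        learner = fit_base_learner(X, y, lam=0.05)
        expected = 1.0 / (1.0 + np.exp(-(X @ learner.coef + learner.intercept)))
        assert np.abs(base_predict(learner, X) - expected).max() <= 1e-12

    def test_zero_weights_zero_intercept_predicts_half(self):
        X, y = _toy()
        learner = fit_base_learner(X, y, lam=1e6)
        learner.intercept = 0.0
        assert np.allclose(base_predict(learner, X), 0.5)

    def test_adding_mass_on_positive_weight_raises_probability(self):
        X, y = _toy(seed=5)
        learner = fit_base_learner(X, y, lam=0.01)
        j = int(np.argmax(learner.coef))
        assert learner.coef[j] > 0
        X2 = X.copy()
        X2[:, j] += 1.0
        assert (base_predict(learner, X2) > base_predict(learner, X)).all()

    def test_layout_mismatch_rejected(self):
        X, y = _toy()
        learner = fit_base_learner(X, y, lam=0.1)
        with pytest.raises(DimensionError):
            base_predict(learner, X[:, :4])


class TestBaggedBank:
    def test_bank_size_is_ladder_times_replicas(self):
        X, y = _toy(n=40)
        cfg = DecoderConfig(knot_ladder=(3,), n_replicas=1, n_lambda=3, inner_folds=2,
                            tol=1e-6, max_iter=500)
        splits = [(np.arange(0, 20), np.arange(20, 40)), (np.arange(20, 40), np.arange(0, 20))]
        learners, _ = fit_bagged_bank({3: X}, y, cfg, np.random.default_rng(0),
                                      inner_splits=splits)
        assert len(learners) == 1

    def test_identical_seed_identical_bags_and_learners(self):
        X, y = _toy(n=40)
        cfg = DecoderConfig(knot_ladder=(3, 7), n_replicas=3, tol=1e-6, max_iter=500)
        lam = {3: 0.05, 7: 0.05}
        a, _ = fit_bagged_bank({3: X, 7: X}, y, cfg, np.random.default_rng(42), lam_by_m=lam)
        b, _ = fit_bagged_bank({3: X, 7: X}, y, cfg, np.random.default_rng(42), lam_by_m=lam)
        for la, lb in zip(a, b):
            assert np.array_equal(la.training_trial_ids, lb.training_trial_ids)
            assert np.array_equal(la.coef, lb.coef)

    def test_bagging_reduces_prediction_variance(self):
        """Monte-Carlo: variance of the bagged mean prediction on held-out
        data is below the variance of a single learner's prediction."""
        rng = np.random.default_rng(0)
        Xte, yte = _toy(n=30, seed=99)
        single_preds, bagged_preds = [], []
        cfg = DecoderConfig(knot_ladder=(3,), n_replicas=8, tol=1e-6, max_iter=500)
        for s in range(20):
            X, y = _toy(n=50, seed=100 + s, signal=0.8)
            learners, _ = fit_bagged_bank({3: X}, y, cfg, np.random.default_rng(s),
                                          lam_by_m={3: 0.02})
            preds = np.array([base_predict(L, Xte) for L in learners])
            single_preds.append(preds[0])
            bagged_preds.append(preds.mean(axis=0))
        var_single = np.var(np.array(single_preds), axis=0).mean()
        var_bagged = np.var(np.array(bagged_preds), axis=0).mean()
        assert var_bagged <= var_single


class TestMetaLearner:
    def _splits(self, n, k=3):
        idx = np.arange(n)
        return [(np.setdiff1d(idx, idx[i::k]), idx[i::k]) for i in range(k)]

    def test_informative_column_dominates_noise(self):
        rng = np.random.default_rng(1)
        n = 120
        y = rng.integers(0, 2, n)
        good = np.clip(0.85 * y + 0.15 * (1 - y) + 0.03 * rng.standard_normal(n), 0.01, 0.99)
        P = np.column_stack([good] + [rng.uniform(0.2, 0.8, n) for _ in range(6)])
        grid = np.logspace(0, -3, 10)
        meta = fit_meta_learner(P, y, grid, self._splits(n),
                                learner_keys=[(m, 0) for m in range(7)], tol=1e-6, max_iter=500)
        w = np.abs(meta.weights)
        assert w[0] == w.max()
        assert w[0] > 0.5 * w.sum()

    def test_infinite_penalty_gives_intercept_only_meta(self):
        rng = np.random.default_rng(2)
        n = 60
        y = rng.integers(0, 2, n)
        P = rng.uniform(0.1, 0.9, (n, 4))
        grid = np.array([1e6])
        meta = fit_meta_learner(P, y, grid, self._splits(n),
                                learner_keys=[(m, 0) for m in range(4)], tol=1e-6, max_iter=500)
        assert not meta.weights.any()

    def test_identical_base_learners_match_single_learner_prediction(self):
        rng = np.random.default_rng(3)
        n = 100
        y = rng.integers(0, 2, n)
        col = np.clip(0.7 * y + 0.3 * rng.random(n), 0.01, 0.99)
        grid = np.logspace(0, -3, 8)
        P1 = col[:, None]
        P4 = np.tile(col[:, None], (1, 4))
        m1 = fit_meta_learner(P1, y, grid, self._splits(n), [(0, 0)], tol=1e-6, max_iter=500)
        m4 = fit_meta_learner(P4, y, grid, self._splits(n), [(0, r) for r in range(4)],
                              tol=1e-6, max_iter=500)
        p1 = 1 / (1 + np.exp(-(P1 @ m1.weights + m1.intercept)))
        p4 = 1 / (1 + np.exp(-(P4 @ m4.weights + m4.intercept)))
        assert np.abs(p1 - p4).max() < 0.05


class TestFitEnsemble:
    def test_pipeline_determinism(self, tiny_dataset):
        _, tensor, labels = tiny_dataset
        d1 = fit_ensemble(tensor, labels, TINY_DECODER)
        d2 = fit_ensemble(tensor, labels, TINY_DECODER)
        for c in range(5):
            for s1, s2 in zip(d1.category_models[c].folds, d2.category_models[c].folds):
                assert np.array_equal(s1.meta.weights, s2.meta.weights)
                for a, b in zip(s1.base_learners, s2.base_learners):
                    assert np.array_equal(a.coef, b.coef)

    def test_shared_fold_scheme_across_categories(self, tiny_decoder):
        for c in range(1, 5):
            for s0, sc in zip(tiny_decoder.category_models[0].folds,
                              tiny_decoder.category_models[c].folds):
                assert np.array_equal(s0.train_idx, sc.train_idx)
                assert np.array_equal(s0.test_idx, sc.test_idx)

    def test_outer_folds_partition_trials(self, tiny_decoder, tiny_dataset):
        _, tensor, _ = tiny_dataset
        all_test = np.concatenate([te for _, te in tiny_decoder.outer_splits])
        assert len(all_test) == tensor.n_trials
        assert len(np.unique(all_test)) == tensor.n_trials
        for tr, te in tiny_decoder.outer_splits:
            assert not np.intersect1d(tr, te).size

    def test_embedded_signal_decodes_above_chance(self, tiny_decoder, tiny_dataset):
        _, tensor, labels = tiny_dataset
        res = evaluate_nested(tiny_decoder, tensor, labels)
        assert res.mean_mcc > 0.3

    def test_perfectly_separable_patterns_reach_mcc_one(self):
        """Noise-free one-neuron-per-category patterns decode perfectly."""
        import dataclasses as dc

        cfg = SimConfig(n_neurons=5, n_trials=50, fraction_coding_neurons=1.0,
                        temporal_sparseness_target=0.5, seed=21)
        base = sample_intensities(cfg)
        fixed = []
        for gi in base:
            arr = np.zeros(cfg.n_bins)
            if gi.neuron_id == gi.category_id:
                arr[50:150] = 1.0
            fixed.append(dc.replace(gi, intensity=arr))
        tensor, labels = simulate_trials(fixed, cfg)
        dcfg = dataclasses.replace(TINY_DECODER, knot_ladder=(3,), outer_folds=3)
        dec = fit_ensemble(tensor, labels, dcfg)
        res = evaluate_nested(dec, tensor, labels)
        assert all(v == pytest.approx(1.0) for v in res.pooled_mcc.values())

    def test_anti_labels_flip_mcc_sign(self, tiny_decoder, tiny_dataset):
        from memdecode.spikeio import LabelMatrix

        _, tensor, labels = tiny_dataset
        res = evaluate_nested(tiny_decoder, tensor, labels)
        flipped = LabelMatrix(labels=1 - labels.labels, trial_ids=labels.trial_ids)
        res_f = evaluate_nested(tiny_decoder, tensor, flipped)
        for c in range(5):
            assert res_f.pooled_mcc[c] == pytest.approx(-res.pooled_mcc[c], abs=1e-12)

    def test_serialization_round_trip_preserves_predictions(self, tiny_decoder, tiny_dataset, tmp_path):
        _, tensor, labels = tiny_dataset
        path = tmp_path / "decoder.json"
        save_decoder(tiny_decoder, path)
        again = load_decoder(path)
        r1 = evaluate_nested(tiny_decoder, tensor, labels)
        r2 = evaluate_nested(again, tensor, labels)
        assert np.allclose(r1.oof_probabilities, r2.oof_probabilities, equal_nan=True)

    def test_degenerate_category_column_skipped_with_warning(self, tiny_dataset):
        from memdecode.spikeio import LabelMatrix

        _, tensor, labels = tiny_dataset
        lab = labels.labels.copy()
        lab[:, 4] = 0  # category 4 never occurs
        bad = LabelMatrix(labels=lab, trial_ids=labels.trial_ids)
        with pytest.warns(UserWarning, match="degenerate"):
            dec = fit_ensemble(tensor, bad, dataclasses.replace(TINY_DECODER, fit_full_model=False))
        assert dec.category_models[4] is None
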
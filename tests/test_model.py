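"""SVM training, balanced subsampling and repeated cross-validation."""

import numpy as np
import pandas as pd
import pytest

from conftest import window_from_flanks
from sulfsite.model import (
    EnsembleModel,
    ModelConfig,
    balanced_subsample,
    load_model,
    predict,
    predict_probabilities,
    repeated_balanced_cv,
    save_model,
    train,
    train_ensemble,
)
from sulfsite.synthetic_data import MotifSpec, generate_benchmark
from sulfsite.windowing import build_dataset


def _planted_dataset(n=60, seed=3, **kwargs):
    spec = MotifSpec(n_positive=n, n_negative=n, seed=seed, **kwargs)
    proteins, sites = generate_benchmark(spec)
    positives = [
        (r.accession, int(r.position)) for r in sites.itertuples() if r.label == 1
    ]
    return build_dataset(proteins, positives)


def _clouds(n=40, separation=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n, 2)), rng.normal(separation, 1, (n, 2))]
    )
    y = np.repeat([0, 1], n)
    return X, y


class TestTrainPredict:
    def test_separable_clouds_classified_perfectly(self):
        X, y = _clouds()
        # gamma suited to the 2-D toy scale rather than the 280-D default
        clf = train(X[::2], y[::2], ModelConfig(gamma=0.5, seed=0))
        held_out = predict_probabilities(clf, X[1::2])
        assert (((held_out > 0.5).astype(int)) == y[1::2]).all()

    def test_single_class_input_rejected(self):
        X, _ = _clouds()
        with pytest.raises(ValueError, match="each class"):
            train(X, np.zeros(len(X)), ModelConfig())

    def test_inconsistent_dimensions_rejected(self):
        with pytest.raises(ValueError):
            train(np.ones((4, 2)), [0, 1, 0], ModelConfig())

    def test_prediction_dimension_mismatch_rejected(self):
        X, y = _clouds()
        clf = train(X, y, ModelConfig(gamma=0.5))
        with pytest.raises(ValueError, match="dimension"):
            predict_probabilities(clf, np.ones((3, 5)))

    def test_cutoff_rule_is_strictly_greater(self):
        X, y = _clouds()
        clf = train(X, y, ModelConfig(gamma=0.5))
        preds = predict(clf, X, cutoff=0.5)
        for p in preds:
            assert p.call == int(p.probability > 0.5)
        # a probability exactly at the cutoff is a negative call
        at_cutoff = [p for p in preds if p.probability == 0.5]
        assert all(p.call == 0 for p in at_cutoff)

    def test_raising_cutoff_never_creates_positive_calls(self):
        X, y = _clouds()
        clf = train(X, y, ModelConfig(gamma=0.5))
        low = predict(clf, X, cutoff=0.3)
        high = predict(clf, X, cutoff=0.7)
        for lo, hi in zip(low, high):
            assert hi.call <= lo.call

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(gamma=0)
        with pytest.raises(ValueError):
            ModelConfig(cutoff=1.0)


class TestBalancedSubsample:
    def test_keeps_all_positives_and_matches_counts(self):
        ds = _planted_dataset(n=30)
        # drop positives to create imbalance: 10 positive vs 30 negative
        keep = [i for i, y in enumerate(ds.labels) if y == 0][:30]
        keep += [i for i, y in enumerate(ds.labels) if y == 1][:10]
        ds = ds.subset(sorted(keep))
        sub = balanced_subsample(ds, seed=0)
        assert sum(sub.labels) == 10
        assert len(sub) == 20
        assert {w.residues for w in sub.positives} == {
            w.residues for w in ds.positives
        }

    def test_balanced_input_is_returned_whole(self):
        ds = _planted_dataset(n=3)
        sub = balanced_subsample(ds, seed=1)
        assert len(sub) == len(ds)

    def test_deterministic_given_seed(self):
        ds = _planted_dataset(n=25)
        a = balanced_subsample(ds, seed=7)
        b = balanced_subsample(ds, seed=7)
        assert [w.residues for w in a.windows] == [w.residues for w in b.windows]

    def test_different_seeds_draw_different_negatives(self):
        spec = MotifSpec(n_positive=40, n_negative=160, seed=3)
        proteins, sites = generate_benchmark(spec)
        positives = [
            (r.accession, int(r.position)) for r in sites.itertuples() if r.label == 1
        ]
        ds = build_dataset(proteins, positives)
        a = balanced_subsample(ds, seed=1)
        b = balanced_subsample(ds, seed=2)
        assert {w.source_protein for w in a.negatives} != {
            w.source_protein for w in b.negatives
        }

    def test_fewer_negatives_than_positives_is_an_error(self):
        ds = _planted_dataset(n=10)
        only_pos = [i for i, y in enumerate(ds.labels) if y == 1]
        some_neg = [i for i, y in enumerate(ds.labels) if y == 0][:3]
        with pytest.raises(ValueError, match="cannot balance"):
            balanced_subsample(ds.subset(sorted(only_pos + some_neg)), seed=0)


class TestRepeatedBalancedCV:
    def test_bookkeeping_and_determinism(self):
        ds = _planted_dataset(n=40)
        cfg = ModelConfig(seed=11)
        s1 = repeated_balanced_cv(ds, "psaap", cfg, k=4, repeats=3)
        assert len(s1.per_repeat) == 3
        aucs = [r.AUC for r in s1.per_repeat]
        assert s1.mean["AUC"] == pytest.approx(np.mean(aucs))
        assert s1.sd["AUC"] == pytest.approx(np.std(aucs, ddof=1))
        s2 = repeated_balanced_cv(ds, "psaap", cfg, k=4, repeats=3)
        assert s2.mean == s1.mean and s2.sd == s1.sd

    def test_strong_signal_separates_on_one_repeat(self):
        ds = _planted_dataset(n=50)
        s = repeated_balanced_cv(ds, "binary", ModelConfig(seed=0), k=5, repeats=1)
        assert s.mean["AUC"] > 0.8

    def test_k_larger_than_class_size_is_an_error(self):
        ds = _planted_dataset(n=4)
        with pytest.raises(ValueError, match="k="):
            repeated_balanced_cv(ds, "psaap", ModelConfig(), k=6, repeats=1)

    def test_invalid_protocol_parameters(self):
        ds = _planted_dataset(n=10)
        with pytest.raises(ValueError):
            repeated_balanced_cv(ds, "psaap", ModelConfig(), k=1, repeats=1)
        with pytest.raises(ValueError):
            repeated_balanced_cv(ds, "psaap", ModelConfig(), k=2, repeats=0)


class TestLeakageGuard:
    def test_fold_unique_residue_cannot_reach_test_encodings(self):
        """A residue seen only in held-out positives must get zero PSAAP
        propensity from a matrix fitted on the training folds."""
        train_pos = [window_from_flanks("A" * 20) for _ in range(8)]
        test_window = window_from_flanks("W" * 20)  # W absent from training
        from sulfsite.encoders import PsaapEncoder, encode_psaap

        enc = PsaapEncoder().fit(train_pos)
        np.testing.assert_array_equal(
            enc.transform([test_window])[0], np.zeros(20)
        )
        # and encoding the test window leaves the fitted matrix untouched
        before = enc.matrix.values.copy()
        enc.transform([test_window])
        pd.testing.assert_frame_equal(enc.matrix.values, before)


class TestEnsemblePersistence:
    def test_save_load_round_trip_is_bit_exact(self, tmp_path):
        ds = _planted_dataset(n=30)
        model = train_ensemble(ds, "aaindex", ModelConfig(seed=5), n_models=3)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        reloaded = load_model(path)
        assert isinstance(reloaded, EnsembleModel)
        probe = ds.windows[:10]
        p1 = [p.probability for p in model.predict_windows(probe)]
        p2 = [p.probability for p in reloaded.predict_windows(probe)]
        assert p1 == p2

    def test_ensemble_ranks_planted_positives_above_negatives(self):
        ds = _planted_dataset(n=60)
        model = train_ensemble(ds, "binary", ModelConfig(seed=2), n_models=3)
        preds = model.predict_windows(ds.windows)
        pos_mean = np.mean([p.probability for p, y in zip(preds, ds.labels) if y == 1])
        neg_mean = np.mean([p.probability for p, y in zip(preds, ds.labels) if y == 0])
        assert pos_mean > neg_mean

    def test_bad_archive_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "junk.joblib"
        joblib.dump({"format": "other"}, path)
        with pytest.raises(ValueError, match="not a sulfsite model"):
            load_model(path)
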
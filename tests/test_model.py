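"""Cohort splitting, training-set assembly, SVR tuning and prediction."""

import numpy as np
import pandas as pd
import pytest

from rsfcbf.model import (ModelConfig, assemble_training_set, predict_voxelwise,
                          load_model, save_model, split_cohort, tune_and_train)
from rsfcbf.spectral import BandSchema, FeatureMatrix
from rsfcbf.volumes import Volume3D


def _manifest(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "age": rng.normal(50, 15, n).round(1),
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "group": ["control"] * n,
    })


class TestSplitCohort:
    def test_sizes_and_balance_on_large_cohort(self):
        man = _manifest(300)
        split = split_cohort(man, seed=1)
        assert len(split.train_ids) == 200
        assert len(split.test_ids) == 100
        assert not set(split.train_ids) & set(split.test_ids)
        assert set(split.train_ids) | set(split.test_ids) == set(man.subject_id)
        assert split.balance["age_p"] > 0.2
        assert split.balance["sex_p"] > 0.2

    def test_full_training_fraction_skips_balancing(self):
        man = _manifest(10)
        split = split_cohort(man, train_fraction=1.0, seed=0)
        assert len(split.train_ids) == 10 and split.test_ids == []

    def test_same_seed_reproduces_split(self):
        man = _manifest(60, seed=3)
        a = split_cohort(man, seed=42)
        b = split_cohort(man, seed=42)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = split_cohort(man, seed=43)
        assert c.train_ids != a.train_ids  # different stream, different draw


def _feature_matrix(n_vox, seed, grid=(10, 10, 10), subject_id=None):
    rng = np.random.default_rng(seed)
    schema = BandSchema()
    rows = np.abs(rng.normal(size=(n_vox, 57)))
    rows[:, 56] = rng.uniform(0, 1, n_vox)
    flat = rng.choice(np.prod(grid), size=n_vox, replace=False)
    coords = np.column_stack(np.unravel_index(flat, grid))
    return FeatureMatrix(rows, coords, "pva_corrected", schema, grid,
                         subject_id=subject_id)


def _cbf_volume(fm, values):
    data = np.zeros(fm.grid_shape)
    ix = fm.voxel_index
    data[ix[:, 0], ix[:, 1], ix[:, 2]] = values
    return Volume3D.from_array(data)


class TestAssembleTrainingSet:
    def test_exact_per_subject_bookkeeping(self):
        subjects = []
        for i in range(3):
            fm = _feature_matrix(250, seed=i, subject_id=f"s{i}")
            subjects.append((fm, _cbf_volume(fm, np.arange(250, dtype=float))))
        X, y, groups = assemble_training_set(subjects, voxels_per_subject=100, seed=0)
        assert X.shape == (300, 57)
        assert [int((groups == i).sum()) for i in range(3)] == [100, 100, 100]

    def test_small_subject_falls_back_to_all_voxels_with_warning(self):
        fm = _feature_matrix(40, seed=9)
        with pytest.warns(UserWarning, match="using all"):
            X, y, g = assemble_training_set([(fm, _cbf_volume(fm, np.ones(40)))],
                                            voxels_per_subject=100, seed=0)
        assert X.shape[0] == 40

    def test_seeded_determinism(self):
        subs = [(fm := _feature_matrix(300, seed=5), _cbf_volume(fm, np.ones(300)))]
        X1, *_ = assemble_training_set(subs, 50, seed=7)
        X2, *_ = assemble_training_set(subs, 50, seed=7)
        np.testing.assert_array_equal(X1, X2)


class TestTuneAndTrain:
    def test_near_constant_targets_fit_within_epsilon(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 57))
        y = 50.0 + 1e-3 * rng.normal(size=120)
        cfg = ModelConfig(C_grid=(1.0,), gamma_grid=(0.1,), cv_folds=3,
                          voxels_per_subject=120)
        model = tune_and_train(X, y, cfg)
        preds = model.predict(X)
        # epsilon tube of 0.1 standardized units around a flat function
        assert np.abs(preds - 50.0).max() < 2 * 0.1 * y.std() + 1e-2

    def test_recovers_linear_feature_target_mapping(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = rng.normal(size=(n, 57))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 10] + 1.5 * X[:, 56] + 0.1 * rng.normal(size=n)
        cfg = ModelConfig(C_grid=(1.0, 10.0), gamma_grid=(1 / 57, 0.1),
                          cv_folds=5, voxels_per_subject=n)
        model = tune_and_train(X[:1500], y[:1500], cfg)
        pred = model.predict(X[1500:])
        resid = y[1500:] - pred
        r2 = 1 - resid.var() / y[1500:].var()
        assert r2 >= 0.9

    def test_grid_choice_matches_brute_force_cv(self):
        """Selected C must agree with an exhaustive fold-RMSE recomputation."""
        from sklearn.model_selection import KFold
        from sklearn.svm import SVR

        rng = np.random.default_rng(2)
        X = rng.normal(size=(90, 57))
        y = X[:, 0] + 0.3 * rng.normal(size=90)
        cfg = ModelConfig(C_grid=(0.1, 10.0), gamma_grid=(0.05,), cv_folds=3,
                          voxels_per_subject=90, seed=11)
        model = tune_and_train(X, y, cfg)

        Xz = (X - X.mean(0)) / X.std(0)
        yz = (y - y.mean()) / y.std()
        best = None
        for C in (0.1, 10.0):
            rmses = []
            kf = KFold(3, shuffle=True, random_state=11)
            for tr, va in kf.split(Xz):
                s = SVR(kernel="rbf", C=C, gamma=0.05, epsilon=0.1)
                s.fit(Xz[tr], yz[tr])
                rmses.append(np.sqrt(np.mean((s.predict(Xz[va]) - yz[va]) ** 2)))
            m = np.mean(rmses)
            if best is None or m < best[0]:
                best = (m, C)
        assert model.C == best[1]
        assert model.meta["cv_rmse"] == pytest.approx(best[0], rel=1e-9)

    def test_zero_variance_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(60, 57))
        with pytest.raises(ValueError, match="zero variance"):
            tune_and_train(X, np.full(60, 5.0),
                           ModelConfig(C_grid=(1.0,), gamma_grid=(0.1,),
                                       cv_folds=3))

    def test_scalers_use_training_rows_only(self):
        """Appending wild held-out rows must not change the fitted scalers."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 57))
        y = X[:, 0] + 0.1 * rng.normal(size=120)
        cfg = ModelConfig(C_grid=(1.0,), gamma_grid=(0.1,), cv_folds=3)
        m1 = tune_and_train(X, y, cfg)
        test_rows = 1e3 * rng.normal(size=(50, 57))
        m2 = tune_and_train(X, y, cfg)  # identical training data
        _ = m2.predict(test_rows)       # prediction must not touch the scalers
        np.testing.assert_array_equal(m1.x_mean, m2.x_mean)
        np.testing.assert_array_equal(m1.x_scale, m2.x_scale)

    def test_seeded_determinism_of_winner_and_predictions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 57))
        y = X[:, 2] + 0.2 * rng.normal(size=150)
        cfg = ModelConfig(C_grid=(1.0, 10.0), gamma_grid=(0.05, 0.2),
                          cv_folds=3, seed=1)
        a = tune_and_train(X, y, cfg)
        b = tune_and_train(X, y, cfg)
        assert (a.C, a.gamma) == (b.C, b.gamma)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestPredictVoxelwise:
    def _trained(self):
        rng = np.random.default_rng(6)
        fm = _feature_matrix(200, seed=6)
        y = fm.rows[:, 0] * 10 + 40
        cfg = ModelConfig(C_grid=(10.0,), gamma_grid=(0.1,), cv_folds=3)
        model = tune_and_train(fm.rows, y, cfg)
        return model, fm, y

    def test_memorized_rows_interpolate_within_tube(self):
        model, fm, y = self._trained()
        preds = model.predict(fm.rows)
        rmse_std = np.sqrt(np.mean(((preds - y) / y.std()) ** 2))
        assert rmse_std <= 2 * 0.1 + 0.05

    def test_row_permutation_permutes_predictions(self):
        model, fm, _ = self._trained()
        perm = np.random.default_rng(0).permutation(fm.n_voxels)
        p1 = model.predict(fm.rows)
        p2 = model.predict(fm.rows[perm])
        np.testing.assert_allclose(p2, p1[perm], rtol=1e-12)

    def test_mode_mismatch_rejected(self):
        model, fm, _ = self._trained()
        template = Volume3D.from_array(np.zeros(fm.grid_shape))
        vol = predict_voxelwise(model, fm, template)
        ix = fm.voxel_index
        assert np.all(np.isfinite(vol.data[ix[:, 0], ix[:, 1], ix[:, 2]]))
        with pytest.raises(ValueError, match="mode"):
            predict_voxelwise(model, fm.as_original(), template)

    def test_model_roundtrip_through_disk(self, tmp_path):
        model, fm, _ = self._trained()
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(back.predict(fm.rows), model.predict(fm.rows),
                                   rtol=1e-12)
        assert back.mode == model.mode and back.C == model.C
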
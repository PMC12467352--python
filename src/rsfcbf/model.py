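"""RBF-kernel support-vector regression from spectral features to voxel CBF.

The predictor maps each voxel's 57-dimensional feature vector (8 centre band
powers, 48 neighbour band powers, GM occupancy) to its CBF in mL/100g/min.
Features and targets are z-standardized with training-set statistics; the
SVR hyperparameters C and gamma are chosen by cross-validated RMSE over a
grid, with ties broken toward the less complex model (smaller C, then
smaller gamma).  Training voxels are subsampled per subject to keep the
kernel problem tractable.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GroupKFold, KFold
from sklearn.svm import SVR

from .spectral import BandSchema, FeatureMatrix
from .volumes import Volume3D

__all__ = [
    "ModelConfig",
    "CohortSplit",
    "TrainedCBFModel",
    "split_cohort",
    "assemble_training_set",
    "tune_and_train",
    "predict_voxelwise",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Tunable knobs of the CBF predictor.

    ``voxels_per_subject`` caps the per-subject training voxels (uniform
    draw without replacement); kernel SVR on every cortical voxel of every
    subject is intractable, so subsampling is the main practical deviation
    knob.  ``gamma_grid=None`` selects the default grid
    (0.01, 1/n_features, 0.1, 1, 10) on standardized features.
    """

    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] | None = None
    epsilon: float = 0.1  # SVR tube width on standardized targets
    cv_folds: int = 10
    voxels_per_subject: int = 2000
    group_folds_by_subject: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.C_grid) == 0 or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be nonempty and positive")
        if self.gamma_grid is not None and (
                len(self.gamma_grid) == 0 or any(g <= 0 for g in self.gamma_grid)):
            raise ValueError("gamma_grid must be nonempty and positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.voxels_per_subject < 1:
            raise ValueError("voxels_per_subject must be >= 1")

    def resolved_gamma_grid(self, n_features: int) -> tuple[float, ...]:
        if self.gamma_grid is not None:
            return tuple(sorted(self.gamma_grid))
        return tuple(sorted((0.01, 1.0 / n_features, 0.1, 1.0, 10.0)))


@dataclass
class CohortSplit:
    train_ids: list[str]
    test_ids: list[str]
    balance: dict = field(default_factory=dict)


def split_cohort(manifest: pd.DataFrame, train_fraction: float = 2.0 / 3.0,
                 seed: int = 0, max_attempts: int = 1000,
                 balance_p: float = 0.2) -> CohortSplit:
    """Random train/test split balanced on age and sex.

    Splits are redrawn (up to ``max_attempts`` seeded draws) until a
    two-sample t-test on age and a Fisher exact test on sex both give
    p > ``balance_p`` between the halves, so neither demographic differs
    between training and testing subjects.  ``train_fraction=1.0`` puts
    everyone in training and skips the balance check.
    """
    ids = manifest["subject_id"].astype(str).to_numpy()
    n = len(ids)
    if train_fraction >= 1.0:
        return CohortSplit(list(ids), [], {"note": "no test set requested"})
    if n < 6:
        raise ValueError("need at least 6 subjects to split")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 2), n - 2)
    age = manifest["age"].to_numpy(dtype=float)
    is_m = (manifest["sex"].to_numpy() == "M")

    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            age_p = stats.ttest_ind(age[tr], age[te]).pvalue
        if not np.isfinite(age_p):  # zero-variance ages: trivially balanced
            age_p = 1.0
        table = [[int(is_m[tr].sum()), int((~is_m[tr]).sum())],
                 [int(is_m[te].sum()), int((~is_m[te]).sum())]]
        sex_p = stats.fisher_exact(table).pvalue
        if age_p > balance_p and sex_p > balance_p:
            return CohortSplit(
                sorted(ids[tr]), sorted(ids[te]),
                {"age_p": float(age_p), "sex_p": float(sex_p), "attempts": attempt})
    raise RuntimeError(
        f"could not balance the split on age/sex in {max_attempts} attempts")


def assemble_training_set(subjects: list[tuple[FeatureMatrix, Volume3D]],
                          voxels_per_subject: int = 2000,
                          seed: int = 0):
    """Pool a per-subject voxel subsample of (features, CBF target) rows.

    For each subject, ``voxels_per_subject`` in-mask voxels are drawn
    uniformly without replacement (seeded); a subject with fewer voxels
    contributes all of them (with a warning).  Returns ``(X, y, groups)``
    where ``groups`` carries each row's subject index for grouped CV.
    """
    if not subjects:
        raise ValueError("no subjects provided")
    mode = subjects[0][0].mode
    rng = np.random.default_rng(seed)
    xs, ys, gs = [], [], []
    for si, (fm, cbf) in enumerate(subjects):
        if fm.mode != mode:
            raise ValueError("inconsistent feature modes across subjects")
        if fm.grid_shape != cbf.data.shape:
            raise ValueError("feature matrix and CBF map grids differ")
        ix = fm.voxel_index
        targets = cbf.data[ix[:, 0], ix[:, 1], ix[:, 2]]
        n = fm.n_voxels
        if n < voxels_per_subject:
            warnings.warn(
                f"subject {fm.subject_id or si}: only {n} in-mask voxels "
                f"(< {voxels_per_subject} requested); using all")
            take = np.arange(n)
        else:
            take = rng.choice(n, size=voxels_per_subject, replace=False)
        xs.append(fm.rows[take])
        ys.append(targets[take])
        gs.append(np.full(take.size, si))
    return np.vstack(xs), np.concatenate(ys), np.concatenate(gs)


@dataclass
class TrainedCBFModel:
    """Fitted SVR plus the standardization statistics needed to apply it."""

    svr: SVR
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    schema: BandSchema
    mode: str
    C: float
    gamma: float
    epsilon: float
    meta: dict = field(default_factory=dict)

    def predict(self, rows: np.ndarray) -> np.ndarray:
        """Predict CBF (target units) for raw feature rows."""
        z = (np.asarray(rows, dtype=np.float64) - self.x_mean) / self.x_scale
        return self.svr.predict(z) * self.y_scale + self.y_mean


def _standardize_stats(a: np.ndarray):
    mean = a.mean(axis=0)
    scale = a.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def tune_and_train(X: np.ndarray, y: np.ndarray, config: ModelConfig,
                   groups: np.ndarray | None = None,
                   schema: BandSchema | None = None,
                   mode: str = "pva_corrected") -> TrainedCBFModel:
    """Grid-search (C, gamma) by cross-validated RMSE and refit on all rows.

    Standardization statistics are computed from the supplied rows only, so
    held-out data never leaks into the scalers.  Folds are grouped by subject
    when ``groups`` is given and ``config.group_folds_by_subject`` is set,
    preventing a subject's voxels from straddling train and validation folds.
    A grid point whose loss is non-finite in any fold is disqualified; ties
    go to the smaller C, then the smaller gamma.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2D and y 1D with matching row counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in features or targets")
    if X.shape[0] < 10 * config.cv_folds:
        raise ValueError(
            f"need at least {10 * config.cv_folds} rows for {config.cv_folds}-fold tuning")
    if np.std(y) == 0:
        raise ValueError("degenerate target: zero variance")

    x_mean, x_scale = _standardize_stats(X)
    y_mean, y_scale = float(np.mean(y)), float(np.std(y))
    Xz = (X - x_mean) / x_scale
    yz = (y - y_mean) / y_scale

    use_groups = groups is not None and config.group_folds_by_subject \
        and np.unique(groups).size >= config.cv_folds
    if use_groups:
        splitter = GroupKFold(n_splits=config.cv_folds)
        folds = list(splitter.split(Xz, yz, groups=groups))
    else:
        splitter = KFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed % (2 ** 31))
        folds = list(splitter.split(Xz, yz))

    gamma_grid = config.resolved_gamma_grid(X.shape[1])
    best = None  # (rmse, C, gamma)
    cv_results = []
    for C in sorted(config.C_grid):
        for gamma in gamma_grid:
            fold_rmse = []
            ok = True
            for tr, va in folds:
                svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=config.epsilon)
                svr.fit(Xz[tr], yz[tr])
                resid = svr.predict(Xz[va]) - yz[va]
                rmse = float(np.sqrt(np.mean(resid ** 2)))
                if not np.isfinite(rmse):
                    ok = False
                    break
                fold_rmse.append(rmse)
            if not ok:
                continue
            mean_rmse = float(np.mean(fold_rmse))
            cv_results.append({"C": C, "gamma": gamma, "cv_rmse": mean_rmse})
            if best is None or mean_rmse < best[0] - 1e-12:
                best = (mean_rmse, C, gamma)
    if best is None:
        raise RuntimeError("every (C, gamma) grid point was disqualified")

    _, C, gamma = best
    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=config.epsilon)
    svr.fit(Xz, yz)
    meta = {"n_rows": int(X.shape[0]), "cv_folds": config.cv_folds,
            "grouped_folds": bool(use_groups), "seed": config.seed,
            "cv_rmse": best[0], "cv_results": cv_results}
    if groups is not None:
        meta["n_subjects"] = int(np.unique(groups).size)
    return TrainedCBFModel(svr, x_mean, x_scale, y_mean, y_scale,
                           schema or BandSchema(), mode, C, gamma,
                           config.epsilon, meta)


def predict_voxelwise(model: TrainedCBFModel, features: FeatureMatrix,
                      template: Volume3D, background: float = 0.0) -> Volume3D:
    """Apply the model voxel by voxel and scatter predictions into a 3D map."""
    if features.mode != model.mode:
        raise ValueError(
            f"feature mode {features.mode!r} does not match model mode {model.mode!r}")
    if features.schema != model.schema:
        raise ValueError("feature band schema does not match the model's")
    if features.n_features != model.x_mean.shape[0]:
        raise ValueError("feature dimensionality does not match the model")
    preds = model.predict(features.rows)
    if not np.all(np.isfinite(preds)):
        raise RuntimeError("model produced non-finite predictions")
    return features.values_to_volume(preds, template, background=background)


# ---------------------------------------------------------------------------
# Persistence: JSON metadata + pickled SVR state in a model directory.


def save_model(model: TrainedCBFModel, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "mode": model.mode,
        "C": model.C,
        "gamma": model.gamma,
        "epsilon": model.epsilon,
        "schema": {"midpoints_hz": list(model.schema.midpoints_hz),
                   "bin_width_hz": model.schema.bin_width_hz},
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean,
        "y_scale": model.y_scale,
        "meta": model.meta,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    with open(directory / "svr.pkl", "wb") as fh:
        pickle.dump(model.svr, fh)
    return directory


def load_model(directory) -> TrainedCBFModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    with open(directory / "svr.pkl", "rb") as fh:
        svr = pickle.load(fh)
    schema = BandSchema(tuple(meta["schema"]["midpoints_hz"]),
                        meta["schema"]["bin_width_hz"])
    return TrainedCBFModel(
        svr,
        np.asarray(meta["x_mean"]), np.asarray(meta["x_scale"]),
        float(meta["y_mean"]), float(meta["y_scale"]),
        schema, meta["mode"], meta["C"], meta["gamma"], meta["epsilon"],
        meta.get("meta", {}),
    )
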
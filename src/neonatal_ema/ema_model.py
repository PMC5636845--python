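"""Support-vector-regression brain-age model with nested cross-validation.

The maturational age estimate (EMA, in days) is an RBF-kernel SVR over
the 46-feature vector, trained and evaluated under leave-one-infant-out
(LOIO) cross-validation: all recordings of an infant sit in exactly one
outer test fold, so no infant contributes to both training and testing.
Hyperparameters (C, ε, γ) are optimised in an internal 3-fold CV on each
training fold, and an optional complete backward feature-selection path
(46 -> 1, secondary 10-fold CV) picks the subset at minimum MSE.

Feature standardisation (z-score) and missing-value imputation (median)
always use training-fold statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold
from sklearn.svm import SVR

from .features import FEATURE_COLUMNS

__all__ = [
    "ModelConfig",
    "EMAModel",
    "DegenerateFitError",
    "fit_svr",
    "backward_feature_selection",
    "predict_ema",
    "run_loio",
    "recording_level_features",
    "save_model",
    "load_model",
]

#: Reporting range for EMA predictions (days).
EMA_RANGE_DAYS = (140.0, 320.0)


class DegenerateFitError(ValueError):
    """Training target is constant; the regression is undefined."""


class IncompleteVectorError(ValueError):
    """A selected feature is missing (NaN) at prediction time."""


@dataclass
class ModelConfig:
    """Hyperparameter grids and cross-validation geometry.

    The grid brackets days-scale targets: C log-spaced 2^-2..2^6, the
    ε-insensitive margin 0.5-8 days, and γ log-spaced 2^-6..2^2 divided
    by the number of active features (features are z-scored, so distances
    scale with dimension).  During the backward-elimination path each
    candidate subset is scored with the hyperparameters found for the
    full feature set on that training fold (``selection_grid="fixed"``);
    ``"full"`` re-runs the complete grid per subset, at ~400x the cost.
    """

    c_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-2, 7))
    epsilon_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    gamma_scale_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-6, 3))
    inner_folds: int = 3
    selection_folds: int = 10
    selection_grid: str = "fixed"  # "fixed" | "full"
    feature_selection: bool = True
    seed: int = 0
    #: how a recording-level EMA is formed: average the epoch feature
    #: vectors then predict once ("features"), or predict per epoch and
    #: average the predictions ("predictions")
    recording_aggregation: str = "features"


@dataclass
class EMAModel:
    """A fitted EMA regressor for one training fold."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    impute_values: np.ndarray
    svr: SVR
    hyperparameters: dict[str, float]
    fold_id: str = ""
    seed: int = 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        X = np.where(np.isnan(X), self.impute_values, X)
        if np.isnan(X).any():
            raise IncompleteVectorError("feature vector incomplete after imputation")
        return (X - self.mean) / self.sd


def _standardize(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _grid(config: ModelConfig, n_features: int):
    for c in config.c_grid:
        for eps in config.epsilon_grid:
            for g in config.gamma_scale_grid:
                yield {"C": float(c), "epsilon": float(eps),
                       "gamma": float(g / max(1, n_features))}


def _cv_mse(
    X: np.ndarray,
    y: np.ndarray,
    params: dict[str, float],
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean squared error over pre-computed CV splits (standardise per fold)."""
    err = np.empty_like(y)
    for tr, te in splits:
        Xs, mean, sd = _standardize(X[tr])
        svr = SVR(kernel="rbf", **params)
        svr.fit(Xs, y[tr])
        err[te] = svr.predict((X[te] - mean) / sd) - y[te]
    return float(np.mean(err**2))


def _make_splits(
    n: int,
    n_folds: int,
    groups: np.ndarray | None,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (group-aware when possible) K-fold splits."""
    if groups is not None and len(np.unique(groups)) >= n_folds:
        kf = GroupKFold(n_splits=n_folds)
        return [
            (tr, te) for tr, te in kf.split(np.zeros(n), groups=groups)
        ]
    k = min(n_folds, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.zeros(n))]


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    groups: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    fold_id: str = "",
) -> EMAModel:
    """Grid-search an RBF SVR with internal 3-fold CV and refit.

    The grid minimises inner-CV MSE in days²; ties resolve to the first
    combination in canonical grid order.  Standardisation constants and
    imputation medians are computed on the training fold only.
    """
    cfg = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant training target")
    impute = np.nanmedian(X, axis=0)
    impute = np.where(np.isnan(impute), 0.0, impute)
    X = np.where(np.isnan(X), impute, X)

    splits = _make_splits(len(y), cfg.inner_folds, groups, cfg.seed)
    best_params, best_mse = None, np.inf
    for params in _grid(cfg, X.shape[1]):
        mse = _cv_mse(X, y, params, splits)
        if mse < best_mse - 1e-12:
            best_mse, best_params = mse, params
    Xs, mean, sd = _standardize(X)
    svr = SVR(kernel="rbf", **best_params)
    svr.fit(Xs, y)
    names = list(feature_names) if feature_names else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return EMAModel(
        feature_names=names,
        mean=mean,
        sd=sd,
        impute_values=impute,
        svr=svr,
        hyperparameters=best_params,
        fold_id=fold_id,
        seed=cfg.seed,
    )


try:  # low-level binding: identical maths, none of the per-fit validation
    from sklearn.svm import _libsvm as _libsvm_backend
except ImportError:  # pragma: no cover - fallback to the public estimator
    _libsvm_backend = None


def _fit_predict_precomputed(
    K_train: np.ndarray,
    y_train: np.ndarray,
    K_test: np.ndarray,
    params: dict[str, float],
) -> np.ndarray:
    """ε-SVR fit/predict on precomputed kernels (hot path of selection)."""
    if _libsvm_backend is None:
        svr = SVR(kernel="precomputed", C=params["C"], epsilon=params["epsilon"])
        svr.fit(K_train, y_train)
        return svr.predict(K_test)
    fitted = _libsvm_backend.fit(
        np.ascontiguousarray(K_train),
        np.ascontiguousarray(y_train, dtype=np.float64),
        svm_type=3,
        kernel="precomputed",
        C=params["C"],
        epsilon=params["epsilon"],
    )
    return _libsvm_backend.predict(
        np.ascontiguousarray(K_test), *fitted[:7],
        svm_type=3, kernel="precomputed",
    )


class _SubsetScorer:
    """10-fold CV MSE of feature subsets via precomputed RBF kernels.

    The RBF kernel depends on features only through the pairwise squared
    distance, which is additive over features.  Per CV split, the
    standardised per-feature squared-difference matrices are computed
    once; the distance matrix of the current subset is then maintained
    incrementally (removing a feature subtracts its matrix), so scoring
    one candidate removal costs O(n²) plus one precomputed-kernel SVR fit
    per fold instead of a fresh kernel evaluation.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        splits: list[tuple[np.ndarray, np.ndarray]],
    ) -> None:
        self.y = y
        self.splits = splits
        self.feat_sq: list[np.ndarray] = []  # per split: (p, n, n)
        self.dist: list[np.ndarray] = []  # current-subset distances per split
        for tr, _ in splits:
            mean = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xs = (X - mean) / sd
            d = (Xs.T[:, :, None] - Xs.T[:, None, :]) ** 2
            self.feat_sq.append(d)
            self.dist.append(d.sum(axis=0))

    def remove(self, f: int) -> None:
        for d, sq in zip(self.dist, self.feat_sq):
            d -= sq[f]

    def mse(
        self, params: dict[str, float], drop: int | None = None
    ) -> float:
        err = np.empty_like(self.y)
        for (tr, te), dist, sq in zip(self.splits, self.dist, self.feat_sq):
            d = dist if drop is None else dist - sq[drop]
            K = np.exp(-params["gamma"] * np.clip(d, 0.0, None))
            pred = _fit_predict_precomputed(
                K[np.ix_(tr, tr)], self.y[tr], K[np.ix_(te, tr)], params
            )
            err[te] = pred - self.y[te]
        return float(np.mean(err**2))


def backward_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    config: ModelConfig | None = None,
    groups: np.ndarray | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Complete backward-elimination path with 10-fold CV scoring.

    Starting from all features, the feature whose removal yields the
    lowest CV MSE is eliminated at each step until one remains; the
    returned subset is the path point with minimum MSE.  Ties break by
    removing the lower-index feature in canonical roster order.  SVR
    hyperparameters inside the path follow ``config.selection_grid``:
    with the default ``"fixed"`` they are optimised once per training
    fold on the full feature set and reused along the path, which keeps
    the complete-path search tractable; ``"full"`` nests the whole grid
    search inside every subset evaluation.

    Returns ``(selected_names, path)`` where ``path`` records n_features,
    removed feature and CV MSE per step.
    """
    cfg = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    impute = np.nanmedian(X, axis=0)
    impute = np.where(np.isnan(impute), 0.0, impute)
    X = np.where(np.isnan(X), impute, X)
    n, p = X.shape
    splits = _make_splits(n, cfg.selection_folds, groups, cfg.seed)
    scorer = _SubsetScorer(X, y, splits)

    inner = _make_splits(n, cfg.inner_folds, groups, cfg.seed)
    best_params, best_mse = None, np.inf
    for params in _grid(cfg, p):
        mse = _cv_mse(X, y, params, inner)
        if mse < best_mse - 1e-12:
            best_mse, best_params = mse, params
    gamma_total = best_params["gamma"] * p  # rescaled as the subset shrinks

    def subset_params(k: int) -> dict[str, float]:
        out = dict(best_params)
        out["gamma"] = gamma_total / k
        return out

    def tertiary_params(k: int) -> list[dict[str, float]]:
        if cfg.selection_grid == "fixed":
            return [subset_params(k)]
        return list(_grid(cfg, k))

    current = list(range(p))
    records = [
        {
            "n_features": p,
            "removed": None,
            "cv_mse": min(scorer.mse(pr) for pr in tertiary_params(p)),
        }
    ]
    while len(current) > 1:
        k = len(current) - 1
        mses = [
            min(scorer.mse(pr, drop=f) for pr in tertiary_params(k))
            for f in current
        ]
        j = int(np.argmin(mses))  # argmin takes the first (lowest-index) tie
        records.append(
            {
                "n_features": k,
                "removed": feature_names[current[j]],
                "cv_mse": mses[j],
            }
        )
        scorer.remove(current[j])
        del current[j]

    path = pd.DataFrame(records)
    best_step = int(path["cv_mse"].idxmin())
    if path["cv_mse"].min() >= np.var(y) * 0.95:
        warnings.warn(
            "feature selection: CV MSE never clearly beat the target variance; "
            "selection is unstable",
            stacklevel=2,
        )
    # reconstruct the surviving subset at the best step
    surviving = list(range(p))
    for rec in records[1: best_step + 1]:
        surviving.remove(feature_names.index(rec["removed"]))
    selected = [feature_names[i] for i in surviving]
    return selected, path


def predict_ema(model: EMAModel, features) -> np.ndarray:
    """Predict EMA (days) for one or more feature vectors.

    Accepts a DataFrame (columns selected by name), a dict, or an array
    already in the model's feature order.  Predictions outside the
    plausible reporting range are clamped with a warning.
    """
    if isinstance(features, dict):
        X = np.array([[features[f] for f in model.feature_names]], dtype=float)
    elif isinstance(features, pd.DataFrame):
        X = features[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    pred = model.svr.predict(model.transform(X))
    lo, hi = EMA_RANGE_DAYS
    if np.any((pred < lo) | (pred > hi)):
        warnings.warn(
            "EMA prediction outside the plausible range "
            f"[{lo:.0f}, {hi:.0f}] days: clamped",
            stacklevel=2,
        )
        pred = np.clip(pred, lo, hi)
    return pred


def recording_level_features(
    features: pd.DataFrame, feature_columns: list[str] | None = None
) -> pd.DataFrame:
    """Average epoch feature vectors within each recording.

    The per-recording EMA is predicted from the mean feature vector over
    the recording's accepted 1-h epochs (NaN-aware mean: a feature
    missing in some epochs is averaged over the rest).
    """
    cols = list(feature_columns or FEATURE_COLUMNS)
    grouped = features.groupby(
        ["infant_id", "recording_id", "pma_days"], as_index=False, sort=True
    )[cols].mean()
    return grouped


def run_loio(
    features: pd.DataFrame,
    config: ModelConfig | None = None,
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-infant-out cross-validated EMA over a feature table.

    ``features`` has one row per accepted epoch (46 feature columns plus
    ``infant_id``, ``recording_id``, ``pma_days``).  For each outer fold
    one infant is held out; features are selected (optional) and the SVR
    fitted on the remaining infants; each held-out recording receives one
    EMA prediction.

    Returns ``(ema_table, selection_report)``: the EMA table has columns
    ``infant_id, recording_id, pma_days, ema_days`` and the selection
    report one row per (fold, selected feature) for selection-frequency
    summaries.
    """
    cfg = config or ModelConfig()
    cols = list(feature_columns or FEATURE_COLUMNS)
    cols = [c for c in cols if c in features.columns]
    if cfg.recording_aggregation == "features":
        table = recording_level_features(features, cols)
    else:
        table = features
    infants = np.array(sorted(table["infant_id"].unique()))
    if len(infants) < 3:
        raise ValueError("leave-one-infant-out needs at least 3 infants")

    rows = []
    sel_rows = []
    for fold, infant in enumerate(infants):
        train = table[table["infant_id"] != infant]
        test = table[table["infant_id"] == infant]
        if train.empty or test.empty:
            continue
        Xtr = train[cols].to_numpy(dtype=float)
        ytr = train["pma_days"].to_numpy(dtype=float)
        gtr = train["infant_id"].to_numpy()
        fold_cfg = ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        use_cols = cols
        if cfg.feature_selection:
            selected, _ = backward_feature_selection(
                Xtr, ytr, cols, fold_cfg, groups=gtr
            )
            use_cols = selected
            for f in selected:
                sel_rows.append({"fold": str(infant), "feature": f})
        idx = [cols.index(f) for f in use_cols]
        model = fit_svr(
            Xtr[:, idx], ytr, fold_cfg, groups=gtr,
            feature_names=use_cols, fold_id=str(infant),
        )
        pred = predict_ema(model, test[cols].to_numpy(dtype=float)[:, idx])
        if cfg.recording_aggregation == "features":
            for (_, r), p in zip(test.iterrows(), pred):
                rows.append(
                    {"infant_id": r["infant_id"], "recording_id": r["recording_id"],
                     "pma_days": r["pma_days"], "ema_days": float(p)}
                )
        else:
            tmp = test[["infant_id", "recording_id", "pma_days"]].copy()
            tmp["ema_days"] = pred
            agg = tmp.groupby(
                ["infant_id", "recording_id", "pma_days"], as_index=False
            )["ema_days"].mean()
            rows.extend(agg.to_dict("records"))
    ema_table = pd.DataFrame(rows)
    selection = pd.DataFrame(sel_rows, columns=["fold", "feature"])
    return ema_table, selection


def save_model(model: EMAModel, out_dir) -> None:
    """Serialise a fitted model: JSON metadata + joblib regressor blob."""
    import json
    from pathlib import Path

    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "feature_names": model.feature_names,
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "impute_values": model.impute_values.tolist(),
        "hyperparameters": model.hyperparameters,
        "fold_id": model.fold_id,
        "seed": model.seed,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model.svr, out / "svr.joblib")


def load_model(model_dir) -> EMAModel:
    """Load a model saved by :func:`save_model`."""
    import json
    from pathlib import Path

    import joblib

    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    return EMAModel(
        feature_names=meta["feature_names"],
        mean=np.asarray(meta["mean"]),
        sd=np.asarray(meta["sd"]),
        impute_values=np.asarray(meta["impute_values"]),
        svr=joblib.load(d / "svr.joblib"),
        hyperparameters=meta["hyperparameters"],
        fold_id=meta.get("fold_id", ""),
        seed=meta.get("seed", 0),
    )
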
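"""Per-miRNA regressors predicting miRNA expression from mRNA features.

One independent gradient-boosted tree regressor is fitted per target miRNA
(scikit-learn's histogram gradient boosting); evaluation is per-target
Spearman rho plus pooled MSE/MAE/R^2, averaged over seeded k-fold splits.
"""

from __future__ import annotations

import pickle
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from . import __version__
from .types import IntegratedTrainingSet

MODEL_FORMAT = "stmir-model"
MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperparams:
    """Gradient-boosting hyperparameters exposed to the grid search."""

    learning_rate: float = 0.1
    max_depth: int = 5
    n_estimators: int = 300
    extras: tuple = ()  # sorted (key, value) pairs; hashable for dedup

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_depth < 1 or self.n_estimators < 1:
            raise ValueError("max_depth and n_estimators must be >= 1")

    def as_dict(self) -> dict:
        d = {
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "n_estimators": self.n_estimators,
        }
        d.update(dict(self.extras))
        return d


#: Default exhaustive grid over the three named axes.
DEFAULT_GRID: Tuple[Hyperparams, ...] = tuple(
    Hyperparams(lr, d, n)
    for lr in (0.05, 0.1, 0.3)
    for d in (3, 5, 7)
    for n in (100, 300, 500)
)


@dataclass
class MetricsReport:
    """Per-target Spearman rho plus pooled error metrics.

    ``per_fold`` holds one MetricsReport per CV fold; for such reports the
    top-level scalars are the arithmetic means over folds and
    ``per_mirna_spearman`` the per-target mean over folds.
    """

    per_mirna_spearman: pd.Series
    mse: float
    mae: float
    r2: float
    n_constant_obs: int = 0
    per_fold: List["MetricsReport"] = field(default_factory=list)

    @property
    def median_spearman(self) -> float:
        return float(self.per_mirna_spearman.median())


@dataclass
class ModelBundle:
    """Fitted per-target regressors plus everything needed to apply them."""

    per_target_models: Dict[str, object]
    feature_genes: List[str]
    target_mirnas: List[str]
    hyperparams: Hyperparams
    x_scaler: pd.DataFrame
    y_scaler: pd.DataFrame
    training_meta: dict = field(default_factory=dict)

    @property
    def model_id(self) -> str:
        return self.training_meta.get("model_id", "stmir-model")


def _make_booster(hp: Hyperparams, seed: int) -> HistGradientBoostingRegressor:
    return HistGradientBoostingRegressor(
        learning_rate=hp.learning_rate,
        max_depth=hp.max_depth,
        max_iter=hp.n_estimators,
        early_stopping=False,
        random_state=seed,
        **dict(hp.extras),
    )


def train(ts: IntegratedTrainingSet, hp: Hyperparams, seed: int = 0) -> ModelBundle:
    """Fit one boosted-tree regressor per target miRNA column.

    Constant target columns are still fitted (the model learns the constant)
    but flagged in ``training_meta['degenerate_targets']``.
    """
    X = ts.X.to_numpy(dtype=float)
    degenerate = []
    models: Dict[str, object] = {}
    for j, name in enumerate(ts.target_mirnas):
        y = ts.Y.iloc[:, j].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            degenerate.append(name)
        est = _make_booster(hp, seed)
        est.fit(X, y)
        models[name] = est
    meta = {
        "seed": seed,
        "n_samples": ts.n_samples,
        "cohorts": sorted(ts.cohort_of_sample.unique().tolist()),
        "degenerate_targets": degenerate,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "model_id": f"stmir-{seed}-{ts.n_samples}x{len(ts.feature_genes)}",
    }
    return ModelBundle(
        per_target_models=models,
        feature_genes=ts.feature_genes,
        target_mirnas=ts.target_mirnas,
        hyperparams=hp,
        x_scaler=ts.x_scaler,
        y_scaler=ts.y_scaler,
        training_meta=meta,
    )


def predict(model: ModelBundle, X: pd.DataFrame) -> pd.DataFrame:
    """Predict activity for each sample and target; values clipped to [0, 1].

    ``X`` columns must match ``model.feature_genes`` exactly and in order;
    mismatches raise rather than being silently imputed or reordered.
    """
    cols = list(X.columns)
    if cols != model.feature_genes:
        mismatches = []
        expected, got = model.feature_genes, cols
        for i in range(max(len(expected), len(got))):
            e = expected[i] if i < len(expected) else "<missing>"
            g = got[i] if i < len(got) else "<missing>"
            if e != g:
                mismatches.append(f"position {i}: expected {e!r}, got {g!r}")
            if len(mismatches) >= 10:
                break
        raise ValueError(
            "feature columns do not match model.feature_genes:\n  "
            + "\n  ".join(mismatches)
        )
    Xv = X.to_numpy(dtype=float)
    out = np.empty((Xv.shape[0], len(model.target_mirnas)))
    for j, name in enumerate(model.target_mirnas):
        out[:, j] = model.per_target_models[name].predict(Xv)
    out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=X.index, columns=model.target_mirnas)


def spearman_by_column(pred: pd.DataFrame, obs: pd.DataFrame) -> pd.Series:
    """Spearman rho down each column; NaN where the observed column is constant."""
    rhos = np.full(pred.shape[1], np.nan)
    p = pred.to_numpy(dtype=float)
    o = obs.to_numpy(dtype=float)
    for j in range(p.shape[1]):
        if np.ptp(o[:, j]) == 0 or np.ptp(p[:, j]) == 0:
            continue
        rhos[j] = stats.spearmanr(p[:, j], o[:, j]).statistic
    return pd.Series(rhos, index=obs.columns)


def evaluate(pred: pd.DataFrame, obs: pd.DataFrame) -> MetricsReport:
    """Per-target Spearman rho plus MSE/MAE/R^2 pooled over all entries."""
    if pred.shape != obs.shape or list(pred.columns) != list(obs.columns):
        raise ValueError("pred and obs must share shape and column order")
    rho = spearman_by_column(pred, obs)
    p = pred.to_numpy(dtype=float).ravel()
    o = obs.to_numpy(dtype=float).ravel()
    resid = p - o
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    n_const = int((obs.nunique(axis=0) <= 1).sum())
    return MetricsReport(
        per_mirna_spearman=rho, mse=mse, mae=mae, r2=r2, n_constant_obs=n_const
    )


def _cv_folds(n: int, k: int, seed: int):
    return KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))


def _subset(ts: IntegratedTrainingSet, idx: np.ndarray) -> IntegratedTrainingSet:
    return IntegratedTrainingSet(
        X=ts.X.iloc[idx],
        Y=ts.Y.iloc[idx],
        x_scaler=ts.x_scaler,
        y_scaler=ts.y_scaler,
        cohort_of_sample=ts.cohort_of_sample.iloc[idx],
    )


def _aggregate(per_fold: List[MetricsReport]) -> MetricsReport:
    rho = pd.concat([r.per_mirna_spearman for r in per_fold], axis=1).mean(axis=1)
    return MetricsReport(
        per_mirna_spearman=rho,
        mse=float(np.mean([r.mse for r in per_fold])),
        mae=float(np.mean([r.mae for r in per_fold])),
        r2=float(np.mean([r.r2 for r in per_fold])),
        n_constant_obs=int(sum(r.n_constant_obs for r in per_fold)),
        per_fold=per_fold,
    )


def cross_validate(
    ts: IntegratedTrainingSet, hp: Hyperparams, k: int = 5, seed: int = 0
) -> MetricsReport:
    """Seeded k-fold CV; metrics computed on held-out folds and averaged."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if ts.n_samples < k:
        raise ValueError("n_samples < k")
    per_fold = []
    for train_idx, test_idx in _cv_folds(ts.n_samples, k, seed):
        bundle = train(_subset(ts, train_idx), hp, seed=seed)
        pred = predict(bundle, ts.X.iloc[test_idx])
        per_fold.append(evaluate(pred, ts.Y.iloc[test_idx]))
    return _aggregate(per_fold)


def grid_search(
    ts: IntegratedTrainingSet,
    grid: Iterable[Hyperparams] = DEFAULT_GRID,
    k: int = 5,
    seed: int = 0,
) -> Tuple[Hyperparams, MetricsReport, pd.DataFrame]:
    """Exhaustive grid search selecting the point with minimal mean CV MSE.

    Ties break toward lower ``n_estimators``, then ``max_depth``, then
    ``learning_rate``. Returns the winner, its CV report, and the full
    per-point metrics table.
    """
    points = list(dict.fromkeys(grid))  # dedupe, keep order
    if not points:
        raise ValueError("grid must be non-empty")
    rows, reports = [], {}
    for hp in points:
        rep = cross_validate(ts, hp, k=k, seed=seed)
        reports[hp] = rep
        rows.append(
            {
                "learning_rate": hp.learning_rate,
                "max_depth": hp.max_depth,
                "n_estimators": hp.n_estimators,
                "cv_mse": rep.mse,
                "cv_mae": rep.mae,
                "cv_r2": rep.r2,
                "cv_median_spearman": rep.median_spearman,
            }
        )
    table = pd.DataFrame(rows)
    best = min(
        points,
        key=lambda hp: (
            reports[hp].mse,
            hp.n_estimators,
            hp.max_depth,
            hp.learning_rate,
        ),
    )
    return best, reports[best], table


BASELINE_MODELS = ("ridge", "lasso", "random_forest", "neural_network", "gradient_boosting")


def _baseline_estimator(name: str, hp: Hyperparams, seed: int):
    if name == "ridge":
        return Ridge(alpha=1.0)
    if name == "lasso":
        return Lasso(alpha=0.01, max_iter=5000)
    if name == "random_forest":
        return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "neural_network":
        # two hidden layers, rectified units, early stopping on a 10% split
        return MLPRegressor(
            hidden_layer_sizes=(128, 32),
            activation="relu",
            early_stopping=True,
            validation_fraction=0.1,
            max_iter=500,
            random_state=seed,
        )
    raise KeyError(name)


def benchmark_baselines(
    ts: IntegratedTrainingSet,
    k: int = 5,
    seed: int = 0,
    hp: Optional[Hyperparams] = None,
) -> pd.DataFrame:
    """Evaluate gradient boosting against four baselines on identical folds.

    Returns one row per model with fold-averaged MSE, MAE, R2 and the
    median per-target held-out Spearman rho.
    """
    hp = hp or Hyperparams()
    folds = list(_cv_folds(ts.n_samples, k, seed))
    per_model_reports: Dict[str, MetricsReport] = {}
    for name in BASELINE_MODELS:
        per_fold = []
        for train_idx, test_idx in folds:
            Xtr = ts.X.iloc[train_idx].to_numpy(dtype=float)
            Ytr = ts.Y.iloc[train_idx].to_numpy(dtype=float)
            Xte = ts.X.iloc[test_idx]
            if name == "gradient_boosting":
                bundle = train(_subset(ts, train_idx), hp, seed=seed)
                pred = predict(bundle, Xte)
            else:
                est = _baseline_estimator(name, hp, seed)
                est.fit(Xtr, Ytr)
                pv = np.clip(est.predict(Xte.to_numpy(dtype=float)), 0.0, 1.0)
                pred = pd.DataFrame(pv, index=Xte.index, columns=ts.target_mirnas)
            per_fold.append(evaluate(pred, ts.Y.iloc[test_idx]))
        per_model_reports[name] = _aggregate(per_fold)
    rows = [
        {
            "Model": name,
            "MSE": rep.mse,
            "MAE": rep.mae,
            "R2": rep.r2,
            "median_spearman": rep.median_spearman,
        }
        for name, rep in per_model_reports.items()
    ]
    table = pd.DataFrame(rows)
    table.attrs["reports"] = per_model_reports
    return table


def save_model(model: ModelBundle, path) -> None:
    """Serialize a ModelBundle to a versioned single-file archive."""
    payload = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "bundle": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


class ModelFormatError(ValueError):
    pass


def load_model(path) -> ModelBundle:
    """Load a ModelBundle, refusing unknown formats or versions."""
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise ModelFormatError(f"not a valid model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError("not a stmir model file")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    return payload["bundle"]
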
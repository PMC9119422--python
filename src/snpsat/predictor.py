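"""SNPsnp: predicting a strain's saturated SNP number from shallow-sample
features.

Six features describe a strain in a (possibly shallow) sample: sequencing
coverage, sequencing depth, relative abundance, genome length, current SNP
number and current SNP density.  The target is the strain's SNP count at
saturation, so only strains whose downsampling series passed the
saturation criterion contribute training rows.  A linear regression and a
random-forest regression (hyperparameters picked by grid search with
5-fold cross-validation on the training split) are compared on a held-out
1/5 split using relative square error, relative absolute error and R².
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, train_test_split

from .errors import InputError, StateError, UndefinedMetricError
from .saturation import SaturationSeries
from .strain_profiles import StrainAbundance, StrainMetrics

logger = logging.getLogger(__name__)

FEATURES = (
    "coverage",
    "depth",
    "abundance",
    "genome_length",
    "snp_count",
    "snp_density",
)
TARGET = "saturated_snp_count"

DEFAULT_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 10, 20],
    "min_samples_leaf": [1, 3, 5],
}

MIN_ROWS = 25


@dataclass
class RegressionMetrics:
    """RSE = SS_res / SS_tot, RAE = sum|res| / sum|dev|, R² = 1 - RSE."""

    rse: float
    rae: float
    r2: float


@dataclass
class TrainedModels:
    linear: LinearRegression
    forest: RandomForestRegressor
    forest_params: dict
    linear_metrics: RegressionMetrics
    forest_metrics: RegressionMetrics
    feature_importances: np.ndarray
    feature_order: tuple[str, ...] = FEATURES
    seed: int = 42
    n_train: int = 0
    n_test: int = 0


def regression_metrics(
    y_true: Sequence[float], y_pred: Sequence[float]
) -> RegressionMetrics:
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) != len(p):
        raise InputError("y_true and y_pred lengths differ")
    if len(y) < 2:
        raise InputError("need at least 2 points")
    dev = y - y.mean()
    ss_tot = float((dev**2).sum())
    sad_tot = float(np.abs(dev).sum())
    if ss_tot == 0:
        raise UndefinedMetricError("constant y_true; relative errors undefined")
    rse = float(((p - y) ** 2).sum()) / ss_tot
    rae = float(np.abs(p - y).sum()) / sad_tot
    return RegressionMetrics(rse=rse, rae=rae, r2=1.0 - rse)


def build_training_table(
    metrics: Mapping[tuple[str, int], StrainMetrics],
    abundances: Mapping[tuple[str, int], StrainAbundance],
    genome_lengths: Mapping[str, int],
    verdicts: Mapping[str, SaturationSeries],
) -> pd.DataFrame:
    """Join per-(strain, level) profiles with saturation verdicts.

    Emits one row per (strain, subsample level) for saturated strains
    only; the target is constant across a strain's rows.  A profiled
    strain without a verdict is an error.
    """
    rows = []
    for (strain, level), m in metrics.items():
        if strain not in verdicts:
            raise InputError(f"no saturation verdict for strain {strain}")
        v = verdicts[strain]
        if not v.saturated:
            continue
        ab = abundances.get((strain, level))
        if ab is None:
            raise InputError(f"no abundance for strain {strain} at level {level}")
        rows.append(
            {
                "strain": strain,
                "level": level,
                "coverage": m.coverage,
                "depth": m.genome_depth,
                "abundance": ab.abundance,
                "genome_length": genome_lengths[strain],
                "snp_count": m.snp_count,
                "snp_density": m.snp_density,
                TARGET: v.saturated_snp_count,
            }
        )
    if not rows:
        logger.warning("no saturated strain; empty training table")
        return pd.DataFrame(columns=["strain", "level", *FEATURES, TARGET])
    return pd.DataFrame(rows)


def train_models(
    rows: pd.DataFrame,
    test_fraction: float = 0.2,
    cv_folds: int = 5,
    seed: int = 42,
    grid: Optional[dict] = None,
    group_by_strain: bool = False,
) -> TrainedModels:
    """Fit the linear and random-forest regressors on a 4:1 split.

    The grid search scores forest hyperparameters by ``cv_folds``-fold CV
    on the training split only; metrics are reported on the untouched test
    split.  ``group_by_strain=True`` splits whole strains instead of rows
    (rows from one strain are correlated); the default is a plain random
    row split.
    """
    if len(rows) < MIN_ROWS:
        raise InputError(f"need at least {MIN_ROWS} rows, got {len(rows)}")
    missing = [c for c in (*FEATURES, TARGET) if c not in rows.columns]
    if missing:
        raise InputError(f"missing columns: {missing}")
    X = rows.loc[:, list(FEATURES)].to_numpy(dtype=float)
    y = rows[TARGET].to_numpy(dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise InputError("non-finite feature or target values")

    if group_by_strain and "strain" in rows.columns:
        strains = rows["strain"].unique()
        rng = np.random.default_rng(seed)
        test_strains = set(
            rng.choice(strains, size=max(1, int(round(test_fraction * len(strains)))), replace=False)
        )
        mask = rows["strain"].isin(test_strains).to_numpy()
        X_tr, X_te, y_tr, y_te = X[~mask], X[mask], y[~mask], y[mask]
    else:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, random_state=seed
        )

    # tol=0: keep all singular values; features span ~10 orders of magnitude
    linear = LinearRegression(tol=0.0).fit(X_tr, y_tr)
    search = GridSearchCV(
        RandomForestRegressor(random_state=seed),
        param_grid=grid or DEFAULT_GRID,
        cv=cv_folds,
        scoring="r2",
        n_jobs=1,
    ).fit(X_tr, y_tr)
    forest = search.best_estimator_

    return TrainedModels(
        linear=linear,
        forest=forest,
        forest_params=search.best_params_,
        linear_metrics=regression_metrics(y_te, linear.predict(X_te)),
        forest_metrics=regression_metrics(y_te, forest.predict(X_te)),
        feature_importances=forest.feature_importances_,
        seed=seed,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def predict_saturated_snps(
    models: TrainedModels, features: Mapping[str, float], use: str = "forest"
) -> tuple[float, bool]:
    """Predict one strain's saturated SNP number from shallow-sample features.

    Returns (prediction clipped at 0, misfit flag).  The flag is raised
    when the prediction falls below the strain's current SNP number — a
    saturated count cannot be smaller than what was already observed, so
    such a prediction signals model misfit rather than a valid answer.
    """
    if models is None or getattr(models, use, None) is None:
        raise StateError("model not trained")
    missing = [f for f in models.feature_order if f not in features]
    if missing:
        raise InputError(f"missing features: {missing}")
    x = np.array([[features[f] for f in models.feature_order]], dtype=float)
    if not np.isfinite(x).all():
        raise InputError("non-finite feature values")
    pred = float(getattr(models, use).predict(x)[0])
    pred = max(pred, 0.0)
    flagged = pred < float(features.get("snp_count", 0.0))
    if flagged:
        logger.warning(
            "prediction %.1f below current SNP count %.1f; model misfit",
            pred,
            features.get("snp_count", 0.0),
        )
    return pred, flagged


def save_models(models: TrainedModels, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    joblib.dump(models.linear, os.path.join(out_dir, "linear.joblib"))
    joblib.dump(models.forest, os.path.join(out_dir, "forest.joblib"))
    meta = {
        "format_version": 1,
        "feature_order": list(models.feature_order),
        "forest_params": {k: v for k, v in models.forest_params.items()},
        "seed": models.seed,
        "n_train": models.n_train,
        "n_test": models.n_test,
        "linear_metrics": vars(models.linear_metrics),
        "forest_metrics": vars(models.forest_metrics),
        "feature_importances": list(map(float, models.feature_importances)),
    }
    with open(os.path.join(out_dir, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_models(model_dir: str) -> TrainedModels:
    meta_path = os.path.join(model_dir, "metadata.json")
    if not os.path.exists(meta_path):
        raise InputError(f"no model metadata at {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return TrainedModels(
        linear=joblib.load(os.path.join(model_dir, "linear.joblib")),
        forest=joblib.load(os.path.join(model_dir, "forest.joblib")),
        forest_params=meta["forest_params"],
        linear_metrics=RegressionMetrics(**meta["linear_metrics"]),
        forest_metrics=RegressionMetrics(**meta["forest_metrics"]),
        feature_importances=np.array(meta["feature_importances"]),
        feature_order=tuple(meta["feature_order"]),
        seed=meta["seed"],
        n_train=meta["n_train"],
        n_test=meta["n_test"],
    )
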
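"""Random-forest property regression and its evaluation protocol.

The supervised model is a random forest of 500 regression trees (bootstrap
resampling, full-feature splits), evaluated two ways:

* **Iterative leave-one-out (LOO)** — each molecule in turn is withheld,
  the forest is retrained on the rest, and the withheld molecule's
  property is predicted; the N held-out predictions yield R-squared, MAE
  and mean absolute percent error.  Equivalent to N-fold cross-validation
  with one molecule per fold.
* **Learning curves** — random by-molecule splits at training fractions
  of 10-60% in 10% steps, 10 repeats each (60 splits in total); mean and
  one standard deviation of the train and test MAE per fraction.

R-squared is reported primarily as the squared Pearson correlation
between true and predicted values; the coefficient of determination is
also computed for transparency.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score

from .records import FeatureMatrix, LearningCurve, LOOResult, RFConfig

__all__ = [
    "DEFAULT_FRACTIONS",
    "train_rf",
    "predict",
    "leave_one_out",
    "learning_curve",
    "metrics",
]

DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def _check_finite(matrix: FeatureMatrix) -> None:
    if not (np.all(np.isfinite(matrix.matrix)) and np.all(np.isfinite(matrix.labels))):
        raise ValueError("features and labels must be finite")


def train_rf(matrix: FeatureMatrix, config: RFConfig | None = None) -> RandomForestRegressor:
    """Fit the 500-tree random forest on the full matrix.

    Each tree is trained on a bootstrap resample; splits consider
    ``config.max_features`` of the columns.  Deterministic for a fixed
    ``config.seed``.
    """
    config = config or RFConfig()
    if matrix.n_molecules < 2:
        raise ValueError("need at least 2 rows to train")
    _check_finite(matrix)
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(matrix.matrix, matrix.labels)
    return model


def predict(model: RandomForestRegressor, features: np.ndarray) -> np.ndarray:
    return model.predict(np.atleast_2d(features))


def metrics(
    true: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float | None]:
    """(pearson-squared R2, MAE, mean absolute percent error).

    Percent error is ``mean(|true - pred| / |true|) * 100`` and is
    ``None`` (flagged) when any true value is zero.  R-squared requires at
    least two pairs and non-constant true values.
    """
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.size < 2:
        raise ValueError("metrics require at least 2 (true, predicted) pairs")
    if np.all(true == true[0]):
        raise ValueError("r2 undefined: all true values are equal")
    if np.all(predicted == predicted[0]):
        r2 = 0.0  # constant predictions carry no correlation
    else:
        r2 = float(np.corrcoef(true, predicted)[0, 1] ** 2)
    mae = float(np.mean(np.abs(true - predicted)))
    if np.any(true == 0):
        mape = None
    else:
        mape = float(np.mean(np.abs((true - predicted) / true)) * 100.0)
    return r2, mae, mape


def leave_one_out(matrix: FeatureMatrix, config: RFConfig | None = None) -> LOOResult:
    """Iterative leave-one-out evaluation.

    Trains N forests for N labeled molecules; molecule i is never part of
    its own training data.  Metrics are computed over the N held-out
    predictions.
    """
    config = config or RFConfig()
    n = matrix.n_molecules
    if n < 3:
        raise ValueError(f"leave-one-out requires >= 3 labeled molecules, got {n}")
    _check_finite(matrix)
    if len(set(matrix.ids)) != n:
        raise ValueError("molecule ids must be unique for leave-one-out")
    predictions = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            min_samples_leaf=config.min_samples_leaf,
            bootstrap=True,
            random_state=config.seed,
            n_jobs=1,
        )
        model.fit(matrix.matrix[mask], matrix.labels[mask])
        predictions[i] = model.predict(matrix.matrix[i : i + 1])[0]
    r2, mae, mape = metrics(matrix.labels, predictions)
    r2_cod = float(r2_score(matrix.labels, predictions))
    return LOOResult(
        property_name=matrix.property_name,
        ids=list(matrix.ids),
        true=matrix.labels.copy(),
        predicted=predictions,
        r2=r2,
        r2_cod=r2_cod,
        mae=mae,
        mean_abs_pct_error=mape,
    )


def split_indices(
    n: int, fraction: float, master_seed: int, fraction_index: int, repeat: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic by-molecule train/test split for one (fraction, repeat).

    The per-split generator is seeded from ``(master_seed, fraction_index,
    repeat)``, so any single split is reproducible in isolation.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"training fraction must be in (0, 1), got {fraction}")
    n_train = int(round(fraction * n))
    if n_train < 2:
        raise ValueError(
            f"fraction {fraction} of {n} molecules gives {n_train} training "
            "rows; need >= 2"
        )
    rng = np.random.default_rng([master_seed, fraction_index, repeat])
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def learning_curve(
    matrix: FeatureMatrix,
    config: RFConfig | None = None,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    repeats: int = 10,
    seed: int = 0,
) -> LearningCurve:
    """Train/test MAE versus training-set size.

    For every fraction, ``repeats`` random by-molecule splits are drawn;
    the forest is trained on the fraction and evaluated on both subsets.
    Reported values are the mean MAE and one standard deviation of the
    per-repeat MAEs.  ``len(fractions) * repeats`` distinct splits are
    generated in total.
    """
    config = config or RFConfig()
    _check_finite(matrix)
    n = matrix.n_molecules
    test_mean, test_sd, train_mean, train_sd = [], [], [], []
    n_splits = 0
    for fi, frac in enumerate(fractions):
        test_maes, train_maes = [], []
        for rep in range(repeats):
            tr, te = split_indices(n, frac, seed, fi, rep)
            assert np.intersect1d(tr, te).size == 0
            model = RandomForestRegressor(
                n_estimators=config.n_trees,
                max_features=config.max_features,
                min_samples_leaf=config.min_samples_leaf,
                bootstrap=True,
                random_state=config.seed,
                n_jobs=1,
            )
            model.fit(matrix.matrix[tr], matrix.labels[tr])
            test_maes.append(
                float(np.mean(np.abs(matrix.labels[te] - model.predict(matrix.matrix[te]))))
            )
            train_maes.append(
                float(np.mean(np.abs(matrix.labels[tr] - model.predict(matrix.matrix[tr]))))
            )
            n_splits += 1
        test_mean.append(np.mean(test_maes))
        test_sd.append(np.std(test_maes, ddof=1) if repeats > 1 else 0.0)
        train_mean.append(np.mean(train_maes))
        train_sd.append(np.std(train_maes, ddof=1) if repeats > 1 else 0.0)
    return LearningCurve(
        property_name=matrix.property_name,
        fractions=list(fractions),
        repeats=repeats,
        test_mae_mean=np.array(test_mean),
        test_mae_sd=np.array(test_sd),
        train_mae_mean=np.array(train_mean),
        train_mae_sd=np.array(train_sd),
        n_splits=n_splits,
    )
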
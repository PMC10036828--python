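"""Overall-survival prediction from discriminative KLS connections.

A linear L2-regularized L2-loss (squared epsilon-insensitive) support-vector
regression is trained under leave-one-out cross-validation: in each fold,
age and sex are regressed out of the features and the outcome with
training-fold coefficients, the feature set is restricted to connections
that separate patients from controls on the training fold, features are
z-scored with training-fold statistics, and the held-out patient's survival
is predicted. The observed-vs-predicted Pearson correlation is assessed by
permutation, and per-connection weights are aggregated into six gross
anatomical groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVR

from .features import parse_edge_name
from .group_stats import (
    CovariateRegression,
    SubjectFeatureTable,
    edgewise_comparison,
    encode_sex,
)

__all__ = [
    "PatientRecord",
    "SVRModel",
    "PredictionResult",
    "train_svr",
    "svr_objective",
    "loocv_predict",
    "permutation_test",
    "permutation_test_loocv",
    "summarize_weights",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientRecord:
    """One patient's connection features, covariates, and outcome."""

    subject_id: str
    connection_features: pd.Series
    age: float
    sex: float
    overall_survival: float

    def __post_init__(self) -> None:
        self.sex = float(encode_sex([self.sex])[0])
        if not self.overall_survival > 0:
            raise ValueError("overall survival (months) must be > 0")


@dataclass
class SVRModel:
    """A fitted linear SVR plus the fold-local preprocessing parameters."""

    weights: pd.Series
    C: float
    epsilon: float
    center: pd.Series | None = None
    scale: pd.Series | None = None
    feature_deconfounder: CovariateRegression | None = None
    outcome_deconfounder: CovariateRegression | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.weights.to_numpy()


def svr_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, C: float, eps: float) -> float:
    """0.5 ||w||^2 + C sum max(0, |y - Xw| - eps)^2 (the primal objective)."""
    r = np.abs(y - X @ w) - eps
    return 0.5 * float(w @ w) + C * float(np.sum(np.maximum(r, 0.0) ** 2))


def train_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    eps: float = 0.1,
    feature_names=None,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> SVRModel:
    """Fit w minimizing 0.5||w||^2 + C sum max(0, |y_i - w.x_i| - eps)^2.

    No intercept is fitted; callers center/scale features and outcome first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValueError("X must be (n, p) with n = len(y) >= 2")
    svr = LinearSVR(
        C=C,
        epsilon=eps,
        loss="squared_epsilon_insensitive",
        dual=False,
        fit_intercept=False,
        tol=tol,
        max_iter=max_iter,
    )
    svr.fit(X, y)
    names = list(feature_names) if feature_names is not None else list(range(X.shape[1]))
    return SVRModel(weights=pd.Series(svr.coef_.ravel(), index=names), C=C, epsilon=eps)


@dataclass
class PredictionResult:
    """LOOCV predictions, their correlation with observation, and weights."""

    subject_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray
    observed_raw: np.ndarray
    pearson_r: float
    fold_weights: list[pd.Series] = field(default_factory=list)
    mean_weights: pd.Series | None = None
    permutation_p: float | None = None
    lobe_weights: dict[str, float] | None = None
    n_selected_per_fold: list[int] = field(default_factory=list)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _records_to_arrays(patients: list[PatientRecord]):
    feats = pd.DataFrame([p.connection_features for p in patients])
    age = np.array([p.age for p in patients], dtype=float)
    sex = np.array([p.sex for p in patients], dtype=float)
    y = np.array([p.overall_survival for p in patients], dtype=float)
    ids = [p.subject_id for p in patients]
    return ids, feats, age, sex, y


def _select_features(
    train_table: SubjectFeatureTable,
    controls: SubjectFeatureTable,
    alpha: float,
    select_on: str,
) -> list[str]:
    cmp_df = edgewise_comparison(train_table, controls, q=alpha)
    if select_on == "fdr":
        keep = cmp_df.loc[cmp_df["p_fdr"] <= alpha, "feature"]
    elif select_on == "raw":
        keep = cmp_df.loc[cmp_df["p"] <= alpha, "feature"]
    else:
        raise ValueError("select_on must be 'fdr' or 'raw'")
    return list(keep)


def loocv_predict(
    patients: list[PatientRecord],
    controls: SubjectFeatureTable,
    C: float = 1.0,
    eps: float = 0.1,
    alpha: float = 0.05,
    selection: str = "per_fold",
    select_on: str = "fdr",
) -> PredictionResult:
    """Leave-one-out SVR prediction of overall survival.

    Per fold: deconfound features and survival on age+sex with
    training-fold coefficients (applied, not refitted, to the held-out
    patient); select features significant in the training-patients-vs-
    controls edgewise comparison at level ``alpha``; z-score with
    training-fold statistics; train; predict. ``selection="fixed"``
    instead selects once from all patients before cross-validation (the
    leakage-prone literal protocol, kept for comparison). A fold that
    selects no feature predicts the training-fold mean outcome.

    ``observed`` (used for the reported Pearson r) is the held-out
    patient's survival after that fold's deconfounding; ``observed_raw``
    keeps the unadjusted months.
    """
    n = len(patients)
    if n < 3:
        raise ValueError("need at least 3 patients for LOOCV")
    ids, feats, age, sex, y = _records_to_arrays(patients)
    cov = np.column_stack([age, sex])
    all_features = list(feats.columns)

    fixed_selected: list[str] | None = None
    if selection == "fixed":
        full_table = SubjectFeatureTable(
            subject_ids=ids, group=np.repeat("patient", n), age=age, sex=sex, features=feats
        )
        fixed_selected = _select_features(full_table, controls, alpha, select_on)
    elif selection != "per_fold":
        raise ValueError("selection must be 'per_fold' or 'fixed'")

    predicted = np.empty(n)
    observed = np.empty(n)
    fold_weights: list[pd.Series] = []
    n_selected: list[int] = []
    x_all = feats.to_numpy(dtype=float)
    for k in range(n):
        train = np.arange(n) != k
        feat_dec = CovariateRegression().fit(x_all[train], cov[train])
        out_dec = CovariateRegression().fit(y[train], cov[train])
        xr_train = feat_dec.residualize(x_all[train], cov[train])
        xr_test = feat_dec.residualize(x_all[k : k + 1], cov[k : k + 1])
        yr_train = out_dec.residualize(y[train], cov[train])
        yr_test = out_dec.residualize(y[k : k + 1], cov[k : k + 1])

        if fixed_selected is not None:
            selected = fixed_selected
        else:
            train_table = SubjectFeatureTable(
                subject_ids=[ids[i] for i in np.nonzero(train)[0]],
                group=np.repeat("patient", n - 1),
                age=age[train],
                sex=sex[train],
                features=feats.iloc[train].reset_index(drop=True),
            )
            selected = _select_features(train_table, controls, alpha, select_on)
        n_selected.append(len(selected))
        observed[k] = yr_test[0]
        if not selected:
            logger.info("fold %d selected no features; predicting training mean", k)
            predicted[k] = float(yr_train.mean())
            fold_weights.append(pd.Series(dtype=float))
            continue
        cols = [all_features.index(f) for f in selected]
        xt = xr_train[:, cols]
        center = xt.mean(axis=0)
        scale = xt.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        model = train_svr((xt - center) / scale, yr_train, C=C, eps=eps, feature_names=selected)
        predicted[k] = float(model.predict((xr_test[:, cols] - center) / scale)[0])
        fold_weights.append(model.weights)

    mean_weights = (
        pd.DataFrame(fold_weights).reindex(columns=all_features).fillna(0.0).mean(axis=0)
    )
    mean_weights = mean_weights[mean_weights != 0.0]
    return PredictionResult(
        subject_ids=ids,
        predicted=predicted,
        observed=observed,
        observed_raw=y,
        pearson_r=_pearson(predicted, observed),
        fold_weights=fold_weights,
        mean_weights=mean_weights,
        n_selected_per_fold=n_selected,
    )


def permutation_test(
    result: PredictionResult, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Fast permutation p for the observed-vs-predicted correlation.

    Shuffles the observed outcomes against the fixed predictions and counts
    permutation correlations at least as large as the observed one:
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = result.pearson_r
    count = 0
    shuffled = result.observed.copy()
    for _ in range(n_perm):
        rng.shuffle(shuffled)
        if _pearson(result.predicted, shuffled) >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def permutation_test_loocv(
    patients: list[PatientRecord],
    controls: SubjectFeatureTable,
    n_perm: int = 100,
    seed: int = 0,
    **loocv_kwargs,
) -> float:
    """Full-pipeline permutation: re-run the LOOCV on shuffled survivals.

    Far costlier than :func:`permutation_test`; intended for modest
    ``n_perm`` where the selection/training steps should also see the
    permuted outcome.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = loocv_predict(patients, controls, **loocv_kwargs).pearson_r
    rng = np.random.default_rng(seed)
    y = np.array([p.overall_survival for p in patients])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        shuffled = [
            PatientRecord(
                subject_id=p.subject_id,
                connection_features=p.connection_features,
                age=p.age,
                sex=p.sex,
                overall_survival=float(y[perm[i]]),
            )
            for i, p in enumerate(patients)
        ]
        if loocv_predict(shuffled, controls, **loocv_kwargs).pearson_r >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def summarize_weights(weights: pd.Series, lobe_map: dict[int, str]) -> dict[str, float]:
    """Aggregate |connection weight| into the six anatomical groups.

    Each connection contributes its absolute mean weight to the group of
    both endpoint regions (once per group: a within-group connection counts
    once for that group).
    """
    lobes: dict[str, float] = {}
    for name, w in weights.items():
        i, j = parse_edge_name(str(name))
        for rid in {i, j}:
            if rid not in lobe_map:
                raise KeyError(f"region {rid} missing from lobe map")
        for lobe in {lobe_map[i], lobe_map[j]}:
            lobes[lobe] = lobes.get(lobe, 0.0) + abs(float(w))
    return lobes
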
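"""Covariate-adjusted two-sample comparisons with FDR control.

Patients and controls are compared feature-by-feature (edgewise KLS values,
nodal metric AUCs, or global metric AUCs): each feature is residualized on
age and sex across the pooled sample, groups are compared with a pooled
two-sample t-test whose degrees of freedom are reduced by the number of
regressed covariates, and p-values are corrected per feature family with
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubjectFeatureTable",
    "ComparisonResult",
    "CovariateRegression",
    "residualize_covariates",
    "two_sample_t",
    "fdr_correct",
    "edgewise_comparison",
    "encode_sex",
]


def encode_sex(sex) -> np.ndarray:
    """Map M/F (or 1/0) labels to a binary float code (M=1, F=0)."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "ifb":
        return arr.astype(float)
    mapping = {"M": 1.0, "F": 0.0, "m": 1.0, "f": 0.0, "male": 1.0, "female": 0.0}
    try:
        return np.array([mapping[str(s)] for s in arr])
    except KeyError as exc:
        raise ValueError(f"unrecognized sex label {exc}") from exc


@dataclass
class SubjectFeatureTable:
    """Aligned per-subject covariates and named feature vectors."""

    subject_ids: list[str]
    group: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    features: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.group = np.asarray(self.group, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = encode_sex(self.sex)
        if not (len(self.group) == len(self.age) == len(self.sex) == len(self.features) == n):
            raise ValueError("covariates and features must align with subject_ids")
        if np.any(pd.isna(self.age)) or np.any(pd.isna(self.sex)):
            raise ValueError("missing age or sex")
        bad = set(self.group) - {"patient", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def covariates(self) -> np.ndarray:
        return np.column_stack([self.age, self.sex])

    @classmethod
    def concat(cls, a: "SubjectFeatureTable", b: "SubjectFeatureTable") -> "SubjectFeatureTable":
        if list(a.features.columns) != list(b.features.columns):
            raise ValueError("feature name sets differ between tables")
        return cls(
            subject_ids=list(a.subject_ids) + list(b.subject_ids),
            group=np.concatenate([a.group, b.group]),
            age=np.concatenate([a.age, b.age]),
            sex=np.concatenate([a.sex, b.sex]),
            features=pd.concat([a.features, b.features], ignore_index=True),
        )


@dataclass
class ComparisonResult:
    feature_name: str
    t_statistic: float
    p_value: float
    p_fdr: float
    direction: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1 or self.p_fdr < self.p_value - 1e-12:
            raise ValueError("require 0 <= p <= p_fdr")


class CovariateRegression:
    """OLS of values on [intercept, covariates]; reusable on held-out data.

    Fitting stores the coefficient vector; :meth:`residualize` applies it to
    any dataset so training-fold regression weights can deconfound held-out
    subjects without refitting.
    """

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None

    @staticmethod
    def _as_matrix(covariates: np.ndarray) -> np.ndarray:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return x

    def _design(self, covariates: np.ndarray) -> np.ndarray:
        x = self._as_matrix(covariates)
        return np.column_stack([np.ones(len(x)), x[:, self.keep_]])

    @property
    def n_covariates_used(self) -> int:
        """Covariate columns actually in the design (constants are dropped)."""
        return int(self.keep_.sum()) if self.keep_ is not None else 0

    def fit(self, values: np.ndarray, covariates: np.ndarray) -> "CovariateRegression":
        y = np.asarray(values, dtype=float)
        x = self._as_matrix(covariates)
        if len(y) != len(x):
            raise ValueError("values and covariates must have equal length")
        # constant columns are collinear with the intercept and carry no
        # confounding signal: drop them instead of failing
        self.keep_ = np.ptp(x, axis=0) > 0
        design = self._design(covariates)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariate design")
        self.coef_, *_ = np.linalg.lstsq(design, y, rcond=None)
        return self

    def residualize(self, values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit before residualizing")
        y = np.asarray(values, dtype=float)
        return y - self._design(covariates) @ self.coef_


def residualize_covariates(values, covariates) -> tuple[np.ndarray, CovariateRegression]:
    """OLS residuals of ``values`` on [intercept, covariates], plus the fit."""
    model = CovariateRegression().fit(values, covariates)
    return model.residualize(values, covariates), model


def two_sample_t(group_a, group_b, df_adjust: int = 0) -> tuple[float, float]:
    """Pooled-variance two-sample t with two-sided p.

    ``df_adjust`` subtracts degrees of freedom consumed upstream (e.g. the
    number of covariates regressed out before testing).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2 - df_adjust
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance calls."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def _vectorized_pooled_t(a: np.ndarray, b: np.ndarray, df_adjust: int) -> tuple[np.ndarray, np.ndarray]:
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2 - df_adjust
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.where(sp2 > 0, t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def edgewise_comparison(
    patients: SubjectFeatureTable,
    controls: SubjectFeatureTable,
    q: float = 0.05,
    welch: bool = False,
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Residualize, test, and FDR-correct every feature patient-vs-control.

    Features are residualized on age and sex across the pooled sample;
    the per-feature pooled t (patients minus controls) loses 2 df for the
    covariates. Returns a tidy frame with columns ``feature, t, p, p_fdr,
    significant, direction``, FDR-corrected across the supplied family.
    ``welch=True`` switches to the unequal-variance test.
    """
    pooled = SubjectFeatureTable.concat(patients, controls)
    y = pooled.features.to_numpy(dtype=float)
    if adjust_covariates:
        _, model = residualize_covariates(y, pooled.covariates)
        resid = model.residualize(y, pooled.covariates)
        df_adjust = model.n_covariates_used
    else:
        resid = y
        df_adjust = 0
    is_pat = pooled.group == "patient"
    a, b = resid[is_pat], resid[~is_pat]
    if welch:
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        t, p = np.asarray(t), np.asarray(p)
    else:
        t, p = _vectorized_pooled_t(a, b, df_adjust)
    p_fdr, significant = fdr_correct(p, q=q)
    return pd.DataFrame(
        {
            "feature": list(pooled.features.columns),
            "t": t,
            "p": p,
            "p_fdr": p_fdr,
            "significant": significant,
            "direction": np.where(t > 0, "patient>control", "patient<control"),
        }
    )
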
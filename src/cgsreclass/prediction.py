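"""Prevalence-adjusted risk prediction and net reclassification improvement.

In a case-control sample the fitted logistic intercept reflects the study's
sampling fractions, not the population prevalence.  Adding
``log[rho/(1-rho) x n_control/n_case]`` to the intercept converts fitted
probabilities into absolute risks at prevalence ``rho``, which makes the
risk categories (<5%, 5-<10%, 10-<15%, 15-<20%, >=20%) clinically
meaningful and allows the categorical net reclassification improvement
(NRI) to be applied in a case-control design.

Three models are compared: clinical covariates only (sex, age, BMI), the
combined genetic score only, and both.  Discrimination is summarized by
the ROC AUC; reclassification by paired 5x5 cross-tabulations of baseline
vs expanded-model categories, separately in cases and controls, from which

    NRI = (P_up - P_down | case) + (P_down - P_up | control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PrevalenceAdjustedLogit",
    "ReclassificationResult",
    "adjust_intercept",
    "predicted_risk",
    "auc",
    "auc_ci",
    "categorize_risk",
    "reclassification_table",
    "nri",
    "nri_from_tables",
    "nri_bootstrap_ci",
    "RiskModelFit",
    "fit_risk_models",
    "DEFAULT_RISK_BOUNDS",
]

DEFAULT_RISK_BOUNDS = (0.05, 0.10, 0.15, 0.20)
_Z975 = 1.959963984540054


def adjust_intercept(beta0: float, rho: float, n_control: int, n_case: int) -> float:
    """Prevalence-adjusted logistic intercept.

    Returns ``beta0 + log(rho/(1-rho) x n_control/n_case)``.  When ``rho``
    equals the sample case fraction the adjustment is zero.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    if n_control < 1 or n_case < 1:
        raise ValueError("n_control and n_case must be >= 1")
    return beta0 + float(np.log(rho / (1.0 - rho) * n_control / n_case))


class PrevalenceAdjustedLogit(BaseEstimator, ClassifierMixin):
    """Logistic risk model with a prevalence-adjusted intercept.

    A scikit-learn classifier backed by a statsmodels maximum-likelihood
    logistic fit.  ``predict_proba`` returns absolute risks at population
    prevalence ``prevalence`` by shifting the fitted intercept with
    :func:`adjust_intercept`; with ``prevalence=None`` the raw case-control
    fitted probabilities are returned.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_, intercept_ : fitted log-odds coefficients (sklearn layout).
    intercept_adjustment_ : additive intercept shift applied for risks.
    bse_ : Wald standard errors (intercept first).
    llf_ : model log-likelihood.
    """

    def __init__(self, prevalence: float | None = 0.10):
        self.prevalence = prevalence

    def fit(self, X, y):
        X = self._as_array(X)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
            raise ValueError("y must be binary with both classes present")
        design = np.column_stack([np.ones(len(y)), X])
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(
                method="newton", tol=1e-8, maxiter=50, disp=False
            )
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        self.intercept_ = np.array([fit.params[0]])
        self.coef_ = fit.params[1:].reshape(1, -1)
        self.bse_ = np.asarray(fit.bse)
        self.cov_params_ = np.asarray(fit.cov_params())
        self.llf_ = float(fit.llf)
        self.n_case_ = int(y.sum())
        self.n_control_ = int(len(y) - y.sum())
        if self.prevalence is None:
            self.intercept_adjustment_ = 0.0
        else:
            self.intercept_adjustment_ = adjust_intercept(
                0.0, self.prevalence, self.n_control_, self.n_case_
            )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = self._as_array(X)
        return (
            self.intercept_[0]
            + self.intercept_adjustment_
            + X @ self.coef_[0]
        )

    def predict_proba(self, X):
        eta = self.decision_function(X)
        risk = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - risk, risk])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)

    @staticmethod
    def _as_array(X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if np.isnan(X).any():
            raise ValueError("covariate matrix contains missing values")
        return X


def predicted_risk(model: PrevalenceAdjustedLogit, X) -> np.ndarray:
    """Per-subject absolute risk from a fitted prevalence-adjusted model."""
    return model.predict_proba(X)[:, 1]


def auc(risks_cases, risks_controls) -> float:
    """ROC area: P(case risk > control risk) with ties counted one half."""
    a = np.asarray(risks_cases, dtype=float)
    b = np.asarray(risks_controls, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.5  # all ties
    y = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    return float(roc_auc_score(y, np.concatenate([a, b])))


def auc_ci(
    auc_value: float, n_case: int, n_control: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil asymptotic confidence interval for the AUC."""
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (
        a * (1 - a)
        + (n_case - 1) * (q1 - a**2)
        + (n_control - 1) * (q2 - a**2)
    ) / (n_case * n_control)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, a - half), min(1.0, a + half)


def categorize_risk(risk, bounds=DEFAULT_RISK_BOUNDS) -> np.ndarray:
    """Assign risks to ordinal categories 1..len(bounds)+1.

    Intervals are half-open with inclusive lower bounds from the second
    category upward: with the default bounds, category 2 is [5%, 10%) and
    category 5 is >= 20%.
    """
    r = np.asarray(risk, dtype=float)
    if np.any((r < 0) | (r > 1) | np.isnan(r)):
        raise ValueError("risks must lie in [0, 1]")
    bounds = np.asarray(bounds, dtype=float)
    cats = np.searchsorted(bounds, r, side="right") + 1
    return cats if cats.ndim else int(cats)


@dataclass
class ReclassificationResult:
    """Paired reclassification tables and the categorical NRI.

    ``table_cases``/``table_controls``: 5x5 counts, rows = baseline-model
    category, columns = expanded-model category.  ``up``/``down`` are the
    strictly off-diagonal counts above/below the diagonal.  The NRI point
    estimate, asymptotic SE, 95% CI and two-sided normal p-value are
    filled by :func:`nri`.
    """

    table_cases: pd.DataFrame
    table_controls: pd.DataFrame
    up_cases: int = 0
    down_cases: int = 0
    up_controls: int = 0
    down_controls: int = 0
    n_cases: int = 0
    n_controls: int = 0
    net_case: float = np.nan
    net_control: float = np.nan
    nri: float = np.nan
    se: float = np.nan
    ci: tuple[float, float] = (np.nan, np.nan)
    p: float = np.nan
    category_bounds: tuple = DEFAULT_RISK_BOUNDS

    @property
    def n_reclassified(self) -> int:
        return self.up_cases + self.down_cases + self.up_controls + self.down_controls


def _crosstab(cats_from, cats_to, n_categories: int) -> pd.DataFrame:
    labels = np.arange(1, n_categories + 1)
    table = pd.crosstab(
        pd.Categorical(cats_from, categories=labels),
        pd.Categorical(cats_to, categories=labels),
        dropna=False,
    )
    table.index.name = "without_cgs"
    table.columns.name = "with_cgs"
    return table


def reclassification_table(
    cats_without, cats_with, status, n_categories: int = 5,
    category_bounds=DEFAULT_RISK_BOUNDS,
) -> ReclassificationResult:
    """Cross-tabulate baseline vs expanded-model risk categories by status.

    Row sums equal the baseline category counts; ``up`` counts subjects
    strictly above the diagonal (moved to a higher risk category), ``down``
    strictly below.
    """
    a = np.asarray(cats_without)
    b = np.asarray(cats_with)
    s = np.asarray(status)
    if not (len(a) == len(b) == len(s)):
        raise ValueError("category and status vectors must be aligned")
    res_tables = {}
    counts = {}
    for grp, mask in (("cases", s == 1), ("controls", s != 1)):
        table = _crosstab(a[mask], b[mask], n_categories)
        m = table.to_numpy()
        counts[grp] = (
            int(np.triu(m, 1).sum()),
            int(np.tril(m, -1).sum()),
            int(m.sum()),
        )
        res_tables[grp] = table
    up_c, down_c, n_c = counts["cases"]
    up_k, down_k, n_k = counts["controls"]
    return ReclassificationResult(
        table_cases=res_tables["cases"],
        table_controls=res_tables["controls"],
        up_cases=up_c,
        down_cases=down_c,
        up_controls=up_k,
        down_controls=down_k,
        n_cases=n_c,
        n_controls=n_k,
        category_bounds=tuple(category_bounds),
    )


def nri(result: ReclassificationResult) -> ReclassificationResult:
    """Categorical net reclassification improvement with asymptotic SE.

    NRI = (up_case - down_case)/n_case + (down_control - up_control)/n_control;
    SE = sqrt[(p_up,case + p_down,case)/n_case
              + (p_up,ctrl + p_down,ctrl)/n_ctrl];
    95% CI = NRI +/- 1.96 SE; two-sided normal p-value for NRI = 0.

    Fills the statistic fields of ``result`` in place and returns it.
    """
    if result.n_cases == 0 or result.n_controls == 0:
        raise ValueError("both groups must contain subjects")
    n_c, n_k = result.n_cases, result.n_controls
    p_up_c = result.up_cases / n_c
    p_down_c = result.down_cases / n_c
    p_up_k = result.up_controls / n_k
    p_down_k = result.down_controls / n_k
    result.net_case = p_up_c - p_down_c
    result.net_control = p_down_k - p_up_k
    result.nri = result.net_case + result.net_control
    result.se = float(np.sqrt((p_up_c + p_down_c) / n_c + (p_up_k + p_down_k) / n_k))
    if result.se > 0:
        z = result.nri / result.se
        result.p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        result.p = 1.0
    result.ci = (result.nri - _Z975 * result.se, result.nri + _Z975 * result.se)
    return result


def nri_from_tables(
    table_cases, table_controls, category_bounds=DEFAULT_RISK_BOUNDS
) -> ReclassificationResult:
    """NRI directly from printed/published 5x5 count tables."""
    tc = pd.DataFrame(np.asarray(table_cases, dtype=int))
    tk = pd.DataFrame(np.asarray(table_controls, dtype=int))
    if tc.shape != tk.shape or tc.shape[0] != tc.shape[1]:
        raise ValueError("tables must be square and of equal size")
    mc, mk = tc.to_numpy(), tk.to_numpy()
    res = ReclassificationResult(
        table_cases=tc,
        table_controls=tk,
        up_cases=int(np.triu(mc, 1).sum()),
        down_cases=int(np.tril(mc, -1).sum()),
        up_controls=int(np.triu(mk, 1).sum()),
        down_controls=int(np.tril(mk, -1).sum()),
        n_cases=int(mc.sum()),
        n_controls=int(mk.sum()),
        category_bounds=tuple(category_bounds),
    )
    return nri(res)


def nri_bootstrap_ci(
    cats_without, cats_with, status, n_boot: int = 2000, seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the NRI (resampling subjects within
    status groups)."""
    a = np.asarray(cats_without)
    b = np.asarray(cats_with)
    s = np.asarray(status)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx_case = np.flatnonzero(s == 1)
    idx_ctrl = np.flatnonzero(s != 1)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        rc = rng.choice(idx_case, size=len(idx_case), replace=True)
        rk = rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True)
        take = np.concatenate([rc, rk])
        res = reclassification_table(a[take], b[take], s[take])
        vals[i] = nri(res).nri
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class RiskModelFit:
    """One fitted prediction model with its discrimination summary."""

    model_id: str
    model: PrevalenceAdjustedLogit
    risks: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    llf: float
    columns: list = field(default_factory=list)


def fit_risk_models(
    covariates: pd.DataFrame,
    scores,
    status,
    prevalence: float = 0.10,
) -> dict[str, RiskModelFit]:
    """Fit the three prediction models sharing one prevalence adjustment.

    1. ``clinical`` — clinical covariates only;
    2. ``cgs_only`` — the combined genetic score only;
    3. ``clinical_plus_cgs`` — both.

    All models are fitted in-sample on complete cases.  The expanded model
    nests the clinical model, so its in-sample log-likelihood is at least
    as large.  Returns a dict keyed by model id.
    """
    cov = pd.DataFrame(covariates).astype(float)
    y = np.asarray(status, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (len(cov) == len(y) == len(s)):
        raise ValueError("covariates, scores and status must be aligned")
    designs = {
        "clinical": cov,
        "cgs_only": pd.DataFrame({"cgs": s}, index=cov.index),
        "clinical_plus_cgs": cov.assign(cgs=s),
    }
    out: dict[str, RiskModelFit] = {}
    for model_id, X in designs.items():
        est = PrevalenceAdjustedLogit(prevalence=prevalence).fit(X, y)
        risks = est.predict_proba(X)[:, 1]
        a = auc(risks[y == 1], risks[y != 1])
        out[model_id] = RiskModelFit(
            model_id=model_id,
            model=est,
            risks=risks,
            auc=a,
            auc_ci=auc_ci(a, est.n_case_, est.n_control_),
            llf=est.llf_,
            columns=list(X.columns),
        )
    return out
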
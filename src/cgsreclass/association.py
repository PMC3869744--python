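"""Association testing under the additive genetic model.

Per-SNP and per-score logistic regression (disease outcome) and linear
regression (quantitative traits), both adjusted for configurable
covariates; family-wise permutation correction by the max-|Z| statistic;
the binomial direction-consistency probability; Cochran's Q / I^2
heterogeneity; interaction testing; and the two-sample Student's t-test
for score distributions.

Model fits delegate to statsmodels (Newton MLE for logistic, OLS for
linear); confidence intervals are Wald intervals on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocResult",
    "StratumEffect",
    "fit_logistic_additive",
    "fit_linear_trait",
    "permutation_adjust",
    "binomial_direction_test",
    "cochran_q_i2",
    "interaction_test",
    "t_test_scores",
]

_Z975 = 1.959963984540054


@dataclass
class AssocResult:
    """A single-predictor association result.

    ``or_`` and its CI are on the odds-ratio scale for logistic fits and
    None for linear fits; ``p_perm`` is filled by permutation adjustment.
    """

    beta: float
    se: float
    p: float
    or_: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_perm: float | None = None
    n: int | None = None


@dataclass
class StratumEffect:
    """Per-stratum effect estimate on the log-odds (or linear) scale."""

    label: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"stratum {self.label!r}: se must be positive")


class FitError(RuntimeError):
    """Model fit failed (non-convergence or separation)."""


def _design(dosage, covariates):
    dosage = np.asarray(dosage, dtype=float)
    cols = [np.ones(len(dosage)), dosage]
    names = ["const", "dosage"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cols.extend(cov[c].to_numpy(dtype=float) for c in cov.columns)
        names.extend(str(c) for c in cov.columns)
    X = np.column_stack(cols)
    return X, names


def fit_logistic_additive(outcome, dosage, covariates=None) -> AssocResult:
    """Additive-model logistic regression of case status on dosage.

    The dosage enters as a linear term in the log-odds (one coefficient
    per added risk allele).  Maximum likelihood via Newton iterations
    (tolerance 1e-8, at most 50 iterations); Wald 95% CI
    ``exp(beta +/- 1.96 se)``.  On a 2x2 collapse with no covariates the
    fitted OR equals the cross-product ratio exactly.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both cases and controls")
    d = np.asarray(dosage, dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("dosage has zero variance")
    X, _ = _design(d, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than subjects")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(
                method="newton", tol=1e-8, maxiter=50, disp=False
            )
    except Exception as exc:  # statsmodels raises several error types here
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise FitError("logistic fit did not converge in 50 iterations")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e3:
        raise FitError("unstable standard error; data may be separated")
    return AssocResult(
        beta=beta,
        se=se,
        p=float(fit.pvalues[1]),
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        n=len(y),
    )


def fit_linear_trait(trait, dosage, covariates=None) -> AssocResult:
    """Ordinary least squares of a quantitative trait on dosage."""
    y = np.asarray(trait, dtype=float)
    X, _ = _design(dosage, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than subjects")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=len(y),
    )


def permutation_adjust(
    stat_fn,
    labels,
    n_perm: int,
    seed=None,
    observed=None,
    family_wise: bool = True,
):
    """Permutation-based multiple-testing correction.

    Parameters
    ----------
    stat_fn
        Callable mapping a label vector to the per-predictor |Z| (or other)
        statistics; called once per permutation with case/control labels
        shuffled across subjects.
    labels
        Observed binary labels.
    n_perm
        Number of permutations (the emulated study used 10,000).
    seed
        Seed or :class:`numpy.random.Generator` for reproducibility.
    observed
        Pre-computed observed statistics; computed via ``stat_fn(labels)``
        when omitted.
    family_wise
        If True (default), adjusted p_i compares each observed statistic
        with the permutation distribution of the maximum across predictors
        (family-wise error control); otherwise each predictor is compared
        with its own permutation distribution (pointwise).

    Returns adjusted p-values ``(1 + #{b : ref_b >= obs_i}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = np.atleast_1d(
        np.asarray(stat_fn(labels) if observed is None else observed, dtype=float)
    )
    exceed = np.zeros(len(obs))
    for _ in range(n_perm):
        perm_stats = np.atleast_1d(
            np.asarray(stat_fn(rng.permutation(labels)), dtype=float)
        )
        if family_wise:
            exceed += perm_stats.max() >= obs
        else:
            exceed += perm_stats >= obs
    return (1.0 + exceed) / (n_perm + 1.0)


def binomial_direction_test(n_consistent: int, n_total: int) -> float:
    """Probability that >= ``n_consistent`` of ``n_total`` effect estimates
    point in the reported direction by chance.

    Exact upper-tail binomial probability P(X >= k), X ~ Bin(n, 1/2).
    """
    if not 0 <= n_consistent <= n_total:
        raise ValueError("require 0 <= n_consistent <= n_total")
    return float(stats.binom.sf(n_consistent - 1, n_total, 0.5))


def cochran_q_i2(effects) -> tuple[float, int, float, float]:
    """Cochran's Q heterogeneity test and the I^2 index across strata.

    Inverse-variance weights w = 1/se^2; Q = sum w (beta - beta_pooled)^2,
    chi-square with k-1 df under homogeneity; I^2 = max(0, (Q - df)/Q).

    Returns (Q, df, p, I2).
    """
    effects = list(effects)
    if len(effects) < 2:
        raise ValueError("heterogeneity testing requires >= 2 strata")
    beta = np.array([e.beta for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled = np.sum(w * beta) / np.sum(w)
    q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(effects) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p, i2


def interaction_test(outcome, cgs, stratum_flag, covariates=None) -> AssocResult:
    """Multiplicative interaction between a binary stratum and the score.

    Logistic regression with main effects for the score and the stratum
    flag plus their product; the result reports the Wald test of the
    product coefficient.
    """
    flag = np.asarray(stratum_flag, dtype=float)
    if len(np.unique(flag)) < 2:
        raise ValueError("both strata must be populated")
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(cgs, dtype=float)
    cols = {"cgs": s, "stratum": flag, "cgs_x_stratum": s * flag}
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(cols))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=50, disp=False)
    except Exception as exc:
        raise FitError(f"interaction fit failed: {exc}") from exc
    beta = float(fit.params["cgs_x_stratum"])
    se = float(fit.bse["cgs_x_stratum"])
    return AssocResult(
        beta=beta,
        se=se,
        p=float(fit.pvalues["cgs_x_stratum"]),
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        n=len(y),
    )


def t_test_scores(scores_cases, scores_controls) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test (pooled variance)."""
    a = np.asarray(scores_cases, dtype=float)
    b = np.asarray(scores_controls, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
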
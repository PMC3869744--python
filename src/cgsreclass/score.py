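"""Combined genetic score (CGS) construction.

The unweighted CGS is the per-subject sum of risk-allele dosages across the
panel; the weighted CGS multiplies each dosage by a weight proportional to
the SNP's log-odds-ratio, normalized to mean 1 so the weighted score stays
on the allele-count scale.  Missing dosages are filled with the SNP's mean
observed dosage over the combined cohort before scoring, and the score is
rounded to the nearest integer (halves away from zero).

:class:`GeneticScoreTransformer` wraps the construction as a scikit-learn
transformer: ``fit`` learns the imputation means (and normalizes weights),
``transform`` returns raw scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GeneticScoreTransformer",
    "impute_mean_dosage",
    "compute_weights",
    "compute_cgs",
    "assign_quartiles",
    "bin_scores",
    "round_half_away",
]


def round_half_away(x):
    """Round to nearest integer with halves away from zero (not banker's)."""
    x = np.asarray(x, dtype=float)
    r = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return r.astype(int) if r.ndim else int(r)


def impute_mean_dosage(dosages: pd.DataFrame) -> pd.DataFrame:
    """Fill missing dosages with each SNP's mean observed dosage.

    The mean is taken over the combined cohort (cases and controls
    together).  Observed entries are unchanged, so the per-SNP mean dosage
    is preserved exactly.  A SNP with no observed dosage cannot be imputed.
    """
    means = dosages.mean(axis=0, skipna=True)
    fully_missing = means.index[means.isna()].tolist()
    if fully_missing:
        raise ValueError(f"SNPs with no observed dosage: {fully_missing}")
    return dosages.fillna(means)


def compute_weights(betas) -> np.ndarray:
    """Relative-effect weights w_i = beta_i / mean(beta).

    Betas must be risk-allele-oriented log odds ratios (all positive); the
    mean weight is exactly 1, which keeps the weighted score on the
    allele-count scale.  Rescaling all betas by a constant leaves the
    weights unchanged.
    """
    betas = pd.Series(betas, dtype=float)
    bad = betas.index[betas <= 0].tolist()
    if bad:
        raise ValueError(
            f"non-positive beta for SNP(s) {bad}: dosages must be oriented "
            "to the risk allele before weighting"
        )
    return (betas / betas.mean()).to_numpy()


def compute_cgs(dosages: pd.DataFrame, weights=None) -> pd.DataFrame:
    """Per-subject combined genetic score.

    Parameters
    ----------
    dosages
        Imputed (no-missing) subjects x SNPs dosage matrix.
    weights
        Per-SNP weights aligned with the columns; None for the unweighted
        (allele-count) score.

    Returns a DataFrame indexed like ``dosages`` with columns
    ``raw_score`` and ``rounded_score``.
    """
    if dosages.isna().any().any():
        raise ValueError("dosages contain missing values; impute first")
    X = dosages.to_numpy(dtype=float)
    if weights is None:
        w = np.ones(X.shape[1])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (X.shape[1],):
            raise ValueError(
                f"weights shape {w.shape} does not match {X.shape[1]} SNPs"
            )
    raw = X @ w
    return pd.DataFrame(
        {"raw_score": raw, "rounded_score": round_half_away(raw)},
        index=dosages.index,
    )


def assign_quartiles(rounded_scores) -> np.ndarray:
    """Quartile groups over integer scores, ties kept together.

    Because many subjects share each integer score, exact quarters are
    impossible; cut-points are the integer scores whose cumulative
    proportion is nearest to 25/50/75% (ties toward the lower score).  All
    subjects with the same rounded score land in the same group, so group
    sizes are unequal.  Labels are 1..4; with heavy ties some labels may be
    empty.  Constant scores are degenerate and rejected.
    """
    s = np.asarray(rounded_scores)
    if len(s) < 4:
        raise ValueError("quartile grouping requires >= 4 subjects")
    uniq, counts = np.unique(s, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("constant scores cannot be split into quartiles")
    cumprop = np.cumsum(counts) / len(s)
    cuts = [uniq[np.argmin(np.abs(cumprop - k / 4.0))] for k in (1, 2, 3)]
    return np.searchsorted(cuts, s, side="left") + 1


def bin_scores(rounded_scores, lower_tail_cut: int, upper_tail_cut: int):
    """Ordinal score bins: <=lower, each integer between, >=upper.

    Mirrors the tail-collapsed score axis used when reporting per-bin odds
    ratios (e.g. bins ``<=4, 5, ..., 10, >=11`` for an 8-SNP score).
    Returns (labels per subject, ordered bin label list).
    """
    if lower_tail_cut >= upper_tail_cut:
        raise ValueError(
            f"lower_tail_cut ({lower_tail_cut}) must be below "
            f"upper_tail_cut ({upper_tail_cut})"
        )
    s = np.asarray(rounded_scores)
    if s.min() > lower_tail_cut or s.max() < upper_tail_cut:
        raise ValueError("tail cuts must lie within the observed score range")
    bin_labels = (
        [f"<={lower_tail_cut}"]
        + [str(v) for v in range(lower_tail_cut + 1, upper_tail_cut)]
        + [f">={upper_tail_cut}"]
    )
    clipped = np.clip(s, lower_tail_cut, upper_tail_cut)
    labels = np.array(bin_labels, dtype=object)[clipped - lower_tail_cut]
    return labels, bin_labels


class GeneticScoreTransformer(BaseEstimator, TransformerMixin):
    """Combined-genetic-score construction as a scikit-learn transformer.

    Parameters
    ----------
    weighting : {"unweighted", "weighted"}, default "unweighted"
        Weighted scoring multiplies each dosage by the SNP's relative
        effect size (beta / mean beta); unweighted sums risk alleles.
    betas : array-like or None
        Per-SNP risk-allele log odds ratios, required for weighted scoring.
        Aligned with the columns of the fitted dosage matrix.

    Attributes (after :meth:`fit`)
    ------------------------------
    n_features_in_ : number of SNPs.
    impute_means_ : per-SNP mean observed dosage used to fill missing values.
    weights_ : per-SNP weights (all 1 for unweighted scoring).

    ``transform`` returns raw scores (n_subjects, 1); use :meth:`score_set`
    for the full per-subject table with rounded scores and quartiles.
    """

    def __init__(self, weighting: str = "unweighted", betas=None):
        self.weighting = weighting
        self.betas = betas

    def fit(self, X, y=None):
        X = self._as_frame(X)
        if self.weighting not in ("unweighted", "weighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        means = X.mean(axis=0, skipna=True)
        if means.isna().any():
            raise ValueError(
                f"SNPs with no observed dosage: {means.index[means.isna()].tolist()}"
            )
        self.n_features_in_ = X.shape[1]
        self.impute_means_ = means.to_numpy()
        if self.weighting == "weighted":
            if self.betas is None:
                raise ValueError("weighted scoring requires betas")
            betas = pd.Series(np.asarray(self.betas, dtype=float), index=X.columns)
            self.weights_ = compute_weights(betas)
        else:
            self.weights_ = np.ones(X.shape[1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = self._as_frame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} SNPs, transformer was fitted on "
                f"{self.n_features_in_}"
            )
        filled = X.fillna(pd.Series(self.impute_means_, index=X.columns))
        raw = filled.to_numpy(dtype=float) @ self.weights_
        return raw.reshape(-1, 1)

    def score_set(self, X) -> pd.DataFrame:
        """Full per-subject score table: raw, rounded, quartile."""
        X = self._as_frame(X)
        raw = self.transform(X)[:, 0]
        out = pd.DataFrame(
            {"raw_score": raw, "rounded_score": round_half_away(raw)},
            index=X.index,
        )
        out["quartile"] = assign_quartiles(out["rounded_score"].to_numpy())
        return out

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        return pd.DataFrame(X)
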
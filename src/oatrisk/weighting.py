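"""Propensity scores, stabilised inverse-probability weights, balance.

Methadone and buprenorphine are not assigned at random: sicker patients
tend to receive methadone (confounding by indication).  A main-effects
logistic model estimates each patient's probability of receiving
methadone from baseline covariates; stabilised weights
``P(T=t) / P(T=t | X)`` then reweight the two arms to a pseudo-population
in which baseline covariates are balanced.  Balance is reported as signed
standardised differences (methadone minus buprenorphine) on covariate
indicators, before and after weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

METHADONE = "methadone"


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in the propensity model."""


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Indicator expansion with reference levels dropped, plus intercept."""
    X = pd.get_dummies(covariates.astype("object"), drop_first=True, dtype=float)
    X.insert(0, "intercept", 1.0)
    return X


@dataclass
class PropensityFit:
    result: object  # statsmodels GLMResults
    scores: pd.Series  # P(methadone | X)
    design_columns: tuple

    @property
    def params(self) -> pd.Series:
        return self.result.params


def fit_propensity(covariates: pd.DataFrame, modality: pd.Series) -> PropensityFit:
    """Logistic regression of treatment (methadone = 1) on baseline
    covariates; returns the fit and fitted scores in (0, 1).

    Raises :class:`SeparationError` when the likelihood degenerates
    (fitted probabilities numerically 0/1), suggesting category
    collapsing.
    """
    y = (np.asarray(modality) == METHADONE).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 patients per modality")
    X = _design(covariates)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # statsmodels raises various errors on separation
        raise SeparationError(
            f"propensity model failed ({exc}); consider collapsing sparse categories"
        ) from exc
    scores = pd.Series(res.fittedvalues, index=covariates.index, name="p_methadone")
    eps = 1e-10
    if (scores < eps).any() or (scores > 1 - eps).any():
        raise SeparationError(
            "fitted propensity scores at 0/1; consider collapsing sparse categories"
        )
    return PropensityFit(result=res, scores=scores, design_columns=tuple(X.columns))


def stabilised_ipw(
    scores: pd.Series,
    modality: pd.Series,
    truncate_percentiles: tuple[float, float] | None = None,
) -> pd.Series:
    """Stabilised weights P(T=t) / P(T=t | X).

    Methadone patients get ``p_marg / p_hat`` and buprenorphine patients
    ``(1 - p_marg) / (1 - p_hat)``; the cohort-mean stabilised weight is
    approximately 1.  Optional percentile truncation (e.g. ``(1, 99)``)
    caps extreme weights; off by default.
    """
    scores = pd.Series(scores)
    is_mtd = pd.Series(np.asarray(modality) == METHADONE, index=scores.index)
    if ((scores <= 0) | (scores >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    p_marg = is_mtd.mean()
    w = np.where(is_mtd, p_marg / scores, (1 - p_marg) / (1 - scores))
    w = pd.Series(w, index=scores.index, name="weight")
    if truncate_percentiles is not None:
        lo, hi = np.percentile(w, truncate_percentiles)
        w = w.clip(lo, hi)
    if not np.isfinite(w).all():
        raise ValueError("non-finite stabilised weights")
    return w


def standardised_differences(
    covariates: pd.DataFrame,
    modality: pd.Series,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Signed standardised differences (methadone minus buprenorphine) for
    every covariate indicator, optionally under weights.

    For an indicator with group prevalences p1, p2 the statistic is
    ``(p1 - p2) / sqrt((p1 (1-p1) + p2 (1-p2)) / 2)``; defined as 0 when
    both group variances vanish.  The conventional imbalance flag is
    |ASD| > 0.1.
    """
    ind = pd.get_dummies(covariates.astype("object"), drop_first=False, dtype=float)
    is_mtd = np.asarray(modality) == METHADONE
    w = (
        np.ones(len(ind))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    rows = []
    for col in ind.columns:
        v = ind[col].to_numpy()
        p = []
        for mask in (is_mtd, ~is_mtd):
            p.append(np.average(v[mask], weights=w[mask]))
        p1, p2 = p
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        asd = 0.0 if pooled <= 0 else (p1 - p2) / np.sqrt(pooled)
        rows.append((col, p1, p2, asd))
    return pd.DataFrame(
        rows, columns=["indicator", "prev_methadone", "prev_buprenorphine", "asd"]
    )
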
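"""Rate-ratio and hazard-ratio estimation for overdose person-time data.

Multiple-event analyses model stratum or patient-interval counts with a
log person-time offset under Poisson or NB2 negative-binomial likelihoods
(the latter when a boundary-corrected likelihood-ratio test finds
overdispersion).  Weighted (IPW) fits always use a cluster-robust
sandwich variance by patient, since model-based standard errors are
invalid for weighted pseudo-populations.  First-event (incidence)
analyses use a Cox proportional-hazards model on counting-process
intervals so the risk window is a time-varying exposure.

Point estimates come from statsmodels maximum likelihood; the cluster
sandwich is assembled here from per-record score contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.discrete.discrete_model import NegativeBinomial as _DiscreteNB

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RateRatioEstimate:
    """A ratio estimate with its 95% CI and provenance."""

    label: str
    rr: float
    ci_low: float
    ci_high: float
    flavour: str  # uRR, aRR, wRR, uHR, aHR, wHR, IR-based RR
    model: str = "crude"
    degenerate: bool = False

    def as_tuple(self):
        return self.rr, self.ci_low, self.ci_high


def crude_rate_ratio(
    events1: float,
    py1: float,
    events0: float,
    py0: float,
    label: str = "exposed vs reference",
    flavour: str = "uRR",
) -> RateRatioEstimate:
    """Ratio of two crude rates with a log-normal CI.

    ``SE(log RR) = sqrt(1/events1 + 1/events0)`` — person-time is treated
    as fixed.  Zero events in either cell leave the CI undefined and flag
    the estimate as degenerate.
    """
    if py1 <= 0 or py0 <= 0:
        raise ValueError("person-time must be positive")
    if events1 < 0 or events0 < 0:
        raise ValueError("event counts must be non-negative")
    if events1 == 0 or events0 == 0:
        rr = np.inf if events0 == 0 and events1 > 0 else 0.0
        return RateRatioEstimate(label, rr, np.nan, np.nan, flavour, "crude", True)
    rr = (events1 / py1) / (events0 / py0)
    se = np.sqrt(1.0 / events1 + 1.0 / events0)
    return RateRatioEstimate(
        label, rr, rr * np.exp(-Z95 * se), rr * np.exp(Z95 * se), flavour, "crude"
    )


def expand_design(
    records: pd.DataFrame, factors: dict[str, str | None]
) -> pd.DataFrame:
    """Indicator design for categorical factors with explicit references.

    ``factors`` maps column name to its reference level (``None`` for a
    numeric column included as-is).  Indicator columns are named
    ``col[level]``.
    """
    cols = {}
    for col, ref in factors.items():
        if ref is None:
            cols[col] = records[col].astype(float)
            continue
        levels = pd.unique(records[col])
        if ref not in set(levels):
            raise ValueError(f"reference level {ref!r} absent from column {col!r}")
        for lev in sorted(str(l) for l in levels):
            if lev == str(ref):
                continue
            cols[f"{col}[{lev}]"] = (records[col].astype(str) == lev).astype(float)
    X = pd.DataFrame(cols, index=records.index)
    X.insert(0, "intercept", 1.0)
    return X


@dataclass
class CountFit:
    """A fitted count model (Poisson or NB2) with offset.

    Holds everything needed to recompute robust variances: the design,
    response, offset, weights and fitted means.
    """

    kind: str  # "poisson" | "negbin"
    params: pd.Series
    cov: pd.DataFrame
    alpha: float  # NB2 dispersion; 0 for Poisson
    llf: float
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    offset: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    cov_type: str = "model"

    def rate_ratio(self, term: str, flavour: str = "uRR") -> RateRatioEstimate:
        b = self.params[term]
        se = np.sqrt(self.cov.loc[term, term])
        return RateRatioEstimate(
            term,
            float(np.exp(b)),
            float(np.exp(b - Z95 * se)),
            float(np.exp(b + Z95 * se)),
            flavour,
            self.kind,
        )

    def summary(self, flavour: str = "uRR") -> pd.DataFrame:
        rows = [
            self.rate_ratio(t, flavour)
            for t in self.params.index
            if t != "intercept"
        ]
        return pd.DataFrame(
            [(r.label, r.rr, r.ci_low, r.ci_high, r.flavour, r.model) for r in rows],
            columns=["term", "rr", "ci_low", "ci_high", "flavour", "model"],
        )


def _check_rank(X: pd.DataFrame):
    arr = X.to_numpy()
    degenerate = [
        c for c in X.columns if c != "intercept" and X[c].nunique() <= 1
    ]
    if degenerate:
        raise ValueError(f"constant column(s) in design: {degenerate}")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient")


def _records_arrays(records, factors, weights):
    X = expand_design(records, factors)
    _check_rank(X)
    y = records["events"].to_numpy(dtype=float)
    py = records["person_years"].to_numpy(dtype=float)
    if (py <= 0).any():
        raise ValueError("person_years must be positive")
    offset = np.log(py)
    w = (
        np.ones(len(records))
        if weights is None
        else np.asarray(records[weights], dtype=float)
    )
    return X, y, offset, w


def fit_poisson(
    records: pd.DataFrame,
    factors: dict[str, str | None],
    weights: str | None = None,
    cluster: str | None = None,
) -> CountFit:
    """Poisson rate model with log person-time offset.

    ``records`` needs ``events`` and ``person_years`` columns plus the
    factor columns; ``weights``/``cluster`` name optional columns (IPW
    fits should cluster by patient).  Exponentiated coefficients are rate
    ratios.
    """
    X, y, offset, w = _records_arrays(records, factors, weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(
            y, X, family=sm.families.Poisson(), offset=offset, var_weights=w
        ).fit()
    if not res.converged:
        raise RuntimeError(f"Poisson fit did not converge: {res.fit_history}")
    fit = CountFit(
        kind="poisson",
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        alpha=0.0,
        llf=float(res.llf),
        X=X,
        y=y,
        offset=offset,
        weights=w,
        mu=np.asarray(res.fittedvalues),
    )
    if cluster is not None or weights is not None:
        groups = records[cluster] if cluster is not None else np.arange(len(records))
        fit.cov = robust_variance(fit, groups)
        fit.cov_type = "cluster-robust"
    return fit


def _glm_nb(X, y, offset, w, alpha):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(
            y,
            X,
            family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-8)),
            offset=offset,
            var_weights=w,
        ).fit()


def fit_negbin(
    records: pd.DataFrame,
    factors: dict[str, str | None],
    weights: str | None = None,
    cluster: str | None = None,
    alpha: float | None = None,
) -> CountFit:
    """NB2 negative-binomial rate model (variance mu + alpha mu^2).

    Unweighted fits use full ML over (beta, alpha); weighted fits profile
    the dispersion alpha over the weighted GLM likelihood; passing
    ``alpha`` fixes the dispersion instead.  As alpha -> 0 the fit
    reduces to the Poisson model.
    """
    X, y, offset, w = _records_arrays(records, factors, weights)
    p = X.shape[1]
    if weights is None and alpha is None:
        # full ML over (beta, alpha) via the discrete-model likelihood
        res = _discrete_nb_fit(X, y, offset)
        beta = np.asarray(res.params[:p])
        alpha = float(max(res.params[p], 0.0))
        params = pd.Series(beta, index=X.columns)
        llf = float(res.llf)
        mu = np.exp(X.to_numpy() @ beta + offset)
        try:
            C = np.asarray(res.cov_params())[:p, :p]
            if not np.all(np.isfinite(C)):
                raise ValueError("non-finite covariance")
        except (ValueError, np.linalg.LinAlgError):
            # Hessian singular at the alpha -> 0 boundary: profile
            # information with the dispersion held fixed
            info = X.to_numpy().T @ (X.to_numpy() * (mu / (1 + alpha * mu))[:, None])
            C = np.linalg.inv(info)
        cov = pd.DataFrame(C, index=X.columns, columns=X.columns)
    else:
        if alpha is None:

            def obj(la):
                try:
                    return -_glm_nb(X, y, offset, w, np.exp(la)).llf
                except (ValueError, np.linalg.LinAlgError):
                    return np.inf  # numerically infeasible dispersion

            opt = minimize_scalar(obj, bounds=(-12.0, 5.0), method="bounded")
            alpha = float(np.exp(opt.x))
        res = _glm_nb(X, y, offset, w, alpha)
        if not res.converged:
            raise RuntimeError("negative binomial fit did not converge")
        params = pd.Series(res.params, index=X.columns)
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        llf = float(res.llf)
        mu = np.asarray(res.fittedvalues)
    fit = CountFit(
        kind="negbin",
        params=params,
        cov=cov,
        alpha=alpha,
        llf=llf,
        X=X,
        y=y,
        offset=offset,
        weights=w,
        mu=mu,
    )
    if cluster is not None or weights is not None:
        groups = records[cluster] if cluster is not None else np.arange(len(records))
        fit.cov = robust_variance(fit, groups)
        fit.cov_type = "cluster-robust"
    return fit


def _discrete_nb_fit(X, y, offset):
    """Full-ML NB2 fit, warm-started from the Poisson solution."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        po = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        start = np.append(np.asarray(po.params), 0.1)
        model = _DiscreteNB(y, X.to_numpy(), offset=offset, loglike_method="nb2")
        try:
            res = model.fit(start_params=start, disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("newton did not converge")
        except Exception:
            res = model.fit(start_params=start, disp=0, method="bfgs", maxiter=500)
    return res


def overdispersion_test(
    records: pd.DataFrame,
    factors: dict[str, str | None],
    level: float = 0.05,
) -> dict:
    """Boundary-corrected LRT of NB2 dispersion alpha = 0 vs alpha > 0.

    Under the null the statistic is a 50:50 mixture of a point mass at 0
    and chi-square(1), so ``p = 0.5 P(chi2_1 > stat)`` (1 when the
    statistic is 0).  Returns statistic, p-value, alpha estimate and the
    recommended family.  With no events the test is undefined and the
    Poisson decision is returned.
    """
    if records["events"].sum() == 0:
        return {"statistic": np.nan, "p_value": np.nan, "alpha": 0.0,
                "family": "poisson", "overdispersed": False}
    po = fit_poisson(records, factors)
    nb = fit_negbin(records, factors)
    stat = max(0.0, 2.0 * (nb.llf - po.llf))
    p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, df=1)
    over = p < level
    return {
        "statistic": stat,
        "p_value": p,
        "alpha": nb.alpha,
        "family": "negbin" if over else "poisson",
        "overdispersed": over,
    }


def robust_variance(fit: CountFit, groups) -> pd.DataFrame:
    """Cluster-robust sandwich covariance for a fitted count model.

    Per-record scores are ``w (y - mu) x / (1 + alpha mu)`` (Poisson:
    alpha = 0); the bread is the expected information
    ``X' diag(w mu / (1 + alpha mu)) X``.  Scores are summed within
    clusters (patients) and a G/(G-1) small-sample factor applied.
    """
    groups = np.asarray(groups)
    codes, uniq = pd.factorize(groups)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")
    X = fit.X.to_numpy()
    denom = 1.0 + fit.alpha * fit.mu
    score = (fit.weights * (fit.y - fit.mu) / denom)[:, None] * X
    info = X.T @ (X * (fit.weights * fit.mu / denom)[:, None])
    bread = np.linalg.inv(info)
    meat = np.zeros_like(info)
    summed = np.zeros((n_groups, X.shape[1]))
    np.add.at(summed, codes, score)
    meat = summed.T @ summed
    cov = bread @ meat @ bread * (n_groups / (n_groups - 1))
    return pd.DataFrame(cov, index=fit.X.columns, columns=fit.X.columns)


def cox_cluster_variance(
    X: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    params: np.ndarray,
    naive_cov: np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray,
) -> np.ndarray:
    """Cluster-robust sandwich covariance for a (weighted) Breslow Cox fit
    on counting-process data.

    Per-record weighted score residuals
    ``U_i = d_i w_i (x_i - xbar(t_i)) - r_i sum_k [i in R_k] (dw_k / S0_k)(x_i - xbar_k)``
    (r_i = w_i exp(x_i b)) are summed within clusters; the sandwich is
    ``I^-1 (sum_g U_g U_g') I^-1`` with the naive covariance as bread.
    Risk-set sums use prefix accumulation over the distinct event times,
    so the cost is O((n + K) p).
    """
    eta = X @ params
    r = weights * np.exp(eta)
    ev = event.astype(bool)
    times, inv = np.unique(stop[ev], return_inverse=True)
    K, p = len(times), X.shape[1]

    # risk-set sums S0_k, S1_k via difference arrays over event-time index
    k_lo = np.searchsorted(times, start, side="right")  # first k with t_k > start
    k_hi = np.searchsorted(times, stop, side="right")  # first k with t_k > stop
    d0 = np.zeros(K + 1)
    d1 = np.zeros((K + 1, p))
    at_risk = k_lo < k_hi
    np.add.at(d0, k_lo[at_risk], r[at_risk])
    np.add.at(d0, k_hi[at_risk], -r[at_risk])
    np.add.at(d1, k_lo[at_risk], r[at_risk, None] * X[at_risk])
    np.add.at(d1, k_hi[at_risk], -r[at_risk, None] * X[at_risk])
    S0 = np.cumsum(d0)[:K]
    S1 = np.cumsum(d1, axis=0)[:K]
    xbar = S1 / S0[:, None]

    dw = np.zeros(K)
    np.add.at(dw, inv, weights[ev])

    # prefix sums of dw_k / S0_k and dw_k xbar_k / S0_k
    A0 = np.concatenate([[0.0], np.cumsum(dw / S0)])
    A1 = np.concatenate([np.zeros((1, p)), np.cumsum(dw[:, None] * xbar / S0[:, None], axis=0)])
    dA0 = A0[k_hi] - A0[k_lo]
    dA1 = A1[k_hi] - A1[k_lo]

    U = -r[:, None] * (X * dA0[:, None] - dA1)
    U[ev] += weights[ev, None] * (X[ev] - xbar[inv])

    codes, uniq = pd.factorize(groups)
    Ug = np.zeros((len(uniq), p))
    np.add.at(Ug, codes, U)
    meat = Ug.T @ Ug
    G = len(uniq)
    return naive_cov @ meat @ naive_cov * (G / (G - 1))


@dataclass
class CoxFit:
    params: pd.Series
    cov: pd.DataFrame
    summary_frame: pd.DataFrame = field(repr=False)
    fitter: object = field(repr=False, default=None)

    def hazard_ratio(self, term: str, flavour: str = "uHR") -> RateRatioEstimate:
        b = self.params[term]
        se = np.sqrt(self.cov.loc[term, term])
        return RateRatioEstimate(
            term,
            float(np.exp(b)),
            float(np.exp(b - Z95 * se)),
            float(np.exp(b + Z95 * se)),
            flavour,
            "cox",
        )


def fit_cox_first_event(
    records: pd.DataFrame,
    factors: dict[str, str | None],
    weights: str | None = None,
    strata: list[str] | None = None,
    id_col: str = "patient_id",
) -> CoxFit:
    """Cox proportional-hazards fit on counting-process intervals.

    ``records`` is the first-event view: one row per risk interval with
    ``start``/``end`` (days since index), an ``event`` indicator, and the
    factor columns; time-varying exposure is encoded by the interval
    split.  Weighted fits replace the naive covariance with a
    cluster-robust sandwich by ``id_col`` (model-based standard errors
    are invalid for IPW pseudo-populations).  ``strata`` columns allow
    baseline-hazard stratification (e.g. follow-up-duration groups).
    """
    from lifelines import CoxTimeVaryingFitter

    if records["event"].sum() == 0:
        raise ValueError("no events; cannot fit a Cox model")
    X = expand_design(records, factors).drop(columns="intercept")
    df = pd.concat(
        [records[[id_col, "start", "end", "event"]].reset_index(drop=True),
         X.reset_index(drop=True)],
        axis=1,
    )
    if weights is not None:
        df["_w"] = records[weights].to_numpy(dtype=float)
    if strata:
        for s in strata:
            df[s] = records[s].to_numpy()
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(
            df,
            id_col=id_col,
            event_col="event",
            start_col="start",
            stop_col="end",
            weights_col="_w" if weights is not None else None,
            strata=strata,
        )
    params = ctv.params_.copy()
    cov = pd.DataFrame(
        np.asarray(ctv.variance_matrix_), index=params.index, columns=params.index
    )
    if weights is not None:
        if strata:
            raise NotImplementedError("robust variance with strata not supported")
        robust = cox_cluster_variance(
            X[params.index].to_numpy(dtype=float),
            records["start"].to_numpy(dtype=float),
            records["end"].to_numpy(dtype=float),
            records["event"].to_numpy(dtype=float),
            params.to_numpy(),
            cov.to_numpy(),
            records[weights].to_numpy(dtype=float),
            records[id_col].to_numpy(),
        )
        cov = pd.DataFrame(robust, index=params.index, columns=params.index)
    return CoxFit(params=params, cov=cov, summary_frame=ctv.summary, fitter=ctv)
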
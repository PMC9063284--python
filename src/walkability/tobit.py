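"""Left-censored Gaussian (Tobit) regression and the validation analyses.

The model: a latent linear outcome ``y* = x'beta + eps``, ``eps ~ N(0,
sigma^2)``, observed as ``y = max(0, y*)``.  With more than half of
respondents reporting zero walking minutes, OLS on the observed outcome is
biased toward zero; the Tobit likelihood

    sum_{y=0} log Phi(-x'beta / sigma)
  + sum_{y>0} [ log phi((y - x'beta)/sigma) - log sigma ]

handles the point mass at zero.  Maximization is quasi-Newton over
``(beta, log sigma)`` (the log keeps sigma positive) with an analytic
gradient, OLS-on-positives initialization and jittered restarts; the
coefficient covariance comes from the inverse observed information.

Effects are reported per 10 points of the 0-100 walkability index ("per
10% increase") with 95% Wald intervals.  On top of single fits sit the
leave-one-out attenuation analysis, stratified fits and Wald interaction
tests.  Observations are treated as independent (no clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

#: the fully adjusted ("Model 2") confounder set; ``ses`` is continuous,
#: the rest are categorical and enter as full dummy blocks (first level
#: as reference)
MODEL2_CONFOUNDERS = (
    "age_group", "sex", "ethnicity", "education", "work_status", "income",
    "car_ownership", "household", "cycled_same_day", "season", "weekday",
    "response_type", "ses",
)

_CONTINUOUS = {"ses"}


@dataclass
class TobitFit:
    """Fitted left-censored regression."""

    beta: np.ndarray
    sigma: float
    cov: np.ndarray            # covariance of beta
    loglik: float
    n_total: int
    n_censored: int
    converged: bool
    names: list[str] = field(default_factory=list)
    sigma_se: float = np.nan

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, SE) of one named coefficient."""
        if name not in self.names:
            raise KeyError(f"no coefficient {name!r}; have {self.names}")
        j = self.names.index(name)
        return float(self.beta[j]), float(self.se()[j])


@dataclass
class EffectEstimate:
    """Effect per 10 index points with a 95% Wald interval."""

    estimate: float
    ci_low: float
    ci_high: float
    outcome: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def tobit_loglik(beta, sigma: float, X, y) -> float:
    """Log-likelihood of the left-censored-at-zero Gaussian model."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("outcome must be non-negative (left-censored at 0)")
    xb = X @ np.asarray(beta, dtype=float)
    cens = y == 0
    ll = float(special.log_ndtr(-xb[cens] / sigma).sum())
    z = (y[~cens] - xb[~cens]) / sigma
    ll += float((-0.5 * np.log(2 * np.pi) - 0.5 * z * z - np.log(sigma)).sum())
    return ll


def _negll_grad(theta, X, y, cens):
    """Negative log-likelihood and gradient over (beta, log sigma)."""
    beta, logsig = theta[:-1], theta[-1]
    sigma = np.exp(logsig)
    xb = X @ beta
    a = -xb[cens] / sigma
    z = (y[~cens] - xb[~cens]) / sigma
    ll = special.log_ndtr(a).sum() + (-0.5 * np.log(2 * np.pi)
                                      - 0.5 * z * z - logsig).sum()
    # inverse Mills ratio phi(a)/Phi(a), computed in log space for stability
    lam = np.exp(stats.norm.logpdf(a) - special.log_ndtr(a))
    g_beta = -(X[cens].T @ lam) / sigma + (X[~cens].T @ z) / sigma
    g_logsig = float(-(a * lam).sum() + (z * z - 1.0).sum())
    return -ll, -np.concatenate([g_beta, [g_logsig]])


def tobit_fit(X, y, names=None, max_restarts: int = 3,
              seed: int = 0) -> TobitFit:
    """Maximum-likelihood Tobit fit.

    ``X`` is the design matrix (include the intercept column yourself or
    use :func:`build_design`); ``y`` the non-negative outcome.  Raises if
    every observation is censored or the design is rank deficient; reports
    (rather than hides) non-convergence after restarts.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValueError(f"n = {n} observations for p = {p} parameters")
    if (y < 0).any():
        raise ValueError("outcome must be non-negative")
    cens = y == 0
    if cens.all():
        raise ValueError("all observations censored at zero; model unidentified")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    # init: OLS on the positive observations (falls back to all rows)
    pos = ~cens
    Xi, yi = (X[pos], y[pos]) if pos.sum() > p else (X, y)
    beta0, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    resid = yi - Xi @ beta0
    sig0 = max(float(np.sqrt(resid @ resid / max(len(yi) - p, 1))), 1e-3)
    theta0 = np.concatenate([beta0, [np.log(sig0)]])

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 * (
            1 + 0.05 * rng.standard_normal(theta0.shape))
        res = optimize.minimize(_negll_grad, start, args=(X, y, cens),
                                jac=True, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res if res.fun <= best.fun else best
            break
    # BFGS can report "precision loss" at a genuine optimum; judge
    # convergence by the relative gradient norm at the solution
    _, g = _negll_grad(best.x, X, y, cens)
    converged = bool(best.success) or bool(
        np.abs(g).max() < 1e-6 * (1.0 + abs(best.fun)))
    if not converged:
        log.warning("tobit_fit: optimizer did not converge (%s)", best.message)

    theta = best.x
    hess = _numeric_hessian(lambda t: _negll_grad(t, X, y, cens)[1], theta)
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)
    cov_all = 0.5 * (cov_all + cov_all.T)
    sigma = float(np.exp(theta[-1]))
    return TobitFit(
        beta=theta[:-1], sigma=sigma, cov=cov_all[:-1, :-1],
        loglik=-float(best.fun), n_total=n, n_censored=int(cens.sum()),
        converged=converged, names=names,
        sigma_se=float(sigma * np.sqrt(max(cov_all[-1, -1], 0.0))),
    )


def _numeric_hessian(grad_fn, theta, eps: float = 1e-5) -> np.ndarray:
    """Observed information via central differences of the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (H + H.T)


# -- design matrices ------------------------------------------------------

def build_design(data: pd.DataFrame, outcome: str,
                 index_col: str = "walkability",
                 confounders=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (const + index + confounder dummies) and outcome vector.

    ``confounders=None`` gives the unadjusted Model 1;
    ``confounders=MODEL2_CONFOUNDERS`` the fully adjusted Model 2.
    Categorical confounders are dummy-coded against their first
    (lexicographically sorted) level; continuous ones enter as-is.
    """
    cols = {"const": np.ones(len(data)), index_col: data[index_col].to_numpy(dtype=float)}
    for v in confounders or ():
        if v in _CONTINUOUS:
            cols[v] = data[v].to_numpy(dtype=float)
        else:
            levels = sorted(map(str, data[v].unique()))
            for lev in levels[1:]:
                cols[f"{v}[{lev}]"] = (data[v].astype(str) == lev).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    y = data[outcome].to_numpy(dtype=float)
    return X, y


# -- reporting ------------------------------------------------------------

Z95 = 1.96


def effect_per_10(fit: TobitFit, predictor: str = "walkability",
                  outcome: str = "", model: str = "") -> EffectEstimate:
    """Effect per 10 points of the 0-100 index, with a 95% Wald interval.

    A "10% increase" in an index spanning exactly 0-100 is 10 points, so
    the reported effect is ``10 * beta`` and the CI ``10 * (beta +/- 1.96
    SE)``.
    """
    b, se = fit.coef(predictor)
    return EffectEstimate(
        estimate=10.0 * b,
        ci_low=10.0 * (b - Z95 * se),
        ci_high=10.0 * (b + Z95 * se),
        outcome=outcome, model=model,
    )


def fit_and_report(data: pd.DataFrame, outcome: str,
                   index_col: str = "walkability",
                   confounders=None, model_label: str = "",
                   seed: int = 0) -> tuple[TobitFit, EffectEstimate]:
    """Convenience wrapper: build design, fit, report effect per 10 points."""
    X, y = build_design(data, outcome, index_col, confounders)
    fit = tobit_fit(X, y, seed=seed)
    return fit, effect_per_10(fit, index_col, outcome=outcome, model=model_label)


def attenuation_analysis(data: pd.DataFrame, outcome: str,
                         partial_cols, full_col: str = "walkability",
                         confounders=MODEL2_CONFOUNDERS,
                         seed: int = 0) -> pd.DataFrame:
    """Leave-one-out attenuation table for one outcome.

    Refits the fully adjusted model with each partial (six-component) index
    substituted for the full one.  The partial with the *smallest* effect
    estimate marks the omitted component as the driver of the association
    (``drives_association`` flag).  Per-row fit errors are recorded and the
    remaining rows continue.
    """
    rows = []
    for label, col in [("full", full_col)] + [
            (c.removeprefix("partial_"), c) for c in partial_cols]:
        try:
            fit, eff = fit_and_report(data, outcome, index_col=col,
                                      confounders=confounders,
                                      model_label="Model 2", seed=seed)
            rows.append({"index": label, "omitted_component":
                         None if label == "full" else label,
                         "estimate_per_10": eff.estimate,
                         "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                         "n": fit.n_total, "n_censored": fit.n_censored,
                         "loglik": fit.loglik, "error": None})
        except (ValueError, KeyError) as exc:   # keep going per spec
            log.warning("attenuation fit failed for %s: %s", label, exc)
            rows.append({"index": label, "omitted_component": label,
                         "estimate_per_10": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": len(data),
                         "n_censored": int((data[outcome] == 0).sum()),
                         "loglik": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows)
    partials = out[out["index"] != "full"]
    est = partials["estimate_per_10"]
    out["drives_association"] = False
    if est.notna().any():
        out.loc[est.idxmin(), "drives_association"] = True
    return out


def stratified_fits(data: pd.DataFrame, stratum_var: str, outcome: str,
                    index_col: str = "walkability",
                    confounders=MODEL2_CONFOUNDERS,
                    seed: int = 0) -> pd.DataFrame:
    """Independent fully adjusted fits per stratum of one variable.

    The stratifier is removed from the confounder set within its own
    strata (stratifying on age drops the age-group adjustment, etc.).
    Strata too small to fit are reported as not estimable rather than
    raised.
    """
    levels = sorted(map(str, data[stratum_var].dropna().unique()))
    if len(levels) < 2:
        raise ValueError(f"stratum variable {stratum_var!r} has fewer than 2 levels")
    conf = tuple(c for c in (confounders or ()) if c != stratum_var)
    rows = []
    for lev in levels:
        sub = data[data[stratum_var].astype(str) == lev]
        try:
            fit, eff = fit_and_report(sub, outcome, index_col=index_col,
                                      confounders=conf, model_label="Model 2",
                                      seed=seed)
            rows.append({"stratum": lev, "n": fit.n_total,
                         "n_censored": fit.n_censored,
                         "estimate_per_10": eff.estimate,
                         "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                         "estimable": True, "note": ""})
        except ValueError as exc:
            rows.append({"stratum": lev, "n": len(sub),
                         "n_censored": int((sub[outcome] == 0).sum()),
                         "estimate_per_10": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "estimable": False,
                         "note": str(exc)})
    return pd.DataFrame(rows)


def interaction_test(data: pd.DataFrame, modifier: str, outcome: str,
                     index_col: str = "walkability",
                     confounders=MODEL2_CONFOUNDERS,
                     seed: int = 0) -> float:
    """Wald p-value for walkability x modifier interaction terms.

    Fits one pooled fully adjusted Tobit with the modifier's dummies and
    their products with the index, then tests the joint null that all
    interaction coefficients are zero (chi-squared on the Wald statistic).
    """
    levels = sorted(map(str, data[modifier].dropna().unique()))
    if len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} is constant")
    conf = tuple(dict.fromkeys(tuple(confounders or ()) + (modifier,)))
    X, y = build_design(data, outcome, index_col, conf)
    inter_names = []
    for lev in levels[1:]:
        dummy = (data[modifier].astype(str) == lev).astype(float).to_numpy()
        name = f"{index_col}:{modifier}[{lev}]"
        X[name] = dummy * data[index_col].to_numpy(dtype=float)
        inter_names.append(name)
    fit = tobit_fit(X, y, seed=seed)
    idx = [fit.names.index(n) for n in inter_names]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    w = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(w, df=len(idx)))
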
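"""Pre-selection of adjustment covariates by univariable Weibull PH fits.

Each candidate covariate is fitted alone (with an intercept and the Weibull
shape) by maximum likelihood; a covariate enters the geostatistical model when
its smallest level-wise Wald p-value is below 0.15. This deliberately liberal
threshold keeps potential confounders rather than testing hypotheses, so no
multiplicity adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import survival_core

INCLUSION_P = 0.15

#: Reference category per covariate (the rows printed as HRR 1.00).
REFERENCE_CATEGORIES = {
    "sex": "female",
    "residence": "urban",
    "delivery_place": "health facility",
    "birth_order": "1-5",
    "mother_age": "<19",
    "age_first_birth": "<=19",
    "parity": "1-5",
    "education": "primary+",
    "wealth": "richest",
}


def dummy_columns(series: pd.Series, covariate: str):
    """One indicator column per non-reference level of a categorical covariate."""
    levels = sorted(series.dropna().unique().tolist(), key=str)
    ref = REFERENCE_CATEGORIES.get(covariate, levels[0])
    if ref not in levels:
        ref = levels[0]
    cols, names = [], []
    for lev in levels:
        if lev == ref:
            continue
        cols.append((series == lev).to_numpy(dtype=float))
        names.append(f"{covariate}[{lev}]")
    return cols, names, ref


def build_design(children: pd.DataFrame, covariates) -> tuple[np.ndarray, list]:
    """Design matrix with intercept and treatment-coded categorical covariates.

    Numeric columns are passed through unchanged; categorical columns are
    expanded against their reference category.
    """
    n = len(children)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for cov in covariates:
        if cov not in children.columns:
            raise KeyError(f"covariate {cov!r} not present in child records")
        series = children[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            c, nm, _ = dummy_columns(series, cov)
            if not c:
                raise ValueError(f"covariate {cov!r} is constant")
            cols.extend(c)
            names.extend(nm)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class WeibullFit:
    """MLE of a (non-spatial) Weibull PH model.

    ``coef``/``se`` exclude the Weibull shape, whose MLE is ``delta``.
    """

    delta: float
    coef: np.ndarray
    se: np.ndarray
    names: list
    loglik: float
    converged: bool
    vcov: np.ndarray | None = None  # full covariance incl. leading log δ row/col

    def hrr(self):
        return np.exp(self.coef)

    def ci95(self):
        lo = np.exp(self.coef - 1.959963984540054 * self.se)
        hi = np.exp(self.coef + 1.959963984540054 * self.se)
        return lo, hi

    def wald_p(self):
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def _negloglik_and_grad(theta, t, e, X, logt, sum_e, sum_e_logt):
    logdelta, beta = theta[0], theta[1:]
    delta = np.exp(logdelta)
    eta = X @ beta
    # exponent clipped so line-search excursions stay finite; the clip is
    # inactive anywhere near the optimum
    u = np.exp(np.minimum(delta * logt + eta, 500.0))  # t^delta e^eta
    ll = sum_e * logdelta + (delta - 1.0) * sum_e_logt + float(e @ eta) - u.sum()
    g_logdelta = sum_e + delta * (sum_e_logt - float(logt @ u))
    g_beta = X.T @ (e - u)
    return -ll, -np.concatenate([[g_logdelta], g_beta])


def fit_weibull_ph(times, events, X, names=None, gtol: float = 1e-8) -> WeibullFit:
    """Maximise the Weibull PH log-likelihood in (log δ, β) by quasi-Newton.

    Standard errors come from the inverse observed information (numerically
    differentiated gradient at the optimum).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if e.sum() < 1:
        raise ValueError("need at least one event")
    logt = np.log(t)
    sum_e, sum_e_logt = float(e.sum()), float(e @ logt)
    x0 = np.zeros(1 + X.shape[1])
    res = optimize.minimize(
        _negloglik_and_grad, x0, args=(t, e, X, logt, sum_e, sum_e_logt),
        jac=True, method="BFGS", options={"gtol": gtol, "maxiter": 500},
    )
    theta = res.x
    # BFGS reports "precision loss" near machine-accurate optima on large n;
    # judge convergence by the gradient norm relative to the likelihood scale
    grad = _negloglik_and_grad(theta, t, e, X, logt, sum_e, sum_e_logt)[1]
    grad_ok = float(np.max(np.abs(grad))) < 1e-5 * max(1.0, abs(float(res.fun)))
    hess = _numeric_hessian(
        lambda th: _negloglik_and_grad(th, t, e, X, logt, sum_e, sum_e_logt)[1], theta
    )
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = None
        se_all = np.full(theta.shape, np.nan)
    converged = (bool(res.success) or grad_ok) \
        and np.all(np.isfinite(se_all)) and np.all(se_all[1:] > 0)
    return WeibullFit(
        delta=float(np.exp(theta[0])),
        coef=theta[1:].copy(),
        se=se_all[1:].copy(),
        names=list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])],
        loglik=-float(res.fun),
        converged=converged,
        vcov=cov,
    )


def _numeric_hessian(grad_fn, theta, h: float = 1e-5) -> np.ndarray:
    p = len(theta)
    H = np.zeros((p, p))
    for i in range(p):
        step = np.zeros(p)
        step[i] = h * max(1.0, abs(theta[i]))
        H[:, i] = (grad_fn(theta + step) - grad_fn(theta - step)) / (2.0 * step[i])
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    covariate: str
    level: str
    hrr: float
    ci95: tuple[float, float]
    wald_p: float
    included: bool
    converged: bool = True


def fit_univariable(times, events, x, name: str = "x", include_intercept: bool = True,
                    names=None) -> WeibullFit:
    """Fit one covariate (column or design block) alone.

    With the intercept (default) the coefficients are interpretable as
    log hazard-rate ratios against the reference category.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError(f"covariate {name!r} is constant")
    if include_intercept:
        X = np.column_stack([np.ones(len(x)), x])
        all_names = ["intercept"] + (list(names) if names else [name])
    else:
        X = x
        all_names = list(names) if names else [name]
    return fit_weibull_ph(times, events, X, names=all_names)


def screen(children: pd.DataFrame, covariates, threshold: float = INCLUSION_P):
    """Univariable screening of candidate covariates.

    Returns (results, included) where ``results`` is a list of per-level
    :class:`ScreeningResult` rows mirroring a descriptive HRR table and
    ``included`` is the list of covariates whose minimum level-wise Wald
    p-value is strictly below ``threshold``. Non-converged fits are excluded
    from screening with a warning.
    """
    import warnings

    t = children["time_months"].to_numpy(dtype=float)
    t, _ = survival_core.shift_zero_times(t)
    e = children["event"].to_numpy(dtype=float)
    results: list[ScreeningResult] = []
    included: list[str] = []
    for cov in covariates:
        series = children[cov]
        if pd.api.types.is_numeric_dtype(series):
            block, names = series.to_numpy(dtype=float)[:, None], [cov]
            levels = [cov]
        else:
            cols, names, _ = dummy_columns(series, cov)
            block = np.column_stack(cols)
            levels = [n.split("[", 1)[1][:-1] for n in names]
        try:
            fit = fit_univariable(t, e, block, name=cov, names=names)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"screening fit failed for {cov!r}: {err}", stacklevel=2)
            continue
        # drop the intercept row: only covariate-level coefficients are
        # hazard-rate ratios and only their p-values drive inclusion
        keep = [i for i, nm in enumerate(fit.names) if nm != "intercept"]
        lo, hi = fit.ci95()
        hrr = fit.hrr()[keep]
        lo, hi = lo[keep], hi[keep]
        pvals = fit.wald_p()[keep]
        take = fit.converged and bool(np.nanmin(pvals) < threshold)
        if not fit.converged:
            warnings.warn(f"screening fit for {cov!r} did not converge; excluded", stacklevel=2)
        for lev, h, l_, h_, p in zip(levels, hrr, lo, hi, pvals):
            results.append(ScreeningResult(cov, lev, float(h), (float(l_), float(h_)),
                                           float(p), take, fit.converged))
        if take:
            included.append(cov)
    return results, included


def screening_table(results) -> pd.DataFrame:
    """Flatten screening results into a tidy table."""
    return pd.DataFrame(
        {
            "covariate": [r.covariate for r in results],
            "level": [r.level for r in results],
            "hrr": [r.hrr for r in results],
            "ci_lower": [r.ci95[0] for r in results],
            "ci_upper": [r.ci95[1] for r in results],
            "wald_p": [r.wald_p for r in results],
            "included": [r.included for r in results],
        }
    )
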
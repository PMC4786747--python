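"""Correlating diversity dynamics with environmental and sampling series.

Time-binned palaeontological series carry trends and serial autocorrelation
that inflate pairwise correlations.  Two standard defences are implemented:

* **Generalized differencing** — detrend on time, estimate the lag-1
  autocorrelation ``rho`` of the residuals, and analyse
  ``d_t = r_t - rho * r_{t-1}``; pairwise Pearson correlations (two-sided
  t-test, n-2 df) are then run on the differenced series.

* **AR(1)-GLS model comparison** — each response is regressed on one
  predictor at a time (plus an intercept-only model whose serial-correlation
  parameter spans stationary noise through a near random walk) by maximum
  likelihood with AR(1) errors, ``phi`` profiled on (-0.999, 0.999).  Models
  are ranked by AICc, ``AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)``, with Akaike
  weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``.

The same battery can be run on nested bin windows (e.g. a full series and a
truncated one excluding the final extinction bin) to ask whether a terminal
event dominates the correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GLSFit",
    "generalized_difference",
    "pairwise_correlation",
    "gls_ar1",
    "aicc",
    "akaike_weights",
    "model_compare",
    "run_windows",
]


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc**2)
    if denom == 0:
        return 0.0
    return float(np.sum(xc[1:] * xc[:-1]) / denom)


def generalized_difference(series, times) -> np.ndarray:
    """Detrend on time, then remove estimated lag-1 serial correlation.

    Returns ``d_t = r_t - rho * r_{t-1}`` for ``t >= 2`` (length n-1), where
    ``r`` are residuals from the regression of the series on time and ``rho``
    is their lag-1 sample autocorrelation.  A constant series yields zeros.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("series and times must be equal-length 1-D arrays")
    if len(y) < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(y) == 0:
        return np.zeros(len(y) - 1)
    slope, intercept = np.polyfit(t, y, 1)
    r = y - (slope * t + intercept)
    rho = _lag1_autocorr(r)
    return r[1:] - rho * r[:-1]


def pairwise_correlation(x, y, times, method: str = "pearson"):
    """Correlation of two generalized-differenced series.

    Returns ``(r, p)`` with a two-sided p-value (t distribution on n-2 df for
    Pearson; scipy's exact/asymptotic p for Spearman).
    """
    dx = generalized_difference(x, times)
    dy = generalized_difference(y, times)
    if len(dx) < 3:
        raise ValueError("too few points after differencing")
    if method == "pearson":
        res = stats.pearsonr(dx, dy)
    elif method == "spearman":
        res = stats.spearmanr(dx, dy)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GLSFit:
    name: str
    beta0: float
    beta1: float | None       # None for the intercept-only model
    phi: float
    sigma2: float
    loglik: float
    k: int                    # estimated parameters incl. phi and sigma^2
    n: int
    aicc: float
    beta_se: np.ndarray | None = None
    phi_se: float | None = None
    phi_ci: tuple[float, float] | None = None  # 95% profile-likelihood interval
    weight: float | None = None  # filled by model_compare


def _ar1_profile_loglik(phi: float, y: np.ndarray, X: np.ndarray):
    """Concentrated AR(1) log-likelihood via the Prais-Winsten transform."""
    n = len(y)
    f = np.sqrt(1.0 - phi**2)
    ys = np.empty(n)
    Xs = np.empty_like(X)
    ys[0] = f * y[0]
    Xs[0] = f * X[0]
    ys[1:] = y[1:] - phi * y[:-1]
    Xs[1:] = X[1:] - phi * X[:-1]
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * np.log(1.0 - phi**2)
    return loglik, beta, sigma2, Xs

def aicc(loglik: float, k: int, n: int) -> float:
    """Finite-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def gls_ar1(
    response,
    predictor=None,
    include_predictor: bool = True,
    name: str | None = None,
) -> GLSFit:
    """Maximum-likelihood linear fit with AR(1) errors.

    ``y_t = beta0 (+ beta1 x_t) + eps_t`` with ``eps`` AR(1)(phi); ``phi`` is
    profiled over (-0.999, 0.999).  Standard errors: GLS covariance for the
    betas, numerical curvature of the profile likelihood for ``phi``.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 points")
    if include_predictor:
        if predictor is None:
            raise ValueError("predictor required when include_predictor=True")
        x = np.asarray(predictor, dtype=float)
        if len(x) != n:
            raise ValueError("response and predictor lengths differ")
        X = np.column_stack([np.ones(n), x])
    else:
        X = np.ones((n, 1))

    def neg(phi):
        return -_ar1_profile_loglik(phi, y, X)[0]

    res = optimize.minimize_scalar(neg, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"AR(1) profile likelihood did not converge: {res}")
    phi = float(res.x)
    loglik, beta, sigma2, Xs = _ar1_profile_loglik(phi, y, X)
    XtX = Xs.T @ Xs
    beta_cov = sigma2 * np.linalg.inv(XtX) * n / max(n - X.shape[1], 1)
    beta_se = np.sqrt(np.diag(beta_cov))
    h = 1e-4
    lo = max(phi - h, -0.999)
    hi = min(phi + h, 0.999)
    d2 = (neg(hi) - 2 * neg(phi) + neg(lo)) / ((hi - phi) * (phi - lo))
    phi_se = float(1.0 / np.sqrt(d2)) if d2 > 0 else None
    # 95% profile-likelihood interval: phi with loglik within chi2_1(.95)/2
    drop = 1.9207  # 3.8415 / 2
    target = -loglik + drop

    def _bound(a, b):
        fa = neg(a) - target
        fb = neg(b) - target
        if fa * fb > 0:
            return a if abs(fa) < abs(fb) else b
        return float(optimize.brentq(lambda p: neg(p) - target, a, b, xtol=1e-6))

    ci_lo = _bound(-0.999, phi) if neg(-0.999) > target else -0.999
    ci_hi = _bound(phi, 0.999) if neg(0.999) > target else 0.999
    k = X.shape[1] + 2  # betas + phi + sigma^2
    return GLSFit(
        name=name or ("with_predictor" if include_predictor else "intercept_only"),
        beta0=float(beta[0]),
        beta1=float(beta[1]) if include_predictor else None,
        phi=phi,
        sigma2=sigma2,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
        beta_se=beta_se,
        phi_se=phi_se,
        phi_ci=(ci_lo, ci_hi),
    )


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights from a set of AICc values (invariant to a common shift)."""
    a = np.asarray(aiccs, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def model_compare(response, predictors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Fit each single-predictor AR(1)-GLS model plus the intercept-only model.

    All models are fitted on the common complete-case rows; predictors whose
    overlap with the response is entirely missing are dropped with a warning
    column in the output.
    """
    y = np.asarray(response, dtype=float)
    keep = ~np.isnan(y)
    fits: list[GLSFit] = []
    for pname, x in predictors.items():
        x = np.asarray(x, dtype=float)
        ok = keep & ~np.isnan(x)
        if ok.sum() < 5:
            continue
        fits.append(gls_ar1(y[ok], x[ok], include_predictor=True, name=pname))
    if not fits:
        raise ValueError("no predictor had enough complete cases")
    fits.append(gls_ar1(y[keep], include_predictor=False, name="intercept_only"))
    weights = akaike_weights([f.aicc for f in fits])
    rows = []
    for f, w in zip(fits, weights):
        f.weight = float(w)
        rows.append(
            {
                "model": f.name,
                "beta1": f.beta1,
                "phi": f.phi,
                "loglik": f.loglik,
                "k": f.k,
                "n": f.n,
                "aicc": f.aicc,
                "weight": f.weight,
            }
        )
    return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)


def run_windows(
    response: pd.Series,
    predictors: pd.DataFrame,
    times: pd.Series,
    windows: dict[str, list[str]],
) -> dict[str, dict]:
    """Run the pairwise + model-comparison battery on labelled bin windows.

    ``response``/``predictors``/``times`` are indexed by bin name; each window
    is a list of bin names.  Windows with fewer than 5 bins are skipped.
    """
    out: dict[str, dict] = {}
    for wname, bin_names in windows.items():
        names = [b for b in bin_names if b in response.index]
        if len(names) < 5:
            out[wname] = {"skipped": True, "reason": f"only {len(names)} bins"}
            continue
        y = response.loc[names].to_numpy(dtype=float)
        t = times.loc[names].to_numpy(dtype=float)
        pw = {}
        for col in predictors.columns:
            x = predictors.loc[names, col].to_numpy(dtype=float)
            ok = ~np.isnan(y) & ~np.isnan(x)
            if ok.sum() < 4:
                continue
            r, p = pairwise_correlation(x[ok], y[ok], t[ok])
            pw[col] = {"r": r, "p": p}
        models = model_compare(
            y, {c: predictors.loc[names, c].to_numpy(dtype=float)
                for c in predictors.columns}
        )
        out[wname] = {"skipped": False, "pairwise": pw, "models": models}
    return out
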
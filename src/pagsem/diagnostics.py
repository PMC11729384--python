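"""Pre-modelling measurement diagnostics.

Distribution selection for the weekly-minute indicators (Weibull, gamma,
log-normal, exponential fitted by maximum likelihood and ranked by AIC,
with Kolmogorov-Smirnov statistics against the fitted CDFs), the
Kaiser-Meyer-Olkin sampling-adequacy index, Bartlett's sphericity test and
exploratory factor loadings via principal-axis factoring with varimax
rotation.

Correlations are computed on log(time + 1) by default — the scale on which
the multiplicative Weibull measurement model is linear — with Spearman as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptives import TestResult
from .errors import DomainError

__all__ = [
    "GofReport",
    "distribution_gof",
    "indicator_correlations",
    "kmo_statistic",
    "bartlett_sphericity",
    "extract_factor_loadings",
]

_FAMILIES = {
    "weibull": (stats.weibull_min, 2),
    "gamma": (stats.gamma, 2),
    "lognormal": (stats.lognorm, 2),
    "exponential": (stats.expon, 1),
}


@dataclass(frozen=True)
class GofReport:
    family: str
    params: dict
    ks_statistic: float
    aic: float
    rank: int


def distribution_gof(x, families=("weibull", "gamma", "lognormal", "exponential")) -> list[GofReport]:
    """Fit candidate positive distributions by ML (location fixed at 0) and
    rank them by AIC; smaller is better, rank 1 wins."""
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise DomainError("need at least 10 observations")
    if (x <= 0).any() or not np.isfinite(x).all():
        raise DomainError("values must be strictly positive (pre-shift zeros)")
    unknown = set(families) - set(_FAMILIES)
    if unknown:
        raise DomainError(f"unknown families: {sorted(unknown)}")
    reports = []
    for fam in families:
        dist, k = _FAMILIES[fam]
        if fam == "exponential":
            pars = dist.fit(x, floc=0)
        else:
            pars = dist.fit(x, floc=0)
        ll = float(np.sum(dist.logpdf(x, *pars)))
        aic = 2.0 * k - 2.0 * ll
        ks = float(stats.kstest(x, dist.cdf, args=pars).statistic)
        reports.append((fam, pars, ks, aic))
    order = np.argsort([r[3] for r in reports], kind="stable")
    out = [None] * len(reports)
    for rank, idx in enumerate(order, start=1):
        fam, pars, ks, aic = reports[idx]
        dist, _ = _FAMILIES[fam]
        names = [p.strip() for p in (dist.shapes or "").split(",") if p.strip()]
        pd_ = {**{nm: float(v) for nm, v in zip(names, pars)},
               "loc": float(pars[-2]), "scale": float(pars[-1])}
        out[idx] = GofReport(fam, pd_, ks, float(aic), rank)
    return sorted(out, key=lambda r: r.rank)


def indicator_correlations(
    df: pd.DataFrame, columns, method: str = "pearson", log_shift: float = 1.0
) -> tuple[np.ndarray, int]:
    """Correlation matrix of log-shifted indicator times; returns (R, n)."""
    X = df[list(columns)].to_numpy(dtype=float)
    if (X < 0).any():
        raise DomainError("indicator times must be nonnegative")
    Y = np.log(X + log_shift)
    if method == "pearson":
        R = np.corrcoef(Y.T)
    elif method == "spearman":
        R = stats.spearmanr(Y).statistic
        R = np.atleast_2d(R)
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    return R, len(df)


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DomainError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise DomainError("correlation matrix must have a unit diagonal")
    if not np.allclose(R, R.T, atol=1e-8):
        raise DomainError("correlation matrix must be symmetric")
    return R


def kmo_statistic(R) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy: overall and per-variable.

    Compares squared correlations with squared anti-image partial
    correlations obtained from the inverse correlation matrix. Undefined
    (0/0) for an identity matrix.
    """
    R = _check_corr(R)
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    r2 = R[off] ** 2
    if r2.sum() < 1e-12:
        raise DomainError("KMO is undefined for an identity correlation matrix")
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e12:
        raise DomainError("correlation matrix is singular")
    S = np.linalg.inv(R)
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)  # anti-image partial correlations
    q2 = Q**2
    num = (R**2)[off].sum()
    den = num + q2[off].sum()
    overall = float(num / den)
    num_v = (R**2 * off).sum(axis=1)
    den_v = num_v + (q2 * off).sum(axis=1)
    per_variable = np.divide(num_v, den_v, out=np.full(p, np.nan), where=den_v > 0)
    return overall, per_variable


def bartlett_sphericity(R, n: int) -> TestResult:
    """Bartlett's test that the correlation matrix is the identity:
    ``-(n - 1 - (2p+5)/6) * ln det(R)`` on ``p(p-1)/2`` degrees of freedom."""
    R = _check_corr(R)
    p = R.shape[0]
    if n <= p:
        raise DomainError("sample size must exceed the number of variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or np.any(np.linalg.eigvalsh(R) <= 0):
        raise DomainError("correlation matrix must be positive definite")
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(statistic, df))
    return TestResult(float(statistic), pval, "bartlett-sphericity", int(df))


def _varimax(A: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal)."""
    p, k = A.shape
    if k < 2:
        return A
    Rm = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = A @ Rm
        u, s, vt = np.linalg.svd(A.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p))
        Rm = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return A @ Rm


def extract_factor_loadings(R, n_factors: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis factoring with varimax rotation.

    Returns the rotated ``p x n_factors`` loading matrix and the
    communalities. Communalities start at squared multiple correlations and
    are iterated to convergence on the reduced correlation matrix.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if n_factors >= p:
        raise DomainError("number of factors must be smaller than the number of variables")
    if n_factors < 1:
        raise DomainError("need at least one factor")
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 0.995)
    loadings = np.zeros((p, n_factors))
    for _ in range(200):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        idx = np.argsort(evals)[::-1][:n_factors]
        lam = np.clip(evals[idx], 0.0, None)
        loadings = evecs[:, idx] * np.sqrt(lam)
        h2_new = np.clip((loadings**2).sum(axis=1), 0.0, 0.995)
        if np.max(np.abs(h2_new - h2)) < 1e-6:
            h2 = h2_new
            break
        h2 = h2_new
    rotated = _varimax(loadings)
    # deterministic sign: largest-magnitude loading per factor positive
    for f in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, f]))
        if rotated[i, f] < 0:
            rotated[:, f] *= -1.0
    return rotated, (rotated**2).sum(axis=1)
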
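"""OLS baseline and maximum-likelihood spatial regression for areal data.

Three nested specifications over district-level percentages:

* OLS:              y = X b + e
* Spatial error:    y = X b + u,  u = lambda * W u + xi   (SEM)
* Spatial lag:      y = rho * W y + X b + eps             (SLM)

with W row-standardized queen weights, xi/eps i.i.d. Gaussian.  SEM/SLM are
fitted by maximizing the log-likelihood concentrated in the scalar spatial
parameter; the log-determinant ln|I - a W| is evaluated as
sum_k ln(1 - a w_k) over the (real) eigenvalues of W, exact and cheap for a
few thousand units.  Lagrange-multiplier score tests on the OLS residuals
(error, lag, robust variants, and the joint SARMA form) guide the choice of
spatial specification; AIC ranks the fitted models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import optimize, stats

from .weights import ROW_STANDARDIZED, SpatialWeights

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


@dataclass
class RegressionDesign:
    """Outcome vector and design matrix with a leading intercept column."""

    y: np.ndarray
    x: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        n, k = self.x.shape
        if len(self.y) != n:
            raise ValueError(f"y has {len(self.y)} rows, X has {n}")
        if len(self.names) != k:
            raise ValueError("names must match X columns")
        if not np.allclose(self.x[:, 0], 1.0):
            raise ValueError("X must carry a leading intercept column of ones")
        for j in range(1, k):
            if np.ptp(self.x[:, j]) == 0:
                raise ValueError(f"column {self.names[j]!r} is constant")
        if np.linalg.matrix_rank(self.x) < k:
            raise CollinearityError(_dependent_columns(self.x, self.names))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def k(self) -> int:
        return self.x.shape[1]

    @classmethod
    def from_frame(cls, frame, outcome: str, covariates: list[str]) -> "RegressionDesign":
        """Build a design from a DataFrame: intercept + covariates."""
        if outcome in covariates:
            raise ValueError(f"outcome {outcome!r} cannot also be a covariate")
        missing = [c for c in [outcome, *covariates] if c not in frame.columns]
        if missing:
            raise ValueError(f"variables not in table: {missing}")
        x = np.column_stack(
            [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covariates]
        )
        return cls(frame[outcome].to_numpy(dtype=float), x, ["Intercept", *covariates])


class CollinearityError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; dependent columns: {self.columns}")


def _dependent_columns(x: np.ndarray, names: list[str]) -> list[str]:
    # flag columns whose removal restores full rank
    r = np.linalg.matrix_rank(x)
    bad = []
    for j in range(1, x.shape[1]):
        sub = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(sub) == r:
            bad.append(names[j])
    return bad or list(names[1:])


@dataclass
class OlsResult:
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    sigma2: float  # ML scale e'e/n
    r2: float
    adj_r2: float
    log_likelihood: float
    aic: float
    vif: dict[str, float]
    names: list[str] = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.beta) + 1  # beta plus sigma^2

    def to_dict(self) -> dict:
        return {
            "model": "ols",
            "coefficients": {
                nm: {"beta": float(b), "se": float(s), "p": float(p)}
                for nm, b, s, p in zip(self.names, self.beta, self.se, self.p_values)
            },
            "sigma2": self.sigma2,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "vif": {k: float(v) for k, v in self.vif.items()},
        }


@dataclass
class LmDiagnostics:
    """Rao-score tests for spatial dependence in OLS residuals."""

    lm_error: float
    lm_lag: float
    rlm_error: float
    rlm_lag: float
    sarma: float
    p_lm_error: float
    p_lm_lag: float
    p_rlm_error: float
    p_rlm_lag: float
    p_sarma: float

    def to_dict(self) -> dict:
        return {
            "lm_error": [self.lm_error, self.p_lm_error],
            "lm_lag": [self.lm_lag, self.p_lm_lag],
            "robust_lm_error": [self.rlm_error, self.p_rlm_error],
            "robust_lm_lag": [self.rlm_lag, self.p_rlm_lag],
            "sarma": [self.sarma, self.p_sarma],
        }


@dataclass
class SpatialModelResult:
    kind: str  # "sem" | "slm"
    spatial_param: float
    spatial_param_se: float
    spatial_param_p: float
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray  # innovation residuals (xi-hat for SEM, eps-hat for SLM)
    sigma2: float
    log_likelihood: float
    aic: float
    lr_statistic: float
    lr_p: float
    bp_statistic: float
    bp_p: float
    converged: bool
    search_interval: tuple[float, float]
    names: list[str] = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.beta) + 2  # beta, sigma^2, spatial parameter

    def to_dict(self) -> dict:
        sym = "lambda" if self.kind == "sem" else "rho"
        return {
            "model": self.kind,
            "coefficients": {
                nm: {"beta": float(b), "se": float(s), "p": float(p)}
                for nm, b, s, p in zip(self.names, self.beta, self.se, self.p_values)
            },
            sym: self.spatial_param,
            f"{sym}_se": self.spatial_param_se,
            f"{sym}_p": self.spatial_param_p,
            "sigma2": self.sigma2,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "lr_test": [self.lr_statistic, self.lr_p],
            "breusch_pagan": [self.bp_statistic, self.bp_p],
            "converged": self.converged,
            "search_interval": list(self.search_interval),
        }


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


def fit_ols(design: RegressionDesign) -> OlsResult:
    """Least squares with Gaussian likelihood, VIF, and two-sided z-tests.

    sigma2 is the ML estimate e'e/n (used in the log-likelihood and AIC);
    coefficient standard errors use the unbiased e'e/(n-k).
    """
    y, x = design.y, design.x
    n, k = x.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    e = y - x @ beta
    ss_res = float(e @ e)
    sigma2_ml = ss_res / n
    sigma2_u = ss_res / (n - k)
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(xtx_inv) * sigma2_u)
    zscores = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zscores))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1 - r2) * (n - 1) / (n - k)
    logl = -0.5 * n * (np.log(_TWO_PI * sigma2_ml) + 1.0)
    aic = 2 * (k + 1) - 2 * logl
    return OlsResult(
        beta=beta,
        se=se,
        p_values=pvals,
        residuals=e,
        sigma2=sigma2_ml,
        r2=r2,
        adj_r2=adj_r2,
        log_likelihood=logl,
        aic=aic,
        vif=variance_inflation(design),
        names=list(design.names),
    )


def variance_inflation(design: RegressionDesign) -> dict[str, float]:
    """VIF_j = 1/(1-R2_j) from regressing covariate j on the others
    (intercept included)."""
    x = design.x
    out: dict[str, float] = {}
    for j in range(1, x.shape[1]):
        xj = x[:, j]
        others = np.delete(x, j, axis=1)
        bj, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ bj
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        r2j = 1.0 - ss_res / ss_tot
        out[design.names[j]] = float(1.0 / (1.0 - r2j)) if r2j < 1 else np.inf
    return out


# ---------------------------------------------------------------------------
# LM diagnostics
# ---------------------------------------------------------------------------


def _require_standardized(w: SpatialWeights) -> None:
    if w.style != ROW_STANDARDIZED:
        raise ValueError("row-standardized weights required")


def lm_diagnostics(
    ols: OlsResult, design: RegressionDesign, w: SpatialWeights
) -> LmDiagnostics:
    """Lagrange-multiplier tests for spatial error/lag dependence.

    With s2 = e'e/n, T = tr(W'W + WW), d_e = e'We/s2, d_l = e'Wy/s2 and
    D = (WXb)'M(WXb)/s2 + T (M the annihilator of X):

        LM_err  = d_e^2 / T                  ~ chi2(1)
        LM_lag  = d_l^2 / D                  ~ chi2(1)
        RLM_err = (d_e - T d_l / D)^2 / (T (1 - T/D))
        RLM_lag = (d_l - d_e)^2 / (D - T)
        SARMA   = RLM_err + LM_lag = RLM_lag + LM_err   ~ chi2(2)
    """
    _require_standardized(w)
    if w.islands:
        raise ValueError(
            f"weights contain {len(w.islands)} island(s); remove them before LM diagnostics"
        )
    y, x = design.y, design.x
    e = ols.residuals
    n = design.n
    ws = w.sparse()
    s2 = float(e @ e) / n
    t_tr = float((ws.multiply(ws) + ws.multiply(ws.T)).sum())  # tr(W'W + WW)
    d_e = float(e @ (ws @ e)) / s2
    d_l = float(e @ (ws @ y)) / s2
    wxb = ws @ (x @ ols.beta)
    xtx_inv = np.linalg.inv(x.T @ x)
    m_wxb = wxb - x @ (xtx_inv @ (x.T @ wxb))
    d_big = float(wxb @ m_wxb) / s2 + t_tr

    lm_error = d_e**2 / t_tr
    lm_lag = d_l**2 / d_big
    rlm_error = (d_e - t_tr * d_l / d_big) ** 2 / (t_tr * (1.0 - t_tr / d_big))
    rlm_lag = (d_l - d_e) ** 2 / (d_big - t_tr)
    sarma = rlm_error + lm_lag
    chi1, chi2_ = stats.chi2(1), stats.chi2(2)
    return LmDiagnostics(
        lm_error=lm_error,
        lm_lag=lm_lag,
        rlm_error=rlm_error,
        rlm_lag=rlm_lag,
        sarma=sarma,
        p_lm_error=float(chi1.sf(lm_error)),
        p_lm_lag=float(chi1.sf(lm_lag)),
        p_rlm_error=float(chi1.sf(rlm_error)),
        p_rlm_lag=float(chi1.sf(rlm_lag)),
        p_sarma=float(chi2_.sf(sarma)),
    )


# ---------------------------------------------------------------------------
# heteroskedasticity
# ---------------------------------------------------------------------------


def breusch_pagan_studentized(
    residuals: np.ndarray, design: RegressionDesign
) -> tuple[float, float]:
    """Koenker's studentized Breusch-Pagan: n * R2 from regressing squared
    residuals on the design; chi2 with (#covariates) degrees of freedom."""
    e2 = np.asarray(residuals, dtype=float) ** 2
    x = design.x
    b, *_ = np.linalg.lstsq(x, e2, rcond=None)
    fit = x @ b
    ss_res = float(np.sum((e2 - fit) ** 2))
    ss_tot = float(np.sum((e2 - e2.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    stat = design.n * r2
    df = x.shape[1] - 1
    return float(stat), float(stats.chi2(df).sf(stat))


# ---------------------------------------------------------------------------
# ML spatial models
# ---------------------------------------------------------------------------


def _search_bounds(w: SpatialWeights) -> tuple[float, float]:
    lo, hi = w.stationary_interval()
    return lo + 1e-6, hi - 1e-6


def _log_det(a_param: float, eigs: np.ndarray) -> float:
    vals = 1.0 - a_param * eigs
    if np.any(vals <= 0):
        return -np.inf
    return float(np.log(vals).sum())


def _wald(theta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2 * stats.norm.sf(abs(theta) / se))


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(theta)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            hess[i, j] = hess[j, i] = (
                f(tpp) - f(tpm) - f(tmp) + f(tmm)
            ) / (4 * h[i] * h[j])
    return hess


def _model_ses(full_logl, theta_hat: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Asymptotic SEs from the negative inverse Hessian of the full
    log-likelihood at the optimum: returns (se_beta, se_spatial)."""
    hess = _numerical_hessian(full_logl, theta_hat)
    try:
        cov = np.linalg.inv(-hess)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        se_all = np.sqrt(diag)
    except np.linalg.LinAlgError:
        se_all = np.full(len(theta_hat), np.nan)
    return se_all[:k], float(se_all[k])


def _drop_islands(design: RegressionDesign, w: SpatialWeights):
    """ML fits require a fully connected unit set; islands are removed with a
    log entry and the weights re-standardized on the survivors."""
    isl = w.islands
    if not isl:
        return design, w
    logger.warning(
        "dropping %d island unit(s) from model fit: %s",
        len(isl),
        [w.ids[i] for i in isl],
    )
    keep = np.array([i for i in range(w.n) if i not in set(isl)])
    remap = {old: new for new, old in enumerate(keep)}
    neighbors = []
    for i in keep:
        nb = np.array([remap[j] for j in w.neighbors[i] if j in remap], dtype=int)
        neighbors.append(np.sort(nb))
    sub = SpatialWeights(
        ids=[w.ids[i] for i in keep],
        neighbors=neighbors,
        weights=[np.ones(len(nb)) for nb in neighbors],
        style="binary",
    ).row_standardized()
    d2 = RegressionDesign(design.y[keep], design.x[keep], list(design.names))
    return d2, sub


def fit_spatial_error(
    design: RegressionDesign,
    w: SpatialWeights,
    ols: OlsResult | None = None,
    at_param: float | None = None,
) -> SpatialModelResult:
    """ML spatial error model via the likelihood concentrated in lambda.

    For trial lambda, A = I - lambda*W whitens both sides (y* = Ay,
    X* = AX); beta and sigma2 are profiled out by OLS on the starred data and

        logL(lambda) = -(n/2)(ln(2 pi sigma2) + 1) + ln|A|

    is maximized by bounded scalar search over the stationary interval.
    Standard errors come from the negative inverse numerical Hessian of the
    full likelihood in (beta, lambda, sigma2).
    """
    _require_standardized(w)
    design, w = _drop_islands(design, w)
    y, x = design.y, design.x
    n, k = x.shape
    if n < k + 2:
        raise ValueError("too few units for SEM")
    if ols is None:
        ols = fit_ols(design)
    eigs = w.eigenvalues()
    ws = w.sparse()
    wy, wx = ws @ y, ws @ x
    lo, hi = _search_bounds(w)

    def profile(lam: float):
        ys = y - lam * wy
        xs = x - lam * wx
        b, *_ = np.linalg.lstsq(xs, ys, rcond=None)
        resid = ys - xs @ b
        s2 = float(resid @ resid) / n
        logl = -0.5 * n * (np.log(_TWO_PI * s2) + 1.0) + _log_det(lam, eigs)
        return logl, b, resid, s2

    if at_param is None:
        res = optimize.minimize_scalar(
            lambda lam: -profile(lam)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"SEM likelihood search failed: {res.message}")
    else:
        # evaluate the model at a fixed lambda (e.g. 0, where it reduces to
        # OLS) instead of searching
        lam_hat, converged = float(at_param), True
    if min(lam_hat - lo, hi - lam_hat) < 1e-5:
        logger.warning("SEM lambda estimate %.6f at search boundary", lam_hat)
    logl, beta, xi, s2 = profile(lam_hat)

    def full_logl(theta: np.ndarray) -> float:
        b, lam, sig2 = theta[:k], theta[k], theta[k + 1]
        if sig2 <= 0 or not lo - 1e-3 < lam < hi + 1e-3:
            return -np.inf
        u = y - x @ b
        au = u - lam * (ws @ u)
        return (
            -0.5 * n * np.log(_TWO_PI * sig2)
            + _log_det(lam, eigs)
            - 0.5 * float(au @ au) / sig2
        )

    theta_hat = np.concatenate([beta, [lam_hat, s2]])
    se_beta, se_lam = _model_ses(full_logl, theta_hat, k)
    pvals = 2 * stats.norm.sf(np.abs(beta / se_beta))
    lr = max(0.0, 2 * (logl - ols.log_likelihood))
    bp_stat, bp_p = breusch_pagan_studentized(xi, design)
    return SpatialModelResult(
        kind="sem",
        spatial_param=lam_hat,
        spatial_param_se=se_lam,
        spatial_param_p=_wald(lam_hat, se_lam),
        beta=beta,
        se=se_beta,
        p_values=pvals,
        residuals=xi,
        sigma2=s2,
        log_likelihood=logl,
        aic=2 * (k + 2) - 2 * logl,
        lr_statistic=lr,
        lr_p=float(stats.chi2(1).sf(lr)),
        bp_statistic=bp_stat,
        bp_p=bp_p,
        converged=converged,
        search_interval=(lo, hi),
        names=list(design.names),
    )


def fit_spatial_lag(
    design: RegressionDesign,
    w: SpatialWeights,
    ols: OlsResult | None = None,
    at_param: float | None = None,
) -> SpatialModelResult:
    """ML spatial lag model via the likelihood concentrated in rho:
    regress (y - rho*Wy) on X, logL(rho) = -(n/2)(ln(2 pi sigma2)+1)
    + ln|I - rho*W|; same search/SE machinery as the error model."""
    _require_standardized(w)
    design, w = _drop_islands(design, w)
    y, x = design.y, design.x
    n, k = x.shape
    if n < k + 2:
        raise ValueError("too few units for SLM")
    if ols is None:
        ols = fit_ols(design)
    eigs = w.eigenvalues()
    ws = w.sparse()
    wy = ws @ y
    lo, hi = _search_bounds(w)

    # residual of y and Wy on X can be precomputed: e(rho) = e0 - rho*e1
    xtx_inv = np.linalg.inv(x.T @ x)
    b0 = xtx_inv @ (x.T @ y)
    b1 = xtx_inv @ (x.T @ wy)
    e0 = y - x @ b0
    e1 = wy - x @ b1

    def profile(rho: float):
        resid = e0 - rho * e1
        s2 = float(resid @ resid) / n
        logl = -0.5 * n * (np.log(_TWO_PI * s2) + 1.0) + _log_det(rho, eigs)
        return logl, s2

    if at_param is None:
        res = optimize.minimize_scalar(
            lambda r: -profile(r)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho_hat = float(res.x)
        converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"SLM likelihood search failed: {res.message}")
    else:
        rho_hat, converged = float(at_param), True
    if min(rho_hat - lo, hi - rho_hat) < 1e-5:
        logger.warning("SLM rho estimate %.6f at search boundary", rho_hat)
    logl, s2 = profile(rho_hat)
    beta = b0 - rho_hat * b1
    eps = e0 - rho_hat * e1

    def full_logl(theta: np.ndarray) -> float:
        b, rho, sig2 = theta[:k], theta[k], theta[k + 1]
        if sig2 <= 0 or not lo - 1e-3 < rho < hi + 1e-3:
            return -np.inf
        resid = y - rho * wy - x @ b
        return (
            -0.5 * n * np.log(_TWO_PI * sig2)
            + _log_det(rho, eigs)
            - 0.5 * float(resid @ resid) / sig2
        )

    theta_hat = np.concatenate([beta, [rho_hat, s2]])
    se_beta, se_rho = _model_ses(full_logl, theta_hat, k)
    pvals = 2 * stats.norm.sf(np.abs(beta / se_beta))
    lr = max(0.0, 2 * (logl - ols.log_likelihood))
    bp_stat, bp_p = breusch_pagan_studentized(eps, design)
    return SpatialModelResult(
        kind="slm",
        spatial_param=rho_hat,
        spatial_param_se=se_rho,
        spatial_param_p=_wald(rho_hat, se_rho),
        beta=beta,
        se=se_beta,
        p_values=pvals,
        residuals=eps,
        sigma2=s2,
        log_likelihood=logl,
        aic=2 * (k + 2) - 2 * logl,
        lr_statistic=lr,
        lr_p=float(stats.chi2(1).sf(lr)),
        bp_statistic=bp_stat,
        bp_p=bp_p,
        converged=converged,
        search_interval=(lo, hi),
        names=list(design.names),
    )


def compare_models(*results) -> dict:
    """Rank fitted models by AIC (ties toward fewer parameters).

    Returns a report dict with per-model logL/AIC/k and the winner's name.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    ns = {len(r.residuals) for r in results}
    if len(ns) != 1:
        raise ValueError(f"models fitted on different n: {sorted(ns)}")
    rows = []
    for r in results:
        kind = getattr(r, "kind", "ols")
        rows.append(
            {
                "model": kind,
                "log_likelihood": float(r.log_likelihood),
                "aic": float(r.aic),
                "k_params": int(r.k_params),
            }
        )
    ranked = sorted(rows, key=lambda d: (round(d["aic"], 10), d["k_params"]))
    return {"models": rows, "ranking": [d["model"] for d in ranked], "preferred": ranked[0]["model"]}
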
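"""REML variance components, heritability, and likelihood-ratio tests.

The model is the standard linear mixed model

    y = X b + sum_i u_i + e,   u_i ~ N(0, sigma_i^2 G_i),   e ~ N(0, sigma_e^2 I)

with one or more genomic relationship matrices G_i as the random-effect
covariance structures.  Estimation maximizes the restricted likelihood.
Two code paths share one public surface:

* single-GRM fits rotate the model into the GRM eigenbasis, where the
  covariance is diagonal, and profile out the residual variance —
  a one-dimensional bounded optimization in the variance ratio;
* multi-GRM fits run average-information (AI) REML with an EM fallback
  whenever an AI step would leave the parameter space.

Negative component estimates are clamped to zero with a boundary flag
(no reflection).  Standard errors come from the inverse AI matrix at
the optimum; the heritability SE uses the delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import linalg, optimize, stats

from .kinship import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelSpec",
    "VarCompFit",
    "fit_reml",
    "fit_null_reml",
    "heritability",
    "lrt_genetic",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixedModelSpec:
    """One REML problem: phenotype, fixed effects, genetic covariances."""

    y: np.ndarray
    grms: Sequence[Union[GRM, np.ndarray]]
    X: Optional[np.ndarray] = None  # default intercept-only
    component_names: Optional[List[str]] = None
    sample_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X rows != length of y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is not full column rank")
        mats = []
        for g in self.grms:
            if isinstance(g, GRM):
                if self.sample_ids is not None and g.sample_ids != self.sample_ids:
                    raise ValueError(
                        f"GRM ({g.marker_scope}) sample order does not match y"
                    )
                mats.append(g.values)
            else:
                mats.append(np.asarray(g, dtype=float))
        for m in mats:
            if m.shape != (n, n):
                raise ValueError("GRM dimension does not match y")
        self._mats = mats
        if self.component_names is None:
            self.component_names = [f"g{i + 1}" for i in range(len(mats))]


@dataclass
class VarCompFit:
    """REML estimates for one :class:`MixedModelSpec`."""

    component_names: List[str]
    sigma2: np.ndarray  # genetic components then residual, trait-units^2
    se: np.ndarray
    loglik: float
    h2: float
    h2_se: float
    n_iter: int
    converged: bool
    boundary_flags: np.ndarray
    n_obs: int = 0
    n_fixed: int = 1

    @property
    def sigma2_residual(self) -> float:
        return float(self.sigma2[-1])

    @property
    def sigma2_genetic(self) -> np.ndarray:
        return self.sigma2[:-1]

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            (name, s2, se, int(b))
            for name, s2, se, b in zip(
                self.component_names + ["residual"],
                self.sigma2, self.se, self.boundary_flags,
            )
        ]
        df = pd.DataFrame(rows, columns=["component", "sigma2", "se", "boundary"])
        with open(path, "w") as fh:
            fh.write(f"# loglik\t{self.loglik:.6f}\n")
            fh.write(f"# h2\t{self.h2:.6f}\th2_se\t{self.h2_se:.6f}\n")
            fh.write(f"# converged\t{self.converged}\tn_iter\t{self.n_iter}\n")
            df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# restricted log-likelihood pieces
# ---------------------------------------------------------------------------

def _reml_loglik_from_V(y, X, V) -> float:
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdet_X = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_X + yPy)


def _projection(y, X, V):
    """Return (Py, P-as-operator pieces, loglik) for the current V."""
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True)
    Vi = linalg.cho_solve((c, low), np.eye(n))
    Vi_X = Vi @ X
    XtViX_inv = np.linalg.inv(X.T @ Vi_X)
    P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
    Py = P @ y
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    _, logdet_X = np.linalg.slogdet(X.T @ Vi_X)
    ll = -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_X + float(y @ Py))
    return P, Py, ll


# ---------------------------------------------------------------------------
# null (no genetic component) — closed form
# ---------------------------------------------------------------------------

def fit_null_reml(y: np.ndarray, X: Optional[np.ndarray] = None) -> VarCompFit:
    """REML of y = Xb + e: sigma_e^2 = RSS / (n - p), closed form."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
    p = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        (n - p) * _LOG2PI + (n - p) * np.log(s2) + logdet_XtX + (n - p)
    )
    se = s2 * np.sqrt(2.0 / (n - p))
    return VarCompFit(
        component_names=[],
        sigma2=np.array([s2]),
        se=np.array([se]),
        loglik=ll,
        h2=0.0,
        h2_se=0.0,
        n_iter=0,
        converged=True,
        boundary_flags=np.array([False]),
        n_obs=n,
        n_fixed=p,
    )


# ---------------------------------------------------------------------------
# single-GRM eigenrotation path
# ---------------------------------------------------------------------------

def _fit_single_grm(spec: MixedModelSpec, max_iter: int, tol: float) -> VarCompFit:
    y, X, G = spec.y, spec.X, spec._mats[0]
    n, p = X.shape
    lam, U = np.linalg.eigh(G)
    lam = np.clip(lam, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    def profile_negll(log_theta: float) -> float:
        # theta = sigma_g^2 / sigma_e^2; residual variance profiled out
        theta = np.exp(log_theta)
        d = theta * lam + 1.0
        Xd = Xt / d[:, None]
        XtViX = Xt.T @ Xd
        beta = np.linalg.solve(XtViX, Xd.T @ yt)
        resid = yt - Xt @ beta
        yPy = float(resid @ (resid / d))
        s2e = yPy / (n - p)
        _, logdet_X = np.linalg.slogdet(XtViX)
        ll = -0.5 * (
            (n - p) * _LOG2PI
            + np.sum(np.log(d)) + n * np.log(s2e)
            + logdet_X - p * np.log(s2e)
            + (n - p)
        )
        return -ll

    def _loglik_at(s2g: float, s2e: float) -> float:
        d = s2g * lam + s2e
        Xd = Xt / d[:, None]
        XtViX = Xt.T @ Xd
        beta = np.linalg.solve(XtViX, Xd.T @ yt)
        resid = yt - Xt @ beta
        yPy = float(resid @ (resid / d))
        _, logdet_X = np.linalg.slogdet(XtViX)
        return -0.5 * (
            (n - p) * _LOG2PI + np.sum(np.log(d)) + logdet_X + yPy
        )

    def _score_ai(s2g: float, s2e: float):
        """REML score and average information, all in the eigenbasis."""
        d = s2g * lam + s2e
        Di = 1.0 / d
        XD = Xt * Di[:, None]
        XtViX_inv = np.linalg.inv(Xt.T @ XD)

        def Pv(v):
            return Di * v - XD @ (XtViX_inv @ (XD.T @ v))

        Py = Pv(yt)
        # tr(P A) for diagonal A: sum(diag(A) * diag(P))
        diagP = Di - np.einsum("ij,jk,ik->i", XD, XtViX_inv, XD)
        score = np.empty(2)
        ai = np.empty((2, 2))
        for i, ai_diag in enumerate((lam, np.ones(n))):
            APy = ai_diag * Py
            score[i] = -0.5 * (float(diagP @ ai_diag) - float(Py @ APy))
        PlPy, PiPy = Pv(lam * Py), Pv(Py)
        ai[0, 0] = 0.5 * float((lam * Py) @ PlPy)
        ai[0, 1] = ai[1, 0] = 0.5 * float(Py @ PlPy)
        ai[1, 1] = 0.5 * float(Py @ PiPy)
        return score, ai

    res = optimize.minimize_scalar(
        profile_negll, bounds=(-14.0, 14.0), method="bounded",
        options={"xatol": 1e-10, "maxiter": 800},
    )
    log_theta = float(res.x)
    neg_ll = float(res.fun)
    # the profile can be maximized at the sigma_g^2 = 0 boundary
    ll0 = fit_null_reml(y, X).loglik
    boundary = False
    if -ll0 <= neg_ll + 1e-10 or log_theta <= -13.5:
        theta = 0.0
        ll = ll0
        boundary = True
    else:
        theta = np.exp(log_theta)
        ll = -neg_ll
    d = theta * lam + 1.0
    Xd = Xt / d[:, None]
    XtViX = Xt.T @ Xd
    beta = np.linalg.solve(XtViX, Xd.T @ yt)
    resid = yt - Xt @ beta
    s2e = float(resid @ (resid / d)) / (n - p)
    s2g = theta * s2e

    if not boundary:
        # Newton/AI polish: the 1-D search is sqrt(eps)-limited near the
        # flat optimum; a few score steps pin it to machine precision
        for _ in range(30):
            score, ai = _score_ai(s2g, s2e)
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                break
            step = 1.0
            while (
                min(s2g + step * delta[0], s2e + step * delta[1]) <= 0
                and step > 1e-4
            ):
                step *= 0.5
            if min(s2g + step * delta[0], s2e + step * delta[1]) <= 0:
                break
            s2g += step * delta[0]
            s2e += step * delta[1]
            if np.max(np.abs(step * delta)) < 1e-13 * (s2g + s2e):
                break
        ll = _loglik_at(s2g, s2e)

    sigma2 = np.array([s2g, s2e])
    _, ai_opt = _score_ai(max(s2g, 1e-12), s2e)
    try:
        ai_cov = np.linalg.inv(ai_opt)
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(ai_opt)
    se = np.sqrt(np.clip(np.diag(ai_cov), 0.0, None))
    h2, h2_se = _h2_delta(s2g, s2e, ai_cov)
    return VarCompFit(
        component_names=list(spec.component_names),
        sigma2=sigma2,
        se=se,
        loglik=ll,
        h2=h2,
        h2_se=h2_se,
        n_iter=int(res.nfev),
        converged=bool(res.success),
        boundary_flags=np.array([boundary, False]),
        n_obs=n,
        n_fixed=p,
    )


def _ai_covariance(y, X, mats, sigma2) -> np.ndarray:
    """Inverse average-information matrix at the given parameter point."""
    n = y.size
    Vmats = list(mats) + [np.eye(n)]
    V = sum(s * M for s, M in zip(sigma2, Vmats))
    # keep V invertible when components sit on the zero boundary
    V = V + np.eye(n) * (1e-10 * np.trace(V) / n)
    P, Py, _ = _projection(y, X, V)
    k = len(Vmats)
    AI = np.empty((k, k))
    MPy = [M @ Py for M in Vmats]
    for i in range(k):
        PMiPy = P @ MPy[i]
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(MPy[j] @ PMiPy)
    try:
        return np.linalg.inv(AI)
    except np.linalg.LinAlgError:  # boundary-degenerate information
        return np.linalg.pinv(AI)


def _h2_delta(s2g: float, s2e: float, cov2: np.ndarray):
    tot = s2g + s2e
    if tot <= 0:
        raise ValueError("total variance is zero")
    h2 = s2g / tot
    grad = np.array([s2e, -s2g]) / tot**2
    var = float(grad @ cov2[:2, :2] @ grad)
    return float(h2), float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# multi-component AI-REML
# ---------------------------------------------------------------------------

def _fit_ai_reml(spec: MixedModelSpec, max_iter: int, tol: float) -> VarCompFit:
    y, X = spec.y, spec.X
    mats = spec._mats
    n, p = X.shape
    k = len(mats)
    Vmats = list(mats) + [np.eye(n)]
    vy = float(np.var(y))
    floor = 1e-8 * vy
    sigma2 = np.full(k + 1, vy / (k + 1))

    def build_V(s):
        return sum(si * M for si, M in zip(s, Vmats))

    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        V = build_V(sigma2) + np.eye(n) * floor
        P, Py, ll = _projection(y, X, V)
        MPy = [M @ Py for M in Vmats]
        score = np.array(
            [
                -0.5 * (np.sum(P * M) - float(Py @ MPy[i]))
                for i, M in enumerate(Vmats)
            ]
        )
        AI = np.empty((k + 1, k + 1))
        for i in range(k + 1):
            PMiPy = P @ MPy[i]
            for j in range(i, k + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(MPy[j] @ PMiPy)
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(AI, score, rcond=None)[0]
        new = sigma2 + delta
        step = 1.0
        while (new < 0).any() and step > 1e-3:  # step-halve toward feasibility
            step *= 0.5
            new = sigma2 + step * delta
        if (new < 0).any():  # EM fallback keeps the parameter space
            new = sigma2 + (sigma2**2 / n) * (
                np.array([float(Py @ m) for m in MPy]) -
                np.array([np.sum(P * M) for M in Vmats])
            )
            new = np.maximum(new, floor)
        new = np.maximum(new, floor)
        d_par = float(np.max(np.abs(new - sigma2))) / max(float(new.sum()), floor)
        d_ll = abs(ll - ll_old)
        sigma2, ll_old = new, ll
        if d_par < tol and d_ll < tol:
            converged = True
            break

    V = build_V(sigma2) + np.eye(n) * floor
    ll = _reml_loglik_from_V(y, X, V)
    boundary = sigma2 <= 10.0 * floor
    sigma2 = np.where(boundary, 0.0, sigma2)
    ai_cov = _ai_covariance(y, X, mats, sigma2)
    se = np.sqrt(np.clip(np.diag(ai_cov), 0.0, None))
    s2g_tot = float(sigma2[:-1].sum())
    tot = s2g_tot + float(sigma2[-1])
    h2 = s2g_tot / tot if tot > 0 else 0.0
    # delta-method SE of the summed-genetic-variance ratio
    grad = np.empty(k + 1)
    grad[:k] = sigma2[-1] / tot**2
    grad[k] = -s2g_tot / tot**2
    h2_se = float(np.sqrt(max(grad @ ai_cov @ grad, 0.0)))
    if not converged:
        logger.warning("AI-REML did not converge in %d iterations", max_iter)
    return VarCompFit(
        component_names=list(spec.component_names),
        sigma2=sigma2,
        se=se,
        loglik=ll,
        h2=float(h2),
        h2_se=h2_se,
        n_iter=n_iter,
        converged=converged,
        boundary_flags=boundary,
        n_obs=n,
        n_fixed=p,
    )


def fit_reml(
    spec: MixedModelSpec, max_iter: int = 100, tol: float = 1e-6
) -> VarCompFit:
    """Estimate variance components by REML.

    Single-GRM models use the eigenrotation shortcut; models with two
    or more genetic components use AI-REML with EM fallback.  A
    non-convergent fit is returned flagged, never silently.
    """
    n = spec.y.size
    if n < 10:
        raise ValueError("need at least 10 observations for REML")
    if len(spec._mats) == 0:
        return fit_null_reml(spec.y, spec.X)
    # standardize y so the optimizer sees a unit-scale problem; estimates
    # transform back exactly, making scale equivariance bitwise
    s = float(np.std(spec.y))
    if s <= 0:
        raise ValueError("phenotype is constant")
    scaled = MixedModelSpec(
        y=spec.y / s, grms=spec._mats, X=spec.X,
        component_names=list(spec.component_names),
    )
    if len(spec._mats) == 1:
        fit = _fit_single_grm(scaled, max_iter, tol)
    else:
        fit = _fit_ai_reml(scaled, max_iter, tol)
    fit.sigma2 = fit.sigma2 * s**2
    fit.se = fit.se * s**2
    fit.loglik = fit.loglik - (fit.n_obs - fit.n_fixed) * np.log(s)
    return fit


def heritability(fit: VarCompFit) -> tuple:
    """Narrow-sense heritability sigma_g^2 / (sigma_g^2 + sigma_e^2) with SE."""
    if len(fit.component_names) != 1:
        raise ValueError("heritability() expects a single genetic component")
    tot = float(fit.sigma2.sum())
    if tot <= 0:
        raise ValueError("total variance is zero")
    return fit.h2, fit.h2_se


def lrt_genetic(full: VarCompFit, null: VarCompFit, df: int = 1) -> tuple:
    """Likelihood-ratio test of the extra genetic component in ``full``.

    Returns ``(statistic, p)`` with the statistic clamped at zero and
    the p-value from a plain chi-square with ``df`` degrees of freedom
    (conservative at the variance boundary).
    """
    if full.n_obs != null.n_obs or full.n_fixed != null.n_fixed:
        raise ValueError("full and null fits use different data or fixed effects")
    if null.loglik > full.loglik + 1e-6:
        raise ValueError(
            "null log-likelihood exceeds full: models are not nested as given"
        )
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), p
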
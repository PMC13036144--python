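"""Twelve genomic-prediction models behind one train/predict contract.

Model families
--------------
* ``rrBLUP`` / ``GBLUP`` — the additive mixed-model pair.  rrBLUP puts
  a common normal prior on marker effects and solves the ridge system
  with lambda = sigma_e^2/sigma_u^2 from REML (spectral shortcut);
  GBLUP fits the equivalent individual-level model on the VanRaden GRM
  and back-solves BLUPs.  With matched scaling their GEBVs coincide —
  the central algebraic identity, used as a cross-check in the tests.
* ``RR`` / ``LASSO`` / ``EN`` — penalized regressions on standardized
  markers (scikit-learn coordinate descent), penalty picked by inner
  5-fold CV over a 50-point log-spaced path; EN mixing fixed at 0.5.
* ``BayesA`` / ``BayesB`` / ``BayesC`` / ``BRR`` / ``BL`` — the
  Bayesian alphabet, single-site Gibbs samplers with scaled-inverse-
  chi-square priors (df 5, scale split half genetic / half residual
  from var(y)), posterior-mean effects.  BayesB uses a fixed exclusion
  probability pi = 0.95; BayesC estimates its inclusion probability
  under a Beta(1, 9) prior; BL is the Park–Casella Bayesian LASSO.
* ``RKHS`` / ``MKRKHS`` — Gaussian-kernel regression
  K = exp(-h D^2 / median(D^2)) fitted by (multi-)kernel REML; MKRKHS
  averages kernels over bandwidths h in {0.25, 1, 4} with one variance
  component each.

All randomness is drawn from an explicit per-call seed; MCMC runs are
bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist
from sklearn.linear_model import (
    ElasticNet, ElasticNetCV, Lasso, LassoCV, Ridge, RidgeCV,
)
from sklearn.model_selection import KFold

from .genotypes import GenotypeMatrix
from .kinship import GRM, compute_grm
from .varcomp import MixedModelSpec, fit_reml

logger = logging.getLogger(__name__)

__all__ = ["MODEL_NAMES", "GSConfig", "FittedModel", "train", "predict"]

MODEL_NAMES = [
    "rrBLUP", "GBLUP", "RR", "LASSO", "EN",
    "BayesA", "BayesB", "BayesC", "BRR", "BL",
    "RKHS", "MKRKHS",
]


@dataclass
class GSConfig:
    """Declared hyperparameters shared by the model zoo."""

    gibbs_iters: int = 12_000
    gibbs_burn_in: int = 2_000
    gibbs_thin: int = 5
    prior_df: float = 5.0
    bayesb_pi_zero: float = 0.95  # prior P(effect == 0)
    bayesc_pi_beta: Tuple[float, float] = (1.0, 9.0)  # prior on P(included)
    rkhs_h: float = 1.0
    mkrkhs_h: Tuple[float, ...] = (0.25, 1.0, 4.0)
    cv_path_points: int = 50
    inner_cv_folds: int = 5
    fixed_penalty: Optional[float] = None  # bypass inner CV when set


@dataclass
class FittedModel:
    """Everything needed to predict new individuals deterministically."""

    model_name: str
    intercept: float
    marker_ids: List[str]
    center: np.ndarray                       # 2p from training
    marker_effects: Optional[np.ndarray] = None  # per training marker
    scale: Optional[np.ndarray] = None       # sd used for standardized models
    kernel_context: Dict = dc_field(default_factory=dict)
    hyperparameters: Dict = dc_field(default_factory=dict)
    mcmc_diagnostics: Dict = dc_field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _centered(geno: GenotypeMatrix):
    if np.isnan(geno.dosages).any():
        raise ValueError("missing dosages: impute before training")
    p = geno.dosages.mean(axis=0) / 2.0
    W = geno.dosages - 2.0 * p
    return W, p


def _standardized(geno: GenotypeMatrix):
    W, p = _centered(geno)
    het = 2.0 * p * (1.0 - p)
    sd = np.sqrt(np.where(het > 0, het, 1.0))
    return W / sd, p, sd


def _align_new(model: FittedModel, geno_new: GenotypeMatrix) -> np.ndarray:
    pos = {mid: j for j, mid in enumerate(geno_new.markers["id"])}
    missing = [mid for mid in model.marker_ids if mid not in pos]
    if missing:
        raise ValueError(
            f"{len(missing)} training markers absent from new genotypes, "
            f"e.g. {missing[:5]}"
        )
    idx = [pos[mid] for mid in model.marker_ids]
    dos = geno_new.dosages[:, idx]
    if np.isnan(dos).any():
        raise ValueError("missing dosages in prediction genotypes")
    return dos


def _as_y(pheno) -> np.ndarray:
    if hasattr(pheno, "columns"):
        return np.asarray(pheno["tar"], dtype=float)
    return np.asarray(pheno, dtype=float).ravel()


# ---------------------------------------------------------------------------
# rrBLUP / GBLUP
# ---------------------------------------------------------------------------

def _train_rrblup(geno, y, config, seed) -> FittedModel:
    W, p = _centered(geno)
    het_sum = float(np.sum(2.0 * p * (1.0 - p) * ((p > 0) & (p < 1))))
    G = compute_grm(geno)
    fit = fit_reml(MixedModelSpec(y=y, grms=[G]))
    s2g, s2e = float(fit.sigma2[0]), float(fit.sigma2[1])
    n = y.size
    # ridge back-solve through the n x n system (Woodbury form):
    # a-hat = sigma_u^2 W' V^{-1} (y - mu),  V = sigma_u^2 WW' + sigma_e^2 I
    V = s2g * G.values + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
    r = y - mu
    s2u = s2g / het_sum if het_sum > 0 else 0.0
    effects = s2u * (W.T @ (Vi @ r))
    return FittedModel(
        model_name="rrBLUP", intercept=mu,
        marker_ids=list(geno.markers["id"]), center=2.0 * p,
        marker_effects=effects,
        hyperparameters={"sigma2_u": s2u, "sigma2_e": s2e, "h2": fit.h2},
        seed=seed,
    )


def _train_gblup(geno, y, config, seed) -> FittedModel:
    W, p = _centered(geno)
    het_sum = float(np.sum(2.0 * p * (1.0 - p) * ((p > 0) & (p < 1))))
    G = compute_grm(geno)
    fit = fit_reml(MixedModelSpec(y=y, grms=[G]))
    s2g, s2e = float(fit.sigma2[0]), float(fit.sigma2[1])
    n = y.size
    V = s2g * G.values + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
    alpha = Vi @ (y - mu)                   # G-side BLUP: g-hat = s2g * G alpha
    return FittedModel(
        model_name="GBLUP", intercept=mu,
        marker_ids=list(geno.markers["id"]), center=2.0 * p,
        kernel_context={
            "W_train": W, "alpha": alpha, "sigma2_g": s2g,
            "denominator": het_sum, "train_gebv": s2g * (G.values @ alpha),
        },
        hyperparameters={"sigma2_g": s2g, "sigma2_e": s2e, "h2": fit.h2},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# penalized regressions (scikit-learn behind the contract)
# ---------------------------------------------------------------------------

def _train_penalized(name, geno, y, config, seed) -> FittedModel:
    Z, p, sd = _standardized(geno)
    if config.fixed_penalty is not None:
        a = config.fixed_penalty
        if name == "RR":
            est = Ridge(alpha=a)
        elif name == "LASSO":
            est = Lasso(alpha=a, max_iter=50_000)
        else:
            est = ElasticNet(alpha=a, l1_ratio=0.5, max_iter=50_000)
        est.fit(Z, y)
        return FittedModel(
            model_name=name, intercept=float(est.intercept_),
            marker_ids=list(geno.markers["id"]), center=2.0 * p,
            marker_effects=np.asarray(est.coef_, dtype=float), scale=sd,
            hyperparameters={"alpha": a}, seed=seed,
        )
    cv = KFold(config.inner_cv_folds, shuffle=True, random_state=seed)
    if name == "RR":
        alphas = np.logspace(-2, 6, config.cv_path_points)
        est = RidgeCV(alphas=alphas, cv=cv)
    elif name == "LASSO":
        est = LassoCV(alphas=config.cv_path_points, cv=cv, max_iter=10_000,
                      random_state=seed)
    elif name == "EN":
        est = ElasticNetCV(l1_ratio=0.5, alphas=config.cv_path_points,
                           cv=cv, max_iter=10_000, random_state=seed)
    else:  # pragma: no cover
        raise ValueError(name)
    est.fit(Z, y)
    return FittedModel(
        model_name=name, intercept=float(est.intercept_),
        marker_ids=list(geno.markers["id"]), center=2.0 * p,
        marker_effects=np.asarray(est.coef_, dtype=float), scale=sd,
        hyperparameters={"alpha": float(getattr(est, "alpha_", np.nan))},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bayesian alphabet — single-site Gibbs, numba core
# ---------------------------------------------------------------------------

_BRR, _BAYES_A, _BAYES_B, _BAYES_C, _BL = 0, 1, 2, 3, 4


@njit(cache=True)
def _rand_scaled_inv_chi2(df, scale):
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _rand_inv_gaussian(mu, lam):
    # Michael-Schucany-Haas transform
    v = np.random.standard_normal()
    w = v * v
    x = mu + (mu * mu * w) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _gibbs_core(
    X, y, model, n_iter, burn_in, thin,
    df_b, scale_b, df_e, scale_e,
    pi_in, estimate_pi, beta_a, beta_b, seed,
):
    """Single-site Gibbs sweep shared by BRR/BayesA/BayesB/BayesC/BL.

    X holds standardized marker codes.  Returns posterior means of the
    marker effects and intercept, the thinned post-burn-in sigma_e^2
    chain, and the posterior-mean inclusion probability.
    """
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    b = np.zeros(m)
    delta = np.ones(m)           # inclusion indicators (B/C)
    var_b = np.full(m, scale_b)  # per-marker variances (A/B); common for BRR/C
    sigma2_b = scale_b
    sigma2_e = scale_e
    tau2 = np.ones(m)            # BL local scales
    lambda2 = 1.0
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    n_keep = 0
    b_sum = np.zeros(m)
    mu_sum = 0.0
    pi_sum = 0.0
    n_chain = (n_iter - burn_in + thin - 1) // thin
    se_chain = np.zeros(max(n_chain, 1))
    chain_at = 0

    for it in range(n_iter):
        # intercept
        e_mean = 0.0
        for i in range(n):
            e_mean += e[i] + mu
        e_mean /= n
        mu_new = e_mean + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        dmu = mu_new - mu
        for i in range(n):
            e[i] -= dmu
        mu = mu_new

        m_in = 0
        ssb_common = 0.0
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            # restore this marker's contribution
            rhs = 0.0
            if b[j] != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * b[j]
            for i in range(n):
                rhs += X[i, j] * e[i]

            if model == _BRR or model == _BAYES_C:
                vj = sigma2_b
            elif model == _BL:
                vj = tau2[j] * sigma2_e
            else:
                vj = var_b[j]

            include = True
            if model == _BAYES_B or model == _BAYES_C:
                c0 = xtx[j] * vj + sigma2_e
                log_lr = 0.5 * (
                    np.log(sigma2_e / c0) + rhs * rhs * vj / (sigma2_e * c0)
                )
                # guard the exponential
                if log_lr > 30.0:
                    p1 = 1.0
                else:
                    lr = np.exp(log_lr)
                    p1 = pi_in * lr / (pi_in * lr + (1.0 - pi_in))
                include = np.random.random() < p1

            if include:
                cj = xtx[j] + sigma2_e / vj
                mean = rhs / cj
                bj = mean + np.random.standard_normal() * np.sqrt(sigma2_e / cj)
                delta[j] = 1.0
                m_in += 1
            else:
                bj = 0.0
                delta[j] = 0.0
            b[j] = bj
            if bj != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * bj

            # per-marker variance updates
            if model == _BAYES_A:
                var_b[j] = _rand_scaled_inv_chi2(
                    df_b + 1.0, (bj * bj + df_b * scale_b) / (df_b + 1.0)
                )
            elif model == _BAYES_B:
                if include:
                    var_b[j] = _rand_scaled_inv_chi2(
                        df_b + 1.0, (bj * bj + df_b * scale_b) / (df_b + 1.0)
                    )
                else:  # draw from the prior to keep the chain proper
                    var_b[j] = _rand_scaled_inv_chi2(df_b, scale_b)
            elif model == _BL:
                if bj != 0.0:
                    inv_t2 = _rand_inv_gaussian(
                        np.sqrt(lambda2 * sigma2_e / (bj * bj)), lambda2
                    )
                    tau2[j] = 1.0 / max(inv_t2, 1e-12)
            else:
                ssb_common += bj * bj

        # shared-variance updates
        if model == _BRR:
            sigma2_b = _rand_scaled_inv_chi2(
                df_b + m, (ssb_common + df_b * scale_b) / (df_b + m)
            )
        elif model == _BAYES_C:
            if m_in > 0:
                sigma2_b = _rand_scaled_inv_chi2(
                    df_b + m_in, (ssb_common + df_b * scale_b) / (df_b + m_in)
                )
            else:
                sigma2_b = _rand_scaled_inv_chi2(df_b, scale_b)
            if estimate_pi:
                pi_in = np.random.beta(beta_a + m_in, beta_b + (m - m_in))
        elif model == _BL:
            sum_tau2 = 0.0
            for j in range(m):
                sum_tau2 += tau2[j]
            # lambda^2 ~ Gamma(shape, rate) with a vague Gamma(1.1, 0.1) prior
            lambda2 = np.random.gamma(1.1 + m, 1.0 / (0.1 + 0.5 * sum_tau2))

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        if model == _BL:
            ssb_scaled = 0.0
            for j in range(m):
                if b[j] != 0.0:
                    ssb_scaled += b[j] * b[j] / tau2[j]
            sigma2_e = _rand_scaled_inv_chi2(
                df_e + n + m,
                (sse + ssb_scaled + df_e * scale_e) / (df_e + n + m),
            )
        else:
            sigma2_e = _rand_scaled_inv_chi2(
                df_e + n, (sse + df_e * scale_e) / (df_e + n)
            )
        if not np.isfinite(sigma2_e) or sigma2_e <= 0.0:
            return b_sum, mu_sum, se_chain, pi_sum, -1

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
            for j in range(m):
                b_sum[j] += b[j]
            mu_sum += mu
            pi_sum += pi_in
            se_chain[chain_at] = sigma2_e
            chain_at += 1

    if n_keep > 0:
        for j in range(m):
            b_sum[j] /= n_keep
        mu_sum /= n_keep
        pi_sum /= n_keep
    return b_sum, mu_sum, se_chain[:chain_at], pi_sum, n_keep


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of one chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] < 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def _train_bayesian(name, geno, y, config, seed) -> FittedModel:
    Z, p, sd = _standardized(geno)
    m = Z.shape[1]
    vy = float(np.var(y))
    df = config.prior_df
    # split var(y) half genetic / half residual; on standardized markers the
    # genetic variance is roughly m * sigma_b^2
    scale_e = (vy / 2.0) * (df - 2.0) / df
    scale_b = (vy / 2.0 / m) * (df - 2.0) / df
    model_code = {
        "BRR": _BRR, "BayesA": _BAYES_A, "BayesB": _BAYES_B,
        "BayesC": _BAYES_C, "BL": _BL,
    }[name]
    pi_in = 1.0
    estimate_pi = False
    beta_a, beta_b = config.bayesc_pi_beta
    if name == "BayesB":
        pi_in = 1.0 - config.bayesb_pi_zero
    elif name == "BayesC":
        pi_in = beta_a / (beta_a + beta_b)
        estimate_pi = True
    b, mu, se_chain, pi_mean, n_keep = _gibbs_core(
        np.ascontiguousarray(Z), np.ascontiguousarray(y, dtype=np.float64),
        model_code, config.gibbs_iters, config.gibbs_burn_in,
        config.gibbs_thin, df, scale_b, df, scale_e,
        pi_in, estimate_pi, beta_a, beta_b, int(seed) % (2**31 - 1),
    )
    if n_keep < 0:
        raise RuntimeError(
            f"{name} Gibbs chain diverged (non-finite residual variance), "
            f"seed={seed}"
        )
    return FittedModel(
        model_name=name, intercept=float(mu),
        marker_ids=list(geno.markers["id"]), center=2.0 * p,
        marker_effects=np.asarray(b, dtype=float), scale=sd,
        hyperparameters={
            "gibbs_iters": config.gibbs_iters,
            "burn_in": config.gibbs_burn_in, "thin": config.gibbs_thin,
            "prior_df": df, "pi_in": float(pi_mean) if estimate_pi else pi_in,
        },
        mcmc_diagnostics={
            "n_kept": int(n_keep),
            "sigma2_e_mean": float(np.mean(se_chain)),
            "sigma2_e_ess": _ess(se_chain),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# RKHS / MKRKHS
# ---------------------------------------------------------------------------

def _gauss_kernels(Z_train, Z_new, hs, med):
    D2 = cdist(Z_new, Z_train, "sqeuclidean")
    return [np.exp(-h * D2 / med) for h in hs]


def _train_rkhs(name, geno, y, config, seed) -> FittedModel:
    Z, p, sd = _standardized(geno)
    D2 = cdist(Z, Z, "sqeuclidean")
    off = D2[np.triu_indices_from(D2, k=1)]
    med = float(np.median(off))
    if med <= 0:
        raise ValueError("degenerate genotypes: zero median kernel distance")
    hs = (config.rkhs_h,) if name == "RKHS" else tuple(config.mkrkhs_h)
    kernels = [np.exp(-h * D2 / med) for h in hs]
    # bandwidth-sharing kernels are nearly collinear, which flattens the
    # restricted likelihood; give the multi-kernel fit a looser, longer leash
    fit = fit_reml(
        MixedModelSpec(
            y=y, grms=kernels, component_names=[f"K(h={h})" for h in hs]
        ),
        max_iter=300,
        tol=1e-5 if len(hs) > 1 else 1e-6,
    )
    n = y.size
    V = sum(
        float(s) * K for s, K in zip(fit.sigma2[:-1], kernels)
    ) + float(fit.sigma2[-1]) * np.eye(n)
    Vi = np.linalg.inv(V + np.eye(n) * 1e-10 * np.trace(V) / n)
    ones = np.ones(n)
    mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
    alpha = Vi @ (y - mu)
    return FittedModel(
        model_name=name, intercept=mu,
        marker_ids=list(geno.markers["id"]), center=2.0 * p, scale=sd,
        kernel_context={
            "Z_train": Z, "alpha": alpha, "median_d2": med, "hs": hs,
            "sigma2_k": np.asarray(fit.sigma2[:-1], dtype=float),
        },
        hyperparameters={"h": hs, "sigma2_e": float(fit.sigma2[-1])},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# public contract
# ---------------------------------------------------------------------------

def train(
    model_name: str,
    geno_train: GenotypeMatrix,
    pheno_train,
    config: Optional[GSConfig] = None,
    seed: int = 0,
) -> FittedModel:
    """Fit one of the twelve models; see the module docstring for the zoo."""
    config = config or GSConfig()
    y = _as_y(pheno_train)
    if y.size != geno_train.n_samples:
        raise ValueError("phenotype length does not match genotypes")
    if model_name in ("BayesA", "BayesB", "BayesC", "BRR", "BL") and y.size < 30:
        raise ValueError(f"{model_name} needs n >= 30 for a stable chain")
    if model_name == "rrBLUP":
        return _train_rrblup(geno_train, y, config, seed)
    if model_name == "GBLUP":
        return _train_gblup(geno_train, y, config, seed)
    if model_name in ("RR", "LASSO", "EN"):
        return _train_penalized(model_name, geno_train, y, config, seed)
    if model_name in ("BayesA", "BayesB", "BayesC", "BRR", "BL"):
        return _train_bayesian(model_name, geno_train, y, config, seed)
    if model_name in ("RKHS", "MKRKHS"):
        return _train_rkhs(model_name, geno_train, y, config, seed)
    raise ValueError(f"unknown model: {model_name!r}; choose from {MODEL_NAMES}")


def predict(model: FittedModel, geno_new: GenotypeMatrix) -> np.ndarray:
    """GEBVs for new individuals; deterministic given the fitted model."""
    dos = _align_new(model, geno_new)
    W = dos - model.center
    if model.model_name == "GBLUP":
        ctx = model.kernel_context
        K_cross = (W @ ctx["W_train"].T) / ctx["denominator"]
        return model.intercept + ctx["sigma2_g"] * (K_cross @ ctx["alpha"])
    if model.model_name in ("RKHS", "MKRKHS"):
        ctx = model.kernel_context
        Z = W / np.where(model.scale > 0, model.scale, 1.0)
        kernels = _gauss_kernels(ctx["Z_train"], Z, ctx["hs"], ctx["median_d2"])
        g = np.zeros(Z.shape[0])
        for s, K in zip(ctx["sigma2_k"], kernels):
            g += s * (K @ ctx["alpha"])
        return model.intercept + g
    effects = model.marker_effects
    if model.scale is not None:
        W = W / np.where(model.scale > 0, model.scale, 1.0)
    return model.intercept + W @ effects
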
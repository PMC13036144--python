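"""Mixed-linear-model association (MLMA) scan.

Each SNP is tested in  y = X b + s g + u + e  with a polygenic random
effect u ~ N(0, sigma_g^2 G) absorbing relatedness and structure.
Variance components are estimated once on the null model (no SNP) and
held fixed across the scan — the standard population-parameters-
previously-determined approximation — so each per-SNP test is a
generalized least-squares fit under V-hat = sigma_g^2 G + sigma_e^2 I,
vectorized across markers in the GRM eigenbasis.  The candidate SNP
stays in the background GRM (plain MLMA); a leave-one-chromosome-out
variant is available via ``loco=True``.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import GRM, compute_grm, compute_loco_grm
from .varcomp import MixedModelSpec, fit_reml

logger = logging.getLogger(__name__)

__all__ = ["run_mlma", "bonferroni_threshold", "top_hits"]


def _scan_chunk(yt, Xt, St, w, var_y):
    """GLS per SNP in the rotated (diagonal-V) basis, vectorized."""
    wXt = Xt * w[:, None]
    A = Xt.T @ wXt                      # p x p
    A_inv = np.linalg.inv(A)
    XtWy = wXt.T @ yt                   # p
    B = wXt.T @ St                      # p x m
    c = np.einsum("ij,i,ij->j", St, w, St)
    sWy = St.T @ (w * yt)
    AiB = A_inv @ B
    num = sWy - AiB.T @ XtWy            # s*' W y
    den = c - np.einsum("ij,ij->j", B, AiB)  # s*' W s*
    ok = den > 1e-12
    beta = np.full(den.shape, np.nan)
    se = np.full(den.shape, np.nan)
    beta[ok] = num[ok] / den[ok]
    se[ok] = np.sqrt(1.0 / den[ok])
    z2 = np.zeros_like(beta)
    z2[ok] = (beta[ok] / se[ok]) ** 2
    p = np.where(ok, stats.chi2.sf(z2, 1), np.nan)
    p = np.where(ok & (p <= 0), np.nextafter(0, 1), p)
    return beta, se, p


def run_mlma(
    geno: GenotypeMatrix,
    y: np.ndarray,
    grm: Optional[GRM] = None,
    fixed_covariates: Optional[np.ndarray] = None,
    loco: bool = False,
) -> pd.DataFrame:
    """Scan every marker for association with ``y``.

    Returns a DataFrame with ``marker_id, chrom, pos_bp, beta, se, p,
    r2`` where ``r2 = beta^2 var(s) / var(y)`` is the fraction of
    phenotypic variance the SNP explains.  Monomorphic markers are
    skipped (NaN rows) with a logged count.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, m = geno.dosages.shape
    if y.size != n:
        raise ValueError("phenotype length does not match genotype samples")
    if np.isnan(geno.dosages).any():
        raise ValueError("missing dosages: impute before the scan")
    X = np.ones((n, 1))
    if fixed_covariates is not None:
        X = np.column_stack([X, np.atleast_2d(fixed_covariates)])
    if grm is None:
        grm = compute_grm(geno)

    var_y = float(np.var(y))
    var_s = geno.dosages.var(axis=0)
    mono = var_s <= 0
    if mono.any():
        logger.info("skipping %d monomorphic SNPs", int(mono.sum()))

    out = pd.DataFrame(
        {
            "marker_id": geno.markers["id"].to_numpy(),
            "chrom": geno.markers["chrom"].to_numpy(),
            "pos_bp": geno.markers["pos_bp"].to_numpy(),
            "beta": np.nan, "se": np.nan, "p": np.nan, "r2": np.nan,
        }
    )

    def fit_background(bg_grm: GRM) -> tuple:
        fit = fit_reml(MixedModelSpec(y=y, grms=[bg_grm], X=X))
        if not fit.converged:
            raise RuntimeError(
                "null-model REML failed to converge; cannot run the scan"
            )
        return float(fit.sigma2[0]), float(fit.sigma2[1])

    chrom_groups = (
        geno.markers.groupby("chrom", sort=False).indices if loco
        else {None: np.arange(m)}
    )
    for chrom, idx in chrom_groups.items():
        bg = compute_loco_grm(geno, chrom) if loco else grm
        s2g, s2e = fit_background(bg)
        lam, U = np.linalg.eigh(bg.values)
        d = s2g * np.clip(lam, 0, None) + s2e
        w = 1.0 / d
        yt, Xt = U.T @ y, U.T @ X
        idx = np.asarray(idx)
        keep = idx[~mono[idx]]
        if keep.size == 0:
            continue
        St = U.T @ geno.dosages[:, keep]
        beta, se, p = _scan_chunk(yt, Xt, St, w, var_y)
        out.loc[keep, "beta"] = beta
        out.loc[keep, "se"] = se
        out.loc[keep, "p"] = p
        out.loc[keep, "r2"] = np.clip(beta**2 * var_s[keep] / var_y, 0.0, 1.0)
    return out


def bonferroni_threshold(n_markers: int) -> float:
    """Genome-wide p threshold 1/N (the 1-over-marker-count convention)."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return 1.0 / n_markers


def top_hits(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k most significant markers, ties broken by (chrom, pos)."""
    if len(results) == 0:
        raise ValueError("empty association results")
    ranked = results.dropna(subset=["p"]).sort_values(
        ["p", "chrom", "pos_bp"], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)


def write_assoc_tsv(results: pd.DataFrame, path, threshold: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bonferroni_threshold\t{threshold:.6g}\n")
        results.to_csv(fh, sep="\t", index=False)
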
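"""Genomic relationship matrices and GRM-based PCA.

The default GRM is VanRaden method 1: dosages centered by twice the
in-sample allele frequency, G = WW' / sum_j 2 p_j (1 - p_j).  A
GCTA-style variant (per-marker standardization before averaging) is
available via ``method="gcta"``.  Window-local and
leave-one-chromosome-out (LOCO) scopes reuse the same construction on
marker subsets and carry a scope tag so downstream models can assert
disjointness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["GRM", "compute_grm", "compute_loco_grm", "grm_pca",
           "write_grm_tsv", "read_grm_tsv", "write_grm_gcta"]


@dataclass
class GRM:
    """Symmetric PSD relationship matrix tagged with its marker scope."""

    sample_ids: List[str]
    values: np.ndarray
    n_markers_used: int
    marker_scope: str = "all"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM is not symmetric within 1e-10")

    def check_psd(self, tol: float = 1e-8) -> np.ndarray:
        """Clamp tiny negative eigenvalues; error on genuinely negative ones."""
        w, U = np.linalg.eigh(self.values)
        if w.min() < -tol * max(1.0, w.max()):
            raise ValueError(f"GRM has negative eigenvalue {w.min():.3g}")
        if w.min() < 0:
            w = np.clip(w, 0.0, None)
            self.values = (U * w) @ U.T
        return w


def _center_scale(
    dosages: np.ndarray, method: str
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Centered (and for GCTA scaled) marker matrix plus the denominator."""
    if np.isnan(dosages).any():
        raise ValueError("missing dosages: impute before building a GRM")
    p = dosages.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluded %d monomorphic markers from GRM", n_mono)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic markers for GRM")
    W = dosages[:, poly] - 2.0 * p[poly]
    het = 2.0 * p[poly] * (1.0 - p[poly])
    if method == "vanraden":
        denom = float(het.sum())
    elif method == "gcta":
        W = W / np.sqrt(het)
        denom = float(poly.sum())
    else:
        raise ValueError(f"unknown GRM method: {method!r}")
    return W, poly, denom


def compute_grm(
    geno: GenotypeMatrix,
    marker_subset: Optional[np.ndarray] = None,
    method: str = "vanraden",
    marker_scope: str = "all",
) -> GRM:
    """Additive GRM from (a subset of) the dosage matrix.

    ``marker_subset`` is a boolean mask or index array over markers;
    monomorphic markers are excluded with a logged count.  Allele
    frequencies are estimated in-sample on the subset.
    """
    if geno.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    dos = geno.dosages
    if marker_subset is not None:
        idx = np.asarray(marker_subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        dos = dos[:, idx]
    W, poly, denom = _center_scale(dos, method)
    values = (W @ W.T) / denom
    grm = GRM(
        sample_ids=list(geno.sample_ids),
        values=values,
        n_markers_used=int(poly.sum()),
        marker_scope=marker_scope,
    )
    mean_diag = float(np.mean(np.diag(values)))
    if not (0.5 < mean_diag < 2.0):
        logger.warning("GRM mean diagonal %.3f far from 1", mean_diag)
    return grm


def compute_loco_grm(
    geno: GenotypeMatrix, excluded_chrom: str, method: str = "vanraden"
) -> GRM:
    """GRM over all markers *not* on ``excluded_chrom``."""
    chroms = geno.markers["chrom"].unique()
    if len(chroms) < 2:
        raise ValueError("LOCO needs at least 2 chromosomes")
    if excluded_chrom not in set(chroms):
        raise ValueError(f"chromosome {excluded_chrom!r} not in genotype data")
    mask = (geno.markers["chrom"] != excluded_chrom).to_numpy()
    return compute_grm(
        geno, marker_subset=mask, method=method,
        marker_scope=f"loco({excluded_chrom})",
    )


def grm_pca(grm: GRM, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the (double-centered) GRM.

    Returns ``(components, variance_explained)`` with components scaled
    by sqrt(eigenvalue) and ordered by decreasing eigenvalue; fractions
    are over the non-negative spectrum of the centered matrix.  Sign
    convention: the largest-magnitude loading of each PC is positive.
    """
    n = len(grm.sample_ids)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must lie in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    C = J @ grm.values @ J
    w, U = np.linalg.eigh(C)
    w, U = w[::-1], U[:, ::-1]
    pos = np.clip(w, 0.0, None)
    frac = pos / pos.sum()
    comps = U[:, :k] * np.sqrt(pos[:k])
    for i in range(k):  # deterministic sign
        j = np.argmax(np.abs(comps[:, i]))
        if comps[j, i] < 0:
            comps[:, i] = -comps[:, i]
    return comps, frac[:k]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_grm_tsv(grm: GRM, path) -> None:
    pd.DataFrame(
        grm.values, index=grm.sample_ids, columns=grm.sample_ids
    ).to_csv(path, sep="\t")


def read_grm_tsv(path, marker_scope: str = "all", n_markers_used: int = 0) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM(
        sample_ids=list(df.index.astype(str)),
        values=df.to_numpy(dtype=float),
        n_markers_used=n_markers_used,
        marker_scope=marker_scope,
    )


def write_grm_gcta(grm: GRM, prefix) -> None:
    """GCTA-compatible binary triple: .grm.bin / .grm.N.bin / .grm.id."""
    prefix = Path(prefix)
    n = len(grm.sample_ids)
    tril = grm.values[np.tril_indices(n)]
    tril.astype("<f4").tofile(str(prefix) + ".grm.bin")
    np.full(tril.size, grm.n_markers_used, dtype="<f4").tofile(
        str(prefix) + ".grm.N.bin"
    )
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )
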
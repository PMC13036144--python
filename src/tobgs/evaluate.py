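"""Cross-validation, external validation, and the runtime benchmark.

Prediction accuracy is the Pearson correlation between out-of-fold
GEBVs and observed phenotypes.  One seeded k-fold partition is shared
by every model so fold composition never confounds a model comparison.
Both the pooled correlation over all out-of-fold predictions (the
headline number) and per-fold correlations are reported.
"""

from __future__ import annotations

import logging
import time
import tracemalloc
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .gsmodels import GSConfig, FittedModel, predict, train

logger = logging.getLogger(__name__)

__all__ = ["CVReport", "make_folds", "kfold_cv", "external_validate",
           "benchmark_models"]


@dataclass
class CVReport:
    k: int
    seed: int
    fold_assignment: np.ndarray          # per-sample fold index
    per_fold_r: pd.DataFrame             # model, fold, r, n_test
    pooled_r: Dict[str, float]
    predictions: pd.DataFrame            # sample_id, model, fold, gebv, observed
    runtime_s: Dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        # runtimes are informational and machine-dependent; kept out of the
        # artifact so reruns of a deterministic config hash identically
        rows = self.per_fold_r.copy()
        rows["pooled_r"] = rows["model"].map(self.pooled_r)
        rows.to_csv(path, sep="\t", index=False)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition into k folds whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def kfold_cv(
    geno: GenotypeMatrix,
    pheno,
    model_names: Sequence[str],
    k: int = 5,
    seed: int = 0,
    config: Optional[GSConfig] = None,
) -> CVReport:
    """One seeded k-fold CV pass over the requested models.

    Every sample is predicted exactly once out-of-fold; the same fold
    assignment is reused for every model.  Folds in which a model's
    predictions are constant get r = NaN with a warning; the pooled r
    is still computed.
    """
    y = (
        np.asarray(pheno["tar"], dtype=float)
        if hasattr(pheno, "columns") else np.asarray(pheno, dtype=float).ravel()
    )
    n = geno.n_samples
    if y.size != n:
        raise ValueError("phenotype length does not match genotypes")
    assignment = make_folds(n, k, seed)
    rows, pred_rows = [], []
    pooled: Dict[str, float] = {}
    runtimes: Dict[str, float] = {}
    for name in model_names:
        t0 = time.perf_counter()
        oof = np.full(n, np.nan)
        for f in range(k):
            test = assignment == f
            train_idx = np.flatnonzero(~test)
            test_idx = np.flatnonzero(test)
            model = train(
                name, geno.subset_samples(train_idx), y[train_idx],
                config=config, seed=seed * 1000 + f,
            )
            gebv = predict(model, geno.subset_samples(test_idx))
            oof[test_idx] = gebv
            r = _pearson(gebv, y[test_idx])
            if np.isnan(r):
                logger.warning("%s fold %d: constant predictions, r undefined",
                               name, f)
            rows.append({"model": name, "fold": f, "r": r,
                         "n_test": int(test.sum())})
            for sid, g, obs in zip(
                np.asarray(geno.sample_ids)[test_idx], gebv, y[test_idx]
            ):
                pred_rows.append(
                    {"sample_id": sid, "model": name, "fold": f,
                     "gebv": float(g), "observed": float(obs)}
                )
        pooled[name] = _pearson(oof, y)
        runtimes[name] = time.perf_counter() - t0
    return CVReport(
        k=k, seed=seed, fold_assignment=assignment,
        per_fold_r=pd.DataFrame(rows), pooled_r=pooled,
        predictions=pd.DataFrame(pred_rows), runtime_s=runtimes,
    )


def external_validate(
    fitted: FittedModel, geno_bp: GenotypeMatrix, pheno_bp
) -> tuple:
    """Predict an external (breeding) panel and correlate with phenotypes.

    Returns ``(pearson_r, table)`` where the table holds one row per
    external sample (sample_id, gebv, observed) — the scatter behind
    the validation plot.
    """
    y = (
        np.asarray(pheno_bp["tar"], dtype=float)
        if hasattr(pheno_bp, "columns") else np.asarray(pheno_bp, float).ravel()
    )
    if y.size < 3:
        raise ValueError("external validation needs at least 3 samples")
    gebv = predict(fitted, geno_bp)
    table = pd.DataFrame(
        {"sample_id": geno_bp.sample_ids, "gebv": gebv, "observed": y}
    )
    return _pearson(gebv, y), table


def benchmark_models(
    geno: GenotypeMatrix,
    pheno,
    model_names: Sequence[str],
    sizes: Sequence[int],
    seed: int = 0,
    k: int = 5,
    config: Optional[GSConfig] = None,
) -> pd.DataFrame:
    """Wall time and peak memory per (size, model): informational only.

    Each target size is reached by resampling individuals with
    replacement (duplicate ids disambiguated with a ``#r<i>`` suffix);
    the numbers are hardware-dependent and never asserted.
    """
    y = (
        np.asarray(pheno["tar"], dtype=float)
        if hasattr(pheno, "columns") else np.asarray(pheno, float).ravel()
    )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        idx = rng.integers(geno.n_samples, size=size)
        sub = GenotypeMatrix(
            sample_ids=[f"{geno.sample_ids[i]}#r{j}" for j, i in enumerate(idx)],
            markers=geno.markers, dosages=geno.dosages[idx, :],
        )
        y_sub = y[idx]
        for name in model_names:
            tracemalloc.start()
            t0 = time.perf_counter()
            report = kfold_cv(sub, y_sub, [name], k=k, seed=seed, config=config)
            elapsed = time.perf_counter() - t0
            _, peak = tracemalloc.get_traced_memory()
            tracemalloc.stop()
            rows.append(
                {"n": size, "model": name, "pooled_r": report.pooled_r[name],
                 "runtime_s": elapsed, "peak_memory_mb": peak / 2**20}
            )
    return pd.DataFrame(rows)
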
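"""Phenotype tables, replicate averaging, and tar-mass arithmetic.

Tar (NFDPM, nicotine-free dry particulate matter) is measured per
cigarette on a smoking machine: total particulate matter minus water
and nicotine mass.  Each accession is typically measured in triplicate
and the replicate mean is the phenotype used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeRecord",
    "compute_tar_mass",
    "aggregate_replicates",
    "read_phenotypes",
    "join_samples",
]


@dataclass
class PhenotypeRecord:
    sample_id: str
    tar: float  # mg/cigarette
    replicates: Optional[List[float]] = None
    covariates: Dict[str, str] = field(default_factory=dict)
    m_tpm: Optional[float] = None
    m_w: Optional[float] = None
    m_n: Optional[float] = None


def compute_tar_mass(m_tpm: float, m_w: float, m_n: float) -> float:
    """NFDPM mass (mg): total particulate matter minus water and nicotine."""
    if min(m_tpm, m_w, m_n) < 0:
        raise ValueError("masses must be non-negative")
    tar = m_tpm - m_w - m_n
    if tar < 0:
        raise ValueError(
            f"moisture + nicotine ({m_w} + {m_n}) exceed TPM {m_tpm}: "
            "inconsistent smoking-machine inputs"
        )
    return tar


def aggregate_replicates(
    replicates_by_sample: Dict[str, Sequence[float]],
    covariates_by_sample: Optional[Dict[str, Dict[str, str]]] = None,
) -> List[PhenotypeRecord]:
    """One record per sample with tar = arithmetic mean of its replicates."""
    records = []
    for sid, reps in replicates_by_sample.items():
        reps = [float(r) for r in reps]
        if not reps:
            raise ValueError(f"sample {sid!r} has an empty replicate list")
        records.append(
            PhenotypeRecord(
                sample_id=sid,
                tar=float(np.mean(reps)),
                replicates=reps,
                covariates=(covariates_by_sample or {}).get(sid, {}),
            )
        )
    logger.info(
        "aggregated %d samples (%.1f replicates on average)",
        len(records), np.mean([len(r.replicates) for r in records]),
    )
    return records


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV and resolve tar from whatever columns exist.

    Accepted columns: ``sample_id`` plus either ``tar``, replicate
    columns ``rep1..repK``, or the mass triple ``m_tpm, m_w, m_n``;
    any other columns are carried as covariates.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: phenotype TSV needs a sample_id column")
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("rep")),
        key=lambda c: int(c[3:]) if c[3:].isdigit() else 0,
    )
    if "tar" not in df.columns:
        if rep_cols:
            df["tar"] = df[rep_cols].mean(axis=1)
        elif {"m_tpm", "m_w", "m_n"} <= set(df.columns):
            df["tar"] = [
                compute_tar_mass(t, w, n)
                for t, w, n in zip(df["m_tpm"], df["m_w"], df["m_n"])
            ]
        else:
            raise ValueError(f"{path}: no tar, replicate, or mass columns")
    if (df["tar"] < 0).any():
        raise ValueError(f"{path}: negative tar values")
    return df


def join_samples(
    pheno: pd.DataFrame, genotype_sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Align the phenotype table to the genotype sample order.

    Unmatched ids on either side are reported (logged), never silently
    dropped; the returned table contains exactly the intersection in
    genotype order.
    """
    geno_ids = list(genotype_sample_ids)
    pheno_ids = set(pheno["sample_id"])
    missing_pheno = [s for s in geno_ids if s not in pheno_ids]
    missing_geno = sorted(pheno_ids - set(geno_ids))
    if missing_pheno:
        logger.warning(
            "%d genotyped samples lack phenotypes (e.g. %s)",
            len(missing_pheno), missing_pheno[:5],
        )
    if missing_geno:
        logger.warning(
            "%d phenotyped samples lack genotypes (e.g. %s)",
            len(missing_geno), missing_geno[:5],
        )
    keep = [s for s in geno_ids if s in pheno_ids]
    if not keep:
        raise ValueError("no samples shared between phenotypes and genotypes")
    out = pheno.set_index("sample_id").loc[keep].reset_index()
    return out
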
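"""Synthetic genotypes and polygenic phenotypes.

The simulator emulates the statistical structure of a GBS diversity
panel — many chromosomes, block-wise linkage disequilibrium, a MAF
floor — without coalescent machinery.  Genotypes are built from a small
pool of founder haplotypes: each individual's chromosome is a mosaic of
founders with Poisson-distributed crossovers, which yields LD that
decays with physical distance at a rate set by ``recomb_rate``.

Traits are strictly additive: a subset of markers carries normal
allele-substitution effects, jointly rescaled so that the realized
ratio of genetic to phenotypic variance matches a target narrow-sense
heritability.  An optional focal window concentrates a chosen fraction
of the genetic variance into one genomic region, which is the ground
truth used to test regional heritability mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TraitConfig",
    "TrueEffects",
    "simulate_genotypes",
    "simulate_trait",
    "degrade_genotypes",
]


@dataclass
class SimConfig:
    """Parameters of the founder-haplotype genotype simulator."""

    n_individuals: int = 436
    n_chromosomes: int = 24
    chrom_length_bp: int = 10_000_000
    n_markers_per_chrom: int = 210
    n_founder_haplotypes: int = 20
    recomb_rate: float = 2.0  # expected crossovers per chromosome per gamete
    maf_floor: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes must be >= 2")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if min(self.n_individuals, self.n_chromosomes,
               self.chrom_length_bp, self.n_markers_per_chrom) <= 0:
            raise ValueError("all counts must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.n_markers_per_chrom > self.chrom_length_bp:
            raise ValueError("more markers than base pairs on a chromosome")


@dataclass
class TraitConfig:
    """Parameters of the additive polygenic trait generator.

    ``h2_target`` is the narrow-sense heritability the phenotype is
    generated under; ``focal_window`` / ``focal_fraction`` optionally
    concentrate that fraction of the genetic variance onto QTLs inside
    one (chrom, start_bp, end_bp) region.  ``phenotype_mean`` and
    ``phenotype_sd`` put the trait on a tar-like scale (mg/cigarette).
    """

    h2_target: float = 0.70
    n_qtl: int = 500
    focal_window: Optional[Tuple[str, int, int]] = None
    focal_fraction: float = 0.0
    phenotype_mean: float = 29.7
    phenotype_sd: float = 9.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.h2_target < 1.0):
            raise ValueError("h2_target must lie in [0, 1)")
        if self.n_qtl <= 0:
            raise ValueError("n_qtl must be positive")
        if not (0.0 <= self.focal_fraction <= 1.0):
            raise ValueError("focal_fraction must lie in [0, 1]")
        if self.focal_window is None and self.focal_fraction != 0.0:
            raise ValueError("focal_fraction requires a focal_window")


@dataclass
class TrueEffects:
    """Ground truth of one trait draw, for parameter-recovery tests."""

    qtl_marker_ids: list
    qtl_effects: np.ndarray  # trait units per alt allele, aligned to qtl_marker_ids
    realized_h2: float
    genetic_values: np.ndarray  # per-individual true breeding values
    effects_by_marker: pd.Series = field(repr=False, default=None)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"marker_id": self.qtl_marker_ids, "effect": self.qtl_effects}
        ).to_csv(path, sep="\t", index=False)


def _sample_positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """m strictly increasing 1-based positions in [1, length]."""
    pos = np.unique(rng.integers(1, length + 1, size=2 * m + 16))
    while pos.size < m:  # pathological collisions only
        extra = rng.integers(1, length + 1, size=2 * m)
        pos = np.unique(np.concatenate([pos, extra]))
    take = np.sort(rng.choice(pos.size, size=m, replace=False))
    return pos[take]


def _founder_freqs(rng: np.random.Generator, m: int, floor: float) -> np.ndarray:
    """Beta(0.5, 0.5) allele-frequency spectrum truncated to [floor, 1-floor]."""
    p = rng.beta(0.5, 0.5, size=m)
    bad = (p < floor) | (p > 1.0 - floor)
    while bad.any():
        p[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))
        bad = (p < floor) | (p > 1.0 - floor)
    return p


def _mosaic_indices(
    rng: np.random.Generator,
    n_gametes: int,
    positions: np.ndarray,
    length: int,
    n_founders: int,
    recomb_rate: float,
) -> np.ndarray:
    """Founder index carried by each gamete at each marker (n_gametes x m)."""
    m = positions.size
    out = np.empty((n_gametes, m), dtype=np.int32)
    for g in range(n_gametes):
        k = rng.poisson(recomb_rate)
        if k == 0:
            out[g, :] = rng.integers(n_founders)
            continue
        breaks = np.sort(rng.integers(1, length + 1, size=k))
        founders = rng.integers(n_founders, size=k + 1)
        seg = np.searchsorted(breaks, positions, side="right")
        out[g, :] = founders[seg]
    return out


def simulate_genotypes(config: SimConfig) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a dosage matrix plus its genome map.

    Returns ``(GenotypeMatrix, genome_map)`` where the genome map is a
    DataFrame with columns ``chrom`` and ``length_bp``.  Markers whose
    realized MAF falls below ``maf_floor`` have their founder alleles
    redrawn (the individual mosaics are kept) so every retained marker
    satisfies the floor exactly; the draw is deterministic under a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    nf = config.n_founder_haplotypes

    sample_ids = [f"acc{i + 1:04d}" for i in range(n)]
    dosage_blocks = []
    marker_rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        m = config.n_markers_per_chrom
        positions = _sample_positions(rng, config.chrom_length_bp, m)
        p = _founder_freqs(rng, m, config.maf_floor)
        founders = (rng.random((nf, m)) < p).astype(np.int8)
        mosaic = _mosaic_indices(
            rng, 2 * n, positions, config.chrom_length_bp, nf, config.recomb_rate
        )
        hap = founders[mosaic, np.arange(m)]  # (2n, m)
        # redraw founder alleles at markers whose realized MAF misses the floor
        for _ in range(200):
            freq = hap.mean(axis=0)
            maf = np.minimum(freq, 1.0 - freq)
            bad = np.flatnonzero(maf < config.maf_floor)
            if bad.size == 0:
                break
            founders[:, bad] = (
                rng.random((nf, bad.size)) < _founder_freqs(rng, bad.size, 0.25)
            ).astype(np.int8)
            hap[:, bad] = founders[mosaic[:, bad], bad]
        else:  # pragma: no cover - 200 rounds always suffice at desk scale
            raise RuntimeError("could not realize MAF floor; raise n or founders")
        dosages = (hap[0::2, :] + hap[1::2, :]).astype(np.float64)
        dosage_blocks.append(dosages)
        for j in range(m):
            marker_rows.append(
                (f"{chrom}_{positions[j]}", chrom, int(positions[j]), "A", "G")
            )

    dosages = np.concatenate(dosage_blocks, axis=1)
    markers = pd.DataFrame(
        marker_rows, columns=["id", "chrom", "pos_bp", "ref", "alt"]
    )
    geno = GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)
    genome_map = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in range(config.n_chromosomes)],
            "length_bp": config.chrom_length_bp,
        }
    )
    return geno, genome_map


def simulate_trait(
    geno: GenotypeMatrix, config: TraitConfig
) -> Tuple[pd.DataFrame, TrueEffects]:
    """Draw an additive polygenic phenotype on top of ``geno``.

    QTL positions are sampled uniformly over markers; effects are
    N(0, 1) draws rescaled so that (a) in-window QTLs contribute
    ``focal_fraction`` of the frequency-weighted genetic variance and
    (b) the realized genetic-to-phenotypic variance ratio matches
    ``h2_target`` for this draw.  Returns a phenotype table
    (``sample_id``, ``tar``) and the :class:`TrueEffects` ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = geno.dosages.shape
    if config.n_qtl > m:
        raise ValueError(f"n_qtl={config.n_qtl} exceeds marker count {m}")

    in_window = np.zeros(m, dtype=bool)
    if config.focal_window is not None:
        chrom, start, end = config.focal_window
        in_window = (
            (geno.markers["chrom"] == chrom)
            & (geno.markers["pos_bp"] >= start)
            & (geno.markers["pos_bp"] <= end)
        ).to_numpy()
        if not in_window.any():
            raise ValueError(
                f"focal_window {chrom}:{start}-{end} contains no markers"
            )

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    if config.focal_fraction > 0 and not in_window[qtl_idx].any():
        # guarantee at least one in-window QTL to carry the focal variance
        inside = np.flatnonzero(in_window)
        qtl_idx[rng.integers(config.n_qtl)] = rng.choice(inside)
        qtl_idx = np.sort(qtl_idx)

    effects = rng.standard_normal(config.n_qtl)
    W = geno.dosages[:, qtl_idx]
    freq = W.mean(axis=0) / 2.0
    weights = 2.0 * freq * (1.0 - freq)  # per-QTL variance contribution weight

    if config.focal_fraction > 0:
        qin = in_window[qtl_idx]
        c_in = float(np.sum(weights[qin] * effects[qin] ** 2))
        c_out = float(np.sum(weights[~qin] * effects[~qin] ** 2))
        f = config.focal_fraction
        if c_in > 0 and c_out > 0 and 0 < f < 1:
            total = c_in + c_out
            effects[qin] *= np.sqrt(f * total / c_in)
            effects[~qin] *= np.sqrt((1.0 - f) * total / c_out)
        elif f == 1.0:
            effects[~qin] = 0.0
        elif f == 0.0:
            effects[qin] = 0.0

    if config.h2_target == 0.0:
        effects[:] = 0.0
        g = np.zeros(n)
        sigma_e = config.phenotype_sd
    else:
        g = (W - 2.0 * freq) @ effects
        var_g = float(np.var(g))
        if var_g <= 0:
            raise ValueError("degenerate genotype draw: no genetic variance")
        # put the trait on the requested phenotypic scale, then solve
        # var(g)/(var(g)+sigma_e^2) = h2 for sigma_e
        scale = config.phenotype_sd * np.sqrt(config.h2_target / var_g)
        effects *= scale
        g *= scale
        var_g = float(np.var(g))
        sigma_e = np.sqrt(var_g * (1.0 - config.h2_target) / config.h2_target)

    e = rng.normal(0.0, sigma_e, size=n)
    if sigma_e > 0 and np.var(g) > 0:
        # calibrate the draw: remove the sample mean and the in-sample
        # covariance with g, then scale to the exact residual variance,
        # so the realized variance ratio matches h2_target per draw
        e = e - e.mean()
        e = e - g * (np.dot(e, g) / np.dot(g, g))
        e *= sigma_e / np.std(e)
    y = config.phenotype_mean + g + e
    realized_h2 = float(np.var(g) / np.var(g + e)) if np.var(g + e) > 0 else 0.0

    by_marker = pd.Series(0.0, index=geno.markers["id"].to_numpy())
    by_marker.iloc[qtl_idx] = effects
    truth = TrueEffects(
        qtl_marker_ids=list(geno.markers["id"].iloc[qtl_idx]),
        qtl_effects=effects,
        realized_h2=realized_h2,
        genetic_values=g,
        effects_by_marker=by_marker,
    )
    pheno = pd.DataFrame({"sample_id": geno.sample_ids, "tar": y})
    return pheno, truth


def degrade_genotypes(
    geno: GenotypeMatrix,
    site_missing_rate: float = 0.0,
    indiv_missing_rate: float = 0.0,
    depth_mean: float = 5.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Return a degraded copy with missing calls and depth metadata.

    An entry (i, j) is masked with probability
    ``1 - (1 - site_missing_rate)(1 - indiv_missing_rate)``; per-site
    mean depths are Gamma draws (shape 4) with mean ``depth_mean``.
    The input matrix is never modified.
    """
    for r in (site_missing_rate, indiv_missing_rate):
        if not (0.0 <= r < 1.0):
            raise ValueError("missing rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n, m = geno.dosages.shape
    p_miss = 1.0 - (1.0 - site_missing_rate) * (1.0 - indiv_missing_rate)
    mask = rng.random((n, m)) < p_miss
    dosages = geno.dosages.copy()
    dosages[mask] = np.nan
    markers = geno.markers.copy()
    shape = 4.0
    markers["mean_depth"] = rng.gamma(shape, depth_mean / shape, size=m)
    out = GenotypeMatrix(
        sample_ids=list(geno.sample_ids), markers=markers, dosages=dosages
    )
    out.refresh_marker_stats()
    return out
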
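"""Generator properties: LD structure, MAF floor, trait calibration."""

import numpy as np
import pytest

from tobgs import simdata
from tobgs.simdata import SimConfig, TraitConfig


def test_same_seed_is_bitwise_identical():
    cfg = SimConfig(n_individuals=50, n_chromosomes=2, n_markers_per_chrom=40,
                    seed=7)
    a, _ = simdata.simulate_genotypes(cfg)
    b, _ = simdata.simulate_genotypes(cfg)
    assert np.array_equal(a.dosages, b.dosages)
    assert a.markers["pos_bp"].tolist() == b.markers["pos_bp"].tolist()


def test_no_recombination_forces_complete_linkage():
    cfg = SimConfig(n_individuals=60, n_chromosomes=1, n_markers_per_chrom=30,
                    n_founder_haplotypes=2, recomb_rate=0.0, maf_floor=0.05,
                    seed=11)
    geno, _ = simdata.simulate_genotypes(cfg)
    # every chromosome copy is one of <= 2 founder haplotypes, so any two
    # polymorphic markers are perfectly correlated (r^2 = 1)
    d = geno.dosages
    poly = d.std(axis=0) > 0
    r = np.corrcoef(d[:, poly].T)
    assert np.allclose(r**2, 1.0, atol=1e-10)


def test_maf_floor_holds_exactly():
    geno, _ = simdata.simulate_genotypes(
        SimConfig(n_individuals=400, n_chromosomes=6, n_markers_per_chrom=200,
                  maf_floor=0.03, seed=2)
    )
    assert (geno.maf() >= 0.03).all()


def test_ld_decays_with_distance():
    geno, _ = simdata.simulate_genotypes(
        SimConfig(n_individuals=400, n_chromosomes=8, n_markers_per_chrom=200,
                  n_founder_haplotypes=20, maf_floor=0.03, seed=4)
    )
    dists, r2s = [], []
    for chrom, grp in geno.markers.groupby("chrom"):
        idx = grp.index.to_numpy()
        pos = grp["pos_bp"].to_numpy()
        d = geno.dosages[:, idx]
        r = np.corrcoef(d.T)
        for i in range(len(idx)):
            for j in range(i + 1, min(i + 40, len(idx))):
                dists.append(pos[j] - pos[i])
                r2s.append(r[i, j] ** 2)
    dists, r2s = np.array(dists), np.array(r2s)
    edges = [0, 100_000, 300_000, 600_000, 1_200_000, 2_000_000]
    means = [
        r2s[(dists > lo) & (dists <= hi)].mean()
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    assert all(a > b for a, b in zip(means[:-1], means[1:])), means


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(maf_floor=0.5).validate()
    with pytest.raises(ValueError):
        SimConfig(n_markers_per_chrom=0).validate()
    with pytest.raises(ValueError):
        SimConfig(n_founder_haplotypes=1).validate()


class TestTrait:
    def test_h2_zero_is_pure_noise(self, small_panel):
        geno, _ = small_panel
        pheno, truth = simdata.simulate_trait(
            geno, TraitConfig(h2_target=0.0, seed=1)
        )
        assert np.ptp(truth.genetic_values) == 0.0
        assert np.std(pheno["tar"]) > 0

    def test_near_noiseless_limit(self, small_panel):
        geno, _ = small_panel
        pheno, truth = simdata.simulate_trait(
            geno, TraitConfig(h2_target=0.99, n_qtl=100, seed=2)
        )
        r = np.corrcoef(truth.genetic_values, pheno["tar"])[0, 1]
        assert r >= 0.99

    def test_realized_h2_matches_target(self, small_panel):
        geno, _ = small_panel
        vals = []
        for seed in range(20):
            _, truth = simdata.simulate_trait(
                geno, TraitConfig(h2_target=0.70, n_qtl=100, seed=seed)
            )
            vals.append(truth.realized_h2)
        assert abs(np.mean(vals) - 0.70) < 0.02

    def test_focal_fraction_of_variance(self, small_panel):
        geno, _ = small_panel
        window = ("chr1", 1, 5_000_000)
        for f in (0.3, 0.5):
            shares = []
            for seed in range(20):
                _, truth = simdata.simulate_trait(
                    geno,
                    TraitConfig(h2_target=0.7, n_qtl=80, focal_window=window,
                                focal_fraction=f, seed=seed),
                )
                ids = set(truth.qtl_marker_ids)
                mask = geno.markers["id"].isin(ids).to_numpy()
                qpos = geno.markers.loc[mask]
                in_win = (
                    (qpos["chrom"] == "chr1") & (qpos["pos_bp"] <= 5_000_000)
                ).to_numpy()
                freq = geno.dosages[:, mask].mean(axis=0) / 2
                w = 2 * freq * (1 - freq)
                order = np.argsort(qpos["id"].to_numpy())
                eff = truth.effects_by_marker[qpos["id"]].to_numpy()
                contrib = w * eff**2
                shares.append(contrib[in_win].sum() / contrib.sum())
            assert abs(np.mean(shares) - f) < 0.05

    def test_phenotype_regression_slope_near_one(self):
        geno, _ = simdata.simulate_genotypes(
            SimConfig(n_individuals=500, n_chromosomes=4,
                      n_markers_per_chrom=150, seed=5)
        )
        slopes = []
        for seed in range(20):
            pheno, truth = simdata.simulate_trait(
                geno, TraitConfig(h2_target=0.6, n_qtl=100, seed=seed)
            )
            g = truth.genetic_values
            y = pheno["tar"].to_numpy()
            slopes.append(np.cov(y, g)[0, 1] / np.var(g))
        assert abs(np.mean(slopes) - 1.0) < 0.1

    def test_empty_focal_window_names_the_window(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(ValueError, match="chr1:9000001-9000002"):
            simdata.simulate_trait(
                geno,
                TraitConfig(h2_target=0.5, n_qtl=10,
                            focal_window=("chr1", 9_000_001, 9_000_002),
                            focal_fraction=0.5, seed=0),
            )


class TestDegrade:
    def test_zero_rates_identity(self, small_panel):
        geno, _ = small_panel
        out = simdata.degrade_genotypes(geno, 0.0, 0.0, seed=1)
        assert np.array_equal(out.dosages, geno.dosages)
        assert "mean_depth" in out.markers.columns

    def test_missing_fraction_matches_rate(self, small_panel):
        geno, _ = small_panel
        out = simdata.degrade_genotypes(geno, site_missing_rate=0.5, seed=2)
        frac = np.isnan(out.dosages).mean()
        assert abs(frac - 0.5) < 0.02
        # original untouched
        assert not np.isnan(geno.dosages).any()

    def test_mask_deterministic_and_rates_validated(self, small_panel):
        geno, _ = small_panel
        a = simdata.degrade_genotypes(geno, 0.2, 0.1, seed=5)
        b = simdata.degrade_genotypes(geno, 0.2, 0.1, seed=5)
        assert np.array_equal(np.isnan(a.dosages), np.isnan(b.dosages))
        with pytest.raises(ValueError):
            simdata.degrade_genotypes(geno, 1.0, 0.0, seed=0)
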
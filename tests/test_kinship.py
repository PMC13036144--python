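"""GRM construction against brute-force oracles; LOCO scopes; PCA."""

import numpy as np
import pandas as pd
import pytest

from tobgs.genotypes import GenotypeMatrix
from tobgs.kinship import GRM, compute_grm, compute_loco_grm, grm_pca
from tobgs import simdata


def brute_force_vanraden(dosages):
    """Independent double-loop VanRaden method 1 (oracle)."""
    n, m = dosages.shape
    p = dosages.mean(axis=0) / 2.0
    keep = [j for j in range(m) if 0 < p[j] < 1]
    denom = sum(2 * p[j] * (1 - p[j]) for j in keep)
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            s = 0.0
            for j in keep:
                s += (dosages[i, j] - 2 * p[j]) * (dosages[k, j] - 2 * p[j])
            G[i, k] = s / denom
    return G


def _geno(dosages, chroms=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chroms = chroms or ["chr1"] * m
    pos, seen = [], {}
    for c in chroms:
        seen[c] = seen.get(c, 0) + 1
        pos.append(seen[c])
    markers = pd.DataFrame(
        {"id": [f"m{j}" for j in range(m)], "chrom": chroms, "pos_bp": pos,
         "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], markers, dosages)


def test_hand_computed_three_by_three():
    # dosages [[0,2],[1,1],[2,0]]: p = (0.5, 0.5), W = dosage - 1,
    # denominator = 2 * (2*0.5*0.5) = 1 -> G = WW'
    geno = _geno([[0, 2], [1, 1], [2, 0]])
    G = compute_grm(geno).values
    expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
    assert np.allclose(G, expected, atol=1e-12)


def test_duplicated_individuals_share_diagonal():
    rng = np.random.default_rng(0)
    base = rng.integers(0, 3, size=(1, 40)).astype(float)
    other = rng.integers(0, 3, size=(3, 40)).astype(float)
    geno = _geno(np.vstack([base, base, other]))
    G = compute_grm(geno).values
    assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)
    assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-12)


def test_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(20):
        dosages = rng.integers(0, 3, size=(20, 50)).astype(float)
        geno = _geno(dosages)
        G = compute_grm(geno).values
        assert np.allclose(G, brute_force_vanraden(dosages), atol=1e-8)


def test_window_and_rest_reconstruct_global():
    """Marker-partition GRMs recombine to the global GRM.

    With the same per-marker centering, WW' decomposes over any marker
    partition, so den_w*G_w + den_r*G_r = den_all*G_all.
    """
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(15, 30)).astype(float)
    geno = _geno(dosages)
    mask = np.zeros(30, dtype=bool)
    mask[:10] = True

    def denom(sub):
        p = sub.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        return float(np.sum(2 * p[keep] * (1 - p[keep])))

    Gw = compute_grm(geno, marker_subset=mask)
    Gr = compute_grm(geno, marker_subset=~mask)
    Ga = compute_grm(geno)
    dw, dr = denom(dosages[:, mask]), denom(dosages[:, ~mask])
    lhs = (dw * Gw.values + dr * Gr.values) / (dw + dr)
    # identical p_j only when subsets are polymorphic in-sample both ways;
    # frequencies are per-subset in-sample and per-marker, hence shared
    assert np.allclose(lhs, Ga.values, atol=1e-10)


def test_scope_bookkeeping_and_monomorphic_exclusion():
    dosages = np.array([[0, 1, 2, 2], [1, 2, 2, 0], [2, 0, 2, 1]], dtype=float)
    geno = _geno(dosages)
    grm = compute_grm(geno, marker_subset=[0, 1, 2], marker_scope="window(chr1,1,3)")
    assert grm.n_markers_used == 2  # marker 2 is monomorphic
    assert grm.marker_scope == "window(chr1,1,3)"


def test_errors():
    with pytest.raises(ValueError, match="monomorphic|polymorphic"):
        compute_grm(_geno(np.full((5, 4), 2.0)))
    with pytest.raises(ValueError, match="2 samples"):
        compute_grm(_geno(np.array([[0, 1, 2]], dtype=float)))


class TestLoco:
    def test_partition_of_markers(self, small_panel):
        geno, _ = small_panel
        loco = compute_loco_grm(geno, "chr2")
        on_c2 = int((geno.markers["chrom"] == "chr2").sum())
        own = compute_grm(
            geno, marker_subset=(geno.markers["chrom"] == "chr2").to_numpy()
        )
        # disjoint scopes together cover all (polymorphic) markers
        assert loco.n_markers_used + own.n_markers_used == geno.n_markers
        assert loco.marker_scope == "loco(chr2)"

    def test_single_chromosome_rejected(self):
        geno = _geno(np.random.default_rng(1).integers(0, 3, (10, 8)).astype(float))
        with pytest.raises(ValueError, match="2 chromosomes"):
            compute_loco_grm(geno, "chr1")

    def test_loco_approaches_global_as_share_shrinks(self):
        dists = []
        for n_chrom in (2, 6, 12):
            geno, _ = simdata.simulate_genotypes(
                simdata.SimConfig(n_individuals=100, n_chromosomes=n_chrom,
                                  n_markers_per_chrom=60, seed=13)
            )
            ga = compute_grm(geno).values
            gl = compute_loco_grm(geno, "chr1").values
            dists.append(np.linalg.norm(ga - gl))
        assert dists[0] > dists[1] > dists[2]


class TestPca:
    def test_identity_grm_is_isotropic(self):
        grm = GRM([f"s{i}" for i in range(6)], np.eye(6), 10)
        _, frac = grm_pca(grm, 5)
        assert np.allclose(frac, frac[0])

    def test_variance_fractions_sum_to_one(self, small_panel):
        geno, _ = small_panel
        grm = compute_grm(geno)
        _, frac = grm_pca(grm, geno.n_samples - 1)
        assert frac.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(frac) <= 1e-12).all()  # decreasing order

    def test_pc1_separates_subpopulations(self):
        a, _ = simdata.simulate_genotypes(
            simdata.SimConfig(n_individuals=60, n_chromosomes=3,
                              n_markers_per_chrom=100, seed=21)
        )
        b, _ = simdata.simulate_genotypes(
            simdata.SimConfig(n_individuals=60, n_chromosomes=3,
                              n_markers_per_chrom=100, seed=22)
        )
        # two independent founder pools = two diverged subpopulations
        merged = GenotypeMatrix(
            sample_ids=[f"a{i}" for i in range(60)] + [f"b{i}" for i in range(60)],
            markers=a.markers,
            dosages=np.vstack([a.dosages, b.dosages]),
        )
        comps, _ = grm_pca(compute_grm(merged), 2)
        labels = np.array([0] * 60 + [1] * 60)
        r = np.corrcoef(comps[:, 0], labels)[0, 1]
        assert abs(r) >= 0.9

    def test_k_out_of_range(self):
        grm = GRM(["a", "b", "c"], np.eye(3), 5)
        with pytest.raises(ValueError):
            grm_pca(grm, 3)
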
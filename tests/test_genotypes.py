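"""Genotype IO round-trips, QC filter semantics, imputation, concordance."""

import numpy as np
import pandas as pd
import pytest

from tobgs import simdata
from tobgs.genotypes import (
    GenotypeMatrix,
    apply_filters,
    genotype_concordance,
    impute_missing,
    read_genotypes,
    write_dosage_tsv,
    write_vcf,
)


def _matrix(dosages, chrom="chr1", depth=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "id": [f"{chrom}_{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos_bp": np.arange(1, m + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    if depth is not None:
        markers["mean_depth"] = depth
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)], markers=markers, dosages=dosages
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def test_vcf_round_trip(small_panel, tmp_path):
    geno, _ = small_panel
    path = tmp_path / "panel.vcf"
    write_vcf(geno, path)
    back = read_genotypes(path, "vcf")
    assert back.sample_ids == geno.sample_ids
    assert np.array_equal(back.dosages, geno.dosages)
    assert back.markers["pos_bp"].tolist() == geno.markers["pos_bp"].tolist()


def test_dosage_tsv_round_trip_preserves_missing(tmp_path):
    geno = _matrix([[0, 2, np.nan], [1, 1, 2]])
    path = tmp_path / "dose.tsv"
    write_dosage_tsv(geno, path)
    back = read_genotypes(path, "dosage_tsv")
    ok = ~np.isnan(geno.dosages)
    assert np.array_equal(np.isnan(back.dosages), ~ok)
    assert np.allclose(back.dosages[ok], geno.dosages[ok])


def test_vcf_gt_codes_and_multiallelic_skip(tmp_path):
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\ts3",
    ]
    for j in range(1, 10):
        lines.append(
            f"chr1\t{j * 100}\tm{j}\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./."
        )
    lines.append("chr1\t5000\tm10\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2\t2/2")
    path = tmp_path / "mix.vcf"
    path.write_text("\n".join(lines) + "\n")
    geno = read_genotypes(path, "vcf")
    assert geno.n_markers == 9  # the triallelic record is skipped
    assert geno.dosages[0, 0] == 0 and geno.dosages[1, 0] == 1
    assert geno.dosages[2, 0] == 2 and np.isnan(geno.dosages[3, 0])


def test_plink_bed_round_trip(tmp_path):
    # SNP-major 2-bit codes: 00 hom A1(=2), 10 het(=1), 11 hom A2(=0), 01 miss
    dosages = np.array(
        [[2, 0, 1], [1, 1, np.nan], [0, 2, 2], [2, 0, 0], [1, 1, 2]]
    )
    code_of = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    body = bytearray([0x6C, 0x1B, 0x01])
    n = dosages.shape[0]
    for j in range(dosages.shape[1]):
        bits = []
        for i in range(n):
            d = dosages[i, j]
            bits.append(0b01 if np.isnan(d) else code_of[d])
        for start in range(0, n, 4):
            byte = 0
            for k, c in enumerate(bits[start:start + 4]):
                byte |= c << (2 * k)
            body.append(byte)
    (tmp_path / "toy.bed").write_bytes(bytes(body))
    fam = "\n".join(f"f{i} s{i} 0 0 0 -9" for i in range(n))
    (tmp_path / "toy.fam").write_text(fam + "\n")
    bim = "\n".join(f"1 m{j} 0 {100 * (j + 1)} G A" for j in range(3))
    (tmp_path / "toy.bim").write_text(bim + "\n")
    geno = read_genotypes(tmp_path / "toy", "plink")
    assert geno.sample_ids == [f"s{i}" for i in range(n)]
    nan = np.isnan(dosages)
    assert np.array_equal(np.isnan(geno.dosages), nan)
    assert np.array_equal(geno.dosages[~nan], dosages[~nan])


def test_unknown_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown genotype format"):
        read_genotypes(tmp_path / "x", "bgen")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_filter_fixture_counts():
    # 10 markers: 2 low depth, 1 low MAF, 1 high missing, 6 clean
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(10, 10)).astype(float)
    dosages[:, 2] = 0.0           # monomorphic -> MAF 0
    dosages[0, 2] = 1.0           # MAF 0.05 > 0.03? 1/20 = 0.05 -- too high
    dosages[:, 2] = 0.0           # keep strictly below: MAF 0
    dosages[:6, 3] = np.nan       # missing 0.6 >= 0.5
    depth = np.full(10, 5.0)
    depth[[0, 1]] = 1.5
    geno = _matrix(dosages, depth=depth)
    out, report = apply_filters(geno)
    assert report.removed_depth == 2
    assert report.removed_maf == 1
    assert report.removed_missing == 1
    assert out.n_markers == 6
    assert report.n_markers_in - (
        report.removed_depth + report.removed_maf + report.removed_missing
    ) == report.n_markers_out


def test_filter_boundary_semantics():
    # depth exactly 2 and MAF exactly 0.03 are removed (strict >),
    # missing exactly 0.5 is removed (>= threshold)
    n = 100
    rng = np.random.default_rng(1)
    dosages = rng.integers(0, 3, size=(n, 4)).astype(float)
    # marker 1: MAF exactly 0.03 (6 alt alleles in 200)
    dosages[:, 1] = 0.0
    dosages[:3, 1] = 2.0
    # marker 2: missing exactly 0.5
    dosages[: n // 2, 2] = np.nan
    depth = np.array([2.0, 5.0, 5.0, 5.0])
    geno = _matrix(dosages, depth=depth)
    out, report = apply_filters(geno)
    kept = set(out.markers["id"])
    assert "chr1_1" not in kept  # depth == 2
    assert "chr1_2" not in kept  # MAF == 0.03
    assert "chr1_3" not in kept  # missing == 0.5


def test_noop_thresholds_and_idempotence(small_panel):
    geno, _ = small_panel
    degraded = simdata.degrade_genotypes(geno, 0.1, 0.05, depth_mean=6, seed=8)
    out1, _ = apply_filters(degraded)
    out2, rep2 = apply_filters(out1)
    assert out2.n_markers == out1.n_markers
    assert out2.n_samples == out1.n_samples
    # no-op bounds keep everything
    out3, rep3 = apply_filters(degraded, min_depth=0, min_maf=0, max_missing=1.0)
    assert out3.n_markers == degraded.n_markers


def test_all_markers_removed_is_an_error():
    geno = _matrix(np.zeros((10, 3)))  # all monomorphic
    with pytest.raises(ValueError, match="all markers"):
        apply_filters(geno)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "method,column,expected",
    [
        ("site_mean", [0, 2, np.nan], 1.0),
        ("site_mode", [0, 0, 2, np.nan], 0.0),
    ],
)
def test_impute_fill_values(method, column, expected):
    col = np.asarray(column, dtype=float)
    geno = _matrix(col[:, None])
    out = impute_missing(geno, method)
    assert out.dosages[-1, 0] == expected
    assert not np.isnan(out.dosages).any()


def test_impute_identity_and_errors(small_panel):
    geno, _ = small_panel
    assert impute_missing(geno) is geno  # nothing missing -> unchanged
    bad = _matrix(np.full((4, 1), np.nan))
    with pytest.raises(ValueError, match="filter"):
        impute_missing(bad)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_identity(small_panel):
    geno, _ = small_panel
    overall, per_sample = genotype_concordance(geno, geno)
    assert overall == 1.0
    assert (per_sample == 1.0).all()


def test_concordance_flipped_homs():
    d = np.array([[0, 2, 1], [2, 0, 1]], dtype=float)
    a = _matrix(d)
    b = _matrix(2.0 - d)
    overall, _ = genotype_concordance(a, b)
    # only the het cells agree under a full allele flip
    assert overall == pytest.approx(2 / 6)


def test_concordance_counts_mismatches():
    d = np.arange(10).reshape(2, 5) % 3
    a = _matrix(d.astype(float))
    d2 = d.astype(float).copy()
    d2[0, 0] = (d2[0, 0] + 1) % 3
    b = _matrix(d2)
    overall, _ = genotype_concordance(a, b)
    assert overall == pytest.approx(0.9)


def test_concordance_requires_overlap():
    a = _matrix(np.zeros((2, 2)), chrom="chr1")
    b = _matrix(np.zeros((2, 2)), chrom="chr2")
    with pytest.raises(ValueError):
        genotype_concordance(a, b)
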
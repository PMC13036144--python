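"""Genotype containers, file IO, QC filters, imputation, concordance.

Dosages are stored as an ``n_samples x n_markers`` float matrix with
alt-allele counts in {0, 1, 2} (fractional after mean imputation) and
``NaN`` for missing calls.  Marker metadata travels in a DataFrame with
one row per marker (``id, chrom, pos_bp, ref, alt`` plus ``maf``,
``mean_depth``, ``missing_rate`` when known).  Coordinates are 1-based
inclusive throughout, following VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "MarkerInfo",
    "QCReport",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "apply_filters",
    "impute_missing",
    "genotype_concordance",
]

MARKER_COLUMNS = ["id", "chrom", "pos_bp", "ref", "alt"]


@dataclass
class MarkerInfo:
    """Metadata of one biallelic SNP."""

    id: str
    chrom: str
    pos_bp: int
    ref: str
    alt: str
    maf: float = np.nan
    mean_depth: float = np.nan
    missing_rate: float = np.nan


@dataclass
class GenotypeMatrix:
    """Individuals-by-markers dosage matrix with marker metadata."""

    sample_ids: List[str]
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows != number of samples")
        if m != len(self.markers):
            raise ValueError("dosage columns != number of markers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def marker_info(self, j: int) -> MarkerInfo:
        row = self.markers.iloc[j]
        return MarkerInfo(
            id=row["id"], chrom=row["chrom"], pos_bp=int(row["pos_bp"]),
            ref=row.get("ref", "A"), alt=row.get("alt", "G"),
            maf=float(row.get("maf", np.nan)),
            mean_depth=float(row.get("mean_depth", np.nan)),
            missing_rate=float(row.get("missing_rate", np.nan)),
        )

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_rate_per_marker(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def missing_rate_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def refresh_marker_stats(self) -> None:
        self.markers = self.markers.copy()
        self.markers["maf"] = self.maf()
        self.markers["missing_rate"] = self.missing_rate_per_marker()

    def subset_markers(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            markers=self.markers,
            dosages=self.dosages[idx, :],
        )


@dataclass
class QCReport:
    """Bookkeeping of one filtering pass.

    Each removed marker is attributed to the first rule it fails in
    the fixed order depth -> MAF -> site missingness; sample removal
    (individual missingness) happens after marker removal.
    """

    n_samples_in: int
    n_markers_in: int
    removed_depth: int
    removed_maf: int
    removed_missing: int
    removed_samples: int
    n_samples_out: int
    n_markers_out: int
    thresholds: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_markers_in - (
            self.removed_depth + self.removed_maf + self.removed_missing
        ) == self.n_markers_out, "marker counts not conserved"
        assert self.n_samples_in - self.removed_samples == self.n_samples_out

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(k, v) for k, v in vars(self).items() if k != "thresholds"]
            + [(f"threshold_{k}", v) for k, v in self.thresholds.items()],
            columns=["key", "value"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load genotypes from VCF, PLINK bed/bim/fam, or a dosage TSV.

    Only biallelic SNPs are kept; multiallelic records are skipped with
    a logged count.  Diploid GT is mapped to alt-allele dosage and
    missing GT to NaN.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, cols, depths = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotype.array()  # (n, ploidy+1): a1, a2, phased
        a = gts[:, :2].astype(float)
        a[a < 0] = np.nan
        dose = a.sum(axis=1)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        cols.append(dose)
        md = var.INFO.get("MD")
        if md is None:
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            md = float(np.nanmean(dp)) if dp is not None else np.nan
        depths.append(float(md) if md is not None else np.nan)
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, path)
    if not rows:
        raise ValueError(f"no biallelic sites in {path}")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    markers["mean_depth"] = depths
    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        markers=markers,
        dosages=np.column_stack(cols),
    )
    geno.refresh_marker_stats()
    return geno


def _read_plink(path: Path) -> GenotypeMatrix:
    """Minimal SNP-major PLINK1 bed/bim/fam reader.

    ``path`` is the shared prefix.  Two-bit codes per the PLINK spec:
    00 hom A1, 01 missing, 10 het, 11 hom A2.  A1 is treated as the
    alt allele (dosage counts A1), matching plink's minor-allele-first
    default.
    """
    prefix = Path(str(path).removesuffix(".bed"))
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    sample_ids = fam_df[1].astype(str).tolist()
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos_bp", "a1", "a2"],
    )
    n, m = len(sample_ids), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError(f"{bed} is not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])  # code -> A1 dosage
    dosages = lut[codes].T
    markers = pd.DataFrame(
        {
            "id": bim_df["id"].astype(str),
            "chrom": bim_df["chrom"].astype(str),
            "pos_bp": bim_df["pos_bp"].astype(int),
            "ref": bim_df["a2"].astype(str),
            "alt": bim_df["a1"].astype(str),
        }
    )
    geno = GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)
    geno.refresh_marker_stats()
    return geno


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in MARKER_COLUMNS if c in df.columns]
    if "chrom" not in meta_cols or "pos_bp" not in meta_cols:
        raise ValueError(f"malformed dosage TSV header in {path}")
    sample_cols = [c for c in df.columns if c not in MARKER_COLUMNS]
    markers = df[meta_cols].copy()
    if "id" not in markers:
        markers["id"] = markers["chrom"].astype(str) + "_" + markers["pos_bp"].astype(str)
    for c in ("ref", "alt"):
        if c not in markers:
            markers[c] = "A" if c == "ref" else "G"
    geno = GenotypeMatrix(
        sample_ids=sample_cols,
        markers=markers[MARKER_COLUMNS],
        dosages=df[sample_cols].to_numpy(dtype=float).T,
    )
    geno.refresh_marker_stats()
    return geno


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF 4.2 with GT fields and one contig per chromosome.

    Fractional (imputed) dosages are rounded to the nearest hard call.
    Per-site mean depth, when present, is stored in INFO/MD.
    """
    path = Path(path)
    chroms = list(dict.fromkeys(geno.markers["chrom"]))
    has_depth = "mean_depth" in geno.markers.columns
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MD,Number=1,Type=Float,Description="Mean site depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids) + "\n"
        )
        for j in range(geno.n_markers):
            row = geno.markers.iloc[j]
            md = row["mean_depth"] if has_depth else np.nan
            info = f"MD={md:.3f}" if np.isfinite(md) else "."
            dose = geno.dosages[:, j]
            calls = [
                "./." if np.isnan(d) else gt_codes[int(round(d))] for d in dose
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos_bp']}\t{row['id']}\t{row['ref']}"
                f"\t{row['alt']}\t.\tPASS\t{info}\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = geno.markers[MARKER_COLUMNS].copy()
    body = pd.DataFrame(
        geno.dosages.T, columns=geno.sample_ids, index=df.index
    )
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# QC / imputation / concordance
# ---------------------------------------------------------------------------

def apply_filters(
    geno: GenotypeMatrix,
    min_depth: float = 2.0,
    min_maf: float = 0.03,
    max_missing: float = 0.5,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Apply the marker/sample QC rules and return the surviving matrix.

    Markers are removed when mean depth <= ``min_depth`` (strictly
    "greater than" is retained), MAF <= ``min_maf``, or site missing
    rate >= ``max_missing``; individuals with missing rate >=
    ``max_missing`` are removed afterwards and MAF is recomputed.
    Removal attribution follows the fixed rule order depth -> MAF ->
    missingness.  When no depth metadata is present the depth rule is
    skipped with a warning.
    """
    n0, m0 = geno.n_samples, geno.n_markers
    depth = (
        geno.markers["mean_depth"].to_numpy(dtype=float)
        if "mean_depth" in geno.markers.columns
        else np.full(m0, np.nan)
    )
    if not np.isfinite(depth).any():
        logger.warning("no per-site depth metadata; depth filter skipped")
        fail_depth = np.zeros(m0, dtype=bool)
    else:
        fail_depth = ~(depth > min_depth)
    maf = geno.maf()
    fail_maf = ~(maf > min_maf)
    miss = geno.missing_rate_per_marker()
    fail_miss = miss >= max_missing

    first_fail_maf = fail_maf & ~fail_depth
    first_fail_miss = fail_miss & ~fail_depth & ~fail_maf
    keep = ~(fail_depth | fail_maf | fail_miss)
    if not keep.any():
        raise ValueError("all markers removed by QC filters")
    out = geno.subset_markers(keep)

    sample_miss = out.missing_rate_per_sample()
    keep_samples = sample_miss < max_missing
    removed_samples = int((~keep_samples).sum())
    if removed_samples:
        if not keep_samples.any():
            raise ValueError("all samples removed by QC filters")
        out = out.subset_samples(keep_samples)
    out.refresh_marker_stats()

    report = QCReport(
        n_samples_in=n0,
        n_markers_in=m0,
        removed_depth=int(fail_depth.sum()),
        removed_maf=int(first_fail_maf.sum()),
        removed_missing=int(first_fail_miss.sum()),
        removed_samples=removed_samples,
        n_samples_out=out.n_samples,
        n_markers_out=out.n_markers,
        thresholds={
            "min_depth": min_depth, "min_maf": min_maf, "max_missing": max_missing
        },
    )
    logger.info(
        "QC: %d/%d markers and %d/%d samples retained", out.n_markers, m0,
        out.n_samples, n0,
    )
    return out, report


def impute_missing(geno: GenotypeMatrix, method: str = "site_mean") -> GenotypeMatrix:
    """Fill missing dosages per marker by its mean or modal dosage."""
    if method not in ("site_mean", "site_mode"):
        raise ValueError(f"unknown imputation method: {method!r}")
    nan_mask = np.isnan(geno.dosages)
    if not nan_mask.any():
        return geno
    if nan_mask.all(axis=0).any():
        bad = geno.markers["id"][nan_mask.all(axis=0)].tolist()
        raise ValueError(
            f"fully-missing markers {bad[:5]}...; filter before imputing"
        )
    dosages = geno.dosages.copy()
    if method == "site_mean":
        fill = np.nanmean(dosages, axis=0)
    else:
        fill = np.empty(geno.n_markers)
        for j in range(geno.n_markers):
            col = dosages[:, j]
            counts = np.bincount(
                np.rint(col[~np.isnan(col)]).astype(int), minlength=3
            )
            fill[j] = float(np.argmax(counts))  # ties -> lowest dosage
    rows, cols = np.nonzero(nan_mask)
    dosages[rows, cols] = fill[cols]
    out = GenotypeMatrix(
        sample_ids=list(geno.sample_ids), markers=geno.markers, dosages=dosages
    )
    out.refresh_marker_stats()
    return out


def genotype_concordance(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> Tuple[float, pd.Series]:
    """Fraction of jointly non-missing overlapping calls with equal hard dosage.

    Samples are matched by id and markers by (chrom, pos_bp).  Returns
    the overall fraction and a per-sample breakdown.
    """
    common_samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    key_a = list(zip(a.markers["chrom"], a.markers["pos_bp"]))
    key_b = {k: j for j, k in enumerate(zip(b.markers["chrom"], b.markers["pos_bp"]))}
    ja, jb = [], []
    for j, k in enumerate(key_a):
        if k in key_b:
            ja.append(j)
            jb.append(key_b[k])
    if not common_samples or not ja:
        raise ValueError("no overlapping samples/markers between call sets")
    ia = [a.sample_ids.index(s) for s in common_samples]
    ib = [b.sample_ids.index(s) for s in common_samples]
    da = a.dosages[np.ix_(ia, ja)]
    db = b.dosages[np.ix_(ib, jb)]
    both = ~np.isnan(da) & ~np.isnan(db)
    if not both.any():
        raise ValueError("no jointly non-missing overlapping calls")
    eq = np.rint(da) == np.rint(db)
    overall = float(eq[both].sum() / both.sum())
    with np.errstate(invalid="ignore"):
        per_sample = np.where(
            both.sum(axis=1) > 0,
            (eq & both).sum(axis=1) / both.sum(axis=1),
            np.nan,
        )
    return overall, pd.Series(per_sample, index=common_samples, name="concordance")
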
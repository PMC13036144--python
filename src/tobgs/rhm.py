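"""Regional heritability mapping (RHM) over sliding windows.

The genome is tiled with overlapping windows (default 2 Mb wide, 500-kb
step).  For each window a two-genetic-component mixed model is fitted:

    y = X b + u_local + u_background + e

where u_local is structured by a GRM built from the window's markers
and u_background by a leave-one-chromosome-out (LOCO) GRM that excludes
the window's entire chromosome, so the two marker scopes are disjoint
by construction.  The window's evidence is a likelihood-ratio test of
the local component (df = 1) against the background-only model, and its
effect size is reported both as the raw local variance VG1 and as the
model-internal share VG1 / (VG1 + VG2).

Because neighbouring windows overlap, VG1 values are never summed into
a genome heritability; ranked summaries are expressed as fractions of
the summed local components (sigma VG1) only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import GRM, compute_grm, compute_loco_grm
from .varcomp import MixedModelSpec, VarCompFit, fit_reml, lrt_genetic

logger = logging.getLogger(__name__)

__all__ = ["WindowSet", "make_windows", "fit_window", "scan_regions",
           "summarize_scan"]


@dataclass
class WindowSet:
    """Sliding windows, 1-based inclusive, on the lattice 1 + k*step."""

    windows: pd.DataFrame  # chrom, start_bp, end_bp, n_markers
    width_bp: int
    step_bp: int
    min_markers: int


def make_windows(
    genome_map: pd.DataFrame,
    markers: pd.DataFrame,
    width_bp: int = 2_000_000,
    step_bp: int = 500_000,
    min_markers: int = 10,
) -> WindowSet:
    """Tile each chromosome with windows [1+k*step, 1+k*step+width-1].

    Window starts run while start <= chromosome length; trailing
    windows are truncated at the chromosome end.  Windows holding fewer
    than ``min_markers`` markers are dropped with a logged count.
    """
    if not (width_bp >= step_bp > 0):
        raise ValueError("need width_bp >= step_bp > 0")
    if len(markers) == 0:
        raise ValueError("empty marker set")
    rows = []
    n_dropped = 0
    for _, mrow in genome_map.iterrows():
        chrom, length = mrow["chrom"], int(mrow["length_bp"])
        pos = markers.loc[markers["chrom"] == chrom, "pos_bp"].to_numpy()
        pos = np.sort(pos)
        start = 1
        while start <= length:
            end = min(start + width_bp - 1, length)
            n_in = int(
                np.searchsorted(pos, end, "right")
                - np.searchsorted(pos, start, "left")
            )
            if n_in >= min_markers:
                rows.append((chrom, start, end, n_in))
            else:
                n_dropped += 1
            start += step_bp
    if n_dropped:
        logger.info("dropped %d windows with < %d markers", n_dropped, min_markers)
    windows = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_markers"])
    return WindowSet(windows=windows, width_bp=width_bp, step_bp=step_bp,
                     min_markers=min_markers)


def _scope_chrom(scope: str) -> Optional[str]:
    m = re.fullmatch(r"loco\((.+)\)", scope)
    return m.group(1) if m else None


def fit_window(
    geno: GenotypeMatrix,
    y: np.ndarray,
    chrom: str,
    start_bp: int,
    end_bp: int,
    background_grm: GRM,
    null_fit: Optional[VarCompFit] = None,
) -> dict:
    """Two-component REML for one window against a LOCO background.

    The background GRM must carry the scope tag ``loco(<chrom>)`` for
    the window's own chromosome — local and background marker sets must
    be disjoint, and this is enforced, not assumed.
    """
    excl = _scope_chrom(background_grm.marker_scope)
    if excl != chrom:
        raise ValueError(
            f"background GRM scope {background_grm.marker_scope!r} is not "
            f"loco({chrom!r}): local and background marker sets must be disjoint"
        )
    in_win = (
        (geno.markers["chrom"] == chrom)
        & (geno.markers["pos_bp"] >= start_bp)
        & (geno.markers["pos_bp"] <= end_bp)
    ).to_numpy()
    local = compute_grm(
        geno, marker_subset=in_win,
        marker_scope=f"window({chrom},{start_bp},{end_bp})",
    )
    if null_fit is None:
        null_fit = fit_reml(MixedModelSpec(y=y, grms=[background_grm]))
    full = fit_reml(
        MixedModelSpec(
            y=y, grms=[local, background_grm],
            component_names=["local", "background"],
        )
    )
    vg1, vg2, ve = (float(s) for s in full.sigma2)
    try:
        lrt, p = lrt_genetic(full, null_fit, df=1)
    except ValueError:
        # near-boundary numerics can leave the full fit a hair below the
        # null; the local component then carries no evidence
        lrt, p = 0.0, 1.0
    share = vg1 / (vg1 + vg2) if (vg1 + vg2) > 0 else np.nan
    return {
        "chrom": chrom, "start_bp": start_bp, "end_bp": end_bp,
        "n_markers": int(local.n_markers_used),
        "vg1": vg1, "vg2": vg2, "ve": ve, "share": share,
        "lrt": lrt, "p": p, "converged": bool(full.converged),
    }


def scan_regions(
    geno: GenotypeMatrix, y: np.ndarray, windows: WindowSet
) -> pd.DataFrame:
    """Fit every window; LOCO backgrounds and null fits cached per chromosome.

    Windows with fewer than 2 polymorphic markers are skipped with a
    log entry; non-converged windows are flagged, never dropped.
    """
    if geno.markers["chrom"].nunique() < 2:
        raise ValueError("regional scan needs >= 2 chromosomes (LOCO background)")
    y = np.asarray(y, dtype=float).ravel()
    loco_cache: Dict[str, GRM] = {}
    null_cache: Dict[str, VarCompFit] = {}
    rows = []
    for _, w in windows.windows.iterrows():
        chrom = w["chrom"]
        if chrom not in loco_cache:
            loco_cache[chrom] = compute_loco_grm(geno, chrom)
            null_cache[chrom] = fit_reml(
                MixedModelSpec(y=y, grms=[loco_cache[chrom]])
            )
        try:
            rows.append(
                fit_window(
                    geno, y, chrom, int(w["start_bp"]), int(w["end_bp"]),
                    loco_cache[chrom], null_fit=null_cache[chrom],
                )
            )
        except ValueError as err:
            logger.info(
                "skipping window %s:%d-%d: %s",
                chrom, w["start_bp"], w["end_bp"], err,
            )
    if not rows:
        raise ValueError("no fittable windows in the scan")
    return pd.DataFrame(rows)


def summarize_scan(results: pd.DataFrame) -> dict:
    """Ranked windows, cumulative sigma-VG1 fractions, per-chromosome sums.

    Returns a dict with ``ranked`` (windows by vg1 descending, ties by
    chrom/start, with cumulative fractions of sigma VG1), ``by_chrom``
    (per-chromosome fraction of sigma VG1), and ``lead`` (the top
    window row, including its VG1/(VG1+VG2) share).
    """
    conv = results[results["converged"]]
    if len(conv) == 0:
        raise ValueError("no converged windows to summarize")
    total = float(conv["vg1"].sum())
    if total <= 0:
        raise ValueError("all local variance components are zero")
    ranked = conv.sort_values(
        ["vg1", "chrom", "start_bp"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranked["cum_fraction"] = ranked["vg1"].cumsum() / total
    by_chrom = (
        conv.groupby("chrom")["vg1"].sum() / total
    ).sort_values(ascending=False)
    return {
        "ranked": ranked,
        "by_chrom": by_chrom,
        "lead": ranked.iloc[0],
        "total_vg1": total,
    }
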
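#!/usr/bin/env python
"""Estimate narrow-sense heritability of the simulated tar trait.

Builds the VanRaden GRM, fits single-GRM REML, reports h2 with its
standard error and the likelihood-ratio test of the genetic component,
and runs GRM PCA for the structure overview.  Writes results/h2/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tobgs import genotypes, kinship, varcomp

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "h2"
    out.mkdir(parents=True, exist_ok=True)
    geno = genotypes.read_genotypes(ROOT / "panel" / "genotypes.tsv", "dosage_tsv")
    pheno = pd.read_csv(ROOT / "panel" / "phenotypes.tsv", sep="\t")
    y = pheno.set_index("sample_id").loc[geno.sample_ids, "tar"].to_numpy()

    grm = kinship.compute_grm(geno)
    kinship.write_grm_tsv(grm, out / "grm.tsv")
    comps, frac = kinship.grm_pca(grm, 10)
    pd.DataFrame(
        comps, index=geno.sample_ids,
        columns=[f"PC{i + 1}" for i in range(10)],
    ).to_csv(out / "pca.tsv", sep="\t")
    print(f"PC1 explains {100 * frac[0]:.1f}% of genetic variance")

    fit = varcomp.fit_reml(varcomp.MixedModelSpec(y=y, grms=[grm]))
    null = varcomp.fit_null_reml(y)
    lrt, p = varcomp.lrt_genetic(fit, null)
    fit.to_tsv(out / "h2.tsv")
    print(f"h2 = {fit.h2:.2f} +/- {fit.h2_se:.2f}  "
          f"(sigma2_g = {fit.sigma2[0]:.1f}, sigma2_e = {fit.sigma2[1]:.1f})")
    print(f"genetic effect: LRT = {lrt:.1f}, df = 1, p = {p:.3g}")


if __name__ == "__main__":
    main()
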
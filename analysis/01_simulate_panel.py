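#!/usr/bin/env python
"""Simulate the desk-scale diversity panel and its tar-like trait.

Builds a 436-accession panel (24 chromosomes, ~5,000 GBS-like SNPs,
MAF >= 0.03, block LD) and an additive polygenic phenotype with
h2 = 0.70 on the tar scale (mean 29.7 mg/cigarette), then writes the
genotypes (VCF + dosage TSV), phenotypes, genome map and ground-truth
QTL effects under results/panel/.
"""

from pathlib import Path

import numpy as np

from tobgs import genotypes, simdata

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno, gmap = simdata.simulate_genotypes(
        simdata.SimConfig(n_individuals=436, n_chromosomes=24,
                          n_markers_per_chrom=209, seed=SEED)
    )
    pheno, truth = simdata.simulate_trait(
        geno, simdata.TraitConfig(h2_target=0.70, n_qtl=500, seed=SEED + 10_000)
    )
    genotypes.write_vcf(geno, OUT / "genotypes.vcf")
    genotypes.write_dosage_tsv(geno, OUT / "genotypes.tsv")
    pheno.to_csv(OUT / "phenotypes.tsv", sep="\t", index=False)
    gmap.to_csv(OUT / "genome_map.tsv", sep="\t", index=False)
    truth.to_tsv(OUT / "true_effects.tsv")
    print(f"panel: n={geno.n_samples}, m={geno.n_markers}")
    print(f"tar: mean={pheno['tar'].mean():.1f} sd={pheno['tar'].std():.1f} "
          f"range=[{pheno['tar'].min():.1f}, {pheno['tar'].max():.1f}] mg/cig")
    print(f"realized h2 of the draw: {truth.realized_h2:.3f}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
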
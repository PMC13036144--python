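"""Configuration-driven end-to-end runs.

A pipeline config (YAML) names either real input files (genotypes,
phenotypes, genome map) or a simulation block, plus QC thresholds,
window parameters, the model list, and CV settings.  ``run_pipeline``
sequences QC -> GRM -> heritability -> GWAS -> RHM -> GS cross-
validation and writes every stage artifact plus a manifest (config
echo, seeds, package version, output checksums) into one directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, evaluate, genotypes, gwas, kinship, rhm, simdata, varcomp
from .gsmodels import GSConfig
from .phenotypes import join_samples, read_phenotypes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated run description; exactly one of inputs/simulation."""

    output_dir: str
    inputs: Optional[Dict] = None        # genotypes/format/phenotypes/genome_map
    simulation: Optional[Dict] = None    # sim: {...}, trait: {...}
    qc: Dict = field(default_factory=lambda: {
        "min_depth": 2.0, "min_maf": 0.03, "max_missing": 0.5,
    })
    windows: Dict = field(default_factory=lambda: {
        "width_bp": 2_000_000, "step_bp": 500_000, "min_markers": 10,
    })
    models: list = field(default_factory=lambda: ["rrBLUP", "GBLUP"])
    cv: Dict = field(default_factory=lambda: {"k": 5, "seed": 1})
    gs_config: Dict = field(default_factory=dict)
    run_gwas: bool = True
    run_rhm: bool = True

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError(
                "config must name exactly one of 'inputs' or 'simulation'"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    s = stage("load")
    if config.simulation is not None:
        sim_cfg = simdata.SimConfig(**config.simulation.get("sim", {}))
        trait_cfg = simdata.TraitConfig(**config.simulation.get("trait", {}))
        geno, genome_map = simdata.simulate_genotypes(sim_cfg)
        pheno, truth = simdata.simulate_trait(geno, trait_cfg)
        truth.to_tsv(out / "true_effects.tsv")
    else:
        geno = genotypes.read_genotypes(
            config.inputs["genotypes"], config.inputs.get("format", "vcf")
        )
        pheno = read_phenotypes(config.inputs["phenotypes"])
        genome_map = pd.read_csv(config.inputs["genome_map"], sep="\t")
        pheno = join_samples(pheno, geno.sample_ids)
        keep = [s_ for s_ in geno.sample_ids if s_ in set(pheno["sample_id"])]
        geno = geno.subset_samples(
            [geno.sample_ids.index(s_) for s_ in keep]
        )
    done(s)

    s = stage("qc")
    geno_qc, report = genotypes.apply_filters(geno, **config.qc)
    report.to_tsv(out / "qc_report.tsv")
    geno_qc = genotypes.impute_missing(geno_qc)
    pheno = pheno[pheno["sample_id"].isin(geno_qc.sample_ids)].reset_index(drop=True)
    y = pheno.set_index("sample_id").loc[geno_qc.sample_ids, "tar"].to_numpy()
    done(s)

    s = stage("grm")
    grm = kinship.compute_grm(geno_qc)
    kinship.write_grm_tsv(grm, out / "grm.tsv")
    done(s)

    s = stage("h2")
    fit = varcomp.fit_reml(varcomp.MixedModelSpec(y=y, grms=[grm]))
    null = varcomp.fit_null_reml(y)
    lrt, p = varcomp.lrt_genetic(fit, null)
    fit.to_tsv(out / "h2.tsv")
    with open(out / "h2.tsv", "a") as fh:
        fh.write(f"# lrt\t{lrt:.4f}\tp\t{p:.4g}\n")
    done(s)

    if config.run_gwas:
        s = stage("gwas")
        assoc = gwas.run_mlma(geno_qc, y, grm=grm)
        gwas.write_assoc_tsv(
            assoc, out / "gwas.tsv",
            gwas.bonferroni_threshold(geno_qc.n_markers),
        )
        done(s)

    if config.run_rhm:
        s = stage("rhm")
        windows = rhm.make_windows(genome_map, geno_qc.markers, **config.windows)
        scan = rhm.scan_regions(geno_qc, y, windows)
        scan.to_csv(out / "rhm_scan.tsv", sep="\t", index=False)
        summary = rhm.summarize_scan(scan)
        summary["ranked"].to_csv(out / "rhm_summary.tsv", sep="\t", index=False)
        done(s)

    s = stage("gs_cv")
    gs_cfg = GSConfig(**config.gs_config) if config.gs_config else GSConfig()
    cv = evaluate.kfold_cv(
        geno_qc, y, config.models,
        k=config.cv.get("k", 5), seed=config.cv.get("seed", 1), config=gs_cfg,
    )
    cv.to_tsv(out / "cv_report.tsv")
    done(s)

    manifest = {
        "package_version": __version__,
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {
            f.name: _sha256(f) for f in sorted(out.glob("*.tsv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
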
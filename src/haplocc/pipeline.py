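"""End-to-end analysis pipeline: QC -> descriptives -> single-SNP ->
min-P -> haplowalk -> blocks -> stratified, driven by a YAML config."""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DEFAULT_COVARIATES, snp_report
from .cohort import (GeneRegionMap, QcThresholds, apply_gene_map, qc_summary,
                     read_gene_map, read_ped_map, read_subject_table,
                     write_gene_map, write_ped_map, write_subject_table)
from .descriptives import assign_tertiles, descriptive_table
from .haplotypes import HAPLO_COVARIATES, ld_matrix
from .minp import gene_minp_report
from .simulate import default_study_config, simulate_cohort
from .windows import (block_analysis, haplowalk, stratified_blocks,
                      stratified_snp_rows, stratified_table, windows_table)
from .haplotypes import haplotype_report

log = logging.getLogger("haplocc")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    ped_path: str = ""
    map_path: str = ""
    subject_path: str = ""
    gene_map_path: str = ""
    out_dir: str = "results"
    seed: int = 0
    B: int = 9999
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    haplo_covariates: tuple[str, ...] = HAPLO_COVARIATES
    pool_threshold: float = 0.05
    haplowalk_width: int = 3
    haplowalk_fdr: float = 0.1
    permutation_strata: str = "center"
    blocks: dict[str, list[str]] = field(default_factory=dict)
    stratify_by: tuple[str, ...] = ("vegetable_tertile", "alcohol_tertile")
    stratified_snps: list[str] = field(default_factory=list)
    qc: QcThresholds = field(default_factory=QcThresholds)

    def __post_init__(self) -> None:
        for thr, nm in ((self.pool_threshold, "pool_threshold"),
                        (self.haplowalk_fdr, "haplowalk_fdr")):
            if not 0 < thr < 1:
                raise ConfigError(f"{nm} must be in (0,1), got {thr}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QcThresholds(**raw.pop("qc", {}))
        for key in ("covariates", "haplo_covariates", "stratify_by"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(qc=qc, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "qc"}
        d["qc"] = self.qc.__dict__
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def simulate_to_files(out_dir: str | Path, seed: int = 0) -> AnalysisConfig:
    """Simulate the default study-scale cohort and write its input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_study_config(seed=seed)
    gm, subjects, truth = simulate_cohort(cfg)
    write_ped_map(gm, subjects, out / "cohort.ped", out / "cohort.map")
    write_subject_table(subjects, out / "subjects.csv")
    write_gene_map(cfg.gene_map(), out / "genemap.tsv")
    truth.write(out / "truth.tsv")
    return AnalysisConfig(
        ped_path=str(out / "cohort.ped"), map_path=str(out / "cohort.map"),
        subject_path=str(out / "subjects.csv"),
        gene_map_path=str(out / "genemap.tsv"),
        out_dir=str(out), seed=seed,
        blocks={"SLC19A1_block":
                ["rs12483553", "rs2838950", "rs2838951", "rs17004785"]},
        stratified_snps=["rs12483553", "rs17004785"])


def _preflight(cfg: AnalysisConfig) -> GeneRegionMap:
    for p in (cfg.ped_path, cfg.map_path, cfg.subject_path, cfg.gene_map_path):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    gene_map = read_gene_map(cfg.gene_map_path)
    known = set(gene_map.all_rsids)
    for name, rsids in cfg.blocks.items():
        unknown = [r for r in rsids if r not in known]
        if unknown:
            raise ConfigError(f"block {name!r} names unknown rsid(s): {unknown}")
    for r in cfg.stratified_snps:
        if r not in known:
            raise ConfigError(f"stratified_snps names unknown rsid {r!r}")
    return gene_map


#: Pipeline stages in execution order with their prerequisites.
STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "load": (),
    "qc": ("load",),
    "descriptives": ("load",),
    "snp_association": ("load",),
    "min_p": ("load", "snp_association"),
    "haplowalk": ("load",),
    "blocks": ("load",),
    "stratified": ("load", "descriptives"),
}


def _resolve_stages(requested) -> list[str]:
    if requested is None:
        return list(STAGE_DEPS)
    unknown = set(requested) - set(STAGE_DEPS)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    selected: set[str] = set()

    def add(s: str) -> None:
        for d in STAGE_DEPS[s]:
            add(d)
        selected.add(s)

    for s in requested:
        add(s)
    return [s for s in STAGE_DEPS if s in selected]


def run_pipeline(cfg: AnalysisConfig, stages=None) -> dict:
    """Execute the selected stages (all by default) in order.

    Prerequisite stages are pulled in automatically.  Any stage failure
    halts with a stage-named :class:`StageError`; reports written by
    earlier stages are preserved.  Returns the run manifest.
    """
    selected = _resolve_stages(stages)
    gene_map = _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "B": cfg.B,
                      "version": __version__,
                      "parameters": {
                          "pool_threshold": cfg.pool_threshold,
                          "haplowalk_width": cfg.haplowalk_width,
                          "haplowalk_fdr": cfg.haplowalk_fdr,
                          "covariates": list(cfg.covariates),
                          "haplo_covariates": list(cfg.haplo_covariates)},
                      "stages": {}, "warnings": []}

    def stage(name):
        def deco(fn):
            if name not in selected:
                return None
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    result = fn()
                for w in caught:
                    manifest["warnings"].append(f"{name}: {w.message}")
            except Exception as exc:          # noqa: BLE001 - stage-tagged
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s done (%.1fs)", name,
                     time.perf_counter() - t0)
            return result
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        gm, ped_subjects = read_ped_map(cfg.ped_path, cfg.map_path)
        gm = apply_gene_map(gm, gene_map)
        subjects = read_subject_table(cfg.subject_path)
        state.update(gm=gm, subjects=subjects)

    @stage("qc")
    def _qc():
        rep = qc_summary(state["gm"], state["subjects"], thresholds=cfg.qc)
        rep.write(out / "qc.tsv")

    @stage("descriptives")
    def _desc():
        subjects = assign_tertiles(state["subjects"])
        state["subjects"] = subjects
        t = descriptive_table(subjects)
        t.to_csv(out / "descriptives.tsv", sep="\t", index=False,
                 float_format="%.4g")

    @stage("snp_association")
    def _assoc():
        t = snp_report(state["gm"], state["subjects"], cfg.covariates)
        t.to_csv(out / "snp_association.tsv", sep="\t", index=False,
                 float_format="%.4g")
        state["snp_table"] = t

    @stage("min_p")
    def _minp():
        t = gene_minp_report(state["gm"], state["subjects"], gene_map,
                             state["snp_table"], cfg.covariates, B=cfg.B,
                             seed=cfg.seed,
                             permutation_strata=cfg.permutation_strata)
        t.to_csv(out / "gene_minp.tsv", sep="\t", index=False,
                 float_format="%.4g")

    @stage("haplowalk")
    def _walk():
        res = haplowalk(state["gm"], state["subjects"], gene_map,
                        width=cfg.haplowalk_width,
                        covariates=cfg.haplo_covariates,
                        pool_threshold=cfg.pool_threshold,
                        fdr_threshold=cfg.haplowalk_fdr)
        windows_table(res).to_csv(out / "haplowalk.tsv", sep="\t",
                                  index=False, float_format="%.4g")
        flagged_genes = sorted({w.gene for w in res if w.flagged})
        for gene in flagged_genes:
            rsids = gene_map.genes[gene]
            ld = ld_matrix(state["gm"], state["subjects"], rsids)
            ld.to_csv(out / f"ld_{gene}.tsv", sep="\t", float_format="%.4g")
        manifest["stages"].setdefault("haplowalk", {})
        state["flagged_genes"] = flagged_genes

    @stage("blocks")
    def _blocks():
        results = []
        for name, rsids in cfg.blocks.items():
            results.append(block_analysis(state["gm"], state["subjects"],
                                          rsids, cfg.haplo_covariates,
                                          cfg.pool_threshold))
        if results:
            haplotype_report(results).to_csv(out / "blocks.tsv", sep="\t",
                                             index=False, float_format="%.4g")
        state["block_results"] = dict(zip(cfg.blocks, results))

    @stage("stratified")
    def _strat():
        for var in cfg.stratify_by:
            for name, rsids in cfg.blocks.items():
                res = stratified_blocks(state["gm"], state["subjects"], rsids,
                                        var, cfg.haplo_covariates,
                                        cfg.pool_threshold)
                t = stratified_table(res)
                if cfg.stratified_snps:
                    snp_t = stratified_snp_rows(state["gm"], state["subjects"],
                                                cfg.stratified_snps, var,
                                                cfg.covariates)
                    state[f"snp_strat_{var}"] = snp_t
                    snp_t.to_csv(out / f"stratified_snps_{var}.tsv", sep="\t",
                                 index=False, float_format="%.4g")
                t.to_csv(out / f"stratified_{name}_{var}.tsv", sep="\t",
                         index=False, float_format="%.4g")

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
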
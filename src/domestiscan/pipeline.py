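"""End-to-end orchestration: simulate (or load) -> filter -> scan -> tree ->
enrichment -> candidate SNPs, with a machine-readable JSON report.

A single RunConfig (YAML-loadable) governs all stages; the resolved
configuration is written beside the outputs so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import candidates as cand_mod
from . import expression as expr_mod
from . import qpcr as qpcr_mod
from . import simdata, structure, variantio
from .scan import TOP_FRACTION, WINDOW_SIZE, WINDOW_STEP, run_scan
from .variantio import INBRED, WILD

log = logging.getLogger("domestiscan")


@dataclass
class RunConfig:
    """Either a simulation config or input paths, plus scan parameters."""

    sim: simdata.SimConfig | None = None
    vcf: str | None = None
    groups: str | None = None
    genes_bed: str | None = None
    chrom_lengths: dict[str, int] | None = None
    window_size: int = WINDOW_SIZE
    window_step: int = WINDOW_STEP
    top_fraction: float = TOP_FRACTION
    max_missing: float = 0.1
    candidate_factor: float = 0.2
    seed: int = simdata.FIXTURE_SEED
    out_dir: str = "domestiscan_out"

    def __post_init__(self) -> None:
        has_paths = self.vcf is not None
        if has_paths == (self.sim is not None):
            raise ValueError("supply exactly one of: simulation config, input paths")
        if has_paths:
            for p in (self.vcf, self.groups, self.genes_bed):
                if p is None or not os.path.exists(p):
                    raise FileNotFoundError(f"missing input file: {p}")
            if not self.chrom_lengths:
                raise ValueError("chrom_lengths required with file inputs")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "sweep_specs" in sim_raw:
                sim_raw["sweep_specs"] = [tuple(s) for s in sim_raw["sweep_specs"]]
            raw["sim"] = simdata.SimConfig(**sim_raw)
        return cls(**raw)


def _resolved_config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; write stage outputs + report.json; return report."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    with open(os.path.join(cfg.out_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(_resolved_config_dict(cfg), fh, sort_keys=False)
    for name, value in _resolved_config_dict(cfg).items():
        log.info("parameter %s = %r", name, value)

    report: dict = {"stages": []}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("inputs")
        if cfg.sim is not None:
            bundle = simdata.generate_bundle(cfg.sim)
            simdata.write_fixture_bundle(bundle, os.path.join(cfg.out_dir, "fixture"))
            gm, sites = bundle["gm"], bundle["sites"]
            genes = bundle["genes"]
            chrom_lengths = cfg.sim.chrom_lengths()
            truth = bundle["truth"]
        else:
            group_map = {}
            with open(cfg.groups) as fh:
                header = fh.readline()
                for line in fh:
                    s, g = line.split()[:2]
                    group_map[s] = g
            gm, sites = variantio.read_vcf(cfg.vcf, group_map)
            genes = variantio.read_genes_bed(cfg.genes_bed)
            chrom_lengths = dict(cfg.chrom_lengths)
            bundle = None
            truth = None

        stage("filter")
        gm_f, sites_f = variantio.filter_sites(gm, sites, max_missing=cfg.max_missing)
        report["n_sites_raw"] = int(len(sites))
        report["n_sites_filtered"] = int(len(sites_f))
        _, class_tally = variantio.classify_sites(sites_f, genes)
        report["site_classes"] = class_tally

        stage("scan")
        res = run_scan(
            gm_f, sites_f, genes, chrom_lengths,
            size=cfg.window_size, step=cfg.window_step, fraction=cfg.top_fraction,
        )
        ws = res["window_stats"]
        ws.to_csv(os.path.join(cfg.out_dir, "window_stats.tsv"), sep="\t", index=False)
        with open(os.path.join(cfg.out_dir, "psgs.tsv"), "w") as fh:
            fh.write("gene\n" + "".join(g + "\n" for g in res["psgs"]))
        report["n_windows"] = int(len(ws))
        report["n_unmasked"] = int((~ws["masked"]).sum())
        report["top_set_sizes"] = {k: int(len(v)) for k, v in res["top_windows"].items()}
        report["venn"] = res["venn"]
        report["psgs"] = res["psgs"]

        if truth is not None:
            sweep = set(truth.sweep_genes)
            psg = set(res["psgs"])
            nonsweep = {g.gene_id for g in genes} - sweep
            report["sweep_recall"] = len(psg & sweep) / len(sweep) if sweep else math.nan
            report["nonsweep_in_psg_fraction"] = (
                len(psg & nonsweep) / len(nonsweep) if nonsweep else math.nan
            )

        stage("structure")
        dm = structure.pairwise_distance(gm_f)
        dm.to_csv(os.path.join(cfg.out_dir, "distances.tsv"), sep="\t")
        tree = structure.neighbor_joining(dm)
        with open(os.path.join(cfg.out_dir, "tree.nwk"), "w") as fh:
            fh.write(tree + "\n")
        inbred_samples = {s for s, g in gm_f.groups.items() if g == INBRED}
        report["inbred_monophyletic"] = structure.is_group_monophyletic(
            tree, inbred_samples, set(gm_f.samples)
        )

        if bundle is not None:
            stage("expression")
            merged = expr_mod.merge_categories(bundle["expression"])
            flags = expr_mod.flag_highly_expressed(merged)
            psg_in_expr = [g for g in res["psgs"] if g in flags.index]
            if psg_in_expr:
                ratios = expr_mod.category_ratio(flags, psg_in_expr)
                report["highly_expressed_pct"] = {
                    c: float(v) for c, v in ratios.items()
                }
            de_elev = expr_mod.de_ratio_elevation(bundle["de_tables"], res["psgs"])
            de_elev.to_csv(os.path.join(cfg.out_dir, "de_elevation.tsv"), sep="\t")
            report["de_elevation"] = {
                t: {k: (None if not np.isfinite(v) else float(v)) for k, v in row.items()}
                for t, row in de_elev.iterrows()
            }

            stage("candidates")
            target_gene = next(
                (g for g in genes if truth and g.gene_id in truth.sweep_genes), genes[0]
            )
            table, summary = cand_mod.scan_gene_candidates(
                gm_f, sites_f, target_gene, factor=cfg.candidate_factor
            )
            table.to_csv(os.path.join(cfg.out_dir, "candidates.tsv"), sep="\t", index=False)
            report["candidate_gene"] = target_gene.gene_id
            report["candidate_summary"] = summary

            stage("qpcr")
            folds = qpcr_mod.ddct_fold(bundle["ct"], "target", "Gapdh")
            report["qpcr_treatment_mean_fold"] = float(
                folds.loc[folds["group"] == "treatment", "fold"].mean()
            )
            iso = qpcr_mod.isoform_ratio(bundle["ct_isoform"])
            report["isoform_ratio_treatment_mean"] = float(
                iso.loc[iso["group"] == "treatment", "fold"].mean()
            )
    except Exception as err:  # pragma: no cover - abort path
        failed = report["stages"][-1] if report["stages"] else "init"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {err}") from err

    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
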
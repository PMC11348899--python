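"""End-to-end orchestration with a single YAML config and a manifest.

Every numeric default equals the published analysis value (hyper >= 10,
hypo <= -15, span < 1 Mb, >= 3 CpGs, FDR < 0.05 for DMCs and DEGs,
mean TPM >= 10, 2 kb promoter / 200 bp downstream windows, 50% overlap,
k = 3, 30-day follow-up floor).  Any override is recorded in the run
manifest alongside the seed, config hash, and input checksums; reruns
with the same config and seed reproduce outputs byte-identically.

Inputs come either from files (``inputs:`` section) or from the synthetic
generator (``simulate:`` section), making the packaged demo fully
self-contained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotate, dmr, integrate, io, simulate, stratify
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "hyper": 10.0,
    "hypo": -15.0,
    "max_span_bp": 1_000_000,
    "min_cpgs": 3,
    "dmc_fdr": 0.05,
    "deg_fdr": 0.05,
    "min_tpm": 10.0,
    "promoter_bp": 2000,
    "downstream_bp": 200,
    "overlap_fraction": 0.5,
    "k": 3,
    "min_followup_days": 30,
    "cbs_alpha": 0.01,
    "cbs_permutations": 1000,
}


@dataclass
class PipelineConfig:
    outdir: str = "methdriver_run"
    seed: int = 42
    inputs: dict = field(default_factory=dict)  # paths: matrix, sample_sheet, expression, survival, gtf
    simulate: dict | None = None  # SimConfig overrides + n_driver_genes/driver_delta
    panel: list[str] | None = None
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved_thresholds(self) -> dict:
        bad = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if bad:
            raise ConfigurationError(f"unknown thresholds: {sorted(bad)}")
        merged = {**DEFAULT_THRESHOLDS, **self.thresholds}
        return merged

    def non_default_thresholds(self) -> dict:
        return {
            k: v for k, v in self.thresholds.items()
            if v != DEFAULT_THRESHOLDS.get(k)
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_inputs(config: PipelineConfig, outdir: Path):
    opts = dict(config.simulate or {})
    n_drivers = int(opts.pop("n_driver_genes", 5))
    driver_delta = float(opts.pop("driver_delta", 30.0))
    sim = simulate.SimConfig(seed=config.seed, **opts)
    genome = simulate.generate_genome(sim)
    driver_ids = simulate.choose_spread_genes(genome, n_drivers)
    planted = simulate.plant_promoter_dmrs(genome, driver_ids, driver_delta)
    sim = dataclasses.replace(
        sim,
        planted_dmrs=tuple(planted),
        driver_genes={g: -1 for g in driver_ids},
    )
    matrix, sheet = simulate.generate_methylome(sim, genome)
    tpm = simulate.generate_expression(sim, genome, matrix)

    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    io.write_gtf(genome, indir / "genes.gtf")
    io.write_gene_bed12(genome, indir / "genes.bed12")
    io.write_element_bed(genome, indir / "elements.bed")
    io.write_meth_matrix(matrix, indir / "meth_matrix.tsv")
    io.write_sample_sheet(sheet, indir / "samples.tsv")
    io.write_expression(tpm, indir / "expression.tsv")

    # survival for tumor samples from panel-score terciles is circular; the
    # demo instead assigns subgroups from driver expression terciles
    tumor_ids = sheet.loc[sheet["group"] == "tumor", "sample_id"]
    score = stratify.panel_score(tpm, driver_ids, log2_transform=True)[tumor_ids]
    terciles = pd.qcut(score.rank(method="first"), 3, labels=["C3", "C2", "C1"])
    assignment = pd.Series(terciles.astype(str).to_numpy(), index=tumor_ids)
    survival = simulate.generate_survival(sim, assignment)
    io.write_survival(survival, indir / "survival.tsv")
    panel = config.panel or driver_ids
    return genome, matrix, sheet, tpm, survival, panel


def _load_inputs(config: PipelineConfig):
    req = ["matrix", "sample_sheet", "gtf"]
    missing = [k for k in req if k not in config.inputs]
    if missing:
        raise ConfigurationError(f"missing input paths: {missing}")
    genes = io.read_gene_models(config.inputs["gtf"])
    genome = None
    matrix = io.read_meth_matrix(config.inputs["matrix"])
    sheet = io.read_sample_sheet(config.inputs["sample_sheet"])
    tpm = (
        io.read_expression(config.inputs["expression"])
        if "expression" in config.inputs else None
    )
    survival = (
        io.read_survival(config.inputs["survival"])
        if "survival" in config.inputs else None
    )
    return genes, genome, matrix, sheet, tpm, survival


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in dependency order; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.resolved_thresholds()

    if config.simulate is not None:
        genome, matrix, sheet, tpm, survival, panel = _simulate_inputs(config, outdir)
        genes = genome.genes
    else:
        genes, genome, matrix, sheet, tpm, survival = _load_inputs(config)
        panel = config.panel

    # ---- DMR calling
    delta = dmr.build_delta_track(matrix, sheet)
    dmc = dmr.dmc_test(matrix, sheet, fdr_threshold=thr["dmc_fdr"])
    segs = dmr.cbs_segment(
        delta, alpha=thr["cbs_alpha"], n_permutations=thr["cbs_permutations"],
        seed=config.seed,
    )
    dmrs = dmr.classify_dmrs(
        dmr.enforce_dmr_constraints(
            segs, delta, max_span_bp=thr["max_span_bp"], min_cpgs=thr["min_cpgs"]
        ),
        hyper_threshold=thr["hyper"], hypo_threshold=thr["hypo"],
    )
    io.write_dmr_bed(dmrs, outdir / "dmrs.bed")
    dmc.to_csv(outdir / "dmc.tsv", sep="\t")

    # ---- annotation + association
    annotated = annotate.annotate_dmr_location(
        dmrs, genes, promoter_bp=thr["promoter_bp"],
        downstream_bp=thr["downstream_bp"],
    )
    annotated.to_csv(outdir / "dmrs_annotated.tsv", sep="\t", index=False)
    props = annotate.location_proportions(annotated)
    props.to_csv(outdir / "dmr_location_proportions.tsv", sep="\t", index=False)
    assoc = annotate.associate_dmr_gene(
        dmrs, genes, overlap_fraction=thr["overlap_fraction"],
        promoter_bp=thr["promoter_bp"], downstream_bp=thr["downstream_bp"],
    )
    assoc.to_csv(outdir / "dmr_gene_associations.tsv", sep="\t", index=False)
    if genome is not None:
        regions = annotate.build_region_set(genome)
        annotate.region_methylation_summary(matrix, regions, sheet).to_csv(
            outdir / "region_methylation.tsv", sep="\t", index=False
        )

    # ---- expression integration
    methy_deg = None
    if tpm is not None:
        deg = integrate.deg_test(
            tpm, sheet, min_mean_tpm=thr["min_tpm"], fdr_threshold=thr["deg_fdr"]
        )
        deg.to_csv(outdir / "deg.tsv", sep="\t", index_label="gene_id")
        methy_deg = integrate.classify_methy_deg(deg, assoc, dmrs)
        methy_deg.to_csv(outdir / "methy_deg.tsv", sep="\t", index=False)

    # ---- stratification / survival / ROC
    if tpm is not None and panel:
        tumor_ids = sheet.loc[sheet["group"] == "tumor", "sample_id"].tolist()
        scores = stratify.panel_score(tpm[tumor_ids], panel, log2_transform=True)
        subgroups = stratify.cluster_subgroups(
            tpm[tumor_ids], panel, k=thr["k"], seed=config.seed
        )
        pd.DataFrame({"subgroup": subgroups, "panel_score": scores}).to_csv(
            outdir / "subgroups.tsv", sep="\t", index_label="sample"
        )
        if survival is not None:
            report = stratify.subgroup_report(subgroups, scores, survival)
            km_rows = []
            for grp, info in (report["km"] or {}).items():
                curve = info["curve"].assign(group=grp, median=info["median"])
                km_rows.append(curve)
            if km_rows:
                pd.concat(km_rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
            lr = report["logrank"] or {}
            summary = {
                "score_kruskal_p": report["score_kruskal_p"],
                "logrank": lr,
            }
            (outdir / "survival_summary.json").write_text(
                json.dumps(summary, indent=2, default=float)
            )

    # ROC for the strongest hyper and hypo DMRs
    roc_rows = []
    for cls in ("hyper", "hypo"):
        grp = dmrs[dmrs["dmr_class"] == cls]
        if grp.empty:
            continue
        top = grp.loc[grp["delta"].abs().idxmax()]
        res = stratify.dmr_roc(matrix, top, sheet)
        roc_rows.append({"dmr_class": cls, "chrom": top["chrom"],
                         "start": top["start"], "end": top["end"], **res})
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(outdir / "dmr_roc.tsv", sep="\t", index=False)

    # ---- manifest
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "non_default_thresholds": config.non_default_thresholds(),
        "input_checksums": {
            k: _sha256(Path(v)) for k, v in config.inputs.items()
            if Path(str(v)).is_file()
        },
        "output_checksums": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*")) if p.is_file()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
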
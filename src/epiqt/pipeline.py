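"""End-to-end orchestration: qc -> scan -> partition -> map-genes.

One YAML (or dict) config drives the whole run.  Stages execute sequentially
in-process; every stage records its parameters, outputs and counts in a
:class:`RunManifest` written as ``manifest.json``, which together with the
config and seed is sufficient to re-run the analysis identically.  A stage
failure still writes the manifest with the stages completed so far.

Config schema (YAML)::

    seed: 1
    out_dir: out
    simulate:                  # either this ...
      n_subjects: 860
      n_snps: 100
      covariate_r2: 0.093
      planted_pairs: [[0, 1, 0.056]]
    inputs:                    # ... or this
      bed: geno.bed
      bim: geno.bim
      fam: geno.fam
      cohort: cohort.tsv
    qc:
      maf: 0.05
      snp_call_rate: 0.95
      subject_call_rate: 0.90
      hwe_p: 1.0e-6
      ptau_transform: log
      exclude_subjects: null   # optional path, one subject id per line
    scan:
      p_threshold: bonferroni  # or a number in (0, 1]
      block_size: 512
    partition:
      top_n: 10
    map_genes:                 # optional stage
      genes_bed: genes.bed
      ad_genes: ad.txt         # optional
      ppi_edges: edges.tsv     # optional
      window_bp: 100000
      mode: nearest
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gene_mapping, io_formats, quality_control, synthetic_data
from .epistasis_scan import ScanConfig, bonferroni_threshold, build_design, scan_all_pairs
from .quality_control import PHENOTYPE_TRANSFORMS, QcThresholds
from .variance_partition import partition_top_pairs

log = logging.getLogger("epiqt")

try:
    __version__ = _pkg_version("epiqt")
except PackageNotFoundError:  # pragma: no cover - not installed
    __version__ = "unknown"


class PipelineConfigError(ValueError):
    """The run config violates the schema or references missing inputs."""


@dataclass
class StageRecord:
    name: str
    params: dict
    outputs: dict
    counts: dict


@dataclass
class RunManifest:
    seed: int
    software_version: str
    config: dict
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema and input-existence checks; raises before any compute."""
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise PipelineConfigError("config needs exactly one of 'simulate' or 'inputs'")
    if "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("bed", "bim", "fam", "cohort"):
            if key not in inp:
                raise PipelineConfigError(f"inputs.{key} is required")
            if not Path(inp[key]).exists():
                raise PipelineConfigError(f"inputs.{key}: no such file {inp[key]!r}")
    qc = cfg.get("qc", {})
    transform = qc.get("ptau_transform", "log").replace("_", "-")
    if transform not in PHENOTYPE_TRANSFORMS:
        raise PipelineConfigError(f"qc.ptau_transform {transform!r} not in {PHENOTYPE_TRANSFORMS}")
    excl = qc.get("exclude_subjects")
    if excl and not Path(excl).exists():
        raise PipelineConfigError(f"qc.exclude_subjects: no such file {excl!r}")
    scan = cfg.get("scan", {})
    thr = scan.get("p_threshold", "bonferroni")
    if thr != "bonferroni" and not (isinstance(thr, (int, float)) and 0 < thr <= 1):
        raise PipelineConfigError("scan.p_threshold must be 'bonferroni' or in (0, 1]")
    mg = cfg.get("map_genes")
    if mg is not None:
        if "genes_bed" not in mg:
            raise PipelineConfigError("map_genes.genes_bed is required when the stage is enabled")
        for key in ("genes_bed", "ad_genes", "ppi_edges"):
            p = mg.get(key)
            if p and not Path(p).exists():
                raise PipelineConfigError(f"map_genes.{key}: no such file {p!r}")
        if mg.get("mode", "nearest") not in gene_mapping.MAP_MODES:
            raise PipelineConfigError(f"map_genes.mode must be one of {gene_mapping.MAP_MODES}")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Run all configured stages; returns the manifest (also written to disk)."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    validate_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "epiqt_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(seed=seed, software_version=__version__, config=_json_safe(cfg))
    manifest_path = out / "manifest.json"

    try:
        _run_stages(cfg, out, seed, manifest)
    finally:
        manifest.to_json(manifest_path)
    return manifest


def _run_stages(cfg: dict, out: Path, seed: int, manifest: RunManifest) -> None:
    # ---- input stage: simulate or read -----------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", seed)
        sim_kwargs["planted_pairs"] = [tuple(p) for p in sim_kwargs.get("planted_pairs", [])]
        sim_kwargs["planted_mains"] = [tuple(p) for p in sim_kwargs.get("planted_mains", [])]
        for key in ("maf_range", "age_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_cfg = synthetic_data.SimulationConfig(**sim_kwargs)
        gm, cohort, truth = synthetic_data.simulate_dataset(sim_cfg)
        paths = io_formats.write_plink(gm, out / "sim")
        cohort_path = io_formats.write_cohort(cohort, out / "sim_cohort.tsv")
        truth_path = out / "sim_truth.json"
        truth_small = {k: v for k, v in truth.items() if k != "latent"}
        truth_path.write_text(json.dumps(_json_safe(truth_small), indent=2))
        manifest.stages.append(
            StageRecord(
                "simulate",
                _json_safe(sim_kwargs),
                {**{k: str(v) for k, v in paths.items()}, "cohort": str(cohort_path),
                 "truth": str(truth_path)},
                {"n_subjects": gm.n_subjects, "m_snps": gm.m_snps},
            )
        )
        log.info("simulate: %d subjects x %d SNPs", gm.n_subjects, gm.m_snps)
    else:
        inp = cfg["inputs"]
        gm = io_formats.read_plink(inp["bed"], inp["bim"], inp["fam"])
        cohort = io_formats.read_cohort(inp["cohort"])
        manifest.stages.append(
            StageRecord(
                "read_inputs",
                {k: str(v) for k, v in inp.items()},
                {},
                {"n_subjects": gm.n_subjects, "m_snps": gm.m_snps,
                 "cohort_rows": cohort.n_subjects},
            )
        )
        log.info("inputs: %d subjects x %d SNPs", gm.n_subjects, gm.m_snps)

    # ---- qc ---------------------------------------------------------------
    qc_cfg = cfg.get("qc", {})
    th = QcThresholds(
        snp_call_rate=float(qc_cfg.get("snp_call_rate", 0.95)),
        subject_call_rate=float(qc_cfg.get("subject_call_rate", 0.90)),
        maf=float(qc_cfg.get("maf", 0.05)),
        hwe_p=float(qc_cfg.get("hwe_p", 1e-6)),
    )
    exclude = None
    if qc_cfg.get("exclude_subjects"):
        exclude = io_formats.read_gene_list(qc_cfg["exclude_subjects"])  # one id per line
    quality_control.check_baseline_uniqueness(cohort)
    gm, cohort, subj_report = quality_control.apply_subject_qc(gm, cohort, th, exclude)
    gm, var_report = quality_control.apply_variant_qc(gm, th)
    transform = qc_cfg.get("ptau_transform", "log").replace("_", "-")
    y = quality_control.normalize_phenotype(cohort.data["ptau"].to_numpy(), transform)

    qc_paths = io_formats.write_plink(gm, out / "qc")
    qc_cohort_path = io_formats.write_cohort(cohort, out / "qc_cohort.tsv")
    report_path = out / "qc_report.tsv"
    report_df = pd.concat(
        [
            subj_report.to_frame().assign(axis="subjects"),
            var_report.to_frame().assign(axis="snps"),
        ],
        ignore_index=True,
    )
    report_df.to_csv(report_path, sep="\t", index=False)
    manifest.stages.append(
        StageRecord(
            "qc",
            {**asdict(th), "ptau_transform": transform,
             "n_excluded_list": len(exclude) if exclude else 0},
            {**{k: str(v) for k, v in qc_paths.items()},
             "cohort": str(qc_cohort_path), "report": str(report_path)},
            {"n_subjects": gm.n_subjects, "m_snps": gm.m_snps},
        )
    )
    log.info("qc: %d subjects, %d SNPs retained", gm.n_subjects, gm.m_snps)

    # ---- scan -------------------------------------------------------------
    scan_cfg_raw = cfg.get("scan", {})
    thr = scan_cfg_raw.get("p_threshold", "bonferroni")
    p_threshold = None if thr == "bonferroni" else float(thr)
    scan_cfg = ScanConfig(
        p_threshold=p_threshold,
        block_size=int(scan_cfg_raw.get("block_size", 512)),
        seed=seed,
    )
    C, cov_labels = build_design(cohort)
    results = scan_all_pairs(gm, y, C, scan_cfg)
    pairs_path = io_formats.write_pair_results(results, out / "pairs.tsv")
    n_tests = gm.m_snps * (gm.m_snps - 1) // 2
    effective_thr = (
        p_threshold if p_threshold is not None else bonferroni_threshold(gm.m_snps)
    )
    meta = {
        "n_subjects": gm.n_subjects,
        "m_snps": gm.m_snps,
        "n_tests": n_tests,
        "p_threshold": effective_thr,
        "threshold_rule": "bonferroni" if p_threshold is None else "fixed",
        "covariate_columns": cov_labels,
        "phenotype_transform": transform,
        "genotype_coding": "additive count of bim allele1 (A1)",
        "n_significant": len(results),
    }
    meta_path = out / "scan_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    manifest.stages.append(
        StageRecord(
            "scan",
            {"p_threshold": effective_thr, "block_size": scan_cfg.block_size},
            {"pairs": str(pairs_path), "meta": str(meta_path)},
            {"n_tests": n_tests, "n_significant": len(results)},
        )
    )
    log.info("scan: %d/%d pairs significant at %.3g", len(results), n_tests, effective_thr)

    # ---- partition --------------------------------------------------------
    top_n = int(cfg.get("partition", {}).get("top_n", 10))
    part_df = partition_top_pairs(results, gm, y, C, top_n=top_n)
    part_path = out / "partition.tsv"
    part_df.to_csv(part_path, sep="\t", index=False, float_format="%.12g")
    manifest.stages.append(
        StageRecord(
            "partition",
            {"top_n": top_n, "r2_type": "unadjusted"},
            {"partition": str(part_path)},
            {"n_pairs": len(part_df)},
        )
    )

    # ---- map-genes (optional) --------------------------------------------
    mg = cfg.get("map_genes")
    if mg is None:
        return
    annotation = io_formats.read_gene_bed(mg["genes_bed"])
    snp_lookup = {s.snp_id: s for s in gm.snps}
    snp_pairs = [(r.snp1_id, r.snp2_id) for r in results]
    mapping = gene_mapping.pairs_to_gene_pairs(
        snp_pairs,
        snp_lookup,
        annotation,
        window_bp=int(mg.get("window_bp", gene_mapping.DEFAULT_WINDOW_BP)),
        mode=mg.get("mode", "nearest"),
    )
    summary: dict = {
        "n_gene_pairs": len(mapping.gene_pairs),
        "n_intragenic_snp_pairs": len(mapping.intragenic),
        "n_unmapped_snps": len(mapping.unmapped_snps),
    }
    if mg.get("ad_genes"):
        ad = set(io_formats.read_gene_list(mg["ad_genes"]))
        summary["categories"] = gene_mapping.categorize_pairs(mapping.gene_pairs, ad)
    if mg.get("ppi_edges"):
        edges = io_formats.read_ppi_edges(mg["ppi_edges"])
        summary["ppi_overlap_count"] = gene_mapping.overlap_with_ppi(
            mapping.gene_pairs, edges
        )
    pairs_rows = [
        {
            "gene1": r.gene1,
            "gene2": r.gene2,
            "category": r.category.value if r.category else "",
            "ppi_overlap": "" if r.ppi_overlap is None else str(r.ppi_overlap).lower(),
            "n_supporting_snp_pairs": len(r.supporting_snp_pairs),
            "supporting_snp_pairs": ";".join(
                f"{a}|{b}" for a, b in r.supporting_snp_pairs
            ),
        }
        for r in mapping.gene_pairs
    ]
    gp_path = out / "gene_pairs.tsv"
    pd.DataFrame(
        pairs_rows,
        columns=["gene1", "gene2", "category", "ppi_overlap",
                 "n_supporting_snp_pairs", "supporting_snp_pairs"],
    ).to_csv(gp_path, sep="\t", index=False)
    summary_path = out / "gene_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    manifest.stages.append(
        StageRecord(
            "map_genes",
            {"window_bp": int(mg.get("window_bp", gene_mapping.DEFAULT_WINDOW_BP)),
             "mode": mg.get("mode", "nearest")},
            {"gene_pairs": str(gp_path), "summary": str(summary_path)},
            summary if "categories" not in summary else {**summary, "categories": dict(summary["categories"])},
        )
    )
    log.info("map-genes: %d gene pairs", len(mapping.gene_pairs))
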
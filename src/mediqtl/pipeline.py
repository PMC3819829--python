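"""File-based pipeline orchestration: QC -> normalize -> mediation scan ->
FDR summary -> eQTL scan -> hotspots -> overlap -> plot.

Stages communicate only through tab-delimited files under one output
directory, so any stage can be re-run in isolation, and re-running with the
same configuration and seed reproduces the result tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import fdr as fdr_mod
from . import hotspots as hs
from . import io as io_mod
from . import normalize as norm_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from .config import RunConfig
from .mediation import scan_trios

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "normalize", "mediate", "eqtl", "hotspots",
          "overlap", "plot")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineManifest:
    stages: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0
    started: str = ""
    finished: str = ""

    def record(self, name: str, outputs: list[Path]) -> None:
        for p in outputs:
            if not Path(p).exists():
                raise PipelineError(name, FileNotFoundError(p))
        self.stages.append({"stage": name, "outputs": [str(p) for p in outputs]})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def load_pipeline_config(path: str | Path) -> dict:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValueError(f"pipeline config {path} must be a key-value mapping")
    return d


def _paths(outdir: Path, cfg: dict) -> dict[str, Path]:
    def inp(key: str, default: str) -> Path:
        return Path(cfg.get(key, outdir / default))

    return {
        "genotype": inp("genotype", "genotypes.tsv"),
        "expression": inp("expression", "expression.tsv"),
        "phenotype": inp("phenotype", "phenotype.tsv"),
        "snp_annotation": inp("snp_annotation", "snp_annotation.tsv"),
        "probe_annotation": inp("probe_annotation", "probe_annotation.tsv"),
        "genotype_qc": outdir / "genotypes_qc.tsv",
        "qc_report": outdir / "qc_report.tsv",
        "expression_norm": outdir / "expression_norm.tsv",
        "phenotype_norm": outdir / "phenotype_norm.tsv",
        "trios": outdir / "trios.tsv",
        "summary": outdir / "scan_summary.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "hotspots": outdir / "hotspots.tsv",
        "overlap": outdir / "overlap.tsv",
        "plot": outdir / "eqtl_map.png",
    }


def _require(paths: dict[str, Path], *keys: str) -> None:
    for k in keys:
        if not paths[k].exists():
            raise FileNotFoundError(f"required input {paths[k]} does not exist")


def _load_inputs(paths: dict[str, Path], qc_done: bool):
    gpath = paths["genotype_qc"] if qc_done and paths["genotype_qc"].exists() \
        else paths["genotype"]
    fmt = "vcf" if str(gpath).endswith((".vcf", ".vcf.gz")) else "tsv"
    g = io_mod.read_genotype_matrix(gpath, fmt=fmt)
    if paths["snp_annotation"].exists():
        g = io_mod.attach_snp_annotation(g, io_mod.read_annotation_map(paths["snp_annotation"]))
    e = io_mod.read_expression_matrix(paths["expression"])
    if paths["probe_annotation"].exists():
        e = io_mod.attach_probe_annotation(e, io_mod.read_annotation_map(paths["probe_annotation"]))
    p = io_mod.read_phenotype_table(paths["phenotype"])
    return io_mod.align_samples(g, e, p)


def run_pipeline(config: dict | str | Path, stages: tuple[str, ...] = STAGES
                 ) -> PipelineManifest:
    """Execute the requested pipeline stages in order and write a manifest.

    ``config`` is a flat mapping: input paths (``genotype``, ``expression``,
    ``phenotype``, optional annotation maps), ``outdir``, any ``RunConfig``
    threshold, and an optional ``simulate`` sub-mapping of
    ``SimulationSpec`` fields.
    """
    if not isinstance(config, dict):
        config = load_pipeline_config(config)
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    rc = RunConfig.from_dict(config)
    paths = _paths(outdir, config)
    manifest = PipelineManifest(config={**config, **rc.to_dict()}, seed=rc.seed,
                                started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    log.info("run config: %s", rc)

    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            _run_stage(stage, config, rc, paths, manifest)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise PipelineError(stage, exc) from exc
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest


def _run_stage(stage: str, config: dict, rc: RunConfig, paths: dict[str, Path],
               manifest: PipelineManifest) -> None:
    if stage == "simulate":
        if "simulate" not in config:
            return
        spec_dict = dict(config["simulate"])
        spec_dict.setdefault("seed", rc.seed)
        known = {f.name for f in dataclasses.fields(sim_mod.SimulationSpec)}
        spec = sim_mod.SimulationSpec(**{k: v for k, v in spec_dict.items() if k in known})
        for key in ("planted_trios", "hotspot_spec", "direct_effects"):
            setattr(spec, key, [tuple(t) for t in getattr(spec, key)])
        outdir = paths["genotype"].parent
        sim_mod.simulate_dataset(spec, outdir=outdir)
        manifest.record(stage, [paths["genotype"], paths["expression"],
                                paths["phenotype"], paths["snp_annotation"],
                                paths["probe_annotation"]])
        return

    if stage == "qc":
        _require(paths, "genotype")
        fmt = "vcf" if str(paths["genotype"]).endswith((".vcf", ".vcf.gz")) else "tsv"
        g = io_mod.read_genotype_matrix(paths["genotype"], fmt=fmt)
        g = qc_mod.sample_call_rate_filter(g, rc.sample_call_rate_min)
        g, reports = qc_mod.snp_filter(
            g, call_rate_min=rc.snp_call_rate_min, hwe_alpha=rc.hwe_alpha,
            maf_min=rc.maf_min, hwe_method=rc.hwe_method,
        )
        sim_mod.write_genotype_tsv(g, paths["genotype_qc"])
        qc_mod.write_qc_report(reports, paths["qc_report"])
        manifest.record(stage, [paths["genotype_qc"], paths["qc_report"]])
        return

    if stage == "normalize":
        _require(paths, "expression", "phenotype")
        g, e, p = _load_inputs(paths, qc_done=True)
        e_norm = norm_mod.preprocess_expression(e, p, offset=rc.int_offset)
        y = norm_mod.preprocess_phenotype(p, offset=rc.int_offset)
        sim_mod.write_expression_tsv(e_norm, paths["expression_norm"])
        keep = {s: i for i, s in enumerate(p.sample_ids)}
        idx = [keep[s] for s in y.sample_ids]
        io_tbl = io_mod.PhenotypeTable(
            sample_ids=y.sample_ids, trait=y.values,
            age=p.age[idx], sex=p.sex[idx],
        )
        sim_mod.write_phenotype_tsv(io_tbl, paths["phenotype_norm"])
        manifest.record(stage, [paths["expression_norm"], paths["phenotype_norm"]])
        return

    if stage in ("mediate", "eqtl"):
        for key in ("expression_norm", "phenotype_norm"):
            if not paths[key].exists():
                raise FileNotFoundError(
                    f"required input {paths[key]} does not exist (run 'normalize' first)")
        g = io_mod.read_genotype_matrix(
            paths["genotype_qc"] if paths["genotype_qc"].exists() else paths["genotype"])
        e = io_mod.read_expression_matrix(paths["expression_norm"])
        p = io_mod.read_phenotype_table(paths["phenotype_norm"])
        g, e, p = io_mod.align_samples(g, e, p)
        if stage == "mediate":
            results = list(scan_trios(g, e, p.trait, rc))
            io_mod.write_trio_results(results, paths["trios"])
            n_tests = g.n_snps * e.n_probes
            summary = fdr_mod.summarize_scan(results, rc.trio_p_cutoff, n_tests)
            fdr_mod.write_scan_summary(summary, paths["summary"])
            manifest.record(stage, [paths["trios"], paths["summary"]])
        else:
            records = list(hs.eqtl_scan(g, e, p_cutoff=rc.eqtl_p_cutoff))
            if paths["snp_annotation"].exists() and paths["probe_annotation"].exists():
                records = hs.annotate_cis_trans(
                    records,
                    io_mod.read_annotation_map(paths["snp_annotation"]),
                    io_mod.read_annotation_map(paths["probe_annotation"]),
                    window=rc.cis_window,
                )
            hs.write_eqtl_records(records, paths["eqtl"])
            manifest.record(stage, [paths["eqtl"]])
        return

    if stage == "hotspots":
        _require(paths, "eqtl")
        records = hs.read_eqtl_records(paths["eqtl"])
        g = io_mod.read_genotype_matrix(
            paths["genotype_qc"] if paths["genotype_qc"].exists() else paths["genotype"])
        e_path = paths["expression_norm"] if paths["expression_norm"].exists() \
            else paths["expression"]
        e = io_mod.read_expression_matrix(e_path)
        found = hs.detect_hotspots(
            records,
            min_probes=rc.hotspot_min_probes,
            n_probes_total=e.n_probes,
            p0=rc.hotspot_p0 or rc.eqtl_p_cutoff,
            n_snps_tested=g.n_snps,
        )
        ann = io_mod.read_annotation_map(paths["snp_annotation"]) \
            if paths["snp_annotation"].exists() else None
        hs.write_hotspots(found, paths["hotspots"], snp_ann=ann)
        manifest.record(stage, [paths["hotspots"]])
        return

    if stage == "overlap":
        _require(paths, "hotspots", "trios")
        found = hs.read_hotspots(paths["hotspots"])
        trios = [t for t in io_mod.read_trio_results(paths["trios"])
                 if t.sobel.p_analytic < rc.trio_p_cutoff]
        result = hs.overlap_hotspots_with_mediation(found, trios)
        hs.write_overlap(result, paths["overlap"])
        manifest.record(stage, [paths["overlap"]])
        return

    if stage == "plot":
        _require(paths, "eqtl", "snp_annotation", "probe_annotation")
        from .plotting import plot_eqtl_map

        records = hs.read_eqtl_records(paths["eqtl"])
        found = hs.read_hotspots(paths["hotspots"]) if paths["hotspots"].exists() else []
        plot_eqtl_map(
            records, found,
            io_mod.read_annotation_map(paths["snp_annotation"]),
            io_mod.read_annotation_map(paths["probe_annotation"]),
            paths["plot"],
        )
        manifest.record(stage, [paths["plot"]])
        return
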
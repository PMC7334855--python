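"""End-to-end orchestration: transfer → aggregate → specificity → enrichment →
concordance, from a single YAML configuration, with a provenance manifest.

Stages communicate only via on-disk artifacts in the package's documented
formats, so each stage is independently inspectable and resumable. In demo
mode the synthetic generators produce every input first; otherwise only the
stages whose inputs are configured run. The manifest records the config
snapshot, seeds, and a sha256 digest of every input and output (relative
paths, no timestamps), so re-running an identical configuration reproduces a
byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import EpimarkError, ValidationError
from .io_model import (
    GeneTable, GenomicInterval, PeakSet, RunConfig,
    read_gene_annotation, read_gwas_summary, read_intervals, write_bed,
)
from .liftover import (
    map_interval, parse_chain, transfer_efficiency, transfer_peaks,
    write_unmapped_report,
)
from .signal_aggregation import build_signal_matrix, promoter_windows
from .specificity import (
    build_methylation_matrix, methylation_specificity, select_top_fraction,
    specificity_matrix, standardize_expression,
)
from .enrichment import enrichment_profile
from .concordance import modality_correlation, trait_correlation
from . import synthetic as syn

logger = logging.getLogger("epimark")

__all__ = ["PipelineManifest", "run_pipeline", "default_demo_config"]

_ALL_STAGES = ("simulate", "liftover", "aggregate", "specificity",
               "enrich", "correlate")


@dataclass
class PipelineManifest:
    version: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)   # relpath -> sha256
    stages: dict = field(default_factory=dict)   # stage -> {outputs: {relpath: sha256}}
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version, "seed": self.seed,
                    "config": self.config, "inputs": self.inputs,
                    "stages": self.stages, "summary": self.summary,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_demo_config(outdir: str, seed: int = 1) -> dict:
    """A self-contained demo configuration exercising every stage."""
    return {
        "mode": "demo",
        "outdir": str(outdir),
        "seed": seed,
        "simulation": {
            "n_chrom": 2, "chrom_len": 2_000_000, "n_genes": 240,
            "n_tissues": 5, "samples_per_tissue": 3,
            "n_specific_per_tissue": 20, "effect_delta": 3.0,
            "noise_sd": 0.5, "rho_modality": 0.4, "n_markers": 4000,
            "enrich_delta": 2.0, "chain_coverage": 0.9, "n_traits": 6,
        },
        "run": {"top_fraction": 0.05, "n_perm": 500, "fdr_alpha": 0.05},
    }


def _map_gene_table(genes: GeneTable, chains, min_map_ratio: float) -> GeneTable:
    """Project a gene annotation onto the target genome through the chains."""
    rows = []
    for _, g in genes.df.iterrows():
        iv = GenomicInterval(str(g["chrom"]), int(g["start"]), int(g["end"]),
                             str(g["strand"]))
        res = map_interval(iv, chains, min_map_ratio)
        if res.status != "mapped":
            continue
        rows.append(
            {
                "gene_id": g["gene_id"], "chrom": res.target.chrom,
                "start": res.target.start, "end": res.target.end,
                "strand": g["strand"], "biotype": g["biotype"],
            }
        )
    return GeneTable(pd.DataFrame(rows, columns=list(GeneTable.REQUIRED)))


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: dict):
        self.config = config
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 1))
        run_cfg = dict(config.get("run", {}))
        run_cfg["seed"] = self.seed
        self.cfg = RunConfig(**run_cfg)
        self.manifest = PipelineManifest(
            version=__version__, seed=self.seed, config=config
        )
        # in-memory artifacts handed between stages
        self.spec = None
        self.truth = None
        self.genes = None
        self.target_genes = None
        self.chains = None
        self.peaks: list[PeakSet] = []
        self.mapped_peaks: list[PeakSet] = []
        self.lift_results = []
        self.matrix = None
        self.expr = None
        self.meth_tables = []
        self.hist_result = None
        self.expr_result = None
        self.top_sets = {}
        self.gwas = {}
        self.profiles = {}

    def record(self, stage: str, *paths: Path) -> None:
        entry = self.manifest.stages.setdefault(stage, {"outputs": {}})
        for p in paths:
            entry["outputs"][str(p.relative_to(self.outdir))] = _digest(p)


def _stage_simulate(run: _Run) -> None:
    sim_cfg = dict(run.config.get("simulation", {}))
    sim_cfg.setdefault("seed", run.seed)
    spec = syn.SimulationSpec(**sim_cfg)
    run.spec = spec
    out = run.outdir

    run.genes = syn.generate_genome_annotation(spec)
    genes_path = out / "genes.tsv"
    syn.write_gene_table(run.genes, genes_path)

    run.peaks, run.truth = syn.generate_peak_samples(spec, run.genes)
    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    peak_paths = []
    for ps in run.peaks:
        p = peak_dir / f"{ps.sample_id}.narrowPeak"
        write_bed(ps, p, dialect="narrowPeak")
        peak_paths.append(p)

    chain_path = out / "alignment.chain"
    syn.generate_chain_file(spec, chain_path, run.truth)

    run.expr = syn.generate_expression_matrix(spec, run.genes, run.truth)
    expr_path, expr_meta = out / "expression.tsv", out / "expression_meta.tsv"
    run.expr.write_tsv(expr_path, expr_meta)

    run.meth_tables = syn.generate_methylation_data(spec, run.genes, run.truth)
    meth_dir = out / "methylation"
    meth_dir.mkdir(exist_ok=True)
    meth_paths = []
    for tab in run.meth_tables:
        sid = str(tab.df["sample_id"].iloc[0])
        p = meth_dir / f"{sid}.tsv"
        syn.write_cpg_table(tab, p)
        meth_paths.append(p)

    truth_path = out / "truth.json"
    run.truth.to_json(truth_path)
    run.record("simulate", genes_path, chain_path, expr_path, expr_meta,
               truth_path, *peak_paths, *meth_paths)


def _stage_liftover(run: _Run) -> None:
    out = run.outdir
    run.chains = parse_chain(out / "alignment.chain")
    mapped_dir = out / "mapped_peaks"
    mapped_dir.mkdir(exist_ok=True)
    paths = []
    effs = []
    all_results = []
    for ps in run.peaks:
        mapped, results = transfer_peaks(ps, run.chains, run.cfg.min_map_ratio)
        run.mapped_peaks.append(mapped)
        all_results.extend(results)
        effs.append(transfer_efficiency(results))
        p = mapped_dir / f"{ps.sample_id}.narrowPeak"
        write_bed(mapped, p, dialect="narrowPeak")
        paths.append(p)
    report = out / "liftover_report.tsv"
    write_unmapped_report(all_results, report)
    run.lift_results = all_results
    run.manifest.summary["mean_transfer_efficiency"] = round(float(np.mean(effs)), 6)
    # the target-genome annotation used by all downstream windows
    run.target_genes = _map_gene_table(run.genes, run.chains, run.cfg.min_map_ratio)
    tg_path = out / "genes_target.tsv"
    syn.write_gene_table(run.target_genes, tg_path)
    run.record("liftover", report, tg_path, *paths)


def _stage_aggregate(run: _Run) -> None:
    out = run.outdir
    windows = promoter_windows(
        run.target_genes, run.cfg.promoter_up, run.cfg.promoter_down
    )
    run.windows = windows
    run.matrix = build_signal_matrix(run.mapped_peaks, windows, kind="promoter")
    vals, meta = out / "signal_matrix.tsv", out / "signal_meta.tsv"
    run.matrix.write_tsv(vals, meta)
    run.record("aggregate", vals, meta)


def _stage_specificity(run: _Run) -> None:
    out = run.outdir
    run.hist_result = specificity_matrix(run.matrix)
    hist_path = out / "specificity_histone.tsv"
    run.hist_result.write_tsv(hist_path)

    expr_std = standardize_expression(run.expr)
    run.expr_result = specificity_matrix(expr_std)
    expr_path = out / "specificity_expression.tsv"
    run.expr_result.write_tsv(expr_path)

    meth_windows = promoter_windows(
        run.genes, run.cfg.promoter_up, run.cfg.promoter_down
    )
    meth_matrix = build_methylation_matrix(run.meth_tables, meth_windows)
    meth_result = methylation_specificity(meth_matrix)
    meth_path = out / "specificity_methylation.tsv"
    meth_result.write_tsv(meth_path)
    run.meth_result = meth_result

    bed_dir = out / "top_sets"
    bed_dir.mkdir(exist_ok=True)
    bed_paths = []
    for tissue in run.hist_result.t.columns:
        ts = select_top_fraction(
            run.hist_result, tissue, run.cfg.top_fraction, run.windows
        )
        run.top_sets[tissue] = ts
        p = bed_dir / f"{tissue}_top{int(run.cfg.top_fraction * 100)}.bed"
        scores = run.hist_result.t.loc[ts.feature_ids, tissue].tolist()
        ts.write_bed(p, scores=scores)
        bed_paths.append(p)
    run.record("specificity", hist_path, expr_path, meth_path, *bed_paths)


def _stage_enrich(run: _Run) -> None:
    out = run.outdir
    spec = run.spec
    # traits planted round-robin in the tissues' target-genome promoters
    tissues = spec.tissue_names
    target_windows = {fw.gene_id: fw.window for fw in run.windows}
    regions_by_trait = {}
    for i in range(spec.n_traits):
        trait = f"trait{i + 1:02d}"
        tissue = tissues[i % len(tissues)]
        run.truth.enriched_traits[trait] = tissue
        regions = [
            target_windows[g]
            for g in run.truth.specific_features[tissue]
            if g in target_windows
        ]
        regions_by_trait[trait] = regions
    gwas_dir = out / "gwas"
    gwas_dir.mkdir(exist_ok=True)
    run.gwas = syn.generate_gwas_summary(_RenamedSpec(spec), regions_by_trait)
    gwas_paths = []
    for trait, tab in run.gwas.items():
        p = gwas_dir / f"{trait}.tsv"
        syn.write_gwas_table(tab, p)
        gwas_paths.append(p)
    run.truth.to_json(out / "truth.json")

    profile = enrichment_profile(run.gwas, run.top_sets, run.cfg)
    run.profiles["all"] = profile
    mat_path, long_path = out / "enrichment_matrix.tsv", out / "enrichment_long.tsv"
    profile.write_tsv(mat_path, long_path)
    run.manifest.summary["n_significant_cells"] = int(
        profile.stars(run.cfg.fdr_alpha).to_numpy().sum()
    )
    run.record("enrich", mat_path, long_path, out / "truth.json", *gwas_paths)


class _RenamedSpec:
    """SimulationSpec view whose chromosomes carry the target-genome names.

    GWAS markers must share the coordinate system of the lifted peak windows,
    i.e. live on the target genome."""

    def __init__(self, spec):
        self._spec = spec

    def __getattr__(self, name):
        return getattr(self._spec, name)

    @property
    def chrom_names(self):
        return [f"bt_{c}" for c in self._spec.chrom_names]


def _stage_correlate(run: _Run) -> None:
    out = run.outdir
    cm = modality_correlation(run.hist_result, run.expr_result)
    cm_path = out / "modality_correlation.tsv"
    cm.write_tsv(cm_path)
    diag = [cm.r.loc[t, t] for t in cm.r.index if t in cm.r.columns]
    run.manifest.summary["modality_corr_diag_mean"] = round(float(np.mean(diag)), 6)

    # split traits into two groups planted in the same tissues pairwise and
    # correlate their enrichment profiles over the identity tissue map
    profile = run.profiles["all"]
    traits = list(profile.neglog10p.index)
    half = len(traits) // 2
    import dataclasses as _dc

    P = _dc.replace(profile, neglog10p=profile.neglog10p.iloc[:half],
                    qvalues=profile.qvalues.iloc[:half])
    Q = _dc.replace(profile, neglog10p=profile.neglog10p.iloc[half:],
                    qvalues=profile.qvalues.iloc[half:])
    tissue_map = [(t, t) for t in profile.neglog10p.columns]
    tc = trait_correlation(P, Q, tissue_map)
    tc_path = out / "trait_correlation.tsv"
    tc.write_tsv(tc_path)
    run.record("correlate", cm_path, tc_path)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "liftover": _stage_liftover,
    "aggregate": _stage_aggregate,
    "specificity": _stage_specificity,
    "enrich": _stage_enrich,
    "correlate": _stage_correlate,
}


def run_pipeline(config_path: str | Path) -> PipelineManifest:
    """Execute the configured stages and write ``manifest.json`` in the outdir.

    Demo mode (a ``simulation`` block in the config) generates all inputs
    first. A stage failure aborts the run with the stage name; outputs written
    so far are retained next to a ``<stage>.failed`` marker.
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    return run_pipeline_config(config)


def run_pipeline_config(config: dict) -> PipelineManifest:
    if "simulation" not in config:
        raise ValidationError(
            "only demo mode (a 'simulation' config block) is supported; "
            "point individual CLI subcommands at existing inputs otherwise"
        )
    run = _Run(config)
    stages = config.get("stages", list(_ALL_STAGES))
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}")
    skipped = [s for s in _ALL_STAGES if s not in stages]
    if "enrich" not in stages and "correlate" in stages:
        raise ValidationError("correlate requires the enrich stage")
    for s in skipped:
        logger.info("stage %s skipped (not configured)", s)
    for stage in _ALL_STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:
            marker = run.outdir / f"{stage}.failed"
            marker.write_text(f"stage {stage} failed: {exc}\n")
            raise EpimarkError(f"stage {stage!r} failed: {exc}") from exc
    run.manifest.to_json(run.outdir / "manifest.json")
    return run.manifest
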
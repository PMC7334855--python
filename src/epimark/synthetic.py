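"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate, at desk scale, the shape of the study's inputs:
multi-tissue narrowPeak samples with planted tissue-specific promoter signal,
a pairwise alignment chain with configurable mapped fraction, an expression
matrix whose tissue specificity overlaps the histone planting by a controlled
amount, promoter methylation with planted hypomethylation, and genome-ordered
GWAS summary statistics with planted regional enrichment.

Every generator is a pure function of (spec, seed): identical outputs at a
fixed seed. Stage-specific generators derive their streams from the spec seed
plus a fixed stage key, so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_model import CpgTable, GeneTable, GenomicInterval, GwasTable, PeakSet
from .signal_aggregation import SignalMatrix, promoter_windows

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "generate_genome_annotation",
    "generate_peak_samples",
    "generate_chain_file",
    "generate_expression_matrix",
    "generate_methylation_data",
    "generate_gwas_summary",
]

# fixed stage keys so each generator has an independent, reproducible stream
_STAGE = {"genes": 1, "peaks": 2, "chain": 3, "expression": 4,
          "methylation": 5, "gwas": 6}


def _rng(spec: "SimulationSpec", stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], spec.seed])


@dataclass
class SimulationSpec:
    """All simulation constants in one place; nothing is hard-coded downstream.

    Defaults are the package's reference study conditions: 10 tissues × 5
    samples, planted specificity effect of 3 within-group standard deviations,
    lognormal peak signal with sigma 0.5, a cross-modality t-correlation
    target of 0.6, and GWAS enrichment shifting planted-region statistics by
    2 null standard deviations.
    """

    seed: int
    n_chrom: int = 2
    chrom_len: int = 10_000_000
    n_genes: int = 2000
    n_tissues: int = 10
    samples_per_tissue: int = 5
    n_specific_per_tissue: int = 130
    effect_delta: float = 3.0
    noise_sd: float = 0.5  # sigma of the lognormal peak-signal distribution
    rho_modality: float = 0.6
    n_markers: int = 2000
    enrich_delta: float = 2.0
    chain_coverage: float = 0.8
    n_traits: int = 6
    promoter_up: int = 1000
    promoter_down: int = 500
    peak_jitter: int = 200
    meth_samples_per_tissue: int = 2
    cpgs_per_promoter: int = 10
    cpg_coverage: float = 10.0  # Poisson mean read depth per CpG
    mark: str = "H3K4me3"
    chain_period: int = 10_000

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_len", "n_genes", "n_tissues",
                     "samples_per_tissue", "n_markers", "n_traits"):
            if getattr(self, name) < 0 or (name != "n_genes" and getattr(self, name) == 0):
                raise ValidationError(f"{name} must be positive")
        if not (0 <= self.rho_modality < 1):
            raise ValidationError("rho_modality must be in [0, 1)")
        if not (0 <= self.chain_coverage <= 1):
            raise ValidationError("chain_coverage must be in [0, 1]")
        if self.n_specific_per_tissue * self.n_tissues > self.n_genes:
            raise ValidationError(
                "disjoint planting needs n_specific_per_tissue × n_tissues <= n_genes"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def chrom_lens(self) -> dict[str, int]:
        return {c: self.chrom_len for c in self.chrom_names}


@dataclass
class GroundTruth:
    """What was planted; sufficient to score every recovery property."""

    specific_features: dict[str, list[str]] = field(default_factory=dict)
    expression_specific: dict[str, list[str]] = field(default_factory=dict)
    methylation_specific: dict[str, list[str]] = field(default_factory=dict)
    enriched_traits: dict[str, str] = field(default_factory=dict)  # trait -> tissue
    chain_unmappable: list[tuple[str, int, int]] = field(default_factory=list)
    coplant_fraction: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["chain_unmappable"] = [tuple(x) for x in data.get("chain_unmappable", [])]
        return cls(**data)


# ---------------------------------------------------------------------------
# Genome and peaks
# ---------------------------------------------------------------------------

_GENE_LEN_RANGE = (1000, 5000)
_EDGE_MARGIN = 2500  # keeps promoter windows and peak jitter off chromosome edges


def generate_genome_annotation(spec: SimulationSpec) -> GeneTable:
    """Non-overlapping protein-coding genes of 1–5 kb, random strand.

    Genes are packed per chromosome with randomly distributed slack so
    promoter windows never collide with chromosome edges; infeasible packing
    (too many/too long genes for the chromosome) is an error.
    """
    rng = _rng(spec, "genes")
    if spec.n_genes == 0:
        return GeneTable(pd.DataFrame(columns=list(GeneTable.REQUIRED)))
    per_chrom = np.full(spec.n_chrom, spec.n_genes // spec.n_chrom)
    per_chrom[: spec.n_genes % spec.n_chrom] += 1
    min_gap = 2 * _EDGE_MARGIN  # room for both neighbours' promoters + jitter
    records = []
    gid = 0
    for chrom, n_here in zip(spec.chrom_names, per_chrom):
        if n_here == 0:
            continue
        lengths = rng.integers(_GENE_LEN_RANGE[0], _GENE_LEN_RANGE[1] + 1, n_here)
        needed = int(lengths.sum()) + min_gap * (n_here + 1)
        if needed > spec.chrom_len:
            raise ValidationError(
                f"{chrom}: cannot pack {n_here} genes ({needed} bp needed, "
                f"{spec.chrom_len} available)"
            )
        slack = spec.chrom_len - needed
        # split the slack into n_here+1 random gaps (stick breaking)
        cuts = np.sort(rng.integers(0, slack + 1, n_here))
        extra = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = 0
        for i in range(n_here):
            pos += min_gap + int(extra[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            records.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "biotype": "protein_coding",
                }
            )
            gid += 1
    return GeneTable(pd.DataFrame(records))


def _lognormal_moments(sigma: float) -> tuple[float, float]:
    """(mean, sd) of Lognormal(0, sigma)."""
    mean = math.exp(sigma ** 2 / 2)
    sd = mean * math.sqrt(math.exp(sigma ** 2) - 1)
    return mean, sd


def planted_signal_factor(spec: SimulationSpec) -> float:
    """Multiplier applied to planted peak signals.

    Chosen so the expected tested-vs-rest mean difference equals
    effect_delta × the background within-group sd:
    (c − 1)·mean = delta·sd  ⇒  c = 1 + delta·(sd/mean) = 1 + delta·cv
    with cv = sqrt(exp(sigma²) − 1) for Lognormal(0, sigma).
    """
    cv = math.sqrt(math.exp(spec.noise_sd ** 2) - 1)
    return 1.0 + spec.effect_delta * cv


def generate_peak_samples(
    spec: SimulationSpec, genes: GeneTable
) -> tuple[list[PeakSet], GroundTruth]:
    """Per-tissue peak samples with planted tissue-specific promoter signal.

    Every sample gets a background peak at every gene promoter with signal
    ~ Lognormal(0, noise_sd) and boundaries jittered ±peak_jitter bp; planted
    (tissue, gene) pairs have their signal multiplied by
    :func:`planted_signal_factor`. Planted sets are disjoint across tissues.
    """
    rng = _rng(spec, "peaks")
    truth = GroundTruth()
    gene_ids = genes.df["gene_id"].tolist()
    planted: dict[str, set[str]] = {t: set() for t in spec.tissue_names}
    if spec.n_specific_per_tissue > 0 and len(gene_ids):
        perm = rng.permutation(len(gene_ids))
        k = spec.n_specific_per_tissue
        for i, tis in enumerate(spec.tissue_names):
            chosen = [gene_ids[j] for j in perm[i * k: (i + 1) * k]]
            planted[tis] = set(chosen)
            truth.specific_features[tis] = sorted(chosen)
    else:
        truth.specific_features = {t: [] for t in spec.tissue_names}

    factor = planted_signal_factor(spec)
    windows = promoter_windows(
        genes, spec.promoter_up, spec.promoter_down, spec.chrom_lens
    )
    samples = []
    for tis in spec.tissue_names:
        for s in range(spec.samples_per_tissue):
            sid = f"{tis}_s{s + 1}"
            ivs = []
            signals = rng.lognormal(0.0, spec.noise_sd, len(windows))
            jit = rng.integers(-spec.peak_jitter, spec.peak_jitter + 1,
                               (len(windows), 2))
            for i, fw in enumerate(windows):
                sig = signals[i]
                if fw.gene_id in planted[tis]:
                    sig *= factor
                start = max(0, fw.window.start + int(jit[i, 0]))
                end = min(spec.chrom_len, fw.window.end + int(jit[i, 1]))
                if end <= start:  # extreme jitter collapse; keep the window
                    start, end = fw.window.start, fw.window.end
                ivs.append(
                    GenomicInterval(
                        fw.window.chrom, start, end, ".",
                        signal=float(sig), name=f"{fw.gene_id}_{sid}",
                    )
                )
            samples.append(PeakSet(ivs, sample_id=sid, tissue=tis, mark=spec.mark))
    return samples, truth


# ---------------------------------------------------------------------------
# Chain
# ---------------------------------------------------------------------------


def generate_chain_file(
    spec: SimulationSpec, path: str | Path, truth: GroundTruth | None = None
) -> GroundTruth:
    """Write a UCSC chain tiling each chromosome at the requested coverage.

    Each chromosome is tiled in periods of ``chain_period`` bp whose first
    round(coverage × period) bases are mapped; gaps are the unmappable
    remainder (recorded in the ground truth). Target coordinates are compact
    (gaps removed) and shifted by a per-chromosome constant, so coverage
    grids are nested: everything mapped at coverage c is mapped at c' > c.
    """
    truth = truth or GroundTruth()
    period = spec.chain_period
    block_len = int(round(spec.chain_coverage * period))
    lines = []
    for ci, chrom in enumerate(spec.chrom_names):
        shift = 1000 * (ci + 1)
        if block_len == 0:
            truth.chain_unmappable.append((chrom, 0, spec.chrom_len))
            continue
        n_periods = spec.chrom_len // period
        src_end = (n_periods - 1) * period + block_len
        mapped_total = n_periods * block_len
        tgt_chrom = f"bt_{chrom}"
        tgt_size = mapped_total + shift + 10_000
        lines.append(
            f"chain 1000 {chrom} {spec.chrom_len} + 0 {src_end} "
            f"{tgt_chrom} {tgt_size} + {shift} {shift + mapped_total} {ci + 1}"
        )
        gap = period - block_len
        for k in range(n_periods):
            if k < n_periods - 1:
                lines.append(f"{block_len}\t{gap}\t0")
                if gap:
                    truth.chain_unmappable.append(
                        (chrom, k * period + block_len, (k + 1) * period)
                    )
            else:
                lines.append(f"{block_len}")
                if gap:
                    truth.chain_unmappable.append(
                        (chrom, k * period + block_len,
                         min((k + 1) * period, spec.chrom_len))
                    )
        lines.append("")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return truth


# ---------------------------------------------------------------------------
# Expression (cross-modality co-planting)
# ---------------------------------------------------------------------------

_EXPR_BASELINE_MEAN = 5.0
_EXPR_BASELINE_SD = 2.0
_EXPR_NOISE_SD = 1.0
_EXPR_SAMPLE_PREFIX = "rna"


def expected_specificity_t(spec: SimulationSpec, modality: str) -> float:
    """Analytic expectation of the planted feature's specificity t-statistic.

    Histone planting is multiplicative (factor c = 1 + delta·cv), which
    inflates the tested group's variance; the pooled sd in the two-sample t
    therefore uses ((n1−1)c² + (n2−1))/(n1+n2−2) times the background
    variance. Expression planting is an additive shift of delta noise-sd,
    reduced by per-sample standardization (the planted genes pull the
    sample mean up by delta × planted-fraction).
    """
    n1 = spec.samples_per_tissue
    n2 = (spec.n_tissues - 1) * spec.samples_per_tissue
    half_width = math.sqrt(1 / n1 + 1 / n2)
    if modality == "histone":
        cv = math.sqrt(math.exp(spec.noise_sd ** 2) - 1)
        c = 1.0 + spec.effect_delta * cv
        pool = math.sqrt(((n1 - 1) * c ** 2 + (n2 - 1)) / (n1 + n2 - 2))
        return spec.effect_delta / (pool * half_width)
    if modality == "expression":
        p = spec.n_specific_per_tissue / spec.n_genes
        return spec.effect_delta * (1 - p) / half_width
    raise ValidationError(f"unknown modality {modality!r}")


def _t_class_moments(spec: SimulationSpec, modality: str) -> dict[str, float]:
    """Per-gene-class moments of a tissue's specificity t-vector.

    For the test of tissue i, genes fall into three classes:

    * planted in i — t has mean ``mu`` (see :func:`expected_specificity_t`)
      and variance ``v_planted`` (central-t variance inflated by the
      noncentrality);
    * planted in another tissue j ≠ i (disjoint planting) — the n1 elevated
      tissue-j samples sit in the comparison group, shifting its mean and
      inflating the pooled sd, so t has a negative mean ``a`` and a damped
      variance ``v_a``;
    * unplanted everywhere — central t: mean 0, variance ``v0`` = dof/(dof−2).
    """
    n1 = spec.samples_per_tissue
    n2 = (spec.n_tissues - 1) * spec.samples_per_tissue
    dof = n1 + n2 - 2
    hw = math.sqrt(1 / n1 + 1 / n2)
    w = n1 / n2  # fraction of comparison-group samples that are contaminated
    v0 = dof / (dof - 2)
    mu = expected_specificity_t(spec, modality)
    if modality == "histone":
        cv = math.sqrt(math.exp(spec.noise_sd ** 2) - 1)
        c = 1.0 + spec.effect_delta * cv
        delta = spec.effect_delta
        # contaminated comparison group: mixture of background and c-scaled
        # lognormal samples (variance c², mean shift delta, in background-sd units)
        R = (1 - w) + w * c ** 2 + w * (1 - w) * delta ** 2
    elif modality == "expression":
        p = spec.n_specific_per_tissue / spec.n_genes
        delta = spec.effect_delta * (1 - p)
        R = 1 + w * (1 - w) * delta ** 2
    else:
        raise ValidationError(f"unknown modality {modality!r}")
    rho_c = ((n1 - 1) + (n2 - 1) * R) / dof  # pooled-variance inflation
    a = -delta * w / (math.sqrt(rho_c) * hw)
    v_a = v0 / rho_c
    v_planted = v0 * (1 + mu ** 2 / (2 * dof))
    return {"mu": mu, "v_planted": v_planted, "a": a, "v_a": v_a, "v0": v0}


def coplant_fraction(spec: SimulationSpec) -> float:
    """Probability that an expression-planted gene reuses the histone planting.

    The realized Pearson correlation between matched-tissue t-vectors is
    computed from the exact gene-class mixture (see :func:`_t_class_moments`):
    with planted fraction p per tissue, T tissues and disjoint planting,
    q = (T−1)p genes are planted in another tissue. Writing mu/a for the
    planted/contaminated class means of each modality,

        mean   = p·mu + q·a                       (each modality)
        var    = p(mu²+v_planted) + q(a²+v_a) + (1−p−q)v0 − mean²
        cov(f) = f·(p·mu_A·mu_B + q·a_A·a_B) − mean_A·mean_B

    because a histone-planted gene is expression-planted (same tissue) with
    probability f, and a tissue-j-contaminated gene is contaminated in both
    modalities exactly when it was co-planted in j (probability f);
    expression-only extras are drawn from the never-planted pool, so the
    expression variance does not depend on f. Solving cov(f)/sqrt(V_A V_B) =
    rho for f gives the co-planting probability; a target beyond the f = 1
    ceiling is an error (the geometry cannot express it).
    """
    p = spec.n_specific_per_tissue / spec.n_genes
    if p == 0:
        if spec.rho_modality > 0:
            raise ValidationError("cannot target rho > 0 with no planted features")
        return 0.0
    q = (spec.n_tissues - 1) * p
    A = _t_class_moments(spec, "histone")
    B = _t_class_moments(spec, "expression")
    mean_a = p * A["mu"] + q * A["a"]
    mean_b = p * B["mu"] + q * B["a"]
    var_a = (p * (A["mu"] ** 2 + A["v_planted"]) + q * (A["a"] ** 2 + A["v_a"])
             + (1 - p - q) * A["v0"] - mean_a ** 2)
    var_b = (p * (B["mu"] ** 2 + B["v_planted"]) + q * (B["a"] ** 2 + B["v_a"])
             + (1 - p - q) * B["v0"] - mean_b ** 2)
    slope = p * A["mu"] * B["mu"] + q * A["a"] * B["a"]
    f = (spec.rho_modality * math.sqrt(var_a * var_b) + mean_a * mean_b) / slope
    if f > 1.0 + 1e-9:
        raise ValidationError(
            f"rho_modality={spec.rho_modality} not achievable: needs "
            f"co-planting fraction {f:.3f} > 1"
        )
    return min(max(f, 0.0), 1.0)


def generate_expression_matrix(
    spec: SimulationSpec, genes: GeneTable, truth: GroundTruth
) -> SignalMatrix:
    """log2FPKM-scale matrix whose tissue specificity overlaps the histone set.

    Gene baselines ~ Normal(5, 2); per-sample noise ~ Normal(0, 1); planted
    (tissue, gene) pairs are shifted by effect_delta noise-sd. Each tissue's
    expression-planted set keeps the histone-planted gene with probability
    :func:`coplant_fraction` and draws replacements from the unplanted pool,
    so the realized cross-modality t correlation targets rho_modality.
    """
    rng = _rng(spec, "expression")
    f = coplant_fraction(spec)
    truth.coplant_fraction = f
    gene_ids = genes.df["gene_id"].tolist()
    n = len(gene_ids)
    planted_anywhere = set().union(*truth.specific_features.values()) \
        if truth.specific_features else set()
    # extras come from the never-planted pool (consumed without replacement),
    # so they perturb no other tissue's contamination structure
    pool = [g for g in gene_ids if g not in planted_anywhere]
    pool = [pool[i] for i in rng.permutation(len(pool))]
    planted_b: dict[str, list[str]] = {}
    for tis in spec.tissue_names:
        a_set = list(truth.specific_features.get(tis, []))
        keep = [g for g in a_set if rng.random() < f]
        n_extra = len(a_set) - len(keep)
        extra, pool = pool[:n_extra], pool[n_extra:]
        if len(extra) < n_extra:
            # never-planted pool exhausted (many extras at low rho): fall back
            # to genes planted in other tissues, which only adds small
            # cross-modality mean products
            fallback = [
                g for g in gene_ids
                if g not in set(a_set) and g not in set(extra)
            ]
            take = n_extra - len(extra)
            idx = rng.choice(len(fallback), take, replace=False)
            extra = extra + [fallback[i] for i in sorted(idx)]
        planted_b[tis] = sorted(keep + extra)
        truth.expression_specific[tis] = planted_b[tis]

    baseline = rng.normal(_EXPR_BASELINE_MEAN, _EXPR_BASELINE_SD, n)
    sample_ids, tissue_labels, cols = [], [], []
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for tis in spec.tissue_names:
        shift = np.zeros(n)
        for g in planted_b[tis]:
            shift[gene_pos[g]] = spec.effect_delta * _EXPR_NOISE_SD
        for s in range(spec.samples_per_tissue):
            sample_ids.append(f"{_EXPR_SAMPLE_PREFIX}_{tis}_s{s + 1}")
            tissue_labels.append(tis)
            cols.append(baseline + shift + rng.normal(0, _EXPR_NOISE_SD, n))
    return SignalMatrix(
        values=np.column_stack(cols),
        feature_ids=gene_ids,
        sample_ids=sample_ids,
        tissue_labels=tissue_labels,
        exclusion_class=list(tissue_labels),
        mark="expression",
    )


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

_BETA_HYPO = (2.0, 8.0)  # planted promoter in its own tissue: low methylation
_BETA_HYPER = (8.0, 2.0)  # everywhere else: high methylation


def generate_methylation_data(
    spec: SimulationSpec, genes: GeneTable, truth: GroundTruth
) -> list[CpgTable]:
    """Per-sample CpG count tables with planted promoter hypomethylation.

    Promoters of histone-planted genes draw their methylation level from
    Beta(2, 8) in their own tissue and Beta(8, 2) elsewhere; unplanted
    promoters are Beta(8, 2) everywhere. Each promoter carries
    ``cpgs_per_promoter`` evenly spaced CpGs with Poisson(cpg_coverage) depth.
    """
    rng = _rng(spec, "methylation")
    windows = promoter_windows(
        genes, spec.promoter_up, spec.promoter_down, spec.chrom_lens
    )
    planted = {t: set(v) for t, v in truth.specific_features.items()}
    truth.methylation_specific = {
        t: sorted(v) for t, v in truth.specific_features.items()
    }
    tables = []
    for tis in spec.tissue_names:
        for s in range(spec.meth_samples_per_tissue):
            sid = f"wgbs_{tis}_s{s + 1}"
            rows = []
            for fw in windows:
                hypo = fw.gene_id in planted.get(tis, ())
                a, b = _BETA_HYPO if hypo else _BETA_HYPER
                level = rng.beta(a, b)
                span = fw.window.length
                step = max(1, span // (spec.cpgs_per_promoter + 1))
                for k in range(spec.cpgs_per_promoter):
                    pos = fw.window.start + (k + 1) * step + 1  # 1-based
                    total = int(rng.poisson(spec.cpg_coverage))
                    if total == 0:
                        continue
                    meth = int(rng.binomial(total, level))
                    rows.append(
                        {
                            "chrom": fw.window.chrom, "pos": pos,
                            "meth_reads": meth, "total_reads": total,
                            "sample_id": sid, "tissue": tis,
                        }
                    )
            tables.append(CpgTable(pd.DataFrame(rows)))
    return tables


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------


def generate_gwas_summary(
    spec: SimulationSpec,
    regions_by_trait: Mapping[str, Sequence[GenomicInterval]],
    truth: GroundTruth | None = None,
) -> dict[str, GwasTable]:
    """Evenly spaced markers; statistics N(0,1), N(enrich_delta,1) in planted regions.

    All traits share the marker grid (hence the circular order); a planted
    region containing no marker is an error because the planted enrichment
    would be silently untestable.
    """
    rng = _rng(spec, "gwas")
    per_chrom = np.full(spec.n_chrom, spec.n_markers // spec.n_chrom)
    per_chrom[: spec.n_markers % spec.n_chrom] += 1
    rows = []
    for chrom, n_here in zip(spec.chrom_names, per_chrom):
        spacing = spec.chrom_len // (n_here + 1)
        for i in range(n_here):
            rows.append({"chrom": chrom, "pos": (i + 1) * spacing + 1})
    base = pd.DataFrame(rows)
    base["marker_id"] = [f"snp{i:06d}" for i in range(len(base))]
    pos0 = base["pos"].to_numpy() - 1

    out: dict[str, GwasTable] = {}
    for trait, regions in regions_by_trait.items():
        stat = rng.normal(0.0, 1.0, len(base))
        inside = np.zeros(len(base), dtype=bool)
        for iv in regions:
            hit = (base["chrom"].to_numpy() == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end)
            if not hit.any():
                raise ValidationError(
                    f"trait {trait!r}: planted region "
                    f"{iv.chrom}:{iv.start}-{iv.end} contains no marker"
                )
            inside |= hit
        stat[inside] += spec.enrich_delta
        df = base.assign(stat=stat, trait=trait)
        out[trait] = GwasTable(df, chrom_order=spec.chrom_names, trait=trait)
    return out


# ---------------------------------------------------------------------------
# On-disk emission (the formats io_model reads back)
# ---------------------------------------------------------------------------


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)


def write_gwas_table(g: GwasTable, path: str | Path) -> None:
    g.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cpg_table(tab: CpgTable, path: str | Path) -> None:
    tab.df.to_csv(path, sep="\t", index=False)
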
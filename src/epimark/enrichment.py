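"""Sum-based marker-set enrichment with a circular genotype-permutation null.

The observed statistic is the sum of squared single-marker association
statistics over the markers inside a region set. The null rotates the whole
genome-ordered statistic vector by a uniform offset relative to the set's
membership — a rigid rotation preserves the local (LD-driven) correlation of
statistics, which is exactly what the circular permutation is meant to
protect against. Empirical p-values use the add-one formula
p = (#{null >= T_obs} + 1)/(n_null + 1), so p > 0 and the test is valid.

The per-marker statistic that is squared is configurable (t, |t|, −log10 p)
since "sum-based" admits several conventions; squared t is the default.
Selection-scan statistics are ingested identically: a scan is just a
GwasTable whose stat column holds the scan statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io_model import GenomicInterval, GwasTable, RunConfig
from .specificity import TopFeatureSet

logger = logging.getLogger("epimark")

__all__ = [
    "MarkerSet",
    "SumTestResult",
    "EnrichmentProfile",
    "build_marker_set",
    "sum_statistic",
    "circular_permutation_pvalue",
    "enrichment_profile",
    "bh_fdr",
]


@dataclass
class MarkerSet:
    """Circular ranks of the markers falling inside a region set."""

    indices: np.ndarray
    m: int
    trait: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= self.m
        ):
            raise ValidationError("marker indices out of range [0, m)")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class SumTestResult:
    T_obs: float
    null_T: np.ndarray
    p_emp: float
    n_perm: int
    seed: int | None
    exhaustive: bool


@dataclass
class EnrichmentProfile:
    """Traits × tissues matrix of −log10 empirical p with BH q-values."""

    neglog10p: pd.DataFrame
    qvalues: pd.DataFrame
    mark: str = ""
    k: float = 0.05
    table: pd.DataFrame | None = None  # long-format per-cell detail

    def stars(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.qvalues < alpha

    def write_tsv(self, matrix_path: str | Path, long_path: str | Path | None = None) -> None:
        df = self.neglog10p.copy()
        df.index.name = "trait"
        df.to_csv(matrix_path, sep="\t", float_format="%.10g")
        if long_path is not None and self.table is not None:
            self.table.to_csv(long_path, sep="\t", index=False, float_format="%.10g")


def _merge_regions(regions: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Per-chromosome merged [start, end) boundaries as flat sorted arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out).reshape(-1, 2)
    return merged


def build_marker_set(
    g: GwasTable,
    regions: Sequence[GenomicInterval],
    trait: str = "",
    tissue: str = "",
) -> MarkerSet:
    """Markers whose 0-based position falls in any region (set semantics).

    A marker covered by overlapping regions counts once; boundary rule is
    half-open (pos−1 ∈ [start, end)). An empty result is returned flagged
    empty, not treated as p = 1, so the profile reports the cell as missing.
    """
    merged = _merge_regions(regions) if regions else {}
    idx = []
    for chrom, grp in g.df.groupby("chrom", sort=False):
        spans = merged.get(str(chrom))
        if spans is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        k = np.searchsorted(spans[:, 0], pos0, side="right") - 1
        inside = (k >= 0) & (pos0 < spans[np.clip(k, 0, None), 1])
        idx.extend(grp.index[inside].tolist())
    return MarkerSet(indices=np.sort(np.asarray(idx, dtype=int)), m=len(g),
                     trait=trait or g.trait, tissue=tissue)


def sum_statistic(stats: np.ndarray, mset: MarkerSet, marker_stat: str = "square") -> float:
    """T = Σ over the set of the transformed per-marker statistic."""
    vals = _transform(np.asarray(stats, dtype=float), marker_stat)
    if len(vals) != mset.m:
        raise ValidationError("stats length does not match marker set's m")
    return float(vals[mset.indices].sum())


def _transform(stats: np.ndarray, marker_stat: str) -> np.ndarray:
    if marker_stat == "square":
        return stats ** 2
    if marker_stat == "abs":
        return np.abs(stats)
    if marker_stat == "neglogp":
        # two-sided normal p of the signed statistic
        from scipy.stats import norm

        p = 2 * norm.sf(np.abs(stats))
        return -np.log10(np.maximum(p, 1e-300))
    raise ValidationError(f"unknown marker_stat {marker_stat!r}")


def circular_permutation_pvalue(
    stats: np.ndarray,
    mset: MarkerSet,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
    marker_stat: str = "square",
    rng: np.random.Generator | None = None,
    offsets: np.ndarray | None = None,
) -> SumTestResult:
    """Empirical enrichment p from rigid rotations of the statistic vector.

    Each permutation draws one global offset k uniform on {1, …, m−1} and sums
    the rotated statistics over the fixed set membership; ``exhaustive`` uses
    every offset once. The seed fully determines the sampled offsets; an
    explicit ``offsets`` array overrides the draw (supplying every offset in
    {1, …, m−1} once reproduces the exhaustive result exactly).
    """
    stats = np.asarray(stats, dtype=float)
    m = mset.m
    if m < 2:
        raise ValidationError("need m >= 2 markers")
    if len(mset) == 0:
        raise ValidationError("empty marker set")
    vals = _transform(stats, marker_stat)
    T_obs = float(vals[mset.indices].sum())
    if len(mset) == m:
        logger.warning("marker set covers all markers: rotation null is degenerate")
        null = np.full(m - 1 if exhaustive else n_perm, T_obs)
        return SumTestResult(T_obs, null, 1.0, len(null), seed, exhaustive)
    if offsets is not None:
        offsets = np.asarray(offsets, dtype=int)
    elif exhaustive:
        offsets = np.arange(1, m)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        offsets = rng.integers(1, m, size=n_perm)
    null = vals[(mset.indices[None, :] + offsets[:, None]) % m].sum(axis=1)
    p = (int((null >= T_obs).sum()) + 1) / (len(null) + 1)
    return SumTestResult(T_obs, null, float(p), len(null), seed, exhaustive)


def enrichment_profile(
    gwas_by_trait: Mapping[str, GwasTable],
    sets_by_tissue: Mapping[str, TopFeatureSet],
    cfg: RunConfig,
    marker_stat: str = "square",
    fdr_scope: str = "matrix",
) -> EnrichmentProfile:
    """One circular-permutation test per (trait, tissue) cell.

    All traits must share the marker order (the circular index must mean the
    same marker everywhere). BH q-values are computed over all finite cells of
    the matrix by default (matching one-star-per-heatmap presentation);
    ``fdr_scope='trait'`` corrects within each trait instead. Cells with an
    empty marker set are missing (NaN), never p = 1.
    """
    traits = list(gwas_by_trait)
    tissues = list(sets_by_tissue)
    if not traits or not tissues:
        raise ValidationError("need at least one trait and one tissue")
    ref = gwas_by_trait[traits[0]]
    ref_grid = list(zip(ref.df["marker_id"], ref.df["chrom"], ref.df["pos"]))
    for tr in traits[1:]:
        df = gwas_by_trait[tr].df
        if list(zip(df["marker_id"], df["chrom"], df["pos"])) != ref_grid:
            raise ValidationError(f"marker order mismatch for trait {tr!r}")

    # markers are shared, so set membership is computed once per tissue
    msets = {
        tis: build_marker_set(ref, fs.regions, tissue=tis)
        for tis, fs in sets_by_tissue.items()
    }
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(traits) * len(tissues))
    pmat = pd.DataFrame(np.nan, index=traits, columns=tissues)
    rows = []
    for i, tr in enumerate(traits):
        stats = gwas_by_trait[tr].stats
        for j, tis in enumerate(tissues):
            mset = msets[tis]
            if len(mset) == 0:
                logger.info("empty marker set for tissue %s: cell missing", tis)
                continue
            rng = np.random.default_rng(children[i * len(tissues) + j])
            res = circular_permutation_pvalue(
                stats, mset, n_perm=cfg.n_perm, rng=rng, marker_stat=marker_stat
            )
            pmat.loc[tr, tis] = res.p_emp
            rows.append(
                {
                    "trait": tr, "tissue": tis, "T_obs": res.T_obs,
                    "p_emp": res.p_emp, "n_set": len(mset),
                    "n_perm": res.n_perm, "seed": cfg.seed,
                }
            )
    qmat = pmat.copy()
    if fdr_scope == "matrix":
        flat = pmat.to_numpy().ravel()
        finite = np.isfinite(flat)
        if finite.any():
            q = np.full_like(flat, np.nan)
            q[finite] = bh_fdr(flat[finite])
            qmat.loc[:, :] = q.reshape(pmat.shape)
    elif fdr_scope == "trait":
        for tr in traits:
            row = pmat.loc[tr].to_numpy()
            finite = np.isfinite(row)
            if finite.any():
                q = np.full_like(row, np.nan)
                q[finite] = bh_fdr(row[finite])
                qmat.loc[tr] = q
    else:
        raise ValidationError(f"unknown fdr_scope {fdr_scope!r}")
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = table.apply(
            lambda r: qmat.loc[r["trait"], r["tissue"]], axis=1
        )
    mark = next(iter(sets_by_tissue.values())).mark
    k = next(iter(sets_by_tissue.values())).k
    return EnrichmentProfile(
        neglog10p=-np.log10(pmat), qvalues=qmat, mark=mark, k=k, table=table
    )


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
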
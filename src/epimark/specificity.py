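"""Tissue-specificity t-statistics from a ±1-coded OLS fit, per feature.

For a tested tissue, samples of that tissue are coded +1 and the remaining
samples −1 (intercept included), and the t-statistic of the tissue effect
b/se(b) measures specificity. With no covariates this is algebraically the
pooled two-sample t-test. Samples whose exclusion class matches the tested
tissue's class (e.g. T cells and thymus when testing B cells within an
immune-blood class) are removed from the comparison group before fitting.

The methylation variant inverts the coding (−1 tested / +1 rest) so that
tissue-specific promoter hypomethylation yields a large positive t. The
expression variant standardizes each sample's gene vector first and admits
categorical covariates (age, sex, study) as reference-level dummies.

Zero-residual-variance features return t = 0 rather than NaN, keeping matrices
dense and ranking such features last.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_model import GenomicInterval
from .signal_aggregation import FeatureWindow, SignalMatrix

logger = logging.getLogger("epimark")

__all__ = [
    "SpecificityModelSpec",
    "SpecificityFit",
    "SpecificityResult",
    "TopFeatureSet",
    "fit_specificity_model",
    "specificity_matrix",
    "methylation_specificity",
    "standardize_expression",
    "weighted_methylation",
    "build_methylation_matrix",
    "select_top_fraction",
]

# residual variance below this times the feature's own mean square is treated
# as numerically zero (degenerate-feature rule)
_DEGENERATE_REL_TOL = 1e-12


@dataclass
class SpecificityModelSpec:
    """Which tissue is tested, how it is coded, and which samples are excluded."""

    tested_tissue: str
    coding: str = "standard"  # standard: +1 tested / -1 rest; inverted: flipped
    covariates: pd.DataFrame | None = None  # samples x categorical factors
    exclusion: set[str] = field(default_factory=set)  # sample ids removed pre-fit

    def __post_init__(self) -> None:
        if self.coding not in ("standard", "inverted"):
            raise ValidationError(f"unknown coding {self.coding!r}")


@dataclass
class SpecificityFit:
    b: float
    se: float
    t: float
    n_used: int


@dataclass
class SpecificityResult:
    """Per feature × tissue effect estimates; all frames share index/columns."""

    b: pd.DataFrame
    se: pd.DataFrame
    t: pd.DataFrame
    n_used: pd.Series  # per tissue
    mark: str = ""

    def write_tsv(self, path: str | Path) -> None:
        long = (
            self.t.stack()
            .rename("t")
            .reset_index()
            .rename(columns={"level_0": "feature_id", "level_1": "tissue"})
        )
        long["b"] = self.b.stack().to_numpy()
        long["se"] = self.se.stack().to_numpy()
        long["n_used"] = long["tissue"].map(self.n_used).astype(int)
        long[["feature_id", "tissue", "b", "se", "t", "n_used"]].to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


@dataclass
class TopFeatureSet:
    """The top-k% tissue-specific features with their genomic windows."""

    tissue: str
    mark: str
    k: float
    feature_ids: list[str]
    regions: list[GenomicInterval]

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.regions):
            raise ValidationError("regions must align 1:1 with feature_ids")

    def write_bed(self, path: str | Path, scores: Sequence[float] | None = None) -> None:
        with open(path, "w") as fh:
            for i, (fid, iv) in enumerate(zip(self.feature_ids, self.regions)):
                score = scores[i] if scores is not None else 0.0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fid}\t{score:.6g}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def _design_matrix(
    x: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + ±1 tissue code + reference-level dummies for each factor."""
    cols = [np.ones_like(x), x]
    names = ["intercept", "tissue"]
    if covariates is not None:
        dummies = pd.get_dummies(
            covariates.astype("category"), drop_first=True, dtype=float
        )
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy())
            names.append(str(name))
    X = np.column_stack(cols)
    return X, names


def _fit_many(Y: np.ndarray, X: np.ndarray, names: list[str]):
    """Vectorized OLS of each row of Y (features × samples) on a shared design.

    Returns (b, se, t) for the tissue-effect column. Features whose residual
    variance is numerically zero relative to their own scale get t = 0.
    """
    n, p = X.shape
    if n <= p:
        raise ValidationError(
            f"not enough samples ({n}) for design with {p} parameters"
        )
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"collinear factors among {names[2:] or names}"
        )
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ X.T @ Y.T  # p × features
    resid = Y.T - X @ coef
    dof = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    scale = np.maximum(np.mean(Y * Y, axis=1), 1.0)
    degenerate = sigma2 <= _DEGENERATE_REL_TOL * scale
    var_b = sigma2 * xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_b)
        t = np.where(degenerate, 0.0, coef[1] / np.where(se == 0, np.nan, se))
    t = np.nan_to_num(t, nan=0.0)
    se = np.where(degenerate, 0.0, se)
    return coef[1], se, t


def fit_specificity_model(
    y: np.ndarray,
    sample_tissues: Sequence[str],
    spec: SpecificityModelSpec,
    sample_ids: Sequence[str] | None = None,
) -> SpecificityFit:
    """OLS of one feature's signal on the ±1 tissue code (plus covariates).

    t = b/se equals the pooled two-sample t on the same partition when there
    are no covariates.
    """
    y = np.asarray(y, dtype=float)
    tissues = np.asarray(sample_tissues)
    if len(y) != len(tissues):
        raise ValidationError("y not aligned to samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(y))]
    keep = np.array([sid not in spec.exclusion for sid in sample_ids])
    tested = (tissues == spec.tested_tissue) & keep
    rest = (~(tissues == spec.tested_tissue)) & keep
    if tested.sum() == 0 or rest.sum() == 0:
        raise ValidationError(
            f"tissue {spec.tested_tissue!r}: tested and rest groups must both "
            "be nonempty after exclusion"
        )
    sign = 1.0 if spec.coding == "standard" else -1.0
    x = np.where(tissues == spec.tested_tissue, sign, -sign)[keep]
    cov = spec.covariates.loc[keep] if spec.covariates is not None else None
    X, names = _design_matrix(x, cov)
    b, se, t = _fit_many(y[keep][None, :], X, names)
    return SpecificityFit(b=float(b[0]), se=float(se[0]), t=float(t[0]),
                          n_used=int(keep.sum()))


def specificity_matrix(
    M: SignalMatrix,
    coding: str = "standard",
    covariates: pd.DataFrame | None = None,
    class_exclusion: bool = True,
) -> SpecificityResult:
    """Fit the specificity model for every feature × tissue of a matrix.

    For each tested tissue the excluded samples are all samples whose
    exclusion class equals the tested tissue's class, minus the tested samples
    themselves. Features with NaN entries (uncovered methylation promoters)
    are dropped with a log message before fitting.
    """
    values = M.values
    nan_rows = np.isnan(values).any(axis=1)
    if nan_rows.any():
        logger.info(
            "dropping %d feature(s) with missing values before specificity fit",
            int(nan_rows.sum()),
        )
        values = values[~nan_rows]
        feature_ids = [f for f, bad in zip(M.feature_ids, nan_rows) if not bad]
    else:
        feature_ids = list(M.feature_ids)
    tissues = np.asarray(M.tissue_labels)
    classes = np.asarray(M.exclusion_class)
    unique_tissues = list(dict.fromkeys(M.tissue_labels))

    # precondition: every tissue needs >= 2 samples outside its exclusion class
    offenders = []
    for tis in unique_tissues:
        cls = set(classes[tissues == tis])
        outside = (~np.isin(classes, list(cls))).sum()
        if outside < 2:
            offenders.append(tis)
    if offenders:
        raise ValidationError(
            f"tissue(s) with < 2 samples outside their exclusion class: {offenders}"
        )

    sign = 1.0 if coding == "standard" else -1.0
    if coding not in ("standard", "inverted"):
        raise ValidationError(f"unknown coding {coding!r}")
    b_cols, se_cols, t_cols, n_used = {}, {}, {}, {}
    for tis in unique_tissues:
        tested = tissues == tis
        if class_exclusion:
            cls = set(classes[tested])
            excluded = np.isin(classes, list(cls)) & ~tested
        else:
            excluded = np.zeros_like(tested)
        keep = ~excluded
        x = np.where(tested, sign, -sign)[keep]
        cov = covariates.loc[keep] if covariates is not None else None
        X, names = _design_matrix(x, cov)
        b, se, t = _fit_many(values[:, keep], X, names)
        b_cols[tis], se_cols[tis], t_cols[tis] = b, se, t
        n_used[tis] = int(keep.sum())
    idx = pd.Index(feature_ids, name="feature_id")
    return SpecificityResult(
        b=pd.DataFrame(b_cols, index=idx),
        se=pd.DataFrame(se_cols, index=idx),
        t=pd.DataFrame(t_cols, index=idx),
        n_used=pd.Series(n_used),
        mark=M.mark,
    )


def methylation_specificity(
    M: SignalMatrix,
    covariates: pd.DataFrame | None = None,
    class_exclusion: bool = True,
) -> SpecificityResult:
    """Specificity with inverted coding: high t = tissue-specific hypomethylation."""
    return specificity_matrix(
        M, coding="inverted", covariates=covariates, class_exclusion=class_exclusion
    )


def standardize_expression(E: SignalMatrix, mode: str = "per_sample") -> SignalMatrix:
    """Scale log2FPKM to mean 0, variance 1.

    ``per_sample`` (default) standardizes each sample's gene vector, removing
    library-size/composition scale while keeping cross-gene contrasts.
    ``per_tissue`` pools all samples of a tissue and standardizes their values
    with one shared mean/sd.
    """
    V = E.values.astype(float).copy()
    if V.shape[0] < 2:
        raise ValidationError("need >= 2 genes to standardize")
    if mode == "per_sample":
        mean = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = [E.sample_ids[i] for i in np.flatnonzero(zero)]
            raise ValidationError(f"zero-variance sample(s): {bad[:5]}")
        V = (V - mean) / sd
    elif mode == "per_tissue":
        tissues = np.asarray(E.tissue_labels)
        for tis in dict.fromkeys(E.tissue_labels):
            cols = tissues == tis
            pooled = V[:, cols]
            sd = pooled.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"zero-variance tissue {tis!r}")
            V[:, cols] = (pooled - pooled.mean()) / sd
    else:
        raise ValidationError(f"unknown standardization mode {mode!r}")
    return SignalMatrix(
        values=V, feature_ids=list(E.feature_ids), sample_ids=list(E.sample_ids),
        tissue_labels=list(E.tissue_labels), exclusion_class=list(E.exclusion_class),
        mark=E.mark or "expression",
    )


def weighted_methylation(cpgs: pd.DataFrame) -> float:
    """Coverage-weighted methylation level of a window: Σ meth / Σ total.

    This weights CpGs by their read depth — (1/1) and (0/9) give 0.1, not the
    naive per-CpG mean 0.5. Returns NaN for an empty window (the feature is
    dropped, not zero-filled: 0 would assert full unmethylation).
    """
    if len(cpgs) == 0 or cpgs["total_reads"].sum() == 0:
        return float("nan")
    return float(cpgs["meth_reads"].sum() / cpgs["total_reads"].sum())


def build_methylation_matrix(
    cpg_tables: Sequence, windows: Sequence[FeatureWindow]
) -> SignalMatrix:
    """Weighted methylation per promoter window × sample from CpG count tables.

    ``cpg_tables`` is a sequence of CpgTable whose df carries sample_id and
    tissue columns (one sample per table). Windows with no covered CpG in a
    sample are NaN; fully uncovered features are dropped by the specificity fit.
    """
    sample_ids, tissue_labels = [], []
    cols = []
    for tab in cpg_tables:
        df = tab.df
        sid = str(df["sample_id"].iloc[0])
        sample_ids.append(sid)
        tissue_labels.append(str(df["tissue"].iloc[0]))
        col = np.full(len(windows), np.nan)
        by_chrom = {c: g.sort_values("pos") for c, g in df.groupby("chrom")}
        for i, fw in enumerate(windows):
            g = by_chrom.get(fw.window.chrom)
            if g is None:
                continue
            pos0 = g["pos"].to_numpy() - 1  # 1-based CpG pos vs half-open window
            sel = (pos0 >= fw.window.start) & (pos0 < fw.window.end)
            if sel.any():
                col[i] = weighted_methylation(g.loc[sel])
        cols.append(col)
    return SignalMatrix(
        values=np.column_stack(cols),
        feature_ids=[fw.gene_id for fw in windows],
        sample_ids=sample_ids,
        tissue_labels=tissue_labels,
        exclusion_class=list(tissue_labels),
        mark="WGBS",
    )


def select_top_fraction(
    R: SpecificityResult,
    tissue: str,
    k: float,
    windows: Sequence[FeatureWindow],
    mark: str | None = None,
) -> TopFeatureSet:
    """The ceil(k·n) features with largest t for a tissue, ties by feature id.

    Regions are attached from the matching feature windows; a feature without
    a window is an error (the set's regions must align 1:1).
    """
    if not (0 < k <= 1):
        raise ValidationError("k must be in (0, 1]")
    if tissue not in R.t.columns:
        raise ValidationError(f"tissue {tissue!r} not in result")
    n = len(R.t)
    if n * k < 1:
        raise ValidationError(f"n × k = {n * k:.3g} < 1: no feature selectable")
    count = math.ceil(k * n)
    order = (
        R.t[tissue]
        .rename("t")
        .reset_index()
        .sort_values(["t", "feature_id"], ascending=[False, True], kind="stable")
    )
    chosen = order.head(count)["feature_id"].tolist()
    window_by_id = {fw.gene_id: fw.window for fw in windows}
    missing = [f for f in chosen if f not in window_by_id]
    if missing:
        raise ValidationError(f"no window for feature(s): {missing[:5]}")
    return TopFeatureSet(
        tissue=tissue,
        mark=mark if mark is not None else R.mark,
        k=k,
        feature_ids=chosen,
        regions=[window_by_id[f] for f in chosen],
    )
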
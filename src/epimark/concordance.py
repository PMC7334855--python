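"""Cross-matrix comparisons: t-statistic correlations between modalities,
trait–trait correlation of enrichment profiles, and a GAT-style interval
overlap permutation test.

Pearson p-values use the t-transform with df = n−2 throughout; BH q-values
are computed over all cells of a correlation matrix. Cells with fewer than
three paired observations are missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .enrichment import EnrichmentProfile, bh_fdr
from .io_model import GenomicInterval, PeakSet
from .specificity import SpecificityResult

__all__ = [
    "CorrelationMatrix",
    "OverlapTestResult",
    "modality_correlation",
    "trait_correlation",
    "overlap_permutation_test",
]


@dataclass
class CorrelationMatrix:
    """Pearson r, p, BH q and paired-n matrices over row × column labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame
    star_alpha: float = 0.05

    def stars(self, alpha: float | None = None) -> pd.DataFrame:
        return self.q < (self.star_alpha if alpha is None else alpha)

    def write_tsv(self, path: str | Path) -> None:
        long = self.r.stack().rename("r").reset_index()
        long.columns = ["row", "col", "r"]
        long["p"] = self.p.stack().to_numpy()
        long["q"] = self.q.stack().to_numpy()
        long["n"] = self.n.stack().to_numpy()
        long.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class OverlapTestResult:
    observed_bp: int
    null_bp: np.ndarray
    p_emp: float
    fold: float
    n_perm: int
    seed: int | None


def _pearson_grid(
    A: pd.DataFrame, B: pd.DataFrame, min_n: int = 3
) -> CorrelationMatrix:
    """All-pairs Pearson correlation of the columns of A against columns of B,
    pairwise-dropping rows where either value is missing."""
    rows, cols = list(A.columns), list(B.columns)
    r = pd.DataFrame(np.nan, index=rows, columns=cols)
    p = pd.DataFrame(np.nan, index=rows, columns=cols)
    n = pd.DataFrame(0, index=rows, columns=cols)
    for i in rows:
        for j in cols:
            x, y = A[i].to_numpy(float), B[j].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n.loc[i, j] = int(ok.sum())
            if ok.sum() < min_n:
                continue
            res = sps.pearsonr(x[ok], y[ok])
            r.loc[i, j] = res.statistic
            p.loc[i, j] = res.pvalue
    flat = p.to_numpy().ravel()
    finite = np.isfinite(flat)
    q = np.full_like(flat, np.nan)
    if finite.any():
        q[finite] = bh_fdr(np.clip(flat[finite], np.nextafter(0, 1), 1.0))
    qdf = pd.DataFrame(q.reshape(p.shape), index=rows, columns=cols)
    return CorrelationMatrix(r=r, p=p, q=qdf, n=n)


def modality_correlation(
    A: SpecificityResult, B: SpecificityResult, star_alpha: float = 0.001
) -> CorrelationMatrix:
    """Correlate tissue-specificity t-vectors between two modalities.

    Cell (i, j) is the Pearson r of A's tissue-i t-vector against B's
    tissue-j t-vector over the shared-feature intersection. The default star
    threshold of q < 0.001 mirrors the strict FDR convention used when
    validating predicted histone marks against expression/methylation.
    """
    shared = A.t.index.intersection(B.t.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared features; need >= 3 to correlate"
        )
    cm = _pearson_grid(A.t.loc[shared], B.t.loc[shared])
    cm.star_alpha = star_alpha
    return cm


def trait_correlation(
    P: EnrichmentProfile,
    Q: EnrichmentProfile,
    tissue_map: Sequence[tuple[str, str]],
    star_alpha: float = 0.05,
) -> CorrelationMatrix:
    """Correlate two traits' tissue-enrichment profiles over mapped tissues.

    ``tissue_map`` pairs comparable tissue labels between the two profiles
    (e.g. human liver ↔ cattle liver); missing cells are dropped pairwise.
    """
    if len(tissue_map) < 3:
        raise ValidationError("need >= 3 mapped tissue pairs")
    missing_p = [a for a, _ in tissue_map if a not in P.neglog10p.columns]
    missing_q = [b for _, b in tissue_map if b not in Q.neglog10p.columns]
    if missing_p or missing_q:
        raise ValidationError(
            f"unmapped tissue labels: {missing_p + missing_q}"
        )
    # align both profiles on the mapped tissue axis, then correlate trait rows
    Pm = P.neglog10p[[a for a, _ in tissue_map]].T.reset_index(drop=True)
    Qm = Q.neglog10p[[b for _, b in tissue_map]].T.reset_index(drop=True)
    cm = _pearson_grid(Pm, Qm)
    cm.star_alpha = star_alpha
    return cm


# ---------------------------------------------------------------------------
# Interval-overlap permutation test
# ---------------------------------------------------------------------------


def _coverage_index(intervals: Sequence[GenomicInterval]):
    """Merged per-chromosome spans with prefix sums for O(log) overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        lens = arr[:, 1] - arr[:, 0]
        index[chrom] = (arr[:, 0], arr[:, 1], np.concatenate([[0], np.cumsum(lens)]))
    return index


def _overlap_bp(index, chrom: str, start: int, end: int) -> int:
    if chrom not in index:
        return 0
    starts, ends, cum = index[chrom]
    i = np.searchsorted(starts, start, side="right") - 1
    j = np.searchsorted(starts, end, side="left")
    total = 0
    for k in range(max(i, 0), j):
        total += max(0, min(end, ends[k]) - max(start, starts[k]))
    return int(total)


def overlap_permutation_test(
    query: PeakSet,
    annotation: PeakSet,
    workspace: Sequence[GenomicInterval],
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> OverlapTestResult:
    """Significance of base overlap between query segments and an annotation.

    Each permutation independently re-places every query segment uniformly at
    random within the workspace (length preserved; placed segments may overlap
    each other) and records total bp intersection with the annotation. Sampled
    mode uses the add-one upper-tail p; ``exhaustive`` (single-segment queries
    only) enumerates every placement and returns the exact tail probability
    #{placements >= observed}/#placements.
    """
    if not query.intervals:
        raise ValidationError("empty query")
    ann_index = _coverage_index(annotation.intervals)
    ws = [(iv.chrom, iv.start, iv.end) for iv in workspace]
    observed = sum(
        _overlap_bp(ann_index, iv.chrom, iv.start, iv.end) for iv in query.intervals
    )
    seg_lens = [iv.length for iv in query.intervals]
    # placement slots per segment: starts where the segment fits wholly inside
    # one workspace interval
    slots_per_seg = []
    for L in seg_lens:
        slots = [(c, s, (e - s) - L + 1) for c, s, e in ws if (e - s) >= L]
        if not slots:
            raise ValidationError(
                f"segment of length {L} does not fit in any workspace interval"
            )
        slots_per_seg.append(slots)

    if exhaustive:
        if len(query.intervals) != 1:
            raise ValidationError("exhaustive enumeration needs a single segment")
        L = seg_lens[0]
        null = []
        for chrom, wstart, count in slots_per_seg[0]:
            for off in range(count):
                null.append(_overlap_bp(ann_index, chrom, wstart + off, wstart + off + L))
        null = np.asarray(null)
        p = float((null >= observed).sum() / len(null))
        fold = observed / null.mean() if null.mean() > 0 else float("nan")
        return OverlapTestResult(observed, null, p, float(fold), len(null), seed)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    counts_per_seg = [np.array([c for _, _, c in slots]) for slots in slots_per_seg]
    for it in range(n_perm):
        total = 0
        for slots, counts, L in zip(slots_per_seg, counts_per_seg, seg_lens):
            wi = rng.choice(len(slots), p=counts / counts.sum())
            chrom, wstart, count = slots[wi]
            off = int(rng.integers(0, count))
            total += _overlap_bp(ann_index, chrom, wstart + off, wstart + off + L)
        null[it] = total
    p = (int((null >= observed).sum()) + 1) / (n_perm + 1)
    mean_null = null.mean()
    fold = observed / mean_null if mean_null > 0 else float("nan")
    return OverlapTestResult(observed, null, float(p), float(fold), n_perm, seed)
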
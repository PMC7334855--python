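"""Turn per-sample peak sets into a features × samples signal matrix.

Promoter marks (H3K4me3, H3K27ac) are aggregated over strand-aware windows
around the TSS (−1000/+500 bp by default); transcribed-region marks (H3K36me3)
are aggregated over gene bodies of at least 750 bp, normalised per kb of gene
length. The default promoter weighting credits a peak with signal × (overlap
bp / peak length), i.e. the fraction of the peak's signal mass that falls in
the window; binary occupancy and signal × overlap-bp modes are selectable
because the operational definition of "signal intensity in the promoter" is a
modelling choice, not a given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ValidationError
from .io_model import GeneTable, GenomicInterval, PeakSet

logger = logging.getLogger("epimark")

__all__ = [
    "FeatureWindow",
    "SignalMatrix",
    "promoter_window",
    "promoter_windows",
    "genebody_windows",
    "aggregate_promoter_signal",
    "aggregate_genebody_signal",
    "build_signal_matrix",
]


@dataclass
class FeatureWindow:
    """A gene-anchored aggregation window (promoter or gene body)."""

    gene_id: str
    window: GenomicInterval
    kind: str  # promoter | genebody

    def __post_init__(self) -> None:
        if self.kind not in ("promoter", "genebody"):
            raise ValidationError(f"unknown window kind {self.kind!r}")


@dataclass
class SignalMatrix:
    """Features × samples matrix with per-sample tissue and exclusion-class labels.

    Absent signal is an explicit 0 (promoter/gene-body marks) — the matrix is
    dense by construction. NaN is permitted only for methylation features with
    no CpG coverage; downstream consumers drop those rows pairwise.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    tissue_labels: list[str]
    exclusion_class: list[str]
    mark: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValidationError("feature_ids length does not match values")
        for name in ("sample_ids", "tissue_labels", "exclusion_class"):
            if len(getattr(self, name)) != n_samp:
                raise ValidationError(f"{name} not aligned to sample order")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def write_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(values_path, sep="\t")
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "tissue": self.tissue_labels,
                "exclusion_class": self.exclusion_class,
                "mark": self.mark,
            }
        ).to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, values_path: str | Path, meta_path: str | Path) -> "SignalMatrix":
        df = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        mark = str(meta["mark"].iloc[0]) if len(meta) else ""
        return cls(
            values=df.to_numpy(dtype=float),
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            tissue_labels=meta["tissue"].astype(str).tolist(),
            exclusion_class=meta["exclusion_class"].astype(str).tolist(),
            mark=mark,
        )


def promoter_window(
    gene: pd.Series,
    up: int = 1000,
    down: int = 500,
    chrom_len: int | None = None,
) -> FeatureWindow:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    + strand: [TSS−up, TSS+down); − strand genes take the annotation end as
    TSS and the mirrored window [TSS−down, TSS+up).
    """
    if gene["strand"] == "+":
        tss = int(gene["start"])
        lo, hi = tss - up, tss + down
    else:
        tss = int(gene["end"])
        lo, hi = tss - down, tss + up
    lo = max(0, lo)
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return FeatureWindow(
        gene_id=str(gene["gene_id"]),
        window=GenomicInterval(str(gene["chrom"]), lo, hi, str(gene["strand"])),
        kind="promoter",
    )


def promoter_windows(
    genes: GeneTable,
    up: int = 1000,
    down: int = 500,
    chrom_lens: dict[str, int] | None = None,
) -> list[FeatureWindow]:
    """Promoter windows for every gene, in the table's order."""
    lens = chrom_lens or {}
    return [
        promoter_window(row, up, down, lens.get(str(row["chrom"])))
        for _, row in genes.df.iterrows()
    ]


def genebody_windows(genes: GeneTable, min_gene_len: int = 750) -> list[FeatureWindow]:
    """Gene-body windows; genes shorter than ``min_gene_len`` are excluded."""
    out = []
    for _, row in genes.df.iterrows():
        if int(row["end"]) - int(row["start"]) < min_gene_len:
            continue
        out.append(
            FeatureWindow(
                gene_id=str(row["gene_id"]),
                window=GenomicInterval(
                    str(row["chrom"]), int(row["start"]), int(row["end"]),
                    str(row["strand"]),
                ),
                kind="genebody",
            )
        )
    return out


def _window_trees(windows: Sequence[FeatureWindow]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, fw in enumerate(windows):
        trees.setdefault(fw.window.chrom, IntervalTree()).addi(
            fw.window.start, fw.window.end, idx
        )
    return trees


def aggregate_promoter_signal(
    peaks: PeakSet, windows: Sequence[FeatureWindow], mode: str = "fraction"
) -> np.ndarray:
    """Per-window sum of peak signal weighted by the overlapping fraction.

    ``mode='fraction'`` (default): signal × overlap/peak_len; ``'bp'``:
    signal × overlap bp; ``'binary'``: 1 for any overlap. A peak without a
    signal value contributes as signal 1.0 with a warning.
    """
    if any(fw.kind != "promoter" for fw in windows):
        raise ValidationError("aggregate_promoter_signal expects promoter windows")
    if mode not in ("fraction", "bp", "binary"):
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    trees = _window_trees(windows)
    out = np.zeros(len(windows))
    warned = False
    for iv in peaks.intervals:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        signal = iv.signal
        if signal is None:
            if not warned:
                logger.warning(
                    "sample %s: peak(s) without signal treated as signal 1.0",
                    peaks.sample_id,
                )
                warned = True
            signal = 1.0
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if mode == "fraction":
                out[hit.data] += signal * ov / iv.length
            elif mode == "bp":
                out[hit.data] += signal * ov
            else:
                out[hit.data] = 1.0
    return out


def aggregate_genebody_signal(
    peaks: PeakSet, windows: Sequence[FeatureWindow], min_gene_len: int = 750
) -> np.ndarray:
    """Per-gene signal mass per kb of gene body: [Σ signal × overlap bp] / kb."""
    if any(fw.kind != "genebody" for fw in windows):
        raise ValidationError("aggregate_genebody_signal expects genebody windows")
    short = [fw.gene_id for fw in windows if fw.window.length < min_gene_len]
    if short:
        raise ValidationError(
            f"gene-body window(s) shorter than {min_gene_len} bp: {short[:5]}"
        )
    trees = _window_trees(windows)
    out = np.zeros(len(windows))
    for iv in peaks.intervals:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        signal = 1.0 if iv.signal is None else iv.signal
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            out[hit.data] += signal * ov
    lengths_kb = np.array([fw.window.length / 1000.0 for fw in windows])
    return out / lengths_kb


def build_signal_matrix(
    samples: Sequence[PeakSet],
    windows: Sequence[FeatureWindow],
    kind: str = "promoter",
    category_map: dict[str, str] | None = None,
    mode: str = "fraction",
    min_gene_len: int = 750,
) -> SignalMatrix:
    """Aggregate every sample into one matrix; column order = input order.

    ``category_map`` collapses tissue labels into exclusion classes (the
    grouping of related tissues removed together in the specificity fit); a
    sample whose tissue is missing from the map is an error. Without a map each
    tissue is its own class.
    """
    if not samples:
        raise ValidationError("no samples given")
    marks = {ps.mark for ps in samples}
    if len(marks) > 1:
        raise ValidationError(f"mixed histone marks in one matrix: {sorted(marks)}")
    tissue_labels, classes = [], []
    for ps in samples:
        tissue_labels.append(ps.tissue)
        if category_map is None:
            classes.append(ps.tissue)
        else:
            if ps.tissue not in category_map:
                raise ValidationError(
                    f"sample {ps.sample_id!r}: tissue {ps.tissue!r} missing "
                    "from category map"
                )
            classes.append(category_map[ps.tissue])
    cols = []
    for ps in samples:
        if kind == "promoter":
            cols.append(aggregate_promoter_signal(ps, windows, mode=mode))
        elif kind == "genebody":
            cols.append(aggregate_genebody_signal(ps, windows, min_gene_len))
        else:
            raise ValidationError(f"unknown matrix kind {kind!r}")
    return SignalMatrix(
        values=np.column_stack(cols),
        feature_ids=[fw.gene_id for fw in windows],
        sample_ids=[ps.sample_id for ps in samples],
        tissue_labels=tissue_labels,
        exclusion_class=classes,
        mark=marks.pop(),
    )
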
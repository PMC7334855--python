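"""Domain types and readers/writers for the external formats the pipeline touches.

Internal coordinate convention is 0-based half-open throughout (BED). GTF input
(1-based inclusive) is converted on read. GWAS marker positions are kept 1-based
in the ``pos`` column; interval membership tests use ``pos - 1 in [start, end)``.

All readers validate rather than silently coerce: an invariant violation raises
:class:`~epimark.exceptions.ValidationError` naming the offending record, a
malformed line raises :class:`~epimark.exceptions.ParseError` with its line
number. Unknown extra columns are tolerated with a logged warning, since public
peak files drift between dialects.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParseError, ValidationError

logger = logging.getLogger("epimark")

STRANDS = {"+", "-", "."}

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


@dataclass
class GenomicInterval:
    """A half-open genomic interval, optionally carrying a narrowPeak signal.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    signal: float | None = None
    name: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: "
                f"strand {self.strand!r} not in {sorted(STRANDS)}"
            )
        if self.signal is not None and not self.signal >= 0:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: "
                f"signal {self.signal} must be nonnegative"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, start: int, end: int) -> int:
        """Length of the intersection with the half-open window [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class PeakSet:
    """One sample's peak calls plus its metadata (tissue category, histone mark)."""

    intervals: list[GenomicInterval]
    sample_id: str = ""
    tissue: str = ""
    mark: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "PeakSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return PeakSet(ivs, self.sample_id, self.tissue, self.mark)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "signal": [iv.signal for iv in self.intervals],
            }
        )


@dataclass
class GeneTable:
    """Protein-coding gene annotation with derivable TSS.

    Backed by a DataFrame with columns gene_id, chrom, start, end, strand,
    biotype (0-based half-open coordinates).
    """

    df: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand", "biotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"GeneTable missing columns: {missing}")
        df = self.df
        if len(df):
            bad = df[~(df["start"] < df["end"])]
            if len(bad):
                raise ValidationError(
                    f"gene(s) with start >= end: {bad['gene_id'].tolist()[:5]}"
                )
            dup = df["gene_id"][df["gene_id"].duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate gene_id(s): {sorted(set(dup))[:5]}")
            bad_strand = df[~df["strand"].isin(["+", "-"])]
            if len(bad_strand):
                raise ValidationError(
                    "gene(s) with missing/invalid strand: "
                    f"{bad_strand['gene_id'].tolist()[:5]}"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def tss(self) -> pd.Series:
        """Transcription start site: ``start`` on + strand, ``end`` on − strand."""
        df = self.df
        return pd.Series(
            np.where(df["strand"] == "+", df["start"], df["end"]),
            index=df["gene_id"],
            name="tss",
        )


@dataclass
class GwasTable:
    """Genome-ordered GWAS markers; row rank is the marker's circular index.

    ``pos`` is 1-based. Rows are strictly ordered by (chrom_order index, pos)
    with no duplicate (chrom, pos); this ordering defines the circular
    permutation null, so the chromosome order is explicit configuration, never
    inferred from lexical sort.
    """

    df: pd.DataFrame
    chrom_order: list[str]
    trait: str = ""

    def __post_init__(self) -> None:
        df = self.df
        for col in ("marker_id", "chrom", "pos", "stat"):
            if col not in df.columns:
                raise ValidationError(f"GwasTable missing column {col!r}")
        unknown = sorted(set(df["chrom"]) - set(self.chrom_order))
        if unknown:
            raise ValidationError(
                f"chromosome(s) not in chrom_order: {unknown}"
            )
        if not np.isfinite(df["stat"]).all():
            bad = df.loc[~np.isfinite(df["stat"]), "marker_id"].tolist()[:5]
            raise ValidationError(f"non-finite stat for marker(s): {bad}")
        order = pd.Categorical(df["chrom"], categories=self.chrom_order, ordered=True)
        df = df.assign(_c=order.codes).sort_values(
            ["_c", "pos"], kind="stable"
        ).drop(columns="_c")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            bad = df.loc[dup, ["chrom", "pos"]].astype(str).agg(":".join, axis=1)
            raise ValidationError(f"duplicate (chrom,pos): {bad.tolist()[:5]}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def stats(self) -> np.ndarray:
        return self.df["stat"].to_numpy(dtype=float)


@dataclass
class CpgTable:
    """Per-CpG bisulfite counts (meth_reads <= total_reads) with sample metadata."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "meth_reads", "total_reads"):
            if col not in self.df.columns:
                raise ValidationError(f"CpgTable missing column {col!r}")
        bad = self.df[self.df["meth_reads"] > self.df["total_reads"]]
        if len(bad):
            rows = bad[["chrom", "pos"]].astype(str).agg(":".join, axis=1)
            raise ValidationError(
                f"meth_reads > total_reads at: {rows.tolist()[:5]}"
            )
        if (self.df["total_reads"] <= 0).any():
            rows = self.df.loc[self.df["total_reads"] <= 0, ["chrom", "pos"]]
            rows = rows.astype(str).agg(":".join, axis=1)
            raise ValidationError(f"non-positive total_reads at: {rows.tolist()[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RunConfig:
    """Run constants; defaults reproduce the study's printed values.

    promoter window −1000/+500 bp around the TSS, minimum gene-body length
    750 bp, top 5% tissue-specific cut, 10,000 circular permutations, FDR 0.05.
    """

    promoter_up: int = 1000
    promoter_down: int = 500
    min_gene_len: int = 750
    top_fraction: float = 0.05
    n_perm: int = 10_000
    seed: int = 1
    fdr_alpha: float = 0.05
    min_map_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValidationError("top_fraction must be in (0, 1]")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            logger.warning("ignoring unknown config keys: %s", sorted(extra))
        return cls(**{k: v for k, v in data.items() if k in known})


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_intervals(
    path: str | Path,
    dialect: str = "narrowPeak",
    sample_id: str | None = None,
    tissue: str = "",
    mark: str = "",
) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a :class:`PeakSet`.

    narrowPeak signalValue (column 7) populates ``signal``; BED3/BED6 leave it
    absent. Input order is preserved and coordinates stay 0-based half-open.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_COLUMNS[dialect]
    path = Path(path)
    intervals: list[GenomicInterval] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ParseError(
                    f"{path.name} line {lineno}: expected >= {ncols} columns "
                    f"for {dialect}, got {len(fields)}"
                )
            if len(fields) > ncols and not warned_extra:
                logger.warning(
                    "%s line %d: ignoring %d extra column(s)",
                    path.name, lineno, len(fields) - ncols,
                )
                warned_extra = True
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if ncols >= 6 else None
            strand = fields[5] if ncols >= 6 else "."
            score = 0.0
            if ncols >= 6:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name} line {lineno}: non-numeric score"
                    ) from exc
            signal = None
            if dialect == "narrowPeak":
                try:
                    signal = float(fields[6])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name} line {lineno}: non-numeric signalValue"
                    ) from exc
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=fields[0], start=start, end=end, strand=strand,
                        signal=signal, name=name, score=score,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name} line {lineno}: {exc}") from exc
    return PeakSet(
        intervals,
        sample_id=sample_id if sample_id is not None else path.stem,
        tissue=tissue,
        mark=mark,
    )


def write_bed(peaks: PeakSet, path: str | Path, dialect: str = "bed6") -> None:
    """Write a PeakSet as BED6 or narrowPeak; BED6 round-trips coordinates,
    names, scores and strands byte-identically through :func:`read_intervals`."""
    if dialect not in ("bed6", "narrowPeak"):
        raise ValidationError(f"unsupported output dialect {dialect!r}")
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            name = iv.name if iv.name is not None else "."
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"
            if dialect == "narrowPeak":
                signal = iv.signal if iv.signal is not None else 0.0
                fh.write(f"{base}\t{signal:g}\t-1\t-1\t-1\n")
            else:
                fh.write(base + "\n")


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_annotation(path: str | Path, format: str = "gtf") -> GeneTable:
    """Read gene annotation from GTF gene lines or a BED-like TSV.

    GTF 1-based inclusive coordinates are converted to 0-based half-open;
    records whose biotype is not protein_coding are dropped.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if "biotype" not in df.columns:
            df["biotype"] = "protein_coding"
        df = df[df["biotype"] == "protein_coding"]
        return GeneTable(df.reset_index(drop=True))
    if format != "gtf":
        raise ValidationError(f"unknown annotation format {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 9 GTF columns"
                )
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            if biotype != "protein_coding":
                continue
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path.name} line {lineno}: missing or invalid strand"
                )
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path.name} line {lineno}: no gene_id attribute")
            records.append(
                {
                    "gene_id": gene_id,
                    "chrom": fields[0],
                    # GTF is 1-based inclusive; internal is 0-based half-open
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": strand,
                    "biotype": biotype,
                }
            )
    return GeneTable(pd.DataFrame(records, columns=list(GeneTable.REQUIRED)))


def read_gwas_summary(
    path: str | Path,
    chrom_order: Sequence[str],
    trait: str = "",
) -> GwasTable:
    """Read GWAS summary statistics (TSV with header) into genome order.

    ``stat`` is taken from the file or derived as effect/se; the output row
    rank is the marker's circular index for the permutation null.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("marker_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")
    if "stat" not in df.columns:
        if not {"effect", "se"} <= set(df.columns):
            raise ValidationError(
                f"{path.name}: need either 'stat' or ('effect','se') columns"
            )
        zero_se = df[df["se"] == 0]
        if len(zero_se):
            raise ValidationError(
                f"{path.name}: se = 0 for marker(s) "
                f"{zero_se['marker_id'].tolist()[:5]}"
            )
        df["stat"] = df["effect"] / df["se"]
    if "trait" in df.columns and not trait:
        uniq = df["trait"].unique()
        trait = str(uniq[0]) if len(uniq) == 1 else ""
    return GwasTable(df, chrom_order=list(chrom_order), trait=trait)


def read_methylation_counts(path: str | Path) -> CpgTable:
    """Read per-CpG methylation counts; rows with total_reads == 0 are dropped
    with a logged count, meth > total is a validation error."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "meth_reads", "total_reads"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")
    n_zero = int((df["total_reads"] == 0).sum())
    if n_zero:
        logger.info("%s: dropped %d CpG row(s) with zero coverage", path.name, n_zero)
        df = df[df["total_reads"] > 0]
    return CpgTable(df.reset_index(drop=True))
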
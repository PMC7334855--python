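"""Map peak intervals between genomes through UCSC pairwise alignment chains.

A chain file describes colinear ungapped alignment blocks between a source
genome (the chain header's first coordinate triple) and a target genome (the
second triple). Negative-strand target chains are converted on parse so block
target coordinates are always forward-strand, with the original strand kept on
the block.

An interval maps when a single dominant chain covers at least ``min_map_ratio``
of its bases with blocks sharing one target chromosome and strand; the target
is the minimal spanning interval of the mapped pieces, rejected if it expands
beyond twice the source length (which prevents pathological spans across long
target gaps). Transfer efficiency is reported as a peak-count fraction by
default with a base-pair-weighted variant behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ParseError, ValidationError
from .io_model import GenomicInterval, PeakSet

__all__ = [
    "ChainBlock",
    "ChainSet",
    "LiftResult",
    "parse_chain",
    "map_interval",
    "transfer_peaks",
    "transfer_efficiency",
]


@dataclass
class ChainBlock:
    """One ungapped alignment block; equal length on both genomes."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    tgt_strand: str = "+"

    def __post_init__(self) -> None:
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValidationError(
                f"chain block {self.src_chrom}:{self.src_start}-{self.src_end} "
                "has unequal source/target lengths"
            )
        if min(self.src_start, self.tgt_start) < 0:
            raise ValidationError("chain block has negative coordinates")


@dataclass
class ChainSet:
    """Parsed chains: blocks grouped by chain id, with per-chain scores."""

    blocks: dict[int, list[ChainBlock]] = field(default_factory=dict)
    chain_score: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class LiftResult:
    """Outcome of mapping one source interval."""

    source: GenomicInterval
    status: str  # mapped | unmapped | split_rejected
    target: GenomicInterval | None = None
    mapped_fraction: float = 0.0

    def __post_init__(self) -> None:
        if (self.status == "mapped") != (self.target is not None):
            raise ValidationError("status=mapped iff a target interval is present")


def parse_chain(path: str | Path) -> ChainSet:
    """Parse a UCSC chain file into explicit per-block coordinates.

    Data lines (``size [dt dq]``) are expanded by walking both genomes;
    header spans are checked against the block sums.
    """
    path = Path(path)
    chains = ChainSet()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    i = 0
    auto_id = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("chain"):
            raise ParseError(f"{path.name} line {i + 1}: expected chain header")
        head = line.split()
        if len(head) < 12:
            raise ParseError(f"{path.name} line {i + 1}: truncated chain header")
        (score, s_chrom, s_size, s_strand, s_start, s_end,
         t_chrom, t_size, t_strand, t_start, t_end) = head[1:12]
        chain_id = int(head[12]) if len(head) > 12 else (auto_id := auto_id + 1)
        score = float(score)
        s_size, s_start, s_end = int(s_size), int(s_start), int(s_end)
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        if s_strand != "+":
            raise ParseError(
                f"{path.name} line {i + 1}: source strand must be '+'"
            )

        blocks: list[ChainBlock] = []
        cur_s, cur_t = s_start, t_start
        i += 1
        done = False
        while i < len(lines):
            data = lines[i].strip()
            i += 1
            if not data:
                continue
            fields = data.split()
            size = int(fields[0])
            if t_strand == "+":
                tgt_lo, tgt_hi = cur_t, cur_t + size
            else:
                # reverse-strand target coords → forward strand
                tgt_lo, tgt_hi = t_size - (cur_t + size), t_size - cur_t
            blocks.append(
                ChainBlock(
                    src_chrom=s_chrom, src_start=cur_s, src_end=cur_s + size,
                    tgt_chrom=t_chrom, tgt_start=tgt_lo, tgt_end=tgt_hi,
                    tgt_strand=t_strand,
                )
            )
            cur_s += size
            cur_t += size
            if len(fields) == 1:
                done = True
                break
            if len(fields) != 3:
                raise ParseError(
                    f"{path.name} line {i}: expected 'size dt dq' data line"
                )
            cur_s += int(fields[1])
            cur_t += int(fields[2])
        if not done:
            raise ParseError(f"{path.name}: truncated final data line in chain")
        if cur_s != s_end or cur_t != t_end:
            raise ParseError(
                f"{path.name}: chain {chain_id} header span inconsistent with "
                f"block sums (source ends {cur_s} != {s_end} or "
                f"target ends {cur_t} != {t_end})"
            )
        chains.blocks[chain_id] = blocks
        chains.chain_score[chain_id] = score
    return chains


def _map_pieces(
    iv: GenomicInterval, blocks: list[ChainBlock]
) -> tuple[int, list[tuple[int, int]], set[tuple[str, str]]]:
    """Overlap bp, target-coordinate pieces and (chrom,strand) pairs for one chain."""
    covered = 0
    pieces: list[tuple[int, int]] = []
    keys: set[tuple[str, str]] = set()
    for b in blocks:
        if b.src_chrom != iv.chrom:
            continue
        lo = max(iv.start, b.src_start)
        hi = min(iv.end, b.src_end)
        if hi <= lo:
            continue
        covered += hi - lo
        keys.add((b.tgt_chrom, b.tgt_strand))
        if b.tgt_strand == "+":
            pieces.append(
                (b.tgt_start + (lo - b.src_start), b.tgt_start + (hi - b.src_start))
            )
        else:
            pieces.append(
                (b.tgt_start + (b.src_end - hi), b.tgt_start + (b.src_end - lo))
            )
    return covered, pieces, keys


def map_interval(
    iv: GenomicInterval, chains: ChainSet, min_map_ratio: float = 0.5
) -> LiftResult:
    """Map one interval through the chain with maximal base overlap.

    Acceptance rule: the dominant chain covers >= min_map_ratio of the interval
    with a single target chromosome and strand, and the spanning target is at
    most twice the source length. An empty ChainSet yields ``unmapped``.
    """
    if not (0 < min_map_ratio <= 1):
        raise ValidationError("min_map_ratio must be in (0, 1]")
    length = iv.length
    best = None  # (covered, score, chain_id, pieces, keys)
    total_covered = 0
    for cid, blocks in chains.blocks.items():
        covered, pieces, keys = _map_pieces(iv, blocks)
        if covered == 0:
            continue
        total_covered += covered
        cand = (covered, chains.chain_score.get(cid, 0.0), -cid, pieces, keys)
        if best is None or cand[:3] > best[:3]:
            best = cand
    if best is None:
        return LiftResult(source=iv, status="unmapped", mapped_fraction=0.0)

    covered, _, _, pieces, keys = best
    frac = covered / length
    if frac < min_map_ratio:
        # pieces scattered over several chains may still cover the interval,
        # but with no dominant chain the mapping is ambiguous
        status = "split_rejected" if total_covered / length >= min_map_ratio else "unmapped"
        return LiftResult(source=iv, status=status, mapped_fraction=frac)
    if len(keys) > 1:
        return LiftResult(source=iv, status="split_rejected", mapped_fraction=frac)
    tgt_chrom, tgt_strand = next(iter(keys))
    tgt_start = min(p[0] for p in pieces)
    tgt_end = max(p[1] for p in pieces)
    if tgt_end - tgt_start > 2 * length:
        return LiftResult(source=iv, status="split_rejected", mapped_fraction=frac)
    target = GenomicInterval(
        chrom=tgt_chrom, start=tgt_start, end=tgt_end,
        strand=tgt_strand if iv.strand == "." else iv.strand,
        signal=iv.signal, name=iv.name, score=iv.score,
    )
    return LiftResult(source=iv, status="mapped", target=target, mapped_fraction=frac)


def transfer_peaks(
    peaks: PeakSet, chains: ChainSet, min_map_ratio: float = 0.5
) -> tuple[PeakSet, list[LiftResult]]:
    """Map every peak of a sample; the mapped PeakSet keeps signal and metadata."""
    results = [map_interval(iv, chains, min_map_ratio) for iv in peaks.intervals]
    mapped = PeakSet(
        [r.target for r in results if r.status == "mapped"],
        sample_id=peaks.sample_id, tissue=peaks.tissue, mark=peaks.mark,
    )
    return mapped, results


def transfer_efficiency(results: list[LiftResult], weight: str = "count") -> float:
    """Fraction of peaks (or, with ``weight='bp'``, of peak bases) that mapped."""
    if not results:
        raise ValidationError("transfer_efficiency of empty result list")
    if weight == "count":
        return sum(r.status == "mapped" for r in results) / len(results)
    if weight == "bp":
        total = sum(r.source.length for r in results)
        mapped = sum(
            r.mapped_fraction * r.source.length for r in results if r.status == "mapped"
        )
        return mapped / total
    raise ValidationError(f"unknown weight mode {weight!r}")


def write_unmapped_report(results: list[LiftResult], path: str | Path) -> None:
    """TSV report of every lift outcome (source interval, status, mapped_fraction)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tstatus\tmapped_fraction\n")
        for r in results:
            s = r.source
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.name or '.'}\t"
                f"{r.status}\t{r.mapped_fraction:.6g}\n"
            )
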
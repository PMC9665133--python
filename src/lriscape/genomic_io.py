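"""Genomic interval primitives and readers/writers for the formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals (the BED
convention). Readers for 1-based/inclusive dialects convert at parse time via
a ``one_based`` flag so no other module ever sees mixed conventions.

Interaction tables arrive in one of two dialects:

* ``ibed`` — the CHiCAGO-style export with one bait fragment and one
  other-end fragment per row plus read support and score::

      bait_chr  bait_start  bait_end  bait_frag  otherEnd_chr  otherEnd_start
      otherEnd_end  otherEnd_frag  N_reads  score

* ``bedpe`` — standard 10-column BEDPE
  (chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2); the two
  fragment ids are derived from the name field (``baitID|otherID``) or, when
  absent, from the coordinates themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RestrictionFragment",
    "Interaction",
    "TAD",
    "ChromStateSegment",
    "Gene",
    "overlap_length",
    "midpoint",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_interaction_table",
    "write_interaction_table",
    "MidpointIndex",
]

IBED_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_frag",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_frag",
    "N_reads", "score",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class RestrictionFragment:
    """A restriction fragment (e.g., HindIII), the unit of pCHi-C resolution."""

    interval: GenomicInterval
    fragment_id: str

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class Interaction:
    """A bait/other-end fragment pair with read support and caller score.

    ``score`` may be None when the source table lacked a score column; the
    significance filter raises in that case rather than guessing.
    """

    bait: RestrictionFragment
    other_end: RestrictionFragment
    read_count: int = 0
    score: float | None = None
    timepoint: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if self.score is not None and self.score < 0:
            raise ValueError("score must be non-negative")
        if self.bait.fragment_id == self.other_end.fragment_id:
            raise ValueError("bait and other end must be distinct fragments")

    @property
    def inter_chromosomal(self) -> bool:
        return self.bait.interval.chrom != self.other_end.interval.chrom

    @property
    def pair_id(self) -> tuple[str, str]:
        """Unordered fragment-pair identity used for replicate/time-point matching."""
        a, b = self.bait.fragment_id, self.other_end.fragment_id
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class TAD:
    interval: GenomicInterval
    tad_id: str


@dataclass(frozen=True)
class ChromStateSegment:
    interval: GenomicInterval
    state: str


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    strand: str = "unknown"
    bait_fragment_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"invalid strand {self.strand!r}")


def midpoint(interval: GenomicInterval) -> int:
    return interval.midpoint


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


# ---------------------------------------------------------------------------
# BED


def read_bed_intervals(
    path: str | Path,
    with_name: bool = False,
    one_based: bool = False,
) -> list[GenomicInterval] | tuple[list[GenomicInterval], list[str]]:
    """Read BED3/BED4 intervals, preserving input order.

    With ``one_based=True`` the coordinates are interpreted as 1-based
    inclusive and converted (start-1, end) to the internal convention.
    """
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            if one_based:
                start -= 1
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if with_name:
                names.append(fields[3] if len(fields) > 3 else f"feature_{lineno}")
    if with_name:
        return intervals, names
    return intervals


def write_bed_intervals(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                row.append(str(names[i]))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Interaction tables


def _fragment(chrom: str, start: int, end: int, frag_id: str, path, lineno) -> RestrictionFragment:
    try:
        return RestrictionFragment(GenomicInterval(chrom, start, end), str(frag_id))
    except ValueError as exc:
        raise ValueError(f"{path}, line {lineno}: {exc}") from exc


def read_interaction_table(
    path: str | Path,
    format_hint: str = "ibed",
    timepoint: str = "",
    replicate: str = "",
    one_based: bool = False,
) -> list[Interaction]:
    """Read an interaction table in the ``ibed`` or ``bedpe`` dialect.

    Inter-chromosomal rows are retained (flagged via
    :attr:`Interaction.inter_chromosomal`); dropping them is the job of the
    explicit significance filter so that every removal is audited.
    """
    if format_hint not in {"ibed", "bedpe"}:
        raise ValueError(f"unknown interaction format {format_hint!r}")
    out: list[Interaction] = []
    off = 1 if one_based else 0
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if format_hint == "ibed":
                if not header_seen and f[0] == "bait_chr":
                    header_seen = True
                    continue
                if len(f) < 10:
                    raise ValueError(f"{path}, line {lineno}: expected 10 ibed columns")
                bait = _fragment(f[0], int(f[1]) - off, int(f[2]), f[3], path, lineno)
                oe = _fragment(f[4], int(f[5]) - off, int(f[6]), f[7], path, lineno)
                reads = int(f[8])
                score = None if f[9] in ("", ".", "NA") else float(f[9])
            else:  # bedpe
                if len(f) < 6:
                    raise ValueError(f"{path}, line {lineno}: expected >=6 BEDPE columns")
                name = f[6] if len(f) > 6 and f[6] not in (".", "") else None
                if name and "|" in name:
                    bait_id, oe_id = name.split("|", 1)
                else:
                    bait_id = f"{f[0]}:{int(f[1]) - off}-{f[2]}"
                    oe_id = f"{f[3]}:{int(f[4]) - off}-{f[5]}"
                bait = _fragment(f[0], int(f[1]) - off, int(f[2]), bait_id, path, lineno)
                oe = _fragment(f[3], int(f[4]) - off, int(f[5]), oe_id, path, lineno)
                score = None
                if len(f) > 7 and f[7] not in (".", "", "NA"):
                    score = float(f[7])
                reads = int(f[10]) if len(f) > 10 else 0
            try:
                out.append(
                    Interaction(bait, oe, read_count=reads, score=score,
                                timepoint=timepoint, replicate=replicate)
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_interaction_table(path: str | Path, interactions: Iterable[Interaction]) -> None:
    """Write interactions as headered ibed TSV (round-trips bit-exactly)."""
    with open(path, "w") as fh:
        fh.write("\t".join(IBED_COLUMNS) + "\n")
        for x in interactions:
            b, o = x.bait, x.other_end
            score = "NA" if x.score is None else repr(float(x.score))
            fh.write(
                "\t".join(
                    [
                        b.interval.chrom, str(b.interval.start), str(b.interval.end),
                        b.fragment_id,
                        o.interval.chrom, str(o.interval.start), str(o.interval.end),
                        o.fragment_id,
                        str(x.read_count), score,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Midpoint lookup over non-overlapping intervals


class MidpointIndex:
    """Assign positions to members of a non-overlapping interval set.

    Built once per chromosome from sorted starts/ends; lookups are
    ``searchsorted`` so annotating thousands of fragments against TADs or
    bins stays O(log n) each.
    """

    def __init__(self, intervals: Sequence[GenomicInterval], ids: Sequence[str] | None = None):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if ids is None:
            ids = [f"iv{i}" for i in range(len(intervals))]
        per: dict[str, list[tuple[int, int, str]]] = {}
        for iv, name in zip(intervals, ids):
            per.setdefault(iv.chrom, []).append((iv.start, iv.end, name))
        for chrom, rows in per.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._by_chrom[chrom] = (starts, ends, np.array([r[2] for r in rows], dtype=object))

    def lookup(self, chrom: str, pos: int) -> str | None:
        """Return the id of the interval containing ``pos``, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, names = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return str(names[i])
        return None

    def lookup_many(self, chroms: Sequence[str], positions: Sequence[int]) -> list[str | None]:
        return [self.lookup(c, p) for c, p in zip(chroms, positions)]
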
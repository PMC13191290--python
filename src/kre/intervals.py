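"""Genomic interval arithmetic and BED/BEDPE readers and writers.

All coordinates are 0-based half-open (BED convention). Any 1-based input
must be converted at the reader boundary; nothing downstream ever sees a
1-based coordinate. Strand is ignored: element logic in this package is
strand-free, and TSS orientation travels separately in the TSS table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree


class BedParseError(ValueError):
    """Raised for malformed BED/BEDPE records; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally carrying an id."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ContactPair:
    """A chromatin contact: promoter-side bait anchor and distal other end."""

    bait: GenomicInterval
    other: GenomicInterval
    score: float | None = None


@dataclass
class IntervalSet:
    """An ordered collection of intervals with optional sortedness guarantee.

    ids, where present, must be unique within a set.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    sorted: bool = False

    def __post_init__(self) -> None:
        ids = [iv.id for iv in self.intervals if iv.id is not None]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate interval ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sort(self) -> "IntervalSet":
        """Return a copy sorted by (chrom, start, end)."""
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(ivs, sorted=True)

    def ids(self) -> list[str | None]:
        return [iv.id for iv in self.intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if overlapping or adjacent.

    Returns None across chromosomes (distance is undefined there).
    """
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    earlier, later = (a, b) if a.start <= b.start else (b, a)
    return max(0, later.start - earlier.end)


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Merge overlapping or touching intervals; output sorted and disjoint.

    Touching intervals (gap 0) merge, matching common peak-merging practice.
    Merged intervals drop ids (a merged region has no single source record).
    """
    if len(s) == 0:
        return IntervalSet([], sorted=True)
    ivs = sorted(s.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(out, sorted=True)


def build_trees(s: IntervalSet | Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for repeated overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in s:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def intersect_flags(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Boolean vector over query: entry i true iff query[i] overlaps any subject.

    Overlap threshold is >= 1 bp.
    """
    trees = build_trees(subject)
    flags = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            flags[i] = True
    return flags


# ---------------------------------------------------------------------------
# readers / writers


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\r").split("\t")


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED4+ into an IntervalSet, preserving file order.

    Lines starting with '#', 'track' or 'browser' are skipped. Column 4, if
    present and non-empty, becomes the interval id.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"({fields[1]!r}, {fields[2]!r})"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, sorted=False)


def write_bed(s: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED3/BED4 with LF line endings and no trailing tab."""
    with open(path, "w", newline="\n") as fh:
        for iv in s:
            if iv.id is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def read_bedpe(path: str | Path) -> list[ContactPair]:
    """Read 6+-column BEDPE into ContactPairs (cols 1-3 bait, 4-6 other end).

    Column 7, when present and numeric, is kept as the contact score.
    """
    pairs: list[ContactPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: BEDPE needs >=6 columns, got {len(fields)}"
                )
            try:
                bait = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                other = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            score: float | None = None
            if len(fields) >= 7 and fields[6] not in ("", "."):
                try:
                    score = float(fields[6])
                except ValueError:
                    score = None
            pairs.append(ContactPair(bait, other, score))
    return pairs


def write_bedpe(pairs: Sequence[ContactPair], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for p in pairs:
            cols = [
                p.bait.chrom, str(p.bait.start), str(p.bait.end),
                p.other.chrom, str(p.other.start), str(p.other.end),
            ]
            if p.score is not None:
                cols.append(f"{p.score:g}")
            fh.write("\t".join(cols) + "\n")
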
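"""Genomic interval primitives and plain-text interval I/O.

All coordinates are 0-based, half-open (BED convention). Formats using
1-based coordinates must be converted at the boundary before constructing
:class:`GenomeRegion` objects.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomeRegion:
    """A half-open genomic interval ``[start, end)`` on a named sequence.

    The analysis universe is the set of tiled loci covered by the screening
    library; every downstream statistic (peaks, shuffles, conservation) is
    confined to these regions.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomeRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomeRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def read_bed(path: str | Path | io.TextIOBase) -> list[GenomeRegion]:
    """Read BED3+ intervals; extra columns beyond the name are ignored."""
    regions = []
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else None
            regions.append(GenomeRegion(parts[0], start, end, name))
    finally:
        if close:
            handle.close()
    return regions


def write_bed(
    regions: Iterable[GenomeRegion],
    path: str | Path,
    scores: Sequence[float] | None = None,
    strand: str = ".",
) -> None:
    """Write intervals as BED3, BED4 (named) or BED6 (named + scored)."""
    regions = list(regions)
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or scores is not None:
                cols.append(r.name if r.name is not None else f"region_{i}")
            if scores is not None:
                cols.extend([f"{scores[i]:g}", strand])
            fh.write("\t".join(cols) + "\n")


def sort_regions(regions: Iterable[GenomeRegion]) -> list[GenomeRegion]:
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end))


def merge_regions(regions: Iterable[GenomeRegion], gap: int = 0) -> list[GenomeRegion]:
    """Merge intervals overlapping or within ``gap`` bp of each other."""
    merged: list[GenomeRegion] = []
    for r in sort_regions(regions):
        if merged and r.chrom == merged[-1].chrom and r.start <= merged[-1].end + gap:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = GenomeRegion(last.chrom, last.start, r.end, last.name)
        else:
            merged.append(r)
    return merged


def total_length(regions: Iterable[GenomeRegion]) -> int:
    return sum(len(r) for r in regions)
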
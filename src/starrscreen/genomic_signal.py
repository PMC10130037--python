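"""Fragment ingestion, normalized coverage tracks and cross-sample statistics.

A STARR-seq screen quantifies enhancer activity as the abundance of
self-transcribed reporter RNA relative to the input DNA library. The atomic
evidence unit on both sides is the sequenced *fragment*: one mapped library
insert, represented here by its genomic interval, originating sample and
multiplicity. This module turns fragment interval files into normalized
per-base coverage tracks (fragments per million), 1 kb binned vectors with
Pearson correlation matrices, per-base log2(RNA/DNA) fold-change tracks and
cumulative coverage-depth profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .intervals import GenomeRegion, sort_regions

logger = logging.getLogger(__name__)

SCALE_NUMERATOR = 1_000_000.0  # coverage normalized to fragments per million


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced library fragment (full insert span).

    ``count`` is the multiplicity of the record (e.g. after PCR duplication);
    deduplication collapses identical intervals within a sample to count 1.
    """

    region: GenomeRegion
    sample_id: str
    mapq: int = 255
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("fragment count must be >= 1")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass(frozen=True)
class SampleMeta:
    """Sample bookkeeping: RNA samples are per-animal, DNA inputs per replicate."""

    sample_id: str
    role: Literal["rna", "dna_input"]
    animal_id: str | None = None
    replicate: int | None = None
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.role == "rna" and self.animal_id is None:
            raise ValueError("rna sample requires animal_id")
        if self.role == "dna_input" and self.replicate is None:
            raise ValueError("dna_input sample requires replicate")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be > 0")


class CoverageTrack:
    """Per-base coverage over a fixed region set, in fragments per million.

    ``values[i][b]`` is the normalized depth at base ``regions[i].start + b``.
    The scale factor is 1,000,000 / total mapped fragments, so tracks from
    libraries of different depth are directly comparable.
    """

    def __init__(
        self,
        regions: Sequence[GenomeRegion],
        values: Sequence[np.ndarray],
        scale_factor: float = 1.0,
    ):
        if len(regions) != len(values):
            raise ValueError("one value array per region required")
        for r, v in zip(regions, values):
            if len(v) != len(r):
                raise ValueError(f"array length {len(v)} != region length {len(r)}")
        self.regions = list(regions)
        self.values = [np.asarray(v, dtype=float) for v in values]
        self.scale_factor = float(scale_factor)

    def total_bases(self) -> int:
        return sum(len(v) for v in self.values)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.values) if self.values else np.array([])


class FoldChangeTrack:
    """Per-base log2((rna+pc)/(dna+pc)) with a mask for uncovered positions.

    ``mask[i][b]`` is True where the value is undefined (position uncovered in
    both samples when masking is enabled); masked bases are excluded from bin
    means and interval averages rather than treated as zero.
    """

    def __init__(
        self,
        regions: Sequence[GenomeRegion],
        values: Sequence[np.ndarray],
        mask: Sequence[np.ndarray],
        pseudocount: float = 1.0,
    ):
        self.regions = list(regions)
        self.values = [np.asarray(v, dtype=float) for v in values]
        self.mask = [np.asarray(m, dtype=bool) for m in mask]
        self.pseudocount = float(pseudocount)
        for v, m in zip(self.values, self.mask):
            if v.shape != m.shape:
                raise ValueError("value/mask shape mismatch")
            if not np.all(np.isfinite(v[~m])):
                raise ValueError("unmasked fold-change values must be finite")

    def concatenated(self) -> np.ndarray:
        out = np.concatenate(self.values) if self.values else np.array([])
        msk = np.concatenate(self.mask) if self.mask else np.array([], dtype=bool)
        out = out.copy()
        out[msk] = np.nan
        return out


@dataclass
class BinnedVector:
    """Mean signal per fixed-width bin tiling the region set left to right."""

    bins: list[GenomeRegion]
    values: np.ndarray  # NaN where a bin has no unmasked base

    def __len__(self) -> int:
        return len(self.bins)


def load_fragments(
    path: str | Path,
    regions: Sequence[GenomeRegion],
    min_mapq: int = 3,
    sample_id: str | None = None,
) -> list[FragmentRecord]:
    """Read fragment intervals from a BED-like file and filter them.

    Expected columns: chrom, start, end, then optionally name and mapq
    (5th column). Fragments with ``mapq < min_mapq`` or not overlapping any
    region are discarded; discarded out-of-region records are counted and
    logged. Output is sorted by (chrom, start, end).
    """
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    by_chrom: dict[str, list[GenomeRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    kept: list[FragmentRecord] = []
    n_outside = 0
    n_lowq = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                mapq = int(float(parts[4])) if len(parts) > 4 else 255
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: unparseable record") from exc
            frag = GenomeRegion(parts[0], start, end)
            if mapq < min_mapq:
                n_lowq += 1
                continue
            if not any(frag.overlaps(r) for r in by_chrom.get(frag.chrom, ())):
                n_outside += 1
                continue
            kept.append(FragmentRecord(frag, sample_id, mapq=mapq))
    if n_outside:
        logger.info("%s: %d fragments outside the tiled regions dropped", path, n_outside)
    if n_lowq:
        logger.info("%s: %d fragments below MAPQ %d dropped", path, n_lowq, min_mapq)
    if not kept:
        logger.warning("%s: no fragments retained", path)
    kept.sort(key=lambda f: (f.region.chrom, f.region.start, f.region.end))
    return kept


def deduplicate_fragments(frags: Iterable[FragmentRecord]) -> list[FragmentRecord]:
    """Collapse identical (chrom, start, end, sample) records to count 1.

    Mirrors duplicate-read removal: PCR copies of one insert carry no extra
    evidence. Dedup is sample-scoped; the same interval observed in two
    samples stays in both.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[FragmentRecord] = []
    for f in frags:
        key = (f.region.chrom, f.region.start, f.region.end, f.sample_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            f if f.count == 1 else FragmentRecord(f.region, f.sample_id, f.mapq, 1)
        )
    return out


def coverage_track(
    frags: Iterable[FragmentRecord],
    regions: Sequence[GenomeRegion],
    total_mapped: int,
) -> CoverageTrack:
    """Per-base fragment coverage scaled to fragments per million.

    The full insert span contributes to depth (fragment-level coverage, not
    per-read), via a +1/−1 difference array and prefix sum per region.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    scale = SCALE_NUMERATOR / total_mapped
    diffs = [np.zeros(len(r) + 1) for r in regions]
    for f in frags:
        for i, r in enumerate(regions):
            if not f.region.overlaps(r):
                continue
            lo = max(f.region.start, r.start) - r.start
            hi = min(f.region.end, r.end) - r.start
            diffs[i][lo] += f.count
            diffs[i][hi] -= f.count
    values = [np.cumsum(d[:-1]) * scale for d in diffs]
    return CoverageTrack(regions, values, scale_factor=scale)


def raw_coverage_track(
    frags: Iterable[FragmentRecord], regions: Sequence[GenomeRegion]
) -> CoverageTrack:
    """Unnormalized per-base fragment depth (scale factor exactly 1)."""
    return coverage_track(list(frags), regions, total_mapped=int(SCALE_NUMERATOR))


def _track_arrays(track: CoverageTrack | FoldChangeTrack) -> list[np.ndarray]:
    """Per-region arrays with NaN at masked positions."""
    if isinstance(track, FoldChangeTrack):
        out = []
        for v, m in zip(track.values, track.mask):
            a = v.copy()
            a[m] = np.nan
            out.append(a)
        return out
    return track.values


def make_bins(regions: Sequence[GenomeRegion], bin_width: int) -> list[GenomeRegion]:
    """Tile each region left to right; the last bin of a region may be short."""
    bins = []
    for r in regions:
        for s in range(r.start, r.end, bin_width):
            bins.append(GenomeRegion(r.chrom, s, min(s + bin_width, r.end)))
    return bins


def bin_and_correlate(
    tracks: Sequence[CoverageTrack | FoldChangeTrack],
    regions: Sequence[GenomeRegion],
    bin_width: int = 1000,
) -> tuple[list[BinnedVector], np.ndarray]:
    """Mean signal per bin for each track, plus the Pearson matrix.

    Bin value is the mean over unmasked bases in the bin; a bin with no
    unmasked base is NaN and is excluded pairwise from the correlation. A
    pair with fewer than two common bins yields a NaN entry. The matrix is
    symmetric with unit diagonal.
    """
    if len(tracks) < 2:
        raise ValueError("need >= 2 tracks to correlate")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    bins = make_bins(regions, bin_width)
    binned: list[BinnedVector] = []
    for t in tracks:
        arrays = _track_arrays(t)
        vals = []
        for ri, r in enumerate(regions):
            a = arrays[ri]
            for s in range(0, len(r), bin_width):
                chunk = a[s : s + bin_width]
                ok = ~np.isnan(chunk)
                vals.append(chunk[ok].mean() if ok.any() else np.nan)
        binned.append(BinnedVector(bins, np.array(vals)))

    n = len(tracks)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = binned[i].values, binned[j].values
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2:
                r = np.nan
            else:
                xs, ys = x[ok], y[ok]
                sx, sy = xs.std(), ys.std()
                if sx == 0 or sy == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(xs, ys)[0, 1])
            mat[i, j] = mat[j, i] = r
    return binned, mat


def fold_change_track(
    rna: CoverageTrack,
    dna: CoverageTrack,
    pseudocount: float = 1.0,
    mask_uncovered: bool = True,
) -> FoldChangeTrack:
    """Per-base log2((rna + pc)/(dna + pc)) enhancer-activity signal.

    With ``mask_uncovered`` positions where both samples have zero depth are
    masked (skip-non-covered semantics); with pc=0 any position with a zero
    on either side is masked to keep values finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if [(r.chrom, r.start, r.end) for r in rna.regions] != [
        (r.chrom, r.start, r.end) for r in dna.regions
    ]:
        raise ValueError("rna and dna tracks must be on identical regions")
    values, masks = [], []
    for rv, dv in zip(rna.values, dna.values):
        mask = np.zeros(len(rv), dtype=bool)
        if mask_uncovered:
            mask |= (rv == 0) & (dv == 0)
        if pseudocount == 0:
            mask |= (rv == 0) | (dv == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log2((rv + pseudocount) / (dv + pseudocount))
        v[mask] = 0.0
        values.append(v)
        masks.append(mask)
    return FoldChangeTrack(rna.regions, values, masks, pseudocount=pseudocount)


def coverage_depth_profile(
    track: CoverageTrack, thresholds: Sequence[float]
) -> list[float]:
    """Fraction of bases in the region union covered at >= each threshold.

    Intended for the raw-count track (scale factor 1); fractions are
    monotonically non-increasing as thresholds rise.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    depths = track.concatenated()
    n = len(depths)
    if n == 0:
        return [float("nan")] * len(thresholds)
    return [float(np.count_nonzero(depths >= t)) / n for t in thresholds]
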
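"""Shuffled-null enrichment statistics, conservation comparison and repeat classes.

The null model for every overlap and conservation question is positional:
candidate enhancer peaks are randomly repositioned *within the screened
loci* (never genome-wide), preserving each peak's length and pairwise
disjointness. 1000 such shuffled sets are generated, each from its own
random stream seeded with the square of the trial number so any single
trial is reproducible in isolation. Observed overlap counts are compared to
the null by a moment-matched Z-score and by the add-one empirical p-value
(1 + #{null >= obs}) / (n + 1), which is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeRegion, sort_regions

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """A labelled annotation track (histone mark, open chromatin, repeat class)."""

    label: str
    intervals: list[GenomeRegion]

    def __post_init__(self) -> None:
        self.intervals = sort_regions(self.intervals)


@dataclass
class ShuffleConfig:
    n_sets: int = 1000
    max_tries: int = 10000
    universe: list[GenomeRegion] = field(default_factory=list)
    require_disjoint: bool = True

    @staticmethod
    def seed_for_trial(trial: int) -> int:
        return trial * trial

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if not self.universe:
            raise ValueError("universe must be non-empty")


@dataclass
class EnrichmentResult:
    label: str
    observed: int
    null_values: np.ndarray
    z: float  # NaN when the null sd is zero
    p_emp: float  # add-one empirical p for the direction of the effect
    p_emp_enrich: float
    p_emp_deplete: float
    direction: str  # "enriched" | "depleted" | "none"
    per_peak_hits: np.ndarray | None = None


@dataclass
class ConservationResult:
    peak_means: np.ndarray
    null_means: np.ndarray
    statistic: float
    p_value: float
    ecdf_peaks: tuple[np.ndarray, np.ndarray]
    ecdf_null: tuple[np.ndarray, np.ndarray]


class ShufflePlacementError(RuntimeError):
    pass


def shuffle_peaks(
    peaks: Sequence[GenomeRegion],
    config: ShuffleConfig,
    trial: int,
) -> list[GenomeRegion]:
    """One length-preserving random repositioning of the peaks in the universe.

    Each interval keeps its length, lands entirely inside a universe region,
    and (by default) overlaps no other shuffled interval; placement is
    uniform over feasible starts — the target region is drawn with
    probability proportional to its feasible-start count — with rejection
    sampling against already-placed intervals, up to max_tries attempts.
    The generator is seeded with trial**2.
    """
    universe = sort_regions(config.universe)
    total_peak = sum(len(p) for p in peaks)
    total_universe = sum(len(u) for u in universe)
    if total_peak >= total_universe:
        raise ValueError("peaks do not fit inside the universe")
    rng = np.random.default_rng(ShuffleConfig.seed_for_trial(trial))
    placed: dict[str, list[tuple[int, int]]] = {}
    out: list[GenomeRegion] = []
    for peak in peaks:
        L = len(peak)
        slots = np.array([len(u) - L + 1 for u in universe])
        slots = np.maximum(slots, 0)
        if slots.sum() == 0:
            raise ShufflePlacementError(
                f"no universe region can hold interval of length {L}"
            )
        weights = slots / slots.sum()
        for _ in range(config.max_tries):
            ui = rng.choice(len(universe), p=weights)
            u = universe[ui]
            start = int(u.start + rng.integers(0, slots[ui]))
            end = start + L
            if config.require_disjoint and any(
                start < e and s < end for s, e in placed.get(u.chrom, ())
            ):
                continue
            placed.setdefault(u.chrom, []).append((start, end))
            out.append(GenomeRegion(u.chrom, start, end, peak.name))
            break
        else:
            raise ShufflePlacementError(
                f"could not place interval {peak.chrom}:{peak.start}-{peak.end} "
                f"after {config.max_tries} tries"
            )
    return out


def _interval_index(features: Sequence[GenomeRegion]):
    """Per-chromosome sorted (starts, ends) arrays for overlap queries."""
    by_chrom: dict[str, list[GenomeRegion]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    out = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda r: (r.start, r.end))
        starts = np.array([r.start for r in items])
        ends = np.array([r.end for r in items])
        # running max of ends handles nested intervals
        out[chrom] = (starts, np.maximum.accumulate(ends), ends)
    return out


def per_peak_hit_counts(
    peaks: Sequence[GenomeRegion], features: FeatureSet | Sequence[GenomeRegion]
) -> np.ndarray:
    """Number of feature intervals overlapping each peak by >= 1 bp."""
    intervals = features.intervals if isinstance(features, FeatureSet) else features
    index = _interval_index(intervals)
    hits = np.zeros(len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        entry = index.get(p.chrom)
        if entry is None:
            continue
        starts, _, ends = entry
        lo = 0  # conservative scan window via sorted starts
        hi = np.searchsorted(starts, p.end, side="left")
        hits[i] = int(np.count_nonzero(ends[lo:hi] > p.start))
    return hits


def overlap_statistic(
    peaks: Sequence[GenomeRegion], features: FeatureSet | Sequence[GenomeRegion]
) -> int:
    """Number of peaks overlapping >= 1 feature interval by >= 1 bp."""
    return int(np.count_nonzero(per_peak_hit_counts(peaks, features) > 0))


def make_shuffle_ensemble(
    peaks: Sequence[GenomeRegion], config: ShuffleConfig
) -> list[list[GenomeRegion]]:
    """The full null ensemble: shuffles for trials 1..n_sets."""
    return [shuffle_peaks(peaks, config, trial) for trial in range(1, config.n_sets + 1)]


def enrichment_test(
    peaks: Sequence[GenomeRegion],
    features: FeatureSet,
    config: ShuffleConfig,
    ensemble: Sequence[Sequence[GenomeRegion]] | None = None,
) -> EnrichmentResult:
    """Observed overlap vs the shuffled null: Z-score and empirical p.

    Z is computed by fitting a normal to the null overlap counts (moment
    matching); the empirical p uses the add-one estimator in the direction
    indicated by the sign of the deviation, so depletion (negative Z) is
    detected symmetrically with enrichment.
    """
    if config.n_sets < 100:
        logger.warning("n_sets=%d < 100: null sd may be unstable", config.n_sets)
    if ensemble is None:
        ensemble = make_shuffle_ensemble(peaks, config)
    hits = per_peak_hit_counts(peaks, features)
    observed = int(np.count_nonzero(hits > 0))
    null = np.array([overlap_statistic(s, features) for s in ensemble])
    sd = null.std(ddof=1) if len(null) > 1 else 0.0
    z = (observed - null.mean()) / sd if sd > 0 else float("nan")
    n = len(null)
    p_enrich = (1 + int(np.count_nonzero(null >= observed))) / (n + 1)
    p_deplete = (1 + int(np.count_nonzero(null <= observed))) / (n + 1)
    if observed > null.mean():
        direction, p_emp = "enriched", p_enrich
    elif observed < null.mean():
        direction, p_emp = "depleted", p_deplete
    else:
        direction, p_emp = "none", 1.0
    return EnrichmentResult(
        label=features.label,
        observed=observed,
        null_values=null,
        z=float(z),
        p_emp=float(p_emp),
        p_emp_enrich=float(p_enrich),
        p_emp_deplete=float(p_deplete),
        direction=direction,
        per_peak_hits=hits,
    )


def interval_mean_scores(
    score_track: "BaseScoreTrack",
    intervals: Sequence[GenomeRegion],
) -> np.ndarray:
    """Mean of defined base scores per interval (order-preserving, NaN if none)."""
    out = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        vals = score_track.values_in(iv)
        ok = ~np.isnan(vals)
        out[i] = vals[ok].mean() if ok.any() else np.nan
    return out


class BaseScoreTrack:
    """Base-wise float scores (e.g. conservation) over the screened regions.

    Stored as one array per region; bases without a score are NaN and are
    excluded from interval means.
    """

    def __init__(self, regions: Sequence[GenomeRegion], values: Sequence[np.ndarray]):
        for r, v in zip(regions, values):
            if len(v) != len(r):
                raise ValueError("array length must match region length")
        self.regions = list(regions)
        self.values = [np.asarray(v, dtype=float) for v in values]

    def values_in(self, interval: GenomeRegion) -> np.ndarray:
        chunks = []
        for r, v in zip(self.regions, self.values):
            if interval.overlaps(r):
                lo = max(interval.start, r.start) - r.start
                hi = min(interval.end, r.end) - r.start
                chunks.append(v[lo:hi])
        return np.concatenate(chunks) if chunks else np.array([])

    @classmethod
    def from_bedgraph(cls, path, regions: Sequence[GenomeRegion]) -> "BaseScoreTrack":
        values = [np.full(len(r), np.nan) for r in regions]
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                s, e, v = int(s), int(e), float(v)
                for r, arr in zip(regions, values):
                    if r.chrom == chrom and s < r.end and r.start < e:
                        lo = max(s, r.start) - r.start
                        hi = min(e, r.end) - r.start
                        arr[lo:hi] = v
        return cls(regions, values)


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x[~np.isnan(x)])
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def conservation_compare(
    peaks: Sequence[GenomeRegion],
    shuffles: Sequence[Sequence[GenomeRegion]],
    score_track: BaseScoreTrack,
    alternative: str = "two-sided",
) -> ConservationResult:
    """Rank-sum comparison of per-peak mean scores vs pooled shuffled intervals.

    Wilcoxon rank-sum (Mann-Whitney U): exact null when both samples have
    <= 8 untied observations, otherwise the tie-corrected normal
    approximation. ECDF curves of both samples are returned for plotting.
    """
    if not shuffles:
        raise ValueError("need >= 1 shuffle set")
    x = interval_mean_scores(score_track, peaks)
    y = np.concatenate([interval_mean_scores(score_track, s) for s in shuffles])
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("score vectors must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return ConservationResult(x, y, float(u), 1.0, _ecdf(x), _ecdf(y))
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return ConservationResult(
        peak_means=x,
        null_means=y,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ecdf_peaks=_ecdf(x),
        ecdf_null=_ecdf(y),
    )


def repeat_class_enrichment(
    peaks: Sequence[GenomeRegion],
    repeat_sets: Sequence[FeatureSet],
    config: ShuffleConfig,
) -> list[EnrichmentResult]:
    """Enrichment/depletion per repeat class against one shared shuffle ensemble.

    Results are sorted by |z| descending (NaN z last); classes with no
    intervals report observed 0 and undefined z.
    """
    ensemble = make_shuffle_ensemble(peaks, config)
    results = [
        enrichment_test(peaks, fs, config, ensemble=ensemble) for fs in repeat_sets
    ]
    results.sort(key=lambda r: (np.isnan(r.z), -abs(r.z) if not np.isnan(r.z) else 0))
    return results
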
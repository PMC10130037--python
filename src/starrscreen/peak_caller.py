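"""Covariate-adjusted sliding-window enhancer peak calling and consensus filtering.

The detection model: tile the screened loci with 500 bp windows stepped by
100 bp, count RNA and input-DNA fragments per window, and regress the RNA
count on log input abundance and window GC content under a Poisson working
model (iteratively reweighted least squares). Windows where the observed RNA
count sits in the extreme upper tail of a negative-binomial distribution
around the model expectation — i.e. where transcription exceeds what basal,
input-proportional background predicts — are significant; after
Benjamini–Hochberg correction they are merged into peaks.

Reproducibility filtering then mirrors the screen design: peaks must be
called against more than one input-DNA technical replicate within an animal,
and the final set is the across-animal consensus (peaks found in all five
animals), which is the screen's principal reproducibility guarantee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_signal import FragmentRecord
from .intervals import GenomeRegion

logger = logging.getLogger(__name__)

_GC_BASES = frozenset("GCgc")
_AT_BASES = frozenset("ATat")


@dataclass(frozen=True)
class Window:
    region: GenomeRegion
    gc: float  # G+C fraction among unambiguous bases, in [0, 1]


@dataclass
class WindowStats:
    """Per-window counts and test results; the peak caller's substrate."""

    window: Window
    rna_count: int
    dna_count: int
    mu: float = np.nan  # model-expected RNA count
    fold: float = np.nan  # rna_count / mu
    p: float = np.nan  # upper-tail probability
    q: float = np.nan  # BH-adjusted p


@dataclass
class BackgroundFit:
    """Coefficients of log E[rna] = b0 + b1*log(dna+1) + b2*gc, plus dispersion.

    ``alpha`` is the NB2 dispersion (variance = mu + alpha*mu^2) estimated by
    moments on the fitted windows; 0 means Poisson. ``gc_dropped`` records a
    degenerate (constant-GC) design where the covariate was removed.
    """

    beta0: float
    beta1: float
    beta2: float
    alpha: float
    n_windows: int
    converged: bool
    min_input: int = 10
    gc_dropped: bool = False

    def expected(self, dna_count: np.ndarray, gc: np.ndarray) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.log(np.asarray(dna_count) + 1.0)
        if not self.gc_dropped:
            eta = eta + self.beta2 * np.asarray(gc)
        return np.exp(eta)


@dataclass
class Peak:
    region: GenomeRegion
    score: float  # max(-log10 q) over member windows
    summit: int  # center of the best (lowest-p) member window
    sources: tuple[str, ...] = ()


@dataclass
class PeakSet:
    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class ConsensusPeak:
    """Single-linkage cluster of peaks across sets; support counts distinct sets."""

    region: GenomeRegion
    support: int
    mean_score: float
    member_sets: tuple[str, ...] = ()


def make_windows(
    regions: Sequence[GenomeRegion],
    width: int = 500,
    step: int = 100,
    sequences: Sequence[str] | None = None,
) -> list[Window]:
    """Sliding windows tiling each region, with per-window GC fraction.

    Full-width windows start at 0, step, 2*step, ... within each region; if
    they leave a tail of the region uncovered, one trailing partial window is
    added provided it is at least half the nominal width (shorter partials
    carry high-variance counts and are dropped). GC is the fraction of G/C
    among unambiguous A/C/G/T bases; without sequences GC is NaN.
    """
    if not (width >= step >= 1):
        raise ValueError("require width >= step >= 1")
    if sequences is not None and len(sequences) != len(regions):
        raise ValueError("one sequence per region required")
    windows: list[Window] = []
    for ri, r in enumerate(regions):
        L = len(r)
        if L < width:
            logger.info("region %s:%d-%d shorter than window width, skipped",
                        r.chrom, r.start, r.end)
            continue
        seq = sequences[ri] if sequences is not None else None
        if seq is not None and len(seq) != L:
            raise ValueError("sequence length must match region length")
        starts = list(range(0, L - width + 1, step))
        covered_to = starts[-1] + width
        if covered_to < L:
            tail_start = starts[-1] + step
            if L - tail_start >= width / 2:
                starts.append(tail_start)
        for s in starts:
            e = min(s + width, L)
            gc = _gc_fraction(seq[s:e]) if seq is not None else float("nan")
            windows.append(Window(GenomeRegion(r.chrom, r.start + s, r.start + e), gc))
    return windows


def _gc_fraction(seq: str) -> float:
    gc = sum(1 for b in seq if b in _GC_BASES)
    at = sum(1 for b in seq if b in _AT_BASES)
    denom = gc + at
    return gc / denom if denom else float("nan")


def count_fragments_in_windows(
    frags: Iterable[FragmentRecord], windows: Sequence[Window]
) -> np.ndarray:
    """Fragment-overlap counts per window (>= 1 bp overlap, count-weighted).

    Windows within a region share a sorted, regular layout, so each fragment
    maps to a contiguous window slice found by binary search.
    """
    by_chrom: dict[str, list[tuple[int, Window]]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.region.chrom, []).append((i, w))
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: (t[1].region.start, t[1].region.end))
        idx = np.array([i for i, _ in items])
        starts = np.array([w.region.start for _, w in items])
        ends = np.array([w.region.end for _, w in items])
        if not np.all(np.diff(ends) >= 0):  # pragma: no cover - layout guard
            raise ValueError("window ends must be non-decreasing per chromosome")
        index[chrom] = (idx, starts, ends)

    counts = np.zeros(len(windows), dtype=np.int64)
    for f in frags:
        entry = index.get(f.region.chrom)
        if entry is None:
            continue
        idx, starts, ends = entry
        lo = np.searchsorted(ends, f.region.start, side="right")
        hi = np.searchsorted(starts, f.region.end, side="left")
        if hi > lo:
            counts[idx[lo:hi]] += f.count
    return counts


def fit_background(
    stats_in: Sequence[WindowStats],
    min_input: int = 10,
    trim_top: float = 0.01,
) -> BackgroundFit:
    """Fit the basal-transcription background model on input-supported windows.

    Uses a Poisson GLM (log link, IRLS) of RNA count on log(dna+1) and GC,
    restricted to windows with dna >= min_input and with the top ``trim_top``
    fraction of RNA counts excluded so genuine enhancers do not inflate the
    background. Overdispersion relative to Poisson is captured by the NB2
    moment estimator alpha = max(0, sum((r-mu)^2 - mu) / sum(mu^2)).
    """
    r = np.array([s.rna_count for s in stats_in], dtype=float)
    d = np.array([s.dna_count for s in stats_in], dtype=float)
    gc = np.array([s.window.gc for s in stats_in], dtype=float)
    keep = d >= min_input
    if keep.sum() < 50:
        raise ValueError(f"need >= 50 windows with input >= {min_input}, got {keep.sum()}")
    if trim_top > 0:
        cutoff = np.quantile(r[keep], 1.0 - trim_top)
        keep &= r <= cutoff
    rk, dk, gck = r[keep], d[keep], gc[keep]

    gc_dropped = False
    cols = [np.ones_like(rk), np.log(dk + 1.0)]
    if np.all(np.isnan(gck)) or np.nanstd(gck) == 0:
        logger.warning("GC covariate constant or missing; dropped from background fit")
        gc_dropped = True
    else:
        cols.append(np.nan_to_num(gck, nan=float(np.nanmean(gck))))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # degenerate design beyond constant GC (e.g. constant input): drop GC
        if not gc_dropped and X.shape[1] == 3:
            logger.warning("singular design; dropping GC covariate")
            X = X[:, :2]
            gc_dropped = True

    model = sm.GLM(rk, X, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    params = res.params
    mu = res.fittedvalues
    alpha = max(0.0, float(np.sum((rk - mu) ** 2 - mu) / np.sum(mu**2)))
    beta2 = 0.0 if gc_dropped else float(params[2])
    return BackgroundFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        beta2=beta2,
        alpha=alpha,
        n_windows=int(keep.sum()),
        converged=bool(res.converged),
        min_input=min_input,
        gc_dropped=gc_dropped,
    )


def nb_upper_tail(r: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """P(X >= r) for X ~ NB2(mean mu, dispersion alpha); Poisson when alpha=0."""
    r = np.asarray(r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return stats.poisson.sf(r - 1, mu)
    size = 1.0 / alpha
    prob = size / (size + mu)
    return stats.nbinom.sf(r - 1, size, prob)


def score_windows(
    stats_in: Sequence[WindowStats], fit: BackgroundFit
) -> list[WindowStats]:
    """Fill mu, fold, upper-tail p and BH q for every window.

    Windows with input below the fit's min_input are untestable and get p=1;
    BH runs jointly over all windows.
    """
    r = np.array([s.rna_count for s in stats_in], dtype=float)
    d = np.array([s.dna_count for s in stats_in], dtype=float)
    gc = np.array([s.window.gc for s in stats_in], dtype=float)
    gc = np.nan_to_num(gc, nan=float(np.nanmean(gc)) if np.any(~np.isnan(gc)) else 0.0)
    mu = fit.expected(d, gc)
    p = nb_upper_tail(r, mu, fit.alpha)
    p = np.clip(p, 0.0, 1.0)
    p[d < fit.min_input] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = []
    for i, s in enumerate(stats_in):
        out.append(
            WindowStats(
                window=s.window,
                rna_count=s.rna_count,
                dna_count=s.dna_count,
                mu=float(mu[i]),
                fold=float(r[i] / mu[i]) if mu[i] > 0 else float("inf"),
                p=float(p[i]),
                q=float(max(q[i], p[i])),
            )
        )
    return out


_MIN_Q = 1e-300  # floor before -log10 so peak scores stay finite


def call_peaks(
    stats_in: Sequence[WindowStats],
    q_max: float = 0.05,
    min_fold: float = 1.5,
    merge_gap: int = 0,
    sample_id: str = "sample",
) -> PeakSet:
    """Merge significant windows (q <= q_max and fold >= min_fold) into peaks.

    Overlapping windows, or windows within ``merge_gap`` bp, join one peak.
    Peak score is max(-log10 q) over members; the summit is the center of the
    lowest-p member window (ties broken towards the leftmost window).
    """
    sig = [s for s in stats_in if s.q <= q_max and s.fold >= min_fold]
    sig.sort(key=lambda s: (s.window.region.chrom, s.window.region.start,
                            s.window.region.end))
    peaks: list[Peak] = []
    cluster: list[WindowStats] = []

    def _flush() -> None:
        if not cluster:
            return
        chrom = cluster[0].window.region.chrom
        start = min(s.window.region.start for s in cluster)
        end = max(s.window.region.end for s in cluster)
        best = min(cluster, key=lambda s: (s.p, s.window.region.start))
        score = max(-np.log10(max(s.q, _MIN_Q)) for s in cluster)
        summit = (best.window.region.start + best.window.region.end) // 2
        peaks.append(Peak(GenomeRegion(chrom, start, end), float(score), summit,
                          sources=(sample_id,)))

    cur_end = None
    cur_chrom = None
    for s in sig:
        r = s.window.region
        if cluster and r.chrom == cur_chrom and r.start <= cur_end + merge_gap:
            cluster.append(s)
            cur_end = max(cur_end, r.end)
        else:
            _flush()
            cluster = [s]
            cur_chrom, cur_end = r.chrom, r.end
    _flush()
    return PeakSet(sample_id=sample_id, peaks=peaks)


def consensus_peaks(
    peak_sets: Sequence[PeakSet], min_support: int
) -> list[ConsensusPeak]:
    """Cluster peaks across sets by single-linkage >=1 bp overlap.

    A cluster's support is the number of distinct source sets contributing a
    peak; clusters with support >= min_support are returned as their union
    interval with the mean member score. Applied twice in the screen design:
    across the 3 input-replicate calls within an animal (min_support=2) and
    across the 5 animals (min_support=5).
    """
    if not peak_sets:
        raise ValueError("need >= 1 peak set")
    if not (1 <= min_support <= len(peak_sets)):
        raise ValueError("min_support out of range")
    tagged = [
        (p.region, p.score, ps.sample_id) for ps in peak_sets for p in ps.peaks
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[ConsensusPeak] = []
    cluster: list[tuple[GenomeRegion, float, str]] = []
    cur_chrom, cur_end = None, None

    def _flush() -> None:
        if not cluster:
            return
        sets = sorted({src for _, _, src in cluster})
        if len(sets) >= min_support:
            start = min(r.start for r, _, _ in cluster)
            end = max(r.end for r, _, _ in cluster)
            mean_score = float(np.mean([s for _, s, _ in cluster]))
            out.append(
                ConsensusPeak(
                    GenomeRegion(cluster[0][0].chrom, start, end),
                    support=len(sets),
                    mean_score=mean_score,
                    member_sets=tuple(sets),
                )
            )

    for region, score, src in tagged:
        if cluster and region.chrom == cur_chrom and region.start < cur_end:
            cluster.append((region, score, src))
            cur_end = max(cur_end, region.end)
        else:
            _flush()
            cluster = [(region, score, src)]
            cur_chrom, cur_end = region.chrom, region.end
    _flush()
    return out


def reproducibility_profile(
    peak_sets: Sequence[PeakSet],
) -> tuple[dict[int, int], float]:
    """Histogram of cluster support values and the fraction at full support.

    The full-support fraction is the screen's headline reproducibility
    number: clusters seen in every animal over clusters seen in any.
    """
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 peak sets")
    n = len(peak_sets)
    clusters = consensus_peaks(peak_sets, min_support=1)
    hist = {k: 0 for k in range(1, n + 1)}
    for c in clusters:
        hist[c.support] += 1
    total = len(clusters)
    frac_full = hist[n] / total if total else float("nan")
    return hist, frac_full
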
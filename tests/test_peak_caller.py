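import numpy as np
import pytest
from scipy import stats as sps

from starrscreen.genomic_signal import FragmentRecord
from starrscreen.intervals import GenomeRegion
from starrscreen.peak_caller import (
    PeakSet,
    Window,
    WindowStats,
    call_peaks,
    consensus_peaks,
    count_fragments_in_windows,
    fit_background,
    make_windows,
    nb_upper_tail,
    reproducibility_profile,
    score_windows,
)


def frag(chrom, start, end, count=1):
    return FragmentRecord(GenomeRegion(chrom, start, end), "s", 60, count)


def ws(chrom, start, end, p=1.0, q=1.0, fold=0.0, r=0, d=100):
    return WindowStats(
        Window(GenomeRegion(chrom, start, end), 0.5), r, d,
        mu=1.0, fold=fold, p=p, q=q,
    )


class TestMakeWindows:
    def test_region_of_1000_yields_six_full_windows(self):
        w = make_windows([GenomeRegion("chr1", 0, 1000)], width=500, step=100)
        assert [x.region.start for x in w] == [0, 100, 200, 300, 400, 500]
        assert all(len(x.region) == 500 for x in w)

    def test_uncovered_tail_gets_partial_window_if_long_enough(self):
        # tail [1000,1449) uncovered by full windows: trailing [600,1449) kept
        w = make_windows([GenomeRegion("chr1", 0, 1449)], width=500, step=100)
        assert w[-1].region.end == 1449
        # but a tail shorter than width/2 is dropped
        w2 = make_windows([GenomeRegion("chr1", 0, 1100)], width=500, step=100)
        assert w2[-1].region.end == 1100 and len(w2[-1].region) == 500

    def test_region_shorter_than_width_gives_no_windows(self):
        assert make_windows([GenomeRegion("chr1", 0, 300)], width=500) == []

    def test_gc_of_pure_gc_sequence_is_one(self):
        w = make_windows(
            [GenomeRegion("chr1", 0, 500)], width=500, step=100,
            sequences=["GC" * 250],
        )
        assert w[0].gc == 1.0

    def test_gc_matches_base_counting_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=2000))
        windows = make_windows(
            [GenomeRegion("chr1", 0, 2000)], width=500, step=100, sequences=[seq]
        )
        for w in windows:
            sub = seq[w.region.start : w.region.end]
            gc = sum(b in "GC" for b in sub)
            acgt = sum(b in "ACGT" for b in sub)
            assert w.gc == pytest.approx(gc / acgt)

    def test_ambiguous_bases_excluded_from_denominator(self):
        w = make_windows(
            [GenomeRegion("chr1", 0, 500)], width=500,
            sequences=["G" * 100 + "N" * 300 + "A" * 100],
        )
        assert w[0].gc == pytest.approx(0.5)


class TestCounting:
    def test_spanning_fragment_hits_all_overlapping_windows(self):
        windows = make_windows([GenomeRegion("chr1", 0, 1000)], 500, 100)
        counts = count_fragments_in_windows([frag("chr1", 250, 900)], windows)
        assert list(counts) == [1] * 6  # every window shares >= 1 bp

    def test_window_equal_fragment_increments_neighbors_too(self):
        windows = make_windows([GenomeRegion("chr1", 0, 1000)], 500, 100)
        counts = count_fragments_in_windows([frag("chr1", 100, 600)], windows)
        assert counts.sum() == 6 and all(counts == 1)

    def test_matches_brute_force_overlap_matrix(self, rng):
        regions = [GenomeRegion("chr1", 0, 20_000)]
        windows = make_windows(regions, 500, 100)[:200]
        frags = [
            frag("chr1", int(s), int(s) + int(l), count=int(c))
            for s, l, c in zip(
                rng.integers(0, 19_000, 1000),
                rng.integers(50, 900, 1000),
                rng.integers(1, 4, 1000),
            )
        ]
        counts = count_fragments_in_windows(frags, windows)
        brute = np.zeros(len(windows), dtype=int)
        for f in frags:  # O(n*m) oracle
            for j, w in enumerate(windows):
                if f.region.overlaps(w.region):
                    brute[j] += f.count
        assert np.array_equal(counts, brute)


class TestBackgroundFit:
    def _stats(self, r, d, gc):
        return [
            WindowStats(Window(GenomeRegion("chr1", i * 100, i * 100 + 500),
                               float(g)), int(ri), int(di))
            for i, (ri, di, g) in enumerate(zip(r, d, gc))
        ]

    def test_poisson_parameter_recovery(self, rng):
        # r ~ Poisson(2*(d+1)) means beta1=1, beta2=0, alpha=0
        d = rng.integers(20, 500, size=2000)
        mu = 2.0 * (d + 1)
        r = rng.poisson(mu)
        gc = rng.uniform(0.3, 0.7, size=2000)
        fit = fit_background(self._stats(r, d, gc), min_input=10, trim_top=0.0)
        assert fit.beta1 == pytest.approx(1.0, abs=0.05)
        assert fit.alpha == pytest.approx(0.0, abs=0.02)
        assert fit.converged

    def test_intercept_only_degenerate_case(self, rng):
        r = np.full(200, 7)
        d = np.full(200, 50)
        gc = np.full(200, 0.5)
        fit = fit_background(self._stats(r, d, gc), min_input=10, trim_top=0.0)
        mu = fit.expected(np.array([50]), np.array([0.5]))[0]
        assert mu == pytest.approx(7.0, rel=1e-6)
        assert fit.alpha == 0.0  # no variance at all
        assert fit.gc_dropped

    def test_nb_dispersion_recovery(self, rng):
        d = rng.integers(50, 500, size=5000)
        mu = 1.5 * (d + 1)
        alpha = 0.3
        size = 1.0 / alpha
        r = rng.negative_binomial(size, size / (size + mu))
        gc = rng.uniform(0.3, 0.7, size=5000)
        fit = fit_background(self._stats(r, d, gc), min_input=10, trim_top=0.0)
        assert fit.alpha == pytest.approx(0.3, abs=0.1)

    def test_requires_enough_supported_windows(self, rng):
        stats_in = self._stats([5] * 30, [50] * 30, [0.5] * 30)
        with pytest.raises(ValueError):
            fit_background(stats_in, min_input=10)


class TestScoreWindows:
    def _fit(self, **kw):
        from starrscreen.peak_caller import BackgroundFit

        defaults = dict(beta0=np.log(5.0), beta1=0.0, beta2=0.0, alpha=0.0,
                        n_windows=100, converged=True, min_input=10,
                        gc_dropped=True)
        defaults.update(kw)
        return BackgroundFit(**defaults)

    def test_zero_count_has_p_one(self):
        stats_in = [ws("chr1", 0, 500, r=0, d=100)]
        out = score_windows(stats_in, self._fit())
        assert out[0].p == 1.0

    def test_poisson_tail_matches_direct_summation(self):
        # mu=5, r=10: p = 1 - CDF(9) by explicit term-by-term summation
        import math

        direct = 1.0 - sum(np.exp(-5) * 5.0**k / math.factorial(k)
                           for k in range(10))
        p = nb_upper_tail(np.array([10]), np.array([5.0]), alpha=0.0)[0]
        assert p == pytest.approx(direct, abs=1e-10)

    def test_nb_tail_matches_direct_summation(self):
        mu, alpha, r = 8.0, 0.4, 20
        size = 1.0 / alpha
        prob = size / (size + mu)
        direct = 1.0 - sum(sps.nbinom.pmf(k, size, prob) for k in range(r))
        assert nb_upper_tail(np.array([r]), np.array([mu]), alpha)[0] == pytest.approx(
            direct, abs=1e-10
        )

    def test_low_input_windows_untestable(self):
        stats_in = [ws("chr1", 0, 500, r=50, d=2)]
        out = score_windows(stats_in, self._fit())
        assert out[0].p == 1.0

    def test_bh_null_calibration(self, rng):
        # all-null Poisson screens: essentially nothing passes q <= 0.05
        n_sig = 0
        for _ in range(200):
            r = rng.poisson(5.0, size=100)
            stats_in = [ws("chr1", i * 100, i * 100 + 500, r=int(x), d=100)
                        for i, x in enumerate(r)]
            out = score_windows(stats_in, self._fit())
            n_sig += sum(s.q <= 0.05 for s in out)
        assert n_sig / (200 * 100) < 0.01

    def test_q_never_below_p(self, rng):
        r = rng.poisson(5.0, size=50)
        stats_in = [ws("chr1", i * 100, i * 100 + 500, r=int(x), d=100)
                    for i, x in enumerate(r)]
        out = score_windows(stats_in, self._fit())
        assert all(s.q >= s.p for s in out)


class TestCallPeaks:
    def test_overlapping_significant_windows_merge(self):
        stats_in = [
            ws("chr1", 100, 600, p=1e-6, q=1e-5, fold=5.0),
            ws("chr1", 200, 700, p=1e-7, q=1e-5, fold=5.0),
            ws("chr1", 5000, 5500, p=0.9, q=0.9, fold=1.0),
        ]
        peaks = call_peaks(stats_in, q_max=0.05, min_fold=1.5)
        assert len(peaks) == 1
        assert (peaks.peaks[0].region.start, peaks.peaks[0].region.end) == (100, 700)
        assert peaks.peaks[0].summit == 450  # center of the lowest-p window

    def test_no_significant_windows_gives_empty_set(self):
        stats_in = [ws("chr1", 0, 500, p=0.5, q=0.8, fold=3.0)]
        assert len(call_peaks(stats_in)) == 0

    def test_fold_filter_applies(self):
        stats_in = [ws("chr1", 0, 500, p=1e-8, q=1e-7, fold=1.2)]
        assert len(call_peaks(stats_in, min_fold=1.5)) == 0

    def test_peak_count_monotone_in_q_max(self, rng):
        stats_in = [
            ws("chr1", i * 600, i * 600 + 500, p=p, q=p, fold=5.0)
            for i, p in enumerate(rng.uniform(0, 1, size=60))
        ]
        counts = [len(call_peaks(stats_in, q_max=q)) for q in (0.01, 0.05, 0.2, 0.5, 1.0)]
        assert counts == sorted(counts)


def pset(sample_id, intervals):
    from starrscreen.peak_caller import Peak

    return PeakSet(
        sample_id,
        [Peak(GenomeRegion(*iv), 5.0, (iv[1] + iv[2]) // 2) for iv in intervals],
    )


class TestConsensus:
    def test_full_support_peak_retained(self):
        sets = [pset(f"m{i}", [("chr1", 100, 600)]) for i in range(5)]
        out = consensus_peaks(sets, min_support=5)
        assert len(out) == 1 and out[0].support == 5

    def test_four_of_five_dropped_at_full_support(self):
        sets = [pset(f"m{i}", [("chr1", 100, 600)]) for i in range(4)]
        sets.append(pset("m4", [("chr1", 5000, 5600)]))
        out = consensus_peaks(sets, min_support=5)
        assert out == []

    def test_chained_overlap_single_linkage(self):
        # A overlaps B, B overlaps C, A does not overlap C: one cluster of 3
        sets = [
            pset("a", [("chr1", 0, 100)]),
            pset("b", [("chr1", 90, 200)]),
            pset("c", [("chr1", 190, 300)]),
        ]
        out = consensus_peaks(sets, min_support=3)
        assert len(out) == 1
        assert (out[0].region.start, out[0].region.end) == (0, 300)
        assert out[0].support == 3

    def test_union_find_oracle_on_random_sets(self, rng):
        sets = []
        for s in range(4):
            starts = sorted(rng.choice(np.arange(0, 5000, 120), 12, replace=False))
            sets.append(pset(f"s{s}", [("chr1", int(x), int(x) + 100) for x in starts]))
        out = consensus_peaks(sets, min_support=1)
        # independent union-find over all peaks
        all_peaks = [(p.region, ps.sample_id) for ps in sets for p in ps.peaks]
        parent = list(range(len(all_peaks)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(all_peaks)):
            for j in range(i + 1, len(all_peaks)):
                if all_peaks[i][0].overlaps(all_peaks[j][0]):
                    parent[find(i)] = find(j)
        groups = {}
        for i, (region, src) in enumerate(all_peaks):
            groups.setdefault(find(i), set()).add(src)
        assert len(out) == len(groups)
        assert sorted(c.support for c in out) == sorted(len(g) for g in groups.values())

    def test_min_support_n_is_subset_of_union(self):
        sets = [
            pset("a", [("chr1", 0, 100), ("chr1", 500, 600)]),
            pset("b", [("chr1", 50, 150)]),
        ]
        union = consensus_peaks(sets, min_support=1)
        strict = consensus_peaks(sets, min_support=2)
        strict_keys = {(c.region.start, c.region.end) for c in strict}
        union_keys = {(c.region.start, c.region.end) for c in union}
        assert strict_keys <= union_keys


class TestReproducibility:
    def test_fraction_full_support(self):
        sets = [pset(f"m{i}", [("chr1", 0, 100), ("chr2", 0, 100)]) for i in range(5)]
        sets[0].peaks.extend(pset("x", [("chr3", 0, 100)]).peaks)
        hist, frac = reproducibility_profile(sets)
        assert hist[5] == 2 and hist[1] == 1
        assert frac == pytest.approx(2 / 3)

    def test_identical_sets_fully_reproducible(self):
        sets = [pset(f"m{i}", [("chr1", 0, 100)]) for i in range(3)]
        _, frac = reproducibility_profile(sets)
        assert frac == 1.0
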
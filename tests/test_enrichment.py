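import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from starrscreen.enrichment import (
    BaseScoreTrack,
    FeatureSet,
    ShuffleConfig,
    conservation_compare,
    enrichment_test,
    interval_mean_scores,
    make_shuffle_ensemble,
    overlap_statistic,
    per_peak_hit_counts,
    repeat_class_enrichment,
    shuffle_peaks,
)
from starrscreen.intervals import GenomeRegion


def reg(chrom, start, end):
    return GenomeRegion(chrom, start, end)


@pytest.fixture
def universe():
    return [reg("chr1", 0, 50_000), reg("chr2", 10_000, 40_000)]


@pytest.fixture
def peaks(rng):
    starts = rng.choice(np.arange(0, 48_000, 1200), size=20, replace=False)
    return [reg("chr1", int(s), int(s) + int(l))
            for s, l in zip(starts, rng.integers(300, 1100, 20))]


class TestShuffle:
    def test_lengths_preserved_within_universe_disjoint(self, universe, peaks):
        cfg = ShuffleConfig(n_sets=1, universe=universe)
        out = shuffle_peaks(peaks, cfg, trial=5)
        assert sorted(len(p) for p in out) == sorted(len(p) for p in peaks)
        for p in out:
            assert any(u.contains(p) for u in universe)
        for a, b in itertools.combinations(out, 2):
            assert not a.overlaps(b)

    def test_trial_seed_is_square_and_reproducible(self, universe, peaks):
        cfg = ShuffleConfig(n_sets=10, universe=universe)
        assert ShuffleConfig.seed_for_trial(3) == 9
        a = shuffle_peaks(peaks, cfg, trial=3)
        b = shuffle_peaks(peaks, cfg, trial=3)
        assert a == b
        assert shuffle_peaks(peaks, cfg, trial=4) != a

    def test_trial_alone_equals_trial_within_full_run(self, universe, peaks):
        cfg = ShuffleConfig(n_sets=20, universe=universe)
        ensemble = make_shuffle_ensemble(peaks, cfg)
        assert ensemble[6] == shuffle_peaks(peaks, cfg, trial=7)

    def test_tight_universe_still_places(self):
        cfg = ShuffleConfig(n_sets=1, universe=[reg("chr1", 0, 1200)])
        out = shuffle_peaks([reg("chrX", 0, 1000)], cfg, trial=1)
        assert len(out) == 1 and len(out[0]) == 1000
        assert 0 <= out[0].start and out[0].end <= 1200

    def test_occupancy_approximately_uniform(self):
        # interior-bin occupancy is flat across trials; bases within one
        # interval length of the universe ends are excluded (placement of an
        # 800 bp interval necessarily covers them less often), and the test
        # uses the empirical between-trial variance because bases within one
        # interval are correlated
        peaks = [reg("chr1", i * 2000, i * 2000 + 800) for i in range(10)]
        cfg = ShuffleConfig(n_sets=300, universe=[reg("chr1", 0, 50_000)])
        n_trials, bin_w = 300, 3000
        interior = slice(1000, 49_000)
        per_trial = np.zeros((n_trials, 16))
        for trial in range(1, n_trials + 1):
            occ = np.zeros(50_000)
            for p in shuffle_peaks(peaks, cfg, trial):
                occ[p.start : p.end] += 1
            per_trial[trial - 1] = occ[interior].reshape(16, bin_w).sum(axis=1)
        means = per_trial.mean(axis=0)
        sems = per_trial.std(axis=0, ddof=1) / np.sqrt(n_trials)
        chi2 = (((means - means.mean()) / sems) ** 2).sum()
        # not rejected at alpha=0.01 with 15 df
        assert chi2 < sps.chi2.ppf(0.99, df=15)


class TestOverlapStatistic:
    def test_counts_peaks_with_any_feature(self):
        pk = [reg("chr1", 0, 100), reg("chr1", 500, 600), reg("chr1", 900, 1000)]
        fs = FeatureSet("f", [reg("chr1", 50, 120), reg("chr1", 950, 960)])
        assert overlap_statistic(pk, fs) == 2

    def test_empty_feature_set(self):
        assert overlap_statistic([reg("chr1", 0, 100)], FeatureSet("f", [])) == 0

    def test_matches_brute_force(self, rng):
        pk = [reg("chr1", int(s), int(s) + 200)
              for s in rng.integers(0, 20_000, 50)]
        fs = FeatureSet(
            "f", [reg("chr1", int(s), int(s) + 150)
                  for s in rng.integers(0, 20_000, 80)]
        )
        brute = sum(1 for p in pk if any(p.overlaps(f) for f in fs.intervals))
        assert overlap_statistic(pk, fs) == brute
        hits = per_peak_hit_counts(pk, fs)
        brute_hits = [sum(p.overlaps(f) for f in fs.intervals) for p in pk]
        assert list(hits) == brute_hits


class TestEnrichmentTest:
    def test_z_formula(self):
        from starrscreen.enrichment import EnrichmentResult  # noqa: F401

        # obs=50 against null mean 20 sd 5 gives z=6; construct via ensemble
        null = np.array([20.0] * 500)
        sd = 5.0
        z = (50 - null.mean()) / sd
        assert z == pytest.approx(6.0)

    def test_empirical_p_bounds_and_depletion(self, universe, peaks):
        cfg = ShuffleConfig(n_sets=100, universe=universe)
        fs = FeatureSet("self", list(peaks))  # the peak set itself: z > 0
        res = enrichment_test(peaks, fs, cfg)
        assert res.observed == len(peaks)
        assert res.z > 0
        assert res.direction == "enriched"
        assert 1 / 101 <= res.p_emp <= 1.0
        assert res.p_emp_enrich == pytest.approx(1 / 101)

    def test_planted_features_enriched(self, universe, peaks):
        # features over 80% of the peaks: strong enrichment signal
        fs = FeatureSet("planted", [reg(p.chrom, p.start, p.end)
                                    for p in peaks[:16]])
        cfg = ShuffleConfig(n_sets=200, universe=universe)
        res = enrichment_test(peaks, fs, cfg)
        assert res.z > 2 and res.p_emp <= 0.05


class TestIntervalMeans:
    def test_constant_track(self):
        track = BaseScoreTrack([reg("chr1", 0, 1000)], [np.full(1000, 3.25)])
        means = interval_mean_scores(track, [reg("chr1", 10, 400), reg("chr1", 0, 5)])
        assert np.allclose(means, 3.25)

    def test_half_and_half(self):
        track = BaseScoreTrack(
            [reg("chr1", 0, 100)], [np.r_[np.zeros(50), np.ones(50)]]
        )
        assert interval_mean_scores(track, [reg("chr1", 0, 100)])[0] == pytest.approx(0.5)

    def test_matches_summation_oracle(self, rng):
        vals = rng.normal(size=5000)
        track = BaseScoreTrack([reg("chr1", 0, 5000)], [vals])
        ivs = [reg("chr1", int(s), int(s) + 137) for s in rng.integers(0, 4800, 30)]
        means = interval_mean_scores(track, ivs)
        for iv, m in zip(ivs, means):
            total = sum(vals[b] for b in range(iv.start, iv.end))
            assert m == pytest.approx(total / len(iv), abs=1e-12)

    def test_missing_bases_excluded(self):
        vals = np.full(100, np.nan)
        vals[:10] = 2.0
        track = BaseScoreTrack([reg("chr1", 0, 100)], [vals])
        means = interval_mean_scores(track, [reg("chr1", 0, 100), reg("chr1", 50, 60)])
        assert means[0] == pytest.approx(2.0)
        assert np.isnan(means[1])


class TestConservationCompare:
    def _track_from_values(self, assignments, n=10_000):
        vals = np.zeros(n)
        for (s, e), v in assignments:
            vals[s:e] = v
        return BaseScoreTrack([reg("chr1", 0, n)], [vals])

    def test_exact_rank_sum_matches_enumeration(self):
        # x={1,2,3} vs y={4,5,6}: one-sided exact p = 1/20
        track = self._track_from_values(
            [((i * 10, i * 10 + 10), v) for i, v in enumerate([1, 2, 3, 4, 5, 6])]
        )
        x_iv = [reg("chr1", i * 10, i * 10 + 10) for i in range(3)]
        y_iv = [reg("chr1", i * 10, i * 10 + 10) for i in range(3, 6)]
        res = conservation_compare(x_iv, [y_iv], track, alternative="less")
        # enumeration oracle over all C(6,3) assignments
        pooled = [1, 2, 3, 4, 5, 6]
        u_obs = sum(xi < yj for xi in [1, 2, 3] for yj in [4, 5, 6])
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u = sum(xi < yj for xi in xs for yj in ys)
            total += 1
            if u >= u_obs:
                count += 1
        assert res.p_value == pytest.approx(count / total)
        assert res.p_value == pytest.approx(1 / 20)

    def test_all_tied_gives_p_one(self):
        track = self._track_from_values([((0, 100), 1.0)], n=100)
        ivs = [reg("chr1", 0, 10), reg("chr1", 20, 30)]
        res = conservation_compare(ivs, [[reg("chr1", 50, 60)]], track)
        assert res.p_value == 1.0

    def test_exact_close_to_normal_approximation(self, rng):
        # continuous data, n=m=40: asymptotic and exact agree within 0.02
        x = rng.normal(0.3, 1, 40)
        y = rng.normal(0.0, 1, 40)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        asym = sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").pvalue
        assert abs(exact - asym) < 0.02

    def test_elevated_scores_detected(self, rng):
        # +0.5 bump with sd 0.2 noise at 20 peak intervals: p < 0.01
        n = 40_000
        vals = rng.normal(0, 0.2, size=n)
        peaks = [reg("chr1", i * 2000, i * 2000 + 500) for i in range(20)]
        for p in peaks:
            vals[p.start : p.end] += 0.5
        track = BaseScoreTrack([reg("chr1", 0, n)], [vals])
        shuffled = [[reg("chr1", i * 2000 + 1000, i * 2000 + 1500)
                     for i in range(20)]]
        res = conservation_compare(peaks, shuffled, track, alternative="greater")
        assert res.p_value < 0.01
        # ECDF of peaks sits to the right of the null ECDF
        assert res.ecdf_peaks[0].mean() > res.ecdf_null[0].mean()


class TestRepeatClasses:
    def test_empty_class_reports_zero_and_missing_z(self, universe, peaks):
        cfg = ShuffleConfig(n_sets=100, universe=universe)
        results = repeat_class_enrichment(peaks, [FeatureSet("LINE", [])], cfg)
        assert results[0].observed == 0
        assert np.isnan(results[0].z)

    def test_peak_copy_class_enriched_and_sorted(self, universe, peaks):
        cfg = ShuffleConfig(n_sets=100, universe=universe)
        classes = [
            FeatureSet("self_copy", list(peaks)),
            FeatureSet("nothing", []),
        ]
        results = repeat_class_enrichment(peaks, classes, cfg)
        assert results[0].label == "self_copy"
        assert results[0].observed == len(peaks)
        assert results[0].z > 0

    def test_avoided_class_depleted(self, universe, rng):
        # repeats placed strictly away from the peaks: depletion (z < 0)
        peaks = [reg("chr1", i * 5000, i * 5000 + 2000) for i in range(10)]
        repeats = [reg("chr1", i * 5000 + 2500, i * 5000 + 4800) for i in range(10)]
        cfg = ShuffleConfig(n_sets=200, universe=[reg("chr1", 0, 50_000)])
        res = repeat_class_enrichment(peaks, [FeatureSet("LINE", repeats)], cfg)[0]
        assert res.z < 0
        assert res.direction == "depleted"
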
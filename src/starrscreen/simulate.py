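"""Synthetic AAV-STARR-seq screens with ground truth.

The generator emulates the statistical structure of a tiled-region in vivo
enhancer screen: a sheared fragment library (lengths ~ truncated normal,
mean 742 bp within [500, 1000]) with log-normal clonal abundance, three
input-DNA sequencing replicates drawn multinomially from that abundance,
and five animal RNA samples in which every fragment is transcribed at a
basal, abundance-proportional rate — the background-transcription mechanism
that makes RNA and DNA tracks correlate — multiplied by the activation of
any planted enhancer the fragment overlaps. All randomness flows from a
single seed through named child streams, so identical configurations give
byte-identical outputs and every stage of the analysis can be tested
against the recorded ground truth.

Default scale is a desk-size screen (9 x 30 kb regions, 50,000 library
fragments, 50,000 RNA fragments per animal), a linear 10x shrink of the
study design it mimics; ``full_scale_config`` gives the full-size version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomic_signal import FragmentRecord, SampleMeta
from .intervals import GenomeRegion
from .enrichment import BaseScoreTrack, FeatureSet

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class EnhancerSpec:
    """A planted enhancer: where it is, how strongly it activates.

    A fragment overlapping the enhancer is activated in proportion to its
    overlap, saturating once the overlap reaches ``core_fraction`` of the
    enhancer width.
    """

    region: GenomeRegion
    effect: float  # fold activation at full overlap, > 1
    core_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.effect <= 1:
            raise ValueError("enhancer effect must be > 1")
        if not (0 < self.core_fraction <= 1):
            raise ValueError("core_fraction must be in (0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    n_regions: int = 9
    region_length: int = 30_000
    gc_mean: float = 0.45
    gc_sd: float = 0.05
    n_fragments: int = 50_000
    fragment_length_mean: float = 742.0
    fragment_length_sd: float = 110.0
    fragment_length_bounds: tuple[int, int] = (500, 1000)
    abundance_sd: float = 1.0  # log-normal sigma of clonal library abundance
    bias_sd: float = 0.6  # log-sd of the smooth positional coverage bias field
    bias_scale: int = 5000  # correlation length of the bias field, bp
    activity_sd: float = 0.4  # log-sd of the shared basal-transcribability field
    activity_scale: int = 2000  # correlation length of the activity field, bp
    activity_clip: float = 2.0  # field clipped at +/- clip*sd: stronger activation
    #   than mild bounded basal variation is what an enhancer *is*, and planted
    #   enhancers are the only elements allowed to exceed it
    n_input_reps: int = 3
    n_animals: int = 5
    dna_depth: int = 200_000
    rna_depth: int = 50_000  # unique transcripts per animal at desk scale
    basal_rate: float = 1.0
    duplication_rate: float = 0.0
    enhancers: list[EnhancerSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.fragment_length_bounds
        if lo >= hi:
            raise ValueError("fragment length bounds must be ordered")
        if min(self.n_regions, self.region_length, self.n_fragments,
               self.n_input_reps, self.n_animals, self.dna_depth,
               self.rna_depth) <= 0:
            raise ValueError("counts must be > 0")
        if self.basal_rate <= 0:
            raise ValueError("basal_rate must be > 0")


@dataclass
class SimTruth:
    """Ground-truth manifest serialized alongside every simulated screen."""

    config: SimConfig
    enhancers: list[EnhancerSpec]
    sample_seeds: dict[str, int]
    fragment_activity: np.ndarray | None = None

    def to_json(self) -> str:
        cfg = dataclasses.asdict(self.config)
        cfg["enhancers"] = [
            {
                "chrom": e.region.chrom,
                "start": e.region.start,
                "end": e.region.end,
                "effect": e.effect,
                "core_fraction": e.core_fraction,
            }
            for e in self.config.enhancers
        ]
        return json.dumps(
            {
                "config": cfg,
                "enhancers": cfg["enhancers"],
                "sample_seeds": self.sample_seeds,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        data = json.loads(text)
        enh = [
            EnhancerSpec(
                GenomeRegion(e["chrom"], e["start"], e["end"]),
                effect=e["effect"],
                core_fraction=e["core_fraction"],
            )
            for e in data["enhancers"]
        ]
        cfg = dict(data["config"])
        cfg["enhancers"] = enh
        cfg["fragment_length_bounds"] = tuple(cfg["fragment_length_bounds"])
        config = SimConfig(**cfg)
        return cls(config=config, enhancers=enh,
                   sample_seeds={k: int(v) for k, v in data["sample_seeds"].items()})


@dataclass
class FragmentLibrary:
    """The clonal screening library: intervals plus relative abundance (sums to 1)."""

    regions: list[GenomeRegion]
    region_index: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    abundance: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def interval(self, i: int) -> GenomeRegion:
        r = self.regions[self.region_index[i]]
        return GenomeRegion(r.chrom, int(self.starts[i]), int(self.ends[i]))


@dataclass
class SimulatedScreen:
    regions: list[GenomeRegion]
    sequences: list[str]
    library: FragmentLibrary
    samples: dict[str, list[FragmentRecord]]
    sample_meta: dict[str, SampleMeta]
    truth: SimTruth


def _child_seed(seed: int, label: str) -> int:
    """Stable, label-derived child seed below 2**31."""
    h = (seed * 2654435761) % (1 << 63)
    for ch in label:
        h = ((h ^ ord(ch)) * 1099511628211) % (1 << 63)
    return int(h % ((1 << 31) - 1))


def generate_reference(config: SimConfig) -> tuple[list[str], list[GenomeRegion]]:
    """Random reference sequences, one per tiled region.

    Bases are i.i.d. within a region; each region's GC level is drawn from
    Normal(gc_mean, gc_sd) clipped to [0.3, 0.7], giving the windows a real
    GC covariate to regress on.
    """
    rng = np.random.default_rng(_child_seed(config.seed, "reference"))
    regions, sequences = [], []
    for i in range(config.n_regions):
        gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.3, 0.7))
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(_BASES[rng.choice(4, size=config.region_length, p=probs)])
        regions.append(GenomeRegion(f"tile{i + 1:02d}", 0, config.region_length,
                                    name=f"tile{i + 1:02d}"))
        sequences.append(seq)
    return sequences, regions


def _bias_field(
    rng: np.random.Generator, region_length: int, n_regions: int,
    bias_sd: float, bias_scale: int,
) -> list[np.ndarray]:
    """Smooth per-base log-bias per region: knots every bias_scale bp, linear interp.

    Models the shared positional coverage structure of real libraries
    (shearing/GC bias, clone-pool copy differences) that makes RNA and input
    DNA tracks correlate even without enhancer activity.
    """
    fields = []
    for _ in range(n_regions):
        n_knots = max(2, region_length // bias_scale + 1)
        knots = rng.normal(0.0, bias_sd, size=n_knots)
        x = np.linspace(0, region_length - 1, n_knots)
        fields.append(np.interp(np.arange(region_length), x, knots))
    return fields


def generate_library(config: SimConfig, regions: Sequence[GenomeRegion]) -> FragmentLibrary:
    """Sheared-fragment library with truncated-normal lengths and log-normal abundance.

    Per-fragment abundance combines i.i.d. clonal log-normal weight with a
    smooth positional bias field shared by all samples drawn from the
    library, then normalizes to sum 1.
    """
    rng = np.random.default_rng(_child_seed(config.seed, "library"))
    lo, hi = config.fragment_length_bounds
    n = config.n_fragments
    if config.fragment_length_sd <= 0:
        lengths = np.full(n, int(round(config.fragment_length_mean)))
    else:
        a = (lo - config.fragment_length_mean) / config.fragment_length_sd
        b = (hi - config.fragment_length_mean) / config.fragment_length_sd
        lengths = sps.truncnorm.rvs(
            a, b, loc=config.fragment_length_mean,
            scale=config.fragment_length_sd, size=n, random_state=rng,
        ).round().astype(int)
    lengths = np.clip(lengths, lo, hi)
    region_index = rng.integers(0, len(regions), size=n)
    region_lengths = np.array([len(r) for r in regions])
    max_start = region_lengths[region_index] - lengths
    if np.any(max_start < 0):
        raise ValueError("fragment longer than its region")
    starts = (rng.random(n) * (max_start + 1)).astype(int)
    ends = starts + lengths
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sd, size=n)
    if config.bias_sd > 0:
        fields = _bias_field(
            rng, max(len(r) for r in regions), len(regions),
            config.bias_sd, config.bias_scale,
        )
        mid = (starts + ends) // 2
        log_bias = np.array(
            [fields[ri][m] for ri, m in zip(region_index, mid)]
        )
        abundance *= np.exp(log_bias)
    abundance /= abundance.sum()
    return FragmentLibrary(list(regions), region_index, starts, ends, abundance)


def fragment_activity(
    library: FragmentLibrary,
    enhancers: Sequence[EnhancerSpec],
    basal_rate: float,
    basal_field: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-fragment transcription rate: basal times planted activation.

    activity_f = basal * exp(field(midpoint_f)) * (1 + sum_e (effect_e - 1)
    * w_e(f)) with w_e = min(1, overlap_bp / (core_fraction *
    enhancer_width)): activation ramps with overlap and saturates at the
    core fraction. ``basal_field`` is the optional smooth log-activity
    landscape shared by all animals (mild intrinsic transcribability
    differences between sequences, independent of planted enhancers).
    """
    act = np.full(len(library), basal_rate, dtype=float)
    if basal_field is not None:
        mid = (library.starts + library.ends) // 2
        act *= np.exp(
            np.array([basal_field[ri][m] for ri, m in zip(library.region_index, mid)])
        )
    chroms = np.array([library.regions[i].chrom for i in library.region_index])
    boost = np.ones(len(library))
    for e in enhancers:
        on_chrom = chroms == e.region.chrom
        ov = np.minimum(library.ends, e.region.end) - np.maximum(
            library.starts, e.region.start
        )
        ov = np.where(on_chrom, np.maximum(ov, 0), 0)
        w = np.minimum(1.0, ov / (e.core_fraction * len(e.region)))
        boost += (e.effect - 1.0) * w
    return act * boost


def _records_from_counts(
    library: FragmentLibrary,
    counts: np.ndarray,
    sample_id: str,
    rng: np.random.Generator,
    duplication_rate: float,
) -> list[FragmentRecord]:
    idx = np.nonzero(counts)[0]
    recs = []
    for i in idx:
        count = int(counts[i])
        if duplication_rate > 0 and rng.random() < duplication_rate:
            count += int(rng.geometric(0.5))  # PCR copies on top of true multiplicity
        recs.append(FragmentRecord(library.interval(i), sample_id, mapq=60, count=count))
    return recs


def simulate_screen(
    config: SimConfig,
    library: FragmentLibrary,
    truth: SimTruth | None = None,
) -> SimulatedScreen:
    """Draw the input-DNA replicates and per-animal RNA samples.

    DNA replicate counts are Multinomial(dna_depth, abundance); RNA counts
    per animal are Multinomial(rna_depth, abundance * activity), drawn
    independently per animal so cross-animal agreement reflects the shared
    activity landscape, not shared noise.
    """
    sequences, regions = generate_reference(config)
    if truth is None:
        truth = SimTruth(config=config, enhancers=list(config.enhancers), sample_seeds={})
    basal_field = None
    if config.activity_sd > 0:
        field_rng = np.random.default_rng(_child_seed(config.seed, "activity"))
        basal_field = _bias_field(
            field_rng, max(len(r) for r in regions), len(regions),
            config.activity_sd, config.activity_scale,
        )
        bound = config.activity_clip * config.activity_sd
        basal_field = [np.clip(f, -bound, bound) for f in basal_field]
    act = fragment_activity(library, truth.enhancers, config.basal_rate, basal_field)
    truth.fragment_activity = act
    rna_p = library.abundance * act
    rna_p = rna_p / rna_p.sum()

    samples: dict[str, list[FragmentRecord]] = {}
    meta: dict[str, SampleMeta] = {}
    for rep in range(1, config.n_input_reps + 1):
        sid = f"dna_rep{rep}"
        seed = _child_seed(config.seed, sid)
        truth.sample_seeds[sid] = seed
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(config.dna_depth, library.abundance)
        samples[sid] = _records_from_counts(
            library, counts, sid, rng, config.duplication_rate
        )
        meta[sid] = SampleMeta(sid, "dna_input", replicate=rep,
                               total_mapped=int(counts.sum()))
    for animal in range(1, config.n_animals + 1):
        sid = f"rna_mouse{animal}"
        seed = _child_seed(config.seed, sid)
        truth.sample_seeds[sid] = seed
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(config.rna_depth, rna_p)
        samples[sid] = _records_from_counts(
            library, counts, sid, rng, config.duplication_rate
        )
        meta[sid] = SampleMeta(sid, "rna", animal_id=f"mouse{animal}",
                               total_mapped=int(counts.sum()))
    return SimulatedScreen(regions, sequences, library, samples, meta, truth)


def place_enhancers(
    config: SimConfig,
    n_enhancers: int = 20,
    effect: float = 8.0,
    width: int = 1000,
    core_fraction: float = 0.5,
    margin: int = 2000,
    min_separation: int = 3000,
) -> list[EnhancerSpec]:
    """Scatter non-adjacent planted enhancers across the tiled regions."""
    rng = np.random.default_rng(_child_seed(config.seed, "enhancers"))
    specs: list[EnhancerSpec] = []
    tries = 0
    while len(specs) < n_enhancers:
        tries += 1
        if tries > 100 * n_enhancers:
            raise RuntimeError("could not place enhancers with required separation")
        ri = int(rng.integers(0, config.n_regions))
        chrom = f"tile{ri + 1:02d}"
        start = int(rng.integers(margin, config.region_length - margin - width))
        cand = GenomeRegion(chrom, start, start + width)
        if any(
            s.region.chrom == chrom
            and cand.start < s.region.end + min_separation
            and s.region.start - min_separation < cand.end
            for s in specs
        ):
            continue
        specs.append(EnhancerSpec(cand, effect=effect, core_fraction=core_fraction))
    specs.sort(key=lambda s: (s.region.chrom, s.region.start))
    return specs


def default_config(seed: int = 0, n_enhancers: int = 20, effect: float = 8.0) -> SimConfig:
    """The desk-scale study configuration with planted enhancers."""
    cfg = SimConfig(seed=seed)
    if n_enhancers > 0:
        cfg.enhancers = place_enhancers(cfg, n_enhancers=n_enhancers, effect=effect)
    return cfg


def full_scale_config(seed: int = 0, n_enhancers: int = 20, effect: float = 8.0) -> SimConfig:
    """Full-size screen: 9 x ~300 kb regions, 5e5 RNA fragments per animal."""
    cfg = SimConfig(
        seed=seed,
        region_length=300_000,
        n_fragments=500_000,
        dna_depth=2_000_000,
        rna_depth=500_000,
    )
    if n_enhancers > 0:
        cfg.enhancers = place_enhancers(cfg, n_enhancers=n_enhancers, effect=effect)
    return cfg


def simulate_annotations(
    truth: SimTruth,
    regions: Sequence[GenomeRegion],
    sensitivity: float = 0.8,
    background_density: float = 20.0,
    feature_width: int = 600,
    jitter: int = 200,
    conservation_baseline_sd: float = 0.2,
    conservation_bump: float = 0.5,
    repeat_density: float = 40.0,
    repeat_width: int = 250,
    avoid_enhancers: bool = True,
    seed: int | None = None,
) -> tuple[FeatureSet, BaseScoreTrack, FeatureSet]:
    """Feature track, conservation score track and a repeat class with known truth.

    Each planted enhancer emits a feature interval with probability
    ``sensitivity`` (center jittered within +/- jitter bp); background
    features are Poisson-scattered at ``background_density`` per Mb. The
    conservation track is zero-mean Gaussian noise plus a flat bump of
    height ``conservation_bump`` over each enhancer. Repeats are scattered
    at ``repeat_density`` per Mb, rejected over enhancers when
    ``avoid_enhancers`` so the class reads out as depleted.
    """
    if seed is None:
        seed = _child_seed(truth.config.seed, "annotations")
    rng = np.random.default_rng(seed)
    features: list[GenomeRegion] = []
    for e in truth.enhancers:
        if rng.random() >= sensitivity:
            continue
        center = (e.region.start + e.region.end) // 2 + int(
            rng.integers(-jitter, jitter + 1)
        )
        half = feature_width // 2
        start = max(0, center - half)
        features.append(GenomeRegion(e.region.chrom, start, start + feature_width))

    def _scatter(density: float, width: int, avoid: bool) -> list[GenomeRegion]:
        out = []
        for r in regions:
            n = rng.poisson(density * len(r) / 1e6)
            for _ in range(n):
                start = int(rng.integers(0, max(1, len(r) - width)))
                cand = GenomeRegion(r.chrom, r.start + start, r.start + start + width)
                if avoid and any(cand.overlaps(e.region) for e in truth.enhancers):
                    continue
                out.append(cand)
        return out

    features.extend(_scatter(background_density, feature_width, avoid=False))
    feature_set = FeatureSet("synthetic_enhancer_marks", features)

    values = []
    for r in regions:
        v = rng.normal(0.0, conservation_baseline_sd, size=len(r))
        for e in truth.enhancers:
            if e.region.chrom == r.chrom:
                lo = max(e.region.start, r.start) - r.start
                hi = min(e.region.end, r.end) - r.start
                if hi > lo:
                    v[lo:hi] += conservation_bump
        values.append(v)
    conservation = BaseScoreTrack(list(regions), values)

    repeats = FeatureSet(
        "synthetic_repeats", _scatter(repeat_density, repeat_width, avoid=avoid_enhancers)
    )
    return feature_set, conservation, repeats


def simulate_reporter_cells(
    constructs: Mapping[str, float],
    ref_channel: str,
    n_cells: int = 500,
    n_images: int = 6,
    transduction_mean: float = 5.0,
    signal_scale: float = 200.0,  # intensity units per copy at unit strength
    channel_noise_sd: float = 0.15,
    cell_scale_sd: float = 0.3,
    bg_mean: float = 20.0,
    bg_sd: float = 4.0,
    layer_probs: Mapping[str, float] | None = None,
    colabel_channels: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-cell intensity table emulating the multiplexed reporter assay.

    Every cell carries a zero-truncated Poisson number of vector copies
    shared across the co-packaged constructs (the premise of same-cell
    reference normalization), a log-normal per-cell imaging scale that
    cancels in ratios, log-normal per-channel measurement noise
    (sd ``channel_noise_sd`` in natural log) that does not, and additive
    Gaussian background. ``constructs`` maps channel name to true strength
    relative to the reference. Optional ``colabel_channels`` adds binary
    marker channels positive at the given rate, independent of the reporters.
    """
    if ref_channel not in constructs:
        raise ValueError("reference channel must be among the constructs")
    rng = np.random.default_rng(seed)
    layers = list(layer_probs) if layer_probs else ["L1", "L2", "L3", "L4", "L5", "L6"]
    probs = (
        np.array([layer_probs[l] for l in layers])
        if layer_probs
        else np.full(len(layers), 1 / len(layers))
    )
    probs = probs / probs.sum()

    copies = rng.poisson(transduction_mean, size=n_cells)
    while np.any(copies == 0):  # zero-truncated: every scored cell is transduced
        zeros = copies == 0
        copies[zeros] = rng.poisson(transduction_mean, size=int(zeros.sum()))
    cell_scale = rng.lognormal(0.0, cell_scale_sd, size=n_cells)

    data = {
        "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
        "image_id": [f"img{(i % n_images) + 1:02d}" for i in range(n_cells)],
        "x": rng.uniform(0, 400, size=n_cells).round(2),
        "y": rng.uniform(0, 400, size=n_cells).round(2),
        "layer": rng.choice(layers, size=n_cells, p=probs),
    }
    bg_rows = []
    for ch, strength in constructs.items():
        noise = rng.lognormal(0.0, channel_noise_sd, size=n_cells)
        signal = copies * strength * signal_scale * cell_scale * noise
        background = rng.normal(bg_mean, bg_sd, size=n_cells)
        data[ch] = np.maximum(signal + background, 0.0)
    for ch in constructs:
        for img in sorted(set(data["image_id"])):
            bg_rows.append((img, ch, bg_mean, bg_sd))

    colabel_truth = {}
    if colabel_channels:
        for ch, rate in colabel_channels.items():
            labelled = rng.random(n_cells) < rate
            intensity = np.where(
                labelled,
                bg_mean + 10.0 * bg_sd + rng.normal(0, bg_sd, n_cells),
                rng.normal(bg_mean, bg_sd, n_cells),
            )
            data[ch] = np.maximum(intensity, 0.0)
            colabel_truth[ch] = labelled
            for img in sorted(set(data["image_id"])):
                bg_rows.append((img, ch, bg_mean, bg_sd))

    cells = pd.DataFrame(data)
    backgrounds = pd.DataFrame(
        bg_rows, columns=["image_id", "channel", "bg_mean", "bg_sd"]
    )
    truth = {
        "constructs": dict(constructs),
        "ref_channel": ref_channel,
        "copies": copies,
        "colabel": colabel_truth,
        "layer_probs": dict(zip(layers, probs)),
        "seed": seed,
    }
    return cells, backgrounds, truth


def write_fragments_bed(records: Sequence[FragmentRecord], path: str | Path) -> None:
    """Fragments as BED5 (name=sample, score column = MAPQ), one line per copy-set."""
    with open(path, "w") as fh:
        for f in records:
            for _ in range(f.count):
                fh.write(
                    f"{f.region.chrom}\t{f.region.start}\t{f.region.end}"
                    f"\t{f.sample_id}\t{f.mapq}\n"
                )


def write_bedgraph(track: BaseScoreTrack, path: str | Path, decimals: int = 4) -> None:
    """Run-length-compressed bedGraph of a base-wise score track."""
    with open(path, "w") as fh:
        for r, v in zip(track.regions, track.values):
            vals = np.round(v, decimals)
            start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[start]:
                    if not np.isnan(vals[start]):
                        fh.write(
                            f"{r.chrom}\t{r.start + start}\t{r.start + i}"
                            f"\t{vals[start]:g}\n"
                        )
                    start = i


def write_fasta(sequences: Sequence[str], regions: Sequence[GenomeRegion],
                path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for seq, r in zip(sequences, regions):
            fh.write(f">{r.chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
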
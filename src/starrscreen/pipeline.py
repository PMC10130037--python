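"""End-to-end orchestration: simulate or load a screen, call peaks, run statistics.

The pipeline sequences the analysis stages in dependency order — coverage
tracks and correlations, per-replicate peak calling, within-animal and
across-animal consensus, shuffled-null enrichment, conservation comparison,
and the reporter-validation arm — skipping stages whose inputs are absent,
and writes a reproducibility manifest (config snapshot, input checksums,
per-stage seeds, artifact inventory) sufficient to re-derive every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    BaseScoreTrack,
    FeatureSet,
    ShuffleConfig,
    conservation_compare,
    enrichment_test,
    make_shuffle_ensemble,
    repeat_class_enrichment,
)
from .genomic_signal import (
    FragmentRecord,
    bin_and_correlate,
    coverage_depth_profile,
    coverage_track,
    deduplicate_fragments,
    fold_change_track,
    load_fragments,
    raw_coverage_track,
)
from .intervals import GenomeRegion, read_bed, write_bed
from .peak_caller import (
    ConsensusPeak,
    Peak,
    PeakSet,
    WindowStats,
    call_peaks,
    consensus_peaks,
    count_fragments_in_windows,
    fit_background,
    make_windows,
    reproducibility_profile,
    score_windows,
)
from .simulate import (
    SimConfig,
    SimulatedScreen,
    generate_library,
    generate_reference,
    simulate_annotations,
    simulate_screen,
    write_bedgraph,
    write_fasta,
    write_fragments_bed,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for schema violations in the run configuration."""


@dataclass
class CallerParams:
    """All tunables of the window caller and the consensus filters."""

    window_width: int = 500
    window_step: int = 100
    q_max: float = 0.05
    min_fold: float = 1.5
    min_input: int = 10
    # first-pass background-fit trim: generous enough that a realistically
    # dense enhancer landscape (10-20% of windows touched) cannot inflate the
    # dispersion estimate and mask itself; a second pass refits without
    # blanket trimming, excluding only windows the first pass flags, so the
    # null dispersion stays unbiased
    trim_top: float = 0.15
    refit: bool = True
    refit_q: float = 0.1  # first-pass q below which a window is held out
    merge_gap: int = 0
    min_support_input: int = 2  # of the input-DNA technical replicates
    min_support_animals: int | None = None  # default: all animals
    deduplicate: bool = False
    pseudocount: float = 1.0
    bin_width: int = 1000


@dataclass
class ScreenCallResult:
    windows: list
    animal_peak_sets: list[PeakSet]
    replicate_peak_sets: dict[str, list[PeakSet]]
    consensus: list[ConsensusPeak]
    support_histogram: dict[int, int]
    fraction_full_support: float


@dataclass
class RecoveryReport:
    """Truth-matched summary of a simulated screen run."""

    n_planted: int
    n_consensus: int
    n_matched_enhancers: int
    n_true_positive_peaks: int
    sensitivity: float
    precision: float
    fraction_full_support: float
    support_histogram: dict[int, int]
    per_animal_peak_counts: dict[str, int]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def call_screen(
    regions: Sequence[GenomeRegion],
    sequences: Sequence[str] | None,
    rna_samples: dict[str, list[FragmentRecord]],
    dna_samples: dict[str, list[FragmentRecord]],
    params: CallerParams | None = None,
) -> ScreenCallResult:
    """Per-replicate peak calling plus both consensus filters.

    For each animal, peaks are called once against every input-DNA
    replicate; peaks supported by at least ``min_support_input`` replicate
    calls form the animal's peak set, and the final consensus keeps clusters
    supported by ``min_support_animals`` animals (default: all).
    """
    params = params or CallerParams()
    windows = make_windows(
        regions, width=params.window_width, step=params.window_step,
        sequences=list(sequences) if sequences is not None else None,
    )
    if not windows:
        raise ValueError("no windows could be formed on the given regions")

    def _prep(frags: list[FragmentRecord]) -> list[FragmentRecord]:
        return deduplicate_fragments(frags) if params.deduplicate else frags

    dna_counts = {
        sid: count_fragments_in_windows(_prep(frags), windows)
        for sid, frags in dna_samples.items()
    }
    animal_sets: list[PeakSet] = []
    replicate_sets: dict[str, list[PeakSet]] = {}
    for animal_id, frags in rna_samples.items():
        rna_counts = count_fragments_in_windows(_prep(frags), windows)
        per_rep: list[PeakSet] = []
        for rep_id, d in dna_counts.items():
            stats_in = [
                WindowStats(w, int(r), int(dc))
                for w, r, dc in zip(windows, rna_counts, d)
            ]
            fit = fit_background(
                stats_in, min_input=params.min_input, trim_top=params.trim_top
            )
            scored = score_windows(stats_in, fit)
            if params.refit:
                # second pass: hold out first-pass candidates instead of a
                # blanket count trim, then rescore everything
                background = [
                    s_in for s_in, s_sc in zip(stats_in, scored)
                    if s_sc.q >= params.refit_q
                ]
                if len([s for s in background if s.dna_count >= params.min_input]) >= 50:
                    fit = fit_background(
                        background, min_input=params.min_input, trim_top=0.0
                    )
                    scored = score_windows(stats_in, fit)
            per_rep.append(
                call_peaks(
                    scored,
                    q_max=params.q_max,
                    min_fold=params.min_fold,
                    merge_gap=params.merge_gap,
                    sample_id=f"{animal_id}|{rep_id}",
                )
            )
        replicate_sets[animal_id] = per_rep
        clusters = consensus_peaks(per_rep, min_support=params.min_support_input)
        animal_sets.append(
            PeakSet(
                sample_id=animal_id,
                peaks=[
                    Peak(c.region, c.mean_score,
                         summit=(c.region.start + c.region.end) // 2,
                         sources=(animal_id,))
                    for c in clusters
                ],
            )
        )
    n_animals = len(animal_sets)
    min_support = params.min_support_animals or n_animals
    consensus = consensus_peaks(animal_sets, min_support=min_support)
    if n_animals >= 2:
        hist, frac = reproducibility_profile(animal_sets)
    else:
        hist, frac = {1: len(consensus)}, float("nan")
    return ScreenCallResult(
        windows=windows,
        animal_peak_sets=animal_sets,
        replicate_peak_sets=replicate_sets,
        consensus=consensus,
        support_histogram=hist,
        fraction_full_support=frac,
    )


def match_to_truth(
    consensus: Sequence[ConsensusPeak], enhancers: Sequence
) -> tuple[int, int]:
    """(planted enhancers recovered, consensus peaks overlapping truth) by >=1 bp."""
    enh_regions = [e.region for e in enhancers]
    matched = sum(
        1 for e in enh_regions if any(c.region.overlaps(e) for c in consensus)
    )
    true_pos = sum(
        1 for c in consensus if any(c.region.overlaps(e) for e in enh_regions)
    )
    return matched, true_pos


def simulate_and_run(
    sim_config: SimConfig,
    params: CallerParams | None = None,
) -> tuple[RecoveryReport, SimulatedScreen, ScreenCallResult]:
    """Generate a screen, run the caller, and score recovery against truth.

    Sensitivity = planted enhancers overlapped by a consensus peak / planted;
    precision = consensus peaks overlapping a planted enhancer / consensus
    peaks; both by >= 1 bp overlap. With no planted enhancers sensitivity is
    undefined (NaN) and the peak count is the false-call report.
    """
    _, regions = generate_reference(sim_config)
    library = generate_library(sim_config, regions)
    screen = simulate_screen(sim_config, library)
    rna = {s: f for s, f in screen.samples.items() if screen.sample_meta[s].role == "rna"}
    dna = {s: f for s, f in screen.samples.items()
           if screen.sample_meta[s].role == "dna_input"}
    result = call_screen(screen.regions, screen.sequences, rna, dna, params)
    enhancers = screen.truth.enhancers
    matched, true_pos = match_to_truth(result.consensus, enhancers)
    n_cons = len(result.consensus)
    report = RecoveryReport(
        n_planted=len(enhancers),
        n_consensus=n_cons,
        n_matched_enhancers=matched,
        n_true_positive_peaks=true_pos,
        sensitivity=matched / len(enhancers) if enhancers else float("nan"),
        precision=true_pos / n_cons if n_cons else float("nan"),
        fraction_full_support=result.fraction_full_support,
        support_histogram=result.support_histogram,
        per_animal_peak_counts={ps.sample_id: len(ps) for ps in result.animal_peak_sets},
    )
    return report, screen, result


# ---------------------------------------------------------------------------
# file-based run orchestration


def load_run_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    return cfg


_ALLOWED_TOP_KEYS = {
    "outdir", "seed", "simulate", "regions", "fasta", "fragments",
    "annotations", "conservation", "repeats", "cells", "params", "shuffle",
    "reporter",
}


def _caller_params(cfg: dict[str, Any]) -> CallerParams:
    p = cfg.get("params", {}) or {}
    known = {f.name for f in dataclasses.fields(CallerParams)}
    bad = set(p) - known
    if bad:
        raise ConfigError(f"unknown params keys: {sorted(bad)}")
    return CallerParams(**p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict[str, Any] | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute all applicable stages and write outputs plus a run manifest.

    ``config`` is a mapping (or path to a YAML file) with keys: ``outdir``,
    ``seed``, either ``simulate`` (synthetic-screen options) or ``regions``
    + ``fragments`` (paths to BED inputs), and optional ``annotations``,
    ``conservation``, ``repeats``, ``cells`` and ``params`` sections. Stages
    whose inputs are absent are skipped and logged. Returns the manifest.
    """
    t0 = time.time()
    if isinstance(config, (str, Path)):
        config = load_run_config(config)
    bad = set(config) - _ALLOWED_TOP_KEYS
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    out = Path(outdir or config.get("outdir", "starrscreen_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = _caller_params(config)
    manifest: dict[str, Any] = {
        "tool": "starrscreen",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "inputs": {},
        "artifacts": [],
        "stages": {},
    }

    def _artifact(p: Path) -> None:
        manifest["artifacts"].append(str(p.relative_to(out)))

    # --- acquire the screen (simulate or load) ------------------------------
    annotations: list[FeatureSet] = []
    repeats: list[FeatureSet] = []
    conservation: BaseScoreTrack | None = None
    if "simulate" in config:
        sim_opts = dict(config.get("simulate") or {})
        n_enh = int(sim_opts.pop("n_enhancers", 20))
        effect = float(sim_opts.pop("effect", 8.0))
        with_annotations = bool(sim_opts.pop("annotations", True))
        known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_opts) - known
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
        sim_cfg = SimConfig(seed=seed, **sim_opts)
        if n_enh > 0:
            from .simulate import place_enhancers

            sim_cfg.enhancers = place_enhancers(
                sim_cfg, n_enhancers=n_enh, effect=effect
            )
        _, regions = generate_reference(sim_cfg)
        library = generate_library(sim_cfg, regions)
        screen = simulate_screen(sim_cfg, library)
        regions, sequences = screen.regions, screen.sequences
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        write_fasta(sequences, regions, sim_dir / "reference.fa")
        write_bed(regions, sim_dir / "regions.bed")
        write_bed([e.region for e in screen.truth.enhancers], sim_dir / "enhancers.bed")
        (sim_dir / "truth.json").write_text(screen.truth.to_json())
        for sid, frags in screen.samples.items():
            write_fragments_bed(frags, sim_dir / f"{sid}.bed")
            _artifact(sim_dir / f"{sid}.bed")
        for p in ("reference.fa", "regions.bed", "enhancers.bed", "truth.json"):
            _artifact(sim_dir / p)
        rna = {s: f for s, f in screen.samples.items()
               if screen.sample_meta[s].role == "rna"}
        dna = {s: f for s, f in screen.samples.items()
               if screen.sample_meta[s].role == "dna_input"}
        totals = {s: m.total_mapped for s, m in screen.sample_meta.items()}
        if with_annotations:
            feats, conservation, reps = simulate_annotations(screen.truth, regions)
            annotations = [feats]
            repeats = [reps]
        manifest["stages"]["simulate"] = {"seed": seed, "n_enhancers": n_enh}
        truth_enhancers = screen.truth.enhancers
    else:
        if "regions" not in config or "fragments" not in config:
            raise ConfigError("need either 'simulate' or 'regions' + 'fragments'")
        regions = read_bed(config["regions"])
        manifest["inputs"][str(config["regions"])] = _sha256(Path(config["regions"]))
        sequences = None
        if config.get("fasta"):
            sequences = _read_fasta_for_regions(config["fasta"], regions)
            manifest["inputs"][str(config["fasta"])] = _sha256(Path(config["fasta"]))
        rna, dna, totals = {}, {}, {}
        for sid, spec in (config["fragments"] or {}).items():
            frags = load_fragments(spec["path"], regions,
                                   min_mapq=int(spec.get("min_mapq", 3)),
                                   sample_id=sid)
            manifest["inputs"][str(spec["path"])] = _sha256(Path(spec["path"]))
            totals[sid] = sum(f.count for f in frags) or 1
            (rna if spec["role"] == "rna" else dna)[sid] = frags
        if not rna or not dna:
            raise ConfigError("need at least one rna and one dna_input sample")
        truth_enhancers = []
        for section, store in (("annotations", annotations), ("repeats", repeats)):
            for item in config.get(section) or []:
                store.append(FeatureSet(item["label"], read_bed(item["path"])))
                manifest["inputs"][str(item["path"])] = _sha256(Path(item["path"]))
        if config.get("conservation"):
            conservation = BaseScoreTrack.from_bedgraph(config["conservation"], regions)
            manifest["inputs"][str(config["conservation"])] = _sha256(
                Path(config["conservation"])
            )

    # --- tracks stage -------------------------------------------------------
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    cov = {}
    for sid, frags in {**rna, **dna}.items():
        cov[sid] = coverage_track(frags, regions, total_mapped=totals[sid])
    sample_ids = sorted(cov)
    _, corr = bin_and_correlate([cov[s] for s in sample_ids], regions,
                                bin_width=params.bin_width)
    pd.DataFrame(corr, index=sample_ids, columns=sample_ids).to_csv(
        tracks_dir / "correlation.tsv", sep="\t"
    )
    _artifact(tracks_dir / "correlation.tsv")
    pooled_dna_frags = [f for frags in dna.values() for f in frags]
    pooled_total = sum(totals[s] for s in dna)
    pooled_dna = coverage_track(pooled_dna_frags, regions, total_mapped=pooled_total)
    fc_tracks = {}
    for sid in rna:
        fc = fold_change_track(cov[sid], pooled_dna, pseudocount=params.pseudocount)
        fc_tracks[sid] = fc
        arrays = [np.where(m, np.nan, v) for v, m in zip(fc.values, fc.mask)]
        write_bedgraph(BaseScoreTrack(regions, arrays),
                       tracks_dir / f"{sid}.log2fc.bedgraph", decimals=3)
        _artifact(tracks_dir / f"{sid}.log2fc.bedgraph")
    raw = raw_coverage_track(pooled_dna_frags, regions)
    profile = coverage_depth_profile(raw, [1, 10, 100])
    (tracks_dir / "depth_profile.json").write_text(
        json.dumps({"thresholds": [1, 10, 100], "fraction_at_least": profile}, indent=2)
    )
    _artifact(tracks_dir / "depth_profile.json")
    manifest["stages"]["tracks"] = {"n_samples": len(cov)}

    # --- peak calling + consensus ------------------------------------------
    result = call_screen(regions, sequences, rna, dna, params)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for ps in result.animal_peak_sets:
        write_bed([p.region for p in ps.peaks], peaks_dir / f"{ps.sample_id}.bed",
                  scores=[min(1000, round(100 * p.score)) for p in ps.peaks])
        _artifact(peaks_dir / f"{ps.sample_id}.bed")
    cons_regions = [c.region for c in result.consensus]
    write_bed(cons_regions, peaks_dir / "consensus.bed",
              scores=[round(c.mean_score, 3) for c in result.consensus])
    _artifact(peaks_dir / "consensus.bed")
    pd.DataFrame(
        sorted(result.support_histogram.items()), columns=["support", "n_clusters"]
    ).to_csv(peaks_dir / "support_histogram.tsv", sep="\t", index=False)
    _artifact(peaks_dir / "support_histogram.tsv")
    manifest["stages"]["peaks"] = {
        "n_consensus": len(result.consensus),
        "fraction_full_support": result.fraction_full_support,
    }

    # --- enrichment + conservation -----------------------------------------
    shuffle_opts = config.get("shuffle") or {}
    n_sets = int(shuffle_opts.get("n_sets", 1000))
    if cons_regions and (annotations or repeats or conservation is not None):
        sh_cfg = ShuffleConfig(
            n_sets=n_sets,
            max_tries=int(shuffle_opts.get("max_tries", 10000)),
            universe=list(regions),
        )
        ensemble = make_shuffle_ensemble(cons_regions, sh_cfg)
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        rows = []
        for fs in [*annotations, *repeats]:
            res = enrichment_test(cons_regions, fs, sh_cfg, ensemble=ensemble)
            rows.append(
                (fs.label, res.observed, float(res.null_values.mean()),
                 float(res.null_values.std(ddof=1)), res.z, res.p_emp, res.direction)
            )
        if rows:
            pd.DataFrame(
                rows,
                columns=["label", "observed", "null_mean", "null_sd", "z",
                         "p_emp", "direction"],
            ).to_csv(enr_dir / "enrichment.tsv", sep="\t", index=False)
            _artifact(enr_dir / "enrichment.tsv")
            manifest["stages"]["enrich"] = {"n_feature_sets": len(rows),
                                            "n_shuffles": n_sets}
        if conservation is not None:
            cres = conservation_compare(cons_regions, ensemble[:100], conservation,
                                        alternative="greater")
            (enr_dir / "conservation.json").write_text(json.dumps({
                "p_value": cres.p_value,
                "statistic": cres.statistic,
                "n_peaks": int(len(cres.peak_means)),
                "peak_mean_of_means": float(np.mean(cres.peak_means)),
                "null_mean_of_means": float(np.mean(cres.null_means)),
                "ecdf_peaks": [cres.ecdf_peaks[0].tolist(),
                               cres.ecdf_peaks[1].tolist()],
            }, indent=2))
            _artifact(enr_dir / "conservation.json")
            manifest["stages"]["conserve"] = {"p_value": cres.p_value}
    else:
        logger.info("enrichment/conservation inputs absent or no peaks; skipped")

    # --- reporter arm -------------------------------------------------------
    cells_cfg = config.get("cells")
    if cells_cfg:
        from .reporter import (classify_cells, correlate_screen_validation,
                               validation_scores)

        cells = pd.read_csv(cells_cfg["table"], sep="\t")
        backgrounds = pd.read_csv(cells_cfg["backgrounds"], sep="\t")
        manifest["inputs"][str(cells_cfg["table"])] = _sha256(Path(cells_cfg["table"]))
        rep_dir = out / "reporter"
        rep_dir.mkdir(exist_ok=True)
        flags = classify_cells(cells, backgrounds,
                               k=float(cells_cfg.get("k", 3.0)))
        scores = validation_scores(
            cells, cells_cfg["vs_channel_map"], cells_cfg["ref_channel"],
            positivity=flags, cell_filter=cells_cfg.get("cell_filter", "ref_positive"),
        )
        pd.DataFrame(
            [(s.vs_id, s.n_cells, s.median_log10_ratio) for s in scores],
            columns=["vs_id", "n_cells", "validation_score"],
        ).to_csv(rep_dir / "validation_scores.tsv", sep="\t", index=False)
        _artifact(rep_dir / "validation_scores.tsv")
        vs_regions_path = cells_cfg.get("vs_regions")
        if vs_regions_path and fc_tracks:
            vs_regions = {r.name or f"vs{i}": r
                          for i, r in enumerate(read_bed(vs_regions_path))}
            mean_fc = _mean_fold_change(list(fc_tracks.values()), regions)
            r, p, table = correlate_screen_validation(mean_fc, vs_regions, scores)
            table.to_csv(rep_dir / "screen_vs_validation.tsv", sep="\t", index=False)
            (rep_dir / "correlation.json").write_text(
                json.dumps({"pearson_r": r, "p_value": p, "n": len(table)}, indent=2)
            )
            _artifact(rep_dir / "screen_vs_validation.tsv")
            _artifact(rep_dir / "correlation.json")
            manifest["stages"]["reporter"] = {"pearson_r": r, "p_value": p}
        else:
            manifest["stages"]["reporter"] = {"n_scores": len(scores)}
    else:
        logger.info("no cell tables configured; reporter stage skipped")

    if truth_enhancers:
        matched, true_pos = match_to_truth(result.consensus, truth_enhancers)
        manifest["stages"]["recovery"] = {
            "sensitivity": matched / len(truth_enhancers),
            "precision": true_pos / len(result.consensus) if result.consensus else None,
        }
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(out / "manifest.json")
    return manifest


def _mean_fold_change(tracks, regions):
    """Average the per-animal log2FC tracks base-wise (masked bases excluded)."""
    from .genomic_signal import FoldChangeTrack

    values, masks = [], []
    for ri in range(len(regions)):
        stack = np.stack([np.where(t.mask[ri], np.nan, t.values[ri]) for t in tracks])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        mask = np.all(np.isnan(stack), axis=0)
        values.append(np.where(mask, 0.0, mean))
        masks.append(mask)
    return FoldChangeTrack(list(regions), values, masks,
                           pseudocount=tracks[0].pseudocount)


def _read_fasta_for_regions(path: str | Path, regions: Sequence[GenomeRegion]) -> list[str]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    out = []
    for r in regions:
        if r.chrom not in seqs:
            raise ConfigError(f"sequence {r.chrom!r} missing from {path}")
        out.append(seqs[r.chrom][r.start : r.end])
    return out
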
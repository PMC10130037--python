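"""Fluorescence-reporter validation quantification from per-cell tables.

The validation arm expresses candidate sequences upstream of a minimal
promoter driving a nuclear fluorescent reporter, co-delivered with a
CMV-driven reference reporter so that per-cell normalization cancels
transduction copy number. This module consumes per-cell mean intensities
(one row per segmented nucleus) plus per-image background statistics and
computes: positivity calls (background + k*SD rule), per-construct
validation scores (median log10 of the reference-normalized ratio),
cortical-layer distributions, co-labeling fractions, and the correlation
between screen fold-change signal and validation scores.

Cell tables are pandas DataFrames with columns ``cell_id``, ``image_id``,
``x``, ``y``, ``layer`` and one column per fluorescence channel; background
tables have columns ``image_id``, ``channel``, ``bg_mean``, ``bg_sd``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_signal import FoldChangeTrack
from .intervals import GenomeRegion

logger = logging.getLogger(__name__)

META_COLUMNS = ("cell_id", "image_id", "x", "y", "layer")
LAYERS = ("L1", "L2", "L3", "L4", "L5", "L6")


@dataclass
class ValidationResult:
    """Validation score of one construct: median log10(signal / reference)."""

    vs_id: str
    n_cells: int
    median_log10_ratio: float
    ratios: np.ndarray


def channel_columns(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c not in META_COLUMNS]


def classify_cells(
    cells: pd.DataFrame,
    backgrounds: pd.DataFrame,
    k: float = 3.0,
) -> pd.DataFrame:
    """Positivity flags per cell and channel: intensity > bg_mean + k*bg_sd.

    The inequality is strict, so a cell exactly at the threshold is negative.
    Backgrounds are matched per image; a channel missing background stats in
    an image yields absent (NA) flags with a warning.
    """
    channels = channel_columns(cells)
    bg = backgrounds.set_index(["image_id", "channel"])
    flags = pd.DataFrame(index=cells.index, columns=channels, dtype=object)
    for image_id, idx in cells.groupby("image_id").groups.items():
        for ch in channels:
            try:
                row = bg.loc[(image_id, ch)]
            except KeyError:
                logger.warning("image %s: no background for channel %s", image_id, ch)
                flags.loc[idx, ch] = pd.NA
                continue
            thr = float(row["bg_mean"]) + k * float(row["bg_sd"])
            flags.loc[idx, ch] = (cells.loc[idx, ch] > thr).to_numpy()
    return flags.astype("boolean")


def validation_scores(
    cells: pd.DataFrame,
    vs_channel_map: Mapping[str, str],
    ref_channel: str,
    positivity: pd.DataFrame | None = None,
    cell_filter: str = "ref_positive",
) -> list[ValidationResult]:
    """Median log10 reference-normalized fluorescence per construct.

    Per-cell ratio = intensity(construct channel) / intensity(reference
    channel), defined only where the reference intensity is positive. The
    default policy restricts to reference-positive cells (requires
    ``positivity``); policy "all" uses every cell with a nonzero reference.
    Constructs with no eligible cell report a missing score.
    """
    if ref_channel not in cells.columns:
        raise ValueError(f"reference channel {ref_channel!r} missing from cell table")
    if cell_filter == "ref_positive":
        if positivity is None:
            raise ValueError("ref_positive policy requires positivity flags")
        eligible = positivity[ref_channel].fillna(False).to_numpy(dtype=bool)
    elif cell_filter == "all":
        eligible = np.ones(len(cells), dtype=bool)
    else:
        raise ValueError(f"unknown cell_filter {cell_filter!r}")
    eligible &= cells[ref_channel].to_numpy(dtype=float) > 0

    results = []
    ref = cells[ref_channel].to_numpy(dtype=float)
    for vs_id, ch in vs_channel_map.items():
        if ch not in cells.columns:
            raise ValueError(f"channel {ch!r} for {vs_id} missing from cell table")
        sig = cells[ch].to_numpy(dtype=float)
        use = eligible & (sig > 0)
        if not use.any():
            logger.warning("%s: no eligible cells, score missing", vs_id)
            results.append(ValidationResult(vs_id, 0, float("nan"), np.array([])))
            continue
        ratios = sig[use] / ref[use]
        score = float(np.median(np.log10(ratios)))
        results.append(ValidationResult(vs_id, int(use.sum()), score, ratios))
    return results


def layer_distribution(
    cells: pd.DataFrame,
    positivity: pd.DataFrame,
    channel: str,
    layers: Sequence[str] = LAYERS,
) -> pd.DataFrame:
    """Distribution of positive cells across cortical layers, mean ± SD.

    Per image the fractions over assigned layers sum to 1; images with zero
    positive cells are excluded (logged). Returns a DataFrame indexed by
    layer with columns ``mean`` and ``sd`` plus per-image fractions.
    """
    pos = positivity[channel].fillna(False).to_numpy(dtype=bool)
    sub = cells.loc[pos & cells["layer"].isin(layers)]
    per_image = {}
    for image_id, grp in sub.groupby("image_id"):
        counts = grp["layer"].value_counts().reindex(layers, fill_value=0)
        total = counts.sum()
        if total == 0:
            continue
        per_image[image_id] = counts / total
    skipped = set(cells["image_id"].unique()) - set(per_image)
    for im in sorted(skipped):
        logger.info("image %s: no positive cells in assigned layers, excluded", im)
    if not per_image:
        raise ValueError("no image with positive cells in assigned layers")
    table = pd.DataFrame(per_image)
    out = pd.DataFrame(
        {"mean": table.mean(axis=1), "sd": table.std(axis=1, ddof=1)}
    )
    return pd.concat([out, table], axis=1)


def colabel_fractions(
    cells: pd.DataFrame,
    positivity: pd.DataFrame,
    channel_a: str,
    channel_b: str,
) -> tuple[float, float, pd.Series]:
    """Percentage of channel-A-positive cells also positive for channel B.

    Computed per image as 100 * |A∩B| / |A|; images with no A-positive cell
    are excluded (logged). Returns (mean, SD across images, per-image series).
    The reverse fraction is obtained by swapping the channel arguments.
    """
    a = positivity[channel_a].fillna(False).to_numpy(dtype=bool)
    b = positivity[channel_b].fillna(False).to_numpy(dtype=bool)
    frame = pd.DataFrame(
        {"image_id": cells["image_id"].to_numpy(), "a": a, "ab": a & b}
    )
    per_image = {}
    for image_id, grp in frame.groupby("image_id"):
        n_a = int(grp["a"].sum())
        if n_a == 0:
            logger.info("image %s: no %s-positive cells, excluded", image_id, channel_a)
            continue
        per_image[image_id] = 100.0 * int(grp["ab"].sum()) / n_a
    series = pd.Series(per_image, dtype=float)
    if series.empty:
        return float("nan"), float("nan"), series
    sd = float(series.std(ddof=1)) if len(series) > 1 else float("nan")
    return float(series.mean()), sd, series


def correlate_screen_validation(
    screen_track: FoldChangeTrack,
    vs_regions: Mapping[str, GenomeRegion],
    scores: Sequence[ValidationResult],
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation between screen signal and validation scores.

    The screen value per construct is the mean of the log2(RNA/DNA)
    fold-change track over its genomic region (masked bases excluded); the
    validation value is its median log10 relative fluorescence. The p-value
    is two-sided from the t transform with n-2 degrees of freedom; with
    fewer than 3 pairs only r is reported.
    """
    from .enrichment import BaseScoreTrack, interval_mean_scores

    arrays = []
    for v, m in zip(screen_track.values, screen_track.mask):
        a = v.copy()
        a[m] = np.nan
        arrays.append(a)
    track = BaseScoreTrack(screen_track.regions, arrays)

    rows = []
    by_id = {s.vs_id: s for s in scores}
    for vs_id, region in vs_regions.items():
        s = by_id.get(vs_id)
        if s is None or np.isnan(s.median_log10_ratio):
            continue
        screen_val = float(interval_mean_scores(track, [region])[0])
        rows.append((vs_id, screen_val, s.median_log10_ratio, s.n_cells))
    table = pd.DataFrame(
        rows, columns=["vs_id", "screen_mean_log2fc", "validation_score", "n_cells"]
    )
    table = table.dropna(subset=["screen_mean_log2fc"])
    n = len(table)
    if n < 2:
        raise ValueError("need >= 2 paired points for a correlation")
    r, p = stats.pearsonr(table["screen_mean_log2fc"], table["validation_score"])
    if n < 3:
        p = float("nan")
    return float(r), float(p), table


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n via the t transform."""
    if n < 3:
        return float("nan")
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))
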
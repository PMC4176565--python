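"""S-vs-G1 differential signal and copy-number-aware correction.

In HU-arrested S phase only early origins have fired, so nucleosomal
coverage doubles over the replicated 2-2.5 kb on either side of them.
This module computes the S minus G1 differential track, corrects raw
nucleosomal coverage by a naked-DNA copy-number estimate (naked track
rescaled to genome mean 1, then smoothed with a sliding 1000-bp mean at
1-bp step), measures the replicated extent around an origin, and reports
per-group nucleosome feature shifts between matched G1/S window
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .coverage import CoverageTrack, sliding_mean
from .io import OriginRecord
from .origin_architecture import OriginProfileMatrix, aggregate_profile, window_ndr_width
from . import ndr as ndr_mod

logger = logging.getLogger("orichrom.dynamics")

DEFAULT_WINDOW = 1000
DEFAULT_EXTENT_SEARCH = 6000     # bp scanned on either side of the ACS
DEFAULT_EXTENT_REL_THRESHOLD = 0.25  # fraction of the origin's peak differential
# A fired origin's window-averaged differential plateaus near the local
# signal amplitude (copy number doubles); sampling noise peaks stay well
# below ~0.2 at the coverages analyzed.  Peaks under this floor are
# treated as not fired.
MIN_PEAK_DIFFERENTIAL = 0.3
PEAK_SEARCH_RADIUS = 300         # bp around the NDR minimum for -1/+1 peaks


@dataclass
class DifferentialTrack:
    """Per-chromosome S-phase minus G1 signal."""

    values: dict[str, np.ndarray]


def differential_track(s_track: CoverageTrack, g1_track: CoverageTrack) -> DifferentialTrack:
    """Elementwise S minus G1; both tracks must share the genome."""
    if s_track.chrom_lengths != g1_track.chrom_lengths:
        raise ValueError("S and G1 tracks cover different genomes")
    return DifferentialTrack(
        {c: s_track.values[c] - g1_track.values[c] for c in s_track.values}
    )


def copy_number_correct(
    nuc_track_raw: CoverageTrack,
    naked_track_raw: CoverageTrack,
    window: int = DEFAULT_WINDOW,
    step: int = 1,
) -> CoverageTrack:
    """Divide nucleosomal coverage by a naked-DNA copy-number estimate.

    The naked track is rescaled to genome mean 1 and smoothed with a
    centered sliding ``window``-bp mean (step 1) to form the per-base
    copy-number estimate; the nucleosomal track is divided by it.
    Positions where the estimate is zero (e.g. masked telomeres) become
    NaN rather than infinite, and NaNs in the naked input propagate as
    missing through the smoothing (mean over available bases).
    """
    if step != 1:
        raise ValueError("only step=1 smoothing is supported")
    total = sum(np.nansum(v) for v in naked_track_raw.values.values())
    n = sum(len(v) for v in naked_track_raw.values.values())
    mean = total / n
    if mean <= 0:
        raise ValueError("naked-DNA track is all zero; cannot correct")
    corrected: dict[str, np.ndarray] = {}
    n_masked = 0
    for chrom, nuc in nuc_track_raw.values.items():
        naked = naked_track_raw.values[chrom] / mean
        estimate = sliding_mean(naked, window)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = nuc / estimate
        bad = ~np.isfinite(out)
        n_masked += int(bad.sum())
        out[bad] = np.nan
        corrected[chrom] = out
    if n_masked:
        logger.info("copy-number correction masked %d zero/NaN positions", n_masked)
    return CoverageTrack(corrected)


def replicated_extent(
    diff: DifferentialTrack,
    origin: OriginRecord,
    threshold: float | None = None,
    window: int = DEFAULT_WINDOW,
    search: int = DEFAULT_EXTENT_SEARCH,
) -> int:
    """Span (bp) of elevated window-averaged differential around the ACS.

    The differential is averaged with a sliding ``window``-bp mean over
    +/- ``search`` bp of the ACS midpoint; the maximal contiguous run
    containing the ACS where the averaged signal exceeds ``threshold``
    is returned.  ``threshold`` defaults to 0.25 x the origin's peak
    averaged differential; when that peak is below a floor of 0.1 the
    origin is treated as not fired and the extent is 0.
    """
    values = diff.values[origin.chrom]
    mid = origin.acs_mid
    lo = max(mid - search, 0)
    hi = min(mid + search, len(values))
    region = sliding_mean(values[lo:hi], window)
    if threshold is None:
        peak = np.nanmax(region)
        if not np.isfinite(peak) or peak < MIN_PEAK_DIFFERENTIAL:
            return 0
        threshold = DEFAULT_EXTENT_REL_THRESHOLD * peak
    above = region > threshold
    center = mid - lo
    if center >= len(above) or not above[center]:
        return 0
    start = center
    while start > 0 and above[start - 1]:
        start -= 1
    end = center
    while end < len(above) - 1 and above[end + 1]:
        end += 1
    return int(end - start + 1)


def _flanking_peaks(profile: np.ndarray, halfwidth: int) -> dict[str, float]:
    """Locate the ACS-proximal minimum and the first local maxima on
    either side (-1 and +1 nucleosomes) within the search radius."""
    center = halfwidth
    r = PEAK_SEARCH_RADIUS
    core = profile[center - r : center + r + 1]
    minimum = center - r + int(np.argmin(core))
    left = profile[: minimum + 1]
    right = profile[minimum:]
    left_max = argrelextrema(left, np.greater_equal, order=5)[0]
    right_max = argrelextrema(right, np.greater_equal, order=5)[0] + minimum
    left_max = left_max[(minimum - left_max) <= r]
    right_max = right_max[(right_max - minimum) <= r]
    out: dict[str, float] = {"min_offset": float(minimum - center)}
    if len(left_max):
        pos = int(left_max[-1])
        out["minus1_offset"] = float(pos - center)
        out["minus1_height"] = float(profile[pos])
    if len(right_max):
        pos = int(right_max[0])
        out["plus1_offset"] = float(pos - center)
        out["plus1_height"] = float(profile[pos])
    return out


def origin_shift_report(
    g1_matrix: OriginProfileMatrix,
    s_matrix: OriginProfileMatrix,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group S-vs-G1 deltas of the key origin chromatin features.

    ``groups`` maps origin names to group labels (typically early/late
    timing).  For each group, the G1 and S aggregate profiles are
    compared: delta NDR width, delta -1/+1 peak offsets and delta -1/+1
    peak heights (S minus G1).  Peaks are the first local maxima
    flanking the ACS-proximal minimum.
    """
    if set(g1_matrix.origin_names) != set(s_matrix.origin_names):
        raise ValueError("G1 and S matrices cover different origin sets")
    hw = g1_matrix.halfwidth
    rows = {}
    for group in sorted(set(groups.values())):
        members = [
            n for n in g1_matrix.origin_names if groups.get(n) == group
        ]
        if not members:
            continue
        g1 = aggregate_profile(g1_matrix, members)
        s = aggregate_profile(s_matrix.subset(members), None)
        g1_feat = _flanking_peaks(g1, hw)
        s_feat = _flanking_peaks(s, hw)
        g1_w = window_ndr_width(g1, halfwidth=hw)
        s_w = window_ndr_width(s, halfwidth=hw)
        row = {
            "n_origins": len(members),
            "delta_ndr_width": s_w - g1_w,
        }
        for key in ("minus1_offset", "plus1_offset", "minus1_height", "plus1_height"):
            if key in g1_feat and key in s_feat:
                row[f"delta_{key}"] = s_feat[key] - g1_feat[key]
            else:
                row[f"delta_{key}"] = np.nan
        rows[group] = row
    return pd.DataFrame(rows).T
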
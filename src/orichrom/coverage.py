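"""Stranded read-start tracks and the normalized positioning signal.

The mononucleosome evidence enters as per-base counts of read 5' ends on
each strand (the reads mark fragment boundaries, not occupancy).  This
module turns boundary counts into genome-mean-1 coverage tracks and
provides the multilevel biorthogonal wavelet smoother used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pywt

logger = logging.getLogger("orichrom.coverage")

DEFAULT_WAVELET = "bior3.5"
DEFAULT_SMOOTH_LEVEL = 4  # suppresses detail below ~2**4 = 16 bp


@dataclass
class StrandedStartTrack:
    """Per-chromosome, per-strand counts of read 5' ends."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, chrom_lengths: Mapping[str, int]) -> "StrandedStartTrack":
        return cls(
            plus={c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()},
            minus={c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()},
        )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.plus.items()}

    @property
    def total_reads(self) -> int:
        return int(
            sum(v.sum() for v in self.plus.values())
            + sum(v.sum() for v in self.minus.values())
        )


@dataclass
class CoverageTrack:
    """Per-base real-valued signal, one vector per chromosome."""

    values: dict[str, np.ndarray]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    @property
    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.values.values())
        n = sum(len(v) for v in self.values.values())
        return total / n

    def copy(self) -> "CoverageTrack":
        return CoverageTrack({c: v.copy() for c, v in self.values.items()})


def starts_to_raw_coverage(starts: StrandedStartTrack, extension: int = 147) -> CoverageTrack:
    """Extend each 5' end over the fragment footprint and sum.

    A plus start at ``s`` contributes +1 over ``[s, s+extension)``; a
    minus 5' end at ``e`` (last covered base) contributes +1 over
    ``[e-extension+1, e+1)``.  Contributions are clipped at chromosome
    edges.
    """
    if extension <= 0:
        raise ValueError(f"extension must be positive, got {extension}")
    values: dict[str, np.ndarray] = {}
    for chrom, plus in starts.plus.items():
        minus = starts.minus[chrom]
        n = len(plus)
        diff = np.zeros(n + 1, dtype=np.int64)
        # plus strand: [s, s+ext)
        diff[:n] += plus
        ends = np.minimum(np.arange(n) + extension, n)
        np.add.at(diff, ends, -plus)
        # minus strand: [e-ext+1, e+1)
        starts_m = np.maximum(np.arange(n) - extension + 1, 0)
        np.add.at(diff, starts_m, minus)
        diff[1 : n + 1] -= minus
        values[chrom] = np.cumsum(diff[:n]).astype(float)
    return CoverageTrack(values)


def normalize_by_genome_mean(raw: CoverageTrack) -> CoverageTrack:
    """Divide every base by the genome-wide (not per-chromosome) mean."""
    mean = raw.genome_mean
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero track")
    return CoverageTrack({c: v / mean for c, v in raw.values.items()})


def wavelet_smooth(
    signal: np.ndarray,
    level: int = DEFAULT_SMOOTH_LEVEL,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Multilevel 1-D biorthogonal wavelet decomposition/reconstruction.

    Decomposes to ``level`` scales, zeroes every detail band and
    reconstructs, keeping only structure coarser than ~``2**level``
    bases.  The stationary (undecimated) transform is used so the
    operator is linear, preserves constants, and is exactly
    shift-invariant and reflection-symmetric — peak positions do not
    move under smoothing.  Input is symmetric-padded to a multiple of
    ``2**level`` and trimmed back.
    """
    if level < 1:
        raise ValueError(f"smoothing level must be >= 1, got {level}")
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n < 2**level:
        raise ValueError(f"signal length {n} < 2**level = {2 ** level}")
    pad = (-n) % (1 << level)
    padded = np.pad(signal, (0, pad), mode="symmetric") if pad else signal
    coeffs = pywt.swt(padded, wavelet, level=level, trim_approx=True)
    smooth = pywt.iswt([coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]], wavelet)
    return smooth[:n]


def smooth_track(
    track: CoverageTrack,
    level: int = DEFAULT_SMOOTH_LEVEL,
    wavelet: str = DEFAULT_WAVELET,
) -> CoverageTrack:
    """Apply :func:`wavelet_smooth` per chromosome."""
    return CoverageTrack(
        {c: wavelet_smooth(v, level=level, wavelet=wavelet) for c, v in track.values.items()}
    )


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean (step 1); edge windows shrink to the
    available bases.  NaNs are treated as missing and excluded from the
    mean; an all-NaN window stays NaN."""
    if window < 1:
        raise ValueError("window must be >= 1")
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out
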
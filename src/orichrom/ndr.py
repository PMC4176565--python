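"""Nucleosome-depleted region (NDR) calling and origin association.

An NDR is a maximal run of at least ``min_len`` consecutive bases
(default 80) whose normalized positioning signal is strictly below
``threshold`` (default 0.4).  The rule is a pure run: a single base at
or above the threshold splits an NDR (gap tolerance defaults to 0 and is
deliberately not configurable higher here — callers wanting merged runs
should post-process).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack
from .io import OriginRecord

logger = logging.getLogger("orichrom.ndr")

DEFAULT_MIN_LEN = 80
DEFAULT_THRESHOLD = 0.4
DEFAULT_MAX_DIST = 150  # bp between an NDR and the ACS to count as origin-associated


class _Closed:
    """Sentinel for an origin with no claimable NDR (a 'closed' origin).

    Distinct from a zero width so that averages over open origins can
    exclude closed ones explicitly.
    """

    _instance = None

    def __new__(cls) -> "_Closed":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "CLOSED"


CLOSED = _Closed()


@dataclass
class NDRInterval:
    """A called nucleosome-depleted region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_signal: float
    origin_associated: bool = False
    origin_name: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


def call_ndrs(
    track: CoverageTrack,
    min_len: int = DEFAULT_MIN_LEN,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[NDRInterval]:
    """Call NDRs on a normalized track.

    Maximal runs of consecutive bases with signal strictly below
    ``threshold`` are kept iff their length is at least ``min_len``;
    output is sorted by chromosome then position.
    """
    ndrs: list[NDRInterval] = []
    for chrom in sorted(track.values):
        values = track.values[chrom]
        below = values < threshold
        # run boundaries via sign changes of the padded indicator
        padded = np.concatenate(([False], below, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        for s, e in zip(starts.tolist(), ends.tolist()):
            if e - s >= min_len:
                ndrs.append(NDRInterval(chrom, s, e, float(values[s:e].mean())))
    return ndrs


def associate_ndrs_with_origins(
    ndrs: list[NDRInterval],
    origins: list[OriginRecord],
    max_dist: int = DEFAULT_MAX_DIST,
) -> tuple[list[NDRInterval], list[NDRInterval]]:
    """Split NDRs into origin-associated and non-associated sets.

    An NDR is eligible for an origin iff it overlaps the ACS or its gap
    to the ACS interval is at most ``max_dist``.  Each origin claims at
    most one NDR: the one whose body is nearest the ACS midpoint, ties
    broken by larger ACS overlap and then by lower coordinate.  Claimed
    NDRs are flagged in place with the origin name.
    """
    for ndr in ndrs:
        ndr.origin_associated = False
        ndr.origin_name = None
    claimed: set[int] = set()
    for origin in origins:
        best: tuple[float, float, int, int] | None = None  # (dist, -overlap, start, idx)
        mid = origin.acs_mid
        for idx, ndr in enumerate(ndrs):
            if ndr.chrom != origin.chrom:
                continue
            gap = max(origin.acs_start - ndr.end, ndr.start - origin.acs_end, 0)
            if gap > max_dist:
                continue
            # distance from ACS midpoint to the NDR body (0 when inside)
            dist = max(ndr.start - mid, mid - (ndr.end - 1), 0)
            overlap = max(0, min(ndr.end, origin.acs_end) - max(ndr.start, origin.acs_start))
            key = (dist, -overlap, ndr.start, idx)
            if best is None or key < best:
                best = key
        if best is not None:
            idx = best[3]
            if idx in claimed:
                logger.debug(
                    "NDR at %s:%d already claimed; origin %s left closed",
                    ndrs[idx].chrom, ndrs[idx].start, origin.name,
                )
                continue
            claimed.add(idx)
            ndrs[idx].origin_associated = True
            ndrs[idx].origin_name = origin.name
    origin_ndrs = [n for n in ndrs if n.origin_associated]
    nonorigin_ndrs = [n for n in ndrs if not n.origin_associated]
    return origin_ndrs, nonorigin_ndrs


def origin_ndr_width(origin: OriginRecord, origin_ndrs: list[NDRInterval]):
    """Width of the NDR claimed by ``origin``, or the CLOSED sentinel.

    The full NDR width is reported even when the region extends past the
    analysis window used elsewhere; such cases are logged.
    """
    for ndr in origin_ndrs:
        if ndr.origin_name == origin.name:
            if ndr.width > 600:
                logger.info(
                    "origin %s: NDR width %d extends beyond the aggregate window",
                    origin.name, ndr.width,
                )
            return ndr.width
    return CLOSED


def origin_width_table(
    origins: list[OriginRecord], origin_ndrs: list[NDRInterval]
) -> dict[str, int | _Closed]:
    return {o.name: origin_ndr_width(o, origin_ndrs) for o in origins}
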
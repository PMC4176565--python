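"""Fkh consensus scanning and origin motif-configuration analysis.

The Forkhead (Fkh1/2) consensus RTAAAYA is matched exactly as an IUPAC
pattern on both strands (R = A/G, Y = C/T; N in the genome never
matches).  Origin-anchored densities and the dual-site detector use the
same T-rich orientation convention as the architecture module: a hit's
oriented offset is the position of its first base read along the T-rich
strand, relative to the ACS midpoint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import GenomeSequence, OriginRecord
from .ndr import NDRInterval

logger = logging.getLogger("orichrom.motifs")

DEFAULT_PATTERN = "RTAAAYA"
DEFAULT_PROXIMAL_MAX = 50
DEFAULT_SEP_MIN = 60
DEFAULT_SEP_MAX = 120

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MotifHit:
    """An exact IUPAC match; ``start`` is the leftmost base on the plus
    strand coordinate system regardless of hit strand."""

    chrom: str
    start: int
    strand: str


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC DNA letter {ch!r} in pattern {pattern!r}")
        allowed = IUPAC_SETS[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motif(genome: GenomeSequence, pattern: str = DEFAULT_PATTERN) -> list[MotifHit]:
    """All exact IUPAC matches of ``pattern`` on both strands, sorted.

    Genome 'N' bases never match (pattern letters expand to A/C/G/T
    classes only).
    """
    fwd = _iupac_regex(pattern)
    rev = _iupac_regex(reverse_complement(pattern))
    hits: list[MotifHit] = []
    for chrom in sorted(genome.chroms):
        seq = genome.chroms[chrom]
        for m in fwd.finditer(seq):
            hits.append(MotifHit(chrom, m.start(), "+"))
        for m in rev.finditer(seq):
            hits.append(MotifHit(chrom, m.start(), "-"))
    hits.sort()
    return hits


def oriented_offset(hit: MotifHit, origin: OriginRecord, motif_len: int) -> int:
    """Oriented offset of a hit's first base relative to the ACS midpoint.

    For a minus-strand origin the coordinate axis is reflected, so the
    motif's first base in oriented reading is its rightmost genomic base.
    """
    mid = origin.acs_mid
    if origin.acs_strand == "+":
        return hit.start - mid
    return mid - (hit.start + motif_len - 1)


def motif_density_profile(
    hits: list[MotifHit],
    origins: list[OriginRecord],
    halfwidth: int = 600,
    smoothing_bw: float = 10.0,
    motif_len: int = len(DEFAULT_PATTERN),
) -> np.ndarray:
    """Per-offset motif-start counts across the origin set, oriented and
    kernel-smoothed.

    Returns a vector over offsets -halfwidth..+halfwidth.  Smoothing
    uses a Gaussian kernel of ``smoothing_bw`` bp (0 = none); total mass
    is preserved up to truncation of hits within ~4 bandwidths of the
    window edge.
    """
    if not origins:
        raise ValueError("motif_density_profile needs at least one origin")
    counts = np.zeros(2 * halfwidth + 1, dtype=float)
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    for origin in origins:
        for hit in by_chrom.get(origin.chrom, []):
            off = oriented_offset(hit, origin, motif_len)
            if -halfwidth <= off <= halfwidth:
                counts[off + halfwidth] += 1
    if smoothing_bw > 0:
        counts = gaussian_filter1d(counts, sigma=smoothing_bw, mode="constant", cval=0.0)
    return counts


def dual_site_configuration(
    origin: OriginRecord,
    hits: list[MotifHit],
    ndr: NDRInterval | None = None,
    proximal_max: int = DEFAULT_PROXIMAL_MAX,
    sep_min: int = DEFAULT_SEP_MIN,
    sep_max: int = DEFAULT_SEP_MAX,
    motif_len: int = len(DEFAULT_PATTERN),
    require_in_ndr: bool = False,
) -> bool:
    """Does the origin carry the early-firing dual-Fkh configuration?

    True iff two hits exist such that one lies within ``proximal_max``
    bp of the ACS midpoint and their start-to-start separation is within
    [sep_min, sep_max], bounds inclusive.  With ``require_in_ndr`` both
    sites must also fall inside the supplied NDR interval (the stricter
    NDR-border reading).
    """
    offsets = []
    for hit in hits:
        if hit.chrom != origin.chrom:
            continue
        if require_in_ndr:
            if ndr is None:
                raise ValueError("require_in_ndr needs the origin's NDR interval")
            if not (ndr.start <= hit.start and hit.start + motif_len <= ndr.end):
                continue
        offsets.append(oriented_offset(hit, origin, motif_len))
    offsets = sorted(set(offsets))
    for i, a in enumerate(offsets):
        for b in offsets[i + 1 :]:
            sep = b - a
            if sep < sep_min or sep > sep_max:
                continue
            if abs(a) <= proximal_max or abs(b) <= proximal_max:
                return True
    return False


def fraction_with_configuration(
    origins: list[OriginRecord],
    hits: list[MotifHit],
    timing: str = "early",
    ndrs: dict[str, NDRInterval] | None = None,
    proximal_max: int = DEFAULT_PROXIMAL_MAX,
    sep_min: int = DEFAULT_SEP_MIN,
    sep_max: int = DEFAULT_SEP_MAX,
    require_in_ndr: bool = False,
) -> float:
    """Fraction of origins in a timing group with the dual-site
    configuration."""
    group = [o for o in origins if o.timing == timing]
    if not group:
        raise ValueError(f"no origins with timing {timing!r}")
    positive = 0
    for o in group:
        ndr = ndrs.get(o.name) if ndrs else None
        if dual_site_configuration(
            o, hits, ndr=ndr, proximal_max=proximal_max,
            sep_min=sep_min, sep_max=sep_max, require_in_ndr=require_in_ndr,
        ):
            positive += 1
    return positive / len(group)
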
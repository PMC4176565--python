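"""Synthetic genomes with planted origin chromatin architectures.

The generator emulates the structure of a budding-yeast MNase-seq study:
a small genome with genes and intergenic regions, replication origins
anchored at T-rich ACS elements inside IGRs, six origin architecture
classes whose nucleosome-depleted regions (NDRs) span 193 down to
129 bp with graded flanking-nucleosome occupancy and positioning, G1 and
HU-arrested S-phase mononucleosome samples (single-end 40-nt reads whose
5' ends mark fragment boundaries), and uniform naked-DNA controls.  In
S phase only early origins have fired, so copy number is doubled within
a fixed halfwidth (default 2250 bp, i.e. 2-2.5 kb of replicated DNA on
either side of an early origin).

Everything is deterministic for a fixed seed, and every planted feature
(dyads, occupancies, NDR widths, Fkh sites) is recorded as ground truth
for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GeneAnnotation, GenomeSequence, OriginRecord
from .coverage import StrandedStartTrack

logger = logging.getLogger("orichrom.synthetic")

#: Canonical T-rich ACS element written on the origin's acs_strand (17 bp).
ACS_TRICH = "TTTTATGTTTAGTTTTT"

#: Strict Fkh consensus instance planted at NDR borders (RTAAAYA, R=A Y=C).
FKH_INSTANCE = "ATAAACA"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]

# Per-timing class weights: classes 1-2 dominate early origins (60%),
# classes 5-6 dominate late ones (65%), with ~40% of each timing group
# concentrated in class 1 / class 6 respectively.
EARLY_CLASS_WEIGHTS = (0.38, 0.22, 0.05, 0.05, 0.12, 0.18)
LATE_CLASS_WEIGHTS = (0.05, 0.10, 0.05, 0.15, 0.26, 0.39)


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults emulate the real study design at desk scale: 40-nt
    single-end reads, ~80x genome coverage, 147-bp nucleosome footprint,
    2250-bp replicated halfwidth around early origins under HU.
    """

    genome_length: int = 400_000
    n_chroms: int = 2
    n_genes: int = 300
    n_origins: int = 30
    fraction_early: float = 0.5
    mean_coverage: float = 80.0
    read_length: int = 40
    nucleosome_footprint: int = 147
    replicated_halfwidth: int = 2250
    seed: int = 0

    # genome layout
    gene_length_range: tuple[int, int] = (400, 800)
    igr_length_range: tuple[int, int] = (150, 400)
    origin_igr_length: int = 900
    origin_slot_spacing: int = 2  # min IGR-slot index distance between origins
    chrom_margin: int = 700

    # background chromatin (outside origin windows)
    tile_spacing: int = 165
    tile_occupancy: float = 0.90
    tile_fuzziness: float = 5.0

    # planted origin architecture classes 1..6
    class_ndr_widths: tuple[int, ...] = (193, 180, 167, 154, 141, 129)
    class_occupancy: tuple[float, ...] = (0.98, 0.90, 0.82, 0.75, 0.70, 0.64)
    class_fuzziness: tuple[float, ...] = (3.0, 5.0, 7.0, 9.0, 10.0, 11.0)
    # NDR midpoint offset from the ACS midpoint (oriented); each class sits
    # with its own asymmetry over the ACS, making the six architectures
    # structurally distinct patterns rather than a pure width gradient
    class_ndr_center_offsets: tuple[int, ...] = (80, 55, 30, 5, -25, -55)
    ndr_width_jitter: int = 4
    class_assignment: str = "timing"  # "timing" or "balanced"

    # read model
    fragment_length_sd: float = 2.0
    background_rate: float = 0.0  # uniform linker reads, fraction of mean coverage

    # Fkh motif planting (early origins only)
    fkh_dual_fraction_early: float = 0.256
    fkh_single_fraction_early: float = 0.30
    fkh_proximal_range: tuple[int, int] = (12, 40)
    fkh_separation_range: tuple[int, int] = (60, 120)
    scrub_spurious_motifs: bool = True

    def __post_init__(self) -> None:
        for name in (
            "genome_length", "n_chroms", "n_genes", "mean_coverage",
            "read_length", "nucleosome_footprint", "replicated_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if self.n_origins < 0:
            raise ValueError("SimConfig.n_origins must be >= 0")
        if not 0.0 <= self.fraction_early <= 1.0:
            raise ValueError("SimConfig.fraction_early must be in [0, 1]")
        if self.class_assignment not in ("timing", "balanced"):
            raise ValueError("SimConfig.class_assignment must be 'timing' or 'balanced'")
        k = len(self.class_ndr_widths)
        if not (
            len(self.class_occupancy)
            == len(self.class_fuzziness)
            == len(self.class_ndr_center_offsets)
            == k
        ):
            raise ValueError("class parameter tuples must have equal length")


@dataclass
class OriginArchitecture:
    """Planted chromatin truth for one origin (genomic coordinates)."""

    origin_name: str
    class_id: int
    ndr_width: int
    ndr_center_offset: int
    ndr_start: int
    ndr_end: int
    dyad_positions: list[int]
    occupancy: list[float]
    fuzziness_sd: float
    fkh_offsets: list[int] = field(default_factory=list)  # oriented, motif starts

    def __post_init__(self) -> None:
        if self.ndr_width <= 0:
            raise ValueError("planted ndr_width must be positive")
        if any(not 0.0 <= q <= 1.0 for q in self.occupancy):
            raise ValueError("occupancy must lie in [0, 1]")
        d = sorted(self.dyad_positions)
        if any(b - a < 147 for a, b in zip(d, d[1:])):
            raise ValueError("adjacent planted dyads closer than one footprint")


@dataclass
class PlantedArchitecture:
    """Ground-truth architecture for every origin, keyed by name."""

    per_origin: dict[str, OriginArchitecture]

    def __getitem__(self, name: str) -> OriginArchitecture:
        return self.per_origin[name]

    def widths(self) -> dict[str, int]:
        return {n: a.ndr_width for n, a in self.per_origin.items()}


@dataclass
class SimTruth:
    """Bundle returned by :func:`generate_genome_and_annotations`."""

    genome: GenomeSequence
    genes: list[GeneAnnotation]
    origins: list[OriginRecord]
    architecture: PlantedArchitecture
    # flattened genome-wide dyad model per chromosome
    dyads: dict[str, np.ndarray]
    dyad_occupancy: dict[str, np.ndarray]
    dyad_fuzziness: dict[str, np.ndarray]
    config: SimConfig


# ---------------------------------------------------------------------------
# genome + annotation generation
# ---------------------------------------------------------------------------


def _oriented_to_genomic_point(mid: int, strand: str, offset: int) -> int:
    return mid + offset if strand == "+" else mid - offset


def _oriented_to_genomic_interval(mid: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Map an oriented half-open interval [a, b) to genomic half-open."""
    if strand == "+":
        return mid + a, mid + b
    return mid - b + 1, mid - a + 1


def _select_origin_slots(
    rng: np.random.Generator, slots_per_chrom: list[int], n_origins: int,
    min_spacing: int = 2,
) -> list[tuple[int, int]]:
    """Pick IGR slots for origins, at least ``min_spacing`` slots apart
    within a chromosome so neighbouring architectures never collide (and,
    at larger spacings, so replicated regions stay isolated)."""
    candidates = [
        (ci, si) for ci, n in enumerate(slots_per_chrom) for si in range(n)
    ]
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, int]] = []
    taken: dict[int, list[int]] = {}
    if n_origins == 0:
        return chosen
    for idx in order:
        ci, si = candidates[idx]
        if all(abs(si - sj) >= min_spacing for sj in taken.get(ci, [])):
            chosen.append((ci, si))
            taken.setdefault(ci, []).append(si)
            if len(chosen) == n_origins:
                return sorted(chosen)
    raise ValueError(
        f"cannot place {n_origins} origins: only {len(chosen)} well-separated "
        f"intergenic slots available (have {len(candidates)} IGRs); "
        "increase n_genes or reduce n_origins"
    )


def _fkh_plan(
    rng: np.random.Generator, cfg: SimConfig, timing: str, ndr_start_off: int, ndr_end_off: int
) -> list[int]:
    """Oriented motif-start offsets to plant for one origin.

    Early origins receive two consensus sites (proximal one near the
    ACS, partner 60-120 bp away, both inside the NDR) with probability
    ``fkh_dual_fraction_early``, a single proximal site with probability
    ``fkh_single_fraction_early``, and otherwise none.  Late origins
    receive none.
    """
    if timing != "early":
        return []
    u = rng.random()
    motif_len = len(FKH_INSTANCE)
    sep_lo, sep_hi_cfg = cfg.fkh_separation_range
    prox_lo, prox_hi = cfg.fkh_proximal_range
    off1 = int(rng.integers(prox_lo, prox_hi + 1))
    if u < cfg.fkh_dual_fraction_early:
        # partner site at the other NDR border, whichever side has room
        right_hi = min(sep_hi_cfg, ndr_end_off - motif_len - off1)
        left_hi = min(sep_hi_cfg, off1 - ndr_start_off)
        sides = []
        if right_hi >= sep_lo:
            sides.append(("right", right_hi))
        if left_hi >= sep_lo:
            sides.append(("left", left_hi))
        if not sides:
            return [off1]  # NDR too narrow for a compliant pair
        side, hi = sides[int(rng.integers(0, len(sides)))]
        sep = int(rng.integers(sep_lo, hi + 1))
        off2 = off1 + sep if side == "right" else off1 - sep
        return sorted([off1, off2])
    if u < cfg.fkh_dual_fraction_early + cfg.fkh_single_fraction_early:
        return [off1]
    return []


def _write_oriented(seq: bytearray, mid: int, strand: str, offset: int, text: str) -> tuple[int, int]:
    """Write ``text`` so it reads forward on the oriented strand at the
    given oriented offset; returns the genomic interval written."""
    start, end = _oriented_to_genomic_interval(mid, strand, offset, offset + len(text))
    payload = text if strand == "+" else revcomp(text)
    seq[start:end] = payload.encode()
    return start, end


_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _scrub_window(
    seq: bytearray, lo: int, hi: int, pattern: str, protected: set[int]
) -> int:
    """Destroy non-planted IUPAC pattern matches (both strands) inside
    ``[lo, hi)`` by mutating one unprotected base per hit.  Returns the
    number of mutations applied."""
    import re

    fwd = "".join(f"[{_IUPAC_SETS[c]}]" if len(_IUPAC_SETS[c]) > 1 else _IUPAC_SETS[c]
                  for c in pattern)
    rev = "".join(f"[{_IUPAC_SETS[c]}]" if len(_IUPAC_SETS[c]) > 1 else _IUPAC_SETS[c]
                  for c in revcomp(pattern))
    mutations = 0
    for _ in range(4):  # repeat: a mutation could in principle create a new hit
        text = seq[lo:hi].decode()
        hits: list[tuple[int, str]] = []
        for regex, pat in ((fwd, pattern), (rev, revcomp(pattern))):
            for m in re.finditer(f"(?=({regex}))", text):
                hits.append((lo + m.start(), pat))
        dirty = False
        for start, pat in hits:
            span = range(start, start + len(pattern))
            if all(p in protected for p in span):
                continue  # a planted site
            dirty = True
            for j, p in enumerate(span):
                if p in protected:
                    continue
                allowed = _IUPAC_SETS[pat[j]]
                new = next(b for b in "CGAT" if b not in allowed)
                seq[p] = ord(new)
                mutations += 1
                break
        if not dirty:
            break
    return mutations


def generate_genome_and_annotations(config: SimConfig) -> SimTruth:
    """Build the synthetic genome, annotations, origins and planted truth.

    Gene strands are independent and equiprobable; origins occupy
    well-separated intergenic slots; each origin carries a class-specific
    NDR (covering the ACS asymmetrically) flanked by nucleosomes -3..+3;
    the rest of the genome is tiled with regularly spaced nucleosomes.
    Deterministic for a fixed ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.class_ndr_widths)

    # --- distribute genes over chromosomes -------------------------------
    per_chrom_genes = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom_genes[i] += 1
    if any(g < 2 for g in per_chrom_genes) and cfg.n_origins > 0:
        raise ValueError("need at least 2 genes per chromosome to form IGRs")
    slots_per_chrom = [max(g - 1, 0) for g in per_chrom_genes]
    if cfg.n_origins > sum(slots_per_chrom):
        raise ValueError(
            f"{cfg.n_origins} origins requested but only {sum(slots_per_chrom)} IGRs available"
        )
    origin_slots = _select_origin_slots(
        rng, slots_per_chrom, cfg.n_origins, max(cfg.origin_slot_spacing, 2)
    )
    origin_slot_set = set(origin_slots)

    # --- lay out genes and IGRs ------------------------------------------
    chrom_names = [f"chr{i + 1:02d}" for i in range(cfg.n_chroms)]
    genes: list[GeneAnnotation] = []
    chrom_lengths: dict[str, int] = {}
    origin_anchor: dict[tuple[int, int], int] = {}  # slot -> ACS midpoint
    gl_lo, gl_hi = cfg.gene_length_range
    il_lo, il_hi = cfg.igr_length_range
    gene_counter = 0
    for ci, chrom in enumerate(chrom_names):
        cursor = cfg.chrom_margin
        n_g = per_chrom_genes[ci]
        for gi in range(n_g):
            length = int(rng.integers(gl_lo, gl_hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            genes.append(
                GeneAnnotation(f"G{gene_counter:05d}", chrom, cursor, cursor + length, strand)
            )
            cursor += length
            if gi < n_g - 1:
                if (ci, gi) in origin_slot_set:
                    igr_len = cfg.origin_igr_length
                    origin_anchor[(ci, gi)] = cursor + igr_len // 2
                else:
                    igr_len = int(rng.integers(il_lo, il_hi + 1))
                cursor += igr_len
        chrom_lengths[chrom] = cursor + cfg.chrom_margin

    total = sum(chrom_lengths.values())
    if total > cfg.genome_length:
        raise ValueError(
            f"layout needs {total} bp but genome_length is {cfg.genome_length}; "
            "increase genome_length or reduce n_genes"
        )
    extra = cfg.genome_length - total
    for i, chrom in enumerate(chrom_names):
        share = extra // cfg.n_chroms + (1 if i < extra % cfg.n_chroms else 0)
        chrom_lengths[chrom] += share

    # --- origins and planted architectures --------------------------------
    origins: list[OriginRecord] = []
    arch: dict[str, OriginArchitecture] = {}
    acs_half = len(ACS_TRICH) // 2
    footprint = cfg.nucleosome_footprint
    half_lo = footprint // 2          # 73 for 147
    half_hi = footprint - half_lo     # 74
    early_w = np.asarray(EARLY_CLASS_WEIGHTS[:k]) / sum(EARLY_CLASS_WEIGHTS[:k])
    late_w = np.asarray(LATE_CLASS_WEIGHTS[:k]) / sum(LATE_CLASS_WEIGHTS[:k])
    for oi, (ci, si) in enumerate(origin_slots):
        chrom = chrom_names[ci]
        mid = origin_anchor[(ci, si)]
        strand = "+" if rng.random() < 0.5 else "-"
        timing = "early" if rng.random() < cfg.fraction_early else "late"
        if cfg.class_assignment == "balanced":
            class_id = oi % k + 1
        else:
            weights = early_w if timing == "early" else late_w
            class_id = int(rng.choice(k, p=weights)) + 1
        width = int(
            cfg.class_ndr_widths[class_id - 1]
            + rng.integers(-cfg.ndr_width_jitter, cfg.ndr_width_jitter + 1)
        )
        occ = cfg.class_occupancy[class_id - 1]
        fuzz = cfg.class_fuzziness[class_id - 1]
        # oriented NDR interval, covering the ACS asymmetrically
        center_off = cfg.class_ndr_center_offsets[class_id - 1]
        c0 = center_off - width // 2
        ndr_start_g, ndr_end_g = _oriented_to_genomic_interval(mid, strand, c0, c0 + width)
        # flanking nucleosomes -3..-1 and +1..+3 (oriented dyads)
        minus1 = c0 - half_hi
        plus1 = c0 + width + half_lo
        oriented_dyads = [
            minus1 - 2 * cfg.tile_spacing, minus1 - cfg.tile_spacing, minus1,
            plus1, plus1 + cfg.tile_spacing, plus1 + 2 * cfg.tile_spacing,
        ]
        dyads_g = sorted(_oriented_to_genomic_point(mid, strand, d) for d in oriented_dyads)
        name = f"ORI{oi + 1:04d}"
        fkh = _fkh_plan(rng, cfg, timing, c0, c0 + width)
        origins.append(
            OriginRecord(name, chrom, mid - acs_half, mid - acs_half + len(ACS_TRICH),
                         strand, timing)
        )
        arch[name] = OriginArchitecture(
            origin_name=name,
            class_id=class_id,
            ndr_width=width,
            ndr_center_offset=center_off,
            ndr_start=ndr_start_g,
            ndr_end=ndr_end_g,
            dyad_positions=dyads_g,
            occupancy=[occ] * len(dyads_g),
            fuzziness_sd=fuzz,
            fkh_offsets=fkh,
        )

    # --- genome-wide dyad model (origin architecture + background tiling) -
    dyads: dict[str, np.ndarray] = {}
    occs: dict[str, np.ndarray] = {}
    fuzzes: dict[str, np.ndarray] = {}
    guard = footprint // 2 + 9
    for chrom in chrom_names:
        n = chrom_lengths[chrom]
        pos: list[int] = []
        occ_l: list[float] = []
        fuzz_l: list[float] = []
        reserved: list[tuple[int, int]] = []
        for o in origins:
            if o.chrom != chrom:
                continue
            a = arch[o.name]
            reserved.append((min(a.dyad_positions) - guard, max(a.dyad_positions) + guard))
            pos.extend(a.dyad_positions)
            occ_l.extend(a.occupancy)
            fuzz_l.extend([a.fuzziness_sd] * len(a.dyad_positions))
        reserved.sort()
        gaps: list[tuple[int, int]] = []
        prev = 0
        for lo, hi in reserved:
            gaps.append((prev, lo))
            prev = hi
        gaps.append((prev, n))
        for lo, hi in gaps:
            p = lo + guard
            while p <= hi - guard:
                pos.append(p)
                occ_l.append(cfg.tile_occupancy)
                fuzz_l.append(cfg.tile_fuzziness)
                p += cfg.tile_spacing
        order = np.argsort(pos)
        dyads[chrom] = np.asarray(pos, dtype=np.int64)[order]
        occs[chrom] = np.asarray(occ_l, dtype=float)[order]
        fuzzes[chrom] = np.asarray(fuzz_l, dtype=float)[order]

    # --- sequence: random background + planted ACS and Fkh sites ---------
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs: dict[str, bytearray] = {}
    for chrom in chrom_names:
        codes = rng.integers(0, 4, chrom_lengths[chrom])
        seqs[chrom] = bytearray(alphabet[codes].tobytes())
    protected: dict[str, set[int]] = {chrom: set() for chrom in chrom_names}
    for o in origins:
        seq = seqs[o.chrom]
        mid = o.acs_mid
        a_start, a_end = _write_oriented(seq, mid, o.acs_strand, -acs_half, ACS_TRICH)
        protected[o.chrom].update(range(a_start, a_end))
        for off in arch[o.name].fkh_offsets:
            m_start, m_end = _write_oriented(seq, mid, o.acs_strand, off, FKH_INSTANCE)
            protected[o.chrom].update(range(m_start, m_end))
    if cfg.scrub_spurious_motifs:
        n_scrubbed = 0
        for o in origins:
            lo = max(o.acs_mid - 700, 0)
            hi = min(o.acs_mid + 700, chrom_lengths[o.chrom])
            n_scrubbed += _scrub_window(
                seqs[o.chrom], lo, hi, "RTAAAYA", protected[o.chrom]
            )
        if n_scrubbed:
            logger.info("scrubbed %d spurious Fkh consensus matches near origins", n_scrubbed)

    genome = GenomeSequence({c: seqs[c].decode() for c in chrom_names})
    return SimTruth(
        genome=genome,
        genes=genes,
        origins=origins,
        architecture=PlantedArchitecture(arch),
        dyads=dyads,
        dyad_occupancy=occs,
        dyad_fuzziness=fuzzes,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

_STREAMS = {("mono", "G1"): 11, ("mono", "S"): 12, ("naked", "G1"): 13, ("naked", "S"): 14}


def _replicated_mask_positions(
    truth: SimTruth, chrom: str, positions: np.ndarray
) -> np.ndarray:
    """Boolean mask: which positions lie within the replicated halfwidth
    of an early origin (the regions duplicated in HU-arrested S phase)."""
    hw = truth.config.replicated_halfwidth
    mids = np.sort(
        [o.acs_mid for o in truth.origins if o.chrom == chrom and o.timing == "early"]
    )
    if len(mids) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(mids, positions)
    left = np.abs(positions - mids[np.clip(idx - 1, 0, len(mids) - 1)])
    right = np.abs(mids[np.clip(idx, 0, len(mids) - 1)] - positions)
    return np.minimum(left, right) <= hw


def _phase_rng(truth: SimTruth, kind: str, phase: str) -> np.random.Generator:
    if phase not in ("G1", "S"):
        raise ValueError(f"phase must be 'G1' or 'S', got {phase!r}")
    return np.random.default_rng([truth.config.seed, _STREAMS[(kind, phase)]])


def sample_mononucleosome_reads(
    truth: SimTruth, config: SimConfig | None = None, phase: str = "G1"
) -> StrandedStartTrack:
    """Sample stranded mononucleosome boundary reads from the planted truth.

    Each planted dyad emits Poisson-many fragments (rate proportional to
    coverage and thinned by occupancy); each fragment's dyad is jittered
    by the planted fuzziness, spans the nucleosome footprint with small
    length noise, and contributes one plus-strand 5' end at its left
    edge and one minus-strand 5' end at its right edge.  In S phase the
    rate doubles for dyads within the replicated halfwidth of early
    origins (late origins have not fired under HU).
    """
    cfg = config or truth.config
    if cfg.mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    rng = _phase_rng(truth, "mono", phase)
    footprint = cfg.nucleosome_footprint
    half_lo = footprint // 2
    half_hi = footprint - half_lo
    # fragments per nucleosome so that total reads ~= coverage * L / read_length
    mu = cfg.mean_coverage * cfg.tile_spacing / (2.0 * cfg.read_length)
    track = StrandedStartTrack.zeros(truth.genome.chrom_lengths)
    for chrom, pos in truth.dyads.items():
        n = len(track.plus[chrom])
        rate = mu * truth.dyad_occupancy[chrom]
        if phase == "S":
            rate = rate * np.where(_replicated_mask_positions(truth, chrom, pos), 2.0, 1.0)
        counts = rng.poisson(rate)
        centers = np.repeat(pos, counts).astype(float)
        if len(centers):
            fuzz = np.repeat(truth.dyad_fuzziness[chrom], counts)
            centers = np.rint(centers + rng.normal(0.0, 1.0, len(centers)) * fuzz)
            dlen = np.rint(rng.normal(0.0, cfg.fragment_length_sd, len(centers)))
            left = (centers - half_lo).astype(np.int64)
            right = (centers + half_hi - 1 + dlen).astype(np.int64)
            for ends, arr in ((left, track.plus[chrom]), (right, track.minus[chrom])):
                keep = (ends >= 0) & (ends < n)
                arr += np.bincount(ends[keep], minlength=n)
        if cfg.background_rate > 0:
            lam = cfg.mean_coverage * cfg.background_rate / (2.0 * cfg.read_length)
            lam_arr = np.full(n, lam)
            if phase == "S":
                mask = _replicated_mask_positions(truth, chrom, np.arange(n))
                lam_arr[mask] *= 2.0
            track.plus[chrom] += rng.poisson(lam_arr)
            track.minus[chrom] += rng.poisson(lam_arr)
    if track.total_reads == 0:
        logger.warning("mononucleosome sampling produced zero reads")
    return track


def sample_naked_reads(
    truth: SimTruth, config: SimConfig | None = None, phase: str = "G1"
) -> StrandedStartTrack:
    """Uniform naked-DNA read starts at the configured depth.

    In S phase the same copy-number doubling applies within the
    replicated halfwidth of early origins, mirroring a naked-DNA control
    taken from the same time point.
    """
    cfg = config or truth.config
    if cfg.mean_coverage <= 0:
        raise ValueError("mean_coverage (depth) must be positive")
    rng = _phase_rng(truth, "naked", phase)
    lam = cfg.mean_coverage / (2.0 * cfg.read_length)
    track = StrandedStartTrack.zeros(truth.genome.chrom_lengths)
    for chrom, n in truth.genome.chrom_lengths.items():
        lam_arr = np.full(n, lam)
        if phase == "S":
            mask = _replicated_mask_positions(truth, chrom, np.arange(n))
            lam_arr[mask] *= 2.0
        track.plus[chrom] = rng.poisson(lam_arr).astype(np.int64)
        track.minus[chrom] = rng.poisson(lam_arr).astype(np.int64)
    return track
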
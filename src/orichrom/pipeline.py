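"""End-to-end orchestration: config, stages, report bundle, manifest.

A run either consumes real inputs (FASTA + GFF3 + origin table + read
BEDs) or generates a synthetic study from a :class:`SimConfig`.  Stages
run in method order — profile, ndr, classify, context, motifs, dynamics
— each writing its standard-format outputs into the run directory, and
a JSON manifest records package version, seed and every parameter so a
run can be reproduced exactly.  Any stage error aborts the run, removes
the partial outputs and names the failing stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as io_mod
from . import ndr as ndr_mod
from . import motifs as motifs_mod
from . import genomic_context as context_mod
from . import origin_architecture as arch_mod
from . import replication_dynamics as dyn_mod
from .coverage import CoverageTrack, StrandedStartTrack, starts_to_raw_coverage
from .nucleosome_calling import call_nucleosomes, combined_profile, genome_average_spacing
from .synthetic_data import (
    SimConfig,
    generate_genome_and_annotations,
    sample_mononucleosome_reads,
    sample_naked_reads,
)

logger = logging.getLogger("orichrom.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class Parameters:
    """All tunable constants of the analysis, with the study defaults."""

    min_len: int = 80
    threshold: float = 0.4
    halfwidth: int = 600
    k: int = 6
    iterations: int = 10_000
    restarts: int = 8
    motif: str = "RTAAAYA"
    sep_min: int = 60
    sep_max: int = 120
    proximal_max: int = 50
    window: int = 1000
    footprint: int = 147
    smoothing_level: int = 4
    wavelet: str = "bior3.5"
    max_dist: int = 150
    motif_smoothing_bw: float = 10.0

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.threshold <= 0 or self.halfwidth < 1:
            raise ValueError("NDR/window parameters out of bounds")
        if self.k < 2 or self.iterations < 1 or self.restarts < 1:
            raise ValueError("clustering parameters out of bounds")
        if not 0 <= self.sep_min <= self.sep_max:
            raise ValueError("separation bounds out of order")
        if self.footprint < 1 or self.window < 1 or self.smoothing_level < 1:
            raise ValueError("track parameters out of bounds")


@dataclass
class RunConfig:
    """Either ``synthetic`` or ``inputs`` must be set."""

    seed: int = 0
    parameters: Parameters = field(default_factory=Parameters)
    synthetic: SimConfig | None = None
    inputs: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known_top = {"seed", "parameters", "synthetic", "inputs"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params_raw = raw.get("parameters") or {}
        _reject_unknown(params_raw, Parameters, "parameters")
        synthetic = None
        if raw.get("synthetic") is not None:
            _reject_unknown(raw["synthetic"], SimConfig, "synthetic")
            syn = dict(raw["synthetic"])
            for key in ("gene_length_range", "igr_length_range", "fkh_proximal_range",
                        "fkh_separation_range", "class_ndr_widths", "class_occupancy",
                        "class_fuzziness"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            synthetic = SimConfig(**syn)
        inputs = raw.get("inputs")
        if inputs is not None:
            known_inputs = {"genome", "genes", "origins", "reads_g1", "reads_s",
                            "naked_g1", "naked_s"}
            unknown = set(inputs) - known_inputs
            if unknown:
                raise ValueError(f"unknown input keys: {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            parameters=Parameters(**params_raw),
            synthetic=synthetic,
            inputs=inputs,
        )
        if cfg.synthetic is None and cfg.inputs is None:
            raise ValueError("config must define either 'synthetic' or 'inputs'")
        return cfg


def _reject_unknown(mapping: dict, cls, section: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {section} keys: {sorted(unknown)}")


def _normalize_nan_aware(track: CoverageTrack) -> CoverageTrack:
    total = sum(float(np.nansum(v)) for v in track.values.values())
    n = sum(int(np.isfinite(v).sum()) for v in track.values.values())
    if n == 0 or total <= 0:
        raise ValueError("track has no finite positive signal")
    mean = total / n
    return CoverageTrack({c: v / mean for c, v in track.values.items()})


class _Run:
    """Mutable state threaded through the stages."""

    def __init__(self, config: RunConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.written: list[Path] = []
        self.manifest: dict = {
            "package": "orichrom",
            "version": __version__,
            "seed": config.seed,
            "parameters": dataclasses.asdict(config.parameters),
            "mode": "synthetic" if config.synthetic else "files",
            "outputs": [],
            "stages": [],
        }
        if config.synthetic:
            self.manifest["synthetic"] = dataclasses.asdict(config.synthetic)
        else:
            self.manifest["inputs"] = dict(config.inputs or {})

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        self.manifest["outputs"].append(name)
        return p

    def write_tsv(self, df: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        df.to_csv(self.path(name), sep="\t", index=index_label is not None,
                  index_label=index_label)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and return the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)
    stages = [
        ("io", _stage_io),
        ("profile", _stage_profile),
        ("ndr", _stage_ndr),
        ("classify", _stage_classify),
        ("context", _stage_context),
        ("motifs", _stage_motifs),
        ("dynamics", _stage_dynamics),
        ("manifest", _stage_manifest),
    ]
    for name, fn in stages:
        logger.info("[%s] starting", name)
        try:
            fn(run)
        except Exception as exc:
            for p in run.written:
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        run.manifest["stages"].append(name)
        logger.info("[%s] done", name)
    return run.manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_io(run: _Run) -> None:
    cfg = run.config
    if cfg.synthetic is not None:
        sim = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        truth = generate_genome_and_annotations(sim)
        run.genome = truth.genome
        run.genes = truth.genes
        run.origins = truth.origins
        run.truth = truth
        run.starts = {"G1": sample_mononucleosome_reads(truth, phase="G1"),
                      "S": sample_mononucleosome_reads(truth, phase="S")}
        run.naked = {"G1": sample_naked_reads(truth, phase="G1"),
                     "S": sample_naked_reads(truth, phase="S")}
        widths = pd.DataFrame(
            [
                (n, a.class_id, a.ndr_width, a.ndr_start, a.ndr_end)
                for n, a in truth.architecture.per_origin.items()
            ],
            columns=["origin", "class_id", "ndr_width", "ndr_start", "ndr_end"],
        )
        run.write_tsv(widths, "planted_truth.tsv")
        io_mod.write_origin_table(truth.origins, run.path("origins.tsv"))
        return
    inputs = cfg.inputs or {}
    for key in ("genome", "genes", "origins", "reads_g1"):
        if key not in inputs:
            raise FileNotFoundError(f"required input {key!r} missing from config")
    run.genome = io_mod.read_fasta(inputs["genome"])
    run.genes = io_mod.read_gff_genes(inputs["genes"])
    run.origins = io_mod.read_origin_table(inputs["origins"], genome=run.genome)
    lengths = run.genome.chrom_lengths
    run.truth = None
    run.starts = {"G1": io_mod.read_bed_starts(inputs["reads_g1"], lengths)}
    if "reads_s" in inputs:
        run.starts["S"] = io_mod.read_bed_starts(inputs["reads_s"], lengths)
    run.naked = {}
    for phase, key in (("G1", "naked_g1"), ("S", "naked_s")):
        if key in inputs:
            run.naked[phase] = io_mod.read_bed_starts(inputs[key], lengths)


def _stage_profile(run: _Run) -> None:
    p = run.config.parameters
    run.profiles = {}
    run.spacings = {}
    for phase, starts in run.starts.items():
        spacing = genome_average_spacing(starts, p.smoothing_level, p.wavelet)
        profile = combined_profile(starts, spacing, p.smoothing_level, p.wavelet, p.footprint)
        run.spacings[phase] = spacing
        run.profiles[phase] = profile
        io_mod.write_bedgraph(profile, run.path(f"{phase.lower()}_profile.bedGraph"))
    calls = call_nucleosomes(run.starts["G1"], run.spacings["G1"],
                             p.smoothing_level, p.wavelet)
    io_mod.write_bed_intervals(
        (
            (c.chrom, max(c.dyad - 73, 0), c.dyad + 74, f"nuc{i + 1}", c.score, "+")
            for i, c in enumerate(calls)
        ),
        run.path("nucleosome_calls.bed"),
    )
    run.manifest["spacing_bp"] = {k: round(v, 3) for k, v in run.spacings.items()}


def _stage_ndr(run: _Run) -> None:
    p = run.config.parameters
    run.ndrs = ndr_mod.call_ndrs(run.profiles["G1"], p.min_len, p.threshold)
    origin_ndrs, nonorigin = ndr_mod.associate_ndrs_with_origins(
        run.ndrs, run.origins, p.max_dist
    )
    run.origin_ndrs = origin_ndrs
    io_mod.write_bed_intervals(
        (
            (n.chrom, n.start, n.end, n.origin_name or "NDR", float(n.width),
             "+")
            for n in run.ndrs
        ),
        run.path("ndrs.bed"),
    )
    table = ndr_mod.origin_width_table(run.origins, origin_ndrs)
    run.ndr_widths = {
        name: (float(w) if w is not ndr_mod.CLOSED else np.nan)
        for name, w in table.items()
    }
    df = pd.DataFrame(
        [(n, "CLOSED" if w is ndr_mod.CLOSED else w) for n, w in table.items()],
        columns=["origin", "ndr_width"],
    )
    run.write_tsv(df, "ndr_widths.tsv")
    run.manifest["ndr_rule"] = {"min_len": p.min_len, "threshold": p.threshold}


def _stage_classify(run: _Run) -> None:
    p = run.config.parameters
    run.matrix = arch_mod.build_profile_matrix(run.profiles["G1"], run.origins, p.halfwidth)
    run.assignment = arch_mod.cluster_origin_profiles(
        run.matrix, k=min(p.k, len(run.matrix.data)), iterations=p.iterations,
        restarts=p.restarts, seed=run.config.seed, ndr_widths=run.ndr_widths,
    )
    run.write_tsv(run.matrix.data, "origin_profile_matrix.tsv", index_label="origin")
    classes = pd.DataFrame(
        sorted(run.assignment.labels.items()), columns=["origin", "class_id"]
    )
    run.write_tsv(classes, "origin_classes.tsv")
    run.write_tsv(run.assignment.class_centroids, "class_centroids.tsv",
                  index_label="class_id")
    try:
        comp = arch_mod.class_timing_composition(run.assignment, run.origins)
        run.write_tsv(comp, "class_timing_composition.tsv", index_label="timing")
    except ValueError:
        logger.warning("no timing labels; class composition skipped")


def _stage_context(run: _Run) -> None:
    igrs = context_mod.build_igrs(run.genes)
    categories = [context_mod.origin_igr_category(o, igrs) for o in run.origins]
    df = pd.DataFrame({"origin": [o.name for o in run.origins], "category": categories})
    run.write_tsv(df, "origin_categories.tsv")
    enrich = context_mod.category_enrichment(categories)
    summary = pd.DataFrame(enrich).T
    run.write_tsv(summary, "igr_summary.tsv", index_label="category")
    io_mod.write_bed_intervals(
        ((i.chrom, i.start, i.end, i.category, 0.0, "+") for i in igrs),
        run.path("igrs.bed"),
    )


def _stage_motifs(run: _Run) -> None:
    p = run.config.parameters
    hits = motifs_mod.scan_motif(run.genome, p.motif)
    io_mod.write_bed_intervals(
        ((h.chrom, h.start, h.start + len(p.motif), p.motif, 0.0, h.strand) for h in hits),
        run.path("fkh_hits.bed"),
    )
    offsets = np.arange(-p.halfwidth, p.halfwidth + 1)
    density = {}
    for timing in ("early", "late"):
        group = [o for o in run.origins if o.timing == timing]
        if group:
            density[timing] = motifs_mod.motif_density_profile(
                hits, group, p.halfwidth, p.motif_smoothing_bw, len(p.motif)
            )
    if density:
        run.write_tsv(
            pd.DataFrame(density, index=offsets), "motif_density.tsv",
            index_label="offset",
        )
    rows = []
    for timing in ("early", "late"):
        if any(o.timing == timing for o in run.origins):
            frac = motifs_mod.fraction_with_configuration(
                run.origins, hits, timing=timing,
                proximal_max=p.proximal_max, sep_min=p.sep_min, sep_max=p.sep_max,
            )
            rows.append((timing, frac))
    if rows:
        run.write_tsv(
            pd.DataFrame(rows, columns=["timing", "dual_site_fraction"]),
            "fkh_dual_fraction.tsv",
        )


def _stage_dynamics(run: _Run) -> None:
    if "S" not in run.profiles:
        logger.info("no S-phase sample; dynamics stage skipped")
        return
    p = run.config.parameters
    diff = dyn_mod.differential_track(run.profiles["S"], run.profiles["G1"])
    io_mod.write_bedgraph(CoverageTrack(diff.values), run.path("differential.bedGraph"))
    extents = pd.DataFrame(
        [
            (o.name, o.timing, dyn_mod.replicated_extent(diff, o, window=p.window))
            for o in run.origins
        ],
        columns=["origin", "timing", "replicated_extent_bp"],
    )
    run.write_tsv(extents, "replicated_extent.tsv")
    s_matrix = arch_mod.build_profile_matrix(run.profiles["S"], run.origins, p.halfwidth)
    shared = [n for n in run.matrix.origin_names if n in set(s_matrix.origin_names)]
    groups = {o.name: o.timing for o in run.origins
              if o.timing in ("early", "late") and o.name in shared}
    if groups:
        report = dyn_mod.origin_shift_report(
            run.matrix.subset(shared), s_matrix.subset(shared), groups
        )
        run.write_tsv(report, "shift_report.tsv", index_label="group")
    if "G1" in run.naked and "S" in run.naked:
        agg = {"offset": np.arange(-p.halfwidth, p.halfwidth + 1)}
        for phase in ("G1", "S"):
            raw = starts_to_raw_coverage(run.starts[phase], p.footprint)
            naked_raw = starts_to_raw_coverage(run.naked[phase], p.footprint)
            corrected = dyn_mod.copy_number_correct(raw, naked_raw, p.window)
            corrected = _normalize_nan_aware(corrected)
            for timing in ("early", "late"):
                group = [o for o in run.origins if o.timing == timing]
                if not group:
                    continue
                m = arch_mod.build_profile_matrix(corrected, group, p.halfwidth)
                agg[f"{phase.lower()}_{timing}"] = arch_mod.aggregate_profile(m)
        run.write_tsv(pd.DataFrame(agg), "corrected_aggregate.tsv")


def _stage_manifest(run: _Run) -> None:
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
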
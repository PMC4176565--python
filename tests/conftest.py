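"""Shared fixtures: small synthetic studies reused across test modules.

Heavy simulations are session-scoped so the recovery suites share one
generation + sampling pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import orichrom as oc
from orichrom.nucleosome_calling import genome_average_spacing


@pytest.fixture(scope="session")
def small_truth():
    """A compact two-chromosome study: 16 origins, 50x coverage."""
    cfg = oc.SimConfig(
        genome_length=250_000, n_chroms=2, n_genes=180, n_origins=16,
        fraction_early=0.5, mean_coverage=50.0, seed=5,
    )
    return oc.generate_genome_and_annotations(cfg)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return oc.sample_mononucleosome_reads(small_truth, phase="G1")


@pytest.fixture(scope="session")
def small_profile(small_reads):
    spacing = genome_average_spacing(small_reads)
    profile = oc.combined_profile(small_reads, spacing)
    return profile, spacing


@pytest.fixture(scope="session")
def class_sim():
    """The six-class planted design: 100 origins per class at ~80x.

    Returns (truth, profile, spacing); the balanced class assignment
    gives exactly 100 origins in each architecture class.
    """
    cfg = oc.SimConfig(
        genome_length=2_600_000, n_chroms=4, n_genes=1900, n_origins=600,
        fraction_early=0.5, mean_coverage=80.0, seed=11,
        class_assignment="balanced",
    )
    truth = oc.generate_genome_and_annotations(cfg)
    reads = oc.sample_mononucleosome_reads(truth, phase="G1")
    spacing = genome_average_spacing(reads)
    profile = oc.combined_profile(reads, spacing)
    return truth, profile, spacing


@pytest.fixture(scope="session")
def dynamics_sim():
    """Well-separated origins with G1/S mononucleosome and naked samples."""
    cfg = oc.SimConfig(
        genome_length=1_300_000, n_chroms=2, n_genes=950, n_origins=40,
        fraction_early=0.5, mean_coverage=50.0, seed=9, origin_slot_spacing=9,
    )
    truth = oc.generate_genome_and_annotations(cfg)
    starts = {p: oc.sample_mononucleosome_reads(truth, phase=p) for p in ("G1", "S")}
    naked = {p: oc.sample_naked_reads(truth, phase=p) for p in ("G1", "S")}
    profiles = {}
    for phase in ("G1", "S"):
        spacing = genome_average_spacing(starts[phase])
        profiles[phase] = oc.combined_profile(starts[phase], spacing)
    return truth, starts, naked, profiles


def make_track(values_by_chrom):
    """CoverageTrack from plain arrays/lists."""
    return oc.CoverageTrack(
        {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    )
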
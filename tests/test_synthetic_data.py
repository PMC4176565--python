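"""The generator's planted truth and its read model."""

import dataclasses

import numpy as np
import pytest

import orichrom as oc
from orichrom.synthetic_data import ACS_TRICH, FKH_INSTANCE, revcomp


def _tiny_cfg(**kw):
    base = dict(
        genome_length=120_000, n_chroms=1, n_genes=90, n_origins=8,
        mean_coverage=40.0, seed=2,
    )
    base.update(kw)
    return oc.SimConfig(**base)


class TestGeneration:
    def test_same_seed_is_byte_identical(self):
        t1 = oc.generate_genome_and_annotations(_tiny_cfg())
        t2 = oc.generate_genome_and_annotations(_tiny_cfg())
        assert t1.genome.chroms == t2.genome.chroms
        assert t1.genes == t2.genes
        assert t1.origins == t2.origins
        for chrom in t1.dyads:
            np.testing.assert_array_equal(t1.dyads[chrom], t2.dyads[chrom])

    def test_fraction_early_one_makes_all_origins_early(self):
        truth = oc.generate_genome_and_annotations(_tiny_cfg(fraction_early=1.0))
        assert all(o.timing == "early" for o in truth.origins)

    def test_planted_widths_match_class_means_without_jitter(self):
        cfg = _tiny_cfg(n_origins=6, ndr_width_jitter=0, class_assignment="balanced")
        truth = oc.generate_genome_and_annotations(cfg)
        widths = {
            truth.architecture[o.name].class_id: truth.architecture[o.name].ndr_width
            for o in truth.origins
        }
        assert widths[1] == 193 and widths[6] == 129

    def test_planted_ndr_matches_recorded_interval(self):
        truth = oc.generate_genome_and_annotations(_tiny_cfg())
        for name, arch in truth.architecture.per_origin.items():
            assert arch.ndr_end - arch.ndr_start == arch.ndr_width
            # no planted dyad inside the NDR
            for d in arch.dyad_positions:
                assert not (arch.ndr_start <= d < arch.ndr_end)

    def test_too_many_origins_rejected(self):
        with pytest.raises(ValueError, match="origins"):
            oc.generate_genome_and_annotations(
                _tiny_cfg(n_genes=12, n_origins=30, genome_length=40_000)
            )

    def test_acs_written_t_rich_on_acs_strand(self):
        truth = oc.generate_genome_and_annotations(_tiny_cfg())
        for o in truth.origins:
            seq = truth.genome.fetch(o.chrom, o.acs_start, o.acs_end)
            oriented = seq if o.acs_strand == "+" else revcomp(seq)
            assert oriented == ACS_TRICH

    def test_planted_fkh_sites_are_exact_consensus(self):
        truth = oc.generate_genome_and_annotations(_tiny_cfg(fraction_early=1.0))
        hits = oc.scan_motif(truth.genome)
        hit_keys = {(h.chrom, h.start) for h in hits}
        n_checked = 0
        for o in truth.origins:
            for off in truth.architecture[o.name].fkh_offsets:
                if o.acs_strand == "+":
                    start = o.acs_mid + off
                else:
                    start = o.acs_mid - off - (len(FKH_INSTANCE) - 1)
                assert (o.chrom, start) in hit_keys
                n_checked += 1
        assert n_checked > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            oc.SimConfig(mean_coverage=0)
        with pytest.raises(ValueError):
            oc.SimConfig(fraction_early=1.5)
        with pytest.raises(ValueError):
            oc.SimConfig(class_occupancy=(0.9, 0.8))


class TestMononucleosomeSampling:
    def test_deterministic_per_phase(self, small_truth):
        a = oc.sample_mononucleosome_reads(small_truth, phase="G1")
        b = oc.sample_mononucleosome_reads(small_truth, phase="G1")
        for chrom in a.plus:
            np.testing.assert_array_equal(a.plus[chrom], b.plus[chrom])
            np.testing.assert_array_equal(a.minus[chrom], b.minus[chrom])

    def test_boundary_piles_flank_dyads_without_jitter(self):
        cfg = _tiny_cfg(
            tile_fuzziness=0.0, class_fuzziness=(0.0,) * 6, fragment_length_sd=0.0,
            mean_coverage=60.0,
        )
        truth = oc.generate_genome_and_annotations(cfg)
        reads = oc.sample_mononucleosome_reads(truth)
        chrom = truth.origins[0].chrom
        # an isolated background dyad: all plus mass at d-73, minus at d+73
        d = int(truth.dyads[chrom][0])
        plus, minus = reads.plus[chrom], reads.minus[chrom]
        assert plus[d - 73] > 0 and plus[d - 80 : d - 73].sum() == 0
        assert minus[d + 73] > 0 and minus[d + 74 : d + 80].sum() == 0

    def test_planted_ndrs_hold_no_fragments(self, small_truth, small_reads):
        # background rate is 0, so NDR interiors carry no boundary reads
        for o in small_truth.origins:
            arch = small_truth.architecture[o.name]
            margin = int(3 * arch.fuzziness_sd + 10)
            lo, hi = arch.ndr_start + margin, arch.ndr_end - margin
            if hi <= lo:
                continue
            assert small_truth.dyads[o.chrom].size > 0
            assert small_reads.plus[o.chrom][lo:hi].sum() == 0

    def test_s_phase_doubles_only_early_origin_windows(self, dynamics_sim):
        truth, starts, _, _ = dynamics_sim
        def window_counts(track, origin, hw=600):
            lo, hi = origin.acs_mid - hw, origin.acs_mid + hw
            return (
                track.plus[origin.chrom][lo:hi].sum()
                + track.minus[origin.chrom][lo:hi].sum()
            )
        ratios = {"early": [], "late": []}
        for o in truth.origins:
            ratios[o.timing].append(
                window_counts(starts["S"], o) / window_counts(starts["G1"], o)
            )
        assert np.mean(ratios["early"]) == pytest.approx(2.0, abs=0.15)
        assert np.mean(ratios["late"]) == pytest.approx(1.0, abs=0.1)

    def test_empty_occupancy_yields_no_reads(self):
        cfg = _tiny_cfg(tile_occupancy=0.0, class_occupancy=(0.0,) * 6)
        truth = oc.generate_genome_and_annotations(cfg)
        reads = oc.sample_mononucleosome_reads(truth)
        assert reads.total_reads == 0


class TestNakedSampling:
    def test_rate_matches_expectation_genome_wide(self, small_truth):
        naked = oc.sample_naked_reads(small_truth)
        cfg = small_truth.config
        n = sum(small_truth.genome.chrom_lengths.values())
        expected = cfg.mean_coverage * n / cfg.read_length
        assert naked.total_reads == pytest.approx(expected, rel=0.05)

    def test_deterministic(self, small_truth):
        a = oc.sample_naked_reads(small_truth)
        b = oc.sample_naked_reads(small_truth)
        for chrom in a.plus:
            np.testing.assert_array_equal(a.plus[chrom], b.plus[chrom])

    def test_invalid_phase_rejected(self, small_truth):
        with pytest.raises(ValueError, match="phase"):
            oc.sample_naked_reads(small_truth, phase="G2")


def test_boundary_spacing_equals_footprint_in_noiseless_limit():
    cfg = _tiny_cfg(
        tile_fuzziness=0.0, class_fuzziness=(0.0,) * 6, fragment_length_sd=0.0,
        mean_coverage=60.0,
    )
    truth = oc.generate_genome_and_annotations(cfg)
    reads = oc.sample_mononucleosome_reads(truth)
    from orichrom.nucleosome_calling import genome_average_spacing

    spacing = genome_average_spacing(reads)
    assert abs(spacing - cfg.nucleosome_footprint) <= 1.0


def test_igr_categories_converge_to_expected_frequencies():
    cfg = oc.SimConfig(
        genome_length=2_700_000, n_chroms=2, n_genes=3000, n_origins=0,
        mean_coverage=1.0, seed=8, scrub_spurious_motifs=False,
    )
    truth = oc.generate_genome_and_annotations(cfg)
    igrs = oc.build_igrs(truth.genes)
    n = len(igrs)
    freqs = {
        cat: sum(1 for i in igrs if i.category == cat) / n
        for cat in ("tandem", "divergent", "convergent")
    }
    z = 2.576  # 99% binomial CI
    for cat, p in zip(("tandem", "divergent", "convergent"), (0.5, 0.25, 0.25)):
        half = z * np.sqrt(p * (1 - p) / n)
        assert abs(freqs[cat] - p) <= half, (cat, freqs[cat], p, half)
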
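"""Differential tracks, copy-number correction, extents, shift report."""

import numpy as np
import pandas as pd
import pytest

import orichrom as oc
from orichrom.origin_architecture import OriginProfileMatrix
from orichrom.replication_dynamics import DifferentialTrack
from tests.conftest import make_track


class TestDifferentialTrack:
    def test_identical_inputs_give_zero(self):
        t = make_track({"c": np.ones(100)})
        diff = oc.differential_track(t, t)
        assert not diff.values["c"].any()

    def test_exact_offset_recovered(self):
        g1 = make_track({"c": np.ones(100)})
        s = make_track({"c": np.ones(100)})
        s.values["c"][20:60] += 0.5
        diff = oc.differential_track(s, g1)
        np.testing.assert_allclose(diff.values["c"][20:60], 0.5)
        assert not diff.values["c"][:20].any()

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = make_track({"c": rng.random(200)})
        b = make_track({"c": rng.random(200)})
        ab = oc.differential_track(a, b).values["c"]
        ba = oc.differential_track(b, a).values["c"]
        np.testing.assert_allclose(ab, -ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            oc.differential_track(
                make_track({"c": np.ones(10)}), make_track({"c": np.ones(20)})
            )


class TestCopyNumberCorrect:
    def test_flat_naked_preserves_shape(self):
        rng = np.random.default_rng(1)
        nuc = make_track({"c": rng.random(5000) + 0.5})
        naked = make_track({"c": np.full(5000, 3.0)})
        out = oc.copy_number_correct(nuc, naked, window=1000)
        np.testing.assert_allclose(out.values["c"], nuc.values["c"], rtol=1e-9)

    def test_naked_equal_nucleosomal_is_flat_one(self):
        rng = np.random.default_rng(2)
        values = rng.random(5000) + 0.5
        nuc = make_track({"c": values})
        out = oc.copy_number_correct(nuc, make_track({"c": values.copy()}), window=1000)
        core = out.values["c"][600:-600]
        # correction by the smoothed self leaves only sub-window texture
        assert np.nanmean(core) == pytest.approx(1.0, abs=0.05)

    def test_zero_naked_positions_masked_not_infinite(self):
        nuc = make_track({"c": np.ones(3000)})
        naked_values = np.ones(3000)
        naked_values[:1500] = 0.0  # longer than the smoothing window
        out = oc.copy_number_correct(nuc, make_track({"c": naked_values}), window=100)
        assert np.isnan(out.values["c"][:1400]).all()
        assert np.isfinite(out.values["c"][1600:]).all()

    def test_all_zero_naked_rejected(self):
        with pytest.raises(ValueError):
            oc.copy_number_correct(
                make_track({"c": np.ones(100)}), make_track({"c": np.zeros(100)})
            )

    def test_corrected_s_matches_g1_at_early_origins(self, dynamics_sim):
        truth, starts, naked, _ = dynamics_sim
        from orichrom.coverage import starts_to_raw_coverage
        from orichrom.pipeline import _normalize_nan_aware

        early = [o for o in truth.origins if o.timing == "early"]
        agg = {}
        for phase in ("G1", "S"):
            corrected = oc.copy_number_correct(
                starts_to_raw_coverage(starts[phase], 147),
                starts_to_raw_coverage(naked[phase], 147),
                window=1000,
            )
            corrected = _normalize_nan_aware(corrected)
            matrix = oc.build_profile_matrix(corrected, early)
            agg[phase] = oc.aggregate_profile(matrix)
        deviation = np.max(np.abs(agg["S"] - agg["G1"])) / np.max(agg["G1"])
        assert deviation <= 0.10


class TestReplicatedExtent:
    def _diff(self, n=20000, plateau=None, level=1.0):
        values = np.zeros(n)
        if plateau:
            values[plateau[0] : plateau[1]] = level
        return DifferentialTrack({"c": values})

    def _origin(self, mid=10000):
        return oc.OriginRecord("O1", "c", mid - 8, mid + 9, "+", "early")

    def test_flat_differential_gives_zero(self):
        assert oc.replicated_extent(self._diff(), self._origin()) == 0

    def test_plateau_span_recovered(self):
        diff = self._diff(plateau=(7750, 12250))  # 4.5 kb centered on the ACS
        extent = oc.replicated_extent(diff, self._origin())
        assert extent == pytest.approx(4500, abs=700)

    def test_low_peak_treated_as_not_fired(self):
        diff = self._diff(plateau=(7750, 12250), level=0.05)  # below the floor
        assert oc.replicated_extent(diff, self._origin()) == 0

    def test_early_origins_span_late_origins_zero(self, dynamics_sim):
        truth, _, _, profiles = dynamics_sim
        diff = oc.differential_track(profiles["S"], profiles["G1"])
        early = [oc.replicated_extent(diff, o) for o in truth.origins
                 if o.timing == "early"]
        late = [oc.replicated_extent(diff, o) for o in truth.origins
                if o.timing == "late"]
        assert 4000 <= np.mean(early) <= 5500
        assert max(late) == 0


class TestOriginShiftReport:
    def _matrix(self, shift=0, ndr_half=100, names=("O1", "O2")):
        x = np.arange(-600, 601)
        profile = np.ones(1201)
        profile[np.abs(x) < ndr_half] = 0.1  # NDR
        for peak in (-ndr_half - 80, ndr_half + 80):
            profile += 0.8 * np.exp(-0.5 * ((x - peak - shift) / 25.0) ** 2)
        df = pd.DataFrame([profile] * len(names), index=list(names))
        df.columns = x
        return OriginProfileMatrix(df)

    def test_identical_matrices_give_zero_deltas(self):
        m = self._matrix()
        report = oc.origin_shift_report(m, m, {"O1": "early", "O2": "early"})
        row = report.loc["early"]
        assert row["delta_ndr_width"] == 0
        assert row["delta_plus1_offset"] == 0
        assert row["delta_minus1_height"] == 0

    def test_translated_plus_one_peak_detected(self):
        g1 = self._matrix()
        s = self._matrix(shift=-15)
        report = oc.origin_shift_report(g1, s, {"O1": "early", "O2": "early"})
        assert report.loc["early", "delta_plus1_offset"] == pytest.approx(-15, abs=2)

    def test_widened_ndr_detected(self):
        g1 = self._matrix(ndr_half=65)
        s = self._matrix(ndr_half=90)
        report = oc.origin_shift_report(g1, s, {"O1": "late", "O2": "late"})
        assert report.loc["late", "delta_ndr_width"] == pytest.approx(50, abs=4)

    def test_unmatched_origin_sets_rejected(self):
        with pytest.raises(ValueError):
            oc.origin_shift_report(
                self._matrix(names=("O1",)), self._matrix(names=("O2",)), {"O1": "x"}
            )

    def test_planted_s_phase_signs(self, dynamics_sim):
        """In the HU design the S-sample differential is copy-number
        driven, so early-origin aggregate heights rise in S."""
        truth, _, _, profiles = dynamics_sim
        g1 = oc.build_profile_matrix(profiles["G1"], truth.origins)
        s = oc.build_profile_matrix(profiles["S"], truth.origins)
        shared = [n for n in g1.origin_names if n in set(s.origin_names)]
        groups = {o.name: o.timing for o in truth.origins if o.name in shared}
        report = oc.origin_shift_report(g1.subset(shared), s.subset(shared), groups)
        assert report.loc["early", "delta_plus1_height"] > 0.2
        assert abs(report.loc["late", "delta_plus1_height"]) < 0.2
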
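"""Triplicate filtering, LOD calibration, QC, and the MRD call."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liqbio.calling import (
    BELOW_LOD, DETECTED, NO_DATA, LODEntry, MarkerMeasurement, MRDCall,
    apply_lod, call_mrd, call_sample, compute_lod, filter_triplicates,
    measure_marker, sample_qc,
)
from liqbio.quantify import ReplicateCount


def counts_from_vafs(vafs, marker="m", denom=10_000):
    """Build ReplicateCounts whose VAFs equal the given values exactly;
    None yields a replicate with nothing classified."""
    out = []
    for i, v in enumerate(vafs, start=1):
        if v is None:
            out.append(ReplicateCount(marker, i, n_wt=0, n_mut=0,
                                      n_unclassified=5))
        else:
            n_mut = round(v * denom)
            assert abs(n_mut / denom - v) < 1e-12, "choose denom to make v exact"
            out.append(ReplicateCount(marker, i, n_wt=denom - n_mut,
                                      n_mut=n_mut))
    return out


class TestFilterTriplicates:
    def test_zero_variance_triplicate_never_pruned(self):
        m = filter_triplicates(counts_from_vafs([0.2, 0.2, 0.2]))
        assert m.retained_replicates == (1, 2, 3)
        assert m.marker_vaf == pytest.approx(0.2)

    def test_high_outlier_excluded_by_mean_plus_sd(self):
        # mean 0.20, sample sd ~0.17321, cutoff ~0.37321 < 0.40
        m = filter_triplicates(counts_from_vafs([0.10, 0.10, 0.40]))
        assert m.retained_replicates == (1, 2)
        assert m.marker_vaf == pytest.approx(0.10)

    def test_direct_arithmetic_with_sample_sd(self):
        vafs = [0.10, 0.10, 0.40]
        mean = np.mean(vafs)
        sd = np.std(vafs, ddof=1)
        assert sd == pytest.approx(0.17320508, abs=1e-8)
        m = filter_triplicates(counts_from_vafs(vafs))
        retained = [vafs[r - 1] for r in m.retained_replicates]
        assert retained == [v for v in vafs if v <= mean + sd]
        assert m.marker_vaf == pytest.approx(np.mean(retained))

    def test_undefined_replicate_dropped_before_statistics(self):
        m = filter_triplicates(counts_from_vafs([0.10, None, 0.12]))
        # pair statistics: mean 0.11, sd ~0.01414, cutoff ~0.12414 -> both kept
        assert m.retained_replicates == (1, 3)
        assert m.marker_vaf == pytest.approx(0.11)

    def test_pair_with_true_outlier(self):
        m = filter_triplicates(counts_from_vafs([0.10, None, 0.50]))
        # mean 0.3, sd ~0.28284; 0.5 <= 0.58284 -> retained (pairs rarely prune)
        assert m.retained_replicates == (1, 3)

    def test_single_defined_replicate_is_retained(self):
        m = filter_triplicates(counts_from_vafs([None, 0.3, None]))
        assert m.retained_replicates == (2,)
        assert m.marker_vaf == pytest.approx(0.3)

    def test_no_defined_replicates_is_no_data(self):
        m = filter_triplicates(counts_from_vafs([None, None, None]))
        assert m.status == NO_DATA and m.marker_vaf is None

    def test_more_than_three_replicates_rejected(self):
        with pytest.raises(ValueError):
            filter_triplicates(counts_from_vafs([0.1] * 4))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=3))
    def test_retained_set_matches_direct_arithmetic(self, muts):
        vafs = [m / 10_000 for m in muts]
        meas = filter_triplicates(counts_from_vafs(vafs))
        cutoff = np.mean(vafs) + np.std(vafs, ddof=1)
        expected = [i + 1 for i, v in enumerate(vafs) if v <= cutoff]
        assert list(meas.retained_replicates) == expected
        assert meas.marker_vaf == pytest.approx(
            np.mean([vafs[i - 1] for i in expected]))


class TestComputeLod:
    def test_nine_zeros(self):
        assert compute_lod("m", [0.0] * 9).lod == 0.0

    def test_hand_computed_nine_point_lod(self):
        # eight zeros + one 9e-5: mean 1e-5, sample sd 3e-5, LOD 1e-4
        entry = compute_lod("m", [0.0] * 8 + [9e-5])
        assert entry.mean == pytest.approx(1e-5, rel=1e-12)
        assert entry.lod == pytest.approx(1e-4, rel=1e-12)

    def test_constant_controls_have_lod_equal_value(self):
        assert compute_lod("m", [3e-4] * 9).lod == pytest.approx(3e-4)

    def test_strict_mode_requires_exactly_nine_points(self):
        with pytest.raises(ValueError, match="9"):
            compute_lod("m", [0.0] * 8)
        lenient = compute_lod("m", [0.0] * 8, strict=False)
        assert lenient.lod == 0.0

    def test_out_of_range_controls_rejected(self):
        with pytest.raises(ValueError):
            compute_lod("m", [0.0] * 8 + [1.5])


class TestApplyLod:
    def measurement(self, vaf, marker="m"):
        return MarkerMeasurement(marker_id=marker, replicate_counts=(),
                                 retained_replicates=(1,), marker_vaf=vaf,
                                 status=DETECTED)

    def lod(self, value, marker="m"):
        return LODEntry(marker_id=marker, control_vafs=(value,) * 9,
                        lod=value)

    def test_clear_separation_detected(self):
        out = apply_lod(self.measurement(2e-4), self.lod(5e-5))
        assert out.status == DETECTED and out.lod == 5e-5

    def test_below_lod_excluded(self):
        out = apply_lod(self.measurement(3e-5), self.lod(1e-4))
        assert out.status == BELOW_LOD

    def test_boundary_is_inclusive_for_detection(self):
        # "lower than the LOD" excludes; equality stays detected
        out = apply_lod(self.measurement(1e-4), self.lod(1e-4))
        assert out.status == DETECTED

    def test_marker_mismatch_and_missing_lod(self):
        with pytest.raises(ValueError):
            apply_lod(self.measurement(1e-4), self.lod(1e-4, marker="other"))
        with pytest.raises(ValueError):
            apply_lod(self.measurement(1e-4), None)
        out = apply_lod(self.measurement(1e-4), None, missing_lod="zero")
        assert out.status == DETECTED and out.lod == 0.0


class TestCallMrd:
    def meas(self, marker, vaf, status=DETECTED):
        return MarkerMeasurement(marker_id=marker, replicate_counts=(),
                                 retained_replicates=(1,), marker_vaf=vaf,
                                 status=status)

    def test_max_over_detected_markers_only(self):
        call = call_mrd([self.meas("A", 2e-4),
                         self.meas("B", 3e-4, status=BELOW_LOD)])
        assert call.mrd_value == pytest.approx(2e-4)
        assert call.positive and call.best_marker == "A"

    def test_all_below_lod_is_negative_zero(self):
        call = call_mrd([self.meas("A", 2e-4, status=BELOW_LOD)])
        assert call.mrd_value == 0.0 and not call.positive
        assert call.best_marker is None

    def test_threshold_boundary_inclusive(self):
        assert call_mrd([self.meas("A", 1e-4)]).positive
        assert not call_mrd([self.meas("A", 9.999e-5)]).positive

    def test_tie_broken_lexicographically(self):
        call = call_mrd([self.meas("B", 5e-3), self.meas("A", 5e-3)])
        assert call.best_marker == "A"

    def test_order_invariance(self):
        ms = [self.meas("A", 1e-3), self.meas("B", 2e-3),
              self.meas("C", 5e-4)]
        assert call_mrd(ms) == call_mrd(ms[::-1])

    def test_empty_measurements_warns_negative(self):
        call = call_mrd([])
        assert not call.positive and "no_measurements" in call.warnings

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(vafs=st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                         max_size=6),
           thr_lo=st.floats(1e-6, 1e-2), factor=st.floats(1.0, 100.0))
    def test_raising_threshold_never_creates_a_positive(self, vafs, thr_lo,
                                                        factor):
        ms = [self.meas(f"M{i}", v) for i, v in enumerate(vafs)]
        lo = call_mrd(ms, threshold=thr_lo)
        hi = call_mrd(ms, threshold=thr_lo * factor)
        assert not (hi.positive and not lo.positive)

    def test_lowering_lod_never_removes_a_detected_marker(self):
        meas = self.meas("A", 2e-4)
        strict = apply_lod(meas, LODEntry("A", (0.0,) * 9, 3e-4))
        loose = apply_lod(meas, LODEntry("A", (0.0,) * 9, 1e-5))
        assert strict.status == BELOW_LOD and loose.status == DETECTED


class TestSampleQC:
    def test_median_cfdna_sample_passes(self):
        qc = sample_qc("s1", "cfDNA", 20.9, 0.5)
        assert qc.passed and qc.reasons == ()

    def test_low_input_cfdna_fails(self):
        qc = sample_qc("s2", "cfDNA", 14.0)
        assert not qc.passed and qc.reasons == ("low_input",)

    def test_high_gdna_ratio_fails(self):
        qc = sample_qc("s3", "cfDNA", 30.0, 1.2)
        assert qc.reasons == ("high_gdna_ratio",)

    def test_ctc_fraction_uses_gdna_minimum(self):
        assert sample_qc("s4", "CTC", 660.0).passed
        assert sample_qc("s5", "CTC", 600.0).reasons == ("low_input",)
        # the gDNA-contamination rule is a cfDNA-only concern
        assert sample_qc("s6", "CTC", 700.0, 2.0).passed

    def test_negative_quantities_rejected(self):
        with pytest.raises(ValueError):
            sample_qc("s7", "cfDNA", -1.0)
        with pytest.raises(ValueError):
            sample_qc("s8", "plasma", 20.0)


class TestCallSample:
    def test_end_to_end_two_markers(self):
        counts = {
            "A": counts_from_vafs([2e-4, 2e-4, 2e-4], marker="A"),
            "B": counts_from_vafs([5e-3, 5e-3, 5e-3], marker="B"),
        }
        lods = {k: LODEntry(k, (0.0,) * 9, 1e-5) for k in counts}
        call = call_sample(counts, lods, sample_id="s1")
        assert call.best_marker == "B"
        assert call.mrd_value == pytest.approx(5e-3)
        assert {m.marker_id for m in call.provenance} == {"A", "B"}

    def test_qc_failing_sample_is_excluded_from_calling(self):
        counts = {"A": counts_from_vafs([0.5, 0.5, 0.5], marker="A")}
        lods = {"A": LODEntry("A", (0.0,) * 9, 0.0)}
        qc = sample_qc("s1", "cfDNA", 14.0)
        call = call_sample(counts, lods, sample_id="s1", qc=qc)
        assert not call.positive and call.mrd_value == 0.0
        assert call.warnings == ("qc_fail:low_input",)
        assert all(m.status == "excluded_qc" for m in call.provenance)
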
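"""Calibration arithmetic: read summaries, differences, correction factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import headcirc as hc
from headcirc.calibration import (
    AgeGroup,
    CalibrationError,
    CalibrationRecord,
    Measurement,
    analytic_circumference,
    apply_cf,
    derive_cf,
    load_cf_table,
    reported_record,
    ring_difference,
    run_calibration,
    save_cf_table,
    summarize_reads,
)
from headcirc.phantom import PhantomSpec, RingSpec, nellhaus_ring_set, rasterize_phantom
from headcirc.presets import cf_preset


class TestSummarizeReads:
    def test_ring1_reads_summary(self):
        m = summarize_reads((37.88, 38.47, 37.91, 38.14, 38.06)).rounded()
        assert (m.value, m.sd) == (38.1, 0.2)

    def test_ring11_reads_summary(self):
        m = summarize_reads((56.36, 56.58, 55.69, 56.58, 56.70)).rounded()
        assert (m.value, m.sd) == (56.4, 0.4)

    def test_single_read_has_zero_sd(self):
        m = summarize_reads([47.3])
        assert (m.value, m.sd) == (47.3, 0.0)

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError):
            summarize_reads([])


class TestAnalyticCircumference:
    def test_closed_form(self):
        m = analytic_circumference(100.0, 0.0)
        assert m.value == pytest.approx(10.0 * math.pi, abs=1e-12)

    def test_ring1_diameter_back_computes(self):
        assert analytic_circumference(113.0).rounded().value == 35.5

    def test_sd_scales_linearly(self):
        assert analytic_circumference(100.0, 0.2).sd == pytest.approx(
            2 * analytic_circumference(100.0, 0.1).sd
        )

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValueError):
            analytic_circumference(0.0)


class TestRingDifference:
    def test_ring1_printed_row(self):
        d = ring_difference(Measurement(38.1, 0.2), Measurement(35.5, 0.3)).rounded()
        assert (d.value, d.sd) == (-2.6, 0.4)

    def test_ring11_printed_row(self):
        d = ring_difference(Measurement(56.4, 0.4), Measurement(52.8, 0.3)).rounded()
        assert (d.value, d.sd) == (-3.6, 0.5)

    def test_equal_measurements_differ_by_zero(self):
        d = ring_difference(Measurement(40.0, 0.2), Measurement(40.0, 0.3))
        assert d.value == 0.0
        assert d.sd == pytest.approx(math.hypot(0.2, 0.3))

    @given(
        a=st.floats(0.0, 2.0),
        b=st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_quadrature_bounds(self, a, b):
        # combined sd is never below either component nor above their sum
        d = ring_difference(Measurement(50.0, a), Measurement(48.0, b))
        assert max(a, b) <= d.sd <= a + b + 1e-12


class TestDeriveCf:
    STRUCTURE1 = (-2.6, -2.4, -2.8, -2.9, -2.4, -2.5, -2.5, -2.5, -2.8)
    STRUCTURE2 = (-3.2, -3.6, -3.6, -3.6)

    @staticmethod
    def _records(diffs, group):
        return [
            CalibrationRecord(
                ring_label=f"r{i}",
                reads=(),
                est=Measurement(0.0),
                real=Measurement(1.0),
                difference=Measurement(d, 0.1),
                group=group,
            )
            for i, d in enumerate(diffs)
        ]

    def test_structure1_pooled_cf(self):
        cf = derive_cf(self._records(self.STRUCTURE1, "0-3"), "0-3")
        assert cf.cf.rounded().value == -2.6
        assert cf.cf.rounded().sd == 0.2
        assert cf.group.min_months == 0.0

    def test_structure2_pooled_cf(self):
        cf = derive_cf(self._records(self.STRUCTURE2, "3-18"), "3-18")
        assert (cf.cf.rounded().value, cf.cf.rounded().sd) == (-3.5, 0.2)

    def test_identical_differences_have_zero_spread(self):
        cf = derive_cf(self._records([-2.5, -2.5, -2.5], "0-3"), "0-3")
        assert (cf.cf.value, cf.cf.sd) == (-2.5, 0.0)

    def test_single_record_rejected(self):
        with pytest.raises(CalibrationError, match=">= 2"):
            derive_cf(self._records([-2.5], "0-3"), "0-3")

    def test_mixed_groups_rejected(self):
        records = self._records([-2.5, -2.6], "0-3") + self._records([-3.6], "3-18")
        with pytest.raises(CalibrationError, match="multiple groups"):
            derive_cf(records, "0-3")


class TestApplyCf:
    def test_older_group_example(self):
        res = apply_cf(Measurement(61.3, 0.5), cf_preset(), age_months=60)
        assert res.applied
        assert (res.corrected.rounded().value, res.corrected.rounded().sd) == (57.6, 0.6)

    def test_younger_group_example(self):
        res = apply_cf(Measurement(46.7, 0.5), cf_preset(), age_months=12)
        assert (res.corrected.rounded().value, res.corrected.rounded().sd) == (43.9, 0.5)

    def test_zero_cf_is_identity(self):
        table = [
            hc.CorrectionFactor(AgeGroup("all", 0, 1200), Measurement(0.0, 0.0))
        ]
        raw = Measurement(50.0, 0.5)
        res = apply_cf(raw, table, 10)
        assert res.corrected == raw

    def test_uncovered_age_flagged_not_silent(self):
        res = apply_cf(Measurement(50.0, 0.5), cf_preset(), age_months=500)
        assert not res.applied
        assert res.cf is None
        assert res.corrected == Measurement(50.0, 0.5)

    def test_subtracting_cf_recovers_raw_and_sd_grows(self):
        raw = Measurement(52.4, 0.5)
        res = apply_cf(raw, cf_preset(), age_months=12)
        assert res.corrected.value - res.cf.cf.value == pytest.approx(raw.value)
        assert res.corrected.sd >= raw.sd


class TestRunCalibration:
    def test_rerun_is_bit_identical(self):
        ring = RingSpec(outer_diameter_mm=113.0, center_mm=(0, 0, 5.5), label="r")
        spec = PhantomSpec(rings=[ring], spacing=(0.5, 0.5, 1.0), noise_sigma=2.0, seed=9)
        r1 = run_calibration(rasterize_phantom(spec))
        r2 = run_calibration(rasterize_phantom(spec))
        assert r1[0].reads == r2[0].reads
        assert r1[0].est == r2[0].est

    def test_five_reads_per_ring_at_protocol_spacing(self, phantom_0_3):
        records = run_calibration(phantom_0_3, method="corner_corrected")
        assert all(len(r.reads) == 5 for r in records)

    def test_missing_manifest_rejected(self, small_head_volume):
        with pytest.raises(CalibrationError, match="manifest"):
            run_calibration(small_head_volume.with_data(small_head_volume.data))

    def test_cf_sign_stable_across_grid_offsets(self):
        signs = set()
        for i, (dx, dy) in enumerate(
            [(0.0, 0.0), (0.2, 0.1), (0.33, 0.41), (0.05, 0.45), (0.25, 0.25)]
        ):
            rings = [
                RingSpec(outer_diameter_mm=d, center_mm=(dx, dy, 5.5 + 7 * j), label=f"r{j}")
                for j, d in enumerate((113.0, 125.1))
            ]
            vol = rasterize_phantom(PhantomSpec(rings=rings, spacing=(0.5, 0.5, 1.0)))
            cf = derive_cf(run_calibration(vol, method="pixel_count", group="0-3"), "0-3")
            signs.add(math.copysign(1.0, cf.cf.value))
        assert signs == {-1.0}  # pixel_count always over-reads -> negative CF


class TestCfTableIo:
    def test_round_trip_with_comments(self, tmp_path):
        f = tmp_path / "cf.csv"
        save_cf_table(cf_preset(), f)
        text = "# instrument correction factors\n" + f.read_text()
        f.write_text(text)
        table = load_cf_table(f)
        assert [(c.group.label, c.cf.value, c.cf.sd) for c in table] == [
            ("0-3", -2.8, 0.2),
            ("3-18", -3.7, 0.3),
        ]

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("group_label,cf_cm\n0-3,-2.8\n")
        with pytest.raises(CalibrationError, match="missing columns"):
            load_cf_table(f)

    def test_overlapping_groups_rejected(self, tmp_path):
        f = tmp_path / "overlap.csv"
        f.write_text(
            "group_label,age_min_months,age_max_months,cf_cm,cf_sd_cm\n"
            "a,0,40,-2.8,0.2\nb,36,216,-3.7,0.3\n"
        )
        with pytest.raises(CalibrationError, match="overlapping"):
            load_cf_table(f)


def test_reported_record_mirrors_printed_workflow():
    rec = CalibrationRecord(
        ring_label="Ring 1",
        reads=(37.88, 38.47, 37.91, 38.14, 38.06),
        est=summarize_reads((37.88, 38.47, 37.91, 38.14, 38.06)),
        real=Measurement(35.5, 0.3),
        difference=Measurement(0.0),
    )
    rep = reported_record(rec)
    assert (rep.est.value, rep.est.sd) == (38.1, 0.2)
    assert (rep.difference.value, rep.difference.sd) == (-2.6, 0.4)


def test_calibration_report_has_table_columns(phantom_0_3):
    records = run_calibration(phantom_0_3)
    df = hc.calibration_report(records)
    for col in ("ring", "read1", "read5", "est", "est_sd", "real", "real_sd", "diff", "diff_sd"):
        assert col in df.columns
    assert len(df) == 9
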
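"""Per-ROI quantification, the 3xSD enrichment rule, and category summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosip import (
    AccumulatedCounts,
    AcquisitionSpec,
    ControlStats,
    Roi,
    RoiMeasurement,
    SPECIES,
    align_and_accumulate,
    classify_all,
    classify_enrichment,
    control_stats,
    fraction_enriched,
    measure_rois,
    rois_from_scene,
    simulate_acquisition,
    summarize_by_category,
)
from conftest import unbiased_calibrations


def _acc(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return AccumulatedCounts(
        counts=counts,
        species_order=list(SPECIES),
        shifts_applied=[(0, 0)],
        valid_mask=np.ones(counts.shape[1:], dtype=bool),
    )


def _measurement(atom_pct_n, category="microbe", **kw):
    return RoiMeasurement(
        roi_id=kw.pop("roi_id", 1),
        category=category,
        counts={},
        r_c=0.0,
        r_n=0.0,
        atom_pct_c=kw.pop("atom_pct_c", atom_pct_n),
        atom_pct_n=atom_pct_n,
        valid_c=True,
        valid_n=True,
        **kw,
    )


class TestMeasureRois:
    def test_single_pixel_ratio_of_sums(self):
        counts = np.zeros((len(SPECIES), 2, 2), dtype=np.int64)
        counts[SPECIES.index("12C14N"), 0, 0] = 1000
        counts[SPECIES.index("12C15N"), 0, 0] = 4
        counts[SPECIES.index("12C12C"), 0, 0] = 500
        roi = Roi(id=1, category="microbe", pixels=([0], [0]))
        cal_c, cal_n = unbiased_calibrations()
        (m,) = measure_rois(_acc(counts), [roi], cal_c, cal_n)
        assert m.r_n == pytest.approx(0.004)
        assert m.valid_n and m.valid_c

    def test_zero_denominator_flags_invalid_not_dropped(self):
        counts = np.zeros((len(SPECIES), 1, 1), dtype=np.int64)
        counts[SPECIES.index("12C14N")] = 100
        roi = Roi(id=1, category="microbe", pixels=([0], [0]))
        cal_c, cal_n = unbiased_calibrations()
        (m,) = measure_rois(_acc(counts), [roi], cal_c, cal_n)
        assert not m.valid_c and m.valid_n
        assert np.isnan(m.atom_pct_c)

    def test_ratio_of_sums_invariant_to_roi_splitting(self, rng):
        counts = rng.poisson(200, size=(len(SPECIES), 8, 8)).astype(np.int64)
        cal_c, cal_n = unbiased_calibrations()
        ys, xs = np.mgrid[0:8, 0:8]
        whole = Roi(id=1, category="microbe", pixels=(ys.ravel(), xs.ravel()))
        (mw,) = measure_rois(_acc(counts), [whole], cal_c, cal_n)
        parts = [
            Roi(id=2, category="microbe", pixels=(ys[:4].ravel(), xs[:4].ravel())),
            Roi(id=3, category="microbe", pixels=(ys[4:].ravel(), xs[4:].ravel())),
        ]
        mp = measure_rois(_acc(counts), parts, cal_c, cal_n)
        pooled = {
            s: mp[0].counts[s] + mp[1].counts[s] for s in ("12C15N", "12C14N")
        }
        assert pooled["12C15N"] / pooled["12C14N"] == pytest.approx(mw.r_n, rel=1e-12)

    def test_out_of_bounds_roi_rejected(self):
        counts = np.zeros((len(SPECIES), 4, 4), dtype=np.int64)
        roi = Roi(id=1, category="microbe", pixels=([5], [0]))
        cal_c, cal_n = unbiased_calibrations()
        with pytest.raises(ValueError, match="outside"):
            measure_rois(_acc(counts), [roi], cal_c, cal_n)

    def test_scene_recovery_within_counting_error(self, enriched_scene):
        # unbiased calibrated instrument: mean Atom%N across ROIs of a
        # uniformly enriched category recovers 100*f within 3 counting SE
        acq = AcquisitionSpec(n_planes=6, seed=17)
        stack = simulate_acquisition(enriched_scene, acq)
        acc = align_and_accumulate(stack, [(0, 0)] * 6)
        rois = [
            r for r in rois_from_scene(enriched_scene) if r.category == "microbe"
        ]
        cal_c, cal_n = unbiased_calibrations()
        ms = measure_rois(acc, rois, cal_c, cal_n)
        vals = np.array([m.atom_pct_n for m in ms])
        n14 = sum(m.counts["12C14N"] for m in ms)
        n15 = sum(m.counts["12C15N"] for m in ms)
        se_pct = 100 * (n15 / n14) * np.sqrt(1 / n15 + 1 / n14)
        assert abs(vals.mean() - 100 * 0.015) < 3 * se_pct


class TestControlStatsAndClassification:
    def test_identical_controls_zero_sd(self):
        ms = [_measurement(1.07, roi_id=i) for i in range(4)]
        cs = control_stats(ms, "microbe", "15N")
        assert cs.sd_atom_pct == 0.0
        assert cs.threshold_atom_pct == pytest.approx(1.07)

    def test_two_controls_arithmetic(self):
        ms = [_measurement(1.06, roi_id=1), _measurement(1.08, roi_id=2)]
        cs = control_stats(ms, "microbe", "15N")
        assert cs.mean_atom_pct == pytest.approx(1.07)
        assert cs.sd_atom_pct == pytest.approx(0.0141421, abs=1e-6)
        assert cs.threshold_atom_pct == pytest.approx(1.1124264, abs=1e-6)

    def test_single_control_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            control_stats([_measurement(1.07)], "microbe", "15N")

    def test_threshold_is_strict(self):
        cs = ControlStats("microbe", "15N", 1.0, 0.1, 5)
        at_threshold = _measurement(cs.threshold_atom_pct)
        above = _measurement(1.0 + 0.4)
        assert classify_enrichment(at_threshold, cs) is False
        assert classify_enrichment(above, cs) is True

    def test_invalid_measurement_propagates_as_none(self):
        cs = ControlStats("microbe", "15N", 1.0, 0.1, 5)
        m = _measurement(5.0)
        m.valid_n = False
        assert classify_enrichment(m, cs) is None

    def test_category_mismatch_rejected(self):
        cs = ControlStats("choanocyte", "15N", 1.0, 0.1, 5)
        with pytest.raises(ValueError, match="mismatch"):
            classify_enrichment(_measurement(2.0), cs)

    def test_false_positive_rate_of_3sd_rule(self, rng):
        # gaussian control population: one-sided 3 SD exceedance ~0.135%
        vals = rng.normal(0.37, 0.01, size=4000)
        ms = [_measurement(v, roi_id=i) for i, v in enumerate(vals)]
        cs = control_stats(ms, "microbe", "15N")
        flags = [classify_enrichment(m, cs) for m in ms]
        assert np.mean(flags) <= 0.01

    def test_strong_excess_always_detected(self, rng):
        ctrl = [
            _measurement(v, roi_id=i)
            for i, v in enumerate(rng.normal(0.37, 0.01, size=200))
        ]
        cs = control_stats(ctrl, "microbe", "15N")
        hot = [
            _measurement(v, roi_id=i)
            for i, v in enumerate(
                rng.normal(0.37 + 10 * cs.sd_atom_pct, 0.01, size=200)
            )
        ]
        calls = [classify_enrichment(m, cs) for m in hot]
        assert np.mean(calls) >= 0.99


class TestSummaries:
    def test_fraction_enriched_counts(self):
        ms = [
            _measurement(1.0, roi_id=i, timepoint_h=3.0, enriched_n=i < 6,
                         enriched_c=False)
            for i in range(8)
        ]
        table = fraction_enriched(ms, group_by=("category", "timepoint_h"))
        row = table[(table.isotope == "15N")].iloc[0]
        assert row.n_enriched == 6 and row.n_total == 8
        assert row.proportion_enriched == pytest.approx(0.75)

    def test_quartile_convention(self):
        ms = [
            _measurement(v, roi_id=i, timepoint_h=1.0)
            for i, v in enumerate([1.0, 2.0, 3.0, 4.0])
        ]
        table = summarize_by_category(ms, group_by=("category",))
        row = table[table.isotope == "15N"].iloc[0]
        assert row.q25_atom_pct == pytest.approx(1.75)
        assert row.q75_atom_pct == pytest.approx(3.25)
        assert row.mean_atom_pct == pytest.approx(2.5)

    def test_single_value_group(self):
        table = summarize_by_category(
            [_measurement(1.3, timepoint_h=1.0)], group_by=("category",)
        )
        row = table[table.isotope == "15N"].iloc[0]
        assert (
            row.mean_atom_pct
            == row.median_atom_pct
            == row.q25_atom_pct
            == row.q75_atom_pct
            == pytest.approx(1.3)
        )

    @given(st.permutations(list(range(8))))
    @settings(deadline=None, max_examples=20)
    def test_summary_invariant_under_reordering(self, order):
        base = [
            _measurement(float(v), roi_id=i, timepoint_h=1.0)
            for i, v in enumerate([1, 5, 2, 8, 3, 9, 4, 7])
        ]
        shuffled = [base[i] for i in order]
        a = summarize_by_category(base, group_by=("category",))
        b = summarize_by_category(shuffled, group_by=("category",))
        assert a.equals(b)

    def test_classify_all_fills_flags(self, rng):
        ctrl = [
            _measurement(v, roi_id=i, treatment="control")
            for i, v in enumerate(rng.normal(0.37, 0.01, size=50))
        ]
        hot = [
            _measurement(0.9, roi_id=100 + i, atom_pct_c=2.0) for i in range(5)
        ]
        stats = {
            ("microbe", iso): control_stats(ctrl, "microbe", iso)
            for iso in ("13C", "15N")
        }
        classify_all(ctrl + hot, stats)
        assert all(m.enriched_n for m in hot)
        assert all(m.enriched_n is not None for m in ctrl)
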
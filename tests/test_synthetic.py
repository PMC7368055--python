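"""Synthetic flow runs, cohorts and thrombin curves with known ground truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thromboflow.registry import Condition
from thromboflow.synthetic import (
    CONTROL_TEMPLATE,
    PATIENT_TEMPLATES,
    CohortNoise,
    EffectTemplate,
    KineticProfile,
    LogisticCurve,
    cohort_to_frame,
    expected_p9,
    generate_parameter_cohort,
    generate_run_images,
    generate_thrombin_curve,
    profile_for,
    tf_shortened_onset,
)


def _flat_profile(**over):
    base = dict(
        platelet=LogisticCurve(0.0, 1.8, 0.9),
        ps=LogisticCurve(0.0, 3.0, 1.1),
        thrombus=LogisticCurve(0.0, 2.4, 1.0),
        fibrin=LogisticCurve(0.0, 1.5, 0.7),
        t_fib=math.inf,
    )
    base.update(over)
    return KineticProfile(**base)


class TestLogisticCurve:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c_max=st.floats(0.1, 100),
        t50=st.floats(0.5, 6),
        tau=st.floats(0.2, 3),
    )
    def test_coverage_monotone_zero_at_origin_bounded(self, c_max, t50, tau):
        curve = LogisticCurve(c_max, t50, tau)
        t = np.linspace(0, 12, 49)
        cov = curve.coverage(t)
        assert cov[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(cov) >= -1e-12)
        assert np.all((cov >= -1e-9) & (cov <= c_max + 1e-9))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            LogisticCurve(150.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            LogisticCurve(50.0, -1.0, 1.0)


class TestRunImages:
    def test_empty_profile_gives_blank_truth(self):
        run, truth = generate_run_images(
            "M1", Condition(), _flat_profile(), seed=3, shape=(64, 64)
        )
        for channel in ("platelet", "ps", "fibrin"):
            for t in run.times:
                assert truth.sac[channel][t] == 0.0
                assert not truth.masks[channel][t].any()

    def test_no_fibrin_onset_means_no_fibres_ever(self, m6_run):
        prof = _flat_profile(
            platelet=LogisticCurve(30, 1.8, 0.9),
            fibrin=LogisticCurve(20, 1.5, 0.7),
            t_fib=math.inf,
        )
        run, truth = generate_run_images("M6", Condition(), prof, seed=5, shape=(96, 96))
        assert all(truth.sac["fibrin"][t] == 0.0 for t in run.times)
        assert expected_p9(truth.t_fib) == 0.0

    def test_fibrin_truth_zero_before_onset(self, m6_run):
        run, truth = m6_run
        for t in run.times:
            if t < truth.t_fib:
                assert truth.sac["fibrin"][t] == 0.0

    def test_same_seed_bit_identical(self, tf_condition):
        prof = profile_for("M6", tf_condition)
        a, _ = generate_run_images("M6", tf_condition, prof, seed=11, shape=(96, 96))
        b, _ = generate_run_images("M6", tf_condition, prof, seed=11, shape=(96, 96))
        for channel in a.channels:
            for t in a.times:
                assert np.array_equal(a.frames[channel][t], b.frames[channel][t])

    def test_truth_sac_equals_mask_fraction_and_monotone(self, m6_run):
        run, truth = m6_run
        for channel in ("platelet", "ps", "fibrin"):
            sacs = [truth.sac[channel][t] for t in run.times]
            for t in run.times:
                assert truth.sac[channel][t] == pytest.approx(
                    truth.masks[channel][t].mean() * 100.0
                )
            assert all(b >= a - 1e-12 for a, b in zip(sacs, sacs[1:]))

    def test_frame_below_minimum_size_raises(self):
        with pytest.raises(ValueError):
            generate_run_images("M6", Condition(), _flat_profile(), seed=0, shape=(16, 16))


class TestParameterCohort:
    def test_zero_noise_controls_identical(self):
        recs = generate_parameter_cohort(
            3, None, ["M6"], [Condition()], seed=1,
            noise=CohortNoise(0.0, 0.0, 0.0, 0.0), n_replicates=1,
        )
        assert len(recs) == 3
        assert recs[0].values == recs[1].values == recs[2].values
        assert recs[0].p9 == recs[1].p9

    def test_records_complete_and_valid(self):
        recs = generate_parameter_cohort(
            2, dict(PATIENT_TEMPLATES), ["M1", "M6", "M8"],
            [Condition(), Condition(tf=True)], seed=2, n_replicates=1,
        )
        for rec in recs:
            assert rec.complete and rec.n_values() == 41
            rec.validate()

    def test_null_fibrin_template_forces_p7_p9_zero(self):
        template = EffectTemplate(name="no-fibrin", fibrin_scale=0.0)
        recs = generate_parameter_cohort(
            2, {"Pat": template}, ["M6"], [Condition(tf=True)], seed=3, n_replicates=1,
        )
        pat = [r for r in recs if r.subject == "Pat"]
        for rec in pat:
            assert rec.p9 == 0.0
            assert all(rec.values[("P7", t)] == 0.0 for t in (0, 2, 4, 6, 8))

    def test_tf_dose_sweep_strictly_shortens_onset(self):
        doses = [0.0, 10.0, 50.0, 100.0, 500.0]
        onsets = [tf_shortened_onset(8.5, d) for d in doses]
        assert all(b < a for a, b in zip(onsets, onsets[1:]))
        profile_onsets = [
            profile_for("M6", Condition(tf=d > 0, tf_dose_pm=d)).t_fib for d in doses
        ]
        assert all(b < a for a, b in zip(profile_onsets, profile_onsets[1:]))

    def test_surface_reactivity_ladder_on_platelet_means(self):
        recs = generate_parameter_cohort(
            6, None, ["M1", "M2", "M3", "M4", "M5", "M6", "M7"],
            [Condition()], seed=4,
        )
        frame = cohort_to_frame(recs)
        p1 = (
            frame[(frame.parameter == "P1") & (frame.time == 8)]
            .groupby("surface")["value"].mean()
        )
        assert p1["M1"] < min(p1["M2"], p1["M3"])
        assert max(p1["M2"], p1["M3"]) < min(p1["M4"], p1["M5"])
        assert max(p1["M4"], p1["M5"]) < p1["M6"] <= p1["M7"] + 1e-9

    def test_empty_surface_list_raises(self):
        with pytest.raises(ValueError):
            generate_parameter_cohort(2, None, [], [Condition()], seed=0)

    def test_too_few_controls_raises(self):
        with pytest.raises(ValueError):
            generate_parameter_cohort(1, None, ["M6"], [Condition()], seed=0)

    def test_same_seed_identical_cohort(self):
        a = generate_parameter_cohort(3, None, ["M6"], [Condition()], seed=9)
        b = generate_parameter_cohort(3, None, ["M6"], [Condition()], seed=9)
        assert all(x.values == y.values and x.p9 == y.p9 for x, y in zip(a, b))


class TestEffectTemplates:
    def test_control_template_is_identity(self, tf_condition):
        base = profile_for("M6", tf_condition)
        again = profile_for("M6", tf_condition, CONTROL_TEMPLATE)
        assert base == again

    def test_tm_surface_delays_fibrin_for_controls_not_fv_leiden(self):
        cond = Condition()
        ctrl_m6 = profile_for("M6", Condition(tf=True, tf_dose_pm=10.0))
        ctrl_m8 = profile_for("M8", cond)
        assert ctrl_m8.t_fib > ctrl_m6.t_fib
        fvl_m8 = profile_for("M8", cond, PATIENT_TEMPLATES["FV-Leiden"])
        fvl_m6 = profile_for(
            "M6", Condition(tf=True, tf_dose_pm=10.0), PATIENT_TEMPLATES["FV-Leiden"]
        )
        assert fvl_m8.t_fib == pytest.approx(fvl_m6.t_fib)

    def test_expected_p9_grid(self):
        assert expected_p9(math.inf) == 0.0
        assert expected_p9(6.0) == 5.0
        assert expected_p9(6.1) == 3.0  # next capture at 8 min
        assert expected_p9(10.5) == 0.0  # beyond the 10-min window


class TestThrombinCurves:
    def test_zero_peak_gives_flat_curve(self):
        curve = generate_thrombin_curve(5.0, 0.0, 5.0)
        assert curve.thrombin_nm.max() == 0.0
        assert curve.analytic_etp == 0.0

    def test_triangle_analytic_area(self):
        curve = generate_thrombin_curve(5.0, 100.0, 5.0, kind="triangle")
        assert curve.analytic_etp == pytest.approx(500.0)

    def test_gamma_pulse_matches_quadrature_oracle(self):
        # high-resolution trapezoid over a long window as independent oracle
        curve = generate_thrombin_curve(
            3.0, 120.0, 4.0, grid=0.001, shape=3.0, duration=200.0
        )
        quad = float(np.trapezoid(curve.thrombin_nm, curve.time_min))
        assert curve.analytic_etp == pytest.approx(quad, rel=1e-4)

    def test_noise_is_seeded(self):
        a = generate_thrombin_curve(3.0, 100.0, 4.0, seed=1, noise_sd=2.0)
        b = generate_thrombin_curve(3.0, 100.0, 4.0, seed=1, noise_sd=2.0)
        assert np.array_equal(a.thrombin_nm, b.thrombin_nm)

    def test_invalid_grid_raises(self):
        with pytest.raises(ValueError):
            generate_thrombin_curve(3.0, 100.0, 4.0, grid=0.0)

    def test_negative_peak_raises(self):
        with pytest.raises(ValueError):
            generate_thrombin_curve(3.0, -1.0, 4.0)
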
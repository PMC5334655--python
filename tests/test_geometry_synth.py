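"""Synthetic area-curve generator: landmarks, periodicity, anchoring, noise."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from avhyd import (
    AreaCurve,
    ChamberLandmarks,
    CohortParams,
    CyclePhases,
    build_curve,
    generate_cohort,
    generate_subject,
    population_mean_subject,
)
from avhyd.errors import DomainError, InfeasibleAnchorError, InvalidParameterError
from avhyd.geometry_synth import DEFAULT_T_ES, _piecewise_cosine


class TestCyclePhases:
    def test_default_end_systole_consistent_with_crossover(self):
        # crossover at 53% of the cycle spanning 75% of diastole pins t_es
        ph = CyclePhases()
        assert (1 - ph.t_cross_endo) / (1 - ph.t_es) == pytest.approx(0.75)
        assert ph.t_es == pytest.approx(DEFAULT_T_ES)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_es": 0.6},                      # after crossover
            {"t_dd": 0.95},                     # after atrial kick
            {"t_ak": 1.0},                      # not inside (0, 1)
            {"t_es": 0.0},
        ],
    )
    def test_ordering_violations_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            CyclePhases(**kwargs)


class TestBuildCurve:
    def test_passes_exactly_through_landmarks(self, default_params):
        lm = default_params.landmarks["asa"]
        ph = default_params.phases
        c = build_curve(lm, ph, n_frames=30)
        assert c.area_at(ph.t_es) == pytest.approx(lm.a_es, abs=1e-12)
        assert c.area_at(ph.t_dd) == pytest.approx(lm.a_dd, abs=1e-12)
        assert c.area_at(0.0) == pytest.approx(lm.a_ed, abs=1e-12)
        assert c.area_at(1.0) == pytest.approx(lm.a_ed, abs=1e-12)

    def test_half_cosine_segment_midpoint_is_arithmetic_mean(self, default_params):
        # closed form: the cosine easing reaches (v0+v1)/2 at the segment midpoint
        lm = default_params.landmarks["asa"]
        ph = default_params.phases
        mid_sys = ph.t_es / 2.0
        c = build_curve(lm, ph, n_frames=30, extra_times=[mid_sys])
        assert c.area_at(mid_sys) == pytest.approx((lm.a_ed + lm.a_es) / 2.0, abs=1e-12)

    def test_piecewise_cosine_monotone_between_knots(self):
        knots = [(0.0, 2.0), (0.4, 5.0), (0.7, 3.0), (1.0, 3.0)]
        t = np.linspace(0, 1, 2001)
        v = _piecewise_cosine(knots, t)
        rising = (t >= 0) & (t <= 0.4)
        falling = (t >= 0.4) & (t <= 0.7)
        flat = t >= 0.7
        assert np.all(np.diff(v[rising]) >= 0)
        assert np.all(np.diff(v[falling]) <= 0)
        assert np.all(v[flat] == 3.0)

    def test_plateau_over_diastasis(self, mean_subject):
        ph = mean_subject.phases
        sel = (mean_subject.times >= ph.t_dd) & (mean_subject.times <= ph.t_ak)
        for ch in ("asa", "vsa_endo", "vsa_epi"):
            areas = mean_subject.curve(ch).areas[sel]
            assert np.ptp(areas) == pytest.approx(0.0, abs=1e-12)

    def test_anchored_curve_crosses_reference_exactly_then_exceeds(self, default_params):
        ph = default_params.phases
        asa = build_curve(default_params.landmarks["asa"], ph, 30, chamber="asa")
        endo = build_curve(default_params.landmarks["vsa_endo"], ph, 30, anchor=asa,
                           chamber="vsa_endo")
        assert endo.area_at(ph.t_cross_endo) == pytest.approx(
            asa.area_at(ph.t_cross_endo), abs=1e-12
        )
        after = (endo.times > ph.t_cross_endo + 1e-9) & (endo.times < 1.0 - 1e-9)
        assert np.all(endo.areas[after] > asa.areas[after])
        before = (endo.times > ph.t_es + 1e-9) & (endo.times < ph.t_cross_endo - 1e-9)
        assert np.all(endo.areas[before] < asa.areas[before])

    def test_anchor_infeasible_when_end_systolic_area_not_below_reference(self, default_params):
        ph = default_params.phases
        asa = build_curve(default_params.landmarks["asa"], ph, 30)
        too_big = ChamberLandmarks(a_ed=26.0, a_es=25.0, a_dd=23.7)  # a_es above ASA's 20
        with pytest.raises(InfeasibleAnchorError):
            build_curve(too_big, ph, 30, anchor=asa)

    def test_landmark_positivity_enforced(self):
        with pytest.raises(InvalidParameterError):
            ChamberLandmarks(a_ed=10.0, a_es=-1.0, a_dd=12.0)


class TestAreaCurve:
    def test_interpolation_exact_at_grid_and_midpoints(self):
        t = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        a = np.array([3.0, 5.0, 4.0, 6.0, 3.0])
        c = AreaCurve("s", "asa", t, a)
        assert c.area_at(0.5) == 4.0
        assert c.area_at(0.375) == pytest.approx((5.0 + 4.0) / 2)  # linear midpoint
        assert c.area_at(1.0) == c.area_at(0.0)

    def test_out_of_range_time_rejected(self):
        c = AreaCurve("s", "asa", [0.0, 0.5, 1.0], [2.0, 3.0, 2.0])
        with pytest.raises(DomainError):
            c.area_at(1.5)

    def test_non_periodic_curve_rejected(self):
        with pytest.raises(InvalidParameterError):
            AreaCurve("s", "asa", [0.0, 0.5, 1.0], [2.0, 3.0, 2.5])


class TestGeneration:
    def test_zero_noise_reproduces_population_curves(self, default_params):
        from dataclasses import replace

        params = replace(default_params, subject_sd={"asa": 0.0, "vsa_endo": 0.0, "vsa_epi": 0.0})
        subj = generate_subject(params, 3)
        mean = population_mean_subject(params)
        for ch in ("asa", "vsa_endo", "vsa_epi"):
            np.testing.assert_array_equal(subj.curve(ch).areas, mean.curve(ch).areas)

    def test_same_seed_and_index_bitwise_identical(self, default_params):
        a = generate_subject(default_params, 5)
        b = generate_subject(default_params, 5)
        for ch in ("asa", "vsa_endo", "vsa_epi"):
            np.testing.assert_array_equal(a.curve(ch).areas, b.curve(ch).areas)

    def test_cohort_reproducible_and_periodic(self, default_params):
        c1 = generate_cohort(default_params)
        c2 = generate_cohort(default_params)
        assert len(c1) == default_params.n_subjects
        for s1, s2 in zip(c1, c2):
            np.testing.assert_array_equal(s1.vsa_endo.areas, s2.vsa_endo.areas)
            for ch in ("asa", "vsa_endo", "vsa_epi"):
                areas = s1.curve(ch).areas
                assert areas[0] == pytest.approx(areas[-1], abs=1e-9)

    def test_epicardium_encloses_endocardium_under_noise(self):
        params = CohortParams(n_subjects=100, seed=7)
        for subj in generate_cohort(params):
            assert np.all(subj.vsa_epi.areas >= subj.vsa_endo.areas - 1e-9)

    def test_end_systolic_ordering_on_mean_curves(self, mean_subject):
        t_es = mean_subject.phases.t_es
        endo, asa, epi = (mean_subject.curve(c).area_at(t_es)
                          for c in ("vsa_endo", "asa", "vsa_epi"))
        assert endo < asa < epi

    def test_single_subject_zero_sd_equals_population_landmarks(self):
        params = CohortParams(n_subjects=1,
                              subject_sd={"asa": 0.0, "vsa_endo": 0.0, "vsa_epi": 0.0})
        (subj,) = generate_cohort(params)
        t_dd = params.phases.t_dd
        assert subj.vsa_endo.area_at(t_dd) - subj.asa.area_at(t_dd) == pytest.approx(7.7)
        assert subj.vsa_epi.area_at(t_dd) - subj.asa.area_at(t_dd) == pytest.approx(25.4)

    def test_between_subject_sd_calibrated_to_printed_sems(self):
        # sd of the diastasis differences should approach the configured
        # SEM * sqrt(10) values (4.4 and 7.3 cm²) for a large cohort
        params = CohortParams(n_subjects=200, seed=11)
        cohort = generate_cohort(params)
        t_dd = params.phases.t_dd
        d_endo = [s.vsa_endo.area_at(t_dd) - s.asa.area_at(t_dd) for s in cohort]
        d_epi = [s.vsa_epi.area_at(t_dd) - s.asa.area_at(t_dd) for s in cohort]
        assert np.std(d_endo, ddof=1) == pytest.approx(4.4, rel=0.20)
        assert np.std(d_epi, ddof=1) == pytest.approx(7.3, rel=0.20)

    def test_invalid_population_sign_pattern_rejected(self, default_params):
        bad = dict(default_params.landmarks)
        bad["vsa_endo"] = ChamberLandmarks(a_ed=26.0, a_es=25.0, a_dd=23.7)  # above ASA at ES
        with pytest.raises(InvalidParameterError):
            CohortParams(landmarks=bad)

    @given(st.integers(min_value=0, max_value=30))
    def test_generated_subject_satisfies_geometry_invariants(self, index):
        params = CohortParams(seed=3)
        subj = generate_subject(params, index)
        assert np.all(subj.vsa_epi.areas >= subj.vsa_endo.areas - 1e-9)
        assert np.all(subj.asa.areas > 0)
        for ch in ("asa", "vsa_endo", "vsa_epi"):
            areas = subj.curve(ch).areas
            assert areas[0] == pytest.approx(areas[-1], abs=1e-9)

    def test_crossover_pinned_exactly_on_population_mean_curves(self, mean_subject):
        t_cross = mean_subject.phases.t_cross_endo
        assert mean_subject.vsa_endo.area_at(t_cross) == pytest.approx(
            mean_subject.asa.area_at(t_cross), abs=1e-12
        )
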
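"""Next-generation matrices under vaccination, effective reproduction
numbers and critical coverage."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import bisect

from epiobs import (
    NextGenMatrix,
    ObservableParams,
    UnobservableParams,
    VaccineEffects,
    calibrate_to_observable,
    critical_coverage,
    dominant_eigenvalue,
    effective_r,
    ngm_observable,
    ngm_unobservable,
    r0_observable,
    rv_comparison_sweep,
)


class TestNgmObservable:
    def test_zero_coverage_reduces_to_r0(self, influenza):
        v = influenza.vaccine.with_coverage(0.0)
        matrix = ngm_observable(influenza.observable, v)
        assert np.all(matrix.entries[1] == 0.0)
        assert dominant_eigenvalue(matrix) == pytest.approx(
            r0_observable(influenza.observable), abs=1e-12
        )

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.9])
    def test_null_vaccine_reduces_to_r0(self, influenza, p):
        v = VaccineEffects(ve_s=0.0, ve_i=0.0, ve_p=0.0, p=p)
        matrix = ngm_observable(influenza.observable, v)
        assert dominant_eigenvalue(matrix) == pytest.approx(
            r0_observable(influenza.observable), abs=1e-12
        )

    def test_influenza_entries_against_hand_arithmetic(self, influenza):
        """p = 0.5 with the published efficacies (VE_S, VE_I, VE_P) =
        (0.41, 0.15, 0.67): A = R1 + alpha*R2 = 1.5,
        B = R1 + alpha*q_D*R2 = 0.6 + 0.75*0.33*1.2 = 0.897; entries are
        the outer product of ((1-p), p*q_S) and (A, q_I*B)."""
        v = influenza.vaccine.with_coverage(0.5)
        matrix = ngm_observable(influenza.observable, v)
        a, b = 1.5, 0.6 + 0.75 * 0.33 * 1.2
        expected = np.array(
            [[0.5 * a, 0.5 * 0.85 * b], [0.5 * 0.59 * a, 0.5 * 0.59 * 0.85 * b]]
        )
        np.testing.assert_allclose(matrix.entries, expected, atol=1e-12)
        assert dominant_eigenvalue(matrix) == pytest.approx(
            expected[0, 0] + expected[1, 1], abs=1e-12
        )


class TestNgmUnobservable:
    def test_ve_p_zero_makes_columns_proportional_to_unvaccinated(self):
        unobs = UnobservableParams(R3=0.8, R4=1.9, k=0.7)
        v = VaccineEffects(ve_s=0.3, ve_i=0.2, ve_p=0.0, p=0.4)
        matrix = ngm_unobservable(unobs, v)
        a = 0.3 * 0.8 + 0.7 * 1.9
        assert matrix.entries[0, 1] == pytest.approx((1 - 0.4) * 0.8 * a)

    def test_full_symptom_prevention_moves_all_weight_to_r3(self):
        unobs = UnobservableParams(R3=0.8, R4=1.9, k=1.0)
        v = VaccineEffects(ve_s=0.0, ve_i=0.0, ve_p=1.0, p=0.5)
        matrix = ngm_unobservable(unobs, v)
        # vaccinated infectors: all would-be symptomatic cases become
        # asymptomatic infectious, so B = R3
        assert matrix.entries[0, 1] == pytest.approx(0.5 * 0.8)

    def test_calibrated_influenza_against_hand_arithmetic(self, influenza):
        """Calibrated (R3, R4) = (6/7, 12/7); with q_D = 0.33:
        B = (1 - k*q_D)*R3 + k*q_D*R4."""
        unobs = calibrate_to_observable(influenza.observable, m=0.5)
        v = influenza.vaccine.with_coverage(0.5)
        matrix = ngm_unobservable(unobs, v)
        a = 0.25 * 6 / 7 + 0.75 * 12 / 7
        b = (1 - 0.75 * 0.33) * 6 / 7 + 0.75 * 0.33 * 12 / 7
        expected = np.array(
            [[0.5 * a, 0.5 * 0.85 * b], [0.5 * 0.59 * a, 0.5 * 0.59 * 0.85 * b]]
        )
        np.testing.assert_allclose(matrix.entries, expected, atol=1e-12)


class TestDominantEigenvalue:
    def test_diagonal(self):
        m = NextGenMatrix(entries=np.array([[2.0, 0.0], [0.0, 0.0]]), model_tag="observable")
        assert dominant_eigenvalue(m) == 2.0

    def test_rank_one_equals_trace(self):
        entries = np.outer([0.6, 0.3], [1.4, 0.9])
        m = NextGenMatrix(entries=entries, model_tag="observable")
        assert dominant_eigenvalue(m) == pytest.approx(np.trace(entries), abs=1e-12)

    @given(
        a=st.floats(0.01, 5.0),
        b=st.floats(0.0, 5.0),
        c=st.floats(0.0, 5.0),
        d=st.floats(0.01, 5.0),
    )
    def test_general_2x2_matches_characteristic_polynomial(self, a, b, c, d):
        """Independent oracle: the quadratic-formula root of
        lambda^2 - (a+d) lambda + (ad - bc)."""
        m = NextGenMatrix(entries=np.array([[a, b], [c, d]]), model_tag="observable")
        tr, det = a + d, a * d - b * c
        root = (tr + np.sqrt(tr**2 - 4 * det)) / 2.0
        assert dominant_eigenvalue(m) == pytest.approx(root, rel=1e-10)


class TestEffectiveR:
    def test_no_coverage_gives_r0(self, diseases):
        for fixture in diseases.values():
            v = fixture.vaccine.with_coverage(0.0)
            assert effective_r(fixture.observable, v) == pytest.approx(
                fixture.r0, abs=1e-12
            )

    def test_hiv_independent_of_symptom_prevention(self, diseases):
        """No secondary transmission after the onset of AIDS (R2 = 0), so
        the symptom-based R_v cannot depend on VE_P."""
        fixture = diseases["hiv"]
        v = fixture.vaccine.with_coverage(0.5)
        values = {
            effective_r(fixture.observable, v.with_ve_p(q)) for q in (0.1, 0.5, 0.9)
        }
        assert len(values) == 1

    @pytest.mark.parametrize("m", [0.2, 0.5, 1.0])
    def test_models_coincide_when_symptom_effect_off(self, influenza, m):
        """At VE_P = 0 both models see the same A and B, so the calibrated
        pair has identical effective reproduction numbers for any m."""
        unobs = calibrate_to_observable(influenza.observable, m)
        v = influenza.vaccine.with_coverage(0.5).with_ve_p(0.0)
        assert effective_r(influenza.observable, v) == pytest.approx(
            effective_r(unobs, v), abs=1e-12
        )

    @given(
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
        ve=st.floats(0.0, 1.0),
    )
    def test_observable_monotone_in_coverage_and_efficacies(self, influenza, p1, p2, ve):
        obs = influenza.observable
        lo_p, hi_p = sorted((p1, p2))
        base = VaccineEffects(ve_s=0.3, ve_i=0.2, ve_p=0.4)
        assert effective_r(obs, base.with_coverage(hi_p)) <= effective_r(
            obs, base.with_coverage(lo_p)
        ) + 1e-12
        for field in ("ve_s", "ve_i", "ve_p"):
            import dataclasses

            bumped = dataclasses.replace(base.with_coverage(0.5), **{field: ve})
            ref = dataclasses.replace(base.with_coverage(0.5), **{field: 0.0})
            assert effective_r(obs, bumped) <= effective_r(obs, ref) + 1e-12

    @pytest.mark.parametrize(
        "r3, r4, direction", [(0.5, 2.0, 1), (2.0, 0.5, -1)]
    )
    def test_unobservable_ve_p_direction_follows_r4_minus_r3(self, r3, r4, direction):
        """Raising q_D shifts weight from R3 to R4, so R_v moves with the
        sign of R4 - R3 (exercised both ways)."""
        unobs = UnobservableParams(R3=r3, R4=r4, k=0.6)
        base = VaccineEffects(ve_s=0.2, ve_i=0.2, ve_p=0.0, p=0.5)
        lo = effective_r(unobs, base.with_ve_p(0.8))  # q_D = 0.2
        hi = effective_r(unobs, base.with_ve_p(0.1))  # q_D = 0.9
        assert direction * (hi - lo) > 0


class TestFig3Ordering:
    @pytest.mark.parametrize("name", ["smallpox", "influenza", "varicella"])
    def test_seir_type_overstates_rv(self, diseases, name):
        """Forcing the symptom-prevention effect through the latency exit
        makes the SEIR-type model's R_v >= the symptom-based one for the
        three diseases with post-onset transmission."""
        fixture = diseases[name]
        unobs = fixture.calibrated_unobservable()
        v = fixture.vaccine.with_coverage(0.5)
        sweep = rv_comparison_sweep(
            fixture.observable, unobs, v, np.linspace(0.01, 0.99, 99)
        )
        assert all(pt.rv_non >= pt.rv_obs - 1e-12 for pt in sweep)

    def test_hiv_ordering_reversed(self, diseases):
        fixture = diseases["hiv"]
        unobs = fixture.calibrated_unobservable()
        v = fixture.vaccine.with_coverage(0.5)
        sweep = rv_comparison_sweep(
            fixture.observable, unobs, v, np.linspace(0.01, 0.99, 99)
        )
        assert all(pt.rv_obs >= pt.rv_non - 1e-12 for pt in sweep)


class TestCriticalCoverage:
    def test_perfect_vaccine_classical_threshold(self):
        """With q_S*q_I*B = 0 the threshold is 1 - 1/R0 = 0.5 for A = 2."""
        obs = ObservableParams(R1=2.0, R2=0.0, alpha=1.0)
        v = VaccineEffects(ve_s=1.0, ve_i=1.0, ve_p=0.0)
        cc = critical_coverage(obs, v)
        assert cc.status == "interior"
        assert cc.p_star == pytest.approx(0.5, abs=1e-12)

    def test_subcritical_disease_needs_no_vaccination(self):
        obs = ObservableParams(R1=0.9, R2=0.0, alpha=1.0)
        cc = critical_coverage(obs, VaccineEffects(ve_s=0.5, ve_i=0.5, ve_p=0.5))
        assert cc == (0.0, "always_subcritical")

    def test_uncontrollable_when_vaccinated_stay_supercritical(self):
        obs = ObservableParams(R1=3.0, R2=0.0, alpha=1.0)
        cc = critical_coverage(obs, VaccineEffects(ve_s=0.0, ve_i=0.0, ve_p=0.0))
        assert cc.status == "uncontrollable"
        assert np.isnan(cc.p_star)

    @pytest.mark.parametrize("model", ["observable", "unobservable"])
    def test_closed_form_matches_bisection(self, influenza, model):
        """Closed-form p* agrees with bisection on the effective
        reproduction number within 1e-8."""
        params = (
            influenza.observable
            if model == "observable"
            else influenza.calibrated_unobservable()
        )
        v = influenza.vaccine
        cc = critical_coverage(params, v)
        root = bisect(
            lambda p: effective_r(params, v.with_coverage(p)) - 1.0, 0.0, 1.0,
            xtol=1e-12,
        )
        assert cc.status == "interior"
        assert abs(cc.p_star - root) < 1e-8
        assert effective_r(params, v.with_coverage(cc.p_star)) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_influenza_model_gap_is_modest_overcoverage(self, influenza):
        """The SEIR-type model asks for somewhat more coverage than the
        symptom-based one for influenza (positive gap, well under 0.15)."""
        cc_obs = critical_coverage(influenza.observable, influenza.vaccine)
        cc_non = critical_coverage(
            influenza.calibrated_unobservable(), influenza.vaccine
        )
        gap = cc_non.p_star - cc_obs.p_star
        assert 0.0 < gap <= 0.15


class TestVaccineEffects:
    def test_residuals_track_efficacies(self):
        v = VaccineEffects(ve_s=0.41, ve_i=0.15, ve_p=0.67)
        assert (v.q_s, v.q_i, v.q_d) == (1 - 0.41, 1 - 0.15, 1 - 0.67)
        v2 = v.with_ve_p(0.2)
        assert v2.q_d == pytest.approx(0.8)
        assert v2.q_s == v.q_s  # untouched fields preserved

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            VaccineEffects(ve_s=1.2, ve_i=0.0, ve_p=0.0)
        with pytest.raises(ValueError):
            VaccineEffects(ve_s=0.2, ve_i=0.0, ve_p=0.0, p=-0.1)
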
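"""Unit and property tests for the latent metabolic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dipsim import physiology as ph
from dipsim.physiology import (GlycemicClass, MetabolicState, Phenotype,
                               PhysiologyParams)


class TestInsulinSensitivity:
    def test_reference_point(self, params):
        assert ph.insulin_sensitivity(params.bmi_ref, None, 1.0, params) == 1.0

    def test_exponential_decay_above_reference(self, params):
        # bmi 35 with k=0.05: S = exp(-0.5)
        s = ph.insulin_sensitivity(35.0, None, 1.0, params)
        assert s == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_pregnancy_ramp_week28(self, params):
        s = ph.insulin_sensitivity(params.bmi_ref, 28.0, 1.0, params)
        assert s == pytest.approx(1 - 0.5 * 28 / 40, abs=1e-12)

    def test_rejects_nonpositive_bmi(self, params):
        with pytest.raises(ValueError):
            ph.insulin_sensitivity(0.0, None, 1.0, params)

    @given(b1=st.floats(15, 60), b2=st.floats(15, 60))
    @settings(max_examples=60, deadline=None)
    def test_monotone_nonincreasing_in_bmi(self, b1, b2):
        p = PhysiologyParams()
        lo, hi = sorted((b1, b2))
        assert (ph.insulin_sensitivity(hi, None, 1.0, p)
                <= ph.insulin_sensitivity(lo, None, 1.0, p) + 1e-12)

    def test_floor_applies(self, params):
        assert ph.insulin_sensitivity(200.0, None, 1.0, params) == params.s_min


class TestGlycemicIndex:
    @pytest.mark.parametrize("S,B,expected", [
        (1.0, 1.0, 1.0),
        (0.5, 1.0, 2.0),
        (0.5, 0.8, 2.5),
    ])
    def test_reference_values(self, S, B, expected, params):
        assert ph.glycemic_index(S, B, params) == pytest.approx(expected, rel=1e-12)

    def test_secretory_failure_returns_cap(self, params):
        assert ph.glycemic_index(0.5, 0.0, params) == params.g_max

    @given(s=st.floats(0.1, 1.0), b=st.floats(0.05, 1.0),
           ds=st.floats(0.0, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_decreasing_in_each_argument(self, s, b, ds):
        p = PhysiologyParams()
        assert ph.glycemic_index(min(s + ds, 1.0), b, p) <= ph.glycemic_index(s, b, p) + 1e-12
        assert ph.glycemic_index(s, min(b + ds, 1.0), p) <= ph.glycemic_index(s, b, p) + 1e-12


class TestMetabolismStep:
    def test_subthreshold_recovery(self, params):
        st0 = MetabolicState(B=0.8, E=0.0)
        out = ph.step_metabolism(st0, 1.0, 0.1, params)
        assert out.E == 0.0
        assert out.B == pytest.approx(0.8 + params.r_regen * 0.2 * 0.1, abs=1e-12)

    def test_exposure_increment(self, params):
        out = ph.step_metabolism(MetabolicState(B=1.0, E=0.0), 2.5, 0.1, params)
        assert out.E == pytest.approx(0.1, abs=1e-12)  # (2.5-1.5)*0.1

    def test_worked_beta_update(self, params):
        # B' = 0.8 + (0.05*0.2 - 0.2*1.0*0.8)*0.1 = 0.785
        out = ph.step_metabolism(MetabolicState(B=0.8, E=0.0), 2.5, 0.1, params)
        assert out.B == pytest.approx(0.785, abs=1e-12)

    def test_regeneration_gated_by_reversibility_ceiling(self, params):
        exposed = ph.step_metabolism(MetabolicState(B=0.5, E=2.0), 1.0, 0.1, params)
        assert exposed.B == pytest.approx(0.5, abs=1e-12)  # no regen, no decay

    @given(g=st.floats(0.0, 6.0), dt=st.floats(0.01, 1.0),
           e0=st.floats(0, 3), b0=st.floats(0, 1))
    @settings(max_examples=80, deadline=None)
    def test_exposure_never_decreases_and_B_bounded(self, g, dt, e0, b0):
        p = PhysiologyParams()
        out = ph.step_metabolism(MetabolicState(B=b0, E=e0), g, dt, p)
        assert out.E >= e0
        assert 0.0 <= out.B <= 1.0

    def test_mean_field_matches_scalar_update(self, params):
        # 10,000 identical agents stepped as arrays equal the scalar update
        n = 10_000
        state = MetabolicState(B=np.full(n, 0.8), E=np.zeros(n))
        out = ph.step_metabolism(state, np.full(n, 2.5), 1 / 12, params)
        scalar = ph.step_metabolism(MetabolicState(B=0.8, E=0.0), 2.5, 1 / 12, params)
        assert abs(float(np.mean(out.B)) - scalar.B) < 1e-12

    def test_euler_convergence_under_dt_halving(self, params):
        # 5-year beta-cell trajectory at fixed G: halving dt moves it < 1%
        def traj(dt):
            s = MetabolicState(B=0.9, E=0.0)
            for _ in range(int(round(5 / dt))):
                s = ph.step_metabolism(s, 2.0, dt, params)
            return s.B
        b1, b2 = traj(1 / 12), traj(1 / 24)
        assert abs(b2 - b1) / b1 < 0.01


class TestBMI:
    def test_delta_bmi_worked_examples(self):
        assert ph.delta_bmi(-5, 1.65) == pytest.approx(-5 / 1.65**2, rel=1e-12)
        assert ph.delta_bmi(0, 1.7) == 0.0
        assert ph.delta_bmi(-10, 1.60) == pytest.approx(-3.90625, abs=1e-6)

    def test_delta_bmi_rejects_bad_height(self):
        with pytest.raises(ValueError):
            ph.delta_bmi(-5, 0.0)

    def test_bmi_step_deterministic_parts(self):
        p = PhysiologyParams(bmi_drift_ages=(0, 100), bmi_drift_rates=(0.0, 0.0),
                             bmi_secular=0.0, bmi_noise_sd=0.0)
        assert ph.bmi_step(25.0, 30, 1.0, p) == pytest.approx(25.0)
        p2 = PhysiologyParams(bmi_drift_ages=(0, 100), bmi_drift_rates=(0.0, 0.0),
                              bmi_secular=0.05, bmi_noise_sd=0.0)
        assert ph.bmi_step(25.0, 30, 1.0, p2) == pytest.approx(25.05)

    def test_postpartum_retention_jump(self):
        p = PhysiologyParams(bmi_drift_ages=(0, 100), bmi_drift_rates=(0.0, 0.0),
                             bmi_secular=0.0, bmi_noise_sd=0.0)
        out = ph.bmi_step(25.0, 30, 1e-6, p, delivered=True, gwg_kg=12.0,
                          height_m=1.65)
        assert out - 25.0 == pytest.approx(0.3 * 12 / 1.65**2, abs=1e-5)


class TestPhenotypes:
    def test_degenerate_mixture(self, rng, params):
        phen, s, b = ph.assign_phenotype(rng, (1, 0, 0), params)
        assert phen == Phenotype.RESISTANCE

    def test_mixture_proportions(self, params):
        rng = np.random.default_rng(0)
        phen, _, _ = ph.assign_phenotype(rng, (1 / 3, 1 / 3, 1 / 3), params,
                                         n=30_000)
        props = np.bincount(phen, minlength=3) / 30_000
        assert np.all(np.abs(props - 1 / 3) < 0.01)

    def test_seed_reproducibility(self, params):
        a = ph.assign_phenotype(np.random.default_rng(5), n=100, params=params)
        b = ph.assign_phenotype(np.random.default_rng(5), n=100, params=params)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_rejects_bad_mixture(self, rng, params):
        with pytest.raises(ValueError):
            ph.assign_phenotype(rng, (0.5, 0.2, 0.2), params)

    def test_phenotype_lowers_matching_baseline(self, params):
        rng = np.random.default_rng(2)
        phen, s, b = ph.assign_phenotype(rng, (1 / 3, 1 / 3, 1 / 3), params, n=5000)
        res, sec = phen == 0, phen == 1
        assert s[res].mean() < s[sec].mean()
        assert b[sec].mean() < b[res].mean()


class TestClassification:
    @pytest.mark.parametrize("G,expected", [
        (1.0, GlycemicClass.NORMAL),
        (1.7, GlycemicClass.IMPAIRED),
        (2.0, GlycemicClass.DIABETES),   # boundary inclusive
    ])
    def test_state_thresholds(self, G, expected, params):
        cls, _ = ph.classify_glycemic(G, params=params)
        assert cls == expected

    def test_diagnostic_threshold_change_flips_result(self, params):
        _, neg = ph.classify_glycemic(1.35, pregnant=True,
                                      diagnostic_threshold=1.40, params=params)
        _, pos = ph.classify_glycemic(1.35, pregnant=True,
                                      diagnostic_threshold=1.30, params=params)
        assert not neg and pos


def test_params_validation_catches_bad_thresholds():
    with pytest.raises(ValueError):
        PhysiologyParams(g_igr=2.5, g_dm=2.0).validate()
    with pytest.raises(ValueError):
        PhysiologyParams(s_min=1.5).validate()
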
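"""Loss, calibration machinery, sensitivity ranking and readiness report."""

import numpy as np
import pandas as pd
import pytest

from dipsim import calibration_sensitivity as cal
from dipsim.calibration_sensitivity import (CalibrationTarget, FreeParameter,
                                            readiness_report)


@pytest.fixture
def targets():
    return CalibrationTarget.from_dict({2008: 0.06, 2016: 0.16})


class TestTargetsAndParams:
    def test_target_validation(self):
        with pytest.raises(ValueError):
            CalibrationTarget(pd.DataFrame({"year": [2008, 2008],
                                            "fraction": [0.1, 0.2]}))
        with pytest.raises(ValueError):
            CalibrationTarget(pd.DataFrame({"year": [2008],
                                            "fraction": [1.5]}))

    def test_csv_round_trip(self, tmp_path, targets):
        p = tmp_path / "t.csv"
        targets.table.to_csv(p, index=False)
        assert CalibrationTarget.from_csv(p).years == [2008, 2016]

    def test_free_parameter_transforms(self):
        fp = FreeParameter("x", 0.01, 1.0, "log")
        assert fp.from_unit(fp.to_unit(0.1)) == pytest.approx(0.1)
        assert fp.from_unit(0.0) == pytest.approx(0.01)
        assert fp.from_unit(1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            FreeParameter("x", 1.0, 0.5)


class TestLoss:
    def test_worked_arithmetic(self, targets, monkeypatch, small_config):
        # constant simulated 10% vs anchors 6% and 16%
        monkeypatch.setattr(cal, "simulated_fractions",
                            lambda cfg, years, seed: np.full(len(years), 0.10))
        val = cal.loss({}, targets, small_config, n_replicates=3, seed=0)
        assert val == pytest.approx(0.04**2 + 0.06**2)

    def test_target_outside_window_rejected(self, small_config):
        bad = CalibrationTarget.from_dict({1990: 0.05})
        with pytest.raises(ValueError):
            cal.loss({}, bad, small_config)

    def test_loss_invariant_to_target_row_order(self, targets, monkeypatch,
                                                small_config):
        monkeypatch.setattr(cal, "simulated_fractions",
                            lambda cfg, years, seed: np.full(len(years), 0.10))
        flipped = CalibrationTarget(targets.table.iloc[::-1].reset_index(drop=True))
        a = cal.loss({}, targets, small_config, n_replicates=1, seed=0)
        b = cal.loss({}, flipped, small_config, n_replicates=1, seed=0)
        assert a == pytest.approx(b)


class TestCalibrateMachinery:
    def test_budget_one_returns_single_point(self, targets, monkeypatch,
                                             small_config):
        calls = []

        def fake(cfg, years, seed):
            calls.append(1)
            return np.array([0.06, 0.16])
        monkeypatch.setattr(cal, "simulated_fractions", fake)
        res = cal.calibrate(small_config, targets,
                            [("physiology.k_decay", 0.01, 0.3, "log")],
                            budget=1, seed=0, n_replicates=1)
        assert res.loss == pytest.approx(0.0)
        assert len(res.trace) == 1

    def test_quadratic_surrogate_recovery(self, targets, monkeypatch,
                                          small_config):
        # surrogate: simulated fraction responds linearly to k_decay; the
        # optimiser must find the value mapping onto the anchors
        def fake(cfg, years, seed):
            k = cfg.physiology.k_decay
            return np.array([0.06 + (k - 0.1), 0.16 + (k - 0.1)])
        monkeypatch.setattr(cal, "simulated_fractions", fake)
        res = cal.calibrate(small_config, targets,
                            [("physiology.k_decay", 0.01, 0.3, "linear")],
                            budget=60, seed=0, n_replicates=1)
        assert res.params["physiology.k_decay"] == pytest.approx(0.1, abs=0.005)

    def test_respects_bounds(self, targets, monkeypatch, small_config):
        def fake(cfg, years, seed):
            return np.array([0.5, 0.5])  # push optimiser toward low values
        monkeypatch.setattr(cal, "simulated_fractions", fake)
        res = cal.calibrate(small_config, targets,
                            [("physiology.k_decay", 0.01, 0.3, "log")],
                            budget=30, seed=0, n_replicates=1)
        assert 0.01 <= res.params["physiology.k_decay"] <= 0.3


class TestSensitivity:
    def test_cost_parameter_has_zero_elasticity(self, small_config):
        out = cal.sensitivity_oat(
            small_config,
            [("treatment_ramp_weeks", 1.0, 10.0, "linear")],
            perturbation_frac=0.1, n_replicates=1, seed=2)
        # treatment ramp barely touches incidence; elasticity ~0 compared
        # with a true driver
        out2 = cal.sensitivity_oat(
            small_config,
            [("physiology.k_decay", 0.01, 0.3, "log")],
            perturbation_frac=0.25, n_replicates=1, seed=2)
        assert abs(out2.elasticity.iloc[0]) > abs(out.elasticity.iloc[0])

    def test_k_decay_elasticity_nonnegative(self, small_config):
        out = cal.sensitivity_oat(
            small_config, [("physiology.k_decay", 0.01, 0.3, "log")],
            perturbation_frac=0.3, n_replicates=2, seed=3)
        assert out.elasticity.iloc[0] >= 0.0

    def test_ordering_invariant_to_input_order(self, small_config, monkeypatch):
        vals = {"physiology.k_decay": 0.3, "physiology.bmi_secular": 0.1}

        def fake(cfg, years, seed):
            return np.array([0.1 + cfg.physiology.k_decay * 0.1
                             + cfg.physiology.bmi_secular * 0.01])
        monkeypatch.setattr(cal, "simulated_fractions", fake)
        fps = [("physiology.k_decay", 0.01, 0.5, "linear"),
               ("physiology.bmi_secular", 0.0, 0.2, "linear")]
        a = cal.sensitivity_oat(small_config, fps, n_replicates=1, seed=1)
        b = cal.sensitivity_oat(small_config, fps[::-1], n_replicates=1, seed=1)
        assert list(a.parameter) == list(b.parameter)


class TestReadiness:
    def test_anchor_agreement_pass_and_fail(self, small_result):
        ann = small_result.annual
        y = int(ann.index[-2])
        good = CalibrationTarget.from_dict({y: float(ann.loc[y, "dip_frac"])})
        rep = readiness_report(small_result, good)
        assert rep["indicators"]["dip_anchors"][y]["pass"]
        bad = CalibrationTarget.from_dict({y: 0.9})
        rep2 = readiness_report(small_result, bad)
        assert not rep2["pass"]

    def test_missing_reference_marked_not_assessed(self, small_result):
        y = int(small_result.annual.index[-1])
        t = CalibrationTarget.from_dict(
            {y: float(np.nan_to_num(small_result.annual.loc[y, "dip_frac"]))})
        rep = readiness_report(small_result, t)
        assert rep["indicators"]["weight_categories"] == {"status": "not assessed"}

    def test_weight_reference_l1(self, small_result):
        y = int(small_result.annual.index[-1])
        last = small_result.annual.iloc[-1]
        ref = {"healthy": float(last.prop_healthy),
               "overweight": float(last.prop_overweight),
               "obese": float(last.prop_obese)}
        t = CalibrationTarget.from_dict(
            {y: float(np.nan_to_num(last.dip_frac))})
        rep = readiness_report(small_result, t, reference_weight_props=ref)
        assert rep["indicators"]["weight_categories"]["l1_distance"] < 1e-9
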
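"""Engine orchestration: determinism, clock consistency, config handling."""

import numpy as np
import pytest

from dipsim import run
from dipsim.health_services import ConfigError
from dipsim.simulation_engine import (ScenarioConfig, act_baseline,
                                      burn_in_check, copy_config)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = ScenarioConfig.from_yaml(p)
        assert back.to_dict() == small_config.to_dict()

    def test_validation_itemises_errors(self):
        cfg = act_baseline()
        cfg.horizon_years = -1
        cfg.etiology = "astrology"
        with pytest.raises(ConfigError) as exc:
            cfg.validate()
        msg = str(exc.value)
        assert "horizon_years" in msg and "astrology" in msg

    def test_with_params_paths(self, small_config):
        cfg = small_config.with_params({
            "physiology.k_decay": 0.123,
            "diagnostic_schedule.post_threshold": 3.0})
        assert cfg.physiology.k_decay == 0.123
        assert cfg.diagnostic_schedule.entries[-1][1] == 3.0
        # original untouched
        assert small_config.physiology.k_decay != 0.123
        with pytest.raises(KeyError):
            small_config.with_params({"physiology.nonexistent": 1})

    def test_reporting_years_window(self):
        cfg = act_baseline()
        years = cfg.reporting_years
        assert years[0] == cfg.calendar_start_year + cfg.burn_in_years
        assert len(years) == cfg.horizon_years - cfg.burn_in_years


class TestRun:
    def test_determinism_same_config_seed(self, small_config, small_result):
        again = run(small_config, seed=7)
        assert again.annual.equals(small_result.annual)
        assert again.events.equals(small_result.events)

    def test_different_seeds_differ(self, small_config, small_result):
        other = run(small_config, seed=8)
        assert not other.annual["births"].equals(small_result.annual["births"])

    def test_reported_years_exclude_burn_in(self, small_config, small_result):
        assert list(small_result.annual.index) == small_config.reporting_years

    def test_dip_fraction_consistency(self, small_result):
        ann = small_result.annual
        with_births = ann[ann.births > 0]
        assert np.allclose(with_births.dip_frac,
                           with_births.dip_births / with_births.births)
        assert ((with_births.dip_frac >= 0) & (with_births.dip_frac <= 1)).all()

    def test_no_births_reports_null_not_zero(self):
        cfg = act_baseline(n_women=200, seed=1)
        cfg.record_stories = False
        cfg.fertility = {15: 0.0}  # nobody conceives
        res = run(cfg, seed=1)
        assert res.annual["births"].sum() == 0
        assert res.annual["dip_frac"].isna().all()

    def test_person_conservation_audit(self, small_result):
        assert small_result.chain_audit["conservation_error"] < 1e-9

    def test_event_log_time_ordered(self, small_result):
        t = small_result.events["time"].to_numpy()
        assert (np.diff(t) >= 0).all()

    def test_population_scaling_roughly_doubles_births(self):
        cfgA = act_baseline(n_women=2000, seed=1)
        cfgB = act_baseline(n_women=4000, seed=1)
        for c in (cfgA, cfgB):
            c.record_stories = False
        bA = np.mean([run(cfgA, seed=s).annual["births"].sum() for s in (1, 2)])
        bB = np.mean([run(cfgB, seed=s).annual["births"].sum() for s in (1, 2)])
        assert bB / bA == pytest.approx(2.0, rel=0.10)

    def test_monthly_metabolism_update_count(self, small_result):
        # a woman pregnant the whole of a calendar year accumulates sumT of
        # ~12 dt steps; proxy check via gestation: deliveries occur at the
        # first step with gest_week >= 40, i.e. within one step of term
        ev = small_result.events
        dl = ev[ev.kind == "delivery_care"]
        conc = ev[ev.kind == "conception"].set_index(["agent_id", "time"])
        # delivery time - conception time == 40 weeks exactly (event times
        # are reconstructed from the gestational clock)
        merged = dl.merge(ev[ev.kind == "conception"], on="agent_id",
                          suffixes=("_d", "_c"))
        gest = merged.time_d - merged.time_c
        gest = gest[(gest > 0) & (gest < 1.0)]
        assert np.allclose(gest, 40 / 52.1775, atol=1e-9)

    def test_high_risk_only_scope_limits_agents(self):
        cfg = act_baseline(n_women=2000, seed=1)
        cfg.record_stories = False
        cfg.bud_scope = "high_risk_only"
        res = run(cfg, seed=3)
        dl = res.events[res.events.kind == "delivery_care"]
        assert (dl.high_risk > 0).all()  # only high-risk women are agents


class TestCommonRandomNumbers:
    def test_screening_mode_switch_preserves_universal_stream(self):
        """Universal-week attendance/diagnoses among shared attendees are
        driven by per-agent keyed draws, so switching universal->selective
        only adds early screens (stream-splitting contract)."""
        cfg_u = act_baseline(n_women=2000, seed=1)
        cfg_u.record_stories = False
        cfg_s = copy_config(cfg_u)
        cfg_s.screening.mode = "selective"
        ru = run(cfg_u, seed=5)
        rs = run(cfg_s, seed=5)
        bu = ru.annual["births"]
        bs = rs.annual["births"]
        assert bu.equals(bs)  # fertility untouched by screening policy
        ogtt_u = ru.events[ru.events.kind == "ogtt"]
        ogtt_s = rs.events[rs.events.kind == "ogtt"]
        # same women attend the routine test at the same times
        assert set(zip(ogtt_u.agent_id, ogtt_u.time.round(6))) == \
            set(zip(ogtt_s.agent_id, ogtt_s.time.round(6)))


class TestMonotonePolicyResponse:
    def test_raising_threshold_never_increases_diagnoses(self):
        cfg_lo = act_baseline(n_women=2000, seed=1)
        cfg_lo.record_stories = False
        cfg_hi = copy_config(cfg_lo)
        lo_entries = [(y, thr) for y, thr in cfg_lo.diagnostic_schedule.entries]
        cfg_hi.diagnostic_schedule.entries = [(y, thr + 0.5) for y, thr in lo_entries]
        for seed in (1, 2, 3):
            lo = run(cfg_lo, seed=seed).annual["dip_births"]
            hi = run(cfg_hi, seed=seed).annual["dip_births"]
            assert (hi <= lo).all()


class TestBurnInCheck:
    def test_constant_series_is_stationary(self):
        assert burn_in_check(np.ones(10), 3) == 0.0

    def test_worked_example(self):
        stat = burn_in_check([1, 1, 1, 2, 2, 2], 3)
        assert stat == pytest.approx(1 / 1.5)

    def test_trending_series_exceeds_tolerance(self):
        stat = burn_in_check(np.arange(100.0), 20)
        assert stat > 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            burn_in_check([1, 2, 3], 2)
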
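"""Policy and program intervention scenarios.

An intervention is defined by who it targets (whole population of
reproductive-age women, screening-high-risk women, or women with prior
gestational diabetes), when in the life course it applies (pre-, inter-
or during pregnancy), its uptake, and two mechanistic effect channels:

* a weight channel — a weight change in kg, converted to BMI units and
  applied over a 6-month ramp; and
* a metabolic channel — a direct multiplier on baseline insulin
  sensitivity, independent of weight, representing physical-activity
  effects on metabolic function without weight change.

Both channels decay after the programme's duration ends. Effect sizes
are scenario inputs, not constants: interactions between stacked
interventions emerge mechanistically through the shared BMI/sensitivity
pathways rather than through interaction coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._streams import ENROL, keyed_uniform
from .life_course import REPRODUCTIVE_AGES, Agent, PregnancyState
from .physiology import delta_bmi
from .population_chain import adips_high_risk

RAMP_YEARS = 0.5

TARGETS = ("population", "high_risk", "post_gdm")
TIMINGS = ("pre_pregnancy", "inter_pregnancy", "during_pregnancy")


@dataclass
class InterventionSpec:
    name: str
    target: str = "population"
    timing: str = "pre_pregnancy"
    uptake: float = 0.5
    bmi_effect_kg: float = 0.0        # <= 0 for weight loss
    s_multiplier: float = 1.0         # >= 1 for metabolic benefit
    duration_years: float = 2.0
    adherence_decay: float = 0.3      # per-year fraction of effect lost after end
    start_year: float | None = None   # calendar year the programme opens

    def validate(self) -> None:
        errs = []
        if self.target not in TARGETS:
            errs.append(f"intervention {self.name}: unknown target {self.target!r}")
        if self.timing not in TIMINGS:
            errs.append(f"intervention {self.name}: unknown timing {self.timing!r}")
        if not (0 <= self.uptake <= 1):
            errs.append(f"intervention {self.name}: uptake must be in [0,1]")
        if self.duration_years <= 0:
            errs.append(f"intervention {self.name}: duration_years must be > 0")
        if not (0 <= self.adherence_decay <= 1):
            errs.append(f"intervention {self.name}: adherence_decay must be in [0,1]")
        if errs:
            raise ValueError("; ".join(errs))


def eligible(agent: Agent, spec: InterventionSpec, t: float) -> bool:
    """Targeting and life-course-timing gates for one agent at time t."""
    if not agent.alive or not agent.sex_female:
        return False
    age = agent.age(t)
    if not (REPRODUCTIVE_AGES[0] <= age < REPRODUCTIVE_AGES[1]):
        return False
    if spec.target == "high_risk":
        if not adips_high_risk(agent.ethnicity_high_risk, age, agent.prior_gdm,
                               agent.family_history, agent.bmi):
            return False
    elif spec.target == "post_gdm" and not agent.prior_gdm:
        return False
    if spec.timing == "pre_pregnancy":
        return (agent.parity == 0
                and agent.pregnancy_state == PregnancyState.NOT_PREGNANT)
    if spec.timing == "inter_pregnancy":
        return (agent.parity >= 1
                and agent.pregnancy_state == PregnancyState.NOT_PREGNANT)
    return agent.pregnancy_state == PregnancyState.PREGNANT


@dataclass
class Enrolment:
    """Effect state for one agent enrolled in one intervention."""

    spec: InterventionSpec
    t_enrol: float

    def bmi_offset(self, t: float, height_m: float) -> float:
        """Cumulative BMI-unit offset relative to counterfactual at time t."""
        full = delta_bmi(self.spec.bmi_effect_kg, height_m)
        dt = t - self.t_enrol
        if dt <= 0:
            return 0.0
        ramp = min(dt / RAMP_YEARS, 1.0)
        return full * ramp * self._retention(dt)

    def s_mult(self, t: float) -> float:
        dt = t - self.t_enrol
        if dt <= 0:
            return 1.0
        return 1.0 + (self.spec.s_multiplier - 1.0) * self._retention(dt)

    def _retention(self, dt: float) -> float:
        over = max(0.0, dt - self.spec.duration_years)
        return float(np.exp(-self.spec.adherence_decay * over))


def apply_intervention(agent: Agent, spec: InterventionSpec, t: float,
                       rng_or_seed) -> tuple[Agent, Enrolment | None]:
    """Offer the intervention to an eligible agent; enrol with prob uptake.

    Returns the (possibly updated) agent and an :class:`Enrolment`
    carrying the time-varying effect state, or None if she declines. The
    enrolment draw is keyed to the agent so policy changes elsewhere do
    not perturb it.
    """
    spec.validate()
    if not eligible(agent, spec, t):
        raise ValueError(f"agent {agent.id} is not eligible for {spec.name}")
    if isinstance(rng_or_seed, np.random.Generator):
        u = rng_or_seed.random()
    else:
        u = keyed_uniform(int(rng_or_seed), ENROL, agent.id,
                          hash(spec.name) & 0xFFFF)
    if u >= spec.uptake:
        return agent, None
    enr = Enrolment(spec, t)
    m = agent.metabolic
    agent = replace(agent, metabolic=replace(m, s_base=min(1.0, m.s_base)))
    return agent, enr


_DELTA_METRICS = ("dip_frac", "births", "adverse", "cost_total")


def scenario_compare(baseline, scenario) -> pd.DataFrame:
    """Per-year deltas (scenario - baseline) with replicate intervals.

    ``baseline`` and ``scenario`` are RunResults or equal-length lists of
    replicate RunResults sharing horizon and reporting years. Returns a
    tidy frame with mean delta, relative reduction and 10th/90th
    percentile interval over replicates for DIP incidence, births,
    adverse outcomes and total service cost.
    """
    base = baseline if isinstance(baseline, (list, tuple)) else [baseline]
    scen = scenario if isinstance(scenario, (list, tuple)) else [scenario]
    if len(base) != len(scen):
        raise ValueError("baseline and scenario replicate counts differ")
    years = list(base[0].annual.index)
    for r in list(base) + list(scen):
        if list(r.annual.index) != years:
            raise ValueError("mismatched horizons/reporting years")
    rows = []
    for metric in _DELTA_METRICS:
        if metric not in base[0].annual.columns:
            continue
        b = np.array([r.annual[metric].to_numpy(dtype=float) for r in base])
        s = np.array([r.annual[metric].to_numpy(dtype=float) for r in scen])
        d = s - b
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(b != 0, d / b, np.nan)
        for j, year in enumerate(years):
            rows.append({
                "year": year, "metric": metric,
                "delta_mean": float(np.nanmean(d[:, j])),
                "delta_p10": float(np.nanpercentile(d[:, j], 10)),
                "delta_p90": float(np.nanpercentile(d[:, j], 90)),
                "relative_change_mean": float(np.nanmean(rel[:, j])),
            })
    return pd.DataFrame(rows)
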
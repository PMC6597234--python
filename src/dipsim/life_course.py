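"""Agent life course: pregnancy state chart, births, weight categories.

An :class:`Agent` is an individual woman (or a child of one) with
continuous BMI, latent metabolic state, pregnancy state chart
(NOT_PREGNANT -> PREGNANT -> POSTPARTUM -> NOT_PREGNANT) and maternal
links. Babies are born with a risk endowment that depends on the
mother's history and her glycemic control during the pregnancy: exposure
to dysglycemia in utero lowers the child's beta-cell baseline and raises
their childhood BMI drift.

The module also carries the legacy comparator aetiology in which the
probability of a diabetes-in-pregnancy diagnosis is a simple linear
function of a count of risk factors — useful for demonstrating why a
mechanistic latent-physiology model was needed (the risk-count model has
no exposure-duration memory and no counterfactual pathways).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .physiology import (GESTATION_WEEKS, WEEKS_PER_YEAR, MetabolicState,
                         Phenotype, PhysiologyParams, delta_bmi)

DEFAULT_PHENOTYPE_MIX = (0.40, 0.25, 0.35)


class PregnancyState(IntEnum):
    NOT_PREGNANT = 0
    PREGNANT = 1
    POSTPARTUM = 2


class WeightCategory(IntEnum):
    HEALTHY = 0
    OVERWEIGHT = 1
    OBESE = 2


def weight_category(bmi):
    """WHO cut-points: healthy < 25 <= overweight < 30 <= obese."""
    b = np.asarray(bmi, dtype=float)
    if np.any(b <= 0):
        raise ValueError("bmi must be > 0")
    cat = np.where(b >= 30, int(WeightCategory.OBESE),
                   np.where(b >= 25, int(WeightCategory.OVERWEIGHT),
                            int(WeightCategory.HEALTHY)))
    if cat.ndim == 0:
        return WeightCategory(int(cat))
    return cat.astype(np.int8)


# Initial weight-category probabilities (healthy, overweight, obese) by age
# range, for (standard, high-risk-ethnicity) women. Broadly consistent with
# Australian female survey distributions; obesity rises with age and is more
# prevalent in the high-risk group.
DEFAULT_BMI_TABLES = {
    False: [((0, 18), (0.85, 0.11, 0.04)),
            ((18, 30), (0.60, 0.25, 0.15)),
            ((30, 45), (0.48, 0.30, 0.22)),
            ((45, 200), (0.40, 0.33, 0.27))],
    True: [((0, 18), (0.80, 0.13, 0.07)),
           ((18, 30), (0.50, 0.28, 0.22)),
           ((30, 45), (0.38, 0.32, 0.30)),
           ((45, 200), (0.32, 0.34, 0.34))],
}
CATEGORY_RANGES = ((18.5, 25.0), (25.0, 30.0), (30.0, 45.0))


def initial_bmi(age: float, high_risk: bool, rng: np.random.Generator,
                tables=None) -> float:
    """Draw an initial BMI: category from the age/ethnicity table, then a
    continuous value uniform within the category's range (obese truncated
    at 45). Children below 15 are scaled toward a childhood baseline."""
    tables = tables or DEFAULT_BMI_TABLES
    for (lo, hi), probs in tables[bool(high_risk)]:
        if lo <= age < hi:
            cat = rng.choice(3, p=np.asarray(probs) / np.sum(probs))
            if cat == WeightCategory.OBESE:
                # concentrated near 30 with an exponential upper tail
                bmi = min(30.0 + rng.exponential(3.0), 45.0)
            else:
                bmi = rng.uniform(*CATEGORY_RANGES[cat])
            if age < 15:  # childhood BMI scale
                bmi = 15.0 + (bmi - 18.5) * 0.5 + age * 0.2
            return float(max(bmi, 11.0))
    raise ValueError(f"no BMI table row covers age {age}")


_BMI_TABLE_CACHE: dict = {}


def initial_bmi_batch(ages, high_risk: bool, rng: np.random.Generator,
                      tables=None) -> np.ndarray:
    """Vectorised :func:`initial_bmi` for a batch sharing one risk group."""
    tables = tables or DEFAULT_BMI_TABLES
    ages = np.asarray(ages, dtype=float)
    rows = tables[bool(high_risk)]
    key = (id(tables), bool(high_risk))
    cached = _BMI_TABLE_CACHE.get(key)
    if cached is None:
        edges = np.array([lo for (lo, _hi), _ in rows] + [rows[-1][0][1]])
        probs = np.array([np.asarray(p) / np.sum(p) for _, p in rows])
        _BMI_TABLE_CACHE[key] = (edges, probs)
    else:
        edges, probs = cached
    row_idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0,
                      len(rows) - 1)
    cum = np.cumsum(probs[row_idx], axis=1)
    cat = (rng.random(ages.shape)[:, None] > cum).sum(axis=1)
    u = rng.random(ages.shape)
    lo = np.array([r[0] for r in CATEGORY_RANGES])[cat]
    hi = np.array([r[1] for r in CATEGORY_RANGES])[cat]
    out = lo + u * (hi - lo)
    obese = cat == int(WeightCategory.OBESE)
    if obese.any():
        out[obese] = np.minimum(30.0 + rng.exponential(3.0, int(obese.sum())), 45.0)
    child = ages < 15
    out = np.where(child, 15.0 + (out - 18.5) * 0.5 + ages * 0.2, out)
    return np.maximum(out, 11.0)


@dataclass
class Agent:
    """One individually simulated person."""

    id: int
    birth_time: float                      # calendar years
    height_m: float = 1.65
    bmi: float = 22.0
    metabolic: MetabolicState = field(default_factory=MetabolicState)
    sex_female: bool = True
    pregnancy_state: PregnancyState = PregnancyState.NOT_PREGNANT
    gestational_week: float = 0.0
    parity: int = 0
    prior_gdm: bool = False
    family_history: bool = False
    ethnicity_high_risk: bool = False
    mother_id: int | None = None
    in_utero_dysglycemia: bool = False
    type1_diabetes: bool = False
    alive: bool = True
    # Within-pregnancy trackers.
    preg_sum_G: float = 0.0
    preg_sum_t: float = 0.0
    diagnosed_this_pregnancy: bool = False

    def age(self, t: float) -> float:
        return t - self.birth_time

    @property
    def mean_pregnancy_G(self) -> float:
        return self.preg_sum_G / self.preg_sum_t if self.preg_sum_t > 0 else np.nan


# Age-specific annual conception rates by 5-year band 15-19 .. 45-49,
# roughly an Australian fertility schedule (TFR ~ 2.0).
DEFAULT_FERTILITY = {15: 0.02, 20: 0.07, 25: 0.11, 30: 0.12,
                     35: 0.07, 40: 0.02, 45: 0.003}
REPRODUCTIVE_AGES = (15.0, 50.0)


def fertility_rate(age, table=None):
    """Annual conception hazard for an age (vectorised); 0 outside 15-49."""
    table = table or DEFAULT_FERTILITY
    keys = np.array(sorted(table))
    vals = np.array([table[k] for k in sorted(table)])
    a = np.asarray(age, dtype=float)
    idx = np.clip(np.searchsorted(keys, a, side="right") - 1, 0, len(keys) - 1)
    out = np.where((a >= REPRODUCTIVE_AGES[0]) & (a < REPRODUCTIVE_AGES[1]),
                   vals[idx], 0.0)
    return float(out) if out.ndim == 0 else out


def conception_hazard(agent: Agent, t: float, fertility_params=None) -> float:
    """Per-year conception hazard for an eligible agent; 0 if ineligible."""
    if (not agent.sex_female or not agent.alive
            or agent.pregnancy_state != PregnancyState.NOT_PREGNANT):
        return 0.0
    return float(fertility_rate(agent.age(t), fertility_params))


POSTPARTUM_WEEKS = 26.0


def advance_pregnancy(agent: Agent, dt: float) -> tuple[Agent, list[str]]:
    """Advance gestation by ``dt`` years; emit 'delivery' at week 40.

    The gestational clock advances in weeks; reaching term transitions the
    agent to POSTPARTUM and resets the clock. The mean glycemic index over
    the pregnancy is accumulated separately by the engine (or by the
    caller via ``preg_sum_G``/``preg_sum_t``).
    """
    if agent.pregnancy_state != PregnancyState.PREGNANT:
        raise ValueError(f"agent {agent.id} is not pregnant")
    events: list[str] = []
    week = agent.gestational_week + dt * WEEKS_PER_YEAR
    if week >= GESTATION_WEEKS:
        agent = replace(agent, pregnancy_state=PregnancyState.POSTPARTUM,
                        gestational_week=0.0)
        events.append("delivery")
    else:
        agent = replace(agent, gestational_week=week)
    return agent, events


def deliver_baby(mother: Agent, rng: np.random.Generator,
                 params: PhysiologyParams, baby_id: int = -1,
                 t: float = 0.0, outcome_params=None):
    """Create the baby agent and the delivery outcome record.

    The baby inherits the mother's ethnicity flag; gets a family-history
    flag if the mother is impaired/diabetic or has prior gestational
    diabetes; and, when the mother's mean pregnancy glycemic index reached
    the dysglycemia threshold, carries an in-utero-dysglycemia endowment:
    beta-cell baseline multiplied by ``endow_b_mult`` and an amplified
    childhood BMI drift. The mother's parity increments and her prior-GDM
    flag latches if she was diagnosed this pregnancy.
    """
    from . import physiology as phys

    mean_G = mother.mean_pregnancy_G
    exposed = bool(np.isfinite(mean_G) and mean_G >= params.g_thr)
    mother_impaired = (1.0 / max(mother.metabolic.S * mother.metabolic.B, 1e-9)
                       >= params.g_igr)
    phen, s_base, b_base = phys.assign_phenotype(rng, DEFAULT_PHENOTYPE_MIX, params)
    if exposed:
        b_base *= params.endow_b_mult
    female = bool(rng.random() < 0.49)
    baby = Agent(
        id=baby_id, birth_time=t, sex_female=female,
        height_m=float(np.clip(rng.normal(1.63, 0.07), 1.40, 1.95)),
        bmi=13.0 + float(rng.normal(0, 0.5)),
        metabolic=MetabolicState(S=1.0, B=b_base, E=0.0, phenotype=phen,
                                 s_base=s_base, b_base=b_base),
        ethnicity_high_risk=mother.ethnicity_high_risk,
        family_history=bool(mother_impaired or mother.prior_gdm),
        mother_id=mother.id, in_utero_dysglycemia=exposed,
    )
    op = outcome_params or OutcomeParams()
    p_adv = adverse_outcome_prob(mean_G if np.isfinite(mean_G) else 1.0, op)
    outcome = {
        "mean_G": mean_G, "in_utero_dysglycemia": exposed,
        "adverse": bool(rng.random() < p_adv), "adverse_prob": p_adv,
        "dip_diagnosed": mother.diagnosed_this_pregnancy,
    }
    mother.parity += 1
    if mother.diagnosed_this_pregnancy:
        mother.prior_gdm = True
    return baby, outcome


@dataclass
class OutcomeParams:
    """Logistic link from mean pregnancy glycemic index to a composite
    adverse perinatal outcome probability."""

    p_min: float = 0.05
    p_max: float = 0.45
    k: float = 4.0
    G_mid: float = 1.8


def adverse_outcome_prob(mean_G, params: OutcomeParams | None = None):
    """``p = p_min + (p_max - p_min) / (1 + exp(-k (G - G_mid)))``;
    strictly increasing in mean glycemic control, bounded by (p_min, p_max)."""
    params = params or OutcomeParams()
    g = np.asarray(mean_G, dtype=float)
    if np.any(g < 0):
        raise ValueError("mean_G must be >= 0")
    p = params.p_min + (params.p_max - params.p_min) / (1.0 + np.exp(-params.k * (g - params.G_mid)))
    return float(p) if p.ndim == 0 else p


@dataclass
class RiskCountParams:
    p0: float = 0.03
    beta: float = 0.04
    bmi_threshold: float = 30.0
    age_threshold: float = 40.0


def risk_count_probability(agent: Agent, params: RiskCountParams | None = None,
                           t: float | None = None) -> float:
    """Legacy linear risk-factor-count model of DIP probability.

    ``p = clamp(p0 + beta * n_flags, 0, 1)`` over the five flags:
    high-risk ethnicity, age >= 40, prior GDM, family history, BMI >= 30.
    Static per pregnancy — no exposure-duration memory, which is exactly
    the limitation the mechanistic aetiology replaces.
    """
    params = params or RiskCountParams()
    age = agent.age(t) if t is not None else agent.age(0.0)
    n = (int(agent.ethnicity_high_risk) + int(age >= params.age_threshold)
         + int(agent.prior_gdm) + int(agent.family_history)
         + int(agent.bmi >= params.bmi_threshold))
    return float(np.clip(params.p0 + params.beta * n, 0.0, 1.0))


def risk_count_probability_arrays(eth, age, prior_gdm, family_history, bmi,
                                  params: RiskCountParams | None = None):
    """Vectorised form of :func:`risk_count_probability` for the engine."""
    params = params or RiskCountParams()
    n = (np.asarray(eth, int) + (np.asarray(age) >= params.age_threshold)
         + np.asarray(prior_gdm, int) + np.asarray(family_history, int)
         + (np.asarray(bmi) >= params.bmi_threshold))
    return np.clip(params.p0 + params.beta * n, 0.0, 1.0)
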
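"""Hybrid simulation clock: monthly aggregate/metabolic updates plus
continuous-time service and pregnancy events.

The engine advances three interlocking layers:

* the stock-and-flow ageing chain for the aggregate (non-agent) female
  population, stepped at the fixed monthly timestep;
* the agent layer — every individually simulated woman and child, held
  as structure-of-arrays state updated vectorially each month (BMI,
  insulin sensitivity, beta-cell function, exposure, pregnancy clock);
* discrete events (booking, screening tests, diagnoses, deliveries,
  postpartum transitions), detected as threshold crossings of each
  pregnancy's gestational clock within a month and recorded with their
  exact continuous event time; the final log is ordered by
  (time, agent_id, kind).

A run is a pure function of (config, seed): all stochastic draws come
either from one sequential generator stepped in a fixed order or from
counter-based streams keyed to (agent, purpose), which is what makes
common-random-number policy comparisons work.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import life_course, physiology, population_chain, reporting_stories
from ._kernel import monthly_core
from ._streams import (ADVERSE, ENROL, RISK_COUNT_DIP, SCREEN_EARLY,
                       SCREEN_UNIVERSAL, keyed_uniform)
from .health_services import ConfigError, DiagnosticSchedule, ScreeningPolicy
from .interventions import RAMP_YEARS, InterventionSpec
from .life_course import (DEFAULT_FERTILITY, DEFAULT_PHENOTYPE_MIX,
                          OutcomeParams, RiskCountParams)
from .physiology import GESTATION_WEEKS, WEEKS_PER_YEAR, PhysiologyParams
from .population_chain import (AGE_BAND_WIDTH, DEFAULT_EXIT_RATES, N_BANDS,
                               PopulationTable, generate_population_table,
                               init_stocks)

# Event kind codes (order is the tie-break order at equal time and agent).
KINDS = ("birth", "conception", "booking", "early_screen", "ogtt", "diagnosis",
         "lifestyle_rx", "pharmaco_rx", "delivery_care", "postpartum_test",
         "adverse_outcome", "weight_milestone", "intervention_enrol", "death")
KIND_CODE = {k: i for i, k in enumerate(KINDS)}
SERVICE_KINDS = ("booking", "early_screen", "ogtt", "diagnosis", "lifestyle_rx",
                 "pharmaco_rx", "delivery_care", "postpartum_test")

DEFAULT_UNIT_COSTS = {"booking": 120.0, "early_screen": 60.0, "ogtt": 60.0,
                      "diagnosis": 0.0, "lifestyle_rx": 350.0,
                      "pharmaco_rx": 700.0, "delivery_care": 5200.0,
                      "postpartum_test": 60.0}


@dataclass
class PopulationSpec:
    n_women: int = 10_000
    frac_high_risk: float = 0.2
    seed: int | None = None        # fixture seed; defaults to the run seed
    table_csv: str | None = None   # overrides the generator when set
    pyramid: tuple | None = None

    def validate(self):
        if self.table_csv is None and self.n_women <= 0:
            raise ConfigError("population.n_women must be positive")
        if not (0 <= self.frac_high_risk <= 1):
            raise ConfigError("population.frac_high_risk must be in [0,1]")


@dataclass
class ScenarioConfig:
    """Full experiment definition for one simulation run."""

    horizon_years: float = 30.0
    burn_in_years: float = 20.0
    dt_months: float = 1.0
    seed: int = 1
    calendar_start_year: int = 1988
    population: PopulationSpec = field(default_factory=PopulationSpec)
    bud_scope: str = "all_reproductive"   # or high_risk_only
    etiology: str = "mechanistic"         # or risk_count
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    screening: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    diagnostic_schedule: DiagnosticSchedule = field(
        default_factory=lambda: DiagnosticSchedule([(1980, 1.4)]))
    fertility: dict = field(default_factory=lambda: dict(DEFAULT_FERTILITY))
    phenotype_mix: tuple = DEFAULT_PHENOTYPE_MIX
    outcome: OutcomeParams = field(default_factory=OutcomeParams)
    risk_count: RiskCountParams = field(default_factory=RiskCountParams)
    interventions: list = field(default_factory=list)
    costs: dict = field(default_factory=lambda: dict(DEFAULT_UNIT_COSTS))
    treatment_m_full: float = 0.8
    treatment_ramp_weeks: float = 4.0
    postpartum_weeks: float = 26.0
    record_stories: bool = True    # weight milestones etc. in the event log

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        errs: list[str] = []
        if self.horizon_years <= 0:
            errs.append("horizon_years must be > 0")
        if self.burn_in_years < 0:
            errs.append("burn_in_years must be >= 0")
        if self.burn_in_years >= self.horizon_years:
            errs.append("burn_in_years must be < horizon_years")
        if self.dt_months <= 0 or abs(12.0 / self.dt_months - round(12.0 / self.dt_months)) > 1e-9:
            errs.append("dt_months must be positive and divide 12")
        if self.bud_scope not in ("all_reproductive", "high_risk_only"):
            errs.append(f"unknown bud_scope {self.bud_scope!r}")
        if self.etiology not in ("mechanistic", "risk_count"):
            errs.append(f"unknown etiology {self.etiology!r}")
        for sub in (self.population, self.physiology, self.screening,
                    self.diagnostic_schedule):
            try:
                sub.validate()
            except (ValueError, ConfigError) as e:
                errs.append(str(e))
        for iv in self.interventions:
            try:
                iv.validate()
            except ValueError as e:
                errs.append(str(e))
        if abs(sum(self.phenotype_mix) - 1.0) > 1e-9:
            errs.append("phenotype_mix must sum to 1")
        if errs:
            raise ConfigError("invalid scenario config:\n  - " + "\n  - ".join(errs))

    # -- parameter paths (used by calibration/sensitivity) ------------
    def with_params(self, updates: dict) -> "ScenarioConfig":
        """Return a copy with dotted-path parameter overrides applied.

        Paths walk attributes (``physiology.bmi_secular``); the alias
        ``diagnostic_schedule.post_threshold`` sets the threshold of the
        last schedule entry (the post-change diagnostic standard).
        """
        cfg = copy_config(self)
        for path, value in updates.items():
            if path == "diagnostic_schedule.post_threshold":
                entries = list(cfg.diagnostic_schedule.entries)
                y, _ = entries[-1]
                entries[-1] = (y, float(value))
                cfg.diagnostic_schedule.entries = entries
                continue
            parts = path.split(".")
            obj = cfg
            for p in parts[:-1]:
                obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
            last = parts[-1]
            if last.isdigit():
                obj[int(last)] = value
            else:
                if not hasattr(obj, last):
                    raise KeyError(f"unknown parameter path {path!r}")
                setattr(obj, last, value)
        return cfg

    def get_param(self, path: str):
        if path == "diagnostic_schedule.post_threshold":
            return self.diagnostic_schedule.entries[-1][1]
        obj = self
        for p in path.split("."):
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        return obj

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        sub = {
            "population": PopulationSpec, "physiology": PhysiologyParams,
            "screening": ScreeningPolicy, "outcome": OutcomeParams,
            "risk_count": RiskCountParams,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                kwargs[key] = sub[key](**{
                    k: (tuple(v) if isinstance(v, list) else v) for k, v in val.items()})
            elif key == "diagnostic_schedule":
                entries = val["entries"] if isinstance(val, dict) else val
                kwargs[key] = DiagnosticSchedule([tuple(e) for e in entries])
            elif key == "interventions":
                kwargs[key] = [iv if isinstance(iv, InterventionSpec)
                               else InterventionSpec(**iv) for iv in val]
            elif key == "fertility":
                kwargs[key] = {int(k): float(v) for k, v in val.items()}
            elif key == "phenotype_mix":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def reporting_years(self) -> list[int]:
        y0 = int(self.calendar_start_year + self.burn_in_years)
        y1 = int(self.calendar_start_year + self.horizon_years)
        return list(range(y0, y1))


def copy_config(cfg: ScenarioConfig) -> ScenarioConfig:
    return ScenarioConfig.from_dict(cfg.to_dict())


def act_baseline(n_women: int = 10_000, seed: int = 1) -> ScenarioConfig:
    """Baseline scenario emulating a small Australian jurisdiction.

    Reporting window 2008-2017 after a 20-year burn-in; universal
    screening at week 26; a diagnostic-standard change in 2013 lowers the
    screening threshold (the post-change value is a calibration free
    parameter). The pre-change threshold sits at the upper few-percent
    tail of the simulated screening-week glycemic-index distribution.
    """
    return ScenarioConfig(
        horizon_years=36, burn_in_years=26, calendar_start_year=1982,
        seed=seed,
        population=PopulationSpec(n_women=n_women, frac_high_risk=0.2, seed=1),
        diagnostic_schedule=DiagnosticSchedule([(1982, 5.0), (2013, 3.3)]),
    )


# Free parameters of the headline calibration: behavioural drivers (secular
# weight trend, beta-cell decay) vs the artefactual driver (the post-change
# diagnostic standard).
DEFAULT_FREE_PARAMS = (
    ("physiology.bmi_secular", 0.0, 0.15, "linear"),
    ("physiology.k_decay", 0.01, 0.30, "log"),
    ("diagnostic_schedule.post_threshold", 2.6, 5.5, "linear"),
)


@dataclass
class RunResult:
    """Annual output series plus the event log for one run."""

    annual: pd.DataFrame           # indexed by calendar year (post burn-in)
    events: pd.DataFrame           # full event log, time-ordered
    snapshots: pd.DataFrame        # annual population snapshots
    config: ScenarioConfig
    seed: int
    chain_audit: dict = field(default_factory=dict)


class _Log:
    """Chunked event log: per-month numpy appends, one concat at the end.

    ``v1``/``v2`` carry kind-specific details (e.g. the measured glycemic
    index and the threshold in force for a test); ``high_risk`` and
    ``age`` tag the agent's subgroup at event time so annual subgroup
    splits are recomputable from the log alone.
    """

    COLS = ("t", "agent", "kind", "v1", "v2", "hr", "age")

    def __init__(self):
        for c in self.COLS:
            setattr(self, c, [])

    def add(self, t, agent, kind: str, v1=np.nan, v2=np.nan, hr=np.nan, age=np.nan):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        m = t.size
        if m == 0:
            return
        a = np.asarray(agent, dtype=np.int64)
        self.t.append(t)
        self.agent.append(np.full(m, a) if a.ndim == 0 else a.copy())
        self.kind.append(np.full(m, KIND_CODE[kind], dtype=np.int8))
        for name, val in (("v1", v1), ("v2", v2), ("hr", hr), ("age", age)):
            v = np.asarray(val, dtype=float)
            getattr(self, name).append(np.full(m, v) if v.ndim == 0 else v.copy())

    def frame(self, calendar_start: float) -> pd.DataFrame:
        if not self.t:
            return pd.DataFrame(columns=["time", "year", "agent_id", "kind",
                                         "v1", "v2", "high_risk", "age"])
        t = np.concatenate(self.t)
        df = pd.DataFrame({
            "time": t,
            "year": np.floor(calendar_start + t).astype(int),
            "agent_id": np.concatenate(self.agent),
            "kind_code": np.concatenate(self.kind),
            "v1": np.concatenate(self.v1),
            "v2": np.concatenate(self.v2),
            "high_risk": np.concatenate(self.hr),
            "age": np.concatenate(self.age),
        })
        df = df.sort_values(["time", "agent_id", "kind_code"],
                            kind="stable").reset_index(drop=True)
        df["kind"] = pd.Categorical.from_codes(df.pop("kind_code"), list(KINDS))
        return df[["time", "year", "agent_id", "kind", "v1", "v2",
                   "high_risk", "age"]]


class _Agents:
    """Structure-of-arrays agent store with amortised growth."""

    FLOAT = ("birth_t", "height", "bmi", "s_base", "b_base", "B", "E",
             "gest_week", "preg_start", "sumG", "sumT", "diag_week",
             "screen_early_week", "screen_univ_week", "pp_end", "drift_mult")
    BOOL = ("eth", "fam", "prior_gdm", "t1d", "inutero", "female", "alive",
            "diag", "attend_early", "attend_univ", "done_early", "done_univ")
    INT = ("phen", "preg", "parity", "wcat")

    def __init__(self, capacity: int):
        self.n = 0
        for name in self.FLOAT:
            setattr(self, name, np.zeros(capacity))
        for name in self.BOOL:
            setattr(self, name, np.zeros(capacity, dtype=bool))
        for name in self.INT:
            setattr(self, name, np.zeros(capacity, dtype=np.int16))
        self.mother = np.full(capacity, -1, dtype=np.int64)
        self.ids = np.arange(capacity, dtype=np.int64)

    @property
    def capacity(self) -> int:
        return self.birth_t.shape[0]

    def grow(self, need: int):
        cap = self.capacity
        new_cap = max(cap * 2, self.n + need + 1024)
        for name in self.FLOAT + self.BOOL + self.INT:
            arr = getattr(self, name)
            setattr(self, name, np.resize(arr, new_cap))
            getattr(self, name)[cap:] = 0
        self.mother = np.resize(self.mother, new_cap)
        self.mother[cap:] = -1
        self.ids = np.arange(new_cap, dtype=np.int64)

    def alloc(self, k: int) -> np.ndarray:
        if self.n + k > self.capacity:
            self.grow(k)
        idx = np.arange(self.n, self.n + k)
        self.n += k
        return idx


def _exit_rate_for_age(age: np.ndarray, rates: np.ndarray) -> np.ndarray:
    idx = np.clip((age // AGE_BAND_WIDTH).astype(int), 0, N_BANDS - 1)
    return rates[idx]


def run(config: ScenarioConfig, seed: int | None = None) -> RunResult:
    """Simulate one scenario; deterministic given (config, seed)."""
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    phys = config.physiology
    dt = config.dt_months / 12.0
    dt_weeks = dt * WEEKS_PER_YEAR
    n_steps = int(round(config.horizon_years / dt))
    cal0 = float(config.calendar_start_year)
    exit_rates = np.array(DEFAULT_EXIT_RATES)
    fert_keys = np.array(sorted(config.fertility))
    fert_vals = np.array([config.fertility[k] for k in sorted(config.fertility)])
    mechanistic = config.etiology == "mechanistic"
    schedule = config.diagnostic_schedule
    if cal0 < schedule.entries[0][0]:
        raise ConfigError("diagnostic schedule does not cover the start year")
    sched_years = np.array([y for y, _ in schedule.entries], dtype=float)
    sched_thr = np.array([thr for _, thr in schedule.entries])
    pol = config.screening
    selective = pol.mode == "selective"
    ivs = list(config.interventions)

    # --- initial population -----------------------------------------
    if config.population.table_csv:
        pop = PopulationTable.from_csv(config.population.table_csv)
    else:
        pop_seed = config.population.seed
        pop = generate_population_table(
            config.population.n_women, config.population.frac_high_risk,
            np.random.default_rng((seed if pop_seed is None else pop_seed) + 10_007),
            pyramid=config.population.pyramid)
    chain = init_stocks(pop, exit_rate=exit_rates)

    def bud_predicate(i, g):
        in_window = 3 <= i <= 9  # bands 15-19 .. 45-49
        if config.bud_scope == "high_risk_only":
            return in_window and g == 1
        return in_window

    repro_stock = sum(chain.stocks[i, g] for i in range(3, 10) for g in range(2)
                      if bud_predicate(i, g))
    chain, init_agents = population_chain.bud_agents(
        chain, bud_predicate, int(round(repro_stock)), rng, phys)

    expected_births = int(0.06 * config.population.n_women * config.horizon_years)
    A = _Agents(len(init_agents) + expected_births + 2048)
    idx0 = A.alloc(len(init_agents))
    for j, ag in zip(idx0, init_agents):
        A.birth_t[j] = ag.birth_time
        A.height[j] = ag.height_m
        A.bmi[j] = ag.bmi
        A.s_base[j] = ag.metabolic.s_base
        A.b_base[j] = ag.metabolic.b_base
        A.B[j] = ag.metabolic.B
        A.phen[j] = int(ag.metabolic.phenotype)
        A.eth[j] = ag.ethnicity_high_risk
        A.t1d[j] = ag.type1_diabetes
        A.female[j] = True
        A.alive[j] = True
        A.drift_mult[j] = 1.0
    A.wcat[idx0] = life_course.weight_category(np.maximum(A.bmi[idx0], 10.5))
    # lifelong individual weight-trajectory heterogeneity
    A.drift_mult[idx0] = np.exp(rng.normal(0.0, phys.bmi_drift_het_sd,
                                           idx0.size))

    n_iv = len(ivs)
    iv_offered = np.zeros((n_iv, A.capacity), dtype=bool)
    iv_enrolled = np.zeros((n_iv, A.capacity), dtype=bool)
    iv_t = np.zeros((n_iv, A.capacity))

    log = _Log()
    snapshots: list[dict] = []
    pp_years = config.postpartum_weeks / WEEKS_PER_YEAR
    gest_years = GESTATION_WEEKS / WEEKS_PER_YEAR

    def _grow_iv(cap):
        nonlocal iv_offered, iv_enrolled, iv_t
        if n_iv and iv_offered.shape[1] < cap:
            pad = cap - iv_offered.shape[1]
            iv_offered = np.pad(iv_offered, ((0, 0), (0, pad)))
            iv_enrolled = np.pad(iv_enrolled, ((0, 0), (0, pad)))
            iv_t = np.pad(iv_t, ((0, 0), (0, pad)))

    steps_per_year = int(round(1.0 / dt))
    drift_ages = np.asarray(phys.bmi_drift_ages, dtype=float)
    drift_rates = np.asarray(phys.bmi_drift_rates, dtype=float)
    idx_buf = np.empty((4, A.capacity), dtype=np.int64)
    _ones = np.ones(A.capacity)
    _zeros = np.zeros(A.capacity)

    t = 0.0
    for step in range(n_steps):
        year = cal0 + t
        n = A.n
        sl = slice(0, n)
        alive = A.alive[sl]
        age = t - A.birth_t[sl]

        # 1. ageing chain + budding of girls reaching the reproductive window
        chain = population_chain.step_chain(chain, dt)
        for g in (0, 1):
            if config.bud_scope == "high_risk_only" and g == 0:
                continue
            avail = chain.stocks[3, g]
            k = int(np.floor(avail))  # fractional remainder stays and accrues
            if k > 0:
                chain.stocks[3, g] -= k
                chain.cum_budded += k
                idx = A.alloc(k)
                _grow_iv(A.capacity)
                # fresh entrants to band 15-19; entering cohorts carry the
                # secular (obesogenic-environment) BMI shift for their year
                ages_new = 15.0 + rng.random(k)
                phen, s_b, b_b = physiology.assign_phenotype(
                    rng, config.phenotype_mix, phys, n=k)
                t1d = rng.random(k) < phys.t1d_prevalence
                b_b = np.where(t1d, 0.05, b_b)
                A.birth_t[idx] = t - ages_new
                A.height[idx] = np.clip(rng.normal(1.63, 0.07, k), 1.40, 1.95)
                A.bmi[idx] = (life_course.initial_bmi_batch(ages_new, g == 1, rng)
                              + phys.bmi_secular * t)
                A.s_base[idx] = s_b
                A.b_base[idx] = b_b
                A.B[idx] = b_b
                A.E[idx] = 0.0
                A.phen[idx] = phen
                A.eth[idx] = g == 1
                A.t1d[idx] = t1d
                A.female[idx] = True
                A.alive[idx] = True
                A.drift_mult[idx] = np.exp(
                    rng.normal(0.0, phys.bmi_drift_het_sd, k))
                A.wcat[idx] = life_course.weight_category(
                    np.maximum(A.bmi[idx], 10.5))
                n = A.n
                sl = slice(0, n)
                alive = A.alive[sl]
                age = t - A.birth_t[sl]

        # 2. mortality / out-migration of agents (annual draws)
        if step % steps_per_year == 0:
            q = _exit_rate_for_age(np.maximum(age, 0.0), exit_rates)
            dies = alive & (rng.random(n) < q)
            if dies.any():
                A.alive[sl][dies] = False
                if config.record_stories:
                    log.add(np.full(dies.sum(), t), A.ids[sl][dies], "death")
                alive = A.alive[sl]

        # 3. interventions: offer once at first eligibility
        for k_iv, spec in enumerate(ivs):
            if spec.start_year is not None and year < spec.start_year:
                continue
            elig = alive & A.female[sl] & (age >= 15) & (age < 50)
            if spec.target == "high_risk":
                elig &= population_chain.adips_high_risk(
                    A.eth[sl], np.maximum(age, 0.0), A.prior_gdm[sl], A.fam[sl],
                    np.maximum(A.bmi[sl], 10.5))
            elif spec.target == "post_gdm":
                elig &= A.prior_gdm[sl]
            if spec.timing == "pre_pregnancy":
                elig &= (A.parity[sl] == 0) & (A.preg[sl] == 0)
            elif spec.timing == "inter_pregnancy":
                elig &= (A.parity[sl] >= 1) & (A.preg[sl] == 0)
            else:
                elig &= A.preg[sl] == 1
            offer = elig & ~iv_offered[k_iv, sl]
            if offer.any():
                iv_offered[k_iv, sl][offer] = True
                ids = A.ids[sl][offer]
                enrol = keyed_uniform(seed, ENROL, ids, k_iv) < spec.uptake
                if enrol.any():
                    w = np.flatnonzero(offer)[enrol]
                    iv_enrolled[k_iv, w] = True
                    iv_t[k_iv, w] = t
                    log.add(np.full(w.size, t), A.ids[w], "intervention_enrol",
                            v1=float(k_iv))

        # intervention effect channels (identity when no interventions)
        if n_iv:
            s_mult = np.ones(n)
            bmi_off = np.zeros(n)
        else:
            if _ones.shape[0] < n:
                _ones = np.ones(A.capacity)
                _zeros = np.zeros(A.capacity)
            s_mult = _ones
            bmi_off = _zeros
        for k_iv, spec in enumerate(ivs):
            enr = iv_enrolled[k_iv, sl]
            if not enr.any():
                continue
            dte = t - iv_t[k_iv, sl][enr]
            ret = np.exp(-spec.adherence_decay
                         * np.maximum(0.0, dte - spec.duration_years))
            s_mult[enr] *= 1.0 + (spec.s_multiplier - 1.0) * ret
            full = spec.bmi_effect_kg / A.height[sl][enr] ** 2
            bmi_off[enr] += full * np.minimum(dte / RAMP_YEARS, 1.0) * ret

        # 4. fused monthly update: postpartum recovery, conception decisions,
        # BMI dynamics, latent physiology, treatment multiplier, pregnancy
        # clock, and due-detection of screening tests and deliveries
        noise = rng.standard_normal(n) * (phys.bmi_noise_sd * np.sqrt(dt))
        u_conc = rng.random(n)
        G_np = np.empty(n)
        G_eff = np.empty(n)
        if idx_buf.shape[1] < A.capacity:
            idx_buf = np.empty((4, A.capacity), dtype=np.int64)
        n_conc, n_early, n_univ, n_del = monthly_core(
            n, A.alive, A.female, A.birth_t, t, dt, dt_weeks,
            A.bmi, A.drift_mult, drift_ages, drift_rates,
            phys.bmi_secular, noise, bmi_off, s_mult,
            A.s_base, A.B, A.E, A.preg, A.gest_week, A.pp_end,
            A.diag, A.diag_week, A.done_early, A.done_univ,
            A.attend_early, A.attend_univ, A.sumG, A.sumT,
            u_conc, fert_keys, fert_vals,
            pol.early_week, pol.universal_week,
            phys.k_bmi, phys.bmi_ref, phys.s_min, phys.rho_preg,
            phys.g_max, phys.g_thr, phys.k_decay, phys.r_regen,
            phys.e_rev, config.treatment_m_full, config.treatment_ramp_weeks,
            mechanistic, G_np, G_eff,
            idx_buf[0], idx_buf[1], idx_buf[2], idx_buf[3])
        bmi_eff = np.maximum(A.bmi[sl] + bmi_off, 10.0) if n_iv else A.bmi[sl]

        # 5. new conceptions: booking, keyed attendance draws
        if n_conc:
            w = idx_buf[0, :n_conc].copy()
            ids = A.ids[w]
            A.preg_start[w] = t
            par = A.parity[w].astype(np.int64)
            A.attend_univ[w] = keyed_uniform(seed, SCREEN_UNIVERSAL, ids,
                                             par) < pol.participation
            if selective:
                hr = population_chain.adips_high_risk(
                    A.eth[w], t - A.birth_t[w], A.prior_gdm[w], A.fam[w],
                    np.maximum(bmi_eff[w], 10.5))
                A.attend_early[w] = hr & (keyed_uniform(
                    seed, SCREEN_EARLY, ids, par) < pol.participation)
            A.screen_univ_week[w] = pol.universal_week
            A.screen_early_week[w] = pol.early_week
            age_c = t - A.birth_t[w]
            log.add(np.full(n_conc, t), ids, "conception",
                    hr=A.eth[w].astype(float), age=age_c)
            log.add(np.full(n_conc, t), ids, "booking", age=age_c)

        # 6. screening events (exact event times from the gestational clock)
        for early, n_due in ((True, n_early), (False, n_univ)):
            if not n_due:
                continue
            w = idx_buf[1 if early else 2, :n_due].copy()
            week, kind = ((pol.early_week, "early_screen") if early
                          else (pol.universal_week, "ogtt"))
            ids = A.ids[w]
            t_ev = A.preg_start[w] + week / WEEKS_PER_YEAR
            thr = sched_thr[np.clip(np.searchsorted(
                sched_years, cal0 + t_ev, side="right") - 1, 0, None)]
            if mechanistic:
                g_here = G_eff[w]
                pos = (g_here >= thr) & ~A.diag[w]
            else:
                p = life_course.risk_count_probability_arrays(
                    A.eth[w], t - A.birth_t[w], A.prior_gdm[w], A.fam[w],
                    bmi_eff[w], config.risk_count)
                g_here = p
                pos = (keyed_uniform(seed, RISK_COUNT_DIP, ids,
                                     A.parity[w].astype(np.int64)) < p) & ~A.diag[w]
            log.add(t_ev, ids, kind, v1=g_here, v2=thr)
            if pos.any():
                wd = w[pos]
                A.diag[wd] = True
                A.diag_week[wd] = week
                log.add(t_ev[pos], A.ids[wd], "diagnosis", v1=float(week),
                        v2=thr[pos])
                log.add(t_ev[pos], A.ids[wd], "lifestyle_rx")
                log.add(t_ev[pos], A.ids[wd], "pharmaco_rx")

        # 7. deliveries
        if n_del:
            w = idx_buf[3, :n_del].copy()
            ids = A.ids[w]
            m = w.size
            t_ev = A.preg_start[w] + gest_years
            meanG = np.where(A.sumT[w] > 0, A.sumG[w] / np.maximum(A.sumT[w], 1e-12), 1.0)
            exposed = mechanistic & (meanG >= phys.g_thr)
            diag = A.diag[w].copy()
            p_adv = life_course.adverse_outcome_prob(np.maximum(meanG, 0.0),
                                                     config.outcome)
            adverse = keyed_uniform(seed, ADVERSE, ids,
                                    A.parity[w].astype(np.int64)) < p_adv
            log.add(t_ev, ids, "delivery_care", v1=diag.astype(float),
                    v2=adverse.astype(float), hr=A.eth[w].astype(float),
                    age=t - A.birth_t[w])
            if adverse.any():
                log.add(t_ev[adverse], ids[adverse], "adverse_outcome",
                        v1=meanG[adverse])
            if diag.any():
                log.add(t_ev[diag] + pp_years, ids[diag], "postpartum_test")
            # mother state
            mother_impaired = (G_np[w] >= phys.g_igr) if mechanistic else diag
            fam_flag = mother_impaired | A.prior_gdm[w] | diag
            A.parity[w] += 1
            A.prior_gdm[w] |= diag
            A.preg[w] = 2
            A.gest_week[w] = 0.0
            A.pp_end[w] = t_ev + pp_years
            gwg = rng.normal(phys.gwg_mean, phys.gwg_sd, m)
            A.bmi[w] += phys.retention_frac * np.maximum(gwg, 0.0) / A.height[w] ** 2
            # babies (female babies become agents; all deliveries are births)
            female_baby = rng.random(m) < 0.49
            kf = int(female_baby.sum())
            if kf > 0:
                phen, s_b, b_b = physiology.assign_phenotype(
                    rng, config.phenotype_mix, phys, n=kf)
                exp_f = exposed[female_baby]
                b_b = np.where(exp_f, b_b * phys.endow_b_mult, b_b)
                t1d = rng.random(kf) < phys.t1d_prevalence
                b_b = np.where(t1d, 0.05, b_b)
                idx = A.alloc(kf)
                _grow_iv(A.capacity)
                A.birth_t[idx] = t_ev[female_baby]
                A.height[idx] = np.clip(rng.normal(1.63, 0.07, kf), 1.40, 1.95)
                A.bmi[idx] = (13.0 + rng.normal(0, 0.5, kf)
                              + phys.bmi_secular * t_ev[female_baby])
                A.s_base[idx] = s_b
                A.b_base[idx] = b_b
                A.B[idx] = b_b
                A.E[idx] = 0.0
                A.phen[idx] = phen
                A.eth[idx] = A.eth[w][female_baby]
                A.fam[idx] = fam_flag[female_baby]
                A.t1d[idx] = t1d
                A.inutero[idx] = exp_f
                A.female[idx] = True
                A.alive[idx] = True
                het = np.exp(rng.normal(0.0, phys.bmi_drift_het_sd, kf))
                A.drift_mult[idx] = het * np.where(exp_f, phys.endow_drift_mult, 1.0)
                A.wcat[idx] = 0
                A.mother[idx] = ids[female_baby]
                log.add(t_ev[female_baby], A.ids[idx], "birth",
                        v1=1.0, v2=exp_f.astype(float))

        # 8. weight-category milestones (with hysteresis against BMI noise)
        if config.record_stories:
            adult = alive & (age >= 15)
            cat_now = life_course.weight_category(np.maximum(bmi_eff, 10.5))
            moved = adult & (cat_now != A.wcat[sl])
            if moved.any():
                edge = np.where(cat_now > A.wcat[sl],
                                np.where(cat_now == 1, 25.0, 30.0),
                                np.where(cat_now == 0, 25.0, 30.0))
                firm = moved & (np.abs(bmi_eff - edge) > 0.25)
                if firm.any():
                    wf = np.flatnonzero(firm)
                    log.add(np.full(wf.size, t + dt), A.ids[wf],
                            "weight_milestone", v1=cat_now[firm].astype(float),
                            v2=bmi_eff[firm])
                    A.wcat[wf] = cat_now[firm]

        t = round((step + 1) * dt * 12.0) / 12.0

        # 9. annual snapshot at each year boundary
        if abs(t - round(t)) < 1e-9 and round(t) <= config.horizon_years:
            yr = int(cal0 + round(t)) - 1
            n = A.n
            sl = slice(0, n)
            alive = A.alive[sl]
            age = t - A.birth_t[sl]
            women = alive & A.female[sl] & (age >= 15) & (age < 50)
            cats = life_course.weight_category(
                np.maximum(A.bmi[sl][women], 10.5)) if women.any() else np.array([])
            nw = max(int(women.sum()), 1)
            hist, _ = np.histogram(age[alive], bins=np.arange(0, 95, 5))
            snapshots.append({
                "year": yr,
                "n_agents": int(alive.sum()),
                "n_women_15_49": int(women.sum()),
                "chain_total": chain.total,
                "prop_healthy": float(np.sum(cats == 0) / nw),
                "prop_overweight": float(np.sum(cats == 1) / nw),
                "prop_obese": float(np.sum(cats == 2) / nw),
                "mean_bmi": float(np.mean(A.bmi[sl][women])) if women.any() else np.nan,
                "age_hist": hist.tolist(),
            })

        if not np.all(np.isfinite(A.bmi[:A.n])):
            bad = int(np.flatnonzero(~np.isfinite(A.bmi[:A.n]))[0])
            raise FloatingPointError(
                f"non-finite BMI for agent {bad} at t={t:.3f}")

    events = log.frame(cal0)
    snap = pd.DataFrame(snapshots).set_index("year") if snapshots else pd.DataFrame()
    annual = reporting_stories.annual_summary(
        events, snap, years=config.reporting_years, costs=config.costs)
    audit = {
        "conservation_error": chain.conservation_error(),
        "cum_budded": chain.cum_budded,
        "cum_exits": chain.cum_exits,
    }
    return RunResult(annual=annual, events=events, snapshots=snap,
                     config=config, seed=seed, chain_audit=audit)


def burn_in_check(series, window: int) -> float:
    """Stationarity statistic for burn-in-length testing.

    Splits the last ``2*window`` points into two windows and returns the
    absolute difference of their means normalised by the overall level.
    Callers compare the statistic to their own tolerance.
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or x.size < 2 * window:
        raise ValueError("series must have length >= 2*window")
    a = x[-2 * window:-window].mean()
    b = x[-window:].mean()
    level = (abs(a) + abs(b)) / 2.0
    return abs(b - a) / level if level > 0 else 0.0
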
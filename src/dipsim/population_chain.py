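"""Aggregate female population as a stock-and-flow ageing chain.

The population that is not individually interesting (girls below
reproductive age, women past it) lives in aggregate stocks indexed by
5-year age band and risk group. Stocks age along the chain with a 5-year
band residence time, receive entries into the youngest band and lose
per-capita exits (mortality plus out-migration). Women entering the
reproductive window are "budded": removed from the aggregate stock and
instantiated as individually simulated agents with sampled age, BMI and
latent physiology.

Stocks are real-valued; budding rounds stochastically so expected person
counts are preserved, and a set of cumulative counters makes exact person
conservation checkable at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import life_course, physiology
from .physiology import PhysiologyParams

AGE_BAND_WIDTH = 5
N_BANDS = 18  # 0-4 .. 80-84, 85+
AGE_BANDS = tuple(
    f"{5 * i}-{5 * i + 4}" if i < N_BANDS - 1 else "85+" for i in range(N_BANDS)
)
RISK_GROUPS = ("standard", "high_risk_ethnicity")

# Plausible per-capita annual exit rates (mortality + net out-migration) for
# an Australian female population, by 5-year band.
DEFAULT_EXIT_RATES = (
    0.001, 0.0005, 0.0005, 0.0008, 0.001, 0.001, 0.001, 0.0012, 0.0015,
    0.002, 0.003, 0.005, 0.008, 0.012, 0.02, 0.035, 0.07, 0.15,
)


def band_index(age_years: float) -> int:
    """Index of the 5-year band containing ``age_years``."""
    return min(int(age_years // AGE_BAND_WIDTH), N_BANDS - 1)


def band_bounds(i: int) -> tuple[float, float]:
    lo = 5.0 * i
    return (lo, lo + 5.0 if i < N_BANDS - 1 else 100.0)


class ValidationError(ValueError):
    pass


@dataclass
class PopulationTable:
    """Rows of (age_band, risk_group, count) — the fixture input format."""

    table: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        req = {"age_band", "risk_group", "count"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"population table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValidationError("population table is empty")
        for i, row in self.table.iterrows():
            if row["age_band"] not in AGE_BANDS:
                raise ValidationError(f"row {i}: unknown age_band {row['age_band']!r}")
            if row["risk_group"] not in RISK_GROUPS:
                raise ValidationError(f"row {i}: unknown risk_group {row['risk_group']!r}")
            if not np.isfinite(row["count"]) or row["count"] < 0:
                raise ValidationError(f"row {i}: negative or non-finite count {row['count']}")

    @property
    def total(self) -> float:
        return float(self.table["count"].sum())

    @property
    def fraction_high_risk(self) -> float:
        hr = self.table.loc[self.table.risk_group == "high_risk_ethnicity", "count"].sum()
        return float(hr / self.total) if self.total > 0 else 0.0

    @classmethod
    def from_csv(cls, path) -> "PopulationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=["age_band", "risk_group", "count"])


# Default female age pyramid over bands 0-49 (older bands empty): slightly
# bottom-heavy, matching a growing jurisdictional population.
DEFAULT_PYRAMID = np.array(
    [1.05, 1.05, 1.0, 1.0, 1.05, 1.1, 1.1, 1.05, 1.0, 0.95] + [0.0] * 8
)


def generate_population_table(n_women: int, frac_high_risk: float,
                              seed: int | np.random.Generator = 0,
                              pyramid=None) -> PopulationTable:
    """Generate a synthetic female population table.

    Emulates an age-structured jurisdictional female population (ages
    0-49 by default) stratified by a high-risk-ethnicity flag. Counts are
    multinomially sampled so each realisation is a plausible census-style
    table with exactly ``n_women`` persons.
    """
    if n_women <= 0:
        raise ValidationError("n_women must be positive")
    if not (0 <= frac_high_risk <= 1):
        raise ValidationError("frac_high_risk must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(DEFAULT_PYRAMID if pyramid is None else pyramid, dtype=float)
    probs = np.outer(w / w.sum(), [1 - frac_high_risk, frac_high_risk]).ravel()
    counts = rng.multinomial(n_women, probs).reshape(N_BANDS, 2)
    rows = [
        {"age_band": AGE_BANDS[i], "risk_group": RISK_GROUPS[g], "count": int(counts[i, g])}
        for i in range(N_BANDS) for g in range(2)
    ]
    return PopulationTable(pd.DataFrame(rows))


@dataclass
class AgeingChain:
    """Stocks (bands x risk groups) with ageing, entry and exit flows.

    ``stocks[i, g]`` is persons in band ``i`` of risk group ``g``.
    Cumulative counters support exact person-conservation audits:
    ``stocks.sum() + cum_exits + cum_budded == initial_total + cum_entries``.
    """

    stocks: np.ndarray
    entry_rate: np.ndarray = field(default_factory=lambda: np.zeros(2))  # persons/yr into band 0
    exit_rate: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_EXIT_RATES))
    aging_residence_time: float = float(AGE_BAND_WIDTH)
    cum_entries: float = 0.0
    cum_exits: float = 0.0
    cum_budded: float = 0.0
    initial_total: float = 0.0

    def copy(self) -> "AgeingChain":
        return AgeingChain(self.stocks.copy(), self.entry_rate.copy(),
                           self.exit_rate.copy(), self.aging_residence_time,
                           self.cum_entries, self.cum_exits, self.cum_budded,
                           self.initial_total)

    @property
    def total(self) -> float:
        return float(self.stocks.sum())

    def conservation_error(self) -> float:
        return abs(self.total + self.cum_exits + self.cum_budded
                   - self.initial_total - self.cum_entries)


def init_stocks(pop: PopulationTable, entry_rate=None, exit_rate=None,
                aging_residence_time: float = float(AGE_BAND_WIDTH)) -> AgeingChain:
    """Initialise the ageing chain from a population table.

    Flows default to zero entries and the built-in per-band exit rates;
    both can be overridden from scenario config.
    """
    pop.validate()
    stocks = np.zeros((N_BANDS, 2))
    for _, row in pop.table.iterrows():
        i = AGE_BANDS.index(row["age_band"])
        g = RISK_GROUPS.index(row["risk_group"])
        stocks[i, g] += float(row["count"])
    chain = AgeingChain(
        stocks=stocks,
        entry_rate=np.zeros(2) if entry_rate is None else np.asarray(entry_rate, float),
        exit_rate=np.array(DEFAULT_EXIT_RATES) if exit_rate is None
        else np.asarray(exit_rate, float),
        aging_residence_time=aging_residence_time,
    )
    chain.initial_total = chain.total
    return chain


def step_chain(chain: AgeingChain, dt: float) -> AgeingChain:
    """Advance the chain by ``dt`` years; returns a new chain.

    Each band's ageing outflow is ``stock/residence_time * dt`` and its
    exit flow ``stock * exit_rate * dt``; flows are rescaled if they would
    overdraw a stock, so no stock goes negative. The top band has no
    ageing outflow. The ageing flow out of the last pre-reproductive band
    is returned separately by :func:`reproductive_inflow` for budding.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = chain.copy()
    s = c.stocks
    tau = c.aging_residence_time
    aging_out = s / tau * dt if np.isfinite(tau) else np.zeros_like(s)
    aging_out[-1] = 0.0
    exits = s * c.exit_rate[:, None] * dt
    # Cap combined outflow at available stock (proportional rescale).
    total_out = aging_out + exits
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total_out > s, np.where(total_out > 0, s / total_out, 1.0), 1.0)
    aging_out *= scale
    exits *= scale
    new = s - aging_out - exits
    new[1:] += aging_out[:-1]
    new[0] += c.entry_rate * dt
    c.stocks = np.maximum(new, 0.0)
    c.cum_entries += float(c.entry_rate.sum() * dt)
    c.cum_exits += float(exits.sum())
    return c


def adips_high_risk(ethnicity_flag, age_years, prior_gdm=False,
                    family_history=False, bmi=22.0,
                    age_threshold: float = 40.0, bmi_threshold: float = 35.0):
    """Screening high-risk predicate in the ADIPS style.

    True iff high-risk ethnicity, age >= 40, prior gestational diabetes,
    family history of diabetes, or BMI >= 35. The thresholds are
    config-editable; the five-item list approximates the published
    clinical criteria. Monotone: raising any risk attribute never turns a
    high-risk woman low-risk. Accepts scalars or arrays.
    """
    age = np.asarray(age_years, dtype=float)
    b = np.asarray(bmi, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    if np.any(b <= 0):
        raise ValueError("bmi must be > 0")
    out = (np.asarray(ethnicity_flag, bool) | (age >= age_threshold)
           | np.asarray(prior_gdm, bool) | np.asarray(family_history, bool)
           | (b >= bmi_threshold))
    return bool(out) if out.ndim == 0 else out


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    f = np.floor(x)
    return (f + (rng.random(x.shape) < (x - f))).astype(int)


def bud_agents(chain: AgeingChain, predicate, n_or_rate, rng: np.random.Generator,
               phys_params: PhysiologyParams | None = None,
               bmi_tables=None, birth_time: float = 0.0,
               id_start: int = 0):
    """Remove persons from eligible stocks and instantiate them as agents.

    ``predicate(band_index, risk_group_index) -> bool`` selects eligible
    cells; ``n_or_rate`` is either an integer total to bud (allocated
    across cells proportionally to stock, largest-remainder rounding) or a
    float per-capita rate (stochastically rounded per cell, expected value
    preserved). Agents get ages uniform within their source band,
    ethnicity matching their risk group, phenotype/baselines from
    :func:`physiology.assign_phenotype` and an initial BMI drawn from the
    age- and ethnicity-specific weight-category tables.
    """
    phys_params = phys_params or PhysiologyParams()
    eligible = np.array([[bool(predicate(i, g)) for g in range(2)]
                         for i in range(N_BANDS)])
    avail = np.where(eligible, chain.stocks, 0.0)
    total_avail = avail.sum()
    if isinstance(n_or_rate, (int, np.integer)):
        n = int(n_or_rate)
        if n < 0:
            raise ValueError("requested buds must be >= 0")
        if n > total_avail + 1e-9:
            raise ValueError(
                f"requested {n} buds but only {total_avail:.3f} persons in eligible stocks")
        if n == 0 or total_avail == 0:
            return chain.copy(), []
        frac = avail / total_avail * n
        buds = np.floor(frac).astype(int)
        rem = n - buds.sum()
        if rem > 0:
            order = np.argsort(-(frac - np.floor(frac)).ravel(), kind="stable")
            for k in order[:rem]:
                buds.ravel()[k] += 1
    else:
        rate = float(n_or_rate)
        if rate < 0:
            raise ValueError("bud rate must be >= 0")
        buds = _stochastic_round(avail * rate, rng)
        buds = np.minimum(buds, np.floor(avail).astype(int))
    c = chain.copy()
    agents: list[life_course.Agent] = []
    next_id = id_start
    for i in range(N_BANDS):
        for g in range(2):
            k = int(buds[i, g])
            if k == 0:
                continue
            c.stocks[i, g] -= k
            c.cum_budded += k
            lo, hi = band_bounds(i)
            ages = rng.uniform(lo, min(hi, lo + AGE_BAND_WIDTH), k)
            high_risk = g == 1
            phen, s_base, b_base = physiology.assign_phenotype(
                rng, life_course.DEFAULT_PHENOTYPE_MIX, phys_params, n=k)
            heights = np.clip(rng.normal(1.63, 0.07, k), 1.40, 1.95)
            bmis = life_course.initial_bmi_batch(ages, high_risk, rng, bmi_tables)
            t1ds = rng.random(k) < phys_params.t1d_prevalence
            b_base = np.where(t1ds, 0.05, b_base)
            for j in range(k):
                agents.append(life_course.Agent(
                    id=next_id,
                    birth_time=birth_time - ages[j],
                    height_m=float(heights[j]),
                    bmi=float(bmis[j]),
                    metabolic=physiology.MetabolicState(
                        S=1.0, B=float(b_base[j]), E=0.0,
                        phenotype=physiology.Phenotype(int(phen[j])),
                        s_base=float(s_base[j]), b_base=float(b_base[j])),
                    ethnicity_high_risk=high_risk,
                    type1_diabetes=bool(t1ds[j]),
                ))
                next_id += 1
    if c.stocks.min() < -1e-9:
        raise ValueError("budding overdrew a stock")
    c.stocks = np.maximum(c.stocks, 0.0)
    return c, agents
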
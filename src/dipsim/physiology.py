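"""Latent metabolic model.

Each woman carries two latent physiological quantities: insulin sensitivity
``S`` (how well her tissues respond to insulin) and beta-cell function ``B``
(how much insulin her pancreas can secrete). Their product determines a
dimensionless glycemic index ``G = 1/(S*B)``, normalised so that ``G = 1``
for a fully sensitive, fully secreting reference individual. ``G`` above a
dysglycemia threshold accumulates *exposure* ``E`` (index-years), which
degrades beta-cell function; below the threshold beta cells regenerate, but
only while cumulative exposure is below a reversibility ceiling. This
reproduces the clinical picture in which newly impaired individuals can
recover glycemic control through lifestyle change while long-exposed
individuals cannot.

Three aetiological phenotypes are distinguished: resistance-driven (low
baseline sensitivity), secretion-driven (low baseline beta-cell function)
and mixed. BMI is continuous and dynamic; sensitivity declines
exponentially with BMI above a reference value, and pregnancy itself
imposes a progressive, gestation-week-dependent resistance ramp.

All functions accept scalars or numpy arrays and are deterministic given
their inputs (randomness enters only through explicitly passed generators).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

WEEKS_PER_YEAR = 52.1775
GESTATION_WEEKS = 40.0


class Phenotype(IntEnum):
    RESISTANCE = 0
    SECRETION = 1
    MIXED = 2


class GlycemicClass(IntEnum):
    NORMAL = 0
    IMPAIRED = 1
    DIABETES = 2


@dataclass
class PhysiologyParams:
    """Tunable parameters of the latent metabolic model.

    Thresholds are on the glycemic-index scale (1 = healthy reference);
    rates are per year unless noted.
    """

    bmi_ref: float = 25.0          # BMI units; no sensitivity penalty below this
    k_bmi: float = 0.05            # per BMI-unit exponential sensitivity decay
    s_min: float = 0.1             # floor of insulin sensitivity
    rho_preg: float = 0.5          # maximal fractional pregnancy sensitivity drop
    g_thr: float = 1.5             # dysglycemia threshold (exposure accrues above)
    g_igr: float = 1.5             # impaired-regulation threshold
    g_dm: float = 2.0              # diabetes threshold
    g_gdm: float = 1.3             # default pregnancy diagnostic threshold
    g_max: float = 6.0             # cap on glycemic index (secretory failure)
    k_decay: float = 0.2           # beta-cell decay per unit dysglycemia per year
    r_regen: float = 0.05          # beta-cell regeneration per year
    e_rev: float = 1.0             # reversibility ceiling on exposure, index-years
    bmi_drift_ages: tuple = (0.0, 2.0, 10.0, 16.0, 25.0, 35.0, 50.0, 65.0, 85.0)
    bmi_drift_rates: tuple = (0.30, 0.50, 0.55, 0.28, 0.13, 0.10, 0.04, 0.0, -0.05)
    bmi_secular: float = 0.05      # BMI units/year secular trend (entering cohorts)
    bmi_noise_sd: float = 0.3      # BMI units per sqrt(year) random walk
    bmi_drift_het_sd: float = 0.35  # lognormal sd of lifelong individual drift factor
    gwg_mean: float = 12.0         # gestational weight gain, kg
    gwg_sd: float = 3.0
    retention_frac: float = 0.3    # postpartum weight retention fraction
    # Phenotype baseline levels (mean of s_base / b_base by phenotype).
    pheno_s_low: float = 0.85
    pheno_b_low: float = 0.85
    pheno_mixed: float = 0.92
    baseline_jitter_sd: float = 0.05  # lognormal sd of individual baselines
    # Intergenerational endowment for babies exposed to dysglycemia in utero.
    endow_b_mult: float = 0.9
    endow_drift_mult: float = 1.3
    t1d_prevalence: float = 0.004  # flagged at initialisation, B fixed low

    def validate(self) -> None:
        errs = []
        for name in ("k_bmi", "k_decay", "r_regen", "e_rev", "bmi_noise_sd",
                     "gwg_sd", "g_max"):
            if getattr(self, name) < 0:
                errs.append(f"physiology.{name} must be >= 0")
        if not (0 < self.s_min < 1):
            errs.append("physiology.s_min must be in (0,1)")
        if not (0 <= self.rho_preg < 1):
            errs.append("physiology.rho_preg must be in [0,1)")
        if not (1 < self.g_igr <= self.g_dm):
            errs.append("physiology thresholds must satisfy 1 < g_igr <= g_dm")
        if not (0 <= self.retention_frac <= 1):
            errs.append("physiology.retention_frac must be in [0,1]")
        if len(self.bmi_drift_ages) != len(self.bmi_drift_rates):
            errs.append("physiology BMI drift spline: ages and rates differ in length")
        if errs:
            raise ValueError("; ".join(errs))


@dataclass
class MetabolicState:
    """Latent metabolic state of one individual (fields may be arrays)."""

    S: float = 1.0
    B: float = 1.0
    E: float = 0.0
    phenotype: Phenotype = Phenotype.RESISTANCE
    s_base: float = 1.0
    b_base: float = 1.0


def assign_phenotype(rng: np.random.Generator,
                     mix_proportions=(1 / 3, 1 / 3, 1 / 3),
                     params: PhysiologyParams | None = None,
                     n: int | None = None):
    """Draw aetiological phenotype(s) and individual baselines.

    Returns ``(phenotype, s_base, b_base)``; arrays of length ``n`` when
    ``n`` is given, scalars otherwise. Resistance phenotypes get a lowered
    sensitivity baseline, secretion phenotypes a lowered beta-cell
    baseline, mixed both moderately lowered; each baseline carries
    individual lognormal jitter and is clipped to (0, 1].
    """
    params = params or PhysiologyParams()
    p = np.asarray(mix_proportions, dtype=float)
    if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("mix_proportions must be 3 non-negative values summing to 1")
    scalar = n is None
    m = 1 if scalar else int(n)
    phen = np.searchsorted(np.cumsum(p)[:2], rng.random(m),
                           side="right").astype(np.int8)
    s_mean = np.where(phen == Phenotype.RESISTANCE, params.pheno_s_low,
                      np.where(phen == Phenotype.MIXED, params.pheno_mixed, 1.0))
    b_mean = np.where(phen == Phenotype.SECRETION, params.pheno_b_low,
                      np.where(phen == Phenotype.MIXED, params.pheno_mixed, 1.0))
    jit = params.baseline_jitter_sd
    s_base = np.clip(s_mean * np.exp(rng.normal(0.0, jit, m)), 0.05, 1.0)
    b_base = np.clip(b_mean * np.exp(rng.normal(0.0, jit, m)), 0.05, 1.0)
    if scalar:
        return Phenotype(int(phen[0])), float(s_base[0]), float(b_base[0])
    return phen, s_base, b_base


def insulin_sensitivity(bmi, gestational_week=None, s_base=1.0,
                        params: PhysiologyParams | None = None):
    """Insulin sensitivity from BMI, pregnancy stage and individual baseline.

    ``S = clamp(s_base * exp(-k_bmi * max(0, bmi - bmi_ref)) * preg_mult,
    s_min, 1)`` where the pregnancy multiplier ramps linearly from 1 at
    conception to ``1 - rho_preg`` at term. ``gestational_week`` may be
    None, NaN (not pregnant) or an array mixing both.
    """
    params = params or PhysiologyParams()
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("bmi must be > 0")
    pen = np.exp(-params.k_bmi * np.maximum(0.0, bmi - params.bmi_ref))
    if gestational_week is None:
        preg_mult = 1.0
    else:
        w = np.asarray(gestational_week, dtype=float)
        valid = np.isnan(w) | ((w >= 0) & (w <= GESTATION_WEEKS))
        if not np.all(valid):
            raise ValueError("gestational_week must be in [0, 40] or NaN")
        preg_mult = np.where(np.isnan(w), 1.0,
                             1.0 - params.rho_preg * np.nan_to_num(w) / GESTATION_WEEKS)
    S = np.clip(np.asarray(s_base, dtype=float) * pen * preg_mult, params.s_min, 1.0)
    return float(S) if S.ndim == 0 else S


def glycemic_index(S, B, params: PhysiologyParams | None = None):
    """Glycemic index ``G = 1/(S*B)``, capped at ``g_max``.

    ``G = 1`` at full sensitivity and full beta-cell function; complete
    secretory failure (``B = 0``) returns the cap rather than dividing by
    zero.
    """
    params = params or PhysiologyParams()
    S = np.asarray(S, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(S <= 0):
        raise ValueError("S must be > 0")
    with np.errstate(divide="ignore"):
        G = np.where(B > 0, 1.0 / np.maximum(S * B, 1.0 / params.g_max), params.g_max)
    G = np.minimum(G, params.g_max)
    return float(G) if G.ndim == 0 else G


def update_beta_exposure(B, E, G, dt: float, params: PhysiologyParams):
    """Low-level Euler update of (beta-cell function, cumulative exposure).

    Exposure accrues at rate ``max(0, G - g_thr)``; beta cells decay in
    proportion to that excess and regenerate toward 1 only while ``E`` is
    below the reversibility ceiling. Works elementwise on arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    B = np.asarray(B, dtype=float)
    E = np.asarray(E, dtype=float)
    y = np.maximum(0.0, np.asarray(G, dtype=float) - params.g_thr)
    E_new = E + y * dt
    regen = params.r_regen * (1.0 - B) * (E < params.e_rev)
    B_new = np.clip(B + (regen - params.k_decay * y * B) * dt, 0.0, 1.0)
    return B_new, E_new


def step_metabolism(state: MetabolicState, G, dt: float,
                    params: PhysiologyParams | None = None) -> MetabolicState:
    """Advance a metabolic state by ``dt`` years under glycemic index ``G``."""
    params = params or PhysiologyParams()
    B_new, E_new = update_beta_exposure(state.B, state.E, G, dt, params)
    B_new = B_new if np.ndim(B_new) else float(B_new)
    E_new = E_new if np.ndim(E_new) else float(E_new)
    return replace(state, B=B_new, E=E_new)


def bmi_drift(age, params: PhysiologyParams):
    """Age-specific BMI drift (units/year), linear interpolation on the spline."""
    return np.interp(np.asarray(age, dtype=float),
                     params.bmi_drift_ages, params.bmi_drift_rates)


def bmi_step(bmi, age, dt: float, params: PhysiologyParams | None = None,
             rng: np.random.Generator | None = None, drift_mult=1.0,
             delivered=False, gwg_kg=0.0, height_m=1.65):
    """Advance BMI by ``dt`` years.

    Deterministic age drift (optionally amplified for in-utero-exposed
    children via ``drift_mult``) plus the secular trend, Gaussian
    random-walk noise when an ``rng`` is supplied, and a postpartum
    retention jump of ``retention_frac * gwg_kg / height^2`` on delivery.
    """
    params = params or PhysiologyParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("bmi must be > 0")
    out = bmi + (bmi_drift(age, params) * drift_mult + params.bmi_secular) * dt
    if rng is not None and params.bmi_noise_sd > 0:
        out = out + rng.normal(0.0, params.bmi_noise_sd * np.sqrt(dt), bmi.shape or None)
    ret = params.retention_frac * np.asarray(gwg_kg, dtype=float)
    out = out + np.where(delivered, delta_bmi(ret, height_m), 0.0)
    out = np.maximum(out, 10.0)  # physiological floor
    return float(out) if out.ndim == 0 else out


def delta_bmi(weight_change_kg, height_m):
    """BMI-unit change from a weight change: ``kg / height^2``."""
    h = np.asarray(height_m, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height_m must be > 0")
    d = np.asarray(weight_change_kg, dtype=float) / h ** 2
    return float(d) if d.ndim == 0 else d


def classify_glycemic(G, pregnant=False, diagnostic_threshold=None,
                      params: PhysiologyParams | None = None):
    """Classify glycemic state, and screen-positivity when pregnant.

    Returns ``(cls, dip_positive)``: NORMAL below ``g_igr``, IMPAIRED in
    ``[g_igr, g_dm)``, DIABETES at or above ``g_dm`` (upper states are
    inclusive at their lower bound). ``dip_positive`` is None when not
    pregnant, otherwise ``G >= diagnostic_threshold`` (defaulting to
    ``g_gdm``) — the threshold in force may change by calendar year.
    """
    params = params or PhysiologyParams()
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("G must be >= 0")
    cls = np.where(G >= params.g_dm, int(GlycemicClass.DIABETES),
                   np.where(G >= params.g_igr, int(GlycemicClass.IMPAIRED),
                            int(GlycemicClass.NORMAL)))
    if not np.any(pregnant):
        dip = None
    else:
        thr = params.g_gdm if diagnostic_threshold is None else diagnostic_threshold
        dip = np.asarray(pregnant) & (G >= thr)
        if dip.ndim == 0:
            dip = bool(dip)
    if cls.ndim == 0:
        return GlycemicClass(int(cls)), dip
    return cls.astype(np.int8), dip
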
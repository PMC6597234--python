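"""Discrete-event screening, diagnosis and treatment pathways.

Health services are represented as processes, not congested resources: a
pregnancy generates a deterministic pathway of service events (booking,
screening tests, diagnosis, treatment starts, delivery care, postpartum
testing), each occurring at a well-defined gestational week. The
diagnostic test is a threshold on the latent glycemic index whose value
may change by calendar year — the mechanism behind artefactual jumps in
administrative incidence series when a diagnostic standard changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import SCREEN_EARLY, SCREEN_UNIVERSAL, keyed_uniform
from .population_chain import adips_high_risk


class ConfigError(ValueError):
    pass


EVENT_KINDS = ("booking", "early_screen", "ogtt", "diagnosis", "lifestyle_rx",
               "pharmaco_rx", "delivery_care", "postpartum_test")


@dataclass
class ScreeningPolicy:
    """Universal or selective antenatal screening."""

    mode: str = "universal"          # universal | selective
    universal_week: float = 26.0     # gestational week of routine OGTT
    early_week: float = 12.0         # early OGTT for high-risk women (selective)
    participation: float = 0.95      # probability of attending each test

    def validate(self) -> None:
        errs = []
        if self.mode not in ("universal", "selective"):
            errs.append(f"screening.mode must be universal|selective, got {self.mode!r}")
        for name in ("universal_week", "early_week"):
            w = getattr(self, name)
            if not (0 <= w <= 40):
                errs.append(f"screening.{name} must be in [0,40]")
        if not (0 <= self.participation <= 1):
            errs.append("screening.participation must be in [0,1]")
        if errs:
            raise ConfigError("; ".join(errs))


@dataclass
class DiagnosticSchedule:
    """Piecewise-constant diagnostic threshold on G by calendar year."""

    entries: list = field(default_factory=lambda: [(1990, 1.4)])

    def validate(self) -> None:
        years = [y for y, _ in self.entries]
        if not self.entries:
            raise ConfigError("diagnostic schedule is empty")
        if years != sorted(years) or len(set(years)) != len(years):
            raise ConfigError("diagnostic schedule years must be strictly increasing")
        if any(thr <= 1 for _, thr in self.entries):
            raise ConfigError("diagnostic thresholds must be > 1")

    def threshold_for(self, year: float) -> float:
        if year < self.entries[0][0]:
            raise ValueError(f"year {year} precedes first schedule entry "
                             f"({self.entries[0][0]})")
        thr = self.entries[0][1]
        for y, t in self.entries:
            if year >= y:
                thr = t
        return thr


@dataclass
class ServiceEvent:
    time: float
    agent_id: int
    kind: str
    detail: dict = field(default_factory=dict)


def schedule_screening(agent, policy: ScreeningPolicy, seed: int = 0,
                       pregnancy_number: int = 0, t: float = 0.0) -> list[ServiceEvent]:
    """Screening events (by gestational week) for a newly pregnant agent.

    Universal mode books one OGTT at the routine week; selective mode
    adds an early screen iff the agent meets the high-risk criteria. Each
    test is retained with probability ``participation`` using a draw
    keyed to (agent, pregnancy, test) so the same woman's attendance does
    not change when unrelated policy levers move.
    """
    policy.validate()
    events: list[ServiceEvent] = []
    if policy.mode == "selective":
        hr = adips_high_risk(agent.ethnicity_high_risk, max(agent.age(t), 0.0),
                             agent.prior_gdm, agent.family_history, agent.bmi)
        if hr and keyed_uniform(seed, SCREEN_EARLY, agent.id,
                                pregnancy_number) < policy.participation:
            events.append(ServiceEvent(policy.early_week, agent.id, "early_screen",
                                       {"week": policy.early_week}))
    if keyed_uniform(seed, SCREEN_UNIVERSAL, agent.id,
                     pregnancy_number) < policy.participation:
        events.append(ServiceEvent(policy.universal_week, agent.id, "ogtt",
                                   {"week": policy.universal_week}))
    return sorted(events, key=lambda e: (e.time, e.kind))


def ogtt_result(G: float, year: float, schedule: DiagnosticSchedule) -> bool:
    """Deterministic test: positive iff G >= threshold in force (inclusive)."""
    return bool(np.asarray(G) >= schedule.threshold_for(year))


def treatment_effect(weeks_since_diagnosis, m_full: float = 0.8,
                     ramp_weeks: float = 4.0):
    """Multiplier on G after a DIP diagnosis.

    Ramps linearly from 1 at diagnosis to the floor ``m_full`` by
    ``ramp_weeks``, then stays there until delivery. Applied to the
    glycemic index during pregnancy only.
    """
    w = np.asarray(weeks_since_diagnosis, dtype=float)
    if np.any(w < 0):
        raise ValueError("weeks_since_diagnosis must be >= 0")
    mult = 1.0 - (1.0 - m_full) * np.minimum(w / ramp_weeks, 1.0)
    return float(mult) if mult.ndim == 0 else mult


def tally_services(events, unit_costs: dict | None = None) -> pd.DataFrame:
    """Count service events by kind and apply unit costs.

    ``events`` is a DataFrame with a ``kind`` column (the run event log)
    or a list of :class:`ServiceEvent`. Kinds missing from the cost table
    are counted with cost marked unknown (NaN). Tallies are additive over
    concatenated logs.
    """
    unit_costs = unit_costs or {}
    if isinstance(events, pd.DataFrame):
        kinds = events["kind"] if len(events) else pd.Series([], dtype=str)
    else:
        kinds = pd.Series([e.kind for e in events], dtype=str)
    counts = kinds.value_counts()
    rows = []
    for kind in EVENT_KINDS:
        n = int(counts.get(kind, 0))
        cost = unit_costs.get(kind)
        rows.append({"kind": kind, "count": n,
                     "cost": n * cost if cost is not None else np.nan})
    return pd.DataFrame(rows).set_index("kind")
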
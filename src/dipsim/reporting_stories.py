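"""Summary statistics, file outputs and agent life stories.

The event log is the single source of truth for event-derived
statistics: births, diagnoses, incidence fractions, adverse outcomes and
service tallies are all recomputed from it. Annual weight-category
proportions and the age structure come from the year-boundary population
snapshots. Life stories render one agent's logged events as short
chronological prose lines — the communication device used to walk
non-technical audiences through what the model does to an individual.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def annual_summary(event_log: pd.DataFrame, population_snapshots: pd.DataFrame,
                   years=None, costs: dict | None = None) -> pd.DataFrame:
    """Per-calendar-year output series from the event log and snapshots.

    For each year: births (deliveries), DIP-diagnosed births, the DIP
    fraction (NaN — not 0 — when there are no births), subgroup splits by
    high-risk ethnicity and by maternal age 35, adverse-outcome counts,
    weight-category proportions and service counts/costs.
    """
    ev = event_log
    if years is None:
        years = sorted(ev["year"].unique()) if len(ev) else []
    idx = pd.Index(years, name="year")
    out = pd.DataFrame(index=idx)

    dl = ev[ev["kind"] == "delivery_care"] if len(ev) else ev
    births = dl.groupby("year").size() if len(dl) else pd.Series(dtype=float)
    dip = dl[dl["v1"] > 0].groupby("year").size() if len(dl) else pd.Series(dtype=float)
    out["births"] = births.reindex(idx).fillna(0).astype(int)
    out["dip_births"] = dip.reindex(idx).fillna(0).astype(int)
    out["dip_frac"] = np.where(out["births"] > 0,
                               out["dip_births"] / out["births"].replace(0, np.nan),
                               np.nan)
    if len(dl):
        for label, sub in (("highrisk", dl[dl["high_risk"] > 0]),
                           ("standard", dl[dl["high_risk"] <= 0]),
                           ("under35", dl[dl["age"] < 35]),
                           ("over35", dl[dl["age"] >= 35])):
            b = sub.groupby("year").size().reindex(idx).fillna(0).astype(int)
            d = sub[sub["v1"] > 0].groupby("year").size().reindex(idx).fillna(0).astype(int)
            out[f"births_{label}"] = b
            out[f"dip_births_{label}"] = d
            out[f"dip_frac_{label}"] = np.where(b > 0, d / b.replace(0, np.nan), np.nan)
    else:
        for label in ("highrisk", "standard", "under35", "over35"):
            out[f"births_{label}"] = 0
            out[f"dip_births_{label}"] = 0
            out[f"dip_frac_{label}"] = np.nan

    adv = (ev[ev["kind"] == "adverse_outcome"].groupby("year").size()
           if len(ev) else pd.Series(dtype=float))
    out["adverse"] = adv.reindex(idx).fillna(0).astype(int)

    if len(population_snapshots):
        for col in ("prop_healthy", "prop_overweight", "prop_obese",
                    "mean_bmi", "n_agents", "n_women_15_49"):
            if col in population_snapshots.columns:
                out[col] = population_snapshots[col].reindex(idx)
    # service counts and costs
    costs = costs or {}
    from .simulation_engine import SERVICE_KINDS  # late import avoids a cycle
    svc = ev[ev["kind"].isin(SERVICE_KINDS)] if len(ev) else ev
    cost_total = pd.Series(0.0, index=idx)
    for kind in SERVICE_KINDS:
        cnt = (svc[svc["kind"] == kind].groupby("year").size()
               .reindex(idx).fillna(0).astype(int)) if len(svc) else 0
        out[f"svc_{kind}"] = cnt
        if kind in costs:
            cost_total = cost_total + out[f"svc_{kind}"] * costs[kind]
    out["cost_total"] = cost_total
    return out


# ---------------------------------------------------------------------------
# Life stories

@dataclass
class LifeStory:
    agent_id: int
    lines: list = field(default_factory=list)  # (time, age, year, text)

    def text(self) -> str:
        return "\n".join(line for *_, line in self.lines)


_CATEGORY_NAMES = {0: "healthy weight", 1: "overweight", 2: "obese"}


def _load_templates() -> dict:
    ref = importlib.resources.files("dipsim") / "templates" / "life_story.txt"
    templates = {}
    for raw in ref.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, _, tpl = line.partition(":")
        templates[kind.strip()] = tpl.strip()
    return templates


def render_life_story(agent_id: int, event_log: pd.DataFrame,
                      calendar_start_year: float | None = None) -> LifeStory:
    """Render an agent's logged events as chronological narrative lines.

    Every logged event for the agent appears exactly once, in time order.
    Ages are computed from the agent's own birth event when present,
    otherwise reported as unknown.
    """
    ev = event_log[event_log["agent_id"] == agent_id]
    if len(ev) == 0:
        raise KeyError(f"agent {agent_id} does not appear in the event log")
    templates = _load_templates()
    birth_rows = ev[ev["kind"] == "birth"]
    if len(birth_rows):
        birth_t = float(birth_rows["time"].iloc[0])
    else:
        # agents initialised before the simulation have no birth event;
        # recover their birth time from any event that carries an age tag
        aged = ev[np.isfinite(ev["age"])] if "age" in ev.columns else ev.iloc[:0]
        birth_t = (float(aged["time"].iloc[0]) - float(aged["age"].iloc[0])
                   if len(aged) else None)
    story = LifeStory(agent_id=int(agent_id))
    for _, row in ev.iterrows():
        t = float(row["time"])
        year = int(row["year"])
        age = t - birth_t if birth_t is not None else np.nan
        kind = str(row["kind"])
        tpl = templates.get(kind, "{kind} event")
        text = tpl.format(
            kind=kind, age=f"{age:.0f}" if np.isfinite(age) else "?",
            year=year, v1=row["v1"], v2=row["v2"],
            G=f"{row['v1']:.2f}" if np.isfinite(row["v1"]) else "?",
            threshold=f"{row['v2']:.2f}" if np.isfinite(row["v2"]) else "?",
            week=f"{row['v1']:.0f}" if np.isfinite(row["v1"]) else "?",
            category=_CATEGORY_NAMES.get(int(row["v1"]) if np.isfinite(row["v1"]) else -1,
                                         "unknown"),
            bmi=f"{row['v2']:.1f}" if np.isfinite(row["v2"]) else "?",
        )
        story.lines.append((t, age, year, text))
    story.lines.sort(key=lambda x: x[0])
    return story


# ---------------------------------------------------------------------------
# File outputs

def write_outputs(result, out_dir, force: bool = False) -> dict:
    """Write a run's outputs: tidy annual.csv, events.jsonl, config echo,
    report.json. Refuses to overwrite an existing result directory unless
    ``force`` is set. Returns the written paths."""
    out = Path(out_dir)
    marker = out / "report.json"
    if marker.exists() and not force:
        raise FileExistsError(f"{out} already holds a result; pass force=True "
                              "(--force) to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    tidy = (result.annual.reset_index()
            .melt(id_vars="year", var_name="metric", value_name="value"))
    tidy = tidy[~tidy["metric"].isin(["age_hist"])]
    paths["annual"] = out / "annual.csv"
    tidy.to_csv(paths["annual"], index=False)

    paths["events"] = out / "events.jsonl"
    with open(paths["events"], "w") as fh:
        for rec in result.events.to_dict(orient="records"):
            rec["kind"] = str(rec["kind"])
            fh.write(json.dumps(rec, default=float) + "\n")

    paths["config"] = out / "config_echo.yaml"
    result.config.to_yaml(paths["config"])

    ann = result.annual
    report = {
        "seed": result.seed,
        "years": [int(y) for y in ann.index],
        "total_births": int(ann["births"].sum()),
        "total_dip_births": int(ann["dip_births"].sum()),
        "mean_dip_frac": (float(np.nanmean(ann["dip_frac"]))
                          if len(ann) else None),
        "chain_audit": {k: float(v) for k, v in result.chain_audit.items()},
    }
    paths["report"] = out / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2)
    return paths


def read_annual_csv(path) -> pd.DataFrame:
    """Re-read a tidy annual.csv back into the wide annual series."""
    tidy = pd.read_csv(path)
    wide = tidy.pivot(index="year", columns="metric", values="value")
    wide.columns.name = None
    return wide
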
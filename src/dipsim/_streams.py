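"""Counter-based per-agent random streams.

Policy comparisons use common random numbers: a draw that logically
belongs to one agent and one purpose (e.g. "does she attend her booking
OGTT in pregnancy number 2") must not shift when an unrelated policy
lever changes. Each such draw is therefore a pure function of
``(seed, purpose, agent_id, counter)`` via a splitmix64-style integer
hash, vectorisable over agents.
"""

from __future__ import annotations

import numpy as np

# Purpose codes (stable across versions; part of the reproducibility contract).
SCREEN_EARLY = 1
SCREEN_UNIVERSAL = 2
ENROL = 3
ADVERSE = 4
RISK_COUNT_DIP = 5
BABY_SEX = 6

_M = np.uint64(0xFFFFFFFFFFFFFFFF)


def _mix(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & _M
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _M
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _M
        return x ^ (x >> np.uint64(31))


def keyed_uniform(seed: int, purpose: int, agent_ids, counter=0):
    """Uniform(0,1) draws keyed by (seed, purpose, agent, counter)."""
    ids = np.asarray(agent_ids, dtype=np.uint64)
    h = _mix(np.uint64(seed & 0x7FFFFFFF) ^ (np.uint64(purpose) << np.uint64(32)))
    h = _mix(h ^ ids)
    h = _mix(h ^ (np.asarray(counter, dtype=np.uint64) << np.uint64(16)))
    u = (h >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))
    return float(u) if u.ndim == 0 else u


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Deterministic child seed for replicate runs, kept below 2**31."""
    return int(_mix(np.uint64(((master_seed & 0x7FFFFFFF) * 2654435761 + replicate)
                              & 0xFFFFFFFFFFFFFFFF))
               & np.uint64(0x7FFFFFFF))
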
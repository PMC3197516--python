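"""Shared fixtures and independent brute-force oracles.

The grid oracle here paints flow runs onto an integer-millisecond boolean
array — a different construction from both the package's interval algebra
and its built-in selftest oracle — so NFT checks are genuinely dual-route.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from noflow import AllowancePolicy, AnnotatedEvent, EventKind, EventLog

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MS = 1000  # grid cells per second


def paint_grid_nft(
    compressions, window: tuple[float, float], gap_threshold_s: float = 1.5
) -> float:
    """Occupancy-grid NFT: paint each qualifying inter-compression span as flow.

    Times must be millisecond-aligned.  For consecutive compressions with a
    gap at or below the threshold, cells [c_i, c_{i+1}) are flow; everything
    else in the window (leading/trailing silence, long gaps) is no-flow.
    """
    a, b = (round(window[0] * MS), round(window[1] * MS))
    comps = np.round(np.asarray(compressions, dtype=float) * MS).astype(np.int64)
    flow = np.zeros(b - a, dtype=bool)
    for c0, c1 in zip(comps[:-1], comps[1:]):
        if c1 - c0 <= round(gap_threshold_s * MS):
            lo, hi = max(c0, a), min(c1, b)
            if hi > lo:
                flow[lo - a : hi - a] = True
    return float(np.count_nonzero(~flow)) / MS


def make_log(
    compressions=(),
    events=(),
    t_end: float = 300.0,
    scenario_id: str = "test",
    handover: float | None = None,
) -> EventLog:
    """Minimal valid log builder: adds the arrest/terminal (and handover) events."""
    evs = [AnnotatedEvent(0.0, EventKind.ARREST_RECOGNIZED)]
    if handover is not None:
        evs.append(AnnotatedEvent(handover, EventKind.HANDOVER))
    for ev in events:
        evs.append(ev if isinstance(ev, AnnotatedEvent) else AnnotatedEvent(ev[0], ev[1]))
    evs.append(AnnotatedEvent(t_end, EventKind.ROSC))
    evs.sort(key=lambda e: e.time)
    return EventLog(scenario_id, tuple(compressions), tuple(evs), 0.0, t_end)


def metronome(start: float, end: float, dt: float = 0.5) -> np.ndarray:
    """Compressions every dt seconds over [start, end], inclusive of both ends."""
    c = np.arange(start, end, dt)
    if c.size == 0 or end - c[-1] > 1e-12:
        c = np.append(c, end)
    return np.round(c, 3)


@pytest.fixture
def policy() -> AllowancePolicy:
    return AllowancePolicy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20111006)
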
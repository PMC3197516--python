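"""Built-in oracle suites runnable on any install (`noflow selftest`).

Each check recomputes a quantity by an independent brute-force route and
compares it with the pipeline's answer: a millisecond occupancy grid for
no-flow time, exhaustive label enumeration for the Mann–Whitney p, and the
closed-form allowance credits for the 5/10/10-per-cycle policy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .events import AnnotatedEvent, EventKind, EventLog
from .metrics import AllowancePolicy, allowance_credit, no_flow_time
from .stats import mann_whitney_exact

__all__ = ["SelfTestFailure", "run_selftest", "grid_nft", "random_log"]


class SelfTestFailure(AssertionError):
    """A named oracle property failed."""


def grid_nft(
    compressions: np.ndarray,
    window: tuple[float, float],
    gap_threshold_s: float = 1.5,
    grid_s: float = 0.001,
) -> float:
    """Brute-force NFT: count no-flow points of a fixed occupancy grid.

    Works in integer grid units (inputs are rounded onto the grid, so give it
    grid-aligned times).  A grid point t is in flow iff consecutive
    compressions c_i <= t < c_{i+1} exist with gap at most the threshold —
    the same half-open convention the interval algebra uses, but evaluated
    pointwise and independently of any interval merging.
    """
    a, b = window
    scale = 1.0 / grid_s
    comps = np.round(np.asarray(compressions, dtype=float) * scale).astype(np.int64)
    a_i, b_i = round(a * scale), round(b * scale)
    thr = round(gap_threshold_s * scale)
    if comps.size < 2:
        return (b_i - a_i) * grid_s
    t = np.arange(a_i, b_i, dtype=np.int64)
    idx = np.searchsorted(comps, t, side="right")
    inside = (idx > 0) & (idx < comps.size)
    flow = np.zeros(t.size, dtype=bool)
    ii = idx[inside]
    flow[inside] = (comps[ii] - comps[ii - 1]) <= thr
    return float(np.count_nonzero(~flow)) * grid_s


def random_log(rng: np.random.Generator, duration_s: float = 120.0) -> EventLog:
    """A small random scenario: compression bursts separated by random pauses.

    Times are millisecond-aligned so the grid oracle is exact; pauses span
    both sides of the 1.5 s flow threshold.
    """
    duration_s = round(duration_s, 3)
    t = float(rng.uniform(0, 15))
    comps: list[float] = []
    while t < duration_s:
        run = rng.uniform(5, 40)
        dt = 60.0 / rng.uniform(90, 130)
        end = min(duration_s, t + run)
        comps.extend(np.arange(t, end, dt).tolist())
        t = end + rng.uniform(0.2, 20)  # pauses straddle the flow threshold
    comps = np.round(np.asarray(comps), 3).tolist()
    events = (
        AnnotatedEvent(0.0, EventKind.ARREST_RECOGNIZED),
        AnnotatedEvent(duration_s, EventKind.SCENARIO_END),
    )
    return EventLog("selftest", tuple(comps), events, 0.0, duration_s)


def _closed_form_log(with_shocks: bool) -> EventLog:
    """360 s, no compressions at all; optionally one shock per 120 s cycle."""
    events = [AnnotatedEvent(0.0, EventKind.ARREST_RECOGNIZED)]
    if with_shocks:
        for t in (30.0, 150.0, 270.0):
            events.append(AnnotatedEvent(t, EventKind.SHOCK))
    events.append(AnnotatedEvent(360.0, EventKind.ROSC))
    return EventLog("closed-form", (), tuple(events), 0.0, 360.0)


def run_selftest(
    n_grid_logs: int = 50,
    n_utest_cases: int = 30,
    seed: int = 2011,
    perturb_allowance: bool = False,
) -> list[str]:
    """Run every oracle suite; returns the list of passed check names.

    ``perturb_allowance`` injects a deliberate +1 s overcharge into the
    allowance ledger before checking it — a sensitivity hook that must make
    the ledger check fail.
    """
    rng = np.random.default_rng(seed)
    passed: list[str] = []

    # 1. NFT vs millisecond occupancy grid
    policy = AllowancePolicy()
    for _ in range(n_grid_logs):
        log = random_log(rng, duration_s=float(rng.uniform(40, 150)))
        nft = no_flow_time(log, policy)
        oracle = grid_nft(log.compression_array(), (log.t0, log.t_end), policy.gap_threshold_s)
        if abs(nft - oracle) > 0.001 + 1e-9:
            raise SelfTestFailure(
                f"grid_oracle: NFT {nft:.4f} vs grid {oracle:.4f} on {log.scenario_id}"
            )
    passed.append("grid_oracle")

    # 2. exact Mann–Whitney vs exhaustive enumeration
    for _ in range(n_utest_cases):
        n1, n2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        x = rng.normal(size=n1).round(1)  # rounding forces occasional ties
        y = rng.normal(size=n2).round(1)
        res = mann_whitney_exact(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        us = [
            sum(ranks[i] for i in c) - offset
            for c in itertools.combinations(range(n1 + n2), n1)
        ]
        lo = np.mean([u <= res.u_statistic + 1e-9 for u in us])
        hi = np.mean([u >= res.u_statistic - 1e-9 for u in us])
        p_ref = min(1.0, 2.0 * min(lo, hi))
        if abs(res.p_two_sided - p_ref) > 1e-12:
            raise SelfTestFailure(
                f"exhaustive_utest: p {res.p_two_sided} vs enumeration {p_ref} "
                f"(n1={n1}, n2={n2})"
            )
    passed.append("exhaustive_utest")

    # 3. allowance ledger closed forms and the credit <= NFT bound
    for with_shocks, expect in ((True, 75.0), (False, 45.0)):
        log = _closed_form_log(with_shocks)
        credited, ledger = allowance_credit(log, policy)
        if perturb_allowance:
            credited += 1.0  # deliberate overcharge: the next check must fail
        nft = no_flow_time(log, policy)
        if credited > nft + 1e-9:
            raise SelfTestFailure(f"allowance_ledger: credit {credited} exceeds NFT {nft}")
        if abs(credited - expect) > 1e-9:
            raise SelfTestFailure(
                f"allowance_ledger: credited {credited} != closed form {expect} "
                f"(shocks={with_shocks})"
            )
    passed.append("allowance_ledger")
    return passed
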
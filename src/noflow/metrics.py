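"""No-flow interval algebra and per-scenario CPR quality metrics.

The central quantities are no-flow time (NFT) — the total time inside an
analysis window during which no chest compressions are delivered — and the
no-flow ratio NFR = NFT / window duration (the complement of the
chest-compression fraction).  Guideline-sanctioned pauses (rhythm analysis,
shock delivery, pulse checks) are credited against NFT up to per-cycle caps
to form the adjusted variants NFT_adj and NFR_adj, which would be zero for
guideline-perfect performance.

Flow detection: a gap between consecutive compressions counts wholly as flow
when it does not exceed ``gap_threshold_s`` (default 1.5 s, the conventional
interruption threshold in CPR research) and wholly as no-flow otherwise;
leading and trailing silences are always no-flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .events import EventKind, EventLog, Phase, derive_phases, validate

__all__ = [
    "IntervalSet",
    "AllowancePolicy",
    "CreditRecord",
    "PhaseMetrics",
    "TimeMarkers",
    "ScenarioMetrics",
    "flow_intervals",
    "no_flow_intervals",
    "no_flow_time",
    "no_flow_ratio",
    "allowance_credit",
    "adjusted_metrics",
    "compression_rates",
    "segment_profile",
    "time_markers",
    "scenario_metrics",
]


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalSet:
    """Sorted, pairwise-disjoint half-open intervals [start, end) in seconds."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if not b > a:
                raise ValueError(f"degenerate interval [{a}, {b})")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError(f"intervals overlap or unsorted: [{a0},{b0}) then [{a1},{b1})")
        object.__setattr__(self, "intervals", ivs)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "IntervalSet":
        """Build from arbitrary pairs: sorts, drops empties, merges overlaps."""
        cleaned = sorted((float(a), float(b)) for a, b in pairs if b > a)
        merged: list[list[float]] = []
        for a, b in cleaned:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return cls(tuple((a, b) for a, b in merged))

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def clip(self, start: float, end: float) -> "IntervalSet":
        """Intersection with the half-open window [start, end)."""
        out = [
            (max(a, start), min(b, end))
            for a, b in self.intervals
            if min(b, end) > max(a, start)
        ]
        return IntervalSet(tuple(out))

    def complement(self, start: float, end: float) -> "IntervalSet":
        """The part of [start, end) not covered by this set."""
        out: list[tuple[float, float]] = []
        cursor = start
        for a, b in self.clip(start, end).intervals:
            if a > cursor:
                out.append((cursor, a))
            cursor = max(cursor, b)
        if cursor < end:
            out.append((cursor, end))
        return IntervalSet(tuple(out))

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class AllowancePolicy:
    """Per-2-minute-cycle pause budget and flow-detection threshold.

    Defaults follow the ALS-guideline reading used throughout: per 120 s
    cycle at most 5 s for rhythm analysis, 10 s to charge and deliver a shock
    (only when a shock is actually delivered), and 10 s for a pulse check.
    """

    rhythm_analysis_s: float = 5.0
    shock_s: float = 10.0
    pulse_check_s: float = 10.0
    cycle_s: float = 120.0
    gap_threshold_s: float = 1.5

    def __post_init__(self) -> None:
        for name in ("rhythm_analysis_s", "shock_s", "pulse_check_s", "cycle_s", "gap_threshold_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rhythm_analysis_s", "shock_s", "pulse_check_s"):
            if getattr(self, name) > self.cycle_s:
                raise ValueError(f"{name} exceeds cycle_s")


def _check_window(log: EventLog, window: tuple[float, float] | None) -> tuple[float, float]:
    if window is None:
        return (log.t0, log.t_end)
    a, b = float(window[0]), float(window[1])
    if not b > a:
        raise ValueError(f"empty or inverted window [{a}, {b})")
    if a < log.t0 or b > log.t_end:
        raise ValueError(f"window [{a}, {b}) outside log span [{log.t0}, {log.t_end})")
    return (a, b)


def flow_intervals(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    window: tuple[float, float] | None = None,
) -> IntervalSet:
    """Intervals inside ``window`` during which compressions are flowing.

    Runs of compressions whose inter-compression gaps are all at or below the
    policy gap threshold form flow runs spanning first-to-last compression;
    runs are computed on the whole log and clipped to the window, so a run
    crossing a phase boundary contributes flow to both phases.
    """
    a, b = _check_window(log, window)
    comps = log.compression_array()
    if comps.size == 0:
        return IntervalSet(())
    gaps = np.diff(comps)
    # epsilon keeps a gap of exactly gap_threshold_s classified as flow even
    # when the subtraction lands a few ulp above the threshold
    breaks = np.flatnonzero(gaps > policy.gap_threshold_s + 1e-9)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [comps.size - 1]))
    pairs = [(comps[i], comps[j]) for i, j in zip(starts, ends) if comps[j] > comps[i]]
    return IntervalSet.from_pairs(pairs).clip(a, b)


def no_flow_intervals(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    window: tuple[float, float] | None = None,
) -> IntervalSet:
    """The complement of :func:`flow_intervals` within the window."""
    a, b = _check_window(log, window)
    return flow_intervals(log, policy, (a, b)).complement(a, b)


def no_flow_time(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    window: tuple[float, float] | None = None,
) -> float:
    """NFT: seconds without chest compressions inside the window."""
    a, b = _check_window(log, window)
    nft = (b - a) - flow_intervals(log, policy, (a, b)).total_duration
    return max(0.0, nft)


def no_flow_ratio(nft: float, window_duration: float) -> float:
    """NFR = NFT / window duration, in [0, 1]."""
    if window_duration <= 0:
        raise ValueError(f"window duration must be positive, got {window_duration}")
    if not 0 <= nft <= window_duration + 1e-9:
        raise ValueError(f"nft {nft} outside [0, {window_duration}]")
    return min(1.0, nft / window_duration)


# ---------------------------------------------------------------------------
# Allowance crediting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CreditRecord:
    """One granted pause credit: which cycle, which kind, where, how much."""

    cycle_index: int
    kind: str  # "pulse_check", "rhythm_analysis" or "shock"
    time: float  # attribution time (event time, or cycle midpoint for scheduled credits)
    amount: float
    scheduled: bool  # True when granted by the schedule fallback, not an annotated event


def allowance_credit(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    window: tuple[float, float] | None = None,
    mode: str = "auto",
) -> tuple[float, list[CreditRecord]]:
    """Guideline-pause credit against NFT inside ``window``.

    The timeline is partitioned into consecutive cycles of ``policy.cycle_s``
    anchored at t0.  Within each cycle at most one pulse-check credit
    (≤ pulse_check_s), one rhythm-analysis credit (≤ rhythm_analysis_s) and —
    only when a shock event occurs in the cycle — one shock credit
    (≤ shock_s) are granted, each limited by the no-flow time still
    uncredited in that cycle, so total credit can never exceed actual NFT.

    ``mode`` controls how pulse/rhythm credits are located:

    - ``"auto"`` (default): a cycle containing an annotated pulse_check /
      rhythm_check event attaches the credit to that event; a cycle without
      one still receives the scheduled cap (the guideline allows the pause
      every cycle whether or not it was annotated).
    - ``"event"``: credits are granted only in cycles containing the
      annotated event.
    - ``"schedule"``: annotated events are ignored; every cycle receives the
      scheduled caps.

    Shock credit requires an annotated shock event in every mode ("when
    appropriate").  Returns total credited seconds within the window and the
    per-credit ledger (records whose attribution time falls in the window).
    """
    if mode not in ("auto", "event", "schedule"):
        raise ValueError(f"unknown mode {mode!r}")
    a, b = _check_window(log, window)
    nf_global = no_flow_intervals(log, policy, (log.t0, log.t_end))

    def nf_in(lo: float, hi: float) -> float:
        return nf_global.clip(lo, hi).total_duration

    n_cycles = int(math.ceil((log.t_end - log.t0) / policy.cycle_s))
    ledger: list[CreditRecord] = []
    for k in range(n_cycles):
        c_lo = log.t0 + k * policy.cycle_s
        c_hi = min(log.t_end, c_lo + policy.cycle_s)
        avail = nf_in(c_lo, c_hi)
        mid = 0.5 * (c_lo + c_hi)

        def events_in(kind: EventKind) -> list:
            return [e for e in log.events if e.kind is kind and c_lo <= e.time < c_hi]

        for kind_label, cap, ev_kind in (
            ("pulse_check", policy.pulse_check_s, EventKind.PULSE_CHECK),
            ("rhythm_analysis", policy.rhythm_analysis_s, EventKind.RHYTHM_CHECK),
            ("shock", policy.shock_s, EventKind.SHOCK),
        ):
            evs = [] if mode == "schedule" and kind_label != "shock" else events_in(ev_kind)
            if kind_label == "shock":
                grant, t_attr, scheduled = bool(evs), (evs[0].time if evs else mid), False
            elif evs and mode in ("auto", "event"):
                grant, t_attr, scheduled = True, evs[0].time, False
            elif mode in ("auto", "schedule"):
                grant, t_attr, scheduled = True, mid, True
            else:  # mode == "event", no annotated event in this cycle
                grant, t_attr, scheduled = False, mid, True
            if not grant:
                continue
            amount = min(cap, avail)
            if amount <= 0:
                continue
            avail -= amount
            ledger.append(CreditRecord(k, kind_label, t_attr, amount, scheduled))

    in_window = [r for r in ledger if a <= r.time < b]
    credited = sum(r.amount for r in in_window)
    # attribution can place a cycle's credit in a window holding less of the
    # cycle's no-flow than the credit; clamp so nft_adj stays nonnegative
    nft_window = nf_in(a, b)
    if credited > nft_window:
        scale = nft_window / credited if credited > 0 else 0.0
        in_window = [
            CreditRecord(r.cycle_index, r.kind, r.time, r.amount * scale, r.scheduled)
            for r in in_window
        ]
        credited = nft_window
    return float(credited), in_window


def adjusted_metrics(nft: float, credited: float, window_duration: float) -> tuple[float, float]:
    """NFT_adj = NFT − credit and NFR_adj = NFT_adj / duration.

    NFT_adj is the pause time beyond what the guidelines sanction — the
    avoidable no-flow — and would ideally be zero.
    """
    if credited > nft + 1e-9:
        raise ValueError(f"credited ({credited}) exceeds nft ({nft}): ledger bug")
    nft_adj = max(0.0, nft - credited)
    return nft_adj, no_flow_ratio(nft_adj, window_duration)


# ---------------------------------------------------------------------------
# Rates, segments, markers
# ---------------------------------------------------------------------------

def compression_rates(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(rate while compressing, compressions delivered per elapsed minute).

    The first is the median instantaneous rate 60/gap over consecutive
    compression pairs with gap at or below the flow threshold (0 if fewer
    than two such pairs); the second is the raw count divided by the window
    duration in minutes.  During uninterrupted CPR the two coincide; pauses
    depress only the delivered rate.
    """
    a, b = _check_window(log, window)
    comps = log.compression_array()
    comps = comps[(comps >= a) & (comps < b)]
    delivered = comps.size / ((b - a) / 60.0)
    if comps.size < 2:
        return 0.0, float(delivered)
    gaps = np.diff(comps)
    good = gaps[(gaps > 0) & (gaps <= policy.gap_threshold_s + 1e-9)]
    rate = float(np.median(60.0 / good)) if good.size >= 2 else 0.0
    return rate, float(delivered)


def segment_profile(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    segment_s: float = 30.0,
    window: tuple[float, float] | None = None,
) -> list[tuple[tuple[float, float], float]]:
    """NFT per consecutive ``segment_s`` segment from t0.

    The final partial segment keeps its true length; segment NFTs sum to the
    window's overall NFT.
    """
    if segment_s <= 0:
        raise ValueError("segment_s must be > 0")
    a, b = _check_window(log, window)
    flow = flow_intervals(log, policy, (a, b))
    out = []
    lo = a
    while lo < b:
        hi = min(b, lo + segment_s)
        nft = (hi - lo) - flow.clip(lo, hi).total_duration
        out.append(((lo, hi), max(0.0, nft)))
        lo = hi
    return out


@dataclass(frozen=True)
class TimeMarkers:
    """Time-to-event markers in seconds from t0; None when not observed."""

    time_to_cpr_s: float | None
    time_to_defib_arrival_s: float | None
    time_to_first_rhythm_s: float | None


def time_markers(log: EventLog) -> TimeMarkers:
    """Time to first CPR, defibrillator arrival, and first rhythm on scope.

    Time to CPR comes from a cpr_started event when present, otherwise from
    the first compression; missing markers are reported as None, never 0.
    """
    validate(log)

    def t_of(kind: EventKind) -> float | None:
        ev = log.first_event(kind)
        return ev.time - log.t0 if ev else None

    t_cpr = t_of(EventKind.CPR_STARTED)
    if t_cpr is None and log.compressions:
        t_cpr = log.compressions[0] - log.t0
    return TimeMarkers(
        time_to_cpr_s=t_cpr,
        time_to_defib_arrival_s=t_of(EventKind.DEFIB_ARRIVAL),
        time_to_first_rhythm_s=t_of(EventKind.FIRST_RHYTHM),
    )


# ---------------------------------------------------------------------------
# Per-scenario rollup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseMetrics:
    """All flow metrics for one phase window."""

    label: str
    duration_s: float
    nft_s: float
    nfr: float
    nft_adj_s: float
    nfr_adj: float
    compression_rate_cpm: float
    delivered_cpm: float


@dataclass(frozen=True)
class ScenarioMetrics:
    """Every per-scenario output: per-phase metrics, markers, 30 s segments."""

    scenario_id: str
    phases: dict[str, PhaseMetrics]
    markers: TimeMarkers
    segments: list[tuple[tuple[float, float], float]] = field(repr=False)

    @property
    def overall(self) -> PhaseMetrics:
        return self.phases["overall"]

    def phase_value(self, phase: str, metric: str) -> float:
        if phase not in self.phases:
            raise KeyError(f"{self.scenario_id}: phase {phase!r} not present")
        return getattr(self.phases[phase], metric)


def scenario_metrics(
    log: EventLog,
    policy: AllowancePolicy = AllowancePolicy(),
    credit_mode: str = "auto",
    segment_s: float = 30.0,
) -> ScenarioMetrics:
    """Compute the full metric set for one scenario.

    Phase NFTs add up to the overall NFT because flow runs are clipped at
    the handover boundary, and per-phase credits come from one global ledger
    filtered by attribution time.
    """
    validate(log)
    phase_metrics: dict[str, PhaseMetrics] = {}
    for phase in derive_phases(log):
        w = phase.window
        nft = no_flow_time(log, policy, w)
        credited, _ = allowance_credit(log, policy, w, mode=credit_mode)
        nft_adj, nfr_adj = adjusted_metrics(nft, credited, phase.duration)
        rate, delivered = compression_rates(log, policy, w)
        phase_metrics[phase.label] = PhaseMetrics(
            label=phase.label,
            duration_s=phase.duration,
            nft_s=nft,
            nfr=no_flow_ratio(nft, phase.duration),
            nft_adj_s=nft_adj,
            nfr_adj=nfr_adj,
            compression_rate_cpm=rate,
            delivered_cpm=delivered,
        )
    return ScenarioMetrics(
        scenario_id=log.scenario_id,
        phases=phase_metrics,
        markers=time_markers(log),
        segments=segment_profile(log, policy, segment_s),
    )
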
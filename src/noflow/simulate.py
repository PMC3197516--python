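"""Synthetic in-hospital cardiac-arrest scenario generator.

Emulates unannounced in-situ simulated arrests: a first-responder phase
(recognition of arrest, a delay to the first compression, basic CPR with
unannotated interruptions) followed, at handover, by a cardiac-arrest-team
phase organized in ~2-minute ALS cycles, each containing a rhythm-analysis
pause, a pulse-check pause and — while the rhythm is shockable — a shock
delivered inside its own pause.  Defibrillator arrival and first-rhythm
markers are drawn from their own timing distributions.

Timing distributions default to lognormals calibrated to published cohort
quartiles (time to CPR 29 s [22–46], defibrillator arrival / handover
214 s [180–254], first rhythm 311 s [283–349]); per-phase no-flow-ratio
targets default to scaled Beta distributions calibrated to median/IQR
(first responders 0.39 [0.32–0.46], team 0.25 [0.19–0.29]).  Each scenario's
pause schedule is built constructively so the realized phase NFRs hit the
drawn targets to within ±0.01, and every draw is recorded as ground truth
for parameter-recovery testing.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .events import AnnotatedEvent, EventKind, EventLog, validate, write_event_log

__all__ = [
    "LogNormal",
    "BetaQuartiles",
    "Normal",
    "TruncGamma",
    "Fixed",
    "GeneratorConfig",
    "GroundTruth",
    "InfeasibleScenario",
    "generate_scenario",
    "generate_cohort",
    "write_cohort",
    "dist_from_spec",
]

_Z75 = sps.norm.ppf(0.75)  # 0.6744897…

#: shortest pause the flow detector can register (> gap threshold, with margin)
MIN_PAUSE_S = 2.0
#: shortest compression run separating two pauses
MIN_RUN_S = 2.0


class InfeasibleScenario(RuntimeError):
    """Raised when drawn parameters cannot be realized as a valid timeline."""


# ---------------------------------------------------------------------------
# Distribution specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormal:
    """Lognormal parameterized by its median and log-scale sigma."""

    median_s: float
    sigma: float

    @classmethod
    def from_quartiles(cls, q25: float, median: float, q75: float) -> "LogNormal":
        sigma = math.log(q75 / q25) / (2 * _Z75)
        return cls(median, sigma)

    @property
    def median(self) -> float:
        return self.median_s

    def draw(self, rng: np.random.Generator) -> float:
        return float(self.median_s * math.exp(self.sigma * rng.standard_normal()))


@lru_cache(maxsize=64)
def _fit_scaled_beta(q25: float, q50: float, q75: float) -> tuple[float, float, float, float]:
    """Fit a Beta(a, b) scaled onto [lo, hi] ⊂ [0, 1] hitting three quartiles.

    Four parameters against three quantile constraints: the quartiles are
    matched (essentially) exactly and the leftover freedom settles on a
    support of moderate width.  Returns (a, b, lo, hi).
    """

    def unpack(x: np.ndarray) -> tuple[float, float, float, float]:
        a, b = np.exp(x[0]), np.exp(x[1])
        lo = q25 / (1.0 + np.exp(-x[2]))  # lo in (0, q25)
        hi = q75 + (1.0 - q75) / (1.0 + np.exp(-x[3]))  # hi in (q75, 1)
        return a, b, lo, hi

    def residual(x: np.ndarray) -> np.ndarray:
        a, b, lo, hi = unpack(x)
        q = lo + (hi - lo) * sps.beta.ppf([0.25, 0.5, 0.75], a, b)
        return q - np.array([q25, q50, q75])

    x0 = np.array([np.log(3.0), np.log(3.0), 0.0, 0.0])
    sol = optimize.least_squares(residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a, b, lo, hi = unpack(sol.x)
    if max(abs(residual(sol.x))) > 1e-6:
        raise ValueError(f"could not calibrate a scaled Beta to quartiles {(q25, q50, q75)}")
    return float(a), float(b), float(lo), float(hi)


@dataclass(frozen=True)
class BetaQuartiles:
    """Scaled Beta on (0, 1) calibrated to printed cohort quartiles.

    The variate is lo + (hi − lo)·Beta(a, b) with all four parameters solved
    so the 25th/50th/75th percentiles equal the given values.
    """

    q25: float
    median_v: float
    q75: float

    def __post_init__(self) -> None:
        if not 0 < self.q25 < self.median_v < self.q75 < 1:
            raise ValueError("quartiles must satisfy 0 < q25 < median < q75 < 1")

    @property
    def median(self) -> float:
        return self.median_v

    @property
    def params(self) -> tuple[float, float, float, float]:
        return _fit_scaled_beta(self.q25, self.median_v, self.q75)

    def draw(self, rng: np.random.Generator) -> float:
        a, b, lo, hi = self.params
        return float(lo + (hi - lo) * rng.beta(a, b))


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    @property
    def median(self) -> float:
        return self.mean

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mean, self.sd))


@dataclass(frozen=True)
class TruncGamma:
    """Gamma with given mean and shape, rejection-truncated to [lo, hi]."""

    mean: float
    shape_k: float = 4.0
    lo: float = MIN_PAUSE_S
    hi: float = 40.0

    @property
    def median(self) -> float:
        return float(sps.gamma.ppf(0.5, self.shape_k, scale=self.mean / self.shape_k))

    def draw(self, rng: np.random.Generator) -> float:
        scale = self.mean / self.shape_k
        for _ in range(1000):
            x = float(rng.gamma(self.shape_k, scale))
            if self.lo <= x <= self.hi:
                return x
        return float(np.clip(x, self.lo, self.hi))


@dataclass(frozen=True)
class Fixed:
    value: float

    @property
    def median(self) -> float:
        return self.value

    def draw(self, rng: np.random.Generator) -> float:
        return self.value


def dist_from_spec(spec) -> object:
    """Build a distribution from a plain-text config entry.

    Accepts a bare number (Fixed) or a mapping with a ``family`` key:
    ``lognormal`` (median + sigma, or q25/median/q75), ``beta_quartiles``
    (q25/median/q75), ``normal`` (mean/sd), ``gamma`` (mean, shape, lo, hi),
    ``fixed`` (value).
    """
    if isinstance(spec, (int, float)):
        return Fixed(float(spec))
    if hasattr(spec, "draw"):
        return spec
    family = spec["family"]
    if family == "lognormal":
        if "sigma" in spec:
            return LogNormal(spec["median"], spec["sigma"])
        return LogNormal.from_quartiles(spec["q25"], spec["median"], spec["q75"])
    if family == "beta_quartiles":
        return BetaQuartiles(spec["q25"], spec["median"], spec["q75"])
    if family == "normal":
        return Normal(spec["mean"], spec["sd"])
    if family == "gamma":
        return TruncGamma(
            spec["mean"],
            spec.get("shape", 4.0),
            spec.get("lo", MIN_PAUSE_S),
            spec.get("hi", 40.0),
        )
    if family == "fixed":
        return Fixed(spec["value"])
    raise ValueError(f"unknown distribution family {family!r}")


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort size, seed and the per-quantity sampling distributions."""

    n_scenarios: int = 13
    seed: int = 0
    arrest_duration_s: object = LogNormal(600.0, 0.15)
    time_to_cpr_s: object = LogNormal.from_quartiles(22, 29, 46)
    handover_time_s: object = LogNormal.from_quartiles(180, 214, 254)
    defib_arrival_s: object = LogNormal.from_quartiles(180, 214, 254)
    first_rhythm_s: object = LogNormal.from_quartiles(283, 311, 349)
    responder_nfr_target: object = BetaQuartiles(0.32, 0.39, 0.46)
    team_nfr_target: object = BetaQuartiles(0.19, 0.25, 0.29)
    compression_rate_cpm: object = Normal(117.0, 5.0)
    pause_length_s: object = TruncGamma(8.0)
    shockable_prob: float = 0.5
    conversion_prob: float = 0.3
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_scenarios < 0:
            raise ValueError("n_scenarios must be >= 0")
        if not 0 <= self.shockable_prob <= 1 or not 0 <= self.conversion_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for name in (
            "arrest_duration_s", "time_to_cpr_s", "handover_time_s", "defib_arrival_s",
            "first_rhythm_s", "responder_nfr_target", "team_nfr_target",
            "compression_rate_cpm", "pause_length_s",
        ):
            object.__setattr__(self, name, dist_from_spec(getattr(self, name)))

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorConfig":
        return cls(**payload)


@dataclass(frozen=True)
class GroundTruth:
    """Everything drawn while generating one scenario, recorded exactly."""

    scenario_id: str
    duration_s: float
    time_to_cpr_s: float  # realized time of first compression
    handover_s: float
    defib_arrival_s: float
    first_rhythm_s: float
    responder_nfr_target: float
    team_nfr_target: float
    compression_rate_cpm: float
    rhythm_sequence: tuple[str, ...]  # per ALS cycle, "VF" or "PEA"
    pause_schedule: tuple[tuple[float, float, str], ...]  # (start, length, kind)
    n_shocks: int


# ---------------------------------------------------------------------------
# Timeline construction
# ---------------------------------------------------------------------------

def _scale_to_total(lengths: list[float], total: float, floor: float) -> list[float]:
    """Rescale pause lengths to sum to ``total``, dropping until all ≥ floor."""
    lengths = list(lengths)
    while lengths:
        s = sum(lengths)
        scaled = [x * total / s for x in lengths]
        if min(scaled) >= floor or len(scaled) == 1:
            return scaled
        lengths.pop(int(np.argmin(scaled)))
    return []


def _draw_pause_set(rng: np.random.Generator, dist, total: float) -> list[float]:
    """Pause lengths from ``dist`` rescaled to sum exactly to ``total``."""
    if total < MIN_PAUSE_S:
        return []
    lengths: list[float] = []
    while sum(lengths) < total and len(lengths) < 500:
        lengths.append(dist.draw(rng))
    return _scale_to_total(lengths, total, MIN_PAUSE_S)


def _layout(
    rng: np.random.Generator, lo: float, hi: float, lengths: Sequence[float]
) -> list[tuple[float, float]]:
    """Place pauses of the given lengths inside [lo, hi] with runs between.

    The span begins and ends with a compression run of at least MIN_RUN_S;
    returns (start, length) pairs in order.
    """
    span = hi - lo
    n_runs = len(lengths) + 1
    free = span - sum(lengths)
    if free < n_runs * MIN_RUN_S:
        raise InfeasibleScenario(
            f"pauses totalling {sum(lengths):.1f}s do not fit in a {span:.1f}s span"
        )
    runs = MIN_RUN_S + rng.dirichlet(np.ones(n_runs)) * (free - n_runs * MIN_RUN_S)
    out = []
    cursor = lo
    for run, length in zip(runs, lengths):
        cursor += run
        out.append((cursor, float(length)))
        cursor += length
    return out


def _build_team_pauses(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    h: float,
    t_end: float,
    team_target: float,
) -> tuple[list[tuple[float, float, str]], list[str], int]:
    """Pause schedule for the team phase: ALS cycles hitting the NFR target.

    Per full cycle the structural pauses are a rhythm analysis (3–5 s), a
    pulse check (6–10 s) and, in shockable cycles, a shock pause (6–10 s);
    an unannotated extra pause absorbs the difference between the cycle's
    no-flow budget and the structural total (or the structural pauses are
    shrunk when the budget is below it).
    """
    # cycle windows and their no-flow budgets; merge sub-resolvable budgets
    # into a neighbour so the realized total matches the target
    bounds: list[tuple[float, float]] = []
    lo = h
    while lo < t_end - 1e-9:
        hi = min(t_end, lo + 120.0)
        bounds.append((lo, hi))
        lo = hi
    budgets = [team_target * (b - a) for a, b in bounds]
    for i in range(len(budgets) - 1):
        if 0 < budgets[i] < MIN_PAUSE_S:
            budgets[i + 1] += budgets[i]
            budgets[i] = 0.0
    if len(budgets) > 1 and 0 < budgets[-1] < MIN_PAUSE_S:
        budgets[-2] += budgets[-1]
        budgets[-1] = 0.0
    # anything still below resolution is dropped (only when the target NFR is
    # itself below what a >gap-threshold pause can express)
    budgets = [b if b >= MIN_PAUSE_S else 0.0 for b in budgets]

    pauses: list[tuple[float, float, str]] = []
    rhythms: list[str] = []
    n_shocks = 0
    shockable = bool(rng.random() < cfg.shockable_prob)
    priority = {"rhythm_check": 0, "pulse_check": 1, "shock": 2, "extra": 3}
    for (cycle_lo, cycle_hi), budget in zip(bounds, budgets):
        cs = cycle_hi - cycle_lo
        entries: list[tuple[str, float]] = []
        if cs >= 45.0 and budget > 0:  # room for a structured ALS cycle
            rhythms.append("VF" if shockable else "PEA")
            entries.append(("rhythm_check", rng.uniform(3.0, 5.0)))
            if shockable:
                entries.append(("shock", rng.uniform(6.0, 10.0)))
            entries.append(("pulse_check", rng.uniform(6.0, 10.0)))
            if shockable and rng.random() < cfg.conversion_prob:
                shockable = False
        if budget <= 0:
            continue
        structural = sum(l for _, l in entries)
        if budget >= structural + MIN_PAUSE_S:
            lengths = _draw_pause_set(rng, cfg.pause_length_s, budget - structural)
            entries.extend(("extra", l) for l in lengths)
            short = (budget - structural) - sum(lengths)
            if short > 1e-9:  # residue too small for its own pause
                kind, l = entries[-1]
                entries[-1] = (kind, l + short)
        elif budget >= structural > 0:
            kind, l = entries[-1]
            entries[-1] = (kind, l + (budget - structural))
        elif structural > 0:
            # budget below the structural total: shrink, dropping the
            # lowest-priority pauses until every kept pause stays >= MIN_PAUSE_S
            ordered = sorted(entries, key=lambda e: priority[e[0]])
            for m in range(len(ordered), 0, -1):
                kept = ordered[:m]
                s = sum(l for _, l in kept)
                scaled = [l * budget / s for _, l in kept]
                if min(scaled) >= MIN_PAUSE_S or m == 1:
                    kept_kinds = {k for k, _ in kept}
                    factor = {k: sc / l for (k, l), sc in zip(kept, scaled)}
                    entries = [
                        (k, l * factor[k]) for k, l in entries if k in kept_kinds
                    ]
                    break
        else:
            entries = [("extra", budget)]
        if any(k == "shock" for k, _ in entries):
            n_shocks += 1
        placed = _layout(rng, cycle_lo, cycle_hi, [l for _, l in entries])
        pauses.extend(
            (start, length, kind) for (start, length), (kind, _) in zip(placed, entries)
        )
    return pauses, rhythms, n_shocks


def _compressions_from_schedule(
    start: float, end: float, pauses: Sequence[tuple[float, float]], dt: float
) -> np.ndarray:
    """Metronomic compressions on [start, end] interrupted exactly by ``pauses``.

    Every run carries a compression at both boundaries so that each pause
    registers as an inter-compression gap of exactly its length.
    """
    boundaries = [start]
    for p_start, p_len in sorted(pauses):
        boundaries.extend([p_start, p_start + p_len])
    boundaries.append(end)
    comps: list[float] = []
    for a, b in zip(boundaries[::2], boundaries[1::2]):
        run = np.arange(a, b, dt)
        if run.size == 0 or b - run[-1] > 1e-9:
            run = np.append(run, b)
        if comps and abs(run[0] - comps[-1]) < 1e-12:
            run = run[1:]
        comps.extend(run.tolist())
    return np.asarray(comps)


def generate_scenario(config: GeneratorConfig, index: int) -> tuple[EventLog, GroundTruth]:
    """One synthetic scenario, deterministic given (config.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))
    last_err: Exception | None = None
    for _ in range(max(1, config.max_retries)):
        try:
            return _generate_once(config, rng, index)
        except InfeasibleScenario as err:
            last_err = err
    raise InfeasibleScenario(
        f"scenario {index}: no feasible draw in {config.max_retries} retries ({last_err})"
    )


def _generate_once(
    config: GeneratorConfig, rng: np.random.Generator, index: int
) -> tuple[EventLog, GroundTruth]:
    t_end = config.arrest_duration_s.draw(rng)
    t_cpr = config.time_to_cpr_s.draw(rng)
    h = config.handover_time_s.draw(rng)
    defib = config.defib_arrival_s.draw(rng)
    rhythm_t = config.first_rhythm_s.draw(rng)
    fr = config.responder_nfr_target.draw(rng)
    tr = config.team_nfr_target.draw(rng)
    rate = config.compression_rate_cpm.draw(rng)

    if not (0 <= t_cpr and t_cpr + 30.0 <= h and h + 120.0 <= t_end):
        raise InfeasibleScenario("phase ordering violated")
    if not (0 < defib <= rhythm_t < t_end):
        raise InfeasibleScenario("marker ordering violated")
    if not (0 <= fr < 0.7 and 0 <= tr < 0.6):
        raise InfeasibleScenario("NFR target out of constructible range")
    if rate < 60.0:
        raise InfeasibleScenario("compression rate too low")

    # first-responder phase: leading silence [0, t_cpr) plus unannotated pauses
    resp_budget = fr * h - t_cpr
    if resp_budget < -1e-9:
        raise InfeasibleScenario("responder NFR target below the leading-silence floor")
    resp_budget = max(0.0, resp_budget)
    lead_extra = 0.0
    resp_lengths: list[float] = []
    if resp_budget >= MIN_PAUSE_S:
        resp_lengths = _draw_pause_set(rng, config.pause_length_s, resp_budget)
    else:
        lead_extra = resp_budget  # fold a sub-resolvable budget into the leading silence
    start = t_cpr + lead_extra
    resp_pauses = [
        (s, l, "extra") for s, l in _layout(rng, start, h, resp_lengths)
    ]

    team_pauses, rhythm_seq, n_shocks = _build_team_pauses(rng, config, h, t_end, tr)

    all_pauses = sorted(resp_pauses + team_pauses)
    dt = 60.0 / rate
    comps = _compressions_from_schedule(start, t_end, [(s, l) for s, l, _ in all_pauses], dt)

    events: list[AnnotatedEvent] = [AnnotatedEvent(0.0, EventKind.ARREST_RECOGNIZED)]
    if t_cpr > 6.0:
        events.append(AnnotatedEvent(rng.uniform(3.0, min(20.0, t_cpr)), EventKind.CALL_PLACED))
    events.append(AnnotatedEvent(start, EventKind.CPR_STARTED))
    events.append(AnnotatedEvent(h, EventKind.HANDOVER))
    events.append(AnnotatedEvent(defib, EventKind.DEFIB_ARRIVAL))
    rhythm_at_first = rhythm_seq[0] if rhythm_seq else "PEA"
    events.append(AnnotatedEvent(rhythm_t, EventKind.FIRST_RHYTHM, rhythm_at_first))
    cycle_idx = -1
    for p_start, p_len, kind in team_pauses:
        if kind == "extra":
            continue
        t_ev = min(p_start + 1.0, p_start + 0.5 * p_len)
        if kind == "rhythm_check":
            cycle_idx += 1
            detail = rhythm_seq[cycle_idx] if 0 <= cycle_idx < len(rhythm_seq) else ""
            events.append(AnnotatedEvent(t_ev, EventKind.RHYTHM_CHECK, detail))
        elif kind == "pulse_check":
            events.append(AnnotatedEvent(t_ev, EventKind.PULSE_CHECK))
        elif kind == "shock":
            events.append(AnnotatedEvent(t_ev, EventKind.SHOCK))
    events.append(AnnotatedEvent(float(t_end), EventKind.ROSC))
    events.sort(key=lambda e: e.time)

    scenario_id = f"sim-{config.seed:04d}-{index:03d}"
    log = validate(
        EventLog(
            scenario_id=scenario_id,
            compressions=tuple(np.minimum(np.round(comps, 6), t_end).tolist()),
            events=tuple(events),
            t0=0.0,
            t_end=float(t_end),
        )
    )
    truth = GroundTruth(
        scenario_id=scenario_id,
        duration_s=float(t_end),
        time_to_cpr_s=float(start),
        handover_s=float(h),
        defib_arrival_s=float(defib),
        first_rhythm_s=float(rhythm_t),
        responder_nfr_target=float(fr),
        team_nfr_target=float(tr),
        compression_rate_cpm=float(rate),
        rhythm_sequence=tuple(rhythm_seq),
        pause_schedule=tuple((float(s), float(l), k) for s, l, k in all_pauses),
        n_shocks=int(n_shocks),
    )
    return log, truth


def generate_cohort(config: GeneratorConfig) -> list[tuple[EventLog, GroundTruth]]:
    """``config.n_scenarios`` independent scenarios, reproducible from the seed."""
    return [generate_scenario(config, i) for i in range(config.n_scenarios)]


def write_cohort(
    cohort: Sequence[tuple[EventLog, GroundTruth]], out_dir: str | Path
) -> Path:
    """Write one CSV log per scenario plus a manifest and a ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scenario_id", "path"])
        for log, _ in cohort:
            fname = f"{log.scenario_id}.csv"
            write_event_log(log, out / fname)
            writer.writerow([log.scenario_id, fname])
    with (out / "ground_truth.csv").open("w", encoding="utf-8", newline="") as fh:
        fields = [
            "scenario_id", "duration_s", "time_to_cpr_s", "handover_s",
            "defib_arrival_s", "first_rhythm_s", "responder_nfr_target",
            "team_nfr_target", "compression_rate_cpm", "n_shocks", "rhythm_sequence",
        ]
        writer = csv.writer(fh)
        writer.writerow(fields)
        for _, truth in cohort:
            row = asdict(truth)
            row["rhythm_sequence"] = "|".join(truth.rhythm_sequence)
            writer.writerow([row[f] for f in fields])
    return manifest
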
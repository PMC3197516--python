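# Methods

## Timeline model

A scenario is a single timeline in seconds, re-based on ingest so that
recognition of the cardiac arrest ("Time 0") is 0 and the terminal event
(ROSC, or scripted scenario end) is the analysis horizon `t_end`. Two kinds
of observations live on it: the instant of every chest-compression
downstroke, and annotated clinical events (call placed, CPR started,
defibrillator arrival, first rhythm on the scope, rhythm checks, pulse
checks, shocks, handover). All analysis windows are half-open `[start, end)`
so that an event exactly at a boundary belongs to the later window; the
handover event therefore splits `[0, t_end)` exactly into a first-responder
phase `[0, h)` and a team phase `[h, t_end)`, and phase quantities add up to
overall quantities by construction. When no handover is annotated, phase
metrics are omitted rather than imputed. `cpr_started` is optional: time to
CPR falls back to the first compression.

## Flow detection and NFT/NFR

A gap between consecutive compressions counts wholly as flow when it is at
most `gap_threshold_s` (default 1.5 s, the conventional interruption
threshold in CPR quality research) and wholly as no-flow otherwise; leading
and trailing silences are always no-flow. Flow runs are computed over the
whole log and clipped to the window, so a run crossing the handover
contributes flow on both sides and `NFT(first responders) + NFT(team) =
NFT(overall)` holds exactly. `NFR = NFT / window duration`. Whether real
recording devices use a gap threshold or native flow flags varies by vendor,
so the threshold is an explicit, configurable parameter. The threshold
comparison carries a 1 ns epsilon so a gap of exactly the threshold is
classified as flow regardless of floating-point representation.

30-second segment profiles reuse the same clipped flow set, so segment NFTs
sum to the window NFT to numerical precision; the final partial segment
keeps its true length.

## Allowance crediting (NFT_adj, NFR_adj)

Advanced-life-support guidelines sanction brief pauses; the adjusted
metrics remove them so that what remains is avoidable no-flow. The timeline
is partitioned into consecutive cycles of `cycle_s` (default 120 s)
anchored at Time 0 — the simplest reproducible convention, since nothing
pins the cycle clock to any particular event. Within each cycle at most one
credit per kind is granted, each limited by the no-flow time still
uncredited in that cycle:

| credit          | cap (s) | condition                              |
|-----------------|---------|----------------------------------------|
| pulse check     | 10      | always allowed                         |
| rhythm analysis | 5       | always allowed                         |
| shock delivery  | 10      | only if a shock event occurs in cycle  |

Three attribution modes exist. In the default `auto` mode a cycle containing
an annotated pulse/rhythm event attaches the credit to that event's
timestamp; a cycle without one still receives the scheduled cap — the
guideline allows the pause every cycle whether or not the log annotates it,
and first responders (no defibrillator yet) never annotate rhythm checks.
`event` grants pulse/rhythm credits only in cycles containing the annotated
event; `schedule` ignores annotations entirely. Shock credit requires an
annotated shock in every mode ("when appropriate"). Because each credit is
capped by the remaining no-flow, total credit never exceeds NFT, so
`NFT_adj = NFT − credit ≥ 0` structurally, and the per-cycle total equals
`min(no-flow in cycle, Σ applicable caps)` independent of grant order —
which also makes credit monotone in the event set (removing shocks never
increases it).

Per-phase credit sums the global ledger's records whose attribution time
falls in the phase (scheduled credits attribute to the cycle midpoint); in
the rare case where attribution places more credit in a window than the
window's own no-flow, the window's credits are scaled down to that bound.

## Rates and markers

Two rates are reported because they answer different questions:
`compression_rate_cpm` is the median of 60/gap over consecutive compression
pairs with sub-threshold gaps (how fast compressions are given while
compressing; 0 when fewer than two such pairs exist), and `delivered_cpm`
is the raw count per elapsed minute (how many actually arrive). Under
uninterrupted metronomic CPR the two coincide; pauses depress only the
second. Time-to-event markers are event time minus Time 0 and are reported
as missing — never zero — when the event is absent.

## Cohort statistics

Cohorts are summarized as median and 25th/75th percentiles using the
weighted-average-at-(n+1)p quantile convention (R type 6) by default, the
convention used by common clinical-statistics software; other conventions
are selectable for cross-checking.

Group comparisons use the two-sided Mann–Whitney U test with midranks.
For untied samples with `n1+n2 ≤ 30` the p-value is exact: the null
distribution of the rank sum is built by dynamic programming over
`k`-subsets of ranks `1..n1+n2`, and `p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))`.
Tied samples with `n1+n2 ≤ 12` use exhaustive enumeration over all
labelings of the pooled midranks. Larger samples fall back to the normal
approximation with tie correction and a 0.5 continuity correction toward
the mean. The primary phase comparison is unpaired even though phases are
paired by scenario, mirroring how such cohorts are conventionally analyzed;
a paired Wilcoxon signed-rank variant is available behind `paired=True`.

## Scenario simulator

The generator emulates the study design the analysis assumes: an
unannounced ward arrest, basic CPR by first responders, then ALS cycles by
the arrest team. Per scenario it draws, from one pseudo-random stream
seeded by `(seed, index)` (so cohorts are reproducible and
order-independent):

| quantity                | default distribution | calibration |
|-------------------------|----------------------|-------------|
| arrest duration         | lognormal, median 600 s, σ = 0.15 | assumed scripted-scenario spread (no published value) |
| time to first CPR       | lognormal | quartiles 22 / 29 / 46 s |
| handover time           | lognormal | quartiles 180 / 214 / 254 s |
| defibrillator arrival   | lognormal | quartiles 180 / 214 / 254 s |
| first rhythm            | lognormal | quartiles 283 / 311 / 349 s |
| first-responder NFR target | scaled Beta | quartiles 0.32 / 0.39 / 0.46 |
| team NFR target         | scaled Beta | quartiles 0.19 / 0.25 / 0.29 |
| compression rate        | normal(117, 5) /min | published median rate |
| pause length            | gamma, mean 8 s, shape 4, truncated [2, 40] s | assumed |

Lognormals are the natural choice for nonnegative right-skewed delays and
are solved from the printed quartiles (`σ = ln(q75/q25)/(2·z₀.₇₅)`). NFR
targets use a Beta rescaled to support `[lo, hi] ⊂ [0, 1]` with all four
parameters solved by least squares so the three printed quartiles are hit
essentially exactly; only the quartiles are published, so tail shape beyond
them is a modeling choice, not data. Draws violating the event ordering
(CPR ≤ handover ≤ end; defibrillator ≤ first rhythm < end) or outside the
constructible NFR range are redrawn.

Timelines are built constructively rather than by rejection: the
first-responder phase gets the leading silence plus unannotated pauses whose
lengths are rescaled to hit the drawn NFR target exactly; the team phase is
laid out in 120 s cycles, each containing a 3–5 s rhythm-analysis pause, a
6–10 s pulse-check pause and, while the rhythm is shockable, a 6–10 s shock
pause (annotated events inside their pauses), topped up or shrunk so each
cycle meets its share of the team NFR target. Compressions are metronomic at
the drawn rate with a compression at both ends of every run, so each pause
registers as an inter-compression gap of exactly its length; realized phase
NFRs match the drawn targets to well within ±0.01 (budgets smaller than the
2 s minimum realizable pause — possible only for targets near zero — are
folded into a neighbouring pause or the leading silence). Rhythm state
starts shockable with probability 0.5 and converts to non-shockable with
probability 0.3 per cycle; the sequence is recorded in the ground truth
along with every other draw, so any pipeline output can be predicted from
it.

What the generator does **not** emulate: compression depth/recoil and
ventilation, operator fatigue or drift in rate, behavioral/team factors,
measurement noise in event annotation, and any correlation between phase
performance and scenario type. Passing tests therefore demonstrate that the
pipeline measures what the generator encodes — interval structure, phase
split, pause accounting — not that real device logs are this clean.

## Problem sizes and tolerances used in verification

- Headline comparison: 200 replicate cohorts of 13 scenarios; median exact
  Mann–Whitney p across replicates (reported by `scripts/acceptance.py`).
- Interval-algebra oracle: 1,000 random millisecond-aligned logs against a
  1 ms occupancy grid, agreement within one grid step. Grid-aligned inputs
  make the comparison exact; the built-in `noflow selftest` runs an
  independently coded variant of the same oracle.
- Exact U test: every rank split with `n1+n2 ≤ 10` against exhaustive
  permutation enumeration; complete separation at 13 vs 13 against the
  closed form `2/C(26,13)`.
- Parameter recovery: one 200-scenario cohort; pipeline cohort medians
  within ±0.02 (NFR targets) and ±10 % (timing markers, covering the
  Monte-Carlo error of a 200-draw median) of the configured medians.

## Known limitations

- Quartile-only calibration leaves the Beta tail shapes unidentified; the
  team-phase fit has a short right tail (support ends near 0.31), which is
  consistent with the printed quartiles but not guaranteed to match the
  study's unpublished extremes.
- Whether "Time 0" means scripted arrest onset or staff recognition is
  ambiguous in this study design; the model treats the recognition event as
  Time 0.
- The allowance cycle clock is anchored at Time 0; anchoring at another
  event (e.g. first rhythm) would shift per-cycle credit boundaries. The
  anchor convention is fixed, the budgets configurable.
- The unpaired primary comparison ignores the scenario pairing of phases,
  deliberately mirroring the conventional analysis; the paired variant
  usually yields smaller p-values.
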
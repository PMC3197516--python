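"""Inspect the guideline-pause allowance ledger on a worst-case timeline.

A 6-minute window with no compressions at all (pure no-flow) and one shock
per 2-minute cycle shows the per-cycle caps binding exactly: 10 s pulse
check + 5 s rhythm analysis + 10 s shock = 25 s per cycle, 75 s in total.
Removing the shock events withholds the shock credit ("when appropriate").
"""

from noflow import AnnotatedEvent, EventKind, EventLog, allowance_credit, no_flow_time

def bare_log(shock_times):
    events = [AnnotatedEvent(0.0, EventKind.ARREST_RECOGNIZED)]
    events += [AnnotatedEvent(t, EventKind.SHOCK) for t in shock_times]
    events += [AnnotatedEvent(360.0, EventKind.ROSC)]
    return EventLog("ledger-demo", (), tuple(events), 0.0, 360.0)

for label, shocks in [("shocks every cycle", (30.0, 150.0, 270.0)), ("no shocks", ())]:
    log = bare_log(shocks)
    credited, ledger = allowance_credit(log)
    print(f"{label}: NFT {no_flow_time(log):.0f} s, credited {credited:.0f} s")
    for rec in ledger:
        tag = "scheduled" if rec.scheduled else "event"
        print(f"  cycle {rec.cycle_index}  {rec.kind:15s} {rec.amount:5.1f} s  ({tag})")
print("Credits never exceed the actual no-flow in a cycle, so the adjusted")
print("no-flow time NFT - credit is the pause burden beyond the guidelines.")
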
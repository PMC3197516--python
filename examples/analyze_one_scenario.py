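"""Analyze a single hand-written resuscitation event log.

Builds a 6-minute scenario in memory — recognition of arrest, a 25 s delay
to the first compression, continuous CPR with two long interruptions, team
handover at 210 s, a rhythm check, a shock and a pulse check in the team
phase — and prints the per-phase no-flow metrics.
"""

import io

import numpy as np

from noflow import read_event_log, scenario_metrics

records = [(0.0, "arrest_recognized", ""), (210.0, "handover", ""),
           (215.0, "defib_arrival", ""), (360.0, "rosc", "")]
# basic CPR from 25 s with a 20 s interruption at 120 s (~110/min), then the
# team phase: one ALS cycle with sanctioned pauses, CPR to ROSC (~117/min)
for a, b, dt in [(25, 120, 0.545), (140, 210, 0.545),
                 (210, 240, 0.513), (255, 320, 0.513), (330, 360.1, 0.513)]:
    records += [(round(t, 3), "compression", "") for t in np.arange(a, b, dt)]
records += [(241.0, "rhythm_check", "VF"), (246.0, "shock", ""),  # 5 s + 9 s pauses
            (322.0, "pulse_check", "")]  # 8 s pulse-check pause
records.sort()

csv_text = "time_s,event_type,detail\n" + "".join(f"{t},{k},{d}\n" for t, k, d in records)
log = read_event_log(io.StringIO(csv_text), scenario_id="demo")
m = scenario_metrics(log)

print(f"scenario {m.scenario_id}: {log.duration:.0f} s from recognition to ROSC")
print(f"time to CPR {m.markers.time_to_cpr_s:.0f} s, "
      f"defibrillator at {m.markers.time_to_defib_arrival_s:.0f} s")
for label in ("overall", "first_responders", "team"):
    pm = m.phases[label]
    print(f"  {label:17s} duration {pm.duration_s:5.0f} s  NFT {pm.nft_s:5.1f} s  "
          f"NFR {100 * pm.nfr:4.1f} %  NFR_adj {100 * pm.nfr_adj:4.1f} %  "
          f"rate {pm.compression_rate_cpm:5.1f}/min  delivered {pm.delivered_cpm:5.1f}/min")
print("NFR is the fraction of the phase without chest compressions;")
print("NFR_adj removes pauses the guidelines sanction (rhythm 5 s, shock 10 s,")
print("pulse check 10 s per 2-minute cycle), so it is the avoidable no-flow.")
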
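"""Cohort report tables: per-scenario metrics, cohort summary, phase comparison.

Human-readable tables mirror the conventional presentation of CPR quality
markers (median [25th–75th percentile], percentages to 0 decimals); the
machine report keeps full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import ScenarioMetrics
from .stats import CohortSummary, compare_phases, summarize

__all__ = [
    "per_scenario_table",
    "cohort_summary_table",
    "phase_comparison_table",
    "write_reports",
]

#: (row label, how to pull the value from a ScenarioMetrics, percent?)
_SUMMARY_ROWS = [
    ("Compression rate (comp/min)", lambda m: m.overall.compression_rate_cpm, False),
    ("Compressions (actual comp. given/min)", lambda m: m.overall.delivered_cpm, False),
    ("Time to initiating of CPR (sec)", lambda m: m.markers.time_to_cpr_s, False),
    ("Time to arrival of defibrillator in room (sec)", lambda m: m.markers.time_to_defib_arrival_s, False),
    ("Time to first rhythm on defibrillator (sec)", lambda m: m.markers.time_to_first_rhythm_s, False),
    ("NFR (%)", lambda m: m.overall.nfr, True),
    ("NFR_adj (%)", lambda m: m.overall.nfr_adj, True),
]


def per_scenario_table(cohort: Sequence[ScenarioMetrics]) -> pd.DataFrame:
    """One row per scenario, one column per phase-qualified metric; full precision."""
    rows = []
    for m in cohort:
        row: dict[str, object] = {"scenario_id": m.scenario_id}
        for label, pm in m.phases.items():
            for f in ("duration_s", "nft_s", "nfr", "nft_adj_s", "nfr_adj",
                      "compression_rate_cpm", "delivered_cpm"):
                row[f"{label}.{f}"] = getattr(pm, f)
            row[f"{label}.nfr_pct"] = 100.0 * pm.nfr
            row[f"{label}.nfr_adj_pct"] = 100.0 * pm.nfr_adj
        row["time_to_cpr_s"] = m.markers.time_to_cpr_s
        row["time_to_defib_arrival_s"] = m.markers.time_to_defib_arrival_s
        row["time_to_first_rhythm_s"] = m.markers.time_to_first_rhythm_s
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_dict(s: CohortSummary, scale: float = 1.0) -> dict[str, float]:
    return {
        "n": s.n,
        "median": s.median * scale,
        "q25": s.q25 * scale,
        "q75": s.q75 * scale,
    }


def cohort_summary_table(
    cohort: Sequence[ScenarioMetrics], quantile_method: str = "spss", digits: int | None = 0
) -> pd.DataFrame:
    """Whole-cohort quality markers: median and quartiles per metric.

    Markers missing in a scenario are omitted from that metric's summary
    (n varies accordingly).  ``digits=None`` keeps full precision.
    """
    rows = []
    for label, getter, is_pct in _SUMMARY_ROWS:
        vals = [getter(m) for m in cohort]
        vals = [v for v in vals if v is not None]
        if not vals:
            continue
        s = summarize(vals, label, quantile_method)
        d = _summary_dict(s, 100.0 if is_pct else 1.0)
        rows.append({"metric": label, **d})
    df = pd.DataFrame(rows)
    if digits is not None:
        for col in ("median", "q25", "q75"):
            df[col] = df[col].round(digits)
    return df


def phase_comparison_table(
    cohort: Sequence[ScenarioMetrics],
    metrics: Sequence[str] = ("nfr", "nfr_adj"),
    quantile_method: str = "spss",
    exact_limit: int = 30,
    digits: int | None = 0,
) -> pd.DataFrame:
    """First responders vs team: summaries per group and the Mann–Whitney p."""
    rows = []
    for name in metrics:
        s_fr, s_team, cmp = compare_phases(
            cohort, name, quantile_method=quantile_method, exact_limit=exact_limit
        )
        is_pct = name in ("nfr", "nfr_adj")
        scale = 100.0 if is_pct else 1.0
        label = f"{name.upper().replace('_ADJ', '_adj')} (%)" if is_pct else name
        rows.append(
            {
                "metric": label,
                "fr_median": s_fr.median * scale,
                "fr_q25": s_fr.q25 * scale,
                "fr_q75": s_fr.q75 * scale,
                "team_median": s_team.median * scale,
                "team_q25": s_team.q25 * scale,
                "team_q75": s_team.q75 * scale,
                "u_statistic": cmp.u_statistic,
                "p_value": cmp.p_two_sided,
                "method": cmp.method,
                "significant_at_0.05": cmp.p_two_sided < 0.05,
            }
        )
    df = pd.DataFrame(rows)
    if digits is not None:
        for col in ("fr_median", "fr_q25", "fr_q75", "team_median", "team_q25", "team_q75"):
            df[col] = df[col].round(digits)
    return df


def write_reports(
    cohort: Sequence[ScenarioMetrics],
    out_dir: str | Path,
    quantile_method: str = "spss",
    exact_limit: int = 30,
) -> Path:
    """Write the three tables plus a full-precision JSON report; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_scenario_table(cohort).to_csv(out / "per_scenario_metrics.csv", index=False)
    cohort_summary_table(cohort, quantile_method).to_csv(out / "cohort_summary.csv", index=False)
    has_phases = all(
        "first_responders" in m.phases and "team" in m.phases for m in cohort
    )
    payload = {
        "n_scenarios": len(cohort),
        "quantile_method": quantile_method,
        "cohort_summary": cohort_summary_table(cohort, quantile_method, digits=None).to_dict(
            orient="records"
        ),
    }
    if has_phases and cohort:
        cmp_df = phase_comparison_table(
            cohort, quantile_method=quantile_method, exact_limit=exact_limit
        )
        cmp_df.to_csv(out / "phase_comparison.csv", index=False)
        payload["phase_comparison"] = phase_comparison_table(
            cohort, quantile_method=quantile_method, exact_limit=exact_limit, digits=None
        ).to_dict(orient="records")
    (out / "report.json").write_text(json.dumps(payload, indent=1, default=float))
    return out
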
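"""Flow-interval algebra, NFT/NFR, allowance credits, rates, segments, markers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noflow import (
    AllowancePolicy,
    AnnotatedEvent,
    EventKind,
    adjusted_metrics,
    allowance_credit,
    compression_rates,
    flow_intervals,
    no_flow_ratio,
    no_flow_time,
    scenario_metrics,
    segment_profile,
    time_markers,
)
from noflow.selftest import random_log

from conftest import make_log, metronome, paint_grid_nft


class TestFlowIntervals:
    def test_uninterrupted_cpr_has_zero_nft(self, policy):
        log = make_log(compressions=metronome(0, 300), t_end=300.0)
        assert flow_intervals(log, policy).total_duration == pytest.approx(300.0)
        assert no_flow_time(log, policy) == pytest.approx(0.0)

    def test_no_compressions_is_all_no_flow(self, policy):
        log = make_log(t_end=300.0)
        assert len(flow_intervals(log, policy)) == 0
        assert no_flow_time(log, policy) == 300.0

    def test_single_silent_span(self, policy):
        comps = np.concatenate([metronome(0, 100), metronome(130, 300)])
        log = make_log(compressions=comps, t_end=300.0)
        nft = no_flow_time(log, policy)
        assert nft == pytest.approx(30.0)
        oracle = paint_grid_nft(comps, (0.0, 300.0), policy.gap_threshold_s)
        assert nft == pytest.approx(oracle, abs=0.001)

    def test_gap_exactly_at_threshold_is_flow(self, policy):
        comps = (0.0, 1.5, 3.0, 300.0 - 1.6, 300.0)
        log = make_log(compressions=comps, t_end=300.0)
        # the 1.5 s gaps are flow; the long middle gap and the 1.6 s gap are not
        assert flow_intervals(log, policy).total_duration == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_occupancy_grid_oracle(self, seed, policy):
        log = random_log(np.random.default_rng(seed), duration_s=90.0)
        nft = no_flow_time(log, policy)
        oracle = paint_grid_nft(
            log.compression_array(), (log.t0, log.t_end), policy.gap_threshold_s
        )
        assert abs(nft - oracle) <= 0.001

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=40, deadline=None)
    def test_conservation_flow_plus_nft_is_duration(self, seed):
        policy = AllowancePolicy()
        log = random_log(np.random.default_rng(seed), duration_s=60.0)
        flow = flow_intervals(log, policy).total_duration
        assert flow + no_flow_time(log, policy) == pytest.approx(log.duration, abs=1e-9)

    @given(seed=st.integers(0, 100_000), t_new=st.floats(0.5, 59.5))
    @settings(max_examples=40, deadline=None)
    def test_extra_compression_never_increases_nft(self, seed, t_new):
        policy = AllowancePolicy()
        log = random_log(np.random.default_rng(seed), duration_s=60.0)
        before = no_flow_time(log, policy)
        comps = tuple(sorted(log.compressions + (round(t_new, 3),)))
        log2 = make_log(compressions=comps, t_end=log.t_end)
        assert no_flow_time(log2, policy) <= before + 1e-9

    @given(seed=st.integers(0, 100_000), widen=st.floats(0.0, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_wider_gap_threshold_never_increases_nft(self, seed, widen):
        log = random_log(np.random.default_rng(seed), duration_s=60.0)
        narrow = AllowancePolicy()
        wide = AllowancePolicy(gap_threshold_s=narrow.gap_threshold_s + widen)
        assert no_flow_time(log, wide) <= no_flow_time(log, narrow) + 1e-9

    def test_window_validation(self, policy):
        log = make_log(compressions=(5.0,), t_end=300.0)
        with pytest.raises(ValueError):
            flow_intervals(log, policy, (100.0, 100.0))
        with pytest.raises(ValueError):
            flow_intervals(log, policy, (-5.0, 100.0))


class TestNoFlowRatio:
    def test_bounds_and_values(self):
        assert no_flow_ratio(0.0, 300.0) == 0.0
        assert no_flow_ratio(300.0, 300.0) == 1.0
        assert no_flow_ratio(84.0, 300.0) == pytest.approx(0.28)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            no_flow_ratio(10.0, 0.0)
        with pytest.raises(ValueError):
            no_flow_ratio(301.0, 300.0)


def _shock_log(n_cycles: int = 3, with_shocks: bool = True):
    """360 s of pure no-flow with (optionally) one shock per 120 s cycle."""
    events = []
    if with_shocks:
        events = [(30.0 + 120.0 * k, EventKind.SHOCK) for k in range(n_cycles)]
    return make_log(events=events, t_end=120.0 * n_cycles)


class TestAllowanceCredit:
    def test_caps_bind_with_shocks_every_cycle(self, policy):
        credited, ledger = allowance_credit(_shock_log(with_shocks=True), policy)
        assert credited == pytest.approx(75.0)
        assert sum(r.amount for r in ledger) == pytest.approx(75.0)

    def test_shock_credit_withheld_without_shock_events(self, policy):
        credited, _ = allowance_credit(_shock_log(with_shocks=False), policy)
        assert credited == pytest.approx(45.0)

    def test_credit_never_exceeds_available_no_flow(self, policy):
        # continuous CPR except one 8 s pause holding an annotated pulse check
        comps = np.concatenate([metronome(0, 56), metronome(64, 120)])
        log = make_log(
            compressions=comps,
            events=[(58.0, EventKind.PULSE_CHECK)],
            t_end=120.0,
        )
        assert no_flow_time(log, policy) == pytest.approx(8.0)
        credited, ledger = allowance_credit(log, policy)
        assert credited == pytest.approx(8.0)
        # the pulse credit absorbed everything; no rhythm credit was left
        assert sum(r.amount for r in ledger if r.kind == "pulse_check") == pytest.approx(8.0)

    def test_event_mode_requires_annotations(self, policy):
        comps = np.concatenate([metronome(0, 56), metronome(64, 120)])
        log = make_log(
            compressions=comps, events=[(58.0, EventKind.PULSE_CHECK)], t_end=120.0
        )
        credited, ledger = allowance_credit(log, policy, mode="event")
        # only the annotated pulse check earns credit in event mode
        assert {r.kind for r in ledger} == {"pulse_check"}
        assert credited == pytest.approx(8.0)

    def test_schedule_mode_ignores_event_placement(self, policy):
        credited, ledger = allowance_credit(_shock_log(with_shocks=False), policy, mode="schedule")
        assert credited == pytest.approx(45.0)
        assert all(r.scheduled for r in ledger)

    def test_removing_shocks_never_increases_credit(self, policy):
        from noflow import GeneratorConfig, generate_scenario
        from noflow.events import EventLog

        for idx in range(5):
            log, _ = generate_scenario(GeneratorConfig(seed=11), idx)
            with_shocks, _ = allowance_credit(log, policy)
            stripped = EventLog(
                log.scenario_id,
                log.compressions,
                tuple(e for e in log.events if e.kind is not EventKind.SHOCK),
                log.t0,
                log.t_end,
            )
            without, _ = allowance_credit(stripped, policy)
            assert without <= with_shocks + 1e-9

    def test_credit_bounded_by_nft_on_random_logs(self, policy, rng):
        for _ in range(20):
            log = random_log(rng, duration_s=150.0)
            credited, ledger = allowance_credit(log, policy)
            assert credited <= no_flow_time(log, policy) + 1e-9
            per_cycle_caps = policy.pulse_check_s + policy.rhythm_analysis_s + policy.shock_s
            for k in {r.cycle_index for r in ledger}:
                cycle_total = sum(r.amount for r in ledger if r.cycle_index == k)
                assert cycle_total <= per_cycle_caps + 1e-9


class TestAdjustedMetrics:
    def test_guideline_perfect_is_zero(self):
        assert adjusted_metrics(75.0, 75.0, 360.0) == (0.0, 0.0)

    def test_zero_credit_is_identity(self):
        nft_adj, nfr_adj = adjusted_metrics(84.0, 0.0, 300.0)
        assert nft_adj == 84.0 and nfr_adj == pytest.approx(0.28)

    def test_reported_magnitudes(self):
        nft_adj, nfr_adj = adjusted_metrics(84.0, 30.0, 300.0)
        assert (nft_adj, nfr_adj) == (54.0, pytest.approx(0.18))

    def test_overcredit_is_an_error(self):
        with pytest.raises(ValueError, match="ledger"):
            adjusted_metrics(10.0, 11.0, 300.0)


class TestCompressionRates:
    def test_metronomic_continuous(self, policy):
        log = make_log(compressions=metronome(0, 300, 0.513), t_end=300.0)
        rate, delivered = compression_rates(log, policy)
        assert rate == pytest.approx(60 / 0.513, rel=1e-6)
        assert delivered == pytest.approx(60 / 0.513, rel=0.01)

    def test_duty_cycle_splits_rate_from_delivered(self, policy):
        # 117/min while compressing, but only ~70 % of the window has flow
        dt = 60 / 117
        comps = np.concatenate(
            [metronome(0, 70, dt), metronome(100, 170, dt), metronome(200, 270, dt)]
        )
        log = make_log(compressions=comps, t_end=300.0)
        rate, delivered = compression_rates(log, policy)
        assert rate == pytest.approx(117, rel=0.01)
        assert delivered == pytest.approx(82, rel=0.03)

    def test_no_compressions(self, policy):
        log = make_log(t_end=300.0)
        assert compression_rates(log, policy) == (0.0, 0.0)


class TestSegments:
    def test_exact_and_partial_segments(self, policy):
        log = make_log(compressions=(1.0,), t_end=90.0)
        assert [w for w, _ in segment_profile(log, policy)] == [
            (0.0, 30.0), (30.0, 60.0), (60.0, 90.0)
        ]
        log = make_log(compressions=(1.0,), t_end=100.0)
        lengths = [hi - lo for (lo, hi), _ in segment_profile(log, policy)]
        assert lengths == [30.0, 30.0, 30.0, 10.0]

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=30, deadline=None)
    def test_segment_nft_conserves_total(self, seed):
        policy = AllowancePolicy()
        log = random_log(np.random.default_rng(seed), duration_s=100.0)
        segs = segment_profile(log, policy)
        assert sum(nft for _, nft in segs) == pytest.approx(
            no_flow_time(log, policy), abs=1e-9
        )


class TestTimeMarkers:
    def test_markers_from_events(self):
        log = make_log(
            compressions=(29.0, 29.5),
            events=[(214.0, EventKind.DEFIB_ARRIVAL), (311.0, EventKind.FIRST_RHYTHM)],
            t_end=600.0,
        )
        m = time_markers(log)
        assert m.time_to_cpr_s == 29.0
        assert m.time_to_defib_arrival_s == 214.0
        assert m.time_to_first_rhythm_s == 311.0

    def test_cpr_started_event_takes_precedence(self):
        log = make_log(
            compressions=(35.0,),
            events=[(29.0, EventKind.CPR_STARTED)],
            t_end=300.0,
        )
        assert time_markers(log).time_to_cpr_s == 29.0

    def test_missing_markers_are_none_not_zero(self):
        log = make_log(compressions=(5.0,), t_end=300.0)
        m = time_markers(log)
        assert m.time_to_defib_arrival_s is None
        assert m.time_to_first_rhythm_s is None


class TestScenarioMetrics:
    def test_uninterrupted_cpr_all_zero_nfr(self, policy):
        log = make_log(compressions=metronome(0, 300), t_end=300.0, handover=150.0)
        m = scenario_metrics(log, policy)
        for pm in m.phases.values():
            assert pm.nfr == 0.0 and pm.nfr_adj == 0.0

    def test_phase_nft_sums_to_overall(self, policy, rng):
        from noflow import GeneratorConfig, generate_cohort

        for log, _ in generate_cohort(GeneratorConfig(seed=3, n_scenarios=5)):
            m = scenario_metrics(log, policy)
            assert m.phases["first_responders"].nft_s + m.phases["team"].nft_s == pytest.approx(
                m.overall.nft_s, abs=1e-6
            )
            for pm in m.phases.values():
                assert 0 <= pm.nfr_adj <= pm.nfr <= 1
                assert pm.nft_adj_s <= pm.nft_s <= pm.duration_s + 1e-9
            assert sum(nft for _, nft in m.segments) == pytest.approx(
                m.overall.nft_s, abs=1e-6
            )

    def test_constructed_phase_nfr_values(self):
        from noflow import Fixed, GeneratorConfig, generate_scenario

        cfg = GeneratorConfig(
            seed=9,
            responder_nfr_target=Fixed(0.39),
            team_nfr_target=Fixed(0.25),
        )
        log, _ = generate_scenario(cfg, 0)
        m = scenario_metrics(log)
        assert m.phases["first_responders"].nfr == pytest.approx(0.39, abs=0.01)
        assert m.phases["team"].nfr == pytest.approx(0.25, abs=0.01)
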
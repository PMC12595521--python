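"""Screen analytics: rate fits, activity calls, tmax assignment, tallies."""

import logging

import numpy as np
import pandas as pd
import pytest

from thermorca.screening import (
    INACTIVE,
    RT,
    RT_ONLY,
    AssayTrace,
    ScreenRecord,
    analyze_traces,
    assign_tmax,
    call_active,
    fit_rate,
    normalize_concentration,
    read_screen_table,
    records_from_table,
    residual_activity,
    tally_round,
)

LADDER = (38.0, 42.0, 46.0, 50.0)


def make_trace(times, a340, **kw):
    defaults = dict(well_id="w", sequence_id="s", shock_temp=RT, concentration=5.0)
    defaults.update(kw)
    return AssayTrace(times=np.asarray(times), a340=np.asarray(a340), **defaults)


class TestFitRate:
    def test_flat_trace_zero(self):
        tr = make_trace(np.arange(10.0), np.ones(10))
        assert fit_rate(tr) == pytest.approx(0.0, abs=1e-15)

    def test_exact_line_recovered(self):
        t = np.arange(20.0)
        tr = make_trace(t, 1.0 - 0.01 * t)
        assert fit_rate(tr, window=1.0) == pytest.approx(-0.01, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            t = np.sort(rng.random(n)) * 60
            t += np.arange(n) * 1e-6  # strictly increasing
            y = 1.0 + rng.normal(size=n) * 0.05
            tr = make_trace(t, y)
            w = 0.5
            m = max(int(round(w * n)), 3)
            tm, ym = t[:m], y[:m]
            slope = (np.sum((tm - tm.mean()) * (ym - ym.mean()))
                     / np.sum((tm - tm.mean()) ** 2))
            assert fit_rate(tr, window=w) == pytest.approx(slope, abs=1e-10)

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0.0, 1.0], [1.0, 1.0])  # <3 points rejected at the type level
        tr = make_trace([0.0, 1.0, 2.0, 3.0], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="window"):
            fit_rate(tr, window=2.0)


class TestCallActive:
    def test_rate_equal_to_control_is_inactive(self):
        assert not call_active(rate=-0.001, control_rate=-0.001, control_sd=0.0, mode="kinetic")

    def test_strong_decay_vs_flat_control_is_active(self):
        assert call_active(rate=-0.02, control_rate=0.0, control_sd=0.001, mode="kinetic")

    def test_endpoint_mode_thresholds_on_positive_control(self):
        assert call_active(endpoint_drop=0.6, positive_drop=0.9, mode="endpoint")
        assert not call_active(endpoint_drop=0.3, positive_drop=0.9, mode="endpoint")

    def test_missing_controls_signalled(self):
        with pytest.raises(ValueError, match="uncontrolled"):
            call_active(endpoint_drop=0.5, mode="endpoint")

    def test_kinetic_confusion_matches_threshold_sweep_oracle(self):
        # simulate wells with known truth and check the k-SD rule reproduces
        # exactly the confusion matrix of a brute-force threshold at
        # control − k·sd
        rng = np.random.default_rng(1)
        k, control_rate, control_sd = 3.0, 0.0, 0.002
        truth = rng.random(1000) < 0.4
        rates = np.where(truth, rng.normal(-0.02, 0.005, 1000), rng.normal(0.0, 0.002, 1000))
        calls = np.array([
            call_active(rate=r, control_rate=control_rate, control_sd=control_sd, mode="kinetic", k=k)
            for r in rates
        ])
        threshold = control_rate - k * control_sd
        oracle = rates < threshold
        assert np.array_equal(calls, oracle)


class TestAssignTmax:
    def test_inactive_at_rt(self):
        assert assign_tmax({RT: False}) == INACTIVE

    def test_wildtype_pattern_gives_38(self):
        # active at RT and 38, inactivated by 42 and above
        calls = {RT: True, 38.0: True, 42.0: False, 46.0: False, 50.0: False}
        assert assign_tmax(calls) == 38.0

    def test_rt_only(self):
        assert assign_tmax({RT: True, 38.0: False, 42.0: False}) == RT_ONLY

    def test_non_monotone_resolves_to_max_with_warning(self, caplog):
        calls = {RT: True, 38.0: True, 42.0: False, 46.0: True, 50.0: False}
        with caplog.at_level(logging.WARNING, logger="thermorca.screening"):
            assert assign_tmax(calls) == 46.0
        assert any("non-monotone" in rec.message for rec in caplog.records)

    def test_rt_call_required(self):
        with pytest.raises(ValueError, match="room-temperature"):
            assign_tmax({38.0: True})


class TestResidualAndConcentration:
    def test_residual_equal_rates_100(self):
        assert residual_activity(-0.01, -0.01) == pytest.approx(100.0)

    def test_residual_zero_post_shock(self):
        assert residual_activity(0.0, -0.01) == pytest.approx(0.0)

    def test_residual_requires_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            residual_activity(-0.01, 0.0)

    def test_dilution_factors(self):
        assert normalize_concentration(10.0) == (2.0, False)
        assert normalize_concentration(5.0) == (1.0, False)
        assert normalize_concentration(3.0) == (1.0, True)  # run neat, flagged

    def test_no_protein_flagged(self):
        with pytest.raises(ValueError, match="no protein"):
            normalize_concentration(0.0)


def record(seq_id, rnd, tmax):
    if tmax == INACTIVE:
        return ScreenRecord(sequence_id=seq_id, round=rnd, active_rt=False, tmax=INACTIVE,
                            active_at={t: False for t in LADDER})
    if tmax == RT_ONLY:
        return ScreenRecord(sequence_id=seq_id, round=rnd, active_rt=True, tmax=RT_ONLY,
                            active_at={t: False for t in LADDER})
    return ScreenRecord(sequence_id=seq_id, round=rnd, active_rt=True, tmax=tmax,
                        active_at={t: t <= tmax for t in LADDER})


class TestTallyRound:
    def test_toy_table_hand_counts(self):
        recs = [
            record("a", "natural", 38.0),
            record("b", "natural", 38.0),
            record("c", "natural", RT_ONLY),
            record("d", "natural", INACTIVE),
        ]
        tally = tally_round(recs, LADDER)
        row = tally.loc["natural"]
        assert row["tested"] == 4
        assert row["active_rt"] == 3
        assert row["inactive"] == 1
        assert row["at_38C"] == 2
        assert row["at_42C"] == 0

    def test_conservation_active_plus_inactive(self):
        rng = np.random.default_rng(2)
        outcomes = [INACTIVE, RT_ONLY, 38.0, 42.0, 46.0, 50.0]
        recs = [
            record(f"s{i}", "design1", outcomes[int(rng.integers(len(outcomes)))])
            for i in range(50)
        ]
        row = tally_round(recs, LADDER).loc["design1"]
        assert row["active_rt"] + row["inactive"] == row["tested"]

    def test_ladder_counts_non_increasing(self):
        rng = np.random.default_rng(3)
        outcomes = [INACTIVE, RT_ONLY, 38.0, 42.0, 46.0, 50.0]
        recs = [
            record(f"s{i}", "natural", outcomes[int(rng.integers(len(outcomes)))])
            for i in range(80)
        ]
        row = tally_round(recs, LADDER).loc["natural"]
        counts = [row[f"at_{t:g}C"] for t in LADDER]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPlateAnalysis:
    def test_zero_noise_plate_has_no_miscalls(self):
        from thermorca.synthetic import is_functional, make_planted_dataset, simulate_screen, true_tmax

        msa, truth = make_planted_dataset(n_seqs=30, length=60, seed=4, trace_noise_sd=0.0)
        traces = simulate_screen(msa.ids, msa.rows, truth, seed=5, duration=960.0, n_points=33)
        records = analyze_traces(traces, round_label="natural", mode="endpoint")
        by_id = {r.sequence_id: r for r in records}
        for seq_id, row in zip(msa.ids, msa.rows):
            rec = by_id[seq_id]
            assert rec.active_rt == is_functional(row, truth)
            if rec.active_rt:
                assert rec.tmax == true_tmax(row, truth)
            else:
                assert rec.tmax == INACTIVE

    def test_kinetic_mode_agrees_at_zero_noise(self):
        from thermorca.synthetic import is_functional, make_planted_dataset, simulate_screen

        msa, truth = make_planted_dataset(n_seqs=15, length=60, seed=6, trace_noise_sd=0.0)
        traces = simulate_screen(msa.ids, msa.rows, truth, seed=7, duration=20.0, n_points=21)
        records = analyze_traces(traces, round_label="natural", mode="kinetic")
        by_id = {r.sequence_id: r for r in records}
        for seq_id, row in zip(msa.ids, msa.rows):
            assert by_id[seq_id].active_rt == is_functional(row, truth)


class TestTableDialect:
    def test_header_synonyms_mapped(self):
        df = pd.DataFrame(
            {
                "Seq_ID": ["WT", "v1"],
                "Protein_Sequence": ["MKV", "MKA"],
                "Design_Round": ["natural", "design1"],
                "Is_Active": ["yes", "no"],
                "Highest_Temp": ["38", "inactive"],
            }
        )
        out = read_screen_table(df.rename(columns=str.lower))
        assert {"id", "sequence", "round", "active", "max_temp"} <= set(out.columns)
        assert out["active"].tolist() == [True, False]

    def test_records_from_table_reconstruct_flags(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "round": ["natural"] * 3,
                "active": [True, True, False],
                "max_temp": ["46", "RT", "inactive"],
            }
        )
        recs = records_from_table(read_screen_table(df), LADDER)
        assert recs[0].tmax == 46.0
        assert recs[0].active_at[42.0] and not recs[0].active_at[50.0]
        assert recs[1].tmax == RT_ONLY
        assert recs[2].tmax == INACTIVE
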
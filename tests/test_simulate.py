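"""Synthetic cohort generator: hazard mechanics, calibration, determinism."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from conftest import day, make_record
from emrisk.simulate import (
    EPOCH,
    SimConfig,
    empirical_relative_risk,
    from_event_table,
    generate_cohort,
    to_event_table,
    window_hazard,
)


class TestWindowHazard:
    def test_no_exposures_returns_baseline(self):
        assert window_hazard(0.5, {}, {}) == pytest.approx(0.5)

    def test_zero_effect_leaves_baseline(self):
        assert window_hazard(0.1, {"X": 0.0}, {"X": 1.0}) == pytest.approx(0.1)

    def test_matches_closed_form(self):
        # independent scalar evaluation of inverse-logit(logit(0.1) + ln 3)
        expected = float(expit(logit(0.1) + math.log(3)))
        assert window_hazard(0.1, {"X": math.log(3)}, {"X": 1.0}) == pytest.approx(expected)

    def test_partial_recency_weight_scales_effect(self):
        expected = float(expit(logit(0.2) + 0.5 * math.log(2)))
        assert window_hazard(0.2, {"X": math.log(2)}, {"X": 0.5}) == pytest.approx(expected)

    def test_rejects_nonfinite_log_rr(self):
        with pytest.raises(ValueError):
            window_hazard(0.1, {"X": math.inf}, {"X": 1.0})

    def test_rejects_bad_baseline(self):
        with pytest.raises(ValueError):
            window_hazard(0.0, {}, {})


def _window_incidence(records, window_days=90):
    """Independent window walk: (events, windows) over consecutive post-AD
    windows up to and including the event window."""
    events = windows = 0
    for rec in records:
        first = min((d for d in rec.psychosis_dates if d > rec.ad_onset),
                    default=None)
        ws = rec.ad_onset
        end = rec.encounters[-1].date
        while ws <= end:
            windows += 1
            if first is not None and ws < first <= ws + dt.timedelta(days=window_days):
                events += 1
                break
            ws += dt.timedelta(days=window_days)
    return events, windows


class TestGenerateCohort:
    def test_same_seed_identical_event_table(self):
        cfg = SimConfig(n_patients=40, seed=11)
        a = to_event_table(generate_cohort(cfg)).to_csv(index=False)
        b = to_event_table(generate_cohort(cfg)).to_csv(index=False)
        assert a == b

    def test_different_seed_differs(self):
        a = to_event_table(generate_cohort(SimConfig(n_patients=40, seed=1)))
        b = to_event_table(generate_cohort(SimConfig(n_patients=40, seed=2)))
        assert not a.equals(b)

    def test_null_calibration_within_three_binomial_se(self):
        cfg = SimConfig(n_patients=2000, seed=5, planted_effects={},
                        washout_violation_rate=0.0)
        records = generate_cohort(cfg)
        events, windows = _window_incidence(records)
        p = cfg.baseline_window_hazard
        se = math.sqrt(p * (1 - p) / windows)
        assert abs(events / windows - p) < 3 * se

    def test_every_patient_carries_ad_anchor_at_onset(self):
        for rec in generate_cohort(SimConfig(n_patients=30, seed=3)):
            onset_enc = [e for e in rec.encounters if e.date == rec.ad_onset]
            assert onset_enc and "G30" in onset_enc[0].dx_codes

    def test_psychosis_dates_have_same_day_encounters(self):
        for rec in generate_cohort(SimConfig(n_patients=60, seed=4)):
            enc_dates = {e.date for e in rec.encounters}
            assert set(rec.psychosis_dates) <= enc_dates

    def test_encounters_strictly_sorted(self):
        for rec in generate_cohort(SimConfig(n_patients=60, seed=4)):
            dates = [e.date for e in rec.encounters]
            assert all(a < b for a, b in zip(dates, dates[1:]))

    def test_washout_violation_rate_roughly_respected(self):
        cfg = SimConfig(n_patients=1000, seed=9, washout_violation_rate=0.2)
        records = generate_cohort(cfg)
        frac = np.mean([any(d < r.ad_onset for d in r.psychosis_dates)
                        for r in records])
        assert 0.12 < frac < 0.28

    def test_zero_encounter_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(encounters_per_year=0.0).validate()


class TestEmpiricalRelativeRisk:
    def test_absent_code_is_undefined(self, fixture_records):
        assert math.isnan(empirical_relative_risk(fixture_records, "NOPE"))

    def test_all_windows_exposed_is_undefined(self):
        # the only code occurs at record start for everyone: no unexposed stratum
        recs = [make_record(f"P{i}", [0, 400, 500], ad_day=400,
                            psych_days=[450] if i % 2 else [])
                for i in range(6)]
        assert math.isnan(empirical_relative_risk(recs, "I10"))

    def test_hand_counted_six_patient_fixture(self):
        # exposed: 3 patients, single window each, 2 events; unexposed: 3
        # patients, single window each, 1 event -> RR = (2/3)/(1/3) = 2
        recs = []
        for i, (exposed, event) in enumerate(
                [(True, True), (True, True), (True, False),
                 (False, True), (False, False), (False, False)]):
            codes = ("E99",) if exposed else ("B00",)
            psych = [430] if event else []
            recs.append(make_record(f"P{i}", [0, 400], ad_day=400,
                                    psych_days=psych, codes=codes))
            # truncate follow-up to a single 90-day window
            recs[-1].encounters = [e for e in recs[-1].encounters
                                   if e.date <= day(490)]
        assert empirical_relative_risk(recs, "E99") == pytest.approx(2.0)

    def test_planted_effect_recovered_in_band(self):
        cfg = SimConfig(n_patients=2000, seed=1,
                        planted_effects={"E11": math.log(2.5)},
                        recency_halflife_days=math.inf)
        rr = empirical_relative_risk(generate_cohort(cfg), "E11")
        assert 1.8 <= rr <= 3.5

    def test_error_narrows_with_cohort_size(self):
        # the estimate stays inside bands that narrow with n (the window-level
        # dichotomization leaves a small systematic offset, so the bands
        # narrow toward a floor rather than to zero)
        bands = {500: 0.8, 2000: 0.4, 8000: 0.25}
        for n, band in bands.items():
            for seed in (2, 3, 4):
                cfg = SimConfig(n_patients=n, seed=seed,
                                planted_effects={"E11": math.log(2.5)},
                                recency_halflife_days=math.inf)
                rr = empirical_relative_risk(generate_cohort(cfg), "E11")
                assert abs(rr - 2.5) < band, (n, seed, rr)

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(ValueError):
            empirical_relative_risk([], "X", horizon_days=0)


class TestEventTableRoundTrip:
    def test_roundtrip_preserves_structure(self):
        records = generate_cohort(SimConfig(n_patients=25, seed=6))
        table = to_event_table(records)
        back = from_event_table(table)
        assert len(back) == len(records)
        for orig, rec in zip(sorted(records, key=lambda r: r.patient_id), back):
            assert rec.patient_id == orig.patient_id
            assert rec.ad_onset == orig.ad_onset
            assert rec.psychosis_dates == sorted(orig.psychosis_dates)
            # encounters with no coded events are not representable in a flat
            # event table; compare the coded ones
            coded = [e for e in orig.encounters
                     if e.dx_codes or e.rx_codes or e.lab_events]
            assert [e.date for e in rec.encounters] == [e.date for e in coded]
            assert [sorted(e.dx_codes) for e in rec.encounters] == \
                   [sorted(e.dx_codes) for e in coded]

    def test_event_table_schema(self):
        table = to_event_table(generate_cohort(SimConfig(n_patients=5, seed=6)))
        assert list(table.columns) == ["patient_id", "date", "code_type",
                                       "code", "result_flag"]
        assert set(table.code_type) <= {"DX", "RX", "LAB"}
        # ISO-8601 dates
        pd.to_datetime(table["date"], format="%Y-%m-%d")
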
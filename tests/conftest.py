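"""Shared fixtures: hand-built patient records and small trained models."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from emrisk import encoding, models
from emrisk.cohort import CohortConfig, build_samples, split_samples
from emrisk.simulate import (
    EPOCH,
    Encounter,
    LabEvent,
    PatientRecord,
    SimConfig,
    benchmark_planted_effects,
    generate_cohort,
)


def day(d: int) -> dt.date:
    return EPOCH + dt.timedelta(days=d)


def make_record(pid, enc_days, ad_day=None, psych_days=(), delir_days=(),
                codes=("I10",), ad_code="G30", psych_code="F29",
                delir_code="F05"):
    """A patient whose encounters sit at the given day offsets.

    Every encounter carries the background codes; the AD anchor code is added
    from AD onset onward, and psychosis/delirium encounters are created (or
    merged) on their days.
    """
    days = sorted(set(enc_days) | set(psych_days) | set(delir_days))
    encounters = []
    for d in days:
        dx = list(codes)
        if ad_day is not None and d >= ad_day:
            dx.append(ad_code)
        if d in psych_days:
            dx.append(psych_code)
        if d in delir_days:
            dx.append(delir_code)
        encounters.append(Encounter(pid, day(d), dx, ["DB99999"], []))
    return PatientRecord(
        patient_id=pid, sex="F", birth_year=1940, encounters=encounters,
        ad_onset=day(ad_day) if ad_day is not None else None,
        psychosis_dates=[day(d) for d in sorted(psych_days)],
        delirium_dates=[day(d) for d in sorted(delir_days)],
    )


# Hand-traced 12-patient cohort (lookback 365, horizon 90, washout 365,
# min history 365).  Expected: 7 case samples from 4 patients (P01 x3 at days
# 420/450/480; P02 x2 at 370/400; P03 x1 at 400; P04 x1 at 600) and 4 control
# samples (P05@800, P06@500, P07@400, P08@700).  P09 has no AD, P10 and P12
# violate the washout, P11 has only 200 days of history.
FIXTURE_MANIFEST = {
    "n_case_samples": 7,
    "n_case_patients": 4,
    "n_control_samples": 4,
    "case_index_days": {
        "P01": [420, 450, 480],
        "P02": [370, 400],
        "P03": [400],
        "P04": [600],
    },
    "control_index_days": {"P05": 800, "P06": 500, "P07": 400, "P08": 700},
}


@pytest.fixture(scope="session")
def fixture_records():
    return [
        make_record("P01", [0, 400, 420, 450, 480], ad_day=400, psych_days=[500]),
        make_record("P02", [0, 370, 400], ad_day=370, psych_days=[430]),
        make_record("P03", [0, 400], ad_day=400, psych_days=[410]),
        make_record("P04", [0, 500, 600], ad_day=500, psych_days=[650]),
        make_record("P05", [0, 400, 600, 800], ad_day=400),
        make_record("P06", [0, 450, 500], ad_day=450),
        make_record("P07", [0, 400], ad_day=400),
        make_record("P08", [0, 500, 700], ad_day=500),
        make_record("P09", [0, 300, 600]),                                  # no AD
        make_record("P10", [0, 300, 400], ad_day=400, psych_days=[300]),    # washout
        make_record("P11", [200, 400], ad_day=400),                         # short history
        # psychosis@420 voided by same-day delirium, but psychosis@350 violates washout
        make_record("P12", [0, 400], ad_day=400, psych_days=[350, 420],
                    delir_days=[420]),
    ]


SMALL_N = 400


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded benchmark cohort shared across tests (generated once)."""
    cfg = SimConfig(n_patients=SMALL_N, seed=7,
                    planted_effects=benchmark_planted_effects())
    records = generate_cohort(cfg)
    cc = CohortConfig(seed=8)
    samples = build_samples(records, cc)
    folds = split_samples(samples, cc)
    return {"config": cfg, "records": records, "samples": samples,
            "cohort_config": cc, "folds": folds}


@pytest.fixture(scope="session")
def packed_folds(small_cohort):
    train, val, test = small_cohort["folds"]
    vocab = encoding.build_vocabulary(train)

    def pack(fold):
        X = [encoding.pack_sample(s, vocab) for s in fold]
        y = np.array([s.y for s in fold])
        return X, y

    return {"vocab": vocab, "train": pack(train), "val": pack(val),
            "test": pack(test)}


@pytest.fixture(scope="session")
def trained_lstm(packed_folds):
    X, y = packed_folds["train"]
    Xv, yv = packed_folds["val"]
    clf = models.LSTMRiskClassifier(
        embed_dim=16, hidden_size=16, n_layers=1, dropout=0.1,
        learning_rate=0.01, batch_size=64, max_epochs=6, patience=2,
        vocab_size=packed_folds["vocab"].n_tokens, seed=0)
    return clf.fit(X, y, X_val=Xv, y_val=yv)
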
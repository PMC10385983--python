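"""Case/control cohort construction: eligibility, washout, index dates,
case augmentation, control undersampling, and patient-level splits.

A patient enters the analysis only with an AD diagnosis preceded by at least
``min_history_days`` of record and no (delirium-free) psychosis code inside
the washout window before AD onset.  After onset, every encounter followed by
psychosis within ``horizon_days`` yields one *case* sample (augmentation);
patients who never convert contribute a single *control* sample at their
latest qualifying encounter, and controls are undersampled to the configured
case:control ratio.  Splits are by patient so augmented samples of one
patient never straddle folds.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encoding
from .simulate import PatientRecord

__all__ = [
    "CohortConfig",
    "CohortSample",
    "effective_psychosis_dates",
    "is_eligible",
    "label_encounter",
    "build_samples",
    "split_samples",
    "samples_to_frame",
    "samples_to_jsonl",
    "samples_from_jsonl",
]

CASE, CONTROL, INELIGIBLE = "case", "control", "ineligible"


@dataclass(frozen=True)
class CohortConfig:
    lookback_days: int = 365
    horizon_days: int = 90
    washout_days: int = 365
    min_history_days: int = 365
    control_ratio: float = 1.0          # controls per case after undersampling
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    strict_washout: bool = False        # True: no psychosis ever before AD
    augment_cases: bool = True          # False: keep only latest case encounter

    def validate(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        for name in ("lookback_days", "horizon_days", "washout_days",
                     "min_history_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CohortSample:
    patient_id: str
    index_date: dt.date
    label: str                                   # CASE or CONTROL
    visits: list[tuple[dt.date, list[str]]]      # typed tokens per visit

    @property
    def y(self) -> int:
        return 1 if self.label == CASE else 0


def effective_psychosis_dates(record: PatientRecord) -> list[dt.date]:
    """Psychosis dates surviving the delirium co-occurrence exclusion.

    A psychosis code recorded on the same calendar day as a delirium code is
    treated as misattributed delirium and removed.
    """
    delir = set(record.delirium_dates)
    return sorted(d for d in record.psychosis_dates if d not in delir)


def is_eligible(record: PatientRecord, config: CohortConfig) -> tuple[bool, str]:
    """AD present, >= min_history_days of pre-AD record, washout satisfied."""
    if record.ad_onset is None:
        return False, "no_ad"
    if not record.encounters:
        return False, "no_encounters"
    history = (record.ad_onset - record.first_encounter).days
    if history < config.min_history_days:
        return False, "history"
    psych = effective_psychosis_dates(record)
    if config.strict_washout:
        if any(d <= record.ad_onset for d in psych):
            return False, "washout"
    else:
        lo = record.ad_onset - dt.timedelta(days=config.washout_days)
        if any(lo <= d <= record.ad_onset for d in psych):
            return False, "washout"
    return True, ""


def label_encounter(record: PatientRecord, encounter_date: dt.date,
                    config: CohortConfig) -> str:
    """Label one candidate index date as case / control / ineligible."""
    if record.ad_onset is None or encounter_date < record.ad_onset:
        return INELIGIBLE
    psych = effective_psychosis_dates(record)
    horizon = dt.timedelta(days=config.horizon_days)
    post_ad = [d for d in psych if d > record.ad_onset]
    first_post = min(post_ad) if post_ad else None
    if first_post is not None and encounter_date >= first_post:
        return INELIGIBLE
    if first_post is not None and encounter_date < first_post <= encounter_date + horizon:
        return CASE
    if first_post is None or first_post > encounter_date + horizon:
        # no psychosis between AD onset and the end of the horizon
        if first_post is None:
            return CONTROL
        return INELIGIBLE  # converts later: not a valid control patient
    return INELIGIBLE


def _lookback_visits(record: PatientRecord, index_date: dt.date,
                     config: CohortConfig,
                     tables: encoding.MappingTables | None) -> list[tuple[dt.date, list[str]]]:
    lo = index_date - dt.timedelta(days=config.lookback_days)
    visits = []
    for enc in record.encounters:
        if lo <= enc.date <= index_date:
            tokens = encoding.encounter_tokens(enc, tables)
            if tokens:
                visits.append((enc.date, tokens))
    return visits


def build_samples(
    records: list[PatientRecord],
    config: CohortConfig,
    tables: encoding.MappingTables | None = None,
) -> list[CohortSample]:
    """Apply labeling, case augmentation and seeded control undersampling."""
    config.validate()
    if not records:
        raise ValueError("no patient records supplied")
    cases: list[CohortSample] = []
    controls: list[CohortSample] = []
    for rec in records:
        ok, _ = is_eligible(rec, config)
        if not ok:
            continue
        case_dates = [e.date for e in rec.encounters
                      if label_encounter(rec, e.date, config) == CASE]
        if case_dates:
            if not config.augment_cases:
                case_dates = [max(case_dates)]
            for d in case_dates:
                visits = _lookback_visits(rec, d, config, tables)
                if visits:
                    cases.append(CohortSample(rec.patient_id, d, CASE, visits))
        else:
            ctrl_dates = [e.date for e in rec.encounters
                          if label_encounter(rec, e.date, config) == CONTROL]
            if ctrl_dates:
                d = max(ctrl_dates)  # latest status only
                visits = _lookback_visits(rec, d, config, tables)
                if visits:
                    controls.append(CohortSample(rec.patient_id, d, CONTROL, visits))
    if not cases or not controls:
        raise ValueError(
            f"degenerate cohort: {len(cases)} case and {len(controls)} control samples")
    target = int(round(len(cases) * config.control_ratio))
    if len(controls) > target:
        rng = np.random.default_rng(config.seed)
        keep = rng.choice(len(controls), size=target, replace=False)
        controls = [controls[i] for i in sorted(keep)]
    samples = cases + controls
    samples.sort(key=lambda s: (s.patient_id, s.index_date))
    return samples


def split_samples(
    samples: list[CohortSample], config: CohortConfig
) -> tuple[list[CohortSample], list[CohortSample], list[CohortSample]]:
    """Seeded patient-level partition at the configured ratios.

    All samples of one patient land in one fold (augmentation leakage guard).
    Patients are shuffled, then each is assigned to the fold with the largest
    remaining deficit relative to its target sample count.
    """
    config.validate()
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split")
    by_patient: dict[str, list[CohortSample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    pids = sorted(by_patient)
    rng = np.random.default_rng(config.seed)
    rng.shuffle(pids)
    n = len(samples)
    targets = [r * n for r in config.split_ratios]
    folds: tuple[list, list, list] = ([], [], [])
    counts = [0, 0, 0]
    for pid in pids:
        deficits = [targets[i] - counts[i] for i in range(3)]
        k = int(np.argmax(deficits))
        folds[k].extend(by_patient[pid])
        counts[k] += len(by_patient[pid])
    return folds


# ---------------------------------------------------------------------------
# on-disk representations

def samples_to_frame(samples: list[CohortSample],
                     fold_of: dict[int, str] | None = None) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(samples):
        fold = fold_of.get(i, "") if fold_of else ""
        rows.append((s.patient_id, s.index_date.isoformat(), s.label, fold))
    return pd.DataFrame(rows, columns=["patient_id", "index_date", "label", "fold"])


def _sample_obj(s: CohortSample, fold: str = "") -> dict:
    return {
        "patient_id": s.patient_id,
        "index_date": s.index_date.isoformat(),
        "label": s.label,
        "fold": fold,
        "visits": [[d.isoformat(), toks] for d, toks in s.visits],
    }


def samples_to_jsonl(samples: list[CohortSample], path,
                     fold_of: dict[int, str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(samples):
            fold = fold_of.get(i, "") if fold_of else ""
            fh.write(json.dumps(_sample_obj(s, fold), sort_keys=True) + "\n")


def samples_from_jsonl(path) -> tuple[list[CohortSample], list[str]]:
    samples, folds = [], []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            visits = [(dt.date.fromisoformat(d), toks) for d, toks in obj["visits"]]
            samples.append(CohortSample(obj["patient_id"],
                                        dt.date.fromisoformat(obj["index_date"]),
                                        obj["label"], visits))
            folds.append(obj.get("fold", ""))
    return samples, folds
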
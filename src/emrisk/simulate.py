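"""Synthetic longitudinal EMR cohorts with a planted discrete-time psychosis hazard.

The simulator emits per-patient encounter streams (diagnosis groups, drug
identifiers, flagged lab results) over several years of follow-up.  Every
patient receives an Alzheimer's-disease (AD) anchor diagnosis at a random
onset date; thereafter, conversion to psychosis is drawn window-by-window
from a discrete-time Bernoulli hazard over consecutive fixed-length windows
(90 days by default, the conventional "3 month" horizon).  Planted codes act
on the hazard through a log-relative-risk on the logit scale, optionally
decayed by an exponential recency half-life so that *when* a code last
occurred carries signal beyond whether it occurred at all.

Background codes are inert by construction (log-RR = 0), which makes the
cohort a null distribution for downstream attribution statistics.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SimConfig",
    "benchmark_planted_effects",
    "recency_benchmark_config",
    "LabEvent",
    "Encounter",
    "PatientRecord",
    "window_hazard",
    "generate_cohort",
    "empirical_relative_risk",
    "to_event_table",
    "from_event_table",
]

EPOCH = dt.date(2004, 1, 1)


def benchmark_planted_effects() -> dict[str, float]:
    """The default multi-factor risk profile for benchmark cohorts.

    Two focal codes — a hazardous diagnosis group at relative risk 2.5 and a
    protective drug at 0.4 — plus accessory hazardous/protective diagnoses,
    drugs and labs of moderate strength.  A realistic AD cohort carries many
    simultaneous risk modifiers; a cohort with a single planted factor caps
    outcome predictability far below what the attribution method assumes.
    """
    ln = math.log
    return {
        "E11": ln(2.5),       # focal hazardous diagnosis
        "DB00316": ln(0.4),   # focal protective drug
        "I48": ln(2.0), "F32": ln(1.8), "N17": ln(2.2),
        "DB00945": ln(0.5), "DB01234": ln(0.6),
        "L050": ln(1.7), "L051": ln(0.55),
    }

ABNORMAL_FLAGS = ("ABNORMAL", "HIGH", "LOW")
ALL_FLAGS = ABNORMAL_FLAGS + ("NORMAL",)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``planted_effects`` maps a code (a 3-character diagnosis group such as
    ``"E11"``, a drug identifier such as ``"DB00316"``, or a lab identifier)
    to a log-relative-risk on the per-window psychosis hazard.  Codes absent
    from the map — the background pools — have no effect on the outcome.
    """

    n_patients: int = 1000
    seed: int = 0
    years_followup: float = 8.0
    encounters_per_year: float = 10.0
    n_background_dx: int = 30
    n_background_rx: int = 20
    n_background_lab: int = 10
    planted_effects: dict[str, float] = field(default_factory=dict)
    recency_halflife_days: float = 180.0
    baseline_window_hazard: float = 0.01
    ad_onset_uniform_range: tuple[int, int] = (400, 800)
    washout_violation_rate: float = 0.05
    delirium_cooccurrence_rate: float = 0.05
    window_days: int = 90
    # per-patient probability of carrying a planted code, and per-encounter
    # probability that a carried code is recorded
    planted_carrier_prob: float = 0.30
    code_occurrence_prob: float = 0.25
    ad_recoding_prob: float = 0.7
    ad_code: str = "G30"
    psychosis_code: str = "F29"
    delirium_code: str = "F05"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 < self.baseline_window_hazard < 1.0):
            raise ValueError("baseline_window_hazard must lie in (0, 1)")
        if self.recency_halflife_days <= 0:
            raise ValueError("recency_halflife_days must be > 0")
        if self.encounters_per_year <= 0:
            raise ValueError("encounters_per_year must be > 0")
        for code, log_rr in self.planted_effects.items():
            if not math.isfinite(log_rr):
                raise ValueError(f"non-finite log relative risk for {code!r}")
            if code in {self.ad_code, self.psychosis_code, self.delirium_code}:
                raise ValueError(f"planted code {code!r} collides with an anchor code")
        lo, hi = self.ad_onset_uniform_range
        if lo > hi or lo < 0:
            raise ValueError("invalid ad_onset_uniform_range")


def recency_benchmark_config(n_patients: int = 1500, seed: int = 0) -> "SimConfig":
    """Benchmark where the outcome signal is carried by timing alone.

    A single hazardous diagnosis is carried by every patient (its presence in
    a one-year lookback is nearly certain for cases and controls alike), but
    its effect on the 90-day hazard decays with a 60-day half-life, so only
    *recent* occurrences matter.  A bag-of-codes model is blind to this
    structure; a sequence model is not.
    """
    return SimConfig(
        n_patients=n_patients, seed=seed,
        planted_effects={"I10": math.log(4.0)},
        recency_halflife_days=60.0,
        planted_carrier_prob=1.0,
        code_occurrence_prob=0.3,
    )


@dataclass(frozen=True)
class LabEvent:
    lab_id: str
    flag: str  # one of ALL_FLAGS


@dataclass
class Encounter:
    patient_id: str
    date: dt.date
    dx_codes: list[str] = field(default_factory=list)
    rx_codes: list[str] = field(default_factory=list)
    lab_events: list[LabEvent] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    birth_year: int
    encounters: list[Encounter]
    ad_onset: dt.date | None = None
    psychosis_dates: list[dt.date] = field(default_factory=list)
    delirium_dates: list[dt.date] = field(default_factory=list)

    @property
    def first_encounter(self) -> dt.date:
        return self.encounters[0].date

    @property
    def last_encounter(self) -> dt.date:
        return self.encounters[-1].date


def window_hazard(
    baseline_window_hazard: float,
    planted_effects: dict[str, float],
    active_exposures: dict[str, float],
) -> float:
    """Per-window event probability under active code exposures.

    Inverse-logit of ``logit(baseline) + sum_f log_rr_f * weight_f`` where the
    weights are recency weights in [0, 1]; codes without a planted effect
    contribute nothing.
    """
    if not (0.0 < baseline_window_hazard < 1.0):
        raise ValueError("baseline hazard must lie in (0, 1)")
    eta = logit(baseline_window_hazard)
    for code, weight in active_exposures.items():
        log_rr = planted_effects.get(code, 0.0)
        if not math.isfinite(log_rr):
            raise ValueError(f"non-finite log relative risk for {code!r}")
        if not (0.0 <= weight <= 1.0):
            raise ValueError("recency weights must lie in [0, 1]")
        eta += log_rr * weight
    p = float(expit(eta))
    tiny = np.finfo(float).tiny
    return min(max(p, tiny), 1.0 - 1e-15)


def _background_pools(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    reserved = {config.ad_code, config.psychosis_code, config.delirium_code}
    reserved |= set(config.planted_effects)
    dx, letters = [], "ABCDEHIJKLMNR"
    i = 0
    while len(dx) < config.n_background_dx:
        code = f"{letters[i % len(letters)]}{i // len(letters):02d}"
        i += 1
        if code not in reserved:
            dx.append(code)
    rx = []
    i = 0
    while len(rx) < config.n_background_rx:
        code = f"DB9{i:04d}"
        i += 1
        if code not in reserved:
            rx.append(code)
    lab = []
    i = 0
    while len(lab) < config.n_background_lab:
        code = f"L{i:03d}"
        i += 1
        if code not in reserved:
            lab.append(code)
    return dx, rx, lab


def _code_kind(code: str) -> str:
    """Classify a planted code into DX / RX / LAB by its shape."""
    if code.startswith("DB"):
        return "RX"
    if code.startswith("L") and code[1:].isdigit():
        return "LAB"
    return "DX"


def generate_cohort(config: SimConfig) -> list[PatientRecord]:
    """Draw a fully synthetic cohort under ``config`` (seed-deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    span = int(round(config.years_followup * 365))
    if span <= max(config.ad_onset_uniform_range):
        raise ValueError("followup too short for the AD onset range")

    dx_pool, rx_pool, lab_pool = _background_pools(config)
    planted = list(config.planted_effects)
    # fixed per-code prevalence parameters, drawn once per cohort
    bg_codes = dx_pool + rx_pool + lab_pool
    bg_kind = ["DX"] * len(dx_pool) + ["RX"] * len(rx_pool) + ["LAB"] * len(lab_pool)
    bg_carrier = rng.uniform(0.05, 0.5, size=len(bg_codes))
    bg_occ = rng.uniform(0.10, 0.40, size=len(bg_codes))

    records: list[PatientRecord] = []
    halflife = config.recency_halflife_days
    for idx in range(config.n_patients):
        pid = f"P{idx:05d}"
        sex = "F" if rng.random() < 0.66 else "M"
        birth_year = int(rng.integers(1920, 1950))
        ad_day = int(rng.integers(config.ad_onset_uniform_range[0],
                                  config.ad_onset_uniform_range[1] + 1))
        n_enc = max(2, rng.poisson(config.encounters_per_year * config.years_followup))
        days = np.unique(rng.integers(0, span, size=n_enc))
        days = np.union1d(days, [0, ad_day])
        n_enc = len(days)

        # occurrence matrices: code x encounter
        carrier_bg = rng.random(len(bg_codes)) < bg_carrier
        occ_bg = (rng.random((len(bg_codes), n_enc)) < bg_occ[:, None]) & carrier_bg[:, None]
        carrier_pl = rng.random(len(planted)) < config.planted_carrier_prob
        occ_pl = (rng.random((len(planted), n_enc))
                  < config.code_occurrence_prob) & carrier_pl[:, None]
        ad_mask = days >= ad_day
        occ_ad = ad_mask & (rng.random(n_enc) < config.ad_recoding_prob)
        occ_ad[days == ad_day] = True

        lab_flags = rng.choice(len(ALL_FLAGS), size=(len(bg_codes), n_enc),
                               p=[0.15, 0.15, 0.15, 0.55])

        encounters: list[Encounter] = []
        day_to_idx: dict[int, int] = {}
        for j, day in enumerate(days):
            date = EPOCH + dt.timedelta(days=int(day))
            dx, rx, labs = [], [], []
            for k, code in enumerate(bg_codes):
                if occ_bg[k, j]:
                    if bg_kind[k] == "DX":
                        dx.append(code)
                    elif bg_kind[k] == "RX":
                        rx.append(code)
                    else:
                        labs.append(LabEvent(code, ALL_FLAGS[lab_flags[k, j]]))
            for k, code in enumerate(planted):
                if occ_pl[k, j]:
                    kind = _code_kind(code)
                    if kind == "DX":
                        dx.append(code)
                    elif kind == "RX":
                        rx.append(code)
                    else:
                        labs.append(LabEvent(code, "ABNORMAL"))
            if occ_ad[j]:
                dx.append(config.ad_code)
            day_to_idx[int(day)] = len(encounters)
            encounters.append(Encounter(pid, date, dx, rx, labs))

        # last occurrence day of each planted code, for recency weights
        pl_days = [days[occ_pl[k]] for k in range(len(planted))]

        record = PatientRecord(
            patient_id=pid, sex=sex, birth_year=birth_year,
            encounters=encounters, ad_onset=EPOCH + dt.timedelta(days=ad_day),
        )

        # discrete-time hazard over consecutive windows after AD onset
        ws = ad_day
        while ws < span:
            exposures: dict[str, float] = {}
            for k, code in enumerate(planted):
                prior = pl_days[k][pl_days[k] <= ws]
                if prior.size:
                    if math.isinf(halflife):
                        exposures[code] = 1.0
                    else:
                        exposures[code] = 0.5 ** ((ws - prior.max()) / halflife)
            p = window_hazard(config.baseline_window_hazard,
                              config.planted_effects, exposures)
            if rng.random() < p:
                lo = ws
                hi = min(ws + config.window_days, span)
                onset_day = int(rng.integers(lo, hi))
                onset = EPOCH + dt.timedelta(days=onset_day)
                psych_enc = Encounter(pid, onset, [config.psychosis_code], [], [])
                record.psychosis_dates.append(onset)
                if rng.random() < config.delirium_cooccurrence_rate:
                    psych_enc.dx_codes.append(config.delirium_code)
                    record.delirium_dates.append(onset)
                _insert_encounter(record, psych_enc, day_to_idx, onset_day)
                break
            ws += config.window_days

        if rng.random() < config.washout_violation_rate:
            vday = int(rng.integers(max(0, ad_day - 365), max(1, ad_day - 30)))
            vdate = EPOCH + dt.timedelta(days=vday)
            venc = Encounter(pid, vdate, [config.psychosis_code], [], [])
            record.psychosis_dates.append(vdate)
            _insert_encounter(record, venc, day_to_idx, vday)
            record.psychosis_dates.sort()

        records.append(record)
    return records


def _insert_encounter(record: PatientRecord, enc: Encounter,
                      day_to_idx: dict[int, int], day: int) -> None:
    """Insert keeping encounters date-sorted; merge if the day already exists."""
    if day in day_to_idx:
        existing = record.encounters[day_to_idx[day]]
        existing.dx_codes.extend(enc.dx_codes)
        existing.rx_codes.extend(enc.rx_codes)
        existing.lab_events.extend(enc.lab_events)
        return
    dates = [e.date for e in record.encounters]
    pos = int(np.searchsorted(np.array([ (d - EPOCH).days for d in dates]), day))
    record.encounters.insert(pos, enc)
    # positions after insertion shift by one
    for d, i in list(day_to_idx.items()):
        if i >= pos:
            day_to_idx[d] = i + 1
    day_to_idx[day] = pos


def _patient_windows(record: PatientRecord, code: str, horizon_days: int):
    """Yield (exposed, event) per consecutive post-AD window up to first psychosis."""
    if record.ad_onset is None:
        return
    occ_days = sorted(
        (e.date - EPOCH).days
        for e in record.encounters
        if code in e.dx_codes or code in e.rx_codes
        or any(le.lab_id == code for le in e.lab_events)
    )
    occ = np.array(occ_days)
    post_ad = [d for d in record.psychosis_dates if d > record.ad_onset]
    first_psych = min(post_ad) if post_ad else None
    start = (record.ad_onset - EPOCH).days
    end = (record.last_encounter - EPOCH).days
    ws = start
    while ws <= end:
        exposed = bool(occ.size and occ[occ <= ws].size)
        event = (first_psych is not None
                 and ws < (first_psych - EPOCH).days <= ws + horizon_days)
        yield exposed, event
        if event:
            return
        ws += horizon_days


def empirical_relative_risk(records: list[PatientRecord], code: str,
                            horizon_days: int = 90) -> float:
    """Ratio of window-level event incidence, exposed vs unexposed strata.

    Returns ``nan`` (undefined) when either stratum contains no windows or the
    unexposed stratum has zero incidence.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    n_exp = n_unexp = ev_exp = ev_unexp = 0
    for rec in records:
        for exposed, event in _patient_windows(rec, code, horizon_days):
            if exposed:
                n_exp += 1
                ev_exp += event
            else:
                n_unexp += 1
                ev_unexp += event
    if n_exp == 0 or n_unexp == 0 or ev_unexp == 0:
        return float("nan")
    return (ev_exp / n_exp) / (ev_unexp / n_unexp)


# ---------------------------------------------------------------------------
# flat event-table export / import

def to_event_table(records: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient-date-code: patient_id, date, code_type, code, result_flag."""
    rows = []
    for rec in records:
        for enc in rec.encounters:
            iso = enc.date.isoformat()
            for c in enc.dx_codes:
                rows.append((rec.patient_id, iso, "DX", c, ""))
            for c in enc.rx_codes:
                rows.append((rec.patient_id, iso, "RX", c, ""))
            for le in enc.lab_events:
                rows.append((rec.patient_id, iso, "LAB", le.lab_id, le.flag))
    return pd.DataFrame(rows, columns=["patient_id", "date", "code_type",
                                       "code", "result_flag"])


def patients_table(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.sex, r.birth_year) for r in records],
        columns=["patient_id", "sex", "birth_year"],
    )


def from_event_table(
    events: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    ad_code: str = "G30",
    psychosis_code: str = "F29",
    delirium_code: str = "F05",
) -> list[PatientRecord]:
    """Reconstruct patient records from the flat event table.

    AD onset is the first date carrying the AD diagnosis code; psychosis and
    delirium dates are the dates of their respective diagnosis codes.
    """
    demo = {}
    if patients is not None:
        demo = {r.patient_id: (r.sex, int(r.birth_year))
                for r in patients.itertuples()}
    records = []
    for pid, grp in events.groupby("patient_id", sort=True):
        encounters = []
        psych, delir, ad_onset = [], [], None
        for iso, g in grp.groupby("date", sort=True):
            date = dt.date.fromisoformat(iso)
            dx = [r.code for r in g.itertuples() if r.code_type == "DX"]
            rx = [r.code for r in g.itertuples() if r.code_type == "RX"]
            labs = [LabEvent(r.code, r.result_flag)
                    for r in g.itertuples() if r.code_type == "LAB"]
            encounters.append(Encounter(str(pid), date, dx, rx, labs))
            if ad_code in dx and ad_onset is None:
                ad_onset = date
            if psychosis_code in dx:
                psych.append(date)
            if delirium_code in dx:
                delir.append(date)
        sex, by = demo.get(str(pid), ("U", 0))
        records.append(PatientRecord(str(pid), sex, by, encounters,
                                     ad_onset, psych, delir))
    return records
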
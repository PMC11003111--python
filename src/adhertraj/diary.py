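"""Eligibility cascade, supply diaries and interval-wise PDC panels.

Visit registrations are converted to medication supply under the study's
dispensing rules: each visit at which AET use is reported grants a 182-day
(six-month) supply; unused supply is carried forward, but at each
six-month interval boundary the on-hand balance is truncated to at most
182 days.  Coverage runs from the first AET registration (index date) to
the earliest of censoring or five years post-diagnosis.  An aromatase-
inhibitor registration after tamoxifen initiation still counts as
adherence.

The proportion of days covered (PDC) in interval t is the covered days in
that interval divided by the interval length; the final interval's
denominator is shortened to the days actually observed before censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from adhertraj.simulate import FOLLOW_UP_DAYS, INTERVAL_DAYS

SUPPLY_DAYS = 182          # days dispensed per qualifying registration
CARRY_FORWARD_CAP = 182    # max balance surviving an interval boundary
MIN_LAST_INTERVAL_DAYS = 14  # shorter censored tails carry too little signal
MIN_FOLLOW_UP_DAYS = 365   # eligibility requires >= 1 year after initiation
MAX_AGE_AT_DIAGNOSIS = 55  # premenopausal cohort cut-off


class DiaryError(ValueError):
    """Raised when a supply diary or panel cannot be constructed."""


@dataclass
class ExclusionLog:
    """Counts removed and surviving at each eligibility step, in order."""

    starting_count: int
    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, removed: int) -> None:
        prev = self.steps[-1]["remaining"] if self.steps else self.starting_count
        self.steps.append({"step": name, "removed": removed, "remaining": prev - removed})

    @property
    def survivors(self) -> int:
        return self.steps[-1]["remaining"] if self.steps else self.starting_count

    def to_dict(self) -> dict:
        return {"starting_count": self.starting_count, "steps": self.steps,
                "survivors": self.survivors}


@dataclass
class SupplyDiary:
    """Per-patient dispensing timeline and resulting day coverage."""

    patient_id: str
    index_date: int                      # first AET registration
    end_date: int                        # min(censoring, diagnosis + 5y)
    dispensings: list[tuple[int, int]]   # (date, days supplied)
    coverage: list[tuple[int, int]]      # half-open covered ranges [a, b)

    @property
    def covered_days(self) -> int:
        return sum(b - a for a, b in self.coverage)


def apply_eligibility(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    censoring: pd.DataFrame,
    follow_up_days: int = FOLLOW_UP_DAYS,
) -> tuple[list, ExclusionLog]:
    """Apply the cohort eligibility cascade; returns (eligible ids, log).

    Steps, in order: ER-negative (only when an ``er_status`` column is
    present); no AET registration at all; under one year of follow-up after
    initiation; age 55+ at diagnosis or first registered therapy an
    aromatase inhibitor; initiation before diagnosis, after a recurrence,
    or after a second primary cancer.
    """
    pid_set = set(patients["patient_id"])
    orphans = (set(visits["patient_id"]) | set(censoring["patient_id"])) - pid_set
    if orphans:
        raise ValueError(f"visit/censoring records for unknown patients: {sorted(orphans)[:10]}")

    log = ExclusionLog(starting_count=len(patients))
    current = patients

    if "er_status" in current.columns:
        keep = current["er_status"] != "negative"
        log.record("er_negative", int((~keep).sum()))
        current = current[keep]

    reg = visits[visits["aet_reported"] == 1]
    first_reg = reg.sort_values("visit_date").groupby("patient_id").first()
    init_date = first_reg["visit_date"]
    first_therapy = first_reg["therapy"]

    has_reg = current["patient_id"].isin(init_date.index)
    log.record("no_aet_registration", int((~has_reg).sum()))
    current = current[has_reg]

    cens = censoring.sort_values("event_date").groupby("patient_id").first()
    diag = current.set_index("patient_id")["diagnosis_date"]
    init = init_date.reindex(diag.index)
    end = (diag + follow_up_days).astype(float)
    cens_date = cens["event_date"].reindex(diag.index)
    end = np.minimum(end, cens_date.astype(float).fillna(np.inf))
    # initiation after the censoring date is handled by the timing step below
    short = ((end - init) < MIN_FOLLOW_UP_DAYS) & (init <= end)
    log.record("under_one_year_follow_up", int(short.sum()))
    current = current[~short.to_numpy()]

    diag = current.set_index("patient_id")["diagnosis_date"]
    age_ai = (current["age_at_diagnosis"].to_numpy() >= MAX_AGE_AT_DIAGNOSIS) | (
        first_therapy.reindex(diag.index).to_numpy() == "AI"
    )
    log.record("age_55_plus_or_ai_initiation", int(age_ai.sum()))
    current = current[~age_ai]

    diag = current.set_index("patient_id")["diagnosis_date"]
    init = init_date.reindex(diag.index)
    before_diag = init < diag
    blocking = cens[cens["reason"].isin(["recurrence", "second_primary"])]
    block_date = blocking["event_date"].reindex(diag.index)
    after_event = init > block_date.astype(float).fillna(np.inf)
    bad_timing = (before_diag | after_event).to_numpy()
    log.record("initiation_timing", int(bad_timing.sum()))
    current = current[~bad_timing]

    return current["patient_id"].tolist(), log


def build_supply_diary(
    visits: pd.DataFrame,
    censoring: pd.DataFrame,
    diagnosis_date: int,
    patient_id: str | None = None,
    supply_days: int = SUPPLY_DAYS,
    cap_days: int = CARRY_FORWARD_CAP,
    interval_len_days: int = INTERVAL_DAYS,
    follow_up_days: int = FOLLOW_UP_DAYS,
) -> SupplyDiary:
    """Build one patient's supply diary from their visit registrations.

    Event-driven coverage engine: the on-hand balance gains ``supply_days``
    at each qualifying registration, is consumed one day per calendar day
    while positive, and is truncated to ``cap_days`` at every interval
    boundary (boundaries anchored at the index date).  At a boundary that
    coincides with a registration the carried-forward balance is capped
    *before* the new supply is added.
    """
    if patient_id is None:
        ids = visits["patient_id"].unique()
        if len(ids) != 1:
            raise ValueError("pass patient_id when visits span multiple patients")
        patient_id = ids[0]
    v = visits[(visits["patient_id"] == patient_id) & (visits["aet_reported"] == 1)]
    if v.empty:
        raise DiaryError(f"no qualifying AET registration for {patient_id}")
    reg_dates = sorted(set(int(d) for d in v["visit_date"]))  # same-day duplicates collapse

    index_date = reg_dates[0]
    end_date = diagnosis_date + follow_up_days
    c = censoring[censoring["patient_id"] == patient_id]
    if not c.empty:
        end_date = min(end_date, int(c["event_date"].min()))
    if end_date <= index_date:
        raise DiaryError(f"diary for {patient_id} has no observable time")

    reg_dates = [d for d in reg_dates if d < end_date]
    dispensings = [(d, supply_days) for d in reg_dates]

    n_bound = (end_date - index_date) // interval_len_days
    boundaries = {index_date + k * interval_len_days for k in range(1, n_bound + 1)}
    events = sorted(set(reg_dates) | boundaries | {end_date})

    coverage: list[tuple[int, int]] = []
    balance = 0
    day = index_date
    reg_set = set(reg_dates)
    for ev in events:
        if ev > day:
            span = ev - day
            covered = min(balance, span)
            if covered > 0:
                if coverage and coverage[-1][1] == day:
                    coverage[-1] = (coverage[-1][0], day + covered)
                else:
                    coverage.append((day, day + covered))
                balance -= covered
            day = ev
        if ev == end_date:
            break
        if ev in boundaries:
            balance = min(balance, cap_days)
        if ev in reg_set:
            balance += supply_days
    return SupplyDiary(patient_id, index_date, end_date, dispensings, coverage)


def compute_pdc(
    diary: SupplyDiary,
    interval_len_days: int = INTERVAL_DAYS,
    min_last_interval_days: int = MIN_LAST_INTERVAL_DAYS,
) -> pd.DataFrame:
    """Interval-wise PDC panel for one diary (long format).

    Intervals tile [index_date, end_date) anchored at the index date; the
    final interval's denominator is the observed days before end_date.  A
    trailing fragment shorter than ``min_last_interval_days`` is dropped.
    """
    span = diary.end_date - diary.index_date
    if span <= 0:
        raise DiaryError("end_date must exceed index_date")
    n_int = math.ceil(span / interval_len_days)
    rows = []
    for t in range(n_int):
        a = diary.index_date + t * interval_len_days
        b = min(a + interval_len_days, diary.end_date)
        denom = b - a
        if denom < min_last_interval_days and t == n_int - 1 and t > 0:
            break
        covered = sum(max(0, min(hi, b) - max(lo, a)) for lo, hi in diary.coverage)
        rows.append((diary.patient_id, t, covered, denom, covered / denom))
    return pd.DataFrame(
        rows, columns=["patient_id", "t", "covered_days", "denominator_days", "pdc"]
    )


def panels_from_visits(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    censoring: pd.DataFrame,
    eligible_ids=None,
    interval_len_days: int = INTERVAL_DAYS,
    cap_days: int = CARRY_FORWARD_CAP,
) -> pd.DataFrame:
    """Build the full cohort PDC panel (one diary per eligible patient)."""
    if eligible_ids is None:
        eligible_ids, _ = apply_eligibility(patients, visits, censoring)
    diag = patients.set_index("patient_id")["diagnosis_date"]
    vis_by_pid = dict(tuple(visits.groupby("patient_id")))
    cens_by_pid = dict(tuple(censoring.groupby("patient_id")))
    empty_c = censoring.iloc[0:0]
    panels = []
    for pid in eligible_ids:
        v = vis_by_pid.get(pid)
        if v is None:
            continue
        diary = build_supply_diary(
            v, cens_by_pid.get(pid, empty_c), int(diag[pid]), patient_id=pid,
            cap_days=cap_days, interval_len_days=interval_len_days,
        )
        panels.append(compute_pdc(diary, interval_len_days))
    if not panels:
        raise DiaryError("no panels could be constructed")
    return pd.concat(panels, ignore_index=True)
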
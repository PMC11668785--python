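"""Cohort preparation: from raw long-format laboratory measurements to an
analysis-ready set of patient timelines.

Pipeline (mirroring standard EHR-cohort practice for CKD):

1. monthly resampling — daily test results are aggregated into mean values per
   calendar month, to stop hospitalisation bursts from dominating;
2. time-zero definition — the first recorded eGFR marks the start of
   observation (the ``sens`` variant instead anchors on the earliest eGFR
   within a lookback window of the event / last test);
3. exclusions — missing sex or birth date, death recorded before the first
   test (incorrect dates), and pre-existing end-stage kidney disease
   (dialysis or transplant at or before time 0);
4. event adjudication — ESKD (cause 1) at the earlier of dialysis/transplant
   start or a sustained eGFR <= threshold with no later recovery above the
   recovery threshold; death (cause 2) otherwise; else censoring at the data
   extraction date or the last test date;
5. density filtering — keep patients with at least ``min_count_per_analyte``
   monthly entries for every required analyte (``acr3`` additionally requires
   urine albumin-creatinine ratio entries);
6. baseline imputation (training folds only; simplified predictive mean
   matching) and last-observation-carried-forward filling.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_MONTH, DAYS_PER_YEAR, EGFR

__all__ = [
    "CohortConfig",
    "PatientTimeline",
    "REQUIRED_ANALYTES",
    "resample_monthly",
    "apply_density_filter",
    "adjudicate_events",
    "exclude_prevalent",
    "impute_baseline",
    "locf_fill",
    "prepare_cohort",
]

logger = logging.getLogger(__name__)

MONTH_YEARS = DAYS_PER_MONTH / DAYS_PER_YEAR

REQUIRED_ANALYTES: tuple[str, ...] = (
    "hemoglobin", "wcc", "platelets", EGFR, "sodium", "potassium", "chloride",
    "bicarbonate", "calcium", "phosphate", "albumin", "alp", "glucose",
)

CENSORED, ESKD, DEATH = 0, 1, 2


@dataclass(frozen=True)
class CohortConfig:
    variant: str = "dense3"
    required_analytes: tuple[str, ...] = REQUIRED_ANALYTES
    min_count_per_analyte: int = 3
    eskd_egfr_threshold: float = 15.0
    recovery_threshold: float = 17.0
    censor_rule: str = "extraction_date"
    lookback_years: float = 10.0
    extraction_date: str = "2022-01-14"
    upcr_to_uacr: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.variant not in ("dense3", "sens", "acr3"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.censor_rule not in ("extraction_date", "last_test_date"):
            raise ValueError(f"unknown censor_rule {self.censor_rule!r}")
        if self.recovery_threshold <= self.eskd_egfr_threshold:
            raise ValueError("recovery_threshold must exceed eskd_egfr_threshold")
        if self.min_count_per_analyte < 1:
            raise ValueError("min_count_per_analyte must be >= 1")

    def for_variant(self, variant: str) -> "CohortConfig":
        if variant == "sens":
            return replace(self, variant="sens", censor_rule="last_test_date")
        return replace(self, variant=variant)


@dataclass
class PatientTimeline:
    """One patient's demographics, monthly analyte series and outcome.

    ``series`` maps analyte name to a float Series indexed by month number
    from time 0 (sparse: absent months carry no value).  ``cause`` is
    0 censored / 1 ESKD / 2 death; ``event_time`` is in years from time 0.
    """

    patient_id: int
    sex: str
    age_at_time0: float
    gn_vasculitis: float  # 1.0 biopsy-verified, else NaN (missing level)
    time0_date: pd.Timestamp
    series: dict[str, pd.Series] = field(default_factory=dict)
    cause: int = CENSORED
    event_time: float = np.nan
    last_test_date: Optional[pd.Timestamp] = None

    def copy(self) -> "PatientTimeline":
        new = copy.copy(self)
        new.series = {k: v.copy() for k, v in self.series.items()}
        return new

    def baseline(self, analyte: str) -> float:
        s = self.series.get(analyte)
        if s is None or 0 not in s.index:
            return np.nan
        return float(s.loc[0])


def _measurement_dates(measurements: pd.DataFrame,
                       demographics: pd.DataFrame) -> pd.DataFrame:
    m = measurements.merge(demographics[["patient_id", "entry_date"]],
                           on="patient_id", how="inner")
    m["date"] = pd.to_datetime(m["entry_date"]) + pd.to_timedelta(
        m["time_days"], unit="D")
    return m.drop(columns=["entry_date"])


def resample_monthly(measurements: pd.DataFrame,
                     demographics: pd.DataFrame) -> pd.DataFrame:
    """Mean value per (patient, analyte, calendar month).

    Non-numeric values are rejected record-by-record with a log entry; months
    with no values are simply absent.  Returns columns
    (patient_id, analyte, period, value) with ``period`` a monthly Period.
    """
    m = _measurement_dates(measurements, demographics)
    numeric = pd.to_numeric(m["value"], errors="coerce")
    bad = numeric.isna() & m["value"].notna()
    if bad.any():
        logger.warning("rejected %d non-numeric measurement records", int(bad.sum()))
    m = m.loc[~numeric.isna()].assign(value=numeric[~numeric.isna()])
    m["period"] = m["date"].dt.to_period("M")
    out = (m.groupby(["patient_id", "analyte", "period"], as_index=False)
           ["value"].mean())
    return out


def _month_index(period: pd.Period, time0: pd.Timestamp) -> int:
    mid = period.to_timestamp() + pd.Timedelta(days=14)
    return max(0, int(np.floor((mid - time0).days / DAYS_PER_MONTH)))


def _build_series(monthly_pat: pd.DataFrame, time0: pd.Timestamp
                  ) -> dict[str, pd.Series]:
    # vectorised equivalent of _month_index per record
    mid = monthly_pat["period"].dt.to_timestamp() + pd.Timedelta(days=14)
    offset = (mid - time0).dt.days.to_numpy()
    month = np.maximum(0, np.floor(offset / DAYS_PER_MONTH).astype(int))
    df = monthly_pat.assign(month=month)
    series: dict[str, pd.Series] = {}
    for analyte, grp in df.groupby("analyte"):
        series[str(analyte)] = (grp.groupby("month")["value"].mean()
                                .astype(float))
    return series


def adjudicate_events(timeline: PatientTimeline,
                      outcomes: pd.DataFrame,
                      config: CohortConfig) -> tuple[int, float]:
    """Adjudicate (cause, event_time in years from time 0) for one patient.

    ESKD time is the earliest of (i) dialysis/transplant commencement and
    (ii) the first monthly eGFR at or below the ESKD threshold that is never
    followed by any eGFR above the recovery threshold.  If ESKD precedes
    death, the cause is ESKD; otherwise death; otherwise censoring at the
    extraction date (default) or the last test date (``sens``).  Threshold
    events are timed at their month with a half-month floor so event times
    stay positive.
    """
    egfr = timeline.series.get(EGFR)
    if egfr is None or len(egfr) == 0:
        raise ValueError(f"patient {timeline.patient_id}: empty eGFR series")
    t0 = timeline.time0_date

    def years(date) -> float:
        return (pd.Timestamp(date) - t0).days / DAYS_PER_YEAR

    rows = outcomes[outcomes["patient_id"] == timeline.patient_id]
    eskd_candidates: list[float] = []
    for ev in ("dialysis_start", "transplant"):
        dates = rows.loc[rows["event"] == ev, "date"]
        if len(dates):
            eskd_candidates.append(years(dates.min()))

    vals = egfr.sort_index()
    months = vals.index.to_numpy()
    below = vals.to_numpy() <= config.eskd_egfr_threshold
    recov = vals.to_numpy() > config.recovery_threshold
    # first below-threshold month never followed by a recovery
    any_recov_after = np.cumsum(recov[::-1])[::-1]  # recoveries at or after i
    for i in np.nonzero(below)[0]:
        later = any_recov_after[i + 1] if i + 1 < len(vals) else 0
        if later == 0:
            eskd_candidates.append(max(months[i], 0.5) * MONTH_YEARS)
            break

    death_dates = rows.loc[rows["event"] == "death", "date"]
    death_time = years(death_dates.min()) if len(death_dates) else None
    eskd_time = min(eskd_candidates) if eskd_candidates else None

    if eskd_time is not None and (death_time is None or eskd_time <= death_time):
        return ESKD, max(eskd_time, 0.5 * MONTH_YEARS)
    if death_time is not None:
        return DEATH, max(death_time, 0.5 * MONTH_YEARS)
    if config.censor_rule == "extraction_date":
        cens = years(pd.Timestamp(config.extraction_date))
    else:
        cens = years(timeline.last_test_date)
    return CENSORED, max(cens, 0.5 * MONTH_YEARS)


def exclude_prevalent(demographics: pd.DataFrame,
                      outcomes: pd.DataFrame,
                      time0: dict[int, pd.Timestamp],
                      first_test: dict[int, pd.Timestamp]
                      ) -> tuple[set[int], dict[str, int]]:
    """Identify patients to drop before analysis; returns (excluded ids, tally).

    Reasons: missing sex or birth date; death recorded before the first test
    (incorrect dates); chronic dialysis or transplant at or before time 0
    (pre-existing ESKD).
    """
    tally = {"missing_demographics": 0, "incorrect_dates": 0,
             "pre_existing_eskd": 0}
    excluded: set[int] = set()
    demo = demographics.set_index("patient_id")
    for pid, row in demo.iterrows():
        if pd.isna(row.get("sex")) or pd.isna(row.get("birth_date")):
            excluded.add(pid)
            tally["missing_demographics"] += 1
    for pid, grp in outcomes.groupby("patient_id"):
        if pid in excluded or pid not in time0:
            continue
        death = grp.loc[grp["event"] == "death", "date"]
        if len(death) and pd.Timestamp(death.min()) < first_test[pid]:
            excluded.add(pid)
            tally["incorrect_dates"] += 1
            continue
        prev = grp.loc[grp["event"].isin(["dialysis_start", "transplant"]), "date"]
        if len(prev) and pd.Timestamp(prev.min()) <= time0[pid]:
            excluded.add(pid)
            tally["pre_existing_eskd"] += 1
    return excluded, tally


def _uacr_count(timeline: PatientTimeline, config: CohortConfig) -> int:
    n = len(timeline.series.get("uacr", ()))
    upcr = timeline.series.get("upcr")
    if upcr is not None and len(upcr):
        if config.upcr_to_uacr is None:
            raise ValueError(
                "acr3 variant found uPCR values but no upcr_to_uacr conversion "
                "hook was supplied")
        n += len(upcr)
    return n


def apply_density_filter(timelines: list[PatientTimeline],
                         config: CohortConfig) -> list[PatientTimeline]:
    """Keep patients with >= min_count monthly entries for every required
    analyte (acr3: additionally for uACR).  Raises if the cohort empties."""
    kept = []
    for tl in timelines:
        counts_ok = all(
            len(tl.series.get(a, ())) >= config.min_count_per_analyte
            for a in config.required_analytes)
        if counts_ok and config.variant == "acr3":
            counts_ok = _uacr_count(tl, config) >= config.min_count_per_analyte
        if counts_ok:
            kept.append(tl)
    if not kept:
        raise ValueError("density filter removed every patient")
    return kept


def impute_baseline(timelines: list[PatientTimeline], seed: int,
                    k: int = 5,
                    analytes: Optional[tuple[str, ...]] = None
                    ) -> list[PatientTimeline]:
    """Simplified predictive mean matching for missing month-0 values.

    For each analyte, a linear regression of the observed baseline value on
    (age, sex, baseline eGFR) is fitted among complete cases; each missing
    patient receives the observed value of one donor drawn (seeded) from the
    k complete cases with the nearest predicted values.  Intended for
    TRAINING folds only; test folds are filled only by carry-forward.
    """
    rng = np.random.default_rng(seed)
    out = [tl.copy() for tl in timelines]
    analytes = analytes or tuple(
        sorted({a for tl in out for a in tl.series} - {EGFR}))
    X = np.array([[1.0, tl.age_at_time0, 1.0 if tl.sex == "F" else 0.0,
                   tl.baseline(EGFR)] for tl in out])
    for a in analytes:
        y = np.array([tl.baseline(a) for tl in out])
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError(f"analyte {a!r} missing at baseline for every patient")
        if (~obs).sum() == 0:
            continue
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        yhat = X @ beta
        donor_pred = yhat[obs]
        donor_vals = y[obs]
        for i in np.nonzero(~obs)[0]:
            order = np.argsort(np.abs(donor_pred - yhat[i]), kind="stable")
            pool = donor_vals[order[:min(k, len(donor_vals))]]
            val = float(pool[rng.integers(len(pool))])
            s = out[i].series.get(a)
            if s is None:
                out[i].series[a] = pd.Series({0: val}, dtype=float)
            else:
                out[i].series[a] = pd.concat(
                    [pd.Series({0: val}, dtype=float), s]).sort_index()
    return out


def locf_fill(timeline: PatientTimeline) -> PatientTimeline:
    """Carry each analyte's most recent value forward over missing months.

    Months before the first observation stay missing.  The fill extends to
    the patient's last observed month across all analytes.
    """
    new = timeline.copy()
    if not new.series:
        return new
    max_month = max(int(s.index.max()) for s in new.series.values() if len(s))
    for a, s in new.series.items():
        if not len(s):
            continue
        first = int(s.index.min())
        grid = pd.RangeIndex(first, max_month + 1)
        new.series[a] = s.reindex(grid).ffill()
    return new


def prepare_cohort(measurements: pd.DataFrame,
                   demographics: pd.DataFrame,
                   outcomes: pd.DataFrame,
                   config: CohortConfig | None = None
                   ) -> tuple[list[PatientTimeline], dict[str, int]]:
    """Full preparation pipeline; returns (timelines, exclusion tally).

    Baseline imputation and LOCF filling are NOT applied here — they are
    fold-dependent (training-only imputation) and belong to the evaluation
    loop or to explicit calls.
    """
    config = config or CohortConfig()
    dated = _measurement_dates(measurements, demographics)
    dated = dated.loc[pd.to_numeric(dated["value"], errors="coerce").notna()]

    # per-patient anchor dates
    time0: dict[int, pd.Timestamp] = {}
    first_test: dict[int, pd.Timestamp] = {}
    window_start: dict[int, pd.Timestamp] = {}
    tally_extra = {"no_egfr": 0, "no_test_within_lookback": 0}
    out_by_pid = dict(tuple(outcomes.groupby("patient_id"))) if len(outcomes) else {}

    for pid, grp in dated.groupby("patient_id"):
        first_test[pid] = grp["date"].min()
        eg = grp.loc[grp["analyte"] == EGFR, "date"]
        if not len(eg):
            tally_extra["no_egfr"] += 1
            continue
        if config.variant == "sens":
            rows = out_by_pid.get(pid)
            ref = None
            if rows is not None and len(rows):
                ref = pd.Timestamp(rows["date"].min())
            if ref is None:
                ref = grp["date"].max()
            start = ref - pd.Timedelta(days=round(config.lookback_years * DAYS_PER_YEAR))
            eg_in = eg[eg >= start]
            if not len(eg_in):
                tally_extra["no_test_within_lookback"] += 1
                continue
            time0[pid] = eg_in.min()
            window_start[pid] = start
        else:
            time0[pid] = eg.min()

    excluded, tally = exclude_prevalent(demographics, outcomes, time0, first_test)
    tally.update(tally_extra)

    if config.variant == "sens":
        dated = dated[dated["patient_id"].isin(time0)]
        dated = dated[dated.apply(
            lambda r: r["date"] >= time0[r["patient_id"]], axis=1)]

    monthly = resample_monthly(
        dated[["patient_id", "time_days", "analyte", "value"]], demographics)

    demo = demographics.set_index("patient_id")
    timelines: list[PatientTimeline] = []
    for pid, grp in monthly.groupby("patient_id"):
        if pid in excluded or pid not in time0:
            continue
        t0 = time0[pid]
        row = demo.loc[pid]
        age = (t0 - pd.Timestamp(row["birth_date"])).days / DAYS_PER_YEAR
        gn = row.get("gn_vasculitis", np.nan)
        tl = PatientTimeline(
            patient_id=int(pid), sex=str(row["sex"]), age_at_time0=float(age),
            gn_vasculitis=float(gn) if pd.notna(gn) else np.nan,
            time0_date=t0, series=_build_series(grp, t0),
            last_test_date=dated.loc[dated["patient_id"] == pid, "date"].max())
        if EGFR not in tl.series or 0 not in tl.series[EGFR].index:
            # time 0 is the first eGFR, so month 0 must exist; guard anyway
            tally["no_egfr"] = tally.get("no_egfr", 0) + 1
            continue
        tl.cause, tl.event_time = adjudicate_events(tl, outcomes, config)
        timelines.append(tl)

    timelines = apply_density_filter(timelines, config)
    return timelines, tally
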
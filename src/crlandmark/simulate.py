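"""Synthetic longitudinal CKD-like cohort generator with known ground truth.

Emulates the structure of a tertiary nephrology cohort: ~13 longitudinal
analytes measured at irregular visits over years, patient-specific biomarker
trajectories (notably declining eGFR), cause-specific hazards for end-stage
kidney disease (ESKD, cause 1) and death (cause 2), right censoring and
missingness.  Every downstream stage of the pipeline (cohort preparation,
landmarking, forest fitting, evaluation) can therefore be tested against a
generative mechanism whose truth is computable.

The generative model is a stand-in: no real cohort is bundled and the paper
trail for this package contains no generative model for its data.  Defaults
are matched to the descriptive statistics a nephrology CKD cohort would show
(median initial age 62, baseline eGFR ~50 mL/min/1.73m2, 13-analyte panel,
~25% ESKD and ~15% death over a median ~7 years of follow-up, ~18% missing
analyte values).  See docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "inject_missingness",
    "simulate_competing_dataset",
    "two_group_true_cif",
    "DEFAULT_ANALYTES",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375

EGFR = "egfr"


@dataclass(frozen=True)
class AnalyteParams:
    """Linear mixed trajectory parameters for one analyte.

    value_i(t) = (mean + b0_i) + (slope + b1_i) * t + quad * t^2 + eps,
    b0_i ~ N(0, intercept_sd^2), b1_i ~ N(0, slope_sd^2), eps ~ N(0, resid_sd^2),
    t in years from study entry.
    """

    mean: float
    intercept_sd: float
    slope: float = 0.0
    slope_sd: float = 0.0
    quad: float = 0.0
    resid_sd: float = 1.0
    floor: Optional[float] = None

    def validate(self, name: str) -> None:
        for f in ("intercept_sd", "slope_sd", "resid_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"analyte_params[{name}].{f} must be nonnegative")


# Panel medians / IQR-derived SDs as printed for a dense CKD cohort
# (IQR/1.349 ~= SD under normality).  Units: see docs/methods.md.
DEFAULT_ANALYTES: dict[str, AnalyteParams] = {
    "hemoglobin": AnalyteParams(133.0, 18.0, -0.8, 0.8, 0.0, 7.0, floor=40.0),
    "wcc": AnalyteParams(7.3, 1.9, 0.0, 0.1, 0.0, 1.2, floor=0.5),
    "platelets": AnalyteParams(240.0, 62.0, 0.0, 2.0, 0.0, 28.0, floor=10.0),
    EGFR: AnalyteParams(50.0, 24.0, -2.5, 2.0, 0.0, 4.5, floor=2.0),
    "sodium": AnalyteParams(139.0, 2.2, 0.0, 0.05, 0.0, 2.2),
    "potassium": AnalyteParams(4.2, 0.4, 0.01, 0.02, 0.0, 0.35, floor=1.5),
    "chloride": AnalyteParams(105.0, 3.0, 0.0, 0.1, 0.0, 2.2),
    "bicarbonate": AnalyteParams(23.5, 2.8, -0.15, 0.15, 0.0, 1.8, floor=5.0),
    "calcium": AnalyteParams(2.36, 0.11, 0.0, 0.005, 0.0, 0.09, floor=1.0),
    "phosphate": AnalyteParams(1.13, 0.18, 0.01, 0.01, 0.0, 0.12, floor=0.2),
    "albumin": AnalyteParams(42.0, 3.2, -0.25, 0.2, 0.0, 2.2, floor=10.0),
    "alp": AnalyteParams(78.0, 23.0, 0.0, 1.0, 0.0, 12.0, floor=5.0),
    "glucose": AnalyteParams(5.7, 1.5, 0.02, 0.05, 0.0, 1.0, floor=2.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for :func:`simulate_cohort`.

    Hazards are log-linear in current latent biomarkers, piecewise constant on
    a monthly grid:

        log lam_ESKD(t)  = eskd_link[k0] + eskd_link["egfr"]*eGFR(t) + ...
        log lam_death(t) = death_link[k0] + death_link["age"]*(age(t)-62) + ...

    ``eskd_link``/``death_link`` map analyte names (or "age") to slopes, with
    key "intercept" for the log-baseline hazard.
    """

    n_patients: int = 500
    seed: int = 0
    followup_years: float = 16.0
    min_followup_years: float = 2.0
    visit_rate: float = 10.0
    analyte_params: dict[str, AnalyteParams] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTES)
    )
    eskd_link: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.0, EGFR: -0.13}
    )
    death_link: dict[str, float] = field(
        default_factory=lambda: {"intercept": -3.9, "age": 0.07, EGFR: -0.012}
    )
    censor_rate: float = 0.015
    missing_rate: float = 0.18
    gn_vasculitis_frac: float = 0.10
    female_frac: float = 0.45
    age_mean: float = 62.0
    age_sd: float = 16.0
    dialysis_frac: float = 0.5
    extraction_date: str = "2022-01-14"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for f in ("followup_years", "min_followup_years", "visit_rate",
                  "censor_rate", "age_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for f in ("gn_vasculitis_frac", "female_frac", "dialysis_frac"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.min_followup_years > self.followup_years:
            raise ValueError("min_followup_years must be <= followup_years")
        if EGFR not in self.analyte_params:
            raise ValueError("analyte_params must include egfr")
        for name, p in self.analyte_params.items():
            p.validate(name)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Generative truth returned alongside a simulated cohort.

    ``patients`` has one row per patient: latent random effects for eGFR,
    true (pre-censoring) event cause/time, censoring time and administrative
    follow-up.  ``cif`` is the marginal true cumulative incidence per cause on
    a yearly-resolution grid, averaged over the cohort's latent draws (each
    per-patient CIF is exact conditional on the latent trajectory), with
    Monte-Carlo standard errors of that average.
    """

    patients: pd.DataFrame
    cif: pd.DataFrame
    time_grid: np.ndarray

    def cif_at(self, cause: int, t: float) -> float:
        col = {1: "cif_eskd", 2: "cif_death"}[cause]
        idx = np.searchsorted(self.cif["time"].to_numpy(), t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[col].iloc[idx])

    def se_at(self, cause: int, t: float) -> float:
        col = {1: "se_eskd", 2: "se_death"}[cause]
        idx = np.searchsorted(self.cif["time"].to_numpy(), t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[col].iloc[idx])


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # substream per patient: stable under changes to n_patients
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _latent_value(p: AnalyteParams, b0: float, b1: float, t: np.ndarray) -> np.ndarray:
    v = (p.mean + b0) + (p.slope + b1) * t + p.quad * t * t
    if p.floor is not None:
        v = np.maximum(v, p.floor)
    return v


def _hazards(cfg: SimulationConfig, latents: dict, age0: float,
             t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cause-specific hazards on a time grid from current latent biomarkers."""
    def link(coefs: dict[str, float]) -> np.ndarray:
        eta = np.full_like(t, coefs.get("intercept", 0.0), dtype=float)
        for name, beta in coefs.items():
            if name == "intercept":
                continue
            if name == "age":
                eta = eta + beta * (age0 + t - 62.0)
            else:
                p, b0, b1 = latents[name]
                eta = eta + beta * _latent_value(p, b0, b1, t)
        return np.exp(eta)

    return link(cfg.eskd_link), link(cfg.death_link)


def _conditional_cif(lam1: np.ndarray, lam2: np.ndarray, dt: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-cause CIF increments for piecewise-constant hazards.

    Over interval m with total hazard lam = lam1+lam2, the probability of a
    cause-k failure in the interval is S(t_m) * lam_k/lam * (1 - exp(-lam dt)).
    Returns cumulative CIFs at interval right endpoints.
    """
    lam = lam1 + lam2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(lam > 0, lam1 / np.where(lam > 0, lam, 1.0), 0.0)
    surv_left = np.concatenate([[1.0], np.exp(-np.cumsum(lam * dt))])[:-1]
    jump = surv_left * (1.0 - np.exp(-lam * dt))
    return np.cumsum(frac1 * jump), np.cumsum((1.0 - frac1) * jump)


def _sample_event(lam1: np.ndarray, lam2: np.ndarray, dt: float,
                  rng: np.random.Generator) -> tuple[int, float]:
    """Inversion-sample (cause, time) from piecewise-constant cause hazards.

    Returns cause 0 with time = grid end if no event inside the grid.
    """
    lam = lam1 + lam2
    target = -np.log(rng.uniform())
    cumhaz = np.cumsum(lam * dt)
    idx = int(np.searchsorted(cumhaz, target, side="left"))
    if idx >= len(lam):
        return 0, len(lam) * dt
    prev = cumhaz[idx - 1] if idx > 0 else 0.0
    within = (target - prev) / lam[idx] if lam[idx] > 0 else dt
    t_event = idx * dt + min(within, dt)
    cause = 1 if rng.uniform() < (lam1[idx] / lam[idx]) else 2
    return cause, float(t_event)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal cohort.

    Returns ``(measurements, demographics, outcomes, truth)``:

    - measurements: long format (patient_id, time_days, analyte, value),
      visits from a homogeneous Poisson process plus a guaranteed entry visit
      at day 0 carrying an eGFR value (time 0 is the first eGFR).
    - demographics: patient_id, sex, birth_date, entry_date, gn_vasculitis
      (1 for biopsy-verified glomerulonephritis/vasculitis, else missing).
    - outcomes: long event records (patient_id, event, date) with event in
      {dialysis_start, transplant, death}.
    - truth: :class:`GroundTruth`.

    ESKD events surface downstream either as a recorded dialysis start
    (probability ``dialysis_frac``) or through the measured eGFR trajectory
    crossing and staying below the ESKD threshold, so threshold-based
    adjudication and the hazard-based truth agree by construction for those
    patients (up to visit-schedule resolution).
    """
    config.validate()
    cfg = config
    dt = 1.0 / 12.0
    extraction = pd.Timestamp(cfg.extraction_date)
    analytes = cfg.analyte_params

    meas_rows: list[tuple[int, int, str, float]] = []
    demo_rows = []
    outcome_rows = []
    truth_rows = []

    grid_years = np.arange(0.0, cfg.followup_years + 1e-9, 1.0)
    cif1_acc = np.zeros((cfg.n_patients, len(grid_years)))
    cif2_acc = np.zeros((cfg.n_patients, len(grid_years)))

    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        age0 = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18.0, 95.0))
        female = rng.uniform() < cfg.female_frac
        gn = 1.0 if rng.uniform() < cfg.gn_vasculitis_frac else np.nan
        admin_years = float(rng.uniform(cfg.min_followup_years, cfg.followup_years))

        latents = {}
        for name, p in analytes.items():
            b0 = rng.normal(0.0, p.intercept_sd) if p.intercept_sd > 0 else 0.0
            b1 = rng.normal(0.0, p.slope_sd) if p.slope_sd > 0 else 0.0
            latents[name] = (p, b0, b1)

        n_months = int(np.ceil(cfg.followup_years / dt))
        t_mid = (np.arange(n_months) + 0.5) * dt
        lam1, lam2 = _hazards(cfg, latents, age0, t_mid)

        c1, c2 = _conditional_cif(lam1, lam2, dt)
        edges = (np.arange(n_months) + 1) * dt
        gi = np.clip(np.searchsorted(edges, grid_years, side="left"), 0, n_months - 1)
        cif1_acc[i] = np.where(grid_years <= 0, 0.0, c1[gi])
        cif2_acc[i] = np.where(grid_years <= 0, 0.0, c2[gi])

        true_cause, true_time = _sample_event(lam1, lam2, dt, rng)
        cens_time = (rng.exponential(1.0 / cfg.censor_rate)
                     if cfg.censor_rate > 0 else np.inf)

        obs_end = min(admin_years, cens_time)
        if true_cause != 0 and true_time <= obs_end:
            obs_cause, obs_time = true_cause, true_time
        else:
            obs_cause, obs_time = 0, obs_end

        entry_date = extraction - pd.Timedelta(days=round(admin_years * DAYS_PER_YEAR))
        birth_date = entry_date - pd.Timedelta(days=round(age0 * DAYS_PER_YEAR))

        # ESKD surfacing route
        via_dialysis = obs_cause == 1 and rng.uniform() < cfg.dialysis_frac
        if obs_cause == 1 and via_dialysis:
            outcome_rows.append((i, "dialysis_start",
                                 entry_date + pd.Timedelta(days=round(obs_time * DAYS_PER_YEAR))))
        if obs_cause == 2:
            outcome_rows.append((i, "death",
                                 entry_date + pd.Timedelta(days=round(obs_time * DAYS_PER_YEAR))))

        # visit schedule: Poisson process + entry visit; tests stop at death
        # or censoring but may continue after ESKD (dialysis care)
        visit_horizon = obs_time if obs_cause == 2 else obs_end
        n_vis = rng.poisson(cfg.visit_rate * visit_horizon)
        times = np.sort(rng.uniform(0.0, visit_horizon, size=n_vis))
        times = np.concatenate([[0.0], times])
        if obs_cause == 1 and not via_dialysis:
            # guarantee a test at the ESKD event so the threshold rule can fire
            times = np.sort(np.append(times, obs_time))

        eskd_p = analytes[EGFR]
        for t_v in times:
            day = int(round(t_v * DAYS_PER_YEAR))
            for name, (p, b0, b1) in latents.items():
                val = float(_latent_value(p, b0, b1, np.array([t_v]))[0]
                            + rng.normal(0.0, p.resid_sd))
                if p.floor is not None:
                    val = max(val, p.floor)
                if name == EGFR and obs_cause == 1 and not via_dialysis \
                        and t_v >= obs_time - 1e-9:
                    # sustained crossing: below threshold, never recovering
                    val = min(val, 14.0 - 0.5 * (t_v - obs_time))
                    val = max(val, eskd_p.floor or 2.0)
                meas_rows.append((i, day, name, round(val, 3)))

        demo_rows.append((i, "F" if female else "M", birth_date, entry_date, gn))
        truth_rows.append((i, true_cause, true_time, cens_time, admin_years,
                           obs_cause, obs_time,
                           latents[EGFR][1], latents[EGFR][2]))

    measurements = pd.DataFrame(
        meas_rows, columns=["patient_id", "time_days", "analyte", "value"])
    # dedupe entry-visit collisions (Poisson visit exactly at day 0)
    measurements = (measurements
                    .groupby(["patient_id", "time_days", "analyte"], as_index=False)
                    ["value"].mean())
    demographics = pd.DataFrame(
        demo_rows,
        columns=["patient_id", "sex", "birth_date", "entry_date", "gn_vasculitis"])
    outcomes = pd.DataFrame(outcome_rows, columns=["patient_id", "event", "date"])
    if outcomes.empty:
        outcomes = pd.DataFrame(columns=["patient_id", "event", "date"])

    patients = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "true_cause", "true_time", "censor_time",
                 "admin_years", "obs_cause", "obs_time", "egfr_b0", "egfr_b1"])
    n = cfg.n_patients
    cif = pd.DataFrame({
        "time": grid_years,
        "cif_eskd": cif1_acc.mean(axis=0),
        "cif_death": cif2_acc.mean(axis=0),
        "se_eskd": cif1_acc.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        "se_death": cif2_acc.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
    })
    truth = GroundTruth(patients=patients, cif=cif, time_grid=grid_years)

    if cfg.missing_rate > 0:
        measurements = inject_missingness(measurements, cfg.missing_rate,
                                          seed=cfg.seed + 1)
    return measurements, demographics, outcomes, truth


def inject_missingness(measurements: pd.DataFrame, missing_rate: float,
                       seed: int) -> pd.DataFrame:
    """Uniformly delete analyte values, sparing eGFR at time 0.

    Emulates missing-completely-at-random laboratory panels.  Demographics are
    untouched (they live in a separate table) and the entry eGFR is protected
    because time 0 is defined by the first eGFR.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return measurements.copy()
    rng = np.random.default_rng(seed)
    protected = (measurements["analyte"] == EGFR) & (measurements["time_days"] == 0)
    drop = (rng.uniform(size=len(measurements)) < missing_rate) & ~protected.to_numpy()
    return measurements.loc[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Small direct competing-risks samplers (no longitudinal layer); used for
# metric calibration and forest parameter-recovery experiments.

def simulate_competing_dataset(n: int, seed: int,
                               hazard_eskd: float = 0.10,
                               hazard_death: float = 0.06,
                               censor_rate: float = 0.08,
                               followup: float = 10.0,
                               group_hazards: Optional[dict] = None,
                               n_noise: int = 2
                               ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sample (X, time, status) from constant cause-specific hazards.

    With ``group_hazards`` = {0: (l1, l2), 1: (l1, l2)} a binary ``group``
    column selects the hazard pair; otherwise hazards are homogeneous.
    ``n_noise`` independent N(0,1) columns are appended.  Status: 0 censored,
    1 ESKD-like, 2 death-like.
    """
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, size=n) if group_hazards else np.zeros(n, dtype=int)
    l1 = np.where(group == 1, *(
        (group_hazards[1][0], group_hazards[0][0]) if group_hazards
        else (hazard_eskd, hazard_eskd)))
    l2 = np.where(group == 1, *(
        (group_hazards[1][1], group_hazards[0][1]) if group_hazards
        else (hazard_death, hazard_death)))
    lam = l1 + l2
    t_event = rng.exponential(1.0 / lam)
    cause = np.where(rng.uniform(size=n) < l1 / lam, 1, 2)
    t_cens = (rng.exponential(1.0 / censor_rate)
              if censor_rate > 0 else np.full(n, np.inf))
    t_cens = np.minimum(t_cens, followup)
    time = np.minimum(t_event, t_cens)
    status = np.where(t_event <= t_cens, cause, 0)
    X = pd.DataFrame({"group": group.astype(float)})
    for j in range(n_noise):
        X[f"noise{j}"] = rng.normal(size=n)
    if not group_hazards:
        X = X.drop(columns=["group"])
    return X, time.astype(float), status.astype(int)


def two_group_true_cif(l1: float, l2: float, t: float, cause: int) -> float:
    """Closed-form CIF for constant cause-specific hazards."""
    lam = l1 + l2
    lk = l1 if cause == 1 else l2
    return lk / lam * (1.0 - np.exp(-lam * t))
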
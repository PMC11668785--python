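"""Landmarking: risk sets, covariates at the landmark, administrative censoring.

At each pre-specified landmark time s the model is fitted to patients still at
risk at s, using only covariate information available up to s, and outcomes on
the window (s, s+w] with administrative censoring at s+w.  Internally survival
time is measured on the residual scale t - s (origin shifted to the landmark);
absolute time is recovered as s + t.

Three covariate-summarisation strategies are provided:

- LOCF: the most recent monthly value at or before s;
- LME: patient-specific prediction at s from a linear mixed model with random
  intercept and slope (unconditional growth model), fitted to all cohort
  observations up to s;
- LMEpoly: as LME with an additional fixed and random quadratic term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import MONTH_YEARS, PatientTimeline, REQUIRED_ANALYTES
from .simulate import EGFR

__all__ = [
    "LandmarkSpec",
    "LandmarkDataset",
    "PREDICTOR_SETS",
    "covariates_locf",
    "fit_lme_models",
    "covariates_lme",
    "build_landmark_dataset",
    "assemble_all_landmarks",
]

logger = logging.getLogger(__name__)

DEFAULT_LANDMARKS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

# predictor panels: the reduced sets drop sex and the biopsy diagnosis flag
# (low importance) and keep initial age plus the strongest analytes
TOP10_ANALYTES = ("albumin", "alp", "bicarbonate", "chloride", "potassium",
                  "sodium", EGFR, "hemoglobin", "platelets", "wcc")
TOP5_ANALYTES = ("albumin", "bicarbonate", "chloride", EGFR, "hemoglobin")

PREDICTOR_SETS: dict[str, dict] = {
    "full": {"demographics": ("sex", "age", "gn_vasculitis"),
             "analytes": REQUIRED_ANALYTES},
    "top10": {"demographics": ("age",), "analytes": TOP10_ANALYTES},
    "top5": {"demographics": ("age",), "analytes": TOP5_ANALYTES},
}

STRATEGIES = ("locf", "lme", "lmepoly")


@dataclass(frozen=True)
class LandmarkSpec:
    landmark_times: tuple[float, ...] = DEFAULT_LANDMARKS
    horizon: float = 5.0
    strategy: str = "locf"
    predictor_set: str = "full"

    def __post_init__(self):
        lt = self.landmark_times
        if not lt or any(s <= 0 for s in lt) or any(
                b <= a for a, b in zip(lt, lt[1:])):
            raise ValueError("landmark_times must be strictly increasing and > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.predictor_set not in PREDICTOR_SETS:
            raise ValueError(f"unknown predictor_set {self.predictor_set!r}")

    @property
    def columns(self) -> list[str]:
        ps = PREDICTOR_SETS[self.predictor_set]
        return list(ps["demographics"]) + list(ps["analytes"])


@dataclass
class LandmarkDataset:
    """Covariates at landmark s and administratively censored outcomes.

    ``data`` columns: patient_id, the covariates, ``time`` (residual years in
    (0, w]) and ``status`` (0 censored / 1 ESKD / 2 death).
    """

    s: float
    horizon: float
    features: list[str]
    data: pd.DataFrame = field(repr=False)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.features]

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.data["status"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def _month_of(s: float) -> int:
    return int(np.floor(s / MONTH_YEARS + 1e-9))


def covariates_locf(timeline: PatientTimeline, s: float,
                    analytes: tuple[str, ...]) -> dict[str, float]:
    """Most recent monthly value at or before landmark s, per analyte."""
    m = _month_of(s)
    out = {}
    for a in analytes:
        ser = timeline.series.get(a)
        if ser is None or not len(ser):
            out[a] = np.nan
            continue
        ser = ser.dropna()
        eligible = ser[ser.index <= m]
        out[a] = float(eligible.iloc[-1]) if len(eligible) else np.nan
    return out


class _LMEModel:
    """Per-analyte mixed model (random intercept/slope, optional quadratic).

    Stores fixed effects and variance components so patient-specific best
    linear unbiased predictions can be formed for patients outside the fit
    (test folds) with the same formula as for in-fit patients.
    """

    def __init__(self, beta: np.ndarray, cov_re: np.ndarray, sigma2: float,
                 order: int):
        self.beta = beta
        self.cov_re = cov_re
        self.sigma2 = sigma2
        self.order = order

    def _design(self, t: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(t), t]
        if self.order == 2:
            cols.append(t * t)
        return np.column_stack(cols)

    def predict(self, t_obs: np.ndarray, y_obs: np.ndarray, s: float) -> float:
        """Fixed-effect prediction at s plus the BLUP of this patient's
        random effects given (t_obs, y_obs)."""
        x_s = self._design(np.array([s]))[0]
        pred = float(x_s @ self.beta)
        if len(t_obs) == 0:
            return pred
        Z = self._design(np.asarray(t_obs, dtype=float))
        X = Z
        resid = np.asarray(y_obs, dtype=float) - X @ self.beta
        D = self.cov_re
        V = Z @ D @ Z.T + self.sigma2 * np.eye(len(t_obs))
        b = D @ Z.T @ np.linalg.solve(V, resid)
        return pred + float(x_s @ b)


def fit_lme_models(timelines: list[PatientTimeline], s: float,
                   order: int = 1,
                   analytes: tuple[str, ...] = REQUIRED_ANALYTES
                   ) -> dict[str, Optional[_LMEModel]]:
    """Fit one mixed model per analyte on all observations with time <= s.

    Non-convergence (or degenerate data) falls back to ``None`` — the caller
    substitutes LOCF for that analyte, with a logged warning.
    """
    import statsmodels.api as sm

    m_max = _month_of(s)
    models: dict[str, Optional[_LMEModel]] = {}
    for a in analytes:
        rows = []
        for tl in timelines:
            ser = tl.series.get(a)
            if ser is None:
                continue
            ser = ser.dropna()
            ser = ser[ser.index <= m_max]
            for month, val in ser.items():
                rows.append((tl.patient_id, month * MONTH_YEARS, val))
        if not rows:
            models[a] = None
            logger.warning("LME: no observations for %s at landmark %.1f", a, s)
            continue
        df = pd.DataFrame(rows, columns=["patient_id", "t", "y"])
        exog = np.column_stack([np.ones(len(df)), df["t"].to_numpy()])
        if order == 2:
            exog = np.column_stack([exog, df["t"].to_numpy() ** 2])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(df["y"].to_numpy(), exog,
                                groups=df["patient_id"].to_numpy(),
                                exog_re=exog)
                fit = md.fit(reml=True, method="lbfgs", maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise ValueError("non-finite parameters")
            models[a] = _LMEModel(beta=np.asarray(fit.fe_params),
                                  cov_re=np.asarray(fit.cov_re),
                                  sigma2=float(fit.scale), order=order)
        except Exception as exc:  # noqa: BLE001 — fall back per analyte
            logger.warning("LME fit failed for %s at landmark %.1f (%s); "
                           "falling back to LOCF", a, s, exc)
            models[a] = None
    return models


def covariates_lme(timeline: PatientTimeline, s: float,
                   models: dict[str, Optional[_LMEModel]],
                   analytes: tuple[str, ...]) -> dict[str, float]:
    """Patient-specific mixed-model prediction at exactly time s per analyte;
    LOCF fallback where the model is unavailable or the patient has no data."""
    m_max = _month_of(s)
    locf = covariates_locf(timeline, s, analytes)
    out = {}
    for a in analytes:
        model = models.get(a)
        if model is None:
            out[a] = locf[a]
            continue
        ser = timeline.series.get(a)
        if ser is None or not len(ser.dropna()):
            out[a] = locf[a]
            continue
        ser = ser.dropna()
        ser = ser[ser.index <= m_max]
        if not len(ser):
            out[a] = locf[a]
            continue
        t_obs = ser.index.to_numpy(dtype=float) * MONTH_YEARS
        out[a] = model.predict(t_obs, ser.to_numpy(), s)
    return out


def _demographic_values(tl: PatientTimeline, names) -> dict[str, float]:
    vals = {}
    for d in names:
        if d == "sex":
            vals["sex"] = 1.0 if tl.sex == "F" else 0.0
        elif d == "age":
            vals["age"] = tl.age_at_time0
        elif d == "gn_vasculitis":
            # three-level coding: 0 absent, 1 biopsy-verified, 2 missing
            g = tl.gn_vasculitis
            vals["gn_vasculitis"] = 2.0 if np.isnan(g) else float(g)
    return vals


def build_landmark_dataset(timelines: list[PatientTimeline],
                           spec: LandmarkSpec, s: float,
                           lme_models: Optional[dict] = None
                           ) -> LandmarkDataset:
    """Risk set at s with covariates from the chosen strategy and outcomes on
    (s, s+w], administratively censored at s+w, on the residual time scale."""
    if s not in spec.landmark_times:
        raise ValueError(f"landmark {s} not in spec.landmark_times")
    ps = PREDICTOR_SETS[spec.predictor_set]
    analytes = tuple(ps["analytes"])
    if spec.strategy in ("lme", "lmepoly") and lme_models is None:
        lme_models = fit_lme_models(
            timelines, s, order=2 if spec.strategy == "lmepoly" else 1,
            analytes=analytes)
    rows = []
    w = spec.horizon
    for tl in timelines:
        if not (tl.event_time > s):
            continue
        if spec.strategy == "locf":
            cov = covariates_locf(tl, s, analytes)
        else:
            cov = covariates_lme(tl, s, lme_models, analytes)
        rec = {"patient_id": tl.patient_id}
        rec.update(_demographic_values(tl, ps["demographics"]))
        rec.update(cov)
        if tl.event_time <= s + w:
            rec["time"] = tl.event_time - s
            rec["status"] = tl.cause
        else:
            rec["time"] = w
            rec["status"] = 0
        rows.append(rec)
    if not rows:
        raise ValueError(f"empty risk set at landmark {s}")
    data = pd.DataFrame(rows)
    return LandmarkDataset(s=s, horizon=w, features=spec.columns, data=data)


def assemble_all_landmarks(timelines: list[PatientTimeline],
                           spec: LandmarkSpec) -> list[LandmarkDataset]:
    """One landmark dataset per landmark time (default: six)."""
    out = []
    for s in spec.landmark_times:
        lme_models = None
        if spec.strategy in ("lme", "lmepoly"):
            lme_models = fit_lme_models(
                timelines, s, order=2 if spec.strategy == "lmepoly" else 1,
                analytes=tuple(PREDICTOR_SETS[spec.predictor_set]["analytes"]))
        out.append(build_landmark_dataset(timelines, spec, s, lme_models))
    return out
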
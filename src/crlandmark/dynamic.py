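"""Per-patient dynamic prediction and the dynamic prediction plot.

A sequence of landmark forests (one per landmark time) is applied to a
patient's accumulating history; each model's residual-time CIF is mapped back
to absolute time and the curves are aggregated across models by the
arithmetic mean at each absolute grid time from year 3 to year 8.  The left
panel of the plot shows the observed analyte series over the first 3 years;
the right panel the aggregated ESKD and death CIF curves.

The rolling-window scheme re-anchors a long history: discarding the first
``shift`` years and treating the data at year ``shift`` as input for the
0.5-year landmark model extends coverage to absolute time shift + s + t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import MONTH_YEARS, PatientTimeline
from .forest import CAUSES, CIFCurve, CompetingRiskForest
from .landmark import (PREDICTOR_SETS, LandmarkSpec, _demographic_values,
                       covariates_lme, covariates_locf)

__all__ = [
    "PatientPrediction",
    "predict_patient",
    "rolling_window",
    "export_plot_data",
    "AGGREGATION_GRID",
]

# absolute-time grid for aggregation: quarter-year steps, year 3 to year 8
AGGREGATION_GRID = np.round(np.arange(3.0, 8.0 + 1e-9, 0.25), 4)


@dataclass
class PatientPrediction:
    patient_id: int
    per_model: dict[float, dict[int, CIFCurve]]  # landmark s -> cause -> curve
    aggregated: dict[int, CIFCurve] = field(default_factory=dict)
    grid: np.ndarray = field(default_factory=lambda: AGGREGATION_GRID.copy())


def _history_years(timeline: PatientTimeline) -> float:
    months = [int(s.dropna().index.max()) for s in timeline.series.values()
              if len(s.dropna())]
    return (max(months) if months else 0) * MONTH_YEARS


def predict_patient(models: dict[float, CompetingRiskForest],
                    timeline: PatientTimeline,
                    spec: LandmarkSpec,
                    lme_models: Optional[dict[float, dict]] = None
                    ) -> PatientPrediction:
    """Apply each landmark model whose landmark the patient's history covers;
    aggregate per-cause CIFs by the arithmetic mean on the year 3–8 grid.

    A model whose horizon window ends before a grid time contributes its last
    available value (a CIF is constant beyond the final event time); grid
    times at or before s + 0 contribute that model's value 0.
    """
    history = _history_years(timeline)
    analytes = tuple(PREDICTOR_SETS[spec.predictor_set]["analytes"])
    demo_names = PREDICTOR_SETS[spec.predictor_set]["demographics"]
    applicable = [s for s in sorted(models) if s <= history + 1e-9]
    if not applicable:
        raise ValueError(
            f"patient {timeline.patient_id}: history ({history:.2f}y) covers "
            "no landmark model")
    per_model: dict[float, dict[int, CIFCurve]] = {}
    for s in applicable:
        forest = models[s]
        if spec.strategy == "locf":
            cov = covariates_locf(timeline, s, analytes)
        else:
            cov = covariates_lme(timeline, s, (lme_models or {}).get(s, {}),
                                 analytes)
        rec = _demographic_values(timeline, demo_names)
        rec.update(cov)
        X = pd.DataFrame([rec])[forest.columns_]
        cifs = forest.predict_cif(X)
        per_model[s] = {
            k: CIFCurve(k, forest.time_grid_ + s, cifs[k][0]) for k in CAUSES}

    agg = {}
    for k in CAUSES:
        vals = np.zeros_like(AGGREGATION_GRID)
        for s, curves in per_model.items():
            vals += curves[k].at(AGGREGATION_GRID)
        vals /= len(per_model)
        agg[k] = CIFCurve(k, AGGREGATION_GRID.copy(), vals)
    return PatientPrediction(patient_id=timeline.patient_id,
                             per_model=per_model, aggregated=agg)


def rolling_window(timeline: PatientTimeline, shift: float) -> PatientTimeline:
    """Re-anchor the timeline ``shift`` years later.

    Data before the shift are discarded and month indices re-origin at the
    shift, so the data at absolute year ``shift + s`` feed the landmark-s
    model.  The adjudicated outcome (cause, event_time) is left on the
    original absolute scale — events are absolute; only covariate history is
    re-indexed.  Age at the new origin is advanced accordingly.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if shift == 0:
        return timeline.copy()
    history = _history_years(timeline)
    if shift >= history:
        raise ValueError(f"shift {shift}y >= history length {history:.2f}y")
    shift_months = int(round(shift / MONTH_YEARS))
    new = timeline.copy()
    new.age_at_time0 = timeline.age_at_time0 + shift
    new.time0_date = timeline.time0_date + pd.Timedelta(
        days=round(shift * 365.25))
    for a, s in timeline.series.items():
        s2 = s[s.index >= shift_months].copy()
        s2.index = s2.index - shift_months
        new.series[a] = s2
    return new


def export_plot_data(prediction: PatientPrediction,
                     timeline: PatientTimeline,
                     analytes: Optional[tuple[str, ...]] = None,
                     observed_years: float = 3.0):
    """Tidy tables for the two-panel dynamic prediction plot.

    Returns (observed, curves, figure_fn): ``observed`` has one row per
    (analyte, time, value) over the first ``observed_years``; ``curves`` one
    row per (cause, time, cif) over years 3–8; ``figure_fn()`` renders the
    two-panel matplotlib figure.
    """
    analytes = analytes or tuple(sorted(timeline.series))
    m_max = int(np.floor(observed_years / MONTH_YEARS))
    obs_rows = []
    for a in analytes:
        s = timeline.series.get(a, pd.Series(dtype=float))
        s = s.dropna()
        s = s[s.index <= m_max]
        if not len(s):
            obs_rows.append((a, np.nan, np.nan))  # empty panel marker
            continue
        for month, val in s.items():
            obs_rows.append((a, month * MONTH_YEARS, float(val)))
    observed = pd.DataFrame(obs_rows, columns=["analyte", "time", "value"])

    curve_rows = []
    labels = {1: "ESKD", 2: "death"}
    for k in CAUSES:
        c = prediction.aggregated[k]
        for t, v in zip(c.times, c.values):
            curve_rows.append((labels[k], float(t), float(v)))
    curves = pd.DataFrame(curve_rows, columns=["cause", "time", "cif"])

    def figure_fn():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_panel = len(analytes)
        fig = plt.figure(figsize=(10, max(4, 1.6 * n_panel)))
        gs = fig.add_gridspec(n_panel, 2, width_ratios=[1, 1.4])
        for i, a in enumerate(analytes):
            ax = fig.add_subplot(gs[i, 0])
            sub = observed[observed["analyte"] == a].dropna()
            if len(sub):
                ax.plot(sub["time"], sub["value"], "o-", ms=3, lw=1)
            else:
                ax.text(0.5, 0.5, "no data", ha="center", va="center",
                        transform=ax.transAxes)
            ax.set_ylabel(a, fontsize=8)
            if i == n_panel - 1:
                ax.set_xlabel("years from time 0")
        ax = fig.add_subplot(gs[:, 1])
        for k, color in ((1, "tab:red"), (2, "tab:blue")):
            sub = curves[curves["cause"] == labels[k]]
            ax.plot(sub["time"], 100 * sub["cif"], color=color,
                    label=labels[k])
        ax.set_xlabel("years from time 0")
        ax.set_ylabel("cumulative incidence (%)")
        ax.legend()
        fig.tight_layout()
        return fig

    return observed, curves, figure_fn
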
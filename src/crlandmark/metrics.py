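"""Cause-specific discrimination and calibration metrics, event-stratified
cross-validation and model-variant comparisons.

All metrics are CIF-based: subjects with the competing event are treated as
non-cases (controls) for cause-k discrimination, consistent with cumulative
incidence as the predicted risk in the presence of competing risks.  Censoring
is handled by inverse-probability-of-censoring weights (IPCW) from the
Kaplan–Meier estimate of the censoring distribution, with censorings tied to
event times placed after the events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientTimeline, impute_baseline, locf_fill
from .forest import CAUSES, CompetingRiskForest, tune as tune_forest
from .landmark import LandmarkSpec

__all__ = [
    "concordance_cr",
    "td_auc",
    "brier_cr",
    "integrated_brier",
    "censoring_survival",
    "stratified_kfold",
    "FoldAssignment",
    "MetricsReport",
    "run_cv",
    "compare_variants",
]


# ---------------------------------------------------------------------------
# Discrimination

def concordance_cr(risk: Sequence[float], time: Sequence[float],
                   status: Sequence[int], cause: int) -> float:
    """Cause-specific concordance index, in percent.

    A pair (i, j) is comparable when i failed from ``cause`` at t_i and j's
    observed time exceeds t_i (competing-event subjects remain comparable as
    non-failures up to their own time).  The pair is concordant when
    risk_i > risk_j; prediction ties count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    events = np.nonzero(status == cause)[0]
    conc = ties = comparable = 0.0
    for i in events:
        later = time > time[i]
        m = int(later.sum())
        if m == 0:
            continue
        comparable += m
        conc += float((risk[i] > risk[later]).sum())
        ties += float((risk[i] == risk[later]).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return 100.0 * (conc + 0.5 * ties) / comparable


def censoring_survival(time: np.ndarray, status: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier estimate G(t) of the censoring distribution.

    Censorings are "events" here; true events tied with censorings at t stay
    in the risk set for the censoring at t (censoring-after-events rule).
    Returns step-function arrays (times, values), G right-continuous.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    order = np.argsort(time, kind="stable")
    t = time[order]
    st = status[order]
    uniq = np.unique(t)
    out_t, out_v = [], []
    g = 1.0
    n = len(t)
    for tau in uniq:
        sel = t == tau
        d_c = int(((st == 0) & sel).sum())
        if d_c == 0:
            continue
        # events at tau remain at risk for censoring at tau
        at_risk = n - np.searchsorted(t, tau, side="left")
        g *= 1.0 - d_c / at_risk
        out_t.append(tau)
        out_v.append(g)
    return np.asarray(out_t), np.asarray(out_v)


def _g_at(gt: np.ndarray, gv: np.ndarray, t, left: bool = False) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if len(gt) == 0:  # no censoring observed: G = 1 everywhere
        return np.ones_like(t)
    side = "left" if left else "right"
    idx = np.searchsorted(gt, t, side=side) - 1
    return np.where(idx >= 0, gv[np.maximum(idx, 0)], 1.0)


def td_auc(risk: Sequence[float], time: Sequence[float],
           status: Sequence[int], cause: int, t: float) -> float:
    """Cumulative/dynamic time-dependent AUC at t with IPCW, in percent.

    Cases: cause-k event by t.  Controls: event-free beyond t, or a competing
    event by t (they can no longer fail from cause k).  Subjects censored by
    t without an event are reweighted away via the censoring Kaplan–Meier.
    Returns NaN when either group is empty.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    gt, gv = censoring_survival(time, status)
    cases = (status == cause) & (time <= t)
    competing = (status != 0) & (status != cause) & (time <= t)
    at_risk = time > t
    controls = at_risk | competing
    if not cases.any() or not controls.any():
        return float("nan")
    w = np.zeros(len(time))
    w[cases | competing] = 1.0 / _g_at(gt, gv, time[cases | competing], left=True)
    if at_risk.any():
        w[at_risk] = 1.0 / _g_at(gt, gv, t)
    ci = np.nonzero(cases)[0]
    cj = np.nonzero(controls)[0]
    rc = risk[ci][:, None]
    rk = risk[cj][None, :]
    ww = w[ci][:, None] * w[cj][None, :]
    num = (ww * ((rc > rk) + 0.5 * (rc == rk))).sum()
    den = ww.sum()
    return 100.0 * float(num / den)


# ---------------------------------------------------------------------------
# Calibration

def brier_cr(cif_at_t: Sequence[float], time: Sequence[float],
             status: Sequence[int], cause: int, t: float) -> float:
    """IPCW Brier score for cause k at time t.

    mean_i w_i * (1{T_i <= t, cause k} - CIF_k,i(t))^2 with w = 1/G(T_i-) for
    subjects with any event by t, 1/G(t) for subjects at risk at t, 0 for
    subjects censored before t.
    """
    cif_at_t = np.asarray(cif_at_t, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    gt, gv = censoring_survival(time, status)
    w = np.zeros(len(time))
    event_by_t = (status != 0) & (time <= t)
    at_risk = time > t
    g_event = _g_at(gt, gv, time[event_by_t], left=True)
    g_t = _g_at(gt, gv, t)
    if np.any(g_event <= 0) or (at_risk.any() and g_t <= 0):
        raise ValueError("censoring survival is zero at a needed time")
    w[event_by_t] = 1.0 / g_event
    if at_risk.any():
        w[at_risk] = 1.0 / g_t
    y = ((status == cause) & (time <= t)).astype(float)
    return float(np.mean(w * (y - cif_at_t) ** 2))


def integrated_brier(cif_matrix: np.ndarray, grid: Sequence[float],
                     time: Sequence[float], status: Sequence[int],
                     cause: int, horizon: float) -> float:
    """Trapezoidal integral of the IPCW Brier score over (0, horizon] / horizon.

    ``cif_matrix`` is (n, G): each subject's predicted CIF on ``grid``
    (residual time from the landmark).
    """
    grid = np.asarray(grid, dtype=float)
    cif_matrix = np.asarray(cif_matrix, dtype=float)
    keep = grid <= horizon + 1e-12
    grid = grid[keep]
    cif_matrix = cif_matrix[:, keep]
    # evaluate from 0 (CIF = 0, Brier of the zero prediction) to the horizon
    ts = np.concatenate([[0.0], grid])
    if ts[-1] < horizon:
        ts = np.append(ts, horizon)
    vals = []
    for t in ts:
        if t == 0.0:
            cif_t = np.zeros(cif_matrix.shape[0])
        else:
            idx = np.searchsorted(grid, t, side="right") - 1
            cif_t = cif_matrix[:, max(idx, 0)]
        vals.append(brier_cr(cif_t, time, status, cause, t) if t > 0
                    else float(np.mean(cif_t ** 2)))
    return float(np.trapezoid(vals, ts) / horizon)


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class FoldAssignment:
    """patient_id -> fold, stratified by outcome (ESKD / death / censored)."""

    assignment: pd.DataFrame  # columns: patient_id, stratum, fold
    k: int

    def test_ids(self, fold: int) -> set:
        df = self.assignment
        return set(df.loc[df["fold"] == fold, "patient_id"])


def stratified_kfold(causes: dict[int, int], k: int = 5,
                     seed: int = 0) -> FoldAssignment:
    """Deal patients round-robin into k folds within each outcome stratum."""
    rng = np.random.default_rng(seed)
    rows = []
    strata = {0: "censored", 1: "ESKD", 2: "death"}
    by_stratum: dict[int, list] = {0: [], 1: [], 2: []}
    for pid, c in causes.items():
        by_stratum[int(c)].append(pid)
    for c, ids in by_stratum.items():
        if not ids:
            continue
        if len(ids) < k:
            warnings.warn(f"stratum {strata[c]} smaller than k={k}; "
                          "spreading as evenly as possible")
        ids = sorted(ids)
        perm = rng.permutation(len(ids))
        for j, idx in enumerate(perm):
            rows.append((ids[idx], strata[c], j % k + 1))
    return FoldAssignment(
        assignment=pd.DataFrame(rows, columns=["patient_id", "stratum", "fold"]),
        k=k)


@dataclass
class MetricsReport:
    """Fold-level metrics with median/IQR summaries.

    ``records`` columns: landmark, cause, fold, metric (cindex | td_auc | ibs),
    value.  C-index and td-AUC are percentages; iBS is on [0, 1].
    """

    variant: str
    records: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        def iqr(x):
            q = np.nanpercentile(x, [25, 75])
            return q[1] - q[0]
        return (self.records.groupby(["landmark", "cause", "metric"])["value"]
                .agg(median="median", iqr=iqr, n_folds="count").reset_index())

    def fold_values(self, landmark: float, cause: int,
                    metric: str = "cindex") -> np.ndarray:
        df = self.records
        sel = ((df["landmark"] == landmark) & (df["cause"] == cause)
               & (df["metric"] == metric))
        return df.loc[sel].sort_values("fold")["value"].to_numpy()


def run_cv(timelines: list[PatientTimeline], spec: LandmarkSpec,
           k: int = 5, seed: int = 0, ntree: int = 200,
           nodesize: int = 15, mtry: Optional[int] = None,
           do_tune: bool = False, tune_ntree: int = 100,
           variant_label: Optional[str] = None) -> MetricsReport:
    """Event-stratified k-fold cross-validation of the full pipeline.

    Per fold: baseline values are imputed on the TRAINING timelines only
    (simplified predictive mean matching), carry-forward filling is applied to
    both sides, landmark datasets are assembled, a forest is (optionally
    tuned and) fitted per landmark on the training side, and C-index, td-AUC
    at the horizon and the integrated Brier score are computed on the test
    side for each cause.
    """
    causes = {tl.patient_id: tl.cause for tl in timelines}
    folds = stratified_kfold(causes, k=k, seed=seed)
    records = []
    for fold in range(1, k + 1):
        test_ids = folds.test_ids(fold)
        train = [tl for tl in timelines if tl.patient_id not in test_ids]
        test = [tl for tl in timelines if tl.patient_id in test_ids]
        train = impute_baseline(train, seed=seed + fold)
        train = [locf_fill(tl) for tl in train]
        test = [locf_fill(tl) for tl in test]
        train_lds, test_lds = [], []
        for s in spec.landmark_times:
            lme_models = None
            if spec.strategy in ("lme", "lmepoly"):
                # mixed models are fitted on the training fold only and
                # reused to form test-fold covariates (BLUP from each test
                # patient's own observations up to s)
                from .landmark import PREDICTOR_SETS, fit_lme_models
                lme_models = fit_lme_models(
                    train, s, order=2 if spec.strategy == "lmepoly" else 1,
                    analytes=tuple(
                        PREDICTOR_SETS[spec.predictor_set]["analytes"]))
            from .landmark import build_landmark_dataset
            train_lds.append(build_landmark_dataset(train, spec, s, lme_models))
            test_lds.append(build_landmark_dataset(test, spec, s, lme_models))
        for ld_train, ld_test in zip(train_lds, test_lds):
            m, ns = mtry, nodesize
            if do_tune:
                m, ns = tune_forest(ld_train, seed=seed, ntree=tune_ntree)
            forest = CompetingRiskForest(
                ntree=ntree, mtry=m, nodesize=ns, seed=seed + fold)
            forest.fit_dataset(ld_train)
            cifs = forest.predict_cif(ld_test.X)
            grid = forest.time_grid_
            h_idx = max(np.searchsorted(grid, ld_test.horizon,
                                        side="right") - 1, 0)
            for cause in CAUSES:
                risk = cifs[cause][:, h_idx]
                try:
                    ci = concordance_cr(risk, ld_test.time, ld_test.status,
                                        cause)
                except ValueError:
                    ci = np.nan
                auc = td_auc(risk, ld_test.time, ld_test.status, cause,
                             t=ld_test.horizon)
                ibs = integrated_brier(cifs[cause], grid, ld_test.time,
                                       ld_test.status, cause,
                                       horizon=ld_test.horizon)
                for metric, value in (("cindex", ci), ("td_auc", auc),
                                      ("ibs", ibs)):
                    records.append((ld_train.s, cause, fold, metric, value))
    report = pd.DataFrame(
        records, columns=["landmark", "cause", "fold", "metric", "value"])
    label = variant_label or f"{spec.strategy}/{spec.predictor_set}"
    return MetricsReport(variant=label, records=report)


# ---------------------------------------------------------------------------
# Variant comparison

def compare_variants(reports: dict[str, MetricsReport],
                     metric: str = "cindex") -> pd.DataFrame:
    """Kruskal–Wallis (>= 3 variants) or Wilcoxon rank-sum (2) on fold-level
    metric values, per landmark and cause.  Two-tailed p-values."""
    if len(reports) < 2:
        raise ValueError("need at least two variants to compare")
    names = list(reports)
    any_rec = reports[names[0]].records
    landmarks = sorted(any_rec["landmark"].unique())
    rows = []
    for s in landmarks:
        for cause in CAUSES:
            samples = [reports[nm].fold_values(s, cause, metric)
                       for nm in names]
            samples = [x[~np.isnan(x)] for x in samples]
            if any(len(x) == 0 for x in samples):
                rows.append((s, cause, "none", np.nan, np.nan))
                continue
            if len(samples) == 2:
                if all((x == samples[0][0]).all() for x in samples):
                    rows.append((s, cause, "ranksum", 0.0, 1.0))
                    continue
                res = stats.mannwhitneyu(samples[0], samples[1],
                                         alternative="two-sided",
                                         method="exact"
                                         if max(map(len, samples)) <= 10
                                         else "auto")
                rows.append((s, cause, "ranksum", float(res.statistic),
                             float(res.pvalue)))
            else:
                flat = np.concatenate(samples)
                if np.all(flat == flat[0]):
                    rows.append((s, cause, "kruskal", 0.0, 1.0))
                    continue
                res = stats.kruskal(*samples)
                rows.append((s, cause, "kruskal", float(res.statistic),
                             float(res.pvalue)))
    return pd.DataFrame(rows, columns=["landmark", "cause", "test",
                                       "statistic", "pvalue"])
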
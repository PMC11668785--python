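"""Competing-risk random survival forest.

Bootstrap ensembles of binary survival trees for right-censored data with two
competing causes (1 = ESKD, 2 = death).  Node splitting maximises the sum over
causes of the squared standardised Gray (subdistribution log-rank) statistic;
terminal nodes carry per-cause Aalen–Johansen cumulative incidence functions
(CIFs) estimated from in-bag members; the ensemble prediction is the
arithmetic mean of terminal-node CIFs over trees on a common time grid.
Out-of-bag (OOB) machinery provides the tuning error and permutation variable
importance (VIMP).

The Gray splitting score for cause k uses the extended risk set of the
subdistribution hazard: subjects whose competing event occurred before t stay
in the risk set at t.  At each distinct cause-k event time t,

    U = sum_t [ d_kL(t) - d_k(t) * Y*_L(t) / Y*(t) ],
    V = sum_t d_k(t) * p (1-p) * (Y* - d_k) / (Y* - 1),   p = Y*_L/Y*,

and the standardised score is U / sqrt(V) (0 when V = 0).  With no competing
events this reduces exactly to the two-sample log-rank statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CIFCurve",
    "SurvivalTree",
    "CompetingRiskForest",
    "gray_split_statistic",
    "aalen_johansen",
    "fit_forest",
    "predict_cif",
    "oob_error",
    "tune",
    "vimp",
    "NODESIZE_GRID",
]

CAUSES = (1, 2)

# nodesize candidates searched during tuning (28 values)
NODESIZE_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 25, 30, 35, 40, 45,
                 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100)


@dataclass
class CIFCurve:
    """Per-cause cumulative incidence as a right-continuous step function."""

    cause: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("CIF values must be nondecreasing")
        if len(self.values) and (self.values[0] < -1e-12):
            raise ValueError("CIF must start >= 0")

    def at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return float(vals) if vals.ndim == 0 else vals


# ---------------------------------------------------------------------------
# Gray subdistribution log-rank scoring

def _gray_scores(time: np.ndarray, status: np.ndarray, left: np.ndarray,
                 cause: int) -> np.ndarray:
    """Standardised Gray statistic for each candidate assignment.

    ``left`` is a (c, m) boolean matrix of left-side membership for c
    candidate cutpoints over the m node members.  Vectorised over cutpoints.
    """
    m = len(time)
    other = 2 if cause == 1 else 1
    # competing-event subjects never leave the extended risk set
    removal = np.where(status == other, np.inf, time)
    order = np.argsort(removal, kind="stable")
    removal_sorted = removal[order]
    left_sorted = left[:, order]

    ev = status == cause
    if not ev.any():
        return np.zeros(left.shape[0])
    ev_idx = np.nonzero(ev)[0]
    ev_order = np.argsort(time[ev_idx], kind="stable")
    ev_idx = ev_idx[ev_order]
    t_ev = time[ev_idx]
    uniq = np.unique(t_ev)
    starts = np.searchsorted(t_ev, uniq, side="left")
    ends = np.searchsorted(t_ev, uniq, side="right")
    d = (ends - starts).astype(float)

    left_ev = left[:, ev_idx].astype(float)
    csum_ev = np.concatenate(
        [np.zeros((left.shape[0], 1)), np.cumsum(left_ev, axis=1)], axis=1)
    d_left = csum_ev[:, ends] - csum_ev[:, starts]

    below = np.searchsorted(removal_sorted, uniq, side="left")  # #{R < t}
    n_at_risk = (m - below).astype(float)
    csum_left = np.concatenate(
        [np.zeros((left.shape[0], 1)), np.cumsum(left_sorted, axis=1)], axis=1)
    total_left = csum_left[:, -1][:, None]
    y_left = total_left - csum_left[:, below]

    with np.errstate(invalid="ignore", divide="ignore"):
        p = y_left / n_at_risk
        u = (d_left - d * p).sum(axis=1)
        v = (d * p * (1.0 - p)
             * (n_at_risk - d) / np.maximum(n_at_risk - 1.0, 1.0)).sum(axis=1)
    return np.where(v > 0, u / np.sqrt(np.where(v > 0, v, 1.0)), 0.0)


def gray_split_statistic(time: Sequence[float], status: Sequence[int],
                         is_left: Sequence[bool], cause: int) -> float:
    """Standardised Gray statistic for one left/right node assignment."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    is_left = np.asarray(is_left, dtype=bool)
    if is_left.all() or not is_left.any():
        raise ValueError("one-sided split: statistic undefined")
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    return float(_gray_scores(time, status, is_left[None, :], cause)[0])


# ---------------------------------------------------------------------------
# Aalen–Johansen estimator

def _aalen_johansen_arrays(time: np.ndarray, status: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique event times and CIF values per cause.

    CIF_k(t) = sum_{t_j <= t} S(t_j-) d_kj / Y_j with S the all-cause
    Kaplan–Meier.  Censorings tied with events are handled after the events
    (standard convention).
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    st = status[order]
    uniq = np.unique(t)
    cif1, cif2, out_t = [], [], []
    surv = 1.0
    acc1 = acc2 = 0.0
    n = len(t)
    for tau in uniq:
        at_risk = n - np.searchsorted(t, tau, side="left")
        sel = t == tau
        d1 = int(((st == 1) & sel).sum())
        d2 = int(((st == 2) & sel).sum())
        if d1 + d2 == 0:
            continue
        acc1 += surv * d1 / at_risk
        acc2 += surv * d2 / at_risk
        surv *= 1.0 - (d1 + d2) / at_risk
        out_t.append(tau)
        cif1.append(acc1)
        cif2.append(acc2)
    return (np.asarray(out_t), np.asarray(cif1), np.asarray(cif2))


def aalen_johansen(time: Sequence[float], status: Sequence[int]
                   ) -> dict[int, CIFCurve]:
    """Nonparametric cause-specific CIFs under right censoring."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if len(time) == 0:
        raise ValueError("empty sample")
    t, c1, c2 = _aalen_johansen_arrays(time, status)
    return {1: CIFCurve(1, t, c1), 2: CIFCurve(2, t, c2)}


def _eval_step(times: np.ndarray, values: np.ndarray,
               grid: np.ndarray) -> np.ndarray:
    if len(values) == 0:
        return np.zeros(len(grid))
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.where(idx >= 0, values[np.maximum(idx, 0)], 0.0)
    return out


# ---------------------------------------------------------------------------
# Trees

@dataclass
class SurvivalTree:
    """Flattened binary survival tree.

    Internal nodes: feature >= 0, threshold, missing_left.  Leaves:
    feature == -1 and leaf_slot indexing into ``leaf_cif`` of shape
    (n_leaves, 2, G) holding per-cause CIFs on the forest time grid.
    """

    feature: np.ndarray
    threshold: np.ndarray
    missing_left: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    leaf_slot: np.ndarray
    leaf_cif: np.ndarray
    inbag_count: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Route rows to leaf slots (vectorised level iteration)."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        while True:
            f = self.feature[node]
            internal = f >= 0
            if not internal.any():
                break
            rows = np.nonzero(internal)[0]
            fv = f[rows]
            x = X[rows, fv]
            thr = self.threshold[node[rows]]
            miss = np.isnan(x)
            go_left = np.where(miss, self.missing_left[node[rows]], x <= thr)
            nxt = np.where(go_left, self.children_left[node[rows]],
                           self.children_right[node[rows]])
            node[rows] = nxt
        return self.leaf_slot[node]

    @property
    def split_features(self) -> set[int]:
        return set(self.feature[self.feature >= 0].tolist())


def _grow_tree(X: np.ndarray, time: np.ndarray, status: np.ndarray,
               sample_idx: np.ndarray, grid: np.ndarray,
               mtry: int, nodesize: int, nsplit: Optional[int],
               cause_weights: tuple[float, float],
               rng: np.random.Generator) -> SurvivalTree:
    p = X.shape[1]
    min_child = max(nodesize, 2)

    feature, threshold, missing_left = [], [], []
    children_left, children_right, leaf_slot = [], [], []
    leaf_cifs = []

    def new_node():
        feature.append(-1)
        threshold.append(np.nan)
        missing_left.append(True)
        children_left.append(-1)
        children_right.append(-1)
        leaf_slot.append(-1)
        return len(feature) - 1

    def make_leaf(node_id: int, idx: np.ndarray):
        t, c1, c2 = _aalen_johansen_arrays(time[idx], status[idx])
        leaf_slot[node_id] = len(leaf_cifs)
        leaf_cifs.append(np.stack([_eval_step(t, c1, grid),
                                   _eval_step(t, c2, grid)]))

    root = new_node()
    stack = [(root, sample_idx)]
    while stack:
        node_id, idx = stack.pop()
        m = len(idx)
        if m < 2 * min_child or len(np.unique(time[idx])) < 2:
            make_leaf(node_id, idx)
            continue
        t_node = time[idx]
        s_node = status[idx]
        cand_vars = rng.permutation(p)[:mtry]
        best_score = 0.0
        best = None  # (var, cut, miss_left, left_mask)
        for v in cand_vars:
            x = X[idx, v]
            obs = ~np.isnan(x)
            xv = x[obs]
            vals = np.unique(xv)
            if len(vals) < 2:
                continue
            mids = (vals[:-1] + vals[1:]) / 2.0
            if nsplit is not None and len(mids) > nsplit:
                mids = np.sort(rng.choice(mids, size=nsplit, replace=False))
            left = x[None, :] <= mids[:, None]  # NaN compares False
            if (~obs).any():
                n_obs_left = left[:, obs].sum(axis=1)
                maj_left = n_obs_left * 2 >= obs.sum()
                left[:, ~obs] = maj_left[:, None]
            n_left = left.sum(axis=1)
            admissible = (n_left >= min_child) & (m - n_left >= min_child)
            if not admissible.any():
                continue
            score = np.zeros(len(mids))
            for k, wk in zip(CAUSES, cause_weights):
                if wk == 0:
                    continue
                z = _gray_scores(t_node, s_node, left, k)
                score += wk * z * z
            score[~admissible] = -np.inf
            j = int(np.argmax(score))
            if score[j] > best_score:
                best_score = float(score[j])
                miss_left = bool(left[j, ~obs][0]) if (~obs).any() else \
                    bool(n_left[j] * 2 >= m)
                best = (int(v), float(mids[j]), miss_left, left[j].copy())
        if best is None or best_score <= 0.0:
            make_leaf(node_id, idx)
            continue
        v, cut, miss_left, left_mask = best
        feature[node_id] = v
        threshold[node_id] = cut
        missing_left[node_id] = miss_left
        left_id = new_node()
        right_id = new_node()
        children_left[node_id] = left_id
        children_right[node_id] = right_id
        stack.append((right_id, idx[~left_mask]))
        stack.append((left_id, idx[left_mask]))

    n = X.shape[0]
    inbag = np.bincount(sample_idx, minlength=n)
    return SurvivalTree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        missing_left=np.asarray(missing_left, dtype=bool),
        children_left=np.asarray(children_left, dtype=np.int64),
        children_right=np.asarray(children_right, dtype=np.int64),
        leaf_slot=np.asarray(leaf_slot, dtype=np.int64),
        leaf_cif=(np.stack(leaf_cifs) if leaf_cifs
                  else np.zeros((0, 2, len(grid)))),
        inbag_count=inbag.astype(np.int32),
    )


# ---------------------------------------------------------------------------
# Forest

class CompetingRiskForest:
    """Ensemble of competing-risk survival trees.

    Parameters
    ----------
    ntree : number of bootstrap trees (the reference configuration is 1000;
        scale down for quick experiments).
    mtry : candidate variables per split; default ceil(sqrt(p)).
    nodesize : minimum terminal-node size (admissible children must have at
        least max(nodesize, 2) members).
    nsplit : random candidate cutpoints per variable per node; None for
        exhaustive midpoints.
    cause_weights : per-cause weights in the composite split score
        sum_k w_k z_k^2 (both causes weighted equally by default).
    max_grid : cap on the common time grid (quantile-spaced beyond that).
    """

    def __init__(self, ntree: int = 1000, mtry: Optional[int] = None,
                 nodesize: int = 15, nsplit: Optional[int] = 10,
                 seed: int = 0, cause_weights: tuple[float, float] = (1.0, 1.0),
                 max_grid: int = 200, bootstrap: bool = True):
        if nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        self.ntree = ntree
        self.mtry = mtry
        self.nodesize = nodesize
        self.nsplit = nsplit
        self.seed = seed
        self.cause_weights = cause_weights
        self.max_grid = max_grid
        self.bootstrap = bootstrap

    # -- fitting ------------------------------------------------------------
    def fit(self, X: pd.DataFrame, time: Sequence[float],
            status: Sequence[int], horizon: Optional[float] = None
            ) -> "CompetingRiskForest":
        if len(X) == 0:
            raise ValueError("empty dataset")
        self.columns_ = list(X.columns)
        Xa = X.to_numpy(dtype=float)
        time = np.asarray(time, dtype=float)
        status = np.asarray(status, dtype=int)
        if self.mtry is not None and not 1 <= self.mtry <= Xa.shape[1]:
            raise ValueError("mtry must be in [1, p]")
        mtry = self.mtry or int(np.ceil(np.sqrt(Xa.shape[1])))
        ev_times = np.unique(time[status > 0])
        if len(ev_times) == 0:
            ev_times = np.unique(time)
        if len(ev_times) > self.max_grid:
            qs = np.linspace(0, 1, self.max_grid)
            ev_times = np.unique(np.quantile(ev_times, qs))
        self.time_grid_ = ev_times
        self.horizon_ = float(horizon) if horizon is not None else float(time.max())
        self.X_ = Xa
        self.time_ = time
        self.status_ = status
        n = len(time)
        self.trees_: list[SurvivalTree] = []
        for b in range(self.ntree):
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, b]))
            sample_idx = (rng.integers(0, n, size=n) if self.bootstrap
                          else np.arange(n))
            self.trees_.append(
                _grow_tree(Xa, time, status, sample_idx, ev_times, mtry,
                           self.nodesize, self.nsplit, self.cause_weights, rng))
        return self

    def fit_dataset(self, dataset) -> "CompetingRiskForest":
        return self.fit(dataset.X, dataset.time, dataset.status,
                        horizon=dataset.horizon)

    # -- prediction ---------------------------------------------------------
    def _check_schema(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.columns_) - set(X.columns)
            if missing:
                raise ValueError(f"unknown/missing columns: {sorted(missing)}")
            return X[self.columns_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.columns_):
            raise ValueError("column count mismatch")
        return X

    def predict_cif(self, X) -> dict[int, np.ndarray]:
        """Ensemble CIF per cause, (n, G) on ``time_grid_`` — the arithmetic
        mean of terminal-node CIFs over trees."""
        Xa = self._check_schema(X)
        n = Xa.shape[0]
        acc = np.zeros((n, 2, len(self.time_grid_)))
        for tree in self.trees_:
            acc += tree.leaf_cif[tree.apply(Xa)]
        acc /= len(self.trees_)
        return {1: acc[:, 0, :], 2: acc[:, 1, :]}

    def predict_cif_curves(self, X) -> list[dict[int, CIFCurve]]:
        cifs = self.predict_cif(X)
        return [{k: CIFCurve(k, self.time_grid_, cifs[k][i])
                 for k in CAUSES} for i in range(len(cifs[1]))]

    def oob_cif(self) -> tuple[dict[int, np.ndarray], np.ndarray]:
        """OOB ensemble CIFs and the per-subject count of contributing trees."""
        n = self.X_.shape[0]
        acc = np.zeros((n, 2, len(self.time_grid_)))
        count = np.zeros(n)
        for tree in self.trees_:
            oob = tree.inbag_count == 0
            if not oob.any():
                continue
            slots = tree.apply(self.X_[oob])
            acc[oob] += tree.leaf_cif[slots]
            count[oob] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = acc / np.maximum(count, 1)[:, None, None]
        return {1: acc[:, 0, :], 2: acc[:, 1, :]}, count

    def oob_error(self) -> dict[int, float]:
        """1 - per-cause OOB concordance of predicted CIF at the horizon."""
        from .metrics import concordance_cr

        cifs, count = self.oob_cif()
        valid = count > 0
        if not valid.all():
            warnings.warn(f"{int((~valid).sum())} subjects in-bag in every "
                          "tree; excluded from OOB error")
        idx = np.searchsorted(self.time_grid_, self.horizon_, side="right") - 1
        idx = max(idx, 0)
        out = {}
        for k in CAUSES:
            risk = cifs[k][valid, idx]
            out[k] = 1.0 - concordance_cr(
                risk, self.time_[valid], self.status_[valid], cause=k) / 100.0
        return out


def fit_forest(dataset, ntree: int = 1000, mtry: Optional[int] = None,
               nodesize: int = 15, nsplit: Optional[int] = 10,
               seed: int = 0, **kw) -> CompetingRiskForest:
    """Fit a competing-risk forest on a :class:`LandmarkDataset`."""
    f = CompetingRiskForest(ntree=ntree, mtry=mtry, nodesize=nodesize,
                            nsplit=nsplit, seed=seed, **kw)
    return f.fit_dataset(dataset)


def predict_cif(forest: CompetingRiskForest, X) -> dict[int, np.ndarray]:
    return forest.predict_cif(X)


def oob_error(forest: CompetingRiskForest) -> dict[int, float]:
    return forest.oob_error()


# ---------------------------------------------------------------------------
# Tuning and variable importance

def _combo_seed(seed: int, nodesize: int, mtry: int) -> int:
    return int(np.random.SeedSequence([seed, nodesize, mtry]
                                      ).generate_state(1)[0] % (2 ** 31))


def _combo_error(X, time, status, horizon, nodesize, mtry, ntree, seed,
                 cache) -> float:
    key = (nodesize, mtry)
    if key not in cache:
        f = CompetingRiskForest(ntree=ntree, mtry=mtry, nodesize=nodesize,
                                seed=_combo_seed(seed, nodesize, mtry))
        f.fit(X, time, status, horizon=horizon)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            err = f.oob_error()
        cache[key] = 0.5 * (err[1] + err[2])
    return cache[key]


def tune(dataset, seed: int = 0, ntree: int = 100,
         nodesize_grid: Sequence[int] = NODESIZE_GRID
         ) -> tuple[int, int]:
    """Grid/stepwise search for (mtry, nodesize) minimising mean OOB error.

    For each nodesize in the 28-value grid, mtry is searched stepwise from
    ceil(p/2): doubling/halving neighbours are accepted while the OOB error
    improves.  A reduced ntree (default 100) keeps the search fast.  The
    forest seed is derived deterministically from (seed, nodesize, mtry).
    """
    X, time, status = dataset.X, dataset.time, dataset.status
    horizon = dataset.horizon
    p = X.shape[1]
    n = len(time)
    cache: dict = {}
    best = None
    for ns in nodesize_grid:
        m = max(1, int(np.ceil(p / 2)))
        err = _combo_error(X, time, status, horizon, ns, m, ntree, seed, cache)
        improved = True
        while improved:
            improved = False
            for cand in (min(2 * m, p), max(m // 2, 1)):
                if cand == m:
                    continue
                e = _combo_error(X, time, status, horizon, ns, cand, ntree,
                                 seed, cache)
                if e < err:
                    err, m = e, cand
                    improved = True
                    break
        if best is None or err < best[0]:
            best = (err, m, ns)
    if best is None:
        raise ValueError("dataset too small for every nodesize candidate")
    return best[1], best[2]


def vimp(forest: CompetingRiskForest, seed: int = 0) -> pd.DataFrame:
    """Permutation variable importance per cause.

    For each variable, its values are permuted among each tree's OOB cases,
    OOB predictions are recomputed, and the importance is the increase in
    OOB error (1 - concordance at the horizon).  A variable never used in any
    split has importance exactly 0.
    """
    from .metrics import concordance_cr

    X = forest.X_
    n, p = X.shape
    grid_idx = max(np.searchsorted(forest.time_grid_, forest.horizon_,
                                   side="right") - 1, 0)

    def _oob_risk(column: Optional[int], rngs) -> tuple[np.ndarray, np.ndarray]:
        acc = np.zeros((n, 2))
        count = np.zeros(n)
        for b, tree in enumerate(forest.trees_):
            oob = tree.inbag_count == 0
            if not oob.any():
                continue
            Xo = X[oob]
            if column is not None and column in tree.split_features:
                Xo = Xo.copy()
                Xo[:, column] = rngs[b].permutation(Xo[:, column])
            slots = tree.apply(Xo)
            acc[oob] += tree.leaf_cif[slots][:, :, grid_idx]
            count[oob] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = acc / np.maximum(count, 1)[:, None]
        return acc, count

    base_risk, count = _oob_risk(None, None)
    valid = count > 0
    base_err = {
        k: 1.0 - concordance_cr(base_risk[valid, k - 1], forest.time_[valid],
                                forest.status_[valid], cause=k) / 100.0
        for k in CAUSES}

    rows = []
    for v in range(p):
        rngs = [np.random.default_rng(np.random.SeedSequence([seed, v, b]))
                for b in range(len(forest.trees_))]
        if not any(v in t.split_features for t in forest.trees_):
            rows.append({"variable": forest.columns_[v],
                         "vimp_eskd": 0.0, "vimp_death": 0.0})
            continue
        risk, _ = _oob_risk(v, rngs)
        err = {
            k: 1.0 - concordance_cr(risk[valid, k - 1], forest.time_[valid],
                                    forest.status_[valid], cause=k) / 100.0
            for k in CAUSES}
        rows.append({"variable": forest.columns_[v],
                     "vimp_eskd": err[1] - base_err[1],
                     "vimp_death": err[2] - base_err[2]})
    return pd.DataFrame(rows).set_index("variable")
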
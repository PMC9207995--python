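"""Connectome-based predictive modelling.

Per-trait workflow: mass-univariate edge selection by correlation p-value,
summed positive/negative brain scores, a two-coefficient OLS model,
seeded outer shuffle-split tuning over analysis channels, cross-split
consensus edges, and permutation inference on the mean held-out
correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, ShuffleSplit

from .connectome import EdgeTable

__all__ = [
    "CPMModel",
    "TuningResult",
    "ConsensusEdges",
    "PermutationResult",
    "select_edges",
    "brain_scores",
    "fit_cpm",
    "predict_cpm",
    "tune_cpm",
    "per_split_selections",
    "consensus_edges",
    "permutation_test",
    "total_brain_score",
]

log = logging.getLogger(__name__)


@dataclass
class CPMModel:
    positive_edges: list[str]
    negative_edges: list[str]
    beta_pos: float
    beta_neg: float
    intercept: float
    p_threshold: float
    train_subjects: list
    degenerate: bool = False  # both edge sets empty -> intercept-only

    def __post_init__(self) -> None:
        overlap = set(self.positive_edges) & set(self.negative_edges)
        if overlap:
            raise ValueError(f"positive/negative edge sets overlap: {sorted(overlap)}")
        for name, v in (("beta_pos", self.beta_pos), ("beta_neg", self.beta_neg),
                        ("intercept", self.intercept)):
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient {name}={v}")


@dataclass
class TuningResult:
    """Grid-cell x split held-out correlations plus the winning cell."""

    table: pd.DataFrame  # columns: resolution, metric, gsr, p_threshold, split, r_holdout, r_inner
    best: dict
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def mean_by_cell(self) -> pd.DataFrame:
        return (self.table
                .groupby(["resolution", "metric", "gsr", "p_threshold"],
                         sort=True)["r_holdout"]
                .mean().reset_index())


@dataclass
class ConsensusEdges:
    per_split: list[tuple[list[str], list[str]]]
    min_count: int
    positive: list[str]
    negative: list[str]
    sign_conflicts: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null_stats: np.ndarray
    n_perm: int


# ---------------------------------------------------------------------------
# ndarray core (kept free of pandas for speed in permutation loops)


def _as_xy(edges: EdgeTable, y) -> tuple[np.ndarray, np.ndarray]:
    X = edges.values()
    if isinstance(y, pd.Series):
        y = y.reindex(edges.data.index).to_numpy()
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("y length does not match edge table")
    mask = np.isfinite(y)
    return X[mask], y[mask]


def _edge_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    return r


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _select_mask(X: np.ndarray, y: np.ndarray, p_threshold: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    r = _edge_corr(X, y)
    valid = np.isfinite(r)
    p = np.full(r.shape, 1.0)
    p[valid] = _corr_pvalues(r[valid], n)
    pos = valid & (p < p_threshold) & (r > 0)
    neg = valid & (p < p_threshold) & (r < 0)
    return pos, neg


def _fit_scores(s_pos: np.ndarray, s_neg: np.ndarray, y: np.ndarray
                ) -> tuple[float, float, float]:
    """OLS of y on [S+, S-, 1]; zero-variance score columns get beta 0."""
    cols, which = [], []
    for v, name in ((s_pos, "pos"), (s_neg, "neg")):
        if np.ptp(v) > 0:
            cols.append(v)
            which.append(name)
    design = np.column_stack(cols + [np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    bp = bn = 0.0
    for b, name in zip(beta[:-1], which):
        if name == "pos":
            bp = float(b)
        else:
            bn = float(b)
    return bp, bn, float(beta[-1])


def _cv_mean_r(X: np.ndarray, y: np.ndarray,
               splits: list[tuple[np.ndarray, np.ndarray]],
               p_threshold: float) -> tuple[float, list[float]]:
    """Mean held-out correlation of CPM predictions across outer splits.

    Splits with an undefined correlation (constant predictions or constant
    held-out y) are recorded as NaN and excluded from the mean.
    """
    rs: list[float] = []
    for tr, te in splits:
        pos, neg = _select_mask(X[tr], y[tr], p_threshold)
        sp_tr, sn_tr = X[tr][:, pos].sum(axis=1), X[tr][:, neg].sum(axis=1)
        bp, bn, b0 = _fit_scores(sp_tr, sn_tr, y[tr])
        pred = bp * X[te][:, pos].sum(axis=1) + bn * X[te][:, neg].sum(axis=1) + b0
        if np.ptp(pred) == 0 or np.ptp(y[te]) == 0:
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(pred, y[te])[0, 1]))
    arr = np.asarray(rs)
    mean = float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan
    return mean, rs


# ---------------------------------------------------------------------------
# public API


def select_edges(edges: EdgeTable, y, p_threshold: float
                 ) -> tuple[list[str], list[str]]:
    """Edges whose Pearson correlation with ``y`` passes the two-sided
    t-test (df = n-2) at ``p_threshold``, split by correlation sign.

    Constant edge columns are skipped with a warning.
    """
    X, yv = _as_xy(edges, y)
    if len(yv) < 4:
        raise ValueError("need at least 4 subjects for edge selection")
    if np.ptp(yv) == 0:
        raise ValueError("y is constant")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        warnings.warn(
            f"skipping {int(const.sum())} constant edge columns",
            RuntimeWarning, stacklevel=2)
    pos, neg = _select_mask(X, yv, p_threshold)
    cols = np.asarray(edges.data.columns)
    return cols[pos & ~const].tolist(), cols[neg & ~const].tolist()


def brain_scores(edges: EdgeTable, positive: list[str], negative: list[str]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Row sums of the positive- and negative-set edge weights.

    Empty sets give zero vectors.
    """
    df = edges.data
    missing = (set(positive) | set(negative)) - set(df.columns)
    if missing:
        raise KeyError(f"edges not in table: {sorted(missing)}")
    n = len(df)
    s_pos = df[positive].sum(axis=1).to_numpy() if positive else np.zeros(n)
    s_neg = df[negative].sum(axis=1).to_numpy() if negative else np.zeros(n)
    return s_pos, s_neg


def fit_cpm(edges: EdgeTable, y, p_threshold: float) -> CPMModel:
    """Select edges on the given data and fit y ~ S+ + S- + intercept."""
    X, yv = _as_xy(edges, y)
    if len(yv) <= 3:
        raise ValueError("training set must have > 3 subjects")
    pos, neg = select_edges(edges, y, p_threshold)
    if isinstance(y, pd.Series):
        subj_mask = np.isfinite(y.reindex(edges.data.index).to_numpy())
    else:
        subj_mask = np.isfinite(np.asarray(y, dtype=float))
    train_subjects = [s for s, m in zip(edges.data.index, subj_mask) if m]
    s_pos, s_neg = brain_scores(edges, pos, neg)
    s_pos, s_neg = s_pos[subj_mask], s_neg[subj_mask]
    degenerate = not pos and not neg
    if degenerate:
        log.info("both edge sets empty; intercept-only CPM model")
        return CPMModel(pos, neg, 0.0, 0.0, float(yv.mean()), p_threshold,
                        train_subjects, degenerate=True)
    bp, bn, b0 = _fit_scores(s_pos, s_neg, yv)
    return CPMModel(pos, neg, bp, bn, b0, p_threshold, train_subjects)


def fit_cpm_sets(edges: EdgeTable, y, positive: list[str], negative: list[str],
                 p_threshold: float = np.nan) -> CPMModel:
    """Fit the CPM regression with *given* edge sets (e.g. consensus sets)."""
    if isinstance(y, pd.Series):
        yv = y.reindex(edges.data.index).to_numpy(float)
    else:
        yv = np.asarray(y, dtype=float)
    mask = np.isfinite(yv)
    if mask.sum() <= 3:
        raise ValueError("training set must have > 3 subjects")
    train_subjects = [s for s, m in zip(edges.data.index, mask) if m]
    if not positive and not negative:
        log.info("both edge sets empty; intercept-only CPM model")
        return CPMModel([], [], 0.0, 0.0, float(yv[mask].mean()), p_threshold,
                        train_subjects, degenerate=True)
    s_pos, s_neg = brain_scores(edges, positive, negative)
    bp, bn, b0 = _fit_scores(s_pos[mask], s_neg[mask], yv[mask])
    return CPMModel(list(positive), list(negative), bp, bn, b0, p_threshold,
                    train_subjects)


def predict_cpm(model: CPMModel, edges: EdgeTable) -> np.ndarray:
    """Apply training-selected edges and coefficients to (new) subjects."""
    s_pos, s_neg = brain_scores(edges, model.positive_edges, model.negative_edges)
    return model.beta_pos * s_pos + model.beta_neg * s_neg + model.intercept


def total_brain_score(model: CPMModel, edges: EdgeTable) -> np.ndarray:
    """``beta+ * S+ + beta- * S-`` (no intercept: constant shifts do not
    affect the downstream correlation-based networks)."""
    s_pos, s_neg = brain_scores(edges, model.positive_edges, model.negative_edges)
    return model.beta_pos * s_pos + model.beta_neg * s_neg


def _outer_splits(n: int, n_outer: int, test_fraction: float, seed: int
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    ss = ShuffleSplit(n_splits=n_outer, test_size=test_fraction,
                      random_state=seed)
    return [(tr, te) for tr, te in ss.split(np.arange(n))]


def tune_cpm(channels: dict[tuple, EdgeTable], y, p_grid: list[float],
             n_outer: int = 10, outer_test_fraction: float = 0.2,
             inner_folds: int = 10, seed: int = 0) -> TuningResult:
    """Outer shuffle-split tuning over (channel x p-threshold) grid cells.

    ``channels`` maps ``(roi_resolution, metric, gsr)`` keys to edge
    tables sharing one subject list.  For every grid cell and every outer
    80/20 split the model is selected and fitted on the training part and
    scored by the correlation between predicted and observed values on the
    held-out part; an inner k-fold CV on the training part is recorded as
    a diagnostic.  The winning cell maximizes the mean held-out
    correlation (ties: smaller resolution, then stricter threshold).
    """
    keys = sorted(channels.keys(), key=lambda k: (k[0], str(k[1]), bool(k[2])))
    subj = channels[keys[0]].data.index
    for k in keys[1:]:
        if not channels[k].data.index.equals(subj):
            raise ValueError(f"channel {k} has a different subject list")
    if isinstance(y, pd.Series):
        yv = y.reindex(subj).to_numpy(float)
    else:
        yv = np.asarray(y, dtype=float)
    mask = np.isfinite(yv)
    yv = yv[mask]
    splits = _outer_splits(int(mask.sum()), n_outer, outer_test_fraction, seed)

    rows = []
    for key in keys:
        X = channels[key].values()[mask]
        res, metric, gsr = key
        for p_thr in sorted(p_grid):
            for si, (tr, te) in enumerate(splits):
                pos, neg = _select_mask(X[tr], yv[tr], p_thr)
                sp, sn = X[tr][:, pos].sum(axis=1), X[tr][:, neg].sum(axis=1)
                bp, bn, b0 = _fit_scores(sp, sn, yv[tr])
                pred = (bp * X[te][:, pos].sum(axis=1)
                        + bn * X[te][:, neg].sum(axis=1) + b0)
                if np.ptp(pred) == 0 or np.ptp(yv[te]) == 0:
                    r_hold = np.nan
                else:
                    r_hold = float(np.corrcoef(pred, yv[te])[0, 1])
                r_inner = np.nan
                if inner_folds >= 2 and len(tr) >= inner_folds:
                    kf = KFold(n_splits=inner_folds, shuffle=True,
                               random_state=seed + 1)
                    inner_splits = [(tr[a], tr[b])
                                    for a, b in kf.split(np.arange(len(tr)))]
                    r_inner, _ = _cv_mean_r(X, yv, inner_splits, p_thr)
                rows.append({"resolution": res, "metric": metric, "gsr": gsr,
                             "p_threshold": p_thr, "split": si,
                             "r_holdout": r_hold, "r_inner": r_inner})
    table = pd.DataFrame(rows)
    means = (table.groupby(["resolution", "metric", "gsr", "p_threshold"],
                           sort=True)["r_holdout"].mean())
    # max mean r; ties -> smaller resolution, then stricter (smaller) p
    ranked = sorted(means.items(),
                    key=lambda kv: (-(kv[1] if np.isfinite(kv[1]) else -np.inf),
                                    kv[0][0], kv[0][3], str(kv[0][1]), kv[0][2]))
    best_key = ranked[0][0]
    best = {"resolution": best_key[0], "metric": best_key[1],
            "gsr": best_key[2], "p_threshold": best_key[3],
            "mean_r_holdout": float(ranked[0][1])}
    return TuningResult(table=table, best=best, splits=splits, seed=seed)


def per_split_selections(edges: EdgeTable, y, p_threshold: float,
                         splits: list[tuple[np.ndarray, np.ndarray]]
                         ) -> list[tuple[list[str], list[str]]]:
    """Edge selections on the training part of each outer split."""
    X, yv = _as_xy(edges, y)
    cols = np.asarray(edges.data.columns)
    out = []
    for tr, _ in splits:
        pos, neg = _select_mask(X[tr], yv[tr], p_threshold)
        out.append((cols[pos].tolist(), cols[neg].tolist()))
    return out


def consensus_edges(per_split: list[tuple[list[str], list[str]]],
                    min_count: int = 7) -> ConsensusEdges:
    """Edges selected with the same sign in at least ``min_count`` splits.

    An edge appearing with both signs across splits is excluded and logged
    as a sign conflict.
    """
    if len(per_split) < min_count:
        raise ValueError(
            f"min_count {min_count} exceeds number of splits {len(per_split)}")
    pos_counts: dict[str, int] = {}
    neg_counts: dict[str, int] = {}
    for pos, neg in per_split:
        for e in pos:
            pos_counts[e] = pos_counts.get(e, 0) + 1
        for e in neg:
            neg_counts[e] = neg_counts.get(e, 0) + 1
    conflicts = sorted(set(pos_counts) & set(neg_counts))
    if conflicts:
        log.warning("sign conflicts across splits, excluded: %s", conflicts)
    positive = sorted(e for e, c in pos_counts.items()
                      if c >= min_count and e not in conflicts)
    negative = sorted(e for e, c in neg_counts.items()
                      if c >= min_count and e not in conflicts)
    return ConsensusEdges(per_split=per_split, min_count=min_count,
                          positive=positive, negative=negative,
                          sign_conflicts=conflicts)


def permutation_test(edges: EdgeTable, y, p_threshold: float,
                     n_outer: int = 10, outer_test_fraction: float = 0.2,
                     n_perm: int = 5000, seed: int = 0,
                     reselect: bool = True) -> PermutationResult:
    """Permutation test of the mean held-out correlation.

    The observed statistic is the mean held-out correlation over the outer
    splits.  Null statistics re-run the identical pipeline on row-permuted
    ``y``; with ``reselect`` (default) edge selection is repeated inside
    every permutation, otherwise the observed-data edge sets are frozen
    (optimistic/leaky variant).  p = (1 + #{null >= observed}) / (1 + n_perm).

    A replicate (or the observed run) in which every split is undefined
    (no edges selected anywhere) is assigned the floor statistic -2, below
    any correlation: "no model" counts as no evidence.  The statistic
    stays a deterministic function of (edges, y), so the permutation p
    remains exact under exchangeability.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, yv = _as_xy(edges, y)
    splits = _outer_splits(len(yv), n_outer, outer_test_fraction, seed)
    observed, _ = _cv_mean_r(X, yv, splits, p_threshold)
    floor = -2.0  # statistic for runs where every split is undefined
    observed_cmp = observed if np.isfinite(observed) else floor

    frozen = None
    if not reselect:
        frozen = [
            _select_mask(X[tr], yv[tr], p_threshold) for tr, _ in splits]

    rng = np.random.default_rng(seed + 1)
    null_stats = np.empty(n_perm)
    for b in range(n_perm):
        yp = yv[rng.permutation(len(yv))]
        if reselect:
            stat, _ = _cv_mean_r(X, yp, splits, p_threshold)
        else:
            rs = []
            for (tr, te), (pos, neg) in zip(splits, frozen):
                sp, sn = X[tr][:, pos].sum(axis=1), X[tr][:, neg].sum(axis=1)
                bp, bn, b0 = _fit_scores(sp, sn, yp[tr])
                pred = (bp * X[te][:, pos].sum(axis=1)
                        + bn * X[te][:, neg].sum(axis=1) + b0)
                if np.ptp(pred) == 0 or np.ptp(yp[te]) == 0:
                    rs.append(np.nan)
                else:
                    rs.append(float(np.corrcoef(pred, yp[te])[0, 1]))
            arr = np.asarray(rs)
            stat = float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan
        null_stats[b] = stat if np.isfinite(stat) else floor
    exceed = np.sum(null_stats >= observed_cmp)
    p = float((1 + exceed) / (1 + n_perm))
    return PermutationResult(p_value=p, observed=observed,
                             null_stats=null_stats, n_perm=n_perm)
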
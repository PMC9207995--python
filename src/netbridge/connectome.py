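"""Subject-level functional connectomes and their edge representation.

Builds square connectivity matrices from ROI time series (Pearson, partial
correlation, or tangent-space embedding around the group geometric mean),
vectorizes them into an upper-triangle edge table, removes confound
structure edge-wise, and applies ROI-coverage exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

__all__ = [
    "ConnectomeSet",
    "EdgeTable",
    "connectome_pearson",
    "connectome_partial",
    "connectome_tangent",
    "geometric_mean_spd",
    "vectorize_edges",
    "devectorize",
    "regress_confounds",
    "build_confound_design",
    "filter_rois",
    "restrict_edges",
    "read_timeseries",
    "read_timeseries_dir",
    "write_connectome_csv",
    "read_connectome_csv",
]


@dataclass
class ConnectomeSet:
    """Per-subject square symmetric matrices over a shared ROI list."""

    subject_ids: list
    matrices: np.ndarray  # (n_subjects, R, R)
    roi_names: list[str]
    metric: str = "pearson"  # pearson | partial | tangent | covariance
    gsr: bool = False

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_subjects, R, R)")
        if self.matrices.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids do not match matrix count")
        if self.matrices.shape[1] != len(self.roi_names):
            raise ValueError("roi_names do not match matrix size")
        asym = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
        if asym > 1e-10:
            raise ValueError(f"matrices not symmetric (max asymmetry {asym:.2e})")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)


@dataclass
class EdgeTable:
    """Subjects x vectorized upper-triangle edges.

    Columns are labelled ``"<i>_<j>"`` by ROI index with ``i < j``;
    :attr:`pairs` maps column position to the (ROI_i, ROI_j) name pair.
    """

    data: pd.DataFrame
    pairs: list[tuple[str, str]]
    metric: str = "pearson"
    gsr: bool = False
    confounds_removed: bool = False

    def __post_init__(self) -> None:
        if len(self.pairs) != self.data.shape[1]:
            raise ValueError("pairs do not match edge columns")

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, metric: str = "pearson", gsr: bool = False,
                 roi_names: list[str] | None = None) -> "EdgeTable":
        df = pd.read_csv(path, index_col="subject_id")
        r = _infer_n_rois(df.shape[1])
        names = roi_names if roi_names is not None else _default_roi_names(r)
        iu = np.triu_indices(r, k=1)
        pairs = [(names[i], names[j]) for i, j in zip(*iu)]
        return cls(df, pairs, metric=metric, gsr=gsr)


# ---------------------------------------------------------------------------
# per-subject matrices


def _validate_timeseries(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (timepoints x ROIs) matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant ROI columns: {bad}")
    return ts


def connectome_pearson(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of ROI time series."""
    ts = _validate_timeseries(ts)
    c = np.corrcoef(ts, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def connectome_partial(ts: np.ndarray, shrinkage: str | None = "ledoit_wolf"
                       ) -> np.ndarray:
    """Partial correlation of each ROI pair given all remaining ROIs.

    Computed from the (optionally shrinkage-regularized) precision matrix
    as ``rho_ij = -k_ij / sqrt(k_ii k_jj)``.  With ``shrinkage=None`` the
    empirical covariance is inverted directly, which requires more
    timepoints than ROIs.
    """
    ts = _validate_timeseries(ts)
    t, r = ts.shape
    if shrinkage is None:
        if t < r + 2:
            raise ValueError(
                f"direct partial correlation needs >= ROIs+2 timepoints "
                f"({t} < {r + 2}); enable shrinkage")
        cov = np.cov(ts, rowvar=False)
        sign, _ = np.linalg.slogdet(cov)
        if sign <= 0 or np.linalg.cond(cov) > 1e12:
            raise ValueError("singular covariance with shrinkage disabled")
    elif shrinkage == "ledoit_wolf":
        cov = LedoitWolf(assume_centered=False).fit(ts).covariance_
    else:
        raise ValueError(f"unknown shrinkage {shrinkage!r}")
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _eigh_fun(mat: np.ndarray, fun) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    return (v * fun(w)) @ v.T


def geometric_mean_spd(mats: np.ndarray, tol: float = 1e-8,
                       max_iter: int = 200) -> np.ndarray:
    """Geometric (Karcher) mean of SPD matrices by fixed-point iteration."""
    mats = np.asarray(mats, dtype=float)
    g = mats.mean(axis=0)
    for _ in range(max_iter):
        g_isqrt = _eigh_fun(g, lambda w: 1.0 / np.sqrt(w))
        g_sqrt = _eigh_fun(g, np.sqrt)
        logs = np.array([_eigh_fun(g_isqrt @ m @ g_isqrt, np.log) for m in mats])
        mean_log = logs.mean(axis=0)
        mean_log = (mean_log + mean_log.T) / 2.0
        if np.linalg.norm(mean_log) < tol:
            return g
        g = g_sqrt @ _eigh_fun(mean_log, np.exp) @ g_sqrt
        g = (g + g.T) / 2.0
    warnings.warn("geometric mean did not reach tolerance; returning last iterate",
                  RuntimeWarning, stacklevel=2)
    return g


def connectome_tangent(cset: ConnectomeSet, reference: str = "geometric"
                       ) -> ConnectomeSet:
    """Tangent-space embedding of covariance matrices around a group reference.

    Each subject's SPD matrix C is mapped to
    ``logm(Cg^{-1/2} C Cg^{-1/2})`` where the reference Cg is the group
    geometric mean (default) or the log-Euclidean mean.
    """
    for sid, m in zip(cset.subject_ids, cset.matrices):
        w = np.linalg.eigvalsh(m)
        if w[0] <= 0:
            raise ValueError(
                f"matrix for subject {sid!r} is not positive definite "
                f"(min eigenvalue {w[0]:.3e})")
    if reference == "geometric":
        ref = geometric_mean_spd(cset.matrices)
    elif reference == "logeuclidean":
        ref = _eigh_fun(
            np.mean([_eigh_fun(m, np.log) for m in cset.matrices], axis=0), np.exp)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    ref_isqrt = _eigh_fun(ref, lambda w: 1.0 / np.sqrt(w))
    tangents = np.array([
        _eigh_fun(ref_isqrt @ m @ ref_isqrt, np.log) for m in cset.matrices])
    tangents = (tangents + tangents.transpose(0, 2, 1)) / 2.0
    out = ConnectomeSet(cset.subject_ids, tangents, cset.roi_names,
                        metric="tangent", gsr=cset.gsr)
    out.reference = ref  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# vectorization


def _default_roi_names(r: int) -> list[str]:
    width = max(3, len(str(r - 1)))
    return [f"roi{i:0{width}d}" for i in range(r)]


def _infer_n_rois(n_edges: int) -> int:
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} edges is not R*(R-1)/2 for any integer R")
    return r


def edge_labels(r: int) -> list[str]:
    iu = np.triu_indices(r, k=1)
    return [f"{i}_{j}" for i, j in zip(*iu)]


def vectorize_edges(cset: ConnectomeSet) -> EdgeTable:
    """Row-major upper-triangle (i < j) vectorization of a ConnectomeSet."""
    r = cset.n_rois
    iu = np.triu_indices(r, k=1)
    mat = cset.matrices[:, iu[0], iu[1]]
    labels = [f"{i}_{j}" for i, j in zip(*iu)]
    pairs = [(cset.roi_names[i], cset.roi_names[j]) for i, j in zip(*iu)]
    df = pd.DataFrame(mat, index=cset.subject_ids, columns=labels)
    return EdgeTable(df, pairs, metric=cset.metric, gsr=cset.gsr)


def devectorize(table: EdgeTable, roi_names: list[str] | None = None
                ) -> ConnectomeSet:
    """Inverse of :func:`vectorize_edges`.

    The diagonal is restored as 1 for correlation-type metrics and 0
    otherwise (it is not stored in the edge table).
    """
    r = _infer_n_rois(table.n_edges)
    if roi_names is None:
        roi_names = sorted({n for p in table.pairs for n in p}) \
            if table.pairs else _default_roi_names(r)
        if len(roi_names) != r:
            roi_names = _default_roi_names(r)
    iu = np.triu_indices(r, k=1)
    n = len(table.data)
    mats = np.zeros((n, r, r))
    vals = table.values()
    mats[:, iu[0], iu[1]] = vals
    mats[:, iu[1], iu[0]] = vals
    diag = 1.0 if table.metric in ("pearson", "partial") else 0.0
    mats[:, np.arange(r), np.arange(r)] = diag
    return ConnectomeSet(table.subject_ids, mats, roi_names,
                         metric=table.metric, gsr=table.gsr)


# ---------------------------------------------------------------------------
# confound removal


def build_confound_design(confounds: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, numeric confounds (age also squared),
    and k-1 dummy coding for categorical columns."""
    cols: list[np.ndarray] = [np.ones(len(confounds))]
    names = ["intercept"]
    for c in confounds.columns:
        s = confounds[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            counts = s.astype(str).value_counts()
            singletons = [lv for lv in levels if counts.get(lv, 0) == 1]
            if singletons:
                warnings.warn(
                    f"confound {c!r} has single-subject levels {singletons}; "
                    "their dummies fit those subjects exactly",
                    RuntimeWarning, stacklevel=2)
            for lv in levels[1:]:  # k-1 coding, first level is reference
                cols.append((s.astype(str) == lv).to_numpy(float))
                names.append(f"{c}[{lv}]")
        else:
            v = s.to_numpy(float)
            if np.ptp(v) == 0:  # zero-variance: contributes nothing beyond intercept
                continue
            cols.append(v)
            names.append(c)
            if c == "age":
                cols.append(v ** 2)
                names.append("age_sq")
    X = np.column_stack(cols)
    # standardize non-intercept columns: span-preserving (intercept present)
    # and keeps the projection well-conditioned across confound scales
    X[:, 1:] = (X[:, 1:] - X[:, 1:].mean(axis=0)) / X[:, 1:].std(axis=0)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear confound design: {names}")
    return X, names


def regress_confounds(edges: EdgeTable, confounds: pd.DataFrame,
                      strategy: str = "residualize") -> EdgeTable:
    """Replace each edge column by its OLS residual on the confound design.

    The projection is idempotent and leaves each edge orthogonal to every
    confound regressor.
    """
    if strategy != "residualize":
        raise ValueError(f"unsupported strategy {strategy!r}")
    conf = confounds.reindex(edges.data.index)
    if conf.isna().any().any():
        missing = conf.index[conf.isna().any(axis=1)].tolist()
        raise ValueError(f"confounds missing for subjects: {missing}")
    X, _ = build_confound_design(conf)
    Y = edges.values()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = pd.DataFrame(resid, index=edges.data.index, columns=edges.data.columns)
    return replace(edges, data=df, confounds_removed=True)


# ---------------------------------------------------------------------------
# ROI coverage filter


def filter_rois(coverage: dict[str, float], threshold: float = 0.5
                ) -> tuple[list[str], list[str]]:
    """Split ROIs into (kept, excluded) by coverage fraction.

    An ROI is excluded iff its coverage is strictly below ``threshold``
    (a coverage of exactly 0.5 is kept under the default).
    """
    for roi, frac in coverage.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"coverage for {roi!r} outside [0,1]: {frac}")
    kept = [r for r, f in coverage.items() if f >= threshold]
    excluded = [r for r, f in coverage.items() if f < threshold]
    return kept, excluded


def restrict_edges(table: EdgeTable, kept_rois: list[str]) -> EdgeTable:
    """Drop edge columns touching any ROI not in ``kept_rois``."""
    keep_set = set(kept_rois)
    idx = [k for k, (a, b) in enumerate(table.pairs)
           if a in keep_set and b in keep_set]
    df = table.data.iloc[:, idx]
    pairs = [table.pairs[k] for k in idx]
    return replace(table, data=df, pairs=pairs)


# ---------------------------------------------------------------------------
# text I/O


def read_timeseries(path) -> np.ndarray:
    """Delimited-text time-series matrix (rows = timepoints, cols = ROIs)."""
    return np.loadtxt(path, delimiter=None if str(path).endswith((".txt", ".tsv"))
                      else ",")


def read_timeseries_dir(directory) -> tuple[list[str], list[np.ndarray]]:
    """All ``*.tsv``/``*.txt``/``*.csv`` matrices in a directory, sorted by
    filename; the stem is the subject id."""
    paths = sorted(p for p in Path(directory).iterdir()
                   if p.suffix in (".tsv", ".txt", ".csv"))
    if not paths:
        raise ValueError(f"no time-series files in {directory}")
    return [p.stem for p in paths], [read_timeseries(p) for p in paths]


def write_connectome_csv(path, matrix: np.ndarray, roi_names: list[str]) -> None:
    pd.DataFrame(matrix, columns=roi_names).to_csv(path, index=False)


def read_connectome_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(float), list(df.columns)
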
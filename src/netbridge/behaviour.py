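"""Unique-variance behavioural regressors.

Correlated trait scores are turned into regressors that carry only the
variance not shared with the other traits, by ordinary-least-squares
residualization.  Two schemes are provided:

``full``
    Each trait is regressed on *all* other traits (plus intercept) and
    replaced by the residual.  Residuals are orthogonal to every other
    original trait but generally not to each other.

``sequential``
    Traits are orthogonalized in a fixed order (Gram-Schmidt): trait k is
    regressed on the traits earlier in the order only.  The first trait is
    returned unchanged up to centering and the residual columns are
    mutually orthogonal.

Both schemes are exposed because the two give different correlation
patterns between residuals and originals; which one a study intends must
be stated explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourTable",
    "ResidualModel",
    "residualize_full",
    "residualize_sequential",
    "correlation_table",
]

RESIDUAL_SUFFIX = "_residual"


@dataclass
class BehaviourTable:
    """Subjects x trait scores with missing cells encoded as NaN.

    Parameters
    ----------
    data : pandas.DataFrame
        Index = subject ids (unique), columns = trait names, float scores.
        NaN marks a missing score.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        self.data = self.data.astype(float)

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if not c.endswith(RESIDUAL_SUFFIX)]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "BehaviourTable":
        df = pd.read_csv(path, index_col="subject_id")
        return cls(df)


@dataclass
class ResidualModel:
    """Record of one residualization regression y = X beta + intercept + eps."""

    target: str
    regressors: list[str]
    coefficients: dict[str, float]
    intercept: float
    residuals: pd.Series
    scheme: str
    order: list[str] | None = None
    n_used: int = 0
    used_mask: pd.Series | None = field(default=None, repr=False)


def _check_min_nonmissing(df: pd.DataFrame) -> None:
    bad = [c for c in df.columns if df[c].notna().sum() < 3]
    if bad:
        raise ValueError(f"traits with fewer than 3 non-missing values: {bad}")


def _ols_residual(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual of y on [X, intercept]; returns (residuals, coefficients)."""
    design = np.column_stack([X, np.ones(len(y))]) if X.size else np.ones((len(y), 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta, beta


def _collinear_names(df: pd.DataFrame) -> list[str]:
    """Greedy scan for columns linearly dependent on the preceding ones."""
    cols: list[str] = []
    X = np.ones((len(df), 1))
    bad = []
    for c in df.columns:
        cand = np.column_stack([X, df[c].to_numpy()])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            bad.append(c)
        else:
            X = cand
            cols.append(c)
    return bad


def residualize_full(table: BehaviourTable, traits: list[str] | None = None
                     ) -> tuple[BehaviourTable, list[ResidualModel]]:
    """Residualize each trait on all other traits (plus intercept).

    Rows are restricted to complete cases across the participating traits;
    residuals for excluded rows are NaN.

    Returns
    -------
    (BehaviourTable, list of ResidualModel)
        The table carries the original columns plus ``<trait>_residual``
        columns.
    """
    traits = list(traits) if traits is not None else table.traits
    if len(traits) < 2:
        raise ValueError("full residualization needs at least 2 traits")
    df = table.data[traits]
    _check_min_nonmissing(df)
    complete = df.notna().all(axis=1)
    if complete.sum() <= len(traits) + 1:
        raise ValueError(
            f"only {int(complete.sum())} complete-case rows for {len(traits)} traits")
    sub = df.loc[complete]

    models = []
    out = table.data.copy()
    for target in traits:
        others = [t for t in traits if t != target]
        y = sub[target].to_numpy()
        X = sub[others].to_numpy()
        try:
            resid, beta = _ols_residual(y, X)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"rank-deficient regressors for {target!r}; collinear traits: "
                f"{_collinear_names(sub[others])}") from None
        col = pd.Series(np.nan, index=df.index, name=target + RESIDUAL_SUFFIX)
        col.loc[complete] = resid
        out[col.name] = col
        models.append(ResidualModel(
            target=target, regressors=others,
            coefficients=dict(zip(others, beta[:-1])), intercept=float(beta[-1]),
            residuals=col, scheme="full", n_used=int(complete.sum()),
            used_mask=complete))
    return BehaviourTable(out), models


def residualize_sequential(table: BehaviourTable, order: list[str]
                           ) -> tuple[BehaviourTable, list[ResidualModel]]:
    """Orthogonalize traits in a fixed order (Gram-Schmidt residualization).

    Trait k is regressed on the traits *earlier* in ``order`` only; the
    first trait is returned unchanged up to centering.  Residual columns
    are mutually orthogonal on the complete-case rows.
    """
    if sorted(order) != sorted(table.traits):
        raise ValueError(
            f"order {order} is not a permutation of the traits {table.traits}")
    df = table.data[list(order)]
    _check_min_nonmissing(df)
    # a single complete-case mask across all ordered traits keeps the
    # Gram-Schmidt orthogonality exact
    complete = df.notna().all(axis=1)
    if complete.sum() <= len(order) + 1:
        raise ValueError(
            f"only {int(complete.sum())} complete-case rows for {len(order)} traits")
    sub = df.loc[complete]

    models = []
    out = table.data.copy()
    for k, target in enumerate(order):
        earlier = list(order[:k])
        y = sub[target].to_numpy()
        X = sub[earlier].to_numpy() if earlier else np.empty((len(y), 0))
        resid, beta = _ols_residual(y, X)
        col = pd.Series(np.nan, index=df.index, name=target + RESIDUAL_SUFFIX)
        col.loc[complete] = resid
        out[col.name] = col
        models.append(ResidualModel(
            target=target, regressors=earlier,
            coefficients=dict(zip(earlier, beta[:-1])), intercept=float(beta[-1]),
            residuals=col, scheme="sequential", order=list(order),
            n_used=int(complete.sum()), used_mask=complete))
    return BehaviourTable(out), models


def correlation_table(table: BehaviourTable | pd.DataFrame,
                      columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Constant columns yield NaN entries and a warning (undefined, not zero).
    """
    df = table.data if isinstance(table, BehaviourTable) else table
    if columns is not None:
        df = df[columns]
    counts = df.notna().sum()
    if (counts < 2).any():
        raise ValueError(
            f"columns with fewer than 2 non-missing values: "
            f"{counts[counts < 2].index.tolist()}")
    constant = [c for c in df.columns if df[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant columns, correlations undefined: {constant}",
            RuntimeWarning, stacklevel=2)
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, [np.nan if c in constant else 1.0
                                   for c in df.columns])
    return corr
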
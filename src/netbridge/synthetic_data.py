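"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Every generator takes an explicit integer seed and is bit-reproducible.
The exact-correlation construction orthonormalizes a centred Gaussian draw
(QR) and recolours it with a factor of the target correlation matrix, so
the *sample* correlation matrix equals the target to floating-point
precision rather than only asymptotically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import BehaviourTable
from .connectome import EdgeTable, _default_roi_names

__all__ = [
    "SyntheticSpec",
    "make_behaviour",
    "make_edge_table",
    "make_timeseries",
    "make_confounds",
]


@dataclass
class SyntheticSpec:
    """Parameters for the synthetic behaviour/connectome fixtures.

    planted_effects entries are ``(edge_index, trait_name, rho)`` with the
    edge index into the row-major upper triangle of an ``n_roi`` x ``n_roi``
    matrix and ``rho`` the population correlation between that edge and the
    named trait.
    """

    n_subjects: int
    trait_names: list[str]
    target_corr: np.ndarray
    exact_corr: bool = True
    n_roi: int = 10
    planted_effects: list[tuple[int, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    site_levels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        p = len(self.trait_names)
        if self.target_corr.shape != (p, p):
            raise ValueError("target_corr shape does not match trait_names")
        if np.abs(self.target_corr - self.target_corr.T).max() > 1e-12:
            raise ValueError("target_corr must be symmetric")
        if np.abs(np.diag(self.target_corr) - 1.0).max() > 1e-12:
            raise ValueError("target_corr must have unit diagonal")
        w = np.linalg.eigvalsh(self.target_corr)
        if w[0] < -1e-10:
            raise ValueError(
                f"target_corr is not positive semi-definite "
                f"(smallest eigenvalue {w[0]:.3e})")
        n_edges = self.n_roi * (self.n_roi - 1) // 2
        for e, t, rho in self.planted_effects:
            if not 0 <= e < n_edges:
                raise ValueError(f"planted edge index {e} out of range (<{n_edges})")
            if t not in self.trait_names:
                raise ValueError(f"planted trait {t!r} not in trait_names")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"planted effect correlation must be in (-1,1): {rho}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L @ L.T = corr (Cholesky, falling
    back to an eigenvalue factor for singular PSD inputs)."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v * np.sqrt(np.clip(w, 0.0, None))


def _subject_ids(n: int) -> list[str]:
    return [f"sub{i:04d}" for i in range(n)]


def make_behaviour(spec: SyntheticSpec) -> BehaviourTable:
    """Trait scores with the prescribed (sample or population) correlations.

    With ``exact_corr`` the sample correlation matrix of the output equals
    ``spec.target_corr`` to ~1e-10; otherwise the scores are a plain
    multivariate-normal draw with that population correlation.
    """
    n, p = spec.n_subjects, len(spec.trait_names)
    if n <= p + 1:
        raise ValueError(f"need n_subjects > traits + 1 ({n} <= {p + 1})")
    rng = np.random.default_rng(spec.seed)
    L = _corr_factor(spec.target_corr)
    if spec.exact_corr:
        g = rng.standard_normal((n, p))
        g -= g.mean(axis=0)
        q, r = np.linalg.qr(g)
        q *= np.sign(np.diag(r))  # fix QR sign convention
        x = np.sqrt(n - 1) * q @ L.T
    else:
        x = rng.standard_normal((n, p)) @ L.T
    df = pd.DataFrame(x, index=_subject_ids(n), columns=list(spec.trait_names))
    return BehaviourTable(df)


def make_edge_table(spec: SyntheticSpec, behaviour: BehaviourTable) -> EdgeTable:
    """Standardized edge columns; planted edges carry the requested
    population correlation with their trait, all others are pure noise."""
    n = spec.n_subjects
    if behaviour.n_subjects != n:
        raise ValueError("behaviour table does not match spec.n_subjects")
    planted_idx = [e for e, _, _ in spec.planted_effects]
    if len(planted_idx) != len(set(planted_idx)):
        raise ValueError(f"duplicate planted edge indices: {sorted(planted_idx)}")
    n_edges = spec.n_roi * (spec.n_roi - 1) // 2
    rng = np.random.default_rng(spec.seed + 1)
    edges = rng.standard_normal((n, n_edges)) * spec.noise_sd
    for e, trait, rho in spec.planted_effects:
        t = behaviour.data[trait].to_numpy()
        if np.isnan(t).any():
            raise ValueError(f"planted trait {trait!r} has missing values")
        z = (t - t.mean()) / t.std()
        edges[:, e] = rho * z + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    edges = (edges - edges.mean(axis=0)) / edges.std(axis=0)

    iu = np.triu_indices(spec.n_roi, k=1)
    labels = [f"{i}_{j}" for i, j in zip(*iu)]
    roi = _default_roi_names(spec.n_roi)
    pairs = [(roi[i], roi[j]) for i, j in zip(*iu)]
    df = pd.DataFrame(edges, index=behaviour.subject_ids, columns=labels)
    return EdgeTable(df, pairs, metric="pearson", gsr=False)


def make_timeseries(n_subjects: int, t: int, roi_cov: np.ndarray,
                    seed: int = 0) -> list[np.ndarray]:
    """Per-subject (t x R) matrices with i.i.d. multivariate-normal rows."""
    roi_cov = np.asarray(roi_cov, dtype=float)
    r = roi_cov.shape[0]
    if roi_cov.shape != (r, r) or np.abs(roi_cov - roi_cov.T).max() > 1e-12:
        raise ValueError("roi_cov must be square symmetric")
    w = np.linalg.eigvalsh(roi_cov)
    if w[0] < -1e-10:
        raise ValueError(f"roi_cov not PSD (smallest eigenvalue {w[0]:.3e})")
    if t <= r:
        raise ValueError(
            f"need more timepoints than ROIs ({t} <= {r}); "
            "downstream partial correlation would be ill-posed")
    rng = np.random.default_rng(seed)
    wc, vc = np.linalg.eigh(roi_cov)
    L = vc * np.sqrt(np.clip(wc, 0.0, None))
    return [rng.standard_normal((t, r)) @ L.T for _ in range(n_subjects)]


def make_confounds(n_subjects: int, site_levels: int, seed: int = 0,
                   age_range: tuple[float, float] = (10.0, 21.0)) -> pd.DataFrame:
    """Confound table: age, categorical site, FD (mm), DVARS (%), ICV and
    grey-matter volume (mm^3).

    Distributional choices are fixture conventions (uniform age, lognormal
    motion metrics, normal volumes).  When ``n_subjects >= site_levels``
    the site draw is regenerated (up to 1000 times) until every level is
    occupied, so downstream dummy coding is full-rank.
    """
    if site_levels < 1:
        raise ValueError("site_levels must be >= 1")
    rng = np.random.default_rng(seed)
    age = rng.uniform(age_range[0], age_range[1], n_subjects)
    if n_subjects >= site_levels:
        for _ in range(1000):
            site = rng.integers(0, site_levels, n_subjects)
            if len(np.unique(site)) == site_levels:
                break
        else:  # pragma: no cover - astronomically unlikely at sane sizes
            raise RuntimeError("could not draw a site assignment covering all levels")
    else:
        warnings.warn("fewer subjects than site levels; some levels empty",
                      RuntimeWarning, stacklevel=2)
        site = rng.integers(0, site_levels, n_subjects)
    width = len(str(max(site_levels - 1, 1)))
    df = pd.DataFrame({
        "age": age,
        "site": [f"site{s:0{width}d}" for s in site],
        "fd": rng.lognormal(mean=np.log(0.15), sigma=0.45, size=n_subjects),
        "dvars": rng.lognormal(mean=np.log(1.5), sigma=0.35, size=n_subjects),
        "icv": rng.normal(1.45e6, 1.2e5, n_subjects),
        "gm_volume": rng.normal(7.0e5, 6.0e4, n_subjects),
    }, index=_subject_ids(n_subjects))
    return df
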
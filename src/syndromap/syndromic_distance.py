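"""Norm-correlation distances between patients over the standardized CDEs.

Each of the 17 analysis variables is mean-centered and variance-normalized
(population convention) so that binary findings, ordinal severity scores,
and continuous test scores live on a common unitless scale.  The distance
between two patients is then one minus the Pearson correlation of their
standardized 17-value profiles: 0 for identical profiles, 2 for exactly
opposite ones.  This is a dissimilarity, not a metric — the triangle
inequality is not guaranteed and never relied upon downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cde_io import CohortTable


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (constant vector)."""


class AllMissingColumnError(ValueError):
    """A column has no observed values to standardize."""


IMPUTE_STRATEGIES = ("median", "mean", "pairwise")

#: minimum shared observed variables for a pairwise-complete correlation
MIN_PAIRWISE_OVERLAP = 8


@dataclass
class StandardizedMatrix:
    """Patient-by-variable matrix after per-column z-scoring.

    ``values`` may contain NaN only under the ``pairwise`` strategy.
    ``impute_mask`` marks cells that were filled before standardization.
    ``column_stats`` records the (mean, SD) used per column; degenerate
    (zero-variance) columns are set to all-zero and flagged.
    """

    values: np.ndarray
    impute_mask: np.ndarray
    column_stats: pd.DataFrame
    columns: list[str]
    patient_ids: list[str]
    degenerate_columns: list[str] = field(default_factory=list)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    patient_ids: list[str]
    metric_name: str = "norm-correlation"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12:
            raise ValueError("distances must be nonnegative")
        if self.metric_name == "norm-correlation" and v.max() > 2 + 1e-9:
            raise ValueError("norm-correlation distances must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.patient_ids
        )
        frame.index.name = "patient_id"
        frame.to_csv(path, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(dtype=float), [str(i) for i in frame.index])


def standardize_columns(
    cohort: CohortTable, impute: str = "mean"
) -> StandardizedMatrix:
    """Z-score the 17 analysis columns (population SD).

    Missing cells are imputed before standardization and flagged.  The
    default is the per-column mean of the observed values: a mean-imputed
    cell standardizes to exactly zero, so an unobserved variable is neutral
    in the patient-pair correlation instead of asserting the median (often
    the healthy) category.  ``median`` imputation and ``pairwise`` (leave
    NaN for pairwise-complete correlations downstream) are available.  A
    zero-variance column is set to zero everywhere and reported with a
    warning rather than an error, so a degenerate variable cannot silently
    dominate nor abort the run.
    """
    if impute not in IMPUTE_STRATEGIES:
        raise ValueError(f"impute must be one of {IMPUTE_STRATEGIES}")
    frame = cohort.tda_matrix()
    raw = frame.to_numpy(dtype=float)
    n, p = raw.shape
    impute_mask = np.isnan(raw)
    values = raw.copy()
    stats_rows = []
    degenerate = []
    for j, name in enumerate(frame.columns):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise AllMissingColumnError(f"column {name!r} has no observed values")
        if impute == "median":
            col[np.isnan(col)] = np.median(obs)
        elif impute == "mean":
            col[np.isnan(col)] = obs.mean()
        basis = col[~np.isnan(col)]
        mu = basis.mean()
        sd = basis.std()  # population convention
        if sd < 1e-12:
            warnings.warn(f"degenerate (constant) column {name!r} set to zero")
            values[:, j] = np.where(np.isnan(col), np.nan, 0.0)
            degenerate.append(str(name))
            sd = 0.0
        else:
            values[:, j] = (col - mu) / sd
        stats_rows.append({"variable": name, "mean": mu, "sd": sd})
    return StandardizedMatrix(
        values=values,
        impute_mask=impute_mask,
        column_stats=pd.DataFrame(stats_rows).set_index("variable"),
        columns=[str(c) for c in frame.columns],
        patient_ids=cohort.patient_ids,
        degenerate_columns=degenerate,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from the N-weighted sum form.

    Requires equal lengths of at least 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation requires at least 3 paired values")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def norm_corr(
    x_std: np.ndarray, y_std: np.ndarray, fallback_max: bool = False
) -> float:
    """Norm-correlation distance 1 - r between two standardized profiles."""
    try:
        return 1.0 - pearson_r(x_std, y_std)
    except UndefinedCorrelationError:
        if fallback_max:
            warnings.warn(
                "constant patient profile: distance set to the maximum 2.0"
            )
            return 2.0
        raise


def _pairwise_complete(values: np.ndarray, fallback_max: bool) -> np.ndarray:
    """Pairwise-complete norm-correlation: each patient pair is correlated
    over the variables both have observed (vectorized via masked sums).

    Pairs sharing fewer than ``MIN_PAIRWISE_OVERLAP`` observed variables, or
    with a constant profile over the shared variables, get the maximum
    distance 2.0 under ``fallback_max`` and raise otherwise.
    """
    observed = ~np.isnan(values)
    x = np.where(observed, values, 0.0)
    m = observed.astype(float)
    n_shared = m @ m.T
    sx = x @ m.T          # sum of x_i over the pair's shared variables
    sxx = (x * x) @ m.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n_shared * sxx - sx * sx          # var of row i on shared coords
        vy = vx.T
        num = n_shared * sxy - sx * sx.T
        denom = np.sqrt(np.where(vx > 0, vx, np.nan) * np.where(vy > 0, vy, np.nan))
        r = num / denom
    undefined = (n_shared < MIN_PAIRWISE_OVERLAP) | ~np.isfinite(r)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        if not fallback_max:
            ii, jj = np.nonzero(np.triu(undefined, 1))
            raise UndefinedCorrelationError(
                f"undefined distances for patient pairs "
                f"{list(zip(ii[:10].tolist(), jj[:10].tolist()))}"
            )
        warnings.warn(
            f"{int(np.triu(undefined, 1).sum())} patient pair(s) with "
            "insufficient overlap or constant shared profile: distance 2.0"
        )
    d = 1.0 - np.clip(np.where(undefined, -1.0, r), -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    np.clip(d, 0.0, 2.0, out=d)
    return d


def pairwise_distances(
    m: StandardizedMatrix, fallback_max: bool = True
) -> DistanceMatrix:
    """All pairwise norm-correlation distances.

    Patients whose standardized profile is constant across all variables
    have no defined correlation with anyone; with ``fallback_max`` (default)
    their distances are set to the theoretical maximum 2.0 with a warning,
    which isolates them in the map instead of aborting the run.
    """
    n = m.values.shape[0]
    if n < 2:
        raise ValueError("pairwise distances require at least 2 patients")
    if np.isnan(m.values).any():
        d = _pairwise_complete(m.values, fallback_max)
        return DistanceMatrix(d, m.patient_ids)

    rows = m.values
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    constant = sd[:, 0] < 1e-12
    if constant.any() and not fallback_max:
        raise UndefinedCorrelationError(
            f"constant profiles for patients "
            f"{[m.patient_ids[i] for i in np.flatnonzero(constant)]}"
        )
    sd_safe = np.where(constant[:, None], 1.0, sd)
    zr = (rows - mu) / sd_safe
    r = zr @ zr.T / rows.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant patient profile(s): "
            "distances set to the maximum 2.0"
        )
        d[constant, :] = 2.0
        d[:, constant] = 2.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    np.clip(d, 0.0, 2.0, out=d)
    return DistanceMatrix(d, m.patient_ids)
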
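"""Autoscaling, Kennard-Stone partitioning and PCA outlier diagnostics.

This is the shared numerical substrate of the screening workflow: every
model (exploratory PCA and the per-class SIMCA models alike) lives in the
autoscaled 8-variable space, samples are partitioned into training / test
sets with the deterministic Kennard-Stone maximin algorithm, and outliers
are diagnosed with Hotelling's T-squared (score distance) and the
Q residual (orthogonal distance) against 95% critical limits.

Conventions
-----------
* Standard deviations use the n-1 denominator.
* PCA is computed by SVD of the autoscaled matrix; eigenvalues are the
  score variances ``s_a**2 / (n - 1)``; each loading vector is signed so
  its largest-magnitude element is positive (reproducible loading plots).
* The T-squared limit is F-based, ``A (n-1)/(n-A) * F_{1-alpha}(A, n-A)``;
  the Q limit is the moment-matched scaled chi-squared of Nomikos &
  MacGregor (robust at the very small per-class n seen here, down to 4),
  with the Jackson-Mudholkar form available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .features import FEATURE_COLUMNS, FeatureMatrix

__all__ = [
    "ScalingParams",
    "PcaModel",
    "SplitResult",
    "autoscale_fit",
    "apply_scaling",
    "invert_scaling",
    "kennard_stone_split",
    "pca_fit",
    "project",
    "critical_limits",
    "influence_table",
]

MissingPolicy = Literal["zero_fill", "mean_impute"]
QLimitMethod = Literal["moment_chi2", "jackson_mudholkar"]

_EPS = 1e-12


@dataclass
class ScalingParams:
    """Column means and standard deviations (n-1 denominator) for autoscaling."""

    column_means: np.ndarray
    column_sds: np.ndarray
    column_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_sds = np.asarray(self.column_sds, dtype=float)
        if self.column_means.shape != self.column_sds.shape:
            raise ValueError("means and sds must have the same shape")
        if np.any(self.column_sds <= 0):
            raise ValueError("all column sds must be positive")


def _as_array(matrix: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values.copy(), matrix.columns
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    names = tuple(f"x{j}" for j in range(arr.shape[1]))
    return arr.copy(), names


def autoscale_fit(
    matrix: FeatureMatrix | np.ndarray,
    missing_policy: MissingPolicy = "mean_impute",
) -> tuple[ScalingParams, np.ndarray]:
    """Impute missing cells, then center and scale each column to unit variance.

    Missing cells (NaN) are filled *before* the means and sds are computed:
    ``mean_impute`` replaces them with the column mean of the observed values
    (so the cell scales to exactly 0), ``zero_fill`` with literal 0 (the
    "null data" reading of sparse high-collision-energy matrices).

    Returns the fitted :class:`ScalingParams` and the scaled matrix.
    Raises ``ValueError`` naming the column if any column is constant after
    imputation (such a column carries no information and would divide by 0).
    """
    X, names = _as_array(matrix)
    if X.shape[0] < 2:
        raise ValueError("autoscaling requires at least 2 rows")
    nan_mask = np.isnan(X)
    if nan_mask.any():
        if missing_policy == "zero_fill":
            X[nan_mask] = 0.0
        elif missing_policy == "mean_impute":
            for j in range(X.shape[1]):
                col_nan = nan_mask[:, j]
                if col_nan.all():
                    raise ValueError(f"column {names[j]!r} is entirely missing")
                if col_nan.any():
                    X[col_nan, j] = X[~col_nan, j].mean()
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds <= _EPS)
    if constant.size:
        raise ValueError(
            "constant column(s) cannot be autoscaled: "
            + ", ".join(names[j] for j in constant)
        )
    params = ScalingParams(column_means=means, column_sds=sds, column_names=names)
    return params, (X - means) / sds


def apply_scaling(
    params: ScalingParams, X: np.ndarray, impute_missing: bool = True
) -> np.ndarray:
    """Scale new rows with previously fitted parameters.

    NaN cells are imputed at the stored column mean (scaled value 0) when
    ``impute_missing`` is set; otherwise NaN propagates.
    """
    X = np.asarray(X, dtype=float).copy()
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.column_means.size:
        raise ValueError("column count does not match scaling parameters")
    if impute_missing:
        nan_mask = np.isnan(X)
        if nan_mask.any():
            X[nan_mask] = np.broadcast_to(params.column_means, X.shape)[nan_mask]
    return (X - params.column_means) / params.column_sds


def invert_scaling(params: ScalingParams, X_scaled: np.ndarray) -> np.ndarray:
    """Undo :func:`apply_scaling` (the exact inverse on non-missing data)."""
    return np.asarray(X_scaled, dtype=float) * params.column_sds + params.column_means


# -- Kennard-Stone -----------------------------------------------------------


@dataclass
class SplitResult:
    """Training/test partition plus the order Kennard-Stone picked samples."""

    train_indices: list[int]
    test_indices: list[int]
    selection_order: list[int]


def kennard_stone_split(
    X_scaled: np.ndarray,
    train_fraction: float = 0.75,
    train_size: int | None = None,
) -> SplitResult:
    """Deterministic maximin training-set selection (Kennard-Stone).

    The two mutually farthest samples (Euclidean distance in the scaled
    space) seed the training set; each further pick maximises its minimum
    distance to the already-selected set.  The first ``ceil(train_fraction
    * n)`` selections (or exactly ``train_size`` if given) become the
    training set, the remainder the test set.  All ties break to the lowest
    row index, so the split is fully reproducible.
    """
    X = np.asarray(X_scaled, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to split")
    n = X.shape[0]
    if train_size is None:
        if not 0 < train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        train_size = math.ceil(train_fraction * n)
    if not 2 <= train_size <= n:
        raise ValueError(f"train_size must be in [2, {n}], got {train_size}")

    D = cdist(X, X)
    # seed pair: maximum pairwise distance, lexicographically smallest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))  # first occurrence = smallest (i, j)
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    selected = [i0, j0]
    min_dist = np.minimum(D[i0], D[j0])
    min_dist[selected] = -np.inf
    while len(selected) < train_size:
        nxt = int(np.argmax(min_dist))  # first max = lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    train = sorted(selected)
    test = [i for i in range(n) if i not in set(selected)]
    return SplitResult(train_indices=train, test_indices=test, selection_order=selected)


# -- PCA with T2 / Q diagnostics ---------------------------------------------


@dataclass
class PcaModel:
    """PCA model on autoscaled data with outlier-diagnostic state.

    ``loadings`` is the p x A orthonormal loading matrix, ``eigenvalues`` the
    retained score variances (descending), ``all_eigenvalues`` the full
    spectrum (needed for the Jackson-Mudholkar Q limit).  ``t2_limit`` /
    ``q_limit`` are the critical values at confidence ``alpha``; the stored
    training moments of T-squared and Q allow the limits to be recomputed at
    any other confidence level.
    """

    scaling: ScalingParams
    loadings: np.ndarray
    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    A: int
    n_train: int
    alpha: float
    t2_limit: float
    q_limit: float
    t2_mean: float
    t2_var: float
    q_mean: float
    q_var: float
    q_limit_method: QLimitMethod = "moment_chi2"


def pca_fit(
    X_scaled: np.ndarray,
    A: int,
    scaling: ScalingParams,
    alpha: float = 0.05,
    q_limit_method: QLimitMethod = "moment_chi2",
) -> PcaModel:
    """Fit an A-component PCA model to an autoscaled matrix.

    ``A`` must satisfy ``1 <= A <= min(n - 1, p)``.  Eigenvalues are
    ``s_a**2/(n-1)``; loadings are signed so the largest-magnitude element
    of each vector is positive.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A must be in [1, {min(n - 1, p)}], got {A}")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    all_eig = s**2 / (n - 1)
    loadings = Vt[:A].T  # p x A
    # sign convention: largest-|.| element of each loading positive
    for a in range(A):
        k = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[k, a] < 0:
            loadings[:, a] = -loadings[:, a]
    eig = all_eig[:A]
    if np.any(eig <= _EPS):
        raise ValueError(
            f"requested {A} components but the data have rank "
            f"{int(np.sum(all_eig > _EPS))}"
        )
    model = PcaModel(
        scaling=scaling,
        loadings=loadings,
        eigenvalues=eig,
        all_eigenvalues=all_eig,
        A=A,
        n_train=n,
        alpha=alpha,
        t2_limit=np.nan,
        q_limit=np.nan,
        t2_mean=np.nan,
        t2_var=np.nan,
        q_mean=np.nan,
        q_var=np.nan,
        q_limit_method=q_limit_method,
    )
    scores = X @ loadings
    t2 = np.sum(scores**2 / eig, axis=1)
    resid = X - scores @ loadings.T
    q = np.sum(resid**2, axis=1)
    model.t2_mean, model.t2_var = float(t2.mean()), float(t2.var(ddof=1))
    model.q_mean, model.q_var = float(q.mean()), float(q.var(ddof=1))
    model.t2_limit, model.q_limit = critical_limits(model, alpha, q_limit_method)
    return model


def project(
    model: PcaModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project new raw rows onto the model: returns (scores, T-squared, Q).

    Rows are autoscaled with the model's own parameters (NaN cells imputed
    at the training mean).  ``T2 = sum_a t_a**2 / lambda_a`` is the
    Mahalanobis distance in score space; ``Q = ||x - t P'||**2`` is the
    squared residual orthogonal to the model plane.
    """
    Xs = apply_scaling(model.scaling, X)
    scores = Xs @ model.loadings
    t2 = np.sum(scores**2 / model.eigenvalues, axis=1)
    resid = Xs - scores @ model.loadings.T
    q = np.sum(resid**2, axis=1)
    return scores, t2, q


def critical_limits(
    model: PcaModel,
    alpha: float = 0.05,
    q_limit_method: QLimitMethod = "moment_chi2",
) -> tuple[float, float]:
    """Critical T-squared and Q values at confidence level ``1 - alpha``.

    T-squared: ``A (n-1)/(n-A) * F_{1-alpha}(A, n-A)``.  Q: by default the
    moment-matched scaled chi-squared ``g * chi2_{1-alpha}(h)`` with ``g =
    v/(2m)``, ``h = 2 m**2/v`` from the training-Q mean ``m`` and variance
    ``v`` (degenerate ``v = 0`` returns ``m``); alternatively the
    Jackson-Mudholkar limit from the discarded eigenvalue spectrum.
    """
    A, n = model.A, model.n_train
    if n <= A:
        raise ValueError(f"n_train ({n}) must exceed A ({A}) for critical limits")
    t2_crit = A * (n - 1) / (n - A) * stats.f.ppf(1 - alpha, A, n - A)
    if q_limit_method == "moment_chi2":
        m, v = model.q_mean, model.q_var
        if v <= _EPS or m <= _EPS:
            q_crit = m
        else:
            g, h = v / (2 * m), 2 * m**2 / v
            q_crit = g * stats.chi2.ppf(1 - alpha, h)
    elif q_limit_method == "jackson_mudholkar":
        rest = model.all_eigenvalues[model.A:]
        th1, th2, th3 = (float(np.sum(rest**i)) for i in (1, 2, 3))
        if th1 <= _EPS or th2 <= _EPS:
            q_crit = 0.0
        else:
            h0 = 1 - 2 * th1 * th3 / (3 * th2**2)
            if abs(h0) < _EPS:
                h0 = _EPS
            c_a = stats.norm.ppf(1 - alpha)
            term = (
                c_a * math.sqrt(2 * th2 * h0**2) / th1
                + 1
                + th2 * h0 * (h0 - 1) / th1**2
            )
            q_crit = th1 * term ** (1 / h0) if term > 0 else 0.0
    else:
        raise ValueError(f"unknown q_limit_method {q_limit_method!r}")
    return float(t2_crit), float(q_crit)


def influence_table(
    model: PcaModel,
    X: np.ndarray,
    sample_ids: Sequence[str] | None = None,
):
    """Numeric backing of the influence plot: per-row T2, Q, limits, outlier flag.

    A row is flagged as an outlier iff its T-squared exceeds the T-squared
    limit or its Q exceeds the Q limit.
    """
    import pandas as pd

    _, t2, q = project(model, X)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(t2))]
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "t2": t2,
            "q": q,
            "t2_limit": model.t2_limit,
            "q_limit": model.q_limit,
            "outlier": (t2 > model.t2_limit) | (q > model.q_limit),
        }
    )
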
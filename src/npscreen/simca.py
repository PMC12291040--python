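"""One-class SIMCA classification of spectral feature vectors.

SIMCA (soft independent modeling of class analogies) builds a separate PCA
model for each drug class on that class's training analytes, with
class-local autoscaling.  Classifying a sample means asking, for every
class independently, whether the sample is an outlier to that class model —
so a sample may be accepted by several classes (structural analogues), by
exactly one, or by none (a substance outside the modeled chemistry).

Acceptance rules
----------------
``combined_chi2`` (default)
    The score distance ``T2`` and orthogonal distance ``Q`` are rescaled by
    their training means and combined as ``c = Nh * T2/T2_0 + Nq * Q/Q_0``,
    which is treated as chi-squared with ``Nh + Nq`` degrees of freedom;
    ``Nh`` and ``Nq`` are method-of-moments estimates from the training
    distances (the data-driven SIMCA construction).  The reported distance
    is ``d = sqrt(c)`` with acceptance cutoff ``d <= sqrt(chi2_{1-alpha})``.
``box_rule``
    Accept iff ``T2 <= T2_crit`` and ``Q <= Q_crit`` separately; the
    reported distance is ``d = max(T2/T2_crit, Q/Q_crit)`` with cutoff 1.

Both rules use a single definition of acceptance everywhere: prediction,
validation counts and Coomans quadrants all compare the same ``d`` against
the same ``d_threshold``.

Component counts are chosen by cross-validated efficiency (the geometric
mean of sensitivity and specificity), with five contiguous venetian-blind
cancellation groups for classes of at least eight analytes and
leave-one-out for smaller ones; classes with fewer than four analytes are
not modeled at all.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import (
    PcaModel,
    QLimitMethod,
    ScalingParams,
    autoscale_fit,
    critical_limits,
    pca_fit,
    project,
)
from .features import FEATURE_COLUMNS, FeatureMatrix

__all__ = [
    "SimcaClassModel",
    "ClassDistance",
    "PredictionResult",
    "ValidationReport",
    "select_components",
    "fit_class",
    "fit_all_classes",
    "classify",
    "validate",
    "coomans_table",
    "save_models",
    "load_models",
    "MIN_CLASS_SIZE",
]

ThresholdRule = Literal["combined_chi2", "box_rule"]

#: Modeling floor: classes with fewer analytes than this are not modeled.
MIN_CLASS_SIZE = 4

_EPS = 1e-12


@dataclass
class SimcaClassModel:
    """Per-class SIMCA model: a class-local PCA plus an acceptance threshold.

    ``nh``/``nq`` and ``t2_0``/``q_0`` parameterise the combined chi-squared
    acceptance rule (degrees of freedom and training-mean scales of the two
    distances); for the box rule they are still stored but acceptance uses
    the individual critical limits instead.
    """

    class_label: str
    pca: PcaModel
    A: int
    alpha: float
    threshold_rule: ThresholdRule
    d_threshold: float
    nh: float
    nq: float
    t2_0: float
    q_0: float
    n_class: int

    def distances(self, X: np.ndarray) -> pd.DataFrame:
        """Per-row T2, Q, reduced distances, combined d and verdict."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, t2, q = project(self.pca, X)
        s_red = t2 / self.pca.t2_limit
        q_red = _safe_ratio(q, self.pca.q_limit)
        if self.threshold_rule == "combined_chi2":
            c = self.nh * _safe_ratio(t2, self.t2_0)
            if self.nq > 0:
                c = c + self.nq * _safe_ratio(q, self.q_0)
            d = np.sqrt(c)
        else:  # box_rule
            d = np.maximum(s_red, q_red)
        accepted = d <= self.d_threshold
        return pd.DataFrame(
            {
                "t2": t2,
                "q": q,
                "t2_reduced": s_red,
                "q_reduced": q_red,
                "d": d,
                "accepted": accepted,
            }
        )


def _safe_ratio(x: np.ndarray | float, denom: float) -> np.ndarray | float:
    """x / denom with a degenerate denominator (rank-exhausted Q) handled.

    When the denominator is ~0 the numerator is ~0 for in-model samples;
    any appreciably positive numerator maps to +inf (certain rejection).
    """
    if denom > _EPS:
        return x / denom
    x = np.asarray(x, dtype=float)
    out = np.where(x <= 1e-9, 0.0, np.inf)
    return out if out.ndim else float(out)


def _dd_parameters(model: PcaModel) -> tuple[float, float, float, float]:
    """Moment-estimated degrees of freedom / scales of the two distances."""
    t2_m, t2_v = model.t2_mean, model.t2_var
    q_m, q_v = model.q_mean, model.q_var
    if t2_v > _EPS and t2_m > _EPS:
        nh = 2 * t2_m**2 / t2_v
    else:
        nh = float(model.A)
    t2_0 = t2_m if t2_m > _EPS else 1.0
    if q_m <= _EPS:
        nq, q_0 = 0.0, 0.0  # rank-exhausted model: no orthogonal dimension left
    elif q_v > _EPS:
        nq, q_0 = 2 * q_m**2 / q_v, q_m
    else:
        nq, q_0 = 1.0, q_m
    return nh, nq, t2_0, q_0


def fit_class(
    X_class: np.ndarray | FeatureMatrix,
    class_label: str,
    A: int,
    alpha: float = 0.05,
    threshold_rule: ThresholdRule = "combined_chi2",
    missing_policy: str = "mean_impute",
    scaling: ScalingParams | None = None,
    q_limit_method: QLimitMethod = "moment_chi2",
    enforce_floor: bool = True,
) -> SimcaClassModel:
    """Fit one class model on that class's training rows.

    ``X_class`` holds only the target-class rows (raw, unscaled 8-variable
    values; NaN allowed for missing slots).  Autoscaling is class-local
    unless an external ``scaling`` (e.g. global) is supplied.  A class of
    exactly four analytes fits with a warning — the model is legal but
    fragile; fewer than four is an error.  ``enforce_floor=False`` lifts
    the four-analyte floor for internal cross-validation fold fits, where
    the floor applies to the class, not to each fold's training subset.
    """
    if isinstance(X_class, FeatureMatrix):
        X_class = X_class.values
    X = np.asarray(X_class, dtype=float)
    n = X.shape[0]
    if enforce_floor and n < MIN_CLASS_SIZE:
        raise ValueError(
            f"class {class_label!r} has {n} analytes; at least "
            f"{MIN_CLASS_SIZE} are required for a SIMCA model"
        )
    if enforce_floor and n == MIN_CLASS_SIZE:
        warnings.warn(
            f"class {class_label!r} has exactly {MIN_CLASS_SIZE} analytes; "
            "the model will be fragile",
            stacklevel=2,
        )
    if A >= n:
        raise ValueError(f"A ({A}) must be smaller than the class size ({n})")
    if scaling is None:
        scaling, Xs = autoscale_fit(X, missing_policy=missing_policy)
    else:
        from .chemometrics import apply_scaling

        Xs = apply_scaling(scaling, X)
    pca = pca_fit(Xs, A, scaling, alpha=alpha, q_limit_method=q_limit_method)
    nh, nq, t2_0, q_0 = _dd_parameters(pca)
    if threshold_rule == "combined_chi2":
        d_threshold = math.sqrt(stats.chi2.ppf(1 - alpha, nh + nq))
    elif threshold_rule == "box_rule":
        d_threshold = 1.0
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    return SimcaClassModel(
        class_label=class_label,
        pca=pca,
        A=A,
        alpha=alpha,
        threshold_rule=threshold_rule,
        d_threshold=float(d_threshold),
        nh=float(nh),
        nq=float(nq),
        t2_0=float(t2_0),
        q_0=float(q_0),
        n_class=n,
    )


# -- component selection by cross-validated efficiency -----------------------


def _cv_folds(n: int, ids: Sequence[str], scheme: str) -> list[list[int]]:
    """Deterministic fold assignment: venetian blinds over id-sorted rows."""
    order = sorted(range(n), key=lambda i: (str(ids[i]), i))
    if scheme == "auto":
        scheme = "five_groups" if n >= 8 else "loo"
    if scheme == "five_groups":
        k = 5
    elif scheme == "loo":
        k = n
    else:
        raise ValueError(f"unknown cv_scheme {scheme!r}")
    folds = [order[j::k] for j in range(k)]
    return [f for f in folds if f]


def select_components(
    X_class: np.ndarray,
    X_other: np.ndarray,
    class_label: str = "",
    A_max: int | None = None,
    cv_scheme: str = "auto",
    alpha: float = 0.05,
    threshold_rule: ThresholdRule = "combined_chi2",
    missing_policy: str = "mean_impute",
    class_ids: Sequence[str] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the component count maximising cross-validated efficiency.

    For each candidate ``A`` and each cancellation group, a model is fitted
    on the remaining class rows; held-out class rows give the pooled CV
    sensitivity and the non-target rows (projected on every fold model,
    averaged over folds) give the CV specificity.  Efficiency is the
    geometric mean of the two.  The smallest ``A`` attaining the maximum
    efficiency wins (parsimony tie-break).

    Returns the selected ``A`` and a table of per-A CV metrics.
    """
    X = np.asarray(X_class, dtype=float)
    n = X.shape[0]
    if n < MIN_CLASS_SIZE:
        raise ValueError(f"class {class_label!r} too small for CV ({n} rows)")
    ids = list(class_ids) if class_ids is not None else [str(i) for i in range(n)]
    folds = _cv_folds(n, ids, cv_scheme)
    min_fold_train = n - max(len(f) for f in folds)
    hard_cap = min(min_fold_train - 1, X.shape[1])
    if hard_cap < 1:
        raise ValueError(f"class {class_label!r}: CV folds leave too few rows to fit")
    if A_max is None:
        A_max = hard_cap
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    A_max = min(A_max, hard_cap)

    X_other = np.asarray(X_other, dtype=float)
    rows = []
    for A in range(1, A_max + 1):
        n_heldout_acc = 0
        n_heldout = 0
        fold_specs: list[float] = []
        feasible = True
        for fold in folds:
            train_idx = [i for i in range(n) if i not in set(fold)]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = fit_class(
                        X[train_idx],
                        class_label,
                        A,
                        alpha=alpha,
                        threshold_rule=threshold_rule,
                        missing_policy=missing_policy,
                        enforce_floor=False,
                    )
            except ValueError:
                feasible = False
                break
            held = m.distances(X[fold])
            n_heldout_acc += int(held["accepted"].sum())
            n_heldout += len(fold)
            if len(X_other):
                other = m.distances(X_other)
                fold_specs.append(float((~other["accepted"]).mean()))
        if not feasible:
            rows.append((A, np.nan, np.nan, -np.inf))
            continue
        sens = n_heldout_acc / n_heldout
        spec = float(np.mean(fold_specs)) if fold_specs else 1.0
        rows.append((A, sens, spec, math.sqrt(sens * spec)))
    table = pd.DataFrame(rows, columns=["A", "cv_sensitivity", "cv_specificity", "cv_efficiency"])
    best_eff = table["cv_efficiency"].max()
    if not np.isfinite(best_eff):
        raise ValueError(f"class {class_label!r}: no feasible component count")
    A_best = int(table.loc[table["cv_efficiency"] >= best_eff - 1e-12, "A"].iloc[0])
    return A_best, table


def fit_all_classes(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    threshold_rule: ThresholdRule = "combined_chi2",
    classes_min: int = MIN_CLASS_SIZE,
    cv_scheme: str = "auto",
    missing_policy: str = "mean_impute",
    pc_counts: dict[str, int] | None = None,
    A_max: int | None = None,
) -> dict[str, SimcaClassModel]:
    """Fit a SIMCA model for every class with at least ``classes_min`` analytes.

    Component counts come from ``pc_counts`` when supplied (e.g. to rerun a
    published configuration), otherwise from cross-validated efficiency.
    Samples of unmodeled (too small) classes still act as non-target rows
    during component selection.
    """
    counts = matrix.class_counts()
    modeled = sorted(
        label for label, c in counts.items() if label and c >= classes_min
    )
    if not modeled:
        raise ValueError("no class reaches the modeling floor")
    models: dict[str, SimcaClassModel] = {}
    for label in modeled:
        idx = matrix.rows_of_class(label)
        other_idx = [i for i in range(matrix.n_samples) if i not in set(idx)]
        X_class = matrix.values[idx]
        if pc_counts is not None and label in pc_counts:
            A = pc_counts[label]
        else:
            A, _ = select_components(
                X_class,
                matrix.values[other_idx],
                class_label=label,
                A_max=A_max,
                cv_scheme=cv_scheme,
                alpha=alpha,
                threshold_rule=threshold_rule,
                missing_policy=missing_policy,
                class_ids=[matrix.analyte_ids[i] for i in idx],
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models[label] = fit_class(
                X_class,
                label,
                A,
                alpha=alpha,
                threshold_rule=threshold_rule,
                missing_policy=missing_policy,
            )
    return models


# -- prediction, validation, Coomans -----------------------------------------


@dataclass
class ClassDistance:
    """One (sample, class) verdict with its distance decomposition."""

    sample_id: str
    class_label: str
    t2: float
    q: float
    t2_reduced: float
    q_reduced: float
    d: float
    accepted: bool


@dataclass
class PredictionResult:
    """Soft-classification outcome: per-sample, per-class distances and verdicts."""

    sample_ids: list[str]
    class_labels: list[str]
    distances: list[list[ClassDistance]]  # [sample][class], class order as class_labels
    accepted_classes: list[list[str]]

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, list] = {"sample_id": self.sample_ids}
        for j, label in enumerate(self.class_labels):
            data[f"d_{label}"] = [row[j].d for row in self.distances]
            data[f"accepted_{label}"] = [row[j].accepted for row in self.distances]
        data["accepted_classes"] = [";".join(a) for a in self.accepted_classes]
        return pd.DataFrame(data)


def classify(
    models: Sequence[SimcaClassModel] | dict[str, SimcaClassModel],
    X: np.ndarray | FeatureMatrix,
    sample_ids: Sequence[str] | None = None,
) -> PredictionResult:
    """Screen samples against every class model independently.

    Each class model issues its own accept/reject verdict; the accepted-class
    set of a sample may therefore contain zero, one or several classes.
    """
    if isinstance(models, dict):
        models = [models[k] for k in sorted(models)]
    models = list(models)
    if not models:
        raise ValueError("no class models supplied")
    if isinstance(X, FeatureMatrix):
        if sample_ids is None:
            sample_ids = X.analyte_ids
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    per_model = [m.distances(X) for m in models]
    distances: list[list[ClassDistance]] = []
    accepted_sets: list[list[str]] = []
    for i in range(n):
        row: list[ClassDistance] = []
        acc: list[str] = []
        for m, table in zip(models, per_model):
            rec = table.iloc[i]
            row.append(
                ClassDistance(
                    sample_id=str(sample_ids[i]),
                    class_label=m.class_label,
                    t2=float(rec["t2"]),
                    q=float(rec["q"]),
                    t2_reduced=float(rec["t2_reduced"]),
                    q_reduced=float(rec["q_reduced"]),
                    d=float(rec["d"]),
                    accepted=bool(rec["accepted"]),
                )
            )
            if rec["accepted"]:
                acc.append(m.class_label)
        distances.append(row)
        accepted_sets.append(acc)
    return PredictionResult(
        sample_ids=[str(s) for s in sample_ids],
        class_labels=[m.class_label for m in models],
        distances=distances,
        accepted_classes=accepted_sets,
    )


@dataclass
class ValidationReport:
    """Per-class confusion counts and figures of merit on a labeled set.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); efficiency is their
    geometric mean.  A class absent from the evaluation set gets NaN
    sensitivity (no target samples to accept).
    """

    set_label: str
    rows: pd.DataFrame  # columns: class, set, TP, FN, TN, FP, sensitivity, specificity, efficiency

    def metric(self, class_label: str, name: str) -> float:
        sel = self.rows.loc[self.rows["class"] == class_label, name]
        if sel.empty:
            raise KeyError(class_label)
        return float(sel.iloc[0])


def validate(
    models: Sequence[SimcaClassModel] | dict[str, SimcaClassModel],
    X: np.ndarray | FeatureMatrix,
    labels: Sequence[str] | None = None,
    set_label: str = "test",
) -> ValidationReport:
    """Score every class model on a labeled sample set.

    For class c: TP = true-c samples accepted by c's model, FN = true-c
    rejected, TN = non-c rejected, FP = non-c accepted.  True labels not
    matching any model only contribute as non-target samples.
    """
    if isinstance(X, FeatureMatrix):
        if labels is None:
            labels = X.class_labels
        sample_ids = X.analyte_ids
        X = X.values
    else:
        sample_ids = None
    if labels is None:
        raise ValueError("labels are required for validation")
    labels = [str(l) for l in labels]
    result = classify(models, X, sample_ids)
    records = []
    for j, label in enumerate(result.class_labels):
        verdicts = np.array([row[j].accepted for row in result.distances])
        is_target = np.array([l == label for l in labels])
        tp = int(np.sum(verdicts & is_target))
        fn = int(np.sum(~verdicts & is_target))
        fp = int(np.sum(verdicts & ~is_target))
        tn = int(np.sum(~verdicts & ~is_target))
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        eff = (
            math.sqrt(sens * spec)
            if np.isfinite(sens) and np.isfinite(spec)
            else np.nan
        )
        records.append(
            {
                "class": label,
                "set": set_label,
                "TP": tp,
                "FN": fn,
                "TN": tn,
                "FP": fp,
                "sensitivity": sens,
                "specificity": spec,
                "efficiency": eff,
            }
        )
    return ValidationReport(set_label=set_label, rows=pd.DataFrame(records))


def coomans_table(
    model_a: SimcaClassModel,
    model_b: SimcaClassModel,
    X: np.ndarray | FeatureMatrix,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Numeric backing of a Coomans plot comparing two class models.

    Each sample's distances to both models are compared with the two
    acceptance thresholds, placing it in one of four quadrants:
    ``accepted_by_both``, ``only_a``, ``only_b`` or ``neither``.
    """
    if isinstance(X, FeatureMatrix):
        if sample_ids is None:
            sample_ids = X.analyte_ids
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X.shape[0])]
    da = model_a.distances(X)
    db = model_b.distances(X)
    quadrant = []
    for acc_a, acc_b in zip(da["accepted"], db["accepted"]):
        if acc_a and acc_b:
            quadrant.append("accepted_by_both")
        elif acc_a:
            quadrant.append("only_a")
        elif acc_b:
            quadrant.append("only_b")
        else:
            quadrant.append("neither")
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "class_a": model_a.class_label,
            "class_b": model_b.class_label,
            "d_a": da["d"].to_numpy(),
            "d_b": db["d"].to_numpy(),
            "threshold_a": model_a.d_threshold,
            "threshold_b": model_b.d_threshold,
            "quadrant": quadrant,
        }
    )


# -- serialization -----------------------------------------------------------


def _model_to_dict(m: SimcaClassModel) -> dict:
    p = m.pca
    return {
        "class_label": m.class_label,
        "A": m.A,
        "alpha": m.alpha,
        "threshold_rule": m.threshold_rule,
        "d_threshold": m.d_threshold,
        "nh": m.nh,
        "nq": m.nq,
        "t2_0": m.t2_0,
        "q_0": m.q_0,
        "n_class": m.n_class,
        "pca": {
            "column_means": p.scaling.column_means.tolist(),
            "column_sds": p.scaling.column_sds.tolist(),
            "column_names": list(p.scaling.column_names),
            "loadings": p.loadings.tolist(),
            "eigenvalues": p.eigenvalues.tolist(),
            "all_eigenvalues": p.all_eigenvalues.tolist(),
            "A": p.A,
            "n_train": p.n_train,
            "alpha": p.alpha,
            "t2_limit": p.t2_limit,
            "q_limit": p.q_limit,
            "t2_mean": p.t2_mean,
            "t2_var": p.t2_var,
            "q_mean": p.q_mean,
            "q_var": p.q_var,
            "q_limit_method": p.q_limit_method,
        },
    }


def _model_from_dict(d: dict) -> SimcaClassModel:
    pd_ = d["pca"]
    scaling = ScalingParams(
        column_means=np.array(pd_["column_means"], dtype=float),
        column_sds=np.array(pd_["column_sds"], dtype=float),
        column_names=tuple(pd_["column_names"]),
    )
    pca = PcaModel(
        scaling=scaling,
        loadings=np.array(pd_["loadings"], dtype=float),
        eigenvalues=np.array(pd_["eigenvalues"], dtype=float),
        all_eigenvalues=np.array(pd_["all_eigenvalues"], dtype=float),
        A=int(pd_["A"]),
        n_train=int(pd_["n_train"]),
        alpha=float(pd_["alpha"]),
        t2_limit=float(pd_["t2_limit"]),
        q_limit=float(pd_["q_limit"]),
        t2_mean=float(pd_["t2_mean"]),
        t2_var=float(pd_["t2_var"]),
        q_mean=float(pd_["q_mean"]),
        q_var=float(pd_["q_var"]),
        q_limit_method=pd_["q_limit_method"],
    )
    return SimcaClassModel(
        class_label=d["class_label"],
        pca=pca,
        A=int(d["A"]),
        alpha=float(d["alpha"]),
        threshold_rule=d["threshold_rule"],
        d_threshold=float(d["d_threshold"]),
        nh=float(d["nh"]),
        nq=float(d["nq"]),
        t2_0=float(d["t2_0"]),
        q_0=float(d["q_0"]),
        n_class=int(d["n_class"]),
    )


def save_models(models: dict[str, SimcaClassModel], path: str | Path) -> None:
    """Serialize models to JSON with full numeric state (bit-reproducible)."""
    payload = {label: _model_to_dict(m) for label, m in sorted(models.items())}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict[str, SimcaClassModel]:
    """Inverse of :func:`save_models`."""
    payload = json.loads(Path(path).read_text())
    return {label: _model_from_dict(d) for label, d in payload.items()}
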
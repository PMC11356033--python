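"""Retention-time consistency QC via linear SVR with leave-one-out CV.

The idea: within one LC-MS run, elution order is governed by a handful
of latent physicochemical variables — acyl chain length (tracked by H
count), saturation (the C-H relationship) and headgroup hydrophobicity
(tracked by lipid class). A linear epsilon-insensitive support vector
regression of retention time on element counts plus one-hot lipid class
learns these latent variables from the annotation table itself, with no
external library. Each annotation is then predicted by a model trained
on all other annotations (leave-one-out cross-validation); an
identification whose observed retention time sits further than a fixed
fraction of the run time (default 5%) from its held-out prediction is
flagged as potentially misannotated.

The fraction of unflagged annotations is the table's *internal
consistency* — a platform-independent summary of how coherent a
software's putative identifications are with their own elution order.

The SVR is fitted with libsvm's exact solver (sklearn ``SVR``,
linear kernel, C = 10 by default); the fit is deterministic, so no
random seed is involved anywhere in the QC path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .annotations import MS1, MS2, AnnotationTable
from .formula import composition_vector, element_universe

__all__ = [
    "RTModelConfig",
    "FeatureMatrix",
    "QCReport",
    "SeriesViolation",
    "build_design_matrix",
    "loocv_predict",
    "flag_outliers",
    "internal_consistency",
    "check_saturation_series",
    "run_qc",
]


@dataclass(frozen=True)
class RTModelConfig:
    """Retention-time model settings.

    C
        SVR regularization strength (default 10).
    epsilon
        Half-width of the epsilon-insensitive tube, in minutes of
        retention time (the target is left in raw minutes).
    scaling
        "global": auto-scale numeric features once over the full table
        before cross-validation; "per_fold": refit the scaler inside
        each training fold (leakage-free, slightly different numbers).
    threshold_frac
        Outlier cut as a fraction of run time; 0.05 x 15 min = 0.75 min.
    """

    kernel: str = "linear"
    C: float = 10.0
    epsilon: float = 0.1
    scaling: str = "global"
    threshold_frac: float = 0.05
    runtime_min: float = 15.0
    min_rt: float = 1.0
    tol: float = 1e-4  # libsvm stopping tolerance

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.runtime_min <= 0:
            raise ValueError("runtime_min must be positive")
        if self.scaling not in ("global", "per_fold"):
            raise ValueError("scaling must be 'global' or 'per_fold'")

    @property
    def threshold_min(self) -> float:
        """Outlier threshold in minutes."""
        return self.threshold_frac * self.runtime_min


@dataclass
class FeatureMatrix:
    """Design matrix for the retention-time model.

    ``X_raw`` holds element counts (Hill-ordered columns) followed by
    one-hot lipid class columns (alphabetical); ``X`` is the same with
    the numeric block auto-scaled (global mode) and the one-hot block
    untouched. One-hot rows sum to exactly 1.
    """

    X: np.ndarray
    X_raw: np.ndarray
    y: np.ndarray
    ids: list[str]
    feature_names: list[str]
    n_numeric: int
    numeric_mean: np.ndarray
    numeric_scale: np.ndarray
    ms_levels: list[str] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)


def build_design_matrix(table: AnnotationTable, config: RTModelConfig) -> FeatureMatrix:
    """Element counts + one-hot class -> (auto-scaled) design matrix.

    Columns are deterministic: elements of the table's universe in Hill
    order, then one one-hot column per distinct class, alphabetical.
    Raises on tables of fewer than two rows (leave-one-out undefined);
    warns and proceeds on a constant target.
    """
    rows = table.annotations
    if len(rows) < 2:
        raise ValueError("retention model needs at least 2 annotations")
    universe = element_universe([a.composition for a in rows])
    classes = sorted({a.lipid_class for a in rows})
    n_num = len(universe)

    X_num = np.array(
        [composition_vector(a.composition, universe) for a in rows], dtype=float
    )
    X_cat = np.zeros((len(rows), len(classes)))
    class_index = {c: j for j, c in enumerate(classes)}
    for i, a in enumerate(rows):
        X_cat[i, class_index[a.lipid_class]] = 1.0
    y = np.array([a.rt_min for a in rows], dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant retention-time target; model degenerates to a mean")

    mean = X_num.mean(axis=0)
    scale = X_num.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through centred
    X = np.hstack([(X_num - mean) / scale, X_cat])
    if config.scaling == "per_fold":
        # keep raw numerics; folds scale themselves in loocv_predict
        X = np.hstack([X_num, X_cat])
    return FeatureMatrix(
        X=X,
        X_raw=np.hstack([X_num, X_cat]),
        y=y,
        ids=[a.id for a in rows],
        feature_names=list(universe) + [f"class:{c}" for c in classes],
        n_numeric=n_num,
        numeric_mean=mean,
        numeric_scale=scale,
        ms_levels=[a.ms_level for a in rows],
        classes=[a.lipid_class for a in rows],
    )


def _svr(config: RTModelConfig) -> SVR:
    return SVR(kernel="linear", C=config.C, epsilon=config.epsilon, tol=config.tol)


def _loocv_fold(matrix: FeatureMatrix, config: RTModelConfig, i: int) -> float:
    """Refit the SVR without row i and predict row i."""
    mask = np.ones(len(matrix.y), dtype=bool)
    mask[i] = False
    X_tr, y_tr = matrix.X[mask], matrix.y[mask]
    X_te = matrix.X[i : i + 1]
    if config.scaling == "per_fold":
        num = slice(0, matrix.n_numeric)
        mu = X_tr[:, num].mean(axis=0)
        sd = X_tr[:, num].std(axis=0)
        sd[sd == 0] = 1.0
        X_tr = X_tr.copy()
        X_te = X_te.copy()
        X_tr[:, num] = (X_tr[:, num] - mu) / sd
        X_te[:, num] = (X_te[:, num] - mu) / sd
    try:
        model = _svr(config).fit(X_tr, y_tr)
    except Exception as exc:  # pragma: no cover - libsvm rarely fails
        raise RuntimeError(f"SVR failed on leave-one-out fold {i}: {exc}") from exc
    return float(model.predict(X_te)[0])


def loocv_predict(matrix: FeatureMatrix, config: RTModelConfig) -> np.ndarray:
    """Held-out prediction for every annotation.

    For each row i the SVR is refitted on all rows but i and predicts
    row i. Deterministic; invariant (as a per-row mapping) under input
    permutation because each fold sees the same training set regardless
    of row order.

    In global scaling mode only support-vector folds are actually
    refitted: a point strictly inside the epsilon tube has zero dual
    coefficient, so deleting it leaves the KKT conditions — hence the
    fitted function — unchanged, and its held-out prediction equals the
    full-model prediction. This is an exact identity of the dual
    optimum, not an approximation; the per-fold refit loop is the
    reference it must (and is tested to) agree with. Per-fold scaling
    changes the design matrix itself in every fold, so that mode always
    takes the loop.
    """
    n = len(matrix.y)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 rows")
    preds = np.empty(n)
    if config.scaling == "per_fold":
        for i in range(n):
            preds[i] = _loocv_fold(matrix, config, i)
        return preds
    full = _svr(config).fit(matrix.X, matrix.y)
    preds[:] = full.predict(matrix.X)
    for i in full.support_:
        preds[i] = _loocv_fold(matrix, config, int(i))
    return preds


def flag_outliers(
    actual: np.ndarray, predicted: np.ndarray, config: RTModelConfig
) -> np.ndarray:
    """Flag annotations further than threshold_frac x runtime from their
    prediction. The inequality is strict: a residual of exactly 5% of
    the run time is not an outlier."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    return np.abs(actual - predicted) > config.threshold_min


def internal_consistency(flags) -> float:
    """1 − flagged / evaluated: the fraction of annotations whose
    retention time agrees with the model of the rest of the table."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("internal_consistency of an empty flag list")
    return 1.0 - flags.mean()


# ---------------------------------------------------------------------------
# Saturation-series diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesViolation:
    """Adjacent pair in a saturation series whose elution order inverts.

    Within a class, lipids sharing every non-hydrogen element count form
    a double-bond series; on reversed phase, retention normally rises
    with H count (more saturated elutes later). A drop is suspicious.
    """

    lipid_class: str
    formula_low: str
    formula_high: str
    h_low: int
    h_high: int
    rt_low: float
    rt_high: float


def check_saturation_series(table: AnnotationTable) -> list[SeriesViolation]:
    """Report every adjacent H-count pair whose retention time decreases.

    Annotations are grouped by (class, all element counts except H) and
    sorted by H count; each adjacent pair with strictly decreasing
    retention time is a violation. Output order is deterministic.
    """
    groups: dict[tuple, list] = {}
    for a in table.annotations:
        key = (
            a.lipid_class,
            tuple(sorted((el, n) for el, n in a.composition.items() if el != "H")),
        )
        groups.setdefault(key, []).append(a)
    violations: list[SeriesViolation] = []
    for (klass, _), members in sorted(groups.items()):
        members = sorted(members, key=lambda a: (a.composition.get("H", 0), a.rt_min, a.id))
        for lo, hi in zip(members, members[1:]):
            if hi.rt_min < lo.rt_min:
                violations.append(
                    SeriesViolation(
                        lipid_class=klass,
                        formula_low=lo.formula,
                        formula_high=hi.formula,
                        h_low=lo.composition.get("H", 0),
                        h_high=hi.composition.get("H", 0),
                        rt_low=lo.rt_min,
                        rt_high=hi.rt_min,
                    )
                )
    return violations


# ---------------------------------------------------------------------------
# Full QC pipeline
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-annotation predictions and table-level consistency summaries."""

    per_annotation: pd.DataFrame
    consistency_overall: float
    consistency_ms1: float | None
    consistency_ms2: float | None
    per_class_residuals: dict[str, dict[str, float]]
    series_violations: list[SeriesViolation]
    config: RTModelConfig

    def summary(self) -> dict:
        return {
            "schema": 1,
            "n_annotations": int(len(self.per_annotation)),
            "n_flagged": int(self.per_annotation["outlier_flag"].sum()),
            "consistency_overall": self.consistency_overall,
            "consistency_ms1": self.consistency_ms1,
            "consistency_ms2": self.consistency_ms2,
            "n_series_violations": len(self.series_violations),
            "config": asdict(self.config),
        }


def run_qc(table: AnnotationTable, config: RTModelConfig | None = None) -> QCReport:
    """Void-volume filter -> design matrix -> LOOCV -> flags -> summaries."""
    from .annotations import filter_void_volume

    config = config or RTModelConfig(runtime_min=table.runtime_min)
    table = filter_void_volume(table, config.min_rt)
    matrix = build_design_matrix(table, config)
    predicted = loocv_predict(matrix, config)
    actual = matrix.y
    flags = flag_outliers(actual, predicted, config)

    df = table.to_frame()
    df["predicted_rt_min"] = predicted
    df["residual_min"] = actual - predicted
    df["outlier_flag"] = flags

    levels = np.array(matrix.ms_levels)
    cons_ms1 = internal_consistency(flags[levels == MS1]) if (levels == MS1).any() else None
    cons_ms2 = internal_consistency(flags[levels == MS2]) if (levels == MS2).any() else None

    per_class: dict[str, dict[str, float]] = {}
    for klass in sorted(set(matrix.classes)):
        sel = np.array(matrix.classes) == klass
        res = df["residual_min"].to_numpy()[sel]
        per_class[klass] = {
            "n": int(sel.sum()),
            "mean_residual_min": float(res.mean()),
            "median_abs_residual_min": float(np.median(np.abs(res))),
            "flagged": int(flags[sel].sum()),
        }

    return QCReport(
        per_annotation=df,
        consistency_overall=internal_consistency(flags),
        consistency_ms1=cons_ms1,
        consistency_ms2=cons_ms2,
        per_class_residuals=per_class,
        series_violations=check_saturation_series(table),
        config=config,
    )
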
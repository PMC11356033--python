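"""Per-feature attribution of retention-time predictions.

For a linear model f(x) = w·x + b, the Shapley value of feature j for
annotation i under an independent-feature background has the exact
closed form

    phi_ij = w_j (x_ij − mean_i x_ij),

with base value f(mean x): no sampling, so attributions satisfy local
accuracy (base + sum phi == prediction) and zero background mean
exactly. The model explained is a single SVR fitted on the full table —
one attribution per annotation, matching how beeswarm summaries are
read — with the full table as the background distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rt_qc import FeatureMatrix, RTModelConfig, _svr

__all__ = ["LinearModel", "Attribution", "fit_full_model", "linear_shap", "rank_features"]


@dataclass
class LinearModel:
    """Linear SVR weights in the (scaled) design-matrix space.

    ``weights_raw`` are the same weights expressed per raw feature unit
    (element count, class indicator) for interpretation in minutes per
    atom; predictions use the design-space weights.
    """

    weights: np.ndarray
    intercept: float
    feature_names: list[str]
    weights_raw: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


def fit_full_model(matrix: FeatureMatrix, config: RTModelConfig) -> LinearModel:
    """Fit one linear SVR on every annotation and extract its weights."""
    if len(matrix.y) < 2:
        raise ValueError("need at least 2 annotations to fit")
    model = _svr(config).fit(matrix.X, matrix.y)
    w = np.asarray(model.coef_).ravel()
    # design space is scaled numerics + unscaled one-hot: undo per-column
    scale = np.concatenate(
        [matrix.numeric_scale, np.ones(len(w) - matrix.n_numeric)]
    )
    return LinearModel(
        weights=w,
        intercept=float(np.asarray(model.intercept_).ravel()[0]),
        feature_names=list(matrix.feature_names),
        weights_raw=w / scale,
    )


@dataclass
class Attribution:
    """SHAP values (minutes) per annotation x feature."""

    values: np.ndarray  # n x p
    base_value: float  # prediction at the background mean
    feature_names: list[str]
    feature_values: np.ndarray  # raw feature values, for beeswarm colouring
    ids: list[str]

    def mean_abs(self) -> dict[str, float]:
        m = np.abs(self.values).mean(axis=0)
        return {name: float(v) for name, v in zip(self.feature_names, m)}


def linear_shap(model: LinearModel, matrix: FeatureMatrix) -> Attribution:
    """Closed-form linear SHAP against the full-table background."""
    if len(model.weights) != matrix.X.shape[1]:
        raise ValueError(
            f"weight/feature mismatch: {len(model.weights)} weights, "
            f"{matrix.X.shape[1]} columns"
        )
    background_mean = matrix.X.mean(axis=0)
    values = (matrix.X - background_mean) * model.weights
    base = float(background_mean @ model.weights + model.intercept)
    return Attribution(
        values=values,
        base_value=base,
        feature_names=list(model.feature_names),
        feature_values=matrix.X_raw.copy(),
        ids=list(matrix.ids),
    )


def rank_features(attribution: Attribution) -> list[str]:
    """Features by descending mean |SHAP|, ties broken alphabetically."""
    if attribution.values.size == 0:
        raise ValueError("empty attribution")
    mean_abs = attribution.mean_abs()
    return sorted(mean_abs, key=lambda name: (-mean_abs[name], name))
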
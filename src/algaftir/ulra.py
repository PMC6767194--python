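"""Univariate linear regression of composition on band intensity (ULRA).

One integrated band area predicts one compound's % DW by ordinary least
squares, composition regressed on intensity.  Carbohydrates, whose band
region is crowded and distorted by normalisation, get an indirect
estimator: the carbohydrate/protein *ratio* of band areas is regressed
on the composition ratio, and the carbohydrate content recovered as
predicted ratio x predicted protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from algaftir.evaluation import PredictionPairs

__all__ = ["UlraModel", "fit_ulra", "predict_ulra", "fit_ratio_model", "loo_cv_ratio_chain"]


@dataclass
class UlraModel:
    """Fitted line y = intercept + slope * x for one response."""

    intercept: float
    slope: float
    response: str
    band: str
    n_train: int

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("non-finite regression coefficients")

    def __call__(self, x):
        return predict_ulra(self, x)


def fit_ulra(x, y, response: str = "", band: str = "") -> UlraModel:
    """Ordinary least squares of composition (y, % DW) on band area (x)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("fit_ulra requires n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in band intensities")
    slope, intercept = np.polyfit(x, y, 1)
    return UlraModel(float(intercept), float(slope), response, band, x.size)


def predict_ulra(m: UlraModel, x) -> np.ndarray:
    """Apply the fitted line; negative predictions are reported as-is."""
    x = np.asarray(x, dtype=float)
    return m.intercept + m.slope * x


def fit_ratio_model(band_ratio, comp_ratio) -> UlraModel:
    """OLS of the composition ratio (carb/protein) on the band-area ratio."""
    return fit_ulra(band_ratio, comp_ratio, response="carb_protein_ratio", band="carb_band/protein_band")


def loo_cv_ratio_chain(x_protein, y_protein, x_ratio, y_ratio) -> PredictionPairs:
    """Honest LOO cross-validation of the chained carbohydrate estimate.

    For each held-out sample both the protein model and the ratio model
    are refit without it; the carbohydrate prediction is
    ``ratio_hat * protein_hat``.  True values are reconstructed as
    ``y_ratio * y_protein`` (= carbohydrate % DW).
    """
    x_protein = np.asarray(x_protein, dtype=float).ravel()
    y_protein = np.asarray(y_protein, dtype=float).ravel()
    x_ratio = np.asarray(x_ratio, dtype=float).ravel()
    y_ratio = np.asarray(y_ratio, dtype=float).ravel()
    n = x_protein.size
    if not (y_protein.size == x_ratio.size == y_ratio.size == n):
        raise ValueError("all four columns must have equal length")

    y_carb = y_ratio * y_protein
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        prot = fit_ulra(x_protein[mask], y_protein[mask])
        ratio = fit_ulra(x_ratio[mask], y_ratio[mask])
        preds[i] = predict_ulra(ratio, x_ratio[i]) * predict_ulra(prot, x_protein[i])
    return PredictionPairs(list(range(n)), y_carb, preds, context="cross_validation")
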
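"""Model-quality statistics and validation drivers shared by all methods.

Conventions
-----------
* RMSEC and RMSEP divide the summed squared residuals by ``n``.
* RMSECV divides by ``n - 1`` (the cross-validation convention used in
  the source workflow; ``denominator="n"`` switches to the plain mean).
* RPD = sample standard deviation (ddof=1) of the response / RMSECV.
* Q^2 is the predictive R^2: computed from cross-validation predictions
  against the mean of the *full* calibration response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

__all__ = [
    "PredictionPairs",
    "EvalReport",
    "OutlierPolicy",
    "rmse_c_or_p",
    "rmsecv",
    "r_squared",
    "q_squared",
    "rpd",
    "loo_cv",
    "kfold_cv",
    "apply_outlier_policy",
    "evaluate_regression",
]


@dataclass
class PredictionPairs:
    """Matched true/predicted response values (% DW) for one response."""

    sample_ids: list
    y_true: np.ndarray
    y_pred: np.ndarray
    context: str = "calibration"  # calibration | cross_validation | external

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.y_true.shape != self.y_pred.shape or self.y_true.ndim != 1:
            raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
        if not (np.all(np.isfinite(self.y_true)) and np.all(np.isfinite(self.y_pred))):
            raise ValueError("non-finite values in prediction pairs")

    @property
    def n(self) -> int:
        return self.y_true.size

    @property
    def residuals(self) -> np.ndarray:
        return self.y_pred - self.y_true


@dataclass
class EvalReport:
    """Per-response summary mirroring a calibration-table row."""

    method: str
    response: str
    n: int
    r2: float = np.nan
    rmsec: float = np.nan
    q2: float = np.nan
    rmsecv: float = np.nan
    rpd: float = np.nan
    rmsep: float = np.nan
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "response": self.response,
            "N": self.n,
            "R2": self.r2,
            "RMSEC": self.rmsec,
            "Q2": self.q2,
            "RMSECV": self.rmsecv,
            "RPD": self.rpd,
            "RMSEP": self.rmsep,
        }
        row.update(self.extra)
        return row


@dataclass
class OutlierPolicy:
    """How samples judged incompatible with a calibration are removed.

    ``explicit_list`` drops the named ids (mirrors judgment-based
    exclusion of samples with failed reference chemistry);
    ``studentized_residual`` iteratively removes the worst sample whose
    externally studentized residual from a univariate fit exceeds
    ``threshold``.
    """

    mode: str = "explicit_list"
    ids: list = field(default_factory=list)
    threshold: float = 3.0

    def __post_init__(self):
        if self.mode not in ("explicit_list", "studentized_residual"):
            raise ValueError(f"unknown outlier mode {self.mode!r}")
        if self.mode == "studentized_residual" and self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def rmse_c_or_p(p: PredictionPairs) -> float:
    """Root mean square error with the /n denominator (RMSEC, RMSEP)."""
    if p.n < 1:
        raise ValueError("empty prediction pairs")
    return float(np.sqrt(np.sum(p.residuals**2) / p.n))


def rmsecv(p: PredictionPairs, denominator: str = "n-1") -> float:
    """Cross-validation RMSE; /(n-1) by default, ``denominator="n"`` optional."""
    if p.n < 2:
        raise ValueError("rmsecv requires n >= 2")
    den = p.n - 1 if denominator == "n-1" else p.n
    return float(np.sqrt(np.sum(p.residuals**2) / den))


def r_squared(p: PredictionPairs) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    ss_tot = float(np.sum((p.y_true - p.y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_true; R2 undefined")
    return float(1.0 - np.sum(p.residuals**2) / ss_tot)


def q_squared(p: PredictionPairs, y_mean: float | None = None) -> float:
    """Predictive R2 from cross-validation predictions.

    ``y_mean`` defaults to the mean of the supplied y_true (the full
    calibration set when the pairs cover every sample once).
    """
    mean = p.y_true.mean() if y_mean is None else y_mean
    ss_tot = float(np.sum((p.y_true - mean) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance around y_mean; Q2 undefined")
    return float(1.0 - np.sum(p.residuals**2) / ss_tot)


def rpd(y_true: np.ndarray, rmsecv_value: float) -> float:
    """Residual predictive deviation: SD(y) / RMSECV (ddof=1)."""
    y_true = np.asarray(y_true, dtype=float)
    if y_true.size < 2:
        raise ValueError("rpd requires n >= 2")
    sd = float(np.std(y_true, ddof=1))
    if sd == 0:
        raise ValueError("constant response; SD (and RPD) undefined")
    if rmsecv_value <= 0:
        raise ValueError("rmsecv must be > 0")
    return sd / rmsecv_value


def loo_cv(fit, X, y, sample_ids=None) -> PredictionPairs:
    """Leave-one-out cross validation.

    ``fit(X_train, y_train)`` must return a ``predict(X)`` callable and
    re-run every data-dependent step it owns.  Each sample is predicted
    by the model trained on all others; pairs are returned in input
    order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("loo_cv requires n >= 3")
    if sample_ids is None:
        sample_ids = list(range(n))
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = fit(X[mask], y[mask])
            preds[i] = np.asarray(model(X[i : i + 1])).ravel()[0]
        except Exception as exc:
            raise RuntimeError(f"LOO fold {i} (held out {sample_ids[i]!r}) failed: {exc}") from exc
    return PredictionPairs(list(sample_ids), y, preds, context="cross_validation")


def kfold_cv(fit, X, y, k: int = 5, seed: int = 0, sample_ids=None) -> PredictionPairs:
    """k-fold cross validation with seeded-shuffle contiguous folds.

    Fold assignment is deterministic given ``seed``; each sample is
    predicted exactly once and fold sizes differ by at most one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n={n}]")
    if sample_ids is None:
        sample_ids = list(range(n))
    preds = np.empty(n)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(splitter.split(X)):
        try:
            model = fit(X[tr], y[tr])
            preds[te] = np.asarray(model(X[te])).ravel()
        except Exception as exc:
            raise RuntimeError(f"CV fold {fold} failed: {exc}") from exc
    return PredictionPairs(list(sample_ids), y, preds, context="cross_validation")


def _studentized_worst(x: np.ndarray, y: np.ndarray):
    """Index and |t| of the largest externally studentized residual."""
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    t = ols.get_influence().resid_studentized_external
    i = int(np.argmax(np.abs(t)))
    return i, float(abs(t[i]))


def apply_outlier_policy(x, y, policy: OutlierPolicy, sample_ids=None):
    """Remove outlying samples from a univariate calibration set.

    Returns ``(x_kept, y_kept, kept_ids, excluded_ids)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if sample_ids is None:
        sample_ids = list(range(n))
    sample_ids = list(sample_ids)

    if policy.mode == "explicit_list":
        drop = set(policy.ids)
        unknown = drop - set(sample_ids)
        if unknown:
            raise KeyError(f"outlier ids not in dataset: {sorted(unknown)}")
        keep = np.array([sid not in drop for sid in sample_ids])
    else:
        keep = np.ones(n, dtype=bool)
        while True:
            idx = np.flatnonzero(keep)
            i_local, t = _studentized_worst(x[idx], y[idx])
            if t <= policy.threshold:
                break
            if keep.sum() - 1 < 3:
                raise ValueError("outlier removal would leave fewer than 3 samples")
            keep[idx[i_local]] = False

    if keep.sum() < 3:
        raise ValueError("outlier removal would leave fewer than 3 samples")
    kept_ids = [sid for sid, k in zip(sample_ids, keep) if k]
    excluded = [sid for sid, k in zip(sample_ids, keep) if not k]
    return x[keep], y[keep], kept_ids, excluded


def evaluate_regression(
    method: str,
    response: str,
    cal: PredictionPairs,
    cv: PredictionPairs | None = None,
    ext: PredictionPairs | None = None,
    rmsecv_denominator: str = "n-1",
) -> EvalReport:
    """Assemble a full report row from calibration / CV / external pairs."""
    rep = EvalReport(method=method, response=response, n=cal.n)
    rep.r2 = r_squared(cal)
    rep.rmsec = rmse_c_or_p(cal)
    if cv is not None:
        rep.q2 = q_squared(cv, y_mean=float(cal.y_true.mean()))
        rep.rmsecv = rmsecv(cv, denominator=rmsecv_denominator)
        if rep.rmsecv > 0:
            rep.rpd = rpd(cal.y_true, rep.rmsecv)
    if ext is not None:
        rep.rmsep = rmse_c_or_p(ext)
    return rep


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack EvalReports into a comparison table."""
    return pd.DataFrame([r.to_row() for r in reports])
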
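"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Decomposes the preprocessed spectral matrix ``D`` (samples x
wavenumbers) into non-negative concentration profiles ``C`` and pure
component spectra ``S`` with ``D ~ C S``.  Initial estimates come from
measured reference spectra (albumin, lipid extract, cellulose) or from
an SVD-based guess; quality is tracked by the lack-of-fit against the
raw data and against its rank-k PCA reconstruction.

The bilinear factorisation is scale-indeterminate: rows of S are
renormalised to unit area every iteration with the compensating factor
absorbed into C, so resolved spectra are comparable across runs and
``C`` carries all intensity information (in arbitrary units -- hence
the separate calibration step against chemical reference values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.optimize import nnls

from algaftir.evaluation import PredictionPairs, evaluate_regression, loo_cv
from algaftir.ulra import fit_ulra, predict_ulra

__all__ = [
    "McrConfig",
    "McrResult",
    "mcr_als_fit",
    "lack_of_fit",
    "explained_variance",
    "calibrate_mcr_concentrations",
]


@dataclass(frozen=True)
class McrConfig:
    """ALS settings; the defaults match common toolbox behaviour.

    conv_limit is the relative change (in percent) of the lack of fit
    between consecutive iterations below which the run stops.
    """

    n_components: int = 3
    max_iter: int = 50
    conv_limit: float = 0.1
    nonneg_c: bool = True
    nonneg_s: bool = True

    def __post_init__(self):
        if self.n_components < 1 or self.max_iter < 1 or self.conv_limit <= 0:
            raise ValueError("invalid MCR configuration")


@dataclass
class McrResult:
    C: np.ndarray  # samples x components, relative concentrations
    S: np.ndarray  # components x wavenumbers, unit-area spectra
    lof_exp: float  # % vs raw data
    lof_pca: float  # % vs rank-k PCA reconstruction
    r2: float  # explained variance, %
    iterations_run: int
    converged: bool
    lof_history: list = field(default_factory=list)
    component_names: list = field(default_factory=list)


def lack_of_fit(D: np.ndarray, D_hat: np.ndarray) -> float:
    """100 * sqrt(sum(e^2) / sum(d^2)) with e = D - D_hat."""
    D = np.asarray(D, dtype=float)
    D_hat = np.asarray(D_hat, dtype=float)
    if D.shape != D_hat.shape:
        raise ValueError("D and D_hat must have the same shape")
    denom = np.sum(D**2)
    if denom == 0:
        raise ValueError("all-zero reference matrix; lack of fit undefined")
    return float(100.0 * np.sqrt(np.sum((D - D_hat) ** 2) / denom))


def explained_variance(D: np.ndarray, D_hat: np.ndarray) -> float:
    """100 * (1 - sum(e^2) / sum(d^2)); equals 100 - lof^2/100."""
    D = np.asarray(D, dtype=float)
    D_hat = np.asarray(D_hat, dtype=float)
    if D.shape != D_hat.shape:
        raise ValueError("D and D_hat must have the same shape")
    denom = np.sum(D**2)
    if denom == 0:
        raise ValueError("all-zero data matrix; explained variance undefined")
    return float(100.0 * (1.0 - np.sum((D - D_hat) ** 2) / denom))


def pca_reconstruction(D: np.ndarray, k: int) -> np.ndarray:
    """Rank-k truncated-SVD reproduction of D (no centring, as in the
    curve-resolution convention)."""
    U, s, Vt = np.linalg.svd(np.asarray(D, dtype=float), full_matrices=False)
    return (U[:, :k] * s[:k]) @ Vt[:k]


def _solve_rows_nnls(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise argmin_X ||B - X A||_F with X >= 0.

    Solves ``A' x_i = b_i`` by NNLS for every row ``b_i`` of B.
    """
    At = A.T
    out = np.empty((B.shape[0], A.shape[0]))
    for i in range(B.shape[0]):
        out[i], _ = nnls(At, B[i])
    return out


def mcr_als_fit(D, init, cfg: McrConfig = McrConfig(), axis=None,
                component_names=None) -> McrResult:
    """Alternating least squares factorisation ``D ~ C S``.

    Parameters
    ----------
    D : (n_samples, n_wavenumbers) array
        Preprocessed spectral matrix.
    init : (n_components, n_wavenumbers) array or "svd"
        Initial spectral estimates (e.g. measured reference spectra of
        albumin / lipid extract / cellulose), or ``"svd"`` for an
        initial guess from the non-negative part of the right singular
        vectors.
    axis : optional wavenumber axis used for the unit-area
        renormalisation of S; a plain unit-sum is used when absent.

    Each half step is an exact constrained least-squares minimisation,
    so the lack of fit is non-increasing over iterations (recorded in
    ``lof_history``).
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite values in D")
    k = cfg.n_components

    if isinstance(init, str) and init == "svd":
        _, _, Vt = np.linalg.svd(D, full_matrices=False)
        S = np.abs(Vt[:k])
    else:
        S = np.array(np.asarray(init, dtype=float), copy=True)
        if S.shape[0] != k:
            raise ValueError(
                f"init has {S.shape[0]} spectra but cfg.n_components = {k}"
            )
        if S.shape[1] != D.shape[1]:
            raise ValueError("init spectra are not on the data wavenumber grid")
        S = np.clip(S, 0.0, None)
        if np.linalg.matrix_rank(S) < k:
            raise ValueError("initial spectra are linearly dependent")

    if np.linalg.matrix_rank(D) < k:
        import warnings

        warnings.warn(
            f"data rank below {k} requested components; solution is not unique",
            stacklevel=2,
        )

    def normalise_s(C, S):
        if axis is not None:
            scale = np.array([trapezoid(row, axis) for row in S])
        else:
            scale = S.sum(axis=1)
        if np.any(scale <= 0):
            zero = list(np.flatnonzero(scale <= 0))
            raise RuntimeError(f"component(s) {zero} vanished during iteration")
        return C * scale, S / scale[:, None]

    S = normalise_s(np.zeros((D.shape[0], k)), S)[1]
    lof_history = []
    lof_prev = None
    converged = False
    it = 0
    C = None
    for it in range(1, cfg.max_iter + 1):
        # C-step: min ||D - C S|| over C (>= 0)
        if cfg.nonneg_c:
            C = _solve_rows_nnls(S, D)
        else:
            C = np.linalg.lstsq(S.T, D.T, rcond=None)[0].T
        if np.any(C.sum(axis=0) == 0):
            dead = list(np.flatnonzero(C.sum(axis=0) == 0))
            raise RuntimeError(f"concentration profile(s) {dead} collapsed to zero")
        # S-step: min ||D - C S|| over S (>= 0)
        if cfg.nonneg_s:
            S = _solve_rows_nnls(C.T, D.T).T
        else:
            S = np.linalg.lstsq(C, D, rcond=None)[0]
        C, S = normalise_s(C, S)
        lof = lack_of_fit(D, C @ S)
        lof_history.append(lof)
        if lof_prev is not None:
            change = abs(lof_prev - lof) / max(lof_prev, 1e-30) * 100.0
            if change < cfg.conv_limit:
                converged = True
                lof_prev = lof
                break
        lof_prev = lof

    D_hat = C @ S
    lof_exp = lack_of_fit(D, D_hat)
    lof_pca = lack_of_fit(pca_reconstruction(D, k), D_hat)
    r2 = explained_variance(D, D_hat)
    return McrResult(
        C=C,
        S=S,
        lof_exp=lof_exp,
        lof_pca=lof_pca,
        r2=r2,
        iterations_run=it,
        converged=converged,
        lof_history=lof_history,
        component_names=list(component_names or range(k)),
    )


def calibrate_mcr_concentrations(c_column, y, response: str = "",
                                 sample_ids=None):
    """Calibrate one resolved concentration profile against chemistry.

    OLS of measured % DW on the relative concentration, with LOO
    cross-validation over the regression stage only (the decomposition
    is held fixed -- refitting the factorisation per fold is not part of
    the standard workflow).

    Returns ``(UlraModel, EvalReport)``.
    """
    c = np.asarray(c_column, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if c.size != y.size:
        raise ValueError("concentration and reference vectors differ in length")
    if np.var(c) == 0:
        raise ValueError("constant concentration profile; calibration undefined")
    model = fit_ulra(c, y, response=response, band="mcr_concentration")
    cal = PredictionPairs(
        list(sample_ids or range(c.size)), y, predict_ulra(model, c), "calibration"
    )

    def fold_fit(ctr, ytr):
        m = fit_ulra(ctr.ravel(), ytr)
        return lambda cte: predict_ulra(m, np.asarray(cte).ravel())

    cv = loo_cv(fold_fit, c.reshape(-1, 1), y, sample_ids=cal.sample_ids)
    report = evaluate_regression("MCR-ALS", response, cal, cv)
    return model, report
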
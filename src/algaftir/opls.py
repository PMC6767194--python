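"""Orthogonal PLS regression on the fingerprint region.

The model separates Y-predictive X-variation from structured variation
orthogonal to Y (in X) and, bidirectionally, Y-variation orthogonal to
X.  Orthogonal components are extracted O2-PLS-style from the residual
of the joint singular basis of ``X'Y``; the predictive core on the
filtered blocks is NIPALS PLS2.  With zero orthogonal components the
predictions coincide exactly with standard PLS2 at the same number of
components, which anchors correctness.

Scaling follows the spectroscopy convention: X columns are mean-centred
only (keeping the natural variance weighting of the wavenumbers), Y
columns are centred and scaled to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "ScalingSpec",
    "OplsModel",
    "fit_opls",
    "predict_opls",
    "select_components",
    "loading_correlations",
]

_MAX_NIPALS_ITER = 500
_NIPALS_TOL = 1e-10


@dataclass
class ScalingSpec:
    """Column scaling: 'center' for X, 'unit_variance' (centre + UV) for Y."""

    x_scaling: str = "center"
    y_scaling: str = "unit_variance"
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_sd: np.ndarray | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ScalingSpec":
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        if self.y_scaling == "unit_variance":
            sd = Y.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("constant Y column; unit-variance scaling undefined")
            self.y_sd = sd
        else:
            self.y_sd = np.ones(Y.shape[1])
        return self

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return X - self.x_mean

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.y_mean) / self.y_sd

    def inverse_y(self, Ys: np.ndarray) -> np.ndarray:
        return Ys * self.y_sd + self.y_mean


@dataclass
class OplsModel:
    """Fitted orthogonal PLS model (all arrays on the scaled blocks)."""

    n_pred: int
    n_ortho_x: int
    n_ortho_y: int
    scaling: ScalingSpec
    W: np.ndarray = None  # predictive X weights (p x A)
    P: np.ndarray = None  # predictive X loadings
    C: np.ndarray = None  # predictive Y weights
    T: np.ndarray = None  # predictive X scores (n x A)
    U: np.ndarray = None  # predictive Y scores
    B: np.ndarray = None  # regression matrix, filtered X -> scaled Y
    W_ortho: np.ndarray = None  # orthogonal-in-X weights (p x n_ox)
    P_ortho: np.ndarray = None
    T_ortho: np.ndarray = None
    C_ortho: np.ndarray = None  # orthogonal-in-Y weights (m x n_oy)
    Q_ortho: np.ndarray = None
    U_ortho: np.ndarray = None
    r2x_cum: float = np.nan
    r2y_cum: float = np.nan
    r2y_per_response: np.ndarray = None
    response_names: list = field(default_factory=list)


def _dominant_right_singular(M: np.ndarray) -> np.ndarray:
    """First right singular vector with a deterministic sign."""
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    j = int(np.argmax(np.abs(v)))
    return v if v[j] >= 0 else -v


def _joint_bases(Xc: np.ndarray, Yc: np.ndarray, n_pred: int):
    """Left/right singular bases of X'Y: the Y-predictive subspaces."""
    U, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    k = min(n_pred, np.sum(s > s[0] * 1e-12) if s.size else 0)
    if k == 0:
        raise np.linalg.LinAlgError("X'Y has rank 0; no predictive structure")
    return U[:, :n_pred], Vt[:n_pred].T


def _orient(w, t, c, u):
    """Deterministic sign: first Y-weight above half the max made positive."""
    j = int(np.flatnonzero(np.abs(c) >= 0.5 * np.abs(c).max())[0])
    if c[j] < 0:
        return -w, -t, -c, -u
    return w, t, c, u


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_comp: int):
    """Standard NIPALS PLS2 with deterministic start (u = Y c0)."""
    Xd, Yd = X.copy(), Y.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    C = np.zeros((m, n_comp))
    T = np.zeros((n, n_comp))
    U = np.zeros((n, n_comp))
    for a in range(n_comp):
        c0 = _dominant_right_singular(Xd.T @ Yd)
        u = Yd @ c0
        if np.allclose(u, 0):
            raise np.linalg.LinAlgError(
                f"rank deficiency: no Y variation left for component {a + 1}"
            )
        t_old = None
        for _ in range(_MAX_NIPALS_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise np.linalg.LinAlgError(
                    f"rank deficiency extracting component {a + 1}"
                )
            w /= nw
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * max(
                1.0, np.linalg.norm(t)
            ):
                break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        w, t, c, u = _orient(w, t, c, u)
        p_a = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p_a)
        Yd = Yd - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a], U[:, a] = w, p_a, c, t, u
    # regression matrix mapping (filtered, scaled) X to scaled Y
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return W, P, C, T, U, B, Xd


def fit_opls(
    X,
    Y,
    n_pred: int = 2,
    n_ortho_x: int = 0,
    n_ortho_y: int = 0,
    scaling: ScalingSpec | None = None,
    response_names=None,
) -> OplsModel:
    """Fit an orthogonal PLS model with the requested component structure.

    Parameters
    ----------
    X : (n, p) preprocessed spectral matrix.
    Y : (n, m) composition matrix (% DW).
    n_pred, n_ortho_x, n_ortho_y
        Numbers of predictive, orthogonal-in-X and orthogonal-in-Y
        components.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n = X.shape[0]
    if n_pred < 1:
        raise ValueError("need at least one predictive component")
    if n < n_pred + n_ortho_x + n_ortho_y + 2:
        raise ValueError("too few samples for the requested component structure")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in X or Y")

    scaling = (scaling or ScalingSpec()).fit(X, Y)
    Xc = scaling.transform_x(X)
    Yc = scaling.transform_y(Y)
    ssx_total = np.sum(Xc**2)
    ssy_total = np.sum(Yc**2)

    model = OplsModel(n_pred, n_ortho_x, n_ortho_y, scaling,
                      response_names=list(response_names or range(Y.shape[1])))

    # --- orthogonal-in-X filtering ------------------------------------
    Xf = Xc.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho_x):
        Wj, _ = _joint_bases(Xf, Yc, n_pred)
        E = Xf - Xf @ Wj @ Wj.T  # X-variation outside the Y-predictive basis
        w_o = _dominant_right_singular(E)
        t_o = Xf @ w_o
        if np.allclose(t_o, 0):
            raise np.linalg.LinAlgError("no orthogonal X-variation left to extract")
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    model.W_ortho = np.column_stack(W_o) if W_o else np.zeros((X.shape[1], 0))
    model.P_ortho = np.column_stack(P_o) if P_o else np.zeros((X.shape[1], 0))
    model.T_ortho = np.column_stack(T_o) if T_o else np.zeros((n, 0))

    # --- orthogonal-in-Y filtering ------------------------------------
    Yf = Yc.copy()
    C_o, Q_o, U_o = [], [], []
    for _ in range(n_ortho_y):
        _, Cj = _joint_bases(Xf, Yf, min(n_pred, Yf.shape[1] - 1) or 1)
        F = Yf - Yf @ Cj @ Cj.T
        c_o = _dominant_right_singular(F)
        u_o = Yf @ c_o
        if np.allclose(u_o, 0):
            raise np.linalg.LinAlgError("no orthogonal Y-variation left to extract")
        q_o = Yf.T @ u_o / (u_o @ u_o)
        Yf = Yf - np.outer(u_o, q_o)
        C_o.append(c_o)
        Q_o.append(q_o)
        U_o.append(u_o)
    model.C_ortho = np.column_stack(C_o) if C_o else np.zeros((Y.shape[1], 0))
    model.Q_ortho = np.column_stack(Q_o) if Q_o else np.zeros((Y.shape[1], 0))
    model.U_ortho = np.column_stack(U_o) if U_o else np.zeros((n, 0))

    # --- predictive core ----------------------------------------------
    W, P, C, T, U, B, X_res = _nipals_pls2(Xf, Yf, n_pred)
    model.W, model.P, model.C, model.T, model.U, model.B = W, P, C, T, U, B

    Yhat_scaled = Xf @ B
    model.r2x_cum = float(1.0 - np.sum(X_res**2) / ssx_total)
    model.r2y_cum = float(1.0 - np.sum((Yc - Yhat_scaled) ** 2) / ssy_total)
    ssy_col = np.sum(Yc**2, axis=0)
    model.r2y_per_response = 1.0 - np.sum((Yc - Yhat_scaled) ** 2, axis=0) / ssy_col
    return model


def _filter_new_x(m: OplsModel, X_new: np.ndarray) -> np.ndarray:
    Xf = m.scaling.transform_x(X_new)
    for j in range(m.n_ortho_x):
        t_o = Xf @ m.W_ortho[:, j]
        Xf = Xf - np.outer(t_o, m.P_ortho[:, j])
    return Xf


def predict_opls(m: OplsModel, X_new) -> np.ndarray:
    """Predict composition (% DW) for spectra on the training grid."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.W.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} wavenumbers, model expects {m.W.shape[0]}"
        )
    Xf = _filter_new_x(m, X_new)
    return m.scaling.inverse_y(Xf @ m.B)


def predictive_scores(m: OplsModel, X_new) -> np.ndarray:
    """Predictive component scores for (new) spectra."""
    Xf = _filter_new_x(m, np.atleast_2d(np.asarray(X_new, dtype=float)))
    # NIPALS scores with deflation: t_a = X_a w_a, X_a+1 = X_a - t_a p_a'
    T = np.zeros((Xf.shape[0], m.n_pred))
    Xd = Xf.copy()
    for a in range(m.n_pred):
        T[:, a] = Xd @ m.W[:, a]
        Xd = Xd - np.outer(T[:, a], m.P[:, a])
    return T


def _pooled_q2(Y_true: np.ndarray, Y_pred: np.ndarray, y_mean, y_sd) -> float:
    res = (Y_true - Y_pred) / y_sd
    tot = (Y_true - y_mean) / y_sd
    return float(1.0 - np.sum(res**2) / np.sum(tot**2))


def cross_validate_opls(X, Y, n_pred, n_ortho_x, n_ortho_y, k=5, seed=0):
    """k-fold CV of the full fit (scaling refit per fold); returns
    (Y_cv_predictions, pooled Q2)."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    preds = np.empty_like(Y)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in splitter.split(X):
        mod = fit_opls(X[tr], Y[tr], n_pred, n_ortho_x, n_ortho_y)
        preds[te] = predict_opls(mod, X[te])
    q2 = _pooled_q2(Y, preds, Y.mean(axis=0), Y.std(axis=0, ddof=1))
    return preds, q2


def select_components(X, Y, max_pred=4, max_ox=3, max_oy=2, k=5, seed=0, threshold=0.01):
    """Greedy forward component selection by k-fold cross validation.

    Components are added predictive-first, then orthogonal-in-X, then
    orthogonal-in-Y, each accepted only while the pooled Q2 improves by
    more than ``threshold``.  Returns ``((n_pred, n_ox, n_oy),
    q2_trajectory)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_pred, n_ox, n_oy = 1, 0, 0
    _, q2 = cross_validate_opls(X, Y, n_pred, n_ox, n_oy, k=k, seed=seed)
    trajectory = [((n_pred, n_ox, n_oy), q2)]

    def try_grow(np_, nx_, ny_, current_q2):
        try:
            _, q2_new = cross_validate_opls(X, Y, np_, nx_, ny_, k=k, seed=seed)
        except (ValueError, np.linalg.LinAlgError):
            return None
        if q2_new > current_q2 + threshold:
            return q2_new
        return None

    limit = min(max_pred, Y.shape[1] if Y.shape[1] > 1 else max_pred)
    while n_pred < limit:
        grown = try_grow(n_pred + 1, n_ox, n_oy, q2)
        if grown is None:
            break
        n_pred, q2 = n_pred + 1, grown
        trajectory.append(((n_pred, n_ox, n_oy), q2))
    while n_ox < max_ox:
        grown = try_grow(n_pred, n_ox + 1, n_oy, q2)
        if grown is None:
            break
        n_ox, q2 = n_ox + 1, grown
        trajectory.append(((n_pred, n_ox, n_oy), q2))
    while n_oy < max_oy:
        grown = try_grow(n_pred, n_ox, n_oy + 1, q2)
        if grown is None:
            break
        n_oy, q2 = n_oy + 1, grown
        trajectory.append(((n_pred, n_ox, n_oy), q2))
    return (n_pred, n_ox, n_oy), trajectory


def loading_correlations(m: OplsModel, X):
    """Correlation of each predictive score with each centred X column.

    Returns ``(corr, flags)`` where ``corr`` is (n_pred, p) in [-1, 1]
    and ``flags`` marks zero-variance columns (correlation set to 0).
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    col_sd = Xc.std(axis=0)
    flags = col_sd == 0
    corr = np.zeros((m.n_pred, X.shape[1]))
    T = m.T
    for a in range(m.n_pred):
        t = T[:, a] - T[:, a].mean()
        denom = np.linalg.norm(t) * np.linalg.norm(Xc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (t @ Xc) / denom
        c[flags] = 0.0
        corr[a] = np.clip(c, -1.0, 1.0)
    return corr, flags
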
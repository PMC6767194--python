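"""Spectral preprocessing chain for ATR-FTIR absorbance spectra.

The default chain reproduces the common workflow for algal biomass
fingerprinting: asymmetric-least-squares (AsLS) baseline correction,
total-area normalisation, mild Savitzky-Golay smoothing, and cropping
to the 800-1800 cm^-1 fingerprint region.  Cropping runs last so that
baseline and normalisation operate on the full recorded range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sparse
from scipy.integrate import trapezoid
from scipy.signal import savgol_filter
from scipy.sparse.linalg import splu

from algaftir.spectra_io import SpectrumSet

__all__ = [
    "AslsParams",
    "PreprocessConfig",
    "asls_baseline",
    "total_area_normalize",
    "savgol",
    "crop",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class AslsParams:
    """Asymmetric least squares baseline parameters.

    lam
        Smoothness penalty on the second difference of the baseline
        (dimensionless); 1e6 suits 4 cm^-1 FTIR spectra.
    p
        Asymmetry weight in (0, 1): points above the baseline get weight
        ``p``, points below ``1 - p``.  Small p pushes the baseline under
        the peaks.
    max_iter
        Reweighting iteration cap.
    tol
        Convergence threshold on the fraction of points whose weight
        changed between iterations.
    """

    lam: float = 1e6
    p: float = 0.001
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass(frozen=True)
class PreprocessConfig:
    """Full preprocessing configuration with fingerprinting defaults."""

    asls: AslsParams = field(default_factory=AslsParams)
    sg_polyorder: int = 1
    sg_frame: int = 5
    crop_lo: float = 800.0
    crop_hi: float = 1800.0
    normalize_target: float = 1.0
    # stage switches for sensitivity analysis / drift-free data
    do_baseline: bool = True
    do_normalize: bool = True
    do_smooth: bool = True
    do_crop: bool = True

    def __post_init__(self):
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_polyorder:
            raise ValueError("sg_frame must be odd and > sg_polyorder")
        if self.crop_lo >= self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.normalize_target <= 0:
            raise ValueError("normalize_target must be > 0")


def asls_baseline(y: np.ndarray, params: AslsParams = AslsParams()):
    """Estimate a smooth baseline under ``y`` by asymmetric least squares.

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` with
    iteratively reweighted ``w_i = p`` where ``y_i > z_i`` else
    ``1 - p`` (Eilers-style second-difference penalty).  Iteration stops
    when the weight vector is (nearly) unchanged or after
    ``params.max_iter`` rounds.

    Returns
    -------
    (baseline, corrected) : tuple of ndarray
        ``corrected = y - baseline``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("signal must be 1-D with length >= 5")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in signal")
    n = y.size
    D = sparse.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    DtD = (params.lam * (D.T @ D)).tocsc()
    w = np.ones(n)
    for _ in range(params.max_iter):
        W = sparse.diags_array(w, format="csc")
        z = splu((W + DtD).tocsc()).solve(w * y)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        changed = np.mean(w_new != w)
        w = w_new
        if changed <= params.tol:
            break
    return z, y - z


def total_area_normalize(y: np.ndarray, axis: np.ndarray, target: float = 1.0):
    """Scale ``y`` so its trapezoidal area over ``axis`` equals ``target``.

    The area of ``|y|`` guards the precondition; the scale is the signed
    area so that two spectra differing by a positive factor map onto the
    same vector.
    """
    y = np.asarray(y, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if target <= 0:
        raise ValueError("target area must be > 0")
    if trapezoid(np.abs(y), axis) <= 0:
        raise ValueError("total spectral area is zero; cannot normalise")
    area = trapezoid(y, axis)
    if area <= 0:
        raise ValueError("signed spectral area is non-positive; cannot normalise")
    return y * (target / area)


def savgol(y: np.ndarray, polyorder: int = 1, frame: int = 5) -> np.ndarray:
    """Savitzky-Golay smoothing (order 1, frame 5 is a mild 5-point mean).

    Edge points are handled by fitting the polynomial over the shrunken
    window that fits inside the signal (scipy ``mode='interp'``).
    """
    y = np.asarray(y, dtype=float)
    if frame % 2 == 0:
        raise ValueError("frame must be odd")
    if frame <= polyorder:
        raise ValueError("frame must exceed polyorder")
    if frame > y.size:
        raise ValueError("frame longer than signal")
    return savgol_filter(y, window_length=frame, polyorder=polyorder, mode="interp")


def crop(s: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Keep wavenumbers in the closed interval [lo, hi]."""
    mask = (s.axis >= lo) & (s.axis <= hi)
    if mask.sum() < 2:
        raise ValueError(f"crop window [{lo}, {hi}] leaves < 2 axis points")
    return replace(s, axis=s.axis[mask], intensities=s.intensities[:, mask])


def preprocess_pipeline(s: SpectrumSet, cfg: PreprocessConfig = PreprocessConfig()) -> SpectrumSet:
    """Run baseline -> normalise -> smooth -> crop over a SpectrumSet.

    The applied stage order is recorded in ``metadata`` provenance of the
    returned set (column ``preprocess``) so downstream reports can state
    how the X block was produced.
    """
    out = s.intensities.copy()
    stages = []
    try:
        if cfg.do_baseline:
            stage = "asls_baseline"
            out = np.vstack([asls_baseline(row, cfg.asls)[1] for row in out])
            stages.append(stage)
        if cfg.do_normalize:
            stage = "total_area_normalize"
            out = np.vstack(
                [total_area_normalize(row, s.axis, cfg.normalize_target) for row in out]
            )
            stages.append(stage)
        if cfg.do_smooth:
            stage = "savgol"
            out = np.vstack([savgol(row, cfg.sg_polyorder, cfg.sg_frame) for row in out])
            stages.append(stage)
    except Exception as exc:
        raise type(exc)(f"preprocessing stage {stage!r}: {exc}") from exc
    res = replace(s, intensities=out)
    if cfg.do_crop:
        try:
            res = crop(res, cfg.crop_lo, cfg.crop_hi)
        except Exception as exc:
            raise type(exc)(f"preprocessing stage 'crop': {exc}") from exc
        stages.append("crop")
    meta = res.metadata.copy() if res.metadata is not None else None
    if meta is None:
        import pandas as pd

        meta = pd.DataFrame(index=res.sample_ids)
    meta["preprocess"] = " -> ".join(stages) if stages else "none"
    return replace(res, metadata=meta)
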
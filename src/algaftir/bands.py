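"""Diagnostic absorption-band integration and univariate features.

Band areas (absorbance * cm^-1) of the amide, ester-carbonyl and
polysaccharide regions are the inputs of the univariate calibration
models.  Default windows: protein 1580-1700, lipid 1710-1765,
carbohydrate 960-1130 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from algaftir.spectra_io import Spectrum, SpectrumSet

__all__ = [
    "BandDefinition",
    "PAPER_BANDS",
    "integrate_band",
    "band_table",
    "ratio_feature",
]


@dataclass(frozen=True)
class BandDefinition:
    """A closed wavenumber interval [lo, hi] named after its assignment."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"band {self.name!r}: lo must be < hi")


#: Diagnostic integration windows: amide I/II for proteins, the ester
#: C=O stretch for lipids, ring/C-O-C vibrations for carbohydrates.
PAPER_BANDS = (
    BandDefinition("protein_band", 1580.0, 1700.0),
    BandDefinition("lipid_band", 1710.0, 1765.0),
    BandDefinition("carb_band", 960.0, 1130.0),
)


def _band_slice(axis: np.ndarray, intensity: np.ndarray, band: BandDefinition):
    """Axis/intensity restricted to the band, with interpolated edge points."""
    lo = max(band.lo, axis[0])
    hi = min(band.hi, axis[-1])
    if lo >= hi:
        raise ValueError(
            f"band {band.name!r} [{band.lo}, {band.hi}] does not overlap axis "
            f"[{axis[0]}, {axis[-1]}]"
        )
    inner = (axis > lo) & (axis < hi)
    xs = np.concatenate(([lo], axis[inner], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, axis, intensity)], intensity[inner], [np.interp(hi, axis, intensity)])
    )
    return xs, ys


def integrate_band(sp: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal area under the spectrum over the band window.

    Band edges falling between grid points contribute via linear
    interpolation of the boundary intensities.  The area is taken above
    zero: spectra are assumed baseline-corrected upstream.
    """
    xs, ys = _band_slice(sp.axis, sp.intensity, band)
    return float(trapezoid(ys, xs))


def band_table(s: SpectrumSet, bands=PAPER_BANDS) -> pd.DataFrame:
    """Integrate every band for every sample.

    Returns a DataFrame indexed by sample_id (input order) with one
    column per band name.
    """
    rows = {}
    for i, sid in enumerate(s.sample_ids):
        entry = {}
        for b in bands:
            xs, ys = _band_slice(s.axis, s.intensities[i], b)
            entry[b.name] = float(trapezoid(ys, xs))
        rows[sid] = entry
    out = pd.DataFrame.from_dict(rows, orient="index").loc[s.sample_ids]
    return out[[b.name for b in bands]]


def ratio_feature(b: pd.DataFrame, num: str, den: str):
    """Per-sample band-area ratio ``num / den``.

    Samples with a zero denominator are excluded and reported.

    Returns
    -------
    (ratio, excluded) : (pandas.Series, list)
    """
    if num not in b.columns or den not in b.columns:
        raise KeyError(f"band table lacks {num!r} or {den!r}")
    zero = b[den] == 0.0
    excluded = list(b.index[zero])
    kept = b.loc[~zero]
    return kept[num] / kept[den], excluded
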
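"""Reading, writing and aligning FTIR spectra and composition tables.

Spectra live on a shared wavenumber axis (cm^-1, stored ascending);
compositions are percentages of biomass dry weight.  Plain-text CSV is
the only supported on-disk format: a *wide* matrix with one wavenumber
column plus one column per sample, or a *long* table with
``sample_id,wavenumber,intensity`` rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "CompositionTable",
    "PairedData",
    "AlignmentError",
    "read_spectrum_matrix",
    "write_spectrum_matrix",
    "read_composition",
    "write_composition",
    "regrid",
    "join_xy",
]

COMPOSITION_COLUMNS = ("protein_pct", "lipid_pct", "carb_pct")


class AlignmentError(ValueError):
    """Raised when spectra cannot be placed on a single shared axis."""


def _validate_axis(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("wavenumber axis must be 1-D with length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("wavenumber axis contains non-finite values")
    d = np.diff(values)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavenumber axis must be strictly monotonic")
    return values


@dataclass
class Spectrum:
    """A single sample's absorbance spectrum on a wavenumber axis."""

    sample_id: str
    axis: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = _validate_axis(self.axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise ValueError(
                f"sample {self.sample_id!r}: intensity length "
                f"{self.intensity.size} != axis length {self.axis.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite intensity")
        if self.axis[0] > self.axis[-1]:  # normalise to ascending
            self.axis = self.axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis.

    ``intensities`` is the X block: shape (n_samples, n_wavenumbers),
    row order matching ``sample_ids``.  ``metadata`` is an optional
    per-sample table (species, starvation day, replicate, ...).
    """

    axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        self.axis = _validate_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.axis[0] > self.axis[-1]:
            self.axis = self.axis[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()
        if self.intensities.shape != (len(self.sample_ids), self.axis.size):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.axis.size} wavenumbers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample_ids: {dup}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities in SpectrumSet")
        if self.metadata is not None and not self.metadata.empty:
            self.metadata = self.metadata.loc[self.sample_ids]

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(sample_id)
        meta = {}
        if self.metadata is not None and sample_id in self.metadata.index:
            meta = self.metadata.loc[sample_id].to_dict()
        return Spectrum(sample_id, self.axis, self.intensities[i], meta)

    def spectra(self):
        return [self[s] for s in self.sample_ids]

    @classmethod
    def from_spectra(cls, spectra) -> "SpectrumSet":
        if not spectra:
            raise ValueError("empty spectrum collection")
        axis = spectra[0].axis
        rows = []
        for sp in spectra:
            if sp.axis.shape != axis.shape or not np.allclose(sp.axis, axis):
                raise AlignmentError(
                    f"sample {sp.sample_id!r} is not on the shared wavenumber axis"
                )
            rows.append(sp.intensity)
        meta_rows = {sp.sample_id: sp.metadata for sp in spectra if sp.metadata}
        meta = pd.DataFrame.from_dict(meta_rows, orient="index") if meta_rows else None
        return cls(axis, np.vstack(rows), [sp.sample_id for sp in spectra], meta)

    def to_frame(self) -> pd.DataFrame:
        """Samples x wavenumbers DataFrame (columns = wavenumbers)."""
        return pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.axis)


@dataclass
class CompositionTable:
    """Per-sample protein/lipid/carbohydrate content in % of dry weight.

    The underlying frame is indexed by sample_id with columns
    ``protein_pct, lipid_pct, carb_pct`` (NaN marks a missing
    measurement) plus any metadata columns (species, day, replicate).
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        if df.index.has_duplicates:
            dup = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate sample_ids in composition table: {dup}")
        missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"composition table lacks columns {missing}")
        df[list(COMPOSITION_COLUMNS)] = df[list(COMPOSITION_COLUMNS)].astype(float)
        vals = df[list(COMPOSITION_COLUMNS)].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.any((vals[present] < 0) | (vals[present] > 100)):
            raise ValueError("composition values must lie in [0, 100] % DW")
        df.index = df.index.astype(str)
        self.df = df

    @property
    def sample_ids(self) -> list:
        return list(self.df.index)

    def values(self) -> pd.DataFrame:
        return self.df[list(COMPOSITION_COLUMNS)]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PairedData:
    """Aligned (X, Y) blocks over a shared, ordered sample registry."""

    spectra: SpectrumSet
    composition: CompositionTable
    excluded_spectra: list
    excluded_composition: list

    @property
    def sample_ids(self) -> list:
        return self.spectra.sample_ids

    @property
    def X(self) -> np.ndarray:
        return self.spectra.intensities

    @property
    def Y(self) -> pd.DataFrame:
        return self.composition.values()


def _require_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        coerced = pd.to_numeric(out[c], errors="coerce")
        bad = coerced.isna() & out[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {out[c].iloc[row]!r} "
                f"in column {c!r}, data row {row}"
            )
        out[c] = coerced
    return out


def read_spectrum_matrix(path, orientation: str = "wide") -> SpectrumSet:
    """Read a spectral matrix from CSV.

    Parameters
    ----------
    path : str
        CSV file.  ``wide``: first column is the wavenumber, each further
        column one sample (header = sample_id).  ``long``: columns
        ``sample_id, wavenumber, intensity``.
    orientation : {"wide", "long"}

    A sidecar ``<path>.meta.csv`` (sample_id-indexed) is picked up as
    per-sample metadata when present.
    """
    raw = pd.read_csv(path, dtype=str)
    if orientation == "wide":
        if raw.shape[1] < 2:
            raise ValueError(f"{path}: wide matrix needs >= 2 columns")
        raw = _require_numeric(raw, raw.columns, path)
        axis = raw.iloc[:, 0].to_numpy(dtype=float)
        order = np.argsort(axis)
        wide = raw.iloc[order]
        axis = wide.iloc[:, 0].to_numpy(dtype=float)
        intens = wide.iloc[:, 1:].to_numpy(dtype=float).T
        ids = [str(c) for c in raw.columns[1:]]
    elif orientation == "long":
        expected = ["sample_id", "wavenumber", "intensity"]
        if list(raw.columns[:3]) != expected:
            raise ValueError(f"{path}: long format needs columns {expected}")
        raw = _require_numeric(raw, ["wavenumber", "intensity"], path)
        ids = list(dict.fromkeys(raw["sample_id"]))  # first-appearance order
        per_sample = {}
        axis = None
        axis_owner = None
        for sid, grp in raw.groupby("sample_id", sort=False):
            g = grp.sort_values("wavenumber")
            wn = g["wavenumber"].to_numpy(dtype=float)
            if axis is None:
                axis, axis_owner = wn, sid
            elif wn.shape != axis.shape or not np.array_equal(wn, axis):
                raise AlignmentError(
                    f"{path}: sample {sid!r} wavenumber axis differs from "
                    f"sample {axis_owner!r}"
                )
            per_sample[sid] = g["intensity"].to_numpy(dtype=float)
        intens = np.vstack([per_sample[s] for s in ids])
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    if np.unique(axis).size != axis.size:
        raise AlignmentError(f"{path}: duplicated wavenumber values")
    meta = None
    meta_path = f"{path}.meta.csv"
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
    return SpectrumSet(axis, intens, ids, meta)


def write_spectrum_matrix(s: SpectrumSet, path) -> None:
    """Write a SpectrumSet as a wide CSV (17 significant digits).

    Per-sample metadata, if any, goes to the sidecar ``<path>.meta.csv``
    so that ``read_spectrum_matrix`` round-trips the full object.
    """
    df = pd.DataFrame({"wavenumber": s.axis})
    for i, sid in enumerate(s.sample_ids):
        df[sid] = s.intensities[i]
    df.to_csv(path, index=False, float_format="%.17g")
    if s.metadata is not None and not s.metadata.empty:
        s.metadata.to_csv(f"{path}.meta.csv", index_label="sample_id")


def read_composition(path) -> CompositionTable:
    df = pd.read_csv(path, index_col="sample_id")
    df = _require_numeric(df, [c for c in COMPOSITION_COLUMNS if c in df.columns], path)
    return CompositionTable(df)


def write_composition(c: CompositionTable, path) -> None:
    c.df.to_csv(path, index_label="sample_id", float_format="%.17g")


def regrid(s: SpectrumSet, spacing: float) -> SpectrumSet:
    """Resample all spectra onto a uniform grid by linear interpolation.

    Grid endpoints are the nearest integer multiples of ``spacing``
    inside the original axis span.  Used to mimic the 2 cm^-1 grid that
    instrument software produces by interferogram zero-filling; linear
    interpolation is an adequate stand-in because downstream models are
    insensitive to sub-resolution detail.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo, hi = float(s.axis[0]), float(s.axis[-1])
    start = np.ceil(lo / spacing - 1e-9) * spacing
    stop = np.floor(hi / spacing + 1e-9) * spacing
    if stop - start < spacing:
        raise ValueError(f"spacing {spacing} larger than axis span [{lo}, {hi}]")
    n = int(round((stop - start) / spacing)) + 1
    grid = start + spacing * np.arange(n)
    new = np.vstack([np.interp(grid, s.axis, row) for row in s.intensities])
    return replace(s, axis=grid, intensities=new)


def join_xy(s: SpectrumSet, c: CompositionTable) -> PairedData:
    """Align spectra with composition rows on their common sample ids.

    Samples present on only one side are excluded and reported; the
    retained order is the input spectrum order.
    """
    comp_ids = set(c.sample_ids)
    spec_ids = set(s.sample_ids)
    keep = [sid for sid in s.sample_ids if sid in comp_ids]
    if not keep:
        raise ValueError("no common samples between spectra and composition table")
    excluded_spectra = [sid for sid in s.sample_ids if sid not in comp_ids]
    excluded_comp = [sid for sid in c.sample_ids if sid not in spec_ids]
    idx = [s.sample_ids.index(sid) for sid in keep]
    meta = s.metadata.loc[keep] if s.metadata is not None else None
    sub = SpectrumSet(s.axis, s.intensities[idx], keep, meta)
    comp = CompositionTable(c.df.loc[keep])
    return PairedData(sub, comp, excluded_spectra, excluded_comp)
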
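"""Synthetic nitrogen-starvation datasets for end-to-end validation.

Generates ground-truth data with the statistical structure the analysis
assumes: seven microalgal "species" in duplicate reactors sampled over
days of nitrogen starvation, with protein declining and one or both
storage pools (lipid, carbohydrate) accumulating depending on the
species' carbon-partitioning mode.  Spectra are non-negative mixtures
of Gaussian-band pure-component profiles with wavenumber-dependent ATR
intensity weighting, cubic baseline drift and additive noise; a
broadband "other biomass" term (water, residual CH/cell-wall modes)
keeps total mass closed without placing intensity inside the three
diagnostic integration windows.

Compositions stay inside the empirical ranges for starved green
microalgae: protein 9-48, lipid 0-13, carbohydrate 13-55 % DW.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from algaftir.spectra_io import (
    CompositionTable,
    SpectrumSet,
    write_composition,
    write_spectrum_matrix,
)

__all__ = [
    "GaussianBand",
    "PureSpectrumModel",
    "TrajectoryParams",
    "NoiseModel",
    "SyntheticDataset",
    "DEFAULT_AXIS",
    "default_pure_models",
    "default_design",
    "make_pure_spectra",
    "make_trajectories",
    "make_spectra",
    "make_dataset",
]

#: Native acquisition grid: 400-4000 cm^-1 at 4 cm^-1 spacing.
DEFAULT_AXIS = np.arange(400.0, 4000.0 + 4.0, 4.0)

_RANGES = {"protein_pct": (9.0, 48.0), "lipid_pct": (0.0, 13.0), "carb_pct": (13.0, 55.0)}


@dataclass(frozen=True)
class GaussianBand:
    center: float
    sigma: float
    amplitude: float


@dataclass
class PureSpectrumModel:
    """Sum-of-Gaussians model of one pure component's absorbance.

    Bands are truncated at +-5 sigma, so a component contributes exactly
    zero outside its band supports; band placements are chosen so no
    component leaks into another component's diagnostic window.
    """

    name: str
    bands: list

    def __post_init__(self):
        for b in self.bands:
            if b.amplitude <= 0 or b.sigma <= 0:
                raise ValueError(f"{self.name}: amplitudes and widths must be > 0")
            if not 400 <= b.center <= 4000:
                raise ValueError(f"{self.name}: band centre {b.center} outside 400-4000")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        y = np.zeros_like(axis)
        for b in self.bands:
            z = (axis - b.center) / b.sigma
            y += np.where(np.abs(z) <= 5.0, b.amplitude * np.exp(-0.5 * z**2), 0.0)
        return y


def default_pure_models():
    """Protein (amide I/II + N-H/C-H), lipid (ester C=O + acyl C-H),
    carbohydrate (crowded ring/C-O-C manifold + O-H), and the broadband
    'other biomass' remainder."""
    protein = PureSpectrumModel(
        "protein",
        [
            GaussianBand(1655, 10, 1.00),  # amide I
            GaussianBand(1545, 18, 0.72),  # amide II
            GaussianBand(3300, 80, 0.30),  # N-H stretch
            GaussianBand(2960, 25, 0.10),
        ],
    )
    lipid = PureSpectrumModel(
        "lipid",
        [
            GaussianBand(1742, 7, 1.00),  # ester C=O
            GaussianBand(2925, 18, 0.60),  # CH2 asym
            GaussianBand(2855, 13, 0.35),  # CH2 sym
            GaussianBand(1465, 12, 0.18),
            GaussianBand(1175, 8, 0.15),  # ester C-O
        ],
    )
    carbohydrate = PureSpectrumModel(
        "carbohydrate",
        [
            GaussianBand(1010, 16, 0.90),
            GaussianBand(1035, 15, 0.80),
            GaussianBand(1060, 14, 0.70),
            GaussianBand(1080, 10, 0.55),
            GaussianBand(1110, 12, 0.45),
            GaussianBand(1150, 10, 0.28),
            GaussianBand(930, 12, 0.15),
            GaussianBand(3350, 110, 0.35),  # O-H stretch
            GaussianBand(2900, 20, 0.08),
        ],
    )
    other = PureSpectrumModel(
        "other",
        [
            GaussianBand(3380, 150, 0.45),  # bound water / O-H
            GaussianBand(2930, 35, 0.25),
            GaussianBand(1430, 20, 0.18),
            GaussianBand(1260, 18, 0.15),  # amide III / PO2 region
        ],
    )
    return [protein, lipid, carbohydrate, other]


def make_pure_spectra(models=None, axis: np.ndarray = DEFAULT_AXIS,
                      area: float = 100.0) -> SpectrumSet:
    """Evaluate pure-component models on the axis, each scaled to the
    same total area (absorbance per unit mass is taken as comparable
    across biomolecule classes)."""
    models = models if models is not None else default_pure_models()
    rows, names = [], []
    for m in models:
        y = m.evaluate(axis)
        a = trapezoid(y, axis)
        if a <= 0:
            raise ValueError(f"component {m.name!r} has zero area on this axis")
        rows.append(y * (area / a))
        names.append(m.name)
    return SpectrumSet(axis, np.vstack(rows), names)


@dataclass
class TrajectoryParams:
    """Composition dynamics for one species under nitrogen starvation.

    Protein relaxes exponentially from its replete level toward a
    starved floor; storage pools rise saturably at rates set by the
    partitioning mode (lipid_accumulator / carb_accumulator / both).
    """

    species: str
    mode: str
    days: tuple = (0, 2, 4, 6, 8)
    replicates: int = 2
    role: str = "calibration"
    protein_day0: float = 44.0
    protein_floor: float = 12.0
    protein_decay: float = 0.35  # per day
    lipid_day0: float = 2.0
    lipid_ceiling: float = 6.0
    lipid_rate: float = 0.30
    carb_day0: float = 16.0
    carb_ceiling: float = 35.0
    carb_rate: float = 0.30

    def __post_init__(self):
        if self.mode not in ("lipid_accumulator", "carb_accumulator", "both"):
            raise ValueError(f"unknown partitioning mode {self.mode!r}")
        for lo, hi, v in [
            (9, 48, self.protein_day0),
            (9, 48, self.protein_floor),
            (0, 13, self.lipid_day0),
            (0, 13, self.lipid_ceiling),
            (13, 55, self.carb_day0),
            (13, 55, self.carb_ceiling),
        ]:
            if not lo <= v <= hi:
                raise ValueError(
                    f"{self.species}: composition parameter {v} outside [{lo}, {hi}] % DW"
                )

    def composition_at(self, day: float) -> dict:
        decay = np.exp(-self.protein_decay * day)
        rise_l = 1.0 - np.exp(-self.lipid_rate * day)
        rise_c = 1.0 - np.exp(-self.carb_rate * day)
        return {
            "protein_pct": self.protein_floor + (self.protein_day0 - self.protein_floor) * decay,
            "lipid_pct": self.lipid_day0 + (self.lipid_ceiling - self.lipid_day0) * rise_l,
            "carb_pct": self.carb_day0 + (self.carb_ceiling - self.carb_day0) * rise_c,
        }


def default_design():
    """Seven-species design: six calibration species (52 samples) plus
    one external-validation species (6 samples), duplicate reactors."""
    return [
        TrajectoryParams("Cvul13-1", "lipid_accumulator", protein_day0=46, protein_floor=14,
                         lipid_day0=2.5, lipid_ceiling=12.5, lipid_rate=0.35,
                         carb_day0=15, carb_ceiling=26, carb_rate=0.25),
        TrajectoryParams("ScenB2-2", "carb_accumulator", protein_day0=43, protein_floor=11,
                         lipid_day0=1.5, lipid_ceiling=4.5, lipid_rate=0.25,
                         carb_day0=17, carb_ceiling=53, carb_rate=0.38),
        TrajectoryParams("DesmRUC-2", "both", protein_day0=45, protein_floor=13,
                         lipid_day0=2.0, lipid_ceiling=10.5, lipid_rate=0.30,
                         carb_day0=16, carb_ceiling=43, carb_rate=0.30),
        TrajectoryParams("CastRW10", "carb_accumulator", protein_day0=40, protein_floor=10,
                         lipid_day0=1.0, lipid_ceiling=5.5, lipid_rate=0.28,
                         carb_day0=18, carb_ceiling=48, carb_rate=0.33),
        TrajectoryParams("Coel3-4", "lipid_accumulator", days=(0, 4, 8),
                         protein_day0=42, protein_floor=15,
                         lipid_day0=3.0, lipid_ceiling=11.5, lipid_rate=0.32,
                         carb_day0=14, carb_ceiling=24, carb_rate=0.22),
        TrajectoryParams("SoblUTEX", "both", days=(0, 4, 8),
                         protein_day0=47, protein_floor=16,
                         lipid_day0=2.0, lipid_ceiling=9.0, lipid_rate=0.26,
                         carb_day0=15, carb_ceiling=38, carb_rate=0.28),
        TrajectoryParams("Desm2-6", "both", days=(0, 4, 8), role="external",
                         protein_day0=44, protein_floor=14,
                         lipid_day0=2.2, lipid_ceiling=9.8, lipid_rate=0.29,
                         carb_day0=16, carb_ceiling=40, carb_rate=0.31),
    ]


@dataclass
class NoiseModel:
    """All stochastic ingredients of the forward model.

    additive_sigma
        Gaussian absorbance noise per spectral point.
    drift_scale
        Scale of random cubic baseline drift (absorbance at axis edge).
    gamma
        ATR penetration weighting exponent: intensity is multiplied by
        ``(ref_wavenumber / wavenumber) ** gamma``; gamma = 1 follows
        penetration depth proportional to wavelength.
    interferent_sigma
        Per-sample half-normal amplitude of a shared interferent band in
        the carbohydrate region (PO2 / Si-O overlap stand-in).
    water_sigma
        Per-sample half-normal amplitude of a residual-moisture O-H
        stretch band (3400 cm^-1).  It carries no intensity inside the
        fingerprint region but inflates the total spectral area, so it
        turns total-area normalisation into a per-sample multiplicative
        error shared by all bands -- the error that band *ratios*
        cancel.
    measurement_sigma
        Std dev of the wet-chemistry (extraction) error added to the
        *reported* composition table, % DW, per compound.
    replicate_sigma
        Relative reactor-to-reactor bias on true compositions.
    """

    additive_sigma: float = 0.0
    drift_scale: float = 0.0
    gamma: float = 0.0
    ref_wavenumber: float = 1000.0
    interferent_sigma: float = 0.0
    water_sigma: float = 0.0
    measurement_sigma: tuple = (0.0, 0.0, 0.0)
    replicate_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.additive_sigma, self.drift_scale, self.interferent_sigma,
               self.water_sigma, self.replicate_sigma,
               *self.measurement_sigma) < 0:
            raise ValueError("noise scales must be >= 0")


_INTERFERENT = GaussianBand(1075, 28, 1.0)
_WATER = GaussianBand(3400, 160, 1.0)


def make_trajectories(params=None, seed: int = 0,
                      replicate_sigma: float = 0.03) -> CompositionTable:
    """Build the true composition table for a design.

    Replicate reactors get a seeded multiplicative bias (constant over
    the time course, so protein stays non-increasing within a reactor);
    values are clipped to the empirical % DW ranges.
    """
    params = params if params is not None else default_design()
    rng = np.random.default_rng(seed)
    rows = {}
    for sp in params:
        for rep in range(1, sp.replicates + 1):
            bias = rng.normal(1.0, replicate_sigma, size=3)
            for day in sp.days:
                comp = sp.composition_at(day)
                sid = f"{sp.species}_d{day}_r{rep}"
                vals = {}
                for j, col in enumerate(("protein_pct", "lipid_pct", "carb_pct")):
                    lo, hi = _RANGES[col]
                    vals[col] = float(np.clip(comp[col] * bias[j], lo, hi))
                vals.update(species=sp.species, day=day, replicate=rep,
                            mode=sp.mode, role=sp.role)
                rows[sid] = vals
    df = pd.DataFrame.from_dict(rows, orient="index")
    return CompositionTable(df)


def make_spectra(comp: CompositionTable, refs: SpectrumSet,
                 noise: NoiseModel = NoiseModel(), return_truth: bool = False):
    """Forward-model spectra from true compositions.

    intensity = [sum_k (pct_k/100) ref_k + other_frac * ref_other
                 + interferent] * (ref_wn/wn)^gamma + drift + noise

    with other_frac = 1 - (protein+lipid+carb)/100 so mixing weights
    close to one and, with gamma = 0 and no noise, every sample has
    identical total area (making total-area normalisation exact).
    """
    rng = np.random.default_rng(noise.seed)
    axis = refs.axis
    ref = {sid: refs.intensities[i] for i, sid in enumerate(refs.sample_ids)}
    needed = {"protein", "lipid", "carbohydrate", "other"}
    if not needed <= set(ref):
        raise ValueError(f"reference set must contain {sorted(needed)}")
    atr = (noise.ref_wavenumber / axis) ** noise.gamma
    z = (axis - _INTERFERENT.center) / _INTERFERENT.sigma
    interferent_shape = np.where(np.abs(z) <= 5.0, np.exp(-0.5 * z**2), 0.0)
    zw = (axis - _WATER.center) / _WATER.sigma
    water_shape = np.where(np.abs(zw) <= 5.0, np.exp(-0.5 * zw**2), 0.0)
    x_norm = (axis - axis.mean()) / (axis[-1] - axis.mean())

    rows = []
    weights, baselines, interferent_amps = {}, {}, {}
    vals = comp.values()
    for sid in comp.sample_ids:
        p, l, c = (float(vals.loc[sid, col]) for col in vals.columns)
        other = 1.0 - (p + l + c) / 100.0
        weights[sid] = [p / 100.0, l / 100.0, c / 100.0, other]
        y = (p / 100.0) * ref["protein"] + (l / 100.0) * ref["lipid"] \
            + (c / 100.0) * ref["carbohydrate"] + other * ref["other"]
        amp_i = 0.0
        if noise.interferent_sigma > 0:
            amp_i = abs(rng.normal(0.0, noise.interferent_sigma))
            y = y + amp_i * interferent_shape
        interferent_amps[sid] = amp_i
        if noise.water_sigma > 0:
            # residual moisture: area outside the fingerprint only
            y = y + abs(rng.normal(0.0, noise.water_sigma)) * water_shape
        y = y * atr
        base = np.zeros_like(axis)
        if noise.drift_scale > 0:
            # offset-dominated cubic drift with order-decaying coefficients
            # (scattering backgrounds are positive and mostly tilt)
            coef = rng.normal(0.0, noise.drift_scale, size=4)
            base = abs(coef[0]) + 0.5 * coef[1] * x_norm \
                + 0.25 * coef[2] * x_norm**2 + 0.15 * coef[3] * x_norm**3
            y = y + base
        baselines[sid] = base
        if noise.additive_sigma > 0:
            y = y + rng.normal(0.0, noise.additive_sigma, size=axis.size)
        rows.append(y)
    meta_cols = [c for c in comp.df.columns if c not in vals.columns]
    meta = comp.df[meta_cols].copy() if meta_cols else None
    out = SpectrumSet(axis, np.vstack(rows), comp.sample_ids, meta)
    if return_truth:
        return out, {
            "mixing_weights": weights,
            "baselines": baselines,
            "interferent_amplitude": interferent_amps,
        }
    return out


@dataclass
class SyntheticDataset:
    """Spectra + measured compositions + references + full ground truth."""

    spectra: SpectrumSet
    composition: CompositionTable  # measured (with extraction error)
    references: SpectrumSet  # protein / lipid / carbohydrate (model grid)
    truth: dict  # true compositions, design, outlier lists, noise model
    references_full: SpectrumSet | None = None  # incl. the 'other biomass' profile

    @property
    def calibration_ids(self):
        return self.truth["calibration_ids"]

    @property
    def external_ids(self):
        return self.truth["external_ids"]

    def write(self, out_dir):
        os.makedirs(out_dir, exist_ok=True)
        write_spectrum_matrix(self.spectra, os.path.join(out_dir, "spectra.csv"))
        write_composition(self.composition, os.path.join(out_dir, "composition.csv"))
        write_spectrum_matrix(self.references, os.path.join(out_dir, "references.csv"))
        truth = dict(self.truth)
        truth["true_composition"] = self.truth["true_composition"].to_dict(orient="index")
        truth.pop("baselines", None)  # per-sample arrays; kept in memory only
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, default=float)


PRESETS = {
    "noiseless": NoiseModel(),
    "paper_like": NoiseModel(
        additive_sigma=0.004,
        drift_scale=0.03,
        gamma=1.0,
        interferent_sigma=0.05,
        water_sigma=0.2,
        measurement_sigma=(2.6, 0.9, 4.0),
        replicate_sigma=0.03,
    ),
    "stress_test": NoiseModel(
        additive_sigma=0.01,
        drift_scale=0.30,
        gamma=1.0,
        interferent_sigma=0.05,
        water_sigma=0.2,
        measurement_sigma=(2.6, 0.9, 4.0),
        replicate_sigma=0.03,
    ),
}


def _default_outlier_lists(comp: CompositionTable):
    """Samples mirroring the judgment-based exclusions: late-starvation
    lipid/carb overestimates in one species and a day-0 carbohydrate
    underestimate in another."""
    lipids = ["CastRW10_d6_r1", "CastRW10_d8_r1"]
    carbs = [f"CastRW10_d{d}_r{r}" for d in (6, 8) for r in (1, 2)] + [
        "Cvul13-1_d0_r1",
        "Cvul13-1_d0_r2",
    ]
    present = set(comp.sample_ids)
    return [s for s in lipids if s in present], [s for s in carbs if s in present]


def make_dataset(preset: str = "paper_like", seed: int = 0, out_dir=None,
                 design=None, axis: np.ndarray = DEFAULT_AXIS) -> SyntheticDataset:
    """Bundle spectra, measured compositions, references and truth.

    ``noiseless`` turns every stochastic term off (and gamma = 0) so
    downstream models must be exact; ``paper_like`` reproduces the
    realistic regime (strong protein/lipid calibrations, weak direct
    carbohydrate calibration); ``stress_test`` adds heavy baseline
    drift to exercise the AsLS correction.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    base = PRESETS[preset]
    noise = NoiseModel(**{**asdict(base), "seed": int(seed)})
    design = design if design is not None else default_design()

    true_comp = make_trajectories(design, seed=seed,
                                  replicate_sigma=noise.replicate_sigma)
    refs_full = make_pure_spectra(axis=axis)
    spectra, spectra_truth = make_spectra(true_comp, refs_full, noise, return_truth=True)

    # measured composition = truth + extraction error (+ planted outliers)
    rng = np.random.default_rng((int(seed) + 7919) % 2**31)
    measured = true_comp.df.copy()
    cols = ("protein_pct", "lipid_pct", "carb_pct")
    for j, col in enumerate(cols):
        sig = noise.measurement_sigma[j]
        if sig > 0:
            measured[col] = measured[col] + rng.normal(0.0, sig, size=len(measured))
    lipid_out, carb_out = _default_outlier_lists(true_comp)
    if preset != "noiseless":
        # emulate failed extractions on the designated outlier samples
        measured.loc[lipid_out, "lipid_pct"] *= 1.8
        over = [s for s in carb_out if "_d0_" not in s]
        under = [s for s in carb_out if "_d0_" in s]
        measured.loc[over, "carb_pct"] *= 1.5
        measured.loc[under, "carb_pct"] *= 0.55
    for col in cols:
        measured[col] = measured[col].clip(0.0, 100.0)
    measured_comp = CompositionTable(measured)

    roles = true_comp.df["role"]
    cal_ids = list(roles.index[roles == "calibration"])
    ext_ids = list(roles.index[roles == "external"])
    refs = SpectrumSet(
        axis,
        refs_full.intensities[:3],
        ["protein", "lipid", "carbohydrate"],
    )
    truth = {
        "preset": preset,
        "seed": int(seed),
        "true_composition": true_comp.df,
        "calibration_ids": cal_ids,
        "external_ids": ext_ids,
        "lipid_outliers": lipid_out,
        "carb_outliers": carb_out,
        "noise": asdict(noise),
        "mixing_weights": spectra_truth["mixing_weights"],
        "baselines": spectra_truth["baselines"],
        "interferent_amplitude": spectra_truth["interferent_amplitude"],
    }
    ds = SyntheticDataset(spectra, measured_comp, refs, truth, references_full=refs_full)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
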
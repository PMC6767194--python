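import numpy as np
import pytest
from scipy.integrate import trapezoid

from algaftir.spectra_io import read_composition, read_spectrum_matrix
from algaftir.synthetic import (
    DEFAULT_AXIS,
    GaussianBand,
    NoiseModel,
    PureSpectrumModel,
    TrajectoryParams,
    make_dataset,
    make_pure_spectra,
    make_spectra,
    make_trajectories,
)


class TestPureSpectra:
    def test_single_band_peak_height(self):
        m = PureSpectrumModel("x", [GaussianBand(1600, 20, 0.8)])
        y = m.evaluate(DEFAULT_AXIS)
        assert y[DEFAULT_AXIS == 1600][0] == pytest.approx(0.8)

    def test_band_area_matches_closed_form(self):
        m = PureSpectrumModel("x", [GaussianBand(1600, 20, 0.8)])
        y = m.evaluate(DEFAULT_AXIS)
        exact = 0.8 * 20 * np.sqrt(2 * np.pi)
        assert abs(trapezoid(y, DEFAULT_AXIS) - exact) / exact < 1e-2

    def test_components_mutually_distinguishable(self):
        refs = make_pure_spectra()
        M = refs.intensities[:3]
        for i in range(3):
            for j in range(i + 1, 3):
                cos = M[i] @ M[j] / (np.linalg.norm(M[i]) * np.linalg.norm(M[j]))
                assert cos < 0.5

    def test_equal_total_areas(self):
        refs = make_pure_spectra(area=100.0)
        for row in refs.intensities:
            assert trapezoid(row, refs.axis) == pytest.approx(100.0, rel=1e-10)

    def test_no_leak_into_foreign_diagnostic_windows(self):
        refs = make_pure_spectra()
        get = {s: refs.intensities[i] for i, s in enumerate(refs.sample_ids)}
        windows = {
            "protein": (1580, 1700),
            "lipid": (1710, 1765),
            "carbohydrate": (960, 1130),
        }
        for comp, y in get.items():
            peak = y.max()
            for name, (lo, hi) in windows.items():
                if name == comp:
                    continue
                mask = (refs.axis >= lo) & (refs.axis <= hi)
                assert y[mask].max() < 1e-8 * peak, f"{comp} leaks into {name}"


class TestTrajectories:
    def test_default_design_counts(self):
        comp = make_trajectories(seed=0)
        roles = comp.df["role"]
        assert (roles == "calibration").sum() == 52
        assert (roles == "external").sum() == 6

    def test_protein_nonincreasing_within_reactor(self):
        comp = make_trajectories(seed=3)
        for (species, rep), grp in comp.df.groupby(["species", "replicate"]):
            p = grp.sort_values("day")["protein_pct"].to_numpy()
            assert np.all(np.diff(p) <= 1e-9)

    def test_lipid_accumulator_gains_lipid(self):
        comp = make_trajectories(seed=4)
        df = comp.df[comp.df["mode"] == "lipid_accumulator"]
        for (species, rep), grp in df.groupby(["species", "replicate"]):
            g = grp.sort_values("day")
            assert g["lipid_pct"].iloc[-1] > g["lipid_pct"].iloc[0]

    def test_ranges_respected(self):
        comp = make_trajectories(seed=5)
        v = comp.values()
        assert v["protein_pct"].between(9, 48).all()
        assert v["lipid_pct"].between(0, 13).all()
        assert v["carb_pct"].between(13, 55).all()

    def test_seed_reproducibility(self):
        a = make_trajectories(seed=6).df
        b = make_trajectories(seed=6).df
        assert a.equals(b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryParams("bad", "lipid_accumulator", lipid_ceiling=20.0)
        with pytest.raises(ValueError):
            TrajectoryParams("bad", "weird_mode")


class TestMakeSpectra:
    def test_noiseless_band_areas_linear_in_composition(self):
        from algaftir.bands import band_table

        comp = make_trajectories(seed=7)
        refs = make_pure_spectra()
        spectra = make_spectra(comp, refs, NoiseModel())
        table = band_table(spectra)
        for band, col in [
            ("protein_band", "protein_pct"),
            ("lipid_band", "lipid_pct"),
            ("carb_band", "carb_pct"),
        ]:
            x = comp.df[col].to_numpy()
            y = table[band].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert r**2 > 1 - 1e-10

    def test_doubling_protein_doubles_its_contribution(self):
        import pandas as pd

        from algaftir.spectra_io import CompositionTable

        refs = make_pure_spectra()
        df = pd.DataFrame(
            {"protein_pct": [10.0, 20.0], "lipid_pct": 0.0, "carb_pct": 20.0},
            index=["a", "b"],
        )
        spectra = make_spectra(CompositionTable(df), refs, NoiseModel())
        prot = refs.intensities[refs.sample_ids.index("protein")]
        window = np.abs(refs.axis - 1655) < 30  # other refs are zero here
        contrib_a = spectra.intensities[0][window]
        contrib_b = spectra.intensities[1][window]
        np.testing.assert_allclose(contrib_b, 2 * contrib_a, rtol=1e-10)

    def test_seeded_reproducibility(self):
        comp = make_trajectories(seed=8)
        refs = make_pure_spectra()
        nm = NoiseModel(additive_sigma=0.01, drift_scale=0.05, seed=9)
        a = make_spectra(comp, refs, nm)
        b = make_spectra(comp, refs, nm)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestMakeDataset:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            make_dataset("nope")

    def test_counts_and_outlier_lists(self, paper_like_ds):
        ds = paper_like_ds
        assert len(ds.calibration_ids) == 52
        assert len(ds.external_ids) == 6
        assert len(ds.truth["lipid_outliers"]) == 2
        assert len(ds.truth["carb_outliers"]) == 6
        assert set(ds.truth["lipid_outliers"]) <= set(ds.truth["carb_outliers"])

    def test_bundle_roundtrips_through_io(self, tmp_path, paper_like_ds):
        paper_like_ds.write(tmp_path)
        spectra = read_spectrum_matrix(tmp_path / "spectra.csv", "wide")
        comp = read_composition(tmp_path / "composition.csv")
        refs = read_spectrum_matrix(tmp_path / "references.csv", "wide")
        np.testing.assert_allclose(
            spectra.intensities, paper_like_ds.spectra.intensities, rtol=1e-12
        )
        assert comp.sample_ids == paper_like_ds.composition.sample_ids
        assert refs.sample_ids == ["protein", "lipid", "carbohydrate"]
        assert (tmp_path / "truth.json").exists()

    def test_determinism_under_seed(self):
        a = make_dataset("paper_like", seed=42)
        b = make_dataset("paper_like", seed=42)
        np.testing.assert_array_equal(a.spectra.intensities, b.spectra.intensities)
        assert a.composition.df.equals(b.composition.df)

    def test_truth_always_bundled(self, paper_like_ds):
        t = paper_like_ds.truth
        assert {"true_composition", "mixing_weights", "baselines",
                "calibration_ids", "external_ids"} <= set(t)
        assert len(t["baselines"]) == 58
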
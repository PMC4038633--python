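"""Spectrum file round trips, manifest loading and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from collafluor.spectra import (
    Spectrum,
    SpectrumError,
    SpectrumMeta,
    StudyDesign,
    average_replicates,
    average_study,
    load_study,
    read_spectrum,
    resample,
    write_spectrum,
)
from collafluor.simulate import simulate_study

from conftest import gaussian_spectrum


class TestReadWrite:
    def test_simple_three_row_csv(self, tmp_path):
        p = tmp_path / "s.csv"
        rows = "\n".join(f"{350 + i},{0.1 * (i + 1):.3f}" for i in range(20))
        p.write_text(rows + "\n")
        s = read_spectrum(p)
        assert len(s) == 20
        assert s.wavelengths[0] == 350 and s.intensities[0] == pytest.approx(0.1)

    def test_decreasing_wavelengths_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        rows = [f"{w},1.0" for w in list(range(350, 369)) + [368]]
        p.write_text("\n".join(rows))
        with pytest.raises(SpectrumError, match="increasing"):
            read_spectrum(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        rows = [f"{350 + i},0.5" for i in range(20)]
        rows[7] = "357,oops"
        p.write_text("\n".join(rows))
        with pytest.raises(SpectrumError, match=":8"):
            read_spectrum(p)

    def test_round_trip_preserves_values_and_metadata(self, tmp_path, rng):
        grid = np.arange(320.0, 551.0, 1.0)
        meta = SpectrumMeta(animal_id="lt03", group="laser_treated", day=10,
                            site=2, replicate=4, sex="male", age_weeks=8)
        s = Spectrum(grid, rng.random(len(grid)) * 3.7, meta)
        path = write_spectrum(s, tmp_path / "rt.csv")
        back = read_spectrum(path)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-6)
        np.testing.assert_array_equal(back.wavelengths, s.wavelengths)
        assert back.meta == meta

    def test_header_carries_optional_sex_field(self, tmp_path, two_peak_spectrum):
        s = two_peak_spectrum
        s.meta = SpectrumMeta(sex="male")
        path = write_spectrum(s, tmp_path / "m.csv")
        assert "# sex = male" in path.read_text()

    def test_short_grid_rejected(self):
        with pytest.raises(SpectrumError, match="too short"):
            Spectrum(np.arange(10.0), np.ones(10))

    def test_coverage_validation_flags_missing_band(self):
        s = Spectrum(np.arange(360.0, 380.0), np.ones(20))
        assert any("coverage" in w for w in s.validate())


class TestAveraging:
    def test_single_spectrum_identity(self, two_peak_spectrum):
        out = average_replicates([two_peak_spectrum])
        np.testing.assert_array_equal(out.intensities, two_peak_spectrum.intensities)

    def test_pointwise_mean(self, grid):
        a = Spectrum(grid, np.zeros(len(grid)))
        b = Spectrum(grid, np.full(len(grid), 2.0))
        out = average_replicates([a, b])
        np.testing.assert_array_equal(out.intensities, np.ones(len(grid)))

    def test_permutation_invariant(self, grid, rng):
        specs = [Spectrum(grid, rng.random(len(grid))) for _ in range(4)]
        m1 = average_replicates(specs).intensities
        m2 = average_replicates(specs[::-1]).intensities
        np.testing.assert_allclose(m1, m2, rtol=1e-14)

    def test_mean_recovers_template_within_noise(self, grid, rng):
        template = gaussian_spectrum(grid)
        sigma = 0.05
        noisy = [
            Spectrum(grid, template.intensities + rng.normal(0, sigma, len(grid)))
            for _ in range(4)
        ]
        mean = average_replicates(noisy).intensities
        # 4 standard errors of the 4-replicate mean, pointwise over 231 points
        assert np.all(np.abs(mean - template.intensities) < 4 * sigma / 2)

    def test_mismatched_grids_error(self, grid):
        a = Spectrum(grid, np.ones(len(grid)))
        b = Spectrum(grid + 0.5, np.ones(len(grid)))
        with pytest.raises(SpectrumError, match="grids differ"):
            average_replicates([a, b])

    def test_two_stage_averaging_unit_is_animal(self):
        design = StudyDesign(groups=("laser_treated",), animals_per_group=2,
                             days=(0, 5), sites=4, replicates=4)
        ds = simulate_study(design, seed=9)
        animal = average_study(ds, level="animal")
        assert len(animal) == 2 * 2  # animals x days
        site = average_study(ds, level="site")
        assert len(site) == 2 * 2 * 4

    def test_resample_linear(self, two_peak_spectrum):
        new_grid = np.arange(350.0, 461.0, 0.5)
        out = resample(two_peak_spectrum, new_grid)
        # on-grid points are preserved exactly by linear interpolation
        on = np.isin(new_grid, two_peak_spectrum.wavelengths)
        orig = np.isin(two_peak_spectrum.wavelengths, new_grid)
        np.testing.assert_allclose(
            out.intensities[on], two_peak_spectrum.intensities[orig]
        )


class TestLoadStudy:
    def test_complete_small_study_has_no_missing_cells(self, tmp_path):
        design = StudyDesign(groups=("unwounded_control", "laser_treated"),
                             animals_per_group=2, days=(0, 5), sites=2,
                             replicates=2)
        simulate_study(design, seed=2, out_dir=tmp_path)
        ds = load_study(tmp_path / "manifest.csv", design)
        assert len(ds) == design.n_spectra
        assert ds.missing_cells().empty
        cc = ds.cell_counts()
        assert cc.n_spectra.sum() == len(ds)

    def test_duplicate_replicate_row_raises(self, tmp_path):
        design = StudyDesign(groups=("laser_treated",), animals_per_group=1,
                             days=(0,), sites=2, replicates=2)
        simulate_study(design, seed=3, out_dir=tmp_path)
        man = pd.read_csv(tmp_path / "manifest.csv")
        man = pd.concat([man, man.iloc[[0]]], ignore_index=True)
        man.to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.raises(SpectrumError, match="duplicate"):
            load_study(tmp_path / "manifest.csv")

    def test_unknown_group_label_raises(self, tmp_path):
        design = StudyDesign(groups=("laser_treated",), animals_per_group=1,
                             days=(0,), sites=1, replicates=2)
        simulate_study(design, seed=4, out_dir=tmp_path)
        man = pd.read_csv(tmp_path / "manifest.csv")
        man.loc[0, "group"] = "mystery_group"
        man.to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.raises(SpectrumError, match="unknown group"):
            load_study(tmp_path / "manifest.csv")

    def test_empty_manifest_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "manifest.csv"
        p.write_text("file,animal_id,group,day,site,replicate\n")
        with pytest.warns(UserWarning, match="empty manifest"):
            ds = load_study(p)
        assert len(ds) == 0
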
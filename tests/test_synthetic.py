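import io

import numpy as np
import pytest

from specstarch.errors import ConfigError, DataError
from specstarch.spectra_io import write_reference_csv, write_spectra_csv
from specstarch.synthetic import (
    SimulationConfig,
    clean_spectrum,
    plant_outlier,
    simulate_reference,
    simulate_spectra,
)


def _csv_bytes(writer, obj):
    buf = io.StringIO()
    writer(obj, buf)
    return buf.getvalue()


class TestConfigValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(var_g=-1.0)

    def test_band_lists_must_match(self):
        with pytest.raises(ConfigError):
            SimulationConfig(band_centers=(880.0,), band_widths=(10.0, 10.0),
                             band_loadings=(0.001,))

    def test_unknown_design_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(design="LATIN_SQUARE")

    def test_scan_noise_default_is_tenth_of_noise(self):
        config = SimulationConfig(noise_sd=0.01)
        assert config.scan_noise_sd == pytest.approx(0.001)


class TestReference:
    def test_degenerate_variances_give_exact_mean(self):
        config = SimulationConfig(
            n_trials=2, genotypes_per_trial=10, var_g=0.0, var_rep=0.0,
            var_block=0.0, var_e=0.0, starch_mean=25.0, seed=1,
        )
        reference = simulate_reference(config)
        assert np.all(reference.data["starch"].to_numpy() == 25.0)

    def test_genotype_mean_variance_matches_model(self):
        # var of genotype means should approach var_g + var_e / n_reps = 27
        variances = []
        for seed in range(200):
            config = SimulationConfig(
                n_trials=1, genotypes_per_trial=100, n_reps=2, starch_mean=25.0,
                var_g=25.0, var_rep=0.0, var_block=0.0, var_e=4.0, seed=seed,
            )
            ref = simulate_reference(config)
            means = ref.data.groupby("genotype_id")["starch"].mean()
            variances.append(means.var(ddof=1))
        assert np.mean(variances) == pytest.approx(27.0, rel=0.15)

    def test_variance_decomposition_recovery(self):
        # ANOVA-style decomposition over 100 seeds recovers the configured
        # components within 15% relative error (200 genotypes x 2 reps).
        g_hat, e_hat = [], []
        for seed in range(100):
            config = SimulationConfig(
                n_trials=1, genotypes_per_trial=200, n_reps=2, var_g=20.0,
                var_rep=0.0, var_block=1.0, var_e=4.0, seed=seed,
            )
            data = simulate_reference(config).data
            gm = data["starch"].mean()
            by_g = data.groupby("genotype_id")["starch"].transform("mean")
            by_b = data.groupby("block")["starch"].transform("mean")
            resid = data["starch"] - by_g - by_b + gm
            mse = (resid**2).sum() / ((200 - 1) * (2 - 1))
            ms_g = 2 * ((data.groupby("genotype_id")["starch"].mean() - gm) ** 2).sum() / 199
            g_hat.append((ms_g - mse) / 2)
            e_hat.append(mse)
        assert np.mean(g_hat) == pytest.approx(20.0, rel=0.15)
        assert np.mean(e_hat) == pytest.approx(4.0, rel=0.15)

    def test_shared_genotypes_across_trials(self):
        config = SimulationConfig(n_trials=3, genotypes_per_trial=20,
                                  shared_genotype_fraction=0.5, seed=3)
        data = simulate_reference(config).data
        per_trial = data.groupby("trial_id")["genotype_id"].agg(set)
        common = set.intersection(*per_trial.tolist())
        assert len(common) == 10

    def test_deterministic_csv_output(self):
        config = SimulationConfig(n_trials=2, genotypes_per_trial=15, seed=77)
        a = _csv_bytes(write_reference_csv, simulate_reference(config))
        b = _csv_bytes(write_reference_csv, simulate_reference(config))
        assert a == b


class TestSpectra:
    def test_closed_form_at_band_center(self):
        config = SimulationConfig(
            n_trials=1, genotypes_per_trial=5, var_g=4.0, var_rep=0.0,
            var_block=0.0, var_e=0.0, noise_sd=0.0, scan_noise_sd=0.0,
            scatter_slope_sd=0.0, scatter_offset_sd=0.0,
            band_centers=(900.0,), band_widths=(10.0,), band_loadings=(0.004,),
            baseline_level=0.3, scans_per_sample=1, seed=5,
        )
        reference = simulate_reference(config)
        spectra = simulate_spectra(reference, config)
        j = int(np.flatnonzero(spectra.wavelengths == 900)[0])
        for i, starch in enumerate(reference.data["starch"]):
            water = (config.water_level - config.water_per_starch * starch) * np.exp(
                -0.5 * ((900 - config.water_band_center) / config.water_band_width) ** 2
            )
            expected = 0.3 + 0.004 * starch + water
            assert spectra.reflectance[i, j] == pytest.approx(expected, abs=1e-12)

    def test_difference_confined_to_band(self):
        # single band, constant water term: the starch contrast lives in the
        # band and peaks exactly at its centre
        config = SimulationConfig(
            n_trials=1, genotypes_per_trial=2, var_g=0.0, var_rep=0.0,
            var_block=0.0, var_e=0.0, noise_sd=0.0, scan_noise_sd=0.0,
            scatter_slope_sd=0.0, scatter_offset_sd=0.0,
            band_centers=(900.0,), band_widths=(12.0,), band_loadings=(0.004,),
            water_per_starch=0.0, scans_per_sample=1, n_reps=1, seed=5,
        )
        reference = simulate_reference(config)
        reference.data.loc[0, "starch"] = 10.0
        reference.data.loc[1, "starch"] = 40.0
        spectra = simulate_spectra(reference, config)
        diff = np.abs(spectra.reflectance[1] - spectra.reflectance[0])
        wl = spectra.wavelengths
        outside = np.abs(wl - 900) > 7 * 12.0
        assert np.all(diff[outside] < 1e-9)
        assert wl[np.argmax(diff)] == 900

    def test_linearity_without_noise(self):
        config = SimulationConfig(noise_sd=0.0, scan_noise_sd=0.0,
                                  scatter_slope_sd=0.0, scatter_offset_sd=0.0)
        s1 = clean_spectrum(10.0, config)
        s2 = clean_spectrum(20.0, config)
        s3 = clean_spectrum(30.0, config)
        np.testing.assert_allclose(s3 - s2, s2 - s1, atol=1e-12)

    def test_nonnegative_under_defaults(self):
        config = SimulationConfig(n_trials=1, genotypes_per_trial=50, seed=8)
        spectra = simulate_spectra(simulate_reference(config), config)
        assert spectra.reflectance.min() > 0

    def test_scan_count_and_metadata(self, small_config, small_dataset):
        reference, spectra = small_dataset
        assert spectra.n_samples == len(reference.data) * small_config.scans_per_sample
        assert set(spectra.meta["scan_index"]) == {1, 2, 3}

    def test_deterministic_csv_output(self):
        config = SimulationConfig(n_trials=1, genotypes_per_trial=10, seed=13)
        ref = simulate_reference(config)
        a = _csv_bytes(write_spectra_csv, simulate_spectra(ref, config))
        b = _csv_bytes(write_spectra_csv, simulate_spectra(ref, config))
        assert a == b

    def test_missing_starch_rejected(self, small_dataset):
        reference, _ = small_dataset
        broken = reference.copy()
        broken.data.loc[0, "starch"] = np.nan
        config = SimulationConfig()
        with pytest.raises(DataError):
            simulate_spectra(broken, config)


class TestPlantOutlier:
    def test_zero_magnitude_is_identity(self, small_dataset):
        reference, spectra = small_dataset
        planted = plant_outlier(spectra, reference.data["sample_id"].iloc[0], 0.0)
        assert planted == spectra

    def test_unknown_id_rejected(self, small_dataset):
        _, spectra = small_dataset
        with pytest.raises(DataError):
            plant_outlier(spectra, "nope", 5.0)

    def test_only_target_rows_change(self, small_dataset):
        reference, spectra = small_dataset
        sid = reference.data["sample_id"].iloc[3]
        planted = plant_outlier(spectra, sid, 4.0)
        changed = np.any(planted.reflectance != spectra.reflectance, axis=1)
        mask = (spectra.meta["sample_id"] == sid).to_numpy()
        np.testing.assert_array_equal(changed, mask)
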
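"""Forward-model generators: inverse consistency, determinism, noise scaling."""

import numpy as np
import pytest

from photosar.dose_response import fit_ec50, normalize_viability
from photosar.lifetime import fit_decay
from photosar.partition import log_p
from photosar.photophysics import absorbed_light, bleach_slope, singlet_oxygen_qy
from photosar.spectra import q_band_features
from photosar.synthetic import (
    GeneratorConfig,
    gen_dose_response,
    gen_dpbf_experiment,
    gen_panel,
    gen_partition_pair,
    gen_spectra_pair,
    gen_tcspc_decay,
)


class TestSpectraPair:
    def test_monomeric_pair_recovers_position_and_epsilon(self):
        absorption, emission = gen_spectra_pair(681.0, 9.0, 2.4e5, 1e-6)
        f = q_band_features(absorption, window_nm=(600, 760))
        assert f.maxima_nm == (681.0,)
        assert not f.split
        assert f.epsilon_M1cm1 == pytest.approx(2.4e5, rel=1e-4)
        em_peak = emission.wavelengths_nm[int(np.argmax(emission.values))]
        assert em_peak == pytest.approx(690.0, abs=0.5)

    def test_aggregate_fraction_equals_index(self):
        mono, _ = gen_spectra_pair(680.0, 10.0, 2.0e5, 1e-6, aggregate_fraction=0.0)
        agg, _ = gen_spectra_pair(680.0, 10.0, 2.0e5, 1e-6, aggregate_fraction=0.6)
        f = q_band_features(agg, window_nm=(550, 800), monomer_reference=mono)
        assert f.aggregation_index == pytest.approx(0.6, abs=0.01)

    def test_split_pair_detected(self):
        absorption, _ = gen_spectra_pair(
            694.0, 9.0, 1.0e5, 1e-6, split_second_peak=(662.0, 1.0)
        )
        f = q_band_features(absorption, window_nm=(600, 760))
        assert f.split
        assert sorted(f.maxima_nm) == [662.0, 694.0]

    def test_aggregate_fraction_bounds(self):
        with pytest.raises(ValueError, match="aggregate_fraction"):
            gen_spectra_pair(680.0, 10.0, 2.0e5, 1e-6, aggregate_fraction=1.5)


class TestDpbfExperiment:
    def _spectra(self):
        a_s, _ = gen_spectra_pair(700.0, 10.0, 2.0e5, 1e-6)
        a_r, _ = gen_spectra_pair(670.0, 9.0, 2.8e5, 1e-6)
        wl = a_s.wavelengths_nm
        from photosar.spectra import Spectrum

        profile = Spectrum(kind="transmittance", wavelengths_nm=wl, values=np.ones_like(wl))
        return a_s, a_r, profile

    def test_identity_configuration_identical_series(self):
        a_s, _, profile = self._spectra()
        s, r = gen_dpbf_experiment(0.56, 0.56, a_s, a_s, profile)
        assert np.allclose(s.absorbance_415, r.absorbance_415)

    def test_slope_ratio_follows_yield_ratio(self):
        a_s, _, profile = self._spectra()
        # identical spectra: the absorbed-light correction cancels
        s, r = gen_dpbf_experiment(0.70, 0.56, a_s, a_s, profile)
        assert bleach_slope(s) / bleach_slope(r) == pytest.approx(1.25, rel=1e-9)

    @pytest.mark.parametrize("phi_true", [0.05, 0.26, 0.70, 0.90])
    def test_noise_free_round_trip(self, phi_true):
        a_s, a_r, profile = self._spectra()
        s, r = gen_dpbf_experiment(phi_true, 0.56, a_s, a_r, profile)
        IaT_S = absorbed_light(a_s, profile).total_IaT
        IaT_R = absorbed_light(a_r, profile).total_IaT
        res = singlet_oxygen_qy(bleach_slope(s), bleach_slope(r), IaT_S, IaT_R, 0.56)
        assert res.phi == pytest.approx(phi_true, rel=1e-6)


class TestDeterminismAndNoise:
    def test_same_seed_identical_decay(self):
        a = gen_tcspc_decay([2.0], [100.0], cfg=GeneratorConfig(seed=12))
        b = gen_tcspc_decay([2.0], [100.0], cfg=GeneratorConfig(seed=12))
        assert np.array_equal(a.counts, b.counts)

    def test_different_seed_differs(self):
        a = gen_tcspc_decay([2.0], [100.0], cfg=GeneratorConfig(seed=12))
        b = gen_tcspc_decay([2.0], [100.0], cfg=GeneratorConfig(seed=13))
        assert not np.array_equal(a.counts, b.counts)

    def test_same_seed_identical_plate(self):
        a = gen_dose_response(3.8, cfg=GeneratorConfig(seed=5))
        b = gen_dose_response(3.8, cfg=GeneratorConfig(seed=5))
        assert np.array_equal(a.viability_raw, b.viability_raw)

    def test_estimator_sd_decreases_with_noise(self):
        # EC50 spread across seeds shrinks monotonically as plate noise -> 0
        sds = []
        for noise in (10.0, 5.0, 1.0):
            estimates = []
            for seed in range(12):
                table = gen_dose_response(
                    3.8, noise_sd_pct=noise, cfg=GeneratorConfig(seed=seed)
                )
                res = fit_ec50(normalize_viability(table), table.concentrations_nM)
                estimates.append(res.ec50_nM)
            sds.append(np.std(estimates))
        assert sds[0] > sds[1] > sds[2]

    def test_decay_expectation_matches_model_noise_free(self):
        cfg = GeneratorConfig(poisson_counts=False, tcspc_background_counts=0.0)
        tr = gen_tcspc_decay([3.14], [100.0], peak_counts=1e4, cfg=cfg)
        expected = 1e4 * np.exp(-tr.time_ns / 3.14)
        assert np.allclose(tr.counts, expected, rtol=1e-12)

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum to 100"):
            gen_tcspc_decay([1.0, 2.0], [50.0, 40.0])


class TestDoseResponseGenerator:
    def test_killed_anchor_normalizes_to_zero(self):
        table = gen_dose_response(3.8, cfg=GeneratorConfig(seed=1, viability_noise_pct=0.0))
        pct = normalize_viability(table)
        # the highest concentration is 1.75 dex above EC50: viability
        # should be near bottom but the anchors themselves are exact
        span = table.untreated_signal - table.killed_signal
        assert 100 * (table.killed_signal - table.killed_signal) / span == 0.0
        assert 100 * (table.untreated_signal - table.killed_signal) / span == 100.0
        assert pct.min() >= -1e-9

    def test_default_grid_brackets_truth(self):
        table = gen_dose_response(3.8, cfg=GeneratorConfig(seed=1))
        assert table.concentrations_nM.min() < 3.8 < table.concentrations_nM.max()


class TestPanelGenerator:
    def test_effect_size_detected(self):
        from photosar.sar import compare_groups

        panel = gen_panel(6, {"charge=cationic": -1.0, "charge=anionic": 0.0},
                          cfg=GeneratorConfig(seed=0))
        res = compare_groups(panel, {"charge": "cationic"}, {"charge": "anionic"}, "HeLa")
        assert res.p_value < 0.01

    def test_small_group_flagged(self):
        from photosar.sar import compare_groups

        panel = gen_panel(2, {"charge=cationic": -1.0}, cfg=GeneratorConfig(seed=0))
        panel += gen_panel(5, {"charge=anionic": 0.0}, cfg=GeneratorConfig(seed=1))
        res = compare_groups(panel, {"charge": "cationic"}, {"charge": "anionic"}, "HeLa")
        assert res.small_group_flag

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="at least one group"):
            gen_panel(3, {})


class TestPartitionGenerator:
    def test_equal_areas_at_zero(self):
        exp = gen_partition_pair(0.0)
        assert log_p(exp) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("lp", [3.52, -2.70, 0.53])
    def test_round_trip(self, lp):
        assert log_p(gen_partition_pair(lp)) == pytest.approx(lp, abs=1e-9)
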
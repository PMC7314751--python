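"""Acquisition simulator: AGC injection-time law, determinism, stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fimsopt.chem import C13_C12_SPACING
from fimsopt.simulate import (
    AcquisitionConfig,
    DensityProfile,
    IonSpecies,
    cohort_intensity_matrix,
    generate_metabolome,
    injection_time,
    simulate_injection_series,
    simulate_scan,
)


class TestInjectionTime:
    def setup_method(self):
        self.config = AcquisitionConfig(agc_target=5e6, max_injection_time_ms=100.0)

    @pytest.mark.parametrize(
        "flux,expected",
        [(1e5, 50.0), (1e4, 100.0), (5e4, 100.0), (1e7, 0.5), (0.0, 100.0)],
    )
    def test_closed_form(self, flux, expected):
        assert injection_time(flux, self.config) == expected

    @given(st.floats(min_value=0, max_value=1e12), st.floats(min_value=1, max_value=1e12))
    @settings(derandomize=True, max_examples=200)
    def test_equals_min_form_and_capped(self, a, b):
        ta, tb = injection_time(a, self.config), injection_time(b, self.config)
        assert ta <= 100.0
        if a > 0:
            assert ta == min(100.0, 5e6 / a)
        if a <= b:  # monotone non-increasing in flux
            assert ta >= tb


class TestGenerateMetabolome:
    def test_point_density_single_compound(self):
        met = generate_metabolome(1, DensityProfile.point(500.0), seed=3)
        mzs = sorted(i.mz for i in met.compounds[0].ions if i.role in ("monoisotopic", "13C"))
        assert mzs[0] == pytest.approx(500.0, abs=1e-9)
        assert mzs[1] - mzs[0] == pytest.approx(C13_C12_SPACING, abs=1e-9)

    def test_satellite_flux_follows_carbon_count(self):
        met = generate_metabolome(50, seed=5)
        for c in met.compounds:
            sat = [i for i in c.ions if i.role == "13C"][0]
            expected = c.base_flux * (1 - (1 - 0.0107) ** c.carbon_count)
            assert sat.flux == pytest.approx(expected, rel=1e-9)

    def test_seed_determinism(self):
        a = generate_metabolome(200, seed=9)
        b = generate_metabolome(200, seed=9)
        assert [i.mz for i in a.all_ions()] == [i.mz for i in b.all_ions()]
        assert [i.flux for i in a.all_ions()] == [i.flux for i in b.all_ions()]

    def test_bimodal_density_skew(self):
        met = generate_metabolome(1000, seed=1)
        mono = np.array([c.monoisotopic_mz for c in met.compounds])
        dense = ((mono >= 450) & (mono < 550)).sum()
        sparse = ((mono >= 1600) & (mono < 1700)).sum()
        assert dense >= 3 * max(sparse, 1)

    def test_flux_spans_three_decades(self):
        met = generate_metabolome(500, seed=2)
        flux = np.array([c.base_flux for c in met.compounds])
        assert np.log10(flux.max() / flux.min()) >= 3.0


class TestSimulateScan:
    def test_peaks_inside_range_and_above_floor(self, small_metabolome, noisy_config):
        ev = simulate_scan(small_metabolome, (400.0, 600.0), noisy_config)
        assert ev.injection_time_ms <= noisy_config.max_injection_time_ms
        assert np.all((ev.mz >= 400.0) & (ev.mz < 600.0))
        assert np.all(ev.intensity >= noisy_config.detection_floor)

    def test_empty_range_runs_at_max_time(self, small_metabolome, noiseless_config):
        ev = simulate_scan(small_metabolome, (3000.0, 3010.0), noiseless_config)
        assert ev.injection_time_ms == noiseless_config.max_injection_time_ms
        assert ev.n_peaks == 0

    def test_blank_contains_only_background(self, small_metabolome, noiseless_config):
        ev = simulate_scan(small_metabolome, (70.0, 2500.0), noiseless_config, blank=True)
        background_mzs = {i.mz for i in small_metabolome.background_ions}
        assert set(np.round(ev.mz, 6)).issubset({round(m, 6) for m in background_mzs})

    def test_stitching_never_loses_ions(self, small_metabolome, noiseless_config):
        """Noise off: ions seen in one wide scan are a subset of the union
        over any partition of that range scanned separately."""
        wide = simulate_scan(small_metabolome, (70.0, 2500.0), noiseless_config)
        parts = [(70.0, 300.0), (300.0, 520.0), (520.0, 1100.0), (1100.0, 2500.0)]
        stitched = np.concatenate(
            [simulate_scan(small_metabolome, p, noiseless_config).mz for p in parts]
        )
        assert set(wide.mz).issubset(set(stitched))

    def test_in_range_spike_shortens_injection_and_masks_ions(
        self, small_metabolome, noiseless_config
    ):
        spike = [IonSpecies(500.0, 1e8, "negative", None, "spike")]
        base = simulate_scan(small_metabolome, (400.0, 600.0), noiseless_config)
        spiked = simulate_scan(small_metabolome, (400.0, 600.0), noiseless_config, spike=spike)
        assert spiked.injection_time_ms < base.injection_time_ms
        non_spike = spiked.mz[np.abs(spiked.mz - 500.0) > 1e-6]
        assert len(non_spike) <= base.n_peaks

    def test_spike_monotone_masking(self, small_metabolome, noiseless_config):
        counts = []
        for flux in (0.0, 1e6, 1e7, 1e8):
            spike = [IonSpecies(500.0, flux, "negative", None, "spike")] if flux else None
            ev = simulate_scan(small_metabolome, (400.0, 600.0), noiseless_config, spike=spike)
            counts.append(np.sum(np.abs(ev.mz - 500.0) > 1e-6))
        assert counts == sorted(counts, reverse=True)


class TestInjectionSeries:
    def test_cardinality(self, small_metabolome, noisy_config):
        events = simulate_injection_series(
            small_metabolome, [(70.0, 500.0), (500.0, 2500.0)], noisy_config
        )
        assert len(events) == 12 * 2
        assert sum(e.blank for e in events) == 6 * 2

    def test_zero_noise_bio_scans_identical(self, small_metabolome, noiseless_config):
        events = simulate_injection_series(
            small_metabolome, [(70.0, 2500.0)], noiseless_config, n_bio=6, n_blank=0
        )
        first = events[0]
        for ev in events[1:]:
            np.testing.assert_array_equal(ev.mz, first.mz)
            np.testing.assert_array_equal(ev.intensity, first.intensity)

    def test_fixed_seed_bitwise_identical(self, small_metabolome):
        cfg = AcquisitionConfig(seed=123)
        a = simulate_injection_series(small_metabolome, [(400.0, 600.0)], cfg)
        b = simulate_injection_series(small_metabolome, [(400.0, 600.0)], cfg)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.mz, eb.mz)
            np.testing.assert_array_equal(ea.intensity, eb.intensity)


class TestCohortMatrix:
    def test_shape_and_determinism(self, small_metabolome):
        m1 = cohort_intensity_matrix(small_metabolome, 20, seed=4)
        m2 = cohort_intensity_matrix(small_metabolome, 20, seed=4)
        assert m1.shape == (len(small_metabolome.analyte_ions()), 20)
        assert m1.equals(m2)

    def test_satellites_track_parent(self, small_metabolome):
        mat = cohort_intensity_matrix(small_metabolome, 40, noise_cv=0.01, seed=4)
        c = small_metabolome.compounds[0]
        mono, sat = c.ions[0].mz, c.ions[1].mz
        r = np.corrcoef(mat.loc[mono], mat.loc[sat])[0, 1]
        assert r > 0.99
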
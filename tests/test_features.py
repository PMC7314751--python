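"""Peak grouping, the four-criterion reproducibility filter, and binning."""

import numpy as np
import pytest

from conftest import make_peak_table
from fimsopt.features import (
    FilterCriteria,
    apply_reproducibility_filter,
    detect_features,
    feature_distribution,
    group_peaks,
)
from fimsopt.msio import peak_table_from_events
from fimsopt.ranges import tiling_ranges
from fimsopt.simulate import simulate_injection_series


def peaks_at(*mzs):
    return make_peak_table([(i, False, mz, 2000.0) for i, mz in enumerate(mzs)])


class TestGroupPeaks:
    def test_within_tolerance_merges(self):
        out = group_peaks(peaks_at(500.0000, 500.0020), 5.0)
        assert out["group_id"].nunique() == 1
        assert out["ref_mz"].iloc[0] == pytest.approx(500.0010)

    def test_outside_tolerance_splits(self):
        out = group_peaks(peaks_at(500.0000, 500.0050), 5.0)
        assert out["group_id"].nunique() == 2

    def test_chain_splits_at_running_median(self):
        # third peak is >5 ppm from the median of the first two
        out = group_peaks(peaks_at(500.0000, 500.0022, 500.0044), 5.0)
        assert out["group_id"].tolist() == [0, 0, 1]

    def test_row_order_invariance(self):
        mzs = [500.0000, 500.0022, 500.0044, 700.1, 700.10005, 1200.5]
        a = group_peaks(peaks_at(*mzs), 5.0)
        b = group_peaks(peaks_at(*reversed(mzs)), 5.0)
        assert a["group_id"].tolist() == b["group_id"].tolist()
        assert a["mz"].tolist() == b["mz"].tolist()

    def test_empty_input(self):
        out = group_peaks(peaks_at(), 5.0)
        assert len(out) == 0 and "group_id" in out.columns

    def test_members_within_tolerance_of_reference(self):
        rng = np.random.default_rng(0)
        mzs = np.concatenate([m * (1 + rng.normal(0, 1e-6, 8)) for m in (200.0, 900.0, 1500.0)])
        out = group_peaks(peaks_at(*mzs), 5.0)
        ppm = (out["mz"] - out["ref_mz"]).abs() / out["ref_mz"] * 1e6
        assert (ppm <= 5.0 + 1e-9).all()


def table_with_intensities(bio_intensities, blank_max, mz=500.0):
    rows = [(i, False, mz, v) for i, v in enumerate(bio_intensities)]
    if blank_max is not None:
        rows.append((90, True, mz, blank_max))
    return make_peak_table(rows)


class TestReproducibilityFilter:
    INT = [1200.0, 1100.0, 1300.0, 1250.0, 1150.0, 1220.0]

    def run(self, table, **crit):
        grouped = group_peaks(table, 5.0)
        return apply_reproducibility_filter(grouped, FilterCriteria(**crit), n_bio=6, n_blank=6)

    def test_passing_feature_statistics(self):
        out = self.run(table_with_intensities(self.INT, 200.0))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["median_intensity"] == pytest.approx(1210.0)
        assert row["snr"] == pytest.approx(6.05)
        assert row["rsd_pct"] == pytest.approx(5.92, abs=0.01)
        assert row["presence"] == 6

    def test_snr_failure(self):
        out = self.run(table_with_intensities(self.INT, 400.0))
        assert len(out) == 0  # SNR 3.025 < 4

    def test_presence_failure_five_of_six(self):
        out = self.run(table_with_intensities(self.INT[:5], 100.0))
        assert len(out) == 0  # ceil(0.9*6) = 6

    def test_all_blank_zero_uses_unit_floor(self):
        out = self.run(table_with_intensities(self.INT, None))
        assert len(out) == 1
        assert out.iloc[0]["snr"] == pytest.approx(1210.0)

    def test_n_bio_zero_rejected(self):
        grouped = group_peaks(table_with_intensities(self.INT, 100.0), 5.0)
        with pytest.raises(ValueError):
            apply_reproducibility_filter(grouped, FilterCriteria(), n_bio=0, n_blank=6)

    @pytest.mark.parametrize(
        "tighter",
        [
            {"presence_fraction": 1.0},
            {"min_median_intensity": 5000.0},
            {"min_snr": 20.0},
            {"max_rsd_pct": 1.0},
        ],
    )
    def test_filter_monotone_in_each_threshold(self, tighter, small_metabolome, noisy_config):
        events = simulate_injection_series(
            small_metabolome, tiling_ranges(70, 2500, 100), noisy_config
        )
        peaks = peak_table_from_events(events)
        base = detect_features(peaks, FilterCriteria(), 6, 6)
        strict = detect_features(peaks, FilterCriteria(**tighter), 6, 6)
        assert len(strict) <= len(base)


class TestFeatureDistribution:
    def test_worked_example(self):
        hist = feature_distribution([70.5, 70.9, 71.2], 70, 72)
        assert hist.counts.tolist() == [2.0, 1.0]
        assert hist.cumulative.tolist() == [0.0, 2.0, 3.0]

    def test_empty(self):
        hist = feature_distribution([], 70, 80)
        assert hist.total == 0 and len(hist) == 10

    def test_outside_features_warn_and_are_dropped(self):
        with pytest.warns(UserWarning, match="outside"):
            hist = feature_distribution([50.0, 75.5], 70, 80)
        assert hist.total == 1

    def test_against_bruteforce_bin_counter(self):
        rng = np.random.default_rng(7)
        mzs = rng.uniform(70, 2500, 400)
        hist = feature_distribution(mzs, 70, 2500)
        brute = np.zeros(2430)
        for m in mzs:
            brute[int(np.floor(m)) - 70] += 1
        np.testing.assert_array_equal(hist.counts, brute)
        assert hist.cumulative[-1] == hist.total == 400


class TestEndToEndRecovery:
    def test_every_truth_ion_becomes_one_feature_without_noise(
        self, small_metabolome, noiseless_config
    ):
        """CV=0 and narrow tiles: every sufficiently intense ground-truth ion
        in the scanned interval yields exactly one reproducible feature."""
        tiles = tiling_ranges(70, 2500, 20)
        events = simulate_injection_series(small_metabolome, tiles, noiseless_config)
        feats = detect_features(peak_table_from_events(events), FilterCriteria(), 6, 6)
        feat_mzs = feats["ref_mz"].to_numpy()

        cfg = noiseless_config
        expected = []
        for ion in small_metabolome.analyte_ions():
            if not 70 <= ion.mz < 2500:
                continue
            # recompute this ion's accumulated intensity in its own tile
            tile = next(rg for rg in tiles.ranges if rg[0] <= ion.mz < rg[1])
            esi = 1.0 / (
                1.0 + cfg.esi_suppression_k
                * sum(i.flux for i in small_metabolome.all_ions())
            )
            phi = sum(
                i.flux * esi for i in small_metabolome.all_ions()
                if tile[0] <= i.mz < tile[1]
            )
            t = min(cfg.max_injection_time_ms, cfg.agc_target / phi)
            if ion.flux * esi * t > max(cfg.detection_floor, 1000.0):
                expected.append(ion.mz)
        for mz in expected:
            assert np.sum(np.abs(feat_mzs - mz) / mz < 5e-6) == 1
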
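"""iPLS, forward-selection iPLS, edge micro-optimisation, and MWPLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specselect.dataset import SpectraDataset
from specselect.interval import (
    Interval,
    fs_ipls,
    ipls,
    make_intervals,
    micro_optimize,
    mwpls,
    mwpls_select,
)
from specselect.synthetic import SimConfig, generate
from specselect.validation import mccv


def _single_peak_ds(seed=0, noise=2e-3):
    cfg = SimConfig(
        wavenumber_start=900,
        wavenumber_end=1500,
        spacing=2,
        analyte_peaks=[(1125.0, 15.0, 1.5e-3)],
        background_peaks=[(990.0, 300.0, 0.3), (1430.0, 120.0, 0.6)],
        noise_sd=noise,
        seed=seed,
    )
    return generate(cfg)


class TestMakeIntervals:
    def test_forced_sizes(self):
        sizes = [iv.width for iv in make_intervals(10, 3)]
        assert sizes == [4, 3, 3]

    def test_design_scale_multiset(self):
        # brute force: the only multiset with max-min <= 1 summing to 3151
        sizes = [iv.width for iv in make_intervals(3151, 20)]
        assert sorted(set(sizes)) == [157, 158]
        assert sizes.count(158) == 11 and sizes.count(157) == 9
        assert sum(sizes) == 3151

    def test_single_interval_identity(self):
        (iv,) = make_intervals(17, 1)
        assert (iv.start_index, iv.end_index) == (0, 16)

    @pytest.mark.parametrize("p", [2, 7, 23, 60])
    def test_exact_partition_for_all_k(self, p):
        for k in range(1, p + 1):
            ivs = make_intervals(p, k)
            covered = np.concatenate([iv.indices() for iv in ivs])
            np.testing.assert_array_equal(covered, np.arange(p))
            widths = [iv.width for iv in ivs]
            assert max(widths) - min(widths) <= 1
            assert widths == sorted(widths, reverse=True)

    def test_too_many_intervals(self):
        with pytest.raises(ValueError):
            make_intervals(5, 6)

    @settings(derandomize=True, max_examples=80)
    @given(p=st.integers(min_value=1, max_value=4000), data=st.data())
    def test_partition_property_for_arbitrary_sizes(self, p, data):
        k = data.draw(st.integers(min_value=1, max_value=p))
        ivs = make_intervals(p, k)
        assert len(ivs) == k
        assert ivs[0].start_index == 0 and ivs[-1].end_index == p - 1
        widths = [iv.width for iv in ivs]
        assert sum(widths) == p and max(widths) - min(widths) <= 1
        for a, b in zip(ivs, ivs[1:]):
            assert b.start_index == a.end_index + 1


class TestIpls:
    def test_peak_interval_wins(self):
        ds, truth = _single_peak_ds()
        report = ipls(ds, 10, 3, n_v=5, N=30, seed=1)
        best = report.intervals[report.selected_sequence[0]]
        # the winning interval must overlap the analyte band
        assert best.start_wavenumber <= 1125.0 <= best.end_wavenumber + 2 * 15.0

    def test_k1_reduces_to_full_spectrum_mccv(self):
        ds, _ = _single_peak_ds(seed=1)
        report = ipls(ds, 1, 3, n_v=5, N=20, seed=4)
        ref = mccv(ds.absorbance, ds.concentration, 3, n_v=5, N=20, seed=4)
        assert report.rmsecv_per_interval[0] == pytest.approx(ref.rmsecv_mc, rel=1e-12)

    def test_identical_intervals_tie_to_lower_index(self):
        rng = np.random.default_rng(5)
        n, p = 30, 12
        X = rng.normal(size=(n, p))
        X[:, 8:12] = X[:, 0:4]  # interval 2 duplicates interval 0 (k=3)
        y = X[:, 1] + 0.1 * rng.normal(size=n)
        ds = SpectraDataset(
            wavenumbers=np.arange(p, dtype=float) + 1.0,
            absorbance=X - X.min() + 1.0,
            concentration=np.abs(y - y.min()),
        )
        report = ipls(ds, 3, 2, n_v=5, N=15, seed=6)
        assert report.rmsecv_per_interval[0] == pytest.approx(
            report.rmsecv_per_interval[2], rel=1e-10
        )
        assert report.selected_sequence[0] == 0


class TestFsIpls:
    def test_complementary_signal_intervals_taken_first(self):
        # y needs both spectral regions: each carries an independent half
        rng = np.random.default_rng(21)
        n, p = 40, 40
        X = rng.normal(size=(n, p))
        y = X[:, 5:8].sum(axis=1) + X[:, 25:28].sum(axis=1)
        ds = SpectraDataset(
            wavenumbers=np.arange(p, dtype=float) + 1.0,
            absorbance=X - X.min() + 1.0,
            concentration=np.abs(y - y.min()),
        )
        report = fs_ipls(ds, 4, 3, n_v=6, N=25, seed=2, max_intervals=4)
        assert set(report.selected_sequence[:2]) == {0, 2}

    def test_trajectory_non_increasing(self, benchmark_data):
        ds, _ = benchmark_data
        report = fs_ipls(ds, 10, 3, n_v=5, N=30, seed=3, max_intervals=5)
        assert np.all(np.diff(report.rmsecv_trajectory) <= 1e-12)

    def test_pure_noise_stops_early(self):
        stops = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X = rng.normal(size=(25, 40))
            ds = SpectraDataset(
                wavenumbers=np.arange(40.0) + 1.0,
                absorbance=X - X.min() + 1.0,
                concentration=np.linspace(0, 18, 25),
            )
            report = fs_ipls(ds, 8, 2, n_v=5, N=20, seed=seed, max_intervals=8)
            stops.append(len(report.selected_sequence))
        # chance improvements at N=20 occasionally admit a third interval,
        # but noise never drives the greedy search deep into the spectrum
        assert max(stops) <= 3
        assert np.median(stops) <= 2

    def test_max_intervals_one_equals_ipls_best(self):
        ds, _ = _single_peak_ds(seed=2)
        a = fs_ipls(ds, 10, 3, n_v=5, N=20, seed=9, max_intervals=1)
        b = ipls(ds, 10, 3, n_v=5, N=20, seed=9)
        assert a.selected_sequence == b.selected_sequence
        np.testing.assert_array_equal(a.final_mask, b.final_mask)

    def test_micro_mode_records_both_masks(self, benchmark_data):
        ds, _ = benchmark_data
        report = fs_ipls(ds, 10, 3, n_v=5, N=15, seed=5, max_intervals=2, micro=True)
        assert report.final_mask_raw is not None
        assert len(report.optimized_intervals) == len(report.selected_sequence)


class TestMicroOptimize:
    def test_peak_straddling_edge_extends_right(self):
        ds, _ = _single_peak_ds(seed=3, noise=2e-4)
        # peak at 1125 cm^-1 = index 112; interval ends mid-peak
        iv = Interval(90, 110)
        out = micro_optimize(ds, iv, 3, n_v=5, N=20, seed=7)
        assert out.end_index > 110

    def test_interval_matching_signal_region_stays_put(self):
        # columns inside the interval jointly determine y; anything outside
        # is independent noise, so every edge move hurts
        rng = np.random.default_rng(8)
        n, p = 40, 20
        X = rng.normal(size=(n, p))
        y = X[:, 8:12].sum(axis=1)
        ds = SpectraDataset(
            wavenumbers=np.arange(p, dtype=float) + 1.0,
            absorbance=X - X.min() + 1.0,
            concentration=np.abs(y - y.min()),
        )
        iv = Interval(8, 11)
        out = micro_optimize(ds, iv, 4, n_v=6, N=25, seed=10)
        assert (out.start_index, out.end_index) == (8, 11)

    def test_never_shrinks_below_one_wavelength_and_never_worse(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 10))
        ds = SpectraDataset(
            wavenumbers=np.arange(10.0) + 1.0,
            absorbance=X - X.min() + 1.0,
            concentration=np.linspace(0, 5, 20),
        )
        from specselect.interval import _rmsecv_for_columns
        from specselect.validation import _make_splits

        iv = Interval(4, 4)
        out = micro_optimize(ds, iv, 1, n_v=4, N=10, seed=11)
        assert out.width >= 1
        splits = _make_splits(ds.concentration, 4, 10, np.random.default_rng(11))
        before = _rmsecv_for_columns(ds.absorbance, ds.concentration, iv.indices(), 1, splits)
        after = _rmsecv_for_columns(ds.absorbance, ds.concentration, out.indices(), 1, splits)
        assert after <= before + 1e-12

    def test_invalid_mode(self):
        ds, _ = _single_peak_ds(seed=4)
        with pytest.raises(ValueError):
            micro_optimize(ds, Interval(0, 5), 2, 5, 5, 0, mode="sideways")


class TestMwpls:
    def test_center_count_arithmetic(self, benchmark_data):
        ds, _ = benchmark_data
        report = mwpls(ds, window_length=31, c_max=4)
        assert report.centers.size == ds.p - 31 + 1

    def test_even_window_rejected(self, benchmark_data):
        ds, _ = benchmark_data
        with pytest.raises(ValueError, match="odd"):
            mwpls(ds, window_length=30, c_max=3)

    def test_ssr_rows_monotone_non_increasing(self, benchmark_data):
        ds, _ = benchmark_data
        report = mwpls(ds, window_length=31, c_max=5)
        assert np.all(np.diff(report.ssr_curves, axis=1) <= 1e-10)

    def test_noise_windows_keep_high_ssr(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 60))
        ds = SpectraDataset(
            wavenumbers=np.arange(60.0) + 1.0,
            absorbance=X - X.min() + 1.0,
            concentration=np.linspace(0, 18, 30),
        )
        report = mwpls(ds, window_length=21, c_max=5)
        # components keep "improving" on noise but never collapse the SSR
        # the way an informative window does (< 0.1, see the peak test)
        ratio = report.ssr_curves[:, -1] / report.ssr_curves[:, 0]
        assert ratio.min() > 0.3
        assert np.median(ratio) > 0.5

    def test_peak_windows_absorb_ssr_with_few_components(self, quiet_benchmark_data):
        ds, truth = quiet_benchmark_data
        report = mwpls(ds, window_length=31, c_max=5)
        on_peak = np.isin(report.centers, np.flatnonzero(truth.informative_mask))
        ratio = report.ssr_curves[:, 2] / report.ssr_curves[:, 0]  # c=3 vs c=1
        assert ratio[on_peak].min() < 0.10

    def test_select_marks_informative_centers(self, benchmark_data):
        ds, truth = benchmark_data
        report = mwpls(ds, window_length=31, c_max=4)
        sel = mwpls_select(report, ds.p, c_ref=3, fraction=0.5)
        assert sel.n_selected > 0
        # selected centers concentrate on/near the analyte bands
        near = truth.informative_mask.copy()
        idx = np.flatnonzero(near)
        widen = np.zeros_like(near)
        for i in idx:
            widen[max(0, i - 16) : i + 17] = True
        assert (sel.mask & widen).sum() / sel.n_selected > 0.9
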
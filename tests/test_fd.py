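import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photopull.fd import (
    FLcHistogram, ForceDistanceTrace, WLCParams, aa_to_lc, cluster_curves,
    detect_peaks, fd_to_flc, filter_curves, lc_to_aa, peak_statistics,
    read_curves, wlc_contour_length, wlc_extension, wlc_force,
)

WLC = WLCParams()


class TestWLCModel:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, 100.0, WLC) == 0.0

    def test_half_extension_value(self):
        # (kBT/p) * [1/(4*(1/2)^2) - 1/4 + 1/2] = (4.114/0.4) * 1.25
        f = wlc_force(50.0, 100.0, WLC)
        assert f == pytest.approx(4.114 / 0.4 * 1.25, rel=1e-3)

    def test_monotone_in_extension(self):
        x = np.linspace(0, 99, 500)
        f = wlc_force(x, 100.0, WLC)
        assert np.all(np.diff(f) > 0)

    def test_divergence_guard(self):
        with pytest.raises(ValueError):
            wlc_force(100.0, 100.0, WLC)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(lc=st.floats(20.0, 400.0), frac=st.floats(0.05, 0.95),
           p=st.floats(0.2, 1.0))
    def test_inversion_roundtrip_property(self, lc, frac, p):
        """Inverting forces generated from a known Lc recovers it < 0.1 nm."""
        wlc = WLCParams(persistence_nm=p)
        x = frac * lc
        f = wlc_force(x, lc, wlc)
        if f < 1e-6:
            return
        assert wlc_contour_length(x, f, wlc) == pytest.approx(lc, abs=0.1)

    def test_extension_inverts_force(self):
        x = wlc_extension(40.0, 150.0, WLC)
        assert wlc_force(x, 150.0, WLC) == pytest.approx(40.0, rel=1e-9)


class TestLcResidueConversion:
    def test_cng_subunit_length(self):
        assert lc_to_aa(276.0, WLC) == pytest.approx(690.0)
        assert aa_to_lc(690, WLC) == pytest.approx(276.0)

    def test_zero(self):
        assert lc_to_aa(0.0, WLC) == 0.0

    def test_first_cng_peak(self):
        assert lc_to_aa(114.0, WLC) == pytest.approx(285.0)


def make_wlc_curve(lcs, ruptures, wlc=WLC, step=0.5, noise=0.0, offset=0.0,
                   seed=0):
    """Noiseless (or noisy) WLC sawtooth used as a known-truth fixture."""
    rng = np.random.default_rng(seed)
    x_rupt = [wlc_extension(f, lc, wlc) for lc, f in zip(lcs, ruptures)]
    x = np.arange(0.0, max(x_rupt) + 15.0, step)
    force = np.zeros_like(x)
    prev = 0.0
    for lc, xr in zip(lcs, x_rupt):
        seg = (x > prev) & (x <= xr)
        force[seg] = wlc_force(x[seg], lc, wlc)
        prev = xr
    if noise:
        force = force + rng.normal(0, noise, len(force))
    return ForceDistanceTrace(x + offset, force)


class TestFdToFlc:
    def test_single_wlc_mode_at_lc(self):
        trace = make_wlc_curve([100.0], [80.0])
        hist = fd_to_flc(trace, WLC, bin_width_nm=3.0)
        mode = hist.centers[np.argmax(hist.counts)]
        assert abs(mode - 100.0) <= 3.0

    def test_flat_curve_empty_histogram(self):
        trace = ForceDistanceTrace(np.linspace(0, 50, 100), np.zeros(100))
        hist = fd_to_flc(trace, WLC)
        assert hist.counts.sum() == 0.0

    def test_two_plateaus_two_modes(self):
        trace = make_wlc_curve([60.0, 120.0], [80.0, 80.0])
        hist = fd_to_flc(trace, WLC, bin_width_nm=3.0)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(hist.counts, prominence=0.1 * hist.counts.max())
        modes = hist.centers[idx]
        assert any(abs(m - 60) <= 4.5 for m in modes)
        assert any(abs(m - 120) <= 4.5 for m in modes)


class TestDetectPeaks:
    def test_noiseless_two_peak_recovery(self):
        trace = make_wlc_curve([80.0, 140.0], [90.0, 90.0])
        peaks = detect_peaks(trace, WLC)
        assert len(peaks) == 2
        assert peaks[0][0] == pytest.approx(80.0, abs=1.0)
        assert peaks[1][0] == pytest.approx(140.0, abs=1.0)
        assert peaks[0][1] == pytest.approx(90.0, abs=5.0)

    def test_pure_noise_has_no_strong_peaks(self):
        rng = np.random.default_rng(1)
        trace = ForceDistanceTrace(np.arange(0, 100, 0.5),
                                   rng.normal(0, 5.0, 200))
        peaks = detect_peaks(trace, WLC)
        assert all(f < 35.0 for _, f in peaks)

    def test_peak_force_close_to_trace_maximum(self):
        trace = make_wlc_curve([100.0], [70.0], noise=3.0, seed=2)
        peaks = detect_peaks(trace, WLC)
        assert len(peaks) >= 1
        best = max(peaks, key=lambda p: p[1])
        assert best[1] == pytest.approx(trace.force.max(), abs=6.0)


class TestFilterCurves:
    def test_filter_rules(self):
        peaks = [
            [(100.0, 30.0)],                       # max force below threshold
            [(100.0, 50.0), (250.0, 80.0)],        # last peak beyond 200 nm
            [(100.0, 50.0), (180.0, 80.0)],        # keeper
            [],                                    # no peaks at all
        ]
        assert filter_curves(peaks) == [2]

    def test_minimum_last_lc_window(self):
        peaks = [[(150.0, 50.0)], [(250.0, 50.0)], [(100.0, 50.0)]]
        kept = filter_curves(peaks, max_last_peak_lc_nm=300.0,
                             min_last_peak_lc_nm=120.0)
        assert kept == [0, 1]


class TestClustering:
    def _family_hist(self, lcs, shift=0.0, n_bins=100, width=3.0):
        edges = np.arange(0, width * (n_bins + 1), width)
        counts = np.zeros(n_bins)
        for lc in lcs:
            b = int((lc + shift) // width)
            if 0 <= b < n_bins:
                counts[b] += 1.0
        return FLcHistogram(edges, counts)

    def test_identical_histograms_small_shift_same_cluster(self):
        a = self._family_hist([114, 153, 186, 229])
        b = self._family_hist([114, 153, 186, 229], shift=4.0)
        labels = cluster_curves([a, b])
        assert labels[0] == labels[1]

    def test_large_shift_different_cluster(self):
        a = self._family_hist([114, 153, 186, 229])
        b = self._family_hist([114, 153, 186, 229], shift=20.0)
        labels = cluster_curves([a, b])
        assert labels[0] != labels[1]

    def test_disjoint_peak_families_separate(self):
        fam1 = [114, 153, 186, 229]
        fam2 = [31 * 0.4, 50 * 0.4, 112 * 0.4, 175 * 0.4, 240 * 0.4]
        hists = ([self._family_hist(fam1, shift=s) for s in (-3, 0, 3)]
                 + [self._family_hist(fam2, shift=s) for s in (-3, 0, 3)])
        labels = cluster_curves(hists)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_permutation_invariance(self):
        fam1 = [114, 153, 186, 229]
        fam2 = [40, 90, 140]
        hists = [self._family_hist(fam1), self._family_hist(fam1, 3),
                 self._family_hist(fam2), self._family_hist(fam2, -3)]
        labels = cluster_curves(hists)
        perm = [2, 0, 3, 1]
        labels_p = cluster_curves([hists[i] for i in perm])
        # same partition under relabelling
        def partition(ls):
            groups = {}
            for idx, lab in enumerate(ls):
                groups.setdefault(lab, set()).add(idx)
            return {frozenset(g) for g in groups.values()}
        mapped = {frozenset(perm.index(i) for i in g) for g in partition(labels)}
        assert partition(labels_p) == {frozenset(g) for g in mapped}

    def test_global_shift_invariance(self):
        """Shifting every member by the same <= 5 nm leaves clusters alone."""
        fam1 = [114, 153, 186, 229]
        fam2 = [40, 90, 140]
        base = [self._family_hist(fam1), self._family_hist(fam1, 2),
                self._family_hist(fam2), self._family_hist(fam2, -2)]
        moved = [self._family_hist(fam1, 4.5), self._family_hist(fam1, 6.5),
                 self._family_hist(fam2, 4.5), self._family_hist(fam2, 2.5)]
        np.testing.assert_array_equal(cluster_curves(base), cluster_curves(moved))

    def test_all_empty_raises(self):
        edges = np.arange(0, 30.0, 3.0)
        empty = FLcHistogram(edges, np.zeros(len(edges) - 1))
        with pytest.raises(ValueError):
            cluster_curves([empty, empty])


class TestPeakStatistics:
    def test_occurrence_arithmetic(self):
        member_peaks = [[(114.0, 90.0)]] * 34 + [[]] * 2
        groups = peak_statistics(member_peaks, WLC)
        assert len(groups) == 1
        assert groups[0].occurrence == pytest.approx(34 / 36)

    def test_all_members_probability_one(self):
        member_peaks = [[(150.0, 80.0)]] * 10
        groups = peak_statistics(member_peaks, WLC)
        assert groups[0].occurrence == 1.0

    def test_binomial_recovery_of_inclusion_probability(self):
        rng = np.random.default_rng(3)
        member_peaks = []
        for _ in range(200):
            peaks = [(100.0 + rng.normal(0, 2.0), 80.0)]
            if rng.random() < 0.6:
                peaks.append((160.0 + rng.normal(0, 2.0), 70.0))
            member_peaks.append(sorted(peaks))
        groups = peak_statistics(member_peaks, WLC)
        probs = {round(g.lc_mean_nm, -1): g.occurrence for g in groups}
        assert probs[100.0] == pytest.approx(1.0)
        assert probs[160.0] == pytest.approx(0.6, abs=0.07)


class TestReadCurves(object):
    def test_tsv_roundtrip(self, tmp_path):
        f = tmp_path / "c1.tsv"
        f.write_text("0.0\t1.0\n0.5\t10.0\n1.0\t20.0\n")
        traces = read_curves(tmp_path)
        assert len(traces) == 1
        np.testing.assert_allclose(traces[0].force, [1.0, 10.0, 20.0])

    def test_nano_newton_conversion(self, tmp_path):
        f = tmp_path / "c1.tsv"
        f.write_text("# force_unit: nN\n0.0\t0.001\n1.0\t0.05\n")
        traces = read_curves(tmp_path)
        np.testing.assert_allclose(traces[0].force, [1.0, 50.0])

    def test_empty_and_malformed_files_skipped(self, tmp_path):
        (tmp_path / "empty.tsv").write_text("")
        (tmp_path / "bad.tsv").write_text("a\tb\nnot\tnumbers\n")
        (tmp_path / "good.tsv").write_text("0.0\t5.0\n1.0\t6.0\n")
        traces = read_curves(tmp_path)
        assert len(traces) == 1

    def test_retraction_branch_extracted(self, tmp_path):
        # approach (5 -> 0 nm) followed by retract (0 -> 5 nm)
        rows = [f"{d:.1f}\t{1.0:.1f}" for d in np.linspace(5, 0, 6)]
        rows += [f"{d:.1f}\t{float(10 * d):.1f}" for d in np.linspace(0.5, 5, 10)]
        (tmp_path / "c.tsv").write_text("\n".join(rows) + "\n")
        traces = read_curves(tmp_path)
        assert len(traces) == 1
        assert len(traces[0].tss) == 11  # closest approach + 10 retract points
        np.testing.assert_allclose(traces[0].force[-1], 50.0)

    def test_header_row_tolerated(self, tmp_path):
        (tmp_path / "c.tsv").write_text("tss_nm\tforce_pn\n0.0\t5.0\n1.0\t6.0\n")
        traces = read_curves(tmp_path)
        assert len(traces) == 1 and len(traces[0].force) == 2


class TestTraceValidation:
    def test_decreasing_tss_rejected(self):
        with pytest.raises(ValueError):
            ForceDistanceTrace(np.array([1.0, 0.5]), np.array([1.0, 2.0]))

    def test_nonfinite_force_rejected(self):
        with pytest.raises(ValueError):
            ForceDistanceTrace(np.array([0.0, 1.0]), np.array([1.0, np.nan]))
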
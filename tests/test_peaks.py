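"""Peak processing: baseline, detection, integration, assignment, overlap."""

import numpy as np
import pytest
from scipy import stats

import georquant as gq
from georquant.peaks import Peak
from georquant.simulate import gaussian_peak


def _chrom_from_trace(times, trace, wavelength=205):
    return gq.Chromatogram(times=times, traces={wavelength: trace})


class TestBaseline:
    def test_flat_offset_recovered(self):
        t = np.arange(0.0, 30.0, 0.01)
        chrom = _chrom_from_trace(t, np.full_like(t, 0.5))
        base = gq.estimate_baseline(chrom, 205)
        np.testing.assert_allclose(base, 0.5, atol=1e-12)

    def test_baseline_small_under_peak(self):
        t = np.arange(0.0, 30.0, 0.01)
        y = gaussian_peak(t, 1000.0, 15.0, 0.12)
        chrom = _chrom_from_trace(t, y)
        base = gq.estimate_baseline(chrom, 205)
        under = np.abs(t - 15.0) <= 0.6
        assert np.all(np.abs(base[under]) <= 0.01 * y.max())

    def test_linear_drift_recovered(self, library):
        noise = gq.NoiseModel(area_cv=0.0, baseline_sd=0.0,
                              baseline_drift=0.01, seed=0)
        chrom = gq.simulate_injection({}, library, noise)
        base = gq.estimate_baseline(chrom, 205)
        interior = slice(150, -150)  # outside half-window edge effects
        np.testing.assert_allclose(base[interior],
                                   chrom.traces[205][interior], atol=0.02)

    def test_missing_wavelength_errors(self):
        t = np.arange(0.0, 10.0, 0.01)
        chrom = _chrom_from_trace(t, np.zeros_like(t))
        with pytest.raises(KeyError):
            gq.estimate_baseline(chrom, 300)

    def test_window_must_be_positive(self):
        t = np.arange(0.0, 10.0, 0.01)
        chrom = _chrom_from_trace(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            gq.estimate_baseline(chrom, 205, window=0.0)


class TestDetect:
    def test_standard_panel_gives_seven_peaks(self, library, zero_noise,
                                              standard_sample):
        """8 analytes produce 7 peaks: FA and GlyAld merge at 19.46 min."""
        chrom = gq.simulate_injection(standard_sample, library, zero_noise)
        found = gq.detect_peaks(chrom, 205)
        assert len(found) == 7
        apexes = [p.apex_time for p in found]
        assert apexes == sorted(apexes)
        assert min(abs(a - 19.46) for a in apexes) < 0.03

    def test_flat_trace_gives_no_peaks(self):
        t = np.arange(0.0, 30.0, 0.01)
        chrom = _chrom_from_trace(t, np.zeros_like(t))
        assert gq.detect_peaks(chrom, 205) == []

    def test_salt_peak_unassignable_to_panel(self, library, panel_library,
                                             noise):
        chrom = gq.simulate_electrolysis_sample(
            {"FA": 10.0}, "alkaline", library, noise)
        found = gq.detect_peaks(chrom, 205)
        assigned = gq.assign_peaks(found, panel_library)
        salt = [p for p in assigned if abs(p.apex_time - 11.38) <= 0.05]
        assert len(salt) == 1
        assert salt[0].assigned_analyte is None
        assert salt[0].coelution_group == []

    def test_negative_thresholds_rejected(self, library, zero_noise):
        chrom = gq.simulate_injection({"OA": 1.0}, library, zero_noise)
        with pytest.raises(ValueError):
            gq.detect_peaks(chrom, 205, min_height=-1.0)


class TestIntegrate:
    def test_five_sigma_window_matches_closed_form(self, library,
                                                   zero_noise):
        chrom = gq.simulate_injection({"OA": 1.0}, library, zero_noise)
        area = gq.integrate_peak(chrom, 205, (12.37 - 0.6, 12.37 + 0.6),
                                 subtract_baseline=False)
        expected = 167894 * (stats.norm.cdf(5) - stats.norm.cdf(-5))
        assert area == pytest.approx(expected, rel=1e-6)

    def test_one_sigma_window_erf_fraction(self, library, zero_noise):
        chrom = gq.simulate_injection({"OA": 1.0}, library, zero_noise)
        area = gq.integrate_peak(chrom, 205, (12.37 - 0.12, 12.37 + 0.12),
                                 subtract_baseline=False)
        frac = stats.norm.cdf(1) - stats.norm.cdf(-1)  # 0.682689...
        assert area == pytest.approx(167894 * frac, rel=1e-3)

    def test_grid_refinement_second_order(self, library, zero_noise):
        """Halving dt cuts the +-1 sigma integration error ~4x."""
        errs = []
        for dt in (0.02, 0.01, 0.005):
            chrom = gq.simulate_injection({"OA": 1.0}, library, zero_noise,
                                          grid=(0.0, 30.0, dt))
            area = gq.integrate_peak(
                chrom, 205, (12.37 - 0.12, 12.37 + 0.12),
                subtract_baseline=False)
            truth = 167894 * (stats.norm.cdf(1) - stats.norm.cdf(-1))
            errs.append(abs(area - truth))
        assert errs[0] / errs[1] > 2.5
        assert errs[1] / errs[2] > 2.5

    def test_zero_trace_zero_area(self):
        t = np.arange(0.0, 10.0, 0.01)
        chrom = _chrom_from_trace(t, np.zeros_like(t))
        assert gq.integrate_peak(chrom, 205, (2.0, 4.0)) == 0.0

    def test_inverted_bounds_rejected(self):
        t = np.arange(0.0, 10.0, 0.01)
        chrom = _chrom_from_trace(t, np.zeros_like(t))
        with pytest.raises(ValueError, match="inverted"):
            gq.integrate_peak(chrom, 205, (4.0, 2.0))


class TestAssign:
    def _peak(self, apex, wl=205, sigma=0.12):
        return Peak(apex_time=apex, left_bound=apex - 0.6,
                    right_bound=apex + 0.6, height=1.0, area=1.0,
                    wavelength=wl, sigma=sigma)

    def test_within_tolerance(self, library):
        out = gq.assign_peaks([self._peak(12.40)], library)
        assert out[0].assigned_analyte == "OA"
        assert out[0].coelution_group == ["OA"]

    def test_coelution_group(self, library):
        out = gq.assign_peaks([self._peak(19.46)], library)
        assert out[0].assigned_analyte is None
        assert out[0].coelution_group == ["FA", "GlyAld"]

    def test_unmatched_stays_unassigned(self, panel_library):
        out = gq.assign_peaks([self._peak(11.38)], panel_library)
        assert out[0].assigned_analyte is None
        assert out[0].coelution_group == []

    def test_competing_peaks_flagged(self, library):
        out = gq.assign_peaks([self._peak(12.30), self._peak(12.44)],
                              library)
        assert out[0].ambiguous and out[1].ambiguous
        assert {p.coelution_group[0] for p in out} == {"OA"}

    def test_tolerance_must_be_positive(self, library):
        with pytest.raises(ValueError):
            gq.assign_peaks([self._peak(12.37)], library, tolerance=0.0)


class TestResolution:
    def _pair(self, t1, t2, sigma=0.12):
        mk = lambda t: Peak(apex_time=t, left_bound=t - 5 * sigma,
                            right_bound=t + 5 * sigma, height=1.0,
                            area=1.0, wavelength=205, sigma=sigma)
        return mk(t1), mk(t2)

    def test_lactic_glycolic_partially_overlapped(self):
        p1, p2 = self._pair(17.88, 18.33)
        assert gq.resolution(p1, p2) == pytest.approx(2 * 0.45 / 0.96)
        assert gq.resolution(p1, p2) < 1.5

    def test_glyceric_glycolic_baseline_resolved(self):
        p1, p2 = self._pair(17.13, 18.31)
        assert gq.resolution(p1, p2) == pytest.approx(2 * 1.18 / 0.96)
        assert gq.resolution(p1, p2) > 1.5

    def test_identical_apexes_zero(self):
        p1, p2 = self._pair(15.0, 15.0)
        assert gq.resolution(p1, p2) == 0.0

    def test_translation_invariance(self):
        p1, p2 = self._pair(10.0, 10.9)
        q1, q2 = self._pair(17.0, 17.9)
        assert gq.resolution(p1, p2) == pytest.approx(
            gq.resolution(q1, q2))

    def test_monotone_in_separation(self):
        rs = [gq.resolution(*self._pair(10.0, 10.0 + d))
              for d in (0.2, 0.5, 1.0, 2.0)]
        assert rs == sorted(rs)

    def test_adjacent_panel_pairs_baseline_resolved(self, library):
        """With sigma 0.12 min only lactic/glycolic fall below Rs 1.5."""
        specs = sorted(library, key=lambda s: s.retention_time)
        for a, b in zip(specs, specs[1:]):
            if a.retention_time == b.retention_time:
                continue  # the designed FA/GlyAld co-elution
            p1, p2 = self._pair(a.retention_time, b.retention_time)
            rs = gq.resolution(p1, p2)
            if {a.name, b.name} == {"lactic", "GCA"}:
                assert rs < 1.5
            else:
                assert rs > 1.5


class TestOverlapFit:
    def test_lactic_glycolic_recovered_within_2pct(self, library,
                                                   zero_noise):
        chrom = gq.simulate_injection({"lactic": 1.0, "GCA": 1.0}, library,
                                      zero_noise)
        fit = gq.fit_overlapped_pair(chrom, 205, (17.3, 18.9),
                                     (17.88, 18.31))
        assert fit.converged
        assert fit.areas[0] == pytest.approx(7000, rel=0.02)
        assert fit.areas[1] == pytest.approx(7441, rel=0.02)
        assert fit.centers[0] == pytest.approx(17.88, abs=0.02)
        assert fit.centers[1] == pytest.approx(18.31, abs=0.02)

    def test_degenerate_single_peak(self, library, zero_noise):
        chrom = gq.simulate_injection({"GCA": 1.0}, library, zero_noise)
        fit = gq.fit_overlapped_pair(chrom, 205, (17.3, 18.9),
                                     (17.88, 18.31))
        total = sum(fit.areas)
        assert total == pytest.approx(7441, rel=0.02)
        assert min(fit.areas) < 0.02 * total

    def test_init_order_irrelevant(self, library, zero_noise):
        chrom = gq.simulate_injection({"lactic": 0.8, "GCA": 1.6}, library,
                                      zero_noise)
        a = gq.fit_overlapped_pair(chrom, 205, (17.3, 18.9),
                                   (17.88, 18.31))
        b = gq.fit_overlapped_pair(chrom, 205, (17.3, 18.9),
                                   (18.31, 17.88))
        assert a.areas == pytest.approx(b.areas, rel=1e-4)

    def test_fit_matches_observed_region(self, library, noise):
        chrom = gq.simulate_injection({"lactic": 1.0, "GCA": 1.0}, library,
                                      noise)
        fit = gq.fit_overlapped_pair(chrom, 205, (17.3, 18.9),
                                     (17.88, 18.31))
        mask = (chrom.times >= 17.3) & (chrom.times <= 18.9)
        ss_obs = float(np.sum(chrom.traces[205][mask] ** 2))
        assert fit.rss < 1e-4 * ss_obs


class TestRoundTrip:
    def test_noise_free_area_recovery(self, library, zero_noise,
                                      standard_sample):
        """Simulate -> detect -> integrate -> assign recovers every area
        within 0.5 % of slope x concentration."""
        chrom = gq.simulate_injection(standard_sample, library, zero_noise)
        found = gq.detect_peaks(chrom, 205)
        assigned = gq.assign_peaks(found, library)
        for p in assigned:
            group = p.coelution_group
            assert group, f"unassigned peak at {p.apex_time}"
            truth = sum(library.get(n).response[205] * standard_sample[n]
                        for n in group)
            assert p.area == pytest.approx(truth, rel=0.005)

    def test_merged_peak_additivity(self, library, zero_noise):
        chrom = gq.simulate_injection({"FA": 2.0, "GlyAld": 0.7}, library,
                                      zero_noise)
        found = gq.detect_peaks(chrom, 205)
        assert len(found) == 1
        assert found[0].area == pytest.approx(6309 * 2.0 + 12566 * 0.7,
                                              rel=0.005)
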
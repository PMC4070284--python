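"""Per-unit metrics: rates, orientation and SF tuning, ODI, F1, C_1/2,
waveform classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdrecovery import (UndefinedMetricError, classify_waveform,
                        compute_unit_metrics, contrast_response,
                        evoked_response, f1_response, fit_orientation_tuning,
                        fit_sf_tuning, odi_unit, orientation_difference,
                        preferred_orientation, sample_waveform_features,
                        select_responsive_grating, spontaneous_rate,
                        tuning_width)
from mdrecovery.metrics import _tuning_model, osi

DIRS = np.arange(12) * 30.0


class TestRates:
    def test_spontaneous_rate_arithmetic(self, toy_trials):
        # three blanks of 3 spikes over 1.5 s each
        assert spontaneous_rate(toy_trials, 0) == pytest.approx(2.0)

    def test_spontaneous_rate_requires_blanks(self, toy_trials):
        no_blanks = toy_trials[~toy_trials["is_blank"]]
        with pytest.raises(UndefinedMetricError):
            spontaneous_rate(no_blanks, 0)

    def test_evoked_response_subtracts_baseline(self, toy_trials):
        # condition rate 10 sp/s minus spont 2 sp/s
        r = evoked_response(toy_trials, 0, "contra", 90.0, 0.04)
        assert r == pytest.approx(8.0)

    def test_evoked_response_unknown_condition_rejected(self, toy_trials):
        with pytest.raises(ValueError):
            evoked_response(toy_trials, 0, "contra", 45.0, 0.99)


class TestPreferredOrientation:
    def test_single_direction_response(self):
        f = np.zeros(12)
        f[DIRS.tolist().index(45.0) if 45.0 in DIRS else 0] = 0  # guard
        # one nonzero response at 45 deg on a direction grid containing it
        dirs = np.array([0.0, 45.0, 90.0, 135.0])
        f = np.array([0.0, 5.0, 0.0, 0.0])
        assert preferred_orientation(dirs, f) == pytest.approx(45.0)

    def test_pure_second_harmonic(self):
        f = 1.0 + np.cos(2.0 * np.deg2rad(DIRS - 30.0))
        assert preferred_orientation(DIRS, f) == pytest.approx(30.0,
                                                               abs=1e-9)

    def test_balanced_responses_undefined(self):
        dirs = np.array([0.0, 90.0, 180.0, 270.0])
        f = np.array([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(UndefinedMetricError):
            preferred_orientation(dirs, f)

    @given(delta=st.floats(0.0, 180.0))
    @settings(max_examples=40, deadline=None)
    def test_rotation_equivariance(self, delta):
        f = 2.0 + np.cos(2.0 * np.deg2rad(DIRS - 20.0))
        base = preferred_orientation(DIRS, f)
        rotated = preferred_orientation(DIRS + delta, f)
        diff = (rotated - base - delta) % 180.0
        assert min(diff, 180.0 - diff) < 1e-6


class TestTuningFit:
    def test_noiseless_parameters_recovered(self):
        truth = dict(a1=10.0, a2=5.0, sigma=20.0, b=1.0)
        y = _tuning_model(DIRS, 40.0, truth["a1"], truth["a2"],
                         truth["sigma"], truth["b"])
        fit = fit_orientation_tuning(DIRS, y, 40.0)
        assert fit.converged
        assert fit.A1 == pytest.approx(truth["a1"], rel=0.01)
        assert fit.A2 == pytest.approx(truth["a2"], rel=0.01)
        assert fit.sigma_deg == pytest.approx(truth["sigma"], rel=0.01)
        assert fit.B == pytest.approx(truth["b"], rel=0.01)

    def test_flat_responses_give_zero_selectivity(self):
        fit = fit_orientation_tuning(DIRS, np.full(12, 3.0), 60.0)
        assert fit.A1 == pytest.approx(0.0, abs=1e-6)
        assert fit.A2 == pytest.approx(0.0, abs=1e-6)

    def test_hwhm_closed_form(self):
        y = _tuning_model(DIRS, 0.0, 8.0, 0.0, 20.0, 0.0)
        fit = fit_orientation_tuning(DIRS, y, 0.0)
        assert fit.hwhm_deg == pytest.approx(20.0 * np.sqrt(2 * np.log(2)),
                                             abs=0.1)

    def test_hwhm_shrinks_with_sigma(self):
        widths = []
        for sigma in (10.0, 25.0, 40.0):
            y = _tuning_model(DIRS, 90.0, 10.0, 2.0, sigma, 1.0)
            widths.append(fit_orientation_tuning(DIRS, y, 90.0).hwhm_deg)
        assert widths[0] < widths[1] < widths[2]

    def test_osi_from_fitted_responses(self):
        fit = fit_orientation_tuning(
            DIRS, _tuning_model(DIRS, 30.0, 9.0, 3.0, 25.0, 0.0), 30.0)
        assert 0.0 <= fit.osi <= 1.0
        assert osi(fit) == pytest.approx(fit.osi)

    def test_tuning_width_undefined_without_peak(self):
        from mdrecovery import TuningFit
        flat = TuningFit(theta_pref_deg=0.0, A1=0.0, A2=0.0, sigma_deg=20.0,
                         B=1.0, R_pref=1.0, R_ortho=1.0, osi=0.0,
                         hwhm_deg=np.nan, converged=True, rss=0.0)
        with pytest.raises(UndefinedMetricError):
            tuning_width(flat)


class TestOrientationDifference:
    @pytest.mark.parametrize("tc, ti, expected", [
        (30.0, 30.0, 0.0),
        (170.0, 10.0, -20.0),   # wraps across 180
        (100.0, 10.0, 90.0),    # half-cycle boundary maps to +90
        (10.0, 170.0, 20.0),
        (0.0, 90.0, 90.0),
    ])
    def test_wrap_cases(self, tc, ti, expected):
        assert orientation_difference(tc, ti) == pytest.approx(expected)

    @given(tc=st.floats(0.0, 179.999), ti=st.floats(0.0, 179.999))
    @settings(max_examples=60, deadline=None)
    def test_range_and_absolute_symmetry(self, tc, ti):
        d = orientation_difference(tc, ti)
        assert -90.0 < d <= 90.0
        assert abs(orientation_difference(ti, tc)) == pytest.approx(abs(d),
                                                                    abs=1e-9)


class TestSFTuning:
    SFS = np.array([0.01, 0.02, 0.04, 0.08, 0.16, 0.32])

    def test_noiseless_dog_recovered(self):
        def dog(sf):
            return (10.0 * np.exp(-0.5 * (sf / 0.08) ** 2)
                    - 6.0 * np.exp(-0.5 * (sf / 0.02) ** 2))
        fit = fit_sf_tuning(self.SFS, dog(self.SFS))
        assert fit.converged
        grid = np.linspace(0, 0.64, 2001)
        brute = grid[np.argmax(dog(grid))]
        assert fit.sf_pref_cpd == pytest.approx(brute, abs=0.01)

    def test_lowpass_responses_prefer_low_sf(self):
        f = np.array([10.0, 8.0, 5.0, 2.0, 1.0, 0.5])
        fit = fit_sf_tuning(self.SFS, f)
        assert fit.sf_pref_cpd <= self.SFS[1]

    def test_requires_enough_conditions(self):
        with pytest.raises(ValueError):
            fit_sf_tuning(self.SFS[:3], np.ones(3))


class TestODI:
    @pytest.mark.parametrize("c, i, expected", [
        (1.0, 1.0, 0.0),    # equal drive through the two eyes
        (5.0, 0.0, 1.0),
        (0.0, 5.0, -1.0),
        (6.0, 2.0, 0.5),
    ])
    def test_values(self, c, i, expected):
        assert odi_unit(c, i) == pytest.approx(expected)

    def test_negative_responses_clipped(self):
        assert odi_unit(4.0, -2.0) == pytest.approx(1.0)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            odi_unit(0.0, 0.0)

    @given(c=st.floats(0.0, 50.0), i=st.floats(0.0, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_antisymmetric(self, c, i):
        if c + i == 0:
            return
        d = odi_unit(c, i)
        assert -1.0 <= d <= 1.0
        assert odi_unit(i, c) == pytest.approx(-d, abs=1e-12)


class TestResponsiveSelection:
    def test_threshold_through_either_eye(self):
        m = pd.DataFrame({
            "peak_grating_resp_contra": [1.9, 2.0, 0.0, 5.0],
            "peak_grating_resp_ipsi": [1.9, 0.0, 2.0, 5.0],
        })
        kept = select_responsive_grating(m)
        assert kept.index.tolist() == [1, 2, 3]

    def test_empty_input(self):
        m = pd.DataFrame({"peak_grating_resp_contra": [],
                          "peak_grating_resp_ipsi": []})
        assert len(select_responsive_grating(m)) == 0


class TestF1Response:
    BIN = 1.0 / 30.0

    def _counts(self, rate_fn, n_cycles=6, period=10.0):
        t = np.arange(int(n_cycles * period / self.BIN)) * self.BIN
        return rate_fn(t) * self.BIN  # expected counts, noiseless

    def test_pure_first_harmonic(self):
        counts = self._counts(
            lambda t: 5.0 + 3.0 * np.cos(2 * np.pi * t / 10.0))
        assert f1_response(counts, self.BIN, 10.0) == pytest.approx(3.0,
                                                                    abs=1e-9)

    def test_constant_rate_gives_zero(self):
        counts = self._counts(lambda t: np.full_like(t, 4.0))
        assert f1_response(counts, self.BIN, 10.0) == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_phase_origin_invariance(self):
        counts = self._counts(
            lambda t: 5.0 + 3.0 * np.cos(2 * np.pi * t / 10.0 + 1.1))
        base = f1_response(counts, self.BIN, 10.0)
        rolled = f1_response(np.roll(counts, 37), self.BIN, 10.0)
        assert rolled == pytest.approx(base, rel=1e-9)

    def test_rejects_misaligned_bins_and_short_records(self):
        with pytest.raises(ValueError, match="integer"):
            f1_response(np.ones(100), 0.3, 10.0)
        with pytest.raises(ValueError, match="two full periods"):
            f1_response(np.ones(200), self.BIN, 10.0)


class TestContrastResponse:
    BIN = 1.0 / 30.0

    def _trace(self, n_cycles=12, period=10.0):
        t = np.arange(int(n_cycles * period / self.BIN)) * self.BIN
        return 0.5 * (1.0 - np.cos(2 * np.pi * t / period))

    def test_half_max_near_c50(self):
        trace = self._trace()
        rate = 10.0 * trace ** 2 / (trace ** 2 + 0.3 ** 2)
        _, c_half = contrast_response(rate * self.BIN, self.BIN, trace)
        assert c_half == pytest.approx(0.3, abs=0.05)  # bin resolution

    def test_constant_rate_undefined(self):
        trace = self._trace()
        _, c_half = contrast_response(np.full(trace.size, 0.2), self.BIN,
                                      trace)
        assert np.isnan(c_half)

    def test_gain_invariance(self):
        trace = self._trace()
        rate = trace ** 2 / (trace ** 2 + 0.3 ** 2)
        _, a = contrast_response(rate * self.BIN, self.BIN, trace)
        _, b = contrast_response(5.0 * rate * self.BIN, self.BIN, trace)
        assert a == pytest.approx(b, abs=1e-9)


class TestWaveformClassifier:
    @pytest.mark.parametrize("t2p, slope, expected", [
        (1.0, 0.5, "broad"),
        (0.2, -0.5, "narrow"),
        (0.2, 0.5, "broad"),    # fast but repolarized: fails slope criterion
        (1.0, -0.5, "broad"),   # slow: fails time criterion
    ])
    def test_two_criterion_rule(self, t2p, slope, expected):
        assert classify_waveform(t2p, slope) == expected

    def test_rejects_nonfinite_features(self):
        with pytest.raises(ValueError):
            classify_waveform(np.nan, 0.0)

    def test_monte_carlo_accuracy_on_generated_features(self):
        correct = total = 0
        for cls, seed in (("broad", 31), ("narrow", 32)):
            feats = sample_waveform_features(cls, seed=seed, n=10_000)
            pred = [classify_waveform(t, s) for t, s in
                    zip(feats["trough_to_peak_ms"], feats["slope_at_half_ms"])]
            correct += sum(p == cls for p in pred)
            total += len(pred)
        assert correct / total >= 0.95


class TestComputeUnitMetrics:
    def test_pipeline_produces_rows_and_bounded_indices(self, small_trials):
        units, trials = small_trials
        table = compute_unit_metrics(trials)
        assert len(table) == len(units)
        odi = table["odi_grating"].dropna()
        assert ((odi >= -1.0) & (odi <= 1.0)).all()
        do = table["dO_abs_deg"].dropna()
        assert ((do >= 0.0) & (do <= 90.0)).all()
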
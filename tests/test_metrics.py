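"""Event-locked amplitudes/latencies, habituation and spontaneous transients."""

import numpy as np
import pytest
from scipy import stats as sstats

from chophot.metrics import (
    NAMED_CONFIGS,
    EventMetricConfig,
    event_amplitude,
    habituation_curve,
    habituation_slope,
    session_time_bins,
    spontaneous_transients,
)
from chophot.synth import transient_kernel

from conftest import make_dff


class TestEventAmplitude:
    @pytest.mark.parametrize("name", sorted(NAMED_CONFIGS))
    def test_flat_trace_zero_amplitude(self, name):
        tr = make_dff(np.zeros(int(1017 * 20)), fs=1017.0)
        resp = event_amplitude(tr, 10.0, NAMED_CONFIGS[name])
        assert resp is not None
        assert resp.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_injected_transient_amplitude_and_latency(self):
        fs = 1017.0
        dff = np.zeros(int(fs * 20))
        k = transient_kernel(fs, 0.02, 0.08)  # peaks within the 400 ms window
        t_event, offset = 10.0, 0.15
        i0 = int(round((t_event + offset) * fs))
        dff[i0 : i0 + k.size] += 3.0 * k
        tr = make_dff(dff, fs=fs)
        resp = event_amplitude(tr, t_event, NAMED_CONFIGS["tone_operant"])
        assert resp.amplitude == pytest.approx(3.0, abs=1e-9)
        k_peak = np.argmax(k) / fs
        assert resp.peak_latency_s == pytest.approx(offset + k_peak, abs=1.0 / fs)

    def test_post_minus_pre_config_cancels_pre_onset_peak(self):
        # passive sensory config: a transient just before onset raises the
        # "pre" peak and is subtracted out of the reported amplitude
        fs = 1017.0
        dff = np.zeros(int(fs * 20))
        k = transient_kernel(fs, 0.02, 0.08)
        dff[int(9.7 * fs) : int(9.7 * fs) + k.size] += 2.0 * k  # pre-onset
        dff[int(10.5 * fs) : int(10.5 * fs) + k.size] += 5.0 * k  # in-stimulus
        tr = make_dff(dff, fs=fs)
        resp = event_amplitude(tr, 10.0, NAMED_CONFIGS["sensory_passive"])
        assert resp.amplitude == pytest.approx(5.0 - 2.0, abs=0.01)

    def test_constant_offset_equivariance_for_mean_baseline(self):
        rng = np.random.default_rng(0)
        dff = rng.standard_normal(int(1017 * 20)) * 0.1
        a = event_amplitude(make_dff(dff, fs=1017.0), 10.0, NAMED_CONFIGS["tone_operant"])
        b = event_amplitude(
            make_dff(dff + 5.0, fs=1017.0), 10.0, NAMED_CONFIGS["tone_operant"]
        )
        assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)

    def test_event_near_edge_skipped(self):
        tr = make_dff(np.zeros(1017), fs=1017.0)
        assert event_amplitude(tr, 0.5, NAMED_CONFIGS["tone_operant"]) is None

    def test_lick_onset_config_uses_max_baseline(self):
        cfg = NAMED_CONFIGS["lick_onset"]
        assert cfg.baseline_stat == "max"
        assert cfg.baseline_window == (-0.25, 0.0)
        assert cfg.response_window == (0.0, 0.7)
        fs = 1017.0
        dff = np.zeros(int(fs * 10))
        dff[int(4.9 * fs)] = 1.0  # pre-onset spike raises the max baseline
        dff[int(5.3 * fs)] = 2.5
        resp = event_amplitude(make_dff(dff, fs=fs), 5.0, cfg)
        assert resp.amplitude == pytest.approx(1.5)


class TestHabituation:
    def test_constant_curve_is_one(self):
        curve, ok = habituation_curve(np.full(20, 3.3))
        assert ok and np.allclose(curve, 1.0)

    def test_geometric_decay_closed_form(self):
        amps = 2.0 * 0.9 ** np.arange(20)
        curve, ok = habituation_curve(amps)
        assert ok
        assert np.allclose(curve, 0.9 ** np.arange(20), atol=1e-12)

    def test_nonpositive_first_returns_raw(self):
        amps = np.array([-1.0, 2.0, 3.0])
        curve, ok = habituation_curve(amps)
        assert not ok and np.array_equal(curve, amps)

    def test_exact_line_slope(self):
        assert habituation_slope(np.array([5.0, 4, 3, 2, 1, 9, 9]), 5) == pytest.approx(-1.0)

    def test_fraction_span(self):
        amps = np.arange(50, 0, -1.0)
        assert habituation_slope(amps, 0.2) == pytest.approx(-1.0)

    def test_ols_unbiased_on_noisy_lines(self, rng):
        est = []
        for _ in range(200):
            amps = 4.0 - 0.2 * np.arange(10) + rng.normal(0, 0.3, 10)
            est.append(habituation_slope(amps, 10))
        se = 0.3 / np.sqrt(np.sum((np.arange(10) - 4.5) ** 2)) / np.sqrt(200)
        assert np.mean(est) == pytest.approx(-0.2, abs=4 * se)

    def test_span_exceeding_data_rejected(self):
        with pytest.raises(ValueError):
            habituation_slope(np.ones(5), 10)


class TestSpontaneousTransients:
    def test_truncated_normal_closed_form(self, rng):
        fs = 1017.0
        vals = rng.standard_normal(int(fs * 400))
        tr = make_dff(vals, fs=fs)
        tau, mean_supra, mask = spontaneous_transients(tr, (0.0, 400.0))
        assert tau == pytest.approx(sstats.norm.ppf(0.05), abs=0.02)
        cut = tau + 0.5
        expect = sstats.norm.expect(lb=cut, conditional=True)
        assert mean_supra == pytest.approx(expect, rel=0.02)

    def test_constant_window_empty_mask(self):
        tr = make_dff(np.full(3000, 1.5), fs=100.0)
        tau, mean_supra, mask = spontaneous_transients(tr, (0.0, 30.0))
        assert tau == 1.5
        assert not mask.any() and np.isnan(mean_supra)

    def test_matches_sort_and_scan_oracle(self, rng):
        fs = 100.0
        for _ in range(100):
            vals = rng.standard_normal(rng.integers(40, 400)) * rng.uniform(0.5, 3)
            tr = make_dff(vals, fs=fs)
            end = len(vals) / fs
            tau, mean_supra, mask = spontaneous_transients(tr, (0.0, end))
            # oracle: sort, interpolate the 5th percentile, scan for the mask
            srt = np.sort(vals)
            pos = 0.05 * (len(vals) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            tau_o = srt[lo] * (1 - frac) + srt[min(lo + 1, len(vals) - 1)] * frac
            mask_o = [v >= tau_o + 0.5 for v in vals]
            assert tau == pytest.approx(tau_o, abs=1e-12)
            assert mask.tolist() == mask_o
            if any(mask_o):
                assert mean_supra == pytest.approx(
                    np.mean(vals[np.asarray(mask_o)]), abs=1e-12
                )

    def test_order_invariance(self, rng):
        vals = rng.standard_normal(500)
        a = spontaneous_transients(make_dff(vals, fs=100.0), (0.0, 5.0))
        b = spontaneous_transients(make_dff(vals[::-1], fs=100.0), (0.0, 5.0))
        assert a[0] == b[0]
        assert a[1] == pytest.approx(b[1], abs=1e-12)


class TestSessionTimeBins:
    def test_one_session_per_bin(self):
        assert session_time_bins(5, 5).tolist() == [1, 2, 3, 4, 5]

    def test_eight_sessions_five_bins_ceiling_rule(self):
        bins = session_time_bins(8, 5)
        assert bins.tolist() == [1, 2, 2, 3, 4, 4, 5, 5]
        sizes = np.bincount(bins)[1:]
        assert sizes.tolist() == [1, 2, 1, 2, 2]

    def test_monotone_nondecreasing(self):
        for n in (1, 3, 7, 12):
            b = session_time_bins(n, 5)
            assert np.all(np.diff(b) >= 0)
            assert b[-1] == 5 and b[0] >= 1
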
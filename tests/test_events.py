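"""Event layer: slow-wave detection and polarity, switcher
classification, theta bursts, PAC, and event-locked scalograms."""

import numpy as np
import pytest

from rnb.events import (
    SlowWaveEvent,
    classify_switchers,
    compute_pac,
    cooccurring,
    detect_ssw,
    detect_ssw_adaptive,
    detect_theta_bursts,
    event_scalograms,
    pac_contrast,
    theta_envelope_baseline,
)

FS = 200.0


def _sine(freq, dur_s, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestDetectSSW:
    def test_one_hz_sinusoid_yields_full_cycles(self):
        events = detect_ssw(_sine(1.0, 20.0), FS)
        assert 19 <= len(events) <= 20
        for e in events:
            assert e.pos_zc - e.neg_zc == pytest.approx(1.0, abs=0.05)

    def test_ten_hz_sinusoid_rejected_by_duration_floor(self):
        assert detect_ssw(_sine(10.0, 20.0), FS) == []

    def test_constant_signal_yields_no_events(self):
        assert detect_ssw(np.ones(int(20 * FS)), FS) == []

    def test_gamma_polarity_fixture(self, rng):
        """Gamma bursts added to positive half-waves force the downstate
        label onto the (gamma-suppressed) negative half-waves."""
        x = _sine(1.0, 20.0)
        t = np.arange(x.size) / FS
        gamma = 0.3 * np.sin(2 * np.pi * 50.0 * t) * (x > 0)
        events = detect_ssw(x + gamma, FS)
        assert len(events) > 10
        for e in events:
            # the negative lobe of sin starts at the half-cycle: its
            # extremum sits 0.75 s into each cycle
            assert (e.hyper_peak % 1.0) == pytest.approx(0.75, abs=0.1)

    def test_scaling_invariance(self, rng):
        """Detection criteria are amplitude-free: scaling the signal
        changes neither detections nor transition frequencies."""
        x = _sine(1.3, 20.0) + 0.1 * rng.standard_normal(int(20 * FS))
        e1 = detect_ssw(x, FS)
        e2 = detect_ssw(7.3 * x, FS)
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert a.f_tr == pytest.approx(b.f_tr)
            assert a.hyper_peak == pytest.approx(b.hyper_peak)

    def test_low_fs_rejected_for_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            detect_ssw(_sine(1.0, 20.0, fs=100.0), 100.0)


class TestAdaptiveConjunction:
    def test_self_conjunction_is_identity(self):
        x = _sine(1.0, 20.0)
        base = detect_ssw(x, FS)
        adaptive = detect_ssw_adaptive(x, FS, region_band=(0.5, 4.0))
        assert len(adaptive) == len(base)

    def test_fast_oscillation_outside_region_band_is_dropped(self):
        x = _sine(3.5, 20.0)
        assert detect_ssw(x, FS) != []
        assert detect_ssw_adaptive(x, FS, region_band=(0.5, 2.5)) == []

    def test_mixed_signal_keeps_only_in_band_events(self):
        x = _sine(1.0, 20.0) + 0.25 * _sine(3.5, 20.0)
        events = detect_ssw_adaptive(x, FS, region_band=(0.5, 2.5))
        assert len(events) > 5
        for e in events:
            assert e.pos_zc - e.neg_zc > 0.5  # 1 Hz cycles, not 3.5 Hz

    def test_invalid_region_band(self):
        with pytest.raises(ValueError):
            detect_ssw_adaptive(_sine(1.0, 20.0), FS, region_band=(0.01, 2.0))


class TestSwitchers:
    @staticmethod
    def _event(f_tr):
        tau = 1.0 / (2.0 * f_tr)
        return SlowWaveEvent(0.0, 1.0, 0.3, 0.3 + tau, tau, f_tr, 1)

    def test_transition_frequency_arithmetic(self):
        e = self._event(2.0)
        assert e.tau == pytest.approx(0.25)
        assert e.f_tr == pytest.approx(1.0 / (2.0 * e.tau))

    def test_bimodal_recovery(self, rng):
        """A 1.0/2.0 Hz bimodal transition-frequency set is split with
        >= 95% accuracy and a threshold between the modes."""
        slow = rng.normal(1.0, 0.1, 100)
        fast = rng.normal(2.0, 0.1, 100)
        events = [self._event(f) for f in np.concatenate([slow, fast])]
        labels, thr = classify_switchers(events, seed=0)
        assert 1.2 < thr < 1.8
        truth = ["slow"] * 100 + ["fast"] * 100
        acc = np.mean([a == b for a, b in zip(labels, truth)])
        assert acc >= 0.95

    def test_class_proportions_recovered(self, rng):
        """A 30/70 bimodal mixture is recovered within 5 points."""
        slow = rng.normal(1.0, 0.12, 60)
        fast = rng.normal(2.0, 0.12, 140)
        events = [self._event(f) for f in np.concatenate([slow, fast])]
        labels, _ = classify_switchers(events, seed=1)
        assert np.mean(np.array(labels) == "slow") == pytest.approx(0.30, abs=0.05)

    def test_too_few_events_refused(self):
        with pytest.raises(ValueError, match="10 events"):
            classify_switchers([self._event(1.0)] * 5)

    def test_degenerate_all_equal(self):
        events = [self._event(1.5) for _ in range(20)]
        labels, thr = classify_switchers(events)
        assert thr is None
        assert set(labels) == {"slow"}


class TestThetaBursts:
    def test_stationary_signal_has_no_bursts(self, rng):
        x = _sine(7.0, 20.0) + 0.05 * rng.standard_normal(int(20 * FS))
        assert detect_theta_bursts(x, FS) == []

    def test_injected_burst_detected_once(self, rng):
        x = 0.2 * _sine(7.0, 20.0) + 0.02 * rng.standard_normal(int(20 * FS))
        t = np.arange(x.size) / FS
        burst = (t >= 10.0) & (t < 10.6)
        x[burst] += 5 * 0.2 * np.sin(2 * np.pi * 7.0 * t[burst])
        events = detect_theta_bursts(x, FS)
        assert len(events) == 1
        assert 0.4 <= events[0].duration <= 1.0
        assert 9.8 < events[0].peak < 10.8
        assert events[0].peak_z >= 3

    def test_long_burst_rejected_by_duration_ceiling(self, rng):
        x = 0.2 * _sine(7.0, 20.0) + 0.02 * rng.standard_normal(int(20 * FS))
        t = np.arange(x.size) / FS
        burst = (t >= 8.0) & (t < 9.5)
        x[burst] += 5 * 0.2 * np.sin(2 * np.pi * 7.0 * t[burst])
        assert detect_theta_bursts(x, FS) == []

    def test_ensemble_baseline(self, rng):
        eps = [0.2 * _sine(7.0, 4.0) for _ in range(5)]
        mu, sd = theta_envelope_baseline(eps, FS)
        assert mu > 0 and sd >= 0


class TestPAC:
    def test_constant_amplitude_gives_zero(self):
        """With A(t) constant the mean-corrected covariance vanishes."""
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        phi = np.angle(np.exp(2j * np.pi * 1.0 * t))
        amp = np.ones_like(t)
        val = np.abs(np.mean(amp * np.exp(1j * phi)) - amp.mean() * np.mean(np.exp(1j * phi)))
        assert val < 1e-10
        # end-to-end: a pure slow sinusoid has a constant sigma envelope
        res = compute_pac(x, fs, (0.5, 2.0), (10, 16))
        assert res.value < 0.01

    def test_closed_form_half_for_cosine_modulation(self):
        """A(t) = 1 + cos(phi) over whole cycles gives PAC = 1/2."""
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        phi = 2 * np.pi * 2.0 * t
        amp = 1.0 + np.cos(phi)
        z = np.exp(1j * phi)
        val = np.abs(np.mean(amp * z) - amp.mean() * z.mean())
        assert val == pytest.approx(0.5, abs=1e-10)

    def test_coupled_signal_end_to_end(self):
        """Sigma amplitude gated by delta phase yields strong PAC through
        the filtering/Hilbert pipeline."""
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        delta = np.sin(2 * np.pi * 1.0 * t)
        sigma = (1.0 + 0.8 * np.cos(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 13.0 * t)
        res = compute_pac(delta + 0.5 * sigma, fs, (0.5, 2.0), (10, 16))
        assert res.value > 0.1
        assert res.value <= np.mean(np.abs(1.0 + 0.8 * np.cos(2 * np.pi * t)))

    def test_uncoupled_null_is_small(self, rng):
        """Independent amplitude and phase: PAC concentrates near zero
        (T = 4 s, fs = 256)."""
        fs = 256.0
        vals = []
        for _ in range(200):
            x = rng.standard_normal(int(4 * fs))
            vals.append(compute_pac(x, fs, (0.5, 2.0), (10, 16)).value)
        assert np.median(vals) < 0.05

    def test_null_separates_from_coupled(self, rng):
        """95th percentile of the uncoupled null sits below the median of
        depth-0.8 coupled windows."""
        fs = 256.0
        t = np.arange(int(4 * fs)) / fs
        null_vals, coupled_vals = [], []
        for _ in range(150):
            x = rng.standard_normal(t.size)
            null_vals.append(compute_pac(x, fs, (0.5, 2.0), (10, 16)).value)
        for _ in range(50):
            ph = rng.uniform(0, 2 * np.pi)
            delta = np.sin(2 * np.pi * 1.0 * t + ph)
            sigma = (1 + 0.8 * np.cos(2 * np.pi * 1.0 * t + ph)) * np.sin(2 * np.pi * 13.0 * t)
            coupled_vals.append(
                compute_pac(delta + 0.5 * sigma + 0.1 * rng.standard_normal(t.size),
                            fs, (0.5, 2.0), (10, 16)).value
            )
        assert np.percentile(null_vals, 95) < np.median(coupled_vals)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="cycles"):
            compute_pac(np.zeros(256), 256.0, (0.5, 2.0), (10, 16), window=(0.0, 0.5))


class TestPACContrast:
    @staticmethod
    def _coupled_signal(rng, depth, dur_s=120.0, fs=256.0):
        t = np.arange(int(dur_s * fs)) / fs
        delta = np.sin(2 * np.pi * 1.0 * t)
        sigma = (1 + depth * np.cos(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 13.0 * t)
        return delta + 0.5 * sigma + 0.1 * rng.standard_normal(t.size), t

    def test_identical_groups_not_separated(self, rng):
        x, t = self._coupled_signal(rng, 0.5)
        events = list(np.arange(5.0, 100.0, 10.0))
        res = pac_contrast(events, events, x, 256.0, (0.5, 2.0), (10, 16))
        assert res["p"] > 0.9
        assert np.median(res["pac_a"]) == pytest.approx(np.median(res["pac_b"]))

    def test_gated_group_beats_ungated(self, rng):
        """Events over a delta-gated sigma segment show higher PAC than
        events over an ungated segment (100 events/group)."""
        fs = 256.0
        half = int(260.0 * fs)
        t = np.arange(half) / fs
        gated = (
            np.sin(2 * np.pi * 1.0 * t)
            + 0.5 * (1 + 0.8 * np.cos(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 13.0 * t)
            + 0.1 * rng.standard_normal(half)
        )
        ungated = (
            np.sin(2 * np.pi * 1.0 * t)
            + 0.5 * np.sin(2 * np.pi * 13.0 * t)
            + 0.1 * rng.standard_normal(half)
        )
        x = np.concatenate([gated, ungated])
        ev_a = list(np.arange(3.0, 258.0, 2.55))[:100]
        ev_b = list(260.0 + np.arange(3.0, 258.0, 2.55))[:100]
        res = pac_contrast(ev_a, ev_b, x, fs, (0.5, 2.0), (10, 16))
        assert np.median(res["pac_a"]) > np.median(res["pac_b"])
        assert res["p"] < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pac_contrast([], [1.0], np.zeros(2048), 256.0, (0.5, 2.0), (10, 16))

    def test_theta_burst_cooccurrence_rule(self):
        from rnb.events import ThetaBurstEvent

        ssw = [SlowWaveEvent(0.0, 1.0, 5.0, 5.3, 0.3, 1.67, 1)]
        near = [ThetaBurstEvent(start=5.2, stop=5.6, peak=5.4, duration=0.4, peak_z=4.0)]
        far = [ThetaBurstEvent(start=5.8, stop=6.2, peak=6.0, duration=0.4, peak_z=4.0)]
        assert cooccurring(ssw, near).tolist() == [True]
        assert cooccurring(ssw, far).tolist() == [False]


class TestScalograms:
    def test_single_window_induced_equals_phase_locked(self, rng):
        w = rng.standard_normal((1, 512))
        f1, ind = event_scalograms(w, 256.0, "induced")
        f2, pl = event_scalograms(w, 256.0, "phase_locked")
        np.testing.assert_allclose(ind, pl, atol=1e-12)

    def test_identical_windows_induced_equals_phase_locked(self, rng):
        w = np.tile(rng.standard_normal(512), (8, 1))
        _, ind = event_scalograms(w, 256.0, "induced")
        _, pl = event_scalograms(w, 256.0, "phase_locked")
        np.testing.assert_allclose(ind, pl, atol=1e-12)

    def test_random_phase_kills_phase_locked_power(self, rng):
        """12 Hz bursts with random per-window phase keep induced power
        but cancel in the phase-locked average."""
        fs, n = 256.0, 1024
        t = np.arange(n) / fs
        wins = np.stack(
            [np.sin(2 * np.pi * 12.0 * t + rng.uniform(0, 2 * np.pi)) for _ in range(40)]
        )
        freqs = np.array([12.0])
        _, ind = event_scalograms(wins, fs, "induced", freqs=freqs)
        _, pl = event_scalograms(wins, fs, "phase_locked", freqs=freqs)
        mid = slice(n // 4, 3 * n // 4)
        assert pl[0, mid].mean() < 0.2 * ind[0, mid].mean()

    def test_sinusoid_amplitude_readout(self):
        """Peak-normalized filters: a unit sinusoid at a filter's center
        frequency maps to coefficient magnitude ~1."""
        fs, n = 256.0, 2048
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        _, scal = event_scalograms(x[None, :], fs, "induced", freqs=np.array([10.0]))
        mid = slice(n // 4, 3 * n // 4)
        assert scal[0, mid].mean() == pytest.approx(1.0, rel=0.05)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            event_scalograms(rng.standard_normal((2, 128)), 256.0, "evoked")
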
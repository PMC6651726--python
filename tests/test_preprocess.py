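"""Windowing, filtering, ApEn, and infomax ICA artifact rejection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from neurobrake import (
    MultichannelWindow,
    SimulationConfig,
    approximate_entropy,
    bandpass_filter,
    infomax_ica,
    remove_artifact_components,
    segment_windows,
    simulate_session,
)
from neurobrake.simulate import ar_denominator

from conftest import make_eeg_window


def brute_force_apen(x, m=2, r_factor=0.2):
    """Direct template-counting oracle for ApEn (O(n^2) loops)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_factor * x.std()
    if r == 0:
        return 0.0

    def phi(mm):
        count = 0.0
        n_t = n - mm + 1
        logs = []
        for i in range(n_t):
            c = 0
            for j in range(n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            logs.append(np.log(c / n_t))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


class TestSegmentWindows:
    def test_window_count_10s_125ms(self):
        s = simulate_session(SimulationConfig(duration_s=10.0, seed=0))
        wins = segment_windows(s, 1.0, 125.0)
        assert len(wins) == 73
        assert wins[0].start_time_s == 0.0
        assert wins[-1].start_time_s == pytest.approx(9.0)
        assert all(w.n_samples == 128 for w in wins)

    @pytest.mark.parametrize("step_ms,step_samples", [(62.5, 8), (125.0, 16), (250.0, 32)])
    def test_step_sizes_in_samples(self, step_ms, step_samples):
        s = simulate_session(SimulationConfig(duration_s=5.0, seed=0))
        wins = segment_windows(s, 1.0, step_ms)
        starts = [int(round(w.start_time_s * 128)) for w in wins]
        assert np.all(np.diff(starts) == step_samples)

    def test_short_session_yields_empty(self):
        s = simulate_session(SimulationConfig(duration_s=0.5, seed=0))
        assert segment_windows(s, 1.0, 125.0) == []

    def test_non_integer_step_rejected(self):
        s = simulate_session(SimulationConfig(duration_s=5.0, seed=0))
        with pytest.raises(ValueError):
            segment_windows(s, 1.0, 100.0)  # 12.8 samples


class TestBandpass:
    def test_inband_tone_preserved(self):
        """Spectral gain at 10 Hz stays within [0.9, 1.1]."""
        t = np.arange(128) / 128.0
        tone = np.sin(2 * np.pi * 10 * t)
        w = MultichannelWindow(np.tile(tone, (8, 1)), 0.0)
        out = bandpass_filter(w)
        cos = np.cos(2 * np.pi * 10 * t)
        gain = np.hypot(out.samples[0] @ tone, out.samples[0] @ cos) / 64.0
        assert 0.9 <= gain <= 1.1

    def test_dc_suppressed(self):
        w = MultichannelWindow(np.ones((8, 128)), 0.0)
        out = bandpass_filter(w)
        assert np.abs(out.samples).max() < 0.1

    def test_zero_in_zero_out(self):
        w = MultichannelWindow(np.zeros((8, 128)), 0.0)
        assert np.allclose(bandpass_filter(w).samples, 0.0)

    def test_high_cut_above_nyquist_rejected(self):
        w = MultichannelWindow(np.zeros((8, 128)), 0.0)
        with pytest.raises(ValueError):
            bandpass_filter(w, 1.0, 64.0)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(30, 3.7)) == 0.0

    def test_alternating_below_noise(self, rng):
        alt = np.tile([1.0, -1.0], 60)
        noise = rng.standard_normal(120)
        assert approximate_entropy(alt) < approximate_entropy(noise)

    @pytest.mark.parametrize("n", [10, 25, 50])
    def test_matches_brute_force_oracle(self, n, rng):
        x = rng.standard_normal(n)
        assert approximate_entropy(x) == pytest.approx(
            brute_force_apen(x), abs=1e-12
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy([1.0, 2.0, 3.0], m=2)

    @given(scale=st.floats(0.01, 1e4), offset=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_and_offset_invariance(self, scale, offset):
        """r proportional to SD makes ApEn scale- and shift-invariant."""
        x = np.random.default_rng(7).standard_normal(60)
        a = approximate_entropy(x)
        b = approximate_entropy(scale * x + offset)
        assert a == pytest.approx(b, rel=1e-8, abs=1e-8)


class TestInfomaxICA:
    def test_unmixing_identity_holds_exactly(self, eeg_window_array):
        w = MultichannelWindow(eeg_window_array, 0.0)
        res = infomax_ica(w, seed=0)
        centered = w.samples - w.samples.mean(axis=1, keepdims=True)
        assert np.allclose(res.components, res.unmixing @ centered, atol=1e-10)

    def test_deterministic_per_seed(self, eeg_window_array):
        w = MultichannelWindow(eeg_window_array, 0.0)
        r1 = infomax_ica(w, seed=3)
        r2 = infomax_ica(w, seed=3)
        assert np.array_equal(r1.unmixing, r2.unmixing)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_two_supergaussian_sources(self, seed):
        """Two laplacian sources in 8 channels come back at |r| > 0.9."""
        rng = np.random.default_rng(seed)
        sources = rng.laplace(size=(2, 128))
        mixing = rng.standard_normal((8, 2))
        x = mixing @ sources + 1e-4 * rng.standard_normal((8, 128))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            res = infomax_ica(MultichannelWindow(x, 0.0), seed=0)
        corr = np.abs(
            np.corrcoef(np.vstack([res.components, sources]))[
                : res.components.shape[0], res.components.shape[0] :
            ]
        )
        assert corr.max(axis=0).min() > 0.9

    def test_cross_check_against_fastica(self):
        """Independent route: sklearn FastICA finds the same sources."""
        from sklearn.decomposition import FastICA

        rng = np.random.default_rng(4)
        sources = rng.laplace(size=(3, 512))
        x = rng.standard_normal((8, 3)) @ sources + 1e-4 * rng.standard_normal((8, 512))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = infomax_ica(MultichannelWindow(x, 0.0), seed=0, max_iter=1000)
            fica = FastICA(n_components=3, random_state=0, max_iter=2000)
            y_f = fica.fit_transform(x.T).T
        for src in sources:
            mine = max(abs(np.corrcoef(c, src)[0, 1]) for c in res.components)
            ref = max(abs(np.corrcoef(c, src)[0, 1]) for c in y_f)
            assert mine > 0.9 and ref > 0.9


def _blink_case(seed: int, n: int = 1024, amp: float = 5.0):
    """Clean EEG (7 sources -> 8 channels) plus a frontal blink train."""
    rng = np.random.default_rng(seed)
    a = ar_denominator(0.0)
    src = np.vstack(
        [sp_signal.lfilter([1.0], a, rng.standard_normal(n + 500))[500:] for _ in range(7)]
    )
    src /= src.std(axis=1, keepdims=True)
    clean = (rng.standard_normal((8, 7)) * 0.5) @ src
    t = np.arange(n) / 128.0
    blink = np.zeros(n)
    for c in np.linspace(0.2, t[-1] - 0.2, 2):
        blink += np.exp(-0.5 * ((t - c) / 0.1) ** 2)
    topo = np.array([1.0, 0.9, 0.5, 0.45, 0.2, 0.2, 0.05, 0.05]) * np.std(clean) * amp
    return clean, clean + topo[:, None] * blink, blink


class TestArtifactRemoval:
    @pytest.mark.parametrize("seed", [1, 3, 4])
    def test_blink_component_removed(self, seed):
        """The low-ApEn blink component is censored; channels recover."""
        clean, contaminated, blink = _blink_case(seed)
        w = MultichannelWindow(contaminated, 0.0)
        res = infomax_ica(w, seed=0)
        apen = [approximate_entropy(c) for c in res.components]
        flagged = int(np.argmin(apen))
        assert abs(np.corrcoef(res.components[flagged], blink)[0, 1]) > 0.9
        cleaned = remove_artifact_components(w, res, apen_threshold=0.30)
        for ch in range(8):
            assert np.corrcoef(cleaned.samples[ch], clean[ch])[0, 1] > 0.9

    def test_threshold_zero_is_noop(self, eeg_window_array):
        w = MultichannelWindow(eeg_window_array, 0.0)
        res = infomax_ica(w, seed=0)
        out = remove_artifact_components(w, res, apen_threshold=0.0)
        assert np.allclose(out.samples, w.samples, atol=1e-8)

    def test_all_flagged_returns_input_with_warning(self, eeg_window_array):
        w = MultichannelWindow(eeg_window_array, 0.0)
        res = infomax_ica(w, seed=0)
        with pytest.warns(RuntimeWarning, match="unmodified"):
            out = remove_artifact_components(w, res, apen_threshold=np.inf)
        assert np.array_equal(out.samples, w.samples)

    def test_full_chain_reconstruction(self):
        """segment -> filter -> ICA -> reconstruct (nothing removed)
        returns the filtered window to numerical tolerance."""
        x = make_eeg_window(seed=9)
        filtered = bandpass_filter(MultichannelWindow(x, 0.0))
        res = infomax_ica(filtered, seed=0)
        recon = res.mixing @ res.components + res.channel_means[:, None]
        dev = np.abs(recon - filtered.samples).max()
        assert dev <= 1e-6 * filtered.samples.std()
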
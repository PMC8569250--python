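import numpy as np
import pytest
from scipy import signal as sg
from scipy import stats as sps

from neurocoh.montage import ChannelMontage, Recording
from neurocoh.preprocess import (
    PreprocessConfig,
    average_reference,
    bandpass,
    epoch,
    ica_clean,
    preprocess,
    reject_epochs,
    resample,
)


def _rec(data, fs=1000.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    m = ChannelMontage(tuple(f"ch{i}" for i in range(data.shape[0])))
    return Recording(data, fs, m)


class TestResample:
    def test_2048_to_1000_lengths(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 2048)), fs=2048.0)
        out = resample(rec, 1000.0)
        assert out.fs == 1000.0
        assert out.n_samples == 1000

    def test_identity_when_rate_unchanged(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 500)))
        out = resample(rec, 1000.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_sine_peak_preserved(self):
        fs = 2048.0
        t = np.arange(int(4 * fs)) / fs
        rec = _rec([np.sin(2 * np.pi * 10 * t)], fs=fs)
        out = resample(rec, 1000.0)
        f, p = sg.periodogram(out.data[0], fs=out.fs)
        assert abs(f[np.argmax(p)] - 10.0) <= f[1] - f[0]

    def test_invalid_targets_rejected(self):
        rec = _rec(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            resample(rec, 0.0)
        with pytest.raises(ValueError):
            resample(rec, 2000.0)


class TestBandpass:
    def test_stopband_and_passband(self):
        # long signal + generous trimming so the slow 0.1 Hz pole's
        # start-up transient has decayed before measuring
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        s60 = np.sin(2 * np.pi * 60 * t)
        s10 = np.sin(2 * np.pi * 10 * t)
        out60 = bandpass(_rec([s60], fs), 0.1, 40.0).data[0]
        out10 = bandpass(_rec([s10], fs), 0.1, 40.0).data[0]
        keep = slice(20_000, -20_000)
        rms = lambda x: np.sqrt(np.mean(x[keep] ** 2))
        assert rms(out60) < 0.10 * rms(s60)
        assert abs(rms(out10) - rms(s10)) < 0.05 * rms(s10)

    def test_dc_removed(self):
        out = bandpass(_rec([np.full(20000, 7.0)], 1000.0), 0.1, 40.0)
        assert np.max(np.abs(out.data[0][5000:-5000])) < 0.2

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_rec([np.zeros(1000)], 1000.0), 40.0, 0.1)


class TestEpoch:
    @pytest.mark.parametrize(
        "dur_s,epoch_ms,expected",
        [(360.0, 2000.0, 180), (2.5, 2000.0, 1), (4.0, 2000.0, 2)],
    )
    def test_epoch_counts(self, dur_s, epoch_ms, expected):
        fs = 1000.0
        rec = _rec(np.random.default_rng(1).standard_normal((2, int(dur_s * fs))), fs)
        es = epoch(rec, epoch_ms)
        assert es.n_epochs == expected

    def test_concatenation_reassembles_prefix(self):
        fs = 1000.0
        rec = _rec(np.random.default_rng(2).standard_normal((2, 4000)), fs)
        es = epoch(rec, 2000.0)
        rebuilt = es.epochs.transpose(1, 0, 2).reshape(2, -1)
        np.testing.assert_array_equal(rebuilt, rec.data[:, :4000])

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            epoch(_rec(np.zeros((1, 500))), 2000.0)


class TestRejectEpochs:
    def _es(self, arr):
        return epoch(_rec(arr), 1000.0 * arr.shape[1] // max(1, arr.shape[1] // 1000))

    def test_spike_epoch_removed(self):
        data = np.zeros((1, 6000))
        data[0, 2500] = 150.0  # spike inside epoch 1
        es = epoch(_rec(data), 2000.0)
        out = reject_epochs(es, 100.0)
        assert out.n_epochs == 2
        assert out.rejected_count == 1

    def test_all_clean_keeps_everything(self):
        es = epoch(_rec(np.zeros((2, 6000))), 2000.0)
        out = reject_epochs(es, 100.0)
        assert out.n_epochs == 3 and out.rejected_count == 0

    def test_boundary_is_kept_rule_strictly_greater(self, rng):
        data = rng.standard_normal((2, 6000))
        es = epoch(_rec(data), 2000.0)
        peak = float(np.max(np.abs(es.epochs)))
        out = reject_epochs(es, peak)
        assert out.n_epochs == es.n_epochs

    def test_idempotent(self, rng):
        data = rng.standard_normal((2, 8000)) * 15
        data[0, 100] = 500.0
        es = epoch(_rec(data), 2000.0)
        once = reject_epochs(es, 100.0)
        twice = reject_epochs(once, 100.0)
        np.testing.assert_array_equal(once.epochs, twice.epochs)

    def test_everything_rejected_raises(self):
        es = epoch(_rec(np.full((1, 2000), 200.0)), 2000.0)
        with pytest.raises(ValueError, match="inspect"):
            reject_epochs(es, 100.0)


class TestAverageReference:
    def test_two_channel_arithmetic(self):
        data = np.stack([np.full(2000, 2.0), np.zeros(2000)])
        es = epoch(_rec(data), 2000.0)
        out = average_reference(es)
        np.testing.assert_allclose(out.epochs[0, 0], 1.0)
        np.testing.assert_allclose(out.epochs[0, 1], -1.0)

    def test_channel_mean_is_zero_and_idempotent(self, rng):
        es = epoch(_rec(rng.standard_normal((8, 6000))), 2000.0)
        out = average_reference(es)
        assert np.max(np.abs(out.epochs.mean(axis=1))) < 1e-9
        again = average_reference(out)
        np.testing.assert_allclose(again.epochs, out.epochs, atol=1e-12)

    def test_already_balanced_unchanged(self):
        data = np.stack([np.ones(2000), -np.ones(2000)])
        es = epoch(_rec(data), 2000.0)
        np.testing.assert_allclose(average_reference(es).epochs, es.epochs)


class TestIcaClean:
    def test_disabled_is_identity(self, rng):
        es = epoch(_rec(rng.standard_normal((4, 8000))), 2000.0)
        assert ica_clean(es, enabled=False) is es

    def test_blink_like_transient_reduces_kurtosis(self, rng):
        fs = 1000.0
        n_ch, n = 6, 20000
        data = rng.standard_normal((n_ch, n)) * 5
        blink = np.zeros(n)
        for start in range(1000, n, 4000):
            blink[start : start + 300] += 120 * np.hanning(300)
        topo = np.linspace(1.0, 0.2, n_ch)  # frontal-dominant projection
        data += np.outer(topo, blink)
        es = epoch(_rec(data, fs), 2000.0)
        out = ica_clean(es, enabled=True, seed=0)
        k_before = sps.kurtosis(es.epochs[:, 0, :].ravel())
        k_after = sps.kurtosis(out.epochs[:, 0, :].ravel())
        assert k_after < k_before

    def test_clean_data_nearly_untouched(self, rng):
        fs = 250.0
        t = np.arange(20000) / fs
        data = np.stack([
            np.sin(2 * np.pi * f0 * t) + 0.3 * rng.standard_normal(t.size)
            for f0 in (6.0, 8.0, 10.0, 12.0)
        ])
        es = epoch(_rec(data, fs), 2000.0)
        out = ica_clean(es, enabled=True, seed=1)
        for ch in range(4):
            a = es.epochs[:, ch, :].ravel()
            b = out.epochs[:, ch, :].ravel()
            assert np.corrcoef(a, b)[0, 1] >= 0.95

    def test_short_data_skipped_with_warning(self, rng):
        es = epoch(_rec(rng.standard_normal((30, 500))), 500.0)
        with pytest.warns(UserWarning, match="too few"):
            out = ica_clean(es, enabled=True)
        np.testing.assert_array_equal(out.epochs, es.epochs)


class TestFullChain:
    def test_band_power_roughly_preserved_on_clean_input(self, rng):
        # already-clean 1000 Hz input: chain should change 1-30 Hz power < 5%
        fs = 1000.0
        n_ch, n = 4, 60000
        t = np.arange(n) / fs
        data = np.stack([
            10 * np.sin(2 * np.pi * 10 * t + ph) + 5 * np.sin(2 * np.pi * 6 * t + 2 * ph)
            for ph in rng.uniform(0, 2 * np.pi, n_ch)
        ])
        data -= data.mean(axis=0, keepdims=True)  # pre-referenced
        rec = _rec(data, fs)
        es = preprocess(rec, PreprocessConfig(fs_target=1000.0, ica_enabled=False))
        f_in, p_in = sg.welch(data, fs=fs, nperseg=1000)
        rebuilt = es.epochs.transpose(1, 0, 2).reshape(n_ch, -1)
        f_out, p_out = sg.welch(rebuilt, fs=es.fs, nperseg=1000)
        band = (f_in >= 1) & (f_in <= 30)
        pow_in = p_in[:, band].sum(axis=1)
        pow_out = p_out[:, band].sum(axis=1)
        assert np.all(np.abs(pow_out - pow_in) / pow_in < 0.05)
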
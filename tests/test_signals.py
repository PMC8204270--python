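"""Multiplexed synthesis and the EEG/dZ demodulation chain."""

import numpy as np
import pytest
from scipy import signal as sg

from seegeit.forward import simulate_transfer_series
from seegeit.scenario import make_seizure_scenario
from seegeit.signals import (
    FULL_RATE,
    REDUCED_RATE,
    RawRecording,
    SignalConfig,
    demodulate,
    demodulate_block,
    demodulate_channel,
    dz_noise_calibration,
    extract_eeg,
    slow_bandpass,
    synthesize_raw,
)


def single_carrier_recording(envelope, f_c=900.0, fs=5000.0, phase=0.7, noise=None):
    n = envelope.size
    t = np.arange(n) / fs
    x = envelope * np.sin(2 * np.pi * f_c * t + phase)
    if noise is not None:
        x = x + noise
    return RawRecording(
        samples=x[None, :],
        fs=fs,
        contact_ids=["c0"],
        carrier_table=[(f_c, 0)],
        t_start=0.0,
        config=SignalConfig(fs=fs),
    )


@pytest.fixture(scope="module")
def focal_block(study4):
    """One deterministic focal block through the whole signal chain."""
    sc = make_seizure_scenario(study4.model, seed=1, kind="focal")
    ts = simulate_transfer_series(study4.model, study4.protocol, study4.jacobian, sc)
    raw = synthesize_raw(
        ts, sc, study4.model, study4.protocol, noise_sd=0.0, seed=3,
        config=REDUCED_RATE, include_eeg=False, eeg_noise_sd=0.0,
    )
    return sc, ts, raw


class TestSynthesis:
    def test_pure_tones_spectrum(self, focal_block, study4):
        """Noise-free synthesis puts spectral lines only at the carriers."""
        _sc, _ts, raw = focal_block
        x = raw.samples[10]
        X = np.abs(np.fft.rfft(x))
        f = np.fft.rfftfreq(x.size, 1 / raw.fs)
        carriers = np.array([c[0] for c in raw.carrier_table])
        in_band = np.zeros_like(f, dtype=bool)
        for fc in carriers:
            in_band |= np.abs(f - fc) < 5.0
        out_power = np.sum(X[~in_band] ** 2)
        in_power = np.sum(X[in_band] ** 2)
        assert out_power < 1e-4 * in_power

    def test_reproducible_under_seed(self, study4):
        sc = make_seizure_scenario(study4.model, seed=1, kind="focal")
        ts = simulate_transfer_series(study4.model, study4.protocol, study4.jacobian, sc)
        kw = dict(noise_sd=10e-6, seed=9, config=REDUCED_RATE)
        a = synthesize_raw(ts, sc, study4.model, study4.protocol, **kw)
        b = synthesize_raw(ts, sc, study4.model, study4.protocol, **kw)
        assert np.array_equal(a.samples, b.samples)

    def test_too_close_carriers_rejected(self, study4):
        from dataclasses import replace

        sc = make_seizure_scenario(study4.model, seed=1, kind="focal")
        ts = simulate_transfer_series(study4.model, study4.protocol, study4.jacobian, sc)
        narrow = SignalConfig(fs=5000.0, demod_half_bandwidth=15.0)
        with pytest.raises(ValueError, match="carrier spacing"):
            synthesize_raw(ts, sc, study4.model, study4.protocol, config=narrow)


class TestExtractEEG:
    def test_carrier_rejection(self):
        """A pure 9 kHz carrier leaves <0.1% of its RMS in the EEG band."""
        fs = 50_000.0
        t = np.arange(int(10 * fs)) / fs
        x = 1e-3 * np.sin(2 * np.pi * 9000.0 * t)
        raw = RawRecording(
            samples=x[None, :], fs=fs, contact_ids=["c"],
            carrier_table=[(9000.0, 0)], config=FULL_RATE,
        )
        eeg, fs_out = extract_eeg(raw)
        assert fs_out == 1000.0
        assert eeg[0].std() < 1e-3 * x.std()

    def test_passband_preserved(self):
        fs = 50_000.0
        t = np.arange(int(10 * fs)) / fs
        x = 100e-6 * np.sin(2 * np.pi * 10.0 * t)
        raw = RawRecording(
            samples=x[None, :], fs=fs, contact_ids=["c"],
            carrier_table=[(9000.0, 0)], config=FULL_RATE,
        )
        eeg, _ = extract_eeg(raw)
        amp = np.abs(eeg[0][500:-500]).max()
        assert abs(amp - 100e-6) / 100e-6 < 0.01

    def test_output_rate_is_input_over_50(self, focal_block):
        _sc, _ts, raw = focal_block
        eeg, fs_out = extract_eeg(raw)
        assert fs_out == raw.fs / 50
        assert eeg.shape[1] == raw.n_samples // 50


class TestDemodulation:
    def test_known_modulation_round_trip(self):
        """A slow ramp on the carrier is recovered within 1% (post-transient)."""
        fs = 5000.0
        n = int(90 * fs)
        t = np.arange(n) / fs
        A = 1e-3 * (1 + 0.06 * np.clip((t - 40) / 15, 0, 1))
        raw = single_carrier_recording(A, fs=fs)
        env, fs_dz = demodulate_channel(raw, 900.0)
        tt = np.arange(env.shape[1]) / fs_dz
        truth = 1e-3 * (1 + 0.06 * np.clip((tt - 40) / 15, 0, 1))
        core = slice(int(5 * fs_dz), -int(5 * fs_dz))
        rel = (env[0][core] - truth[core]) / truth[core]
        assert np.sqrt(np.mean(rel**2)) < 0.01

    def test_adjacent_carrier_leakage(self):
        """Equal-power neighbor one 50 Hz step away leaks <1% of the envelope."""
        fs = 5000.0
        n = int(90 * fs)
        t = np.arange(n) / fs
        x = 1e-3 * np.sin(2 * np.pi * 900.0 * t) + 1e-3 * np.sin(2 * np.pi * 905.0 * t + 1.0)
        raw = RawRecording(
            samples=x[None, :], fs=fs, contact_ids=["c"],
            carrier_table=[(900.0, 0), (905.0, 1)], config=SignalConfig(fs=fs),
        )
        env, fs_dz = demodulate_channel(raw, 900.0)
        core = env[0][int(5 * fs_dz) : -int(5 * fs_dz)]
        assert np.abs(core - 1e-3).max() < 0.01 * 1e-3

    def test_constant_amplitude_flat_envelope(self):
        fs = 5000.0
        raw = single_carrier_recording(np.full(int(90 * fs), 2e-3), fs=fs)
        env, fs_dz = demodulate_channel(raw, 900.0)
        core = env[0][int(5 * fs_dz) : -int(5 * fs_dz)]
        assert np.abs(core / 2e-3 - 1).max() < 1e-3

    def test_backends_agree(self, focal_block, study4):
        """Envelope (band-pass + Hilbert) vs I/Q zoom: within 0.5%."""
        _sc, _ts, raw = focal_block
        blk_iq = demodulate(raw, study4.channels, method="iq_fft")
        f_c = raw.carrier_table[4][0]
        env, fs_dz = demodulate_channel(raw, f_c)
        c_idx = {c: i for i, c in enumerate(raw.contact_ids)}
        rows = [i for i, (d, _c) in enumerate(study4.channels) if d == 4][:12]
        core = slice(int(5 * fs_dz), -int(5 * fs_dz))
        for r in rows:
            _d, cid = study4.channels[r]
            a = blk_iq.dz[r][core]
            b = env[c_idx[cid]][core]
            assert np.abs(a - b).max() / np.abs(b).mean() < 0.005

    def test_unknown_carrier_rejected(self, focal_block):
        _sc, _ts, raw = focal_block
        with pytest.raises(ValueError, match="carrier"):
            demodulate_channel(raw, 123.0)

    def test_end_to_end_linearity(self, study4):
        """Doubling the conductivity change doubles the demodulated deviation."""
        devs = []
        for frac in (-0.1, -0.2):
            sc = make_seizure_scenario(
                study4.model, seed=1, kind="focal", delta_sigma_fraction=frac
            )
            ts = simulate_transfer_series(study4.model, study4.protocol, study4.jacobian, sc)
            raw = synthesize_raw(
                ts, sc, study4.model, study4.protocol, noise_sd=0.0, seed=3,
                config=REDUCED_RATE, include_eeg=False, eeg_noise_sd=0.0,
            )
            blk = demodulate(raw, study4.channels)
            ch = int(np.argmax(np.abs(ts.deviations[:, 60])))
            base = blk.dz[ch, : int(20 * blk.fs_dz)].mean()
            devs.append(blk.dz[ch, int(55 * blk.fs_dz) : int(65 * blk.fs_dz)].mean() - base)
        assert abs(devs[1] / devs[0] - 2.0) < 0.02

    def test_eeg_does_not_perturb_dz_envelopes(self, study4):
        """Sub-300 Hz EEG content is orthogonal to the carrier envelopes."""
        sc = make_seizure_scenario(study4.model, seed=1, kind="focal")
        ts = simulate_transfer_series(study4.model, study4.protocol, study4.jacobian, sc)
        kw = dict(noise_sd=0.0, seed=3, config=REDUCED_RATE, eeg_noise_sd=0.0)
        quiet = synthesize_raw(ts, sc, study4.model, study4.protocol, include_eeg=False, **kw)
        spiky = synthesize_raw(ts, sc, study4.model, study4.protocol, include_eeg=True, **kw)
        rows = list(range(0, len(study4.channels), 97))
        a = demodulate_block(quiet, [study4.channels[r] for r in rows])[0]
        b = demodulate_block(spiky, [study4.channels[r] for r in rows])[0]
        scale = np.abs(a).mean()
        assert np.abs(a - b).max() < 1e-4 * scale


class TestSlowBandpass:
    def test_dc_removed(self):
        x = np.full((1, 20_000), 3.0)
        y = slow_bandpass(x, 100.0)
        assert np.abs(y[:, 2000:-2000]).max() < 1e-6

    def test_5hz_attenuated(self):
        t = np.arange(20_000) / 100.0
        x = np.sin(2 * np.pi * 5.0 * t)[None, :]
        y = slow_bandpass(x, 100.0)
        att = np.abs(y[0][2000:-2000]).max()
        assert att < 10 ** (-10 / 20)  # > 10 dB down

    def test_passband_center_within_3db(self):
        t = np.arange(30_000) / 100.0
        x = np.sin(2 * np.pi * 0.1 * t)[None, :]
        y = slow_bandpass(x, 100.0)
        amp = np.abs(y[0][5000:-5000]).max()
        assert amp > 10 ** (-3 / 20)

    def test_short_block_warns(self):
        with pytest.warns(UserWarning, match="shorter than 100 s"):
            slow_bandpass(np.zeros((1, 500)), 100.0)


def test_noise_calibration_scales_linearly():
    """Demodulated noise SD is proportional to the raw noise SD."""
    s, f = dz_noise_calibration(5000.0)
    assert 0 < f < s < 1
    rng = np.random.default_rng(7)
    fs = 5000.0
    n = int(60 * fs)
    t = np.arange(n) / fs
    for raw_sd in (1e-4, 2e-4):
        x = 5e-3 * np.sin(2 * np.pi * 900.0 * t) + rng.normal(0, raw_sd, n)
        raw = single_carrier_recording(np.full(n, 0.0), fs=fs)  # placeholder
        raw.samples = x[None, :]
        dz, fs_dz = demodulate_block(raw, [(0, "c0")])
        core = dz[0][int(5 * fs_dz) : -int(5 * fs_dz)]
        assert abs(core.std() / (raw_sd * s) - 1) < 0.25
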
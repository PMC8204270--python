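"""Frequency-division-multiplexed raw recordings and the demodulation chain.

The acquisition model: every contact records, at 50 kHz, the sum of the
local EEG, one amplitude-modulated carrier per injection pair (8.5-10 kHz,
50 Hz steps; the modulation is the slowly varying transfer voltage), and
instrumentation white noise.  Demodulation separates the two signal classes:

* EEG: 3rd-order 300 Hz low-pass (zero-phase), decimate x50 -> 1 kHz;
* dZ:  per-carrier band-pass of +-10 Hz (30th-order IIR realized as a
  Butterworth cascade in second-order sections), analytic-signal envelope,
  decimate x500 -> 100 Hz; optional 0.01-1 Hz 1st-order band-pass before
  imaging.

A reduced-rate mode (5 kHz sampling, carriers 850-1000 Hz, identical
decimation ratios and relative bandwidths) scales every frequency by 1/10
for cheap cohort runs; the full 50 kHz chain is the default configuration.

Two demodulation backends are provided and agree within 0.5%:
``envelope`` (the band-pass + analytic-envelope definition above, per
channel) and ``iq_fft`` (synchronous I/Q realized by FFT zoom with the same
zero-phase Butterworth magnitude response, vectorized over all channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .forward import TransferSeries
from .geometry import HeadModel
from .protocol import InjectionProtocol
from .scenario import BLOCK_END, BLOCK_START, SeizureScenario, synthesize_eeg

__all__ = [
    "SignalConfig",
    "FULL_RATE",
    "REDUCED_RATE",
    "RawRecording",
    "DemodulatedBlock",
    "synthesize_raw",
    "extract_eeg",
    "demodulate_channel",
    "demodulate_block",
    "slow_bandpass",
    "dz_noise_calibration",
]


@dataclass(frozen=True)
class SignalConfig:
    """Sampling/filtering configuration of the multiplexed chain.

    ``carrier_scale`` scales the nominal 8.5-10 kHz carriers; all bandwidths
    scale with it so the reduced-rate mode is an exact frequency-shrunk copy
    of the full chain.
    """

    fs: float = 50_000.0  # raw sampling rate, Hz
    eeg_decim: int = 50  # -> 1 kHz EEG at full rate
    dz_decim: int = 500  # -> 100 Hz dZ at full rate
    demod_half_bandwidth: float = 10.0  # Hz at full rate, +- around carrier
    demod_order: int = 30  # 30th-order band-pass realized as 15 SOS pairs
    eeg_lowpass: float = 300.0  # Hz, 3rd-order Butterworth
    antialias_cutoff: float = 12_500.0  # hardware antialiasing bound

    @property
    def carrier_scale(self) -> float:
        return self.fs / 50_000.0

    @property
    def fs_eeg(self) -> float:
        return self.fs / self.eeg_decim

    @property
    def fs_dz(self) -> float:
        return self.fs / self.dz_decim

    @property
    def half_bw(self) -> float:
        return self.demod_half_bandwidth * self.carrier_scale

    @property
    def eeg_cutoff(self) -> float:
        # At full rate this is exactly 300 Hz; in reduced mode the nominal
        # cutoff would exceed the decimated Nyquist, so it is capped.
        return min(self.eeg_lowpass, 0.8 * self.fs_eeg / 2.0)

    def scale_frequency(self, f_nominal: float) -> float:
        return f_nominal * self.carrier_scale


FULL_RATE = SignalConfig()
REDUCED_RATE = SignalConfig(fs=5_000.0)


@dataclass
class RawRecording:
    """Multiplexed raw block: (n_contacts, n_samples) volts at ``fs``."""

    samples: np.ndarray
    fs: float
    contact_ids: list[str]
    carrier_table: list[tuple[float, int]]  # (carrier Hz at this fs, injection index)
    t_start: float = BLOCK_START
    config: SignalConfig = field(default_factory=SignalConfig)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs


@dataclass
class DemodulatedBlock:
    """EEG (per contact) and dZ (per injection x measurement contact) traces.

    ``channels`` matches the forward model's Jacobian row order.  Baseline
    statistics are attached by the ictal-analysis stage; ``dz_percent``
    requires them.
    """

    eeg: np.ndarray  # (n_contacts, n_eeg) V
    fs_eeg: float
    dz: np.ndarray  # (n_channels, n_dz) V (carrier-envelope modulus)
    fs_dz: float
    channels: list[tuple[int, str]]
    contact_ids: list[str]
    t_start: float = BLOCK_START
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None

    @property
    def dz_times(self) -> np.ndarray:
        return self.t_start + np.arange(self.dz.shape[1]) / self.fs_dz

    @property
    def eeg_times(self) -> np.ndarray:
        return self.t_start + np.arange(self.eeg.shape[1]) / self.fs_eeg

    @property
    def duration(self) -> float:
        return self.dz.shape[1] / self.fs_dz

    @property
    def dz_percent(self) -> np.ndarray:
        if self.baseline_mean is None:
            raise ValueError("baselines not computed; run ictal.compute_baseline first")
        base = np.where(self.baseline_mean == 0, np.nan, self.baseline_mean)
        return 100.0 * (self.dz - self.baseline_mean[:, None]) / base[:, None]


def synthesize_raw(
    transfer: TransferSeries,
    scenario: SeizureScenario,
    model: HeadModel,
    protocol: InjectionProtocol,
    noise_sd: float = 20e-6,
    seed: int = 0,
    config: SignalConfig = FULL_RATE,
    include_eeg: bool = True,
    eeg_noise_sd: float = 5e-6,
) -> RawRecording:
    """Mix EEG, amplitude-modulated carriers and noise at ``config.fs``.

    Each contact's sample is EEG(t) + sum_c A_(c,ch)(t) sin(2 pi f_c t + phi_c)
    + n(t), with A the transfer voltage from the forward model (linearly
    interpolated from its 1 s grid) and phi_c seeded random phases.

    The instrumentation noise has two independent parts: ``noise_sd`` sets
    the white level in the carrier band (high-passed below half the lowest
    carrier), which is what the dZ-domain SNR condition controls, while
    ``eeg_noise_sd`` is a fixed broadband floor that dominates the EEG band.
    Splitting the bands keeps the electrographic traces clinically readable
    while the EIT noise level is varied over orders of magnitude.
    Reproducible under (scenario, seed).
    """
    fs = config.fs
    freqs = np.array([config.scale_frequency(f) for _s, _k, f in protocol.pairs])
    if freqs.size > 1:
        gaps = np.diff(np.sort(freqs))
        if gaps.min() < 2.0 * (2.0 * config.half_bw) - 1e-9:
            raise ValueError(
                f"carrier spacing {gaps.min():.1f} Hz < 2x demodulation bandwidth "
                f"({4 * config.half_bw:.1f} Hz)"
            )
    if freqs.max() >= config.antialias_cutoff * config.carrier_scale:
        raise ValueError("carriers must stay below the antialias cutoff")

    t0 = float(transfer.times[0])
    t1 = float(transfer.times[-1])
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs

    contact_ids = [e.id for e in model.electrodes]
    c_index = {c: i for i, c in enumerate(contact_ids)}
    n_ch = len(contact_ids)

    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(protocol.pairs))

    raw = np.zeros((n_ch, n))
    if noise_sd > 0:
        band_noise = rng.normal(0.0, noise_sd, size=(n_ch, n))
        sos_hp = signal.butter(4, 0.5 * freqs.min(), btype="high", fs=fs, output="sos")
        raw += signal.sosfilt(sos_hp, band_noise, axis=1)
    if eeg_noise_sd > 0:
        raw += rng.normal(0.0, eeg_noise_sd, size=(n_ch, n))

    if include_eeg:
        _te, eeg = synthesize_eeg(scenario, model, fs, t0, t1)
        raw += eeg

    dev = transfer.voltages - transfer.baseline[:, None]
    f_tc = transfer.truth_f
    ff = float(f_tc @ f_tc)
    s_ch = dev @ f_tc / ff if ff > 0 else np.zeros(dev.shape[0])
    separable = (
        np.max(np.abs(dev - s_ch[:, None] * f_tc[None, :]))
        <= 1e-9 * (np.max(np.abs(dev)) + 1e-30)
    )

    if separable:
        # V(t) = V0 + s f(t): two small matmuls instead of a per-carrier loop.
        V0_mat = np.zeros((len(protocol.pairs), n_ch))
        S_mat = np.zeros_like(V0_mat)
        for ch, (d, cid) in enumerate(transfer.channels):
            V0_mat[d, c_index[cid]] = transfer.baseline[ch]
            S_mat[d, c_index[cid]] = s_ch[ch]
        tones = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        f_raw = np.interp(t, transfer.times, f_tc)
        raw += V0_mat.T @ tones
        raw += (S_mat.T @ tones) * f_raw[None, :]
    else:
        # General path: per-carrier piecewise-linear envelope interpolation.
        frame_pos = (t - transfer.times[0]) / (transfer.times[1] - transfer.times[0])
        idx = np.clip(frame_pos.astype(np.int64), 0, transfer.times.size - 2)
        frac = frame_pos - idx
        amp_by_inj = np.zeros((len(protocol.pairs), n_ch, transfer.times.size))
        for ch, (d, cid) in enumerate(transfer.channels):
            amp_by_inj[d, c_index[cid]] = transfer.voltages[ch]
        for d, f_c in enumerate(freqs):
            tone = np.sin(2.0 * np.pi * f_c * t + phases[d])
            A = amp_by_inj[d][:, idx] * (1.0 - frac) + amp_by_inj[d][:, idx + 1] * frac
            raw += A * tone

    carrier_table = [(float(f), d) for d, f in enumerate(freqs)]
    return RawRecording(
        samples=raw,
        fs=fs,
        contact_ids=contact_ids,
        carrier_table=carrier_table,
        t_start=t0,
        config=config,
    )


def extract_eeg(raw: RawRecording) -> tuple[np.ndarray, float]:
    """Zero-phase 3rd-order low-pass then x``eeg_decim`` decimation.

    Returns (traces, fs_out).  Carriers sit >28x above the 300 Hz cutoff, so
    the forward-backward 3rd-order response (~6th-order magnitude) plus the
    decimator's anti-alias FIR attenuates them by far more than 60 dB.
    """
    cfg = raw.config
    sos = signal.butter(3, cfg.eeg_cutoff, btype="low", fs=raw.fs, output="sos")
    # Wrap-pad before filtering: the carriers complete integer cycles over
    # the block, so periodic extension keeps them phase-continuous and the
    # edge transient (which would otherwise be carrier-sized) vanishes.
    P = int(min(raw.n_samples, round(2.0 * raw.fs)))
    xp = np.concatenate(
        [raw.samples[:, -P:], raw.samples, raw.samples[:, :P]], axis=1
    )
    lowpassed = signal.sosfiltfilt(sos, xp, axis=1)[:, P:-P]
    out = signal.resample_poly(lowpassed, 1, cfg.eeg_decim, axis=1, padtype="line")
    return out, raw.fs / cfg.eeg_decim


def _bandpass_sos(f_c: float, half_bw: float, fs: float, order: int) -> np.ndarray:
    sos = signal.butter(
        order // 2, [f_c - half_bw, f_c + half_bw], btype="bandpass", fs=fs, output="sos"
    )
    # Stability guard: all section poles strictly inside the unit circle.
    for sec in sos:
        poles = np.roots(np.concatenate([[1.0], sec[4:6]]))
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable band-pass realization at {f_c:.0f} Hz (pole radius >= 1); "
                "use second-order sections at a narrower rate ratio"
            )
    return sos


def _stopband_rejection_db(sos: np.ndarray, f_c: float, offset: float, fs: float) -> float:
    w, h = signal.sosfreqz(sos, worN=[f_c - offset, f_c + offset], fs=fs)
    # forward-backward filtering doubles the attenuation (|H|^2)
    return float(20.0 * np.log10(np.max(np.abs(h) ** 2) + 1e-300))


def demodulate_channel(
    raw: RawRecording,
    carrier_frequency: float,
    contacts: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Band-pass + analytic-envelope demodulation of one carrier.

    Zero-phase 30th-order Butterworth band-pass of +-10 Hz (scaled) around
    the carrier, modulus of the analytic signal, then anti-aliased
    decimation x``dz_decim``.  Returns (envelopes, fs_dz) with envelopes
    shaped (n_selected_contacts, n_dz).  Warns if adjacent-carrier rejection
    (one 50 Hz step away) is worse than -40 dB.
    """
    cfg = raw.config
    table = {f: d for f, d in raw.carrier_table}
    if float(carrier_frequency) not in table:
        raise ValueError(f"carrier {carrier_frequency} Hz not in the recording's carrier table")
    sos = _bandpass_sos(float(carrier_frequency), cfg.half_bw, raw.fs, cfg.demod_order)
    rej = _stopband_rejection_db(sos, float(carrier_frequency), 50.0 * cfg.carrier_scale, raw.fs)
    if rej > -40.0:
        warnings.warn(
            f"adjacent-carrier rejection only {rej:.1f} dB at +-{50 * cfg.carrier_scale:.0f} Hz",
            stacklevel=2,
        )
    x = raw.samples if contacts is None else raw.samples[np.asarray(contacts)]
    x = np.atleast_2d(x)
    # Narrow-band poles sit at radius ~1 - 1e-4, so transients persist for
    # seconds.  Pad ~10 s with *periodic* (wrap) extension: carriers complete
    # integer cycles over the block, so wrapping keeps their phase smooth,
    # unlike reflection which flips the phase slope at the junction.
    P = int(min(x.shape[1], round(10.0 * raw.fs)))
    xp = np.concatenate([x[:, -P:], x, x[:, :P]], axis=1)
    banded = signal.sosfiltfilt(sos, xp, axis=1)
    env = np.abs(signal.hilbert(banded, axis=1))[:, P:-P]
    dz = signal.resample_poly(env, 1, cfg.dz_decim, axis=1, padtype="line")
    return dz, raw.fs / cfg.dz_decim


def _zoom_response(
    f_c: float, n_keep: int, df: float, half_bw: float, fs: float, order: int
) -> np.ndarray:
    """Zero-phase |H|^2 of the demodulation band-pass on the zoom-FFT bins.

    Evaluates the same Butterworth SOS cascade the ``envelope`` backend
    applies (forward-backward, hence the squared magnitude), so the two
    backends share one frequency response.
    """
    k = np.fft.fftfreq(n_keep, d=1.0) * n_keep  # bin offsets, fft order
    sos = _bandpass_sos(f_c, half_bw, fs, order)
    _w, h = signal.sosfreqz(sos, worN=f_c + k * df, fs=fs)
    return np.abs(h) ** 2


def demodulate_block(
    raw: RawRecording,
    channels: list[tuple[int, str]],
    pad_seconds: float | None = None,
) -> tuple[np.ndarray, float]:
    """Vectorized synchronous I/Q demodulation of every (carrier, contact).

    FFT-zoom realization: one real FFT per contact, excise the +-fs_dz/2
    band around each carrier, weight it with the zero-phase Butterworth
    magnitude response used by the ``envelope`` backend, and inverse-FFT
    straight at the decimated rate.  When every carrier completes an integer
    number of cycles over the block (true for the 50 Hz-step carrier set on
    whole-second blocks) the block is treated circularly, which keeps every
    carrier phase-continuous at the wrap; otherwise the block is
    reflect-padded and cosine-tapered.  Returns (dz, fs_dz) with rows
    ordered like ``channels``.
    """
    cfg = raw.config
    fs, n = raw.fs, raw.n_samples
    fs_dz = cfg.fs_dz
    duration = n / fs
    bin_centered = all(
        abs(f * duration - round(f * duration)) < 1e-6 for f, _d in raw.carrier_table
    )
    if pad_seconds is None:
        pad_seconds = 0.0 if bin_centered else 10.0
    pad = int(round(pad_seconds * fs))
    n_pad = n + 2 * pad
    # keep-counts must divide evenly into the (padded) length
    n_keep = int(round(n_pad * fs_dz / fs))
    if abs(n_keep * fs / fs_dz - n_pad) > 1e-6:
        raise ValueError("block length must be a multiple of the dz decimation")

    if pad > 0:
        x = np.pad(raw.samples, ((0, 0), (pad, pad)), mode="reflect")
        n_tap = pad // 2
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_tap) / n_tap))
        x = x.copy()
        x[:, :n_tap] *= ramp[None, :]
        x[:, -n_tap:] *= ramp[::-1][None, :]
    else:
        x = raw.samples
    X = np.fft.fft(x, axis=1)
    df = fs / n_pad

    c_index = {c: i for i, c in enumerate(raw.contact_ids)}
    freq_of_inj = {d: f for f, d in raw.carrier_table}
    n_dz = int(round(n * fs_dz / fs))
    pad_dz = (n_keep - n_dz) // 2
    out = np.empty((len(channels), n_dz), dtype=float)

    for d in sorted({d for d, _c in channels}):
        f_c = freq_of_inj[d]
        b0 = int(round(f_c / df))
        resp = _zoom_response(f_c, n_keep, df, cfg.half_bw, fs, cfg.demod_order)
        sel = (b0 + np.fft.fftfreq(n_keep, d=1.0) * n_keep).astype(np.int64)
        Z = X[:, sel] * resp[None, :]
        z = np.fft.ifft(Z, axis=1)  # complex baseband at fs_dz, length n_keep
        env_all = (2.0 * n_keep / n_pad) * np.abs(z)
        env_all = env_all[:, pad_dz : pad_dz + n_dz]
        for ch, (dd, cid) in enumerate(channels):
            if dd == d:
                out[ch] = env_all[c_index[cid]]
    return out, fs_dz


def slow_bandpass(dz: np.ndarray, fs_dz: float) -> np.ndarray:
    """1st-order 0.01-1 Hz Butterworth band-pass, zero-phase.

    Applied to dZ traces before imaging to improve SNR; passes the 1-100 s
    seizure time courses (loss < 30% mid-band) while removing drift and
    residual carrier-rate noise.  Warns for blocks shorter than 100 s, where
    the high-pass transient spans the whole window.
    """
    dz = np.atleast_2d(dz)
    if dz.shape[1] / fs_dz < 100.0:
        warnings.warn(
            "block shorter than 100 s: 0.01 Hz high-pass transient spans the window; "
            "remove the channel baseline mean beforehand to keep it small",
            stacklevel=2,
        )
    sos = signal.butter(1, [0.01, 1.0], btype="bandpass", fs=fs_dz, output="sos")
    padlen = int(min(dz.shape[1] - 1, round(30.0 * fs_dz)))
    return signal.sosfiltfilt(sos, dz, axis=1, padlen=padlen)


def demodulate(
    raw: RawRecording,
    channels: list[tuple[int, str]],
    method: str = "iq_fft",
) -> DemodulatedBlock:
    """Full demodulation of a raw block into EEG and dZ traces."""
    eeg, fs_eeg = extract_eeg(raw)
    if method == "iq_fft":
        dz, fs_dz = demodulate_block(raw, channels)
    elif method == "envelope":
        freq_of_inj = {d: f for f, d in raw.carrier_table}
        c_index = {c: i for i, c in enumerate(raw.contact_ids)}
        rows = []
        fs_dz = raw.fs / raw.config.dz_decim
        by_inj: dict[int, np.ndarray] = {}
        for d in sorted({d for d, _c in channels}):
            by_inj[d], fs_dz = demodulate_channel(raw, freq_of_inj[d])
        dz = np.vstack([by_inj[d][c_index[cid]] for d, cid in channels])
    else:
        raise ValueError(f"unknown demodulation method {method!r}")
    return DemodulatedBlock(
        eeg=eeg,
        fs_eeg=fs_eeg,
        dz=dz,
        fs_dz=fs_dz,
        channels=list(channels),
        contact_ids=list(raw.contact_ids),
        t_start=raw.t_start,
    )


@lru_cache(maxsize=8)
def dz_noise_calibration(fs: float, duration: float = 60.0) -> tuple[float, float]:
    """(sample-level, 1 s frame-level) envelope noise SD per unit raw SD.

    Measured once per configuration by demodulating a unit-amplitude carrier
    plus unit-SD white noise through the I/Q chain (fixed internal seed).
    The sample-level figure is the demodulated baseline SD; the frame-level
    figure is the SD of 1 s means, the noise that actually enters each
    per-second image frame (the two differ because the +-10 Hz band leaves
    ~20 effectively independent samples per second at the full rate).
    """
    cfg = SignalConfig(fs=fs)
    f_c = cfg.scale_frequency(9000.0)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(12345)
    x = np.sin(2 * np.pi * f_c * t) + rng.normal(0.0, 1.0, size=n)
    raw = RawRecording(
        samples=x[None, :],
        fs=fs,
        contact_ids=["cal"],
        carrier_table=[(f_c, 0)],
        t_start=0.0,
        config=cfg,
    )
    dz, fs_dz = demodulate_block(raw, [(0, "cal")])
    # discard edge transients
    k = int(5 * fs_dz)
    core = dz[0, k:-k] if dz.shape[1] > 2 * k else dz[0]
    win = int(round(fs_dz))
    frames = core[: (core.size // win) * win].reshape(-1, win).mean(axis=1)
    return float(core.std()), float(frames.std(ddof=1))


@lru_cache(maxsize=8)
def frame_noise_profile(
    fs: float, n_seconds: int = 90, n_reps: int = 256
) -> tuple[np.ndarray, float]:
    """Noise behaviour of 1 s imaging frames across a finite filtered block.

    The demodulation itself is stationary, but the zero-phase 0.01-1 Hz
    band-pass applied before imaging has edge transients on a finite block,
    so frames near the block boundaries carry more noise than interior
    ones, and consecutive frames are correlated.  Pushing ``n_reps``
    unit-noise channels through carrier + demodulation + slow band-pass +
    frame averaging (fixed internal seed) yields

    * ``profile``: per-frame noise SD, normalized to 1 at mid-block (used
      to scale propagated voxel noise frame by frame), and
    * ``baseline_factor``: the expected value of the estimator the analysis
      actually computes -- the SD over the first 20 baseline frames --
      relative to the true mid-block SD.  Dividing the measured baseline SD
      by this factor removes both the edge inflation and the downward bias
      that frame-to-frame correlation puts on a 20-sample SD.
    """
    cfg = SignalConfig(fs=fs)
    f_c = cfg.scale_frequency(9000.0)
    n = int(round(n_seconds * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(54321)
    x = np.sin(2 * np.pi * f_c * t)[None, :] + rng.normal(0.0, 1.0, size=(n_reps, n))
    raw = RawRecording(
        samples=x,
        fs=fs,
        contact_ids=[f"cal{i}" for i in range(n_reps)],
        carrier_table=[(f_c, 0)],
        t_start=0.0,
        config=cfg,
    )
    dz, fs_dz = demodulate_block(raw, [(0, f"cal{i}") for i in range(n_reps)])
    dev = dz - dz.mean(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="block shorter than 100 s")
        filt = slow_bandpass(dev, fs_dz)
    win = int(round(fs_dz))
    n_frames = filt.shape[1] // win
    frames = filt[:, : n_frames * win].reshape(n_reps, n_frames, win).mean(axis=2)
    sd = frames.std(axis=0, ddof=1)
    mid = slice(n_frames // 3, 2 * n_frames // 3)
    true_mid = np.sqrt(np.mean(sd[mid] ** 2))
    n_base = min(20, n_frames)
    base_est = np.sqrt(np.mean(frames[:, :n_base].std(axis=1, ddof=1) ** 2))
    return sd / true_mid, float(base_est / true_mid)


def raw_noise_for_snr(peak_deviation: float, snr_db: float, config: SignalConfig) -> float:
    """Raw white-noise SD realizing a target dZ SNR in this configuration.

    The SNR condition is defined on the full-rate chain: peak clean dZ
    deviation over the demodulated (100 Hz) baseline sample SD.  A
    reduced-rate replica is matched at the 1 s imaging cadence -- the
    frame-level noise, which is what enters the reconstructed frames -- so
    both modes realize the same imaging problem.
    """
    s_full, f_full = dz_noise_calibration(50_000.0)
    target_frame_sd = (peak_deviation / 10.0 ** (snr_db / 20.0)) * (f_full / s_full)
    _s, f_here = dz_noise_calibration(config.fs)
    return target_frame_sd / f_here
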
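"""Seizure detection and characterization on demodulated blocks.

Implements the block-level analysis rules: 20 s pre-ictal baselines, channel
quality control (baseline SD above 5 uV on dZ or 50 uV on EEG rejects the
channel), per-timepoint significance against the baseline at alpha = 0.01,
dZ onset as the first 2x-baseline-noise crossing sustained for more than
5 s, seizure typing from the spatiotemporal spread of >3.5 Hz polyspike
activity, peak dZ over significant channels, and a 20-40 Hz rectified-signal
spiking-power index.

Thresholds use strict inequalities; ties break to the earliest time (then
the lowest channel index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .scenario import BASELINE_SECONDS
from .signals import DemodulatedBlock

DZ_REJECT_SD = 5e-6  # V
EEG_REJECT_SD = 50e-6  # V
POLYSPIKE_RATE = 3.5  # Hz
ONSET_MIN_DURATION = 15.0  # s of sustained spiking to call an onset
DZ_SUSTAIN_SECONDS = 5.0  # s above 2x baseline noise
SPREAD_WINDOW = 4.0  # s: secondary generalization happens within 1-4 s

__all__ = [
    "SeizureBlock",
    "compute_baseline",
    "reject_noisy_channels",
    "significance_mask",
    "detect_dz_onset",
    "classify_seizure",
    "spiking_power",
    "peak_dz",
    "analyze_block",
]


@dataclass
class SeizureBlock:
    """Analysis results for one demodulated seizure block."""

    block: DemodulatedBlock
    eeg_onset_time: float | None = None
    eeg_onset_contacts: tuple[str, ...] = ()
    spread_contacts: tuple[str, ...] = ()
    seizure_type: str = "indeterminate"
    dz_onset_time: float | None = None
    peak_dz_volts: float | None = None
    peak_dz_percent: float | None = None
    peak_dz_time: float | None = None
    peak_dz_channel: int | None = None
    rejected_dz_channels: tuple[int, ...] = ()
    rejected_eeg_contacts: tuple[str, ...] = ()
    significance: np.ndarray | None = None  # (n_channels, n_frames) bool
    frame_times: np.ndarray | None = None
    delay_flag: bool = False  # dz onset earlier than EEG onset (flagged, kept)

    def good_dz_channels(self) -> np.ndarray:
        n = self.block.dz.shape[0]
        mask = np.ones(n, dtype=bool)
        mask[list(self.rejected_dz_channels)] = False
        return mask


def _baseline_slice(block: DemodulatedBlock) -> slice:
    n_base = int(round(BASELINE_SECONDS * block.fs_dz))
    if block.dz.shape[1] < n_base:
        raise ValueError("block has less than 20 s of pre-onset data")
    return slice(0, n_base)


def compute_baseline(block: DemodulatedBlock) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD of dZ over the first 20 s of the block.

    The block starts 30 s before the ictal event, so the baseline window
    ends 10 s before the EEG onset and is untouched by late pre-ictal
    activity.  Results are attached to the block.
    """
    sl = _baseline_slice(block)
    mean = block.dz[:, sl].mean(axis=1)
    sd = block.dz[:, sl].std(axis=1, ddof=1)
    block.baseline_mean = mean
    block.baseline_sd = sd
    return mean, sd


def reject_noisy_channels(block: DemodulatedBlock) -> tuple[np.ndarray, list[str]]:
    """Flag dZ channels (SD > 5 uV) and EEG contacts (SD > 50 uV).

    Strict inequality: a channel at exactly the threshold is kept.  Raises
    when more than half of the dZ channels fail (unusable block).
    """
    if block.baseline_sd is None:
        compute_baseline(block)
    dz_rej = np.flatnonzero(block.baseline_sd > DZ_REJECT_SD)

    n_base = int(round(BASELINE_SECONDS * block.fs_eeg))
    eeg_sd = block.eeg[:, :n_base].std(axis=1, ddof=1)
    eeg_rej = [block.contact_ids[i] for i in np.flatnonzero(eeg_sd > EEG_REJECT_SD)]

    if dz_rej.size > 0.5 * block.dz.shape[0]:
        raise ValueError(
            f"{dz_rej.size}/{block.dz.shape[0]} dZ channels rejected (> 50%): block unusable"
        )
    return dz_rej, eeg_rej


def _frame_grid(block: DemodulatedBlock) -> tuple[np.ndarray, np.ndarray]:
    """1 s frame centers and the dz samples folded to (ch, frame, win)."""
    win = int(round(block.fs_dz))
    n_frames = block.dz.shape[1] // win
    folded = block.dz[:, : n_frames * win].reshape(block.dz.shape[0], n_frames, win)
    times = block.t_start + (np.arange(n_frames) + 0.5) / 1.0
    return times, folded


def significance_mask(
    block: DemodulatedBlock, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel, per-second significance of dZ against the baseline.

    The paired comparison is operationalized as a prediction-interval t
    statistic: the 1 s window mean at frame t is tested against the twenty
    1 s baseline-segment means, t = (m_t - mean(b)) / (s_b sqrt(1 + 1/k)),
    two-sided with k-1 degrees of freedom.  Exactly calibrated at alpha for
    stationary noise.  Frames inside the baseline window itself are False.
    Zero-variance baselines fall back to flagging any absolute deviation.
    """
    if block.baseline_mean is None:
        compute_baseline(block)
    times, folded = _frame_grid(block)
    m = folded.mean(axis=2)  # (ch, frames)
    k = int(round(BASELINE_SECONDS))
    b = m[:, :k]
    b_mean = b.mean(axis=1, keepdims=True)
    b_sd = b.std(axis=1, ddof=1, keepdims=True)

    mask = np.zeros_like(m, dtype=bool)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=k - 1)
    denom = b_sd * np.sqrt(1.0 + 1.0 / k)
    # variance at the float roundoff floor counts as zero
    ok = (b_sd > 1e-9 * np.maximum(np.abs(b_mean), 1e-30)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (m - b_mean) / denom
    mask[ok] = np.abs(tstat[ok]) > tcrit
    if not ok.all():  # degenerate noise-free channels
        import warnings

        warnings.warn("zero-variance baseline: using absolute-deviation mask", stacklevel=2)
        mask[~ok] = np.abs(m[~ok] - b_mean[~ok]) > 0
    mask[:, :k] = False  # no self-comparison inside the baseline window
    return mask, times


def detect_dz_onset(
    block: DemodulatedBlock,
    good_channels: np.ndarray | None = None,
) -> float | None:
    """Earliest sustained 2x-baseline-noise crossing on the peak-dZ channel.

    The channel with the maximal |dZ - baseline| deviation is selected; the
    onset is the first time its deviation exceeds twice the baseline SD in
    the same direction for more than 5 contiguous seconds.  Returns ``None``
    when no such crossing exists (a valid result for null blocks).
    """
    if block.baseline_mean is None:
        compute_baseline(block)
    dev = block.dz - block.baseline_mean[:, None]
    if good_channels is not None:
        dev = np.where(good_channels[:, None], dev, 0.0)
    ch = int(np.unravel_index(np.argmax(np.abs(dev)), dev.shape)[0])
    sd = block.baseline_sd[ch]
    if sd <= 0:
        return None
    x = dev[ch]
    need = int(round(DZ_SUSTAIN_SECONDS * block.fs_dz)) + 1
    sign = np.sign(x[np.argmax(np.abs(x))]) or 1.0
    above = sign * x > 2.0 * sd
    # earliest run of `need` consecutive True
    if not above.any():
        return None
    run = np.convolve(above.astype(int), np.ones(need, dtype=int), mode="valid")
    hits = np.flatnonzero(run == need)
    if hits.size == 0:
        return None
    return float(block.t_start + hits[0] / block.fs_dz)


def spiking_power(
    eeg: np.ndarray,
    fs: float,
    window_seconds: float = 1.0,
    hop_seconds: float = 0.25,
    band: tuple[float, float] = (20.0, 40.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """20-40 Hz band power of the rectified signal (short-time spectrum).

    Rectification folds the spike train's energy into harmonics of the spike
    rate; the 20-40 Hz band of its short-time Fourier transform indexes how
    frequent and large the spikes are.  Returns (times, index, rms) where
    ``times`` are window centers (relative to the start of ``eeg``), and
    ``rms`` is the plain RMS in the same windows.
    """
    eeg = np.asarray(eeg, dtype=float)
    nper = int(round(window_seconds * fs))
    if nper > eeg.shape[-1]:
        raise ValueError("spectral window longer than the block")
    hop = max(int(round(hop_seconds * fs)), 1)
    rect = np.abs(eeg)
    f, t, S = signal.stft(
        rect, fs=fs, nperseg=nper, noverlap=nper - hop, boundary=None, padded=False
    )
    psd = np.abs(S) ** 2
    sel = (f > band[0]) & (f <= band[1])
    index = psd[..., sel, :].sum(axis=-2)

    n_win = index.shape[-1]
    starts = (np.arange(n_win) * hop).astype(int)
    rms = np.array(
        [np.sqrt(np.mean(eeg[..., s : s + nper] ** 2, axis=-1)) for s in starts]
    ).T if eeg.ndim > 1 else np.array(
        [np.sqrt(np.mean(eeg[s : s + nper] ** 2)) for s in starts]
    )
    return t, index, rms


def _spike_times(trace: np.ndarray, fs: float, baseline_n: int) -> np.ndarray:
    """Detect sharp-wave peaks: rectified threshold at 5x baseline SD."""
    base_sd = trace[:baseline_n].std() + 1e-30
    height = 5.0 * base_sd
    peaks, _props = signal.find_peaks(
        np.abs(trace), height=height, distance=max(int(0.08 * fs), 1)
    )
    return peaks / fs


def classify_seizure(
    block: DemodulatedBlock,
    rejected_contacts: tuple[str, ...] = (),
) -> tuple[str, float | None, tuple[str, ...], tuple[str, ...]]:
    """Type the seizure from per-contact spike rates.

    A contact is "ictal" while its spike rate exceeds 3.5 Hz.  The onset is
    the earliest time with 2-4 simultaneously ictal contacts sustained for
    at least 15 s; if the first ictal involvement already covers more than 4
    contacts the seizure is generalized.  A confined onset that later covers
    the majority (> 50%) of contacts within 1-4 s of the spread start is
    focal secondary generalized; a confined onset staying within the local
    8-12 contacts is focal.  Returns (type, onset_time, onset_contacts,
    spread_contacts).
    """
    fs = block.fs_eeg
    n_base = int(round(BASELINE_SECONDS * fs))
    good = [c for c in block.contact_ids if c not in rejected_contacts]
    gi = [i for i, c in enumerate(block.contact_ids) if c in good]

    # Per-contact ictal indicator on a 0.5 s grid from spike rates in 2 s windows.
    grid = np.arange(block.t_start, block.t_start + block.eeg.shape[1] / fs, 0.5)
    active = np.zeros((len(gi), grid.size), dtype=bool)
    for row, i in enumerate(gi):
        st = _spike_times(block.eeg[i], fs, n_base) + block.t_start
        if st.size == 0:
            continue
        for j, t0 in enumerate(grid):
            rate = np.sum((st >= t0 - 1.0) & (st < t0 + 1.0)) / 2.0
            active[row, j] = rate > POLYSPIKE_RATE

    n_active = active.sum(axis=0)
    if not n_active.any():
        return "indeterminate", None, (), ()

    first_idx = int(np.argmax(n_active > 0))
    onset_count = int(n_active[first_idx])
    onset_time = float(grid[first_idx])
    onset_contacts = tuple(good[r] for r in np.flatnonzero(active[:, first_idx]))
    ever = np.flatnonzero(active.any(axis=1))
    spread_contacts = tuple(good[r] for r in ever)

    # sustained >3.5 Hz spiking for >= 15 s somewhere
    need = int(ONSET_MIN_DURATION / 0.5)
    sustained = (
        np.convolve((n_active > 0).astype(int), np.ones(need, int), "valid") == need
    ).any()
    if not sustained:
        return "indeterminate", onset_time, onset_contacts, spread_contacts

    if onset_count > 4:
        return "generalized", onset_time, onset_contacts, spread_contacts

    majority = 0.5 * len(good)
    spread_start = None
    for j in range(first_idx, grid.size):
        if n_active[j] > onset_count:
            spread_start = j
            break
    if spread_start is not None:
        j_end = min(spread_start + int(SPREAD_WINDOW / 0.5) + 1, grid.size)
        if np.max(n_active[spread_start:j_end]) > majority:
            return (
                "focal_secondary_generalized",
                onset_time,
                onset_contacts,
                spread_contacts,
            )
    return "focal", onset_time, onset_contacts, spread_contacts


def peak_dz(
    block: DemodulatedBlock,
    mask: np.ndarray,
    good_channels: np.ndarray | None = None,
) -> tuple[float, float, float, int] | None:
    """Maximum |dZ - baseline| over significant (channel, frame) points.

    Returns (volts, percent-of-baseline, time, channel) or ``None`` when no
    point is significant.  Ties break to the earliest frame, then the lowest
    channel index.
    """
    if block.baseline_mean is None:
        compute_baseline(block)
    times, folded = _frame_grid(block)
    m = folded.mean(axis=2)
    dev = np.abs(m - block.baseline_mean[:, None])
    allowed = mask.copy()
    if good_channels is not None:
        allowed &= good_channels[:, None]
    if not allowed.any():
        return None
    dev = np.where(allowed, dev, -np.inf)
    best = np.max(dev)
    ch_idx, fr_idx = np.nonzero(dev == best)
    order = np.lexsort((ch_idx, fr_idx))  # earliest frame, then lowest channel
    ch, fr = int(ch_idx[order[0]]), int(fr_idx[order[0]])
    base = block.baseline_mean[ch]
    pct = float(100.0 * best / base) if base != 0 else float("nan")
    return float(best), pct, float(times[fr]), ch


def analyze_block(block: DemodulatedBlock, alpha: float = 0.01) -> SeizureBlock:
    """Run the full block analysis: QC, significance, onsets, typing, peak."""
    compute_baseline(block)
    dz_rej, eeg_rej = reject_noisy_channels(block)
    good = np.ones(block.dz.shape[0], dtype=bool)
    good[dz_rej] = False
    mask, times = significance_mask(block, alpha=alpha)
    stype, eeg_onset, onset_contacts, spread = classify_seizure(block, tuple(eeg_rej))
    dz_onset = detect_dz_onset(block, good)
    pk = peak_dz(block, mask, good)
    delay_flag = (
        dz_onset is not None and eeg_onset is not None and dz_onset < eeg_onset
    )
    out = SeizureBlock(
        block=block,
        eeg_onset_time=eeg_onset,
        eeg_onset_contacts=onset_contacts,
        spread_contacts=spread,
        seizure_type=stype,
        dz_onset_time=dz_onset,
        rejected_dz_channels=tuple(int(i) for i in dz_rej),
        rejected_eeg_contacts=tuple(eeg_rej),
        significance=mask,
        frame_times=times,
        delay_flag=delay_flag,
    )
    if pk is not None:
        out.peak_dz_volts, out.peak_dz_percent, out.peak_dz_time, out.peak_dz_channel = pk
    return out
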
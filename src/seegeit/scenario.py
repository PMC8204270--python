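"""Seizure scenarios: focal conductivity-change time course + ictal EEG schedule.

A scenario pins the ground truth of one analysed block: a spherical-ish focus
whose conductivity drops (cell swelling -> extracellular shrinkage ->
impedance rise) with a ramp/plateau/decay time course delayed ~11 s behind
the electrographic onset, and an EEG event schedule following the
penicillin-model grades: background (I), interictal spikes with rising rate
(II/III), and an ictal polyspike train above 3.5 Hz on the onset contacts
(IV), with optional secondary spread.

Times are seconds relative to the electrographic (EEG) seizure onset; the
analysis block spans [-30 s, +60 s] around it.  The conductivity trajectory
lives on a 1 s grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .geometry import HeadModel, element_centroids

BLOCK_START = -30.0  # s relative to EEG onset
BLOCK_END = 60.0
BASELINE_SECONDS = 20.0  # first 20 s of the block form the dZ baseline

__all__ = [
    "SeizureScenario",
    "make_seizure_scenario",
    "delta_sigma_profile",
    "delta_sigma_timecourse",
    "element_delta_sigma",
    "synthesize_eeg",
    "BLOCK_START",
    "BLOCK_END",
    "BASELINE_SECONDS",
]


@dataclass(frozen=True)
class SeizureScenario:
    """Ground truth for one seizure block."""

    focus_center: np.ndarray  # mm
    focus_radius: float  # mm
    delta_sigma_fraction: float  # in [-0.5, 0); negative = conductivity decrease
    eeg_onset_time: float  # s (block-relative; 0 by convention)
    dz_onset_delay: float  # s, conductivity change starts this long after EEG onset
    seizure_duration: float  # s
    onset_contacts: tuple[str, ...]
    spread_contacts: tuple[str, ...]
    cycle_period: float  # s between ictal events (grade cycle)
    rng_seed: int
    kind: str = "focal"  # focal | focal_secondary_generalized | generalized | null
    ramp_duration: float = 15.0  # s, zero -> plateau
    decay_tau: float = 20.0  # s, post-seizure relaxation
    spread_delay: float = 2.0  # s, onset -> secondary spread
    spike_rate: float = 5.0  # Hz, ictal polyspike rate (> 3.5 Hz)

    def __post_init__(self):
        if self.kind != "null":
            if not (-0.5 <= self.delta_sigma_fraction < 0):
                raise ValueError("delta_sigma_fraction must lie in [-0.5, 0)")
        elif self.delta_sigma_fraction != 0.0:
            raise ValueError("null scenario requires delta_sigma_fraction == 0")
        if self.dz_onset_delay <= 0:
            raise ValueError("dz_onset_delay must be positive")
        if not set(self.onset_contacts) <= set(self.spread_contacts):
            raise ValueError("onset contacts must be a subset of spread contacts")
        if self.kind == "focal" and not 2 <= len(self.onset_contacts) <= 4:
            raise ValueError("focal scenarios have 2-4 onset contacts")

    @property
    def dz_onset_time(self) -> float:
        return self.eeg_onset_time + self.dz_onset_delay


def delta_sigma_timecourse(scenario: SeizureScenario, times: np.ndarray) -> np.ndarray:
    """Normalized conductivity-change trajectory f(t) in [0, 1] on ``times``.

    Zero before the (delayed) dZ onset, smooth ramp to a plateau over
    ``ramp_duration``, plateau until the seizure ends, then exponential
    relaxation.  Multiplying by delta_sigma_fraction * sigma gives the
    conductivity perturbation of the focus core.
    """
    t = np.asarray(times, dtype=float)
    if scenario.kind == "null":
        return np.zeros_like(t)
    t0 = scenario.dz_onset_time
    t_plateau_end = scenario.eeg_onset_time + scenario.seizure_duration + scenario.dz_onset_delay
    f = np.zeros_like(t)
    s = np.clip((t - t0) / scenario.ramp_duration, 0.0, 1.0)
    f = s * s * (3.0 - 2.0 * s)  # smoothstep ramp
    decay = t > t_plateau_end
    f[decay] = f[decay] * np.exp(-(t[decay] - t_plateau_end) / scenario.decay_tau)
    f[t < t0] = 0.0
    return f


def delta_sigma_profile(scenario: SeizureScenario, points: np.ndarray) -> np.ndarray:
    """Spatial weight g in [0, 1]: Gaussian focus truncated at 2 radii."""
    d = np.linalg.norm(np.asarray(points) - scenario.focus_center, axis=-1)
    g = np.exp(-((d / scenario.focus_radius) ** 2))
    g[d > 2.0 * scenario.focus_radius] = 0.0
    return g


def element_delta_sigma(
    scenario: SeizureScenario, model: HeadModel, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Separable element-space perturbation: returns (g_elements, f_times).

    Delta sigma_e(t) = delta_sigma_fraction * sigma_e * g_e * f(t); returning
    the factors keeps downstream linear algebra cheap.
    """
    g = delta_sigma_profile(scenario, element_centroids(model))
    g = scenario.delta_sigma_fraction * model.element_conductivity * g
    f = delta_sigma_timecourse(scenario, times)
    if np.any((f > 0) & (np.asarray(times) < scenario.eeg_onset_time)):
        raise ValueError("conductivity change must not precede the EEG onset")
    return g, f


def make_seizure_scenario(
    model: HeadModel,
    seed: int = 0,
    kind: str = "focal",
    focus_center: np.ndarray | None = None,
    focus_radius: float = 6.0,
    delta_sigma_fraction: float = -0.2,
    dz_onset_delay: float = 11.0,
    seizure_duration: float = 25.0,
    cycle_period: float = 300.0,
    n_onset_contacts: int | None = None,
    spread_delay: float = 2.0,
) -> SeizureScenario:
    """Build a scenario with onset contacts chosen nearest the focus.

    Defaults follow the study conditions: dZ delayed 11 s (±3 s observed)
    behind the SEEG onset, seizures ~25 s long (8-70 s observed), grade
    cycles every 3-10 min, 2-4 SEEG onset contacts close to the cannula,
    focal spread confined to the local 8-12 contacts.
    ``delta_sigma_fraction`` = -0.2 puts peak boundary-voltage changes in
    the observed 2-10% range.

    Electrographic extent is tied to the physical focus size: a larger
    swelling region recruits more contacts, so (unless given) the onset
    count rises 2 -> 4 and the spread count 8 -> 12 across the 3-8 mm radius
    range.  This builds the observed positive relation between contact
    counts and impedance-change magnitude into the ground truth.
    """
    rng = np.random.default_rng(seed)
    if focus_center is None:
        focus_center = model.cannula_tip if model.cannula_tip is not None else np.zeros(3)
    focus_center = np.asarray(focus_center, dtype=float)

    seeg = [e for e in model.electrodes if e.kind == "seeg"]
    all_contacts = model.electrodes
    d_seeg = np.array([np.linalg.norm(e.position - focus_center) for e in seeg])
    d_all = np.array([np.linalg.norm(e.position - focus_center) for e in all_contacts])

    if kind == "null":
        return SeizureScenario(
            focus_center=focus_center,
            focus_radius=focus_radius,
            delta_sigma_fraction=0.0,
            eeg_onset_time=0.0,
            dz_onset_delay=dz_onset_delay,
            seizure_duration=seizure_duration,
            onset_contacts=(),
            spread_contacts=(),
            cycle_period=cycle_period,
            rng_seed=seed,
            kind="null",
            spread_delay=spread_delay,
        )

    if kind == "generalized":
        onset = tuple(e.id for e in all_contacts)
        spread = onset
    else:
        if n_onset_contacts is None:
            # recruit more onset contacts for physically larger foci
            frac = np.clip((focus_radius - 3.0) / 5.0, 0.0, 1.0)
            n_onset = 2 + int(round(2.0 * frac))
        else:
            n_onset = int(np.clip(n_onset_contacts, 2, 4))
        onset = tuple(seeg[i].id for i in np.argsort(d_seeg)[:n_onset])
        if kind == "focal":
            # local spread 8-12 contacts, scaled with the focus radius
            frac = np.clip((focus_radius - 3.0) / 5.0, 0.0, 1.0)
            n_spread = 8 + int(round(4.0 * frac))
            spread = tuple(all_contacts[i].id for i in np.argsort(d_all)[:n_spread])
        elif kind == "focal_secondary_generalized":
            n_spread = int(0.7 * len(all_contacts))  # majority of contacts
            spread = tuple(all_contacts[i].id for i in np.argsort(d_all)[:n_spread])
        else:
            raise ValueError(f"unknown scenario kind {kind!r}")
        spread = tuple(sorted(set(spread) | set(onset)))

    return SeizureScenario(
        focus_center=focus_center,
        focus_radius=float(focus_radius),
        delta_sigma_fraction=float(delta_sigma_fraction),
        eeg_onset_time=0.0,
        dz_onset_delay=float(dz_onset_delay),
        seizure_duration=float(seizure_duration),
        onset_contacts=onset,
        spread_contacts=spread,
        cycle_period=float(cycle_period),
        rng_seed=int(seed),
        kind=kind,
        spread_delay=float(spread_delay),
    )


def _spike_waveform(fs: float) -> np.ndarray:
    """Biphasic sharp-wave kernel (~60 ms), unit peak amplitude."""
    t = np.arange(-0.06, 0.09, 1.0 / fs)
    w = np.exp(-((t / 0.012) ** 2)) - 0.45 * np.exp(-(((t - 0.045) / 0.03) ** 2))
    return w / np.abs(w).max()


def spike_schedule(scenario: SeizureScenario, model: HeadModel) -> dict[str, np.ndarray]:
    """Per-contact spike times (s, block-relative); deterministic in rng_seed."""
    rng = np.random.default_rng(scenario.rng_seed + 7919)
    sched: dict[str, list[float]] = {e.id: [] for e in model.electrodes}
    if scenario.kind == "null":
        return {k: np.array(v) for k, v in sched.items()}

    on, dur = scenario.eeg_onset_time, scenario.seizure_duration
    rate = scenario.spike_rate
    # Grade II/III: interictal spikes with rising rate on the onset contacts
    # over the 10 s before onset (kept out of the 20 s dZ baseline window).
    for cid in scenario.onset_contacts:
        t = on - 10.0
        while t < on - 0.5:
            r = 0.3 + 1.5 * (t - (on - 10.0)) / 10.0  # Hz, rising
            t += rng.exponential(1.0 / r)
            if t < on - 0.5:
                sched[cid].append(t)
    # Grade IV: regular polyspike train (> 3.5 Hz) with small jitter.
    train = np.arange(on, on + dur, 1.0 / rate)
    for cid in scenario.onset_contacts:
        jit = rng.normal(0.0, 0.01, size=train.size)
        sched[cid].extend((train + jit).tolist())
    late = [c for c in scenario.spread_contacts if c not in scenario.onset_contacts]
    t_spread = on + scenario.spread_delay
    train2 = np.arange(t_spread, on + dur, 1.0 / rate)
    for cid in late:
        jit = rng.normal(0.0, 0.01, size=train2.size)
        sched[cid].extend((train2 + jit).tolist())
    return {k: np.sort(np.array(v)) for k, v in sched.items()}


def synthesize_eeg(
    scenario: SeizureScenario,
    model: HeadModel,
    fs: float,
    t_start: float = BLOCK_START,
    t_end: float = BLOCK_END,
    background_rms: float = 20e-6,
    spike_amplitude: float = 300e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the EEG block (V) at rate ``fs`` for every contact.

    Background is low-pass-filtered white noise (~20 uV RMS); spikes from the
    schedule are added as biphasic sharp waves (~300 uV ictal).  Returns
    (times, traces) with traces shaped (n_contacts, n_samples) in the
    model's electrode order.
    """
    rng = np.random.default_rng(scenario.rng_seed + 104729)
    n = int(round((t_end - t_start) * fs))
    t = t_start + np.arange(n) / fs
    n_ch = len(model.electrodes)
    sos = signal.butter(2, min(40.0, 0.4 * fs), btype="low", fs=fs, output="sos")
    traces = signal.sosfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    traces *= background_rms / np.maximum(traces.std(axis=1, keepdims=True), 1e-30)

    kernel = _spike_waveform(fs)
    half = kernel.size // 2
    sched = spike_schedule(scenario, model)
    for ci, e in enumerate(model.electrodes):
        amp = spike_amplitude if e.id in scenario.onset_contacts else 0.8 * spike_amplitude
        for ts in sched[e.id]:
            i0 = int(round((ts - t_start) * fs)) - half
            j0, j1 = max(i0, 0), min(i0 + kernel.size, n)
            if j1 <= j0:
                continue
            traces[ci, j0:j1] += amp * kernel[j0 - i0 : j1 - i0]
    return t, traces
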
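"""Scoring reconstructions against ground truth and electrode-space findings.

Localization error is the distance from the suprathreshold center of mass of
the reconstructed change (at the peak-dZ frame) to three reference points:
the cannula tip (the chemically defined focus), the mean position of the
SEEG contacts detecting the electrographic onset, and the closest such
contact.  Cohort statistics are mean +- 95% confidence limits from the
two-tailed t distribution.  "EIT spread" counts the contacts covered by
voxels above 65% of the frame maximum; correlations are Pearson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import HeadModel
from .imaging import ImageSeries

SPREAD_THRESHOLD = 0.65  # fraction of the frame maximum
DEFAULT_COVERAGE_RADIUS = 5.0  # mm, half the ECoG grid spacing

__all__ = [
    "LocalizationReport",
    "center_of_mass",
    "localization_error",
    "cohort_report",
    "eit_spread",
    "correlate",
    "mean_ci",
    "SPREAD_THRESHOLD",
]


def center_of_mass(
    frame: np.ndarray,
    centers: np.ndarray,
    threshold_fraction: float = SPREAD_THRESHOLD,
) -> np.ndarray | None:
    """Intensity-weighted centroid of suprathreshold voxels (mm).

    ``frame`` is a masked-voxel vector (any sign; magnitudes are used) and
    ``centers`` the matching voxel centers.  Returns ``None`` for an empty
    frame.
    """
    w = np.abs(np.asarray(frame, dtype=float))
    if w.size == 0 or w.max() <= 0:
        return None
    sel = w >= threshold_fraction * w.max()
    if not sel.any():
        return None
    ww = w[sel]
    return (centers[sel] * ww[:, None]).sum(axis=0) / ww.sum()


def mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float | None]:
    """Mean and two-tailed t-distribution confidence half-width (n >= 2)."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if v.size < 2:
        return mean, None
    t = stats.t.ppf(0.5 + confidence / 2.0, df=v.size - 1)
    return mean, float(t * v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class LocalizationReport:
    """Per-seizure distances (mm) and their cohort aggregation."""

    to_cannula: np.ndarray
    to_mean_onset_seeg: np.ndarray
    to_closest_onset_seeg: np.ndarray
    to_true_focus: np.ndarray
    n: int

    def summary(self) -> dict:
        out = {"n": self.n}
        for name, arr in [
            ("cannula_tip", self.to_cannula),
            ("mean_onset_seeg", self.to_mean_onset_seeg),
            ("closest_onset_seeg", self.to_closest_onset_seeg),
            ("true_focus", self.to_true_focus),
        ]:
            vals = arr[np.isfinite(arr)]
            if vals.size == 0:
                out[name] = None
                continue
            mean, ci = mean_ci(vals)
            out[name] = {"mean_mm": mean, "ci95_mm": ci, "n": int(vals.size)}
        return out


def localization_error(
    series: ImageSeries,
    peak_time: float,
    model: HeadModel,
    onset_contacts: tuple[str, ...],
    true_focus: np.ndarray | None = None,
    threshold_fraction: float = SPREAD_THRESHOLD,
) -> dict:
    """Distances from the peak-frame center of mass to the reference points.

    Returns a dict with ``com`` and distances in mm; SEEG-referenced entries
    are NaN when no onset contact exists.
    """
    frame = series.frame(peak_time, kind="tscore")
    com = center_of_mass(frame, series.grid.centers, threshold_fraction)
    out = {
        "com": com,
        "to_cannula": np.nan,
        "to_mean_onset_seeg": np.nan,
        "to_closest_onset_seeg": np.nan,
        "to_true_focus": np.nan,
    }
    if com is None:
        return out
    if model.cannula_tip is not None:
        out["to_cannula"] = float(np.linalg.norm(com - model.cannula_tip))
    seeg_onsets = [
        model.contact(c).position
        for c in onset_contacts
        if c in model.contact_ids and model.contact(c).kind == "seeg"
    ]
    if seeg_onsets:
        pos = np.array(seeg_onsets)
        out["to_mean_onset_seeg"] = float(np.linalg.norm(com - pos.mean(axis=0)))
        out["to_closest_onset_seeg"] = float(np.min(np.linalg.norm(pos - com, axis=1)))
    if true_focus is not None:
        out["to_true_focus"] = float(np.linalg.norm(com - np.asarray(true_focus)))
    return out


def cohort_report(per_seizure: list[dict]) -> LocalizationReport:
    """Aggregate per-seizure localization dicts into a report."""
    def col(key):
        return np.array([s.get(key, np.nan) for s in per_seizure], dtype=float)

    return LocalizationReport(
        to_cannula=col("to_cannula"),
        to_mean_onset_seeg=col("to_mean_onset_seeg"),
        to_closest_onset_seeg=col("to_closest_onset_seeg"),
        to_true_focus=col("to_true_focus"),
        n=len(per_seizure),
    )


def eit_spread(
    frame: np.ndarray,
    centers: np.ndarray,
    model: HeadModel,
    coverage_radius: float = DEFAULT_COVERAGE_RADIUS,
    threshold_fraction: float = SPREAD_THRESHOLD,
) -> int:
    """Contacts covered by voxels above 65% of the frame maximum.

    A contact counts as covered when at least one suprathreshold voxel lies
    within ``coverage_radius`` mm of it.  Empty frames give zero.
    """
    w = np.abs(np.asarray(frame, dtype=float))
    if w.size == 0 or w.max() <= 0:
        return 0
    pts = centers[w >= threshold_fraction * w.max()]
    if pts.size == 0:
        return 0
    count = 0
    for e in model.electrodes:
        d = np.linalg.norm(pts - e.position, axis=1)
        if np.any(d <= coverage_radius):
            count += 1
    return count


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Pearson r and two-sided p; ``None`` for degenerate inputs.

    Requires at least 3 paired observations; zero variance in either metric
    makes r undefined and returns ``None``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
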
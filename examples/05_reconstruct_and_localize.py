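"""Reconstruct 3D conductivity-change images and localize the focus.

One focal seizure, end to end: cross-validated zeroth-order Tikhonov
inversion onto 2 mm voxels, noise-weighted t-score frames, and the
center-of-mass localization error against the known focus.
"""

import numpy as np

from seegeit import Study, StudyDesign, make_seizure_scenario
from seegeit.pipeline import run_seizure

study = Study(StudyDesign(edge_length=4.0))
scenario = make_seizure_scenario(study.model, seed=8, kind="focal")
res = run_seizure(study, scenario, seed=108, snr_db=20.0)

s = res.series
print(f"image series: {s.n_frames} frames x {s.grid.n_voxels} voxels "
      f"({s.grid.voxel_size:.0f} mm), lambda = {s.lam:.3g}")
peak_frame = s.frame(res.peak_time)
print(f"peak-dZ frame at {res.peak_time:+.1f} s: max |t| = {np.abs(peak_frame).max():.1f} sigma")

loc = res.localization
print(f"center of mass: {np.round(loc['com'], 1)} mm "
      f"(true focus {np.round(scenario.focus_center, 1)} mm)")
print(f"localization error: {loc['to_true_focus']:.1f} mm to the true focus, "
      f"{loc['to_cannula']:.1f} mm to the cannula tip, "
      f"{loc['to_closest_onset_seeg']:.1f} mm to the closest onset SEEG contact")
print(f"EIT spread: {res.eit_spread_contacts} contacts covered at the 65% threshold "
      f"(generated spread: {len(scenario.spread_contacts)} contacts)")
# A well-posed focal seizure localizes within a few millimetres -- inside the
# ~10 mm accuracy regime needed to point at a seizure-onset zone.
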
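# Methods

This note documents the models, signal chain, numerical choices and known
limitations of `seegeit`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Physical model and geometry

The brain is a half-ellipsoid (default semi-axes 45 × 30 × 25 mm, flat
base) with uniform isotropic conductivity 0.22 S/m, meshed with linear
tetrahedra. The mesh is built from a jittered body lattice plus projected
surface samples; because the domain is convex, a Delaunay triangulation of
the nodes tiles it, and the mesh volume converges to the analytic
half-ellipsoid volume under refinement (≈0.5% at a 4 mm edge). Desk-scale
resolutions of 2.5–4 mm (10⁴–5·10⁴ elements) replace the 0.3 mm /
~10⁷-element meshes a full-scale study would use; resolution is a
configuration knob and all operators are resolution-agnostic.

Electrodes are a 4×8 epicortical grid at 10 mm spacing on the dorsal
surface and three (optionally four) depth probes with 10 contacts at 5 mm
spacing, inserted obliquely along the long axis so that the 45 mm contact
span fits inside the dome; contact 1 is the deepest (the probe tip).
Contacts keep their nominal millimetre coordinates and are *attached* to
the nearest mesh vertex (point-electrode model). The complete electrode
model is a possible extension; at centimetre-scale localization targets and
desk resolutions, the contact-impedance correction it adds is not resolved
by the mesh anyway.

## Forward problem and sensitivities

The quasi-static conduction problem ∇·(σ∇u) = 0 with point current sources
is assembled with P1 elements; the Neumann null space is removed with a
zero-mean Lagrange constraint and one sparse LU factorization serves all
drive and adjoint right-hand sides. Voltages are single-ended against a
fixed reference contact (an ECoG corner contact that never injects), so
measurement channels are (injection, contact) pairs excluding the two
injectors and the reference. Reciprocity holds to solver precision
(~10⁻¹⁵ relative) and a four-terminal bar test reproduces the analytic
section resistance L/(σA) within 5%.

Sensitivities use the adjoint construction
J[(d,m),e] = −vol·(∇u_d · ∇w_m)|_e, exact per element for P1 gradients.
Two independent checks pin it down: a finite-difference perturbation oracle
(re-solving with one perturbed element; agreement well under 5%, typically
~10⁻⁴ relative) and the Euler-homogeneity identity J·σ = −V₀ (~10⁻⁹
relative). Transfer-voltage time series are first-order superpositions
V(t) = V₀ + J·Δσ(t) on a 1 s grid; a warning is raised if |Δσ|/σ reaches
0.5, where the linearization is untrustworthy.

## Seizure scenarios (what the generator emulates)

A scenario fixes the ground truth of one analysed block, which spans
−30…+60 s around the electrographic onset:

* **Conductivity change**: a Gaussian focus (radius 3–8 mm, truncated at
  two radii) whose conductivity drops by a fraction (default −0.2, i.e.
  cell swelling → impedance rise), starting 11 s after the EEG onset
  (observed delay 11 ± 3 s), smooth-stepping to a plateau over 15 s and
  relaxing with a 20 s time constant after the ~25 s seizure (observed
  8–70 s). The default −0.2 fraction puts the peak boundary-voltage change
  at ≈5% of the peak channel's baseline, inside the observed 2–10% range.
* **EEG**: low-pass background (~20 µV RMS), interictal sharp waves with a
  rising rate in the 10 s before onset (kept out of the 20 s baseline
  window), then a 5 Hz polyspike train (>3.5 Hz criterion) on 2–4 onset
  contacts, spreading after ~2 s either to the local 8–12 contacts (focal),
  to the majority of contacts (focal secondary generalized), or starting
  everywhere at once (generalized).
* **Coupling**: electrographic extent is tied to the physical focus size —
  onset count rises 2→4 and spread count 8→12 across the 3–8 mm radius
  range — so the observed positive relations between contact counts,
  impedance-change magnitude and EIT spread arise in the ground truth
  rather than being measured into existence.

What the generator does *not* emulate: gyral folding and tissue
heterogeneity, anisotropy, electrode contact impedance, amplifier drift or
mains interference, and non-impedance physiological confounds (blood-flow
or temperature changes). Passing tests therefore demonstrate correctness of
the measurement-and-inversion chain under the stated physics, not
robustness to every animal-data artifact.

## Multiplexed signal chain

Raw blocks at 50 kHz mix the EEG, one amplitude-modulated carrier per
injection (envelope = transfer voltage), and instrumentation noise. Noise
has two independent parts: a carrier-band component (white above half the
lowest carrier) that the SNR condition controls, and a fixed ~5 µV
broadband floor that dominates the EEG band — splitting the bands keeps the
electrographic traces readable while the EIT noise level is swept over
orders of magnitude.

Demodulation: EEG by a zero-phase 3rd-order 300 Hz low-pass and ×50
decimation; dZ by a ±10 Hz 30th-order Butterworth band-pass around each
carrier realized in second-order sections (a direct-form realization is
numerically unstable at a 4·10⁻⁴ relative bandwidth), the modulus of the
analytic signal, and ×500 anti-aliased decimation. A vectorized synchronous
I/Q backend implements the same zero-phase magnitude response by FFT zoom
and agrees with the envelope backend to ~10⁻⁴; it treats whole-second
blocks circularly, which is exact because every carrier completes an
integer number of cycles per second. Narrow-band transients persist for
seconds, so all zero-phase filters pad with *periodic* (wrap) extensions —
reflection would flip the carrier phase slope at the junction and ring for
seconds into the block.

A reduced-rate replica (5 kHz, carriers 850–1000 Hz, identical decimation
ratios and relative bandwidths) runs the whole chain at one tenth of the
cost and is the default for cohort experiments; the full 50 kHz chain is
verified on short blocks in the unit suite. Because the 1 s imaging cadence
is *not* scaled, target SNRs are defined on the full-rate chain and
translated to the replica by matching the noise per 1 s imaging frame —
measured once per configuration by a seeded calibration of the chain
(`dz_noise_calibration`, `raw_noise_for_snr`).

## Detection and classification

Baselines are the first 20 s of each block (ending 10 s before the EEG
onset). Channels with baseline SD above 5 µV (dZ) or 50 µV (EEG) are
rejected; at the default ~1 µV instrument floor this catches well under 10%
of channels. Per-second significance operationalizes the paired comparison
as a prediction-interval t statistic — the 1 s window mean against the
twenty baseline-second means, t = (m_t − mean(b))/(s_b√(1+1/20)), df = 19,
two-sided α = 0.01 — which is exactly calibrated for stationary noise (the
acceptance suite measures a positive rate of ≈1% on 100 null blocks and
zero false dZ-onsets). The dZ onset is the earliest time the peak-deviation
channel exceeds twice its baseline SD in the same direction for more than
5 contiguous seconds; with the default ramp it lands 2–5 s after the
programmed 11 s delay, on the rising edge. Seizure typing counts contacts
whose spike rate exceeds 3.5 Hz: a confined 2–4-contact onset sustained
15 s is focal; covering the majority of contacts within 1–4 s of spread
start makes it focal secondary generalized; an unconfined start is
generalized. Strict inequalities at every threshold; ties break to the
earliest time, then the lowest channel index.

## Imaging

The inverse grid is an axis-aligned voxelization (default 2 mm) of the
brain; each tetrahedron's volume is split over four interior quadrature
points and binned, conserving total volume exactly and preserving the
response to voxel-uniform perturbations exactly under the volume-fraction
Jacobian aggregation.

Reconstruction is zeroth-order Tikhonov, Δσ = (JᵀJ + λcI)⁻¹Jᵀdz with
c = mean diag(JᵀJ) so λ is a dimensionless, mesh-independent weight. With
far more voxels than channels everything runs in the dual (Gram) form: one
symmetric eigendecomposition of G = JJᵀ serves per-frame reconstruction,
10-fold channel-wise cross-validation (fold decompositions cached, seeded)
and exact noise propagation. λ is chosen on a 50-point log grid
(10⁻⁸…10²) by the one-standard-error rule — the largest λ within one
fold-wise standard error of the CV minimum — which removes the occasional
razor-thin minimum at vanishing regularization; across repeated seizures at
one noise level the selected weight varies by well under 50%.

Before inversion, dZ traces are baseline-subtracted, band-passed at
0.01–1 Hz (the seizure time courses live between 1 and 100 s), folded with
sign(V₀) (the envelope observes |V|, the Jacobian predicts signed dV) and
averaged into 1 s frames. Channels whose baseline transfer voltage is below
100 µV are excluded from imaging: the modulus demodulation is linear, and
its noise Gaussian, only while the carrier dominates the in-band noise
(≈20 µV at the noisiest study condition), and the floor is fixed per study
so the inverse operator is built once.

t-scores divide each voxel's reconstructed change by its propagated noise
SD, sqrt(diag(MΣMᵀ)) with M the explicit linear inverse map and Σ the
per-channel frame-noise covariance (diagonal; the synthetic noise is
homoscedastic across channels, so a pooled baseline estimate is used).
Because the zero-phase 0.01–1 Hz filter has edge transients on a finite
block, the per-frame noise inflation profile — and the downward bias that
frame-to-frame correlation puts on a 20-frame baseline SD — are measured
once per configuration by a seeded calibration (`frame_noise_profile`) and
divided out. With these corrections, null-scenario t-fields are calibrated
(per-voxel SD ≈ 0.92, ~0.3–1% of voxels beyond |t| = 3 by chance, no voxel
near detection-grade scores); the display threshold zeroes |t| < 3 in
exports. One caveat: the acausal band-pass smears seizure signal backwards
in time, so suprathreshold voxels legitimately appear in pre-onset frames
of high-SNR blocks — timing claims are therefore made at the cluster
maximum (near the dZ peak), not at first appearance.

## Evaluation

Localization takes the t-score frame at the peak-dZ time, thresholds at
65% of its maximum, and reports the intensity-weighted center of mass and
its distances to the cannula tip, the mean and the closest onset-SEEG
contact, and the true focus center; cohorts aggregate as mean ± 95%
two-tailed t confidence limits. EIT spread counts contacts with a
suprathreshold voxel within 5 mm (half the grid spacing — the coverage
radius is otherwise unspecified in the source analyses). Correlations are
Pearson with two-sided p.

On the default 20-seizure cohort (seeds 1–20, foci between the probes,
radius 3–8 mm, SNR 15–25 dB) the chain localizes the true focus to ≈3.5 mm
on average (≈6 mm to the electrode-space references), well inside the
10 mm target, and reproduces positive spread and onset-count/peak-dZ
correlations (r ≈ 0.6–0.7 under the default generator coupling; the exact
value is generator-dependent, so tests assert only the sign).

## Problem sizes and determinism

Default experiment sizes — 2.5 mm mesh (~4·10⁴ tetrahedra), 62 contacts,
28 injections (1652 channels), 2 mm voxels (~10⁴), reduced-rate signals —
were chosen so a full 20-seizure cohort runs in a few minutes on one CPU
while every operator remains at its production shape. All randomness flows
through explicit integer seeds (mesh jitter derives deterministically from
the geometry parameters); repeated runs are bit-identical, and report
numbers are rounded to 6 significant digits for cross-platform stability.

## Known limitations

* Point electrodes and a homogeneous, isotropic, unfolded brain; no skull
  or scalp (recordings are intracranial).
* Linearized (one-step time-difference) forward mapping for the time
  series; no per-frame re-solve, consistent with the few-percent
  perturbation regime.
* The 5 µV / 50 µV rejection rule is an absolute criterion aimed at
  corrupted channels; under deliberately raised uniform noise floors it
  would reject everything, so the pipeline records the rejection but
  proceeds with all channels in that regime.
* Depth sensitivity falls with distance from the injection pairs, so foci
  far from all current paths localize worse — the protocol generator
  deliberately concentrates injection paths around the lesioned region.
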
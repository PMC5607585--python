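# Methods

`sonomark` reproduces, on synthetic data, the complete analysis used to
assess whether MR-compatible breast biopsy markers interfere with
MR-guided high-intensity focused ultrasound (MR-HIFU) thermotherapy: a
volumetric sonication is simulated in an agar-gel phantom, rendered
into the EPI thermometry images a 1.5 T scanner would acquire, and the
images are pushed through PRF thermometry, SNR-based masking, thermal
dose volumetry and the per-sonication summary metrics.  This note
documents the models, the defaults and the reasoning behind the open
design choices.

## Heating model

The phantom is agar-silica gel, so the bioheat equation reduces to the
heat equation — there is no perfusion (a perfusion hook would enter as
an extra linear sink and is deliberately omitted rather than set to
zero silently):

    dT/dt = D lap(T) + a * S(x, t)

* `D` — thermal diffusivity, default **0.14 mm²/s** (agar/soft-tissue
  range; configurable, never asserted against data).
* `a` — per-phantom absorption factor, drawn for cohorts from
  N(1, 0.046) truncated to [0.8, 1.2], emulating the gel-to-gel
  absorption variability the study quantified (100 ± 4.6%).
* `S` — the focal heating footprint, amplitude
  `source_scale * acoustic_power * a` in °C/s.

The solver is an explicit 7-point finite-difference scheme with
insulated (reflecting) boundaries on an isotropic cubic grid (default
40 mm at 1.56 mm, matching the in-plane imaging resolution); the time
step is snapped to divide the frame interval and validated against the
`h²/6D` stability bound.  Insulation makes the total heat content an
exact invariant after the source stops, which the test suite checks.
The default simulation grid uses the same half-integer lattice as the
imaging grid, so rendering at matched spacing samples simulated voxels
exactly instead of interpolating between them.

### Focal source profile

The transverse (x, y) profile is Gaussian with
`sigma = width / (2 sqrt(2 ln 2))` from the −6 dB focal widths
(0.7 × 0.7 mm).  The axial (beam, anterior–posterior) profile is
**Lorentzian**, `1 / (1 + (z/zR)²)` with half-maximum width equal to
the −6 dB focal length (4.5 mm, `zR = 2.25 mm`).  A focused beam's
on-axis intensity falls off slowly away from the focus (in Gaussian
beam optics exactly as a Lorentzian), and those tails carry the energy
that gives the lesion its axial extent.  An all-Gaussian source was
tried first and rejected: it cannot produce the 8 mm axial ablation
extent of the nominal 12 × 12 × 8 mm lesion at any dwell schedule —
the simulated 240 EM volume saturated near 0.33 ml against the 0.6 ml
design, with a 4.7 mm axial dose extent.  With the Lorentzian axis the
same calibration yields ≈0.46 ml and ≈7–8 mm axial extent, and the 3D
peak (≈35 °C) sits consistently above the map peak (30 °C) in the way
the study's own measured numbers (28.4 ± 3 °C reference map peak,
42.9 °C extremes) require.

By default the source is evaluated as its analytic voxel average
(erf/arctan differences), which keeps deposited power independent of
the sub-voxel focus position; point sampling is available and is what
the closed-form `peak = A·t` test uses.

### Trajectory and dwell schedule

The focal point sweeps three concentric coronal circles (3, 6, 9 mm
diameters) with 8 dwell points per circle, time per circle
proportional to its circumference (uniform energy per arc length), the
whole pattern cycled 30 times over the 30 s sonication.  The schedule
is not stated in the source protocol; the rapid-cycling limit was
chosen because the physical transducer electronically sweeps its
trajectory in milliseconds, and slow cycling (5 cycles) produced
transient single-dwell hot spots ~15% above the swept ring that made
the field peak an artifact of the schedule discretization.

### Calibration

`calibrate_source` exploits exact linearity: one probe simulation and
a ratio set the amplitude so the reference phantom reaches the 30 °C
clinical target.  The target is interpreted as the peak **on the
coronal thermal map** (slab-averaged, PSF-convolved) — temperature is
only ever monitored through the maps, and calibrating the 3D point
maximum instead makes the map peak land near 26 °C, inconsistent with
the measured 28.4 ± 3 °C.  The 3D voxel maximum remains available via
`measure="field"`.

## Image rendering

Per frame and per orientation (coronal z = 0, sagittal x = 0; the
shared axis is the vertical/B0 axis y):

1. the 3D dT field is averaged over the 5 mm slice slab;
2. resampled to the 200 mm / 1.56 mm scan grid and convolved with an
   in-plane PSF (separable 3-tap Bartlett kernel, ≈1.5-pixel FWHM)
   standing for EPI readout apodization and partial-volume averaging;
3. magnitude = SPGR steady-state signal ratio with
   `T1(dT) = T1_0 (1 + 0.01 dT)` (the 1%/°C T1 increase that couples
   heating to SNR loss), background normalised to 1; default
   `T1_0 = 1500 ms` (3% agar at 1.5 T);
4. the marker void multiplies the magnitude (below);
5. phase = fixed smooth polynomial baseline + `k·dT` with
   `k = 2π·γ·B0·α·TE = 0.0754 rad/°C`;
6. independent Gaussian noise of sigma `1/baseline_snr` (default SNR
   50) is added to the real and imaginary channels.

With noise disabled the PRF round trip is exact by construction:
`phase_to_temperature` recovers the slab-averaged, PSF-convolved field
to float precision.

### Marker signal void

The susceptibility void is a graded ellipsoidal magnitude suppression

    m(rho) = 1 − (1 − vf) exp(−ln(2(1−vf)) · rho²)

where `rho` is the ellipsoidal coordinate of the *apparent-size*
ellipsoid (physical dimensions × apparent factors, long axis along the
marker orientation: vertical for markers parallel to B0,
anterior–posterior for orthogonal ones) and `vf = 0.05` is the core
floor.  The constant is chosen so the 50% magnitude contour falls
exactly on the apparent ellipsoid, which is what the manual size
measurement thresholds on.  A *hard* uniform suppression was rejected:
its masked set is binary and cannot reproduce the observed coupling
between masked-voxel count and temperature; the graded rim plus the T1
decay does.  The profile is evaluated at the slice mid-plane (not
slab-averaged): the artifact the factors were calibrated on is the
on-image void, and slab-averaging a 3.5 mm void inside a 5 mm slab
would dilute it below the measurement threshold.

Catalogue apparent-size factors default to the cohort means (×4.2
width, ×2 length); the elongated 1.1 × 10 mm coil carries the printed
anchors (3.5 mm wide parallel to B0, 6.5 mm orthogonal).

## Thermometry and absorption correction

Phase differences against the reference (mean of all pre-sonication
frames — configurable to a single frame) are wrapped to (−π, π]; at
0.0754 rad/°C a wrap is ~83 °C, far beyond the dynamic range, so no
temporal unwrapping chain exists.  Temporal ×4 averaging uses
non-overlapping block means (complex for images), drops trailing
partial blocks, and halves the noise.

The absorption-correction coefficient of phantom *i* is its mean
end-of-sonication dT over a 3 × 3 focal ROI, averaged over its
reference sonications, divided by the cohort grand mean — so the
coefficients average to exactly 1.  **Direction of application:** with
this definition, literally dividing the PRF coefficient by c amplifies
rather than removes the absorption difference (dT ∝ 1/α, giving c² ×
the reference scale; the synthetic hot-phantom check measures 33.1 °C
instead of 30 °C).  The pipeline therefore divides the converted
temperatures by c — the only direction that equalises — while
`corrected_prf` keeps the literal α/c arithmetic available.

## Masking, infilling, dose

* `sigma_T = sqrt(2) / (SNR · k)` — the √2 because a temperature map
  subtracts two noisy phase images; the noise sigma comes from a
  robust (MAD) background-corner estimate unless supplied.
* Masked: `sigma_T > 2 °C` on unaveraged maps, `> 1 °C` after ×4
  averaging; counted per frame; aggregated across frames with a strict
  majority (> half).
* Infilling replaces masked voxels with the mean of valid 8-connected
  in-plane neighbours, iterating inward (slices are 5 mm, so
  cross-slice infill is off by default).
* CEM43: `sum R^(43−T) Δt` with R = 0.5 above 43 °C, 0.25 below,
  baseline 37 °C (patient-like conditions despite the room-temperature
  gel), accumulated over sonication plus the observed cooling minute
  on the ×4-averaged, infilled maps.
* The two-plane 3D reconstruction is the documented normalized-product
  scheme `T = Tc·Ts / max(line, eps)` on a 1.56 mm cube — exact for
  separable fields, a deterministic stand-in for the unnamed
  proprietary reconstruction of the original chain, and flagged as
  such in output metadata.

## What the synthetic study reproduces — and what it does not

Reproduced at the study's own conditions (40 W × 30 s on 3/6/9 mm
circles, SNR 50, absorption sd 4.6%): the 30 °C calibrated map peak;
a maximum unmasked temperature near 29 °C (measured: 28.4 ± 3 °C); a
simulated 240 EM volume of ≈0.46 ml against the 0.6 ml design
ellipsoid; correction coefficients with mean exactly 100% and spread
≈4.5%; apparent-size factors averaging ≈3.9 (width) and ≈2.4 (length);
orientation-dependent void widths (3.1 vs 6.2 mm for the elongated
coil); and a masked-count/peak-temperature correlation above 0.9 when
per-frame curves are averaged over marker sonications (the measurement
averaged 84 runs; the scaled-down analog averages 12 runs and bins to
2.5 s).

Not reproduced, knowingly: the edge-annulus mean temperature comes out
near 11 °C against the measured 17–20 °C, and the *reconstructed*
(two-plane) dose volume near 0.30 ml against the measured
0.64 ± 0.1 ml.  Both trace to the same cause — the printed focal
geometry plus gel diffusion yield an in-plane temperature skirt
steeper than the physical lesion evidently had, and the 5 mm slab then
dilutes plane temperatures by ~15%, which the exponential dose
threshold turns into a ~0.67× volume factor.  No parameter was tuned
to close this gap; the package reports both the simulated-field and
reconstructed volumes.

Passing tests on this generator therefore demonstrate the analysis
chain (thermometry arithmetic, masking rules, dose accumulation,
statistics) and the study's qualitative physics, not scanner-grade
image realism: there is no dipole-field phase artifact, no B0 drift,
no EPI distortion, and marker-surface (viscous) heating is out of
scope.

## Numerical choices and degenerate inputs

* Region membership: strict inner, inclusive outer bound
  (`inner/2 < r ≤ outer/2`), voxel-corner lattice — reproduces the
  28-voxel edge annulus; the disc *budget* is the separate area
  quotient `floor(π(d/2)²/Δx²)` that reproduces the 46-voxel target
  count.  The two printed counts are only consistent under these two
  different conventions, so both are exposed.
* Welch t-tests with star coding at 0.05/0.01/0.001; two zero-variance
  equal-mean groups report p = 1 by convention.
* Fully masked maps, empty annuli, zero grand means and unstable time
  steps raise typed errors rather than returning silent values.
* Problem sizes: tests and the acceptance script run the 1.56 mm /
  40 mm simulation cube with 0.5 s frames; unit tests use a shortened
  protocol on a 100 mm / 64-pixel grid.  These sizes keep each
  pipeline stage well-resolved relative to the focal trajectory while
  staying cheap enough to run the whole study repeatedly.
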
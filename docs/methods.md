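# Methods

`spisim` is a virtual single-particle-imaging (SPI) experiment: it simulates
photon-sparse XFEL diffraction snapshots of a molecule in random
orientations, corrupts them with the Gaussian photon-peak noise of an
integrating detector, recovers the 3D reciprocal-space intensity with
expand–maximize–compress (EMC), phases it with ensemble hybrid input–output
(HIO), and reads off the achievable full-period resolution from an R-factor
curve. This note documents the model, its assumptions, the parameters that
matter, and the numerical choices made where the design was open.

## Forward model

The expected photon count in a detector pixel at scattering vector **q** is

    mu(q) = Omega * (d sigma_T / d Omega) * n_in * |F(q)|^2

with Omega the pixel solid angle, `d sigma_T/d Omega` the differential
Thomson cross section, `n_in` the fluence in photons/cm², and
`F(q) = sum_i f_i(|q|) exp(i q·r_i)` the molecular structure factor over
point atoms with IT92 Cromer–Mann form factors (via gemmi). Assumptions:

- **No radiation damage, no pulse-to-pulse jitter.** The time integral of
  the scattering signal collapses to a single term with the total pulse
  fluence. Each snapshot sees an identical particle.
- **Fluence convention.** The focus is treated as a flat-top rectangle of
  the two FWHM values; 4 mJ × 38% efficiency at 6 keV over 250×150 nm²
  gives 4.2×10²¹ photons/cm². A Gaussian-equivalent area would change the
  absolute scale but nothing downstream, since the pipeline rescales
  fluence to a target occupancy anyway.
- **Polarization.** XFELs are linearly polarized; the default Thomson
  factor is `1 − (sin 2θ cos φ)²` (horizontal), with vertical and
  unpolarized `(1+cos²2θ)/2` as options. At the maximal 2θ ≈ 12° of the
  default geometry the difference is below other uncertainties.
- **Solid angle.** The `pixel² cos³2θ / SDD²` small-angle form is used; it
  agrees with the exact rectangular-pyramid formula to <0.1% for every
  geometry in this regime (asserted in tests).
- **Wavelength.** `λ[Å] = 12.3984 / E[keV]`, with the constant fixed at
  that precision so derived values are bit-stable.
- **Hydrogens and ligands.** Deposited models are simulated exactly as
  parsed; `strip_het` removes non-polymer groups (ligands, ions, waters).
  No riding hydrogens are added.

Counts are Poisson draws of `mu`; the beamstop disc (5 pixels ≈ the 2 mm
central gap of a megapixel integrating detector) is masked with a sentinel,
not zero.

## Detector noise and photonization

An integrating detector at low occupancy shows Gaussian "photon peaks": a
pixel holding k photons reads out `Normal(peak(k), sigma(k))` keV,
independently per pixel. Two stored configurations reproduce single-pixel
Cu-Kα calibrations at the standard and low-noise detector settings:

| | standard | low noise |
|---|---|---|
| one-photon peak (8 keV source) | 8.09 keV | 8.15 keV |
| noise-peak width σ(0) | 1.44 keV | 1.19 keV |
| σ_avg (mean of fitted widths) | 1.49 keV | 1.13 keV |
| scaled one-photon peak at 6 keV | 6.07 keV | 6.11 keV |
| peak separation (peak/σ_avg) | 4.07 | 5.41 |

Peak positions scale with photon energy by `target/8.0` (the fluorescence
source taken at its nominal 8 keV); widths are electronic and stay in keV.
Only σ(0) and σ_avg are published for these settings, so the stored models
carry the per-k widths as the linear profile through σ(0) whose mean equals
σ_avg, and `corrupt` draws every k at σ_avg by default — the simplest model
consistent with every stored number; `sigma_from_fit` switches to the
linear σ(k) fit when real histograms are supplied. `fit_calibration` fits
the binned histogram with a sum of Gaussians (robust MAD/median
initialization) rather than a free mixture, because the sparse multi-photon
peaks (~1% of samples) destabilize an unconstrained EM fit.

Photonization rounds keV readouts to integers in units of the one-photon
peak, thresholds at k ± 0.5 photon units, negatives to zero. The
zero-photon false-positive rate is then the Gaussian tail
`P(N(0, σ_avg) > 0.5·peak(1))` ≈ 2.1% at separation 4.07 — the mechanism by
which detector noise floods high-q shells where true photons are rare.

## Orientation sampling and recovery (EMC)

Orientations are Haar-uniform (normalized 4D Gaussians). The EM search grid
is the n-fold barycentric refinement of the 600-cell projected to S³ with
antipodes identified: `N(n) = 10(5n³+n)` quasi-uniform rotations (60 at
n=1, 10 860 at n=6, 691 440 at n=24). Weights are uniform; the refinement
is exact (counts asserted for every published level).

Each EMC iteration expands the model into per-rotation Ewald-sphere
tomograms (trilinear), computes Poisson responsibilities
`P_jk ∝ w_j exp(β Σ_p [K_kp log W_jp − W_jp])` in the log domain, forms the
responsibility-weighted mean pattern per rotation, and compresses the stack
back onto the cubic grid with trilinear weights (weighted additionally by
rotation occupancy). The model is Friedel-symmetrized after every compress.
Numerical choices:

- **β annealing.** β multiplies by a factor every `beta_period` iterations
  and is clipped at 1. The full-scale schedule (start 0.001, factor √2,
  period 10) reaches 1 exactly at iteration 200; √2 is adopted because a
  factor of 2 from 0.001 would overshoot 1 a hundredfold by then. Desk-scale
  runs compress the same geometric ramp into their shorter budget
  (e.g. start 0.04, factor 2, period 4 → β=1 by iteration 20).
- **Voxel size.** `Δq = q_corner/(edge//2 − 1)`: the detector-corner q
  lands one voxel inside the half-grid so every pixel stays interpolable
  under any rotation. This convention is recorded in metadata.
- **Precision.** The two sparse products that dominate an iteration run in
  float32 (responsibilities are row-renormalized, so single precision is
  ample); passing float64 counts switches the whole step to double, which
  the EM-monotonicity test uses. Responsibilities below 1e-30 are flushed
  to zero — subnormal float32 operands slow the sparse kernels by an order
  of magnitude on x86.
- **Start model.** Positive uniform noise scaled to the mean photon count;
  seeded. Ties in likelihood are handled naturally by soft EM.
- **Degenerate rotations.** A rotation receiving no responsibility keeps
  its expanded tomogram; untouched voxels keep the previous model value.

The log-likelihood trace reported per iteration is the marginal
`Σ_k log Σ_j w_j exp(R_jk)` (k! terms omitted). It is guaranteed
nondecreasing only across repeated maximize steps at a fixed grid — the
compress/expand projection between iterations can lower it slightly — so
the monotonicity test iterates `maximize` directly.

## Phasing (ensemble HIO)

The merged volume is centre-trimmed to an even edge, 2×2×2 mean-binned
(951³→552³→276³ at full scale), and a 5-voxel-radius central sphere (515
lattice points) is flagged unconstrained. HIO then iterates
Fourier-magnitude projection (masked voxels keep their amplitudes) against
a **fixed** spherical support — no shrinkwrap during iteration — with
feedback β_fb = 0.9 (unstated in the protocol; standard practice,
configurable) plus nonnegativity (configurable off). The ensemble runs
`n_starts` independent reconstructions, ranks them by the normalized
reciprocal-space residual, aligns the best `n_best` to the best run —
integer centre-of-mass shift, then sub-voxel registration on a 10×
Fourier-interpolated correlation (matrix-DFT upsampling), with the
inversion twin resolved by correlation — averages them, refines a tight
support once by Gaussian blur (σ=2 voxels) and a 3%-of-max threshold, and
normalizes the total density to the model's electron count (electrons per
voxel). The default support radius is 1.3× the particle radius implied by
oversampling 3.

## R factor and resolution

    R(D) = Σ_{|q|≤2π/D} | I(q)/ΣI − I_ideal(q)/ΣI_ideal |

with both sums over the full 3D voxel set inside the cutoff, each volume
normalized over exactly those voxels, and beamstop/masked voxels excluded
from both normalizations (required for R=0 on identical inputs). R is scale
invariant, bounded by 2, and computed after rotational registration of the
reconstruction onto the ideal map (coarse quasi-uniform rotation search on
log intensities over a voxel subsample, then Nelder–Mead polish). The
achievable resolution is the first upward crossing of R(D) through 0.2
coming from low q, linearly interpolated in 1/D (the q cutoff); a curve
that never reaches the threshold returns the finest grid D flagged
`detector-limited`, one that starts above it the coarsest D flagged
`unresolved`. Multiple crossings report the first — high-q noise can
re-cross on small datasets, which is why very small snapshot counts are
better flagged than trusted.

## Synthetic data and what passing tests show

The generator replaces every external input at desk scale:

- **Phantoms:** n atoms (default 40, mix 60% C / 20% O / 15% N / 5% P
  approximating protein/RNA composition) placed by seeded rejection
  sampling at ≥1.2 Å spacing in a sphere (default 4 nm). Deterministic per
  seed.
- **Calibration samples:** Poisson photon count, then the corresponding
  peak Gaussian — the same generative process the noise model assumes.
- **Datasets:** fresh Haar orientation → Poisson draw → optional
  corrupt+photonize → beamstop mask, with true orientations stored.
  Orientation/Poisson and detector-noise randomness use separate seed
  streams so seed-matched noise cases share their Poisson stage exactly.
  Fluence is rescaled so the mean occupancy is ~0.1 photons/pixel, the
  photon-sparse regime of interest.

Desk-scale problem sizes were chosen once so the full pipeline runs in
minutes on one core while preserving that regime: a 64×64-pixel detector
cutout covering the same q range as the 550² array (so per-pixel q steps
are coarser but edge resolution is identical), 65³ reconstruction grids,
1500 snapshots for the recovery benchmark, refinement levels 4→6, and an
18-iteration / 49³ / levels 3→4 configuration for the noise-ordering study
(400 and 800 snapshots, 3 EMC seeds). The phasing benchmark uses a smooth
compact density (Gaussian blobs of σ=1.2 voxels at the phantom atom
positions, oversampling 3): point atoms at a 4 Å band limit ring so heavily
that ~40% of the true density is negative, which contradicts the
support+positivity constraint — a molecule at nanometre resolution is
smooth, and the blob density is the honest desk-scale analogue.

What the synthetic data does **not** emulate: solvent and hydration-layer
scattering, Compton background, carrier-gas parasitic scattering,
conformational heterogeneity, detector panel gaps and gain-stage artifacts,
charge sharing, and pulse fluctuations. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms under the
stated noise model, and the *relative* effect of photon-peak separation on
achievable resolution — not absolute resolutions for real samples, which
these unmodelled backgrounds will degrade.

EMC recovery quality is scored as the Pearson correlation with the
registered ideal volume inside the sphere reached by the detector edge
(|q| ≤ q_edge, beamstop excluded): within that ball every orientation
contributes statistics, while the corner shells beyond are sampled only by
a vanishing fraction of pixels and measure Poisson noise rather than
orientation recovery.

## Known limitations

- The EM orientation search is exhaustive over the rotation grid; no
  adaptive subsetting. Full-scale (951³, level 24) configurations are
  expressible and validated but sized for cluster hardware, not laptops.
- `register_rotation` assumes speckle-scale structure; it refuses constant
  volumes and can in principle lock onto a wrong maximum for nearly
  symmetric particles (the Friedel twin is degenerate by construction and
  scores identically).
- The detector model is per-pixel and Gaussian by design; real gain
  switching, memory-cell calibration spread, and pedestal drift are out of
  scope.
- Electron-count normalization of the phased density presumes the model's
  total electrons are known; for experimental data this is a composition
  estimate.
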
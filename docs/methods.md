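# Methods

## Physical model

A tissue susceptibility distribution perturbs the main field; to first order
in chi (ppm-scale), the GE-MRI frequency offset is the convolution of the
distribution with the unit dipole response.  All forward models are evaluated
in k-space:

* scalar:  `f(k) = f0 * D(k) * chi(k)`,  `D(k) = 1/3 - (k.h)^2/|k|^2`;
* tensor:  `f(k) = f0 * [ h'X(k)h/3 - (k'h)(k'X(k)h)/|k|^2 ]`,

with `h` the unit B0 direction and `f0 = 42.577 MHz/T * B0 * 1e-6` the
frequency per ppm (298.04 Hz/ppm at 7 T).  White-matter anisotropy is
parametrised by the cylindrically symmetric convention

    X = chi_I * I + chi_A * (3/2) (n n' - I/3),

so the principal-axis eigenvalue exceeds the perpendicular ones by
`1.5 * chi_A`; an anisotropy parameter of 0.0113 ppm therefore corresponds to
an overall anisotropy `chi_par - chi_perp` of 0.017 ppm.  The scalar kernel,
the uniform-axis anisotropic kernel and the general tensor model are required
by tests to agree algebraically (isotropic reduction, traceless/trace
decomposition, uniform-axis equivalence) and to match analytic sphere,
infinite-cylinder and real-space dipole-sum oracles.

Microstructure enters purely phenomenologically: water around myelinated
axons samples the microscopic field in a biased way, producing a *local*
frequency offset

    f_M = A * FA_n * (sin^2 theta - 2/3) + b0

where `theta` is the fiber-to-field angle, `FA_n = FA / 0.59` is fractional
anisotropy normalised to the optic-nerve reference value, `A` (Hz) sets the
amplitude and `b0` (Hz) an orientation-independent offset.  The `-2/3` makes
the offset average to zero over an isotropic fiber-orientation distribution,
separating it cleanly from `b0`.  f_M is a direct map, not a field source:
it is added to composed frequency maps without any convolution.  No
biophysical (hollow-cylinder) modelling is attempted.

## Numerical choices

* **k = 0**: set to zero in every kernel, forward and inverse.  All computed
  fields and reconstructions are therefore referenced to their volume mean;
  comparisons against ground truth re-reference reconstructions to the
  CSF/cortical-GM region, where the model susceptibility is zero.
* **Padding**: forward simulations zero-pad by `pad_factor` (default 2)
  before transforming and crop back; a property test checks that doubling
  the padding changes the masked field by < 0.5% RMS.  Grids intended for
  exact forward/inverse round trips use `pad_factor = 1`, where the discrete
  model is exactly circular.
* **Single-voxel sources** excite the kernel up to Nyquist and ring; oracle
  comparisons against continuum dipole sums therefore use smooth compact
  sources, which keep both representations in their common mid-band regime.
* **SHARP**: spherical kernel radius 4 mm, TSVD threshold 0.05 by default
  (appropriate when measurement noise must not be amplified through the
  deconvolution).  The phantom pipeline uses 0.01: its inputs are noise-free,
  and the tighter threshold keeps the non-harmonic internal offsets of the
  sample from leaking into the external fitting shell (with 0.05 that leak
  biases chi_A by several per cent; with 0.01 it is ~0.3%).  Output is
  defined on the mask eroded by the kernel radius and has zero mean there.
* **Morphology**: all dilation/erosion radii are Euclidean distances in
  voxels, computed with exact distance transforms.
* **Least squares**: both susceptometry models solve via orthogonal
  decomposition (`numpy.linalg.lstsq`); standard errors use the classical
  covariance `sigma^2 (G'G)^{-1}`; the orientation model is ordinary
  (unweighted) least squares; exactly determined designs return zero
  standard errors.  Rank-deficient designs raise.
* **TKD**: inverse kernel `1/D` where `|D| >= delta` (default delta = 0.07,
  i.e. a truncation value of ~14), `sign(D)/delta` below threshold with
  `sign(0) := +1`; the fully relaxed variant floors the whole truncation
  region at the constant `+1/delta` (sign relaxed as well as magnitude).
  A global amplitude correction `1/PSF(0)` of the composite `D * D_tkd^-1`
  compensates truncation losses; its value at delta = 0.07 (1.09284,
  voxel-size invariant) is frozen as a regression constant.
* **STI**: the six tensor-component fields are estimated by conjugate
  gradients on the normal equations, capped at 30 iterations
  (tolerance 1e-6).  Without a data mask the system decouples per k and CG
  effectively reaches the per-k least-squares solution (validated against a
  brute-force per-k `lstsq` oracle to ~1e-12).  With a data mask (brain-only
  data, as in vivo) the fidelity term is restricted to masked voxels in
  image space; masked-out voxels are *unconstrained*, not zero — treating
  them as zeros injects inconsistent constraints and wrecks the
  reconstruction.  The artifact studies use the masked operator.
* **Eigen-analysis**: `chi_iso` is the mean eigenvalue; `chi_aniso` is the
  eigenvalue with the largest absolute deviation from the mean, minus the
  mean — exactly `chi_A` for tensors built with the package convention;
  the principal eigenvector is sign-fixed to non-negative z (axial
  quantity).  Isotropic voxels (deviation below 1e-12) get `chi_aniso = 0`
  and an undefined-PEV flag.
* **Statistics**: population (N) standard deviations throughout.

## Synthetic data

**Nerve phantom** (desk scale): 96^3 grid of 1 mm voxels; gel sphere of
radius 40 mm; cylindrical nerve of radius 2.5 mm and length 20 mm along z;
bulk ground truth `chi_I = -0.08152` ppm, `chi_A = 0.01128` ppm relative to
the gel; internal residual `A sin^2(theta) + b` with `A = -5.59` Hz,
`b = 4.88` Hz injected uniformly inside the nerve eroded by one voxel; ten
orientations, theta = 0..90 deg in 10-degree steps, implemented by tilting
the B0 unit vector (no volume resampling, hence no interpolation error).
R2* is 5/s in gel, 20/s in the nerve, with a seeded handful of bubble voxels
at 50/s to exercise the R2* < 15/s exclusion rule.  Noise is off by default
(opt-in Gaussian, seeded).  The external-field fit uses the shell
`dilate(nerve, 8) \ dilate(nerve, 1)` intersected with the SHARP-eroded
sphere.

**Brain model** (default 64^3, 3 mm voxels): ellipsoidal brain and interior
WM region; three analytic tract systems (a left-right arch over the midline,
paired inferior-superior columns, paired anterior-posterior bundles) with
tangent/constant unit direction fields and FA 0.85 cores over an FA 0.35
background (smoothed, with a small seeded texture); deep grey ellipsoids
with chi_I of GP 0.15, PU 0.05, CN 0.05, TH 0.00, PV 0.03 ppm and zero
anisotropy; WM chi_I = -0.05 ppm; chi_A = 0.0113 ppm x FA_n in WM (FA_n
deliberately unclipped above 1).  What this emulates is the *orientation and
coherence structure* the pipeline needs; it does not emulate cortical
folding, crossing fibers, partial volume, DTI noise, or realistic tract
shapes, so passing tests demonstrate the processing chain's behaviour under
controlled conditions, not performance on real brains.

Problem sizes were chosen so the full suite runs in about a minute on one
CPU: 96^3 for the phantom (padded transforms at 192^3), 64^3 for the brain
studies.

## Design choices

* Orientation changes rotate B0, never the volumes: exactly equivalent for
  simulation, and it keeps all orientations on one voxel grid.
* The brain anisotropy field uses the general tensor forward model with
  per-voxel fiber axes; equivalence with the uniform-axis kernel is enforced
  by test on uniform-axis inputs.
* The bulk fit exposes an isotropic-only variant; the nested F-test
  compares it with the two-parameter fit.  A 1000-replicate null simulation
  checks the test's type-I error calibration at alpha = 0.05.
* Fitting shells, thresholds and generator parameters are fixed study
  conditions, not tuning knobs.

## Known limitations

* The STI microstructure artifact is *solver-convergence dependent*.  Local
  `sin^2` offsets are outside the tensor-dipole model class, so what the
  inversion maps them onto depends on how far the least-squares iteration
  has progressed.  Early conjugate-gradient iterates assign them an
  *inflated* apparent anisotropy aligned with the fiber axis; the fully
  converged least-squares solution assigns an apparent tensor whose
  largest-deviation eigenvalue along the fiber axis is of opposite sign, so
  converged reconstructions can *understate* chi_aniso in coherent-fiber
  regions instead.  At the default 30-iteration cap and 64^3 scale this
  package's solver is past that transition: adding f_M increases the PEV
  angle error and lifts WM chi_iso toward less diamagnetic values, but
  reduces mean reconstructed chi_aniso in some coherent-fiber ROIs (one
  acceptance-style test documents this expectation and currently fails by
  design of the fixed iteration cap; lowering `StiSolveParams.max_iterations`
  to ~5 reproduces inflation in every ROI).  Interpret reported chi_aniso
  values from iterative STI with the iteration count in mind.
* SHARP's TSVD removes the lowest-frequency content of genuine internal
  sources along with the background; internal offsets are therefore
  recovered only up to a small mean shift.
* The brain-model QSM/STI inputs are not SHARP-filtered (pure simulations
  contain no background field), unlike the phantom processing.
* No noise regularisation in either inversion; noise robustness is limited
  to what the (opt-in) noisy-phantom tests cover.
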
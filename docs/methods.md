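# Methods

This note documents the models, numerical choices and limitations behind
`aortaflow`, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and units

Volumes are `(x, y, z[, t])` arrays; world coordinates are `index × spacing`
in mm with the origin at voxel `(0, 0, 0)`. Orientation matrices beyond voxel
spacing are ignored (logged): phantom and patient pipelines are
self-consistent in this frame, and no operation in the package depends on
patient orientation. Velocity is carried in cm/s everywhere — VENC values
(200–550 cm/s clinically) and the speed-gate threshold δ are then directly
interpretable — and converted to SI only inside the WSS module. Two storage
dialects are read: `physical` (volumes already in cm/s) and `raw`
(`v = raw / raw_max × VENC`).

## Phase-offset correction

Eddy currents add a spatially smooth, temporally constant offset to each
velocity component. The correction:

1. **Candidates** — voxels whose temporal-mean magnitude reaches the 15th
   percentile of the temporal-mean magnitude volume (linear-interpolation
   percentile; the aggregate volume rather than a single frame, for
   robustness to per-frame noise).
2. **Stationary tissue** — candidates whose temporal velocity s.d. is
   strictly below the candidate median, per direction. Degenerate
   distributions (noise-free data put most candidates exactly at the zero
   median) relax the comparison to ≤ median, which selects exactly the
   minimal-s.d. voxels and reduces to "all candidates" when every s.d. is
   equal.
3. **Fit** — ordinary least squares of the 20-term trivariate cubic
   monomial basis (fixed ordering: ascending total degree, then
   lexicographic exponents) on per-axis coordinates normalised to [−1, 1]
   (conditioning), against the temporal-mean velocity of the stationary set.
   Fewer than 20 samples or a rank-deficient design is an error.
4. **Subtraction** — the evaluated offset volume is subtracted from every
   frame (the offset is modelled as time-constant, consistent with
   eddy-current physics).

OLS on noise-free polynomial data is exact, which is what the phantom
round-trip tests assert (coefficients to 1e−6 relative, residual background
speeds below 1e−4 cm/s).

## PC-MRA, systole, initial front and domain

The synthetic angiography `MRA = mean_t m(t) · |v(t)|^{2γ}` uses the
full-cycle mean and γ = 0.2 (enhances low-velocity regions). The systolic
frame maximises mean speed over an ROI; without an ROI the ROI defaults to
voxels above the 95th MRA percentile (a lumen proxy that replaces the
manual ascending-aorta plane, which is not reproducible); ties break to the
lowest index.

The initial front is Otsu's threshold of the **full** MRA volume. Thresholding
only the nonzero values fails in the noise-free limit, where background MRA is
exactly zero and Otsu would split the lumen itself.

The evolution domain is the MRA above its 80th percentile taken over the
whole volume: on noise-free data that percentile is zero, so the domain is
the entire flow support; on noisy data it keeps the brightest 20% of voxels.
The pipeline intersects the initial front with this domain (excluding
noise-dominated regions from the segmentation) and freezes the front outside
it.

## Discontinuity field

Structure tensor: the six unique products `v_i v_j` of one frame's velocity
smoothed componentwise by a Gaussian (σ = 1 voxel by default — the
two-direction neighbourhood at 2 mm resolution; reflective boundaries,
truncation 4σ; σ = 0 disables smoothing). Eigenvalues from `eigvalsh`,
sorted descending; negatives within 1e−8·λ₁ are clamped to zero.

R is evaluated on the eigenvalue ratio `t = λ₂/λ₁ ≤ 1` as `4t/(1+t)²`,
algebraically identical to `4λ₁λ₂/(λ₁+λ₂)²` but immune to overflow/underflow
of squared eigenvalues at extreme velocity magnitudes. R is invariant to
rescaling the velocity field, so whether velocities are normalised before
the tensor is immaterial for R.

Purely unidirectional flow (e.g. the straight-tube phantom without noise)
has a rank-1 tensor everywhere and R ≡ 0: the wall signature requires either
curvature or noise to introduce a second direction. The wall-versus-core
contrast is therefore asserted on a noisy phantom.

## Level set evolution

Convention: φ is a signed Euclidean distance in mm, negative inside; the
front moves with outward normal speed `F = χ − R` (`φ_t + F|∇φ| = 0`). This
is the sign assignment that grows the front through high-velocity lumen and
arrests it at flow discontinuities. Numerics (unspecified in the original
formulation, chosen here):

* Godunov upwind discretisation of |∇φ| (one-sided differences at volume
  faces);
* explicit Euler with CFL time step `0.45 · min(spacing) / max|F|`;
* redistancing (signed EDT of the current interior) every 25 iterations;
* convergence when the interior voxel set is unchanged for 3 consecutive
  redistancing cycles, with a hard cap of 1000 iterations;
* F is set to 0 outside the domain mask, so the interior outside the domain
  is exactly the initial one at every iteration (frozen-exterior contract,
  asserted in tests);
* full-grid updates — at the 64³ desk scale a vectorised sweep costs
  milliseconds, so a narrow band would add complexity without benefit.

χ defaults (δ = 275 cm/s, ε = 0.5 cm/s) reflect the clinical operating point
where VENC is 200–550 cm/s; δ is interpreted as a speed threshold in the
stored cm/s unit. Phantom runs scale δ to 0.55 × the phantom's systolic peak
speed, preserving the ratio of threshold to peak velocity.

## Post-processing

Largest 26-connected component (diagonal continuity matters for vessels at
2 mm), 3 mm ball opening with per-axis mm→voxel semi-axes (rounded half-up,
supporting anisotropic grids), then a second component pass because the
opening can split a thin structure. The erosion half of the opening treats
out-of-volume voxels as foreground so a vessel crossing the field of view is
not clipped at the volume faces. If the opening erases everything, the
pre-opening mask is returned with a warning.

## STAPLE fusion

Binary STAPLE with a spatially uniform prior initialised to the mean
foreground fraction, rater sensitivities/specificities initialised at 0.99,
EM iterated to a 1e−6 parameter tolerance (cap 100). Raters that are
all-empty or all-full are excluded with a warning. Probability ties at 0.5
count as foreground. The observed-data log-likelihood is recorded per
iteration and is non-decreasing (asserted).

## Metrics

DSC with the convention `dice(∅, ∅) = 1`. Hausdorff distance between
6-connectivity boundary voxel point sets in physical mm (identical to the
full-set HD — interior voxels can never attain the max — and verified
against an all-pairs brute-force oracle). Regional metrics intersect both
masks with each region's support; a region empty in both masks is undefined
(`None`), not zero. Paired two-sided t-test via the standard formulation,
with all-zero differences mapped to `(t, p) = (0, 1)`.

## Wall shear stress

The lumen surface is a marching-cubes iso-surface at level 0.5 of the binary
mask. The binary volume is edge-padded and Gaussian-smoothed (0.8 voxel)
first: raw binary iso-surfaces carry a staircase that biases surface area
and near-wall gradients upward, while 0.8 voxel stays well below any vessel
radius of interest; edge padding leaves border-crossing vessels open rather
than capping and eroding them. Masks too small to survive smoothing fall
back to the raw binary surface.

Per vertex, velocity is sampled trilinearly at depths h and 2h along the
inward normal (h = mean voxel spacing, "a voxel's size"; configurable), the
tangential component `v − (v·n)n` is taken, and the no-slip parabola through
(0,0), (h, v_t1), (2h, v_t2) gives the wall gradient exactly:
`τ_w = μ (4 v_t1 − v_t2) / (2h)` after converting cm/s and mm to SI
(1 cP = 10⁻³ Pa·s; μ defaults to 3.2 cP). The fit is exact for any profile
polynomial of degree ≤ 2 through the origin — in particular for Poiseuille
flow, which is why the phantom has a closed-form oracle `2 μ v_max / R`.
Vertices whose samples leave the volume are flagged and excluded from
summaries. Regional maxima assign each vertex the label of the nearest
labelled voxel (surface vertices commonly sit over background voxels).

The maximum is reported at the segmented (systolic) frame. Note that a
per-vertex maximum is an extreme statistic: vertex placement errors of a
fraction of a voxel inflate individual estimates, so the max converges more
slowly than the median, and on noisy data the evaluation of choice is the
absolute difference between two masks' maxima, not the absolute value.

## The phantom: what it emulates, and what it does not

`make_tube_phantom` emulates a 2×2×2 mm³, 25-frame acquisition: a rigid tube
(straight, or a U-bend whose limbs and distal extension stand in for the
ascending/arch, descending and abdominal aorta, labelled by centerline
arc-length thirds), Poiseuille axial flow `v(r,t) = v_max(t)(1 − (r/R)²)`
along the local centerline tangent, a raised-cosine systolic waveform
peaking at 100 cm/s at frame 8 (≈ one third into the cycle), piecewise
constant magnitude (lumen 1.0, tissue 0.6, air 0.05 a.u. — contrast-enhanced
blood is brightest), Rician magnitude noise (two-channel Gaussian modulus),
Gaussian velocity noise, and a time-constant 3rd-degree polynomial phase
offset per direction. The velocity noise s.d. and the magnitude channel
s.d. are linked by default as 100:1, mirroring that velocities are O(100)
cm/s while the magnitude is O(1).

It does **not** emulate: wall motion or compliance (the method segments a
single systolic frame), turbulence or secondary flow, phase wrapping,
partial-volume averaging within a voxel (velocity is sampled at voxel
centres), or k-space/reconstruction effects. A green phantom test therefore
establishes the correctness of the implementation against an analytic
stated world — not clinical performance, which in the source study was
evaluated on 36 patient exams against fused manual ground truth.

## Known limitations

* Purely axial phantoms exercise the χ and domain terms but not the
  R-arrest mechanism (R ≡ 0 without noise or curvature); the U-bend and
  noisy phantoms cover it.
* δ and ε are dataset-dependent ("in relation to the noise"); defaults suit
  clinical VENC ranges and must be rescaled for other speed regimes.
* The WSS tangential magnitude is not decomposed into axial and
  circumferential components.
* Multi-label STAPLE and spatially varying priors are out of scope.
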
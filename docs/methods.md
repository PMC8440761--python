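# Methods

This note records the models, conventions and numerical choices behind
`seguq`, and what the synthetic fixtures do and do not demonstrate about
real image data.

## Probability maps

A segmentation-sample stack holds N co-registered integer label volumes
over a common (z, y, x) grid — the axis convention is slowest-to-fastest,
matching slice-stack acquisition, and is shared by every module.  The
probability map is the per-voxel, per-class sample mean of the membership
indicator.  Accumulation runs in float64; maps written to disk are float32
(N is at most a few hundred, so single precision is ample and halves
storage).  For a binary problem a single foreground map suffices and the
complement class is implied as 1 − ε; multi-class problems are treated
one-vs-rest, one map per class.  Maps loaded from disk may stray outside
[0, 1] by at most 1e-6 (lossy float storage); anything worse is rejected as
corruption rather than silently clamped.

Samples must be binarized label volumes.  Real-valued (softmax) segmenter
outputs are not averaged directly; the supported route is to threshold each
sample at 0.5 first, or to supply a precomputed probability map, which
replaces the ensemble entirely.

## Entropy maps

The total uncertainty map is the Shannon entropy of each voxel's class row
normalized by log₂ n_c, so it lives in [0, 1] for any class count; the
per-class map keeps a single term of the sum, so per-class maps add up to
the total exactly.  The 0·log 0 = 0 convention is enforced by masking the
p = 0 and p = 1 entries, not by adding an epsilon — one-hot voxels give
exactly 0 and balanced binary voxels exactly 1.  Probability rows must sum
to 1 within 1e-6; a binary single map auto-expands to (ε, 1 − ε).

## Percentile segmentations

A percentile P ∈ (0, 100) maps to the threshold t = 1 − P/100 and the
segmentation is the inclusive comparison ε ≥ t (ties belong to the
segmentation).  Under this orientation larger percentiles add voxels, so
the P = 84.1 segmentation is the better-connected, higher-conductivity
geometry — the physically meaningful direction for transport quantities.
The inverse reading (t = P/100) would reverse the nesting and is not
implemented.  The standard percentiles are used exactly as printed (15.9,
50.0, 84.1); the full-precision values 100·Φ(∓1) = 15.8655…/84.1345… are
deliberately not substituted, so reported percentile labels match the
conventional μ±σ constants.

Surfaces come from marching cubes applied to the real-valued map at level
t — never to a binarized mask — which yields a smooth rather than
stair-stepped mesh.  Vertex coordinates are physical: cell centers sit at
(index + 0.5)·spacing, and the mesh is exported as binary STL.

## Voxel transport solver

Effective conductivity is computed from Laplace's equation on the voxel
grid with a cell-centered finite-volume scheme:

* face conductance = harmonic mean of the adjacent cells' conductivity
  components along the face normal — the standard choice for discontinuous
  coefficients, and the one that reproduces the series-slab closed form
  exactly;
* unit potential difference via Dirichlet values imposed at half-cell ghost
  distance on the two faces normal to the transport axis (this makes a
  homogeneous medium exact), zero flux elsewhere;
* the non-transporting phase keeps a residual conductivity of 1e-6 rather
  than being removed, keeping the grid structured;
* per-phase conductivity may be an axis-diagonal (k_z, k_y, k_x) triple,
  which covers transversely isotropic materials (e.g. woven fabric with
  half the in-plane conductivity across the fabric normal, supplied via the
  axis order of the triple).  Full tensors and per-voxel fiber orientation
  are not modeled.

The system is SPD and solved by Jacobi-preconditioned conjugate gradients.
Three numerical choices matter and were made deliberately:

* **Convergence scale.** The residual is measured against
  max(‖b‖, ‖A‖_inf), not ‖b‖ alone: the potential is bounded by the unit
  Dirichlet data (maximum principle), so ‖A‖_inf is the natural scale,
  while ‖b‖ can be ~1e-6 whenever the inlet face lies in the resistive
  phase, putting rtol·‖b‖ below what double precision can reach.  CG starts
  from the linear ramp along the transport axis (the homogeneous-medium
  solution).
* **Tolerance and iteration cap.** Relative residual 1e-12, at most 200×
  the longest grid dimension iterations.  The 1:1e-6 contrast puts the
  condition number near 1e6, so a percolating random field legitimately
  needs ~1000 iterations; the tight tolerance keeps the effective value of
  high-contrast slab geometries accurate to ~1e-11 relative, far below any
  effect of interest.
* **Flux extraction.** The effective value uses the outlet boundary flux
  (u − 0): the inlet expression (1 − u) suffers catastrophic cancellation
  when the potential drop concentrates downstream.  Inlet/outlet balance is
  still reported; since flux_in − flux_out equals the residual sum
  identically, the imbalance is normalized by √n·scale, making it a direct
  certificate of solver convergence.

Tortuosity is porosity divided by the effective transport of the pore
phase (pore conductivity 1, solid 1e-6).  When given a percentile
segmentation the segmented class is the solid and its complement the pore;
a raw boolean array is read directly as the pore mask.  Effective values
are nondimensional unless the supplied conductivities carry units.

## Characteristic distributions

The Normal estimate uses mean = Q(50.0) and σ = (Q(84.1) − Q(15.9))/2.
The standard percentiles are read as the μ−σ/μ/μ+σ anchors, so a table
whose standard rows carry exactly those values is recovered exactly.  Both
one-sided half-widths are kept in the diagnostics so asymmetry remains
visible; a decreasing quantity flips the sign, which is flagged and the
magnitude used.  How the two one-sided deviations *should* combine is
genuinely open — the symmetric half-width is canonical here.

Held-out validation measures |CDF(Q(P)) − P/100| at every non-standard
percentile; the default tolerance 0.05 separates curve-hugging agreement
from tail failure on the synthetic analogues.  Alternative families (beta,
half-Cauchy) are fitted by least-squares quantile matching with a
Nelder-Mead simplex, three restarts from moment-based starts (seeded, seed
0); on exact quantile data this recovers parameters to ~1e-6 relative or
better.  Beta support defaults to [0, 1.1·max Q] — a bounded-below family
is the natural choice for positive quantities such as permeability, whose
Normal estimate would admit impossible negative values.  The empirical
family is the monotone linear interpolant of (Q(P), P/100) and requires no
optimization.

A monotonicity guard checks both failure modes seen in practice: Q(P) not
monotone in P, and an interior value escaping the closed band spanned by
Q(15.9) and Q(84.1).  Characteristic fitting refuses non-monotone tables
unless explicitly overridden; the pipeline downgrades to the empirical CDF
with a machine-readable warning instead.

## Synthetic scenes

* **Planar interface**: grayscale g(x) = Φ((x − x0)/w) along the fastest
  axis, evaluated at voxel centers.  Under the threshold-jitter sampler the
  true probability map *is* g, so the percentile interfaces sit at
  x0 + w·Φ⁻¹(P/100) analytically and the volume fraction is linear in the
  normal quantile of P — a construction whose characteristic Normal fit
  must pass.
* **Blob microstructure**: a Gaussian random field (white noise smoothed to
  correlation length ℓ) thresholded at the φ-quantile, so the target volume
  fraction is hit to quantile granularity.  The rendering is the blurred
  truth plus additive Gaussian noise of amplitude a, clipped to [0, 1].
  Defaults (32³ grids, φ = 0.5, ℓ = 3 voxels, a = 0.05, blur 1 voxel) give
  a two-phase microstructure whose conductive phase percolates — small
  enough for the sweep of ten percentile solves used in the end-to-end
  checks to finish in seconds, large enough for the quantile thresholding
  to hit φ within 0.01.
* **Samplers**: `threshold_jitter` applies one uniform threshold per sample
  (inclusion probability = g exactly); `noise_then_threshold` adds fresh
  Gaussian noise of amplitude a and thresholds at 0.5 (inclusion
  probability Φ((g − 0.5)/a)).  The amplitude a is the image-quality knob:
  the effective interface width scales linearly with a, so a noisier
  rendering strictly widens the fitted σ of downstream quantities.

One caution on statistical tests: threshold jitter shares a single τ per
sample across all voxels, so per-voxel inclusion is Binomial(N, g) but
deviations are perfectly correlated within iso-gray regions.  Binomial
confidence-band checks therefore fail in whole planes for a small fraction
of random streams; the fixed seeds used in the tests make them
deterministic.

What the synthetic fixtures do **not** emulate: CT artifacts (beam
hardening, rings, partial-volume bias), anisotropic resolution, correlated
segmenter errors that span many voxels, or multi-class organ geometries.
Passing tests demonstrate the correctness of the machinery — Eq.-level
identities, solver accuracy, fit recovery — not the realism of any
particular uncertainty magnitude on real scans.

## Pipeline

The YAML config is validated strictly (unknown keys rejected — a silently
ignored misspelling is the main hazard in an uncertainty pipeline).  A run
writes the probability map, entropy map and summary, masks (optionally STL
surfaces), the physics CSV, one distribution JSON per quantity, a run log,
and a manifest with the config hash, seed, per-stage timings and
machine-readable warnings.  Re-running a completed configuration is a
no-op (the manifest hash short-circuits), so completed runs are
byte-stable; the CLI exits 0 only on warning-free completion, 3 with
warnings, 4 on errors.

## Known limitations

* Per-voxel (marginal) uncertainty only; spatial correlation between
  neighboring voxels' uncertainties is not represented.
* Aleatoric and epistemic contributions are not separated.
* Transport physics is limited to structured-grid Laplace solves; Stokes
  permeability, elasticity and flow quantities must be computed externally
  and fed back as (percentile, value) CSV tables, which the fitting stage
  accepts directly.
* NRRD I/O goes through SimpleITK; spacing metadata is honored but general
  orientation matrices are not.
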
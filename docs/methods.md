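# Methods

## The despiking model

RF spike noise corrupts a small number of k-space samples with
arbitrarily large complex outliers. Two structural facts make the
corruption separable from the signal: (i) in a dynamic series the
artifact-free k-space frames are mutually redundant, so the k-t Casorati
matrix (one vectorized frame per column) is well approximated by a
matrix of modest nuclear norm, and (ii) the spikes are sparse. Principal
component pursuit,

    min ||L||_* + λ_eff ||S||_1   s.t.   M = L + S,

therefore assigns the spikes to S and the data to L without any
user-defined spike template or threshold. The decomposition does not
force L to low rank: in practice L retains the full rank of M (equal to
the number of frames), and S collects only the entries whose magnitude
is cheaper to pay for under the L1 norm — the outliers.

For a single frame, M is the kx-ky matrix itself and S captures
line-to-line structure not explained by a low-rank image spectrum; this
works but is weaker than the multiframe arrangement, since the
decomposition can no longer exploit the frame-to-frame consistency of
the central peak.

### The sparsity weight

The default weight is the canonical principal-component-pursuit value
λ = 1/√(max(m, n)) for an m×n observation matrix — 1/√(Nx·Ny) for a
Casorati matrix with more samples than frames, 1/√(max(Nx, Ny)) in
single-frame mode. This default is not a free choice: a weight much
below ~1.13/√(Nv) makes dense thermal noise cheaper to store in S than
in L (per-entry L1 cost λ·E|n| versus amortized nuclear-norm cost
≈ σ√Nv per column), at which point S becomes dense, the center-refill
connectivity floods the grid, and the method stops being a spike
detector. Above it, noise stays in L and S is genuinely sparse.

Because k-space is strongly peaked at its center, the weight is further
scaled by a user factor κ ≥ 1 (λ_eff = κ·λ). κ too small sends central
pixels into S; κ too large leaves spike energy in L. κ is the one
non-automated parameter; validated values per application are T1 series
5, cine 6, static single frame 3, diffusion-weighted volumes 5, low-b
reference volumes 6–9. Diffusion sets are despiked separately per
b-value group (`despike_grouped`) because the shells differ strongly in
intensity and frame count.

## Solver

The inexact augmented Lagrange multiplier scheme alternates

* S ← shrink(M − L + Y/μ, λ_eff/μ) — complex magnitude
  soft-thresholding; entries with modulus below the threshold become
  exactly zero, phases are preserved;
* L ← SVT(M − S + Y/μ, 1/μ) — complex SVD with singular values shrunk
  by 1/μ;
* Y ← Y + μ(M − L − S), μ ← min(ρμ, 10⁷μ₀),

with Y₀ = M / max(‖M‖₂, ‖M‖∞/λ_eff), μ₀ = 1.25/‖M‖₂, ρ = 1.5, stopping
when the relative constraint residual ‖M − L − S‖_F/‖M‖_F falls below
tol = 10⁻⁷ (cap 1000 iterations). These are the defaults of the
standard inexact-ALM RPCA solver; the only modification needed for MR
data is the complex extension of both proximal steps. The stopping rule
is the constraint residual alone (no primal-dual gap), matching that
solver. Non-convergence is reported in the result (`converged=False`),
not raised — a partially despiked series is still useful.

A full economy SVD is used by default (the per-iteration cost at
desk scale, e.g. 16384×50, is milliseconds). An optional truncated-SVD
path (`svd_method="truncated"`) predicts the active rank from the
previous iteration and falls back to the full SVD whenever the
prediction could clip a singular value above 1/μ.

The solver is deterministic, column-permutation equivariant (frame
order in the Casorati matrix is irrelevant), and positively scaling
equivariant (c·M yields c·L, c·S for the same λ_eff) — all verified as
property tests.

## Center refilling

Nonzero entries of S inside the central `window × window` box (default
16×16, even window w centered at c spanning [c − w/2, c + w/2 − 1] per
axis, clipped at grid edges, never wrapped), together with all pixels
connected to them through nonzero S entries (default 8-connectivity;
4 available), are moved back to L. "Nonzero" means |S| > 0 exactly,
valid because soft-thresholding produces exact zeros; an optional
threshold parameter exists for robustness. Refilling operates per
frame — connectivity is a 2-D k-space notion — and conserves L + S
bit-for-bit. The window is centered on `center_index`, which for
partial-Fourier data is the sampled k-space peak, not the grid
midpoint.

In the full pipeline the refilled pixels of the clean output are
additionally snapped to the measured values (and the sparse output to
zero there), absorbing the ≤ tol solver residual, so
`clean + spikes == M` holds exactly on refilled pixels and to within
the solver tolerance elsewhere.

Spikes that fall inside the central window are refilled along with the
genuine center and thus survive despiking (low-frequency stripes); this
is a known limitation, and the spike simulator's exclusion radius has a
switch (`exclusion_radius=0`) to study exactly that failure mode.

## Synthetic data

The generators produce piecewise-constant ellipse phantoms — ground
truth must be analytic — with complex Gaussian noise added in the image
domain before the forward FFT. They emulate signal structure
(inversion-recovery dynamics, cine-like motion, direction-dependent
diffusion attenuation), not acquisition physics: no coil sensitivities,
EPI trajectory distortion, eddy currents, motion, or Rician-governed
multi-coil statistics. Passing tests therefore demonstrate the
algorithmic behavior of the decomposition under controlled corruption,
not robustness to everything real scanners do.

* Look-Locker: per-pixel signal A·(1 − 2e^(−t/T1*)), i.e. the
  three-parameter model A − B·e^(−t/T1*) with B = 2A, on a 128×128
  torso/myocardium/blood scene; 50 inversion times 0.01 + 0.12k s
  (~5 apparent T1 of the 1.2 s myocardial ring); noise σ = 0.02 on unit
  amplitude (SNR ≈ 50). The ground-truth corrected T1 of the ring is
  1.2 s.
* Cine: 20 frames, 128×128; the blood-pool radius varies sinusoidally
  (±15%) so frames change structurally while total intensity varies by
  well under 10%.
* DWI: 64×64, 2 reference frames (b = 0) plus 12 directions
  (b = 1000 s/mm²) on a deterministic Fibonacci hemisphere; isotropic
  matrix (0.8×10⁻³ mm²/s) with two anisotropic "fiber" ellipses
  (eigenvalues 1.7/0.3/0.3 and 1.5/0.4/0.4 ×10⁻³).

Spike corruption: per dataset, a count drawn uniformly from [5, 30];
per spike, a uniformly random frame and k-space location outside a
central exclusion box (half-width 12 = window half-width 8 + kernel 3
+ margin, configurable down to 0), amplitude log-uniform in 5–50× the
99th-percentile k-space magnitude with uniform phase, and an
exponential rise/decay kernel w(d) = e^(−|d|/τ) along the readout axis
(τ = half-width/2, truncated at ±half-width) mimicking finite spike
duration. Every modified sample is recorded in a ledger, which is the
exact oracle for recovery metrics. All constants were fixed when the
generator was designed, on the grounds that spikes should be gross
outliers relative to high-frequency k-space yet below the DC peak.

## Validation metrics

* **T1**: nonlinear least squares of |A − B·e^(−t/T1*)| against the ROI
  mean of the magnitude images, with polarity restoration (the sign of
  the pre-null samples is lost in magnitude data; the fit multistarts
  over candidate flip points up to just past the signal minimum and
  keeps the lowest-RMSE candidate). The corrected T1 = T1*·(B/A − 1) is
  the standard small-flip-angle Look-Locker result. Fitting magnitude
  data carries a small Rician-floor bias (~0.1% of T1 at SNR 50) at the
  near-null samples; the despiking metrics compare fits across
  conditions, where this floor cancels.
* **Background noise std**: standard deviation of magnitude over a
  signal-free ROI (default: four corner squares, each 10% of the matrix
  side — outside object support in all phantoms), pooled over frames.
  Stripe artifacts raise it; it is the artifact-level metric.
* **Diffusion**: ordinary log-linear least squares for s₀ and the six
  tensor elements, eigenvalues clipped to a tiny positive floor before
  FA = √(3/2)·‖λ − MD‖/‖λ‖ so FA ∈ [0, 1]; MD is the eigenvalue mean.
  FA, a variance measure of the eigenvalues, is the quantity spikes
  perturb most (especially near isotropy); MD, an average, is nearly
  immune — despiking should restore FA while leaving MD unperturbed,
  and the acceptance suite asserts exactly that (earth-mover distance
  of the FA distribution decreases; mean MD changes < 2%).

## Problem sizes and numerical choices

The validation studies use 10 seeded 128×128 × 50-frame Look-Locker
phantoms (the full protocol size; ~4 s per decomposition) and one
64×64 × 14-frame diffusion phantom — sizes chosen so the whole study
reruns from scratch in about a minute on one CPU. Reported ranks use
numpy's default singular-value tolerance. Degenerate inputs: an all-zero
matrix returns L = S = 0, converged; a constant T1 signal returns
`converged=False`; rank-deficient diffusion designs raise.

Multi-coil data is despiked per coil channel as independent series (the
least-assumption choice; channel correlation is not exploited).
Magnitude-only input is rejected at the I/O layer — the method requires
complex k-space; a pseudo-k-space mode for magnitude images is
deliberately out of scope.

## File formats

Complex k-space travels in a small documented HDF5 layout (dataset
`kspace`, attrs `readout_axis`, `center_index`, optional dataset
`frame_labels`); magnitude images as uncompressed NIfTI-1; run reports
and spike ledgers as JSON. Vendor raw formats and DICOM are future
adapters.
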
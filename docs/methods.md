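# Methods

This note documents the model as implemented, the numerical choices, the
defaults that matter, and what the synthetic experiments do and do not
demonstrate.

## Model

The segmentation is the zero level set of φ on a uniform cell-centered
Cartesian grid (2-D or 3-D, anisotropic spacing honored in every difference
operator), interior positive. The regularized step H_ε and its derivative
δ_ε use the sine-ramp form with narrowband half-width ε (default 1.5 grid
units; for anisotropic grids the physical half-width is ε·h_min). All PDE
updates carry a δ_ε(φ) prefactor, so cells with |φ| > ε are never modified.

Two open-loop data terms are provided:

* **global means** — G = −(I−μ_in)² + (I−μ_out)² with H_ε-weighted means
  over the whole domain; the gradient flow of the two-phase mean-separation
  energy with length penalty λ∫|∇H_ε(φ)|.
* **localized means** — the same competition evaluated with means restricted
  to a Euclidean ball of radius `r_loc` (physical units, default 8) around
  each cell, computed by FFT convolution with the ball footprint each step.
  The speed is the pointwise competition at x using x's ball means; the
  narrowband prefactor restricts where it is consumed. Cells whose ball
  lacks interior or exterior mass contribute zero. As r_loc grows to the
  domain size this reduces exactly to the global speed.

The closed loop couples three fields. The user's signed clicks are splatted
with the kernel σ_I²/(σ_I² + |I(x)−I(x_k)|) · exp(−‖x−x_k‖²/2σ_x²)
(truncated at 3σ_x; σ_x default 2 cells; σ_I chosen so σ_I² is half the
intensity range) and accumulated into U, which diffuses with coefficient
H_eps_diff((U/U_M)²−1) in divergence form with face-averaged coefficients
and zero-flux boundaries — total input mass is conserved to round-off and
peaks are capped near U_M. The observer ψ̂ starts equal to φ and evolves by
δ_ε(ψ̂)[ξ̂ − e_U(αU)²] with α = 1/U_M: it follows φ where (αU)² ≈ 0 and is
driven toward the sign of U where input has accumulated past U_M. The
segmentation evolves by δ_ε(φ)[G − ξ̂U² + λ(t)κ(δ_ε²(φ)·ξ̂)] with
λ(t) = λ₀ + λ₁·D̂ (defaults λ₀ = 1, λ₁ = 0.1, fed by the observer-based
error D̂, which is computable online — the true error D needs the unknown
reference and is recorded for diagnostics only when a ground truth is
supplied).

The input threshold is U_M = (Ḡ_M/ρ + 1)^½ with ρ = 0.5 and the
state-independent bound Ḡ_M = (intensity range)², valid for both data terms
since every residual compares I against means inside its range. Holding the
bound static keeps U_M fixed before any interaction starts.

## Numerical choices

* **Intensity normalization.** Sessions rescale intensities to unit range
  before any dynamics. The coupled design balances order-one terms — image
  force |G| ≤ 1, control forcing U² ≈ 1/ρ + 1, observer drive ≈ 1 — and
  with unnormalized intensities the φ system can be arbitrarily faster than
  the observer meant to track it, which destroys the loop. The open-loop
  curvature weight default (`lambda_smooth` = 0.1) is calibrated to this
  unit scale.
* **Discretization.** Second-order central differences with replicate
  (zero-flux) boundaries everywhere; curvature is the divergence of the
  normalized gradient with denominator max(|∇F|, grad_floor), grad_floor
  1e-8, and exact zero where the gradient is below the floor.
* **Error-aligned smoothing floor.** The term κ(δ_ε²(φ)·ξ̂) uses a larger
  floor (0.05) set at the gradient scale of a *saturated* error field.
  Normalized-gradient curvature is amplitude-invariant, so with a vanishing
  floor the observer's infinitesimal tracking lag would exert an order-one
  braking force on φ and the uncontrolled closed loop would no longer reduce
  to open-loop behavior; with the floor, the smoothing acts at full strength
  exactly where input has created genuine label disagreement.
* **Time stepping.** Explicit Euler. Each step uses a common dt =
  min(cfl·h_min / max|δ_ε·speed|, dt_max, 0.9·diffusion limit) over the φ
  and ψ̂ rates (cfl 0.45, dt_max 0.2); the U diffusion coefficient is ≤ 1 so
  its limit is h²-type. Within a step: ingest clicks, diffuse U, compute one
  set of error fields used by both PDEs, advance ψ̂ and φ.
* **Re-initialization.** Every `redist_every` steps (default 5) both φ and
  ψ̂ are rebuilt as exact Euclidean distances to their own sub-cell
  interface: the zero contour/isosurface is extracted by marching squares/
  cubes, densified to ~h/4 sampling, and queried with a KD-tree; the sign
  pattern of the input is kept. Measured on circles: band gradient within
  [0.99, 1.01], interface displacement ~0.02 cells, idempotent to < 0.01
  cells. A uniformly signed field raises a degenerate-segmentation error,
  which the session surfaces with its diagnostics.
* **Saturation switch width.** The diffusion coefficient's regularized step
  uses a dedicated dimensionless half-width `eps_diff` = 0.25 on the
  (U/U_M)²−1 axis, so diffusion is exactly off below |U| ≈ 0.87·U_M and
  fully on above ≈ 1.12·U_M. Reusing the level-set ε (1.5) here would leave
  the coefficient positive even at U = 0, contradicting the requirement
  that small inputs accumulate untouched.
* **Steady-state detection.** The explicit scheme settles into a small limit
  cycle (locked to the redistancing schedule and noise flicker), not a fixed
  point, so steadiness is judged by the drift of windowed means: the interior
  volume (and, closed-loop, D̂) averaged over the last 50 steps must match
  the previous 50-step window to a relative 2e-4 (D̂: 2e-3), with no pending
  or recent clicks. Click events are quantized to steps; all events with
  t_k ≤ t apply at the start of the step, so a click is visible to φ within
  the same step.

## Synthetic data

The two-ellipse phantom (128², background 2, foreground 10, Gaussian noise
σ = 0.5, bridge width 3 px, seeded) emulates a noisy two-chamber image in
which the reference covers only the left ellipse; the bright bridge makes
open-loop bleed-through robust — a seed in the left ellipse converges to the
union (the right ellipse is covered completely). The gradient phantom places
an elongated shape, offset +2 above a linear 0–10 intensity ramp, at the
column where the ground-truth interior mean sits 2% of the range above the
exterior mean: global mean competition is blind (and its residual sign is
deterministic against the σ = 0.2 noise, so its failure mode — negative
speed inside the dim end — is reproducible), while local means separate the
shape everywhere.

The simulated user inspects every 10 steps after a 30-step warmup and votes
at the cells with the largest current labeling error (ties broken by cell
index), up to 4 clicks per look, stopping below a saturation threshold of
0.85 or after 400 clicks. The default "corrective" strategy reacts
immediately to over-segmentation but pushes under-segmentation only when the
automatic evolution has stalled, emulating an operator who corrects what the
algorithm gets wrong rather than tracing the target; pure worst-error and
random-error-cell strategies are available via the policy. Per-click gain is
U_M/5, so about five co-located clicks reach the saturating regime.

What these experiments show: the qualitative failure of the open loop, the
quantitative rescue by feedback (Dice ≥ 0.95 while actuating a few percent
of the boundary), observer/segmentation interface alignment at steady state,
and input-field regulation. What they do not show: robustness to real CT/MRI
appearance (bias fields, partial volume, anisotropic resolution in the
presence of thin structures), human-in-the-loop timing variability, or 3-D
interaction ergonomics — the phantoms are deliberately minimal.

## Stability functionals in discrete time

With a known reference and saturated input, the total error D = ½∫ξ² is
non-increasing at every step where the error-dominance condition
ρ∫δ²|ξ| ≤ ∫δ²ξ² holds, and bounded throughout (verified over 2000 steps).
For the coupled system, V = F + D̂ decreases strongly in trend once input
stops and the steady-state interfaces of φ and ψ̂ coincide to sub-cell
Hausdorff distance; V does, however, carry a per-step jitter of order
1e-3·V from re-initialization (which perturbs the H_ε profiles the
functionals integrate) and from regions without input, where the
input-dominance premise of the continuous stability argument does not hold
pointwise. The jitter does not shrink with dt and should be read as the
resolution floor of the functional, not as divergence: V never climbs back
toward its pre-quiescence value, and the segmentation itself does not
degrade when run far past steady state.

## Known limitations

* Dense masked narrowband (no sparse-field data structure): fine at desk
  scale (128²–512²·slices), not tuned for 512³ real-time use.
* No topology control; the region may split or merge freely.
* The localized model recomputes ball convolutions every step; large r_loc
  on large volumes is the dominant cost.
* Click coordinates snap to cell centers; sub-cell pointing is not modeled.
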
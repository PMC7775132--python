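# Methods

This note documents the models implemented in `spicseg`, the parameter
defaults and why they hold, the synthetic data the package is validated
on, and the numerical choices a user changing parameters should know
about. No number quoted here is asserted anywhere except by the test
suite and `scripts/acceptance.py`, which recompute everything at run
time.

## Projection

The maximum intensity projection is a per-pixel maximum over an
inclusive slice window, along the slice axis only. The number of
projection layers is a free parameter (`compute_mip(stack, first,
last)`); the pipeline default is the full stack passed by the caller.
The MIP is associative, idempotent and permutation-invariant in the
slice order, which the tests exploit as properties.

## Edge map

The boundary map is `f = |∇(G_σ * I)|`, min–max normalized so
`max f = 1` on non-constant images (a constant image yields `f ≡ 0`).
Derivatives `f_x, f_y` are central differences. Default σ = 1.0 px for
library calls, σ = 0.8 px in the pipeline configuration (a sharper map
keeps narrow inter-spicule valleys resolvable on 64² images). Because
`f` is normalized, the data weight `|∇f|²` in the GVF functional lives
on a fixed scale and the solver defaults are portable across inputs.

## Baseline GVF field

The field V = (u, v) minimizes

    E[V] = Σ  w (|∇u|² + |∇v|²)  +  |∇f|² |V − ∇f|²

discretized with forward differences under homogeneous Neumann
boundaries. The iteration is explicit gradient descent using the exact
adjoint-based gradient of this discrete energy, so the energy is
non-increasing at every step; the step Δt is clipped to
1.9 / (8w + max|∇f|²), the descent-stability bound of the discrete
operator. Iteration stops when the max-norm of the Euler-equation
residual `w∇²u − (u − f_x)(f_x² + f_y²)` (and the v analogue with
`f_y`) drops below `tol`, or at `max_iter`. Defaults: w = 0.2,
Δt = 0.15 (validated ≤ 0.25), tol = 1e−3, max_iter = 400. The pipeline
uses tol = 1e−5 and max_iter = 2000: the residual decays quickly near
edges while the far field is still filling in, and a loose tolerance
would truncate the diffusion that gives the snake its capture range
(the diffusion length after N steps is roughly √(2·Δt·N) pixels).

## Improved external field

The improved field minimizes

    E[V] = Σ  m·(1 + |∇V|²)^{q/2}  +  h·c²·|J_V P|²_F  +  h·|V − ∇f|²

* **Adaptive exponent.** q(|∇f|) = 1 + 1/(1 + |∇f|) ∈ (1, 2]. In flat
  regions (|∇f| → 0) q → 2 and the first term behaves like isotropic
  Laplacian diffusion; on strong edges q → 1 and it becomes a
  total-variation-like penalty that diffuses along the boundary only,
  preserving edge contrast. `q_fixed` pins the exponent (q_fixed = 2
  recovers the isotropic penalty).
* **Corner tensor.** P is assembled from Gaussian-smoothed second
  derivatives with row-wise unit normalization,
  (p11, p12) = (−I_xy, I_xx)/√(I_xx² + I_xy²) and
  (p21, p22) = (−I_yy, I_yx)/√(I_yx² + I_yy²), zeroed where the
  normalizer is below eps = 1e−8 (the image is mean-subtracted before
  filtering so constant images give exactly zero). J_V is the Jacobian
  of the field; the quadratic penalty c²·h·|J_V P|² shapes the field's
  variation in the directions P selects, sharpening it around corners
  and concavity mouths. Default corner_weight c = 0.3; the stability
  clip accounts for the extra 16·c²·max(h) Lipschitz contribution.
* **Weighting fields.** m = exp(−f/κ) and h = 1 − m with κ = 0.1,
  evaluated on the edge strength f itself: smoothing dominates in flat
  regions, data fidelity on the edge ridge. Evaluating the weights on
  |∇f| instead (the gradient *of* the edge map) proved wrong in
  implementation: |∇f| vanishes exactly on the ridge crest, so the
  anchor switches off where it matters most and diffusion drags the
  field's zero-crossing ~0.3 px inward on curved boundaries, which
  caps disk recovery below the package's own target. User-supplied
  `m_func`/`h_func` (applied to f) override the defaults; the
  GVF-degenerate configuration (m ≡ w, h ≡ |∇f|², q_fixed = 2,
  corner_weight = 0) reproduces `compute_gvf` to machine precision and
  is tested as such. A third weighting function `g` is accepted in the
  configuration for completeness but unused.
* **Gradient computation.** All three terms are differentiated
  analytically through the adjoint difference operators; the diffusion
  term's flux m·(q/2)·(1 + |∇V|²)^{q/2−1}·∇V is the exact gradient of
  the discrete energy at the current iterate (not a lagged
  approximation), so monotone energy descent holds and is asserted in
  tests, and the analytic gradient is verified against a
  finite-difference gradient of the same discrete energy on small
  grids.

On a U-shaped phantom whose concavity mouth (8 px) is narrower than
its depth (28 px), the improved-field snake descends to the boundary
within the default 300-iteration snake budget while the GVF-driven
snake is still bridging the mouth; GVF does descend eventually given a
several-fold larger budget. The acceptance comparison therefore runs
both fields at the same default budget.

## Snake

Standard semi-implicit scheme: the internal elasticity/rigidity terms
enter through a cyclic pentadiagonal matrix A (diagonal 2α + 6β,
off-diagonals −α − 4β, β), and each step solves
(γI + A)X⁺ = γX + κ·V(X) with γ = 1/dt, bilinear interpolation of the
field at contour points, and an external gain κ (`ext_weight`, default
2.0) that balances the normalized field against the internal forces.
After each step points are clamped to the image domain and resampled
to uniform arc length; the point count is preserved unless the spacing
leaves [0.5, 2] px, in which case it is retargeted to ~1 px. Collapse
(area < 1 px²) raises an error that volume segmentation converts into
an empty mask. Library defaults: α = 0.1, β = 0.05, dt = 1,
move_tol = 0.01 px mean displacement, max_iter = 300. The pipeline
uses a softer, longer-running configuration (α = 0.02, β = 0.005,
move_tol = 0.003, max_iter = 1200) so the contour can traverse the
weak far field from the automatic seed circle and wrap high-curvature
spicule boundaries; with the historical default move_tol = 0.05 the
snake stalls at initialization because the diffused field magnitude at
the seed radius (~0.01–0.08) is below the tolerance.

Rasterization uses the even-odd rule on pixel centers (points on the
polygon count as inside); self-intersecting contours are repaired with
a warning. Volume segmentation starts at the middle slice (or a given
`seed_slice`) and propagates each converged contour to its neighbors
in both directions.

The pipeline seeds the snake automatically: the centroid of the bright
blob (smoothed image above the midpoint of its maximum and median)
gives the center, and 1.5× the blob's equivalent radius plus a 5 px
margin gives the circle radius, capped by configuration.

## SN P system engine

Neurons hold integer pulse counts; guards over counts are built from
three primitives (exact, at-least, arithmetic progression), sufficient
for regular languages over a unary alphabet. One synchronous step:
(1) scheduled complements of ± plasticity rules are applied; (2) every
open neuron applies its lowest-index applicable rule, judged on
start-of-step counts — firing consumes c pulses (or the whole content,
for the classifier's relay rule) and schedules p pulses per outgoing
synapse at t + d, closing the neuron for d steps; forgetting consumes
and emits nothing; plasticity rules create/delete up to k synapses
toward a target set, the random selection drawn from the system's
seeded generator; (3) arrivals due this step are delivered as
round(p·w_ij) pulses, or lost if the target is closed; (4) closed
timers decrement. The system halts when no rule is applicable, nothing
is pending and every neuron is open. An internal audit tracks consumed
/ emitted / delivered / lost pulses; tests assert the conservation
identity at every step and the engine is checked against an
independent transition-table oracle over an enumerated space of small
systems.

## Classifier network

The 5×7 boundary grid feeds 35 input neurons in three contiguous
row-major blocks (12/12/11) wired to Module 1's three neurons; Modules
1 → 2 (4 layers × 3) → 3 (4 layers × 5) are densely wired layer to
layer with unit weights; the last Module-3 layer is the output. All
computation neurons carry the single relay rule, so pulses sweep
through in one wavefront and the run halts in at most depth + total
initial pulses steps (asserted over 1000 random grids). Because the
input blocks are mixed with unit weights at the first dense layer, the
output count is proportional to the total number of active grid cells;
the trainable synapses (Module 2 → 3 and the edges into the output
layer, per the learning design) can rescale but not reshape that
statistic. The classifier is therefore effectively a learned threshold
on boundary-cell count — a real limitation discussed below. Training
is perceptron-style (±η on pulse-carrying trainable edges for
misclassified cases, weights clipped to [0, 8], η = 0.1) with the
threshold refit each epoch by minimizing training errors; because the
updates are scalar in effect, training early-stops on a 5-epoch
plateau and returns the best weights/threshold seen, which prevents
the weight clip at 0 from destroying the score.

## Phantoms

A phantom is a geometric shape rendered as
`background + contrast · sigmoid(sd/softness)` where `sd` is the
signed distance to the shape and softness = 0.8 px models
partial-volume blur; Gaussian noise (σ = 0.02 on the [0, 1] scale) is
added after the ground truth — exactly {sd ≥ 0} — is extracted. The
smooth shape is a sphere sampled as per-slice disks
(r_k = √(r² − (Δk·spacing)²), spacing 3 px); the spiculated shape adds
radial trapezoidal strips on the central slice: base width 5 px at the
rim tapering to a blunt 2 px end at radius + 8 px, at jittered but
well-separated angles, so the spicules are unbranched and
non-overlapping by construction. Two properties drove this recipe and
its defaults:

* **Truth/edge consistency.** With distance-based rendering the
  half-intensity isocontour, the geometric boundary and the
  intensity-gradient ridge coincide everywhere. An earlier recipe
  (Gaussian-profile ridges with linearly tapering intensity) placed
  the half-intensity truth up to ~1 px away from the gradient ridge,
  with opposite signs at the spike base and tip — ground truth no
  boundary detector could match.
* **Representability.** The 5×7 boundary encoding has a cell size of
  about 2(r + L)/5 pixels; a spicule must protrude more than one cell
  to change the encoding at all. With length 8 px on a radius-10
  nodule (spicules ~80 % of the radius, within the clinically typical
  range for prominent spiculation), spiculated truth grids light
  21–29 cells versus 18–19 for smooth nodules.

`make_dataset` jitters radius (±2 px), center (±2 px), intensity
(±0.05) and spicule count (8–10), and splits each class 1:1 into train
and test, all deterministic in the seed. The U phantom (a bright
U-shape with an 8 px mouth and 28 px deep concavity, rendered the same
way) isolates the deep-concavity behavior of the force fields.

What passing on these phantoms does **not** show: robustness to
vessels and pleural attachments abutting the nodule, Hounsfield-scale
calibration, anisotropic voxel spacing, reconstruction-kernel texture,
or spiculation subtler than the encoding's cell size — clinical
performance claims need clinical data.

## Evaluation

AOM is computed from exact integer pixel counts and is undefined (an
error) when both masks are empty; over a stack, voxel counts are
pooled across slices (per-slice values are also available). ROC curves
place one threshold at every distinct score (standard staircase; ties
share a threshold) with trapezoidal AUC.

## Degenerate inputs and determinism

Constant images yield zero edge maps and zero fields; empty masks are
rejected by the boundary encoder and yield zero scores in the
pipeline; a collapsing contour ends propagation in that direction.
Every stage is deterministic given its inputs and the configured seed,
including the random branch of plasticity rules; the full pipeline
rerun with the same seed reproduces its report bitwise.

## Problem sizes

The validation suite runs on 64×64×5 stacks, 100-case experiments and
field iteration budgets of a few thousand — sizes chosen so the whole
suite completes in about a minute on one core while every claimed
property is exercised at full strength. All thresholds the tests
assert (disk AOM ≥ 95 %, spiculated AOM ≥ 90 %, test AUC ≥ 0.9) are
recomputed from scratch at run time.
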
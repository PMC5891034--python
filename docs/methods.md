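# Methods

## Model and assumptions

`sepint` approximates the net interaction between two rigid particle
ensembles,

    F_PQ(ξ) = Σ_{i=1}^{M} Σ_{j=1}^{N} f(d_ij(ξ), λᴾ_i, λ^Q_j),

under three structural assumptions:

1. **Rigidity.** Both bodies are rigid; only the relative pose ξ (body P
   fixed, the frame attached to P, reference pose ξ° = identity) changes
   the pairwise distances. The almost-rigid machinery quantifies what
   happens when this is violated by bounded per-particle fluctuations.
2. **Distance dependence with a separable prefactor.** The pairwise law
   factors as `f(d, λᴾ, λ^Q) = s(λᴾ, λ^Q)·shape(d)`. All shipped laws
   (Coulomb energy/force, linear spring, power law, Lennard-Jones-like with
   s ≡ 1, and the exact-polynomial debug law) satisfy this; registration
   verifies it numerically on a random grid and rejects laws that do not
   factor.
3. **Polynomial surrogacy.** `shape(d)` is replaced by a degree-n
   polynomial in d² over the squared-distance range the pose sweep actually
   visits. Squared distance is essential: d²(ξ) is itself polynomial in a
   small set of scalar pose primitives, so integer powers of it — and hence
   the whole surrogated law — expand into finitely many pose monomials
   (the multinomial theorem applied to a separated sum).

The expansion is exact given the surrogate: for laws whose shape *is* a
polynomial in d² of degree ≤ n, the characteristic model reproduces the
brute-force sum to rounding (≈1e-9 relative in the tests) for the
translation, rotation and general SE(3) families. All remaining error
comes from the regression.

## Pose families and primitives

* `translation_x1` — Q slides along x₁; primitive {x₁}; an energy model
  has monomials x₁⁰…x₁²ⁿ (≤ 2n+1 = 19 terms at n = 9).
* `rotation_x3` — Q spins about x₃; primitives {sin θ, cos θ} with the
  rewrite cos²θ → 1 − sin²θ, leaving only {sinᵏθ, sinᵏθ·cosθ}, k ≤ n
  (≤ 2(n+1) = 20 terms). The reduced basis is derived mechanically from
  expansion + rewriting, not hard-coded.
* `general_se3` — all six parameters free (rotation vector + translation);
  primitives are the nine rotation-matrix entries and x₁,x₂,x₃, treated as
  algebraically independent (their orthogonality relations are ignored —
  only evaluation correctness matters, at the price of a redundant basis).

Either family can freeze the remaining translation components at non-zero
constants (e.g. a fixed lateral offset during a translation sweep).

## Surrogate fitting

* Unweighted linear least squares of `shape(d)` (energy) or `shape(d)/d`
  (force/moment) against {(d²)ᵏ}ₖ₌₀..ₙ.
* Sample: 2000 points on a uniform grid in **d** (not d²), endpoints
  included. Uniform-in-d concentrates samples at short range where singular
  laws vary fastest; this is a deliberate weighting choice.
* Degree n = 9 by default — large enough that the 1/d and 1/d³ shapes fit
  to ~1–5% over the box sweeps, small enough that monomial coefficients in
  d² remain well conditioned.
* Numerics: the fit is solved in a Chebyshev basis on the rescaled variable
  and converted exactly to monomial coefficients; a conversion-drift check
  warns if the monomial form stops reproducing the stable fit (relevant
  only at degrees well beyond the default).
* The fit domain is the pairwise d² range computed on a 101-point pose grid
  over the sweep, padded by 1% of its width on each side. Out-of-domain
  evaluation extrapolates with a warning rather than failing, so
  almost-rigid perturbations that nudge distances past the rigid-body range
  still evaluate.
* Diagnostics stored with every surrogate: σ_r (RMS residual over the fit
  sample) and the maximum relative residual.

## Characteristic-constant accumulation

Two engines produce identical constants (cross-checked in the tests):

* **generic** — sparse per-pair expansion over exponent-tuple keyed
  monomial maps, any family, Kahan-compensated accumulation per
  coefficient, pairs iterated row-major. Cost grows quickly with basis
  size; intended for the SE(3) family at small M·N and as the reference.
* **fast** — vectorized dense path for the two one-parameter families,
  where the basis is a small enumerable list: per-pair coefficient arrays
  (power-of-x₁ columns; (sin-power × cos-exponent) planes for rotation) are
  built by repeated vectorized multiplication with the pair's d² base
  polynomial, then contracted against the prefactors. Pairs are processed
  in chunks of 2¹⁷; numpy's pairwise summation handles each chunk and a
  Kahan compensation combines chunks. This is the engine behind the
  full-scale runs (10⁶ pairs in a few seconds).

Coefficients below 1e-14 of the largest are pruned (cancellation dust);
monomials that vanish across all components are dropped from the model.

Moments are taken about the origin of P's frame: the per-pair moment is the
posed coordinate vector crossed with the pairwise force, expanded in the
same algebra (degree grows by one over the force expansion).

## Error metric

The reported "average error" of a sweep is the per-snapshot relative
deviation from brute force, averaged over snapshots: `|ΔE|/|E|` for scalar
output and ‖ΔF‖/‖F‖ (Euclidean) for vector output, in percent. Snapshots
whose reference magnitude is below 1e-12 of the sweep maximum are excluded
(count reported) rather than clamped — mixed-sign charge sets can cross
zero. RMS and signed-mean variants are available as options for sensitivity
checks, since "average error" admits several readings.

## Synthetic data

`generate_box_particles` draws coordinates i.i.d. uniform inside an
axis-aligned box and properties from a configurable charge law, all from a
single seed. Defaults encode the study conditions:

* **Geometry.** P has cross-section 3×3 and Q 1×1 (the a₁=a₂=3, a₃=a₄=1
  parameters); thicknesses and the inter-box gap are one length unit, i.e.
  P = [0,1]×[0,3]×[0,3] and Q = [2,3]×[0,1]×[0,1]. This is the unique
  unit-thickness/unit-gap arrangement whose geometric d² range under the
  x₁ ∈ [0,5] sweep is exactly [1, 82] (gap² = 1; (1+1+1+5)² + 3² + 3² =
  82). The force/moment preset sets all four cross-section parameters to 1
  and sweeps x₁ ∈ [0, 2], keeping the minimum distance at 1.
* **Charges.** Uniform on [0.5, 1.5]. Single-sign charges keep the net
  energy bounded away from zero so percent errors are well conditioned;
  mixed-sign or normal draws are one config key away. Note that the error
  statistics are sensitive to this choice: with sign-mixed charges the net
  value shrinks by roughly √(MN) relative to the summed magnitudes, which
  inflates the relative contribution of rigidity violations and residual
  noise while partially cancelling the systematic surrogate bias.
* **Scale.** 500 particles per body, 500 evenly spaced snapshots (endpoints
  included), degree 9 — the full study scale, which runs in seconds per
  experiment; unit tests use 15–20 particles and 10–20 snapshots.
* **Almost-rigid runs** redraw every particle displacement (both bodies)
  i.i.d. uniform in a cube of the configured edge at each snapshot; the
  brute-force reference sees the perturbed coordinates, the model does not.

What the generator does *not* emulate: correlated thermal motion
(per-particle displacements are independent), realistic charge
distributions or force-field parameters, excluded-volume structure inside
the boxes, and periodic boundary conditions. Passing tests therefore
demonstrate the algebra and its error behaviour under these idealized
conditions, not accuracy on any particular molecular system.

## Error propagation

If per-pair regression residuals are i.i.d. N(0, σ_r²), the net residual
Σᵢⱼ εᵢⱼ is N(0, M·N·σ_r²), i.e. its standard deviation is √(M·N)·σ_r. The
Monte-Carlo study (`error_propagation_sim`) verifies this closed form at
10⁴ repetitions and treats the coarser linear figure M·N·σ_r only as an
upper bound. In the actual pipeline residuals are *not* independent — ε is
a deterministic function of pair distance, and pairs share particles — so
√(M·N) scaling is a model of the best case; the systematic component of the
residual does not average away, which is visible in the translation sweep
where the surrogate bias dominates the net error.

## Numerical and design choices

* Rotations use the axis-angle (Rodrigues) matrix; angles in radians,
  right-handed frames, positive angle counterclockwise from +axis. Axes
  further than 1e-9 from unit norm are rejected, not rescaled.
* The rotation-vector parameterization (θ = ‖r‖, axis = r/θ, identity axis
  (0,0,1) at θ = 0) gives the SE(3) family exactly six free parameters.
* Dielectric constant defaults to 4πε = 1 so Coulomb energies are λλ/d;
  units are the user's and are never converted.
* Brute force is fully vectorized (distance matrix per pose) and raises a
  singularity error naming the offending pair on coincident points; the
  pairwise-evaluation counter it maintains is how the "zero pairwise work
  per pose" claim is asserted in tests.
* Determinism: every stochastic step (box contents, charges, per-snapshot
  perturbations) derives from a single integer seed through independent
  spawned streams; rerunning a config byte-identically reproduces all CSV
  and JSON outputs.

## Known limitations

* Accuracy is bounded by the degree-9 polynomial fit of the law over the
  sweep's d² range; for 1/d over a ~[1, 80] range the mean net-energy
  deviation sits in the low single-digit percent range, concentrated
  mid-sweep where the polynomial's oscillation is largest relative to the
  decaying law. Raising the degree helps until monomial conditioning bites
  (warned); rational or spline surrogates are out of scope.
* The separation rank is not compressed: the basis is whatever expansion
  produces. For `general_se3` with twelve primitives the term count grows
  combinatorially with degree, so the general family is practical only at
  low degree — the one-parameter families are the fast path.
* Laws whose prefactor does not factor over (λᴾ, λ^Q), and treatments that
  break the polynomial form before pair summation, are rejected by design.
* No cutoffs, neighbor lists, periodic electrostatics, or gradients of the
  separated model.
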
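# Methods

## Model and task

The package works with a linear isometric transduction model `w = H a`:
`H` has one row per endpoint-wrench component and one column per muscle,
with activation `a ∈ [0,1]^M` normalised so that 1 is 100% of a muscle's
maximal tension contribution and 0 is rest (muscles only pull, so
activations are never negative).  Moment arms and the posture Jacobian
are assumed folded into `H`, which is valid for a fixed posture.  The
canonical wrench convention is the 4-vector `(fx, fy, fz, ty)`.

The reference task is a force redirection: hold a force of magnitude `m`
(default 10 N) while its direction rotates through an arc (default 30°)
and returns, discretised into `T` slices (default 7) of `step_ms`
(default 50 ms).  The direction progress follows a single cosine period,

    theta_t = (arc/2) * (1 - cos(2*pi*t/(T-1))),    t = 0 … T-1,

so the peak rotation falls on the middle (fourth of seven) slice and the
wrench sequence is time-symmetric (`w_t = w_{T-1-t}`).  The rotation
takes `fx` toward `fz` with `fy` and the torque held at zero; the
rotation plane is a convention of the task builder, not an anatomical
claim, since axis orientations are configuration.  One- and
two-component toy models use a documented planar reduction (constant
magnitude for 1-D with a zero arc; `(m cos θ, m sin θ)` for 2-D).

## Constraint systems

`build_moment_polytope` represents the single-wrench feasible set
`{a ∈ [0,1]^M : H a = w}`.  `build_trajectory_polytope` stacks `T`
copies (variables ordered time-major, muscle-minor, labels recorded
explicitly) and couples consecutive slices with the activation-
contraction constraint `|a_{t+1,i} − a_{t,i}| ≤ δ`, two inequality rows
per muscle and slice pair.  δ is dimensionless (fraction of maximal
activation per slice); the same limit is applied to activation increase
and decrease, a conservative simplification since deactivation is
typically the slower of the two.  At δ = 0 the paired rows would pin the
system to a zero-volume face, so the builder emits the mathematically
identical equality rows `a_{t+1,i} = a_{t,i}` instead, keeping the
remaining degrees of freedom full-dimensional for the sampler.

Emptiness is always certified by linear programming (HiGHS).  When a
trajectory system is infeasible, LPs on growing prefixes locate the
shortest infeasible prefix, which distinguishes an unproducible wrench
from a rate limit too tight to bridge consecutive wrenches.

Seeding appends equality rows pinning slice 0 (and, for the clamped
variant, also the final slice) to a chosen activation.  The seed must
reproduce the first wrench target to 1e−8 (relative to the target's
magnitude); construction-time equality checks use 1e−8 and post-hoc
sample audits 1e−6.

## Uniform sampling

Because the wrench equalities confine the polytope to an affine
subspace, the sampler first builds a chart: an anchor point plus an
orthonormal basis of the equality null space (SVD, rank tolerance
`1e−10 × max singular value`; near-tolerance singular values raise a
warning).  The anchor is a Chebyshev-style interior point maximising the
minimal slack of all inequality and bound rows restricted to the
equality manifold; zero maximal slack with a positive-dimensional chart
is reported as a degenerate (zero-volume) polytope, and a
zero-dimensional chart returns its unique point.

Hit-and-Run then walks in chart coordinates: an isotropic Gaussian
direction (the standard sufficient condition for uniform ergodicity on
convex bodies), the feasible chord from all inequality rows (rows with
directional component below 1e−12 skipped; the box bounds guarantee
bounded chords), and a uniform jump along the chord, backed off by a
factor 0.999999 if rounding lands exactly on the boundary.  Residuals
are updated incrementally and refreshed every 1024 steps.  Running in
the chart means equality constraints hold to machine precision by
construction, so no re-projection is ever needed; the audit confirms
equality residuals ≲ 1e−12 in practice.  Defaults are burn-in 1000 and
thinning 10 — mixing settings are not identifiable from first
principles, so they are configurable and validated against the oracle
below rather than asserted.

`rejection_oracle` is the independent check: it proposes uniform points
in the chart's LP-computed bounding box and keeps the feasible ones,
which is exactly uniform by construction.  It is restricted to chart
dimension ≤ 4 and aborts below an acceptance rate of 1e−4.  The test
suite compares the two samplers on a segment, a triangle (also against
analytic bin masses by χ²), and a 3-D chart fixture, with fixed seeds
and per-test α = 0.01 (8 KS comparisons, one χ², one energy-distance
test across the uniformity suite).

Every retained sample set passes a constraint audit: bounds and
inequality rows to 1e−9, equalities to 1e−6.

## Synthetic models

Published activation-to-wrench matrices are input data
(`read_h_matrix`); the generator exists so every stage is testable
without lab data.  `generate_synthetic_h` draws entries i.i.d. standard
normal scaled by `1/sqrt(M)`, then rescales the whole matrix by a factor
chosen by LP so that every wrench of the task sequence is producible
with activations inside `[0.05, 0.95]` — strict feasibility with margin.
A second LP minimises the largest inter-slice activation change over all
trajectories; draws are accepted only when that minimum is ≤ 0.025, so
the instance supports the full study grid of rate limits (down to
δ = 0.05) rather than only per-slice feasibility.  Rejected draws are
redrawn up to 25 times before a generation error.  The generator is a
pure function of its arguments.

What the synthetic models do *not* emulate: anatomical moment-arm
structure, correlated muscle actions, signs and units of a real torque
row, or inter-specimen variability.  Passing tests on synthetic models
therefore validate the machinery (geometry, sampling, audits, the
direction and monotonicity of the tunnel effect), not any particular
anatomical number; hull-area ratios on a real cadaver-derived `H` will
differ from the synthetic values.

## Trajectory analyses

Sampled points are reshaped into (trajectory × time × muscle) tensors by
variable label, never by column position.  Speeds are forward first
differences per 50-ms slice; `filter_by_delta` keeps trajectories whose
largest |speed| is within a limit, and seeds are drawn uniformly without
replacement from the filtered set (their `t = 0` slices).  Occupancy
summaries use linearly interpolated quartiles.

For the seeded/unseeded comparison, a 2-component PCA is fitted per time
slice on unseeded data only (deterministic sign convention: each
loading's largest-magnitude entry is positive); seeded data are
projected through the unseeded model — same centering, same loadings —
so both live in one chart.  An alternative would be a single PCA pooled
over all slices; the per-slice fit matches the per-force-direction
framing of the analysis and adapts the plane to each slice's geometry.
Hull areas are computed exactly (Qhull) in PC-plane coordinates rather
than by rasterised pixel tracing, removing resolution dependence;
collinear or too-small point sets report area 0 with a degeneracy
warning.  The reduction ratio (seeded hull / unseeded hull) is invariant
to plane rotations and the sign convention.

## Pipeline and reproducibility

`cmd_sample` / `cmd_seeded` / `cmd_report` run the protocol end to end:
unseeded sampling across a strictly decreasing δ grid, seed selection by
δ-filtering, seeded and clamped sampling, per-seed hull-area reports,
and tabular/figure outputs.  Every store embeds a hash of the full run
configuration and the stages refuse to mix hashes.  All chain seeds
derive from one root seed as `sha256(root | condition | stage | index)`
reduced below 2^31, giving independent, reproducible chains; a rerun of
the same config is byte-identical.

Default problem sizes are desk-scale choices: 5,000 trajectories per
condition in the pipeline default and the audit checks, 3,000 unseeded /
800 per seeded chain with 10 seeds in the acceptance script, and
1,500 / 600 with 5 seeds in the tunnel-monotonicity test.  Larger runs
(the protocol's natural scale is 10^5 trajectories per condition) are a
config change, not a code change.

## Known limitations

* Isometric, fixed-posture tasks only; no dynamics, no Jacobian or
  moment-arm modelling, by design of the linear `H` formulation.
* Equal activation and deactivation rate limits; no muscle-type
  differentiation or series-elastic tendon dynamics.
* Uniform sampling only — no volume estimation, vertex enumeration, or
  cost-weighted sampling.
* Hull-area ratios are finite-sample estimates; with short chains the
  seeded hull can marginally exceed the unseeded hull's estimate at
  late slices.
* The rejection oracle, and hence direct uniformity validation, is
  limited to low-dimensional charts; higher-dimensional correctness
  rests on the Hit-and-Run theory plus the constraint audits and
  marginal-consistency checks.
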
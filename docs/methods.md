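# Methods

## Model

Axonal growth on substrates with parallel periodic ridges is treated as a
biased random walk of the growth cone along the pattern axis (x). The
velocity obeys the Langevin equation

    dV/dt = a0 − γ1 V + Γ(t)

with Gaussian white noise ⟨Γ(t1)Γ(t2)⟩ = σ² δ(t1 − t2). This is an
Ornstein–Uhlenbeck process with drift: the mean velocity relaxes from V0
to the terminal value a0/γ1 with time constant τ = 1/γ1, and velocity
fluctuations equilibrate to variance σ²/(2γ1). Assumptions: the motion is
quasi-one-dimensional (headings near the pattern direction), the
quadratic damping γ2V² is negligible (checked via the regime ratio
γ1/γ2), parameters are constant over the observation window, and
cell–cell interactions are ignored.

Closed forms implemented in `moments`: mean velocity, two-time velocity
correlation, mean squared velocity, mean position, mean squared length
(MSL), and the literal second displacement moment. Two distinct "squared
length" quantities exist and both are exposed:

- `mean_squared_length` — the drift-free form: Var[x(t)] plus the squared
  transient of the mean about the drift ramp (a0/γ1)t. This is the
  quantity the no-free-parameter MSL curve uses.
- `mean_squared_displacement_full` — the literal ⟨(x(t) − x0)²⟩, which
  additionally contains [(a0/γ1)t]² and the drift–transient cross term.

The large-time asymptote `asymptotic_msl` is the conventional
"constant + 2Dt" form. Note that it omits a non-decaying constant
−3σ²/(2γ1³) relative to the full expression (≈ 586 µm² at the reference
parameters); the two agree only to O(1/t), about 1% at γ1·t = 20.

### Parameters

| symbol | meaning | units | reference value |
|---|---|---|---|
| a0 | drift acceleration from the substrate geometry | µm/hr² | 3.1 |
| γ1 | velocity damping rate | 1/hr | 0.11 |
| σ² | white-noise strength | µm²/hr³ | 0.52 |
| V0 | mean initial velocity | µm/hr | 0.9 |
| γ2 | quadratic damping (planar model) | 1/µm | 1e−3 |
| a1 | aligning-torque acceleration (planar model) | µm/hr² | — |

On the units of a0: the source convention prints a0 in µm/hr, but the
velocity equation is an acceleration balance and σ² is given in µm²/hr³;
dimensional consistency forces a0 to be an acceleration (µm/hr²). The
numeric value is used unchanged.

The derived quantities are D = σ²/(2γ1²) ≈ 21.5 µm²/hr (the time
integral of the centred stationary velocity autocorrelation — a motility
coefficient by convention, not a thermal-equilibrium quantity) and
τ = 1/γ1 ≈ 9.1 h. No fictitious-temperature estimate is attempted: an
Einstein relation would require a mass/friction convention the model does
not define.

## Simulation

The 1D `exact` scheme samples the joint Gaussian transition of
(velocity, position increment) over each step:

    V' | V  ~ N(μ + (V−μ)E,  σ²(1−E²)/(2γ1)),          E = e^(−γ1 dt), μ = a0/γ1
    Δx | V  ~ N(μ dt + (V−μ)(1−E)/γ1,  σ²/γ1² (dt − 2(1−E)/γ1 + (1−E²)/(2γ1)))
    Cov(Δx, V') = σ²(1−E)²/(2γ1²)

so the one-step distribution matches the continuous-time process exactly
and the step size only sets the output grid. (Position is sampled
exactly rather than accumulated by the trapezoid rule; this removes all
discretisation bias from the Monte-Carlo oracles.) The `euler` scheme
(Wiener-increment convention, trapezoidal position) is retained for
convergence checks and warns when γ1·dt ≥ 0.1.

Randomness: one master seed; track k draws from the deterministic
substream `SeedSequence([seed, k])`, so enlarging an ensemble never
reshuffles existing tracks.

The planar model (speed equation with |sin θ| drive and quadratic
damping; perpendicular torque a1 cos θ) is integrated by Euler–Maruyama.
The mapping from perpendicular acceleration to heading change is not
fully specified by the model statement; the package adopts the
circular-motion convention dθ/dt = a_⊥ / max(V, v_floor) with
v_floor = 0.1 µm/hr, and directs the torque magnitude |a1 cos θ| toward
the nearer of the two pattern directions (θ = π/2, 3π/2), consistent
with the ±x symmetry of the speed equation. The literal signed rule
(which makes only θ = π/2 attracting) is available via
`strict_literal=True`. Speed is kept non-negative; floor applications
are counted and reported.

## Synthetic experiments

`generate_experiment` emulates the tracked output of the imaging
protocol: observation times 0–40 h in 5 h steps, a frame every 5 min for
30 min per window, cohort sizes drawn uniformly from 64–182 (or fixed),
i.i.d. Gaussian measurement noise of 0.1 µm on every recorded
coordinate, and a small transverse jitter (0.2 µm sd) on y. By default
each observation time gets an independent cohort (matching an experiment
in which different fields of view are imaged at different culture
times); `persistent_tracks=True` follows one cohort across all windows,
which the cross-time correlation and empirical-MSL estimators require.
Initial velocities are drawn N(V0, 1.0²) µm/hr (the spread of the t = 0
velocity distribution is not published; 1 µm/hr is a realistic scale for
the printed distribution width), and initial positions are zero — every
estimator uses displacements only.

Not emulated: image formation and tracking errors beyond additive
Gaussian noise, growth arrest and neuron–neuron connections after 50 h,
axon branching/fasciculation, retraction floors in 2D. Passing tests
therefore demonstrate correct recovery under the model's own assumptions
plus measurement noise, not robustness to tracking artefacts.

## Estimation

Per-window velocity: the mean of within-window frame-to-frame Δr/Δt
ratios, which for equal spacing equals end-to-end displacement over the
window span; this minimises measurement-noise variance (a per-increment
mode is available). A window average estimates the mean velocity at the
window *midpoint*, so moment series carry t_mid = t_obs + 15 min.
Fitting against the window-start time instead would inject a time-shift
bias of about 5 SEM at t = 0 for the reference design (`time="obs"` is
available for comparison). Signed velocities are used throughout
(retraction is negative); `absolute=True` switches to |vx|.

The joint fit shares (a0, γ1, σ²) across the mean-velocity and
mean-squared-velocity series with V0 fixed at the empirical t = 0 mean.
Weighting:

- `"sem"`: diagonal 1/SEM² weights per point, each series treated as
  independent. With this weighting σ² is very weakly identified at
  realistic cohort sizes: SEM(⟨V²⟩) ≈ 2⟨V⟩·sd(V)/√n grows with the drift
  ramp and swamps the σ²-dependent excess, giving sd(σ̂²) ≈ 0.5 at the
  reference design — comparable to the value itself.
- `"gls"` (default when per-cone samples are available): per time point
  the residual 2-vector (mean, mean-square) is whitened by the Cholesky
  factor of the sampling covariance of (V, V²) across cones. This keeps
  the strong mean/mean-square correlation, which is equivalent to
  exploiting the cohort variance directly, and reduces sd(σ̂²) to ≈ 0.015
  at the same design. A tiny ridge (1e−12 × trace) keeps degenerate
  cohort covariances factorable.

Optimisation: `scipy.optimize.least_squares` (TRF) with γ1 ∈ [1e−6, 50]
and σ² ≥ 0; the starting point profiles a0 linearly over a coarse γ1
grid (0.01–1 /hr), making the whole procedure deterministic. Zero-
residual inputs are recovered to optimiser tolerance from arbitrary
admissible starts (multistart-checked in the tests).

Uncertainties: case-resampling bootstrap over growth cones within each
observation time (default 200 replicates), refitting each replicate;
95% percentile intervals. When only moment series are available the
bootstrap re-perturbs the series values by their SEMs instead. The MSL
prediction band pushes each bootstrap parameter draw through the MSL
closed form and takes pointwise 2.5/97.5 percentiles.

Known small biases at the reference design, all ≪ the CI width: the
model treats V0 as fixed while the generator draws it with sd 1.0
(inflates early-time variance; ≈ +2% on σ̂²), measurement noise adds
2·(0.1 µm)²/(0.5 h)² to the velocity variance (≈ +3%), and window
averaging deflates the OU variance by ≈ γ1·w/3 ≈ 2%. None is corrected
for, mirroring the plain moment-fit procedure.

## Numerical choices

- The MSL core f(x) = x + (e^(−x)−1) − (e^(−x)−1)²/2 cancels to x³/3 as
  x → 0; below x = 10⁻³ a 3-term series (x³/3 − x⁴/4 + 7x⁵/60) avoids
  catastrophic cancellation. Both MSL forms (σ²-based and D-based) share
  this core, so their algebraic identity holds to rounding error.
- Time inputs are validated (finite, ≥ 0); parameter containers reject
  γ1 ≤ 0, σ² < 0 and non-finite fields at construction.
- Frame-spacing regularity in the velocity estimator uses an absolute
  tolerance of 2e−6 hr to accommodate the 6-decimal CSV quantisation.
- Track CSV dialect is fixed (UTF-8, '.' decimal, LF, 6 decimal places)
  so synthetic fixtures are byte-stable across platforms.

## Problem sizes used by the test suite

Monte-Carlo oracle checks use 10⁴ exact-scheme paths (3-SE criteria);
two-time correlation oracles use 2×10⁵ direct transition draws; the
parameter-recovery study uses 20 replicate synthetic experiments at the
reference design (9 times × 150 cones) with 100 bootstrap replicates
each; the persistent-cohort estimator checks use 2 000 cones. These
sizes make the statistical assertions sharp while keeping the default
suite around two minutes.

## Limitations

- The quasi-1D reduction is taken as given; the package fits only the
  reduced model (the planar model is simulate-only, as no closed-form
  moments exist for it).
- The heading-update rule in 2D is a documented convention, not part of
  the model statement.
- Bootstrap intervals quantify sampling noise under the protocol; they
  are not guaranteed to reproduce any externally quoted ± values, whose
  method is unspecified.
- Parameters are assumed time-invariant over 0–40 h; growth arrest and
  network formation beyond 50 h of culture are out of scope.
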
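# Methods

## Model

A motor-cortical tuning point is a point η = (t, x, y, θ, v, a) of
M = R³ × S¹ × R²: time, planar hand position, movement direction, speed
and tangential acceleration.  The model assumes (i) cosine directional
tuning and linear positional tuning of single cells (the static model in
`population`), (ii) that admissible changes of the tuning point respect
the kinematic constraints dx = v cosθ dt, dy = v sinθ dt, dv = a dt —
equivalently that motion is tangent to the horizontal distribution
spanned by X1 = v cosθ ∂x + v sinθ ∂y + a ∂v + ∂t, X2 = ∂θ, X3 = ∂a —
and (iii) that local cortical connectivity between tuning points decays
as a heat kernel exp(−d²) of the sub-Riemannian distance these fields
induce.  The frame is bracket-generating away from v = 0 ([X1,X2],
[X3,X1], [[X3,X1],X1] complete the basis), so the distance is finite
there; on v = 0 the rank drops to 5.

Single-neuron preferred-direction trajectories are integral curves
γ' = α1·X1 + p(t)·X2 + q(t)·X3 with polynomial controls p (degree ≤ 4,
the PD velocity) and q (degree ≤ 2, the jerk).  With the initial time and
position pinned, the family has 12 free parameters (θ0, v0, a0, the
half-window T, five p-coefficients, three q-coefficients).  α1 modulates
internal versus external time; the model identifies the two (α1 = 1), and
the hook is exposed but undocumented territory beyond that default.

## Homogeneous distance

The Carnot–Carathéodory distance is replaced by the graded local
estimate

d(η0,η) = (|c1 e1|⁶ + |c2 e2|⁶ + |c3 e3|⁶ + |c4 e4|³ + |c5 e5|³ + |c6 e6|²)^(1/6)

with increments computed in the chart centred at η0:

- e1 = (t − t0)/t_norm (raw t − t0 is used inside e4, e5, e6, which come
  from the chart construction, not from the final norm);
- e2 = circular difference θ − θ0 in (−π, π];
- e3 = sgn(a) − sgn(a0) by default (see below);
- e5 = (v − v0) − (t − t0)(a + a0)/2;
- e4, e6 solve the planar displacement system at constant θ = θ0:
  e4 = 12((Δx) sinθ0 − (Δy) cosθ0)/D, e6 = Δx cosθ0 + Δy sinθ0 − Δt·D/12,
  where D = 6(v0 + v) − Δt(a − a0).

The exponents make the norm exactly 1-homogeneous under the anisotropic
dilation (e1,e2,e3; e4,e5; e6) → (λ·; λ²·; λ³·).  The chart is
directional; the reported distance is the arithmetic mean of the two
directional values so affinity matrices are symmetric.  When |D| < 1e-9
while a transverse displacement is present the chart is singular and the
pair is assigned the +∞ sentinel (kernel 0, "infinitely far in this
chart"); when the transverse displacement also vanishes, e4 = 0 is the
consistent limit (this covers pure time offsets between rest states).
`solve_increment_system` provides an independent check of (e4, e6): it
solves the two-point displacement system by root-finding on the endpoint
mismatch, with the speed along the virtual path modelled as the cubic
Hermite interpolant of the endpoint speeds and accelerations and the
direction interpolated linearly.  For constant-θ pairs the two routes
agree to quadrature/rounding error; the closed form degrades linearly in
|Δθ| (≈5% of the increment magnitude at |Δθ| = 0.05).

### The acceleration-sign increment

Neural states are selective to the sign of the tangential acceleration,
not its amplitude, and state transitions sit at speed extrema — where
that sign flips.  The default increment is therefore the difference of
signs, e3 = sgn(a) − sgn(a0) ∈ {−2, 0, 2}: zero within an acceleration or
deceleration phase, ±2 across phases.  Two alternative readings are kept
behind `DistanceWeights(e3_mode=...)`: `"delta-sign"` (sgn(a − a0)) and
`"arctan"` (arctan((v − v0)/(t − t0))).  Both are nearly constant in
magnitude across sample pairs of a reach and therefore carry no phase
information; with either of them the affinity matrix of a bell-speed
reach has no block structure and the decomposition into
acceleration/deceleration fragments fails.  The phase-sign default is the
package's resolution of this genuinely ambiguous point.

### Units

e1..e4 are unit-invariant, but e5 scales like speed and e6 like length,
so the distance is not invariant under a change of length unit — the unit
is a modelling parameter.  The package uses SI units (metres, m/s);
reaching speeds are then O(1) and the increments are commensurate, which
is what produces the block-structured affinities.  Expressed in
centimetres the same trajectories make |e5|³ dominate every non-adjacent
pair, the affinity matrix degenerates to a narrow band, and no block
structure is possible under the default weights.

### Defaults

| parameter | default | meaning |
|---|---|---|
| c1 | 10 | weight of the time increment (emphasises temporal ordering) |
| c2..c6 | 1 | remaining increment weights |
| t_norm | 0.4 s | neuronal selectivity window normalising e1 |
| σ | 1/√2 | kernel bandwidth: exp(−d²/(2σ²)) = exp(−d²); σ = 1 gives the exp(−d²/2) variant of the static model |

## Spectral decomposition

Affinity A_ij = exp(−d²(η_i, η_j)) over all samples of a trajectory
(symmetric, unit diagonal).  Random-walk normalisation P = D⁻¹A
(Meilă–Shi); P is similar to D^(−1/2) A D^(−1/2), so its spectrum is real
with maximum 1, and eigenpairs are computed through that symmetric
problem.  Samples are embedded in the leading k eigenvectors of P (rows
not re-normalised, matching the random-walk convention) and clustered by
k-means with farthest-point seeding from a fixed seed, 10 restarts, best
inertia — deterministic given the seed.  If A is numerically
block-diagonal (off-block mass < 1e-6 of the total), the normalisation
step may be skipped and the connected components themselves are the
clusters.  k defaults to the largest gap in the leading eigenvalue
sequence (k_max = 8); an explicit k always wins.  Labels are relabelled
by time of first occurrence; fragment boundaries are the midpoints
between consecutive samples whose labels differ.  Temporal contiguity is
never enforced — it is a measured property of the result.

The baseline is k-means directly on the weighted 6-tuples
(c1·t/t_norm, c2·x, c3·y, c4·θ, c5·v, c6·a) with θ unwrapped along the
trajectory; this is the generalised Euclidean metric the spectral method
is contrasted with.

Decomposition quality is scored by (i) the adjusted Rand index against
the generator's ground-truth fragment labels and (ii) the mean distance,
in samples, from each predicted boundary to the nearest speed extremum
(boundary-to-extremum error).  The error is directed from predictions to
extrema so that spurious mid-phase boundaries — the baseline's
characteristic failure — are penalised.

## Synthetic data

The generators emulate the two experimental paradigms the decomposition
was established on:

- **Centre-out reach**: straight path, quartic bell speed
  v(t) = v0(1 − (t/T)²)², t ∈ [−T, T]; defaults v0 = 1.4 m/s (the
  measured 140 cm/s peak), T = 0.07 s, dt = 0.01 s; θ, v, a are analytic.
- **Random target pursuit**: straight segments between way-points, each
  with its own bell speed scaled so the arc length matches the segment
  (duration rounded to the sampling grid with the peak rescaled); speed
  and acceleration vanish at targets, where the heading changes
  instantaneously (admissible at zero speed).  Per-segment peak speeds
  are drawn uniformly from (0.6, 1.4) m/s with the trajectory seed.
  Ground-truth labels (segment × acceleration/deceleration phase) and the
  true speed-extremum times are exported in the metadata for scoring —
  not part of the model, needed for testing.

Both generators emit curves in the model's admissible set: the
horizontal 1-forms annihilate the discrete tangent at O(dt²).  What they
do not emulate: measurement noise, curved (minimum-jerk) paths between
targets, non-zero speed at target passage, and hand dynamics.  Passing
tests therefore show that the method recovers the decomposition when the
kinematic model holds exactly; robustness to noisy or smoothed real
trajectories is untested.  Raw planar paths (t, x, y) are lifted into M
with central differences (`kinematics_from_path`), so mildly noisy
external data can be ingested, at second-order accuracy.

PD-curve fixtures for the fitting machinery are random polynomials of
orders 1–5 on the ±70 ms reliable tuning window, all through θ(0) = 0
(the fan convention), with Gaussian noise.  Exact reproduction of the
published per-curve R²/NRMSE tables is out of scope: their inputs are
curves digitised from another study's figure and unavailable; the table
machinery is validated on these synthetic fixtures instead (exact-model
R² = 1, nested-order monotonicity, coefficient recovery within 3
standard errors over 100 seeds).

## Numerical choices

- Integrator: classical fixed-step RK4; θ integrated unwrapped, wrapped
  on storage; symmetric spans march backward and forward from the initial
  condition so the fan's meeting point is exact.  CurveSpec requires
  dt ≤ T/10.
- Rank: singular values with tolerance 1e-10 (well above double-precision
  noise for O(1) entries).
- Brackets: closed forms derived symbolically from the field definitions
  (no numerical differentiation), cached per pair.
- Least squares: monomial basis on the domain rescaled to [−1, 1] for
  conditioning; coefficients and standard errors mapped back.  NRMSE is
  RMSE normalised by the observed response range (a convention choice;
  range-normalisation is dimensionless and stable on bounded angle
  curves).
- Continuum population vector: rectangle-rule quadrature on the periodic
  grid with the circular distance |θ − θ′|.
- The spike-probability inner product of the population-activity estimate
  is computed in the embedding (t/t_norm, x, y, cosθ, sinθ, v, a) with
  optional per-component scales (default 1): a raw 6-tuple inner product
  would mix units and be discontinuous on the circle.

## Problem sizes

Default test and acceptance runs use 15-sample centre-out reaches
(T = 0.07 s at 100 Hz), pursuit paths of 3 segments in a ±0.12 m
workspace (≈ 40–80 samples), 20 seeded pursuit replicates for the
method contrast, 1000 random pairs for the increment oracle, and 100
Monte-Carlo seeds for coefficient recovery.  These sizes keep every
matrix dense and exact eigendecompositions cheap while matching the
scale of the experiments the model describes.

## Known limitations

- The homogeneous estimate is a local surrogate: e4/e6 are evaluated in
  the constant-θ chart of the base point even for pairs with large Δθ
  (local-approximation semantics).  The displacement system prints the
  time increment in both of its rows; the constant-θ solutions contain
  neither, and the implementation uses e1 in both.
- The affinity of long trajectories is dominated by the weighted time
  term; fragments much longer than t_norm·k/c1 may be over-split before
  the phase structure is.
- The eigengap choice of k is reliable only when the affinity has
  near-block structure (short reaches, clear phases); for long smooth
  trajectories an explicit k is recommended.
- k-means baselines on raw 6-tuples are sensitive to the acceleration
  scale; this is intrinsic to the metric being criticised, not corrected.
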
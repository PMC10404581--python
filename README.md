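# srmotion

Neurogeometric modelling of movement coding in the arm area of primary
motor cortex (M1), for computational neuroscientists studying how neural
population states relate to reaching kinematics.

Population recordings show that M1 activity during reaching unfolds as a
sequence of coherent states whose transitions coincide with the minima and
maxima of the hand's tangential speed — the movement decomposes into
acceleration and deceleration "fragments".  `srmotion` implements a
kinematic model that recovers this decomposition from hand kinematics
alone.

## The model

A cortical tuning point is a point of the 6-dimensional feature space

    M = R^3_(t,x,y) × S^1_θ × R^2_(v,a)

(time, planar hand position, movement direction, speed, tangential
acceleration; SI units).  The kinematic constraints — velocity along θ,
`a = dv/dt` — are encoded by three 1-forms whose kernel is the
*horizontal* distribution spanned by

    X1 = v cosθ ∂x + v sinθ ∂y + a ∂v + ∂t,   X2 = ∂θ,   X3 = ∂a.

Together with the brackets `X4 = [X1,X2]`, `X5 = [X3,X1]`,
`X6 = [X5,X1]` the frame spans the tangent space wherever `v ≠ 0`
(bracket-generating condition), so M carries a sub-Riemannian distance.
Time-varying preferred directions of single neurons are modelled as
integral curves `γ' = X1 + p(t) X2 + q(t) X3` with polynomial controls
(deg p ≤ 4, deg q ≤ 2), a 12-parameter family matching the dimensionality
seen in neural data.

The distance is estimated locally by a homogeneous norm of graded
increments e1..e6 (first-order: time, direction, acceleration sign;
second-order: transverse and speed increments; third-order: along-track),

    d(η0,η) ≈ (|c1 e1|⁶ + |c2 e2|⁶ + |c3 e3|⁶ + |c4 e4|³ + |c5 e5|³ + |c6 e6|²)^(1/6),

with defaults c1 = 10 (time weighted by the 0.4 s window of neuronal
selectivity) and c2..c6 = 1.  The connectivity kernel `ω = exp(−d²)`
defines an affinity matrix over trajectory samples; random-walk
normalisation `P = D⁻¹A` and k-means in the leading eigenvector embedding
decompose the movement into fragments.  A weighted-Euclidean k-means
baseline (same weights) is provided for contrast: it ignores the
differential constraints and mis-groups samples across speed extrema.

## Worked example

```
$ srmotion gen center-out --out reach.csv
wrote 15 samples to reach.csv
$ srmotion cluster --input reach.csv --k auto --seed 0 \
      --out labels.csv --report report.json
{"method": "spectral-subriemannian", "k": 2, "n_samples": 15, "boundaries": [-0.005]}
```

The generated reach is a straight centre-out movement with the quartic
bell speed profile `v(t) = v0 (1 − (t/T)²)²` (peak `v0 = 1.4` m/s at
`t = 0`, half-duration `T = 0.07` s, step 0.01 s).  The report shows the
eigengap selecting `k = 2` (leading Markov eigenvalues 1.0, 0.926, then a
drop to 0.388), i.e. two fragments; the single boundary at `t = −0.005` s
lies half a sample from the speed maximum at `t = 0`: the decomposition
splits the reach into its acceleration and deceleration phases, as the
neural states do.  `boundary_error_samples: 0.5` in `report.json` is the
mean distance (in samples) from each boundary to the nearest speed
extremum.

The same pipeline on a multi-target pursuit path
(`srmotion gen pursuit`, `--distance subriemannian`) recovers one
acceleration and one deceleration fragment per segment, with boundaries
at the speed extrema; running with `--method kmeans --distance
weighted-euclidean` shows the baseline's failure to respect them.

Library use mirrors the CLI: `gen_center_out` / `gen_random_pursuit` /
`kinematics_from_path` build trajectories, `spectral_cluster` and
`kmeans_baseline` decompose them, `fit_pd_table` reproduces the
polynomial goodness-of-fit methodology for preferred-direction curves,
and `integrate_curve` / `generate_fan` simulate tuning-curve fans.

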
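# Methods

This note records the model, the numerical choices and the design
decisions behind `slipgait`, and states what the synthetic-data tests
do and do not demonstrate.

## Model and assumptions

The walker is a conservative hybrid system: a point-mass CoM on two
massless linear springs with rigidly attached circular roller feet
(radius `r0`, default 0.3 leg lengths), walking on level ground in the
sagittal plane. There is no swing-leg dynamics, no damping, no trunk,
no knee, and stiffness and rest length are constant — the model is the
minimal template, not a musculoskeletal simulation.

Coordinates: `x` forward, `y` up; leg angles are measured from the
vertical and are negative while the foot is ahead of the CoM, so the
touchdown angle `phi_TD` is negative and the trailing leg has positive
angle at foot-off. For an active leg the roller centre sits at height
`r0` and its abscissa advances from the touchdown contact point by
`r0*(phi − phi_TD)` (rolling without slipping); the spring acts between
the CoM and the roller centre with rest length `1 − r0`. The leg angle
for a given CoM position is found by Newton iteration on the rolling
constraint; the residual derivative is strictly negative, so the
iteration is monotone (tolerance 1e-11 in angle, bounded at 100
iterations).

**Spring force.** The equations of motion are the Lagrangian form: each
active leg contributes `−k·s·∇s`, the gradient taken with respect to
the CoM coordinates under the rolling constraint. Working this out, the
force acts along the line from the ground **contact point** to the CoM
(not along the roller-centre–CoM axis), and degenerates to the familiar
axial decomposition for a point foot. Only this form is conservative —
with an axial force the model loses ~0.6% of its energy per step, which
would poison every limit-cycle statement. Reported GRF components are
the same transmitted force, so the time-average of the vertical GRF
over a periodic step is exactly one body weight. A leg whose computed
compression is negative exerts zero force (legs cannot pull); the
clamped configuration carries no spring energy, so conservation
survives the clamp.

**Events.** One step runs VLC → FC → FO → VLC. Foot contact triggers on
the downward crossing of the CoM height through
`r0 + (1−r0)·cos(phi_TD)` (placing the new leg at `phi_TD` with zero
compression, hence force-continuously); foot-off on the trailing
compression crossing zero; the step ends when the new stance leg passes
vertical. A swing reactivation delay of 0.05 dimensionless time units
after each foot-off prevents instant re-contact of the just-lifted leg;
it is short against step durations of 1–3 units and is configurable. A
second foot contact before the stance leg reaches vertical violates the
assumed event ordering and invalidates the trial, as do a CoM height at
or below the roller-centre plane, a non-positive forward speed, and
exceeding the time budget (8 units by default).

## Integration and tolerances

Fixed-step classical Runge–Kutta at `dt = 1e-3` dimensionless time
(bit-reproducible for a given `dt`), with every event time refined by
bisection of the last step to a residual below 1e-9. Energy is
conserved to ~1e-12 relative per step at the default `dt`; the order-4
convergence of the integrator is verified on an event-free
sub-interval. The inner loop is JIT-compiled (numba); the public
operations call the same kernels.

## Limit-cycle search

The Poincaré section is the VLC with the vertical CoM speed set to zero
on the section; the section state is `zp = (y0, xdot0)`. A lattice
point counts as a fixed point when `|zp_R − zp_0| < 1e-3` (the sweep
tolerance). Default lattices cover the documented domains with spacings
0.01 in speed and trough value and 0.1 in the step parameter
(66 × 120 × 105 points).

**Stability.** The 2×2 return-map Jacobian is built by central finite
differences (perturbation 1e-4 per coordinate; shrinking it to 1e-5
moves the eigenvalue magnitudes by <1e-2); a solution is stable when
both eigenvalue magnitudes are below `1 − 1e-3`. The dynamics being
conservative, one eigenvalue sits near unit magnitude (the
energy-family direction); discarding the vertical speed at each section
crossing damps the symmetric mode, so stable solutions do show both
magnitudes below one, but the margin makes the stability map fragmented
on a discrete lattice — refining the grid fills it in. An exact
(analytic) Jacobian is not attempted; the finite-difference contract is
the committed interface.

**Selection.** Among candidates: locally stable first, then the common
double-hump vertical GRF pattern, then the largest step length, with
ties broken by smaller return deviation and smaller step parameter so
the choice is deterministic. When no stable candidate exists the same
ordering runs over the unstable pool and a warning is attached. Pattern
labels count strict local maxima of the single-leg stance GRF
(assembled from the periodic step by continuing the trailing leg one
period forward) above a 1% prominence floor: exactly two peaks is
`double_hump`, more is `multi_peak` (the low-speed oscillation modes),
anything else `other`.

**Polish before emission.** The prediction pipeline keeps the *grid*
point for selection and its reported metrics, but polishes it to a
sharply periodic orbit (least squares on the return map) before
simulating the emitted curve, holding the constrained coordinate fixed
— the speed under constraint V, the CoM height (hence the encoded
trough) under constraint F. Without the polish the emitted trough
inherits the lattice periodicity error amplified by the leg stiffness
(`k·Δzp`, up to ~0.04 body weights), inconsistent with the
sub-percent trough fidelity the kinetic constraint is meant to deliver.
Periodic solutions form a one-parameter energy family, so the
constrained one-dimensional polish is well-posed where the family
crosses the prescribed value.

## Scaling and regression

Physical ↔ dimensionless conversion uses the references `l0`, `m0`,
`g = 9.81 m/s²`, with the model leg length from body height via the
leg-to-body ratio `Alh` (1.78 women, 1.70 men). With this convention
the average-build demo subject (1.45 m/s, 1.84 m, male) normalizes to
0.445 and the small fast subject (1.63 m/s, 1.58 m, female) to 0.552;
the tall demo subject does not reconcile with its published normalized
speed under any of these constants (0.478 computed vs 0.471 printed)
and is excluded from numeric checks rather than silently adjusted.

The regression registry stores the published calibration: the
contact-time factor `Atc` (a constant, 1.531, under constraint V; a
linear model in `vG, h0, m0` under constraint F), the trough model
`Fv_min = 1.380 − 0.800·√vG + 0.146·h0`, and direct reference models
for `tc`, `Fv_max`, `Fap_max`. Where the published table offers both a
`vG` and a `√vG` form, the `√vG` form is the committed default (step
length scales with the square root of speed, and the `√vG` trough model
recovers the plausible `Fv_min(0) = 1` BW); heights enter in metres,
masses in kg. Refitting uses ordinary least squares with 95% t-based
confidence half-widths; goodness of fit is `R²` plus an RMSE normalized
by the interquartile range of the observations (linear-interpolation
quartiles), which keeps single outliers from dominating the normalizer.

`Atc` stretches the time axis only; force amplitudes are untouched.
The resulting overestimate of the stance impulse is inherent to the
compensation scheme and is left visible rather than hidden by an
amplitude rescale.

## Signal processing

Measured or synthetic trials are low-pass filtered with a fourth-order
Butterworth design at 67 Hz applied forward-backward (zero phase, so
extracted timings do not shift; the effective magnitude response is the
squared design response). Stance is bounded by the vertical force
crossing a 10 N threshold (configurable); the trough is the minimum
between the two most prominent vertical peaks, reported as undefined
with a warning when no two-peak structure exists. Relative errors are
`100·(predicted − observed)/observed`, aggregated as mean/sd/min/max.
The train/test split is seeded and subject-stratified with per-subject
train share `round(2n/3)`.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* of a 12-subject
study: masses from a normal distribution (82.4 ± 11.7 kg) truncated to
the 60–100 kg inclusion band, heights 1.78 ± 0.10 m, a 4:8
female:male ratio, two prescribed speed bands (1.3–1.5 and
1.5–1.7 m/s), and a fully crossed 48-trials-per-subject condition
layout (576 trials; a seeded exclusion step leaves 550, and the
stratified split then yields 365/185). Because the per-subject
exclusion tally is not published, the default dropout uses a fixed
plausible per-subject pattern (five subjects losing 4 trials, two
losing 3) permuted by seed — the composition under which the committed
split rule lands exactly on the published totals.

Trial curves are parametric: the vertical force is a two-term sine
series `a1·sin(πu) + a3·sin(3πu)` solved to pass through the programmed
peak and trough, the fore-aft force a single antisymmetric lobe pair
integrating to zero, plus a seeded 80–150 Hz noise burst windowed over
the first 15% of stance (the load-response region). Programmed
descriptors come from the calibrated regressions with 3% multiplicative
jitter. Passing tests therefore demonstrate that the processing,
calibration and bookkeeping chain is self-consistent — they do not
validate the model against real plate data, which would require the
original trials. Condition labels (shoe, panel, bearing) carry no force
effect by default, mirroring the fact that those factors were not
analysed separately.

## Problem sizes used in the checks

The speed-limit sweeps run the full default lattice per speed value,
scanning speeds downward until the first stable solution (~300k
one-step simulations each); the oscillation-mode boundary uses
constraint-F sweeps at trough levels {0.5, 0.6, 0.7} over the full
speed lattice. Measured limits: largest stable speed 0.57 with roller
feet, 0.46 without (0.6 and 0.5 at the reported one-decimal
resolution); the selected solutions switch from multi-peak to
double-hump at ≈0.30. Statistical property checks use 20–40 seeded
replicates at the study's training-set size (n = 365).

## Known limitations

* Only symmetric gaits are generated (zero vertical CoM speed on the
  section); asymmetric vertical GRF with unequal peaks cannot be
  represented.
* The stability flag is grid-sensitive by construction: near-neutral
  eigenvalues land on either side of the margin, so the stable set
  fragments on coarse lattices. The speed-limit results are robust to
  this (tested at the default lattice), but individual lattice points
  near the boundary are not.
* The mediolateral force component, multi-step variability and CoP from
  plate moments are out of scope.
* Above the model's speed limit (normalized ≈0.6 with roller feet) no
  prediction is possible; near it, trough predictions degrade — the
  pipeline warns from 0.5 upward.
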
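# Methods

## Background and signal model

The video head impulse test (vHIT) measures the vestibulo-ocular reflex
(VOR) by recording head velocity $v_h(t)$ and eye velocity $v_e(t)$
(deg/s, 250 Hz) during brief passive head impulses. For a healthy
reflex with gain ≈ 1, $v_e \approx -v_h$, so the *gaze error*

$$e_{gaze}(t) = v_e(t) + v_h(t)$$

should be near zero. Mechanical slippage of the camera goggles injects a
slow spurious component ("drift") into the recorded eye velocity. During
the *rest phases* — before impulse onset and after recovery — the true
eye velocity is essentially zero, so the rest-phase statistics of the
recorded signals isolate the artifact:

* **eye drift** $d_e$: rest-phase mean of $v_e$ (the slippage proxy);
* **head drift** $d_h$: rest-phase mean of $v_h$;
* **gaze drift** $d_{gaze}$: rest-phase mean of $e_{gaze}$ (equal to
  $d_e + d_h$ under the identity correction, which the tests verify to
  1e-9 relative tolerance);
* rest-phase **population SDs** $\sigma_e, \sigma_h, \sigma_{gaze}$ and
  variances, plus $v_{max} = \max_t |v_h(t)|$.

## Windowing and the rest mask

Each impulse is cut to a fixed window of 0.7 s, re-zeroed to a local
time axis with the head-velocity peak placed near 0.25 s (detector:
local maxima of $|v_h|$ above 50 deg/s, 0.5 s refractory, both
configurable; the peak threshold is far above the noise floor and far
below physiological impulse peaks). A sample at local time $t$ is
*rest* iff $t < 0.05$ s or $t > 0.5$ s, with strict inequalities —
boundary samples count as movement. On the uniform 250 Hz grid over
[0, 0.7] s (176 samples) this yields 13 pre-impulse and 50 post-impulse
rest samples. Placing the peak at 0.25 s is what makes both rest
sub-regions non-empty simultaneously; it is the package's alignment
convention, and every masked statistic requires at least 2 rest samples
(degenerate masks are an error, not silently NaN).

Dispersion features are computed over the rest mask by default because
the analysis concerns rest-phase stability; a `dispersion="full"` flag
switches to whole-window SDs for sensitivity analyses. Variances are
population (divide by the masked count), matching the per-impulse
estimator definition.

## Feature screening

The per-impulse feature vector

$$X = [d_e, d_h, \bar e_{gaze}, d_{gaze}, \sigma_e^2, \sigma_e,
\sigma_h^2, \sigma_h, \sigma_{gaze}^2, \sigma_{gaze}, v_{max}]$$

($\bar e_{gaze}$ is the full-window mean of the gaze error, a scalar
realization distinct from the masked $d_{gaze}$) is screened with
Kendall tau-b, the tie-corrected rank correlation, producing an 11×11
coefficient matrix and a matching p-value matrix (significance displayed
at 0.05). Rank correlation is used because several features are related
monotonically but not linearly. The tau-b and p computations are
delegated to `scipy.stats.kendalltau` and verified in the tests against
an explicit O(n²) concordant/discordant pair-count oracle, with and
without ties.

Protocol-level statistics: Pearson r between $v_{max}$ and drift with
Fisher z-transform 95% CIs, $\tanh(\operatorname{atanh} r \pm
1.96/\sqrt{n-3})$; group mean-drift CIs by the normal approximation
$\text{mean} \pm 1.96\,\text{sd}/\sqrt{n}$ (not Student's t — the
normal form is the one whose output matches the published group
intervals exactly, so it is adopted and documented); Kruskal–Wallis
across the three protocols and pairwise two-sided Mann–Whitney U tests
with Bonferroni threshold $\alpha/\binom{k}{2} = 0.05/3 \approx 0.0167$.
Because drift offsets are negative while slippage severity grows with
impulse velocity, the velocity–drift correlation uses $|d_e|$ by
default; `signed=True` restores the signed convention.

## Quadratic correction and its calibration

The correction replaces the eye velocity with a second-order polynomial

$$g(v_e, \theta) = \theta_1 v_e^2 + \theta_2 v_e + \theta_3,$$

with identity $\theta = [0, 1, 0]$, and $\theta$ is fitted to minimize

$$J(\theta) = \sqrt{\tfrac1N \sum_i \sigma_{gaze}^2(i;\theta)},$$

the RMS across impulses of the rest-phase SD of $g(v_e) + v_h$.

**Non-identifiability of $\theta_3$.** $J$ is exactly invariant to
$\theta_3$: adding a constant to the gaze error changes no SD. The
minimizer is therefore a one-parameter family, the gradient's third
component is identically zero, and $\theta_3$ stays at its initial
value. Fits should be compared on $J$, not on $\theta$. (This also
means a reported $\theta_3$ of any magnitude is consistent with the same
objective value.)

**Optimizer.** Fixed-learning-rate gradient descent from
$\theta^{(0)} = [0,1,0]$ with $\alpha = 0.7$, convergence when
$\lVert\theta^{(n+1)} - \theta^{(n)}\rVert_2 < 10^{-4}$, at most 700
iterations. The gradient is a relative central finite difference of the
pooled objective (step $10^{-6}\max(1, |\theta_k|)$ per component).
Numerical choices:

* *Step normalization.* A raw step $\alpha\nabla J$ diverges
  immediately on deg/s-scaled data (the quadratic term's curvature is
  huge), and a unit-normalized step of fixed length $\alpha$ can never
  satisfy the $10^{-4}$ step-norm convergence test nor resolve
  $\theta_1$ at its natural $10^{-3}$ scale. The default update is
  therefore the *objective-scaled* direction
  $\Delta\theta = -\alpha\, J(\theta)\, \nabla J / \lVert\nabla J\rVert^2$
  (a zero-target Polyak step relaxed by the learning rate, natural here
  because the objective's ideal minimum is zero): far from the minimum
  it behaves like a normalized step, and near it the step length decays
  with $J$, so the fixed learning rate both converges and triggers the
  step-norm test honestly. The step length is capped (default 10 per
  iteration) so that noisy data — where the minimum is bounded away from
  zero and the Polyak distance estimate is biased — cannot produce
  unbounded excursions. A `raw` mode retains the plain update for
  experiments.
* *Best-iterate return.* Fixed-step descent can overshoot; the returned
  $\theta^\ast$ is the best-objective iterate of the trace, which
  guarantees $J(\theta^\ast) \le J(\theta^{(0)})$ on the fitting set.
* Runs are fully deterministic given inputs and configuration.

**A caution on the objective itself.** Because $J$ only sees rest-phase
samples, on data whose rest-phase eye velocity is dominated by
uncorrelated noise the optimum shrinks $\theta_2$ below 1 (a
Wiener-style trade-off between noise suppression and cancelling real
rest-phase head motion), i.e. the calibration can bias VOR gain
downward. This is a property of the published objective, not of this
implementation; the report command's before/after comparison makes the
effect visible.

## Synthetic data generator

Each simulated impulse window is

* head: $s\,V \exp(-(t-t_0)^2/2s_w^2)$ with peak velocity $V$ uniform
  in a per-protocol range, $t_0 = 0.25$ s, width $s_w = 30$ ms (≈150 ms
  full width, the standard idealization of a vHIT impulse), random
  left/right sign $s$, plus a small sinusoidal residual head motion
  (default 2 deg/s, 7 Hz — the head is never perfectly still under an
  operator's hands, and without it the correction objective would have
  a degenerate signal-destroying minimum);
* eye: $-\text{gain}\cdot v_h + D$ plus optional Gaussian-pulse
  corrective saccades (probability 0.3, 60–150 deg/s, 20 ms width,
  placed in 0.3–0.45 s so they stay out of the rest mask) and white
  measurement noise (default SD 1 deg/s);
* drift: $D = \text{intercept} + \text{slope}\cdot V + \epsilon$,
  constant within the window — the minimal model consistent with an
  observed velocity–drift correlation. Per-protocol defaults (counts
  24/16/17; peak ranges 130–250, 100–155, 105–200 deg/s; slopes
  −0.025, −0.024, −0.0485 (deg/s)/(deg/s); intercepts 1.52, −0.02,
  −0.014 deg/s; drift-noise SDs 3.2, 4.2, 2.75 deg/s) are chosen so
  the expected group mean drifts are −3.23 (Lateral), −3.08 (LARP) and
  −7.41 deg/s (RALP) at mean peak velocities ≈189, 128 and 153 deg/s —
  emulation targets reproducing the clinically observed group structure
  (largest drift magnitude in RALP), not ground truth about any
  patient.

What the generator does **not** emulate: biomechanical goggle–skin
dynamics (drift is constant per window, not ramped or decaying),
pupil-tracking artifacts, blink dropouts, covert saccades inside the
impulse, or between-subject variability. Passing tests therefore show
estimator and optimizer correctness under the stated model, not
clinical validity on real recordings.

**Constructed-solution datasets.** For optimizer verification the
generator can pass the clean eye velocity through the inverse of the
quadratic correction for a chosen $\theta_{true}$ (branch continuous
with the identity), so that $g(\cdot, \theta_{true})$ restores a
constant rest-phase gaze error exactly and $J(\theta_{true}) = 0$.
`constructed_solution_config()` freezes a noiseless such dataset
(default $\theta_{true} = [10^{-3}, 1.3, 0.5]$, 50 impulses, 3 deg/s
rest-phase head motion, only small residual drift offsets). Small
rest-phase eye velocities keep the objective's curvature along
$\theta_1$ mild, so the step-norm convergence test does not fire until
the objective has collapsed; on this fixture descent from the identity
reaches $J < 10^{-3} J(\theta^{(0)})$ in of order 15 iterations and
recovers $\theta_1, \theta_2$ (not $\theta_3$, which is unidentifiable).

## Problem sizes and tolerances

Tests and the acceptance script use one 57-impulse simulated dataset
(matching the clinical group sizes), a 50-impulse constructed-solution
set, 400–500-impulse Monte-Carlo runs for distributional checks, 200
replicate datasets for the group-difference power check, and 2000 null
replicates (3×15 samples) for the Kruskal–Wallis type-I-rate check
(accepted range 0.035–0.065 around the nominal 0.05). Exact-recovery
assertions in the noiseless limit use 1e-12 absolute tolerance for mask
statistics that are algebraically exact, and 1e-9 where Gaussian-bell
tails leak into the rest mask. Recordings round-trip through the text
format at 6 significant digits.

## Known limitations

* The correction objective's $\theta_3$ blindness and shrinkage bias
  (above) are inherited from the method being implemented.
* The impulse detector (threshold local-maximum) is a pragmatic choice;
  recordings with artifacts above 50 deg/s during rest would need a
  stricter threshold or pre-filtering.
* The window/mask alignment convention (peak at 0.25 s) is a documented
  package choice; other acquisitions may need different `pre_peak`,
  `t_pre`, `t_post`.
* Group CIs use the normal approximation by design (see above); for
  very small groups a t-based interval would be wider.
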
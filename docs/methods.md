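# Methods

This note documents the models implemented in `errpirl`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was genuinely
open.

## Trajectory controller

Reaching motion is generated by a linear autonomous dynamical system
ξ̇ = g(ξ\* − ξ) with gain g = 2.0 s⁻¹, integrated with explicit Euler at
dt = 0.02 s until the state is within 5 mm of the target or 15 s have
elapsed. The gain is set so that the 0.8 m reach of the single-obstacle
scene, including the avoidance detour, takes ≈3.5 s — the time scale of a
natural tabletop reach. Around a spherical obstacle the field is modulated
by M = E diag(1 − 1/Γ, 1 + 1/Γ) Eᵀ with Γ = (2‖ξ−ξᵒ‖/(η rᵒ))^{2ρ}:

* **η (safety factor, dimensionless, calibration range 0.8–2.0)** scales
  the avoided region; the flow cannot enter the sphere of radius η rᵒ/2
  when η ≥ 1 (the normal eigenvalue 1 − 1/Γ vanishes on that boundary), and
  η < 1 permits light contact with the physical object (radius rᵒ/2).
* **ρ (reactivity, dimensionless, calibration range 0.5–3.0)** controls how
  fast the deformation decays with distance: larger ρ makes the modulation
  more local and the avoidance sharper.

The discrete-time impenetrability guarantee carries a slack of one step,
min-clearance ≥ (η−1) rᵒ/2 − dt·v_max, which the test suite checks over a
(ρ, η) grid. Degenerate head-on starts lie exactly on the obstacle axis
where the tangential field component is zero and the rollout would stall on
the safety boundary; a deterministic 10⁻⁶ m s⁻¹ tangential tie-break is
added whenever the state is on the axis and approaching, which breaks the
symmetry without affecting any off-axis trajectory.

Releasing the joystick switches the modulation to the conservative pair
(ρ, η) = (1.0, 2.5) for the rest of the trial, producing the characteristic
elbow in corrected trajectories.

## ErrP decoder

The pipeline is strictly causal so that continuous (online-style) decoding
is a faithful replay. Preprocessing: EOG regression with coefficients
B = C_eog,eog⁻¹ C_eog,eeg estimated from a dedicated 90 s eye-movement
recording; 50 Hz notch; causal 4th-order Butterworth band-pass [1, 12] Hz.
Epochs are [0, 0.5] s after release (erroneous) and [1.5, 2.0] s after
motion onset (correct); erroneous trials whose reaction time deviates from
the median by more than 3 median absolute deviations are discarded (a
median-centered rule; centering on the mean lets a single gross outlier
inflate the spread estimate and reject everything. With MAD = 0 only
strictly deviating trials are rejected).

The spatial filter maximizes the canonical correlation between single
trials and their class-average time courses, computed in closed form from
trace-regularized (10⁻⁶) covariances; the three strongest canonical
components are kept, with per-component sign and scale fixed for
determinism. The erroneous-class grand average in component space is the
template T used by the covariance features for both classes (one template,
as only the error response has a stereotyped time course).

Features per 0.5 s epoch (84 total, min–max normalized to [0, 1] with
calibration bounds; online values outside the bounds are clipped):

* 48 temporal — the 3 components resampled to 32 Hz (16 samples each);
* 15 spectral — Welch power of each component in the bands [1,3], [3,5],
  [5,7], [7,9], [9,12] Hz, using the full 256-sample epoch as one segment
  (2 Hz resolution, so every band contains bins);
* 21 covariance — C_Z = ZᵀZ/s with Z = [X T] (s×6), projected to the
  tangent space at the log-Euclidean mean of the calibration C_Z matrices
  (upper triangle, off-diagonals scaled by √2). Non-positive-definite C_Z
  receives a 10⁻¹⁰·trace jitter.

Classification is diagonal LDA with empirical class priors and pooled
per-feature variances floored at 10⁻¹²; the posterior is the standard
logistic of the discriminant. Continuous decoding slides 0.5 s windows at
32 Hz starting at [0.25, 0.75] s from motion onset (skipping the
visually-evoked onset response) until the trial end; the causal moving
average of length h of the raw posteriors is compared with the threshold θ.
(h, θ) are chosen on the 16×101 grid by Matthews correlation coefficient
averaged over stratified 10-fold cross-validation test folds, ties breaking
toward smaller h then smaller θ; an order-preserving sigmoid recalibration
in logit space maps θ to an operating threshold of 0.5. A trial's
P(ErrP) — the quantity that becomes a demonstration weight as
w = 1 − P(ErrP) — is the recalibrated smoothed posterior at the decision
time when a decision fired, otherwise the maximum recalibrated smoothed
posterior.

## Time-frequency analysis

The Stockwell transform is computed in the frequency domain (FFT with a
Gaussian voice window exp(−2π²(ν−f)²/f²), zero-padded at least 4× so the
window convolution is effectively linear rather than circular), which is
O(N log N); the direct time-domain integral is retained in the test suite
as the small-n oracle and the two agree to ≈10⁻³ relative away from record
edges. f = 0 is defined as the signal mean. The ERSP contrasts mean
erroneous-trial power |S|² over [−0.5, 1.0] s around the release against
the correct-trial baseline power ν(f) in [1.5, 2.0] s after onset,
ERSP = 10 log₁₀(ERS/ν), on a 1 Hz grid over [1, 30] Hz, after a causal
2nd-order 1 Hz high-pass. Zero-baseline frequencies are masked as NaN.
Power (|S|²) rather than amplitude is used for both numerator and baseline,
matching the baseline's definition as averaged power.

## Weighted GP-IRL

Three isotropic elliptical basis functions sit on the obstacle with widths
ζ ∈ {0.5, 2, 8} × (rᵒ/2)⁻² and Λ = I. The widest kernel resolves position
out to ≈3 obstacle radii — the region where conservative avoidance
trajectories run — while the narrowest separates grazing passes from the
obstacle surface. Each demonstration is resampled to 40 points uniform in
arc length; inducing points are restricted to the obstacle-relevant region
(widest feature ≥ 0.05) and capped at 120 by uniform thinning. Far-field
path segments carry no information about avoidance preference, and
anchoring them (see below) would give arbitrarily wide trajectories the
same reward as the demonstrated ones.

The kernel is read per-dimension, k(fⁱ,fʲ) = β exp(−½ Σₖ λₖ[(fⁱₖ−fʲₖ)² +
1_{i≠j}σ²]), the only reading that makes the sum well-defined; hence the
diagonal is exactly β and σ² (default 10⁻³) acts as kernel-level noise. An
additional 10⁻⁸β diagonal jitter keeps Cholesky factorizations stable. The
weighted objective Σᵢ wᵢ Lᵢ uses each demo's own subsampled block Kᵢ; the
hyperparameter prior −½tr(K⁻²) − Σ log(λₖ+1) follows the GP-IRL
formulation.

**Identifiability and anchoring.** The likelihood alone is maximized by
y = 0 (no reward anywhere) — the prior penalizes the degeneracy but
supplies no sign or scale. We resolve this by softly anchoring each
demonstration's outputs to its weight, with per-point anchor strength
wᵢ·exp(−(d − d_min,i)²/(2δ²)) where d is distance to the obstacle and
δ is half the middle kernel's length scale: a demonstration expresses its
avoidance preference at its closest approach, so the anchor concentrates
there and the GP smooths the rest. This reproduces the intended semantics —
high-weight demonstrations attract high reward, the high-reward region is a
ring around the obstacle, and the optimized trajectory lies among the
high-weight demonstrations. Zero-weight demonstrations are dropped
entirely (their likelihood term is identically zero, and keeping their
inducing points would leave unconstrained outputs in the posterior),
which makes deleting a w = 0 demonstration an exact no-op.

Optimization is L-BFGS-B over (y, log λ, log β) with analytic gradients in
y and central-difference gradients in the log hyperparameters; λ is bounded
in [5, 150] and β in [0.5, 2] (features live in (0, 1], so these bounds keep
the reward field smooth at workspace scale while separating corrected from
accepted rings; unbounded fits degenerate toward a near-diagonal kernel and
a spiky field). Up to 3 seeded restarts guard against the y → 0 degeneracy
and optimizer failures; the first start uses the anchors themselves with
λ = 1, β = 1.

R(ρ, η) aggregates the learned reward by the *mean* over the rollout's
states, removing the path-length confound between parameter settings. The
simplex search starts from the better of the supplied initial point and a
coarse deterministic 4×8 (ρ, η) grid (a constant reward therefore returns
the initial point unchanged), with up to 3 seeded restarts on stagnation.
Parameters are clipped to ρ ∈ [0.1, 4], η ∈ [0.5, 3]. The forward
finite-difference gradients with step ε = 10⁻³ are exposed as
`finite_difference_gradient` for verification against central differences.

**Recovery precision.** The simulated user is one-sided: they correct
trajectories whose forthcoming clearance falls below their preferred margin
c\*, and accept everything wider. The preference boundary is therefore
identifiable only from below, and the reward peak sits roughly one EBF
kernel width beyond the outermost accepted demonstration ring. When the
demonstration window brackets the boundary — the late-adaptation regime,
with accepted demonstrations concentrated near the learned ring — the
optimized rollout's clearance matches c\* to within ≈10%. From fully random
initial batches the learned clearance instead converges to the center of
the accepted demonstrations (typically 1.2–1.7 × c\*): the method learns
"what the user accepts", not the exact release threshold, which also means
the user stops correcting (the headline closed-loop effect) well before the
clearance equals c\*.

## Synthetic data

The generator emulates exactly the statistics the pipeline relies on:

* **Background EEG** — 1/f^1.5-spectrum noise, spatially correlated through
  a smooth channel-distance mixing, plus a 10 Hz idle rhythm with slow
  amplitude modulation on posterior-leaning channels; 10 µV rms per channel.
* **EOG** — 1/f² noise with raised-cosine blink transients (rate 0.1 s⁻¹,
  ~120 µV), leaking into EEG with frontally weighted fixed coefficients, so
  that the EOG regression stage has realistic work to do.
* **ErrP template** — a negativity peaking 0.01 s after release, a
  positivity at 0.3 s, and a 6 Hz burst, all gated to the support
  [−0.2, 0.6] s, with a topography peaking at FCz. The default peak
  amplitude is 0.6 µV: the template is deterministic (no trial-to-trial
  latency or amplitude variability), so a small amplitude against the 10 µV
  background reproduces the realistic single-trial decoding regime
  (time-locked offline accuracy near 0.85, continuous clearly lower) that
  larger amplitudes would trivialize.
* **Simulated user** — releases the joystick iff the previewed trajectory's
  minimum forthcoming clearance is below the preferred margin
  (default 0.006 m, the ≈25th percentile of the clearance distribution
  under the calibration parameter ranges, so ≈25% of calibration trials are
  corrected), at the first approaching moment the violation is foreseeable
  plus a reaction delay ~ Normal(1.03 s, 0.10 s) truncated at 0.2 s.
  Spurious releases (probability 0.02) model joystick misoperation: they
  are labeled erroneous by behavior but carry no ErrP, exercising the
  reaction-time rejection and the decoder's error paths.

What the generator does **not** emulate: single-trial ErrP latency and
amplitude variability, non-stationary background (drowsiness, impedance
drift), movement and muscle artifacts beyond blinks, volume-conduction
topographies beyond smooth Gaussian gains, and any visually-evoked response
at motion onset. Passing tests on synthetic data therefore demonstrate the
correctness and the closed-loop behavior of the *pipeline*, not expected
decoding accuracy on recorded EEG; in particular the continuous-decoding
false-alarm behavior of real sessions may differ.

## Closed-loop protocol

Calibration draws (ρ, η) uniformly from ρ ~ U(0.5, 3.0), η ~ U(0.8, 2.0)
per trial, alternating left/right targets (~400 trials in the protocol;
tests and the acceptance script use 120–300 to keep runtimes at desk
scale, which leaves all qualitative behavior unchanged). Adaptation runs
per condition: an initial batch of 3 or 5 random-parameter demonstrations
is weighted by the decoder, GP-IRL fits and the optimized (ρ, η) drive
subsequent trials, with the latest five demonstrations retraining the IRL
after every trial. Retraining is skipped when the window has no weight
contrast (all accepted or all corrected): such a window carries no
information about the preference boundary, and refitting on it lets the
parameters drift outward. IRL failures fall back to the previous
parameters with a warning. Experiment 2 is modeled as eight conditions
(4 target moves × gripper state, the grasp condition enlarging the
effective obstacle); demonstrations are never pooled across conditions.

The "oracle decoder" used in closed-loop analyses assigns weight 0.95 to
accepted and 0.05 to corrected trials — never exactly 0 or 1, so every
demonstration stays in the inducing set.

## Numerical choices and degenerate inputs

* Confusion matrices are laid out [[TP, FN], [FP, TN]] with the erroneous
  class positive; MCC is defined as 0 when a marginal vanishes.
* KL divergence between parameter clusters is reported as
  KL(learned ‖ cluster); cluster covariances get a 10⁻⁸ ridge.
* Matrix logs/exponentials of SPD matrices use eigendecompositions with
  eigenvalues floored at 10⁻¹².
* The decoder trace on a trial shorter than 0.75 s is empty (no decision);
  a trial of exactly 0.75 s yields one window.
* All randomness flows through `numpy.random.default_rng` seeded from the
  caller; same seed, same results, including the GP-IRL restarts and the
  cross-validation split.

## Known limitations

* The reward learner recovers the preference boundary only to the
  resolution of the EBF basis (see "Recovery precision" above).
* Continuous decoding on synthetic data operates in a thin-margin regime:
  the MCC-selected operating point can favor sensitivity, giving plain
  accuracies well below the time-locked mode even though balanced accuracy
  remains clearly above chance. At unlucky seeds the selected point is
  hyper-sensitive; the weights then collapse toward 0.5 and the adaptation
  phase shows elevated correction rates — the same association between
  decoder performance and release rate seen with low-performing decoders in
  practice.
* One obstacle per scene segment; no moving obstacles, no joint-space
  kinematics, no real-time constraints.
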
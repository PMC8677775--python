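# errpirl

Closed-loop learning of a user's preferred robot obstacle-avoidance behavior
from EEG error-related potentials (ErrPs).

## The problem

Assistive robot arms can avoid obstacles autonomously, but *how* they avoid
them — grazing past a glass or giving it a wide berth — is a matter of
personal preference that users with severe motor impairment cannot easily
communicate. When an ongoing robot trajectory violates the user's
expectation (for example, it looks like it will pass too close to the
obstacle), the brain produces a stereotyped error-related potential: a
fronto-central negativity followed by a positivity ~0.3 s later, with a
theta-band (4–8 Hz) power increase. This package implements, end to end and
on synthetic data, a shared-control loop that

1. generates planar reaching trajectories from a **dynamical system (DS)**
   with local obstacle-avoidance modulation, parameterized by a reactivity
   ρ and a safety factor η;
2. decodes single-trial ErrPs from 16-channel EEG, both time-locked and
   continuously along the robot's motion, yielding a posterior probability
   P(ErrP) per trajectory;
3. feeds each demonstrated trajectory, weighted by w = 1 − P(ErrP), into a
   **weighted Gaussian-process inverse reinforcement learning (GP-IRL)**
   scheme that infers a reward field over the workspace and re-optimizes
   (ρ, η) so that future trajectories match the user's preference.

It is written for BCI/robot-learning researchers who want a fully testable,
self-contained implementation of the pipeline: every stage runs on a
synthetic-data generator that emulates the statistical structure of the
calibration and adaptation protocols (background 1/f EEG, EOG artifacts, an
injectable ErrP template, and a simulated user who releases a joystick when
a trajectory's forthcoming obstacle clearance falls below an individual
preferred margin, with ≈1.03 s reaction delay).

## The model

**Controller.** Trajectories follow ξ̇ = M(ξ; ξᵒ, rᵒ, ρ, η) f(ξ) where
f(ξ) = g(ξ\* − ξ) is a linear field with a single attractor at the target
ξ\*, and the modulation matrix

    Γ(ξ) = (2‖ξ − ξᵒ‖ / (η rᵒ))^{2ρ},
    M = E diag(1 − 1/Γ, 1 + 1/Γ) Eᵀ,  E = [n̂, t̂]

deforms the flow around a spherical obstacle (center ξᵒ, diameter rᵒ). On
the safety boundary (Γ = 1) the normal velocity component vanishes, so with
η ≥ 1 the flow provably cannot penetrate the safety sphere of radius
η rᵒ/2; η < 1 allows light contact with the object.

**Decoder.** EOG regression (autocovariance coefficients), 50 Hz notch,
causal 4th-order Butterworth band-pass [1, 12] Hz; epochs [0, 0.5] s after
joystick release (erroneous) and [1.5, 2.0] s after motion onset (correct);
a CCA spatial filter keeping 3 components; 84 features per epoch = 48
temporal (32 Hz samples) + 15 spectral (Welch band powers in [1, 12] Hz) +
21 Riemannian (tangent-space projection of the template-augmented 6×6
covariance C_Z, Z = [X T]); diagonal LDA posterior p(error|x) =
1/(1 + e^{−(wᵀx + b)}). Continuous decoding slides 0.5 s windows at 32 Hz
from [0.25, 0.75] s; a smoothing length h ∈ {1..16} and threshold
θ ∈ {0, 0.01, …, 1} are selected on a 16×101 grid by fold-averaged Matthews
correlation coefficient under 10-fold cross-validation, and a sigmoid
recalibration maps θ to an operating threshold of 0.5.

**Reward learner.** Workspace positions are embedded by three elliptical
basis functions centered on the obstacle, fᵏ(ξ) = exp(−ζₖ/2 (ξ−μ)ᵀΛₖ(ξ−μ)).
A GP with ARD kernel k(fⁱ, fʲ) = β exp(−½ Σₖ λₖ[(fⁱₖ−fʲₖ)² + 1_{i≠j}σ²])
carries the reward; the weighted log likelihood L_N = Σᵢ wᵢ Lᵢ with
Lᵢ = −½ yᵢᵀKᵢ⁻¹yᵢ − ½ log|Kᵢ| − ½ tr(Kᵢ⁻²) − Σₖ log(λₖ+1) is maximized over
(y, λ, β), with each demonstration's outputs softly anchored to its weight
(see `docs/methods.md` for why and for the identifiability analysis). The
learned reward r(ξ) = K₍\*,y₎ᵀ K⁻¹ y is mapped back to modulation parameters
by maximizing the mean on-rollout reward R(ρ, η) with a Nelder–Mead simplex;
the finite-difference gradients gᵨ = [R(ρ,η) − R(ρ+ε,η)]/ε (ε = 10⁻³) are
exposed for verification.

## Worked example

```python
from errpirl import (RunConfig, UserModel, OracleDecoder,
                     run_calibration, run_adaptation)
from errpirl.metrics import correction_rate

config = RunConfig(seed=42, n_calibration_trials=120, n_adaptation_trials=10,
                   batch_size=3, user=UserModel())
calibration = run_calibration(config)
print(calibration.decoder.summary())

log = run_adaptation(config, calibration.decoder,
                     calibration_trials=calibration.dataset.trials)
calib_rate = correction_rate(calibration.dataset.trials, "calibration")
adapt_rate = correction_rate(
    [t for t in log.trials if t.phase == "adaptation"], "adaptation")
print(f"correction rate: calibration {calib_rate:.3f} -> adaptation {adapt_rate:.3f}")
rho, eta = log.learned_params["exp1_lr"][-1]
print(f"learned modulation parameters: rho = {rho:.2f}, eta = {eta:.2f}")
```

prints

```
ErrP decoder summary
====================
epochs: 115 (20 erroneous), rejected trials: 5
selected smoothing h = 6, threshold theta = 0.86 (peak fold-averaged MCC = 0.200)
Offline-Timelock accuracy: 0.852 (balanced 0.693)
Offline-Continuous accuracy: 0.696 (balanced 0.618)
Offline continuous detection latency: 0.91 +/- 1.26 s
correction rate: calibration 0.208 -> adaptation 0.000
learned modulation parameters: rho = 4.00, eta = 2.16
```

Reading the numbers: of 120 synthetic calibration trials, 5 were rejected
for anomalous reaction times; the decoder classifies the time-locked epochs
at 85% accuracy, dropping to 70% when applied continuously along the whole
trajectory (the expected time-locked > continuous ordering). During
adaptation, the user — who corrected 21% of the random-parameter calibration
trajectories by releasing the joystick — no longer needs to correct the
robot once the decoder-weighted IRL has learned the modulation parameters:
here a strongly localized (ρ = 4.0), conservative (η = 2.16) avoidance.

A command-line interface wraps the same loop:

```bash
errpirl synth --out runs/demo --trials 40 --seed 1
errpirl calibrate --out runs/demo --seed 1
errpirl adapt --run runs/demo --batch 3 --seed 1
errpirl report --run runs/demo
```

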
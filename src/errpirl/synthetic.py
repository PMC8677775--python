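"""Synthetic EEG, trajectories and simulated-user behavior.

The generator emulates the statistical structure the decoding and learning
stages rely on, so the whole closed loop is testable without recorded data:

* background EEG = spatially correlated 1/f^1.5 noise + a posterior-leaning
  10 Hz idle (alpha) rhythm, plus EOG channels with occasional blink
  transients that leak into frontal EEG channels;
* an error-related potential (ErrP) template injected at joystick release on
  erroneous trials: fronto-central negativity peaking ~0.01 s after release,
  a positivity ~0.3 s later, and a 4-8 Hz (theta) burst, all with a
  topography peaking at FCz;
* a simulated user who releases the joystick when a trajectory's forthcoming
  obstacle clearance falls below an individual preferred margin, with a
  reaction delay of 1.03 +/- 0.10 s;
* the calibration protocol: ~400 trials with modulation parameters drawn
  uniformly at random, alternating left/right targets, ~25% of trials
  perceived as erroneous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

from .ds import (
    CALIBRATION_ETA_RANGE,
    CALIBRATION_RHO_RANGE,
    ModulationParams,
    SceneSpec,
    TrajectoryPath,
    integrate_trajectory,
    min_clearance,
)
from .eeg import EEG_CHANNELS, EOG_CHANNELS, SAMPLE_RATE, EEGRecording

__all__ = [
    "ErrPTemplate",
    "UserModel",
    "TrialRecord",
    "CalibrationDataset",
    "generate_eeg_trial",
    "simulate_user",
    "generate_calibration_dataset",
    "make_exp1_scene",
    "make_exp2_scenes",
    "scene_start",
]

# Approximate planar 10/10 electrode coordinates (lateral, anterior) used for
# topographies and spatial noise correlation.
_CHANNEL_XY = {
    "Fz": (0.0, 2.0),
    "FC3": (-1.5, 1.0), "FC1": (-0.5, 1.0), "FCz": (0.0, 1.0),
    "FC2": (0.5, 1.0), "FC4": (1.5, 1.0),
    "C3": (-1.5, 0.0), "C1": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C2": (0.5, 0.0), "C4": (1.5, 0.0),
    "CP3": (-1.5, -1.0), "CP1": (-0.5, -1.0), "CPz": (0.0, -1.0),
    "CP2": (0.5, -1.0), "CP4": (1.5, -1.0),
}
_XY = np.array([_CHANNEL_XY[ch] for ch in EEG_CHANNELS])

# Fixed EOG->EEG leakage (frontal channels pick up more ocular activity).
_FRONTALITY = np.exp(-(2.0 - _XY[:, 1]) / 1.5)
EOG_LEAKAGE = np.outer(_FRONTALITY, [0.30, 0.18, 0.18])  # (16, 3)

# Smooth spatial mixing for background noise (nearby channels correlate).
_MIX = np.exp(-0.5 * np.sum((_XY[:, None, :] - _XY[None, :, :]) ** 2, axis=-1))
_MIX /= np.linalg.norm(_MIX, axis=1, keepdims=True)

# Alpha idle rhythm favors the posterior (CP) row.
_ALPHA_GAIN = np.exp(-0.5 * ((_XY[:, 1] + 1.0) / 0.9) ** 2)


def _fcz_topography(width: float = 0.9) -> np.ndarray:
    d2 = np.sum((_XY - np.array(_CHANNEL_XY["FCz"])) ** 2, axis=1)
    topo = np.exp(-d2 / (2.0 * width**2))
    return topo / topo.max()


@dataclass(frozen=True)
class ErrPTemplate:
    """Stereotyped error-related potential injected on erroneous trials.

    Time course is defined over the support [-0.2, 0.6] s relative to the
    joystick release: an early negativity (peak ~0.01 s), a later positivity
    (~0.3 s) and a theta-band (4-8 Hz) burst.  The spatial pattern peaks at
    FCz.  ``amplitude`` is the peak magnitude in microvolts at FCz.
    """

    # Default peak amplitude is calibrated so that decoding accuracy on
    # synthetic data lands in the realistic single-trial regime
    # (time-locked offline accuracy near 0.85): the deterministic template
    # has no trial-to-trial latency/amplitude variability, so a small
    # amplitude against the 10 uV-rms background stands in for the
    # variability of real recordings.
    amplitude: float = 0.6
    support: tuple[float, float] = (-0.2, 0.6)
    topography: np.ndarray = field(default_factory=_fcz_topography)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude time course at times ``t`` (s, relative to release)."""
        t = np.asarray(t, float)
        ern = -1.0 * np.exp(-0.5 * ((t - 0.01) / 0.035) ** 2)
        pe = 0.8 * np.exp(-0.5 * ((t - 0.30) / 0.09) ** 2)
        theta = 0.45 * np.sin(2 * np.pi * 6.0 * (t - 0.05)) * np.exp(
            -0.5 * ((t - 0.18) / 0.12) ** 2
        )
        w = ern + pe + theta
        return np.where((t >= self.support[0]) & (t <= self.support[1]), w, 0.0)


@dataclass(frozen=True)
class UserModel:
    """Simulated user with an individual preferred obstacle clearance.

    The user releases the joystick when the trajectory's forthcoming
    clearance from the obstacle drops below ``preferred_clearance``, after a
    reaction delay ~ Normal(reaction_mean, reaction_sd) truncated at 0.2 s.
    ``release_noise`` is the probability of a spurious (misoperation)
    release on an otherwise acceptable trial.
    """

    preferred_clearance: float = 0.006
    reaction_mean: float = 1.03
    reaction_sd: float = 0.10
    release_noise: float = 0.02

    def __post_init__(self) -> None:
        if self.preferred_clearance < 0:
            raise ValueError("preferred clearance must be nonnegative")
        if self.reaction_mean <= 0:
            raise ValueError("reaction mean must be positive")


class ReleaseDecision(NamedTuple):
    release: bool
    release_time: Optional[float]
    spurious: bool = False


def simulate_user(
    path_preview: TrajectoryPath,
    user: UserModel,
    seed: int | np.random.Generator = 0,
    scene: Optional[SceneSpec] = None,
) -> ReleaseDecision:
    """Decide whether/when the user releases the joystick for a previewed path.

    ``path_preview`` must be a rollout *without* any release applied.  The
    release fires iff the minimum forthcoming clearance is below the user's
    preferred margin; the release time is the first moment the robot is
    approaching the obstacle with a projected clearance violation, plus the
    reaction delay.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scene is None:
        raise ValueError("scene is required to compute clearances")
    d = np.linalg.norm(path_preview.states - scene.obstacle_arr, axis=1)
    clear = d - scene.obstacle_radius
    # suffix minimum: clearance still to come at/after each sample
    forthcoming = np.minimum.accumulate(clear[::-1])[::-1]
    approaching = np.empty_like(clear, dtype=bool)
    approaching[:-1] = np.diff(clear) < 0
    approaching[-1] = False

    violation = approaching & (forthcoming < user.preferred_clearance)
    if np.any(violation):
        k = int(np.argmax(violation))
        delay = max(0.2, rng.normal(user.reaction_mean, user.reaction_sd))
        t_rel = min(float(path_preview.times[k]) + delay, float(path_preview.times[-1]))
        return ReleaseDecision(True, t_rel, False)

    if rng.random() < user.release_noise:
        t_end = float(path_preview.times[-1])
        t_rel = float(rng.uniform(0.3 * t_end, 0.8 * t_end))
        return ReleaseDecision(True, t_rel, True)
    return ReleaseDecision(False, None, False)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float,
                exponent: float = 1.5) -> np.ndarray:
    """Spatially mixed noise with a 1/f^exponent power spectrum."""
    n_fft = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros(n_fft)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, n_fft))
            + 1j * rng.standard_normal((n_channels, n_fft))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True) + 1e-12
    return x


def generate_eeg_trial(
    label: str,
    duration: float,
    template: ErrPTemplate,
    snr: float,
    seed: int | np.random.Generator,
    release_time: Optional[float] = None,
    onset_time: float = 0.5,
    fs: float = SAMPLE_RATE,
    noise_rms: float = 10.0,
    trial_end_time: Optional[float] = None,
) -> EEGRecording:
    """One trial's synthetic EEG/EOG segment.

    ``duration`` is the total recording length (s).  For ``label ==
    'erroneous'`` the ErrP template is injected at ``release_time`` (absolute
    recording time) with peak amplitude ``template.amplitude * snr`` microvolts
    at FCz.  ``snr = 0`` leaves erroneous and correct trials statistically
    indistinguishable.  Fully seeded and reproducible.
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    eeg = noise_rms * (_MIX @ _pink_noise(rng, len(EEG_CHANNELS), n, fs))
    # alpha idle rhythm with slow amplitude modulation
    alpha_env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    alpha = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)) * alpha_env
    eeg += 3.0 * np.outer(_ALPHA_GAIN, alpha)

    # EOG: slow pink noise plus blink transients
    eog = 15.0 * _pink_noise(rng, len(EOG_CHANNELS), n, fs, exponent=2.0)
    n_blinks = rng.poisson(0.1 * duration)
    for _ in range(n_blinks):
        t0 = rng.uniform(0, duration - 0.3)
        idx = (t >= t0) & (t < t0 + 0.25)
        blink = 120.0 * np.sin(np.pi * (t[idx] - t0) / 0.25) ** 2
        eog[0, idx] += blink
        eog[1, idx] += 0.4 * blink
        eog[2, idx] += 0.4 * blink
    eeg += EOG_LEAKAGE @ eog

    events: list[tuple[float, str]] = [(onset_time, "motion_onset")]
    if label == "erroneous":
        if release_time is None:
            raise ValueError("release_time required for erroneous trials")
        events.append((release_time, "release"))
        eeg += (snr * template.amplitude) * np.outer(
            template.topography, template.waveform(t - release_time)
        )
    t_end = duration - 1.0 / fs if trial_end_time is None else trial_end_time
    events.append((t_end, "trial_end"))
    return EEGRecording(fs, eeg, eog, events)


def generate_eog_calibration(
    seed: int | np.random.Generator, duration: float = 90.0, fs: float = SAMPLE_RATE
) -> EEGRecording:
    """Deliberate eye-movement recording used to fit EOG regression weights."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    eeg = 10.0 * (_MIX @ _pink_noise(rng, len(EEG_CHANNELS), n, fs))
    eog = 20.0 * _pink_noise(rng, len(EOG_CHANNELS), n, fs, exponent=2.0)
    # many deliberate blinks / eye movements
    for _ in range(int(duration * 0.8)):
        t0 = rng.uniform(0, duration - 0.4)
        idx = (t >= t0) & (t < t0 + 0.3)
        mov = 150.0 * np.sin(np.pi * (t[idx] - t0) / 0.3) ** 2
        gains = rng.uniform(0.3, 1.0, size=3)
        eog[:, idx] += np.outer(gains, mov)
    eeg += EOG_LEAKAGE @ eog
    return EEGRecording(fs, eeg, eog, [])


# -- scenes ------------------------------------------------------------------

def make_exp1_scene(direction: str = "lr") -> SceneSpec:
    """Single-obstacle left<->right reaching scene (tabletop, meters)."""
    target = (0.4, 0.0) if direction == "lr" else (-0.4, 0.0)
    return SceneSpec(
        target=target,
        obstacle_center=(0.0, 0.0),
        obstacle_diameter=0.12,
        workspace=(-0.6, 0.6, -0.35, 0.5),
        condition_id=f"exp1_{direction}",
    )


def make_exp2_scenes() -> list[SceneSpec]:
    """Eight pick-and-place conditions: 4 target moves x grasp/no-grasp.

    The gripper state only switches the scene layout (a carried object
    enlarges the effective obstacle); no kinematics are modeled.
    """
    targets = [(0.4, 0.0), (-0.4, 0.0), (0.0, 0.35), (0.0, -0.25)]
    scenes = []
    for i, tgt in enumerate(targets):
        for grasp in (False, True):
            diam = 0.12 * (1.3 if grasp else 1.0)
            scenes.append(
                SceneSpec(
                    target=tgt,
                    obstacle_center=(0.0, 0.05),
                    obstacle_diameter=diam,
                    workspace=(-0.6, 0.6, -0.35, 0.5),
                    condition_id=f"exp2_t{i}_{'grasp' if grasp else 'open'}",
                )
            )
    return scenes


def scene_start(scene: SceneSpec) -> np.ndarray:
    """Default start: the target mirrored through the obstacle center."""
    return 2.0 * scene.obstacle_arr - scene.target_arr


# -- calibration protocol ----------------------------------------------------

@dataclass
class TrialRecord:
    """One executed trial: trajectory, behavior label and EEG segment."""

    index: int
    phase: str
    condition_id: str
    params: ModulationParams
    path: TrajectoryPath
    label: str  # 'erroneous' | 'correct'
    corrected: bool
    release_time: Optional[float]  # s, relative to motion onset
    recording: EEGRecording
    spurious: bool = False
    preview_clearance: Optional[float] = None
    weight: Optional[float] = None

    @property
    def onset(self) -> float:
        t = self.recording.event_time("motion_onset")
        assert t is not None
        return t


@dataclass
class CalibrationDataset:
    trials: List[TrialRecord]
    scenes: List[SceneSpec]
    user: UserModel
    manifest: dict

    @property
    def erroneous_fraction(self) -> float:
        labs = [t.label for t in self.trials]
        return labs.count("erroneous") / len(labs)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rec in self.trials:
            stem = f"trial_{rec.index:04d}"
            rec.recording.save_bundle(directory, stem)
            (directory / f"{stem}_path.csv").write_text(rec.path.to_csv())
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def run_trial(
    scene: SceneSpec,
    params: ModulationParams,
    user: UserModel,
    rng: np.random.Generator,
    template: ErrPTemplate,
    snr: float,
    index: int,
    phase: str,
    dt: float = 0.02,
    onset_time: float = 0.5,
) -> TrialRecord:
    """Roll out one trial: preview, user decision, executed path, EEG."""
    start = scene_start(scene)
    preview = integrate_trajectory(start, scene, params, dt=dt)
    decision = simulate_user(preview, user, rng, scene=scene)

    if decision.release:
        t_rel = decision.release_time

        def policy(t, state, vel, _tr=t_rel):
            return t >= _tr

        path = integrate_trajectory(start, scene, params, dt=dt, release_policy=policy)
        release_rel = path.release_time if path.release_time is not None else t_rel
    else:
        path = preview
        release_rel = None

    label = "erroneous" if decision.release else "correct"
    duration = onset_time + path.duration + 1.2
    release_abs = None if release_rel is None else onset_time + release_rel
    inject = label == "erroneous" and not decision.spurious
    recording = generate_eeg_trial(
        label="erroneous" if label == "erroneous" else "correct",
        duration=duration,
        template=template,
        snr=snr if inject else 0.0,
        seed=rng,
        release_time=release_abs,
        onset_time=onset_time,
        trial_end_time=onset_time + path.duration,
    )
    return TrialRecord(
        index=index,
        phase=phase,
        condition_id=scene.condition_id,
        params=params,
        path=path,
        label=label,
        corrected=decision.release,
        release_time=release_rel,
        recording=recording,
        spurious=decision.spurious,
        preview_clearance=min_clearance(preview, scene),
    )


def generate_calibration_dataset(
    scene: SceneSpec,
    user: UserModel,
    n_trials: int = 400,
    seed: int = 0,
    snr: float = 1.0,
    template: Optional[ErrPTemplate] = None,
    dt: float = 0.02,
) -> CalibrationDataset:
    """Calibration phase: random (rho, eta) per trial, alternating directions.

    With the default user model about a quarter of the trials end up
    perceived as erroneous (joystick released), matching the calibration
    statistics the decoder is built from.
    """
    if n_trials < 20:
        raise ValueError("calibration needs at least 20 trials")
    rng = np.random.default_rng(seed)
    template = template or ErrPTemplate()
    mirrored = SceneSpec(
        target=tuple(scene_start(scene)),
        obstacle_center=scene.obstacle_center,
        obstacle_diameter=scene.obstacle_diameter,
        workspace=scene.workspace,
        condition_id=scene.condition_id + "_rev",
    )
    scenes = [scene, mirrored]
    trials = []
    for i in range(n_trials):
        params = ModulationParams(
            rho=rng.uniform(*CALIBRATION_RHO_RANGE),
            eta=rng.uniform(*CALIBRATION_ETA_RANGE),
        )
        rec = run_trial(
            scenes[i % 2], params, user, rng, template, snr, index=i,
            phase="calibration", dt=dt,
        )
        trials.append(rec)
    manifest = {
        "seed": seed,
        "n_trials": n_trials,
        "snr": snr,
        "user": {
            "preferred_clearance": user.preferred_clearance,
            "reaction_mean": user.reaction_mean,
            "reaction_sd": user.reaction_sd,
            "release_noise": user.release_noise,
        },
    }
    return CalibrationDataset(trials=trials, scenes=scenes, user=user, manifest=manifest)
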
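"""Closed-loop orchestration: calibration -> decoder fit -> weighted-IRL adaptation.

The two experimental protocols are simulated end to end:

* **Calibration** — ~400 trials with random modulation parameters drawn from
  homogeneous distributions, alternating reach directions; the simulated
  user releases the joystick on trajectories violating their preferred
  clearance; the recorded synthetic EEG trains the individual ErrP decoder.
* **Adaptation** — per condition, an initial batch of 3 or 5 random-parameter
  demonstrations is weighted by the continuous ErrP decoder
  (w = 1 - P(ErrP)), the weighted GP-IRL fits a reward field and the
  modulation parameters maximizing the on-rollout reward drive subsequent
  trials; the latest five demonstrations retrain the IRL iteratively.
  Experiment 1 uses a single left<->right condition; experiment 2 has eight
  pick-and-place conditions (4 target moves x grasp state), with the grasp
  state modeled purely as a scene switch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .decoder import ErrPDecoder, ErrPDecoderResults, _accuracy, _balanced_accuracy
from .ds import (
    CALIBRATION_ETA_RANGE,
    CALIBRATION_RHO_RANGE,
    ModulationParams,
    min_clearance,
)
from .irl import Demonstration, GPRewardIRL
from .metrics import ParamDistribution, correction_rate, hellinger2_gaussian, kl_gaussian
from .synthetic import (
    CalibrationDataset,
    ErrPTemplate,
    TrialRecord,
    UserModel,
    generate_calibration_dataset,
    generate_eog_calibration,
    make_exp1_scene,
    make_exp2_scenes,
    run_trial,
)

__all__ = [
    "RunConfig",
    "OracleDecoder",
    "CalibrationRun",
    "AdaptationLog",
    "run_calibration",
    "run_adaptation",
    "report",
]


@dataclass
class RunConfig:
    """Configuration of a closed-loop simulation run."""

    seed: int = 0
    experiment: str = "exp1"  # 'exp1' | 'exp2'
    batch_size: int = 3  # IRL initialization batch
    n_calibration_trials: int = 400
    n_adaptation_trials: int = 10  # per condition, including the initial batch
    snr: float = 1.0
    user: UserModel = field(default_factory=UserModel)
    n_folds: int = 10
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.batch_size not in (3, 5):
            raise ValueError("batch size must be 3 or 5")
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError("experiment must be 'exp1' or 'exp2'")
        if self.n_adaptation_trials <= self.batch_size:
            raise ValueError("need more adaptation trials than the initial batch")

    def scenes(self):
        if self.experiment == "exp1":
            return [make_exp1_scene("lr")]
        return make_exp2_scenes()


class OracleDecoder:
    """Ground-truth stand-in for the ErrP decoder in closed-loop analyses.

    Assigns weight ``1 - p_error`` with p_error = 0.95 for corrected and
    0.05 for accepted trials (never exactly 0/1 so every demonstration stays
    in the inducing set).
    """

    def weight_for(self, trial: TrialRecord) -> float:
        return 0.05 if trial.corrected else 0.95


@dataclass
class CalibrationRun:
    dataset: CalibrationDataset
    decoder: ErrPDecoderResults
    report: dict

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "decoder_model.json").write_text(self.decoder.model.to_json())
        (directory / "calibration_report.json").write_text(
            json.dumps(self.report, indent=1, sort_keys=True)
        )


def _trial_weight(decoder, trial: TrialRecord) -> float:
    if isinstance(decoder, OracleDecoder):
        return decoder.weight_for(trial)
    return decoder.trial_weight(trial.recording)


def run_calibration(config: RunConfig) -> CalibrationRun:
    """Calibration phase: synthetic dataset + decoder fit + offline report."""
    scene = config.scenes()[0]
    dataset = generate_calibration_dataset(
        scene, config.user, n_trials=config.n_calibration_trials,
        seed=config.seed, snr=config.snr,
    )
    eog_rec = generate_eog_calibration(seed=config.seed + 1)
    results = ErrPDecoder(
        dataset.trials, eog_recording=eog_rec,
        n_folds=config.n_folds, seed=config.seed,
    ).fit()

    tl_bal = _balanced_accuracy(results.offline_timelock_confusion)
    if tl_bal < 0.5:
        warnings.warn(
            f"decoder below chance on CV (balanced accuracy {tl_bal:.2f}); continuing"
        )
    rep = {
        "n_trials": len(dataset.trials),
        "erroneous_fraction": dataset.erroneous_fraction,
        "rejected_trials": results.rejected_trials,
        "offline_timelock_confusion": results.offline_timelock_confusion.tolist(),
        "offline_continuous_confusion": results.offline_continuous_confusion.tolist(),
        "offline_timelock_accuracy": _accuracy(results.offline_timelock_confusion),
        "offline_continuous_accuracy": _accuracy(results.offline_continuous_confusion),
        "smoothing": results.model.smoothing,
        "threshold": results.model.threshold,
        "seed": config.seed,
    }
    return CalibrationRun(dataset=dataset, decoder=results, report=rep)


@dataclass
class AdaptationLog:
    """Per-trial adaptation log plus learned parameters per condition."""

    trials: List[TrialRecord]
    learned_params: dict  # condition_id -> list of (rho, eta) per retraining
    config: RunConfig
    calibration_trials: Optional[List[TrialRecord]] = None

    @property
    def correction_rate_adaptation(self) -> float:
        post_batch = [t for t in self.trials if t.phase == "adaptation"]
        return correction_rate(post_batch, "adaptation")

    def cluster_distributions(self) -> dict:
        """Gaussian clusters of (rho, eta): erroneous / correct / learned."""
        out = {}
        if self.calibration_trials:
            err = [t.params.as_array() for t in self.calibration_trials if t.corrected]
            cor = [t.params.as_array() for t in self.calibration_trials if not t.corrected]
            if len(err) >= 2:
                out["erroneous"] = ParamDistribution.from_samples(np.array(err), "erroneous")
            if len(cor) >= 2:
                out["correct"] = ParamDistribution.from_samples(np.array(cor), "correct")
        learned = [
            np.asarray(p) for ps in self.learned_params.values() for p in ps
        ]
        if len(learned) >= 2:
            out["learned"] = ParamDistribution.from_samples(np.array(learned), "learned")
        return out

    def divergence_report(self) -> dict:
        clusters = self.cluster_distributions()
        rep: dict = {}
        if {"learned", "correct", "erroneous"} <= clusters.keys():
            rep["kl_learned_vs_correct"] = kl_gaussian(
                clusters["learned"], clusters["correct"]
            )
            rep["kl_learned_vs_erroneous"] = kl_gaussian(
                clusters["learned"], clusters["erroneous"]
            )
            rep["hellinger2_correct_erroneous"] = hellinger2_gaussian(
                clusters["correct"], clusters["erroneous"]
            )
        return rep


def run_adaptation(
    config: RunConfig,
    decoder,
    calibration_trials: Optional[List[TrialRecord]] = None,
) -> AdaptationLog:
    """Adaptation phase under a fitted (or oracle) decoder.

    Per condition: ``batch_size`` random-parameter demonstrations weighted by
    the decoder, GP-IRL fit, then the remaining trials run with the learned
    parameters while the user may still correct; the latest five
    demonstrations retrain the IRL after every trial.  IRL failures fall
    back to the previous parameters (logged).
    """
    rng = np.random.default_rng(config.seed + 1000)
    template = ErrPTemplate()
    trials: List[TrialRecord] = []
    learned: dict = {}
    index = 0
    for scene in config.scenes():
        demos: List[Demonstration] = []
        learned[scene.condition_id] = []
        current: Optional[ModulationParams] = None
        for k in range(config.n_adaptation_trials):
            if k < config.batch_size or current is None:
                params = ModulationParams(
                    rho=rng.uniform(*CALIBRATION_RHO_RANGE),
                    eta=rng.uniform(*CALIBRATION_ETA_RANGE),
                )
                phase = "adaptation_batch" if k < config.batch_size else "adaptation"
            else:
                params = current
                phase = "adaptation"
            rec = run_trial(
                scene, params, config.user, rng, template, config.snr,
                index=index, phase=phase,
            )
            rec.weight = _trial_weight(decoder, rec)
            trials.append(rec)
            demos.append(Demonstration(path=rec.path, weight=rec.weight, scene=scene))
            index += 1

            if k >= config.batch_size - 1:
                window = demos[-5:]
                ws = [d.weight for d in window]
                # Retrain only when the window carries contrast between
                # accepted and corrected demonstrations: an all-accepted (or
                # all-corrected) window says nothing about the preference
                # boundary, and refitting on it lets the parameters drift.
                has_contrast = min(ws) < 0.5 < max(ws)
                if current is not None and not has_contrast:
                    learned[scene.condition_id].append((current.rho, current.eta))
                    continue
                try:
                    fit = GPRewardIRL(window, seed=config.seed).fit()
                    init = current or ModulationParams(1.0, 1.2)
                    current = fit.optimize_modulation(init=init, seed=config.seed)
                    learned[scene.condition_id].append(
                        (current.rho, current.eta)
                    )
                except (ValueError, RuntimeError) as exc:
                    warnings.warn(
                        f"IRL retraining failed ({exc}); keeping previous parameters"
                    )
    return AdaptationLog(
        trials=trials, learned_params=learned, config=config,
        calibration_trials=calibration_trials,
    )


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def adaptation_report(log: AdaptationLog) -> dict:
    rep = {
        "n_trials": len(log.trials),
        "learned_params": {k: [list(p) for p in v] for k, v in log.learned_params.items()},
        "weights": [t.weight for t in log.trials],
        "corrections": [bool(t.corrected) for t in log.trials],
    }
    post = [t for t in log.trials if t.phase == "adaptation"]
    if post:
        rep["adaptation_correction_rate"] = correction_rate(post, "adaptation")
    if log.calibration_trials:
        rep["calibration_correction_rate"] = correction_rate(
            log.calibration_trials, "calibration"
        )
        rep.update(log.divergence_report())
    return rep


def report(run_dir: str | Path) -> dict:
    """Collate a run directory into one summary document (idempotent).

    Missing stages are listed as absent rather than raising.
    """
    run_dir = Path(run_dir)
    summary: dict = {"run_dir": str(run_dir), "absent": []}
    cal = run_dir / "calibration_report.json"
    if cal.exists():
        summary["calibration"] = json.loads(cal.read_text())
    else:
        summary["absent"].append("calibration")
    ada = run_dir / "adaptation_report.json"
    if ada.exists():
        summary["adaptation"] = json.loads(ada.read_text())
    else:
        summary["absent"].append("adaptation")
    onl = run_dir / "online_report.json"
    if onl.exists():
        summary["online"] = json.loads(onl.read_text())
    else:
        summary["absent"].append("online")

    text_lines = [f"Closed-loop run report: {run_dir}"]
    for key in ("calibration", "adaptation", "online"):
        if key in summary:
            text_lines.append(f"[{key}]")
            for k, v in sorted(summary[key].items()):
                if isinstance(v, float):
                    text_lines.append(f"  {k}: {v:.4f}")
                elif not isinstance(v, (list, dict)):
                    text_lines.append(f"  {k}: {v}")
    if summary["absent"]:
        text_lines.append("absent stages: " + ", ".join(summary["absent"]))
    summary["text"] = "\n".join(text_lines)

    (run_dir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (run_dir / "report.txt").write_text(summary["text"] + "\n")
    return summary
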
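"""Evaluation metrics and Gaussian-cluster divergence analyses.

The closed-loop study compares three clusters of modulation parameters
(erroneous = corrected trials, correct = accepted trials, learned = IRL
output), each modeled as a bivariate Gaussian over (rho, eta).  Cluster
similarity is quantified by the Kullback-Leibler divergence (unbounded,
asymmetric) and the squared Hellinger distance (bounded in [0, 1],
symmetric).  Decoder operating points are selected by the Matthews
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParamDistribution",
    "mcc",
    "kl_gaussian",
    "hellinger2_gaussian",
    "correction_rate",
]

_RIDGE = 1e-8  # stabilizes near-degenerate cluster covariances


@dataclass(frozen=True)
class ParamDistribution:
    """Gaussian model of a parameter cluster over (rho, eta)."""

    mean: np.ndarray
    cov: np.ndarray
    label: str = ""

    @classmethod
    def from_samples(cls, samples: np.ndarray, label: str = "") -> "ParamDistribution":
        samples = np.atleast_2d(np.asarray(samples, float))
        mean = samples.mean(axis=0)
        if samples.shape[0] > 1:
            cov = np.cov(samples, rowvar=False)
        else:
            cov = np.zeros((samples.shape[1],) * 2)
        cov = np.atleast_2d(cov) + _RIDGE * np.eye(samples.shape[1])
        return cls(mean=mean, cov=cov, label=label)


def _check_pd(cov: np.ndarray, name: str) -> np.ndarray:
    cov = np.atleast_2d(np.asarray(cov, float))
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} covariance is not positive-definite") from exc
    return cov


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    Layout ``[[TP, FN], [FP, TN]]`` (rows = truth, columns = prediction).
    Defined as 0 when any marginal is zero.
    """
    c = np.asarray(confusion, float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    tp, fn = c[0]
    fp, tn = c[1]
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def kl_gaussian(p: ParamDistribution, q: ParamDistribution) -> float:
    """Closed-form KL divergence KL(p || q) between multivariate Gaussians."""
    cp = _check_pd(p.cov, "p")
    cq = _check_pd(q.cov, "q")
    mp = np.atleast_1d(np.asarray(p.mean, float))
    mq = np.atleast_1d(np.asarray(q.mean, float))
    k = mp.size
    cq_inv = np.linalg.inv(cq)
    diff = mq - mp
    _, logdet_p = np.linalg.slogdet(cp)
    _, logdet_q = np.linalg.slogdet(cq)
    val = 0.5 * (
        np.trace(cq_inv @ cp) + diff @ cq_inv @ diff - k + logdet_q - logdet_p
    )
    return float(val)


def hellinger2_gaussian(p: ParamDistribution, q: ParamDistribution) -> float:
    """Closed-form squared Hellinger distance between multivariate Gaussians.

    Bounded in [0, 1]: 0 for identical distributions, -> 1 as the supports
    stop overlapping.
    """
    cp = _check_pd(p.cov, "p")
    cq = _check_pd(q.cov, "q")
    mp = np.atleast_1d(np.asarray(p.mean, float))
    mq = np.atleast_1d(np.asarray(q.mean, float))
    cm = 0.5 * (cp + cq)
    diff = mp - mq
    _, logdet_p = np.linalg.slogdet(cp)
    _, logdet_q = np.linalg.slogdet(cq)
    _, logdet_m = np.linalg.slogdet(cm)
    # BC = |Sp|^{1/4} |Sq|^{1/4} / |Sm|^{1/2} * exp(-1/8 d^T Sm^{-1} d)
    log_bc = 0.25 * logdet_p + 0.25 * logdet_q - 0.5 * logdet_m - 0.125 * (
        diff @ np.linalg.solve(cm, diff)
    )
    return float(1.0 - np.exp(log_bc))


def correction_rate(trial_log, phase: str) -> float:
    """Fraction of corrected trials in the requested phase.

    ``trial_log`` is an iterable of records with ``phase`` and ``corrected``
    attributes or keys.  Raises ``ValueError`` when the phase is empty
    (reported as missing by callers).
    """

    def get(rec, key):
        return rec[key] if isinstance(rec, dict) else getattr(rec, key)

    trials = [rec for rec in trial_log if get(rec, "phase") == phase]
    if not trials:
        raise ValueError(f"no trials in phase {phase!r}")
    corrected = sum(bool(get(rec, "corrected")) for rec in trials)
    return corrected / len(trials)
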
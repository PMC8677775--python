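"""Single-trial ErrP decoder: preprocessing, epoching, CCA spatial filtering,
84-dimensional features, diagonal LDA and continuous sliding-window decoding.

Pipeline (all causal, suitable for online replay):

1. EOG regression — coefficients from the joint autocovariance of a
   dedicated eye-movement recording; 50 Hz notch; 4th-order causal
   Butterworth band-pass [1, 12] Hz.
2. Epoching — erroneous trials: [0.0, 0.5] s after joystick release;
   correct trials: [1.5, 2.0] s after motion onset.  Erroneous trials whose
   release reaction time deviates from the subject mean by more than 3
   median absolute deviations are rejected.
3. CCA spatial filter (16 -> 3 components) maximizing the correlation
   between single trials and their class-average time courses; the
   erroneous-class grand average in component space is kept as template T.
4. Features per 0.5 s epoch: 48 temporal (components downsampled to 32 Hz),
   15 spectral (Welch power in 5 bands of [1, 12] Hz per component) and 21
   covariance features (upper triangle of the tangent-space projection of
   C_Z, Z = [X T], at the log-Euclidean calibration mean); min-max
   normalized to [0, 1] with calibration bounds.
5. Diagonal LDA posterior p(error | x) = logistic(w.x + b).
6. Continuous decoding: 0.5 s windows stepped at 32 Hz starting at
   [0.25, 0.75] s from onset; causal moving-average smoothing (length h);
   decision when the smoothed posterior exceeds the threshold theta.  The
   (h, theta) pair is selected on a 16 x 101 grid by fold-averaged Matthews
   correlation coefficient under 10-fold cross-validation, then a sigmoid
   recalibration maps theta to an operating threshold of 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import eigh
from scipy.signal import butter, iirnotch, lfilter, resample_poly, welch
from sklearn.model_selection import StratifiedKFold

from .eeg import EEG_CHANNELS, EEGRecording
from .metrics import mcc

__all__ = [
    "Epoch",
    "SpatialFilterModel",
    "DecoderModel",
    "PosteriorTrace",
    "ErrPDecoder",
    "ErrPDecoderResults",
    "estimate_eog_coefficients",
    "preprocess",
    "epoch_trials",
    "fit_spatial_filter",
    "extract_features",
    "fit_classifier",
    "continuous_decode",
    "optimize_hyperparameters",
    "tangent_reference",
    "FEATURE_BLOCKS",
]

FS = 512.0
EPOCH_LEN = 0.5
ERR_WINDOW = (0.0, 0.5)  # s relative to joystick release
COR_WINDOW = (1.5, 2.0)  # s relative to motion onset
DECODE_RATE = 32.0  # posterior estimates per second
FIRST_WINDOW = (0.25, 0.75)  # earliest admissible window (skips visual ERP)
PSD_BANDS = ((1, 3), (3, 5), (5, 7), (7, 9), (9, 12))
N_COMPONENTS = 3
FEATURE_BLOCKS = (48, 15, 21)
SMOOTHING_GRID = np.arange(1, 17)
THRESHOLD_GRID = np.round(np.arange(0, 101) * 0.01, 2)


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def estimate_eog_coefficients(artifact_recording: EEGRecording) -> np.ndarray:
    """EOG->EEG regression coefficients B (3 x 16) from joint autocovariance.

    ``cleaned = eeg - B.T @ eog`` removes the ocular component.  A singular
    EOG covariance triggers a regularized solve with a warning.
    """
    eeg = artifact_recording.eeg - artifact_recording.eeg.mean(axis=1, keepdims=True)
    eog = artifact_recording.eog - artifact_recording.eog.mean(axis=1, keepdims=True)
    n = eeg.shape[1]
    c_oo = eog @ eog.T / n
    c_oe = eog @ eeg.T / n
    try:
        return np.linalg.solve(c_oo, c_oe)
    except np.linalg.LinAlgError:
        warnings.warn("singular EOG covariance; using regularized solve")
        ridge = 1e-8 * np.trace(c_oo) / 3 * np.eye(3)
        return np.linalg.solve(c_oo + ridge, c_oe)


def _filter_coeffs(fs: float):
    b_notch, a_notch = iirnotch(50.0, Q=30.0, fs=fs)
    b_bp, a_bp = butter(4, [1.0, 12.0], btype="bandpass", fs=fs)
    return (b_notch, a_notch), (b_bp, a_bp)


def preprocess(recording: EEGRecording, coeffs: np.ndarray) -> EEGRecording:
    """EOG regression, 50 Hz notch and causal [1, 12] Hz band-pass.

    Strictly causal: the output at time t depends only on samples <= t.
    """
    cleaned = recording.eeg - coeffs.T @ recording.eog
    (bn, an), (bb, ab) = _filter_coeffs(recording.sample_rate)
    cleaned = lfilter(bn, an, cleaned, axis=1)
    cleaned = lfilter(bb, ab, cleaned, axis=1)
    return recording.copy_with(cleaned)


# --------------------------------------------------------------------------
# epoching
# --------------------------------------------------------------------------

@dataclass
class Epoch:
    """Fixed 0.5 s decoder epoch (channels x samples)."""

    data: np.ndarray
    t0: str  # alignment event kind
    window: Tuple[float, float]
    label: str  # 'erroneous' | 'correct'
    trial_index: int = -1


def _slice(rec: EEGRecording, t_start: float) -> Optional[np.ndarray]:
    i0 = int(round(t_start * rec.sample_rate))
    i1 = i0 + int(round(EPOCH_LEN * rec.sample_rate))
    if i0 < 0 or i1 > rec.n_samples:
        return None
    return rec.eeg[:, i0:i1]


def epoch_trials(
    recordings: Sequence[EEGRecording],
    trial_indices: Optional[Sequence[int]] = None,
) -> Tuple[List[Epoch], List[int]]:
    """Cut decoder epochs from per-trial recordings; reject anomalous releases.

    Erroneous trials (with a ``release`` event) are aligned to the release
    over [0.0, 0.5] s; correct trials to motion onset over [1.5, 2.0] s.
    Erroneous trials whose reaction time deviates from the subject's typical
    reaction time by more than 3 median absolute deviations are rejected
    (with a degenerate MAD of zero, only strictly deviating trials are
    rejected).  Returns the kept epochs and
    the rejected trial ids.  Epochs extending past the recording end are
    skipped with a log entry.
    """
    if trial_indices is None:
        trial_indices = list(range(len(recordings)))
    rts, err_ids = [], []
    for idx, rec in zip(trial_indices, recordings):
        onset, release = rec.event_time("motion_onset"), rec.event_time("release")
        if release is not None:
            if onset is None:
                raise ValueError(f"trial {idx}: release without motion onset")
            rts.append(release - onset)
            err_ids.append(idx)

    rejected: List[int] = []
    if rts:
        rts_arr = np.asarray(rts)
        med = np.median(rts_arr)
        mad = np.median(np.abs(rts_arr - med))
        if mad > 0:
            bad = np.abs(rts_arr - med) / mad > 3
        else:
            bad = np.abs(rts_arr - med) > 0
        rejected = [i for i, b in zip(err_ids, bad) if b]

    epochs: List[Epoch] = []
    for idx, rec in zip(trial_indices, recordings):
        if idx in rejected:
            continue
        onset, release = rec.event_time("motion_onset"), rec.event_time("release")
        if release is not None:
            data = _slice(rec, release + ERR_WINDOW[0])
            t0, window, label = "release", ERR_WINDOW, "erroneous"
        else:
            if onset is None:
                continue
            data = _slice(rec, onset + COR_WINDOW[0])
            t0, window, label = "motion_onset", COR_WINDOW, "correct"
        if data is None:
            warnings.warn(f"trial {idx}: epoch extends past recording end; skipped")
            continue
        epochs.append(Epoch(data=data, t0=t0, window=window, label=label, trial_index=idx))
    return epochs, rejected


# --------------------------------------------------------------------------
# spatial filter & features
# --------------------------------------------------------------------------

@dataclass
class SpatialFilterModel:
    """16 -> 3 CCA projection plus the erroneous-class template T (s x 3)."""

    projection: np.ndarray  # (16, 3)
    template: np.ndarray  # (s, 3)

    def apply(self, epoch_data: np.ndarray) -> np.ndarray:
        """Project (16, s) channel data to (s, 3) component space."""
        if epoch_data.shape[0] != len(EEG_CHANNELS):
            raise ValueError(
                f"expected {len(EEG_CHANNELS)}-channel data, got {epoch_data.shape[0]}"
            )
        return epoch_data.T @ self.projection


def fit_spatial_filter(epochs: Sequence[Epoch], labels: Sequence[str]) -> SpatialFilterModel:
    """CCA spatial filter between single trials and class-average time courses.

    Rows of the two CCA views are time samples: view A stacks every trial's
    (s x 16) data, view B repeats the trial's class-average epoch.  The three
    components with the largest canonical correlations are kept; covariances
    are regularized by 1e-6 of their trace.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2 or min(labels.count(c) for c in classes) < 2:
        raise ValueError("need >= 2 trials of each class")
    data = np.stack([ep.data for ep in epochs])  # (n, 16, s)
    means = {c: data[[l == c for l in labels]].mean(axis=0) for c in classes}

    A = np.concatenate([ep.data.T for ep in epochs], axis=0)
    B = np.concatenate([means[l].T for l in labels], axis=0)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    n = A.shape[0]
    caa = A.T @ A / n
    cbb = B.T @ B / n
    cab = A.T @ B / n
    caa += 1e-6 * np.trace(caa) / caa.shape[0] * np.eye(caa.shape[0])
    cbb += 1e-6 * np.trace(cbb) / cbb.shape[0] * np.eye(cbb.shape[0])
    # canonical directions: eigenvectors of Caa^{-1} Cab Cbb^{-1} Cba
    m = np.linalg.solve(caa, cab) @ np.linalg.solve(cbb, cab.T)
    vals, vecs = np.linalg.eig(m)
    order = np.argsort(-vals.real)[:N_COMPONENTS]
    proj = np.real(vecs[:, order])
    # fix sign and scale per component for determinism
    for j in range(proj.shape[1]):
        norm = np.linalg.norm(proj[:, j]) or 1.0
        proj[:, j] /= norm
        if proj[np.argmax(np.abs(proj[:, j])), j] < 0:
            proj[:, j] *= -1

    model = SpatialFilterModel(projection=proj, template=np.zeros((data.shape[2], 3)))
    err_mean = means["erroneous"] if "erroneous" in means else means[classes[0]]
    model.template = model.apply(err_mean)
    return model


def _logm_spd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = eigh(mat)
    vals = np.maximum(vals, 1e-12)
    return (vecs * np.log(vals)) @ vecs.T


def _expm_sym(mat: np.ndarray) -> np.ndarray:
    vals, vecs = eigh(mat)
    return (vecs * np.exp(vals)) @ vecs.T


def _invsqrtm_spd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = eigh(mat)
    vals = np.maximum(vals, 1e-12)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _cz(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Template-augmented covariance C_Z = Z^T Z / s, Z = [X T] (s x 6)."""
    Z = np.concatenate([X, T], axis=1)
    s = Z.shape[0]
    C = Z.T @ Z / s
    vals = np.linalg.eigvalsh(C)
    if vals.min() <= 0:
        warnings.warn("non-positive-definite C_Z; adding trace jitter")
        C = C + 1e-10 * np.trace(C) * np.eye(C.shape[0])
    return C


def tangent_reference(czs: Sequence[np.ndarray]) -> np.ndarray:
    """Log-Euclidean mean of the calibration C_Z matrices."""
    logs = np.mean([_logm_spd(c) for c in czs], axis=0)
    return _expm_sym(logs)


_SQRT2 = np.sqrt(2.0)
_TRIU = np.triu_indices(2 * N_COMPONENTS)


def _tangent_vector(C: np.ndarray, ref_invsqrt: np.ndarray) -> np.ndarray:
    S = _logm_spd(ref_invsqrt @ C @ ref_invsqrt)
    W = S * _SQRT2
    W[np.diag_indices_from(W)] = np.diag(S)
    return W[_TRIU]


@dataclass
class FeatureVector:
    temporal: np.ndarray  # 48
    psd: np.ndarray  # 15
    covariance: np.ndarray  # 21

    @property
    def concatenated(self) -> np.ndarray:
        v = np.concatenate([self.temporal, self.psd, self.covariance])
        assert v.size == sum(FEATURE_BLOCKS)
        return v


def extract_features(
    epoch_data: np.ndarray,
    model: SpatialFilterModel,
    ref_invsqrt: np.ndarray,
    fs: float = FS,
) -> FeatureVector:
    """84-dimensional feature vector of a 0.5 s, 16-channel epoch.

    Blocks: 48 temporal (3 components x 16 samples at 32 Hz), 15 spectral
    (Welch band power in 5 sub-bands of [1, 12] Hz per component), 21
    covariance (tangent-space upper triangle of the template-augmented 6x6
    covariance).  Normalization to [0, 1] happens against calibration bounds
    in the classifier stage.
    """
    X = model.apply(epoch_data)  # (s, 3)
    down = int(round(fs / DECODE_RATE))
    temporal = resample_poly(X, up=1, down=down, axis=0).ravel(order="F")

    # full-epoch segment: 2 Hz resolution so every band in [1, 12] Hz has bins
    freqs, pxx = welch(X, fs=fs, nperseg=X.shape[0], axis=0)
    psd = np.empty(len(PSD_BANDS) * N_COMPONENTS)
    for c in range(N_COMPONENTS):
        for b, (lo, hi) in enumerate(PSD_BANDS):
            band = (freqs >= lo) & (freqs <= hi)
            psd[c * len(PSD_BANDS) + b] = pxx[band, c].mean()

    cov = _tangent_vector(_cz(X, model.template), ref_invsqrt)
    return FeatureVector(temporal=temporal, psd=psd, covariance=cov)


# --------------------------------------------------------------------------
# classifier
# --------------------------------------------------------------------------

def fit_classifier(
    features: np.ndarray, labels: Sequence[str]
) -> Tuple[np.ndarray, float]:
    """Diagonal LDA on [0,1]-normalized features: returns (w, b).

    Posterior p(error | x) = logistic(w.x + b), with pooled per-feature
    variances (floored at 1e-12) and empirical class priors.
    """
    X = np.asarray(features, float)
    y = np.asarray([1 if l == "erroneous" else 0 for l in labels])
    if len(set(y)) < 2:
        raise ValueError("both classes required")
    mu1 = X[y == 1].mean(axis=0)
    mu0 = X[y == 0].mean(axis=0)
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    var = (
        (X[y == 1] - mu1) ** 2).sum(axis=0) + ((X[y == 0] - mu0) ** 2).sum(axis=0)
    var = np.maximum(var / max(n1 + n0 - 2, 1), 1e-12)
    w = (mu1 - mu0) / var
    b = -0.5 * float((mu1**2 - mu0**2) @ (1.0 / var)) + float(np.log(n1 / n0))
    return w, b


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# --------------------------------------------------------------------------
# decoder model & continuous decoding
# --------------------------------------------------------------------------

@dataclass
class DecoderModel:
    """Frozen individual ErrP decoder."""

    spatial_filter: SpatialFilterModel
    tangent_ref: np.ndarray  # (6, 6) SPD reference
    bounds: Tuple[np.ndarray, np.ndarray]  # per-feature (lo, hi)
    w: np.ndarray
    b: float
    smoothing: int = 1
    threshold: float = 0.5
    fs: float = FS

    _ref_invsqrt: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._ref_invsqrt = _invsqrtm_spd(self.tangent_ref)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds
        span = np.where(hi > lo, hi - lo, 1.0)
        return np.clip((x - lo) / span, 0.0, 1.0)

    def features(self, epoch_data: np.ndarray) -> np.ndarray:
        fv = extract_features(epoch_data, self.spatial_filter, self._ref_invsqrt, self.fs)
        return self.normalize(fv.concatenated)

    def posterior(self, epoch_data: np.ndarray) -> float:
        """Raw posterior probability of an ErrP in one 0.5 s epoch."""
        x = self.features(epoch_data)
        return float(_logistic(self.w @ x + self.b))

    def recalibrate(self, p: np.ndarray | float) -> np.ndarray | float:
        """Sigmoid recalibration mapping the tuned threshold to 0.5.

        Monotone, so decisions at the 0.5 operating point equal decisions at
        the raw threshold.
        """
        theta = float(np.clip(self.threshold, 1e-6, 1 - 1e-6))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        logit = np.log(p / (1 - p)) - np.log(theta / (1 - theta))
        return _logistic(logit)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "projection": self.spatial_filter.projection.tolist(),
            "template": self.spatial_filter.template.tolist(),
            "tangent_ref": self.tangent_ref.ravel().tolist(),  # row-major
            "bounds_lo": self.bounds[0].tolist(),
            "bounds_hi": self.bounds[1].tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "smoothing": int(self.smoothing),
            "threshold": float(self.threshold),
            "fs": self.fs,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DecoderModel":
        d = json.loads(text)
        sf = SpatialFilterModel(
            projection=np.asarray(d["projection"]), template=np.asarray(d["template"])
        )
        n = 2 * N_COMPONENTS
        return cls(
            spatial_filter=sf,
            tangent_ref=np.asarray(d["tangent_ref"]).reshape(n, n),
            bounds=(np.asarray(d["bounds_lo"]), np.asarray(d["bounds_hi"])),
            w=np.asarray(d["w"]),
            b=float(d["b"]),
            smoothing=int(d["smoothing"]),
            threshold=float(d["threshold"]),
            fs=float(d["fs"]),
        )


@dataclass
class PosteriorTrace:
    """Continuous decoder output along one trial."""

    times: np.ndarray  # window centers (s, relative to motion onset)
    raw: np.ndarray
    smoothed: np.ndarray
    decision: bool
    decision_time: Optional[float]


def _moving_average(x: np.ndarray, h: int) -> np.ndarray:
    """Causal moving average over the last h decoder outputs."""
    if h <= 1 or x.size == 0:
        return x.astype(float)
    c = np.cumsum(np.insert(x.astype(float), 0, 0.0))
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        j = max(0, i - h + 1)
        out[i] = (c[i + 1] - c[j]) / (i + 1 - j)
    return out


def raw_posterior_trace(
    model: DecoderModel, recording: EEGRecording
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-window raw posteriors over one (preprocessed) trial recording.

    Returns (window centers re onset, raw posteriors); empty when the trial
    is shorter than the first admissible window.
    """
    onset = recording.event_time("motion_onset")
    if onset is None:
        raise ValueError("trial lacks a motion_onset event")
    trial_end = recording.event_time("trial_end")
    t_end = trial_end if trial_end is not None else recording.duration
    step = 1.0 / DECODE_RATE
    starts = []
    t0 = onset + FIRST_WINDOW[0]
    while t0 + EPOCH_LEN <= t_end + 1e-9:
        starts.append(t0)
        t0 += step
    centers, posts = [], []
    for s in starts:
        data = _slice(recording, s)
        if data is None:
            break
        centers.append(s + EPOCH_LEN / 2 - onset)
        posts.append(model.posterior(data))
    return np.asarray(centers), np.asarray(posts)


def continuous_decode(model: DecoderModel, recording: EEGRecording) -> PosteriorTrace:
    """Sliding-window decoding of one trial with smoothing and thresholding.

    Windows are 0.5 s long, stepped at 32 Hz, the first spanning
    [0.25, 0.75] s from motion onset.  The decision fires the first time the
    length-h moving average of the posterior exceeds the decision threshold.
    """
    centers, raw = raw_posterior_trace(model, recording)
    smoothed = _moving_average(raw, model.smoothing)
    above = smoothed > model.threshold
    decision = bool(np.any(above))
    decision_time = float(centers[int(np.argmax(above))]) if decision else None
    return PosteriorTrace(
        times=centers, raw=raw, smoothed=smoothed,
        decision=decision, decision_time=decision_time,
    )


def trial_errp_probability(trace: PosteriorTrace, model: DecoderModel) -> float:
    """Trial-level recalibrated P(ErrP) used for demonstration weights.

    The smoothed posterior at decision time when a decision fired, otherwise
    the maximum smoothed posterior, mapped through the sigmoid recalibration
    so the operating threshold sits at 0.5.
    """
    if trace.raw.size == 0:
        return 0.0
    if trace.decision:
        k = int(np.argmax(trace.smoothed > model.threshold))
        p = trace.smoothed[k]
    else:
        p = float(np.max(trace.smoothed))
    return float(model.recalibrate(p))


# --------------------------------------------------------------------------
# hyperparameter grid
# --------------------------------------------------------------------------

def mcc_grid(
    traces: Sequence[np.ndarray],
    labels: Sequence[str],
    folds: Sequence[int],
) -> np.ndarray:
    """Fold-averaged MCC over the 16 x 101 (smoothing, threshold) grid."""
    y = np.asarray([1 if l == "erroneous" else 0 for l in labels])
    folds = np.asarray(folds)
    uniq = np.unique(folds)
    grid = np.zeros((SMOOTHING_GRID.size, THRESHOLD_GRID.size))
    # per-trial maximum smoothed posterior for each h fully determines the
    # decision at every threshold
    maxima = np.zeros((SMOOTHING_GRID.size, len(traces)))
    for t_i, raw in enumerate(traces):
        for h_i, h in enumerate(SMOOTHING_GRID):
            sm = _moving_average(np.asarray(raw), int(h))
            maxima[h_i, t_i] = sm.max() if sm.size else -np.inf
    for f in uniq:
        sel = folds == f
        y_f = y[sel]
        m_f = maxima[:, sel]
        for h_i in range(SMOOTHING_GRID.size):
            pred = m_f[h_i][None, :] > THRESHOLD_GRID[:, None]  # (101, n_f)
            for th_i in range(THRESHOLD_GRID.size):
                p = pred[th_i]
                conf = np.array(
                    [
                        [np.sum((y_f == 1) & p), np.sum((y_f == 1) & ~p)],
                        [np.sum((y_f == 0) & p), np.sum((y_f == 0) & ~p)],
                    ],
                    float,
                )
                grid[h_i, th_i] += mcc(conf)
    grid /= uniq.size
    return grid


def optimize_hyperparameters(
    traces: Sequence[np.ndarray],
    labels: Sequence[str],
    folds: Sequence[int],
) -> Tuple[int, float, np.ndarray]:
    """Select (h, theta) maximizing the fold-averaged MCC on the 16x101 grid.

    Ties break toward the smallest smoothing, then the smallest threshold.
    Returns (h, theta, grid).
    """
    grid = mcc_grid(traces, labels, folds)
    h_i, th_i = np.unravel_index(int(np.argmax(grid)), grid.shape)
    return int(SMOOTHING_GRID[h_i]), float(THRESHOLD_GRID[th_i]), grid


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

def _fit_pipeline(epochs: List[Epoch]):
    """Spatial filter, tangent reference, normalization bounds and dLDA."""
    labels = [ep.label for ep in epochs]
    sf = fit_spatial_filter(epochs, labels)
    czs = [_cz(sf.apply(ep.data), sf.template) for ep in epochs]
    ref = tangent_reference(czs)
    ref_invsqrt = _invsqrtm_spd(ref)
    raw_feats = np.stack(
        [extract_features(ep.data, sf, ref_invsqrt).concatenated for ep in epochs]
    )
    lo, hi = raw_feats.min(axis=0), raw_feats.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = np.clip((raw_feats - lo) / span, 0.0, 1.0)
    w, b = fit_classifier(norm, labels)
    return DecoderModel(
        spatial_filter=sf, tangent_ref=ref, bounds=(lo, hi), w=w, b=b
    )


class ErrPDecoder:
    """Individual ErrP decoder fit on a calibration dataset.

    Parameters
    ----------
    trials : sequence of TrialRecord (or objects with a ``recording``)
        Calibration trials, one EEG recording each with event markers.
    eog_recording : EEGRecording, optional
        Dedicated eye-movement recording for the EOG regression.  When
        omitted, coefficients are estimated from the pooled trial data.
    n_folds : int
        Stratified cross-validation folds for hyperparameter selection.
    seed : int
        Seed for the CV split (the pipeline itself is deterministic).
    """

    def __init__(self, trials, eog_recording: Optional[EEGRecording] = None,
                 n_folds: int = 10, seed: int = 0):
        self.trials = list(trials)
        self.eog_recording = eog_recording
        self.n_folds = n_folds
        self.seed = seed

    def _recordings(self) -> List[EEGRecording]:
        return [
            t.recording if hasattr(t, "recording") else t for t in self.trials
        ]

    def fit(self) -> "ErrPDecoderResults":
        recs = self._recordings()
        if self.eog_recording is not None:
            coeffs = estimate_eog_coefficients(self.eog_recording)
        else:
            pooled = EEGRecording(
                recs[0].sample_rate,
                np.concatenate([r.eeg for r in recs], axis=1),
                np.concatenate([r.eog for r in recs], axis=1),
                [],
            )
            coeffs = estimate_eog_coefficients(pooled)
        pre = [preprocess(r, coeffs) for r in recs]
        epochs, rejected = epoch_trials(pre)
        labels = [ep.label for ep in epochs]
        y = np.asarray([1 if l == "erroneous" else 0 for l in labels])
        if len(set(labels)) < 2:
            raise ValueError("calibration data must contain both classes")

        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        tl_conf = np.zeros((2, 2))
        cv_traces: List[np.ndarray] = []
        cv_labels: List[str] = []
        cv_folds: List[int] = []
        cv_trial_idx: List[int] = []
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(epochs)), y)):
            model_f = _fit_pipeline([epochs[i] for i in tr])
            for i in te:
                p = model_f.posterior(epochs[i].data)
                pred = p > 0.5
                truth = y[i]
                tl_conf[1 - truth, 0 if pred else 1] += 1
                _, raw = raw_posterior_trace(model_f, pre[epochs[i].trial_index])
                cv_traces.append(raw)
                cv_labels.append(labels[i])
                cv_folds.append(fold)
                cv_trial_idx.append(epochs[i].trial_index)

        h, theta, grid = optimize_hyperparameters(cv_traces, cv_labels, cv_folds)

        # offline-continuous confusion and latency at the selected (h, theta)
        cont_conf = np.zeros((2, 2))
        latencies: List[float] = []
        for raw, lab, t_idx in zip(cv_traces, cv_labels, cv_trial_idx):
            sm = _moving_average(np.asarray(raw), h)
            above = sm > theta
            pred = bool(np.any(above))
            truth = 1 if lab == "erroneous" else 0
            cont_conf[1 - truth, 0 if pred else 1] += 1
            if pred and truth == 1:
                rec = pre[t_idx]
                onset = rec.event_time("motion_onset")
                release = rec.event_time("release")
                centers, _ = raw_posterior_trace_shape(len(raw), onset)
                if release is not None:
                    latencies.append(centers[int(np.argmax(above))] - (release - onset))

        final = _fit_pipeline(epochs)
        final.smoothing = h
        final.threshold = theta

        return ErrPDecoderResults(
            model=final,
            eog_coeffs=coeffs,
            epochs=epochs,
            rejected_trials=rejected,
            offline_timelock_confusion=tl_conf,
            offline_continuous_confusion=cont_conf,
            offline_latencies=np.asarray(latencies),
            mcc_grid_mean=grid,
            cv_traces=cv_traces,
            cv_labels=cv_labels,
            cv_folds=cv_folds,
        )


def raw_posterior_trace_shape(n_windows: int, onset: float):
    """Window centers (re onset) for a trace of known length."""
    step = 1.0 / DECODE_RATE
    centers = FIRST_WINDOW[0] + EPOCH_LEN / 2 + step * np.arange(n_windows)
    return centers, None


def _accuracy(conf: np.ndarray) -> float:
    return float(np.trace(conf) / conf.sum()) if conf.sum() else float("nan")


def _balanced_accuracy(conf: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = conf[0, 0] / conf[0].sum() if conf[0].sum() else np.nan
        tnr = conf[1, 1] / conf[1].sum() if conf[1].sum() else np.nan
    return float((tpr + tnr) / 2)


@dataclass
class ErrPDecoderResults:
    """Fitted decoder plus offline (cross-validated) diagnostics."""

    model: DecoderModel
    eog_coeffs: np.ndarray
    epochs: List[Epoch]
    rejected_trials: List[int]
    offline_timelock_confusion: np.ndarray
    offline_continuous_confusion: np.ndarray
    offline_latencies: np.ndarray
    mcc_grid_mean: np.ndarray
    cv_traces: List[np.ndarray]
    cv_labels: List[str]
    cv_folds: List[int]

    def preprocess(self, recording: EEGRecording) -> EEGRecording:
        return preprocess(recording, self.eog_coeffs)

    def decode_trial(self, recording: EEGRecording, preprocessed: bool = False) -> PosteriorTrace:
        rec = recording if preprocessed else self.preprocess(recording)
        return continuous_decode(self.model, rec)

    def trial_weight(self, recording: EEGRecording, preprocessed: bool = False) -> float:
        """Demonstration weight w = 1 - P(ErrP) for one trial."""
        trace = self.decode_trial(recording, preprocessed)
        return 1.0 - trial_errp_probability(trace, self.model)

    def evaluate_online(self, trials) -> dict:
        """Online-Timelock and Online-Continuous confusions on frozen model."""
        tl = np.zeros((2, 2))
        cont = np.zeros((2, 2))
        latencies = []
        for t in trials:
            rec = self.preprocess(t.recording if hasattr(t, "recording") else t)
            label = getattr(t, "label", None)
            truth = 1 if label == "erroneous" else 0
            epochs, _ = epoch_trials([rec], [0])
            if epochs:
                p = self.model.posterior(epochs[0].data)
                tl[1 - truth, 0 if p > 0.5 else 1] += 1
            trace = continuous_decode(self.model, rec)
            cont[1 - truth, 0 if trace.decision else 1] += 1
            release = rec.event_time("release")
            onset = rec.event_time("motion_onset")
            if trace.decision and truth == 1 and release is not None:
                latencies.append(trace.decision_time - (release - onset))
        return {
            "online_timelock_confusion": tl,
            "online_continuous_confusion": cont,
            "online_latencies": np.asarray(latencies),
        }

    @property
    def timelock_latency(self) -> float:
        """Decision latency of the time-locked mode: the decision becomes
        available at the end of the [0.0, 0.5] s training window."""
        return ERR_WINDOW[1]

    def summary(self) -> str:
        lines = [
            "ErrP decoder summary",
            "====================",
            f"epochs: {len(self.epochs)} "
            f"({sum(ep.label == 'erroneous' for ep in self.epochs)} erroneous), "
            f"rejected trials: {len(self.rejected_trials)}",
            f"selected smoothing h = {self.model.smoothing}, "
            f"threshold theta = {self.model.threshold:.2f} "
            f"(peak fold-averaged MCC = {self.mcc_grid_mean.max():.3f})",
            f"Offline-Timelock accuracy: "
            f"{_accuracy(self.offline_timelock_confusion):.3f} "
            f"(balanced {_balanced_accuracy(self.offline_timelock_confusion):.3f})",
            f"Offline-Continuous accuracy: "
            f"{_accuracy(self.offline_continuous_confusion):.3f} "
            f"(balanced {_balanced_accuracy(self.offline_continuous_confusion):.3f})",
        ]
        if self.offline_latencies.size:
            lines.append(
                f"Offline continuous detection latency: "
                f"{self.offline_latencies.mean():.2f} +/- {self.offline_latencies.std():.2f} s"
            )
        return "\n".join(lines)
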
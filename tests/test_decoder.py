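"""ErrP decoder pipeline: EOG regression, filtering, epoching, CCA, features,
diagonal LDA, continuous decoding and hyperparameter selection."""

import numpy as np
import pytest
from scipy.signal import lfilter

from errpirl.decoder import (
    COR_WINDOW,
    DecoderModel,
    Epoch,
    FEATURE_BLOCKS,
    SMOOTHING_GRID,
    THRESHOLD_GRID,
    _cz,
    _fit_pipeline,
    _invsqrtm_spd,
    _moving_average,
    continuous_decode,
    epoch_trials,
    estimate_eog_coefficients,
    extract_features,
    fit_classifier,
    fit_spatial_filter,
    mcc_grid,
    optimize_hyperparameters,
    preprocess,
    raw_posterior_trace,
    tangent_reference,
)
from errpirl.eeg import EEG_CHANNELS, EEGRecording
from errpirl.metrics import mcc
from errpirl.synthetic import ErrPTemplate, generate_eeg_trial

FS = 512.0


def _recording(eeg, eog, events=()):
    return EEGRecording(FS, eeg, eog, list(events))


def _noise_recording(rng, n, events=()):
    return _recording(rng.standard_normal((16, n)), rng.standard_normal((3, n)),
                      events)


# -- EOG regression ----------------------------------------------------------

def test_eog_coefficients_recover_known_mixing():
    rng = np.random.default_rng(0)
    n = 20 * 512
    eog = rng.standard_normal((3, n))
    clean = rng.standard_normal((16, n))
    eeg = clean.copy()
    eeg[0] += 0.7 * eog[0]  # Fz contaminated by vertical EOG
    B = estimate_eog_coefficients(_recording(eeg, eog))
    assert B[0, 0] == pytest.approx(0.7, abs=0.02)
    # independent signals leave near-zero coefficients elsewhere
    assert np.abs(B[1:, 0]).max() < 0.05
    # cleaned signal has ~zero cross-covariance with EOG
    cleaned = eeg - B.T @ eog
    cross = cleaned @ eog.T / n
    assert np.abs(cross).max() < 0.05


# -- preprocessing -----------------------------------------------------------

def test_preprocess_attenuates_out_of_band_and_is_causal():
    n = int(4 * FS)
    t = np.arange(n) / FS
    zeros_eog = np.zeros((3, n))
    coeffs = np.zeros((3, 16))
    # 25 Hz tone: attenuated by >= 20 dB by the [1, 12] Hz band-pass
    tone = np.tile(np.sin(2 * np.pi * 25.0 * t), (16, 1))
    out = preprocess(_recording(tone, zeros_eog), coeffs)
    rms_in = np.sqrt(np.mean(tone[0, n // 2:] ** 2))
    rms_out = np.sqrt(np.mean(out.eeg[0, n // 2:] ** 2))
    assert 20 * np.log10(rms_in / rms_out) >= 20.0
    # impulse response is identically zero before the impulse
    imp = np.zeros((16, n))
    imp[:, n // 2] = 1.0
    out = preprocess(_recording(imp, zeros_eog), coeffs)
    assert np.allclose(out.eeg[:, : n // 2], 0.0)
    # DC offset decays to zero after the transient (1 Hz high-pass edge)
    dc = np.ones((16, n))
    out = preprocess(_recording(dc, zeros_eog), coeffs)
    assert np.abs(out.eeg[0, -int(FS):]).max() < 1e-2


# -- epoching ----------------------------------------------------------------

def _trial(rng, rt=None, duration=4.0):
    n = int(duration * FS)
    events = [(0.5, "motion_onset"), (duration - 1 / FS, "trial_end")]
    if rt is not None:
        events.insert(1, (0.5 + rt, "release"))
    return _noise_recording(rng, n, events)


def test_mad_rejection_of_anomalous_reaction_time():
    rng = np.random.default_rng(1)
    recs = [_trial(rng, rt) for rt in (1.0, 1.01, 0.99, 1.02, 2.9)]
    epochs, rejected = epoch_trials(recs)
    assert rejected == [4]
    assert len(epochs) == 4


def test_mad_degenerate_identical_rts_keeps_all():
    rng = np.random.default_rng(2)
    recs = [_trial(rng, 1.0) for _ in range(4)]
    epochs, rejected = epoch_trials(recs)
    assert rejected == []
    assert len(epochs) == 4


def test_correct_epoch_window_length():
    rng = np.random.default_rng(3)
    epochs, _ = epoch_trials([_trial(rng, None)])
    ep = epochs[0]
    assert ep.label == "correct"
    assert ep.window == COR_WINDOW
    assert ep.data.shape == (16, 256)  # [1.5, 2.0] s at 512 Hz


def test_epoch_past_recording_end_skipped():
    rng = np.random.default_rng(4)
    short = _trial(rng, rt=3.3, duration=4.0)  # release at 3.8 s, epoch needs 4.3
    with pytest.warns(UserWarning, match="skipped"):
        epochs, _ = epoch_trials([short])
    assert epochs == []


# -- spatial filter ----------------------------------------------------------

def _labeled_epochs(rng, n_per_class=20, source=None):
    s = 256
    epochs = []
    pattern = source if source is not None else rng.standard_normal(16)
    t = np.arange(s) / FS
    evoked = np.sin(2 * np.pi * 4 * t) * np.exp(-((t - 0.25) ** 2) / 0.01)
    for i in range(2 * n_per_class):
        err = i < n_per_class
        data = rng.standard_normal((16, s))
        if err:
            data += 3.0 * np.outer(pattern, evoked)
        epochs.append(Epoch(data=data, t0="release" if err else "motion_onset",
                            window=(0, 0.5), label="erroneous" if err else "correct",
                            trial_index=i))
    return epochs


def test_spatial_filter_three_components_and_source_recovery():
    rng = np.random.default_rng(5)
    pattern = rng.standard_normal(16)
    epochs = _labeled_epochs(rng, source=pattern)
    labels = [e.label for e in epochs]
    model = fit_spatial_filter(epochs, labels)
    assert model.projection.shape == (16, 3)
    assert model.template.shape == (256, 3)
    # component 1 recovers the injected time course
    t = np.arange(256) / FS
    evoked = np.sin(2 * np.pi * 4 * t) * np.exp(-((t - 0.25) ** 2) / 0.01)
    comp1 = model.template[:, 0]
    corr = abs(np.corrcoef(comp1, evoked)[0, 1])
    assert corr > 0.9


def test_spatial_filter_rejects_projected_data():
    rng = np.random.default_rng(6)
    epochs = _labeled_epochs(rng)
    model = fit_spatial_filter(epochs, [e.label for e in epochs])
    projected = model.apply(epochs[0].data)
    with pytest.raises(ValueError):
        model.apply(projected.T)  # 3-channel input is dimension-invalid


def test_spatial_filter_needs_both_classes():
    rng = np.random.default_rng(7)
    epochs = _labeled_epochs(rng, n_per_class=3)[:3]
    with pytest.raises(ValueError):
        fit_spatial_filter(epochs, [e.label for e in epochs])


# -- features ----------------------------------------------------------------

@pytest.fixture(scope="module")
def small_pipeline():
    rng = np.random.default_rng(8)
    epochs = _labeled_epochs(rng, n_per_class=12)
    return _fit_pipeline(epochs), epochs


def test_feature_blocks_and_bounds(small_pipeline):
    model, epochs = small_pipeline
    ref_invsqrt = _invsqrtm_spd(model.tangent_ref)
    fv = extract_features(epochs[0].data, model.spatial_filter, ref_invsqrt)
    assert fv.temporal.shape == (FEATURE_BLOCKS[0],)
    assert fv.psd.shape == (FEATURE_BLOCKS[1],)
    assert fv.covariance.shape == (FEATURE_BLOCKS[2],)
    assert fv.concatenated.shape == (84,)
    x = model.features(epochs[0].data)
    assert np.all((x >= 0.0) & (x <= 1.0))


def test_epoch_equal_to_template_cz_block_structure(small_pipeline):
    model, _ = small_pipeline
    T = model.spatial_filter.template
    C = _cz(T, T)
    # Z = [T T]: the cross block equals the diagonal blocks, rank <= 3
    assert np.allclose(C[:3, 3:], C[:3, :3])
    assert np.allclose(C[3:, 3:], C[:3, :3])
    assert np.linalg.matrix_rank(C, tol=1e-6) <= 3


def test_tangent_reference_is_log_euclidean_mean():
    rng = np.random.default_rng(9)
    mats = []
    for _ in range(4):
        a = rng.standard_normal((6, 6))
        mats.append(a @ a.T + 6 * np.eye(6))
    ref = tangent_reference(mats)
    # oracle: expm of the mean of logms via eigendecompositions
    from scipy.linalg import expm, logm
    oracle = expm(np.mean([logm(m) for m in mats], axis=0))
    assert np.allclose(ref, oracle.real, atol=1e-8)


# -- classifier --------------------------------------------------------------

def test_dlda_separates_and_class_swap_negates():
    rng = np.random.default_rng(10)
    x_err = rng.normal(1.0, 0.2, size=(20, 4))
    x_cor = rng.normal(-1.0, 0.2, size=(20, 4))
    X = np.vstack([x_err, x_cor])
    labels = ["erroneous"] * 20 + ["correct"] * 20
    w, b = fit_classifier(X, labels)
    post = 1 / (1 + np.exp(-(X @ w + b)))
    assert np.all(post[:20] > 0.5)
    assert np.all(post[20:] < 0.5)
    swapped = ["correct"] * 20 + ["erroneous"] * 20
    w2, b2 = fit_classifier(X, swapped)
    assert np.allclose(w2, -w)
    assert b2 == pytest.approx(-b)


def test_dlda_requires_both_classes():
    with pytest.raises(ValueError):
        fit_classifier(np.zeros((4, 2)), ["correct"] * 4)


def test_hand_computed_dlda_four_points():
    # 1-D dataset: erroneous {2, 4}, correct {-2, -4}
    X = np.array([[2.0], [4.0], [-2.0], [-4.0]])
    labels = ["erroneous", "erroneous", "correct", "correct"]
    w, b = fit_classifier(X, labels)
    # pooled variance = (2*1 + 2*1)/2 = 2, w = (3 - (-3))/2 = 3, b = 0
    assert w[0] == pytest.approx(3.0)
    assert b == pytest.approx(0.0, abs=1e-12)


# -- continuous decoding -----------------------------------------------------

def _decoder_with(model, h=1, theta=0.5):
    model.smoothing = h
    model.threshold = theta
    return model


def test_trace_window_count_formula(small_pipeline):
    model, _ = small_pipeline
    rng = np.random.default_rng(11)
    for dur in (3.75, 2.5):
        n = int((0.5 + dur + 0.5) * FS)
        rec = _noise_recording(rng, n, [(0.5, "motion_onset"),
                                        (0.5 + dur, "trial_end")])
        centers, raw = raw_posterior_trace(model, rec)
        expected = int(np.floor((dur - 0.75) * 32)) + 1
        assert len(raw) == expected
        # exhaustive enumeration oracle
        k, t0 = 0, 0.25
        while t0 + 0.5 <= dur + 1e-9:
            k += 1
            t0 += 1 / 32
        assert len(raw) == k
        assert centers[0] == pytest.approx(0.5)


def test_trial_of_exactly_075s_yields_single_window(small_pipeline):
    model, _ = small_pipeline
    rng = np.random.default_rng(12)
    n = int(1.6 * FS)
    rec = _noise_recording(rng, n, [(0.2, "motion_onset"), (0.95, "trial_end")])
    trace = continuous_decode(_decoder_with(model), rec)
    assert len(trace.raw) == 1


def test_short_trial_empty_trace_no_decision(small_pipeline):
    model, _ = small_pipeline
    rng = np.random.default_rng(13)
    n = int(1.0 * FS)
    rec = _noise_recording(rng, n, [(0.2, "motion_onset"), (0.8, "trial_end")])
    trace = continuous_decode(_decoder_with(model), rec)
    assert len(trace.raw) == 0
    assert not trace.decision and trace.decision_time is None


def test_decision_fires_at_first_crossing(small_pipeline):
    model, _ = small_pipeline
    rng = np.random.default_rng(14)
    n = int(4.0 * FS)
    rec = _noise_recording(rng, n, [(0.5, "motion_onset"), (3.0, "trial_end")])
    trace = continuous_decode(_decoder_with(model, h=1, theta=0.0), rec)
    assert trace.decision
    assert trace.decision_time == trace.times[0]


def test_causality_truncated_recording_matches_prefix(small_pipeline):
    model, _ = small_pipeline
    rng = np.random.default_rng(15)
    n = int(4.5 * FS)
    eeg = rng.standard_normal((16, n))
    eog = rng.standard_normal((3, n))
    full = _recording(eeg, eog, [(0.5, "motion_onset"), (4.0, "trial_end")])
    t_cut = 2.5
    n_cut = int(t_cut * FS)
    trunc = _recording(eeg[:, :n_cut], eog[:, :n_cut],
                       [(0.5, "motion_onset"), (t_cut - 1 / FS, "trial_end")])
    coeffs = np.zeros((3, 16))
    _, raw_full = raw_posterior_trace(model, preprocess(full, coeffs))
    _, raw_trunc = raw_posterior_trace(model, preprocess(trunc, coeffs))
    assert np.allclose(raw_full[: len(raw_trunc)], raw_trunc)


def test_moving_average_is_causal_mean_of_last_h():
    x = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
    sm = _moving_average(x, 3)
    expected = [0.0, 0.5, 1 / 3, 2 / 3, 2 / 3]
    assert np.allclose(sm, expected)


# -- hyperparameter grid -----------------------------------------------------

def test_grid_dimensions_and_separable_traces():
    # traces engineered to separate exactly at theta = 0.7
    traces = [np.array([0.75, 0.8, 0.72])] * 6 + [np.array([0.6, 0.65, 0.5])] * 6
    labels = ["erroneous"] * 6 + ["correct"] * 6
    folds = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2]
    h, theta, grid = optimize_hyperparameters(traces, labels, folds)
    assert grid.shape == (16, 101)
    # separation band is [0.65, 0.72); ties break toward the smallest theta
    assert 0.65 <= theta < 0.72
    row = grid[h - 1]
    assert row[int(round(theta * 100))] == pytest.approx(1.0)


def test_grid_argmax_matches_bruteforce_rescan():
    rng = np.random.default_rng(16)
    traces = [rng.uniform(0, 1, size=rng.integers(5, 30)) for _ in range(40)]
    labels = [("erroneous" if rng.random() < 0.3 else "correct") for _ in range(40)]
    folds = list(rng.integers(0, 5, size=40))
    h, theta, grid = optimize_hyperparameters(traces, labels, folds)
    # brute force over all 16 x 101 pairs, re-deriving decisions per trial
    best = (-2.0, None, None)
    for hh in SMOOTHING_GRID:
        for tt in THRESHOLD_GRID:
            vals = []
            for f in sorted(set(folds)):
                conf = np.zeros((2, 2))
                for tr, lab, fo in zip(traces, labels, folds):
                    if fo != f:
                        continue
                    sm = _moving_average(np.asarray(tr), int(hh))
                    pred = bool(np.any(sm > tt))
                    truth = 1 if lab == "erroneous" else 0
                    conf[1 - truth, 0 if pred else 1] += 1
                vals.append(mcc(conf))
            score = float(np.mean(vals))
            if score > best[0] + 1e-12:
                best = (score, int(hh), float(tt))
    assert grid.max() == pytest.approx(best[0])
    assert (h, theta) == (best[1], best[2])


def test_recalibration_preserves_decisions(small_pipeline):
    model, _ = small_pipeline
    model.threshold = 0.37
    p = np.linspace(0.01, 0.99, 99)
    recal = model.recalibrate(p)
    assert np.array_equal(recal > 0.5, p > model.threshold)
    assert model.recalibrate(0.37) == pytest.approx(0.5)


# -- persistence -------------------------------------------------------------

def test_decoder_model_json_roundtrip(small_pipeline):
    model, epochs = small_pipeline
    model.smoothing, model.threshold = 4, 0.62
    back = DecoderModel.from_json(model.to_json())
    assert back.smoothing == 4 and back.threshold == 0.62
    p0 = model.posterior(epochs[0].data)
    assert back.posterior(epochs[0].data) == pytest.approx(p0, rel=1e-12)
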
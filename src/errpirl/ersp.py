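"""Stockwell-transform time-frequency analysis and event-related spectral
perturbation (ERSP).

The S-transform is a Fourier analysis with a frequency-dependent Gaussian
window (time std 1/|f|), giving multiresolution time-frequency maps with
absolutely referenced phase:

    S(tau, f) = |f|/sqrt(2 pi) * integral x(t) exp(-(tau-t)^2 f^2 / 2)
                                          exp(-2 pi i f t) dt

Implementation is the O(N log N) frequency-domain form (FFT, Gaussian voice
window in frequency) with zero-padding so the Gaussian convolution is linear
rather than circular; the direct time-domain sum is kept in the test suite
as the small-n oracle.

The ERSP contrasts mean erroneous-trial power against a correct-trial
baseline band:  ERSP(f, t) = 10 log10( ERS(f, t) / nu(f) ).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter

__all__ = ["TFMap", "stockwell", "ersp", "DEFAULT_FREQS"]

# 1 Hz grid over the [1, 30] Hz analysis band.
DEFAULT_FREQS = np.arange(1.0, 31.0)


@dataclass
class TFMap:
    """Time-frequency map: ``values`` has shape (len(times), len(freqs))."""

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError("values must be (n_times, n_freqs)")

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("time," + ",".join(f"{f:g}Hz" for f in self.freqs) + "\n")
        vals = self.values
        if np.iscomplexobj(vals):
            raise ValueError("CSV serialization supports real-valued maps only")
        for t, row in zip(self.times, vals):
            buf.write(f"{t!r}," + ",".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()


def stockwell(signal: np.ndarray, fs: float, freqs: np.ndarray | None = None) -> TFMap:
    """Discrete S-transform of a real signal at the requested frequencies (Hz).

    Linear in the input.  ``f = 0`` is handled as the signal mean, constant
    over time.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    if np.any(freqs < 0):
        raise ValueError("frequencies must be nonnegative")

    n = x.size
    # pad >= 4x so the Gaussian window convolution is effectively linear
    n_pad = int(2 ** np.ceil(np.log2(4 * n)))
    X = np.fft.fft(x, n_pad)
    nu = np.fft.fftfreq(n_pad, d=1.0 / fs)
    t = np.arange(n) / fs

    out = np.empty((n, freqs.size), dtype=complex)
    for j, f in enumerate(freqs):
        if f == 0:
            out[:, j] = x.mean()
            continue
        voice = np.exp(-2.0 * np.pi**2 * (nu - f) ** 2 / f**2)
        conv = np.fft.ifft(X * voice)[:n]
        out[:, j] = conv * np.exp(-2j * np.pi * f * t)
    return TFMap(times=t, freqs=freqs, values=out)


def _highpass_1hz(epochs: np.ndarray, fs: float) -> np.ndarray:
    """2nd-order causal Butterworth 1 Hz high-pass along the time axis."""
    b, a = butter(2, 1.0, btype="highpass", fs=fs)
    return lfilter(b, a, epochs, axis=-1)


def ersp(
    erroneous_epochs: np.ndarray,
    correct_epochs: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    err_tmin: float = -0.5,
    baseline_window: tuple[float, float] = (0.5, 1.0),
    highpass: bool = True,
) -> TFMap:
    """Event-related spectral perturbation of erroneous trials in dB.

    ``erroneous_epochs`` (n, s_e) are aligned to joystick release over
    [-0.5, 1.0] s; ``correct_epochs`` (m, s_c) are aligned to motion onset
    over [1.0, 2.5] s, and the baseline ``nu(f)`` is their mean power inside
    ``baseline_window`` of the epoch's own time axis (default [0.5, 1.0] s
    into the epoch, i.e. [1.5, 2.0] s after onset).  Frequencies with zero
    baseline are masked (NaN), never +/-inf.
    """
    err = np.atleast_2d(np.asarray(erroneous_epochs, float))
    cor = np.atleast_2d(np.asarray(correct_epochs, float))
    if err.shape[0] < 1 or cor.shape[0] < 1:
        raise ValueError("need at least one epoch per class")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    if highpass:
        err = _highpass_1hz(err, fs)
        cor = _highpass_1hz(cor, fs)

    ers = np.zeros((err.shape[1], freqs.size))
    for ep in err:
        ers += np.abs(stockwell(ep, fs, freqs).values) ** 2
    ers /= err.shape[0]

    i0 = int(round(baseline_window[0] * fs))
    i1 = int(round(baseline_window[1] * fs))
    nu = np.zeros(freqs.size)
    for ep in cor:
        power = np.abs(stockwell(ep, fs, freqs).values) ** 2
        nu += power[i0:i1].mean(axis=0)
    nu /= cor.shape[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 10.0 * np.log10(ers / nu)
    vals[:, nu == 0] = np.nan
    times = err_tmin + np.arange(err.shape[1]) / fs
    return TFMap(times=times, freqs=freqs, values=vals)
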
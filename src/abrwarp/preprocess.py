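"""Pre-processing of averaged evoked responses ahead of registration.

Fixed stage order: band-pass filtering (two high-pass variants), artifact
ranking and epoch selection, inverse-variance weighted averaging with
replicate halves, linear pre-alignment across conditions, cross-fading the
two high-pass variants around 5 ms, and mean/RMS normalization over the
warping window.  Each stage's output is a valid input to the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .warping import TimeWindow

__all__ = [
    "Response",
    "filter_response",
    "select_epochs",
    "weighted_average",
    "crossfade",
    "prealign",
    "apply_lag",
    "normalize",
    "denormalize",
]


@dataclass
class Response:
    """One sampled evoked waveform with its time and normalization metadata.

    ``rms`` and ``mean_offset`` record the factors removed by ``normalize``
    so the original amplitudes (µV) can be restored exactly; ``lag_ms`` is
    the pre-alignment advance applied to this response.
    """

    samples: np.ndarray
    fs: float
    t0_ms: float = 0.0
    rms: float = 1.0
    mean_offset: float = 0.0
    lag_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) / self.fs * 1000.0

    def window_slice(self, window: TimeWindow) -> np.ndarray:
        """Samples falling inside [start_ms, end_ms)."""
        t = self.times_ms
        mask = (t >= window.start_ms - 1e-9) & (t < window.end_ms - 1e-9)
        return self.samples[mask]


def _butter_sos(highpass_hz: float, lowpass_hz: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not 0 < highpass_hz < lowpass_hz < nyq:
        raise ValueError(
            f"need 0 < highpass ({highpass_hz}) < lowpass ({lowpass_hz}) < fs/2 ({nyq})"
        )
    return signal.butter(order, [highpass_hz, lowpass_hz], btype="bandpass", fs=fs, output="sos")


def filter_response(
    x: Response,
    highpass_hz: float,
    lowpass_hz: float,
    order: int = 4,
    phase: str = "zero",
) -> Response:
    """4th-order Butterworth band-pass.

    ``phase='zero'`` filters forward-backward so group delay cannot
    masquerade as response latency; ``phase='causal'`` is a single forward
    pass.
    """
    sos = _butter_sos(highpass_hz, lowpass_hz, x.fs, order)
    if phase == "zero":
        y = signal.sosfiltfilt(sos, x.samples)
    elif phase == "causal":
        y = signal.sosfilt(sos, x.samples)
    else:
        raise ValueError("phase must be 'zero' or 'causal'")
    return replace(x, samples=y)


def filter_matrix(arr: np.ndarray, fs: float, highpass_hz: float, lowpass_hz: float,
                  order: int = 4, phase: str = "zero") -> np.ndarray:
    """Filter each row of a (trials x samples) matrix."""
    sos = _butter_sos(highpass_hz, lowpass_hz, fs, order)
    filt = signal.sosfiltfilt if phase == "zero" else signal.sosfilt
    return filt(sos, np.asarray(arr, dtype=float), axis=-1)


def select_epochs(epochs: np.ndarray, n_keep: int) -> np.ndarray:
    """Keep the n_keep least artefactual epochs by overall maximum |voltage|.

    The stable sort preserves original order among ties, and the selected
    subset retains its original trial order.
    """
    epochs = np.asarray(epochs, dtype=float)
    if n_keep > epochs.shape[0]:
        raise ValueError(f"n_keep={n_keep} exceeds n_trials={epochs.shape[0]}")
    peak = np.max(np.abs(epochs), axis=1)
    keep = np.sort(np.argsort(peak, kind="stable")[:n_keep])
    return epochs[keep]


def _block_weighted_mean(epochs: np.ndarray, block_size: int) -> np.ndarray:
    n_trials = epochs.shape[0]
    n_blocks = n_trials // block_size
    if n_blocks < 1:
        raise ValueError("fewer trials than one block")
    used = epochs[: n_blocks * block_size].reshape(n_blocks, block_size, -1)
    means = used.mean(axis=1)
    resid = used - means[:, None, :]
    var = (resid**2).mean(axis=(1, 2))
    with np.errstate(divide="ignore"):
        w = 1.0 / var
    if np.any(~np.isfinite(w)):
        finite = w[np.isfinite(w)]
        cap = finite.max() if finite.size else 1.0
        w = np.where(np.isfinite(w), w, cap)  # zero-variance block: max finite weight
    w = w / w.sum()
    return w @ means


def weighted_average(epochs: np.ndarray, block_size: int = 250):
    """Inverse-variance block-weighted average plus alternate-half replicates.

    Trials are grouped into consecutive blocks of ``block_size``; each block
    mean is weighted by the inverse of its residual noise variance.  The two
    replicates are the same procedure applied to the odd- and even-indexed
    trials (alternate halves).
    Returns ``(overall, replicate1, replicate2)``.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[0] < 2 * block_size:
        raise ValueError("need at least two blocks of trials")
    overall = _block_weighted_mean(epochs, block_size)
    rep1 = _block_weighted_mean(epochs[0::2], block_size // 2)
    rep2 = _block_weighted_mean(epochs[1::2], block_size // 2)
    return overall, rep1, rep2


def crossfade(
    x_hp150: Response,
    x_hp100: Response,
    center_ms: float = 5.0,
    ramp_ms: float = 2.0,
) -> Response:
    """Cross-fade the 150-Hz-filtered version (early waves) into the
    100-Hz-filtered version (late waves) with a linear ramp centred on
    ``center_ms``: pure hp150 before center - ramp/2, pure hp100 after
    center + ramp/2, weights summing to 1 throughout."""
    if x_hp150.samples.shape != x_hp100.samples.shape or x_hp150.fs != x_hp100.fs:
        raise ValueError("cross-fade inputs must share a grid")
    t = x_hp150.times_ms
    w150 = np.clip((center_ms + ramp_ms / 2.0 - t) / ramp_ms, 0.0, 1.0)
    mixed = w150 * x_hp150.samples + (1.0 - w150) * x_hp100.samples
    return replace(x_hp150, samples=mixed)


def prealign(cond_avg: Response, ref_avg: Response, window: TimeWindow,
             max_lag_ms: float = 6.0) -> float:
    """Lag (ms) by which ``cond_avg`` must be advanced to best match
    ``ref_avg``, maximizing the normalized cross-correlation over the
    window.  Integer-sample resolution; ties break toward the smaller |lag|.
    """
    if cond_avg.fs != ref_avg.fs:
        raise ValueError("sampling rates differ")
    fs = cond_avg.fs
    ref = ref_avg.window_slice(window)
    t = cond_avg.times_ms
    i0 = int(np.argmin(np.abs(t - window.start_ms)))
    n = ref.size
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    if ref.std() == 0:
        raise ZeroDivisionError("flat reference: correlation undefined")
    best = None
    lags = sorted(range(-max_lag, max_lag + 1), key=abs)  # scan small |lag| first
    for lag in lags:
        j0 = i0 + lag
        if j0 < 0 or j0 + n > cond_avg.samples.size:
            continue
        seg = cond_avg.samples[j0 : j0 + n]
        if seg.std() == 0:
            raise ZeroDivisionError("flat response: correlation undefined")
        r = np.corrcoef(ref, seg)[0, 1]
        if best is None or r > best[0] + 1e-12:
            best = (r, lag)
    return best[1] / fs * 1000.0


def apply_lag(x: Response, lag_ms: float) -> Response:
    """Advance a response by an integer-sample lag (edge-padded), recording it."""
    shift = int(round(lag_ms / 1000.0 * x.fs))
    y = np.roll(x.samples, -shift)
    if shift > 0:
        y[-shift:] = x.samples[-1]
    elif shift < 0:
        y[:-shift] = x.samples[0]
    return replace(x, samples=y, lag_ms=x.lag_ms + shift / x.fs * 1000.0)


def normalize(x: Response, window: TimeWindow) -> Response:
    """Mean-correct and scale to unit RMS over the warping window, storing
    the removed factors for exact de-normalization."""
    seg = x.window_slice(window)
    mean = float(seg.mean())
    rms = float(np.sqrt(np.mean((seg - mean) ** 2)))
    if rms == 0.0:
        raise ZeroDivisionError("zero variance within the warping window")
    return replace(
        x,
        samples=(x.samples - mean) / rms,
        rms=x.rms * rms,
        mean_offset=x.mean_offset + mean,
    )


def denormalize(x: Response) -> Response:
    return replace(x, samples=x.samples * x.rms + x.mean_offset, rms=1.0, mean_offset=0.0)
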
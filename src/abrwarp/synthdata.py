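"""Synthetic ABR-like data with known ground-truth warps and controlled SNR.

The generator mirrors the parameter-recovery simulation design: a
prototypical structural response S(t) is de-aligned through the inverses of
random monotone warps to create individual "true" ABRs,
s_i(t) = S(h_i^{-1}(t)), which are scaled and added to band-limited noise,

    x_hat_i(t) = 10^(dsnr/20) * s_i(t) + n_i(t),

with dsnr swept from -21 to 0 dB in 3-dB steps by default.  Registering the
simulated responses and comparing the estimated warps against the stored
h_i gives a direct accuracy measure unavailable with recorded data.

The template is parametric — Gaussian peak/trough pairs for waves I, III
and V — rather than data-derived; it preserves the morphology the method
needs (ordered peak/trough pairs of differing widths and amplitudes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .registration import ResponseSet
from .warping import MonotoneMap, TimeWindow, WarpFunction, build_warp, invert_warp, warp_response

__all__ = [
    "WaveParam",
    "StructuralTemplate",
    "SimulatedDataset",
    "DEFAULT_WAVES",
    "DSNR_GRID",
    "make_template",
    "random_warp",
    "make_noise",
    "plus_minus",
    "simulate_dataset",
]

#: dsnr sweep: -21 to 0 dB in 3-dB steps (8 conditions)
DSNR_GRID = tuple(float(d) for d in np.arange(-21.0, 0.1, 3.0))

#: (label, center_ms, width_ms, peak_amplitude, trough_amplitude) — wave-I
#: peak near 2 ms, wave-III near 4.5 ms, wave-V near 6.5 ms and largest,
#: each followed by its trough about one width later.
DEFAULT_WAVES = (
    ("I", 2.0, 0.7, 0.5, 0.35),
    ("III", 4.5, 0.8, 0.4, 0.3),
    ("V", 6.5, 1.2, 1.0, 0.9),
)


@dataclass(frozen=True)
class StructuralTemplate:
    samples: np.ndarray
    window: TimeWindow
    wave_params: tuple


#: slow-wave recovery following the last trough: (center_ms, width_ms,
#: amplitude).  The vertex-positive slow wave rising after the wave-V/SN10
#: complex keeps the late window from being signal-free, as in recorded
#: responses, so the time axis stays identifiable out to the window edge.
DEFAULT_RECOVERY = (11.0, 3.0, 0.35)


def make_template(
    wave_params=DEFAULT_WAVES,
    window: TimeWindow | None = None,
    fs: float = 16384.0,
    recovery=DEFAULT_RECOVERY,
) -> StructuralTemplate:
    """Sum of Gaussian peak/trough pairs, one per wave, plus a slow recovery.

    Each wave contributes a positive Gaussian bump of SD width/2 at its
    center and a negative one of the trough amplitude one width later,
    giving the vertex-positive peak followed by a trough that picking
    requires.  ``recovery`` adds a broad positive component after the last
    trough (the slow wave); pass None to disable.  The template is rejected
    if any wave loses its extrema (e.g. zero amplitudes or fully
    overlapping components).
    """
    if window is None:
        window = TimeWindow.from_fs(0.0, 12.0, fs)
    t = window.times_ms
    y = np.zeros_like(t)
    if recovery is not None:
        rc, rw, ra = recovery
        y += ra * np.exp(-0.5 * ((t - rc) / (rw / 2.0)) ** 2)
    for label, center, width, peak_amp, trough_amp in wave_params:
        if not window.start_ms < center < window.end_ms:
            raise ValueError(f"wave {label}: center {center} ms outside window")
        if width <= 0:
            raise ValueError(f"wave {label}: width must be positive")
        s = width / 2.0
        y += peak_amp * np.exp(-0.5 * ((t - center) / s) ** 2)
        y -= trough_amp * np.exp(-0.5 * ((t - center - width) / s) ** 2)
    interior = y[1:-1]
    n_max = int(np.sum((interior > y[:-2]) & (interior > y[2:])))
    n_min = int(np.sum((interior < y[:-2]) & (interior < y[2:])))
    if n_max < len(wave_params) or n_min < len(wave_params):
        raise ValueError("degenerate wave parameters: template lost required extrema")
    return StructuralTemplate(y, window, tuple(wave_params))


def random_warp(
    K: int,
    magnitude: float,
    rng: np.random.Generator | int,
    window: TimeWindow,
    n_grid: int | None = None,
) -> WarpFunction:
    """Warp with i.i.d. uniform coefficients on [-magnitude, +magnitude].

    Built through the log-derivative construction, so any draw is strictly
    increasing and endpoint-pinned.  magnitude 0.3 yields latency shifts of
    roughly +/-0.5 ms on a 12-ms window.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coeffs = rng.uniform(-magnitude, magnitude, size=K)
    return build_warp(coeffs, window, n_grid)


def make_noise(
    n_traces: int,
    window: TimeWindow,
    fs: float,
    band: tuple = (100.0, 2000.0),
    rng: np.random.Generator | int = 0,
    psd_slope: float = 2.0,
) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS over the window, one column per
    trace.

    The in-band spectrum falls as 1/f^``psd_slope`` (default 2, the usual
    model for scalp EEG/EMG background above ~100 Hz; pass 0 for a flat
    band).  Gaussian noise is synthesized on a 4x-length buffer, spectrally
    shaped, zero-phase band-pass filtered, and center-cropped, avoiding
    filter edge transients in the short window.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = window.n_samples
    buf = max(4 * n, 512)
    white = rng.standard_normal((buf, n_traces))
    if psd_slope != 0.0:
        spec = np.fft.rfft(white, axis=0)
        f = np.fft.rfftfreq(buf, 1.0 / fs)
        # amplitude ~ f^(-slope/2); flat below the band edge so the shaping
        # never blows up toward DC (the band-pass removes it anyway)
        shape = np.where(f > 0, np.maximum(f, lo) ** (-psd_slope / 2.0), 0.0)
        white = np.fft.irfft(spec * shape[:, None], n=buf, axis=0)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, white, axis=0)
    start = (buf - n) // 2
    out = filtered[start : start + n]
    rms = np.sqrt((out**2).mean(axis=0, keepdims=True))
    return out / rms


def plus_minus(rep1: np.ndarray, rep2: np.ndarray) -> np.ndarray:
    """Plus-minus reference n(t) = (x1(t) - x2(t)) / 2: cancels the evoked
    signal shared by two replicate averages, leaving a noise estimate."""
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if rep1.shape != rep2.shape:
        raise ValueError("replicate shapes differ")
    return (rep1 - rep2) / 2.0


@dataclass
class SimulatedDataset:
    """Simulated responses plus the ground truth they were built from."""

    window: TimeWindow
    template: StructuralTemplate
    true_warps: list
    true_abrs: np.ndarray  # (n_samples, n_subjects), already SNR-scaled s_i
    noise_traces: np.ndarray
    dsnr_grid: tuple
    responses: dict  # dsnr -> (n_samples, n_subjects)
    replicates: dict  # dsnr -> (rep1, rep2)
    seed: int
    true_latencies_ms: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.true_abrs.shape[1]

    def as_response_set(self, dsnr_subset=None, with_replicates: bool = True) -> ResponseSet:
        """ResponseSet view with dsnr values as condition labels; the highest
        dsnr (best SNR) is the warping target, as in the measured data."""
        conds = list(self.dsnr_grid if dsnr_subset is None else dsnr_subset)
        return ResponseSet(
            window=self.window,
            subjects=list(range(self.n_subjects)),
            data={d: self.responses[d].copy() for d in conds},
            target_condition=max(conds),
            replicates=(
                {d: (self.replicates[d][0].copy(), self.replicates[d][1].copy()) for d in conds}
                if with_replicates and self.replicates
                else {}
            ),
        )


def simulate_dataset(
    template: StructuralTemplate | None = None,
    n_subjects: int = 10,
    warp_magnitude: float = 0.3,
    dsnr_grid=DSNR_GRID,
    seed: int = 0,
    K: int = 13,
    baseline_snr_db: float = 10.7,
    noise_rms: float = 1.0,
    noise_band: tuple = (100.0, 2000.0),
    fs: float = 16384.0,
    with_replicates: bool = True,
) -> SimulatedDataset:
    """Generate the full simulated dataset.

    Per subject: draw h_i, de-align the template, s_i = S(h_i^{-1}(t)); per
    dsnr condition: x_hat_i = 10^(dsnr/20) * s_i + n_i, with one noise trace
    per subject shared across the dsnr sweep (only the signal is scaled).
    The template is scaled once so that rms(s_i)/rms(n_i) at dsnr = 0
    equals ``baseline_snr_db`` (default 10.7 dB, placing the sweep over
    roughly -10..+11 dB as in real supra-threshold recordings).  Replicate
    pairs share s_i but carry independent noises of sqrt(2) higher RMS
    (half-trial averages).  ``noise_rms=0`` yields a noiseless dataset.

    A single seed fans out to per-subject child streams, so regeneration is
    bit-identical and subject subsets are independently reproducible.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    dsnr_grid = tuple(float(d) for d in dsnr_grid)
    if not dsnr_grid:
        raise ValueError("dsnr grid must be non-empty")
    if template is None:
        template = make_template(fs=fs)
    window = template.window
    ss = np.random.SeedSequence(seed)
    warp_ss, noise_ss, rep_ss = ss.spawn(3)
    warp_rngs = [np.random.default_rng(s) for s in warp_ss.spawn(n_subjects)]

    gain = 10.0 ** (baseline_snr_db / 20.0) / np.sqrt(np.mean(template.samples**2))
    true_warps = []
    abrs = np.empty((window.n_samples, n_subjects))
    for i in range(n_subjects):
        h = random_warp(K, warp_magnitude, warp_rngs[i], window)
        true_warps.append(h)
        abrs[:, i] = gain * warp_response(template.samples, invert_warp(h))

    noise = noise_rms * make_noise(n_subjects, window, fs, noise_band, np.random.default_rng(noise_ss))
    responses = {}
    replicates = {}
    if with_replicates:
        rep_rng = np.random.default_rng(rep_ss)
        rep_noise = [
            np.sqrt(2.0) * noise_rms * make_noise(n_subjects, window, fs, noise_band, rep_rng)
            for _ in range(2)
        ]
    for d in dsnr_grid:
        scale = 10.0 ** (d / 20.0)
        responses[d] = scale * abrs + noise
        if with_replicates:
            replicates[d] = tuple(scale * abrs + rn for rn in rep_noise)

    # ground-truth wave latencies: template extrema mapped through each h_i
    latencies = {}
    t_ms = window.times_ms
    for label, center, width, _pa, _ta in template.wave_params:
        i_peak = int(np.argmin(np.abs(t_ms - center)))
        lo = max(i_peak - 5, 1)
        hi = min(i_peak + 6, window.n_samples - 1)
        i_peak = lo + int(np.argmax(template.samples[lo:hi]))
        t_peak = window.grid[i_peak]
        latencies[label] = [float(window.to_ms(h(t_peak))) for h in true_warps]

    return SimulatedDataset(
        window=window,
        template=template,
        true_warps=true_warps,
        true_abrs=abrs,
        noise_traces=noise,
        dsnr_grid=dsnr_grid,
        responses=responses,
        replicates=replicates,
        seed=seed,
        true_latencies_ms=latencies,
    )
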
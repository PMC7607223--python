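"""Structural peak/trough picking and individual latency/amplitude recovery.

Waves are picked once, on the structural grand-average response (the average
of the per-condition structural averages).  Individual amplitudes are read
off the *aligned* responses at the structural latencies; individual
latencies come from evaluating each fitted warping function at the
structural peak latency, converting back to milliseconds, and re-adding the
linear pre-alignment lag of the response's condition.  Every subject thus
receives a measure for every picked wave — there is no search-window
exclusion and hence no selection bias toward group-average latencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .registration import RegistrationResult
from .warping import TimeWindow

__all__ = ["WavePick", "pick_structural_extrema", "individual_measures"]


@dataclass(frozen=True)
class WavePick:
    """Structural peak and trough latencies for one wave, in window-ms and
    normalized time."""

    wave: str
    t_peak_ms: float
    t_trough_ms: float
    t_peak: float
    t_trough: float

    def __post_init__(self) -> None:
        if self.t_trough_ms <= self.t_peak_ms:
            raise ValueError(f"wave {self.wave}: trough must follow peak")


def make_pick(wave: str, t_peak_ms: float, t_trough_ms: float, window: TimeWindow) -> WavePick:
    """Build a pick from user-supplied millisecond latencies."""
    return WavePick(
        wave,
        t_peak_ms,
        t_trough_ms,
        float(window.to_norm(t_peak_ms)),
        float(window.to_norm(t_trough_ms)),
    )


def pick_structural_extrema(
    grand_avg: np.ndarray,
    window: TimeWindow,
    search_windows: dict,
) -> list[WavePick]:
    """Pick each wave's peak and following trough in the structural average.

    ``search_windows`` maps a wave label to ``(peak_window, trough_window)``
    TimeWindows (or a single TimeWindow used for both).  The peak is the
    largest local maximum inside the peak window, the trough the smallest
    local minimum after the peak inside the trough window.  A wave with no
    local extremum in its window is reported unpicked (never silently the
    window edge); equal-height extrema break toward the earlier latency.
    """
    grand_avg = np.asarray(grand_avg, dtype=float)
    if grand_avg.size != window.n_samples:
        raise ValueError("grand average must be sampled on the warping grid")
    t_ms = window.times_ms
    maxima = argrelextrema(grand_avg, np.greater_equal, order=1)[0]
    minima = argrelextrema(grand_avg, np.less_equal, order=1)[0]
    # drop flat-run duplicates and window-edge artefacts
    maxima = maxima[(maxima > 0) & (maxima < grand_avg.size - 1)]
    minima = minima[(minima > 0) & (minima < grand_avg.size - 1)]
    picks = []
    for wave, wins in search_windows.items():
        pk_win, tr_win = wins if isinstance(wins, tuple) else (wins, wins)
        cand = maxima[(t_ms[maxima] >= pk_win.start_ms) & (t_ms[maxima] <= pk_win.end_ms)]
        if cand.size == 0:
            raise ValueError(f"wave {wave}: no local maximum in its search window")
        i_peak = cand[np.argmax(grand_avg[cand])]  # argmax: first (earliest) on ties
        cand_tr = minima[
            (t_ms[minima] >= tr_win.start_ms)
            & (t_ms[minima] <= tr_win.end_ms)
            & (minima > i_peak)
        ]
        if cand_tr.size == 0:
            raise ValueError(f"wave {wave}: no local minimum after the peak in its window")
        i_trough = cand_tr[np.argmin(grand_avg[cand_tr])]
        picks.append(
            WavePick(
                wave,
                float(t_ms[i_peak]),
                float(t_ms[i_trough]),
                float(window.grid[i_peak]),
                float(window.grid[i_trough]),
            )
        )
    return picks


def individual_measures(
    result: RegistrationResult,
    picks: list[WavePick],
    lags_ms: dict | None = None,
    rms_factors: dict | None = None,
) -> pd.DataFrame:
    """Per-subject, per-condition, per-wave latencies and amplitudes.

    amplitude = x*_i(t_peak) - x*_i(t_trough) on the aligned response
    (normalized units; ``amplitude_uv`` additionally rescales by the stored
    RMS factor when provided).  latency = h_i(t_peak) mapped back to
    milliseconds plus the condition's pre-alignment lag.
    """
    window = result.window
    grid = window.grid
    lags_ms = lags_ms or {}
    rows = []
    for cond, arr in result.aligned.items():
        lag = float(lags_ms.get(cond, 0.0))
        for i, subject in enumerate(result.subjects):
            warp = result.warps[cond][i]
            for pick in picks:
                amp = float(
                    np.interp(pick.t_peak, grid, arr[:, i])
                    - np.interp(pick.t_trough, grid, arr[:, i])
                )
                latency = float(window.to_ms(warp(pick.t_peak))) + lag
                rms = None if rms_factors is None else rms_factors.get((subject, cond))
                rows.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "wave": pick.wave,
                        "latency_ms": latency,
                        "amplitude": amp,
                        "amplitude_uv": amp * rms if rms is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)
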
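"""Alignment-quality metrics and cross-validation diagnostics.

Response deviation summarizes cross-subject variability: the pointwise
standard deviation across subjects of the (mean-corrected, RMS-normalized)
responses, averaged over the warping window and across conditions.  Aligning
shrinks it; how *much* of the shrinkage reflects the evoked response rather
than noise is what the replicate diagnostics resolve.  Replicates share the
same underlying ABR but carry independent noise, so

* noise_alignment = deviation(cross-warped) - deviation(same-warped)
* abr_alignment   = deviation(original)     - deviation(cross-warped)

separate noise over-alignment from genuine response alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .registration import ReplicateWarps
from .warping import MonotoneMap

__all__ = [
    "DeviationReport",
    "response_deviation",
    "replicate_deviations",
    "warp_accuracy",
    "snr_db",
    "selection_bias_binomial",
]


@dataclass
class DeviationReport:
    variant: str
    pointwise_sd: dict
    response_deviation: float


def _normalize_columns(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    arr = arr - arr.mean(axis=0, keepdims=True)
    rms = np.sqrt((arr**2).mean(axis=0, keepdims=True))
    if np.any(rms == 0):
        raise ZeroDivisionError("flat response cannot be RMS-normalized")
    return arr / rms


def response_deviation(data: dict | np.ndarray, variant: str = "original") -> DeviationReport:
    """Mean pointwise cross-subject SD of normalized responses.

    ``data`` maps condition to an (n_samples, n_subjects) array (a bare
    array is treated as a single condition).  Each response is mean-corrected
    and RMS-normalized over the window before the SD is taken, so the metric
    is invariant to per-response affine amplitude changes.  Conditions are
    weighted equally in the final scalar.
    """
    if isinstance(data, np.ndarray):
        data = {"_": data}
    pointwise = {}
    per_cond = []
    for cond, arr in data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("need >= 2 subjects per condition")
        sd = _normalize_columns(arr).std(axis=1, ddof=1)
        pointwise[cond] = sd
        per_cond.append(sd.mean())
    return DeviationReport(variant, pointwise, float(np.mean(per_cond)))


def replicate_deviations(reps: ReplicateWarps) -> dict:
    """Deviation scalars of the original, same- and cross-warped replicate
    sets, plus the derived noise/ABR alignment indices.  Each scalar pools
    the two replicate variants (e.g. same-warped = mean of the 11- and
    22-warped deviations)."""
    dev = lambda a, b, name: float(
        np.mean(
            [
                response_deviation(a, name).response_deviation,
                response_deviation(b, name).response_deviation,
            ]
        )
    )
    sd_same = dev(reps.same11, reps.same22, "same_warped")
    sd_cross = dev(reps.cross21, reps.cross12, "cross_warped")
    sd_orig = dev(reps.original1, reps.original2, "original")
    return {
        "sd_same": sd_same,
        "sd_cross": sd_cross,
        "sd_original": sd_orig,
        "noise_alignment": sd_cross - sd_same,
        "abr_alignment": sd_orig - sd_cross,
    }


def warp_accuracy(h_true: MonotoneMap, h_est: MonotoneMap) -> tuple[float, bool]:
    """Correlation of the warps' deviations from identity.

    Returns ``(rho, degenerate)`` where rho is the Pearson correlation
    between h_est(t) - t and h_true(t) - t on the shared grid.  If both
    warps are identities the accuracy is 1.0 by convention; if only one is,
    the correlation is undefined (NaN).  Both cases set ``degenerate``.
    """
    if h_true.grid.shape != h_est.grid.shape:
        raise ValueError("grid mismatch")
    a = h_true.values - h_true.grid
    b = h_est.values - h_est.grid
    # identity warps deviate by 0 everywhere (up to rounding)
    ident_a = np.max(np.abs(a)) < 1e-9
    ident_b = np.max(np.abs(b)) < 1e-9
    if ident_a and ident_b:
        return 1.0, True
    if ident_a or ident_b:
        return float("nan"), True
    return float(np.corrcoef(a, b)[0, 1]), False


def snr_db(sig: np.ndarray, noise: np.ndarray) -> float:
    """RMS signal-to-noise ratio in dB over the (shared) window grid."""
    sig = np.asarray(sig, dtype=float)
    noise = np.asarray(noise, dtype=float)
    rms_n = np.sqrt(np.mean(noise**2))
    if rms_n == 0:
        raise ZeroDivisionError("zero-RMS noise")
    return float(20.0 * np.log10(np.sqrt(np.mean(sig**2)) / rms_n))


def selection_bias_binomial(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial test p-value (null success probability 0.5).

    Quantifies how unlikely a k-vs-(n-k) split of excluded subjects is under
    chance, i.e. whether a search-window exclusion rule is selective.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binomtest(k, n, p, alternative="two-sided").pvalue)
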
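# abrwarp

Automated extraction of auditory brainstem response (ABR) wave latencies and
amplitudes by continuous monotone curve registration.

## The problem

ABRs are scalp-recorded potentials evoked in the first ~10 ms after a
transient sound: a series of waves (I–V) from successive stations of the
subcortical auditory pathway.  Measuring a wave's amplitude only makes sense
at that wave's latency in *each individual* response — but latencies vary
across subjects and conditions, and the usual workflow (an expert picking
peaks and troughs by eye, or derivative zero-crossings inside fixed search
windows) is slow, subjective, and — in the search-window case — creates a
selection bias toward group-average latencies by excluding exactly the
subjects with extreme latencies.

`abrwarp` instead aligns the whole set of responses with smooth, strictly
increasing time warps; waves are picked **once**, on the structural average
of the aligned responses, and every subject's latency and amplitude is
recovered through their (invertible) warp.  No subject is ever excluded for
having an unusual latency.

## The model

Each response `x_i(t)` on the normalized warping window `t ∈ [0, 1]`
(0–12 ms by default) is aligned to a target via a warping function `h_i`
built from the log-derivative expansion

    ln h_i'(t) = w_i(t) = Σ_k c_ik B_k(t),
    h_i(t) = A + B ∫₀ᵗ exp{w_i(u)} du,   h_i(0)=0, h_i(1)=1,

with `B_k` linear B-splines on `K = 13` equally spaced knots (1-ms spacing).
Because `exp{w} > 0`, `h_i` is strictly increasing — and hence invertible —
for *any* coefficient vector the optimizer proposes.  Coefficients are
fitted by minimizing one of four penalized criteria between the warped
response `x_i*(t) = x_i{h_i(t)}` and the target `y(t)`:

| criterion | data term | rationale |
|---|---|---|
| `psd`  | `∫ (y − x*)² dt` | classic squared difference |
| `psdd` | `∫ (y′ − x*′)² dt` | aligns rises/falls, robust to offsets |
| `pmc`  | `−ρ(y, x*)` | amplitude-scale free |
| `pmcd` | `−ρ(y′, x*′)` | both of the above |

each plus the roughness penalty `λ ∫ w′(t)² dt`, which shrinks the warp's
relative curvature `h″/h′` (λ ∈ {0, 0.001, 0.01, 0.1, 1}).  Two procedures
register a whole set: **average-target** (`at`; warp everyone to the
cross-sectional average, then once more to the resulting structural
average) and **pairwise** (`pw`; warp each response to every other subject's
target response and average the warps pointwise).  Replicate
cross-validation (same- vs cross-warped alternate-half replicates)
quantifies how much of the apparent alignment is noise being over-fitted.

A synthetic-data module generates ABR-like datasets (three Gaussian
peak/trough wave complexes plus a slow-wave recovery, de-aligned by random
monotone warps, in 1/f²-band-limited noise at a controlled SNR sweep) with
stored ground-truth warps, so the whole pipeline is testable without any
recordings.

## Worked example

```python
import numpy as np
from abrwarp import (LossConfig, TimeWindow, individual_measures,
                     pick_structural_extrema, register_at,
                     response_deviation, simulate_dataset, warp_accuracy)

sim = simulate_dataset(n_subjects=10, warp_magnitude=0.3,
                       dsnr_grid=[-9.0, 0.0], seed=1)
rset = sim.as_response_set(with_replicates=False)
result = register_at(rset, LossConfig("psdd", 0.0))

dev_o = response_deviation(rset.data).response_deviation
dev_a = response_deviation(result.aligned).response_deviation
print(f"response deviation: original {dev_o:.3f} -> aligned {dev_a:.3f}")

acc = np.nanmean([warp_accuracy(sim.true_warps[i], result.warps[0.0][i])[0]
                  for i in range(10)])
print(f"mean warp accuracy vs ground truth (dsnr=0): {acc:.3f}")

picks = pick_structural_extrema(
    result.structural_grand_avg, rset.window,
    {"I": (TimeWindow(1, 3.5, 2), TimeWindow(1.5, 4.5, 2)),
     "V": (TimeWindow(5, 8, 2), TimeWindow(6, 10, 2))})
for p in picks:
    print(f"wave {p.wave}: structural peak {p.t_peak_ms:.2f} ms, "
          f"trough {p.t_trough_ms:.2f} ms")
measures = individual_measures(result, picks)
print(measures.head(4).round(2).to_string(index=False))
```

prints:

```text
response deviation: original 0.590 -> aligned 0.392
mean warp accuracy vs ground truth (dsnr=0): 0.583
wave I: structural peak 2.08 ms, trough 2.94 ms
wave V: structural peak 6.37 ms, trough 7.78 ms
 subject  condition wave  latency_ms  amplitude  amplitude_uv
       0       -9.0    I        2.07       2.38           NaN
       0       -9.0    V        5.88       8.21           NaN
       1       -9.0    I        2.26       3.57           NaN
       1       -9.0    V        6.77       7.37           NaN
```

The deviation drop (0.590 → 0.392) is the cross-subject pointwise standard
deviation of the normalized responses shrinking as the ABRs are aligned;
the warp accuracy is the correlation `ρ(ĥ(t)−t, h(t)−t)` between estimated
and ground-truth warps at the best SNR; the table is the first rows of the
tidy per-subject measures (10 subjects × 2 conditions × 2 waves = 40 rows;
latencies in ms on each subject's original time axis, amplitudes as
peak-minus-trough in the responses' units — `amplitude_uv` is only filled
when stored RMS normalization factors are supplied for back-scaling).

The same pipeline is scriptable from the shell:

```bash
abrwarp simulate --seed 1 --n-subjects 10 --out-dir runs/sim
abrwarp register --procedure at --criterion psdd --lambda 0 \
    --target-condition +0 --in-dir runs/sim --out-dir runs/reg
abrwarp extract --result-dir runs/reg --auto-pick \
    --window I:1-3.5:1.5-4.5 --window V:5-8:6-10 --out runs/measures.csv
abrwarp validate --in-dir runs/sim --result-dir runs/reg --out runs/report.json
```

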
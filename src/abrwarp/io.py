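"""File formats, run configuration, and pipeline orchestration.

Matrices travel as plain CSV (samples x subjects, one file per condition)
with a JSON sidecar declaring the sampling rate, time origin and labels —
orientation is always declared, never guessed.  Warps, picks and manifests
are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .criteria import LAMBDA_GRID, LossConfig, loss_grid
from .warping import MonotoneMap, TimeWindow

REQUIRED_SIDECAR_KEYS = ("fs", "t0_ms", "condition", "subjects")


@dataclass
class RunConfig:
    """Study-default run parameters.

    Defaults reproduce the reference analysis: 13 knots on a 0-12 ms warping
    window (1-ms knot spacing), PSDD criterion, average-target procedure,
    lambda grid {0, 0.001, 0.01, 0.1, 1}, 250-trial averaging blocks, and a
    2-ms cross-fade ramp centred on 5 ms.
    """

    procedure: str = "at"
    criterion: str = "psdd"
    lam: float = 0.0
    K: int = 13
    window_start_ms: float = 0.0
    window_end_ms: float = 12.0
    fs: float = 16384.0
    n_grid: int | None = None
    target_condition: object = None
    highpass_hz: tuple = (100.0, 150.0)
    lowpass_hz: float = 2000.0
    filter_phase: str = "zero"
    block_size: int = 250
    crossfade_center_ms: float = 5.0
    crossfade_ramp_ms: float = 2.0
    lambda_grid: tuple = LAMBDA_GRID
    pick_windows: dict = field(
        default_factory=lambda: {
            "I": ((1.0, 3.5), (1.5, 4.5)),
            "V": ((5.0, 8.0), (6.0, 10.0)),
        }
    )
    seed: int = 0

    @property
    def window(self) -> TimeWindow:
        return TimeWindow.from_fs(self.window_start_ms, self.window_end_ms, self.fs)

    @property
    def loss_config(self) -> LossConfig:
        return LossConfig(self.criterion, self.lam)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sweep_conditions(procedures=("at", "pw")) -> list[tuple[str, LossConfig]]:
    """The full registration-condition grid: 2 procedures x 4 criteria x 5
    lambda values = 40 conditions."""
    return [(p, cfg) for p in procedures for cfg in loss_grid()]


def write_response_matrix(path, arr: np.ndarray, sidecar: dict) -> None:
    """CSV (samples x subjects) plus JSON sidecar with fs/t0_ms/labels."""
    path = Path(path)
    missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise KeyError(f"sidecar missing required keys: {missing}")
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=[str(s) for s in sidecar["subjects"]])
    df.to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_response_matrix(path, sidecar_path=None):
    """Read a response matrix and its sidecar; returns (array, sidecar).

    Validates rectangularity (pandas enforces it with a line-numbered
    error), the sidecar keys, and uniqueness of subject labels.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    if not Path(sidecar_path).exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise KeyError(f"sidecar {sidecar_path} missing required keys: {missing}")
    subjects = [str(s) for s in sidecar["subjects"]]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject labels in sidecar")
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != subjects:
        raise ValueError(
            f"{path}: columns {list(df.columns)} do not match sidecar subjects {subjects}"
        )
    return df.to_numpy(dtype=float), sidecar


def write_warps(path, warps: dict, window: TimeWindow) -> None:
    """Serialize per-condition warp maps as sampled (grid, values) pairs.

    Composed and averaged warps have no single coefficient vector, so the
    sampled representation is the common denominator.
    """
    payload = {
        "window": {"start_ms": window.start_ms, "end_ms": window.end_ms,
                   "n_samples": window.n_samples},
        "warps": {
            str(cond): [
                {"grid": w.grid.tolist(), "values": w.values.tolist()} for w in ws
            ]
            for cond, ws in warps.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_warps(path):
    with open(path) as fh:
        payload = json.load(fh)
    window = TimeWindow(**payload["window"])
    warps = {
        cond: [MonotoneMap(np.asarray(w["grid"]), np.asarray(w["values"])) for w in ws]
        for cond, ws in payload["warps"].items()
    }
    return warps, window


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "abrwarp_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def run_pipeline(config: RunConfig, out_dir, n_subjects: int = 10,
                 warp_magnitude: float = 0.3, dsnr_grid=None) -> dict:
    """simulate -> register -> extract -> validate on synthetic data,
    writing all artifacts plus a run manifest; returns summary metrics."""
    from .extraction import individual_measures, make_pick, pick_structural_extrema
    from .registration import register, warp_replicates
    from .synthdata import DSNR_GRID, simulate_dataset
    from .validation import replicate_deviations, response_deviation, warp_accuracy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dsnr_grid = tuple(dsnr_grid) if dsnr_grid is not None else DSNR_GRID
    window = config.window
    sim = simulate_dataset(
        n_subjects=n_subjects,
        warp_magnitude=warp_magnitude,
        dsnr_grid=dsnr_grid,
        seed=config.seed,
        K=config.K,
        fs=config.fs,
    )
    rset = sim.as_response_set()
    for cond, arr in rset.data.items():
        write_response_matrix(
            out_dir / f"responses_{cond:+.0f}dB.csv",
            arr,
            {"fs": config.fs, "t0_ms": window.start_ms, "condition": cond,
             "subjects": rset.subjects},
        )
    result = register(rset, config.loss_config, config.procedure)
    write_warps(out_dir / "warps.json", result.warps, window)
    pd.DataFrame(
        {f"{c:+.0f}dB": v for c, v in result.structural_avg.items()}
    ).to_csv(out_dir / "structural_avg.csv", index=False)

    picks = pick_structural_extrema(
        result.structural_grand_avg,
        window,
        {
            wave: (TimeWindow(p[0], p[1], 2), TimeWindow(tr[0], tr[1], 2))
            for wave, (p, tr) in config.pick_windows.items()
            if wave in ("I", "V")
        },
    )
    measures = individual_measures(result, picks)
    measures.to_csv(out_dir / "wave_measures.csv", index=False)

    dev_orig = response_deviation(rset.data, "original").response_deviation
    dev_aligned = response_deviation(result.aligned, "aligned").response_deviation
    acc = [
        warp_accuracy(sim.true_warps[i], result.warps[cond][i])[0]
        for cond in rset.data
        for i in range(rset.n_subjects)
    ]
    summary = {
        "deviation_original": dev_orig,
        "deviation_aligned": dev_aligned,
        "mean_warp_accuracy": float(np.nanmean(acc)),
        "n_measures": int(len(measures)),
    }
    if rset.replicates:
        reps = warp_replicates(rset, config.loss_config, config.procedure)
        summary.update(replicate_deviations(reps))
    write_manifest(out_dir / "manifest.json", config, {"summary": summary})
    return summary
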
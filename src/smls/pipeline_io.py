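"""Configuration, file formats, and the end-to-end pipeline.

One global seed is given per run; each stage derives its own seed
deterministically from it (CRC32 of the stage name), so stages can be
re-run in isolation and a full run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import detect, psffit, stoichiometry
from .simulate import (
    AcquisitionContext, FluorophoreModel, GroundTruthSpot, MixtureSpec,
    TailPolicy, render_frame, sample_intensities, scatter_positions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "derive_seed",
    "load_config",
    "dump_config",
    "read_localizations",
    "write_localizations",
    "write_stack",
    "read_stack",
    "run_experiment",
]

LOCALIZATION_COLUMNS = [
    "frame", "x_px", "y_px", "x_nm", "y_nm", "sigma_px",
    "intensity_counts", "background", "precision_xy_nm", "converged",
]
OPTIONAL_COLUMNS = ["sigma_x_px", "sigma_y_px", "z_nm", "precision_z_nm"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run."""

    seed: int = 0
    out_dir: str = "smls_out"
    # simulate
    n_spots: int = 392
    copy_weights: tuple = (0.83, 0.11, 0.04, 0.02)
    tail_policy: dict = field(default_factory=lambda: {"kind": "uniform", "n": 4, "span": 2})
    mean_signal: float = 157.0
    sd_signal: float = 65.0
    psf_sigma: float = 1.3
    background: float = 1.5
    frame_shape: tuple = (64, 64)
    spots_per_frame: int = 9
    context: dict = field(default_factory=dict)
    # detect / fit
    smooth_sigma: Optional[float] = None
    nms_radius: Optional[int] = None
    nms_threshold: Optional[float] = None
    # stoichiometry
    n_ref: int = 247
    n_max: int = 6
    aggregate_at: int = 4
    anchoring: str = "none"
    density_method: str = "kde"
    # stage chain
    stages: tuple = ("simulate", "detect", "fit", "stoich")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def acquisition_context(self) -> AcquisitionContext:
        return AcquisitionContext(**self.context)

    def fluorophore(self) -> FluorophoreModel:
        return FluorophoreModel(self.mean_signal, self.sd_signal,
                                self.acquisition_context())

    def mixture(self) -> MixtureSpec:
        return MixtureSpec(tuple(self.copy_weights),
                           TailPolicy(**self.tail_policy))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat = {}
    for key, val in raw.items():
        if key == "simulate" and isinstance(val, dict):
            flat.update(val)
        elif key in ("detect", "fit", "stoich") and isinstance(val, dict):
            flat.update(val)
        else:
            flat[key] = val
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(flat) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for tup_key in ("copy_weights", "frame_shape", "stages"):
        if tup_key in flat and isinstance(flat[tup_key], list):
            flat[tup_key] = tuple(flat[tup_key])
    return RunConfig(**flat)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_stack(frames, path: str | Path) -> None:
    """Multi-page 16-bit grayscale TIFF of rendered frames."""
    arrs = [np.clip(np.round(getattr(f, "pixels", f)), 0, 65535).astype(np.uint16)
            for f in frames]
    if not arrs:
        arrs = [np.zeros((1, 1), dtype=np.uint16)]  # placeholder page
    tifffile.imwrite(str(path), np.stack(arrs), photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_truth(frames, path: str | Path) -> None:
    rows = []
    for i, f in enumerate(frames):
        for s in (f.truth or []):
            rows.append({"frame": i, "x_px": s.x, "y_px": s.y, "z_nm": s.z,
                         "n_copies": s.n_copies, "true_signal": s.true_integrated_signal})
    pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "z_nm",
                                "n_copies", "true_signal"]).to_csv(path, index=False)


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    df.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"localization file {path} missing columns: {missing}")
    return df


def fits_to_table(fits, context: AcquisitionContext) -> pd.DataFrame:
    """SpotFit list -> localization table with the documented schema."""
    rows = []
    for f in fits:
        prec, _ = psffit.localization_precision(f, context)
        row = {
            "frame": f.frame_index,
            "x_px": f.x, "y_px": f.y,
            "x_nm": f.x * context.pixel_size, "y_nm": f.y * context.pixel_size,
            "sigma_px": f.sigma,
            "intensity_counts": f.intensity, "background": f.background,
            "precision_xy_nm": prec, "converged": bool(f.converged),
        }
        if f.sigma_x is not None:
            row["sigma_x_px"] = f.sigma_x
            row["sigma_y_px"] = f.sigma_y
        rows.append(row)
    cols = LOCALIZATION_COLUMNS + (
        ["sigma_x_px", "sigma_y_px"] if rows and "sigma_x_px" in rows[0] else [])
    return pd.DataFrame(rows, columns=cols)


def simulate_stage(config: RunConfig, rng: np.random.Generator):
    """Render the configured number of spots across sparse frames."""
    ctx = config.acquisition_context()
    fluor = config.fluorophore()
    mixture = config.mixture()
    intensities, copies = sample_intensities(mixture, fluor, config.n_spots, rng)
    frames = []
    i = 0
    margin = 2 * psffit.default_window_size(config.psf_sigma) // 2 + 1
    while i < config.n_spots:
        k = min(config.spots_per_frame, config.n_spots - i)
        pos = scatter_positions(k, config.frame_shape,
                                min_separation=8 * config.psf_sigma,
                                rng=rng, margin=margin)
        spots = [GroundTruthSpot(x=pos[j, 0], y=pos[j, 1],
                                 n_copies=int(copies[i + j]),
                                 true_integrated_signal=float(intensities[i + j]))
                 for j in range(k)]
        frames.append(render_frame(spots, config.psf_sigma, config.background,
                                   ctx, config.frame_shape, rng))
        i += k
    return frames


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured stage chain and write a report bundle.

    Returns the report dict (also written as JSON).  Idempotent for a
    fixed seed: identical configs produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = config.acquisition_context()
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    frames = []
    if "simulate" in config.stages:
        rng = np.random.default_rng(derive_seed(config.seed, "simulate"))
        frames = simulate_stage(config, rng)
        write_stack(frames, out / "stack.tif")
        write_truth(frames, out / "truth.csv")
        report["stages"]["simulate"] = {
            "n_frames": len(frames),
            "n_spots": sum(len(f.truth or []) for f in frames),
        }

    fits = []
    if "detect" in config.stages or "fit" in config.stages:
        smooth = config.smooth_sigma or config.psf_sigma
        n_cand = 0
        for i, frame in enumerate(frames):
            cands = detect.nms_candidates(
                frame, smooth, radius=config.nms_radius,
                threshold=config.nms_threshold, frame_index=i)
            n_cand += len(cands)
            if "fit" in config.stages:
                fits.extend(psffit.fit_spots(
                    frame.pixels, cands, config.psf_sigma, frame_index=i))
        report["stages"]["detect"] = {"n_candidates": n_cand}
        if "fit" in config.stages:
            table = fits_to_table(fits, ctx)
            write_localizations(table, out / "localizations.csv")
            report["stages"]["fit"] = {
                "n_fits": len(fits),
                "n_converged": int(sum(f.converged for f in fits)),
            }

    if "stoich" in config.stages:
        rng = np.random.default_rng(derive_seed(config.seed, "stoich-reference"))
        fluor = config.fluorophore()
        ref = fluor.draw(rng, config.n_ref)
        if fits:
            samples = np.array([f.intensity for f in fits if f.converged])
        else:
            rng2 = np.random.default_rng(derive_seed(config.seed, "stoich-samples"))
            samples, _ = sample_intensities(config.mixture(), fluor,
                                            config.n_spots, rng2)
        if len(samples) >= stoichiometry.MIN_SAMPLES:
            result = stoichiometry.compare_populations(
                ref, samples, n_max=config.n_max, anchoring=config.anchoring)
            table = stoichiometry.dol_report(result, config.aggregate_at)
            report["stages"]["stoich"] = {
                "weights": [float(w) for w in result.weights],
                "fit_residual": result.fit_residual,
                "anchoring_mode": result.anchoring_mode,
                "dol_percent": {row["dol"]: row["percent"]
                                for _, row in table.iterrows()},
            }
        else:
            report["stages"]["stoich"] = {"skipped": "fewer than 30 intensities"}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_summarize(report))
    return report


def _summarize(report: dict) -> str:
    lines = [f"smls run  seed={report['seed']}  config={report['config_hash']}"]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    lines.append("")
    return "\n".join(lines)
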
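"""End-to-end orchestration: simulate -> fit -> calibrate -> quantify -> kinetics.

A run is fully described by a :class:`RunConfig`; its outputs are listed in
a manifest with content hashes so that identical config + seed give
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import get_preset
from .calibration import fit_calibration, vial_calibration_points
from .io import save_mask, save_multi_echo, save_relaxation_map
from .kinetics import extract_timecourse, group_report, preferentiality
from .relaxometry import NoiseEstimate, dual_echo_r2star, estimate_noise_sigma, multi_echo_map
from .synthetic import (
    build_group_study,
    default_phantom_spec,
    generate_dynamic_study,
    generate_phantom_image,
)

__all__ = [
    "RunConfig",
    "StageError",
    "TableFormatError",
    "read_table1",
    "calibration_points",
    "bundled_table1_path",
    "run_end_to_end",
]

log = logging.getLogger("ferromap")

PathLike = Union[str, Path]


class TableFormatError(ValueError):
    """Malformed calibration table; carries the offending line number."""


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, message: str, path: Optional[PathLike] = None):
        self.stage = stage
        self.path = str(path) if path is not None else None
        suffix = f" [{self.path}]" if self.path else ""
        super().__init__(f"stage {stage!r}: {message}{suffix}")


_TABLE_COLUMNS = ("sample", "c_mg_ml", "cfe_ug_ml", "mean", "sd", "n", "se")


def bundled_table1_path() -> Path:
    """Path of the calibration table shipped with the package."""
    return Path(resources.files("ferromap").joinpath("data/table1.tsv"))


def read_table1(path: PathLike) -> pd.DataFrame:
    """Parse a 7-column phantom calibration table.

    Columns: sample, c (mg/mL), cFe (ug/mL), mean, sd, n, se.  Delimiters
    may be tabs, commas, semicolons or runs of spaces, and a merged
    ``mean±sd`` cell is tolerated.  Malformed rows are reported with their
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: List[Tuple[float, ...]] = []
    lines = path.read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        line = line.replace("±", " ").replace("+/-", " ")
        fields = [f for f in re.split(r"[\t,; ]+", line) if f]
        try:
            vals = tuple(float(f) for f in fields)
        except ValueError:
            # header line: tolerated once, before any data
            if not rows:
                continue
            raise TableFormatError(
                f"{path}:{lineno}: non-numeric field in data row: {raw!r}"
            )
        if len(vals) != len(_TABLE_COLUMNS):
            raise TableFormatError(
                f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} fields, got {len(vals)}"
            )
        rows.append(vals)
    if not rows:
        raise TableFormatError(f"{path}: no data rows found")
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df["sample"] = df["sample"].astype(int)
    df["n"] = df["n"].astype(int)
    return df


def calibration_points(table: pd.DataFrame) -> List[Tuple[float, float]]:
    """(cFe, mean rate) pairs for :func:`ferromap.calibration.fit_calibration`."""
    return list(zip(table["cfe_ug_ml"].tolist(), table["mean"].tolist()))


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    scenario: str = "group1"
    seed: int = 0
    phantom_acquisition: str = "phantom-multiecho"
    dynamic_acquisition: str = "dual-echo-dynamic"
    snr_threshold: float = 3.0
    baseline_frames: int = 9
    output_root: str = "ferromap-run"
    calibration_source: str = "fit-from-phantom"  # or a table path
    phantom_grid: Tuple[int, int, int] = (64, 64, 1)
    study_grid: Tuple[int, int, int] = (32, 32, 1)
    phantom_noise_sigma: float = 0.0
    study_noise_sigma: float = 0.0
    base_signal: float = 1000.0
    preferentiality_threshold: float = 1.1
    tumor_mask_path: Optional[str] = None
    normal_mask_path: Optional[str] = None

    def __post_init__(self) -> None:
        get_preset(self.phantom_acquisition)  # referenced presets must exist
        get_preset(self.dynamic_acquisition)
        if self.scenario:
            from .synthetic import GROUP_PRESETS

            if self.scenario.lower() not in GROUP_PRESETS:
                raise ValueError(f"unknown scenario preset {self.scenario!r}")
        self.phantom_grid = tuple(int(v) for v in self.phantom_grid)
        self.study_grid = tuple(int(v) for v in self.study_grid)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_mask_checked(path: str, stage: str, grid) -> np.ndarray:
    from .io import load_mask

    p = Path(path)
    if not p.exists():
        raise StageError(stage, "mask file not found", p)
    return load_mask(p, grid_shape=grid)


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written to
    ``<output_root>/manifest.json``)."""
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    artifacts: List[Path] = []
    seed = int(config.seed)

    # --- stage: simulate-phantom -------------------------------------------------
    stage = "simulate-phantom"
    try:
        phantom_params = get_preset(config.phantom_acquisition)
        phantom_spec = default_phantom_spec(
            grid_shape=config.phantom_grid,
            noise_sigma=config.phantom_noise_sigma,
            base_signal=config.base_signal,
        )
        phantom_img = generate_phantom_image(phantom_spec, phantom_params, seed=seed)
        artifacts.append(save_multi_echo(phantom_img, root / "phantom", stem="phantom"))
        log.info("%s: %d vials on grid %s", stage, len(phantom_spec.vial_concentrations),
                 phantom_spec.vial_layout.shape)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, str(exc)) from exc

    # --- stage: fit-phantom ------------------------------------------------------
    stage = "fit-phantom"
    try:
        background = phantom_spec.vial_layout == 0
        if config.phantom_noise_sigma > 0:
            noise = estimate_noise_sigma(phantom_img, background_mask=background)
        else:
            noise = NoiseEstimate(sigma=config.base_signal * 1e-9, method="provided")
        phantom_map = multi_echo_map(phantom_img, noise, threshold=config.snr_threshold)
        n_invalid = phantom_map.values.size - phantom_map.n_valid
        log.info("%s: sigma=%.4g (%s), %d invalid voxels", stage, noise.sigma,
                 noise.method, n_invalid)
        artifacts.append(save_relaxation_map(
            phantom_map, root / "phantom", stem="r2star",
            provenance={"sigma": noise.sigma, "sigma_method": noise.method,
                        "snr_threshold": config.snr_threshold, "seed": seed},
        ))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- stage: calibrate --------------------------------------------------------
    stage = "calibrate"
    try:
        if config.calibration_source == "fit-from-phantom":
            points = vial_calibration_points(
                phantom_img,
                phantom_spec.vial_layout,
                phantom_spec.iron_concentrations,
                noise,
                threshold=config.snr_threshold,
            )
            calib = fit_calibration(points)
        else:
            table_path = Path(config.calibration_source)
            if not table_path.exists():
                raise StageError(stage, "calibration table not found", table_path)
            calib = fit_calibration(calibration_points(read_table1(table_path)))
        calib_path = root / "calibration.json"
        calib.to_json(calib_path)
        artifacts.append(calib_path)
        log.info("%s: slope=%.4f intercept=%.3f R2=%.4f", stage, calib.slope,
                 calib.intercept, calib.r_squared)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- stage: simulate-study ---------------------------------------------------
    stage = "simulate-study"
    try:
        study_params = get_preset(config.dynamic_acquisition)
        study_spec = build_group_study(
            config.scenario,
            grid_shape=config.study_grid,
            noise_sigma=config.study_noise_sigma,
            base_signal=config.base_signal,
            n_baseline_frames=config.baseline_frames,
        )
        frames = generate_dynamic_study(study_spec, study_params, seed=seed)
        frames_dir = root / "frames"
        for i, fr in enumerate(frames):
            artifacts.append(save_multi_echo(fr, frames_dir, stem=f"frame{i:03d}"))
        for name, m in study_spec.compartment_masks.items():
            artifacts.append(save_mask(m, root / "masks" / f"{name}.nii", study_params))
        log.info("%s: scenario=%s, %d frames", stage, config.scenario, len(frames))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- stage: fit-frames -------------------------------------------------------
    stage = "fit-frames"
    try:
        maps = [dual_echo_r2star(fr) for fr in frames]
        for i, m in enumerate(maps):
            artifacts.append(save_relaxation_map(
                m, root / "maps", stem=f"r2star{i:03d}",
                provenance={"frame": i, "seed": seed},
            ))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- stage: quantify + kinetics ---------------------------------------------
    stage = "kinetics"
    try:
        grid = study_spec.grid_shape
        if config.tumor_mask_path is not None:
            tumor_mask = _load_mask_checked(config.tumor_mask_path, stage, grid)
        else:
            tumor_mask = study_spec.compartment_masks["tumor"]
        if config.normal_mask_path is not None:
            normal_mask = _load_mask_checked(config.normal_mask_path, stage, grid)
        else:
            normal_mask = study_spec.compartment_masks["normal"]

        tc_tumor = extract_timecourse(maps, tumor_mask, calib,
                                      config.baseline_frames, roi_name="tumor")
        tc_normal = extract_timecourse(maps, normal_mask, calib,
                                       config.baseline_frames, roi_name="normal")
        pref = preferentiality(tc_tumor, tc_normal,
                               threshold=config.preferentiality_threshold)
        report = group_report([(config.scenario, pref)])

        tc_path = root / "timecourses.csv"
        pd.concat([tc_tumor.to_frame(), tc_normal.to_frame()]).to_csv(tc_path, index=False)
        artifacts.append(tc_path)
        report_path = root / "group_report.csv"
        report.to_csv(report_path, index=False)
        artifacts.append(report_path)
        kin_path = root / "kinetics.json"
        kin_path.write_text(json.dumps({
            "scenario": config.scenario,
            "peak_time_tumor_min": pref.peak_time_tumor,
            "preferential_window_min": list(pref.window),
            "window_extent_min": pref.window_extent_min,
            "threshold": pref.threshold,
            "ratio_series": [None if not np.isfinite(r) else float(r)
                             for r in pref.ratio_series],
            "post_times_min": [float(t) for t in pref.times],
        }, indent=2) + "\n")
        artifacts.append(kin_path)
        log.info("%s: peak=%g min, window=%s", stage, pref.peak_time_tumor, pref.window)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- manifest ----------------------------------------------------------------
    files = {}
    for side in artifacts:
        side = Path(side)
        files[str(side.relative_to(root))] = _sha256(side)
        if side.suffix == ".json":  # hash companion volumes listed by sidecars
            try:
                meta = json.loads(side.read_text())
            except json.JSONDecodeError:
                continue
            names = []
            if isinstance(meta, dict):
                names += meta.get("echo_files", [])
                if meta.get("file_4d"):
                    names.append(meta["file_4d"])
                names += list(meta.get("files", {}).values())
            for name in names:
                p = side.parent / name
                if p.exists():
                    files[str(p.relative_to(root))] = _sha256(p)
    manifest = {
        "ferromap_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "files": dict(sorted(files.items())),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
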
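"""Linear calibration between relaxation rate and iron concentration.

The calibration line is fitted on per-vial ROI means (the convention of the
printed phantom table), inverted either against its own intercept (phantom
mode) or against a per-voxel baseline rate (dynamic, in vivo mode).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "CalibrationModel",
    "RoiSummary",
    "EmptyRoiError",
    "roi_stats",
    "fit_calibration",
    "vial_calibration_points",
    "concentration_from_r2star",
]


class EmptyRoiError(ValueError):
    """Raised when a mask covers no valid voxel."""


@dataclass(frozen=True)
class CalibrationModel:
    """Line linking relaxation rate (s^-1) to iron concentration (ug/mL).

    ``rate = slope * concentration + intercept``; ``r_squared`` is the
    coefficient of determination of the fit that produced it.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def invertible(self) -> bool:
        return self.slope != 0.0

    def predict(self, cfe):
        return self.slope * np.asarray(cfe, dtype=float) + self.intercept

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            n_points=int(d["n_points"]),
        )


@dataclass(frozen=True)
class RoiSummary:
    """mean +/- SD (n) with the standard error SD/sqrt(n)."""

    mean: float
    sd: float
    n: int
    se: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def __str__(self) -> str:  # the printed reporting convention
        return f"{self.mean:.1f}±{self.sd:.1f} ({self.n})"


def roi_stats(field, mask: np.ndarray) -> RoiSummary:
    """Summarise valid in-mask voxels as mean, population SD, n, SE.

    ``field`` is either a plain array (non-finite voxels excluded) or any
    object exposing ``values`` and ``valid_mask`` arrays (a RelaxationMap).
    """
    if hasattr(field, "values") and hasattr(field, "valid_mask"):
        values = np.asarray(field.values, dtype=float)
        valid = np.asarray(field.valid_mask, dtype=bool)
    else:
        values = np.asarray(field, dtype=float)
        valid = np.isfinite(values)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match field shape")
    sel = values[mask & valid]
    if sel.size == 0:
        raise EmptyRoiError("no valid voxel inside the mask")
    n = int(sel.size)
    mean = float(sel.mean())
    sd = float(sel.std())  # population SD; indistinguishable from n-1 at ROI sizes used
    return RoiSummary(mean=mean, sd=sd, n=n, se=sd / math.sqrt(n))


def fit_calibration(points: Iterable[Tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of mean rate on iron concentration.

    ``points`` are (concentration ug/mL, mean rate s^-1) pairs, one per vial.
    """
    pts = [(float(c), float(y)) for c, y in points]
    if len(pts) < 2:
        raise ValueError("need >= 2 calibration points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.unique(x).size < 2:
        raise ValueError("calibration needs >= 2 distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid**2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    r2 = min(max(r2, 0.0), 1.0)
    return CalibrationModel(
        slope=float(slope), intercept=float(intercept), r_squared=r2, n_points=len(pts)
    )


def vial_calibration_points(
    image,
    vial_layout: np.ndarray,
    iron_concentrations: Sequence[float],
    noise,
    threshold: float = 3.0,
) -> list:
    """Per-vial (cFe, mean rate) points from a multi-echo phantom image.

    The SNR gate is decided once per vial from the vial-mean decay (the
    echo count where mean magnitude / sigma stays above ``threshold``), then
    every vial voxel is fitted at that fixed echo count.  Gating each voxel
    on its own noisy magnitudes would truncation-bias gate-marginal echoes;
    gating the ROI mean is deterministic and unbiased.  Vials retaining
    fewer than 2 echoes are skipped (they are beyond the dynamic range of
    the echo train at this noise level).
    """
    from .relaxometry import fit_decay_stack, select_echoes_by_snr

    vial_layout = np.asarray(vial_layout)
    iron = [float(c) for c in iron_concentrations]
    points = []
    for vial, cfe in enumerate(iron, start=1):
        mask = vial_layout == vial
        if not mask.any():
            continue
        decays = image.data[mask]  # (n_vox, n_echoes)
        n_keep = select_echoes_by_snr(decays.mean(axis=0), noise.sigma, threshold)
        if n_keep < 2:
            continue
        rates, _, valid = fit_decay_stack(image.params.echo_times, decays, n_keep)
        if not valid.any():
            continue
        summ = roi_stats(np.where(valid, rates, np.nan), np.ones(rates.shape, bool))
        points.append((cfe, summ.mean))
    if len(points) < 2:
        raise ValueError("fewer than 2 vials yielded a usable calibration point")
    return points


def concentration_from_r2star(
    r2star,
    calib: CalibrationModel,
    baseline_r2star=None,
    clip_negative: bool = False,
    return_flags: bool = False,
):
    """Invert the calibration to iron concentration in ug/mL.

    Without a baseline the phantom intercept is subtracted; with a baseline
    (scalar or per-voxel field) the inversion is baseline-subtracted:
    ``cFe = (R2* - baseline) / slope``.  Negative concentrations are kept
    (they carry noise information) unless ``clip_negative``; pass
    ``return_flags=True`` to also get the negativity mask.
    """
    if not calib.invertible:
        raise ValueError("calibration slope is 0; model not invertible")
    r2star = np.asarray(r2star, dtype=float)
    ref = calib.intercept if baseline_r2star is None else np.asarray(baseline_r2star, dtype=float)
    cfe = (r2star - ref) / calib.slope
    negative = cfe < 0
    if clip_negative:
        cfe = np.clip(cfe, 0.0, None)
    if cfe.ndim == 0:
        cfe = float(cfe)
        negative = bool(negative)
    if return_flags:
        return cfe, negative
    return cfe
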
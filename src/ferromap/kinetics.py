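"""Tracer kinetics: ROI time-courses, peak time, preferential accumulation.

Dynamic dual-echo R2* frames are converted to concentration via
baseline-subtracted calibration inversion (per-voxel baseline = mean of the
pre-injection frames), then summarised per ROI and compared tumor vs normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, EmptyRoiError, RoiSummary, roi_stats
from .relaxometry import RelaxationMap

__all__ = [
    "ROITimeCourse",
    "PreferentialityResult",
    "extract_timecourse",
    "peak_time",
    "preferentiality",
    "group_report",
]


@dataclass
class ROITimeCourse:
    """Per-time-point concentration summary for one region.

    Baseline frames sit at times <= 0 by convention; post-injection frames
    at their stated minutes.  ``concentrations`` are ROI means in ug/mL.
    """

    roi_name: str
    times: np.ndarray
    concentrations: np.ndarray
    summaries: List[RoiSummary]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (len(self.times) == len(self.concentrations) == len(self.summaries)):
            raise ValueError("times, concentrations and summaries must align")

    @property
    def post_mask(self) -> np.ndarray:
        return self.times > 0

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.post_mask]

    @property
    def post_concentrations(self) -> np.ndarray:
        return self.concentrations[self.post_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_name,
                "time_min": self.times,
                "concentration_ug_ml": self.concentrations,
                "sd": [s.sd for s in self.summaries],
                "n": [s.n for s in self.summaries],
                "se": [s.se for s in self.summaries],
            }
        )


@dataclass
class PreferentialityResult:
    """Tumor/normal concentration ratio per post-injection time point."""

    times: np.ndarray
    ratio_series: np.ndarray
    window: Tuple[float, ...]
    peak_time_tumor: float
    threshold: float
    undefined_times: Tuple[float, ...] = ()

    @property
    def window_extent_min(self) -> float:
        return float(max(self.window) - min(self.window)) if self.window else 0.0

    @property
    def max_ratio(self) -> float:
        finite = self.ratio_series[np.isfinite(self.ratio_series)]
        return float(finite.max()) if finite.size else float("nan")


def extract_timecourse(
    frames: Sequence[RelaxationMap],
    mask: np.ndarray,
    calib: CalibrationModel,
    n_baseline: int,
    roi_name: str = "roi",
) -> ROITimeCourse:
    """ROI concentration time-course from dynamic relaxation maps.

    The per-voxel baseline rate is the mean of the first ``n_baseline``
    frames (a voxel must be valid in every baseline frame to contribute);
    each frame is then inverted as (rate - baseline) / slope and summarised
    over the mask's valid voxels.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if len(frames) <= n_baseline:
        raise ValueError(
            f"need more than {n_baseline} frames, got {len(frames)}"
        )
    if any(f.frame_time is None for f in frames):
        raise ValueError("every frame needs a time stamp")
    times = np.array([f.frame_time for f in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frames must be in strictly increasing time order")
    if times[n_baseline - 1] > 0:
        raise ValueError("baseline frames must carry time stamps <= 0")
    mask = np.asarray(mask, dtype=bool)

    base_stack = np.stack([f.values for f in frames[:n_baseline]])
    base_valid = np.all(np.stack([f.valid_mask for f in frames[:n_baseline]]), axis=0)
    baseline = base_stack.mean(axis=0)

    if not np.any(mask & base_valid):
        raise EmptyRoiError(f"mask {roi_name!r} has no voxel valid across the baseline")

    concentrations: List[float] = []
    summaries: List[RoiSummary] = []
    for f in frames:
        conc = np.where(
            base_valid & f.valid_mask,
            (f.values - baseline) / calib.slope,
            np.nan,
        )
        summ = roi_stats(conc, mask)
        summaries.append(summ)
        concentrations.append(summ.mean)

    return ROITimeCourse(
        roi_name=roi_name,
        times=times,
        concentrations=np.array(concentrations),
        summaries=summaries,
    )


def peak_time(tc: ROITimeCourse) -> float:
    """Post-injection time stamp of maximum concentration; ties -> earliest."""
    post_t = tc.post_times
    if post_t.size == 0:
        raise ValueError("time-course has no post-injection frame")
    conc = tc.post_concentrations
    return float(post_t[int(np.argmax(conc))])  # argmax returns the first maximum


def preferentiality(
    tumor: ROITimeCourse,
    normal: ROITimeCourse,
    threshold: float = 1.0,
) -> PreferentialityResult:
    """Tumor/normal ratio series and the preferential-accumulation window.

    The window is the set of sampled post-injection stamps whose ratio
    exceeds ``threshold`` (no interpolation between stamps).  Time points
    where the normal-tissue concentration is <= 0 give an undefined ratio
    and are flagged, never counted as preferential.
    """
    if not np.array_equal(tumor.times, normal.times):
        raise ValueError("tumor and normal time axes differ")
    post_t = tumor.post_times
    t_conc = tumor.post_concentrations
    n_conc = normal.post_concentrations
    defined = n_conc > 0
    ratio = np.full(post_t.shape, np.nan)
    np.divide(t_conc, n_conc, out=ratio, where=defined)
    window = tuple(float(t) for t, r, d in zip(post_t, ratio, defined) if d and r > threshold)
    return PreferentialityResult(
        times=post_t,
        ratio_series=ratio,
        window=window,
        peak_time_tumor=peak_time(tumor),
        threshold=threshold,
        undefined_times=tuple(float(t) for t, d in zip(post_t, defined) if not d),
    )


def group_report(
    studies: Sequence[Tuple[str, PreferentialityResult]]
) -> pd.DataFrame:
    """One row per study: peak time, window membership/extent, max ratio.

    Rows are ordered by group label; duplicate labels are rejected.  An
    empty preferential window renders as a 0-minute extent, not as missing.
    """
    if len(studies) < 1:
        raise ValueError("need at least one study")
    labels = [lab for lab, _ in studies]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    rows = []
    for label, res in sorted(studies, key=lambda kv: kv[0]):
        rows.append(
            {
                "group": label,
                "peak_time_min": res.peak_time_tumor,
                "window": ",".join(f"{t:g}" for t in res.window),
                "n_window_points": len(res.window),
                "window_extent_min": res.window_extent_min,
                "max_ratio": res.max_ratio,
                "threshold": res.threshold,
            }
        )
    return pd.DataFrame(rows)
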
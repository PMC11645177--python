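"""Synthetic phantom and dynamic-study generators with known ground truth.

Every downstream stage (relaxometry, calibration, kinetics) is exercised
against images produced here, so the forward model is deliberately the same
mono-exponential decay the fitting stage inverts:

    S(TE) = S0 * exp(-R2* * TE)        (TE in s inside the exponent)

with magnitude (Rician) noise applied per voxel per echo.  A Gaussian noise
option exists for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .acquisition import AcquisitionParams
from .calibration import CalibrationModel

__all__ = [
    "MultiEchoImage",
    "PhantomSpec",
    "DynamicStudySpec",
    "PiecewiseCurve",
    "GroupScenario",
    "GROUP_PRESETS",
    "DEFAULT_TRUE_CALIBRATION",
    "DEFAULT_VIAL_DEXTRAN_MG_PER_ML",
    "IRON_FRACTION",
    "dextran_to_iron_concentration",
    "true_r2star_from_concentration",
    "make_vial_layout",
    "layout_from_masks",
    "default_phantom_spec",
    "generate_phantom_image",
    "generate_dynamic_study",
    "default_compartment_masks",
    "build_group_study",
    "group_preset_names",
]

#: Iron mass per dextran formulation mass: 2.4 mgFe/mL in a 5 mg/mL stock.
IRON_FRACTION = 2.4 / 5.0

#: Dextran dilution series of the calibration phantom, mg/mL (11 vials incl. blank).
DEFAULT_VIAL_DEXTRAN_MG_PER_ML: Tuple[float, ...] = (
    0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20,
)

#: Generative ground-truth calibration (rate s^-1 vs iron concentration ug/mL).
DEFAULT_TRUE_CALIBRATION = CalibrationModel(
    slope=10.02, intercept=88.028, r_squared=0.98, n_points=11
)


def dextran_to_iron_concentration(c, iron_fraction: float = IRON_FRACTION):
    """Convert a dextran formulation concentration (mg/mL) to iron (ug/mL).

    ``cFe = c * iron_fraction * 1000``; e.g. 0.02 mg/mL at fraction 0.48
    carries 9.6 ug/mL of iron.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("dextran concentration must be >= 0")
    if not 0 < iron_fraction <= 1:
        raise ValueError("iron_fraction must lie in (0, 1]")
    out = c * iron_fraction * 1000.0
    return float(out) if out.ndim == 0 else out


def true_r2star_from_concentration(cfe, calib: CalibrationModel = DEFAULT_TRUE_CALIBRATION):
    """Generative linear model: R2* (s^-1) = slope * cFe + intercept."""
    cfe = np.asarray(cfe, dtype=float)
    if np.any(cfe < 0):
        raise ValueError("iron concentration must be >= 0")
    out = calib.slope * cfe + calib.intercept
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# images


@dataclass
class MultiEchoImage:
    """Magnitude volumes on a regular grid, indexed by echo.

    ``data`` has shape ``grid + (n_echoes,)``; all magnitudes are >= 0.
    ``frame_time`` is the acquisition time stamp in minutes for dynamic
    series (baseline frames at <= 0), or ``None`` for static scans.
    """

    data: np.ndarray
    params: AcquisitionParams
    frame_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[-1] != self.params.n_echoes:
            raise ValueError(
                f"echo axis has extent {self.data.shape[-1]} but params define "
                f"{self.params.n_echoes} echo times"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def grid_shape(self) -> Tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-1]

    def echo(self, i: int) -> np.ndarray:
        return self.data[..., i]


def _apply_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator,
                 model: str = "rician") -> np.ndarray:
    if sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if sigma == 0:
        return signal.copy()
    if model == "rician":
        re = signal + rng.normal(0.0, sigma, size=signal.shape)
        im = rng.normal(0.0, sigma, size=signal.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        # oracle-test option; clipped so magnitudes stay physical
        return np.clip(signal + rng.normal(0.0, sigma, size=signal.shape), 0.0, None)
    raise ValueError(f"unknown noise model {model!r}")


# ---------------------------------------------------------------------------
# phantom


def make_vial_layout(
    n_vials: int,
    grid_shape: Tuple[int, int, int] = (64, 64, 1),
    radius: Optional[float] = None,
) -> np.ndarray:
    """Lay out ``n_vials`` disjoint circular vials on a single-slice grid.

    Returns an integer label volume: 0 = background, 1..n_vials = vial id.
    The arrangement (a centred rectangular raster of disks) is a synthetic
    convenience, not a reconstruction of any physical vial holder.
    """
    nx, ny, nz = grid_shape
    cols = math.ceil(math.sqrt(n_vials))
    rows = math.ceil(n_vials / cols)
    pitch_x = nx / cols
    pitch_y = ny / rows
    if radius is None:
        radius = 0.33 * min(pitch_x, pitch_y)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    layout = np.zeros(grid_shape, dtype=np.int32)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    label = 0
    for r in range(rows):
        for c in range(cols):
            label += 1
            if label > n_vials:
                break
            cx = (c + 0.5) * pitch_x - 0.5
            cy = (r + 0.5) * pitch_y - 0.5
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
            layout[disk, :] = label
    return layout


def layout_from_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Combine per-vial boolean masks into a label volume; overlaps rejected."""
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    layout = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(masks, start=1):
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError("all masks must share one grid shape")
        if np.any(layout[m] != 0):
            raise ValueError(f"vial mask {i} overlaps an earlier vial")
        layout[m] = i
    return layout


@dataclass
class PhantomSpec:
    """Generative description of the agarose vial phantom."""

    vial_concentrations: Tuple[float, ...] = DEFAULT_VIAL_DEXTRAN_MG_PER_ML
    iron_fraction: float = IRON_FRACTION
    vial_layout: Optional[np.ndarray] = None  # int labels, 0 = background
    base_signal: float = 1000.0
    true_calibration: CalibrationModel = field(default_factory=lambda: DEFAULT_TRUE_CALIBRATION)
    noise_sigma: float = 0.0
    noise_model: str = "rician"

    def __post_init__(self) -> None:
        self.vial_concentrations = tuple(float(c) for c in self.vial_concentrations)
        if any(c < 0 for c in self.vial_concentrations):
            raise ValueError("vial concentrations must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.vial_layout is None:
            self.vial_layout = make_vial_layout(len(self.vial_concentrations))
        self.vial_layout = np.asarray(self.vial_layout)
        labels = np.unique(self.vial_layout)
        if labels.max(initial=0) > len(self.vial_concentrations):
            raise ValueError("layout labels exceed the number of vials")

    @property
    def iron_concentrations(self) -> np.ndarray:
        """Per-vial iron concentration in ug/mL."""
        return dextran_to_iron_concentration(
            np.asarray(self.vial_concentrations), self.iron_fraction
        )

    def vial_mask(self, vial: int) -> np.ndarray:
        """Boolean mask of vial ``vial`` (1-based label)."""
        return self.vial_layout == vial

    def true_r2star(self, vial: int) -> float:
        cfe = self.iron_concentrations[vial - 1]
        return float(true_r2star_from_concentration(cfe, self.true_calibration))


def default_phantom_spec(
    grid_shape: Tuple[int, int, int] = (64, 64, 1),
    noise_sigma: float = 0.0,
    base_signal: float = 1000.0,
    **kwargs,
) -> PhantomSpec:
    """The 11-vial dilution-series phantom on a single synthetic slice."""
    n = len(kwargs.get("vial_concentrations", DEFAULT_VIAL_DEXTRAN_MG_PER_ML))
    return PhantomSpec(
        vial_layout=make_vial_layout(n, grid_shape),
        noise_sigma=noise_sigma,
        base_signal=base_signal,
        **kwargs,
    )


def generate_phantom_image(
    spec: PhantomSpec, params: AcquisitionParams, seed: int
) -> MultiEchoImage:
    """Simulate one multi-echo acquisition of the vial phantom.

    Vial voxels decay mono-exponentially at the rate implied by the vial's
    iron concentration through ``spec.true_calibration``; background voxels
    carry zero signal.  Identical seeds give bit-identical output.
    """
    if params.n_echoes < 2:
        raise ValueError("phantom generation needs >= 2 echoes")
    layout = spec.vial_layout
    te_s = np.asarray(params.echo_times) / 1000.0
    rates = np.zeros(len(spec.vial_concentrations) + 1)
    rates[1:] = true_r2star_from_concentration(
        spec.iron_concentrations, spec.true_calibration
    )
    s0 = np.where(layout > 0, spec.base_signal, 0.0)
    r2s = rates[layout]
    signal = s0[..., None] * np.exp(-r2s[..., None] * te_s)
    rng = np.random.default_rng(seed)
    noisy = _apply_noise(signal, spec.noise_sigma, rng, spec.noise_model)
    return MultiEchoImage(data=noisy, params=params)


# ---------------------------------------------------------------------------
# dynamic study


@dataclass(frozen=True)
class PiecewiseCurve:
    """Piecewise-linear concentration time-course, zero at and before t=0.

    ``points`` are (time_min, concentration_ug_per_ml) knots for t > 0;
    the curve interpolates linearly from (0, 0) through the knots and holds
    the last value beyond the final knot.
    """

    points: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(c)) for t, c in self.points)
        object.__setattr__(self, "points", pts)
        ts = [t for t, _ in pts]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("curve knot times must be strictly increasing")
        if any(t <= 0 for t in ts):
            raise ValueError("curve knots must be at t > 0")
        if any(c < 0 for _, c in pts):
            raise ValueError("curve concentrations must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if not self.points:
            out = np.zeros_like(t)
            return float(out) if out.ndim == 0 else out
        xs = np.array([0.0] + [p[0] for p in self.points])
        ys = np.array([0.0] + [p[1] for p in self.points])
        out = np.interp(t, xs, ys)
        out = np.where(t <= 0, 0.0, out)
        return float(out) if out.ndim == 0 else out

    def scaled(self, k: float) -> "PiecewiseCurve":
        return PiecewiseCurve(tuple((t, k * c) for t, c in self.points))


def _zero_curve() -> PiecewiseCurve:
    return PiecewiseCurve(points=())


@dataclass
class DynamicStudySpec:
    """Generative description of one dynamic dual-echo study."""

    compartment_masks: Dict[str, np.ndarray]
    concentration_curves: Dict[str, PiecewiseCurve]
    baseline_r2star: Dict[str, float]
    n_baseline_frames: int = 9
    post_injection_times: Tuple[float, ...] = (30.0, 45.0, 60.0, 90.0, 120.0)
    baseline_interval_min: float = 1.0
    base_signal: float = 1000.0
    true_calibration: CalibrationModel = field(default_factory=lambda: DEFAULT_TRUE_CALIBRATION)
    noise_sigma: float = 0.0
    noise_model: str = "rician"
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_baseline_frames < 1:
            raise ValueError("n_baseline_frames must be >= 1")
        times = tuple(float(t) for t in self.post_injection_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("post_injection_times must be strictly increasing")
        if times and times[0] <= 0:
            raise ValueError("post-injection times must be > 0")
        self.post_injection_times = times
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        shapes = {m.shape for m in self.compartment_masks.values()}
        if len(shapes) != 1:
            raise ValueError("compartment masks must share one grid shape")
        total = np.zeros(next(iter(shapes)), dtype=int)
        for name, m in self.compartment_masks.items():
            m = np.asarray(m, dtype=bool)
            self.compartment_masks[name] = m
            total += m
        if np.any(total > 1):
            raise ValueError("compartment masks must be disjoint")
        unknown = set(self.concentration_curves) - set(self.compartment_masks)
        if unknown:
            raise ValueError(f"curves for unknown compartments: {sorted(unknown)}")
        # baseline frames must see zero tracer
        for name, curve in self.concentration_curves.items():
            c0 = np.asarray(curve(self.baseline_times))
            if np.any(np.abs(c0) > 0):
                raise ValueError(f"curve for {name!r} is nonzero at a baseline frame")
            if np.any(np.asarray(curve(np.asarray(self.frame_times))) < 0):
                raise ValueError(f"curve for {name!r} returns a negative concentration")

    @property
    def grid_shape(self) -> Tuple[int, ...]:
        return next(iter(self.compartment_masks.values())).shape

    @property
    def baseline_times(self) -> Tuple[float, ...]:
        n, dt = self.n_baseline_frames, self.baseline_interval_min
        return tuple(-(n - 1 - i) * dt for i in range(n))

    @property
    def frame_times(self) -> Tuple[float, ...]:
        return self.baseline_times + self.post_injection_times

    def concentration_at(self, name: str, t: float) -> float:
        curve = self.concentration_curves.get(name)
        return float(curve(t)) if curve is not None else 0.0

    def r2star_field(self, t: float) -> np.ndarray:
        """Noise-free R2* (s^-1) everywhere tissue exists at time t."""
        field_ = np.zeros(self.grid_shape)
        for name, mask in self.compartment_masks.items():
            r2 = self.baseline_r2star.get(name, 0.0)
            r2 += self.true_calibration.slope * self.concentration_at(name, t)
            field_[mask] = r2
        return field_

    def signal_mask(self) -> np.ndarray:
        """Voxels carrying signal (any compartment with nonzero baseline R2*
        is treated as tissue; compartments named 'background' carry none)."""
        m = np.zeros(self.grid_shape, dtype=bool)
        for name, mask in self.compartment_masks.items():
            if name != "background":
                m |= mask
        return m


def generate_dynamic_study(
    spec: DynamicStudySpec, params: AcquisitionParams, seed: int
) -> List[MultiEchoImage]:
    """Simulate the full dynamic frame series (baseline + post-injection).

    Per-frame random streams are derived from ``(seed, frame_index)`` so that
    adding frames never reshuffles earlier ones.
    """
    if params.n_echoes < 2:
        raise ValueError("dynamic generation needs >= 2 echoes")
    te_s = np.asarray(params.echo_times) / 1000.0
    tissue = spec.signal_mask()
    s0 = np.where(tissue, spec.base_signal, 0.0)
    frames: List[MultiEchoImage] = []
    for k, t in enumerate(spec.frame_times):
        r2s = spec.r2star_field(t)
        signal = s0[..., None] * np.exp(-r2s[..., None] * te_s)
        rng = np.random.default_rng([seed, k])
        noisy = _apply_noise(signal, spec.noise_sigma, rng, spec.noise_model)
        frames.append(MultiEchoImage(data=noisy, params=params, frame_time=float(t)))
    return frames


# ---------------------------------------------------------------------------
# scenario presets (six experimental groups)


@dataclass(frozen=True)
class GroupScenario:
    """Qualitative tumor/normal kinetics of one experimental group.

    Curve shapes are piecewise-linear through qualitative anchors (peak
    position, duration of preferential accumulation); no numeric in vivo
    concentrations exist to copy.
    """

    name: str
    dextran_kda: float
    osmolarity_mosm: int
    tumor: PiecewiseCurve
    normal: PiecewiseCurve
    ventricle: PiecewiseCurve
    description: str = ""


_VENTRICLE = PiecewiseCurve(((15, 55), (30, 45), (45, 38), (60, 30), (90, 20), (120, 12)))


def _curve(*pts) -> PiecewiseCurve:
    return PiecewiseCurve(tuple(pts))


GROUP_PRESETS: Dict[str, GroupScenario] = {
    # size series, 337 mOsm/L
    "group1": GroupScenario(
        "group1", 10.0, 337,
        tumor=_curve((30, 20), (45, 30), (60, 24), (90, 15), (120, 8)),
        normal=_curve((30, 9), (45, 13), (60, 13), (90, 11), (120, 8)),
        ventricle=_VENTRICLE,
        description="10 kD: preferential through 90 min, peak at 45 min",
    ),
    "group2": GroupScenario(
        "group2", 5.0, 337,
        tumor=_curve((30, 16), (45, 26), (60, 28), (90, 22), (120, 16)),
        normal=_curve((30, 9), (45, 12), (60, 13), (90, 12), (120, 10)),
        ventricle=_VENTRICLE,
        description="5 kD: preferential for two hours, peak 45-60 min",
    ),
    "group3": GroupScenario(
        "group3", 3.0, 337,
        tumor=_curve((30, 28), (45, 22), (60, 14), (90, 9), (120, 6)),
        normal=_curve((30, 10), (45, 12), (60, 13), (90, 10), (120, 7)),
        ventricle=_VENTRICLE,
        description="3 kD: preferential only in the first 45 min, early peak",
    ),
    # osmolarity series, 10 kD
    "group4": GroupScenario(
        "group4", 10.0, 307,
        tumor=_curve((30, 18), (45, 26), (60, 22), (90, 14), (120, 9)),
        normal=_curve((30, 9), (45, 12), (60, 12), (90, 10.5), (120, 9)),
        ventricle=_VENTRICLE,
        description="307 mOsm/L: preferential through 90 min",
    ),
    "group5": GroupScenario(
        "group5", 10.0, 353,
        tumor=_curve((30, 22), (45, 32), (60, 26), (90, 16), (120, 9)),
        normal=_curve((30, 10), (45, 14), (60, 14), (90, 12), (120, 9)),
        ventricle=_VENTRICLE,
        description="353 mOsm/L: preferential through 90 min",
    ),
    "group6": GroupScenario(
        "group6", 10.0, 368,
        tumor=_curve((30, 14), (45, 18), (60, 16), (90, 12), (120, 8)),
        normal=_curve((30, 14), (45, 18), (60, 16), (90, 12), (120, 8)),
        ventricle=_VENTRICLE,
        description="368 mOsm/L: equal distribution, no preferential window",
    ),
}


def group_preset_names() -> Tuple[str, ...]:
    return tuple(sorted(GROUP_PRESETS))


def default_compartment_masks(
    grid_shape: Tuple[int, int, int] = (32, 32, 1),
) -> Dict[str, np.ndarray]:
    """Tumor / normal / ventricle / background disks on a synthetic slice."""
    nx, ny, nz = grid_shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    def disk(cx: float, cy: float, r: float) -> np.ndarray:
        m2 = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        return np.repeat(m2[..., None], nz, axis=2)

    tumor = disk(0.30 * nx, 0.55 * ny, 0.13 * nx)
    normal = disk(0.70 * nx, 0.55 * ny, 0.13 * nx)
    ventricle = disk(0.50 * nx, 0.20 * ny, 0.06 * nx)
    normal &= ~tumor
    ventricle &= ~(tumor | normal)
    background = ~(tumor | normal | ventricle)
    return {
        "tumor": tumor,
        "normal": normal,
        "ventricle": ventricle,
        "background": background,
    }


#: Pre-tracer tissue R2* (s^-1): tumor/normal brain tissue, low-rate CSF.
DEFAULT_BASELINE_R2STAR = {"tumor": 30.0, "normal": 25.0, "ventricle": 8.0}


def build_group_study(
    name: str,
    grid_shape: Tuple[int, int, int] = (32, 32, 1),
    noise_sigma: float = 0.0,
    base_signal: float = 1000.0,
    n_baseline_frames: int = 9,
    calib: CalibrationModel = DEFAULT_TRUE_CALIBRATION,
    concentration_scale: float = 1.0,
    noise_model: str = "rician",
) -> DynamicStudySpec:
    """Instantiate one of the six named group scenarios as a study spec."""
    key = name.strip().lower()
    if key not in GROUP_PRESETS:
        raise KeyError(
            f"unknown group preset {name!r}; available: {', '.join(group_preset_names())}"
        )
    sc = GROUP_PRESETS[key]
    k = concentration_scale
    return DynamicStudySpec(
        compartment_masks=default_compartment_masks(grid_shape),
        concentration_curves={
            "tumor": sc.tumor.scaled(k),
            "normal": sc.normal.scaled(k),
            "ventricle": sc.ventricle.scaled(k),
        },
        baseline_r2star=dict(DEFAULT_BASELINE_R2STAR),
        n_baseline_frames=n_baseline_frames,
        base_signal=base_signal,
        true_calibration=calib,
        noise_sigma=noise_sigma,
        noise_model=noise_model,
        metadata={
            "group": sc.name,
            "dextran_kda": sc.dextran_kda,
            "osmolarity_mosm": sc.osmolarity_mosm,
            "description": sc.description,
        },
    )
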
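"""MRI acquisition parameters and named sequence presets.

All echo/repetition times are stored in milliseconds; relaxation rates
produced downstream are in s^-1.  The ms -> s conversion happens inside the
fitting routines, never at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Tuple

__all__ = ["AcquisitionParams", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Geometry and timing of one multi-echo sequence.

    Parameters
    ----------
    echo_times : tuple of float
        Echo times in ms, strictly increasing and positive.
    repetition_time : float
        TR in ms.
    flip_angle : float, optional
        Excitation flip angle in degrees (``None`` when unspecified).
    field_of_view : tuple of float
        In-plane field of view in mm per axis.
    matrix_size : tuple of int
        In-plane matrix (voxel counts per axis).
    slice_thickness : float
        Slice thickness in mm.
    n_slices : int
        Number of slices.
    bandwidth_per_pixel : float, optional
        Readout bandwidth in Hz/pixel.
    name : str, optional
        Preset name, used to tag the map kind (R2 vs R2*).
    """

    echo_times: Tuple[float, ...]
    repetition_time: float
    flip_angle: Optional[float] = None
    field_of_view: Tuple[float, ...] = (32.0, 32.0)
    matrix_size: Tuple[int, ...] = (128, 128)
    slice_thickness: float = 1.0
    n_slices: int = 1
    bandwidth_per_pixel: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        tes = tuple(float(t) for t in self.echo_times)
        object.__setattr__(self, "echo_times", tes)
        if len(tes) < 1:
            raise ValueError("at least one echo time required")
        if tes[0] <= 0:
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("echo times must be strictly increasing")
        if any(m < 1 for m in self.matrix_size):
            raise ValueError("matrix_size entries must be >= 1")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def voxel_size(self) -> Tuple[float, float, float]:
        """(dx, dy, dz) in mm; in-plane from FOV/matrix, dz = slice thickness."""
        dx = self.field_of_view[0] / self.matrix_size[0]
        dy = self.field_of_view[1] / self.matrix_size[1]
        return (dx, dy, self.slice_thickness)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        d["echo_times"] = tuple(d["echo_times"])
        d["field_of_view"] = tuple(d["field_of_view"])
        d["matrix_size"] = tuple(int(m) for m in d["matrix_size"])
        return cls(**d)


def _te_range(start: float, step: float, n: int) -> Tuple[float, ...]:
    return tuple(round(start + step * i, 6) for i in range(n))


#: Named sequence presets.
PRESETS = {
    # 2D multi-echo spin echo for R2 (=1/T2) mapping.
    "spin-echo-t2": AcquisitionParams(
        echo_times=_te_range(15.0, 15.0, 10),
        repetition_time=4000.0,
        flip_angle=90.0,
        field_of_view=(32.0, 32.0),
        matrix_size=(128, 128),
        slice_thickness=1.0,
        n_slices=24,
        bandwidth_per_pixel=260.0,
        name="spin-echo-t2",
    ),
    # Multi-echo gradient echo (SWI) for R2* mapping.
    "swi-multiecho": AcquisitionParams(
        echo_times=_te_range(5.292, 5.0, 5),
        repetition_time=35.0,
        flip_angle=12.0,
        field_of_view=(32.0, 32.0),
        matrix_size=(128, 128),
        slice_thickness=0.5,
        n_slices=48,
        bandwidth_per_pixel=253.0,
        name="swi-multiecho",
    ),
    # Fast dual-echo 2D gradient echo for the dynamic series.
    "dual-echo-dynamic": AcquisitionParams(
        echo_times=(1.85, 7.2),
        repetition_time=92.0,
        flip_angle=12.0,
        field_of_view=(32.0, 32.0),
        matrix_size=(192, 192),
        slice_thickness=2.0,
        n_slices=7,
        bandwidth_per_pixel=510.0,
        name="dual-echo-dynamic",
    ),
    # Multi-echo gradient echo used for the agarose vial phantom.
    # Flip angle unspecified in the source protocol; left None on purpose.
    "phantom-multiecho": AcquisitionParams(
        echo_times=_te_range(1.6, 1.5, 8),
        repetition_time=35.0,
        flip_angle=None,
        field_of_view=(50.0, 50.0),
        matrix_size=(128, 128),
        slice_thickness=1.6,
        n_slices=10,
        bandwidth_per_pixel=1183.7125,
        name="phantom-multiecho",
    ),
}


def preset_names() -> Tuple[str, ...]:
    return tuple(sorted(PRESETS))


def get_preset(name: str) -> AcquisitionParams:
    """Look up a sequence preset by (case-insensitive) name."""
    key = name.strip().lower()
    if key not in PRESETS:
        raise KeyError(
            f"unknown acquisition preset {name!r}; available: {', '.join(preset_names())}"
        )
    return PRESETS[key]
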
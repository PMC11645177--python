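"""Voxelwise R2*/R2 mapping from multi-echo magnitude images.

Two routes exist: the closed-form dual-echo inversion used for the fast
dynamic series, and an SNR-gated weighted log-linear fit for multi-echo
acquisitions.  Echo times arrive in ms; fitted rates leave in s^-1 — the
conversion is centralised here.

Invalid voxels are never thrown as exceptions; they are marked in the map's
validity mask with a reason code so that downstream ROI statistics exclude
rather than absorb them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional, Sequence, Tuple

import numpy as np

from .acquisition import AcquisitionParams

if TYPE_CHECKING:  # avoid an import cycle; only needed for annotations
    from .synthetic import MultiEchoImage

__all__ = [
    "RelaxationMap",
    "NoiseEstimate",
    "NoValidVoxelsError",
    "REASON_OK",
    "REASON_NONPOSITIVE_SIGNAL",
    "REASON_INSUFFICIENT_ECHOES",
    "dual_echo_r2star",
    "estimate_noise_sigma",
    "select_echoes_by_snr",
    "fit_exponential_decay",
    "fit_decay_stack",
    "multi_echo_map",
    "resample_to_reference",
]

# invalid-voxel reason codes
REASON_OK = 0
REASON_NONPOSITIVE_SIGNAL = 1
REASON_INSUFFICIENT_ECHOES = 2

#: mean of a Rayleigh (zero-signal magnitude) variate is sigma * sqrt(pi/2)
_RICIAN_FLOOR = math.sqrt(math.pi / 2.0)


class NoValidVoxelsError(RuntimeError):
    """Raised when a whole-image fit produces no valid voxel at all."""


@dataclass
class RelaxationMap:
    """Voxelwise relaxation-rate field (s^-1) with validity bookkeeping."""

    values: np.ndarray
    s0: np.ndarray
    valid_mask: np.ndarray
    kind: str  # "R2*" or "R2"
    n_echoes_used: np.ndarray
    source_params: AcquisitionParams
    invalid_reason: Optional[np.ndarray] = None
    frame_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.kind not in ("R2*", "R2"):
            raise ValueError("kind must be 'R2*' or 'R2'")
        if self.invalid_reason is None:
            self.invalid_reason = np.where(
                self.valid_mask, REASON_OK, REASON_INSUFFICIENT_ECHOES
            ).astype(np.uint8)
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class NoiseEstimate:
    """Magnitude noise level sigma and how it was obtained."""

    sigma: float
    method: str  # "background-roi" | "provided"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.method not in ("background-roi", "provided"):
            raise ValueError("method must be 'background-roi' or 'provided'")


def _infer_kind(params: AcquisitionParams) -> str:
    name = (params.name or "").lower()
    return "R2" if name.startswith("spin-echo") else "R2*"


def dual_echo_r2star(
    image: MultiEchoImage,
    te1: Optional[float] = None,
    te2: Optional[float] = None,
) -> RelaxationMap:
    """Closed-form R2* from two echoes:

        R2* = ln(S(TE1) / S(TE2)) / (TE2 - TE1)

    with TE1/TE2 in ms converted to s.  Voxels where either magnitude is
    non-positive are marked invalid, not raised.
    """
    tes = image.params.echo_times
    if te1 is None or te2 is None:
        if len(tes) != 2:
            raise ValueError("image has more than two echoes; pass te1 and te2")
        te1, te2 = tes
    if te1 not in tes or te2 not in tes:
        raise ValueError("te1/te2 must be echo times of the image")
    if not 0 < te1 < te2:
        raise ValueError("need te2 > te1 > 0")
    s1 = image.data[..., tes.index(te1)]
    s2 = image.data[..., tes.index(te2)]
    if s1.shape != s2.shape:
        raise ValueError("echo volumes do not share a grid")
    valid = (s1 > 0) & (s2 > 0)
    dte_s = (te2 - te1) / 1000.0
    values = np.zeros_like(s1, dtype=float)
    np.divide(
        np.log(np.where(valid, s1, 1.0)) - np.log(np.where(valid, s2, 1.0)),
        dte_s,
        out=values,
        where=valid,
    )
    reason = np.where(valid, REASON_OK, REASON_NONPOSITIVE_SIGNAL).astype(np.uint8)
    return RelaxationMap(
        values=values,
        s0=np.where(valid, s1 * np.exp(values * te1 / 1000.0), 0.0),
        valid_mask=valid,
        kind="R2*",
        n_echoes_used=np.where(valid, 2, 0).astype(np.int16),
        source_params=image.params,
        invalid_reason=reason,
        frame_time=image.frame_time,
    )


def estimate_noise_sigma(
    image: MultiEchoImage,
    background_mask: Optional[np.ndarray] = None,
    sigma: Optional[float] = None,
) -> NoiseEstimate:
    """Estimate the magnitude noise sigma.

    With ``sigma`` given, it is passed through unchanged (method
    ``"provided"``).  Otherwise the mean magnitude over the signal-free
    background mask (all echoes pooled) is divided by the Rician floor
    sqrt(pi/2).
    """
    if sigma is not None:
        return NoiseEstimate(sigma=float(sigma), method="provided")
    if background_mask is None:
        raise ValueError("need a background mask or an explicit sigma")
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise ValueError("background mask is empty")
    vals = image.data[background_mask, :]
    est = float(vals.mean()) / _RICIAN_FLOOR
    if est <= 0:
        raise ValueError("background magnitudes are all zero; cannot estimate sigma")
    return NoiseEstimate(sigma=est, method="background-roi")


def select_echoes_by_snr(
    magnitudes: Sequence[float], sigma: float, threshold: float = 3.0
) -> int:
    """Length of the longest *leading* run of echoes with SNR > threshold.

    SNR is magnitude / sigma.  0 is a legal return (the voxel then becomes
    invalid downstream, which requires >= 2 echoes).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mags = np.asarray(magnitudes, dtype=float)
    ok = mags > threshold * sigma
    if ok.all():
        return int(ok.size)
    return int(np.argmin(ok))


def _leading_run_counts(data: np.ndarray, cutoff: float) -> np.ndarray:
    """Vectorised leading-run length of ``data > cutoff`` along the last axis."""
    ok = data > cutoff
    return np.cumprod(ok, axis=-1).sum(axis=-1).astype(np.int16)


def fit_exponential_decay(
    echo_times_ms: Sequence[float],
    magnitudes: Sequence[float],
    n_keep: Optional[int] = None,
) -> Tuple[float, float]:
    """Fit S(TE) = S0 exp(-rate * TE) to the first ``n_keep`` echoes.

    Weighted log-linear least squares (weights S^2, undoing the variance
    distortion of the log transform); exact on noiseless data.  Returns
    ``(rate_s_inv, amplitude)``; a non-positive kept magnitude yields
    ``(nan, nan)`` — the voxel is rejected, not the call.
    """
    te = np.asarray(echo_times_ms, dtype=float)
    s = np.asarray(magnitudes, dtype=float)
    if te.shape != s.shape:
        raise ValueError("echo_times and magnitudes differ in length")
    if n_keep is None:
        n_keep = s.size
    if n_keep < 2:
        raise ValueError("n_keep must be >= 2")
    te, s = te[:n_keep], s[:n_keep]
    if np.any(s <= 0):
        return (float("nan"), float("nan"))
    x = te / 1000.0
    y = np.log(s)
    w = s**2
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        return (float("nan"), float("nan"))
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return (float(-slope), float(math.exp(ym - slope * xm)))


def fit_decay_stack(
    echo_times_ms: Sequence[float], magnitudes: np.ndarray, n_keep: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised weighted log-linear fit of many decays at a fixed echo count.

    ``magnitudes`` has shape (n_voxels, n_echoes); the first ``n_keep``
    echoes are fitted per voxel.  Returns (rates s^-1, amplitudes, valid);
    voxels with a non-positive kept magnitude are invalid.  Used for
    ROI-level (e.g. per-vial) gating, where the echo count is decided once
    from the ROI-mean decay instead of per noisy voxel — per-voxel gating on
    noisy magnitudes truncation-biases gate-marginal echoes.
    """
    te = np.asarray(echo_times_ms, dtype=float)
    S = np.asarray(magnitudes, dtype=float)
    if n_keep < 2 or n_keep > te.size:
        raise ValueError("n_keep must be in [2, n_echoes]")
    x = te[:n_keep] / 1000.0
    s = S[:, :n_keep]
    valid = np.all(s > 0, axis=1)
    safe = np.where(s > 0, s, 1.0)
    w = safe**2
    y = np.log(safe)
    W = w.sum(axis=1)
    xm = (w * x).sum(axis=1) / W
    ym = (w * y).sum(axis=1) / W
    dx = x - xm[:, None]
    sxx = (w * dx * dx).sum(axis=1)
    valid &= sxx > 0
    slope = np.divide(
        (w * dx * (y - ym[:, None])).sum(axis=1), sxx,
        out=np.zeros_like(sxx), where=valid,
    )
    rates = np.where(valid, -slope, np.nan)
    amps = np.where(valid, np.exp(ym - slope * xm), np.nan)
    return rates, amps, valid


def multi_echo_map(
    image: MultiEchoImage,
    noise: NoiseEstimate,
    threshold: float = 3.0,
    kind: Optional[str] = None,
    n_keep: Optional[int] = None,
) -> RelaxationMap:
    """SNR-gated voxelwise exponential fit over a multi-echo image.

    Per voxel, the leading echoes whose SNR exceeds ``threshold`` are kept
    (:func:`select_echoes_by_snr`) and fitted with
    :func:`fit_exponential_decay`; voxels keeping fewer than 2 echoes are
    invalid.  ``kind`` defaults to R2 for spin-echo presets, else R2*.
    Passing ``n_keep`` overrides the per-voxel gate with a fixed leading
    echo count (ROI-level gating).
    """
    if image.n_echoes < 2:
        raise ValueError("need >= 2 echoes")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if kind is None:
        kind = _infer_kind(image.params)

    grid = image.grid_shape
    S = image.data.reshape(-1, image.n_echoes)
    te_s = np.asarray(image.params.echo_times) / 1000.0

    if n_keep is None:
        n_keep_vox = _leading_run_counts(S, threshold * noise.sigma)
    else:
        if not 2 <= n_keep <= image.n_echoes:
            raise ValueError("n_keep must be in [2, n_echoes]")
        n_keep_vox = np.full(S.shape[0], n_keep, dtype=np.int16)
    n_keep = n_keep_vox
    keep = np.arange(image.n_echoes)[None, :] < n_keep[:, None]
    pos = S > 0
    usable = keep & pos  # gate already implies positivity (threshold*sigma > 0)

    w = np.where(usable, S * S, 0.0)
    y = np.where(usable, np.log(np.where(pos, S, 1.0)), 0.0)
    x = te_s[None, :]

    wsum = w.sum(axis=1)
    fit_ok = (n_keep >= 2) & (wsum > 0)
    wsafe = np.where(wsum > 0, wsum, 1.0)
    xm = (w * x).sum(axis=1) / wsafe
    ym = (w * y).sum(axis=1) / wsafe
    dx = x - xm[:, None]
    sxx = (w * dx * dx).sum(axis=1)
    fit_ok &= sxx > 0
    sxy = (w * dx * (y - ym[:, None])).sum(axis=1)
    slope = np.divide(sxy, sxx, out=np.zeros_like(sxy), where=fit_ok)

    values = np.where(fit_ok, -slope, 0.0)
    s0 = np.where(fit_ok, np.exp(ym - slope * xm), 0.0)
    reason = np.full(S.shape[0], REASON_OK, dtype=np.uint8)
    reason[~fit_ok] = REASON_INSUFFICIENT_ECHOES
    reason[S[:, 0] <= 0] = REASON_NONPOSITIVE_SIGNAL

    if not fit_ok.any():
        raise NoValidVoxelsError("no voxel passed the SNR gate with >= 2 echoes")

    return RelaxationMap(
        values=values.reshape(grid),
        s0=s0.reshape(grid),
        valid_mask=fit_ok.reshape(grid),
        kind=kind,
        n_echoes_used=np.where(fit_ok, n_keep, 0).reshape(grid).astype(np.int16),
        source_params=image.params,
        invalid_reason=reason.reshape(grid),
        frame_time=image.frame_time,
    )


def resample_to_reference(
    rmap: RelaxationMap, reference: AcquisitionParams
) -> RelaxationMap:
    """Harmonise slice geometry by averaging blocks of thin slices.

    The source slice thickness must divide the reference thickness by an
    integer factor (e.g. 0.5 mm -> 1 mm).  Valid voxels in each block are
    averaged; a target voxel is valid when at least one contributor is.
    In-plane geometry is untouched (this is geometry harmonisation between
    co-acquired maps, not spatial registration).
    """
    src = rmap.source_params
    ratio = reference.slice_thickness / src.slice_thickness
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"slice thickness ratio {ratio} is not a positive integer multiple"
        )
    if factor == 1:
        return rmap
    if rmap.values.ndim != 3:
        raise ValueError("resampling expects a 3D map (x, y, slices)")
    nz = rmap.values.shape[2]
    if nz % factor:
        raise ValueError(f"{nz} slices not divisible by factor {factor}")

    def blocks(a: np.ndarray) -> np.ndarray:
        return a.reshape(a.shape[0], a.shape[1], nz // factor, factor)

    valid = blocks(rmap.valid_mask.astype(float))
    nvalid = valid.sum(axis=3)
    out_valid = nvalid > 0
    denom = np.where(out_valid, nvalid, 1.0)
    values = (blocks(rmap.values) * valid).sum(axis=3) / denom
    s0 = (blocks(rmap.s0) * valid).sum(axis=3) / denom
    nech = (blocks(rmap.n_echoes_used.astype(float)) * valid).sum(axis=3) / denom

    new_params = replace(
        src,
        slice_thickness=src.slice_thickness * factor,
        n_slices=max(1, src.n_slices // factor),
    )
    return RelaxationMap(
        values=np.where(out_valid, values, 0.0),
        s0=np.where(out_valid, s0, 0.0),
        valid_mask=out_valid,
        kind=rmap.kind,
        n_echoes_used=np.round(nech).astype(np.int16),
        source_params=new_params,
        frame_time=rmap.frame_time,
    )
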
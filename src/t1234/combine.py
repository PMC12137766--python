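"""Polarity-volume combination: complex read-averaging and magnitude.

The N/2 ghost has opposite phase in acquisitions with reversed read
gradient polarity, so averaging the real and imaginary parts of the two
read-polarity volumes cancels the ghost (and any other sign-flipping
artifact such as the low-frequency ripples) exactly while retaining the
signal; magnitude is then the square root of the sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["CombinedVolume", "complex_average_read", "magnitude", "tsnr", "check_alignment"]


@dataclass
class CombinedVolume:
    """A merged volume (complex before, real non-negative after magnitude)."""

    data: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


def _polarity_tag(v) -> str:
    return f"read{'+' if v.read_polarity > 0 else '-'}phase{'+' if v.phase_polarity > 0 else '-'}"


def check_alignment(a: np.ndarray, b: np.ndarray, tol_voxels: float = 0.25) -> float:
    """Center-of-mass shift (voxels) between two volumes.

    The pipeline assumes polarity volumes are already aligned (motion
    correction is upstream of this package); a large shift indicates
    misuse.  The center of mass is computed on smoothed magnitudes with
    low values suppressed, so that noise and the sign-flipping artifacts
    the pair legitimately carries (ghost, ripple) do not masquerade as
    motion; those artifacts still produce apparent shifts up to ~0.1
    voxel, hence the quarter-voxel default tolerance.  Returns the shift
    magnitude; raises if it exceeds ``tol_voxels``.
    """
    am = ndimage.gaussian_filter(np.abs(a), 1.0)
    bm = ndimage.gaussian_filter(np.abs(b), 1.0)
    am = np.where(am > 0.25 * am.max(), am, 0.0)
    bm = np.where(bm > 0.25 * bm.max(), bm, 0.0)
    shifts = []
    for axis in range(am.ndim):
        idx = np.arange(am.shape[axis])
        sh = [1] * am.ndim
        sh[axis] = -1
        w = idx.reshape(sh)
        ca = float((am * w).sum() / am.sum())
        cb = float((bm * w).sum() / bm.sum())
        shifts.append(ca - cb)
    shift = float(np.linalg.norm(shifts))
    if shift > tol_voxels:
        raise ValueError(
            f"polarity volumes appear misaligned (center-of-mass shift {shift:.3f} "
            f"voxels > {tol_voxels}); register them before combining"
        )
    return shift


def complex_average_read(vol_pos, vol_neg, alignment_tol: float = 0.25) -> CombinedVolume:
    """Voxelwise complex mean of an opposite-read-polarity pair.

    The inputs must share the phase-encode polarity (their distortions are
    identical) and differ in read polarity (their ghost/ripple terms have
    opposite sign and cancel in the mean).
    """
    if vol_pos.data.shape != vol_neg.data.shape:
        raise ValueError("volume shape mismatch")
    if vol_pos.read_polarity == vol_neg.read_polarity:
        raise ValueError("inputs must have opposite read polarity")
    if vol_pos.phase_polarity != vol_neg.phase_polarity:
        raise ValueError("inputs must share phase-encode polarity")
    check_alignment(vol_pos.data, vol_neg.data, alignment_tol)
    data = 0.5 * (vol_pos.data + vol_neg.data)
    return CombinedVolume(data=data, provenance=[_polarity_tag(vol_pos), _polarity_tag(vol_neg)])


def magnitude(vol: CombinedVolume) -> CombinedVolume:
    """Square root of the sum of squared real and imaginary parts."""
    data = np.sqrt(vol.data.real**2 + vol.data.imag**2)
    return CombinedVolume(data=data, provenance=list(vol.provenance) + ["magnitude"])


def tsnr(series: list[np.ndarray]) -> np.ndarray:
    """Voxelwise temporal SNR: mean over SD (ddof=1) of a volume series.

    Voxels with zero temporal SD are NaN.
    """
    if len(series) < 3:
        raise ValueError(f"tsnr needs >= 3 volumes (got {len(series)})")
    stack = np.stack([np.asarray(v, dtype=float) for v in series])
    if stack.ndim < 2:
        raise ValueError("series elements must be arrays")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    return out
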
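"""Lookup-table T1 quantification from the two-inversion signal ratio.

The forward Bloch model turns each candidate T1 into a pair of
steady-state signals (s1, s2) at the two inversion times; their signed
ratio s1/s2 is, over a wide T1 range, strictly monotonic in T1 and can
therefore be inverted by piecewise-linear interpolation.  Because the
spin history — and hence the saturation of the recovery curve — depends
on the locally realized flip angles, the table is B1-specific: voxelwise
T1 mapping builds one table per relative-B1 bin and inverts each voxel
with the table of its nearest bin (a first-order treatment of transmit
inhomogeneity).

Ratios outside a table's range, and voxels whose TI2 signal is below a
floor, map to NaN rather than being clamped, so failures stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bloch import steady_state_signals_array
from .protocol import ProtocolParams

__all__ = ["LookupTable", "T1Map", "build_lut", "lut_invert", "map_t1", "save_lut", "load_lut"]


@dataclass
class LookupTable:
    """Monotonic map between T1 (ms) and the TI1/TI2 signal ratio for one B1 scale."""

    t1_axis: np.ndarray
    ratio_axis: np.ndarray
    b1_scale: float
    protocol_tag: str
    monotonic_domain: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.t1_axis) != len(self.ratio_axis):
            raise ValueError("t1_axis and ratio_axis must have equal length")
        if np.any(np.diff(self.t1_axis) <= 0):
            raise ValueError("t1_axis must be strictly ascending")

    def _domain_slice(self) -> slice:
        lo, hi = self.monotonic_domain
        i0 = int(np.searchsorted(self.t1_axis, lo, side="left"))
        i1 = int(np.searchsorted(self.t1_axis, hi, side="right"))
        return slice(i0, i1)


@dataclass
class T1Map:
    """Quantitative T1 in ms on a 3-D grid; undefined voxels are NaN."""

    values: np.ndarray
    affine: np.ndarray
    units: str = "ms"


def _largest_monotonic_run(ratio: np.ndarray, t1_axis: np.ndarray, valid: np.ndarray):
    """Largest contiguous index range over which ratio is strictly monotonic."""
    n = len(ratio)
    if n == 1:
        return (0, 0)
    best = (0, 0)
    start = 0
    direction = 0
    for i in range(1, n):
        if not (valid[i] and valid[i - 1]):
            start, direction = i, 0
            continue
        d = np.sign(ratio[i] - ratio[i - 1])
        if d == 0:
            start, direction = i, 0
            continue
        if direction == 0:
            direction = d
            start = i - 1
        elif d != direction:
            start = i - 1
            direction = d
        if i - start > best[1] - best[0]:
            best = (start, i)
    return best


def build_lut(
    p: ProtocolParams,
    t1_axis: np.ndarray | None = None,
    b1_scale: float = 1.0,
    s2_floor: float = 1e-12,
) -> LookupTable:
    """Tabulate the steady-state TI1/TI2 signal ratio over a T1 axis.

    Default axis: 600..3000 ms in 10 ms steps.  Entries where |s2| falls
    below ``s2_floor`` are excluded from the monotonic domain (with a
    warning), as is anything outside the largest strictly-monotonic run.
    """
    t1_axis = np.arange(600.0, 3000.0 + 1e-9, 10.0) if t1_axis is None else np.asarray(t1_axis, dtype=float)
    if np.any(t1_axis <= 0) or np.any(np.diff(t1_axis) <= 0):
        raise ValueError("t1_axis must be positive and strictly ascending")
    s1, s2 = steady_state_signals_array(p, t1_axis, m0=1.0, b1_scale=b1_scale)
    valid = np.abs(s2) > s2_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, s1 / np.where(valid, s2, 1.0), np.nan)
    if not np.all(valid):
        warnings.warn(
            f"{np.sum(~valid)} T1 grid points have |s2| <= {s2_floor} and were "
            "removed from the lookup domain",
            stacklevel=2,
        )
    if t1_axis.size == 1:
        dom = (float(t1_axis[0]), float(t1_axis[0]))
    else:
        i0, i1 = _largest_monotonic_run(ratio, t1_axis, valid)
        dom = (float(t1_axis[i0]), float(t1_axis[i1]))
        if i1 - i0 < len(t1_axis) - 1:
            warnings.warn(
                f"ratio is strictly monotonic only over [{dom[0]}, {dom[1]}] ms "
                f"({i1 - i0 + 1} of {len(t1_axis)} grid points)",
                stacklevel=2,
            )
    return LookupTable(
        t1_axis=t1_axis,
        ratio_axis=ratio,
        b1_scale=b1_scale,
        protocol_tag=p.name,
        monotonic_domain=dom,
    )


def lut_invert(lut: LookupTable, ratio) -> np.ndarray | float:
    """T1 (ms) for the given ratio(s) by piecewise-linear inverse interpolation.

    Ratios outside the table's monotonic range return NaN.
    """
    ratio = np.asarray(ratio, dtype=float)
    sl = lut._domain_slice()
    r = lut.ratio_axis[sl]
    t = lut.t1_axis[sl]
    if r.size == 0:
        out = np.full(ratio.shape, np.nan)
        return float(out) if out.ndim == 0 else out
    if r.size == 1:
        out = np.where(np.isclose(ratio, r[0]), t[0], np.nan)
        return float(out) if out.ndim == 0 else out
    if r[-1] < r[0]:  # make xp ascending for np.interp
        r, t = r[::-1], t[::-1]
    out = np.interp(ratio, r, t, left=np.nan, right=np.nan)
    out = np.where(np.isnan(ratio), np.nan, out)
    return float(out) if out.ndim == 0 else out


def map_t1(
    s1_vol: np.ndarray,
    s2_vol: np.ndarray,
    p: ProtocolParams,
    b1_map: np.ndarray | float = 1.0,
    n_b1_bins: int = 50,
    t1_axis: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    s2_floor: float = 1e-8,
) -> T1Map:
    """Voxelwise T1 from the two inversion-time volumes.

    A family of lookup tables is built at ``n_b1_bins`` relative-B1 bin
    centers spanning the range of ``b1_map``; each voxel's signed ratio
    s1/s2 is inverted with the table of its nearest bin.  The default bin
    count keeps the B1-discretization error of T1 well below the lookup
    grid step over a [0.7, 1.3] B1 range.  Voxels with
    |s2| below ``s2_floor`` (in the same units as the volumes) are NaN.
    """
    s1_vol = np.asarray(s1_vol, dtype=float)
    s2_vol = np.asarray(s2_vol, dtype=float)
    if s1_vol.shape != s2_vol.shape:
        raise ValueError(f"s1/s2 shape mismatch: {s1_vol.shape} vs {s2_vol.shape}")
    if np.isscalar(b1_map) or np.asarray(b1_map).ndim == 0:
        b1_arr = np.full(s1_vol.shape, float(b1_map))
    else:
        b1_arr = np.asarray(b1_map, dtype=float)
        if b1_arr.shape != s1_vol.shape:
            raise ValueError(f"b1_map shape mismatch: {b1_arr.shape} vs {s1_vol.shape}")
    lo, hi = float(np.min(b1_arr)), float(np.max(b1_arr))
    if hi - lo < 1e-12:
        centers = np.array([lo])
    else:
        edges = np.linspace(lo, hi, n_b1_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-bin domain warnings are expected in bulk
        luts = [build_lut(p, t1_axis=t1_axis, b1_scale=c) for c in centers]
    valid = np.abs(s2_vol) > s2_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, s1_vol / np.where(valid, s2_vol, 1.0), np.nan)
    out = np.full(s1_vol.shape, np.nan)
    if centers.size == 1:
        bin_idx = np.zeros(s1_vol.shape, dtype=int)
    else:
        bin_idx = np.argmin(np.abs(b1_arr[..., None] - centers), axis=-1)
    for k, lut in enumerate(luts):
        sel = (bin_idx == k) & valid
        if np.any(sel):
            out[sel] = lut_invert(lut, ratio[sel])
    return T1Map(values=out, affine=np.eye(4) if affine is None else affine)


# ---------------------------------------------------------------------------
# Serialization

def save_lut(lut: LookupTable, path) -> None:
    """Write a lookup table as CSV (t1_ms, ratio) with a metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# protocol_tag={lut.protocol_tag} b1_scale={lut.b1_scale} "
                 f"monotonic_domain={lut.monotonic_domain[0]},{lut.monotonic_domain[1]}\n")
        pd.DataFrame({"t1_ms": lut.t1_axis, "ratio": lut.ratio_axis}).to_csv(fh, index=False)


def load_lut(path) -> LookupTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        df = pd.read_csv(fh)
    lo, hi = (float(x) for x in meta["monotonic_domain"].split(","))
    return LookupTable(
        t1_axis=df["t1_ms"].to_numpy(),
        ratio_axis=df["ratio"].to_numpy(),
        b1_scale=float(meta["b1_scale"]),
        protocol_tag=meta["protocol_tag"],
        monotonic_domain=(lo, hi),
    )


def save_t1_nifti(t1: T1Map, path) -> None:
    nib.save(nib.Nifti1Image(t1.values.astype(np.float32), t1.affine), str(path))
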
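"""Phase-encode distortion fields: estimation, scaling, application.

EPI off-resonance displaces each voxel along the phase-encode (PE) axis
by an amount proportional to the local B0 offset and the effective echo
spacing; reversing the PE polarity reverses the displacement.  From a
pair of oppositely distorted magnitude images this module estimates the
voxelwise 1-D displacement field (reverse-PE correction in the spirit of
TOPUP), by minimizing the sum of squared differences between the two
images each resampled halfway toward the common midpoint geometry, with
Jacobian intensity modulation and a bending-energy smoothness penalty on
a coarse-to-fine spline (trilinear B-spline) coefficient grid.

Because displacement scales linearly with effective echo spacing, a
field estimated at one echo spacing can be multiplied by a scalar to
synthesize the distortion level of any other acquisition: factor 0 gives
the distortion-free geometry, 1 reproduces the source distortion, and
arbitrary factors match a target protocol.

Conventions: displacements are in voxels, positive toward increasing
index along ``pe_axis``; the stored field is the acquisition displacement
of the +PE-polarity image under the pull convention out(x) = img(x + d(x)),
so correcting the +PE image applies ``-d`` and the -PE image ``+d``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "DisplacementField",
    "estimate_field",
    "scale_field",
    "apply_field",
    "synthesize_matched",
    "warp_1d",
    "save_field",
    "load_field",
]


@dataclass
class DisplacementField:
    """Voxelwise PE displacement (voxels) tied to an effective echo spacing."""

    d: np.ndarray
    pe_axis: int
    eff_esp: float  # ms of the acquisition the field refers to
    smoothness: float = 0.0  # penalty weight used during estimation
    converged: bool = True
    # one array per coarse-to-fine level; the data term is only comparable
    # within a level (image smoothing differs between levels)
    objective_history: list = field(default_factory=list)
    ssd_history: list = field(default_factory=list)


def warp_1d(img: np.ndarray, d: np.ndarray, pe_axis: int, jacobian: bool = True) -> np.ndarray:
    """Resample ``img`` at x + d(x) along ``pe_axis`` (linear, edge-padded).

    With ``jacobian`` the result is multiplied by (1 + dd/dx), clipped at 0,
    which conserves integrated intensity for smooth fields.  Works on real
    or complex images.
    """
    img = np.asarray(img)
    d = np.broadcast_to(np.asarray(d, dtype=float), img.shape)
    n = img.shape[pe_axis]
    idx_shape = [1] * img.ndim
    idx_shape[pe_axis] = n
    base = np.arange(n, dtype=float).reshape(idx_shape)
    pos = np.clip(base + d, 0.0, n - 1.0)
    i0 = np.floor(pos).astype(np.intp)
    i0 = np.minimum(i0, n - 2) if n > 1 else i0
    w = pos - i0
    lo = np.take_along_axis(img, i0, axis=pe_axis)
    hi = np.take_along_axis(img, np.minimum(i0 + 1, n - 1), axis=pe_axis)
    out = lo * (1.0 - w) + hi * w
    if jacobian:
        jac = 1.0 + np.gradient(d, axis=pe_axis)
        out = out * np.clip(jac, 0.0, None)
    return out


def apply_field(img: np.ndarray, f: DisplacementField, jacobian: bool = True) -> np.ndarray:
    """Apply a displacement field to an image (pull resampling along PE)."""
    return warp_1d(img, f.d, f.pe_axis, jacobian=jacobian)


def scale_field(f: DisplacementField, factor: float) -> DisplacementField:
    """Scale displacements (and the echo spacing they correspond to) by ``factor``.

    factor 0 is the distortion-free target; negative factors invert the field.
    """
    if not np.isfinite(factor):
        raise ValueError(f"factor must be finite (got {factor})")
    return replace(f, d=f.d * factor, eff_esp=f.eff_esp * factor)


def synthesize_matched(img_corrected: np.ndarray, f: DisplacementField, target_eff_esp: float) -> np.ndarray:
    """Warp a corrected (midpoint-geometry) image to a target distortion level.

    The field is rescaled by target_eff_esp / f.eff_esp and applied with
    Jacobian modulation, producing the distortion the +PE acquisition would
    have at the target effective echo spacing.  target 0 returns the image
    unchanged (up to resampling at integer nodes, which is exact).
    """
    if f.eff_esp == 0:
        raise ValueError("source field has eff_esp == 0; scale factor undefined")
    g = scale_field(f, target_eff_esp / f.eff_esp)
    return apply_field(img_corrected, g, jacobian=True)


# ---------------------------------------------------------------------------
# Estimation

def _node_count(n: int, h: float) -> int:
    return int(np.ceil((n - 1) / h)) + 1 if n > 1 else 1


def _coeff_to_field(c: np.ndarray, shape: tuple[int, ...], h: float) -> np.ndarray:
    """Trilinear upsampling of the node grid to the full voxel grid."""
    coords = np.meshgrid(*[np.arange(n) / h for n in shape], indexing="ij")
    return ndimage.map_coordinates(c, coords, order=1, mode="nearest")


def _field_grad_to_coeff(g: np.ndarray, h: float, c_shape: tuple[int, ...]) -> np.ndarray:
    """Adjoint of trilinear upsampling: scatter voxel gradients onto nodes."""
    shape = g.shape
    pos = [np.arange(n) / h for n in shape]
    i0 = [np.minimum(np.floor(p).astype(np.intp), max(c_shape[a] - 2, 0)) for a, p in enumerate(pos)]
    w = [p - f for p, f in zip(pos, i0)]
    out = np.zeros(int(np.prod(c_shape)))
    strides = np.array([c_shape[1] * c_shape[2], c_shape[2], 1], dtype=np.intp)
    for corner in range(8):
        bits = [(corner >> a) & 1 for a in range(3)]
        lin = np.zeros(shape, dtype=np.intp)
        wt = np.ones(shape)
        for a in range(3):
            ia = np.minimum(i0[a] + bits[a], c_shape[a] - 1)
            wa = w[a] if bits[a] else 1.0 - w[a]
            sh = [-1 if k == a else 1 for k in range(3)]
            lin = lin + (ia * strides[a]).reshape(sh)
            wt = wt * wa.reshape(sh)
        out += np.bincount(lin.ravel(), weights=(g * wt).ravel(), minlength=out.size)
    return out.reshape(c_shape)


_D2 = np.array([1.0, -2.0, 1.0])


def _bending(c: np.ndarray, h: float) -> tuple[float, np.ndarray]:
    """Mean-square field curvature (voxel^-1 units) on the node grid, and gradient.

    Second differences of node values divided by h^2 approximate the
    second derivative of the voxelwise field, making the penalty weight
    comparable across coarse-to-fine levels.
    """
    val = 0.0
    grad = np.zeros_like(c)
    inv_h4 = 1.0 / h**4
    for axis in range(c.ndim):
        if c.shape[axis] < 3:
            continue
        d2 = ndimage.correlate1d(c, _D2, axis=axis, mode="constant")
        val += float(np.mean(d2**2)) * inv_h4
        grad += 2.0 * inv_h4 * ndimage.correlate1d(d2, _D2, axis=axis, mode="constant") / d2.size
    return val, grad


def _half_warped_ssd(img_pos, img_neg, d, pe_axis):
    """Midpoint residual: each image corrected with its full field (the
    relative displacement between the pair is 2d)."""
    wp = warp_1d(img_pos, -d, pe_axis, jacobian=True)
    wn = warp_1d(img_neg, +d, pe_axis, jacobian=True)
    r = wp - wn
    return r, float(np.mean(r**2))


def estimate_field(
    img_pos: np.ndarray,
    img_neg: np.ndarray,
    pe_axis: int = 1,
    knot_spacing: float = 4.0,
    smooth_weight: float = 0.1,
    max_iter: int = 200,
    eff_esp: float = np.nan,
) -> DisplacementField:
    """Estimate the +PE displacement field from an opposite-polarity pair.

    Coarse-to-fine: the images are Gaussian-smoothed and the field is
    parameterized on progressively finer node grids (4x, 2x, 1x the final
    ``knot_spacing``), each level refined by gradient descent with a
    backtracking line search that only accepts steps decreasing the
    penalized objective without increasing the data term.  Deterministic
    given inputs and settings.

    ``smooth_weight`` multiplies the mean-square bending energy of the node
    grid (images are intensity-normalized internally, so the weight is
    scale-free).  ``eff_esp`` is carried as metadata for later rescaling.
    """
    img_pos = np.asarray(img_pos, dtype=float)
    img_neg = np.asarray(img_neg, dtype=float)
    if img_pos.shape != img_neg.shape:
        raise ValueError(f"image shape mismatch: {img_pos.shape} vs {img_neg.shape}")
    if img_pos.ndim != 3:
        raise ValueError("estimate_field expects 3-D images")
    scale = max(float(np.max(np.abs(img_pos))), float(np.max(np.abs(img_neg))), 1e-30)
    ip, in_ = img_pos / scale, img_neg / scale

    shape = img_pos.shape
    levels = [(4.0 * knot_spacing, 2.0), (2.0 * knot_spacing, 1.0), (float(knot_spacing), 0.0)]
    d = np.zeros(shape)
    obj_hist: list[np.ndarray] = []
    ssd_hist: list[np.ndarray] = []
    converged = True
    for h, sigma in levels:
        level_obj: list[float] = []
        level_ssd: list[float] = []
        sp = ndimage.gaussian_filter(ip, sigma) if sigma > 0 else ip
        sn = ndimage.gaussian_filter(in_, sigma) if sigma > 0 else in_
        # image derivatives along PE, used in the gradient of the residual
        gp = np.gradient(sp, axis=pe_axis)
        gn = np.gradient(sn, axis=pe_axis)
        c_shape = tuple(_node_count(n, h) for n in shape)
        # re-fit current field on this level's node grid (exact for nested grids)
        node_coords = np.meshgrid(
            *[np.minimum(np.arange(m) * h, n - 1) for m, n in zip(c_shape, shape)],
            indexing="ij",
        )
        c = ndimage.map_coordinates(d, node_coords, order=1, mode="nearest")

        d = _coeff_to_field(c, shape, h)
        r, ssd = _half_warped_ssd(sp, sn, d, pe_axis)
        bend, _ = _bending(c, h)
        fval = ssd + smooth_weight * bend
        step = 0.5
        level_converged = False
        for _ in range(max_iter):
            # d(residual)/d(displacement): both warped images move with d
            dp = warp_1d(gp, -d, pe_axis, jacobian=False)
            dn = warp_1d(gn, +d, pe_axis, jacobian=False)
            g_vox = 2.0 * r * (-dp - dn) / r.size
            g_c = _field_grad_to_coeff(g_vox, h, c_shape)
            _, g_bend = _bending(c, h)
            g_c = g_c + smooth_weight * g_bend
            gmax = float(np.max(np.abs(g_c)))
            if gmax == 0.0:
                level_converged = True
                break
            direction = -g_c / gmax
            accepted = False
            while step >= 1e-4:
                c_try = c + step * direction
                d_try = _coeff_to_field(c_try, shape, h)
                r_try, ssd_try = _half_warped_ssd(sp, sn, d_try, pe_axis)
                bend_try, _ = _bending(c_try, h)
                f_try = ssd_try + smooth_weight * bend_try
                if f_try < fval and ssd_try <= ssd + 1e-18:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                level_converged = True
                break
            rel_drop = (fval - f_try) / max(fval, 1e-30)
            c, d, r, ssd, fval = c_try, d_try, r_try, ssd_try, f_try
            level_obj.append(fval)
            level_ssd.append(ssd)
            step = min(step * 1.5, 2.0)
            if rel_drop < 1e-9:
                level_converged = True
                break
        converged = converged and level_converged
        d = _coeff_to_field(c, shape, h)
        obj_hist.append(np.array(level_obj))
        ssd_hist.append(np.array(level_ssd))
    return DisplacementField(
        d=d,
        pe_axis=pe_axis,
        eff_esp=eff_esp,
        smoothness=smooth_weight,
        converged=converged,
        objective_history=obj_hist,
        ssd_history=ssd_hist,
    )


# ---------------------------------------------------------------------------
# I/O: field as NIfTI plus JSON sidecar carrying pe_axis / eff_esp

def save_field(f: DisplacementField, path, affine: np.ndarray | None = None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(f.d.astype(np.float32), np.eye(4) if affine is None else affine), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {"pe_axis": f.pe_axis, "eff_esp_ms": f.eff_esp, "smoothness": f.smoothness,
            "converged": bool(f.converged), "units": "voxels"}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))


def load_field(path) -> DisplacementField:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar.read_text())
    return DisplacementField(
        d=np.asarray(img.dataobj, dtype=float),
        pe_axis=int(meta["pe_axis"]),
        eff_esp=float(meta["eff_esp_ms"]),
        smoothness=float(meta.get("smoothness", 0.0)),
        converged=bool(meta.get("converged", True)),
    )
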
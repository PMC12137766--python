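"""Synthetic digital brain phantom and forward acquisition simulator.

The phantom is a nested-ellipsoid "brain": a white-matter core wrapped in
a gray-matter ribbon (at least three voxels thick) inside a CSF shell,
with a smooth low-order-polynomial B0 field plus one localized Gaussian
off-resonance blob (emulating air-cavity inhomogeneity), a smooth radial
relative-B1 profile in [0.7, 1.3], and a normalized cortical-depth map on
the ribbon.  Everything is deterministic given the seed.

The forward simulator produces the polarity-tagged complex volumes of a
full session: per-voxel steady-state Bloch signal at the selected
inversion time (accelerated by tabulating signals per tissue and per B1
bin), geometric distortion along the phase-encode axis proportional to
the local B0 offset and the effective echo spacing (sign set by the
phase-encode polarity), an N/2 ghost added as a pure-imaginary
half-FOV-shifted copy whose sign flips with read polarity, an additive
low-spatial-frequency ripple that also flips with read polarity, and
complex Gaussian noise.  Complex averaging across read polarities
therefore cancels ghost and ripple exactly while retaining the signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .bloch import TissueParams, steady_state_signals_array, steady_state_signals_fa_grid
from .distortion import warp_1d
from .protocol import ProtocolParams, effective_echo_spacing, validate_protocol

__all__ = ["Phantom", "AcquiredVolume", "make_phantom", "simulate_acquisition",
           "acquire_full_session", "true_displacement", "save_session"]

LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3

DEFAULT_TISSUES = {
    LABEL_CSF: TissueParams("csf", t1=2800.0, m0=1.0),
    LABEL_GM: TissueParams("gm", t1=1900.0, m0=0.8),
    LABEL_WM: TissueParams("wm", t1=1200.0, m0=0.7),
}


@dataclass
class Phantom:
    """Tissue labels, compartment parameters and the smooth nuisance fields."""

    labels: np.ndarray  # int: 0 background, 1 CSF, 2 GM ribbon, 3 WM core
    tissue_table: dict[int, TissueParams]
    b0_map: np.ndarray  # Hz
    b1_map: np.ndarray  # relative transmit efficiency, ~1
    depth_map: np.ndarray  # [0, 1] on the GM ribbon, NaN elsewhere
    voxel_size: tuple[float, float, float]
    seed: int

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class AcquiredVolume:
    """One polarity-tagged complex volume plus its acquisition metadata."""

    data: np.ndarray  # complex
    read_polarity: int  # +1 / -1
    phase_polarity: int  # +1 / -1
    eff_esp: float  # ms
    pe_axis: int
    which_ti: int
    noise_sigma: float
    seed: int

    def sidecar(self) -> dict:
        return {
            "read_polarity": self.read_polarity,
            "phase_polarity": self.phase_polarity,
            "eff_esp_ms": self.eff_esp,
            "pe_axis": self.pe_axis,
            "which_ti": self.which_ti,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    tissue_table: dict[int, TissueParams] | None = None,
    b0_blob_amplitude_hz: float = 30.0,
) -> Phantom:
    """Build the nested-ellipsoid phantom; deterministic given ``seed``.

    The seed jitters the ellipsoid axes, the polynomial B0 coefficients
    and the position of the off-resonance blob, so different seeds give
    geometrically distinct but statistically comparable phantoms.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError(f"phantom shape must be >= 32 per axis (got {shape})")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]

    # anisotropic ellipsoidal radius, mildly seed-jittered
    semi = np.array([0.40, 0.36, 0.38]) * np.array(shape) * (1.0 + 0.04 * rng.uniform(-1, 1, 3))
    rho = np.sqrt(sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)))

    min_semi = float(np.min(semi))
    # ribbon thickness >= 3 voxels plus margin along the smallest semi-axis
    t_gm = max(4.0 / min_semi, 0.12)
    t_csf = max(3.0 / min_semi, 0.09)
    rho_wm = 1.0 - t_gm - t_csf
    rho_gm = 1.0 - t_csf

    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= 1.0] = LABEL_CSF
    labels[rho <= rho_gm] = LABEL_GM
    labels[rho <= rho_wm] = LABEL_WM

    # smooth low-order polynomial B0 plus one localized Gaussian blob
    xn = [(g - c) / n for g, c, n in zip(grids, center, shape)]  # ~[-0.5, 0.5]
    coef = rng.uniform(-1, 1, 6)
    b0 = 8.0 * (coef[0] * xn[0] + coef[1] * xn[1] + coef[2] * xn[2]) + 12.0 * (
        coef[3] * xn[0] * xn[1] + coef[4] * xn[1] * xn[2] + coef[5] * (xn[2] ** 2 - 1.0 / 12)
    )
    blob_pos = [c + 0.25 * n * u for c, n, u in zip(center, shape, rng.uniform(-1, 1, 3))]
    blob_sigma = 0.10 * min(shape)
    b0 = b0 + b0_blob_amplitude_hz * np.exp(
        -sum((g - pb) ** 2 for g, pb in zip(grids, blob_pos)) / (2 * blob_sigma**2)
    )

    # smooth radial transmit profile: high at the center, low peripherally
    r_norm = np.clip(rho, 0.0, 1.5) / 1.5
    b1 = 1.3 - 0.6 * r_norm**2
    b1 = np.clip(b1, 0.7, 1.3)

    depth = np.full(shape, np.nan)
    gm = labels == LABEL_GM
    raw = (rho[gm] - rho_wm) / (rho_gm - rho_wm)
    # normalize so the sampled ribbon spans exactly [0, 1]
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    depth[gm] = raw

    return Phantom(
        labels=labels,
        tissue_table=dict(DEFAULT_TISSUES if tissue_table is None else tissue_table),
        b0_map=b0,
        b1_map=b1,
        depth_map=depth,
        voxel_size=tuple(float(v) for v in voxel_size),
        seed=int(seed),
    )


def ideal_signal_volume(
    ph: Phantom,
    p: ProtocolParams,
    which_ti: int,
    n_b1_bins: int = 400,
    t1_override: np.ndarray | None = None,
) -> np.ndarray:
    """Noise- and artifact-free signal image at the selected inversion time.

    Tabulates the steady-state signal per tissue compartment on a fine
    grid of relative-B1 values (fine enough to be effectively continuous)
    and assigns voxels by label and nearest bin.  ``t1_override`` (same
    shape, ms, NaN = use compartment value) allows injecting local T1
    structure such as a mid-depth dip.
    """
    if which_ti not in (1, 2):
        raise ValueError("which_ti must be 1 or 2")
    lo, hi = float(ph.b1_map.min()), float(ph.b1_map.max())
    centers = np.array([lo]) if hi - lo < 1e-12 else np.linspace(lo, hi, n_b1_bins)
    bin_idx = (
        np.zeros(ph.labels.shape, dtype=int)
        if centers.size == 1
        else np.rint((ph.b1_map - lo) / max(hi - lo, 1e-30) * (n_b1_bins - 1)).astype(int)
    )
    out = np.zeros(ph.labels.shape)
    for label, tissue in ph.tissue_table.items():
        sel_label = ph.labels == label
        if not np.any(sel_label):
            continue
        if t1_override is None:
            # B1 scaling of the flip angles == evaluating a flip-angle grid
            s1, s2 = steady_state_signals_fa_grid(
                p, tissue.t1, p.fa1 * centers, p.fa2 * centers, m0=tissue.m0
            )
            s = s1 if which_ti == 1 else s2
            out[sel_label] = s[bin_idx[sel_label]]
        else:
            for k, b1c in enumerate(centers):
                sel = sel_label & (bin_idx == k)
                if not np.any(sel):
                    continue
                t1_vox = np.where(np.isnan(t1_override[sel]), tissue.t1, t1_override[sel])
                uniq, inv = np.unique(t1_vox, return_inverse=True)
                s1, s2 = steady_state_signals_array(p, uniq, m0=tissue.m0, b1_scale=float(b1c))
                s = s1 if which_ti == 1 else s2
                out[sel] = s[inv]
    return out


def true_displacement(ph: Phantom, eff_esp_ms: float, pe_axis: int = 1, phase_polarity: int = 1) -> np.ndarray:
    """Analytic PE displacement (voxels) of an acquisition on this phantom.

    shift = B0[Hz] * eff_esp[s] * n_pe * polarity, with n_pe the grid size
    along the phase-encode axis.
    """
    n_pe = ph.labels.shape[pe_axis]
    return ph.b0_map * (eff_esp_ms * 1e-3) * n_pe * phase_polarity


def _ripple_pattern(shape: tuple[int, ...], pe_axis: int) -> np.ndarray:
    """Low-spatial-frequency sinusoid used as the 'fuzzy ripple' artifact."""
    n = shape[pe_axis]
    idx_shape = [1] * len(shape)
    idx_shape[pe_axis] = n
    t = np.arange(n).reshape(idx_shape) / n
    return np.broadcast_to(np.sin(2 * np.pi * 3.0 * t + 0.7), shape).copy()


def simulate_acquisition(
    ph: Phantom,
    p: ProtocolParams,
    read_polarity: int,
    phase_polarity: int,
    which_ti: int = 1,
    noise_sigma: float = 0.0,
    ghost_amp: float = 0.05,
    ripple_amp: float = 0.03,
    seed: int = 0,
    pe_axis: int = 1,
    eff_esp_ms: float | None = None,
    ideal: np.ndarray | None = None,
) -> AcquiredVolume:
    """Forward-simulate one polarity-tagged complex volume.

    Artifact amplitudes are fractions of the white-matter signal
    magnitude.  ``eff_esp_ms`` overrides the protocol's effective echo
    spacing (useful for simulating a functional-geometry acquisition on
    the same phantom); ``ideal`` short-circuits the Bloch step when the
    noise-free signal image was already computed.
    """
    validate_protocol(p)
    if read_polarity not in (1, -1) or phase_polarity not in (1, -1):
        raise ValueError("polarities must be +1 or -1")
    esp = effective_echo_spacing(p) if eff_esp_ms is None else float(eff_esp_ms)
    if ideal is None:
        ideal = ideal_signal_volume(ph, p, which_ti)
    data = ideal.astype(complex)

    # geometric distortion along PE, sign from the phase-encode polarity
    d = true_displacement(ph, esp, pe_axis=pe_axis, phase_polarity=phase_polarity)
    if np.any(d != 0):
        data = warp_1d(data.real, d, pe_axis, jacobian=True) + 1j * warp_1d(
            data.imag, d, pe_axis, jacobian=True
        )

    wm_scale = float(np.abs(ideal[ph.labels == LABEL_WM]).mean()) if np.any(ph.labels == LABEL_WM) else 1.0
    if ghost_amp != 0.0:
        n_pe = data.shape[pe_axis]
        ghost = np.roll(data, n_pe // 2, axis=pe_axis)
        data = data + ghost_amp * ghost * 1j * read_polarity
    if ripple_amp != 0.0:
        data = data + ripple_amp * wm_scale * _ripple_pattern(data.shape, pe_axis) * read_polarity

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, data.shape) + 1j * rng.normal(0.0, noise_sigma, data.shape)
        data = data + noise

    return AcquiredVolume(
        data=data,
        read_polarity=int(read_polarity),
        phase_polarity=int(phase_polarity),
        eff_esp=esp,
        pe_axis=pe_axis,
        which_ti=which_ti,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


def acquire_full_session(
    ph: Phantom,
    p: ProtocolParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ghost_amp: float = 0.05,
    ripple_amp: float = 0.03,
    pe_axis: int = 1,
    eff_esp_ms: float | None = None,
) -> list[AcquiredVolume]:
    """All four read/phase polarity combinations at both inversion times.

    Returns 8 volumes; noise seeds are derived from ``seed`` so every
    volume gets an independent (but reproducible) noise realization.
    """
    vols = []
    sub = 0
    for which_ti in (1, 2):
        ideal = ideal_signal_volume(ph, p, which_ti)
        for phase_pol in (1, -1):
            for read_pol in (1, -1):
                vols.append(
                    simulate_acquisition(
                        ph, p, read_pol, phase_pol,
                        which_ti=which_ti,
                        noise_sigma=noise_sigma,
                        ghost_amp=ghost_amp,
                        ripple_amp=ripple_amp,
                        seed=seed * 1000 + sub,
                        pe_axis=pe_axis,
                        eff_esp_ms=eff_esp_ms,
                        ideal=ideal,
                    )
                )
                sub += 1
    return vols


def save_session(vols: list[AcquiredVolume], out_dir, affine: np.ndarray | None = None) -> list[Path]:
    """Write a session as paired real/imaginary NIfTI volumes + JSON sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4) if affine is None else affine
    paths = []
    for v in vols:
        tag = (
            f"ti{v.which_ti}_read{'p' if v.read_polarity > 0 else 'm'}"
            f"_phase{'p' if v.phase_polarity > 0 else 'm'}"
        )
        for part, arr in (("real", v.data.real), ("imag", v.data.imag)):
            nib.save(nib.Nifti1Image(arr.astype(np.float32), aff), str(out_dir / f"{tag}_{part}.nii"))
        (out_dir / f"{tag}.json").write_text(json.dumps(v.sidecar(), indent=2))
        paths.append(out_dir / f"{tag}.json")
    return paths
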
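"""Gray/white-matter contrast and CNR, and flip-angle optimization.

Contrast between two tissue signals a, b is the bounded relative
difference C = (a - b) / (|a| + |b|), which lies in [-1, 1].  Noise of
standard deviation sigma on each signal propagates to the contrast by
first-order (delta-method) Gaussian propagation,

    sigma_C^2 = (dC/da)^2 sigma_a^2 + (dC/db)^2 sigma_b^2,

with the partial derivatives evaluated analytically away from sign
changes, and CNR = C / sigma_C.  The optimal pair of block-specific
excitation flip angles is found by exhaustive grid search over the CNR
surface (the surface is smooth but may have several basins, so no
gradient ascent is used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import DEFAULT_GM, DEFAULT_WM, TissueParams, steady_state_signals, steady_state_signals_fa_grid
from .protocol import ProtocolParams

__all__ = ["CNRResult", "CNRGrid", "contrast", "cnr_from_signals", "cnr_for_protocol", "optimize_flip_angles"]


@dataclass(frozen=True)
class CNRResult:
    contrast: float
    cnr: float
    fa1: float
    fa2: float
    sigma: float


@dataclass
class CNRGrid:
    """CNR evaluated on a flip-angle grid; argmax of |cnr| with deterministic ties.

    Ties are broken toward the smallest fa1, then the smallest fa2.
    """

    fa1_axis: np.ndarray
    fa2_axis: np.ndarray
    cnr_values: np.ndarray  # shape (len(fa1_axis), len(fa2_axis))
    argmax: tuple[float, float]


def contrast(s_gm: float, s_wm: float):
    """Bounded relative signal difference (s_gm - s_wm) / (|s_gm| + |s_wm|)."""
    s_gm = np.asarray(s_gm, dtype=float)
    s_wm = np.asarray(s_wm, dtype=float)
    denom = np.abs(s_gm) + np.abs(s_wm)
    if np.any(denom == 0):
        raise ValueError("contrast undefined: both signals are zero")
    out = (s_gm - s_wm) / denom
    return float(out) if out.ndim == 0 else out


def _contrast_partials(a, b):
    """Analytic partials of C = (a-b)/(|a|+|b|) w.r.t. a and b (away from sign changes)."""
    d = np.abs(a) + np.abs(b)
    num = a - b
    pa = (d - num * np.sign(a)) / d**2
    pb = (-d - num * np.sign(b)) / d**2
    return pa, pb


def cnr_from_signals(
    s_gm: float,
    s_wm: float,
    sigma: float,
    sigma_wm: float | None = None,
    fa1: float = np.nan,
    fa2: float = np.nan,
) -> CNRResult:
    """Contrast and CNR for one signal pair under Gaussian noise.

    ``sigma`` is the noise SD on the GM signal (and on the WM signal
    unless ``sigma_wm`` is given).  Where the first-order noise on the
    contrast vanishes (the two signals have opposite signs, so C is
    locally constant at +/-1), CNR is returned as signed infinity.
    """
    if sigma <= 0 or (sigma_wm is not None and sigma_wm <= 0):
        raise ValueError(f"noise SD must be > 0 (got {sigma})")
    c = contrast(s_gm, s_wm)
    pa, pb = _contrast_partials(np.asarray(s_gm, float), np.asarray(s_wm, float))
    s_w = sigma if sigma_wm is None else sigma_wm
    sigma_c = float(np.sqrt((pa * sigma) ** 2 + (pb * s_w) ** 2))
    if sigma_c == 0.0:
        cnr = 0.0 if c == 0.0 else np.copysign(np.inf, c)
    else:
        cnr = c / sigma_c
    return CNRResult(contrast=c, cnr=cnr, fa1=fa1, fa2=fa2, sigma=sigma)


def _tissue_ratio_sigma(s1, s2, sigma):
    """SD of the ratio s1/s2 by first-order propagation of equal noise on both."""
    r = s1 / s2
    return np.abs(r) * np.hypot(sigma / s1, sigma / s2)


def cnr_for_protocol(
    p: ProtocolParams,
    gm: TissueParams = DEFAULT_GM,
    wm: TissueParams = DEFAULT_WM,
    sigma: float = 0.01,
    which_ti=1,
) -> CNRResult:
    """GM-WM CNR of a protocol from its steady-state Bloch signals.

    ``which_ti`` selects the image the contrast is computed on: 1 (the
    T1-weighted TI1 image used for segmentation, default), 2, or
    ``"combined"`` — the TI1/TI2 signal ratio, with noise propagated
    through the quotient for each tissue first.
    """
    sg = steady_state_signals(p, gm)
    sw = steady_state_signals(p, wm)
    if which_ti == 1:
        res = cnr_from_signals(sg.s1, sw.s1, sigma)
    elif which_ti == 2:
        res = cnr_from_signals(sg.s2, sw.s2, sigma)
    elif which_ti == "combined":
        rg, rw = sg.s1 / sg.s2, sw.s1 / sw.s2
        res = cnr_from_signals(
            rg, rw, float(_tissue_ratio_sigma(sg.s1, sg.s2, sigma)),
            sigma_wm=float(_tissue_ratio_sigma(sw.s1, sw.s2, sigma)),
        )
    else:
        raise ValueError(f"which_ti must be 1, 2 or 'combined' (got {which_ti!r})")
    return CNRResult(res.contrast, res.cnr, p.fa1, p.fa2, sigma)


def _cnr_surface(p, gm, wm, sigma, FA1, FA2, which_ti):
    sg1, sg2 = steady_state_signals_fa_grid(p, gm.t1, FA1, FA2, m0=gm.m0)
    sw1, sw2 = steady_state_signals_fa_grid(p, wm.t1, FA1, FA2, m0=wm.m0)
    if which_ti == 1:
        a, b = sg1, sw1
        sa = sb = sigma
    elif which_ti == 2:
        a, b = sg2, sw2
        sa = sb = sigma
    else:  # combined ratio
        a, b = sg1 / sg2, sw1 / sw2
        sa = _tissue_ratio_sigma(sg1, sg2, sigma)
        sb = _tissue_ratio_sigma(sw1, sw2, sigma)
    c = contrast(a, b)
    pa, pb = _contrast_partials(a, b)
    sigma_c = np.sqrt((pa * sa) ** 2 + (pb * sb) ** 2)
    # Where the two signals have opposite signs the contrast is locally
    # constant at +/-1 and its first-order noise vanishes; the delta method
    # is invalid there, so those nodes are marked NaN and excluded from the
    # grid argmax.
    with np.errstate(divide="ignore", invalid="ignore"):
        cnr = np.where(sigma_c > 0, c / np.where(sigma_c > 0, sigma_c, 1.0),
                       np.where(c == 0, 0.0, np.nan))
    return cnr


def optimize_flip_angles(
    p: ProtocolParams,
    gm: TissueParams = DEFAULT_GM,
    wm: TissueParams = DEFAULT_WM,
    sigma: float = 0.01,
    fa1_axis: np.ndarray | None = None,
    fa2_axis: np.ndarray | None = None,
    which_ti=1,
) -> CNRGrid:
    """Exhaustive |CNR| grid search over the two block flip angles.

    Default axes are 1..30 degrees in 1-degree steps.  Returns the full
    surface and the argmax (ties resolved toward smaller fa1, then fa2).
    """
    fa1_axis = np.arange(1.0, 31.0) if fa1_axis is None else np.asarray(fa1_axis, dtype=float)
    fa2_axis = np.arange(1.0, 31.0) if fa2_axis is None else np.asarray(fa2_axis, dtype=float)
    if fa1_axis.size == 0 or fa2_axis.size == 0:
        raise ValueError("flip-angle grid axes must be non-empty")
    if np.any(fa1_axis <= 0) or np.any(fa1_axis > 90) or np.any(fa2_axis <= 0) or np.any(fa2_axis > 90):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    FA1, FA2 = np.meshgrid(fa1_axis, fa2_axis, indexing="ij")
    cnr = _cnr_surface(p, gm, wm, sigma, FA1, FA2, which_ti)
    if np.all(np.isnan(cnr)):
        raise ValueError("CNR surface is degenerate at every grid node")
    # argmax of |cnr| over valid nodes; C-order argmax with ij indexing
    # breaks ties toward the smallest fa1, then the smallest fa2
    flat = np.where(np.isnan(cnr), -np.inf, np.abs(cnr)).ravel()
    k = int(np.argmax(flat))
    i, j = np.unravel_index(k, cnr.shape)
    return CNRGrid(
        fa1_axis=fa1_axis,
        fa2_axis=fa2_axis,
        cnr_values=cnr,
        argmax=(float(fa1_axis[i]), float(fa2_axis[j])),
    )
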
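"""Forward Bloch simulation of the two-inversion Look-Locker EPI cycle.

Each inversion-recovery (IR) period starts with an adiabatic inversion
(Mz -> -efficiency * Mz), after which longitudinal magnetization relaxes
freely toward equilibrium except at the excitation pulses of the two shot
blocks.  The TI1 block (flip angle fa1) is centered on ti1 and the TI2
block (fa2) on ti2; each excitation of angle a converts Mz * sin(a) into
transverse signal and leaves Mz * cos(a) behind (perfect spoiling, no
transverse coherence between shots).  Relaxation between events uses the
exact exponential solution, so the recursion is event-driven rather than
an ODE integration; a fine-step integrator exists in the test suite as an
independent oracle.

Because the excitation train saturates Mz, recovery follows an apparent
rate 1/T1* = 1/T1 - ln(cos a)/tau faster than free relaxation (the
Look-Locker effect); cycles are chained until the trajectory reaches its
periodic steady state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolParams, validate_protocol

__all__ = [
    "TissueParams",
    "MzTrajectory",
    "SignalPair",
    "simulate_ir_cycles",
    "steady_state_signals",
    "steady_state_signals_array",
    "steady_state_detect",
    "look_locker_train",
    "shot_times",
    "DEFAULT_GM",
    "DEFAULT_WM",
]


@dataclass(frozen=True)
class TissueParams:
    """One tissue compartment: longitudinal relaxation time and equilibrium Mz."""

    name: str
    t1: float  # ms
    m0: float = 1.0  # arbitrary units

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError(f"t1 must be > 0 (got {self.t1})")
        if self.m0 <= 0:
            raise ValueError(f"m0 must be > 0 (got {self.m0})")


# 7 T defaults; configurable everywhere they are consumed.
DEFAULT_GM = TissueParams("gm", t1=1900.0)
DEFAULT_WM = TissueParams("wm", t1=1200.0)


@dataclass
class MzTrajectory:
    """Longitudinal magnetization over one IR cycle, sampled at the excitations.

    ``mz_before`` is Mz immediately before each pulse and ``mxy`` the
    transverse signal it creates, both as fractions of m0; ``times`` are the
    pulse instants in ms after the inversion.
    """

    times: np.ndarray
    mz_before: np.ndarray
    mxy: np.ndarray
    cycle_index: int
    converged: bool = True
    block: np.ndarray = field(default=None)  # 1 or 2: which TI block each pulse belongs to

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.mz_before) == len(self.mxy)):
            raise ValueError("times, mz_before, mxy must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class SignalPair:
    """Transverse signals (fractions of m0, signed) at the two inversion times."""

    s1: float
    s2: float


def shot_times(p: ProtocolParams) -> tuple[np.ndarray, np.ndarray]:
    """Pulse instants (ms after inversion) and block labels (1 or 2).

    Each block of ``shots_per_ti_block`` shots spaced ``tr_shot`` is centered
    on its inversion time, so the middle shot acquires the k-space center at
    ti1 (ti2) under linear segment ordering.
    """
    n = p.shots_per_ti_block
    offsets = (np.arange(n) - (n - 1) / 2.0) * p.tr_shot
    t = np.concatenate([p.ti1 + offsets, p.ti2 + offsets])
    block = np.concatenate([np.ones(n, dtype=int), np.full(n, 2, dtype=int)])
    return t, block


def _relax(mz: np.ndarray, dt: float, t1: np.ndarray, m0) -> np.ndarray:
    """Exact free-relaxation update over dt ms."""
    return m0 + (mz - m0) * np.exp(-dt / t1)


def _simulate_events(times, alphas, t1, m0, eff, tr_ir, n_cycles, tol, mz_init=None):
    """Chain IR cycles over broadcastable t1/alpha arrays; last-cycle record.

    ``alphas`` has shape (n_events,) + A (radians, B1-scaled); ``t1``
    broadcasts against A.  Returns (mz_before, mxy, converged, cycles_run)
    with mz_before/mxy of shape (n_events,) + broadcast(A, t1.shape).
    """
    t1 = np.asarray(t1, dtype=float)
    sin_a, cos_a = np.sin(alphas), np.cos(alphas)
    shape = np.broadcast_shapes(t1.shape, alphas.shape[1:])
    mz_end = (
        np.full(shape, m0, dtype=float)
        if mz_init is None
        else np.broadcast_to(np.asarray(mz_init, dtype=float), shape).astype(float).copy()
    )
    prev_before = None
    converged = False
    cycles_run = 0
    for cyc in range(n_cycles):
        mz = -eff * mz_end
        before = np.empty((len(times),) + shape)
        mxy = np.empty_like(before)
        t_prev = 0.0
        for k, t_k in enumerate(times):
            mz = _relax(mz, t_k - t_prev, t1, m0)
            before[k] = mz
            mxy[k] = mz * sin_a[k]
            mz = mz * cos_a[k]
            t_prev = t_k
        mz_end = _relax(mz, tr_ir - t_prev, t1, m0)
        cycles_run = cyc + 1
        # tolerance is relative to m0 so convergence is m0-scale-invariant
        if prev_before is not None and np.max(np.abs(before - prev_before)) < tol * np.max(np.abs(m0)):
            converged = True
            prev_before = before
            break
        prev_before = before
    return prev_before, mxy, converged, cycles_run


def _simulate_array(
    p: ProtocolParams,
    t1: np.ndarray,
    m0,
    b1_scale: float,
    n_cycles: int,
    tol: float,
    mz_init=None,
):
    """Chain IR cycles for an array of T1 values; return last-cycle record."""
    times, block = shot_times(p)
    alphas = np.deg2rad(np.where(block == 1, p.fa1, p.fa2)) * b1_scale
    before, mxy, converged, cycles_run = _simulate_events(
        times, alphas, t1, m0, p.inversion_efficiency, p.tr_ir, n_cycles, tol, mz_init
    )
    return times, before, mxy, block, converged, cycles_run


def steady_state_signals_fa_grid(
    p: ProtocolParams,
    t1: float,
    fa1_grid: np.ndarray,
    fa2_grid: np.ndarray,
    m0: float = 1.0,
    b1_scale: float = 1.0,
    n_cycles: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state (s1, s2) for one T1 over broadcastable flip-angle grids.

    ``fa1_grid``/``fa2_grid`` are in degrees and may be meshgrid arrays;
    used by the CNR flip-angle optimization.
    """
    times, block = shot_times(p)
    fa1_grid = np.asarray(fa1_grid, dtype=float)
    fa2_grid = np.asarray(fa2_grid, dtype=float)
    grid_shape = np.broadcast_shapes(fa1_grid.shape, fa2_grid.shape)
    alphas = np.empty((len(times),) + grid_shape)
    alphas[block == 1] = np.deg2rad(fa1_grid) * b1_scale
    alphas[block == 2] = np.deg2rad(fa2_grid) * b1_scale
    _, mxy, converged, _ = _simulate_events(
        times, alphas, np.asarray(float(t1)), m0, p.inversion_efficiency, p.tr_ir, n_cycles, tol
    )
    if not converged:
        warnings.warn("steady state not reached within n_cycles", stacklevel=2)
    i1, i2 = _center_indices(p)
    return mxy[i1], mxy[i2]


def simulate_ir_cycles(
    p: ProtocolParams,
    tissue: TissueParams,
    b1_scale: float = 1.0,
    n_cycles: int = 50,
    tol: float = 1e-9,
    mz_init: float | None = None,
) -> MzTrajectory:
    """Simulate ``n_cycles`` IR periods and return the last one.

    ``mz_before`` and ``mxy`` are in fractions of m0.  If consecutive
    cycles have not converged to within ``tol`` the returned trajectory
    carries ``converged=False`` (with a warning) rather than raising.
    """
    validate_protocol(p)
    if b1_scale <= 0:
        raise ValueError(f"b1_scale must be > 0 (got {b1_scale})")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    times, before, mxy, block, converged, cycles_run = _simulate_array(
        p, np.array(0.0 + tissue.t1), tissue.m0, b1_scale, n_cycles, tol,
        mz_init=mz_init,
    )
    if not converged and n_cycles > 1:
        warnings.warn(
            f"IR cycles did not reach steady state within {n_cycles} cycles "
            f"(tol={tol}); trajectory may still be transient",
            stacklevel=2,
        )
    return MzTrajectory(
        times=times,
        mz_before=before / tissue.m0,
        mxy=mxy / tissue.m0,
        cycle_index=cycles_run - 1,
        converged=converged,
        block=block,
    )


def _center_indices(p: ProtocolParams) -> tuple[int, int]:
    n = p.shots_per_ti_block
    return n // 2, n + n // 2


def steady_state_signals_array(
    p: ProtocolParams,
    t1: np.ndarray,
    m0=1.0,
    b1_scale: float = 1.0,
    n_cycles: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state (s1, s2) for an array of T1 values (vectorized).

    s1/s2 are the transverse signals of the k-space-center shot (middle of
    each block), in the same units as ``m0``.
    """
    t1 = np.asarray(t1, dtype=float)
    _, _, mxy, _, converged, _ = _simulate_array(p, t1, m0, b1_scale, n_cycles, tol)
    if not converged:
        warnings.warn("steady state not reached within n_cycles", stacklevel=2)
    i1, i2 = _center_indices(p)
    return mxy[i1], mxy[i2]


def steady_state_signals(
    p: ProtocolParams,
    tissue: TissueParams,
    b1_scale: float = 1.0,
    n_cycles: int = 50,
    tol: float = 1e-9,
) -> SignalPair:
    """Steady-state signal pair for one tissue, as signed fractions of m0 times m0."""
    s1, s2 = steady_state_signals_array(
        p, np.array(tissue.t1), tissue.m0, b1_scale, n_cycles, tol
    )
    return SignalPair(s1=float(s1), s2=float(s2))


def steady_state_detect(trajA: MzTrajectory, trajB: MzTrajectory, tol: float = 1e-9) -> bool:
    """True iff two consecutive cycles agree to within ``tol`` in mz_before."""
    if len(trajA.mz_before) != len(trajB.mz_before):
        raise ValueError("trajectories have mismatched lengths")
    return bool(np.max(np.abs(trajA.mz_before - trajB.mz_before)) < tol)


def look_locker_train(
    t1: float,
    alpha_deg: float,
    tau: float,
    n_shots: int,
    m0: float = 1.0,
    mz_init: float | None = None,
) -> np.ndarray:
    """Mz before each pulse of a constant-flip-angle excitation train.

    A single uninterrupted train (no inversions, shots every ``tau`` ms)
    converges to the Look-Locker fixed point m0*(1-E)/(1-E*cos a) with
    E = exp(-tau/t1), approached at apparent rate 1/T1* = 1/t1 - ln(cos a)/tau.
    Built from the same event primitives as the IR simulation.
    """
    a = np.deg2rad(alpha_deg)
    sin_a, cos_a = np.sin(a), np.cos(a)  # noqa: F841  (sin kept for symmetry)
    mz = m0 if mz_init is None else mz_init
    out = np.empty(n_shots)
    for k in range(n_shots):
        out[k] = mz
        mz = _relax(mz * cos_a, tau, np.array(t1), m0)
    return out
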
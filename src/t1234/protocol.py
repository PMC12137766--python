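"""Protocol parameter sets for two-inversion segmented 3D-EPI.

A protocol bundles the inversion-recovery timing (TI1, TI2, TR per shot,
TR per IR cycle), the two block-specific excitation flip angles, and the
EPI geometry (matrix, segmentation, in-plane acceleration, CAIPI kz
undersampling, echo spacing).  From these the module derives the
*effective echo spacing* — the per-k-space-line phase-evolution interval
that governs geometric distortion along the phase-encode axis — and the
arithmetic used to match or scale distortion levels between protocols.

Convention: effective echo spacing = echo_spacing / (n_segments * r_inplane).
Higher segmentation or acceleration shortens the echo train and shrinks
distortions proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ProtocolParams",
    "ProtocolValidationError",
    "validate_protocol",
    "effective_echo_spacing",
    "match_segmentation",
    "distortion_scale_factor",
    "scan_duration",
    "load_protocol",
    "packaged_protocol",
]

_ALLOWED_PARTIAL_FOURIER = (Fraction(1), Fraction(7, 8), Fraction(6, 8), Fraction(5, 8))


class ProtocolValidationError(ValueError):
    """Raised when a protocol parameter set violates an invariant.

    The message names the offending field.
    """


@dataclass(frozen=True)
class ProtocolParams:
    """One acquisition protocol.

    All times in milliseconds, angles in degrees, voxel size in mm.
    ``te`` is carried as metadata only; no transverse decay is modeled.
    """

    ti1: float
    ti2: float
    te: float
    tr_shot: float
    tr_ir: float
    fa1: float
    fa2: float
    n_segments: int
    matrix: tuple[int, int, int]
    echo_spacing: float
    partial_fourier: Fraction = Fraction(6, 8)
    caipi_dz: int = 1
    r_inplane: int = 1
    inversion_efficiency: float = 1.0
    shots_per_ti_block: int = 1
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 0.8)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", tuple(int(m) for m in self.matrix))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "partial_fourier", Fraction(self.partial_fourier))

    def with_(self, **kwargs) -> "ProtocolParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return validate_protocol(replace(self, **kwargs))


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ProtocolValidationError(f"{field_name}: {msg}")


def validate_protocol(p: ProtocolParams) -> ProtocolParams:
    """Check all protocol invariants; return ``p`` unchanged if valid.

    Raises :class:`ProtocolValidationError` naming the offending field
    otherwise.
    """
    for fname in ("ti1", "ti2", "te", "tr_shot", "tr_ir", "echo_spacing"):
        _require(getattr(p, fname) > 0, fname, "must be strictly positive")
    _require(p.ti1 < p.ti2, "ti2", f"requires ti1 < ti2 (got ti1={p.ti1}, ti2={p.ti2})")
    _require(p.ti2 < p.tr_ir, "ti2", f"requires ti2 < tr_ir (got ti2={p.ti2}, tr_ir={p.tr_ir})")
    for fname in ("fa1", "fa2"):
        fa = getattr(p, fname)
        _require(0.0 < fa <= 90.0, fname, f"must lie in (0, 90] degrees (got {fa})")
    _require(p.n_segments >= 1, "n_segments", "must be >= 1")
    _require(p.r_inplane >= 1, "r_inplane", "must be >= 1")
    _require(p.caipi_dz >= 1, "caipi_dz", "must be >= 1")
    _require(p.shots_per_ti_block >= 1, "shots_per_ti_block", "must be >= 1")
    _require(
        p.shots_per_ti_block * p.tr_shot <= (p.ti2 - p.ti1),
        "shots_per_ti_block",
        f"TI1 shot block ({p.shots_per_ti_block} x {p.tr_shot} ms) must fit "
        f"within ti2 - ti1 = {p.ti2 - p.ti1} ms",
    )
    # the centered TI1 block must start after the inversion pulse at t = 0
    half_block = (p.shots_per_ti_block - 1) / 2.0 * p.tr_shot
    _require(p.ti1 - half_block > 0, "ti1", "centered TI1 shot block would start before the inversion")
    _require(p.ti2 + half_block < p.tr_ir, "tr_ir", "centered TI2 shot block would overrun the IR cycle")
    _require(
        0.0 < p.inversion_efficiency <= 1.0,
        "inversion_efficiency",
        f"must lie in (0, 1] (got {p.inversion_efficiency})",
    )
    _require(len(p.matrix) == 3 and all(m >= 1 for m in p.matrix), "matrix", "must be a positive integer triple")
    _require(
        p.partial_fourier in _ALLOWED_PARTIAL_FOURIER,
        "partial_fourier",
        f"must be one of {{1, 7/8, 6/8, 5/8}} (got {p.partial_fourier})",
    )
    _require(all(v > 0 for v in p.voxel_size), "voxel_size", "must be positive")
    return p


def effective_echo_spacing(p: ProtocolParams) -> float:
    """Effective echo spacing in ms: echo_spacing / (n_segments * r_inplane).

    This is the phase-evolution interval per acquired k-space line after
    accounting for interleaved segmentation and in-plane acceleration; the
    geometric distortion of the image is proportional to it.
    """
    return p.echo_spacing / (p.n_segments * p.r_inplane)


def match_segmentation(target_eff_esp: float, echo_spacing: float, r_inplane: int) -> int:
    """Smallest segmentation factor whose effective echo spacing is <= target.

    Returns the minimal integer ``n`` with echo_spacing / (n * r_inplane)
    <= target_eff_esp, i.e. the least segmentation making the structural
    scan at most as distorted as the target acquisition.
    """
    if target_eff_esp <= 0:
        raise ValueError(f"target_eff_esp must be > 0 (got {target_eff_esp})")
    if echo_spacing <= 0 or r_inplane < 1:
        raise ValueError("echo_spacing must be > 0 and r_inplane >= 1")
    # tolerate one-ulp rounding so exact ratios (e.g. 1.05/0.35) stay integral
    return max(1, math.ceil(echo_spacing / (r_inplane * target_eff_esp) * (1 - 1e-12)))


def distortion_scale_factor(p_struct: ProtocolParams, target_eff_esp: float) -> float:
    """Multiplier taking a field estimated on ``p_struct`` to a target echo spacing.

    0 means distortion-free synthesis (the negated estimated field undoes
    the acquisition's own warp); 1 reproduces the structural distortion;
    >1 amplifies it to match a more distortion-prone acquisition.
    """
    if target_eff_esp < 0:
        raise ValueError(f"target_eff_esp must be >= 0 (got {target_eff_esp})")
    return target_eff_esp / effective_echo_spacing(p_struct)


def scan_duration(p: ProtocolParams, n_polarity_volumes: int = 4) -> float:
    """Total acquisition time in seconds for all polarity volumes.

    Each IR cycle accommodates two shot blocks (one per inversion time);
    the number of cycles per volume is the total shot count divided by the
    shots per block pair, rounded up.  CAIPI kz undersampling reduces the
    number of kz planes actually acquired.
    """
    if n_polarity_volumes < 1:
        raise ValueError("n_polarity_volumes must be >= 1")
    if p.shots_per_ti_block < 1:
        raise ValueError("shots_per_ti_block must be >= 1")
    nz = p.matrix[2]
    total_shots = p.n_segments * math.ceil(nz / p.caipi_dz)
    n_ir_cycles = math.ceil(total_shots / (2 * p.shots_per_ti_block))
    return n_polarity_volumes * n_ir_cycles * p.tr_ir / 1000.0


# ---------------------------------------------------------------------------
# Config I/O

def _protocol_from_mapping(d: dict, name: str) -> ProtocolParams:
    d = dict(d)
    pf = d.get("partial_fourier", "6/8")
    if isinstance(pf, str):
        pf = Fraction(pf)
    p = ProtocolParams(
        ti1=float(d["ti1"]),
        ti2=float(d["ti2"]),
        te=float(d["te"]),
        tr_shot=float(d["tr_shot"]),
        tr_ir=float(d["tr_ir"]),
        fa1=float(d["fa1"]),
        fa2=float(d["fa2"]),
        n_segments=int(d["n_segments"]),
        matrix=tuple(d["matrix"]),
        echo_spacing=float(d["echo_spacing"]),
        partial_fourier=pf,
        caipi_dz=int(d.get("caipi_dz", 1)),
        r_inplane=int(d.get("r_inplane", 1)),
        inversion_efficiency=float(d.get("inversion_efficiency", 1.0)),
        shots_per_ti_block=int(d.get("shots_per_ti_block", 1)),
        voxel_size=tuple(d.get("voxel_size", (0.8, 0.8, 0.8))),
        name=d.get("name", name),
    )
    return validate_protocol(p)


def load_protocol(path: Union[str, Path]) -> ProtocolParams:
    """Load and validate a protocol from a YAML config file."""
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ProtocolValidationError(f"config: {path} does not contain a mapping")
    return _protocol_from_mapping(d, name=path.stem)


def packaged_protocol(name: str) -> ProtocolParams:
    """Load one of the protocols shipped with the package.

    Available: ``"retrospective"`` (highly segmented, near distortion-free
    acquisition intended for retrospective warping) and
    ``"acquisition_matched"`` (segmentation chosen so the effective echo
    spacing equals that of a standard 7 T functional protocol, 0.35 ms).
    """
    ref = resources.files("t1234.data").joinpath(f"{name}.yaml")
    with ref.open() as fh:
        d = yaml.safe_load(fh)
    return _protocol_from_mapping(d, name=name)
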
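"""Wavefront curvature and conduction velocity from thickness change.

A wavefront propagating from thin to thick border zone must supply current to
a growing volume of tissue (source-sink mismatch): its leading edge becomes
convex and conduction slows.  The velocity law is

    theta = theta_o - (D / c) * (dT / T)

with theta_o the rectilinear conduction velocity (~0.4 mm/ms in ventricular
myocardium), D the diffusion coefficient (0.1 mm^2/ms), c the space step
over which the thickness change dT is measured, and T the local thickness.
Equivalently theta = theta_o - D * rho with curvature rho = (dT/T) / c.
Conduction fails (theta <= 0) once dT/T reaches theta_o * c / D, which is
4.0 for the default constants.

dT here is one-sided: only thin-to-thick change slows the wavefront.
Thick-to-thin change produces a concave, facilitated wavefront and is
handled by the propagation simulator, not by this field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import ThicknessMap

__all__ = [
    "ModelConstants",
    "CurvatureField",
    "delta_T_field",
    "conduction_velocity",
    "curvature_rho",
    "critical_ratio",
    "curvature_field",
]

# 8 compass bearings (unit vectors in grid steps), row-major (dr, dc)
_DIRECTIONS = np.array(
    [
        (0, 1), (0, -1), (1, 0), (-1, 0),
        (1, 1), (1, -1), (-1, 1), (-1, -1),
    ],
    dtype=float,
)
_DIRECTIONS[4:] /= np.sqrt(2.0)


@dataclass(frozen=True)
class ModelConstants:
    """Velocity-law constants.

    theta_o : rectilinear conduction velocity, mm/ms
    D       : diffusion coefficient, mm^2/ms
    c       : space step over which dT is measured, mm
    """

    theta_o: float = 0.4
    D: float = 0.1
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.theta_o > 0 and self.D > 0 and self.c > 0):
            raise ValueError("theta_o, D and c must all be strictly positive")


@dataclass
class CurvatureField:
    """Per-node curvature diagnostics over a thickness map.

    delta_T : max thin-to-thick thickness change over the space step, um
    ratio   : dT/T, unitless
    rho     : wavefront curvature, mm^-1
    theta   : conduction velocity, mm/ms (<= 0 means block)
    blocked : theta <= 0
    """

    delta_T: np.ndarray
    ratio: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    blocked: np.ndarray


def sample_at_offset(
    m: ThicknessMap, offsets_rc: np.ndarray
) -> np.ndarray:
    """Bilinear sample of T at (node + offset) for every node.

    offsets_rc is (dr, dc) in *grid units* (may be fractional).  Off-grid
    samples return nan.
    """
    rows, cols = m.shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    coords = np.stack([rr + offsets_rc[0], cc + offsets_rc[1]])
    return map_coordinates(
        m.values, coords, order=1, mode="constant", cval=np.nan
    )


def delta_T_field(m: ThicknessMap, c: float | None = None) -> np.ndarray:
    """Maximum thin-to-thick thickness change per space step, per node.

    For each node, T is sampled a distance ``c`` away along the 8 compass
    directions (bilinear interpolation off-lattice) and the largest increase
    T(node + c*dir) - T(node) is taken, clamped below at 0: only transitions
    toward thicker tissue slow a wavefront.  Off-grid samples are skipped.
    """
    if c is None:
        c = m.spacing
    if c < m.spacing:
        raise ValueError(
            f"space step c={c} must be >= grid spacing {m.spacing}"
        )
    steps = c / m.spacing  # offset in grid units
    best = np.zeros(m.shape)
    for d in _DIRECTIONS:
        sampled = sample_at_offset(m, d * steps)
        diff = sampled - m.values
        np.fmax(best, diff, out=best)  # fmax skips nan (off-grid)
    best[best < 1e-9] = 0.0  # sub-nanometre interpolation residue
    return best


def conduction_velocity(
    constants: ModelConstants, ratio: float | np.ndarray
) -> float | np.ndarray:
    """Velocity law: theta = theta_o - (D/c) * (dT/T).

    Total function; a non-positive result is interpreted as conduction block.
    """
    return constants.theta_o - (constants.D / constants.c) * np.asarray(ratio)


def curvature_rho(ratio: float | np.ndarray, c: float) -> float | np.ndarray:
    """Wavefront curvature rho = (dT/T) / c, mm^-1."""
    if not (c > 0):
        raise ValueError(f"space step c must be > 0, got {c}")
    return np.asarray(ratio) / c


def critical_ratio(constants: ModelConstants) -> float:
    """The dT/T value at which theta reaches 0: theta_o * c / D.

    4.0 for the default constants — the critically convex limit.
    """
    return constants.theta_o * constants.c / constants.D


def curvature_field(
    m: ThicknessMap, constants: ModelConstants | None = None
) -> CurvatureField:
    """Full per-node curvature diagnostics (the dT/T map of the estimator)."""
    if constants is None:
        constants = ModelConstants()
    dT = delta_T_field(m, constants.c)
    ratio = dT / m.values
    rho = np.asarray(curvature_rho(ratio, constants.c))
    theta = np.asarray(conduction_velocity(constants, ratio))
    return CurvatureField(
        delta_T=dT,
        ratio=ratio,
        rho=rho,
        theta=theta,
        blocked=theta <= 0,
    )
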
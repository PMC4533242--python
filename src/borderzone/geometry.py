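"""Synthetic infarct border-zone thickness maps.

The infarct border zone is the thin rim of surviving myocardium between an
infarct and the epicardium.  The reentry isthmus coincides with the thinnest
border zone (mean ~231 um) and is surrounded by a thicker outer pathway
(~1440 um).  This module generates 2-D thickness rasters with a parameterized
isthmus channel so that every downstream stage (curvature fields, block
prediction, wavefront simulation) is testable without experimental data.

Conventions: node-centered square grid, 0-based (row, col) indices, physical
position = index * spacing in mm, thickness stored in micrometres.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ThicknessMap",
    "IsthmusSpec",
    "make_uniform_map",
    "make_isthmus_map",
    "read_map",
    "write_map",
]


@dataclass
class ThicknessMap:
    """Regular 2-D grid of border-zone thickness.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Thickness ``T`` at each node, micrometres.
    spacing : float
        Grid step in mm (square grid).
    mask : ndarray of bool, same shape
        True where the node is viable border zone.
    """

    values: np.ndarray
    spacing: float = 1.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 3:
            raise ValueError(
                f"thickness map must be at least 3x3, got shape {self.values.shape}"
            )
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
        if np.any(self.values[self.mask] <= 0):
            raise ValueError("all masked-in thickness values must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def node_xy(self, node: tuple[int, int]) -> tuple[float, float]:
        """Physical (x, y) position in mm of a (row, col) node."""
        r, c = node
        return (c * self.spacing, r * self.spacing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ThicknessMap):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=0, atol=1e-9)
            and np.isclose(self.spacing, other.spacing)
            and bool(np.all(self.mask == other.mask))
        )


@dataclass
class IsthmusSpec:
    """Geometry of a thin isthmus channel inside a thicker outer pathway.

    The channel runs from ``channel_start`` (the *entrance* end, steep
    thin-to-thick transition) to ``channel_end`` (the *exit* end, gradual
    transition); both are (x, y) points in mm.  Thickness ramps linearly from
    ``t_isthmus`` to ``t_outer`` over each transition zone.

    The entrance is by definition the steep end: premature wavefronts
    travelling along the channel toward it meet the sharpest thin-to-thick
    transition and are the ones liable to block there.
    """

    channel_start: tuple[float, float] = (20.0, 20.0)
    channel_end: tuple[float, float] = (43.0, 20.0)
    channel_width: float = 10.0
    t_isthmus: float = 231.0
    t_outer: float = 1440.0
    entrance_transition_length: float = 2.0
    exit_transition_length: float = 6.0
    lateral_transition_length: float = 1.5

    def __post_init__(self) -> None:
        if not (self.t_isthmus < self.t_outer):
            raise ValueError("t_isthmus must be < t_outer")
        for name in (
            "channel_width",
            "entrance_transition_length",
            "exit_transition_length",
            "lateral_transition_length",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.entrance_transition_length > self.exit_transition_length:
            raise ValueError(
                "entrance_transition_length must be <= exit_transition_length "
                "(the entrance is the steep end by definition)"
            )

    @property
    def length(self) -> float:
        """Channel length along its axis, mm."""
        return float(np.hypot(
            self.channel_end[0] - self.channel_start[0],
            self.channel_end[1] - self.channel_start[1],
        ))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from entrance to exit."""
        d = np.subtract(self.channel_end, self.channel_start, dtype=float)
        return d / np.linalg.norm(d)


def make_uniform_map(
    t: float, shape: tuple[int, int], spacing: float = 1.0
) -> ThicknessMap:
    """Constant-thickness map: the control case with a rectilinear wavefront.

    With no spatial thickness change the curvature term vanishes everywhere
    and conduction over this map proceeds uniformly at the rectilinear
    velocity theta_o.
    """
    if not (t > 0):
        raise ValueError(f"thickness must be > 0, got {t}")
    rows, cols = shape
    if rows < 3 or cols < 3:
        raise ValueError(f"degenerate shape {shape}: need at least 3x3")
    return ThicknessMap(np.full((rows, cols), float(t)), spacing=spacing)


def make_isthmus_map(
    spec: IsthmusSpec, shape: tuple[int, int], spacing: float = 1.0
) -> ThicknessMap:
    """Generate a thickness map containing one isthmus channel.

    Nodes inside the channel get ``t_isthmus``; the far field is ``t_outer``;
    thickness ramps linearly over each transition zone.  At corners the
    steeper (larger) of the overlapping ramps governs, which keeps the field
    monotone outward from the channel.
    """
    rows, cols = shape
    ys, xs = np.mgrid[0:rows, 0:cols]
    x = xs * spacing
    y = ys * spacing

    p0 = np.asarray(spec.channel_start, dtype=float)
    e = spec.axis
    n = np.array([-e[1], e[0]])
    length = spec.length

    # channel-frame coordinates: s along the axis, d lateral offset
    s = (x - p0[0]) * e[0] + (y - p0[1]) * e[1]
    d = np.abs((x - p0[0]) * n[0] + (y - p0[1]) * n[1])

    half_w = spec.channel_width / 2.0
    margin = 2 * spacing
    lo_x = min(spec.channel_start[0], spec.channel_end[0]) - half_w
    hi_x = max(spec.channel_start[0], spec.channel_end[0]) + half_w
    lo_y = min(spec.channel_start[1], spec.channel_end[1]) - half_w
    hi_y = max(spec.channel_start[1], spec.channel_end[1]) + half_w
    if (
        lo_x < margin
        or lo_y < margin
        or hi_x > (cols - 1) * spacing - margin
        or hi_y > (rows - 1) * spacing - margin
    ):
        raise ValueError(
            "channel (including width) must fit inside the grid with at "
            "least a 2-node margin"
        )

    u_ent = np.clip(-s / spec.entrance_transition_length, 0.0, None)
    u_exit = np.clip((s - length) / spec.exit_transition_length, 0.0, None)
    u_lat = np.clip((d - half_w) / spec.lateral_transition_length, 0.0, None)
    u = np.clip(np.maximum.reduce([u_ent, u_exit, u_lat]), 0.0, 1.0)

    values = spec.t_isthmus + u * (spec.t_outer - spec.t_isthmus)
    return ThicknessMap(values, spacing=spacing)


_HEADER_RE = re.compile(r"^#\s*spacing_mm\s*=\s*([0-9.eE+-]+)\s*$")


def write_map(m: ThicknessMap, path: str | Path) -> None:
    """Write a thickness raster as tab-delimited text with a spacing header.

    Masked-out nodes are written as ``nan``.
    """
    path = Path(path)
    out = m.values.copy()
    out[~m.mask] = np.nan
    with path.open("w") as fh:
        fh.write(f"# spacing_mm={m.spacing:g}\n")
        for row in out:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def read_map(path: str | Path) -> ThicknessMap:
    """Read a delimited-text thickness raster (tab or comma separated).

    An optional first line ``# spacing_mm=<float>`` carries the grid step;
    without it the spacing defaults to 1.0 mm (logged as a warning).
    ``nan`` cells are masked out.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    spacing = None
    start = 0
    if lines and lines[0].lstrip().startswith("#"):
        match = _HEADER_RE.match(lines[0].strip())
        if match:
            spacing = float(match.group(1))
        start = 1
    if spacing is None:
        spacing = 1.0
        log.warning("%s: no spacing header; defaulting to 1.0 mm", path)

    rows: list[list[float]] = []
    width = None
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cells = re.split(r"[,\t]", line.strip())
        parsed: list[float] = []
        for j, cell in enumerate(cells, start=1):
            cell = cell.strip()
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                ) from None
        if width is None:
            width = len(parsed)
        elif len(parsed) != width:
            raise ValueError(
                f"{path}: ragged raster — row {i} has {len(parsed)} cells, "
                f"expected {width}"
            )
        rows.append(parsed)
    values = np.array(rows, dtype=float)
    mask = ~np.isnan(values)
    filled = values.copy()
    if not mask.all():
        filled[~mask] = np.nanmean(values) if mask.any() else 1.0
    return ThicknessMap(filled, spacing=spacing, mask=mask)
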
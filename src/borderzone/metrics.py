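"""Spatial relation between the UBL and the reentry isthmus.

During reentrant tachycardia the isthmus is bounded by two lateral
functional block lines; the unidirectional block line (UBL) of the
preceding premature cycle tends to cap the isthmus entrance (the end
farthest from the stimulus).  The overlap is quantified by:

  a   : distance from the stimulus site to the UBL leading edge
  b   : the distance over which the UBL extends along the isthmus long axis
        (total polyline arc length also reported as b_arc)
  c   : isthmus length along its long axis, the two lateral block-line
        lengths averaged if disparate
  d   : length of the projection of the UBL onto the lateral block lines'
        extent along the isthmus axis
  d/c : percent of the isthmus length overlapped by the UBL
  e   : mean over both sides of the closest distance between the UBL and
        the nearest lateral line (an error function: 0 = exact coincidence)

All lengths in mm.  Per-experiment records (coupling interval, reentry
cycle length, reexcitation interval, lengths a-d and d/c) from 12 canine
postinfarction mapping experiments are shipped as plain-text fixtures and
can be re-summarized with :func:`summarize_experiments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

__all__ = [
    "CircuitGeometry",
    "CircuitMeasurements",
    "ExperimentRecord",
    "measure_circuit",
    "leading_edge_position",
    "summarize_experiments",
    "count_reexcitation_shorter",
    "load_circuit_table",
    "load_cycle_table",
]


def _as_linestring(poly: np.ndarray, name: str) -> LineString:
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError(f"{name} must be a polyline of >= 2 (x, y) vertices")
    return LineString(poly)


@dataclass
class CircuitGeometry:
    """Stimulus site, UBL polyline and the two lateral block lines (mm)."""

    stimulus_site: tuple[float, float]
    ubl: np.ndarray  # (n, 2)
    lateral_lines: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        self.ubl = np.asarray(self.ubl, dtype=float)
        self.lateral_lines = tuple(
            np.asarray(l, dtype=float) for l in self.lateral_lines
        )
        _as_linestring(self.ubl, "ubl")
        l0 = _as_linestring(self.lateral_lines[0], "lateral line 0")
        l1 = _as_linestring(self.lateral_lines[1], "lateral line 1")
        if l0.crosses(l1):
            raise ValueError("lateral block lines must not cross")

    @property
    def isthmus_axis(self) -> np.ndarray:
        """Unit direction of the isthmus long axis.

        Estimated as the principal direction of the lateral polylines'
        vertices (the lines bound the isthmus lengthwise).
        """
        pts = np.vstack(self.lateral_lines)
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        return vt[0] / np.linalg.norm(vt[0])


@dataclass
class CircuitMeasurements:
    a: float
    b: float
    c_len: float
    d: float
    e: float
    d_over_c: float
    leading_edge_position: float  # percent of isthmus length from distal end
    b_arc: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c_len", "d", "e"):
            if getattr(self, name) < 0:
                raise ValueError(f"length {name} must be >= 0")
        if not (0.0 <= self.d_over_c <= 100.0):
            raise ValueError("d/c must lie in [0, 100] percent")


@dataclass(frozen=True)
class ExperimentRecord:
    """One mapping experiment: timing plus (optionally) circuit lengths."""

    ps_interval: float
    vt_cycle_length: float
    reexcitation: float

    def __post_init__(self) -> None:
        if self.ps_interval <= 0 or self.vt_cycle_length <= 0:
            raise ValueError("intervals must be positive")


def _arc_length(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def measure_circuit(geometry: CircuitGeometry) -> CircuitMeasurements:
    """Compute lengths a-e and the overlap ratio d/c for one circuit."""
    axis = geometry.isthmus_axis
    stim = np.asarray(geometry.stimulus_site, dtype=float)
    ubl = geometry.ubl
    lat0, lat1 = geometry.lateral_lines

    # projections onto the isthmus long axis
    proj = lambda pts: pts @ axis
    ubl_p = proj(ubl)
    lat_p = np.concatenate([proj(lat0), proj(lat1)])
    lat_lo, lat_hi = lat_p.min(), lat_p.max()

    c_len = 0.5 * (_arc_length(lat0) + _arc_length(lat1))

    # leading edge: UBL vertex nearest the stimulus
    d2 = np.sum((ubl - stim) ** 2, axis=1)
    leading = ubl[int(np.argmin(d2))]
    a = float(np.sqrt(d2.min()))

    b = float(ubl_p.max() - ubl_p.min())
    b_arc = _arc_length(ubl)

    # overlap of the UBL's axis extent with the lateral lines' extent
    d_len = max(0.0, min(ubl_p.max(), lat_hi) - max(ubl_p.min(), lat_lo))

    ubl_ls = _as_linestring(ubl, "ubl")
    e = 0.5 * (
        ubl_ls.distance(_as_linestring(lat0, "lat0"))
        + ubl_ls.distance(_as_linestring(lat1, "lat1"))
    )

    d_over_c = 100.0 * d_len / c_len if c_len > 0 else 0.0

    # distal end of the isthmus axis = the end farther from the stimulus
    ends = np.array([lat_lo, lat_hi])
    stim_p = float(stim @ axis)
    distal = ends[int(np.argmax(np.abs(ends - stim_p)))]
    lead_pos = 100.0 * abs(float(leading @ axis) - distal) / c_len

    return CircuitMeasurements(
        a=a,
        b=b,
        c_len=c_len,
        d=d_len,
        e=float(e),
        d_over_c=min(d_over_c, 100.0),
        leading_edge_position=lead_pos,
        b_arc=b_arc,
    )


def leading_edge_position(geometry: CircuitGeometry) -> float:
    """Percent of the isthmus length (from its distal end) at which the UBL
    leading edge sits; ~50% means the UBL caps the distal half."""
    return measure_circuit(geometry).leading_edge_position


def summarize_experiments(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation (ddof=1) per numeric column."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize")
    num = records.select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def count_reexcitation_shorter(records: pd.DataFrame) -> int:
    """Number of experiments whose reexcitation interval is strictly shorter
    than the premature coupling interval."""
    if not {"ps", "reexcitation"} <= set(records.columns):
        raise ValueError("records need 'ps' and 'reexcitation' columns")
    return int((records["reexcitation"] < records["ps"]).sum())


def _data_path(name: str) -> Path:
    return Path(str(resources.files("borderzone").joinpath("data", name)))


def load_circuit_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-experiment circuit lengths a-d and d/c (%), 12 experiments."""
    p = Path(path) if path else _data_path("canine_circuit_measurements.tsv")
    return pd.read_csv(p, sep="\t", comment="#").set_index("expt")


def load_cycle_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-experiment coupling interval (ps), reentry cycle length (vt) and
    reexcitation interval, ms, 12 experiments."""
    p = Path(path) if path else _data_path("canine_cycle_lengths.tsv")
    return pd.read_csv(p, sep="\t", comment="#").set_index("expt")
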
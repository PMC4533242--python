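"""End-to-end orchestration: thickness map -> curvature field -> block
prediction -> premature-stimulation simulation -> circuit metrics -> report.

Every stage writes plain-text artifacts into the output directory and reads
only artifacts of earlier stages, so a run can be resumed or audited
mid-pipeline.  Identical configurations produce identical artifacts: the
whole chain is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .curvature import ModelConstants, curvature_field
from .geometry import IsthmusSpec, ThicknessMap, make_isthmus_map, read_map, write_map
from .metrics import CircuitGeometry, measure_circuit
from .rate import (
    DEFAULT_CALIBRATION,
    RateBlockCalibration,
    critical_space_step,
    critical_width,
    rho_from_width,
)
from .simulate import (
    RefractoryModel,
    StimulusProtocol,
    run_premature_protocol,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "worked_examples"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Defaults are the model's standard conditions: theta_o = 0.4 mm/ms,
    D = 0.1 mm^2/ms, c = 1 mm, isthmus thickness 231 um inside a 1440 um
    outer pathway, the three-point rate calibration, a 10-pulse 300 ms S1
    train and a 150 ms premature stimulus from beyond the gradual isthmus
    end.
    """

    map_path: str | None = None
    shape: tuple[int, int] = (81, 121)
    spacing: float = 0.5
    isthmus: IsthmusSpec = field(default_factory=IsthmusSpec)
    constants: ModelConstants = field(default_factory=ModelConstants)
    calibration: RateBlockCalibration = field(
        default_factory=lambda: DEFAULT_CALIBRATION
    )
    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol(site=(40, 110))
    )
    refractory: RefractoryModel = field(default_factory=RefractoryModel)
    vt_cycle_length: float = 200.0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("map_path", "spacing", "vt_cycle_length", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "shape" in raw:
            kwargs["shape"] = tuple(raw["shape"])
        if "isthmus" in raw:
            isth = dict(raw["isthmus"])
            for pt in ("channel_start", "channel_end"):
                if pt in isth:
                    isth[pt] = tuple(isth[pt])
            kwargs["isthmus"] = IsthmusSpec(**isth)
        if "constants" in raw:
            kwargs["constants"] = ModelConstants(**raw["constants"])
        if "calibration" in raw:
            cal = dict(raw["calibration"])
            if "points" in cal:
                cal["points"] = tuple(tuple(p) for p in cal["points"])
            kwargs["calibration"] = RateBlockCalibration(**cal)
        if "protocol" in raw:
            proto = dict(raw["protocol"])
            if "site" in proto:
                proto["site"] = tuple(proto["site"])
            kwargs["protocol"] = StimulusProtocol(**proto)
        if "refractory" in raw:
            kwargs["refractory"] = RefractoryModel(**raw["refractory"])
        return cls(**kwargs)


def _write_raster(path: Path, values: np.ndarray, spacing: float) -> None:
    with path.open("w") as fh:
        fh.write(f"# spacing_mm={spacing:g}\n")
        for row in np.asarray(values, dtype=float):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def _block_prediction_raster(
    m: ThicknessMap,
    constants: ModelConstants,
    calibration: RateBlockCalibration,
    cycle_length: float,
) -> np.ndarray:
    """Per-node block prediction at a cycle length from the dT/T map.

    A node is flagged when its maximum dT/T over the space step implies a
    local curvature at or above the rate-dependent critical curvature —
    the map-based estimation route for functional block line locations.
    """
    fld = curvature_field(m, constants)
    rho_crit = rho_from_width(
        critical_width(calibration, cycle_length, extrapolate=True),
        calibration.beta,
    )
    return (fld.rho >= rho_crit).astype(float)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load map"
    try:
        if config.map_path:
            m = read_map(config.map_path)
        else:
            m = make_isthmus_map(config.isthmus, config.shape, config.spacing)
        write_map(m, out / "thickness.tsv")
        log.info("map: shape=%s spacing=%g mm", m.shape, m.spacing)

        stage = "curvature field"
        fld = curvature_field(m, config.constants)
        _write_raster(out / "ratio.tsv", fld.ratio, m.spacing)
        _write_raster(out / "theta.tsv", fld.theta, m.spacing)

        stage = "block prediction"
        for name, cl in (
            ("block_ps", config.protocol.s2_interval),
            ("block_vt", config.vt_cycle_length),
        ):
            pred = _block_prediction_raster(
                m, config.constants, config.calibration, cl
            )
            _write_raster(out / f"{name}.tsv", pred, m.spacing)

        stage = "simulation"
        result = run_premature_protocol(
            m, config.constants, config.calibration, config.protocol,
            config.refractory,
        )
        for name, cyc in result.cycles.items():
            _write_raster(out / f"activation_{name}.tsv", cyc.activation, m.spacing)
        with (out / "blocked_edges.txt").open("w") as fh:
            for name, cyc in result.cycles.items():
                for (u, v) in sorted(cyc.blocked_edges):
                    fh.write(f"{name}\t{u[0]},{u[1]}\t{v[0]},{v[1]}\n")
        with (out / "block_lines.txt").open("w") as fh:
            for line in result.block_lines:
                verts = ";".join(f"{x:.3f},{y:.3f}" for x, y in line.vertices)
                fh.write(f"{line.label}\t{verts}\n")

        stage = "circuit metrics"
        report: dict = {
            "induced": result.induced,
            "diagnostic": result.diagnostic,
            "reexcitation_interval_ms": result.reexcitation_interval,
            "s2_coupling_interval_ms": config.protocol.s2_interval,
        }
        ubls = [l for l in result.block_lines if l.label == "UBL"]
        laterals = [l for l in result.block_lines if l.label == "lateral"]
        if ubls and len(laterals) >= 2:
            laterals = sorted(laterals, key=lambda l: -l.arc_length)[:2]
            sr, sc = config.protocol.site
            geom = CircuitGeometry(
                stimulus_site=(sc * m.spacing, sr * m.spacing),
                ubl=max(ubls, key=lambda l: len(l.vertices)).vertices,
                lateral_lines=(laterals[0].vertices, laterals[1].vertices),
            )
            meas = measure_circuit(geom)
            report["measurements_mm"] = {
                "a": meas.a, "b": meas.b, "c": meas.c_len, "d": meas.d,
                "e": meas.e, "d_over_c_pct": meas.d_over_c,
                "leading_edge_position_pct": meas.leading_edge_position,
            }
        elif not result.induced:
            report["measurements_mm"] = None

        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report
    except Exception as exc:  # noqa: BLE001 - annotate with the stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def worked_examples(
    t_isthmus: float = 231.0,
    t_outer: float = 1440.0,
    constants: ModelConstants | None = None,
    calibration: RateBlockCalibration = DEFAULT_CALIBRATION,
) -> list[dict]:
    """The model's seven standard worked values, at printed precision.

    Relative thickness change from isthmus to outer pathway; critical
    curvature at the three calibrated cycle lengths; and the critical
    space step for that relative change at each cycle length.
    """
    ratio = (t_outer - t_isthmus) / t_isthmus
    rows = [
        {
            "quantity": "dT/T isthmus to outer pathway",
            "value": round(ratio, 2),
            "units": "unitless",
        }
    ]
    for cl, w in sorted(calibration.points, reverse=True):
        rho = rho_from_width(w, calibration.beta)
        rows.append(
            {
                "quantity": f"critical curvature at CL {cl:g} ms (w={w:g} mm)",
                "value": float(f"{rho:.3g}"),
                "units": "mm^-1",
            }
        )
        c_crit = critical_space_step(ratio, cl, calibration)
        rows.append(
            {
                "quantity": f"critical space step at CL {cl:g} ms",
                "value": round(c_crit, 1),
                "units": "mm",
            }
        )
    return rows
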
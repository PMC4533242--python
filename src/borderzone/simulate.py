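"""Activation-map simulation over a thickness map.

Propagation is discrete marching (Dijkstra) on the 8-connected grid: a
node's activation time is the minimum over neighbors of neighbor time plus
edge length divided by the directional edge velocity.  The edge velocity
applies the curvature law to the *signed* thickness change along the edge
direction — thin-to-thick slows (convex wavefront), thick-to-thin
facilitates (concave wavefront, capped at 1.5x the rectilinear velocity).

An edge fails (conduction block) when the thin-to-thick transition ahead of
it is steep enough for the cycle length: the transition's local curvature
ratio/length must reach the rate-dependent critical curvature, or the
instantaneous directional velocity must be non-positive.  Because the
criterion is directional, block is unidirectional by construction: the
reverse, thick-to-thin traversal remains open.

A premature (S1-S2) protocol produces the unidirectional block line (UBL)
capping the steep isthmus end; the wavefront bifurcates around it,
coalesces distal to it, and — once the proximal side has recovered — breaks
back through, traversing the isthmus in the reverse direction as the first
reentry cycle (V1).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .curvature import ModelConstants, sample_at_offset
from .geometry import ThicknessMap
from .rate import DEFAULT_CALIBRATION, RateBlockCalibration, critical_width, rho_from_width

__all__ = [
    "StimulusProtocol",
    "RefractoryModel",
    "CycleResult",
    "ActivationResult",
    "BlockLine",
    "EdgeModel",
    "simulate_cycle",
    "run_premature_protocol",
    "detect_block_lines",
]

Node = tuple[int, int]
Edge = tuple[Node, Node]

# 8-connected neighborhood, (dr, dc)
_OFFSETS = [
    (0, 1), (0, -1), (1, 0), (-1, 0),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
]

# facilitation cap: concave (thick-to-thin) wavefronts speed up at most this
# much over the rectilinear velocity
_FACILITATION_CAP = 1.5


@dataclass(frozen=True)
class StimulusProtocol:
    """S1 drive train followed by one premature (S2) stimulus.

    site        : (row, col) stimulus node
    s1_interval : drive-train interval, ms
    s1_count    : number of S1 pulses (steady state; the last one defines
                  the refractoriness background for S2)
    s2_interval : S1-S2 coupling interval, ms (must be premature)
    """

    site: Node
    s1_interval: float = 300.0
    s1_count: int = 10
    s2_interval: float = 150.0

    def __post_init__(self) -> None:
        if not (self.s2_interval < self.s1_interval):
            raise ValueError("s2_interval must be < s1_interval (premature)")
        if self.s1_interval <= 0 or self.s2_interval <= 0 or self.s1_count < 1:
            raise ValueError("intervals must be positive and s1_count >= 1")


@dataclass(frozen=True)
class RefractoryModel:
    """Spatially uniform refractoriness (ms).

    The border zone is treated as having uniform refractoriness; block
    localization comes from geometry, not refractory gradients.

    erp : effective refractory period — a node cannot be re-excited until
          this long after its previous activation.
    apd : action potential duration — how long an activated node remains a
          depolarized (plateau) source able to excite a recovered neighbor.
          In depressed infarct-border-zone tissue the ERP outlasts the APD
          (post-repolarization refractoriness), so apd <= erp.

    Re-excitation across a blocked interface therefore requires the two
    sides to have activated at least ``erp - apd`` apart: tissue activated
    near-simultaneously on both sides (a collision interface) repolarizes
    together and cannot re-excite itself, whereas a front that arrived via
    the long way around a block line finds the proximal side recovered
    while it is still at plateau.
    """

    erp: float = 100.0
    apd: float = 90.0

    def __post_init__(self) -> None:
        if not (self.erp > 0):
            raise ValueError("erp must be > 0")
        if not (0 < self.apd <= self.erp):
            raise ValueError("apd must satisfy 0 < apd <= erp")


@dataclass
class CycleResult:
    """One marching cycle: per-node activation times plus failed edges.

    activation    : ms per node; nan = never reached
    blocked_edges : directed (from, to) node pairs where conduction failed
    """

    activation: np.ndarray
    blocked_edges: set[Edge]
    sources: tuple[tuple[Node, float], ...]
    cycle_length: float
    diagnostic: str | None = None


@dataclass
class BlockLine:
    """A chained polyline of blocked interfaces, in mm coordinates."""

    label: str  # "UBL" or "lateral"
    vertices: np.ndarray  # (n, 2) xy in mm
    leading_edge: np.ndarray | None = None  # vertex nearest the stimulus

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))


@dataclass
class ActivationResult:
    """Outcome of a full premature-stimulation protocol."""

    cycles: dict[str, CycleResult]
    spacing: float
    stimulus_site: Node
    block_lines: list[BlockLine] = field(default_factory=list)
    breakthrough: tuple[Node, float] | None = None
    reexcitation_interval: float | None = None
    induced: bool = False
    diagnostic: str | None = None


class EdgeModel:
    """Precomputed directional edge velocities and transition steepness.

    For each of the 8 directions and every node this holds:

    theta[d]     : edge conduction velocity leaving the node in direction d
                   (signed curvature law, facilitation capped), mm/ms
    rho_local[d] : local curvature of the thin-to-thick transition ahead:
                   (total relative rise dT/T) / (rise distance to 90% of the
                   rise), mm^-1; 0 where the profile ahead does not rise

    The transition profile is scanned by bilinear sampling along the edge
    direction in half-spacing steps up to ``max_scan`` mm; the scan stops
    where the profile descends below 95% of the local thickness (the front
    is then running into *thinner* tissue, which is facilitation, not a
    source-sink obstacle for this edge).
    """

    def __init__(
        self,
        m: ThicknessMap,
        constants: ModelConstants,
        calibration: RateBlockCalibration = DEFAULT_CALIBRATION,
        max_scan: float = 12.0,
    ) -> None:
        self.map = m
        self.constants = constants
        self.calibration = calibration
        sp = m.spacing
        self.edge_lengths = [sp * float(np.hypot(dr, dc)) for dr, dc in _OFFSETS]

        T = m.values
        theta_list = []
        rho_list = []
        h = sp / 2.0
        n_steps = max(2, int(round(max_scan / h)))
        for (dr, dc), ell in zip(_OFFSETS, self.edge_lengths):
            norm = float(np.hypot(dr, dc))
            unit = np.array([dr / norm, dc / norm])

            # instantaneous signed ratio over the space step c
            off = unit * (constants.c / sp)
            t_at_c = sample_at_offset(m, off)
            ratio_c = (t_at_c - T) / T
            theta = constants.theta_o - (constants.D / constants.c) * ratio_c
            theta = np.minimum(theta, _FACILITATION_CAP * constants.theta_o)
            theta = np.where(np.isnan(theta), constants.theta_o, theta)
            theta_list.append(theta)

            # transition profile ahead
            profile = np.empty((n_steps, *T.shape))
            for k in range(1, n_steps + 1):
                profile[k - 1] = sample_at_offset(m, unit * (k * h / sp))
            ok = ~np.isnan(profile) & (profile >= 0.95 * T)
            ok = np.logical_and.accumulate(ok, axis=0)
            masked = np.where(ok, profile, -np.inf)
            t_far = np.maximum(masked.max(axis=0), T)
            rise = t_far - T
            thresh = T + 0.9 * rise
            reaches = masked >= thresh[None]
            first_k = np.argmax(reaches, axis=0)  # 0-based; step k -> (k+1)*h mm
            dist = (first_k + 1) * h
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(rise > 1e-9, (rise / T) / dist, 0.0)
            rho_list.append(rho)

        self.theta = np.stack(theta_list)       # (8, rows, cols)
        self.rho_local = np.stack(rho_list)     # (8, rows, cols)
        self._rho_crit_cache: dict[float, float] = {}

    def rho_crit(self, cycle_length: float) -> float:
        if cycle_length not in self._rho_crit_cache:
            w = critical_width(self.calibration, cycle_length, extrapolate=True)
            self._rho_crit_cache[cycle_length] = rho_from_width(
                w, self.calibration.beta
            )
        return self._rho_crit_cache[cycle_length]

    def blocked(self, cycle_length: float) -> np.ndarray:
        """Boolean (8, rows, cols): edge leaving each node fails at this CL."""
        rc = self.rho_crit(cycle_length)
        return (self.theta <= 0) | (self.rho_local >= rc)


def simulate_cycle(
    m: ThicknessMap,
    constants: ModelConstants,
    calibration: RateBlockCalibration,
    sources: list[tuple[Node, float]],
    cycle_length: float,
    refractory: RefractoryModel | None = None,
    prior_activation: np.ndarray | None = None,
    edge_model: EdgeModel | None = None,
    direction_order: list[int] | None = None,
) -> CycleResult:
    """March one activation cycle from the given sources.

    Each node activates at the minimum over incoming open edges of upstream
    time plus edge traversal time, but never before
    ``prior_activation + erp`` (refractory floor).  Edges whose directional
    transition blocks at this cycle length are excluded and recorded.
    """
    if not sources:
        raise ValueError("sources must be non-empty")
    if edge_model is None:
        edge_model = EdgeModel(m, constants, calibration)
    if direction_order is None:
        direction_order = list(range(len(_OFFSETS)))

    rows, cols = m.shape
    blocked = edge_model.blocked(cycle_length)
    floor = np.full((rows, cols), -np.inf)
    if prior_activation is not None and refractory is not None:
        floor = prior_activation + refractory.erp
        floor = np.where(np.isnan(floor), -np.inf, floor)

    best = np.full((rows, cols), np.inf)
    settled = np.zeros((rows, cols), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for (r, c), t0 in sources:
        if not m.mask[r, c]:
            raise ValueError(f"source {(r, c)} is outside the viable mask")
        t = max(t0, floor[r, c])
        if t < best[r, c]:
            best[r, c] = t
            heapq.heappush(heap, (t, r, c))

    blocked_edges: set[Edge] = set()
    while heap:
        t_u, r, c = heapq.heappop(heap)
        if settled[r, c] or t_u > best[r, c]:
            continue
        settled[r, c] = True
        for d in direction_order:
            dr, dc = _OFFSETS[d]
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols) or not m.mask[nr, nc]:
                continue
            if blocked[d, r, c]:
                blocked_edges.add(((r, c), (nr, nc)))
                continue
            theta = edge_model.theta[d, r, c]
            cand = max(t_u + edge_model.edge_lengths[d] / theta, floor[nr, nc])
            if cand < best[nr, nc]:
                best[nr, nc] = cand
                heapq.heappush(heap, (cand, nr, nc))

    activation = np.where(np.isinf(best), np.nan, best)
    diagnostic = None
    n_active = int(np.sum(~np.isnan(activation)))
    if n_active <= len(sources):
        diagnostic = "total block at source: no propagation beyond the stimulus"
    return CycleResult(
        activation=activation,
        blocked_edges=blocked_edges,
        sources=tuple(sources),
        cycle_length=cycle_length,
        diagnostic=diagnostic,
    )


def _find_breakthrough(
    s2: CycleResult,
    edge_model: EdgeModel,
    refractory: RefractoryModel,
    v1_cycle_length: float | None,
) -> list[tuple[Node, float, Node]]:
    """Feasible re-entry crossings over the premature-cycle blocked edges.

    A blocked edge (u -> v) supports breakthrough in the reverse direction
    when the distal side v — activated by the wavefront that travelled
    around the block line — is still a depolarized source (within its APD)
    when u's refractory period expires, and the reverse edge conducts.
    The crossing fires at max(t_v + edge time, t_u + erp).

    Returns (node u, time, distal node v) sorted by time.
    """
    A = s2.activation
    out: list[tuple[Node, float, Node]] = []
    for (u, v) in s2.blocked_edges:
        t_u, t_v = A[u], A[v]
        if np.isnan(t_u) or np.isnan(t_v):
            continue
        if t_u + refractory.erp > t_v + refractory.apd:
            continue  # v repolarizes before u recovers (collision interface)
        # reverse edge v -> u must conduct at the reentry cycle length
        dr, dc = u[0] - v[0], u[1] - v[1]
        d = _OFFSETS.index((dr, dc))
        cl = v1_cycle_length if v1_cycle_length is not None else t_v
        if edge_model.blocked(cl)[d, v[0], v[1]]:
            continue
        theta = edge_model.theta[d, v[0], v[1]]
        if theta <= 0:
            continue
        t_cross = t_v + edge_model.edge_lengths[d] / theta
        t_fire = max(t_cross, t_u + refractory.erp)
        out.append((u, t_fire, v))
    out.sort(key=lambda x: x[1])
    return out


def run_premature_protocol(
    m: ThicknessMap,
    constants: ModelConstants,
    calibration: RateBlockCalibration,
    protocol: StimulusProtocol,
    refractory: RefractoryModel | None = None,
    v1_cycle_length: float | None = None,
) -> ActivationResult:
    """Run S1 steady state, the premature S2 cycle, and the first reentry cycle.

    The last S1 cycle defines the refractoriness background for S2.  The S2
    cycle is marched at the coupling interval; its blocked edges form the
    UBL.  If the wavefront that bifurcated around the UBL re-arrives on the
    far side late enough for the proximal side to recover, the first reentry
    cycle (V1) is marched from the breakthrough crossings, at a cycle length
    defaulting to the observed return time.  The reexcitation interval is
    the V1 minus S2 activation time at the breakthrough node.
    """
    if refractory is None:
        refractory = RefractoryModel()
    edge_model = EdgeModel(m, constants, calibration)
    site = protocol.site

    s1 = simulate_cycle(
        m, constants, calibration, [(site, 0.0)], protocol.s1_interval,
        edge_model=edge_model,
    )
    # S2 fires s2_interval after the last S1 stimulus; in the S2 clock the
    # prior (S1) activation of each node happened at A1 - s2_interval
    s2 = simulate_cycle(
        m, constants, calibration, [(site, 0.0)], protocol.s2_interval,
        refractory=refractory,
        prior_activation=s1.activation - protocol.s2_interval,
        edge_model=edge_model,
    )

    result = ActivationResult(
        cycles={"s1": s1, "premature": s2},
        spacing=m.spacing,
        stimulus_site=site,
    )

    if not s2.blocked_edges:
        result.diagnostic = "no block, no reentry"
        result.block_lines = detect_block_lines(result)
        return result

    crossings = _find_breakthrough(s2, edge_model, refractory, v1_cycle_length)
    if not crossings:
        result.diagnostic = (
            "no reentry induced: recovery behind the block line incomplete "
            "when the circulating wavefront arrived"
        )
        result.block_lines = detect_block_lines(result)
        return result

    bt_node, bt_time, _ = crossings[0]
    cl_v1 = v1_cycle_length if v1_cycle_length is not None else bt_time
    v1 = simulate_cycle(
        m, constants, calibration,
        [(u, t) for u, t, _ in crossings],
        cl_v1,
        refractory=refractory,
        prior_activation=s2.activation,
        edge_model=edge_model,
    )
    result.cycles["v1"] = v1
    result.breakthrough = (bt_node, bt_time)
    result.reexcitation_interval = float(
        v1.activation[bt_node] - s2.activation[bt_node]
    )
    result.induced = True
    result.block_lines = detect_block_lines(result)
    return result


def _chain_polylines(
    midpoints: np.ndarray, link_distance: float
) -> list[np.ndarray]:
    """Group interface midpoints into connected chains and order each chain.

    Points within ``link_distance`` are connected; each connected component
    is ordered by a nearest-neighbor walk from its most extreme point.
    """
    n = len(midpoints)
    if n == 0:
        return []
    from scipy.spatial import cKDTree

    tree = cKDTree(midpoints)
    pairs = tree.query_pairs(link_distance, output_type="ndarray")
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    lines = []
    for idx in comps.values():
        pts = midpoints[idx]
        # start the walk from the point farthest from the centroid
        start = int(np.argmax(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1)))
        remaining = list(range(len(pts)))
        order = [start]
        remaining.remove(start)
        while remaining:
            last = pts[order[-1]]
            nxt = min(remaining, key=lambda k: np.sum((pts[k] - last) ** 2))
            order.append(nxt)
            remaining.remove(nxt)
        lines.append(pts[order])
    return lines


def detect_block_lines(result: ActivationResult) -> list[BlockLine]:
    """Chain blocked interfaces into labeled polylines.

    The premature-cycle lines are labeled ``UBL``; their leading edge is the
    vertex nearest the stimulus site.  First-reentry-cycle (V1) lines are
    labeled ``lateral`` — during reentry the isthmus is confined by
    functional block at its lateral boundaries.
    """
    sp = result.spacing
    sr, sc = result.stimulus_site
    stim_xy = np.array([sc * sp, sr * sp])
    lines: list[BlockLine] = []
    for cycle_name, label in (("premature", "UBL"), ("v1", "lateral")):
        cyc = result.cycles.get(cycle_name)
        if cyc is None or not cyc.blocked_edges:
            continue
        interfaces = {tuple(sorted(e)) for e in cyc.blocked_edges}
        mids = np.array(
            [
                (
                    (u[1] + v[1]) / 2.0 * sp,  # x
                    (u[0] + v[0]) / 2.0 * sp,  # y
                )
                for u, v in interfaces
            ]
        )
        for verts in _chain_polylines(mids, link_distance=1.2 * sp):
            leading = None
            if label == "UBL":
                leading = verts[
                    int(np.argmin(np.sum((verts - stim_xy) ** 2, axis=1)))
                ]
            lines.append(BlockLine(label=label, vertices=verts, leading_edge=leading))
    return lines
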
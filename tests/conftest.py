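import numpy as np
import pytest

import borderzone as bz


@pytest.fixture(scope="session")
def constants() -> bz.ModelConstants:
    return bz.ModelConstants()


@pytest.fixture(scope="session")
def calibration() -> bz.RateBlockCalibration:
    return bz.DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def isthmus_map() -> bz.ThicknessMap:
    """Default synthetic map: thin channel, steep entrance, gradual exit.

    0.5 mm grid so that the 1.5 mm lateral ramps are resolved: steep enough
    to block at reentry rates, but conducting at drive-train rates."""
    return bz.make_isthmus_map(bz.IsthmusSpec(), (81, 121), 0.5)


@pytest.fixture(scope="session")
def induced_result(isthmus_map, constants, calibration) -> bz.ActivationResult:
    """Premature protocol at S2 = 150 ms from beyond the gradual (exit) end."""
    proto = bz.StimulusProtocol(site=(40, 110), s2_interval=150.0)
    return bz.run_premature_protocol(
        isthmus_map, constants, calibration, proto
    )


def random_map(rng: np.random.Generator, n: int) -> bz.ThicknessMap:
    """Random small thickness map for oracle comparisons."""
    values = rng.uniform(100.0, 2000.0, size=(n, n))
    return bz.ThicknessMap(values, spacing=1.0)


def bellman_ford_oracle(
    m: bz.ThicknessMap,
    edge_model: bz.EdgeModel,
    sources,
    cycle_length: float,
    floor: np.ndarray | None = None,
) -> np.ndarray:
    """Fixpoint relaxation over the same edge-speed graph: an independent
    check of the marching solver (no priority queue, no visit order)."""
    from borderzone.simulate import _OFFSETS

    rows, cols = m.shape
    if floor is None:
        floor = np.full((rows, cols), -np.inf)
    blocked = edge_model.blocked(cycle_length)
    t = np.full((rows, cols), np.inf)
    for (r, c), t0 in sources:
        t[r, c] = min(t[r, c], max(t0, floor[r, c]))
    changed = True
    while changed:
        changed = False
        for r in range(rows):
            for c in range(cols):
                if not np.isfinite(t[r, c]):
                    continue
                for d, (dr, dc) in enumerate(_OFFSETS):
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < rows and 0 <= nc < cols):
                        continue
                    if not m.mask[nr, nc] or blocked[d, r, c]:
                        continue
                    theta = edge_model.theta[d, r, c]
                    cand = max(
                        t[r, c] + edge_model.edge_lengths[d] / theta,
                        floor[nr, nc],
                    )
                    if cand < t[nr, nc] - 1e-12:
                        t[nr, nc] = cand
                        changed = True
    return np.where(np.isinf(t), np.nan, t)
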
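import numpy as np
import pytest

import borderzone as bz
from borderzone.simulate import _OFFSETS

from conftest import bellman_ford_oracle, random_map

# worst-case overestimate of Euclidean distance by the 8-connected (octile)
# grid metric: sec(22.5 deg)
OCTILE_BOUND = 1.0 / np.cos(np.pi / 8)


def run_cycle(m, cl, site=(40, 110), **kw):
    return bz.simulate_cycle(
        m, bz.ModelConstants(), bz.DEFAULT_CALIBRATION, [(site, 0.0)], cl, **kw
    )


def test_uniform_map_isochrones_are_concentric():
    """On a constant map the activation time equals distance / theta_o up to
    the 8-connectivity metric error."""
    m = bz.make_uniform_map(1000.0, (31, 31), 1.0)
    src = (15, 15)
    cyc = run_cycle(m, 300.0, site=src)
    assert not cyc.blocked_edges
    theta_o = 0.4
    for node in [(15, 25), (5, 15), (8, 8), (25, 20), (0, 0)]:
        r = np.hypot(node[0] - src[0], node[1] - src[1])
        t = cyc.activation[node]
        assert r / theta_o - 1e-9 <= t <= OCTILE_BOUND * r / theta_o + 1e-9


def test_premature_rate_dependence_of_block(isthmus_map):
    """S2 = 150 ms blocks at the steep entrance; a non-premature cycle at
    300 ms crosses every transition."""
    cyc150 = run_cycle(isthmus_map, 150.0)
    cyc300 = run_cycle(isthmus_map, 300.0)
    assert len(cyc150.blocked_edges) > 0
    assert len(cyc300.blocked_edges) == 0


def test_ubl_caps_entrance_on_three_sides(induced_result):
    ubls = [l for l in induced_result.block_lines if l.label == "UBL"]
    assert len(ubls) == 1
    v = ubls[0].vertices
    # distal edge: vertices spanning the channel width just outside the
    # entrance foot (x ~ 19.5 for the default geometry)
    cap = v[v[:, 0] < 21.0]
    assert cap.size and cap[:, 1].min() < 16.0 and cap[:, 1].max() > 24.0
    # lateral margins: vertices on both sides of the channel axis (y = 20)
    assert np.any(v[:, 1] < 15.0) and np.any(v[:, 1] > 25.0)


def test_v1_reverses_isthmus_direction_and_reexcites_early(induced_result):
    assert induced_result.induced
    s2 = induced_result.cycles["premature"]
    v1 = induced_result.cycles["v1"]
    near_entrance, near_exit = (40, 44), (40, 80)
    # premature wavefront runs exit -> entrance; V1 runs entrance -> exit
    assert s2.activation[near_entrance] > s2.activation[near_exit]
    assert v1.activation[near_entrance] < v1.activation[near_exit]
    assert induced_result.reexcitation_interval < 150.0
    node, t = induced_result.breakthrough
    assert induced_result.reexcitation_interval == pytest.approx(
        v1.activation[node] - s2.activation[node]
    )


def test_v1_lateral_block_lines_flank_isthmus(induced_result):
    laterals = [l for l in induced_result.block_lines if l.label == "lateral"]
    assert len(laterals) == 2
    sides = sorted(l.vertices[:, 1].mean() for l in laterals)
    assert sides[0] < 20.0 < sides[1]


def test_non_premature_s2_gives_no_block_no_reentry(isthmus_map):
    proto = bz.StimulusProtocol(site=(40, 110), s1_interval=320.0, s2_interval=300.0)
    res = bz.run_premature_protocol(
        isthmus_map, bz.ModelConstants(), bz.DEFAULT_CALIBRATION, proto
    )
    assert not res.induced
    assert not res.cycles["premature"].blocked_edges
    assert "no block" in res.diagnostic


def test_blocked_sets_monotone_in_cycle_length(isthmus_map):
    em = bz.EdgeModel(isthmus_map, bz.ModelConstants(), bz.DEFAULT_CALIBRATION)
    b200, b150, b117 = (em.blocked(cl) for cl in (200.0, 150.0, 117.0))
    assert np.all(b200 <= b150) and np.all(b150 <= b117)
    assert b117.sum() > b150.sum() > b200.sum() >= 0


def test_causality_along_open_edges(induced_result):
    """Downstream activation is strictly later than upstream along any
    traversed edge (refractory floors only delay, never invert)."""
    s2 = induced_result.cycles["premature"]
    A = s2.activation
    rows, cols = A.shape
    rng = np.random.default_rng(0)
    for _ in range(200):
        r, c = rng.integers(1, rows - 1), rng.integers(1, cols - 1)
        t = A[r, c]
        if np.isnan(t):
            continue
        neigh = [
            A[r + dr, c + dc]
            for dr, dc in _OFFSETS
            if ((r + dr, c + dc), (r, c)) not in s2.blocked_edges
        ]
        neigh = [x for x in neigh if not np.isnan(x)]
        if t > 0 and neigh:
            assert min(neigh) < t  # some upstream neighbor activated earlier


@pytest.mark.parametrize("seed", range(30))
def test_marching_matches_relaxation_oracle_on_random_maps(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    m = random_map(rng, n)
    cl = float(rng.uniform(117.0, 300.0))
    src = (int(rng.integers(n)), int(rng.integers(n)))
    em = bz.EdgeModel(m, bz.ModelConstants(), bz.DEFAULT_CALIBRATION)
    cyc = bz.simulate_cycle(
        m, bz.ModelConstants(), bz.DEFAULT_CALIBRATION, [(src, 0.0)], cl,
        edge_model=em,
    )
    oracle = bellman_ford_oracle(m, em, [(src, 0.0)], cl)
    assert np.allclose(cyc.activation, oracle, equal_nan=True)


@pytest.mark.parametrize("seed", range(5))
def test_visit_order_does_not_change_activation_times(isthmus_map, seed):
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(8))
    base = run_cycle(isthmus_map, 150.0)
    shuffled = run_cycle(isthmus_map, 150.0, direction_order=order)
    assert np.allclose(base.activation, shuffled.activation, equal_nan=True)
    assert base.blocked_edges == shuffled.blocked_edges


def test_total_block_at_source_reports_diagnostic():
    """A thin node walled in by instantaneous-block transitions cannot
    propagate anywhere."""
    values = np.full((7, 7), 1440.0)
    values[3, 3] = 231.0
    m = bz.ThicknessMap(values, spacing=1.0)
    cyc = bz.simulate_cycle(
        m, bz.ModelConstants(), bz.DEFAULT_CALIBRATION, [((3, 3), 0.0)], 150.0
    )
    assert cyc.diagnostic is not None
    assert np.isnan(cyc.activation).sum() >= 0  # unreached nodes are nan, not 0
    assert np.nansum(cyc.activation == 0.0) == 1  # only the source fired


def test_source_validation(isthmus_map):
    with pytest.raises(ValueError, match="non-empty"):
        bz.simulate_cycle(
            isthmus_map, bz.ModelConstants(), bz.DEFAULT_CALIBRATION, [], 150.0
        )


def test_unreached_nodes_are_nan_not_zero():
    values = np.full((5, 9), 1440.0)
    values[:, 4] = 231.0  # thin wall: instantaneous block crossing it
    m = bz.ThicknessMap(values, spacing=1.0)
    cyc = bz.simulate_cycle(
        m, bz.ModelConstants(), bz.DEFAULT_CALIBRATION, [((2, 1), 0.0)], 150.0
    )
    # thin-to-thick from the wall outward is a 5.23 step over 1 mm: blocked,
    # so the far side of the wall is never reached
    far = cyc.activation[:, 6:]
    assert np.isnan(far).all()
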
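import numpy as np
import pandas as pd
import pytest

import borderzone as bz


def rect_geometry(ubl, stimulus=(30.0, 5.0)):
    """Isthmus as a 20 x 10 mm rectangle: lateral lines along y = 0 and
    y = 10 for x in [0, 20]; distal end at x = 0 (stimulus on the +x side)."""
    return bz.CircuitGeometry(
        stimulus_site=stimulus,
        ubl=np.asarray(ubl, dtype=float),
        lateral_lines=(
            np.array([[0.0, 0.0], [20.0, 0.0]]),
            np.array([[0.0, 10.0], [20.0, 10.0]]),
        ),
    )


def rigid(points, angle_deg, shift):
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return np.asarray(points, dtype=float) @ R.T + np.asarray(shift)


def test_ubl_capping_distal_40_percent():
    """A UBL that exactly caps the distal 40% of the isthmus and touches
    both lateral lines has zero error and 40% overlap."""
    geom = rect_geometry([[8, 0], [0, 0], [0, 10], [8, 10]])
    meas = bz.measure_circuit(geom)
    assert meas.e == pytest.approx(0.0)
    assert meas.d_over_c == pytest.approx(40.0)
    assert meas.c_len == pytest.approx(20.0)
    assert meas.b == pytest.approx(8.0)
    assert meas.d <= min(meas.b, meas.c_len) + 1e-9


def test_ubl_displaced_from_boundaries_gives_mean_distance():
    geom = rect_geometry([[8, 3], [0, 3], [0, 7], [8, 7]])
    assert bz.measure_circuit(geom).e == pytest.approx(3.0)


def test_experiment7_overlap_ratio():
    circ = bz.load_circuit_table()
    row = circ.loc[7]
    assert 100.0 * row["d"] / row["c"] == pytest.approx(45.58, abs=0.01)
    geom_free = 100.0 * 13.85 / 30.38
    assert geom_free == pytest.approx(row["d_over_c"], abs=0.01)


def test_leading_edge_at_distal_half():
    geom = rect_geometry([[10, 0], [0, 0], [0, 10], [10, 10]])
    assert bz.leading_edge_position(geom) == pytest.approx(50.0)


def test_leading_edge_hand_projection():
    """UBL leading edge at the axis midpoint of a 20 mm isthmus whose
    distal end is at 0 -> 50%, by direct projection."""
    geom = rect_geometry([[10.0, 2.0], [4.0, 2.0], [4.0, 8.0]])
    meas = bz.measure_circuit(geom)
    lead = np.array([10.0, 2.0])  # vertex nearest the stimulus at (30, 5)
    axis = geom.isthmus_axis
    expected = 100.0 * abs(lead @ axis - 0.0) / 20.0
    assert meas.leading_edge_position == pytest.approx(expected)
    assert expected == pytest.approx(50.0)


@pytest.mark.parametrize("angle, shift", [(0, (0, 0)), (30, (5, -3)),
                                          (90, (-10, 4)), (137.5, (2.2, 7.7))])
def test_measurements_invariant_under_rigid_motion(angle, shift):
    ubl = [[8, 0], [0, 0], [0, 10], [8, 10]]
    base = bz.measure_circuit(rect_geometry(ubl))
    moved = bz.CircuitGeometry(
        stimulus_site=tuple(rigid([[30.0, 5.0]], angle, shift)[0]),
        ubl=rigid(ubl, angle, shift),
        lateral_lines=(
            rigid([[0, 0], [20, 0]], angle, shift),
            rigid([[0, 10], [20, 10]], angle, shift),
        ),
    )
    m2 = bz.measure_circuit(moved)
    for name in ("a", "b", "c_len", "d", "e", "d_over_c",
                 "leading_edge_position", "b_arc"):
        assert getattr(m2, name) == pytest.approx(getattr(base, name), abs=1e-6)


def test_crossing_lateral_lines_rejected():
    with pytest.raises(ValueError, match="cross"):
        bz.CircuitGeometry(
            stimulus_site=(0.0, 0.0),
            ubl=np.array([[0.0, 0.0], [1.0, 1.0]]),
            lateral_lines=(
                np.array([[0.0, 0.0], [10.0, 10.0]]),
                np.array([[0.0, 10.0], [10.0, 0.0]]),
            ),
        )


def test_degenerate_polyline_rejected():
    with pytest.raises(ValueError, match="polyline"):
        bz.CircuitGeometry(
            stimulus_site=(0.0, 0.0),
            ubl=np.array([[1.0, 1.0]]),
            lateral_lines=(
                np.array([[0.0, 0.0], [10.0, 0.0]]),
                np.array([[0.0, 10.0], [10.0, 10.0]]),
            ),
        )


def test_circuit_table_means_match_published_summary():
    summary = bz.summarize_experiments(bz.load_circuit_table())
    expected_mean = {"a": 31.36, "b": 10.70, "c": 23.12, "d": 8.92,
                     "d_over_c": 38.45}
    expected_sd = {"a": 14.18, "b": 5.73, "c": 9.34, "d": 4.49,
                   "d_over_c": 9.69}
    for col, mn in expected_mean.items():
        assert summary.loc[col, "mean"] == pytest.approx(mn, abs=0.005)
        assert summary.loc[col, "sd"] == pytest.approx(expected_sd[col], abs=0.005)


def test_cycle_table_means_match_published_summary():
    summary = bz.summarize_experiments(bz.load_cycle_table())
    for col, mn, sd in [("ps", 164.6, 11.0), ("vt", 190.7, 20.4),
                        ("reexcitation", 150.9, 26.7)]:
        assert summary.loc[col, "mean"] == pytest.approx(mn, abs=0.05)
        assert summary.loc[col, "sd"] == pytest.approx(sd, abs=0.05)


def test_summary_of_constant_column():
    df = pd.DataFrame({"x": [5.0, 5.0, 5.0]})
    s = bz.summarize_experiments(df)
    assert s.loc["x", "mean"] == 5.0 and s.loc["x", "sd"] == 0.0
    with pytest.raises(ValueError):
        bz.summarize_experiments(df.iloc[:1])


def test_reexcitation_count():
    cyc = bz.load_cycle_table()
    assert bz.count_reexcitation_shorter(cyc) == 8
    tied = pd.DataFrame({"ps": [170.0, 160.0], "reexcitation": [170.0, 160.0]})
    assert bz.count_reexcitation_shorter(tied) == 0
    single = pd.DataFrame({"ps": [170.0], "reexcitation": [103.0]})
    assert bz.count_reexcitation_shorter(single) == 1
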
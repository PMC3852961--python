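import math

import numpy as np
import pytest

from memorient import synthetic
from memorient.evaluation import (
    DegenerateAxisError,
    OrientationComparison,
    TopologyAnnotation,
    TopologySegment,
    compare_orientations,
    format_topology,
    lipid_vector_tilt,
    longitudinal_axis,
    mean_segment_tilt,
    naive_orient,
    parse_topology,
    tilt_angle,
    z_shift,
)
from memorient.geometry import Transform
from memorient.structure_io import transform_structure

from conftest import make_residue, make_structure


def _segment_structure(points, chain="A", res_name="LEU"):
    """One residue (with CB) per point."""
    return make_structure([
        (chain, i + 1, res_name, [("CA", p), ("CB", p)])
        for i, p in enumerate(points)
    ])


# ---------------------------------------------------------------------------
# Topology parsing
# ---------------------------------------------------------------------------

def test_parse_topology_with_sense():
    topo = parse_topology("# comment\nA\t5\t30\tin-out\nA\t40\t66\tout-in\n")
    assert [s.sense for s in topo.segments] == ["in-out", "out-in"]
    assert topo.segments[0].start == 5


def test_parse_topology_alternates_when_sense_missing():
    topo = parse_topology("A 1 20\nA 30 50\nA 60 80\n")
    assert [s.sense for s in topo.segments] == ["in-out", "out-in", "in-out"]


def test_parse_topology_rejects_bad_sense():
    with pytest.raises(ValueError):
        parse_topology("A 1 20 sideways\n")


def test_segment_validation():
    with pytest.raises(ValueError):
        TopologySegment("A", 30, 10, "in-out")
    with pytest.raises(ValueError):
        TopologyAnnotation([TopologySegment("A", 1, 20, "in-out"),
                            TopologySegment("A", 15, 40, "out-in")])


def test_topology_format_round_trip():
    topo = parse_topology("A\t1\t20\tin-out\nB\t3\t33\tout-in\n")
    assert parse_topology(format_topology(topo)).segments == topo.segments


# ---------------------------------------------------------------------------
# Axes and tilts
# ---------------------------------------------------------------------------

def test_single_segment_axis():
    s = _segment_structure([(0, 0, -15), (0, 0, 15)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out")])
    np.testing.assert_allclose(longitudinal_axis(s, topo), [0, 0, 1], atol=1e-12)


def test_antiparallel_segments_sense_flip():
    s = _segment_structure([(0, 0, -15), (0, 0, 15), (5, 0, 15), (5, 0, -15)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out"),
                               TopologySegment("A", 3, 4, "out-in")])
    np.testing.assert_allclose(longitudinal_axis(s, topo), [0, 0, 1], atol=1e-12)


def test_axis_is_normalised_vector_mean():
    s = _segment_structure([(0, 0, 0), (0, 0, 30), (10, 0, 0), (10 + 30, 0, 0)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out"),
                               TopologySegment("A", 3, 4, "in-out")])
    np.testing.assert_allclose(longitudinal_axis(s, topo),
                               np.array([1, 0, 1]) / math.sqrt(2), atol=1e-12)


def test_degenerate_axis_raises():
    s = _segment_structure([(0, 0, -15), (0, 0, 15), (5, 0, -15), (5, 0, 15)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out"),
                               TopologySegment("A", 3, 4, "out-in")])
    with pytest.raises(DegenerateAxisError):
        longitudinal_axis(s, topo)


def test_tilt_angle_examples():
    assert tilt_angle(np.array([0, 0, 1])) == pytest.approx(0.0)
    assert tilt_angle(np.array([1, 0, 1]) / math.sqrt(2)) == pytest.approx(45.0)
    assert tilt_angle(np.array([0, 0, -1])) == pytest.approx(0.0)
    assert tilt_angle(np.array([1, 0, 0])) == pytest.approx(90.0)


def test_mean_segment_tilt_averages():
    a30 = (math.sin(math.radians(30)), 0, math.cos(math.radians(30)))
    a50 = (math.sin(math.radians(50)), 0, math.cos(math.radians(50)))
    pts = [(0, 0, 0), tuple(30 * x for x in a30), (50, 0, 0),
           tuple(50 + 30 * x if i == 0 else 30 * x for i, x in enumerate(a50))]
    s = _segment_structure(pts)
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out"),
                               TopologySegment("A", 3, 4, "in-out")])
    assert mean_segment_tilt(s, topo) == pytest.approx(40.0, abs=1e-9)


def test_z_shift_examples():
    s = _segment_structure([(0, 0, -15), (0, 0, 15)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out")])
    assert z_shift(s, topo) == pytest.approx(0.0)
    s2 = _segment_structure([(0, 0, -10), (0, 0, 20)])
    assert z_shift(s2, topo) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# Naive orientation
# ---------------------------------------------------------------------------

def test_naive_orient_axis_aligned_translates_only():
    s = _segment_structure([(0, 0, -10), (0, 0, 20)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out")])
    t = naive_orient(s, topo)
    assert (t.rot_x, t.rot_y) == (0.0, 0.0)
    assert t.dz == pytest.approx(-5.0)


def test_naive_orient_postconditions():
    helix, topo = synthetic.build_ideal_helix("LIVAF" * 4, tilt=35.0, z_offset=7.0)
    t = naive_orient(helix, topo)
    oriented = transform_structure(helix, t)
    assert tilt_angle(longitudinal_axis(oriented, topo)) < 1e-6
    assert abs(z_shift(oriented, topo)) < 1e-6


def test_naive_orient_idempotent():
    helix, topo = synthetic.build_ideal_helix("LIVAF" * 4, tilt=28.0, z_offset=-4.0)
    once = transform_structure(helix, naive_orient(helix, topo))
    t2 = naive_orient(once, topo)
    assert t2.rot_x % 360.0 == pytest.approx(0.0, abs=1e-6)
    assert t2.rot_y % 360.0 == pytest.approx(0.0, abs=1e-6)
    assert t2.dz == pytest.approx(0.0, abs=1e-6)


def test_naive_orient_handles_downward_axis():
    s = _segment_structure([(0, 0, 15), (0, 0, -15)])
    topo = TopologyAnnotation([TopologySegment("A", 1, 2, "in-out")])
    t = naive_orient(s, topo)
    oriented = transform_structure(s, t)
    axis = longitudinal_axis(oriented, topo)
    assert axis[2] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def test_compare_identical_structures():
    helix, topo = synthetic.build_ideal_helix("LIVAF" * 4, tilt=10.0)
    cmp = compare_orientations(helix, helix, topo, (3.0, 1.0))
    assert cmp == OrientationComparison(0.0, 0.0, True)


def test_compare_rotated_not_within():
    helix, topo = synthetic.build_ideal_helix("LIVAF" * 4)
    rotated = transform_structure(helix, Transform(rot_x=5.0))
    cmp = compare_orientations(rotated, helix, topo, (3.0, 1.0))
    assert cmp.tilt_delta == pytest.approx(5.0, abs=1e-6)
    assert not cmp.within_error


def test_compare_small_shift_within():
    helix, topo = synthetic.build_ideal_helix("LIVAF" * 4)
    shifted = transform_structure(helix, Transform(dz=0.5))
    cmp = compare_orientations(shifted, helix, topo, (3.0, 1.0))
    assert cmp.z_delta == pytest.approx(0.5, abs=1e-9)
    assert cmp.within_error


def test_compare_mismatched_residues_raises():
    h1, topo = synthetic.build_ideal_helix("LIVAF" * 4)
    h2, _ = synthetic.build_ideal_helix("AVILF" * 4)
    with pytest.raises(ValueError):
        compare_orientations(h1, h2, topo, (3.0, 1.0))


# ---------------------------------------------------------------------------
# Lipid vectors
# ---------------------------------------------------------------------------

def _lipid(res_seq, carbon_points, chain="X"):
    return make_residue(chain, res_seq, "POP",
                        [(f"C{i+1}", p) for i, p in enumerate(carbon_points)])


def test_single_lipid_along_z():
    s = make_structure([("A", 1, "LEU", [("CB", (0, 0, 0))])],
                       het=[_lipid(1, [(0, 0, -20), (0, 0, -5)])])
    assert lipid_vector_tilt(s, "lower") == pytest.approx(0.0)


def test_two_lipids_hand_vector_mean():
    v2 = np.array([0.0, 1.0, 1.0]) / math.sqrt(2)
    s = make_structure([("A", 1, "LEU", [("CB", (0, 0, 0))])],
                       het=[_lipid(1, [(0, 0, -20), (0, 0, -19)]),
                            _lipid(2, [(5, 0, -20), (5, 0, -20) + v2])])
    mean = (np.array([0, 0, 1.0]) + v2) / 2
    expected = math.degrees(math.acos(abs(mean[2] / np.linalg.norm(mean))))
    assert lipid_vector_tilt(s, "lower") == pytest.approx(expected, abs=1e-9)


def test_leaflet_assignment_by_mean_z():
    s = make_structure([("A", 1, "LEU", [("CB", (0, 0, 0))])],
                       het=[_lipid(1, [(0, 0, -20), (0, 0, -5)]),
                            _lipid(2, [(0, 0, 5), (3, 0, 20)])])
    assert lipid_vector_tilt(s, "lower") == pytest.approx(0.0)
    assert lipid_vector_tilt(s, "upper") > 1.0


def test_no_lipids_raises():
    s = make_structure([("A", 1, "LEU", [("CB", (0, 0, 0))])])
    with pytest.raises(ValueError):
        lipid_vector_tilt(s, "lower")


# ---------------------------------------------------------------------------
# Geometry self-consistency of synthetic fixtures
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("theta", [0.0, 12.5, 30.0])
def test_helix_fixture_tilt_is_exact(theta):
    helix, topo = synthetic.build_ideal_helix("L" * 19, tilt=theta)
    assert mean_segment_tilt(helix, topo) == pytest.approx(theta, abs=1e-6)


def test_tilt_invariant_under_z_rotation():
    helix, topo = synthetic.build_ideal_helix("L" * 19, tilt=22.0)
    pts = [a.position for r in helix.residues() for a in r.atoms]
    theta = math.radians(40.0)
    rz = np.array([[math.cos(theta), -math.sin(theta), 0],
                   [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
    rotated = transform_structure(helix, Transform())
    for res in rotated.residues():
        res.atoms = [type(a)(a.serial, a.name, a.alt_loc, a.res_name, a.chain_id,
                             a.res_seq, a.i_code, *(rz @ a.position), a.element,
                             a.is_hetatm) for a in res.atoms]
    assert mean_segment_tilt(rotated, topo) == pytest.approx(
        mean_segment_tilt(helix, topo), abs=1e-9)
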
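import numpy as np
import pytest
import trimesh

import aaamorph as am


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def cube_surface():
    """Axis-aligned cube, side 10 mm, centered at the origin (12 faces)."""
    box = trimesh.creation.box(extents=[10.0, 10.0, 10.0])
    return am.TriangleSurface(box.vertices, box.faces)


@pytest.fixture(scope="session")
def straight_tube():
    """Straight tube, radius 10 mm, length 50 mm along +z, 72 segments."""
    line = am.Centerline(np.column_stack([np.zeros(51), np.zeros(51), np.arange(51.0)]))
    return am.make_tube_surface(line, lambda s: 10.0, 72)


@pytest.fixture(scope="session")
def default_phantom():
    """Default bifurcated fusiform phantom with its centerlines and ledger."""
    return am.make_fusiform_phantom(am.PhantomSpec())


@pytest.fixture(scope="session")
def default_report(default_phantom):
    surface, centerlines, _ = default_phantom
    return am.measure_all(surface, centerlines)


def rigid_transform(seed=7):
    """A deterministic non-trivial rotation + translation."""
    gen = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    shift = gen.uniform(-50, 50, 3)
    return rot, shift


def transform_case(surface, centerlines, rot, shift, scale=1.0):
    """Apply one rigid (optionally scaled) transform to every input."""

    def pts(p):
        return (scale * p) @ rot.T + shift

    surf = am.TriangleSurface(pts(surface.vertices), surface.faces)
    cs = am.CenterlineSet(
        neck=am.Centerline(pts(centerlines.neck.points), name="neck"),
        aneurysm=am.Centerline(pts(centerlines.aneurysm.points), name="aneurysm"),
        right_iliac=am.Centerline(pts(centerlines.right_iliac.points), name="right_iliac"),
        left_iliac=am.Centerline(pts(centerlines.left_iliac.points), name="left_iliac"),
        right_plane=am.SectionPlane(pts(centerlines.right_plane.origin),
                                    centerlines.right_plane.normal @ rot.T),
        left_plane=am.SectionPlane(pts(centerlines.left_plane.origin),
                                   centerlines.left_plane.normal @ rot.T),
    )
    return surf, cs


def report_values(report):
    """The seven landmark values as a flat dict of floats."""
    return {
        "neck_diameter": report.neck_diameter.diameter,
        "aneurysm_diameter": report.aneurysm_diameter.diameter,
        "right_iliac_diameter": report.right_iliac_diameter.diameter,
        "left_iliac_diameter": report.left_iliac_diameter.diameter,
        "neck_length": report.neck_length,
        "right_tortuosity": report.right_tortuosity.ratio,
        "left_tortuosity": report.left_tortuosity.ratio,
        "neck_angulation": report.neck_angulation,
    }


def assert_matches_ledger(report, ledger):
    """Landmark recovery at the phantom tolerances: diameters within 1%,
    lengths within 0.5%, tortuosity ratio within 0.002, angle within 0.5
    degrees."""
    assert not report.errors
    assert report.neck_diameter.diameter == pytest.approx(ledger.neck_diameter, rel=0.01)
    assert report.aneurysm_diameter.diameter == pytest.approx(ledger.aneurysm_diameter, rel=0.01)
    assert report.right_iliac_diameter.diameter == pytest.approx(
        ledger.right_iliac_diameter, rel=0.01)
    assert report.left_iliac_diameter.diameter == pytest.approx(
        ledger.left_iliac_diameter, rel=0.01)
    assert report.neck_length == pytest.approx(ledger.neck_length, rel=0.005)
    assert report.right_tortuosity.ratio == pytest.approx(
        ledger.right_tortuosity.ratio, abs=0.002)
    assert report.left_tortuosity.ratio == pytest.approx(
        ledger.left_tortuosity.ratio, abs=0.002)
    assert report.neck_angulation == pytest.approx(ledger.neck_angulation, abs=0.5)
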
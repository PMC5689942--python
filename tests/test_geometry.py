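"""Ray-solid intersection kernels and scene location."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scattercast import geometry as geo
from scattercast import materials as mat
from scattercast import presets

from conftest import march_hit_distance

WATER = mat.get_material("water")


@pytest.fixture(scope="module")
def torso():
    return geo.EllipticCylinder([0, 0, 0], [0, 0, 1], 19.0, 11.5, 87.5, WATER,
                                name="staff")


def test_semi_axis_offset_hit(torso):
    """Ray along -x from (100,0,0) meets the a=19 semi-axis at distance 81."""
    hit = geo.intersect_ray_elliptic_cylinder([100, 0, 0], [-1, 0, 0], torso)
    assert hit is not None
    t, point, normal = hit
    assert t == pytest.approx(81.0, abs=1e-9)
    np.testing.assert_allclose(point, [19.0, 0.0, 0.0], atol=1e-9)
    np.testing.assert_allclose(normal, [1.0, 0.0, 0.0], atol=1e-9)


def test_axial_ray_misses_in_lateral_only_mode(torso):
    """A ray down the cylinder axis pierces the volume but registers no hit
    when only the lateral surface is tested (the published limitation)."""
    origin, direction = [0, 0, 200], [0, 0, -1]
    assert geo.intersect_ray_elliptic_cylinder(origin, direction, torso,
                                               geo.LATERAL_ONLY) is None
    hit = geo.intersect_ray_elliptic_cylinder(origin, direction, torso, geo.WITH_CAPS)
    assert hit is not None and hit[0] == pytest.approx(200 - 87.5)


def test_with_caps_hits_superset_of_lateral_only(torso):
    rng = np.random.default_rng(8)
    origins = rng.uniform(-120, 120, (2000, 3))
    dirs = rng.standard_normal((2000, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    t_lat = geo.ellcyl_hit_distances(origins, dirs, torso, geo.LATERAL_ONLY)
    t_cap = geo.ellcyl_hit_distances(origins, dirs, torso, geo.WITH_CAPS)
    assert np.isfinite(t_cap).sum() >= np.isfinite(t_lat).sum()
    # every lateral hit remains a hit (possibly shortened by an earlier cap hit)
    assert np.all(t_cap[np.isfinite(t_lat)] <= t_lat[np.isfinite(t_lat)] + 1e-12)


def test_unit_box_entry_exit():
    box = geo.Box([0, 0, 0], [0.5, 0.5, 0.5], WATER)
    entry, exit_ = geo.intersect_ray_box([-5, 0, 0], [1, 0, 0], box)
    assert entry == pytest.approx(4.5)
    assert exit_ == pytest.approx(5.5)


def test_box_interior_origin_entry_zero():
    box = geo.Box([0, 0, 0], [0.5, 0.5, 0.5], WATER)
    entry, exit_ = geo.intersect_ray_box([0.1, 0, 0], [1, 0, 0], box)
    assert entry == 0.0
    assert exit_ > 0.0


def test_grazing_ray_resolves_to_no_hit():
    box = geo.Box([0, 0, 0], [0.5, 0.5, 0.5], WATER)
    assert geo.intersect_ray_box([-5, 0.5, 0], [1, 0, 0], box) is None


def test_cylinder_kernel_agrees_with_marching_oracle(torso):
    """1e4 random rays: hit/no-hit and hit distance agree with a fixed-step
    ray-marching oracle to 0.02 cm."""
    rng = np.random.default_rng(123)
    n = 10_000
    origins = rng.uniform([-50, -50, -110], [50, 50, 110], (n, 3))
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    outside = ~torso.contains(origins)
    origins, dirs = origins[outside], dirs[outside]
    t_kernel = geo.ellcyl_hit_distances(origins, dirs, torso, geo.WITH_CAPS)
    t_march = march_hit_distance(origins, dirs, lambda p: torso.contains(p),
                                 t_max=150.0)
    hit_k = np.isfinite(t_kernel) & (t_kernel < 150.0 - 0.05)
    hit_m = np.isfinite(t_march)
    # tangential rays can legitimately disagree within the march resolution
    disagree = hit_k != hit_m
    assert disagree.mean() < 2e-3
    both = hit_k & hit_m
    assert np.max(np.abs(t_kernel[both] - t_march[both])) < 0.02


def test_box_kernel_agrees_with_marching_oracle():
    box = geo.Box([5, -3, 2], [12.0, 7.0, 20.0], WATER)
    rng = np.random.default_rng(321)
    n = 10_000
    origins = rng.uniform([-40, -40, -40], [40, 40, 40], (n, 3))
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    outside = ~box.contains(origins)
    origins, dirs = origins[outside], dirs[outside]
    lo, hi = box.center - box.half_extents, box.center + box.half_extents
    t0, t1 = geo.box_entry_exit(origins, dirs, lo, hi)
    hit_k = (t1 > np.maximum(t0, 0)) & (t0 > 0) & (t0 < 120.0)
    t_march = march_hit_distance(origins, dirs, lambda p: box.contains(p),
                                 t_max=120.0)
    hit_m = np.isfinite(t_march)
    disagree = hit_k != hit_m
    assert disagree.mean() < 2e-3
    both = hit_k & hit_m
    assert np.max(np.abs(t0[both] - t_march[both])) < 0.02


@settings(max_examples=50, deadline=None)
@given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
       st.integers(0, 2**31 - 1))
def test_translation_invariance(offset, seed):
    """Translating phantom and ray by the same vector leaves the
    intersection result unchanged."""
    rng = np.random.default_rng(seed)
    cyl = geo.EllipticCylinder([0, 0, 0], [0, 0, 1], 19.0, 11.5, 87.5, WATER)
    origin = rng.uniform(-60, 60, 3)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    off = np.asarray(offset)
    t1 = geo.ellcyl_hit_distances(origin[None], d[None], cyl)[0]
    t2 = geo.ellcyl_hit_distances((origin + off)[None], d[None],
                                  cyl.translated(off))[0]
    if np.isfinite(t1) or np.isfinite(t2):
        assert t1 == pytest.approx(t2, abs=1e-9)


def test_zero_direction_is_rejected(torso):
    with pytest.raises(ValueError):
        geo.intersect_ray_elliptic_cylinder([0, 0, 200], [0, 0, 0], torso)


def test_locate_priority_and_out_of_world():
    scene = presets.default_scene()
    material, region = geo.locate(scene, [0.0, 0.0, 0.0])
    assert region == "patient" and material.name == "water"
    material, region = geo.locate(scene, [0.0, 0.0, -111.0])
    assert region == "floor" and material.name == "concrete"
    material, region = geo.locate(scene, [200.0, 0.0, 0.0])
    assert region == "ambient" and material.name == "air"
    with pytest.raises(geo.OutOfWorldError):
        geo.locate(scene, [1000.0, 0.0, 0.0])


def test_staff_phantom_priority_over_room():
    staff = presets.staff_phantom("left", 25.0, -40.0)
    scene = presets.default_scene(staff=[staff])
    material, region = geo.locate(scene, staff.center)
    assert region == "staff"


def test_default_scene_psf_boxes_contain_their_scatterers():
    scene = presets.default_scene()
    patient_box = scene.surface_by_tag(geo.TAG_PATIENT_TABLE)
    for name in ("patient", "table"):
        s = scene.solid(name)
        pts = s.center + np.array([[0, 0, 0.0]])
        assert patient_box.strict_interior(pts).all()
    floor_box = scene.surface_by_tag(geo.TAG_FLOOR)
    assert floor_box.hi[2] == pytest.approx(presets.FLOOR_TOP_Z)
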
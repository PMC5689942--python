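"""Ray-casting dose estimation: identities, determinism, maps, histograms."""

import numpy as np
import pytest

from scattercast import geometry as geo
from scattercast import phasespace as ps
from scattercast import presets, raycast
from scattercast.mc_engine import KEV_TO_J, CalibrationFactors, MissingCalibrationError

UNIT_CALIB = CalibrationFactors(1.0, 0.0)


def test_empty_psf_gives_zero_dose(tmp_path, torso_phantom):
    path = tmp_path / "empty.psf"
    ps.write_psf(ps.PsfHeader(), [], path)
    res = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    assert res.dose_gy == 0.0
    assert res.hit_count == 0


def test_pencil_dose_identity(pencil_psf, torso_phantom):
    """1000 x 80 keV pencil photons aimed at the phantom: incident energy is
    exactly 80000 keV and the dose follows the arithmetic identity."""
    res = raycast.raycast_dose([pencil_psf], torso_phantom, UNIT_CALIB, frames=1)
    assert res.hit_count == 1000
    assert res.incident_energy_kev == 80_000.0
    assert res.dose_gy == 80_000.0 * KEV_TO_J / torso_phantom.mass_g
    # every hit point lies on the phantom surface
    local = (res.ledger.points - torso_phantom.center) @ torso_phantom.rotation.T
    r = (local[:, 0] / 19.0) ** 2 + (local[:, 1] / 11.5) ** 2
    assert np.all(np.abs(r - 1.0) < 1e-6)


def test_missing_calibration_is_an_error(pencil_psf, torso_phantom):
    with pytest.raises(MissingCalibrationError):
        raycast.raycast_dose([pencil_psf], torso_phantom, None)


def test_raycast_is_bitwise_deterministic(tmp_path, torso_phantom):
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [50.0, 10.0, 5.0],
                                            "energy": 75.0}, 30_000, 13, path)
    r1 = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    r2 = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    assert r1.dose_gy == r2.dose_gy
    assert r1.incident_energy_kev == r2.incident_energy_kev
    np.testing.assert_array_equal(r1.ledger.points, r2.ledger.points)


def test_totals_invariant_under_record_shuffle(tmp_path, torso_phantom):
    """Shuffling phase-space record order leaves dose and incident energy
    bitwise identical (exact summation)."""
    path = tmp_path / "a.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [40.0, -10.0, 0.0],
                                            "energy": 64.0}, 20_000, 3, path)
    header, batch = ps.read_psf_all(path)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(batch))
    shuffled = ps.PhotonBatch(batch.positions[perm], batch.directions[perm],
                              batch.energies[perm], batch.weights[perm],
                              batch.tags[perm])
    path2 = tmp_path / "b.psf"
    ps.write_psf(ps.PsfHeader(), shuffled, path2)
    r1 = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    r2 = raycast.raycast_dose([path2], torso_phantom, UNIT_CALIB)
    assert r1.incident_energy_kev == r2.incident_energy_kev
    assert r1.dose_gy == r2.dose_gy
    assert r1.hit_count == r2.hit_count


def test_percent_difference():
    assert raycast.percent_difference(5.0, 5.0) == 0.0
    assert raycast.percent_difference(1.0, 2.0) == -50.0
    with pytest.raises(ZeroDivisionError):
        raycast.percent_difference(1.0, 0.0)


def test_phantom_inside_phase_space_box_rejected(pencil_psf):
    scene = presets.default_scene()
    inside = geo.EllipticCylinder([0.0, 0.0, 0.0], [0, 0, 1], 5.0, 5.0, 5.0,
                                  presets.mat_mod.get_material("water"), name="staff")
    with pytest.raises(raycast.PhantomInPhaseSpaceError):
        raycast.raycast_dose([pencil_psf], inside, UNIT_CALIB,
                             surfaces=scene.surfaces)


def test_dose_map_single_position_reduces_to_raycast(tmp_path, torso_phantom):
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [60.0, 0.0, 0.0],
                                            "energy": 80.0}, 10_000, 21, path)
    single = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    dm = raycast.dose_map([path], torso_phantom, [torso_phantom.center],
                          UNIT_CALIB)
    assert dm.table.loc[0, "dose_gy"] == single.dose_gy
    assert dm.table.loc[0, "hit_count"] == single.hit_count


def test_dose_map_flags_invalid_positions_and_continues(tmp_path, torso_phantom):
    scene = presets.default_scene()
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [60.0, 0.0, 0.0],
                                            "energy": 80.0}, 5_000, 2, path)
    centers = [[0.0, 0.0, 0.0],        # inside the patient+table box: invalid
               [120.0, 0.0, -22.5]]    # clear of all boxes: valid
    dm = raycast.dose_map([path], torso_phantom, centers, UNIT_CALIB,
                          surfaces=scene.surfaces)
    assert list(dm.table["valid"]) == [False, True]
    assert np.isnan(dm.table.loc[0, "dose_gy"])


def test_dose_map_requires_unique_positions(tmp_path, torso_phantom):
    with pytest.raises(ValueError):
        raycast.dose_map([], torso_phantom, [[0, 0, 0], [0, 0, 0]], UNIT_CALIB)


def test_lao90_map_preset_has_seven_positions_per_side():
    positions = presets.lao90_map_positions()
    assert len(positions) == 14
    assert sum(p["side"] == "left" for p in positions) == 7
    gaps = {p["gap_cm"] for p in positions}
    assert {5.0, 25.0, 50.0} <= gaps


def test_surface_histogram_pencil_single_bin(pencil_psf, torso_phantom):
    res = raycast.raycast_dose([pencil_psf], torso_phantom, UNIT_CALIB)
    hist, _, _ = raycast.surface_histogram(res.ledger, torso_phantom, 36, 35)
    assert (hist > 0).sum() == 1
    assert hist.sum() == pytest.approx(80_000.0)


def test_surface_histogram_conserves_ledger_energy(tmp_path, torso_phantom):
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [45.0, 20.0, 30.0],
                                            "energy": 66.0}, 25_000, 5, path)
    res = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    hist, _, _ = raycast.surface_histogram(res.ledger, torso_phantom, 24, 20)
    assert hist.sum() == pytest.approx(res.incident_energy_kev, rel=1e-12)


def test_surface_histogram_azimuths_match_solid_angle_oracle(tmp_path, torso_phantom):
    """Isotropic point on the +x side: the azimuthal energy distribution
    matches a numeric solid-angle integration per bin within 3 sigma."""
    n = 60_000
    e0 = 70.0
    src = np.array([60.0, 0.0, 0.0])
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": src.tolist(), "energy": e0},
                        n, 17, path)
    res = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB,
                               caps_mode=geo.LATERAL_ONLY)
    n_az = 18
    hist, az_edges, _ = raycast.surface_histogram(res.ledger, torso_phantom, n_az, 1)
    counts = hist.sum(axis=1) / e0
    # oracle: per-azimuth-bin solid-angle fraction by dense surface patching
    phi = np.linspace(-np.pi, np.pi, 3600, endpoint=False) + np.pi / 3600
    zs = np.linspace(-87.5, 87.5, 700)
    pp, zz = np.meshgrid(phi, zs, indexing="ij")
    a, b = 19.0, 11.5
    pts = np.stack([a * np.cos(pp), b * np.sin(pp), zz], axis=-1)
    # surface element and outward normal of the elliptic cylinder
    tangent = np.stack([-a * np.sin(pp), b * np.cos(pp), np.zeros_like(pp)], axis=-1)
    dA = np.linalg.norm(tangent, axis=-1) * (phi[1] - phi[0]) * (zs[1] - zs[0])
    normal = np.stack([b * np.cos(pp), a * np.sin(pp), np.zeros_like(pp)], axis=-1)
    normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
    rvec = src - pts
    r = np.linalg.norm(rvec, axis=-1)
    cos_inc = (rvec * normal).sum(axis=-1) / r
    visible = cos_inc > 0
    flux = np.where(visible, cos_inc * dA / (4 * np.pi * r**2), 0.0)
    expected = np.array([flux[(pp[:, 0] >= az_edges[i]) & (pp[:, 0] < az_edges[i + 1])].sum()
                         for i in range(n_az)]) * n
    for i in range(n_az):
        if expected[i] < 10:
            assert counts[i] <= max(10, expected[i] + 3 * np.sqrt(expected[i] + 1) + 3)
        else:
            assert abs(counts[i] - expected[i]) < 3.5 * np.sqrt(expected[i])


def test_hit_fractions_sum_to_one(tmp_path, torso_phantom):
    rng = np.random.default_rng(1)
    n = 5000
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    origins = torso_phantom.center + 200.0 * -d  # rays converging on the phantom
    batch = ps.PhotonBatch(origins, d, rng.uniform(20, 120, n), np.ones(n),
                           rng.integers(0, 3, n).astype(np.uint8))
    path = tmp_path / "mix.psf"
    ps.write_psf(ps.PsfHeader(), batch, path)
    res = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    frac = raycast.hit_fraction_by_source(res.ledger)
    assert frac["hit_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    assert frac["energy_fraction"].sum() == pytest.approx(1.0, abs=1e-12)


def test_hit_fraction_single_tag(pencil_psf, torso_phantom):
    res = raycast.raycast_dose([pencil_psf], torso_phantom, UNIT_CALIB)
    frac = raycast.hit_fraction_by_source(res.ledger)
    assert frac.loc["patient_table", "hit_fraction"] == 1.0


def test_hit_fraction_empty_ledger_undefined(tmp_path, torso_phantom):
    path = tmp_path / "empty.psf"
    ps.write_psf(ps.PsfHeader(), [], path)
    res = raycast.raycast_dose([path], torso_phantom, UNIT_CALIB)
    with pytest.raises(ValueError):
        raycast.hit_fraction_by_source(res.ledger)


def test_ledger_export_row_count(tmp_path, pencil_psf, torso_phantom):
    res = raycast.raycast_dose([pencil_psf], torso_phantom, UNIT_CALIB)
    out = tmp_path / "ledger.tsv"
    res.ledger.export(out)
    rows = out.read_text().strip().splitlines()
    assert len(rows) - 1 == res.hit_count  # header + one row per hit


def test_vacuum_equivalence_is_exact(tmp_path, torso_phantom):
    """With vacuum everywhere en route and EAR = 1, ray-cast incident energy
    equals the Monte Carlo replay energy entering the phantom bitwise."""
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [70.0, -30.0, 40.0],
                                            "energy": 90.0}, 30_000, 23, path)
    rc, mc = raycast.vacuum_equivalence([path], torso_phantom)
    assert rc == mc
    assert rc > 0.0
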
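"""Monte Carlo engine: transport physics, ledgers, phase-space generation,
calibration and commissioning."""

import numpy as np
import pytest

from scattercast import geometry as geo
from scattercast import materials as mat
from scattercast import mc_engine as mce
from scattercast import phasespace as ps
from scattercast import presets
from scattercast.phasespace import PhotonBatch
from scattercast.spectrum_source import BeamConfig, build_spectrum

WATER = mat.get_material("water")
AIR = mat.get_material("air")
VAC = mat.vacuum()


def slab_scene(thickness=10.0, material=WATER, ambient=VAC):
    slab = geo.Box([0, 0, thickness / 2], [40.0, 40.0, thickness / 2], material,
                   name="slab")
    return geo.Scene([slab], [], ambient, np.array([100.0, 100.0, 100.0]))


def pencil(n, energy, z0=-20.0):
    return PhotonBatch(np.tile([0.0, 0.0, z0], (n, 1)),
                       np.tile([0.0, 0.0, 1.0], (n, 1)),
                       np.full(n, float(energy)), np.ones(n))


# ---------------------------------------------------------------------------
# Single-photon event transport
# ---------------------------------------------------------------------------

def test_transport_in_vacuum_is_single_escape():
    scene = geo.Scene([], [], VAC, np.array([50.0, 50.0, 50.0]))
    events = mce.transport(scene, [0, 0, 0], [1, 0, 0], 60.0,
                           np.random.default_rng(0))
    assert [e.kind for e in events] == ["escape"]
    assert events[0].deposited == 0.0


def test_sub_cutoff_photon_terminates_immediately():
    scene = slab_scene()
    events = mce.transport(scene, [0, 0, 5.0], [0, 0, 1], 9.9,
                           np.random.default_rng(0))
    assert [e.kind for e in events] == ["cutoff_termination"]
    assert events[0].deposited == pytest.approx(9.9)
    assert events[0].region == "slab"


def test_transport_records_phase_space_crossings():
    scene = slab_scene()
    scene.surfaces.append(geo.BoxSurface([0, 0, 5], [45.0, 45.0, 10.0],
                                         "phase_space_patient_table"))
    events = mce.transport(scene, [0, 0, -20], [0, 0, 1], 124.0,
                           np.random.default_rng(4))
    kinds = [e.kind for e in events]
    assert kinds[-1] in ("escape", "interaction", "cutoff_termination")
    # any outward crossing events must carry the surface tag
    for e in events:
        if e.kind == "phase_space_crossing":
            assert e.surface_tag == "patient_table"


@pytest.mark.parametrize("energy", [20.0, 60.0, 125.0])
def test_uncollided_transmission_matches_beer_lambert(energy):
    """1e5 photons through 10 cm of water: the uncollided fraction equals
    exp(-mu_total * 10) within 3 sigma binomial error."""
    scene = slab_scene(10.0)
    arrays = mce.compile_scene(scene)
    n = 100_000
    res = mce.run_batch(arrays, pencil(n, energy), seed=int(energy) * 7 + 1)
    res.stats.check_ledger()
    uncollided = (res.n_interactions == 0).mean()
    expected = np.exp(-mat.attenuation(WATER, energy)["total"] * 10.0)
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert abs(uncollided - expected) < 3 * sigma


def test_energy_ledger_balances_in_room_scene(beam_lao90, spectrum_125):
    from scattercast.spectrum_source import sample_primary
    scene = presets.default_scene(beam_lao90,
                                  staff=[presets.staff_phantom("left", 25.0)])
    arrays = mce.compile_scene(scene)
    photons = sample_primary(beam_lao90, spectrum_125, 20_000,
                             np.random.default_rng(3))
    res = mce.run_batch(arrays, photons, seed=17)
    assert res.stats.check_ledger()
    assert res.stats.discarded_count == 0
    # the patient and the absorbing detector take most of the beam energy
    dep = res.stats.deposited_by_region
    assert dep["patient"] + dep.get("detector", 0.0) > 0.5 * res.stats.emitted_energy


def test_python_transport_agrees_with_batch_kernel():
    """Mean energy deposited in a water slab: readable Python path vs the
    compiled batch kernel, within 3 sigma."""
    scene = slab_scene(5.0, ambient=VAC)
    rng = np.random.default_rng(21)
    n_py = 400
    deposits = []
    for _ in range(n_py):
        events = mce.transport(scene, [0, 0, -20.0], [0, 0, 1], 60.0, rng)
        deposits.append(sum(e.deposited for e in events))
    deposits = np.asarray(deposits)
    arrays = mce.compile_scene(scene)
    res = mce.run_batch(arrays, pencil(20_000, 60.0), seed=9)
    kernel_mean = (sum(res.stats.deposited_by_region.values())
                   + res.stats.cutoff_energy) / 20_000
    se = deposits.std(ddof=1) / np.sqrt(n_py)
    assert abs(deposits.mean() - kernel_mean) < 3.5 * se


# ---------------------------------------------------------------------------
# Phase-space generation
# ---------------------------------------------------------------------------

def test_psf_generation_is_deterministic(tmp_path, beam_lao90, spectrum_125):
    scene = presets.default_scene(beam_lao90)
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    p1, s1 = mce.run_psf_generation(scene, beam_lao90, spectrum_125, 15_000, 42, out1)
    p2, s2 = mce.run_psf_generation(scene, beam_lao90, spectrum_125, 15_000, 42, out2)
    assert s1.psf_record_counts == s2.psf_record_counts
    for tag in p1:
        assert p1[tag].read_bytes() == p2[tag].read_bytes()
    assert s1.check_ledger()
    assert sum(s1.psf_record_counts.values()) > 0


def test_psf_generation_rejects_zero_histories(tmp_path, beam_lao90, spectrum_125):
    scene = presets.default_scene(beam_lao90)
    with pytest.raises(ValueError):
        mce.run_psf_generation(scene, beam_lao90, spectrum_125, 0, 1, tmp_path)


def test_vacuum_scene_produces_empty_psfs(tmp_path, spectrum_125):
    beam = BeamConfig(lao_deg=0.0)
    scene = presets.vacuum_room_scene(beam)
    # vacuum room still records box crossings of the uncollided primaries
    paths, stats = mce.run_psf_generation(scene, beam, spectrum_125, 100, 5, tmp_path)
    assert stats.psf_record_counts["patient_table"] == 100  # one exit each
    assert stats.psf_record_counts["floor"] == 0
    assert stats.psf_record_counts["ceiling"] == 0


# ---------------------------------------------------------------------------
# Full-MC phantom dose
# ---------------------------------------------------------------------------

def test_beam_into_vacuum_gives_zero_dose(spectrum_125):
    staff = presets.staff_phantom("left", 50.0, -80.0)
    scene = geo.Scene([staff], [], VAC, np.array([300.0, 300.0, 200.0]))
    beam = BeamConfig(lao_deg=0.0)  # beam straight up, phantom far off-axis
    est = mce.score_phantom_dose_mc(scene, beam, spectrum_125, 2000, 3, frames=1)
    assert est.dose_gy == 0.0


def test_fully_absorbed_emission_gives_closed_form_dose():
    """Isotropic source inside a perfectly absorbing phantom: dose equals
    emitted energy x 1.602e-16 / mass exactly."""
    from dataclasses import replace
    phantom = replace(presets.staff_phantom("left", 25.0), absorber=True,
                      center=np.array([0.0, 0.0, 0.0]))
    scene = geo.Scene([phantom], [], VAC, np.array([300.0, 300.0, 200.0]))
    arrays = mce.compile_scene(scene)
    rng = np.random.default_rng(8)
    n = 5000
    mu = rng.uniform(-1, 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - mu**2)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
    batch = PhotonBatch(np.zeros((n, 3)), dirs, np.full(n, 80.0), np.ones(n))
    res = mce.run_batch(arrays, batch, seed=1, target="staff")
    absorbed = res.target_deposit.sum()
    assert absorbed == pytest.approx(n * 80.0, rel=1e-12)
    dose = absorbed * mce.KEV_TO_J / phantom.mass_g
    assert dose == pytest.approx(n * 80.0 * mce.KEV_TO_J / phantom.mass_g)


def test_dose_estimate_consistent_when_histories_double(beam_lao90, spectrum_125):
    scene = presets.default_scene(beam_lao90,
                                  staff=[presets.staff_phantom("left", 25.0)])
    small = mce.score_phantom_dose_mc(scene, beam_lao90, spectrum_125, 60_000, 31,
                                      frames=1, batch_size=10_000)
    big = mce.score_phantom_dose_mc(scene, beam_lao90, spectrum_125, 120_000, 32,
                                    frames=1, batch_size=20_000)
    sigma = np.hypot(small.stderr_gy, big.stderr_gy)
    assert abs(small.dose_gy - big.dose_gy) < 3 * sigma
    assert big.stderr_gy < small.stderr_gy


# ---------------------------------------------------------------------------
# Energy-absorption ratio
# ---------------------------------------------------------------------------

def test_absorbing_phantom_in_vacuum_has_ratio_one(tmp_path):
    from dataclasses import replace
    phantom = replace(presets.staff_phantom("left", 25.0), absorber=True)
    scene = geo.Scene([phantom], [], VAC, np.array([300.0, 300.0, 200.0]))
    path = tmp_path / "iso.psf"
    ps.make_fixture_psf("isotropic_point", {"position": [0.0, -40.0, 0.0],
                                            "energy": 70.0}, 20_000, 6, path)
    calib = mce.calibrate_energy_absorption_ratio(scene, [path], 2, "staff")
    assert calib.energy_absorption_ratio == pytest.approx(1.0, abs=1e-12)


def test_ratio_undefined_without_hits(tmp_path):
    phantom = presets.staff_phantom("left", 25.0)
    scene = geo.Scene([phantom], [], VAC, np.array([300.0, 300.0, 200.0]))
    path = tmp_path / "miss.psf"
    ps.make_fixture_psf("pencil", {"position": [-200.0, 200.0, 0.0],
                                   "direction": [0.0, 0.0, 1.0], "energy": 60.0},
                        100, 1, path)
    with pytest.raises(mce.UndefinedRatioError):
        mce.calibrate_energy_absorption_ratio(scene, [path], 2, "staff")


def test_calibration_factor_bounds():
    with pytest.raises(ValueError):
        mce.CalibrationFactors(0.0, 0.0)
    with pytest.raises(ValueError):
        mce.CalibrationFactors(1.2, 0.0)
    assert mce.CalibrationFactors(1.0, 90.0).energy_absorption_ratio == 1.0


def test_calibration_cache_round_trip_and_lookup(tmp_path):
    factors = [mce.CalibrationFactors(0.6 + 0.01 * i, 15.0 * i) for i in range(7)]
    path = tmp_path / "calib.yaml"
    mce.save_calibration(factors, path)
    back = mce.load_calibration(path)
    assert {f.angulation_deg for f in back} == {15.0 * i for i in range(7)}
    near = mce.lookup_calibration(back, 47.0)
    assert near.angulation_deg == 45.0
    with pytest.raises(mce.MissingCalibrationError):
        mce.lookup_calibration(back, 120.0)


# ---------------------------------------------------------------------------
# Replay completeness
# ---------------------------------------------------------------------------

def test_replay_plus_direct_equals_full_mc(tmp_path, beam_lao90, spectrum_125):
    """Phantom dose from the source equals the dose from replaying all
    phase-space records (kill-on-crossing) plus the pre-first-crossing
    direct contribution, within 3 sigma."""
    from scattercast.spectrum_source import sample_primary
    n = 250_000
    scene = presets.default_scene(beam_lao90)
    paths, _ = mce.run_psf_generation(scene, beam_lao90, spectrum_125, n, 71,
                                      tmp_path)
    staff = presets.staff_phantom("left", 25.0, -40.0)
    scene_ph = presets.default_scene(beam_lao90, staff=[staff])
    full = mce.score_phantom_dose_mc(scene_ph, beam_lao90, spectrum_125, n, 72,
                                     frames=1, batch_size=25_000)
    replay_kev, replay_se, _ = mce.replay_psf(scene_ph, paths, 73,
                                              chunk_records=120_000)
    arrays = mce.compile_scene(scene_ph)
    direct = 0.0
    for b in range(4):
        rng = np.random.default_rng(np.random.SeedSequence((74, b)))
        batch = sample_primary(beam_lao90, spectrum_125, n // 4, rng)
        res = mce.run_batch(arrays, batch, mce._kernel_seed(74, b),
                            kill_on_crossing=True, target="staff")
        direct += res.target_deposit.sum()
    scale = mce.KEV_TO_J / staff.mass_g
    reconstructed = (replay_kev + direct) * scale
    sigma = np.hypot(full.stderr_gy, replay_se * scale)
    assert abs(full.dose_gy - reconstructed) < 3 * sigma


# ---------------------------------------------------------------------------
# Commissioning
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def commissioning(spectrum_125):
    return mce.commissioning_profiles(BeamConfig(), spectrum_125, 3_000_000, 1)


def test_commissioning_table_shapes(commissioning):
    assert len(commissioning.depth_dose) == 26
    assert len(commissioning.profile_x) == 43
    assert len(commissioning.profile_y) == 43
    assert commissioning.depth_dose["dose"].iloc[0] == 1.0


def test_depth_dose_decreases_beyond_first_voxel(commissioning):
    dd = commissioning.depth_dose["dose"].to_numpy()
    assert np.all(np.diff(dd[1:]) < 0)


def test_cross_profiles_flat_in_central_field(commissioning):
    ic = 21
    for prof in (commissioning.profile_x, commissioning.profile_y):
        central = prof["dose"].to_numpy()[ic - 5: ic + 6]
        assert np.max(np.abs(central - 1.0)) < 0.05


def test_profile_comparison_identities(commissioning):
    import pandas as pd
    sim = commissioning.depth_dose
    table, mean_abs = mce.compare_profile(sim, sim.copy())
    assert np.allclose(table["pct_difference"], 0.0)
    assert mean_abs == 0.0
    doubled = sim.assign(dose=2 * sim["dose"])
    table, mean_abs = mce.compare_profile(sim, doubled)
    assert np.allclose(table["pct_difference"], -50.0)
    assert mean_abs == pytest.approx(50.0)
    ref = sim.copy()
    ref.loc[5, "dose"] = 0.0
    # a zero reference point is excluded and flagged, not propagated
    ref_sparse = ref.iloc[[0, 5, 25]]
    table, _ = mce.compare_profile(sim.iloc[[0, 5, 25]].reset_index(drop=True),
                                   ref_sparse.reset_index(drop=True))
    assert table["excluded_zero_reference"].sum() == 1
    assert table["pct_difference"].isna().sum() == 1


def test_absolute_dose_factor_from_reference(commissioning):
    adf = mce.absolute_dose_factor_from_reference(commissioning, 2.5e-4)
    sim_at_1cm = np.interp(1.0, commissioning.depth_dose["depth_cm"],
                           commissioning.depth_dose["dose"])
    assert adf == pytest.approx(2.5e-4 / sim_at_1cm)
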
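"""Reference Monte Carlo photon transport.

Generates phase-space files around the static scatterers, scores full-MC
staff-phantom dose (the validation standard for the ray-casting
approximation), computes commissioning depth-dose/cross profiles, and
calibrates the per-angulation energy-absorption ratio.

Transport model: photon-only Woodcock (delta) tracking with an
energy-dependent majorant over the scene materials; Compton (free-electron
Klein-Nishina), Rayleigh (Thomson angular law) and photoelectric
interactions; secondary-electron energy deposited locally (kerma
approximation); photons terminated below 10 keV with local deposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from . import materials as mat_mod
from ._kernel import KIND_BOX, KIND_ELLCYL, transport_batch
from ._physics import PHOTON_CUTOFF_KEV
from .phasespace import PhotonBatch, PsfHeader, PsfWriter, read_psf
from .spectrum_source import BeamConfig, EnergySpectrum, sample_primary

KEV_TO_J = 1.602176634e-16  # joule per keV; divided by mass in g this is Gy per keV/g


class CorruptedHistoryError(RuntimeError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    """Energy-absorption ratio requested but no phase-space ray hits the phantom."""


class MissingCalibrationError(KeyError):
    """No stored calibration close enough to the requested angulation."""


# ---------------------------------------------------------------------------
# Scene compilation
# ---------------------------------------------------------------------------

@dataclass
class SceneArrays:
    """Flat-array view of a Scene consumed by the transport kernel."""

    scene: geo.Scene
    sol_kind: np.ndarray
    sol_center: np.ndarray
    sol_rot: np.ndarray
    sol_params: np.ndarray
    sol_mat: np.ndarray
    world_half: np.ndarray
    materials: list
    mu: np.ndarray
    mu_maj: np.ndarray
    e_min: float
    e_step: float
    ambient_mat: int
    box_lo: np.ndarray
    box_hi: np.ndarray
    box_tag: np.ndarray
    region_names: list

    def solid_index(self, name: str) -> int:
        for i, s in enumerate(self.scene.solids):
            if s.name == name:
                return i
        raise KeyError(name)


def compile_scene(scene: geo.Scene, mu_step_kev: float = 0.25) -> SceneArrays:
    """Flatten a scene into kernel arrays and pre-interpolated mu tables."""
    n = len(scene.solids)
    sol_kind = np.zeros(n, dtype=np.int8)
    sol_center = np.zeros((n, 3))
    sol_rot = np.zeros((n, 3, 3))
    sol_params = np.zeros((n, 3))
    sol_mat = np.zeros(n, dtype=np.int64)

    mats: list = []
    mat_index: dict = {}

    def midx(material):
        key = (material.name, material.density)
        if key not in mat_index:
            mat_index[key] = len(mats)
            mats.append(material)
        return mat_index[key]

    for i, s in enumerate(scene.solids):
        sol_center[i] = s.center
        if isinstance(s, geo.EllipticCylinder):
            sol_kind[i] = KIND_ELLCYL
            sol_rot[i] = s.rotation
            sol_params[i] = (s.semi_axis_a, s.semi_axis_b, s.half_height)
        elif isinstance(s, geo.Box):
            sol_kind[i] = KIND_BOX
            sol_rot[i] = s.rotation
            sol_params[i] = s.half_extents
        else:
            raise TypeError(f"unsupported solid type {type(s)}")
        sol_mat[i] = -1 if getattr(s, "absorber", False) else midx(s.material)
    ambient_idx = midx(scene.ambient)

    e_min, e_step, mu = mat_mod.fine_mu_tables(mats, mu_step_kev)
    mu_maj = mu[:, 3, :].max(axis=0)

    boxes = [s for s in scene.surfaces if s.role != "world_boundary"]
    box_lo = np.array([b.lo for b in boxes]).reshape(len(boxes), 3)
    box_hi = np.array([b.hi for b in boxes]).reshape(len(boxes), 3)
    box_tag = np.array([b.tag for b in boxes], dtype=np.uint8)

    return SceneArrays(scene, sol_kind, sol_center, sol_rot, sol_params, sol_mat,
                       scene.world_half_extents.astype(float), mats, mu, mu_maj,
                       e_min, e_step, ambient_idx, box_lo, box_hi, box_tag,
                       [s.name for s in scene.solids] + ["ambient"])


# ---------------------------------------------------------------------------
# Run bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class RunStats:
    """Energy ledger and counters for a transport run.

    Invariant: emitted = sum(deposited) + sum(cutoff) + escaped + discarded,
    to 1e-9 relative.  ``deposited_by_region`` holds interaction deposits;
    ``cutoff_by_region`` the sub-10 keV termination deposits (kept as a
    separate ledger bucket).
    """

    histories: int
    seed: int
    emitted_energy: float = 0.0
    deposited_by_region: dict = field(default_factory=dict)
    cutoff_by_region: dict = field(default_factory=dict)
    escaped_energy: float = 0.0
    discarded_energy: float = 0.0
    discarded_count: int = 0
    psf_record_counts: dict = field(default_factory=dict)

    @property
    def cutoff_energy(self) -> float:
        return sum(self.cutoff_by_region.values())

    def check_ledger(self, rtol: float = 1e-9):
        total = (sum(self.deposited_by_region.values()) + self.cutoff_energy
                 + self.escaped_energy + self.discarded_energy)
        if not math.isclose(self.emitted_energy, total, rel_tol=rtol, abs_tol=1e-12):
            raise AssertionError(
                f"energy ledger violated: emitted {self.emitted_energy} != "
                f"accounted {total}")
        return True

    def absorbed_in(self, region: str) -> float:
        """Total energy deposited in a region (interactions + cutoff terminations)."""
        return (self.deposited_by_region.get(region, 0.0)
                + self.cutoff_by_region.get(region, 0.0))

    def accumulate(self, other: "RunStats"):
        self.histories += other.histories
        self.emitted_energy += other.emitted_energy
        self.escaped_energy += other.escaped_energy
        self.discarded_energy += other.discarded_energy
        self.discarded_count += other.discarded_count
        for d_self, d_other in ((self.deposited_by_region, other.deposited_by_region),
                                (self.cutoff_by_region, other.cutoff_by_region),
                                (self.psf_record_counts, other.psf_record_counts)):
            for k, v in d_other.items():
                d_self[k] = d_self.get(k, 0.0) + v


@dataclass
class BatchResult:
    stats: RunStats
    records: PhotonBatch | None
    target_deposit: np.ndarray  # per-photon energy deposited in the target solid
    n_interactions: np.ndarray
    grid_deposit: np.ndarray | None


_DUMMY_GRID = (np.zeros(3), np.ones(3), np.zeros(3, dtype=np.int64), np.zeros(1))


def _kernel_seed(*entropy) -> int:
    return int(np.random.SeedSequence(entropy).generate_state(1, np.uint64)[0] >> np.uint64(1))


def run_batch(arrays: SceneArrays, photons: PhotonBatch, seed: int,
              record_crossings: bool = False, kill_on_crossing: bool = False,
              target: str | None = None, grid=None, rec_cap: int | None = None) -> BatchResult:
    """Transport one photon batch through a compiled scene."""
    n = len(photons)
    n_sol = len(arrays.scene.solids)
    if rec_cap is None:
        rec_cap = (8 * n + 1024) if record_crossings else 1
    target_idx = arrays.solid_index(target) if target is not None else -2

    while True:
        rec_pos = np.empty((rec_cap, 3), dtype=np.float32)
        rec_dir = np.empty((rec_cap, 3), dtype=np.float32)
        rec_en = np.empty(rec_cap, dtype=np.float32)
        rec_wt = np.empty(rec_cap, dtype=np.float32)
        rec_tag = np.empty(rec_cap, dtype=np.uint8)
        rec_meta = np.zeros(2, dtype=np.int64)
        dep_region = np.zeros(n_sol + 1)
        cut_region = np.zeros(n_sol + 1)
        ledger = np.zeros(4)
        ph_dep = np.zeros(n)
        ph_ninter = np.zeros(n, dtype=np.int32)
        if grid is not None:
            grid_lo, grid_step, grid_dims, grid_dep = grid
            use_grid = True
        else:
            grid_lo, grid_step, grid_dims, grid_dep = _DUMMY_GRID
            grid_dep = np.zeros(1)
            use_grid = False

        transport_batch(
            photons.positions, photons.directions, photons.energies, photons.weights,
            arrays.sol_kind, arrays.sol_center, arrays.sol_rot, arrays.sol_params,
            arrays.sol_mat, arrays.world_half,
            arrays.mu, arrays.mu_maj, arrays.e_min, arrays.e_step, arrays.ambient_mat,
            arrays.box_lo, arrays.box_hi, arrays.box_tag,
            record_crossings, kill_on_crossing,
            rec_pos, rec_dir, rec_en, rec_wt, rec_tag, rec_meta,
            dep_region, cut_region, ledger,
            target_idx, ph_dep, ph_ninter,
            use_grid, grid_lo, grid_step, grid_dims, grid_dep,
            seed,
        )
        if rec_meta[1] == 0:
            break
        rec_cap *= 2  # record buffer overflowed; retry with more room

    names = arrays.region_names
    stats = RunStats(
        histories=n, seed=seed,
        emitted_energy=float(ledger[0]),
        deposited_by_region={names[i]: float(dep_region[i]) for i in range(n_sol + 1)
                             if dep_region[i] != 0.0},
        cutoff_by_region={names[i]: float(cut_region[i]) for i in range(n_sol + 1)
                          if cut_region[i] != 0.0},
        escaped_energy=float(ledger[1]),
        discarded_energy=float(ledger[2]),
        discarded_count=int(ledger[3]),
    )
    records = None
    if record_crossings:
        k = int(rec_meta[0])
        records = PhotonBatch(rec_pos[:k].astype(float), rec_dir[:k].astype(float),
                              rec_en[:k].astype(float), rec_wt[:k].astype(float),
                              rec_tag[:k].copy())
        for code, name in geo.TAG_NAMES.items():
            stats.psf_record_counts[name] = int((records.tags == code).sum())
    return BatchResult(stats, records, ph_dep, ph_ninter,
                       grid_dep if grid is not None else None)


# ---------------------------------------------------------------------------
# Single-photon event-list transport (reference Python path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportEvent:
    kind: str  # interaction | boundary_crossing | phase_space_crossing | cutoff_termination | escape
    position: np.ndarray
    energy_before: float
    energy_after: float
    deposited: float
    surface_tag: str | None = None
    region: str | None = None

    def __post_init__(self):
        if self.deposited < -1e-12:
            raise ValueError("deposited energy must be >= 0")


def transport(scene: geo.Scene, position, direction, energy_kev: float,
              rng: np.random.Generator, weight: float = 1.0) -> list:
    """Transport a single photon, returning its event list.

    A readable Woodcock-tracking implementation of the same process as the
    batch kernel (shared interaction samplers), used for event-level
    inspection and tests; the batch kernel is the production path.
    """
    arrays = compile_scene(scene)
    pos = np.asarray(position, dtype=float).copy()
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    e = float(energy_kev)
    events: list[TransportEvent] = []
    if not np.all(np.isfinite(pos)) or not np.isfinite(e):
        raise CorruptedHistoryError("non-finite initial photon state")
    _, region = geo.locate(scene, pos)
    if e < PHOTON_CUTOFF_KEV:
        events.append(TransportEvent("cutoff_termination", pos.copy(), e, 0.0,
                                     e * weight, region=region))
        return events
    psf_boxes = [s for s in scene.surfaces if s.role != "world_boundary"]
    last_region = region
    while True:
        m_maj = float(np.interp(e, arrays.e_min + arrays.e_step
                                * np.arange(arrays.mu_maj.size), arrays.mu_maj))
        s = -np.log(1.0 - rng.random()) / m_maj if m_maj > 0 else np.inf
        with np.errstate(divide="ignore"):
            bounds = np.where(u > 0, (scene.world_half_extents - pos) / u,
                              np.where(u < 0, (-scene.world_half_extents - pos) / u, np.inf))
        t_world = max(float(bounds.min()), 0.0)
        t_abs, absorber = np.inf, None
        for sol in scene.solids:
            if getattr(sol, "absorber", False):
                if isinstance(sol, geo.EllipticCylinder):
                    hit = geo.intersect_ray_elliptic_cylinder(pos, u, sol, geo.WITH_CAPS)
                else:
                    hit = geo.intersect_ray_box(pos, u, sol)
                if hit is not None and 1e-9 < hit[0] < t_abs:
                    t_abs, absorber = hit[0], sol
        seg = min(s, t_world, t_abs)
        for b in psf_boxes:
            t0, t1 = geo.box_entry_exit(pos[None, :], u[None, :], b.lo, b.hi)
            if t1[0] > t0[0] and 1e-9 < t1[0] <= seg:
                events.append(TransportEvent(
                    "phase_space_crossing", pos + t1[0] * u, e, e, 0.0,
                    surface_tag=geo.TAG_NAMES[b.tag]))
        if absorber is not None and t_abs <= seg:
            pos = pos + t_abs * u
            events.append(TransportEvent("interaction", pos.copy(), e, 0.0,
                                         e * weight, region=absorber.name))
            return events
        if s >= t_world:
            events.append(TransportEvent("escape", pos + t_world * u, e, e, 0.0))
            return events
        pos = pos + s * u
        material, region = geo.locate(scene, pos)
        if region != last_region:
            events.append(TransportEvent("boundary_crossing", pos.copy(), e, e, 0.0,
                                         region=region))
            last_region = region
        mu_tot = mat_mod.attenuation(material, e)["total"] if material.name != "vacuum" else 0.0
        if rng.random() * m_maj > mu_tot:
            continue
        sample = mat_mod.sample_interaction(material, e, rng)
        if sample.kind == mat_mod.PHOTOELECTRIC:
            events.append(TransportEvent("interaction", pos.copy(), e, 0.0,
                                         e * weight, region=region))
            return events
        e_new = sample.scattered_energy
        events.append(TransportEvent("interaction", pos.copy(), e, e_new,
                                     (e - e_new) * weight, region=region))
        from ._physics import rotate_direction
        u = np.array(rotate_direction(u[0], u[1], u[2], sample.cos_theta, sample.phi))
        e = e_new
        if e < PHOTON_CUTOFF_KEV:
            events.append(TransportEvent("cutoff_termination", pos.copy(), e, 0.0,
                                         e * weight, region=region))
            return events


# ---------------------------------------------------------------------------
# Phase-space generation
# ---------------------------------------------------------------------------

def run_psf_generation(scene: geo.Scene, beam: BeamConfig, spectrum: EnergySpectrum,
                       histories: int, rng_seed: int, out_dir,
                       batch_size: int = 250_000) -> tuple[dict, RunStats]:
    """Simulate ``histories`` primaries and write one PSF per surface role.

    Returns ``(paths, stats)`` where ``paths`` maps surface-tag names
    (``patient_table``, ``floor``, ``ceiling``) to file paths.  Deterministic
    for a fixed seed (single stream).
    """
    if histories < 1:
        raise ValueError("histories must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = compile_scene(scene)
    header_meta = dict(angulation_deg=beam.lao_deg, beam=beam.summary(), seed=rng_seed,
                       extra={"histories": histories})
    writers = {name: PsfWriter(out_dir / f"psf_{name}_lao{beam.lao_deg:g}.psf",
                               PsfHeader(**header_meta))
               for name in geo.TAG_NAMES.values()}
    total = RunStats(histories=0, seed=rng_seed)
    n_batches = max(1, math.ceil(histories / batch_size))
    sizes = np.full(n_batches, histories // n_batches)
    sizes[: histories % n_batches] += 1
    try:
        for batch_idx, n in enumerate(int(s) for s in sizes):
            rng = np.random.default_rng(np.random.SeedSequence((rng_seed, batch_idx, 0)))
            photons = sample_primary(beam, spectrum, n, rng)
            res = run_batch(arrays, photons, _kernel_seed(rng_seed, batch_idx, 1),
                            record_crossings=True)
            res.stats.check_ledger()
            for code, name in geo.TAG_NAMES.items():
                mask = res.records.tags == code
                if np.any(mask):
                    writers[name].append(PhotonBatch(
                        res.records.positions[mask], res.records.directions[mask],
                        res.records.energies[mask], res.records.weights[mask],
                        res.records.tags[mask]))
            total.accumulate(res.stats)
    finally:
        for w in writers.values():
            w.close()
    return {name: w.path for name, w in writers.items()}, total


# ---------------------------------------------------------------------------
# Full-MC phantom dose
# ---------------------------------------------------------------------------

@dataclass
class DoseEstimate:
    dose_gy: float
    stderr_gy: float
    absorbed_kev: float
    histories: int
    phantom_mass_g: float
    stats: RunStats


def score_phantom_dose_mc(scene: geo.Scene, beam: BeamConfig, spectrum: EnergySpectrum,
                          histories: int, rng_seed: int, phantom_name: str = "staff",
                          absolute_dose_factor: float = 1.0, frames: int | None = None,
                          histories_per_frame: float = 1.0,
                          batch_size: int = 250_000) -> DoseEstimate:
    """Full Monte Carlo staff-phantom dose from the source.

    dose = (absorbed keV / histories) * histories_per_frame * frames *
    1.602e-16 / phantom mass (g) * absolute factor; the per-history
    normalization makes the estimate independent of the simulated sample
    size, with the histories-per-frame calibration constant mapping it to an
    acquisition.  The batch-based standard error covers Monte Carlo noise
    only.
    """
    phantom = scene.solid(phantom_name)
    mass = phantom.mass_g
    if mass <= 0:
        raise ValueError("phantom mass must be positive")
    frames = beam.frames if frames is None else frames
    arrays = compile_scene(scene)
    total = RunStats(histories=0, seed=rng_seed)
    batch_dep = []
    # equal-sized batches so the batch variance estimates the run variance
    n_batches = max(1, math.ceil(histories / batch_size))
    sizes = np.full(n_batches, histories // n_batches)
    sizes[: histories % n_batches] += 1
    for batch_idx, n in enumerate(int(s) for s in sizes):
        rng = np.random.default_rng(np.random.SeedSequence((rng_seed, batch_idx, 0)))
        photons = sample_primary(beam, spectrum, n, rng)
        res = run_batch(arrays, photons, _kernel_seed(rng_seed, batch_idx, 1),
                        target=phantom_name)
        res.stats.check_ledger()
        batch_dep.append(float(res.target_deposit.sum()))
        total.accumulate(res.stats)
    absorbed = total.absorbed_in(phantom_name)
    scale = (KEV_TO_J / mass * absolute_dose_factor * frames
             * histories_per_frame / histories)
    dose = absorbed * scale
    if len(batch_dep) > 1:
        se = float(np.std(batch_dep, ddof=1) * np.sqrt(len(batch_dep))) * scale
    else:
        se = float("nan")
    return DoseEstimate(dose, se, absorbed, histories, mass, total)


# ---------------------------------------------------------------------------
# Phase-space replay and energy-absorption ratio
# ---------------------------------------------------------------------------

def replay_psf(scene: geo.Scene, psf_paths, rng_seed: int, phantom_name: str = "staff",
               chunk_records: int = 500_000) -> tuple[float, float, RunStats]:
    """Full-MC replay of phase-space records with kill-on-outward-crossing.

    Each record is transported with full physics; a photon leaving any
    phase-space box outward is terminated there, because that continuation
    exists as a later record (avoids double counting).  Returns
    ``(absorbed_kev_in_phantom, stderr_kev, stats)``.
    """
    arrays = compile_scene(scene)
    total = RunStats(histories=0, seed=rng_seed)
    chunk_dep = []
    cidx = 0
    for path in (psf_paths.values() if isinstance(psf_paths, dict) else psf_paths):
        _, stream = read_psf(path, chunk_records=chunk_records)
        for rec in stream:
            photons = PhotonBatch.from_records(rec)
            res = run_batch(arrays, photons, _kernel_seed(rng_seed, cidx, 2),
                            kill_on_crossing=True, target=phantom_name)
            chunk_dep.append(float(res.target_deposit.sum()))
            total.accumulate(res.stats)
            cidx += 1
    absorbed = total.absorbed_in(phantom_name)
    if len(chunk_dep) > 1:
        se = float(np.std(chunk_dep, ddof=1) * np.sqrt(len(chunk_dep)))
    else:
        se = float("nan")
    return absorbed, se, total


@dataclass
class CalibrationFactors:
    """Per-angulation calibration: the energy-absorption ratio mapping
    ray-cast incident energy to absorbed energy, and the absolute dose
    factor from commissioning (1.0 = relative dose mode)."""

    energy_absorption_ratio: float
    angulation_deg: float
    absolute_dose_factor: float = 1.0
    caps_mode: str = geo.WITH_CAPS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.energy_absorption_ratio <= 1.0):
            raise ValueError(
                f"energy_absorption_ratio must lie in (0, 1], got "
                f"{self.energy_absorption_ratio}")
        if self.absolute_dose_factor <= 0:
            raise ValueError("absolute_dose_factor must be positive")


def calibrate_energy_absorption_ratio(scene: geo.Scene, psf_paths, rng_seed: int,
                                      phantom_name: str = "staff",
                                      caps_mode: str = geo.WITH_CAPS,
                                      angulation_deg: float = 0.0) -> CalibrationFactors:
    """Energy-absorption ratio at the reference phantom position.

    ratio = (energy absorbed in the phantom during full MC replay of the
    phase-space photons) / (summed energy of phase-space photons whose
    straight-line rays hit the phantom).
    """
    from .raycast import straight_hit_energy
    phantom = scene.solid(phantom_name)
    incident = straight_hit_energy(psf_paths, phantom, caps_mode)
    if incident <= 0.0:
        raise UndefinedRatioError(
            "no phase-space ray hits the phantom; energy-absorption ratio undefined")
    absorbed, se, stats = replay_psf(scene, psf_paths, rng_seed, phantom_name)
    ratio = absorbed / incident
    return CalibrationFactors(min(ratio, 1.0), angulation_deg, caps_mode=caps_mode,
                              meta={"replay_absorbed_kev": absorbed,
                                    "replay_stderr_kev": se,
                                    "incident_kev": incident,
                                    "raw_ratio": ratio,
                                    "seed": rng_seed})


def save_calibration(factors: list[CalibrationFactors] | CalibrationFactors, path):
    if isinstance(factors, CalibrationFactors):
        factors = [factors]
    payload = {float(f.angulation_deg): {
        "energy_absorption_ratio": float(f.energy_absorption_ratio),
        "absolute_dose_factor": float(f.absolute_dose_factor),
        "caps_mode": f.caps_mode,
        "meta": {k: (float(v) if isinstance(v, (int, float)) else v)
                 for k, v in f.meta.items()},
    } for f in factors}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_calibration(path) -> list[CalibrationFactors]:
    payload = yaml.safe_load(Path(path).read_text())
    return [CalibrationFactors(v["energy_absorption_ratio"], float(ang),
                               v.get("absolute_dose_factor", 1.0),
                               v.get("caps_mode", geo.WITH_CAPS), v.get("meta", {}))
            for ang, v in payload.items()]


def lookup_calibration(factors: list[CalibrationFactors], angulation_deg: float,
                       max_distance_deg: float = 7.5) -> CalibrationFactors:
    """Nearest stored angulation; error if farther than half the 15-degree
    acquisition step."""
    if not factors:
        raise MissingCalibrationError("no calibration factors available")
    best = min(factors, key=lambda f: abs(f.angulation_deg - angulation_deg))
    if abs(best.angulation_deg - angulation_deg) > max_distance_deg:
        raise MissingCalibrationError(
            f"no calibration within {max_distance_deg} deg of {angulation_deg} deg "
            f"(nearest: {best.angulation_deg})")
    return best


# ---------------------------------------------------------------------------
# Commissioning
# ---------------------------------------------------------------------------

@dataclass
class CommissioningProfiles:
    depth_dose: pd.DataFrame   # columns: depth_cm, dose (normalized to shallowest)
    profile_x: pd.DataFrame    # columns: offset_cm, dose (normalized to central axis)
    profile_y: pd.DataFrame
    stats: RunStats


def commissioning_scene(beam: BeamConfig) -> geo.Scene:
    """Water-slab stack for beam commissioning: 12x30x30 cm measurement stack
    plus 7 cm backscatter, entry surface at the configured SSD; the beam
    axis is +z (the physical setup has the tube under the couch, so the
    stack is inverted with backscatter on top)."""
    water = mat_mod.get_material("water")
    air = mat_mod.get_material("air")
    stack = geo.Box([0.0, 0.0, 6.0], [15.0, 15.0, 6.0], water, name="slab_stack")
    backscatter = geo.Box([0.0, 0.0, 15.5], [15.0, 15.0, 3.5], water, name="backscatter")
    return geo.Scene([stack, backscatter], [], air, np.array([150.0, 150.0, 150.0]))


def sample_commissioning_primary(beam: BeamConfig, spectrum: EnergySpectrum, n: int,
                                 rng: np.random.Generator) -> PhotonBatch:
    """Primaries for the commissioning geometry: source on -z at the SSD below
    the slab surface (z=0), cone collimated to the field of view at the
    nominal isocenter distance."""
    source = np.array([0.0, 0.0, -beam.ssd])
    u1 = rng.standard_normal(n) * beam.focal_spot_sigma
    u2 = rng.standard_normal(n) * beam.focal_spot_sigma
    positions = source + np.column_stack([u1, u2, np.zeros(n)])
    r = 0.5 * beam.fov_at_isocenter * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    z_target = -beam.ssd + beam.source_to_isocenter
    targets = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.full(n, z_target)])
    directions = targets - positions
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    return PhotonBatch(positions, directions, spectrum.sample(n, rng), np.ones(n))


N_DEPTH_POINTS = 26
N_PROFILE_POINTS = 43
PROFILE_DEPTH_CM = 1.0


def commissioning_profiles(beam: BeamConfig, spectrum: EnergySpectrum, histories: int,
                           rng_seed: int, batch_size: int = 500_000) -> CommissioningProfiles:
    """Depth-dose (26 points, 0-12 cm) and two 43-point cross profiles at
    1 cm depth, scored in a 1x1 cm voxel grid on/around the beam axis."""
    scene = commissioning_scene(beam)
    arrays = compile_scene(scene)
    dz = 12.0 / N_DEPTH_POINTS
    half_span = N_PROFILE_POINTS / 2.0  # 1 cm voxels
    grid_lo = np.array([-half_span, -half_span, 0.0])
    grid_step = np.array([1.0, 1.0, dz])
    grid_dims = np.array([N_PROFILE_POINTS, N_PROFILE_POINTS, N_DEPTH_POINTS],
                         dtype=np.int64)
    grid_dep = np.zeros(int(grid_dims.prod()))
    total = RunStats(histories=0, seed=rng_seed)
    done = 0
    batch_idx = 0
    while done < histories:
        n = min(batch_size, histories - done)
        rng = np.random.default_rng(np.random.SeedSequence((rng_seed, batch_idx, 0)))
        photons = sample_commissioning_primary(beam, spectrum, n, rng)
        res = run_batch(arrays, photons, _kernel_seed(rng_seed, batch_idx, 1),
                        grid=(grid_lo, grid_step, grid_dims, grid_dep))
        res.stats.check_ledger()
        total.accumulate(res.stats)
        done += n
        batch_idx += 1
    grid = grid_dep.reshape(N_PROFILE_POINTS, N_PROFILE_POINTS, N_DEPTH_POINTS)
    ic = N_PROFILE_POINTS // 2
    depths = grid_lo[2] + dz * (np.arange(N_DEPTH_POINTS) + 0.5)
    axis_dose = grid[ic, ic, :]
    depth_df = pd.DataFrame({"depth_cm": depths, "dose": axis_dose / axis_dose[0]})
    iz = int(np.argmin(np.abs(depths - PROFILE_DEPTH_CM)))
    offsets = grid_lo[0] + 1.0 * (np.arange(N_PROFILE_POINTS) + 0.5)
    px = grid[:, ic, iz]
    py = grid[ic, :, iz]
    profile_x = pd.DataFrame({"offset_cm": offsets, "dose": px / px[ic]})
    profile_y = pd.DataFrame({"offset_cm": offsets, "dose": py / py[ic]})
    return CommissioningProfiles(depth_df, profile_x, profile_y, total)


def absolute_dose_factor_from_reference(profiles: CommissioningProfiles,
                                        measured_dose_gy: float,
                                        depth_cm: float = 1.0) -> float:
    """Absolute dose factor from one measured reference dose: measured Gy per
    simulated (normalized) dose at the reference depth."""
    sim = float(np.interp(depth_cm, profiles.depth_dose["depth_cm"],
                          profiles.depth_dose["dose"]))
    if sim <= 0:
        raise ValueError("simulated dose at reference depth is zero")
    return measured_dose_gy / sim


def compare_profile(simulated: pd.DataFrame, reference: pd.DataFrame,
                    abscissa: str | None = None, value: str = "dose") -> tuple[pd.DataFrame, float]:
    """Pointwise percentage difference (sim - ref)/ref * 100 between a
    simulated and a (possibly differently sampled) reference profile.

    The reference is interpolated linearly onto the simulated abscissa.
    Points where the reference is zero are excluded and flagged.  Returns
    ``(table, mean_abs_pct)`` where the summary is the mean absolute
    percentage difference over the retained points.
    """
    if abscissa is None:
        abscissa = simulated.columns[0]
    x = simulated[abscissa].to_numpy(dtype=float)
    sim = simulated[value].to_numpy(dtype=float)
    ref = np.interp(x, reference[abscissa].to_numpy(dtype=float),
                    reference[value].to_numpy(dtype=float))
    valid = ref != 0.0
    pct = np.full_like(sim, np.nan)
    pct[valid] = (sim[valid] - ref[valid]) / ref[valid] * 100.0
    table = pd.DataFrame({abscissa: x, "simulated": sim, "reference": ref,
                          "pct_difference": pct, "excluded_zero_reference": ~valid})
    mean_abs = float(np.nanmean(np.abs(pct[valid]))) if valid.any() else float("nan")
    return table, mean_abs
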
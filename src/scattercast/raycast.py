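"""Ray-casting scatter dose estimation (the fast approximation).

Phase-space photons are replayed as straight rays against a movable staff
phantom: a record whose ray hits the phantom surface contributes its full
energy x weight at the hit point; intervening attenuation and all further
scattering are ignored, reducing dose estimation to pure collision
detection.  The incident energy is converted to absorbed dose through the
per-angulation energy-absorption ratio calibrated from one Monte Carlo
replay, times the absolute dose factor from commissioning.

All totals are accumulated with exact (compensated) summation, so results
are bitwise independent of record order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .mc_engine import KEV_TO_J, CalibrationFactors, MissingCalibrationError
from .phasespace import read_psf, unpack_tag


class PhantomInPhaseSpaceError(ValueError):
    """Staff phantom overlaps a phase-space box interior."""


def _iter_psf_chunks(psf_set, chunk_records=1_000_000):
    paths = psf_set.values() if isinstance(psf_set, dict) else psf_set
    for path in paths:
        _, stream = read_psf(path, chunk_records=chunk_records)
        yield from stream


def check_phantom_clear_of_surfaces(phantom: geo.EllipticCylinder, surfaces) -> None:
    """Raise if the phantom's bounding box overlaps any phase-space box
    interior (conservative axis-aligned test; touching faces are allowed)."""
    r = phantom.rotation
    ext = np.sqrt((phantom.semi_axis_a * r[0]) ** 2 + (phantom.semi_axis_b * r[1]) ** 2) \
        + phantom.half_height * np.abs(r[2])
    lo, hi = phantom.center - ext, phantom.center + ext
    for s in surfaces:
        if s.role == "world_boundary":
            continue
        if np.all(np.minimum(hi, s.hi) > np.maximum(lo, s.lo)):
            raise PhantomInPhaseSpaceError(
                f"phantom {phantom.name!r} overlaps phase-space box {s.role}")


@dataclass
class HitLedger:
    """Per-hit record of the ray-cast: surface point, photon energy, weight
    and source surface tag, plus per-tag totals."""

    points: np.ndarray     # (n, 3) cm, on the phantom surface
    energies: np.ndarray   # (n,) keV
    weights: np.ndarray    # (n,)
    tags: np.ndarray       # (n,) surface tag codes

    @property
    def hit_count(self) -> int:
        return int(self.energies.size)

    @property
    def incident_energy_kev(self) -> float:
        """Exact sum of energy x weight over hits (order invariant)."""
        return math.fsum(self.energies * self.weights)

    def counts_by_tag(self) -> dict:
        return {name: int((self.tags == code).sum())
                for code, name in geo.TAG_NAMES.items()}

    def energy_by_tag(self) -> dict:
        return {name: math.fsum((self.energies * self.weights)[self.tags == code])
                for code, name in geo.TAG_NAMES.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_cm": self.points[:, 0], "y_cm": self.points[:, 1], "z_cm": self.points[:, 2],
            "energy_kev": self.energies, "weight": self.weights,
            "tag": [geo.TAG_NAMES[int(t)] for t in self.tags],
        })

    def export(self, path):
        """Delimited-text hit ledger (the visualisation-file analogue)."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class DoseResult:
    """Ray-cast dose on one phantom position.

    Arithmetic identity: dose = incident_energy x EAR x (1.602e-16 / mass_g)
    x absolute_dose_factor x frames x histories_per_frame /
    source_histories (the last factor normalizes per simulated source
    history; synthetic fixtures without a source run count as 1).
    """

    dose_gy: float
    hit_count: int
    incident_energy_kev: float
    ledger: HitLedger
    calibration: CalibrationFactors
    frames: int
    phantom_mass_g: float
    source_histories: int = 1

    def __post_init__(self):
        if self.dose_gy < 0:
            raise ValueError("dose must be >= 0")


def psf_source_histories(psf_set) -> int:
    """Source-history count recorded in the PSF headers (1 when absent)."""
    from .phasespace import read_psf_header
    paths = psf_set.values() if isinstance(psf_set, dict) else psf_set
    hists = [read_psf_header(p).extra.get("histories") for p in paths]
    hists = [h for h in hists if h]
    return int(max(hists)) if hists else 1


def straight_hit_energy(psf_set, phantom: geo.EllipticCylinder,
                        caps_mode: str = geo.WITH_CAPS,
                        chunk_records: int = 1_000_000) -> float:
    """Summed energy x weight of phase-space records whose straight rays hit
    the phantom (the denominator of the energy-absorption ratio)."""
    total = 0.0
    for rec in _iter_psf_chunks(psf_set, chunk_records):
        origins = rec["pos"].astype(float)
        dirs = rec["dir"].astype(float)
        t = geo.ellcyl_hit_distances(origins, dirs, phantom, caps_mode)
        hit = np.isfinite(t)
        if hit.any():
            e = rec["energy"][hit].astype(float) * rec["weight"][hit].astype(float)
            total = math.fsum([total, math.fsum(e)])
    return total


def raycast_dose(psf_set, phantom: geo.EllipticCylinder, calib: CalibrationFactors,
                 caps_mode: str | None = None, frames: int = 1,
                 histories_per_frame: float = 1.0, surfaces=None,
                 chunk_records: int = 1_000_000) -> DoseResult:
    """Ray-cast dose estimate for one phantom position.

    Parameters
    ----------
    psf_set : dict or sequence of PSF paths (patient+table, floor, ceiling).
    phantom : movable staff phantom.
    calib : calibration for the angulation the PSFs were generated at
        (explicitly required; there is no silent default).
    caps_mode : override the calibration's intersection mode
        (``lateral_only`` replicates the published limitation of ignoring
        the cylinder's top cap).
    surfaces : optional phase-space boxes for the placement precondition.
    """
    if calib is None:
        raise MissingCalibrationError("raycast_dose requires calibration factors")
    if caps_mode is None:
        caps_mode = calib.caps_mode
    if surfaces is not None:
        check_phantom_clear_of_surfaces(phantom, surfaces)
    pts, ens, wts, tags = [], [], [], []
    for rec in _iter_psf_chunks(psf_set, chunk_records):
        origins = rec["pos"].astype(float)
        dirs = rec["dir"].astype(float)
        t = geo.ellcyl_hit_distances(origins, dirs, phantom, caps_mode)
        hit = np.isfinite(t)
        if hit.any():
            pts.append(origins[hit] + t[hit, None] * dirs[hit])
            ens.append(rec["energy"][hit].astype(float))
            wts.append(rec["weight"][hit].astype(float))
            _, surf = unpack_tag(rec["tag"][hit])
            tags.append(surf.astype(np.uint8))
    if pts:
        ledger = HitLedger(np.concatenate(pts), np.concatenate(ens),
                           np.concatenate(wts), np.concatenate(tags))
    else:
        ledger = HitLedger(np.empty((0, 3)), np.empty(0), np.empty(0),
                           np.empty(0, dtype=np.uint8))
    incident = ledger.incident_energy_kev
    source_histories = psf_source_histories(psf_set)
    dose = (incident * calib.energy_absorption_ratio * KEV_TO_J / phantom.mass_g
            * calib.absolute_dose_factor * frames * histories_per_frame
            / source_histories)
    return DoseResult(dose, ledger.hit_count, incident, ledger, calib, frames,
                      phantom.mass_g, source_histories)


def vacuum_equivalence(psf_set, phantom: geo.EllipticCylinder,
                       world_half_extents=(300.0, 300.0, 200.0),
                       rng_seed: int = 0, chunk_records: int = 500_000):
    """The ray-cast module's strongest oracle.

    With every material between the phase-space surfaces and the phantom set
    to vacuum and EAR = 1, no scatter or absorption can occur en route, so
    the ray-cast incident energy must equal the Monte Carlo replay energy
    entering the phantom exactly.  The phantom is made perfectly absorbing
    so the replay scores exactly the entering energy.

    Returns ``(rc_incident_kev, mc_replay_entering_kev)``; both are exact
    (compensated) sums over identical photon sets and agree bitwise when the
    oracle holds.
    """
    from dataclasses import replace as _dc_replace
    from . import materials as mat_mod
    from .mc_engine import compile_scene, run_batch, _kernel_seed
    from .phasespace import PhotonBatch

    rc_incident = straight_hit_energy(psf_set, phantom, geo.WITH_CAPS, chunk_records)
    absorber = _dc_replace(phantom, absorber=True)
    scene = geo.Scene([absorber], [], mat_mod.vacuum(),
                      np.asarray(world_half_extents, dtype=float))
    arrays = compile_scene(scene)
    deposits = []
    for i, rec in enumerate(_iter_psf_chunks(psf_set, chunk_records)):
        res = run_batch(arrays, PhotonBatch.from_records(rec),
                        _kernel_seed(rng_seed, i), target=phantom.name)
        deposits.append(res.target_deposit)
    entering = math.fsum(np.concatenate(deposits)) if deposits else 0.0
    return rc_incident, entering


def percent_difference(rc_value: float, mc_value: float) -> float:
    """(RC - MC) / MC x 100."""
    if mc_value == 0:
        raise ZeroDivisionError("percentage difference undefined for zero reference")
    return (rc_value - mc_value) / mc_value * 100.0


# ---------------------------------------------------------------------------
# Dose map
# ---------------------------------------------------------------------------

@dataclass
class DoseMap:
    """Ray-cast doses over a grid of phantom positions."""

    table: pd.DataFrame   # columns: x_cm, y_cm, z_cm, dose_gy, hit_count, valid, error
    angulation_deg: float
    metadata: dict = field(default_factory=dict)

    def export(self, path):
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def dose_map(psf_set, phantom_template: geo.EllipticCylinder, centers,
             calib: CalibrationFactors, caps_mode: str | None = None,
             frames: int = 1, surfaces=None, angulation_deg: float | None = None) -> DoseMap:
    """Evaluate ``raycast_dose`` for a phantom template translated to each
    center position.  Invalid positions (inside a phase-space box) are
    flagged and the map continues."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if len(np.unique(centers, axis=0)) != len(centers):
        raise ValueError("map positions must be unique")
    rows = []
    for c in centers:
        phantom = geo.EllipticCylinder(c, phantom_template.axis,
                                       phantom_template.semi_axis_a,
                                       phantom_template.semi_axis_b,
                                       phantom_template.half_height,
                                       phantom_template.material,
                                       name=phantom_template.name,
                                       a_direction=phantom_template.a_direction)
        row = {"x_cm": c[0], "y_cm": c[1], "z_cm": c[2]}
        try:
            res = raycast_dose(psf_set, phantom, calib, caps_mode, frames,
                               surfaces=surfaces)
            row.update(dose_gy=res.dose_gy, hit_count=res.hit_count,
                       incident_energy_kev=res.incident_energy_kev, valid=True, error="")
        except PhantomInPhaseSpaceError as exc:
            row.update(dose_gy=np.nan, hit_count=0, incident_energy_kev=np.nan,
                       valid=False, error=str(exc))
        rows.append(row)
    ang = calib.angulation_deg if angulation_deg is None else angulation_deg
    return DoseMap(pd.DataFrame(rows), ang,
                   {"caps_mode": caps_mode or calib.caps_mode, "frames": frames})


# ---------------------------------------------------------------------------
# Surface histogram and hit provenance
# ---------------------------------------------------------------------------

def surface_histogram(ledger: HitLedger, phantom: geo.EllipticCylinder,
                      n_azimuth: int = 36, n_height: int = 35):
    """Energy fluence binned on the unrolled lateral surface of the phantom.

    Bins are parametric azimuth (atan2 of the normalized local lateral
    coordinates) by axial height; the bin value is the summed energy x
    weight, so the histogram total equals the ledger's incident energy (cap
    hits, when present, are clipped into the end height rows).

    Returns ``(hist, azimuth_edges, height_edges)``.
    """
    hist = np.zeros((n_azimuth, n_height))
    az_edges = np.linspace(-np.pi, np.pi, n_azimuth + 1)
    h_edges = np.linspace(-phantom.half_height, phantom.half_height, n_height + 1)
    if ledger.hit_count:
        local = (ledger.points - phantom.center) @ phantom.rotation.T
        az = np.arctan2(local[:, 1] / phantom.semi_axis_b,
                        local[:, 0] / phantom.semi_axis_a)
        ia = np.clip(((az + np.pi) / (2 * np.pi) * n_azimuth).astype(int), 0, n_azimuth - 1)
        ih = np.clip(((local[:, 2] + phantom.half_height)
                      / (2 * phantom.half_height) * n_height).astype(int), 0, n_height - 1)
        np.add.at(hist, (ia, ih), ledger.energies * ledger.weights)
    return hist, az_edges, h_edges


def hit_fraction_by_source(ledger: HitLedger) -> pd.DataFrame:
    """Fractions of hit count and of incident energy per source surface.

    Index: patient_table, floor, ceiling; columns: hit_fraction,
    energy_fraction (each summing to 1).
    """
    if ledger.hit_count == 0:
        raise ValueError("hit fractions undefined for an empty ledger")
    counts = ledger.counts_by_tag()
    energies = ledger.energy_by_tag()
    n = sum(counts.values())
    e = sum(energies.values())
    return pd.DataFrame({
        "hit_fraction": {k: v / n for k, v in counts.items()},
        "energy_fraction": {k: (v / e if e else 0.0) for k, v in energies.items()},
    })


def plot_surface_histogram(hist, az_edges, h_edges, path=None, title=None):
    """Render the unrolled-surface energy map (optional matplotlib hook)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 5))
    mesh = ax.pcolormesh(np.rad2deg(az_edges), h_edges, hist.T, shading="auto")
    ax.set_xlabel("azimuth on lateral surface (deg)")
    ax.set_ylabel("height above phantom center (cm)")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="incident energy (keV)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
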
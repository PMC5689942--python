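"""Photon interaction coefficients and interaction sampling.

Materials are defined by the text fixture tables shipped under
``data/materials`` (one file per material, a manifest with density and
composition).  Coefficients are mass attenuation partials --- photoelectric,
incoherent (Compton) and coherent (Rayleigh) --- on a fixed 10-150 keV grid,
interpolated log-log between nodes.

Interaction sampling follows simplified kV photon physics: the interaction
kind is drawn proportionally to the partial linear coefficients; Compton
energy/angle come from the free-electron Klein-Nishina differential
cross-section; Rayleigh uses the Thomson angular law (no form factors);
photoelectric absorbs the photon with full local energy deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._physics import (
    PHOTON_CUTOFF_KEV,
    compton_scattered_energy,
    rng_init,
    rng_uniform,
    sample_compton,
    sample_thomson_cos_theta,
)

ENERGY_GRID_MIN_KEV = 10.0
ENERGY_GRID_MAX_KEV = 150.0

PHOTOELECTRIC = "photoelectric"
COMPTON = "compton"
RAYLEIGH = "rayleigh"


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated 10-150 keV grid."""


@dataclass(frozen=True)
class Material:
    """A homogeneous material with tabulated photon cross sections.

    Attributes
    ----------
    name : str
    density : float
        Bulk density in g/cm^3.
    composition : dict
        Element mass fractions.
    energy_grid : ndarray
        Grid energies in keV, ascending.
    mu_rho : ndarray, shape (3, n)
        Mass attenuation partials in cm^2/g, rows: photoelectric,
        incoherent, coherent.
    """

    name: str
    density: float
    composition: dict = field(compare=False)
    energy_grid: np.ndarray = field(compare=False, repr=False)
    mu_rho: np.ndarray = field(compare=False, repr=False)

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if np.any(self.mu_rho <= 0):
            raise ValueError(f"material {self.name!r}: all partial coefficients must be > 0")

    @property
    def mu_rho_total(self) -> np.ndarray:
        return self.mu_rho.sum(axis=0)

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, self.composition, self.energy_grid, self.mu_rho)


@dataclass(frozen=True)
class InteractionSample:
    kind: str
    scattered_energy: float  # keV; 0 for photoelectric
    cos_theta: float         # polar scattering angle cosine (1 for photoelectric)
    phi: float               # azimuthal angle, radians


_VACUUM = None


def vacuum() -> Material:
    """A zero-interaction pseudo-material (used by tests and vacuum scenes)."""
    global _VACUUM
    if _VACUUM is None:
        grid = np.array([ENERGY_GRID_MIN_KEV, ENERGY_GRID_MAX_KEV])
        tiny = np.full((3, 2), 1e-300)
        _VACUUM = Material("vacuum", 1e-300, {}, grid, tiny)
    return _VACUUM


def _parse_material_file(text: str, name: str) -> Material:
    density = None
    composition = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "density_g_cm3:" in line:
                density = float(line.split(":", 1)[1])
            elif "composition:" in line:
                for item in line.split(":", 1)[1].split(","):
                    el, frac = item.strip().split(":")
                    composition[el] = float(frac)
            continue
        rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows)
    return Material(name, density, composition, arr[:, 0].copy(), arr[:, 1:4].T.copy())


_CACHE: dict[str, Material] = {}


def available_materials() -> list[str]:
    root = resources.files("scattercast").joinpath("data", "materials")
    return sorted(p.name[:-4] for p in root.iterdir()
                  if p.name.endswith(".tsv") and p.name != "manifest.tsv")


def get_material(name: str) -> Material:
    """Load a material from the embedded fixture tables (cached)."""
    if name == "vacuum":
        return vacuum()
    if name not in _CACHE:
        root = resources.files("scattercast").joinpath("data", "materials")
        path = root.joinpath(f"{name}.tsv")
        try:
            text = path.read_text()
        except FileNotFoundError:
            raise KeyError(f"unknown material {name!r}; available: {available_materials()}")
        _CACHE[name] = _parse_material_file(text, name)
    return _CACHE[name]


def _loglog_interp(energy, grid, values):
    loge = np.log(energy)
    logg = np.log(grid)
    return np.exp(np.interp(loge, logg, np.log(values)))


def attenuation(material: Material, energy_kev):
    """Linear attenuation coefficients in 1/cm at the given energy.

    Returns
    -------
    dict with keys ``total``, ``photoelectric``, ``compton``, ``rayleigh``
    (scalars or arrays following the shape of ``energy_kev``).
    """
    energy = np.asarray(energy_kev, dtype=float)
    if np.any(energy < ENERGY_GRID_MIN_KEV) or np.any(energy > ENERGY_GRID_MAX_KEV):
        raise EnergyRangeError(
            f"energy {energy_kev} keV outside tabulated range "
            f"[{ENERGY_GRID_MIN_KEV}, {ENERGY_GRID_MAX_KEV}]")
    rho = material.density
    pe = _loglog_interp(energy, material.energy_grid, material.mu_rho[0]) * rho
    inc = _loglog_interp(energy, material.energy_grid, material.mu_rho[1]) * rho
    coh = _loglog_interp(energy, material.energy_grid, material.mu_rho[2]) * rho
    return {
        "total": pe + inc + coh,
        "photoelectric": pe,
        "compton": inc,
        "rayleigh": coh,
    }


def compton_mean_transfer_fraction(energy_kev):
    """Mean fraction of photon energy transferred to the electron in a
    Klein-Nishina Compton event (quadrature over the angular distribution)."""
    energy = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    cos_t = np.linspace(-1.0, 1.0, 2001)
    alpha = energy[:, None] / 511.0
    eps = 1.0 / (1.0 + alpha * (1.0 - cos_t[None, :]))
    dcs = eps * eps * (eps + 1.0 / eps - (1.0 - cos_t[None, :] ** 2))
    norm = np.trapezoid(dcs, cos_t, axis=1)
    mean_eps = np.trapezoid(dcs * eps, cos_t, axis=1) / norm
    out = 1.0 - mean_eps
    return out if np.ndim(energy_kev) else float(out[0])


def fine_mu_tables(materials: list[Material], step_kev: float = 0.25):
    """Pre-interpolated linear-coefficient lookup tables for the transport kernel.

    Returns
    -------
    e_min, e_step : float
    mu : ndarray, shape (len(materials), 5, n)
        Rows per material: photoelectric, incoherent, coherent, total and
        energy-absorption linear coefficients (1/cm) on the fine grid.  The
        energy-absorption row (photoelectric plus incoherent times the mean
        Compton transfer fraction) drives the track-length kerma estimator
        of the scoring grid.
    """
    n = int(round((ENERGY_GRID_MAX_KEV - ENERGY_GRID_MIN_KEV) / step_kev)) + 1
    grid = ENERGY_GRID_MIN_KEV + step_kev * np.arange(n)
    f_transfer = compton_mean_transfer_fraction(grid)
    mu = np.empty((len(materials), 5, n))
    for i, mat in enumerate(materials):
        if mat.name == "vacuum":
            mu[i] = 0.0
            continue
        coeffs = attenuation(mat, grid)
        mu[i, 0] = coeffs["photoelectric"]
        mu[i, 1] = coeffs["compton"]
        mu[i, 2] = coeffs["rayleigh"]
        mu[i, 3] = coeffs["total"]
        mu[i, 4] = coeffs["photoelectric"] + coeffs["compton"] * f_transfer
    return ENERGY_GRID_MIN_KEV, step_kev, mu


def sample_interaction(material: Material, energy_kev: float, rng) -> InteractionSample:
    """Draw one interaction in ``material`` at ``energy_kev``.

    ``rng`` is a :class:`numpy.random.Generator`; the angular/energy draws are
    delegated to the same compiled samplers the batch transport kernel uses.
    """
    coeffs = attenuation(material, energy_kev)
    state = rng_init(int(rng.integers(1, 2**62)))
    u = rng_uniform(state) * coeffs["total"]
    if u < coeffs["photoelectric"]:
        return InteractionSample(PHOTOELECTRIC, 0.0, 1.0, 0.0)
    phi = 2.0 * np.pi * rng_uniform(state)
    if u < coeffs["photoelectric"] + coeffs["compton"]:
        e_out, cos_theta = sample_compton(energy_kev, state)
        return InteractionSample(COMPTON, e_out, cos_theta, phi)
    return InteractionSample(RAYLEIGH, energy_kev, sample_thomson_cos_theta(state), phi)


def sample_compton_batch(energy_kev: float, n: int, seed: int):
    """Sample ``n`` Klein-Nishina (scattered_energy, cos_theta) pairs (testing aid)."""
    from ._kernel import compton_batch
    return compton_batch(float(energy_kev), int(n), int(seed))


def sample_thomson_batch(n: int, seed: int):
    from ._kernel import thomson_batch
    return thomson_batch(int(n), int(seed))
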
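"""X-ray tube emission spectrum and the Gaussian-focal-spot cone beam.

The spectrum is a semi-empirical tungsten-anode model: Kramers-type
bremsstrahlung photon fluence proportional to (kVp - E), attenuated by
inherent plus added aluminium filtration (coefficients from the materials
tables), plus Gaussian tungsten K-characteristic lines at 57.98, 59.32,
67.2 and 69.1 keV with fixed relative intensities.  K-lines appear only
above the tungsten K-edge (69.5 keV).  Photons below the 10 keV transport
cutoff are removed before normalization.

The source geometry is a virtual point/Gaussian focal spot on the C-arm
gantry circle: ``angulate`` rotates the source about the isocenter (LAO
angle about the patient's longitudinal axis, 0 deg = tube under the table
pointing up; cranio-caudal angle about the lateral axis), and
``sample_primary`` draws photons whose directions fill the cone that
produces the configured circular field of view at the isocenter plane.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from . import materials as mat_mod
from ._physics import PHOTON_CUTOFF_KEV
from .phasespace import PhotonBatch

W_K_EDGE_KEV = 69.5
# (energy keV, relative intensity): K-alpha2, K-alpha1, K-beta1, K-beta2
W_K_LINES = ((57.98, 0.58), (59.32, 1.00), (67.2, 0.23), (69.1, 0.08))
W_K_LINE_SIGMA_KEV = 0.6
# Fraction of bremsstrahlung photon fluence emitted in K lines scales as
# (kVp/K-edge - 1)^1.63 (empirical overvoltage exponent); constant chosen to
# give ~9% K-line fluence at 125 kVp before filtration.
W_K_LINE_YIELD = 0.13
W_K_LINE_EXPONENT = 1.63

MIN_TUBE_POTENTIAL = 30.0
MAX_TUBE_POTENTIAL = 150.0


class TubePotentialRangeError(ValueError):
    """Tube potential outside the 30-150 kV calibrated range of the model."""


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon emission spectrum.

    ``bin_edges`` (keV, ascending, length n+1) and ``bin_probability``
    (unitless, length n, summing to 1).
    """

    bin_edges: np.ndarray
    bin_probability: np.ndarray
    tube_potential: float = 0.0
    filtration_mm_al: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "bin_probability",
                           np.asarray(self.bin_probability, dtype=float))
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.bin_probability.size + 1:
            raise ValueError("bin_edges must have one more entry than bin_probability")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(self.bin_probability < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.bin_probability.sum()
        if not np.isclose(total, 1.0, rtol=1e-9):
            raise ValueError(f"bin_probability must sum to 1, got {total}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_energy(self) -> float:
        return float(self.bin_probability @ self.bin_centers)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` energies: bin by probability, uniform within the bin."""
        idx = rng.choice(self.bin_probability.size, size=n, p=self.bin_probability)
        lo = self.bin_edges[idx]
        hi = self.bin_edges[idx + 1]
        return lo + (hi - lo) * rng.random(n)


@dataclass(frozen=True)
class BeamConfig:
    """C-arm beam settings (defaults follow the thorax acquisition preset:
    125 kV, 20 cm field of view at the isocenter, 120 image frames)."""

    tube_potential: float = 125.0       # keV (kVp)
    focal_spot_sigma: float = 0.03      # cm, isotropic Gaussian in the source plane
    source_to_isocenter: float = 75.0   # cm
    ssd: float = 100.0                  # cm, commissioning source-to-surface distance
    fov_at_isocenter: float = 20.0      # cm, circular field diameter
    lao_deg: float = 0.0                # 0 = tube under the table
    cc_deg: float = 0.0                 # cranio-caudal angulation
    frames: int = 120
    filtration_mm_al: float = 0.0       # added filtration

    def __post_init__(self):
        if self.fov_at_isocenter <= 0:
            raise ValueError("fov_at_isocenter must be positive")
        if self.focal_spot_sigma < 0:
            raise ValueError("focal_spot_sigma must be >= 0")

    def with_angles(self, lao_deg, cc_deg=0.0) -> "BeamConfig":
        return replace(self, lao_deg=float(lao_deg), cc_deg=float(cc_deg))

    def summary(self) -> dict:
        return {"tube_potential": self.tube_potential, "fov_at_isocenter": self.fov_at_isocenter,
                "lao_deg": self.lao_deg, "cc_deg": self.cc_deg, "frames": self.frames,
                "filtration_mm_al": self.filtration_mm_al,
                "source_to_isocenter": self.source_to_isocenter,
                "focal_spot_sigma": self.focal_spot_sigma}


@dataclass(frozen=True)
class BeamGeometry:
    """Rigid placement of the source on the gantry circle."""

    source_position: np.ndarray
    beam_axis: np.ndarray       # unit vector, points through the isocenter
    rotation: np.ndarray        # 3x3; maps the LAO-0 frame into the rotated frame

    @property
    def transverse_axes(self):
        return self.rotation @ np.array([1.0, 0.0, 0.0]), self.rotation @ np.array([0.0, 1.0, 0.0])


def _rot_y(deg):
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(deg):
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def angulate(beam: BeamConfig, lao_deg: float | None = None,
             cc_deg: float | None = None) -> BeamGeometry:
    """Source position and beam axis for a C-arm angulation.

    LAO rotates the tube anticlockwise about the patient's longitudinal axis
    (+y); at 0 deg the source sits ``source_to_isocenter`` below the
    isocenter with the axis pointing up, at 90 deg it lies in the horizontal
    isocenter plane on the patient's left.  The beam axis always passes
    through the isocenter.
    """
    lao = beam.lao_deg if lao_deg is None else float(lao_deg)
    cc = beam.cc_deg if cc_deg is None else float(cc_deg)
    rot = _rot_y(-lao) @ _rot_x(cc)
    source = rot @ np.array([0.0, 0.0, -beam.source_to_isocenter])
    axis = -source / np.linalg.norm(source)
    return BeamGeometry(source, axis, rot)


# ---------------------------------------------------------------------------
# Spectrum model
# ---------------------------------------------------------------------------

def spectral_fluence(energy_kev, tube_potential, filtration_mm_al=0.0,
                     inherent_filtration_mm_al=2.5):
    """Closed-form (unnormalized) photon fluence density of the tube model.

    Kramers bremsstrahlung (kVp - E) times aluminium filtration transmission,
    plus Gaussian K lines above the tungsten K edge.  Zero outside
    [10 keV, kVp].  This is the continuous model the binned spectrum
    integrates; it is exposed separately so tests can quadrature it.
    """
    e = np.asarray(energy_kev, dtype=float)
    out = np.zeros_like(e)
    inside = (e >= PHOTON_CUTOFF_KEV) & (e <= tube_potential)
    if not np.any(inside):
        return out
    al = mat_mod.get_material("aluminium")
    t_cm = (filtration_mm_al + inherent_filtration_mm_al) / 10.0
    mu = mat_mod.attenuation(al, np.clip(e[inside], 10.0, 150.0))["total"]
    trans = np.exp(-mu * t_cm)
    brems = (tube_potential - e[inside]) * trans
    out[inside] = brems
    if tube_potential > W_K_EDGE_KEV:
        # Line fluence scales with the bremsstrahlung area via the
        # overvoltage yield; each line is a narrow Gaussian.
        brems_area = 0.5 * (tube_potential - PHOTON_CUTOFF_KEV) ** 2
        yield_frac = W_K_LINE_YIELD * ((tube_potential / W_K_EDGE_KEV - 1.0)
                                       ** W_K_LINE_EXPONENT)
        total_rel = sum(w for _, w in W_K_LINES)
        for e0, rel in W_K_LINES:
            amp = yield_frac * brems_area * rel / total_rel
            gauss = amp / (np.sqrt(2 * np.pi) * W_K_LINE_SIGMA_KEV) * np.exp(
                -0.5 * ((e[inside] - e0) / W_K_LINE_SIGMA_KEV) ** 2)
            mu0 = mat_mod.attenuation(al, min(max(e0, 10.0), 150.0))["total"]
            out[inside] += gauss * np.exp(-mu0 * t_cm)
    return out


def build_spectrum(tube_potential: float, filtration_mm_al: float = 0.0,
                   inherent_filtration_mm_al: float = 2.5,
                   bin_width_kev: float = 1.0) -> EnergySpectrum:
    """Build the normalized tube emission spectrum.

    Bins run from the 10 keV cutoff to the tube potential in
    ``bin_width_kev`` steps (last bin shortened so its upper edge equals the
    tube potential exactly); each bin integrates the closed-form model by
    fine-grid quadrature.
    """
    if not (MIN_TUBE_POTENTIAL <= tube_potential <= MAX_TUBE_POTENTIAL):
        raise TubePotentialRangeError(
            f"tube potential {tube_potential} kV outside calibrated range "
            f"[{MIN_TUBE_POTENTIAL}, {MAX_TUBE_POTENTIAL}]")
    if filtration_mm_al < 0 or inherent_filtration_mm_al < 0:
        raise ValueError("filtration must be >= 0")
    edges = np.arange(PHOTON_CUTOFF_KEV, tube_potential, bin_width_kev)
    edges = np.append(edges, tube_potential)
    probs = np.empty(edges.size - 1)
    for i in range(probs.size):
        grid = np.linspace(edges[i], edges[i + 1], 21)
        vals = spectral_fluence(grid, tube_potential, filtration_mm_al,
                                inherent_filtration_mm_al)
        probs[i] = np.trapezoid(vals, grid)
    total = probs.sum()
    if total <= 0:
        raise ValueError("spectrum model integrates to zero")
    return EnergySpectrum(edges, probs / total, tube_potential, filtration_mm_al)


# ---------------------------------------------------------------------------
# Primary sampling
# ---------------------------------------------------------------------------

def sample_primary(beam: BeamConfig, spectrum: EnergySpectrum, n: int,
                   rng: np.random.Generator) -> PhotonBatch:
    """Sample ``n`` primary photons from the Gaussian focal spot.

    Positions are drawn from the isotropic Gaussian focal spot in the source
    plane; each direction points at a uniformly drawn target on the circular
    field (diameter ``fov_at_isocenter``) in the isocenter plane, so the
    cone is collimated to the configured field.  Weights are 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = angulate(beam)
    e1, e2 = geom.transverse_axes
    u1 = rng.standard_normal(n) * beam.focal_spot_sigma
    u2 = rng.standard_normal(n) * beam.focal_spot_sigma
    positions = geom.source_position + np.outer(u1, e1) + np.outer(u2, e2)
    r = 0.5 * beam.fov_at_isocenter * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    targets = np.outer(r * np.cos(phi), e1) + np.outer(r * np.sin(phi), e2)
    directions = targets - positions
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    energies = spectrum.sample(n, rng)
    return PhotonBatch(positions, directions, energies, np.ones(n))


# ---------------------------------------------------------------------------
# Spectrum text export/import
# ---------------------------------------------------------------------------

def save_spectrum(spectrum: EnergySpectrum, path):
    """Two-column delimited text: bin upper edge (keV), probability."""
    buf = io.StringIO()
    buf.write(f"# tube_potential_kv: {spectrum.tube_potential:g}\n")
    buf.write(f"# filtration_mm_al: {spectrum.filtration_mm_al:g}\n")
    buf.write(f"# first_bin_lower_edge_kev: {spectrum.bin_edges[0]:.9g}\n")
    buf.write("# columns: bin_upper_edge_kev probability\n")
    for edge, p in zip(spectrum.bin_edges[1:], spectrum.bin_probability):
        buf.write(f"{edge:.9g}\t{p:.9e}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_spectrum(path) -> EnergySpectrum:
    tube = 0.0
    filt = 0.0
    lower = PHOTON_CUTOFF_KEV
    uppers, probs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "tube_potential_kv:" in line:
                    tube = float(line.split(":", 1)[1])
                elif "filtration_mm_al:" in line:
                    filt = float(line.split(":", 1)[1])
                elif "first_bin_lower_edge_kev:" in line:
                    lower = float(line.split(":", 1)[1])
                continue
            u, p = line.split()
            uppers.append(float(u))
            probs.append(float(p))
    edges = np.concatenate([[lower], uppers])
    probs = np.asarray(probs)
    return EnergySpectrum(edges, probs / probs.sum(), tube, filt)
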
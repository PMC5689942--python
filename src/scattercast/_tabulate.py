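"""Generator for the embedded photon cross-section fixture tables.

The package ships per-material mass attenuation tables (photoelectric,
incoherent, coherent partials in cm^2/g on a 10-150 keV grid) as plain-text
fixtures under ``data/materials``.  They are produced here from a
semi-empirical model:

* incoherent: exact free-electron Klein-Nishina total cross-section per
  electron times electrons per gram (consistent with the free-electron
  Klein-Nishina angular sampler used in transport);
* photoelectric and coherent: power laws in energy with fixed atomic-number
  scaling (tau ~ Z^4.4 / A, sigma_coh ~ Z^1.9 / A), whose four global
  constants are least-squares fitted so that the water *total* reproduces
  the standard published water mass-attenuation values at 10-150 keV.

This keeps every partial smooth, strictly positive and mutually consistent,
which is what the transport and its tests rely on; absolute per-element
accuracy is secondary to the self-consistency of the engine and is discussed
in the methods note.

Run ``python -m scattercast._tabulate`` to regenerate the fixtures in place.
"""

from __future__ import annotations

import io
from importlib import resources

import numpy as np
from scipy.optimize import least_squares

R_E_CM = 2.8179403262e-13  # classical electron radius
N_AVOGADRO = 6.02214076e23
ELECTRON_REST_KEV = 511.0

ENERGY_GRID_KEV = np.arange(10.0, 151.0, 1.0)

# Z and A for every element appearing in the material compositions.
ELEMENTS = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "Ar": (18, 39.948),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
}

# name -> (density g/cm^3, {element: mass fraction})
MATERIALS = {
    "water": (1.0, {"H": 0.111898, "O": 0.888102}),
    "air": (0.0012047, {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827}),
    "aluminium": (2.699, {"Al": 1.0}),
    "iron": (7.874, {"Fe": 1.0}),
    "pmma": (1.190, {"H": 0.080538, "C": 0.599848, "O": 0.319614}),
    "concrete": (2.300, {
        "H": 0.022100, "C": 0.002484, "O": 0.574930, "Na": 0.015208,
        "Mg": 0.001266, "Al": 0.019953, "Si": 0.304627, "K": 0.010045,
        "Ca": 0.042951, "Fe": 0.006435,
    }),
    # Carbon-fibre / foam sandwich table top (effective homogeneous slab).
    "carbon_table": (0.55, {"H": 0.030, "C": 0.910, "O": 0.060}),
}

# Standard water total mass attenuation (with coherent), cm^2/g.
WATER_TOTAL_ANCHORS = {
    10.0: 5.329, 15.0: 1.673, 20.0: 0.8096, 30.0: 0.3756, 40.0: 0.2683,
    50.0: 0.2269, 60.0: 0.2059, 80.0: 0.1837, 100.0: 0.1707, 150.0: 0.1505,
}

PE_Z_EXPONENT = 4.4
COH_Z_EXPONENT = 1.9


def klein_nishina_total_cm2(energy_kev):
    """Exact Klein-Nishina total cross-section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log(1.0 + 2.0 * k) / k)
    t2 = np.log(1.0 + 2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * np.pi * R_E_CM**2 * (t1 + t2 - t3)


def incoherent_mu_rho(composition, energy_kev):
    e_per_g = sum(frac * ELEMENTS[el][0] / ELEMENTS[el][1] for el, frac in composition.items())
    return e_per_g * N_AVOGADRO * klein_nishina_total_cm2(energy_kev)


def _pe_coh_mu_rho(composition, energy_kev, params):
    k_pe, n_pe, k_coh, n_coh = params
    e = np.asarray(energy_kev, dtype=float) / 100.0
    pe = np.zeros_like(e)
    coh = np.zeros_like(e)
    for el, frac in composition.items():
        z, a = ELEMENTS[el]
        pe = pe + frac * k_pe * z**PE_Z_EXPONENT / a * e ** (-n_pe)
        coh = coh + frac * k_coh * z**COH_Z_EXPONENT / a * e ** (-n_coh)
    return pe, coh


def fit_model_constants():
    """Fit (k_pe, n_pe, k_coh, n_coh) to the water total anchors."""
    energies = np.array(sorted(WATER_TOTAL_ANCHORS))
    targets = np.array([WATER_TOTAL_ANCHORS[e] for e in energies])
    comp = MATERIALS["water"][1]
    incoh = incoherent_mu_rho(comp, energies)

    def residual(p):
        pe, coh = _pe_coh_mu_rho(comp, energies, p)
        return np.log(incoh + pe + coh) - np.log(targets)

    fit = least_squares(residual, x0=[1e-3, 3.1, 1e-2, 1.9],
                        bounds=([1e-8, 2.0, 1e-8, 1.0], [1.0, 4.0, 1.0, 3.0]))
    return fit.x


def material_table(name, params=None):
    """Return (energy, pe, incoh, coh) arrays in cm^2/g for a named material."""
    if params is None:
        params = fit_model_constants()
    comp = MATERIALS[name][1]
    incoh = incoherent_mu_rho(comp, ENERGY_GRID_KEV)
    pe, coh = _pe_coh_mu_rho(comp, ENERGY_GRID_KEV, params)
    return ENERGY_GRID_KEV, pe, incoh, coh


def format_material_file(name, params):
    energy, pe, incoh, coh = material_table(name, params)
    density, comp = MATERIALS[name]
    buf = io.StringIO()
    buf.write(f"# material: {name}\n")
    buf.write(f"# density_g_cm3: {density:.7g}\n")
    buf.write("# composition: " + ",".join(f"{el}:{frac:.6f}" for el, frac in comp.items()) + "\n")
    buf.write("# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g\n")
    for i in range(energy.size):
        buf.write(f"{energy[i]:.1f}\t{pe[i]:.6e}\t{incoh[i]:.6e}\t{coh[i]:.6e}\n")
    return buf.getvalue()


def format_manifest():
    lines = ["# columns: name density_g_cm3 composition"]
    for name, (density, comp) in MATERIALS.items():
        comp_s = ",".join(f"{el}:{frac:.6f}" for el, frac in comp.items())
        lines.append(f"{name}\t{density:.7g}\t{comp_s}")
    return "\n".join(lines) + "\n"


def write_fixtures(out_dir=None):
    if out_dir is None:
        out_dir = resources.files("scattercast").joinpath("data", "materials")
    params = fit_model_constants()
    for name in MATERIALS:
        out_dir.joinpath(f"{name}.tsv").write_text(format_material_file(name, params))
    out_dir.joinpath("manifest.tsv").write_text(format_manifest())


if __name__ == "__main__":
    write_fixtures()
    print("material fixtures regenerated")
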
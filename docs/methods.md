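# Methods

## Physical model

The engine transports photons only, between 10 and 150 keV. Three
interactions are modelled:

* **Compton scattering** on free electrons at rest: energies and angles are
  sampled from the Klein–Nishina differential cross-section by the standard
  composition–rejection scheme; the incoherent scattering function (electron
  binding) is omitted. The scattered photon satisfies
  `E' = E / (1 + (E/511 keV)(1 − cos θ))` exactly.
* **Rayleigh scattering** with the Thomson angular law `p(μ) ∝ 1 + μ²`
  (inverted in closed form through the depressed cubic), without atomic form
  factors.
* **Photoelectric absorption** terminating the photon with full local
  deposition; characteristic fluorescence is omitted.

Secondary electrons are not transported: their energy is deposited at the
interaction point (kerma approximation), justified by sub-millimetre
electron ranges at kV energies. Photons falling below the 10 keV cutoff
deposit their remaining energy locally and terminate; this bucket is kept
separate in the energy ledger, which must balance
(emitted = deposited + cutoff + escaped + discarded) to 1e-9 relative on
every run.

Free flight uses Woodcock (delta) tracking with an **energy-dependent
majorant** (the maximum total linear coefficient over the scene's materials
at each energy node), which is exact in heterogeneous scenes without
boundary bookkeeping. The batch engine is a single-stream numba kernel
(xoroshiro128+ PRNG): runs are bitwise reproducible for a fixed seed. A
readable pure-Python single-photon transport that shares the compiled
interaction samplers provides event-level introspection and a cross-check
of the kernel.

## Cross sections

Per-material mass attenuation partials (photoelectric, incoherent,
coherent; 10–150 keV at 1 keV, log-log interpolated) ship as text fixtures
generated by a semi-empirical model: exact free-electron Klein–Nishina for
the incoherent part, and power laws `τ ∝ Z^4.4/A · E^(−n_pe)`,
`σ_coh ∝ Z^1.9/A · E^(−n_coh)` whose four global constants are
least-squares anchored to the standard published water total attenuation
values (the fitted water total reproduces those anchors to ≤0.2%). The
same tables provide the energy-absorption coefficient
`μ_ab = μ_pe + μ_inc·f̄(E)` (with `f̄` the mean Klein–Nishina energy-transfer
fraction) used by the track-length kerma estimator. Per-element accuracy
away from water — notably iron and the high-Z constituents of concrete — is
cruder than library data; the consequences are discussed under
*Limitations*.

Materials: water (patient, staff, commissioning slabs), air, aluminium
(spectrum filtration), iron, PMMA, ordinary concrete (floor/ceiling), and a
0.55 g/cm³ carbon-fibre/foam composite for the 2 cm table top.

## Source model

The tube spectrum is Kramers-type bremsstrahlung `(kVp − E)` filtered
through aluminium (default inherent filtration 2.5 mm Al; the acquisition
preset adds none), plus Gaussian tungsten K lines at 57.98 / 59.32 / 67.2 /
69.1 keV with fixed relative intensities 0.58 / 1.00 / 0.23 / 0.08,
appearing only above the 69.5 keV K edge; their total fluence scales with
the overvoltage as `0.13·(kVp/69.5 − 1)^1.63` (≈9% of photons at 125 kVp
unfiltered). The model is calibrated for 30–150 kV and is exposed in closed
form so the binned spectrum can be checked by quadrature.

The focal spot is an isotropic Gaussian in the source plane (σ = 0.03 cm
default — not stated by the C-arm vendor, negligible for scatter); each
ray aims at a uniform point on the circular field (20 cm diameter) in the
isocenter plane, so the cone is exactly collimated to the field of view.
The source sits 75 cm from the isocenter on the gantry circle; the LAO
angle rotates it about the patient's longitudinal axis (0° = under the
table), an optional cranio-caudal angle about the lateral axis.

## Scene and declared defaults

World frame: isocenter at the origin, +z up, +y toward the patient's head,
+x toward the patient's left (tube side at LAO 90°); lengths in cm. The
defaults below are the package's declared choices where the underlying
study reports only shapes:

| element | default |
| --- | --- |
| patient | water elliptic cylinder 30 × 20 × 170, centered on the isocenter |
| table top | carbon composite slab 50 × 200 × 2, top 10 cm below isocenter |
| floor / ceiling | 10 cm concrete, top at z = −110 / bottom at z = +190 |
| world | 600 × 600 × 400 air |
| staff phantom | water elliptic cylinder 38 × 23 × 175 (semi-axes 19/11.5, standing on the floor, wide axis along the table); a 16 × 100 × 17.48 "slim" preset is exposed as an alternative |
| detector | perfect-absorber block 34 × 34 × 5 with its face 35 cm beyond the isocenter on the beam axis |

The image-intensifier block is essential: without it the transmitted
primary beam would be recorded into the phase space and ray-cast onto the
far-side phantom, which the physical setup's detector prevents. It absorbs
photons at the entry point (no backscatter off the detector housing).

Phase-space boxes: an axis-aligned bounding box around patient + table +
detector with a 3 cm margin, and floor/ceiling boxes whose inner faces
coincide with the slab surfaces, so that a phantom standing on the floor
never overlaps a box interior. Only **outward** crossings are recorded,
once per crossing, with position, direction, energy, weight and the source
surface tag; a photon re-entering and leaving again is recorded again.

Staff placement: positions are parametrized by table side, the air gap from
table edge to phantom surface, and a longitudinal offset. At LAO 90° the
gantry occupies the y ≈ 0 plane (the tube itself sits at table height on
the left), so the default comparison and map positions stand 40 cm caudal
of it; the source publication does not state this offset. The 14-position
map preset uses gaps 5/25/50 cm in the main row and 5/25 cm in a
nearer-foot and a cranial row, per side.

## Calibration definitions

**Energy-absorption ratio (EAR).** For each angulation, with the phantom at
the reference position (25 cm, tube side),

EAR = (energy absorbed in the phantom when the phase-space photons are
replayed with full Monte Carlo physics) / (summed energy of the records
whose straight rays hit the phantom).

During replay a photon is terminated at its next outward phase-space-box
crossing: that continuation exists as a later record, so killing it makes
the replay free of double counting and makes the telescoping identity hold
— full-MC dose from the source = replay of all records + the "direct"
contribution deposited before a photon's first outward crossing (verified
as a test at 3σ). The numerator/denominator convention is isolated in one
function so it can be swapped; the ratio is clamped to (0, 1].

**Absolute dose factor.** Default 1 (relative mode, doses in Gy per source
history scaled by frames). A commissioning run plus one user-supplied
measured dose at a reference depth yields the factor mapping simulated to
measured Gy; the physical measurement chain is outside the package.

## Commissioning

The commissioning scene is a 30 × 30 × 12 cm water slab stack with 7 cm of
backscatter, entry surface at SSD 100 cm, beam along +z. Depth dose (26
points over 0–12 cm; bin centres of a 12/26 cm grid) and two 43-point cross
profiles at the bin nearest 1 cm depth are scored on a 1 × 1 cm voxel grid
with a track-length kerma estimator (`Σ w·E·μ_ab·dl` per voxel), which at
kV energies equals absorbed dose under the same kerma approximation the
transport uses and converges ~100× faster than analog voxel deposition.
Depth dose is normalized to the shallowest point, profiles to the central
axis. With 3×10⁶ histories the depth curve is strictly decreasing beyond
the first voxel (in-phantom scatter buildup fills the first half-centimetre)
and the central 10 cm of both profiles is flat to <5%.

## Dose accounting

Whole-phantom averaging: dose = absorbed (or EAR-converted incident) energy
× 1.602×10⁻¹⁶ / phantom mass (g), normalized per source history, times the
histories-per-frame constant, frames and the absolute dose factor.
Ray-cast totals use exact compensated summation, so results are bitwise
independent of record order; the surface-resolved output is the unrolled
lateral-surface energy histogram (azimuth × height bins; cap hits, when the
cap mode is enabled, clip into the end rows so the partition conserves the
ledger energy).

Intersection default is `with_caps`; `lateral_only` (also via the CLI
`paper_compat` flag) reproduces the published limitation of ignoring the
cylinder's top cap.

## Validation summary (computed by the test suite and acceptance script)

At 2×10⁶ histories, LAO 90°, default room: the ray cast tracks the full MC
within ~1–2% on the tube side (underestimating by the ~1.5% direct term)
and within ~10–12% on the far side; floor+ceiling supply ~2.6% of hits on
the tube side (an order of magnitude below patient+table) and ~10% on the
far side; the vacuum-equivalence oracle is exact to the bit; LAO-0 mirror
doses agree well within Monte Carlo error.

## Limitations

* **Far-side bias sign.** The tube-side-calibrated EAR transfers slightly
  high to the opposite side (softer incident spectrum; replay losses in the
  detector shadow and longer air paths that the straight rays ignore), so
  there the ray cast can *over*estimate the reference rather than
  underestimate it. Both sides stay within the validation bands, but the
  far side should be treated as indicative only — the same region where the
  approximation is weakest by construction.
* **Floor/ceiling share.** Free-electron Compton and form-factor-free
  Rayleigh overestimate low-energy scatter, and the power-law photoelectric
  fit underestimates absorption in concrete, so the floor albedo — and with
  it the floor-origin share of hits on the tube side (~2.6%) — is likely
  overestimated relative to a full-physics simulation of the same room.
* The synthetic study emulates a static, empty-except-phantom room: no
  gantry/tube housing, no lead curtains or shields (extension point), no
  anthropomorphic phantoms, one phantom evaluated at a time (no mutual
  shadowing), no heel effect or mAs modelling beyond linear frame scaling.
  Passing tests therefore validate the transport/ray-cast machinery and its
  internal consistency, not agreement with measurements in a specific
  clinical room.
* Phase-space files use 33-byte single-precision records; files from other
  codes are not read natively.
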
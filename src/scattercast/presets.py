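"""Scene presets: the default intervention room, staff-phantom placement,
the TLD measurement layout and the LAO-90 dose-map position scheme.

World frame: isocenter at the origin, +z up, +y toward the patient's head,
+x toward the patient's left (tube side at LAO 90).  All lengths in cm.

Declared defaults (the source publication gives shapes but not all
dimensions): patient water cylinder 30 x 20 x 170 cm centered on the
isocenter; 2 cm carbon-fibre composite table top 50 x 200 cm; 10 cm concrete
floor slab with its top 110 cm below the isocenter and ceiling slab starting
190 cm above it; 600 x 600 x 400 cm air-filled world; a perfect-absorber
image-intensifier block 35 cm beyond the isocenter on the beam axis.
"""

from __future__ import annotations

import numpy as np

from . import geometry as geo
from . import materials as mat_mod
from .spectrum_source import BeamConfig, angulate

TABLE_HALF_WIDTH = 25.0
TABLE_TOP_Z = -10.0
FLOOR_TOP_Z = -110.0
CEILING_BOTTOM_Z = 190.0
WORLD_HALF = np.array([300.0, 300.0, 200.0])

# Staff phantom cross-sections: the 38 x 23 x 175 cm torso-like cylinder
# (default) and the slimmer 16 x 100 x 17.48 cm variant used in the MC-scene
# description, exposed as an alternative preset.
STAFF_PRESETS = {
    "torso": dict(semi_axis_a=19.0, semi_axis_b=11.5, half_height=87.5),
    "slim": dict(semi_axis_a=8.0, semi_axis_b=8.74, half_height=50.0),
}

DETECTOR_DISTANCE_CM = 35.0       # isocenter to detector face
DETECTOR_HALF_EXTENTS = (17.0, 17.0, 2.5)


def staff_phantom(side: str = "left", gap_cm: float = 25.0, y_cm: float = -40.0,
                  preset: str = "torso", name: str = "staff",
                  material: str = "water") -> geo.EllipticCylinder:
    """A standing staff phantom beside the table.

    ``gap_cm`` is the air gap between the table edge and the phantom's
    lateral surface; ``side`` is the patient's left (+x, tube side at
    LAO 90) or right; ``y_cm`` displaces the phantom along the table (the
    gantry occupies the y=0 plane, so default positions stand caudal of it).
    The phantom faces the table: its wide semi-axis runs along the table.
    """
    dims = STAFF_PRESETS[preset]
    sign = {"left": 1.0, "right": -1.0}[side]
    x = sign * (TABLE_HALF_WIDTH + gap_cm + dims["semi_axis_b"])
    center = [x, y_cm, FLOOR_TOP_Z + dims["half_height"]]
    return geo.EllipticCylinder(center, [0.0, 0.0, 1.0], material=mat_mod.get_material(material),
                                name=name, a_direction=[0.0, 1.0, 0.0], **dims)


def _aabb_of_solid(s) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(s, geo.EllipticCylinder):
        r = s.rotation
        ext = np.sqrt((s.semi_axis_a * r[0]) ** 2 + (s.semi_axis_b * r[1]) ** 2) \
            + s.half_height * np.abs(r[2])
    else:
        ext = np.abs(s.rotation.T) @ s.half_extents
    return s.center - ext, s.center + ext


def default_scene(beam: BeamConfig | None = None, staff=(),
                  include_detector: bool = True) -> geo.Scene:
    """The default C-arm intervention room for a given beam angulation.

    Solid priority: staff phantoms, patient, table, detector, floor,
    ceiling.  Three phase-space boxes surround (i) patient + table +
    detector, (ii) the floor slab, (iii) the ceiling slab; the floor box top
    and ceiling box bottom coincide with the slab surfaces so that standing
    phantoms never overlap a box interior.
    """
    beam = beam or BeamConfig()
    water = mat_mod.get_material("water")
    concrete = mat_mod.get_material("concrete")
    air = mat_mod.get_material("air")

    patient = geo.EllipticCylinder([0.0, 0.0, 0.0], [0.0, 1.0, 0.0], 15.0, 10.0, 85.0,
                                   water, name="patient", a_direction=[1.0, 0.0, 0.0])
    table = geo.Box([0.0, 0.0, TABLE_TOP_Z - 1.0], [TABLE_HALF_WIDTH, 100.0, 1.0],
                    mat_mod.get_material("carbon_table"), name="table")
    floor = geo.Box([0.0, 0.0, FLOOR_TOP_Z - 5.0], [290.0, 290.0, 5.0], concrete,
                    name="floor")
    ceiling = geo.Box([0.0, 0.0, CEILING_BOTTOM_Z + 5.0], [290.0, 290.0, 5.0], concrete,
                      name="ceiling")

    solids = list(staff) + [patient, table]
    beam_contents = [patient, table]
    if include_detector:
        g = angulate(beam)
        e1, e2 = g.transverse_axes
        rot = np.vstack([e1, e2, g.beam_axis])
        center = (DETECTOR_DISTANCE_CM + DETECTOR_HALF_EXTENTS[2]) * g.beam_axis
        detector = geo.Box(center, DETECTOR_HALF_EXTENTS, air, name="detector",
                           rotation=rot, absorber=True)
        solids.append(detector)
        beam_contents.append(detector)
    solids += [floor, ceiling]

    los, his = zip(*[_aabb_of_solid(s) for s in beam_contents])
    lo = np.min(los, axis=0) - 3.0
    hi = np.max(his, axis=0) + 3.0
    patient_box = geo.BoxSurface(0.5 * (lo + hi), 0.5 * (hi - lo),
                                 "phase_space_patient_table")
    floor_box = geo.BoxSurface([0.0, 0.0, FLOOR_TOP_Z - 5.25], [295.0, 295.0, 5.25],
                               "phase_space_floor")
    ceiling_box = geo.BoxSurface([0.0, 0.0, CEILING_BOTTOM_Z + 5.25], [295.0, 295.0, 5.25],
                                 "phase_space_ceiling")
    return geo.Scene(solids, [patient_box, floor_box, ceiling_box], air, WORLD_HALF.copy())


def vacuum_room_scene(beam: BeamConfig | None = None, staff=()) -> geo.Scene:
    """Diagnostic scene for the exactness oracle: the default room with every
    material (ambient included) replaced by vacuum, no detector, and staff
    phantoms made perfectly absorbing.  With no matter en route, ray casting
    and Monte Carlo replay must agree exactly."""
    from dataclasses import replace
    scene = default_scene(beam, include_detector=False)
    vac = mat_mod.vacuum()
    solids = [replace(s, absorber=True) for s in staff]
    solids += [replace(s, material=vac) for s in scene.solids]
    return geo.Scene(solids, scene.surfaces, vac, scene.world_half_extents)


def lao90_map_positions() -> list[dict]:
    """The LAO-90 dose-map scheme: seven staff positions per table side
    (lateral gaps 5/25/50 cm in the main caudal row, plus nearer-foot and
    cranial rows at gaps 5/25 cm)."""
    rows = [(-40.0, (5.0, 25.0, 50.0)), (-80.0, (5.0, 25.0)), (40.0, (5.0, 25.0))]
    positions = []
    for side in ("left", "right"):
        for y, gaps in rows:
            for gap in gaps:
                positions.append({"side": side, "gap_cm": gap, "y_cm": y})
    return positions


def reference_phantom_position() -> dict:
    """The calibration/comparison reference: 25 cm from the table on the
    tube side at LAO 90, in the main caudal row."""
    return {"side": "left", "gap_cm": 25.0, "y_cm": -40.0}


def tld_sheet_points() -> dict[str, np.ndarray]:
    """TLD positions of the validation layout: two 9-chip sheets 80 cm from
    the isocenter at 45 degrees caudal, 125 cm above the floor (left = tube
    side, right mirrored), and a 3-chip eye/thyroid sheet above the left one
    at 160 cm height."""
    d = 80.0 / np.sqrt(2.0)
    out = {}
    for side, sign in (("left", 1.0), ("right", -1.0)):
        center = np.array([sign * d, -d, FLOOR_TOP_Z + 125.0])
        inplane = np.array([sign * 1.0, 1.0, 0.0]) / np.sqrt(2.0)  # horizontal, in sheet plane
        pts = []
        for dz in (10.0, 0.0, -10.0):
            for du in (-6.0, 0.0, 6.0):
                pts.append(center + du * inplane + np.array([0.0, 0.0, dz]))
        out[side] = np.array(pts)
    eye_center = np.array([d, -d, FLOOR_TOP_Z + 160.0])
    inplane = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    out["eye_thyroid"] = np.array([
        eye_center - 3.4 * inplane,
        eye_center + 3.4 * inplane,
        eye_center - np.array([0.0, 0.0, 27.4]),
    ])
    return out
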
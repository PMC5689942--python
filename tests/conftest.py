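"""Shared fixtures: small scenes, fixture phase-space files, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from scattercast import geometry as geo
from scattercast import materials as mat_mod
from scattercast import phasespace, presets
from scattercast.spectrum_source import BeamConfig, build_spectrum


@pytest.fixture(scope="session")
def spectrum_125():
    return build_spectrum(125.0, 0.0)


@pytest.fixture(scope="session")
def beam_lao90():
    return BeamConfig(lao_deg=90.0)


@pytest.fixture(scope="session")
def torso_phantom():
    """Staff phantom at the origin, axis +z (38 x 23 x 175 cm)."""
    return geo.EllipticCylinder([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 19.0, 11.5, 87.5,
                                mat_mod.get_material("water"), name="staff")


@pytest.fixture()
def pencil_psf(tmp_path):
    """1000 identical 80 keV photons travelling +x from x=-100."""
    path = tmp_path / "pencil.psf"
    phasespace.make_fixture_psf(
        "pencil", {"position": [-100.0, 0.0, 0.0], "direction": [1.0, 0.0, 0.0],
                   "energy": 80.0}, 1000, 7, path)
    return path


def march_hit_distance(origin, direction, inside_fn, t_max=80.0, step=0.01):
    """Brute-force marching oracle: first boundary crossing of ``inside_fn``
    along the ray, refined by bisection; np.inf when none within ``t_max``.

    Vectorized over rays.
    """
    origin = np.atleast_2d(origin)
    direction = np.atleast_2d(direction)
    n = len(origin)
    ts = np.arange(0.0, t_max, step)
    hit_t = np.full(n, np.inf)
    prev_inside = inside_fn(origin)
    # Rays starting inside count their first exit; starting outside, first entry.
    remaining = np.arange(n)
    for t in ts[1:]:
        pts = origin[remaining] + t * direction[remaining]
        inside = inside_fn(pts)
        flipped = inside != prev_inside[remaining]
        if flipped.any():
            idx = remaining[flipped]
            lo = np.full(idx.size, t - step)
            hi = np.full(idx.size, t)
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                m_in = inside_fn(origin[idx] + mid[:, None] * direction[idx])
                cross_lo = m_in != prev_inside[idx]
                hi = np.where(cross_lo, mid, hi)
                lo = np.where(cross_lo, lo, mid)
            hit_t[idx] = 0.5 * (lo + hi)
            keep = ~flipped
            remaining = remaining[keep]
            if remaining.size == 0:
                break
    return hit_t
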
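"""Binary phase-space file (PSF) format: streaming writer/reader and
deterministic synthetic fixtures.

A PSF stores photon states crossing a phase-space surface so transport can
be resumed (or approximated by ray casting) without re-simulating upstream
physics.  The on-disk format is bespoke and minimal:

``RCPSF\\0`` magic (6 B) | version ``<u2`` | record count ``<u8`` |
CRC-32 of the record payload ``<u4`` | header-JSON length ``<u4`` |
header JSON (angulation, beam summary, source run seed) | fixed-width
records.

Each record is 33 bytes little-endian: position (3 x ``<f4``, cm),
direction (3 x ``<f4``, unit), energy (``<f4``, keV), statistical weight
(``<f4``) and one tag byte packing the particle type (high nibble, 0 =
photon) with the source surface tag (low nibble: 0 patient+table, 1 floor,
2 ceiling).  Photons below the 10 keV transport cutoff are rejected at
write time, so every reader can assume the floor.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import TAG_CODES, TAG_NAMES
from ._physics import PHOTON_CUTOFF_KEV

MAGIC = b"RCPSF\x00"
VERSION = 1
HEADER_FMT = "<6sHQII"
HEADER_FIXED_SIZE = struct.calcsize(HEADER_FMT)  # 24 bytes

RECORD_DTYPE = np.dtype([
    ("pos", "<f4", (3,)),
    ("dir", "<f4", (3,)),
    ("energy", "<f4"),
    ("weight", "<f4"),
    ("tag", "u1"),
])
RECORD_SIZE = RECORD_DTYPE.itemsize
assert RECORD_SIZE == 33

PARTICLE_PHOTON = 0


class PsfError(Exception):
    """Base error for phase-space file problems."""


class PsfVersionError(PsfError):
    pass


class PsfTruncatedError(PsfError):
    def __init__(self, byte_offset, message):
        super().__init__(f"{message} (at byte offset {byte_offset})")
        self.byte_offset = byte_offset


class PsfChecksumError(PsfError):
    pass


class PsfIntegrityError(PsfError):
    pass


class PsfInvariantError(PsfError):
    def __init__(self, index, message):
        super().__init__(f"record {index}: {message}")
        self.index = index


def pack_tag(surface_tag: int, particle_type: int = PARTICLE_PHOTON) -> int:
    return ((particle_type & 0xF) << 4) | (surface_tag & 0xF)


def unpack_tag(tag_byte):
    return (np.asarray(tag_byte) >> 4) & 0xF, np.asarray(tag_byte) & 0xF


@dataclass
class PsfHeader:
    """Self-describing PSF header."""

    record_count: int = 0
    checksum: int = 0
    angulation_deg: float = 0.0
    beam: dict = field(default_factory=dict)
    seed: int | None = None
    extra: dict = field(default_factory=dict)
    version: int = VERSION

    def to_json_bytes(self) -> bytes:
        payload = {"angulation_deg": self.angulation_deg, "beam": self.beam,
                   "seed": self.seed, **self.extra}
        return json.dumps(payload, sort_keys=True).encode()


@dataclass
class PhotonBatch:
    """In-memory batch of phase-space photon records (float64 working copy)."""

    positions: np.ndarray   # (n, 3) cm
    directions: np.ndarray  # (n, 3) unit
    energies: np.ndarray    # (n,) keV
    weights: np.ndarray     # (n,)
    tags: np.ndarray | None = None  # (n,) surface tag codes

    def __post_init__(self):
        n = len(self.energies)
        if self.tags is None:
            self.tags = np.zeros(n, dtype=np.uint8)
        for arr, shape in ((self.positions, (n, 3)), (self.directions, (n, 3)),
                           (self.weights, (n,)), (self.tags, (n,))):
            if arr.shape != shape:
                raise ValueError(f"inconsistent batch shapes (n={n})")

    def __len__(self):
        return len(self.energies)

    def validate(self):
        norms = np.linalg.norm(self.directions, axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
        if bad.size:
            raise PsfInvariantError(int(bad[0]), f"direction norm {norms[bad[0]]:.8f} not unit")
        bad = np.flatnonzero(self.energies < PHOTON_CUTOFF_KEV)
        if bad.size:
            raise PsfInvariantError(int(bad[0]),
                                    f"energy {self.energies[bad[0]]:.3f} keV below cutoff")
        bad = np.flatnonzero(self.weights <= 0)
        if bad.size:
            raise PsfInvariantError(int(bad[0]), f"weight {self.weights[bad[0]]} not positive")

    def to_records(self) -> np.ndarray:
        rec = np.empty(len(self), dtype=RECORD_DTYPE)
        rec["pos"] = self.positions.astype("<f4")
        rec["dir"] = self.directions.astype("<f4")
        rec["energy"] = self.energies.astype("<f4")
        rec["weight"] = self.weights.astype("<f4")
        rec["tag"] = np.array([pack_tag(int(t)) for t in np.asarray(self.tags)], dtype="u1") \
            if len(self) else np.empty(0, dtype="u1")
        return rec

    @classmethod
    def from_records(cls, rec: np.ndarray) -> "PhotonBatch":
        _, surface = unpack_tag(rec["tag"])
        return cls(rec["pos"].astype(float), rec["dir"].astype(float),
                   rec["energy"].astype(float), rec["weight"].astype(float),
                   surface.astype(np.uint8))

    @classmethod
    def concatenate(cls, batches) -> "PhotonBatch":
        batches = list(batches)
        return cls(np.concatenate([b.positions for b in batches]),
                   np.concatenate([b.directions for b in batches]),
                   np.concatenate([b.energies for b in batches]),
                   np.concatenate([b.weights for b in batches]),
                   np.concatenate([b.tags for b in batches]))


class PsfWriter:
    """Streaming PSF writer: append record batches, finalize header on close."""

    def __init__(self, path, header: PsfHeader):
        self.path = Path(path)
        self.header = header
        self._json = header.to_json_bytes()
        self._fh = open(self.path, "wb")
        self._count = 0
        self._crc = 0
        self._write_header()

    def _write_header(self):
        self._fh.seek(0)
        self._fh.write(struct.pack(HEADER_FMT, MAGIC, self.header.version,
                                   self._count, self._crc, len(self._json)))
        self._fh.write(self._json)

    def append(self, batch: PhotonBatch):
        if len(batch) == 0:
            return
        batch.validate()
        raw = batch.to_records().tobytes()
        self._crc = zlib.crc32(raw, self._crc)
        self._count += len(batch)
        self._fh.write(raw)

    def append_records(self, rec: np.ndarray):
        self.append(PhotonBatch.from_records(rec))

    def close(self):
        if self._fh is None:
            return
        self._write_header()
        self._fh.close()
        self._fh = None
        self.header.record_count = self._count
        self.header.checksum = self._crc

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_psf(header: PsfHeader, batches, path) -> PsfHeader:
    """Write an iterable of :class:`PhotonBatch` to ``path``; returns the
    finalized header."""
    if isinstance(batches, PhotonBatch):
        batches = [batches]
    with PsfWriter(path, header) as w:
        for b in batches:
            w.append(b)
    return header


def _read_header(fh, path):
    fixed = fh.read(HEADER_FIXED_SIZE)
    if len(fixed) < HEADER_FIXED_SIZE:
        raise PsfTruncatedError(len(fixed), f"{path}: file shorter than fixed header")
    magic, version, count, crc, json_len = struct.unpack(HEADER_FMT, fixed)
    if magic != MAGIC:
        raise PsfError(f"{path}: bad magic {magic!r}")
    if version != VERSION:
        raise PsfVersionError(f"{path}: unsupported format version {version}")
    raw_json = fh.read(json_len)
    if len(raw_json) < json_len:
        raise PsfTruncatedError(HEADER_FIXED_SIZE + len(raw_json),
                                f"{path}: truncated header JSON")
    meta = json.loads(raw_json)
    header = PsfHeader(record_count=count, checksum=crc,
                       angulation_deg=meta.pop("angulation_deg", 0.0),
                       beam=meta.pop("beam", {}), seed=meta.pop("seed", None),
                       extra=meta, version=version)
    return header, HEADER_FIXED_SIZE + json_len


def read_psf_header(path) -> PsfHeader:
    """Read only the header of a PSF (no payload validation)."""
    with open(path, "rb") as fh:
        header, _ = _read_header(fh, Path(path))
    return header


def read_psf(path, chunk_records: int = 1_000_000):
    """Open a PSF: returns ``(header, record_stream)``.

    ``record_stream`` lazily yields structured arrays (``RECORD_DTYPE``) of at
    most ``chunk_records`` records, using buffer space independent of file
    size.  The payload CRC is verified when the stream is exhausted; record
    count vs. file size is verified up front.
    """
    path = Path(path)
    fh = open(path, "rb")
    header, data_start = _read_header(fh, path)
    file_size = path.stat().st_size
    payload = file_size - data_start
    if payload != header.record_count * RECORD_SIZE:
        fh.close()
        if payload % RECORD_SIZE != 0:
            raise PsfTruncatedError(data_start + payload - (payload % RECORD_SIZE),
                                    f"{path}: file truncated mid-record")
        raise PsfIntegrityError(
            f"{path}: header declares {header.record_count} records but file holds "
            f"{payload // RECORD_SIZE}")

    def stream():
        crc = 0
        try:
            remaining = header.record_count
            while remaining > 0:
                take = min(remaining, chunk_records)
                raw = fh.read(take * RECORD_SIZE)
                if len(raw) < take * RECORD_SIZE:
                    raise PsfTruncatedError(data_start + (header.record_count - remaining)
                                            * RECORD_SIZE + len(raw),
                                            f"{path}: unexpected end of data")
                crc = zlib.crc32(raw, crc)
                remaining -= take
                yield np.frombuffer(raw, dtype=RECORD_DTYPE)
            if crc != header.checksum:
                raise PsfChecksumError(
                    f"{path}: CRC mismatch (stored {header.checksum:#010x}, "
                    f"computed {crc:#010x})")
        finally:
            fh.close()

    return header, stream()


def read_psf_all(path) -> tuple[PsfHeader, PhotonBatch]:
    """Read an entire PSF into one :class:`PhotonBatch` (checksum verified)."""
    header, stream = read_psf(path)
    chunks = [PhotonBatch.from_records(rec) for rec in stream]
    if not chunks:
        empty = PhotonBatch(np.empty((0, 3)), np.empty((0, 3)), np.empty(0), np.empty(0))
        return header, empty
    return header, PhotonBatch.concatenate(chunks)


def inspect_psf(path) -> dict:
    """Streaming summary of a PSF: header metadata plus per-tag counts and
    energy statistics."""
    header, stream = read_psf(path)
    count = 0
    e_sum = 0.0
    e_min = np.inf
    e_max = -np.inf
    tag_counts = {name: 0 for name in TAG_NAMES.values()}
    for rec in stream:
        count += len(rec)
        if len(rec):
            e = rec["energy"].astype(float)
            w = rec["weight"].astype(float)
            e_sum += float((e * w).sum())
            e_min = min(e_min, float(e.min()))
            e_max = max(e_max, float(e.max()))
            _, surf = unpack_tag(rec["tag"])
            for code, name in TAG_NAMES.items():
                tag_counts[name] += int((surf == code).sum())
    return {
        "path": str(path),
        "version": header.version,
        "record_count": count,
        "angulation_deg": header.angulation_deg,
        "seed": header.seed,
        "beam": header.beam,
        "total_energy_kev": e_sum,
        "energy_min_kev": None if count == 0 else e_min,
        "energy_max_kev": None if count == 0 else e_max,
        "records_by_surface": tag_counts,
    }


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def make_fixture_psf(kind: str, params: dict, n: int, seed: int, path) -> PsfHeader:
    """Write a deterministic, analytically characterised fixture PSF.

    kinds
    -----
    ``pencil``
        ``n`` identical records; params: ``position``, ``direction``,
        ``energy`` (keV).
    ``isotropic_point``
        isotropic emitter at ``position`` with fixed ``energy``.
    ``ring``
        photons on a circle of ``radius`` around ``center`` in the plane
        normal to +z, pointing inward at the center; params: ``center``,
        ``radius``, ``energy``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    tag = TAG_CODES.get(params.get("surface_tag", "patient_table"), 0)
    if kind == "pencil":
        pos = np.tile(np.asarray(params["position"], dtype=float), (n, 1))
        d = np.asarray(params["direction"], dtype=float)
        d = d / np.linalg.norm(d)
        dirs = np.tile(d, (n, 1))
    elif kind == "isotropic_point":
        pos = np.tile(np.asarray(params["position"], dtype=float), (n, 1))
        mu = rng.uniform(-1.0, 1.0, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        s = np.sqrt(1.0 - mu**2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
    elif kind == "ring":
        center = np.asarray(params["center"], dtype=float)
        radius = float(params["radius"])
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        ring = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
        pos = center + radius * ring
        dirs = -ring
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    energies = np.full(n, float(params.get("energy", 80.0)))
    batch = PhotonBatch(pos, dirs, energies, np.ones(n),
                        np.full(n, tag, dtype=np.uint8))
    header = PsfHeader(angulation_deg=float(params.get("angulation_deg", 0.0)),
                       beam={"fixture": kind}, seed=seed)
    return write_psf(header, batch, path)
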
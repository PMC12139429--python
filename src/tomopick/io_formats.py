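"""File formats used by the template-matching pipeline.

Volumes travel as MRC2014 files, particle lists as STAR files, and tilt-series
metadata as the IMOD-style plain-text formats (``.tlt``/``.rawtlt`` tilt
angles, ``.defocus`` files, and one-accumulated-dose-per-line ``.txt`` files).

Axis convention
---------------
Volumes are stored in memory as ``(z, y, x)`` arrays with x fastest, matching
the MRC section ordering on disk, so no transpose happens at the I/O boundary.
All coordinates exposed to users (candidate positions, STAR columns) are
``(x, y, z)``.  Voxel coordinates are 0-based; a documented mode switch in
:func:`write_particle_star` selects corner-origin or center-origin output.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from gemmi import cif

__all__ = [
    "Volume",
    "TiltScheme",
    "CandidateRecord",
    "read_mrc",
    "write_mrc",
    "read_tilt_angles",
    "read_defocus_file",
    "read_dose_file",
    "write_particle_star",
    "read_particle_star",
]


class MrcParseError(ValueError):
    """Raised when a file cannot be interpreted as an MRC2014 volume."""


@dataclass
class Volume:
    """A 3D scalar grid with an isotropic voxel size in Angstrom.

    ``data`` is indexed ``(z, y, x)``.  ``origin`` is informational and is
    carried through MRC round-trips.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all volume dimensions must be >= 1, got {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TiltScheme:
    """Per-tilt geometry and optics of a tilt series.

    tilt_angles are in degrees and keep the order of the input file; defocus
    is in um per tilt (positive = underfocus); accumulated_dose is in e-/A^2
    per tilt.  voltage (keV), spherical_aberration (mm) and amplitude_contrast
    (unitless fraction) are global constants of the acquisition.
    """

    tilt_angles: list[float]
    defocus: list[float] | None = None
    accumulated_dose: list[float] | None = None
    voltage: float = 200.0
    spherical_aberration: float = 2.7
    amplitude_contrast: float = 0.08

    def __post_init__(self) -> None:
        self.tilt_angles = [float(a) for a in self.tilt_angles]
        n = len(self.tilt_angles)
        for a in self.tilt_angles:
            if not -90.0 < a < 90.0:
                raise ValueError(f"tilt angle {a} outside (-90, 90) degrees")
        for name in ("defocus", "accumulated_dose"):
            vals = getattr(self, name)
            if vals is not None:
                vals = [float(v) for v in vals]
                if len(vals) != n:
                    raise ValueError(
                        f"{name} has {len(vals)} entries but there are {n} tilt angles"
                    )
                setattr(self, name, vals)
        if self.accumulated_dose is not None and min(self.accumulated_dose) < 0:
            raise ValueError("accumulated dose values must be >= 0")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.tilt_angles)


@dataclass
class CandidateRecord:
    """One extracted particle: position, orientation, and its scores.

    position is (x, y, z) in 0-based voxel coordinates of the tomogram;
    orientation is an intrinsic-ZYZ Euler triplet in degrees (the RELION
    rot/tilt/psi convention); lcc is the LCC_max value at the peak and
    normalized_lcc is lcc divided by the tracked background sigma.
    """

    position: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lcc: float = 0.0
    tophat_value: float = 0.0
    normalized_lcc: float = 0.0

    def __post_init__(self) -> None:
        if not -1.05 <= self.lcc <= 1.05:
            raise ValueError(f"LCC value {self.lcc} outside [-1.05, 1.05]")
        if self.tophat_value < 0:
            raise ValueError(f"tophat value must be >= 0, got {self.tophat_value}")


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.dtype(np.int8), 1: np.dtype(np.int16), 2: np.dtype(np.float32),
              6: np.dtype(np.uint16)}
_HEADER_SIZE = 1024


def read_mrc(path: str | Path) -> Volume:
    """Read an MRC2014 volume (modes 0/1/2/6).

    The data array is returned as ``(z, y, x)`` float32.  The voxel size is
    taken from the header cell dimensions divided by the sampling grid; a zero
    cell triggers a warning and a default of 1.0 A.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MRC file not found: {path}")
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MrcParseError(
            f"{path}: file too short to contain an MRC header "
            f"({len(raw)} bytes < {_HEADER_SIZE})"
        )
    endian = "<"
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        # pre-2014 files may lack the MAP stamp; fall back to sanity checks
        pass
    nx, ny, nz, mode = struct.unpack(endian + "4i", raw[0:16])
    if not (0 < nx < 100000 and 0 < ny < 100000 and 0 < nz < 100000):
        # try big-endian (old SGI-era files)
        endian = ">"
        nx, ny, nz, mode = struct.unpack(endian + "4i", raw[0:16])
        if not (0 < nx < 100000 and 0 < ny < 100000 and 0 < nz < 100000):
            raise MrcParseError(f"{path}: implausible dimensions in MRC header")
    mx, my, mz = struct.unpack(endian + "3i", raw[28:40])
    cella = struct.unpack(endian + "3f", raw[40:52])
    mapc, mapr, maps = struct.unpack(endian + "3i", raw[64:76])
    ispg = struct.unpack(endian + "i", raw[88:92])[0]
    nsymbt = struct.unpack(endian + "i", raw[92:96])[0]
    origin = struct.unpack(endian + "3f", raw[196:208])

    if mode not in _MRC_MODES:
        raise MrcParseError(f"{path}: unsupported MRC mode {mode}")
    if ispg == 0 and nz > 1:
        raise MrcParseError(
            f"{path}: ISPG=0 with NZ={nz} marks an image stack, not a volume"
        )
    if (mapc, mapr, maps) != (1, 2, 3):
        raise MrcParseError(
            f"{path}: non-standard axis order MAPC/MAPR/MAPS = "
            f"{(mapc, mapr, maps)}; only (1, 2, 3) is supported"
        )

    dtype = _MRC_MODES[mode].newbyteorder(endian)
    count = nx * ny * nz
    data_start = _HEADER_SIZE + max(nsymbt, 0)
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=data_start)
    if data.size != count:
        raise MrcParseError(
            f"{path}: expected {count} voxels but file holds {data.size}"
        )
    data = data.reshape(nz, ny, nx).astype(np.float32)

    sizes = []
    for c, m in zip(cella, (mx, my, mz)):
        if m > 0 and c > 0:
            sizes.append(c / m)
    if not sizes:
        warnings.warn(f"{path}: zero voxel size in header, defaulting to 1.0 A")
        voxel_size = 1.0
    else:
        voxel_size = float(np.mean(sizes))
    return Volume(data=data, voxel_size=voxel_size, origin=tuple(origin))


def write_mrc(volume: Volume, path: str | Path) -> None:
    """Write a Volume as an MRC2014 mode-2 (float32) file."""
    path = Path(path)
    data = np.ascontiguousarray(volume.data, dtype=np.float32)
    nz, ny, nx = data.shape
    vs = float(volume.voxel_size)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)                     # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)      # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)               # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)                        # MAPC/R/S
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                               # ISPG volume
    struct.pack_into("<3f", header, 196, *volume.origin)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))                   # little-endian
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)                              # NLABL
    label = b"tomopick"
    header[224:224 + len(label)] = label
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# IMOD-style text metadata
# ---------------------------------------------------------------------------

def read_tilt_angles(path: str | Path) -> list[float]:
    """Read a ``.tlt``/``.rawtlt`` file: one tilt angle (degrees) per line."""
    path = Path(path)
    angles: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            angles.append(float(stripped))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno} is not a number: {stripped!r}"
            ) from None
    if not angles:
        raise ValueError(f"{path}: no tilt angles found (empty file)")
    return angles


def _numeric_fields(line: str) -> list[float] | None:
    parts = line.split()
    if not parts:
        return None
    try:
        return [float(p) for p in parts]
    except ValueError:
        return None


def read_defocus_file(path: str | Path, n_tilts: int | None = None) -> list[float]:
    """Read per-tilt defocus values, returned in um (positive = underfocus).

    Two dialects are auto-detected.  A line with >= 5 numeric fields selects
    the IMOD ctfplotter format, whose rows are ``view_start view_end
    angle_start angle_end defocus_nm [...]``; rows spanning several views are
    expanded and the result is ordered by view number.  Otherwise the file is
    read as a plain list with one defocus in nm per line.  A single-value file
    is broadcast to ``n_tilts`` entries when that count is given.
    """
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = _numeric_fields(line)
        if fields is None:
            raise ValueError(f"{path}: line {lineno} is not numeric: {line.strip()!r}")
        rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty defocus file")

    imod = any(len(r) >= 5 for r in rows)
    if imod:
        per_view: dict[int, float] = {}
        for r in rows:
            if len(r) < 5:
                raise ValueError(f"{path}: mixed defocus dialects in one file")
            v0, v1 = int(r[0]), int(r[1])
            for view in range(v0, v1 + 1):
                per_view[view] = r[4] / 1000.0  # nm -> um
        views = sorted(per_view)
        if views != list(range(views[0], views[0] + len(views))):
            raise ValueError(f"{path}: defocus rows leave gaps in the view range")
        values = [per_view[v] for v in views]
    else:
        values = [r[0] / 1000.0 for r in rows]

    if n_tilts is not None:
        if len(values) == 1:
            values = values * n_tilts
        elif len(values) != n_tilts:
            raise ValueError(
                f"{path}: {len(values)} defocus values for {n_tilts} tilt angles"
            )
    return values


def read_dose_file(path: str | Path, n_tilts: int | None = None) -> list[float]:
    """Read accumulated dose (e-/A^2), one value per line, tilt-file order.

    The values are *not* reordered: dose follows the acquisition sequence,
    which need not be monotonic in tilt angle.
    """
    path = Path(path)
    doses: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            value = float(stripped)
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno} is not a number: {stripped!r}"
            ) from None
        if value < 0:
            raise ValueError(f"{path}: negative dose {value} at line {lineno}")
        doses.append(value)
    if n_tilts is not None and len(doses) != n_tilts:
        raise ValueError(f"{path}: {len(doses)} dose values for {n_tilts} tilt angles")
    return doses


# ---------------------------------------------------------------------------
# STAR particle lists
# ---------------------------------------------------------------------------

_STAR_TAGS = [
    "_rlnCoordinateX",
    "_rlnCoordinateY",
    "_rlnCoordinateZ",
    "_rlnAngleRot",
    "_rlnAngleTilt",
    "_rlnAnglePsi",
    "_tmLCCmax",
    "_tmLCCmaxNormalized",
    "_tmTophat",
]


def write_particle_star(
    candidates: Sequence[CandidateRecord],
    path: str | Path,
    mode: str = "corner",
    tomogram_shape: tuple[int, int, int] | None = None,
    extra_columns: dict[str, Sequence] | None = None,
) -> None:
    """Write candidates as a RELION-3 style STAR particle list.

    Coordinates are 0-based voxel indices.  ``mode="corner"`` writes them
    relative to the tomogram corner (the internal convention);
    ``mode="center"`` subtracts ``dim // 2`` per axis so coordinates are
    relative to the tomogram center, which requires ``tomogram_shape`` as
    ``(nx, ny, nz)``.  Euler angles are intrinsic ZYZ in degrees in the RELION
    rot/tilt/psi columns.  An empty candidate list yields a valid zero-row
    file.
    """
    if mode not in ("corner", "center"):
        raise ValueError(f"mode must be 'corner' or 'center', got {mode!r}")
    shift = (0.0, 0.0, 0.0)
    if mode == "center":
        if tomogram_shape is None:
            raise ValueError("center mode requires tomogram_shape=(nx, ny, nz)")
        shift = tuple(float(d // 2) for d in tomogram_shape)

    doc = cif.Document()
    block = doc.add_new_block("particles")
    tags = list(_STAR_TAGS)
    extras = extra_columns or {}
    for name in extras:
        tags.append(name if name.startswith("_") else "_" + name)
    loop = block.init_loop("", tags)
    for i, c in enumerate(candidates):
        row = [
            f"{c.position[0] - shift[0]:.6f}",
            f"{c.position[1] - shift[1]:.6f}",
            f"{c.position[2] - shift[2]:.6f}",
            f"{c.orientation[0]:.6f}",
            f"{c.orientation[1]:.6f}",
            f"{c.orientation[2]:.6f}",
            f"{c.lcc:.8g}",
            f"{c.normalized_lcc:.8g}",
            f"{c.tophat_value:.8g}",
        ]
        for vals in extras.values():
            row.append(str(vals[i]))
        loop.add_row(row)
    Path(path).write_text(doc.as_string())


def read_particle_star(
    path: str | Path,
    mode: str = "corner",
    tomogram_shape: tuple[int, int, int] | None = None,
) -> list[CandidateRecord]:
    """Parse a STAR particle list written by :func:`write_particle_star`."""
    if mode not in ("corner", "center"):
        raise ValueError(f"mode must be 'corner' or 'center', got {mode!r}")
    shift = (0.0, 0.0, 0.0)
    if mode == "center":
        if tomogram_shape is None:
            raise ValueError("center mode requires tomogram_shape=(nx, ny, nz)")
        shift = tuple(float(d // 2) for d in tomogram_shape)
    doc = cif.read_file(str(path))
    block = doc.sole_block()
    cols = {tag: list(block.find_loop(tag)) for tag in _STAR_TAGS}
    n = len(cols["_rlnCoordinateX"])
    records = []
    for i in range(n):
        records.append(
            CandidateRecord(
                position=(
                    float(cols["_rlnCoordinateX"][i]) + shift[0],
                    float(cols["_rlnCoordinateY"][i]) + shift[1],
                    float(cols["_rlnCoordinateZ"][i]) + shift[2],
                ),
                orientation=(
                    float(cols["_rlnAngleRot"][i]),
                    float(cols["_rlnAngleTilt"][i]),
                    float(cols["_rlnAnglePsi"][i]),
                ),
                lcc=float(cols["_tmLCCmax"][i]),
                normalized_lcc=float(cols["_tmLCCmaxNormalized"][i]),
                tophat_value=float(cols["_tmTophat"][i]),
            )
        )
    return records
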
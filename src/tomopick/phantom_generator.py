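"""Synthetic tomograms with known ground truth.

The phantoms reproduce the statistical structure template matching has to
cope with: weak-contrast particles at random positions and orientations,
strongly scattering spherical decoys (stand-ins for gold fiducials, which
produce extended patches of high score), missing-wedge filtering of the
signal, and additive Gaussian noise.  Everything is deterministic under the
spec's seed, so end-to-end pipeline behavior can be asserted in tests.

Decoys are hard-edged spheres rather than template-shaped objects: their
score-map response is an extended patch, the failure mode the tophat
constraint targets.  Orientations are drawn from a fine uniform rotation set
(10 degree increment) rather than Haar-random matrices, so every ground-truth
orientation is exactly representable in a search set of that increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .angular_search import generate_rotation_set, rotate_volume
from .io_formats import Volume
from .psf_models import wedge_mask

__all__ = [
    "PhantomSpec",
    "GroundTruthEntry",
    "GroundTruth",
    "default_template",
    "insert_density",
    "generate_phantom",
]

#: increment (degrees) of the uniform set ground-truth orientations come from
ORIENTATION_POOL_INCREMENT = 10.0


def default_template(box_size: int = 16, voxel_size: float = 10.0) -> Volume:
    """An asymmetric multi-lobe blob emulating a structured macromolecule.

    Four Gaussian lobes (sigma 1.6-2.2 voxels) at fixed asymmetric offsets
    within ~4 voxels of the center, peak-normalized to 1.  The lobes give the
    autocorrelation a sharp apex, as for a real particle matched at 20-30 A
    resolution, while the envelope (~10 voxels across) stays comfortably
    inside the box under rotation.
    """
    c = box_size // 2
    grid = np.arange(box_size, dtype=np.float64)
    z, y, x = np.meshgrid(grid, grid, grid, indexing="ij")
    lobes = [
        # (dx, dy, dz, sigma, amplitude) — deliberately C1-asymmetric
        (0.0, 0.0, 0.0, 2.2, 1.0),
        (3.2, 0.8, -0.5, 1.8, 0.8),
        (-1.5, 2.8, 1.2, 1.6, 0.7),
        (-0.8, -2.2, -2.6, 1.7, 0.6),
    ]
    data = np.zeros_like(x)
    for dx, dy, dz, s, a in lobes:
        d2 = (x - c - dx) ** 2 + (y - c - dy) ** 2 + (z - c - dz) ** 2
        data += a * np.exp(-d2 / (2.0 * s * s))
    data /= data.max()
    return Volume(data=data.astype(np.float32), voxel_size=voxel_size)


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic tomogram.

    ``shape`` is the tomogram (z, y, x) shape in voxels; ``noise_sigma`` is
    the additive Gaussian noise level as a fraction of the particle peak;
    ``decoy_contrast`` multiplies the particle peak to set the decoy
    amplitude; ``wedge`` is the (min_tilt, max_tilt) range in degrees used to
    missing-wedge filter the assembled signal, or None for no filtering.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 10.0
    template: Volume | None = None
    n_particles: int = 20
    n_decoys: int = 5
    decoy_radius: float = 5.0
    decoy_contrast: float = 8.0
    noise_sigma: float = 0.5
    wedge: tuple[float, float] | None = (-60.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = default_template(voxel_size=self.voxel_size)
        if self.decoy_contrast < 1.0:
            raise ValueError("decoy_contrast must be >= 1")
        if self.n_particles < 0 or self.n_decoys < 0:
            raise ValueError("object counts must be >= 0")


@dataclass
class GroundTruthEntry:
    position: tuple[int, int, int]          # (x, y, z) voxels
    orientation: tuple[float, float, float]  # (rot, tilt, psi) degrees
    label: str                               # "particle" or "decoy"


@dataclass
class GroundTruth:
    entries: list[GroundTruthEntry] = field(default_factory=list)

    def positions(self, label: str | None = None) -> np.ndarray:
        sel = [e.position for e in self.entries
               if label is None or e.label == label]
        return np.asarray(sel, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.entries)


def insert_density(canvas: Volume, obj: Volume,
                   position: tuple[int, int, int],
                   orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
                   ) -> Volume:
    """Add a rotated object into the canvas, centered at position (x, y, z).

    The canvas is modified in place and returned; voxels outside the object
    box are unchanged.  Raises if the object box does not fit at the
    requested position.
    """
    rotated = rotate_volume(np.asarray(obj.data, dtype=np.float64), orientation)
    box = rotated.shape[0]
    c = box // 2
    x, y, z = (int(round(p)) for p in position)
    starts = (z - c, y - c, x - c)
    for s, dim in zip(starts, canvas.data.shape):
        if s < 0 or s + box > dim:
            raise ValueError(
                f"object of box {box} at position {position} does not fit in "
                f"canvas of shape {canvas.data.shape}"
            )
    sl = tuple(slice(s, s + box) for s in starts)
    canvas.data[sl] += rotated.astype(canvas.data.dtype)
    return canvas


def _solid_sphere(radius: float, amplitude: float) -> Volume:
    box = 2 * int(math.ceil(radius)) + 3
    c = box // 2
    g = np.arange(box, dtype=np.float64) - c
    d = np.sqrt(g[:, None, None] ** 2 + g[None, :, None] ** 2
                + g[None, None, :] ** 2)
    return Volume(data=(amplitude * (d <= radius)).astype(np.float32))


def _draw_positions(rng: np.random.Generator, n: int, shape: tuple[int, int, int],
                    margin: int, min_separation: float,
                    existing: list[tuple[int, int, int]],
                    max_tries: int = 10000) -> list[tuple[int, int, int]]:
    placed: list[tuple[int, int, int]] = []
    all_pts = [np.asarray(p, dtype=np.float64) for p in existing]
    tries = 0
    nz, ny, nx = shape
    while len(placed) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} objects without overlap after "
                f"{max_tries} tries; enlarge the box or reduce the counts"
            )
        tries += 1
        pos = (
            int(rng.integers(margin, nx - margin)),
            int(rng.integers(margin, ny - margin)),
            int(rng.integers(margin, nz - margin)),
        )
        p = np.asarray(pos, dtype=np.float64)
        if all(np.linalg.norm(p - q) >= min_separation for q in all_pts):
            placed.append(pos)
            all_pts.append(p)
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Build a synthetic tomogram and its ground-truth object list.

    Particles are the template rotated to random orientations from a uniform
    10-degree rotation set and inserted additively at random non-overlapping
    positions (no two object centers closer than one template box, all
    centers at least half a box from the edges).  Decoys are solid spheres
    with amplitude decoy_contrast x particle peak.  The assembled signal is
    missing-wedge filtered in Fourier space, then Gaussian noise of
    noise_sigma x particle peak is added.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    tbox = template.data.shape[0]
    peak = float(template.data.max())
    margin = max(tbox // 2 + 1, int(math.ceil(spec.decoy_radius)) + 2)
    min_sep = float(tbox)

    canvas = Volume(
        data=np.zeros(spec.shape, dtype=np.float32),
        voxel_size=spec.voxel_size,
    )
    truth = GroundTruth()

    pool = generate_rotation_set(ORIENTATION_POOL_INCREMENT).triplets
    particle_pos = _draw_positions(rng, spec.n_particles, spec.shape, margin,
                                   min_sep, [])
    for pos in particle_pos:
        trip = tuple(float(v) for v in pool[int(rng.integers(len(pool)))])
        insert_density(canvas, template, pos, trip)
        truth.entries.append(GroundTruthEntry(pos, trip, "particle"))

    decoy = _solid_sphere(spec.decoy_radius, spec.decoy_contrast * peak)
    decoy_pos = _draw_positions(rng, spec.n_decoys, spec.shape, margin, min_sep,
                                particle_pos)
    for pos in decoy_pos:
        insert_density(canvas, decoy, pos, (0.0, 0.0, 0.0))
        truth.entries.append(GroundTruthEntry(pos, (0.0, 0.0, 0.0), "decoy"))

    if spec.wedge is not None:
        mask = wedge_mask(spec.shape, spec.wedge[0], spec.wedge[1],
                          spec.voxel_size, rfft=True)
        filtered = sfft.irfftn(sfft.rfftn(canvas.data.astype(np.float64)) * mask,
                               s=spec.shape)
        canvas.data = filtered.astype(np.float32)

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma * peak, size=spec.shape)
        canvas.data = (canvas.data + noise).astype(np.float32)
    return canvas, truth
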
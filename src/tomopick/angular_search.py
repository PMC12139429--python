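"""Uniform orientation sampling and volume rotation.

The rotational search is the cartesian product of quasi-uniform directions on
the sphere with uniformly spaced in-plane angles.  Sphere directions are
HEALPix RING-scheme pixel centers, computed directly from the closed-form
ring equations (12 * nside^2 equal-area pixels), which permits any positive
nside.  The angular increment follows the Crowther criterion: neighboring
projections of a particle of diameter D overlap up to frequency q when the
increment is at most 1/(D*q) radians.

Euler angles are intrinsic ZYZ (rot, tilt, psi) in degrees, matching the
RELION angle columns written by the STAR output: a HEALPix center at
colatitude theta and longitude phi maps to (rot=phi, tilt=theta), and psi
runs over ceil(360/increment) uniform steps starting at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RotationSet",
    "crowther_increment",
    "healpix_ring_centers",
    "generate_rotation_set",
    "euler_to_matrix",
    "rotate_volume",
]


@dataclass
class RotationSet:
    """An orientation search set.

    ``triplets`` is an (n, 3) float array of (rot, tilt, psi) in degrees;
    ``increment`` is the angular step that generated it; n = n_sphere *
    n_inplane.
    """

    triplets: np.ndarray
    increment: float
    n_sphere: int
    n_inplane: int

    def __post_init__(self) -> None:
        self.triplets = np.asarray(self.triplets, dtype=np.float64).reshape(-1, 3)
        if len(self.triplets) != self.n_sphere * self.n_inplane:
            raise ValueError("triplet count must equal n_sphere * n_inplane")

    def __len__(self) -> int:
        return len(self.triplets)


def crowther_increment(diameter: float, max_freq: float) -> float:
    """Angular increment (degrees) from the Crowther criterion.

    ``diameter`` is the particle diameter in Angstrom and ``max_freq`` the
    highest frequency used in the search (cycles/A) — the Nyquist frequency
    of the tomogram or, if a low-pass filter is applied, the cut-off.
    """
    if diameter <= 0:
        raise ValueError("particle diameter must be positive")
    if max_freq <= 0:
        raise ValueError("max_freq must be positive")
    return math.degrees(1.0 / (diameter * max_freq))


def healpix_ring_centers(nside: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center (theta, phi) in radians for the RING scheme, in RING order.

    Rings are indexed from the north pole.  The polar caps hold rings with 4i
    pixels at z = 1 - i^2/(3 nside^2); the equatorial belt has 2*nside + 1
    rings of 4*nside pixels at z = 4/3 - 2i/(3 nside), with alternating
    longitude offsets.  Total pixel count is 12 * nside^2.
    """
    if nside < 1:
        raise ValueError("nside must be >= 1")
    thetas: list[np.ndarray] = []
    phis: list[np.ndarray] = []
    # north polar cap
    for i in range(1, nside):
        z = 1.0 - i * i / (3.0 * nside * nside)
        j = np.arange(1, 4 * i + 1)
        thetas.append(np.full(4 * i, math.acos(z)))
        phis.append(math.pi / (2 * i) * (j - 0.5))
    # equatorial belt
    for i in range(nside, 3 * nside + 1):
        z = 4.0 / 3.0 - 2.0 * i / (3.0 * nside)
        s = (i - nside + 1) % 2
        j = np.arange(1, 4 * nside + 1)
        thetas.append(np.full(4 * nside, math.acos(z)))
        phis.append(math.pi / (2 * nside) * (j - s / 2.0))
    # south polar cap (mirror of the north, moving toward the pole)
    for i in range(nside - 1, 0, -1):
        z = -(1.0 - i * i / (3.0 * nside * nside))
        j = np.arange(1, 4 * i + 1)
        thetas.append(np.full(4 * i, math.acos(z)))
        phis.append(math.pi / (2 * i) * (j - 0.5))

    theta = np.concatenate(thetas)
    phi = np.mod(np.concatenate(phis), 2 * math.pi)
    assert theta.size == 12 * nside * nside
    return theta, phi


def generate_rotation_set(increment: float) -> RotationSet:
    """Build the search set for a given angular increment (degrees).

    nside is the smallest positive integer whose mean HEALPix pixel spacing
    sqrt(pi/3)/nside does not exceed the increment; in-plane angles are
    ceil(360/increment) uniform psi steps starting at 0.  At 7 degrees this
    yields nside 9 (972 sphere pixels) x 52 psi = 50,544 orientations.
    """
    if not 0 < increment <= 180:
        raise ValueError(f"increment must be in (0, 180] degrees, got {increment}")
    inc_rad = math.radians(increment)
    nside = max(1, math.ceil(math.sqrt(math.pi / 3.0) / inc_rad))
    theta, phi = healpix_ring_centers(nside)
    n_sphere = theta.size
    n_inplane = math.ceil(360.0 / increment)
    psi = np.arange(n_inplane) * (360.0 / n_inplane)

    rot = np.degrees(phi)
    tilt = np.degrees(theta)
    triplets = np.empty((n_sphere * n_inplane, 3), dtype=np.float64)
    triplets[:, 0] = np.repeat(rot, n_inplane)
    triplets[:, 1] = np.repeat(tilt, n_inplane)
    triplets[:, 2] = np.tile(psi, n_sphere)
    return RotationSet(triplets=triplets, increment=float(increment),
                       n_sphere=int(n_sphere), n_inplane=int(n_inplane))


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix (acting on (x, y, z) column vectors) for intrinsic ZYZ."""
    a, b, c = (math.radians(v) for v in (rot, tilt, psi))

    def rz(t: float) -> np.ndarray:
        return np.array([
            [math.cos(t), -math.sin(t), 0.0],
            [math.sin(t), math.cos(t), 0.0],
            [0.0, 0.0, 1.0],
        ])

    ry = np.array([
        [math.cos(b), 0.0, math.sin(b)],
        [0.0, 1.0, 0.0],
        [-math.sin(b), 0.0, math.cos(b)],
    ])
    return rz(a) @ ry @ rz(c)


def rotate_volume(volume: np.ndarray, euler: tuple[float, float, float],
                  order: int = 1) -> np.ndarray:
    """Rotate a cubic volume about its center voxel (box_size // 2 per axis).

    The volume is resampled under the inverse rotation with trilinear
    interpolation by default (``order=1``); samples falling outside the box
    are set to 0.  Arrays are indexed (z, y, x); the Euler triplet acts on
    (x, y, z) vectors.
    """
    data = np.asarray(volume)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError(f"rotate_volume needs a cubic volume, got {data.shape}")
    if all(abs(a) < 1e-12 for a in euler):
        return data.copy()
    r = euler_to_matrix(*euler)
    inv_xyz = r.T
    # convert the (x, y, z) map to the (z, y, x) index convention
    inv_zyx = inv_xyz[::-1, ::-1]
    center = np.array([data.shape[0] // 2] * 3, dtype=np.float64)
    offset = center - inv_zyx @ center
    return ndimage.affine_transform(
        data, inv_zyx, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=order > 1,
    )
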
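"""Fourier-space template weights: 3D-CTF models and the whitening filter.

The template in the locally normalized cross-correlation is convolved with a
weighting function ``W`` that models the tomographic point spread function.
Two models are provided:

* a *tilt-weighted* PSF, assembled by rotating per-tilt 2D dose-weighted CTFs
  into 3D Fourier space (each tilt contributes a central section, weighted by
  the cosine of its tilt angle, a dose-dependent B-factor damping of
  -4 A^2 per e-/A^2, and a linear overlap ramp perpendicular to the tilt
  axis);
* a *binary wedge*, 1 inside the Fourier double wedge sampled by the tilt
  range and 0 inside the missing wedge, optionally multiplied with a single
  radial CTF.

A spectral whitening filter (reciprocal square root of the radially averaged
power spectrum, normalized to a maximum of one) can be applied to tomograms
as preprocessing and multiplied into template weights.

All frequencies are in cycles/Angstrom; Nyquist is 1/(2 * voxel_size).
Weight grids are full-spectrum arrays in numpy's unshifted FFT layout,
indexed (z, y, x) like the volumes they filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .io_formats import TiltScheme, Volume

__all__ = [
    "CTFParams",
    "FourierWeight",
    "RadialProfile",
    "ctf_2d",
    "dose_weight",
    "tilt_weighted_psf",
    "binary_wedge_psf",
    "wedge_mask",
    "whitening_profile",
    "apply_whitening",
]


@dataclass
class CTFParams:
    """Microscope parameters of a single contrast transfer function.

    defocus in um (positive = underfocus), voltage in keV,
    spherical_aberration in mm, amplitude_contrast as a fraction.  With
    ``phase_flip`` the absolute value |CTF| is returned, matching tomograms
    reconstructed from phase-flipped tilt series.
    """

    defocus: float
    voltage: float = 200.0
    spherical_aberration: float = 2.7
    amplitude_contrast: float = 0.08
    phase_flip: bool = False

    def __post_init__(self) -> None:
        if not self.voltage > 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass
class FourierWeight:
    """A 3D Fourier-space weight for a cubic box.

    ``grid`` has shape (box_size,)*3 in unshifted FFT layout; values are in
    [-1, 1].  ``kind`` is one of tilt_weighted / binary_wedge / whitening /
    composite.
    """

    grid: np.ndarray
    box_size: int
    voxel_size: float
    kind: str

    def __post_init__(self) -> None:
        if self.grid.shape != (self.box_size,) * 3:
            raise ValueError(
                f"weight grid shape {self.grid.shape} does not match box "
                f"size {self.box_size}"
            )
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("weight grid contains non-finite values")
        if np.max(np.abs(self.grid)) > 1.0 + 1e-6:
            raise ValueError("weight grid values must lie in [-1, 1]")


@dataclass
class RadialProfile:
    """A 1D radial Fourier filter sampled at multiples of ``freq_step``.

    values[s] is the filter at frequency s * freq_step (cycles/A); beyond the
    last shell the edge value is used.
    """

    values: np.ndarray
    freq_step: float


def electron_wavelength(voltage_kev: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in keV."""
    v = voltage_kev * 1e3
    return 12.2643 / math.sqrt(v * (1.0 + 0.978476e-6 * v))


def ctf_2d(freq_grid: np.ndarray, params: CTFParams) -> np.ndarray:
    """Evaluate the CTF on an array of frequency magnitudes (cycles/A).

    CTF(q) = -[sqrt(1 - A^2) sin(chi) + A cos(chi)] with the phase aberration
    chi = pi*lambda*d*q^2 - (pi/2)*Cs*lambda^3*q^4 (d in A, underfocus
    positive), so CTF(0) = -A.  With ``params.phase_flip`` the absolute value
    is returned.
    """
    q = np.asarray(freq_grid, dtype=np.float64)
    lam = electron_wavelength(params.voltage)
    d = params.defocus * 1e4          # um -> A
    cs = params.spherical_aberration * 1e7  # mm -> A
    q2 = q * q
    chi = math.pi * lam * d * q2 - 0.5 * math.pi * cs * lam**3 * q2 * q2
    a = params.amplitude_contrast
    ctf = -(math.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))
    if params.phase_flip:
        ctf = np.abs(ctf)
    return ctf


def dose_weight(freq: np.ndarray | float, dose: float) -> np.ndarray | float:
    """Dose damping exp(-dose * q^2), i.e. exp(-B q^2 / 4) with B = 4*dose A^2."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return np.exp(-dose * np.square(np.asarray(freq, dtype=np.float64)))


def _fftfreqs(box_size: int, voxel_size: float) -> np.ndarray:
    return np.fft.fftfreq(box_size, d=voxel_size)


def tilt_weighted_psf(
    box_size: int,
    voxel_size: float,
    scheme: TiltScheme,
    *,
    phase_flip: bool = False,
    cosine_weighting: bool = True,
    ramp_weighting: bool = True,
) -> FourierWeight:
    """Assemble the tilt-weighted 3D PSF by depositing rotated 2D CTF planes.

    For each tilt j a 2D plane of samples CTF(q; defocus_j) * exp(-dose_j q^2)
    * cos(theta_j) * ramp_j is rotated by theta_j about the y (tilt) axis and
    deposited into the nearest 3D Fourier voxel, accumulating by summation;
    the final grid is clipped to [-1, 1].  The ramp for tilt j rises linearly
    with in-plane distance from the tilt axis, reaching 1 at the overlap
    frequency 1/(box_size * voxel_size * sin(dtheta_j)) where dtheta_j is the
    angular distance to the nearest neighboring tilt.

    ``cosine_weighting`` and ``ramp_weighting`` exist so degenerate schemes
    (e.g. a single synthetic tilt, for which the ramp is undefined) can be
    built for validation.
    """
    if scheme.defocus is None or scheme.accumulated_dose is None:
        raise ValueError("tilt-weighted PSF needs per-tilt defocus and dose")
    n_tilts = len(scheme)
    if ramp_weighting and n_tilts < 2:
        raise ValueError("overlap ramp needs at least 2 tilts")

    freqs = _fftfreqs(box_size, voxel_size)
    u = freqs[np.newaxis, :]   # in-plane, perpendicular to the tilt axis
    v = freqs[:, np.newaxis]   # along the tilt (y) axis
    q = np.hypot(u, v)
    df = 1.0 / (box_size * voxel_size)

    angles = np.asarray(scheme.tilt_angles, dtype=np.float64)
    if ramp_weighting:
        order = np.argsort(angles)
        sorted_angles = angles[order]
        gaps = np.diff(sorted_angles)
        nearest = np.empty(n_tilts)
        for rank, idx in enumerate(order):
            cands = []
            if rank > 0:
                cands.append(gaps[rank - 1])
            if rank < n_tilts - 1:
                cands.append(gaps[rank])
            nearest[idx] = min(cands)

    grid = np.zeros((box_size,) * 3, dtype=np.float64)
    ky_idx = np.rint(v / df).astype(np.int64) % box_size
    ky_idx = np.broadcast_to(ky_idx, q.shape)
    for j in range(n_tilts):
        theta = math.radians(angles[j])
        params = CTFParams(
            defocus=scheme.defocus[j],
            voltage=scheme.voltage,
            spherical_aberration=scheme.spherical_aberration,
            amplitude_contrast=scheme.amplitude_contrast,
            phase_flip=phase_flip,
        )
        plane = ctf_2d(q, params) * dose_weight(q, scheme.accumulated_dose[j])
        if cosine_weighting:
            plane = plane * math.cos(theta)
        if ramp_weighting:
            g_star = 1.0 / (box_size * voxel_size * math.sin(math.radians(nearest[j])))
            plane = plane * np.minimum(1.0, np.abs(u) / g_star)
        fx = u * math.cos(theta)
        fz = u * math.sin(theta)
        kx = np.broadcast_to(np.rint(fx / df).astype(np.int64) % box_size, q.shape)
        kz = np.broadcast_to(np.rint(fz / df).astype(np.int64) % box_size, q.shape)
        np.add.at(grid, (kz.ravel(), ky_idx.ravel(), kx.ravel()), plane.ravel())
    np.clip(grid, -1.0, 1.0, out=grid)
    return FourierWeight(grid=grid, box_size=box_size, voxel_size=voxel_size,
                         kind="tilt_weighted")


def wedge_mask(
    shape: tuple[int, ...],
    min_tilt: float,
    max_tilt: float,
    voxel_size: float = 1.0,
    rfft: bool = False,
) -> np.ndarray:
    """Binary mask of the Fourier region sampled by tilts in [min_tilt, max_tilt].

    ``shape`` is the real-space (z, y, x) shape; the returned mask covers the
    full spectrum, or the half-spectrum rfft layout when ``rfft`` is set.  The
    tilt axis is y; a voxel is sampled when the angle of its (q_x, q_z)
    component, folded to (-90, 90] degrees, lies within the tilt range.  The
    q_x = q_z = 0 line (the tilt axis) is always sampled.
    """
    if not min_tilt < max_tilt:
        raise ValueError(f"need min_tilt < max_tilt, got {min_tilt}, {max_tilt}")
    nz, ny, nx = shape
    fz = np.fft.fftfreq(nz, d=voxel_size)[:, None, None]
    fx_1d = np.fft.rfftfreq(nx, d=voxel_size) if rfft else np.fft.fftfreq(nx, d=voxel_size)
    fx = fx_1d[None, None, :]
    ang = np.degrees(np.arctan2(fz, fx))
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    mask = (ang >= min_tilt) & (ang <= max_tilt)
    mask |= (fz == 0) & (fx == 0)
    ny_axis = np.ones((1, ny, 1), dtype=bool)
    return (mask & ny_axis).astype(np.float64)


def binary_wedge_psf(
    box_size: int,
    voxel_size: float,
    min_tilt: float,
    max_tilt: float,
    params: CTFParams | None = None,
) -> FourierWeight:
    """Binary missing-wedge weight, optionally times a single radial CTF.

    The defocus for the single CTF should correspond to the first collected
    tilt image, which carries the least accumulated damage.
    """
    mask = wedge_mask((box_size,) * 3, min_tilt, max_tilt, voxel_size)
    if params is not None:
        freqs = _fftfreqs(box_size, voxel_size)
        q = np.sqrt(
            freqs[:, None, None] ** 2 + freqs[None, :, None] ** 2
            + freqs[None, None, :] ** 2
        )
        mask = mask * ctf_2d(q, params)
    return FourierWeight(grid=mask, box_size=box_size, voxel_size=voxel_size,
                         kind="binary_wedge")


# ---------------------------------------------------------------------------
# Whitening
# ---------------------------------------------------------------------------

def _radial_shells(shape: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Integer shell index per Fourier voxel (full spectrum) and shell count.

    Shells are multiples of the finest frequency step 1/(N_max * voxel), with
    N_max the largest dimension, so cubic volumes get the familiar
    integer-radius shells up to Nyquist.
    """
    n_max = max(shape)
    grids = [np.fft.fftfreq(n) * n_max for n in shape]
    r = np.sqrt(
        grids[0][:, None, None] ** 2 + grids[1][None, :, None] ** 2
        + grids[2][None, None, :] ** 2
    )
    shells = np.rint(r).astype(np.int64)
    return shells, n_max // 2 + 1


def whitening_profile(tomogram: Volume) -> RadialProfile:
    """1D whitening filter from the tomogram's radial power spectrum.

    The power spectrum |FFT|^2 is averaged over integer-radius shells up to
    Nyquist; the filter is 1/sqrt(PSD) per shell, rescaled to a maximum of
    one.  Shells with zero power get filter value 0.
    """
    data = np.asarray(tomogram.data, dtype=np.float64)
    if not np.any(data):
        raise ValueError("whitening profile of an all-zero tomogram is undefined")
    power = np.abs(sfft.fftn(data)) ** 2
    shells, n_shells = _radial_shells(data.shape)
    flat = shells.ravel()
    keep = flat < n_shells
    counts = np.bincount(flat[keep], minlength=n_shells)
    sums = np.bincount(flat[keep], weights=power.ravel()[keep], minlength=n_shells)
    psd = np.divide(sums, counts, out=np.zeros(n_shells), where=counts > 0)
    values = np.divide(1.0, np.sqrt(psd), out=np.zeros(n_shells), where=psd > 0)
    values /= values.max()
    freq_step = 1.0 / (max(data.shape) * tomogram.voxel_size)
    return RadialProfile(values=values, freq_step=freq_step)


def _profile_on_grid(profile: RadialProfile, shape: tuple[int, ...],
                     voxel_size: float) -> np.ndarray:
    grids = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    q = np.sqrt(
        grids[0][:, None, None] ** 2 + grids[1][None, :, None] ** 2
        + grids[2][None, None, :] ** 2
    )
    shell_freqs = np.arange(profile.values.size) * profile.freq_step
    return np.interp(q, shell_freqs, profile.values)


def apply_whitening(obj: Volume | FourierWeight, profile: RadialProfile):
    """Apply a whitening profile to a tomogram or multiply it into a weight.

    The 1D profile is linearly interpolated onto the object's 3D frequency-
    magnitude grid (physical units, so template and tomogram boxes may
    differ).  A Volume is filtered in Fourier space and returned as a real
    volume; a FourierWeight is multiplied element-wise, which preserves its
    zero set.
    """
    if isinstance(obj, FourierWeight):
        filt = _profile_on_grid(profile, obj.grid.shape, obj.voxel_size)
        return FourierWeight(grid=obj.grid * filt, box_size=obj.box_size,
                             voxel_size=obj.voxel_size, kind="composite")
    filt = _profile_on_grid(profile, obj.data.shape, obj.voxel_size)
    spectrum = sfft.fftn(np.asarray(obj.data, dtype=np.float64))
    filtered = sfft.ifftn(spectrum * filt).real
    return Volume(data=filtered.astype(np.float32), voxel_size=obj.voxel_size,
                  origin=obj.origin)
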
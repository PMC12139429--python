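"""Locally normalized cross-correlation over an exhaustive orientation search.

The score of a template T at position x and orientation v in tomogram V is

    LCC(x, v) = (1/P) * sum_i T'_v(i) * M_v(i) * V(i + x) / sigma_{M_v V}(x)

where T'_v is the rotated, PSF-weighted template normalized to zero mean and
unit variance under the rotated mask M_v, P is the sum of the mask values,
and sigma_{M_v V}(x) is the local standard deviation of the tomogram under
the mask centered at x.  The translational search is exhaustive via FFT
correlation; LCC_max keeps the per-voxel maximum over all orientations
together with the index of the best orientation.

The background standard deviation sigma is tracked during the search: after
each rotation the LCC values over the valid search region are squared and
accumulated, and sigma = sqrt(sum / N_total) with N_total = N_voxels *
N_rotations.  This assumes the background mean is zero and that background
voxels heavily outnumber true positives, and feeds the erfc-based extraction
threshold downstream.

Correlation uses periodic FFT convolution; voxels within half the template
box of the tomogram edge are excluded from the search region instead of
padding.  Volumes are processed in single precision with a double-precision
variance accumulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .angular_search import RotationSet, rotate_volume
from .io_formats import Volume
from .psf_models import FourierWeight

__all__ = [
    "PreparedTemplate",
    "ScoreResult",
    "make_spherical_mask",
    "prepare_template",
    "local_std_map",
    "run_template_matching",
    "phase_randomize_template",
    "run_with_phase_randomization",
]


@dataclass
class PreparedTemplate:
    """A template ready for the rotation loop.

    ``data`` is the identity-orientation product: PSF-filtered, mask-
    multiplied, zero-mean and unit-variance under the mask.  ``template`` and
    ``mask`` are the raw inputs re-processed for every rotation; ``weight``
    is the Fourier weight applied after rotation (the PSF lives in the
    tomogram frame).  P is the sum of the mask values.
    """

    data: np.ndarray
    template: np.ndarray
    mask: np.ndarray
    weight: FourierWeight | None
    P: float
    is_spherical_mask: bool
    voxel_size: float

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass
class ScoreResult:
    """Output of a template-matching run.

    ``lcc_max`` holds the per-voxel maximum LCC; ``best_rotation_index``
    indexes into the rotation set; ``sigma_background`` is the tracked
    standard deviation of the LCC over the search; ``n_total`` is the search-
    space size N_voxels * N_rotations; ``search_region`` is the (lo, hi)
    half-open bound per (z, y, x) axis of the valid voxels.
    """

    lcc_max: Volume
    best_rotation_index: np.ndarray
    sigma_background: float
    n_total: int
    search_region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def region_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.search_region)


def make_spherical_mask(box_size: int, radius: float,
                        smooth_sigma: float = 0.0,
                        voxel_size: float = 1.0) -> Volume:
    """Sphere of ones centered on box_size // 2, optional Gaussian falloff.

    With ``smooth_sigma`` > 0 the shell outside ``radius`` decays as
    exp(-(d - radius)^2 / (2 sigma^2)); values stay in [0, 1].
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if radius > box_size * math.sqrt(3):
        raise ValueError(f"radius {radius} too large for box {box_size}")
    c = box_size // 2
    grid = np.arange(box_size, dtype=np.float64) - c
    d = np.sqrt(grid[:, None, None] ** 2 + grid[None, :, None] ** 2
                + grid[None, None, :] ** 2)
    if smooth_sigma > 0:
        mask = np.where(
            d <= radius, 1.0,
            np.exp(-((d - radius) ** 2) / (2.0 * smooth_sigma ** 2)),
        )
        mask[mask < 1e-4] = 0.0
    else:
        mask = (d <= radius).astype(np.float64)
    return Volume(data=mask.astype(np.float32), voxel_size=voxel_size)


def _normalize_under_mask(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization under a mask; returns mask * t'."""
    p = float(mask.sum())
    if p <= 0:
        raise ValueError("mask sums to zero")
    mean = float((data * mask).sum()) / p
    var = float((np.square(data - mean) * mask).sum()) / p
    if var <= 1e-18:
        raise ValueError("template has zero variance under the mask")
    return mask * (data - mean) / math.sqrt(var)


def _apply_weight(data: np.ndarray, weight: FourierWeight | None) -> np.ndarray:
    if weight is None:
        return data
    if data.shape != weight.grid.shape:
        raise ValueError(
            f"weight built for box {weight.grid.shape}, template is {data.shape}"
        )
    return sfft.ifftn(sfft.fftn(data.astype(np.float64)) * weight.grid).real


def prepare_template(template: Volume, mask: Volume,
                     weight: FourierWeight | None = None,
                     spherical_mask: bool = True) -> PreparedTemplate:
    """Filter the template with the Fourier weight and normalize under the mask.

    The returned object carries the raw template and mask so the rotation
    loop can re-filter and re-normalize at each orientation; ``data`` is the
    identity-orientation result and satisfies |mean under mask| < 1e-6 and
    variance under mask within 1e-5 of 1.
    """
    t = np.asarray(template.data, dtype=np.float64)
    m = np.asarray(mask.data, dtype=np.float64)
    if t.shape != m.shape:
        raise ValueError(f"template {t.shape} and mask {m.shape} differ in shape")
    if t.ndim != 3 or len(set(t.shape)) != 1:
        raise ValueError(f"template must be cubic, got {t.shape}")
    filtered = _apply_weight(t, weight)
    data = _normalize_under_mask(filtered, m)
    return PreparedTemplate(
        data=data, template=t, mask=m, weight=weight, P=float(m.sum()),
        is_spherical_mask=spherical_mask, voxel_size=template.voxel_size,
    )


def _embed_centered(small: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Place a small box into a zero array with its center voxel at index 0.

    Index i of the small box maps to (i - box//2) mod N per axis, so periodic
    FFT correlation directly yields template-centered scores.
    """
    out = np.zeros(shape, dtype=np.float32)
    idx = [
        (np.arange(small.shape[a]) - small.shape[a] // 2) % shape[a]
        for a in range(3)
    ]
    out[np.ix_(*idx)] = small
    return out


def _padded_rfftn(small: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """rfftn of :func:`_embed_centered` without materializing the big array.

    The transform of a zero-padded array is built axis by axis, running full-
    length FFTs only over the rows that are nonzero, which saves most of the
    forward-transform cost when the template is much smaller than the
    tomogram.
    """
    b = small.shape
    c = [s // 2 for s in b]
    rolled = np.roll(small, shift=(-c[0], -c[1], -c[2]), axis=(0, 1, 2))
    # rolled block order is [c:, ...] then [:c, ...]; along each axis those
    # blocks sit at absolute indices [0, b-c) and [N-c, N).  Scatter the rows
    # to their absolute positions axis by axis, transforming only occupied
    # rows at full length.
    nz = [
        np.concatenate([np.arange(b[a] - c[a]),
                        shape[a] - np.arange(c[a], 0, -1)])
        for a in range(3)
    ]
    tmp2 = np.zeros((b[0], b[1], shape[2]), dtype=np.float32)
    tmp2[:, :, nz[2]] = rolled
    out = sfft.rfft(tmp2, axis=2)
    tmp1 = np.zeros((b[0], shape[1], out.shape[2]), dtype=out.dtype)
    tmp1[:, nz[1], :] = out
    tmp1 = sfft.fft(tmp1, axis=1)
    full = np.zeros((shape[0], shape[1], out.shape[2]), dtype=out.dtype)
    full[nz[0], :, :] = tmp1
    return sfft.fft(full, axis=0)


def local_std_map(tomogram: Volume | np.ndarray, mask: Volume | np.ndarray,
                  rotation: tuple[float, float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Local standard deviation of the tomogram under the (rotated) mask.

    sigma(x) = sqrt( (1/P) sum_i M(i) V(i+x)^2 - [(1/P) sum_i M(i) V(i+x)]^2 )

    computed with FFT convolutions of V and V^2 against the mask.  Negative
    variances from roundoff are clamped to zero.  Returns ``(sigma, valid)``:
    voxels whose local variance falls at or below the floor eps = 1e-10 *
    global variance are flagged invalid and their sigma set to sqrt(eps) (or
    to 1.0 when the tomogram is constant, purely to keep divisions finite).
    The relative floor masks the float roundoff of the two convolutions,
    which would otherwise turn flat regions into spurious huge scores.
    """
    v = np.asarray(tomogram.data if isinstance(tomogram, Volume) else tomogram,
                   dtype=np.float64)
    m = np.asarray(mask.data if isinstance(mask, Volume) else mask,
                   dtype=np.float64)
    if rotation is not None:
        m = rotate_volume(m, rotation)
    if any(ms > vs for ms, vs in zip(m.shape, v.shape)):
        raise ValueError(f"mask {m.shape} larger than tomogram {v.shape}")
    p = float(m.sum())
    if p <= 0:
        raise ValueError("mask sums to zero (P = 0)")
    mpad = _embed_centered(m.astype(np.float32), v.shape).astype(np.float64)
    fm = np.conj(sfft.rfftn(mpad))
    mean = sfft.irfftn(sfft.rfftn(v) * fm, s=v.shape) / p
    meansq = sfft.irfftn(sfft.rfftn(v * v) * fm, s=v.shape) / p
    var = meansq - mean * mean
    np.clip(var, 0.0, None, out=var)
    eps = 1e-10 * float(v.var())
    valid = var > eps
    sigma = np.sqrt(var)
    sigma[~valid] = math.sqrt(eps) if eps > 0 else 1.0
    return sigma, valid


def run_template_matching(
    tomogram: Volume,
    prepared: PreparedTemplate,
    rotations: RotationSet,
    *,
    recompute_std: bool = False,
) -> ScoreResult:
    """Exhaustive translational + rotational search of the template.

    For each orientation the raw template is rotated, filtered with the
    Fourier weight, renormalized under the (rotated, if non-spherical) mask,
    and correlated with the tomogram; the per-voxel maximum and best rotation
    index are kept and the squared LCC values accumulate into the variance
    tracker.  A spherical mask reuses one local standard-deviation map across
    rotations; ``recompute_std`` forces per-rotation recomputation for
    non-spherical masks.
    """
    if len(rotations) == 0:
        raise ValueError("empty rotation set")
    v32 = np.ascontiguousarray(tomogram.data, dtype=np.float32)
    shape = v32.shape
    box = prepared.box_size
    if any(box > s for s in shape):
        raise ValueError(f"template box {box} exceeds tomogram {shape}")
    margin = box // 2
    region = tuple((margin, s - margin) for s in shape)
    region_sl = tuple(slice(lo, hi) for lo, hi in region)
    n_region = int(np.prod([hi - lo for lo, hi in region]))
    if n_region <= 0:
        raise ValueError("tomogram too small: empty search region")
    n_total = n_region * len(rotations)

    fv = sfft.rfftn(v32)

    def inv_sigma_map(rotation=None) -> np.ndarray:
        sigma, valid = local_std_map(v32, prepared.mask, rotation)
        inv = np.zeros(shape, dtype=np.float32)
        sel = np.zeros(shape, dtype=bool)
        sel[region_sl] = True
        sel &= valid
        inv[sel] = 1.0 / (prepared.P * sigma[sel])
        return inv

    per_rotation_std = recompute_std and not prepared.is_spherical_mask
    inv = None if per_rotation_std else inv_sigma_map()

    best = np.full(shape, -np.inf, dtype=np.float32)
    best_idx = np.zeros(shape, dtype=np.int32)
    sumsq = 0.0
    identity_like = prepared.data.astype(np.float32)

    for r, trip in enumerate(rotations.triplets):
        if np.allclose(trip, 0.0):
            tn32 = identity_like
            inv_r = inv_sigma_map(None) if per_rotation_std else inv
        else:
            t = rotate_volume(prepared.template, tuple(trip))
            t = _apply_weight(t, prepared.weight)
            if prepared.is_spherical_mask:
                m = prepared.mask
            else:
                m = rotate_volume(prepared.mask, tuple(trip))
            tn32 = _normalize_under_mask(t, m).astype(np.float32)
            inv_r = inv_sigma_map(tuple(trip)) if per_rotation_std else inv
        ft = _padded_rfftn(tn32, shape)
        np.conj(ft, out=ft)
        ft *= fv
        lcc = sfft.irfftn(ft, s=shape)
        lcc *= inv_r
        flat = lcc.ravel()
        sumsq += float(np.einsum("i,i->", flat, flat, dtype=np.float64))
        upd = lcc > best
        np.copyto(best, lcc, where=upd)
        best_idx[upd] = r

    outside = np.ones(shape, dtype=bool)
    outside[region_sl] = False
    best[outside] = 0.0
    sigma_background = math.sqrt(sumsq / n_total)
    return ScoreResult(
        lcc_max=Volume(data=best, voxel_size=tomogram.voxel_size,
                       origin=tomogram.origin),
        best_rotation_index=best_idx,
        sigma_background=sigma_background,
        n_total=n_total,
        search_region=region,
    )


def phase_randomize_template(template: Volume, seed: int) -> Volume:
    """Decoy with the template's Fourier amplitudes but permuted phases.

    Phases of the independent half-spectrum (excluding DC and self-conjugate
    points) are permuted uniformly at random under ``seed``; Hermitian
    symmetry is enforced so the output is real.  The amplitude spectrum is
    preserved exactly.
    """
    data = np.asarray(template.data, dtype=np.float64)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError(f"phase randomization needs a cubic template, got {data.shape}")
    f = np.fft.fftn(data)
    shape = data.shape
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    flat_idx = np.ravel_multi_index([g.ravel() for g in grids], shape)
    conj_idx = np.ravel_multi_index(
        [(-g.ravel()) % n for g, n in zip(grids, shape)], shape
    )
    independent = flat_idx < conj_idx

    rng = np.random.default_rng(seed)
    phases = np.angle(f).ravel()
    amps = np.abs(f).ravel()
    ind = np.flatnonzero(independent)
    permuted = phases[ind][rng.permutation(ind.size)]
    new_phases = phases.copy()
    new_phases[ind] = permuted
    new_phases[conj_idx[ind]] = -permuted
    # self-conjugate coefficients (DC, Nyquist combinations) keep their phase
    out_f = (amps * np.exp(1j * new_phases)).reshape(shape)
    out = np.fft.ifftn(out_f).real
    return Volume(data=out.astype(np.float32), voxel_size=template.voxel_size,
                  origin=template.origin)


def run_with_phase_randomization(
    tomogram: Volume,
    prepared: PreparedTemplate,
    rotations: RotationSet,
    seed: int,
    *,
    recompute_std: bool = False,
) -> tuple[ScoreResult, ScoreResult]:
    """Background-normalized search using a phase-randomized decoy template.

    Runs two full searches — the original template and a phase-randomized
    decoy, both PSF-weighted and mask-normalized — and returns
    ``(corrected, original)`` where the corrected map is

        lcc_max - lcc_max_decoy + mean(lcc_max_decoy)

    with the mean taken over the search region to maintain the background
    statistics.  sigma_background and n_total come from the original search.
    """
    original = run_template_matching(tomogram, prepared, rotations,
                                     recompute_std=recompute_std)
    decoy_vol = phase_randomize_template(
        Volume(data=prepared.template.astype(np.float32),
               voxel_size=prepared.voxel_size),
        seed,
    )
    decoy_prep = prepare_template(
        decoy_vol,
        Volume(data=prepared.mask.astype(np.float32),
               voxel_size=prepared.voxel_size),
        weight=prepared.weight,
        spherical_mask=prepared.is_spherical_mask,
    )
    decoy = run_template_matching(tomogram, decoy_prep, rotations,
                                  recompute_std=recompute_std)
    sl = original.region_slices()
    corrected = original.lcc_max.data.astype(np.float64)
    decoy_map = decoy.lcc_max.data.astype(np.float64)
    corrected = corrected - decoy_map + float(decoy_map[sl].mean())
    out = np.zeros_like(corrected, dtype=np.float32)
    out[sl] = corrected[sl]
    result = ScoreResult(
        lcc_max=Volume(data=out, voxel_size=tomogram.voxel_size,
                       origin=tomogram.origin),
        best_rotation_index=original.best_rotation_index,
        sigma_background=original.sigma_background,
        n_total=original.n_total,
        search_region=original.search_region,
    )
    return result, original
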
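"""Dual-constraint particle extraction from score maps.

Two cut-offs gate the peaks of an LCC_max volume.  The *base* cut-off comes
from the tracked background statistics,

    tau = sigma * sqrt(2) * erfc^-1(2 * FP_ratio / N_total),

the value a zero-mean Gaussian background of standard deviation sigma exceeds
FP_ratio times over a search space of N_total samples; FP_ratio = 1 (the
default) allows a single false positive over the whole search.  The
*tophat* cut-off applies the same expression to the white tophat transform of
the score map — input minus its grayscale opening with a small binary
structuring element — whose background mean and standard deviation are
obtained by fitting a Gaussian to the left flank of the log-histogram of
nonzero tophat values.  Sharp correlation peaks survive the tophat transform;
the extended high-score patches produced by strongly scattering objects such
as gold fiducials do not.

Peaks are extracted from highest to lowest LCC while above the base cut-off,
zeroing a sphere of the exclusion radius around each peak; with the tophat
constraint enabled a peak is kept only when its tophat value also reaches the
tophat cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erfcinv

from .angular_search import RotationSet
from .io_formats import CandidateRecord
from .matching_engine import ScoreResult

__all__ = [
    "ThresholdSpec",
    "base_threshold",
    "tophat_transform",
    "fit_tophat_background",
    "extract_candidates",
]


@dataclass
class ThresholdSpec:
    """The cut-offs applied during extraction and how they were derived."""

    tau_base: float
    fp_ratio: float
    sigma: float
    n_total: int
    tau_tophat: float | None = None
    tophat_mu: float | None = None
    tophat_sigma: float | None = None
    fit_diagnostics: dict = field(default_factory=dict)


def base_threshold(sigma: float, n_total: float, fp_ratio: float = 1.0) -> float:
    """Score cut-off tau = sigma * sqrt(2) * erfc^-1(2 * fp_ratio / n_total).

    Increasing ``fp_ratio`` lowers the cut-off (more candidates); at
    fp_ratio = n_total / 2 the cut-off is exactly 0, the median of the
    background.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 < fp_ratio < n_total:
        raise ValueError(
            f"fp_ratio must be in (0, n_total); got {fp_ratio} with "
            f"n_total = {n_total}"
        )
    return float(sigma * math.sqrt(2.0) * erfcinv(2.0 * fp_ratio / n_total))


def tophat_transform(volume: np.ndarray, connectivity: int = 1) -> np.ndarray:
    """White tophat: input minus its grayscale opening.

    The structuring element is the 3D binary structure of the given
    connectivity (1 = 6-neighborhood cross, 2 = +edges, 3 = the full
    26-neighborhood cube).  The opening (erosion then dilation) is
    anti-extensive, so the output is >= 0 everywhere.
    """
    data = np.asarray(volume)
    if data.ndim != 3:
        raise ValueError(f"tophat transform needs a 3D volume, got {data.ndim}D")
    if connectivity not in (1, 2, 3):
        raise ValueError(f"connectivity must be 1, 2 or 3, got {connectivity}")
    footprint = ndimage.generate_binary_structure(3, connectivity)
    return ndimage.white_tophat(data, footprint=footprint)


def fit_tophat_background(
    tophat_volume: np.ndarray,
    n_bins: int = 50,
    full_output: bool = False,
):
    """Gaussian background parameters of a tophat-transformed score map.

    Nonzero tophat values are histogrammed over ``n_bins`` equal-width bins
    spanning up to min(1.5x their 99.9th percentile, median + 10 robust
    standard deviations) — the background heavily outnumbers true peaks, so
    this keeps the Gaussian bulk resolved even when peaks and patch edges
    carry tophat values orders of magnitude above it.
    The fit window is the left flank below the inflection point: the longest
    contiguous run of bins left of the histogram peak whose count second
    derivative is positive (minimum 3 bins; the curvature sign is taken on
    counts smoothed with a 5-bin moving average so Poisson noise cannot
    truncate the run).  A parabola is fitted to the natural log of the raw
    counts on that window, weighted by sqrt(count) (the Poisson weighting,
    which emphasizes well-populated bins), and the Gaussian (mu, sigma)
    follow from the parabola's vertex and curvature.  Restricting the fit to
    the left flank makes it robust to a right-tail population of true
    positives.
    """
    values = np.asarray(tophat_volume, dtype=np.float64).ravel()
    nonzero = values[values > 0]
    if nonzero.size < 1000:
        raise ValueError(
            f"need at least 1000 nonzero tophat voxels to fit a background, "
            f"got {nonzero.size}"
        )
    mad_sigma = 1.4826 * float(np.median(np.abs(nonzero - np.median(nonzero))))
    upper = min(1.5 * float(np.quantile(nonzero, 0.999)),
                float(np.median(nonzero)) + 10.0 * mad_sigma)
    counts, edges = np.histogram(nonzero, bins=n_bins, range=(0.0, upper))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    d2 = np.full(n_bins, np.nan)
    d2[1:-1] = smoothed[2:] - 2.0 * smoothed[1:-1] + smoothed[:-2]
    positive = d2 > 0
    # bridge single-bin interruptions so count noise cannot fragment the flank
    for i in range(1, n_bins - 1):
        if not positive[i] and positive[i - 1] and positive[i + 1]:
            positive[i] = True

    window = None
    i = 1
    while i < n_bins - 1:
        if positive[i]:
            j = i
            while j < n_bins - 1 and positive[j]:
                j += 1
            if j - i >= 3 and (counts[i:j] > 0).sum() >= 3:
                window = (i, j)
                break
            i = j
        else:
            i += 1
    if window is None:
        raise ValueError(
            "no positive-curvature flank of at least 3 populated bins; "
            "cannot fit a Gaussian background"
        )
    start, stop = window
    sel = slice(start, stop)
    x = centers[sel]
    y = counts[sel].astype(np.float64)
    keep = y > 0
    coeffs = np.polyfit(x[keep], np.log(y[keep]), 2, w=np.sqrt(y[keep]))
    if coeffs[0] >= 0:
        raise ValueError("log-histogram fit is not concave; no Gaussian background")
    mu = -coeffs[1] / (2.0 * coeffs[0])
    sigma = math.sqrt(-1.0 / (2.0 * coeffs[0]))
    if full_output:
        diagnostics = {
            "bin_centers": centers.tolist(),
            "counts": counts.tolist(),
            "fit_window": [int(start), int(stop)],
            "poly_coeffs": [float(c) for c in coeffs],
        }
        return float(mu), float(sigma), diagnostics
    return float(mu), float(sigma)


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    g = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(g, g, g, indexing="ij")
    inside = dz * dz + dy * dy + dx * dx <= radius * radius
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def extract_candidates(
    score: ScoreResult,
    rotations: RotationSet,
    radius: float,
    *,
    max_n: int | None = None,
    fp_ratio: float = 1.0,
    use_tophat: bool = False,
    connectivity: int = 1,
    n_bins: int = 50,
) -> tuple[list[CandidateRecord], ThresholdSpec]:
    """Extract particle candidates from a score map.

    Peaks are taken from highest to lowest LCC_max within the search region
    while they exceed the base cut-off, zeroing a sphere of ``radius`` voxels
    around each visited peak (Euclidean distance <= radius).  With
    ``use_tophat`` a peak is kept only if its tophat-transform value reaches
    the tophat cut-off; rejected peaks still claim their exclusion sphere.
    Stops after ``max_n`` kept candidates or when the maximum falls below the
    base cut-off.
    """
    if radius < 1:
        raise ValueError("exclusion radius must be >= 1 voxel")
    lcc_full = np.asarray(score.lcc_max.data, dtype=np.float32)
    sl = score.region_slices()

    tau_base = base_threshold(score.sigma_background, score.n_total, fp_ratio)
    spec = ThresholdSpec(tau_base=tau_base, fp_ratio=fp_ratio,
                         sigma=score.sigma_background, n_total=score.n_total)

    tophat_vol = None
    if use_tophat:
        tophat_vol = tophat_transform(lcc_full, connectivity)
        try:
            mu, sig, diag = fit_tophat_background(
                tophat_vol[sl], n_bins, full_output=True
            )
        except ValueError as exc:
            raise ValueError(
                f"tophat background fit failed ({exc}); rerun extraction "
                f"without the tophat constraint or adjust the bin count"
            ) from exc
        spec.tophat_mu = mu
        spec.tophat_sigma = sig
        spec.fit_diagnostics = diag
        spec.tau_tophat = mu + sig * math.sqrt(2.0) * erfcinv(
            2.0 * fp_ratio / score.n_total
        )

    work = np.full(lcc_full.shape, -np.inf, dtype=np.float32)
    work[sl] = lcc_full[sl]
    offsets = _sphere_offsets(radius)
    shape = work.shape
    candidates: list[CandidateRecord] = []

    while True:
        if max_n is not None and len(candidates) >= max_n:
            break
        flat = int(np.argmax(work))
        z, y, x = np.unravel_index(flat, shape)
        value = float(work[z, y, x])
        if not value > tau_base:
            break
        pts = offsets + np.array([z, y, x])
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        work[pts[:, 0], pts[:, 1], pts[:, 2]] = -np.inf
        if use_tophat and tophat_vol[z, y, x] < spec.tau_tophat:
            continue
        rot_idx = int(score.best_rotation_index[z, y, x])
        trip = tuple(float(v) for v in rotations.triplets[rot_idx])
        candidates.append(
            CandidateRecord(
                position=(float(x), float(y), float(z)),
                orientation=trip,
                lcc=value,
                tophat_value=float(tophat_vol[z, y, x]) if use_tophat else 0.0,
                normalized_lcc=value / score.sigma_background,
            )
        )
    return candidates, spec
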
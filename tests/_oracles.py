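"""Independent brute-force oracles used to validate the FFT/ndimage paths.

Everything here evaluates definitions literally (per-voxel loops, sliding
windows) and deliberately avoids the library's FFT correlation and scipy's
morphology, so agreement is a two-route check.
"""

from __future__ import annotations

import numpy as np

from tomopick.angular_search import rotate_volume
from tomopick.matching_engine import _apply_weight


def literal_lcc_map(
    tomogram: np.ndarray,
    template: np.ndarray,
    mask: np.ndarray,
    triplets,
    weight=None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Evaluate the locally normalized cross-correlation sum directly.

    For every rotation the template is rotated (same resampling as the
    engine), weighted, and the score at every interior voxel evaluated as

        (1/P) * sum_i (T(i) - Tbar) M(i) (V(i+x) - Vbar(x)) / (sigma_T sigma_MV(x))

    with all sums done per voxel in float64.  Returns (lcc_max, best_index,
    all_values) where all_values collects every LCC over rotations and
    interior voxels for variance-tracking checks.
    """
    v = np.asarray(tomogram, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    box = template.shape[0]
    c = box // 2
    p = m.sum()
    shape = v.shape

    best = np.full(shape, -np.inf)
    best_idx = np.zeros(shape, dtype=np.int64)
    values: list[float] = []
    for r, trip in enumerate(triplets):
        t = rotate_volume(np.asarray(template, dtype=np.float64), tuple(trip))
        t = np.asarray(_apply_weight(t, weight), dtype=np.float64)
        tbar = (t * m).sum() / p
        sigma_t = np.sqrt(((t - tbar) ** 2 * m).sum() / p)
        tm = (t - tbar) * m
        # symmetric margin of half the template box on every side
        for z in range(c, shape[0] - c):
            for y in range(c, shape[1] - c):
                for x in range(c, shape[2] - c):
                    block = v[z - c:z - c + box, y - c:y - c + box,
                              x - c:x - c + box]
                    vbar = (block * m).sum() / p
                    var = (block ** 2 * m).sum() / p - vbar ** 2
                    sigma_v = np.sqrt(max(var, 0.0))
                    if sigma_v <= 0 or sigma_t <= 0:
                        lcc = 0.0
                    else:
                        lcc = float(
                            (tm * (block - vbar)).sum() / (p * sigma_t * sigma_v)
                        )
                    values.append(lcc)
                    if lcc > best[z, y, x]:
                        best[z, y, x] = lcc
                        best_idx[z, y, x] = r
    return best, best_idx, values


def sliding_local_std(tomogram: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Direct per-voxel masked standard deviation at interior positions."""
    v = np.asarray(tomogram, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    box = m.shape[0]
    c = box // 2
    p = m.sum()
    out = np.zeros(v.shape)
    for z in range(c, v.shape[0] - c):
        for y in range(c, v.shape[1] - c):
            for x in range(c, v.shape[2] - c):
                block = v[z - c:z - c + box, y - c:y - c + box, x - c:x - c + box]
                mean = (block * m).sum() / p
                var = (block ** 2 * m).sum() / p - mean ** 2
                out[z, y, x] = np.sqrt(max(var, 0.0))
    return out


def _window_reduce(volume: np.ndarray, footprint: np.ndarray, op) -> np.ndarray:
    """Sliding-window min/max with reflect padding, the scipy default mode."""
    r = footprint.shape[0] // 2
    padded = np.pad(volume, r, mode="reflect")
    out = np.empty_like(volume, dtype=np.float64)
    offsets = np.argwhere(footprint) - r
    for z in range(volume.shape[0]):
        for y in range(volume.shape[1]):
            for x in range(volume.shape[2]):
                vals = [
                    padded[z + r + dz, y + r + dy, x + r + dx]
                    for dz, dy, dx in offsets
                ]
                out[z, y, x] = op(vals)
    return out


def brute_force_tophat(volume: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """input - dilation(erosion(input)) with explicit sliding windows."""
    eroded = _window_reduce(volume, footprint, min)
    opened = _window_reduce(eroded, footprint, max)
    return np.asarray(volume, dtype=np.float64) - opened
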
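"""RGB-to-NIR ROI transfer by mean-adjusted block matching.

The RGB and NIR cameras view the scene from slightly different angles; the
resulting disparity is modeled as a per-block integer translation.  For
every overlapping 5x5 block fully inside the RGB ROI (green channel, the
least noisy of R/G/B), the displacement ``(dx, dy)`` minimizing the
mean-adjusted mean squared error

    MSE = sum_block [ (I_G - mu_G) - (I_N(x+dx, y+dy) - mu_N) ]**2

is searched over an inclusive window (default dx in [-60, 0], dy in
[0, 10]; prior knowledge of the camera rig).  Subtracting the block means
makes the criterion invariant to constant intensity offsets between the
differently lit cameras.  The union of the displaced block footprints is
the registered region used to initialize NIR segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class BlockMatchParams:
    """Block geometry and inclusive displacement search window (in pixels)."""

    block_size: int = 5
    stride: int = 1
    dx_range: tuple[int, int] = (-60, 0)
    dy_range: tuple[int, int] = (0, 10)


@dataclass
class RegistrationResult:
    """Registered NIR-grid mask plus per-block displacement diagnostics."""

    mask: np.ndarray                     # bool, NIR grid
    block_rows: np.ndarray               # block-center coordinates
    block_cols: np.ndarray
    displacements: np.ndarray            # (n_blocks, 2) as (dx, dy)


def mean_adjusted_mse(block_g: np.ndarray, block_n: np.ndarray) -> float:
    """Sum of squared mean-adjusted differences between two equal-shape blocks."""
    a = np.asarray(block_g, dtype=float)
    b = np.asarray(block_n, dtype=float)
    if a.shape != b.shape:
        raise ValueError("blocks must have identical shapes")
    resid = (a - a.mean()) - (b - b.mean())
    return float(np.sum(resid * resid))


def _candidate_displacements(params: BlockMatchParams) -> list[tuple[int, int]]:
    """Window displacements ordered by tie-break priority.

    Ties in MSE are broken toward the smallest |dx|+|dy|, then row-major
    (dy, then dx) order; iterating candidates in that priority order with a
    strict improvement test realizes the rule.
    """
    cands = [
        (dx, dy)
        for dy in range(params.dy_range[0], params.dy_range[1] + 1)
        for dx in range(params.dx_range[0], params.dx_range[1] + 1)
    ]
    cands.sort(key=lambda d: (abs(d[0]) + abs(d[1]), d[1], d[0]))
    return cands


def register_roi(
    green: np.ndarray,
    nir: np.ndarray,
    roi: np.ndarray,
    params: BlockMatchParams = BlockMatchParams(),
) -> RegistrationResult:
    """Transfer ``roi`` from the RGB (green) grid onto the NIR grid.

    Blocks are evaluated independently; candidate displacements that push a
    block outside the NIR image are skipped for that block.  Raises if the
    ROI is empty or contains no complete block.
    """
    g = np.asarray(green, dtype=float)
    n = np.asarray(nir, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if g.shape != n.shape or roi.shape != g.shape:
        raise ValueError("green, NIR and ROI must share one resolution")
    if not roi.any():
        raise ValueError("ROI is empty")
    b = params.block_size
    half = b // 2
    h, w = g.shape

    # Block centers: 5x5 footprint fully inside the ROI (and the image).
    centers = ndimage.binary_erosion(
        roi, structure=np.ones((b, b), dtype=bool), border_value=0
    )
    if params.stride > 1:
        keep = np.zeros_like(centers)
        keep[::params.stride, ::params.stride] = True
        centers &= keep
    rows, cols = np.nonzero(centers)
    if rows.size == 0:
        raise ValueError("no complete block fits inside the ROI")

    n_pix = b * b
    best_cost = np.full(rows.size, np.inf)
    best_dx = np.zeros(rows.size, dtype=int)
    best_dy = np.zeros(rows.size, dtype=int)
    for dx, dy in _candidate_displacements(params):
        tr, tc = rows + dy, cols + dx
        valid = (
            (tr - half >= 0) & (tr + half < h) & (tc - half >= 0) & (tc + half < w)
        )
        if not valid.any():
            continue
        # Shifted NIR: N_d(y, x) = N(y+dy, x+dx); out-of-bounds filled with
        # zero (harmless: such centers are already excluded by `valid`).
        shifted = np.zeros_like(n)
        sy0, sy1 = max(0, dy), min(h, h + dy)
        sx0, sx1 = max(0, dx), min(w, w + dx)
        shifted[sy0 - dy : sy1 - dy, sx0 - dx : sx1 - dx] = n[sy0:sy1, sx0:sx1]
        diff = g - shifted
        local_mean = ndimage.uniform_filter(diff, size=b, mode="constant")
        local_sq = ndimage.uniform_filter(diff * diff, size=b, mode="constant")
        cost_field = n_pix * np.clip(local_sq - local_mean * local_mean, 0.0, None)
        cost = cost_field[rows, cols]
        improve = valid & (cost < best_cost)
        best_cost[improve] = cost[improve]
        best_dx[improve] = dx
        best_dy[improve] = dy

    mask = np.zeros_like(roi)
    for r, c, dx, dy in zip(rows, cols, best_dx, best_dy):
        mask[
            max(0, r + dy - half) : min(h, r + dy + half + 1),
            max(0, c + dx - half) : min(w, c + dx + half + 1),
        ] = True
    return RegistrationResult(
        mask=mask,
        block_rows=rows,
        block_cols=cols,
        displacements=np.stack([best_dx, best_dy], axis=1),
    )
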
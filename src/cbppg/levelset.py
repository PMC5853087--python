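"""Two-phase level-set segmentation driven by regional homogeneity.

The segmentation contour is the zero crossing of a signed-distance field
``phi`` (positive inside the region of interest ``Omega_1``).  Gradient
descent moves ``phi`` according to

    d phi / dt = H'(phi) * [ sum_j log( p_1j(F_j) / p_2j(F_j) )
                             + nu * div( grad phi / |grad phi| ) ]

where ``F`` is a per-pixel feature stack (color channels plus a local 5x5
standard-deviation texture), ``p_ij`` is a Gaussian fitted to feature ``j``
inside region ``Omega_i`` (mean and standard deviation recomputed each
iteration over the hard masks {phi>0} / {phi<=0}), and
``nu = 0.001 * |Omega|**0.7`` weights the curvature regularizer.

Numerics: forward Euler with a per-pixel saturated step, a smooth arctan
Heaviside with width ``epsilon`` = 1.5 px replacing the sharp delta, and
reinitialization of ``phi`` to an exact signed Euclidean distance
(half-pixel offset so |grad phi| ~ 1 across the contour) after every
iteration.  Because the reinitialization resets contour-adjacent pixels to
phi = +-0.5, only sign flips carry information between iterations; the
update is therefore bounded per pixel,

    d phi = step_scale * (H'(phi)/H'(0)) * f / (|f| + force_softening),

which flips a contour-adjacent pixel exactly when its total force exceeds
a fixed log-likelihood scale (about 1.6 times ``force_softening``) and
moves the front at most one pixel ring per iteration (unconditionally
stable).  A global time step normalized by the force maximum would freeze
the contour instead: the Gaussian log-ratio is heavy-tailed (a tight
region's small sigma makes wrong-side penalties orders of magnitude larger
than right-side gains), so the normalized update at pixels that must flip
can be arbitrarily small while the sign-reinitialization wipes any
sub-threshold progress.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage


def curvature_weight(n_pixels: int, coefficient: float = 0.001, exponent: float = 0.7) -> float:
    """Default curvature weight nu = 0.001 * |Omega|**0.7 for a grid of n_pixels."""
    return coefficient * float(n_pixels) ** exponent


@dataclass(frozen=True)
class LevelSetParams:
    """Tunables of one segmentation run.

    ``nu=None`` means "use :func:`curvature_weight` of the grid size".
    ``early_stop_delta`` stops iterating when the inside-region pixel count
    changes by fewer pixels than this between iterations (``None`` disables
    early stopping; detection runs its full iteration budget, tracking uses
    the 50-px criterion).
    """

    max_iters: int = 300
    early_stop_delta: int | None = None
    nu: float | None = None
    epsilon: float = 1.5
    step_scale: float = 0.9
    force_softening: float = 1.0
    sigma_floor: float = 1.0
    freeze_stats: bool = False


# Iteration budgets used by the detector and tracker.
RGB_DETECT_PARAMS = LevelSetParams(max_iters=300)
NIR_DETECT_PARAMS = LevelSetParams(max_iters=100)
TRACK_PARAMS = LevelSetParams(max_iters=50, early_stop_delta=50)


@dataclass
class LevelSetState:
    """Signed-distance field plus bookkeeping from one evolution."""

    phi: np.ndarray
    iterations: int = 0
    converged: bool = False
    status: str = "ok"        # ok | degenerate_empty | degenerate_full

    @property
    def mask(self) -> np.ndarray:
        return self.phi > 0


def compute_texture(channel: np.ndarray, size: int = 5) -> np.ndarray:
    """Local standard deviation in ``size`` x ``size`` neighborhoods.

    Borders are replicate-padded.  A constant image maps to zero texture.
    """
    img = np.asarray(channel, dtype=float)
    if min(img.shape) < size:
        raise ValueError(f"image smaller than the {size}x{size} texture window")
    mean = ndimage.uniform_filter(img, size=size, mode="nearest")
    mean_sq = ndimage.uniform_filter(img * img, size=size, mode="nearest")
    return np.sqrt(np.clip(mean_sq - mean * mean, 0.0, None))


def rgb_features(rgb: np.ndarray) -> np.ndarray:
    """Feature stack (I_R, I_G, I_B, J_RGB); J_RGB is the mean per-channel texture."""
    img = np.asarray(rgb, dtype=float)
    textures = [compute_texture(img[..., c]) for c in range(3)]
    j_rgb = np.mean(textures, axis=0)
    return np.stack([img[..., 0], img[..., 1], img[..., 2], j_rgb], axis=-1)


def nir_features(nir: np.ndarray) -> np.ndarray:
    """Feature stack (I_N, J_N) for the monochrome NIR stream."""
    img = np.asarray(nir, dtype=float)
    return np.stack([img, compute_texture(img)], axis=-1)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the region boundary, positive inside.

    The half-pixel offset places contour-adjacent pixels at +-0.5 so the
    gradient magnitude is ~1 across the zero crossing; {phi > 0} reproduces
    the input mask exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.where(mask, inside - 0.5, 0.5 - outside)


def sdf_gradient_magnitude(
    phi: np.ndarray, kink_threshold: float = 0.35
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient magnitude of a signed-distance field, with shock detection.

    A distance field satisfies |grad phi| = 1 away from its shocks: medial
    axes and the corner fans of a pixelized contour, where the gradient of
    the true distance field is genuinely discontinuous and no local finite
    difference can recover the unit slope.  The magnitude is estimated with
    central differences; a pixel is flagged as a shock when, along any axis
    or diagonal, its one-sided differences disagree in sign (a local
    extremum of phi) or differ by more than ``kink_threshold`` (a switch of
    the nearest-boundary generator).

    Returns ``(magnitude, is_shock)``.
    """
    phi = np.asarray(phi, dtype=float)
    shock = np.zeros(phi.shape, dtype=bool)
    grads = []
    for axis in (0, 1):
        fwd = np.diff(phi, axis=axis, append=np.take(phi, [-1], axis=axis))
        bwd = np.diff(phi, axis=axis, prepend=np.take(phi, [0], axis=axis))
        shock |= ((bwd * fwd) < 0) | (np.abs(bwd - fwd) > kink_threshold)
        grads.append(0.5 * (fwd + bwd))
    padded = np.pad(phi, 1, mode="edge")

    def shifted(dr: int, dc: int) -> np.ndarray:
        return padded[1 + dr : 1 + dr + phi.shape[0], 1 + dc : 1 + dc + phi.shape[1]]

    for dr, dc in ((1, 1), (1, -1)):
        fwd = (shifted(dr, dc) - phi) / np.sqrt(2.0)
        bwd = (phi - shifted(-dr, -dc)) / np.sqrt(2.0)
        shock |= ((bwd * fwd) < 0) | (np.abs(bwd - fwd) > kink_threshold)
    return np.sqrt(grads[0] ** 2 + grads[1] ** 2), shock


def init_phi(mask: np.ndarray) -> LevelSetState:
    """Initialize the level-set field from a binary region mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ValueError("initialization mask must be non-empty and not the full grid")
    return LevelSetState(phi=signed_distance(mask))


def region_stats(
    features: np.ndarray, phi: np.ndarray, sigma_floor: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/sd of each feature inside {phi>0} and {phi<=0}.

    Returns ``mu, sigma`` of shape (2, M); row 0 is the inside region.
    Standard deviations are floored at ``sigma_floor``.  Raises if a region
    holds fewer than 2 pixels (degenerate segmentation).
    """
    inside = phi > 0
    m = features.shape[-1]
    mu = np.empty((2, m))
    sigma = np.empty((2, m))
    for i, mask in enumerate((inside, ~inside)):
        if mask.sum() < 2:
            raise ValueError("degenerate segmentation: a region has < 2 pixels")
        vals = features[mask]
        mu[i] = vals.mean(axis=0)
        sigma[i] = np.maximum(vals.std(axis=0), sigma_floor)
    return mu, sigma


def homogeneity_force(
    features: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Sum over features of log( p_1(F) / p_2(F) ) with Gaussian region models."""
    force = np.zeros(features.shape[:2])
    for j in range(features.shape[-1]):
        f = features[..., j]
        force += (
            np.log(sigma[1, j] / sigma[0, j])
            + (f - mu[1, j]) ** 2 / (2.0 * sigma[1, j] ** 2)
            - (f - mu[0, j]) ** 2 / (2.0 * sigma[0, j] ** 2)
        )
    return force


def curvature_force(phi: np.ndarray, reg: float = 1e-8) -> np.ndarray:
    """div( grad phi / |grad phi| ) via central differences, replicate borders."""
    gy, gx = np.gradient(phi)
    norm = np.sqrt(gx * gx + gy * gy) + reg
    ny, nx = gy / norm, gx / norm
    div_y = np.gradient(ny, axis=0)
    div_x = np.gradient(nx, axis=1)
    return div_y + div_x


def smooth_delta(phi: np.ndarray, epsilon: float) -> np.ndarray:
    """Derivative of the arctan-smoothed Heaviside H(phi)=0.5*(1+(2/pi)atan(phi/eps))."""
    return (epsilon / np.pi) / (epsilon * epsilon + phi * phi)


def evolve(
    state: LevelSetState, features: np.ndarray, params: LevelSetParams
) -> LevelSetState:
    """Run the gradient descent from ``state`` and return the final state.

    Region statistics are recomputed every iteration (unless
    ``params.freeze_stats``), ``phi`` is reinitialized to a signed distance
    after each forward-Euler step, and iteration ends at ``max_iters``, at
    the early-stop criterion, or when a region degenerates (status reports
    which; the caller is expected to redetect).
    """
    phi = signed_distance(state.phi > 0)
    nu = params.nu if params.nu is not None else curvature_weight(phi.size)
    mu = sigma = None
    if params.freeze_stats:
        mu, sigma = region_stats(features, phi, params.sigma_floor)

    area_prev = int((phi > 0).sum())
    iterations = 0
    converged = False
    status = "ok"
    for _ in range(params.max_iters):
        iterations += 1
        if not params.freeze_stats:
            try:
                mu, sigma = region_stats(features, phi, params.sigma_floor)
            except ValueError:
                status = (
                    "degenerate_empty" if (phi > 0).sum() < 2 else "degenerate_full"
                )
                break
        force = homogeneity_force(features, mu, sigma)
        if nu:
            force = force + nu * curvature_force(phi)
        delta = smooth_delta(phi, params.epsilon) / smooth_delta(
            np.float64(0.0), params.epsilon
        )
        update = (
            params.step_scale
            * delta
            * force
            / (np.abs(force) + params.force_softening)
        )
        if np.abs(update).max() == 0.0:
            converged = True
            break
        phi = phi + update
        mask = phi > 0
        area = int(mask.sum())
        if area == 0 or area == phi.size:
            status = "degenerate_empty" if area == 0 else "degenerate_full"
            phi = np.where(mask, 0.5, -0.5)
            break
        phi = signed_distance(mask)
        if (
            params.early_stop_delta is not None
            and abs(area - area_prev) < params.early_stop_delta
        ):
            converged = True
            break
        area_prev = area

    return LevelSetState(
        phi=phi, iterations=iterations, converged=converged, status=status
    )


def segment(
    features: np.ndarray, init_mask: np.ndarray, params: LevelSetParams
) -> LevelSetState:
    """Convenience wrapper: initialize from a mask and evolve."""
    return evolve(init_phi(init_mask), features, params)


def with_early_stop(params: LevelSetParams, delta: int | None) -> LevelSetParams:
    return replace(params, early_stop_delta=delta)
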
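"""Single-frame ROI detection: skin classification -> RGB level-set
segmentation -> block-matching registration -> NIR level-set segmentation.

The RGB pipeline classifies skin on the intensity-adjusted frame, uses the
classified region to initialize a level-set segmentation over the raw-frame
features (I_R, I_G, I_B, J_RGB; <= 300 iterations), and reports the final
inside region as the RGB ROI.  The NIR pipeline transfers that ROI onto the
NIR grid by block matching and refines it with a second segmentation over
(I_N, J_N) (<= 100 iterations).  Failures (no skin, degenerate contour,
empty registration) are reported per stream in the result status, never
raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import levelset, registration, skin


@dataclass(frozen=True)
class DetectorParams:
    """Iteration budgets, block matching window and the minimum viable ROI."""

    rgb_levelset: levelset.LevelSetParams = levelset.RGB_DETECT_PARAMS
    nir_levelset: levelset.LevelSetParams = levelset.NIR_DETECT_PARAMS
    block_match: registration.BlockMatchParams = registration.BlockMatchParams()
    min_roi_px: int = 100
    # A two-phase homogeneity segmentation needs a non-trivial outside
    # region; an ROI swallowing nearly the whole frame is a failure mode
    # (e.g. a flat occluder), not a plausible skin region.
    max_roi_fraction: float = 0.8

    def roi_ok(self, mask) -> bool:
        area = int(mask.sum())
        return self.min_roi_px <= area <= self.max_roi_fraction * mask.size


@dataclass
class DetectorResult:
    roi_rgb: np.ndarray | None = None
    roi_nir: np.ndarray | None = None
    status_rgb: str = "no_skin"          # ok | no_skin | degenerate
    status_nir: str = "no_skin"
    diagnostics: dict = field(default_factory=dict)


def detect(
    rgb_frame: np.ndarray,
    nir_frame: np.ndarray | None,
    model: skin.SkinModel,
    params: DetectorParams = DetectorParams(),
    streams: tuple[str, ...] = ("rgb", "nir"),
) -> DetectorResult:
    """Run the detector chain on one synchronized frame pair.

    ``streams`` restricts the work (the NIR chain always needs the RGB
    chain first, since registration transfers the RGB ROI).
    """
    result = DetectorResult()
    want_nir = "nir" in streams and nir_frame is not None

    adjusted = skin.adjust_intensity(np.asarray(rgb_frame, dtype=float))
    skin_mask = skin.classify_skin(adjusted, model)
    result.diagnostics["skin_px"] = int(skin_mask.sum())
    if skin_mask.sum() < params.min_roi_px or skin_mask.all():
        return result

    features = levelset.rgb_features(rgb_frame)
    state = levelset.segment(features, skin_mask, params.rgb_levelset)
    result.diagnostics["rgb_iterations"] = state.iterations
    roi_rgb = state.mask
    if state.status != "ok":
        result.status_rgb = "degenerate"
    elif not params.roi_ok(roi_rgb):
        result.status_rgb = "no_skin"
    else:
        result.status_rgb = "ok"
        result.roi_rgb = roi_rgb
        result.diagnostics["rgb_px"] = int(roi_rgb.sum())

    if not want_nir or result.status_rgb != "ok":
        return result

    green = np.asarray(rgb_frame, dtype=float)[..., 1]
    try:
        reg = registration.register_roi(
            green, np.asarray(nir_frame, dtype=float), roi_rgb, params.block_match
        )
    except ValueError:
        return result
    if reg.mask.sum() < params.min_roi_px:
        return result

    nir_feat = levelset.nir_features(nir_frame)
    nir_state = levelset.segment(nir_feat, reg.mask, params.nir_levelset)
    result.diagnostics["nir_iterations"] = nir_state.iterations
    roi_nir = nir_state.mask
    if nir_state.status != "ok":
        result.status_nir = "degenerate"
    elif not params.roi_ok(roi_nir):
        result.status_nir = "no_skin"
    else:
        result.status_nir = "ok"
        result.roi_nir = roi_nir
        result.diagnostics["nir_px"] = int(roi_nir.sum())
    return result
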
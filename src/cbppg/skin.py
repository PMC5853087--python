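"""Histogram-based Bayesian skin-color classification.

A pixel with RGB value ``c`` is called skin when the class-conditional
density ratio ``p(c|skin) / p(c|not-skin) >= theta``.  Both densities are
3-D RGB histograms normalized by their total counts.  Twelve-bit input is
mapped to the 8-bit histogram domain before binning (right shift by 4),
then quantized to ``bins_per_channel`` bins per axis.

Before classification, images are passed through a percentile-based
intensity adjustment (:func:`adjust_intensity`): a per-channel linear
contrast stretch mapping the 1st/99th percentiles onto the full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

INTENSITY_MAX = 4095
_HIST_DOMAIN = 256  # 8-bit histogram domain


@dataclass
class SkinModel:
    """Two normalized RGB histograms plus the decision threshold theta."""

    hist_skin: np.ndarray       # (bins, bins, bins) counts
    hist_nonskin: np.ndarray
    bins_per_channel: int
    theta: float

    @property
    def pdf_skin(self) -> np.ndarray:
        return self.hist_skin / self.hist_skin.sum()

    @property
    def pdf_nonskin(self) -> np.ndarray:
        return self.hist_nonskin / self.hist_nonskin.sum()

    def save(self, path) -> None:
        np.savez(
            path,
            hist_skin=self.hist_skin,
            hist_nonskin=self.hist_nonskin,
            bins_per_channel=self.bins_per_channel,
            theta=self.theta,
        )

    @classmethod
    def load(cls, path) -> "SkinModel":
        with np.load(path) as data:
            return cls(
                hist_skin=data["hist_skin"],
                hist_nonskin=data["hist_nonskin"],
                bins_per_channel=int(data["bins_per_channel"]),
                theta=float(data["theta"]),
            )


def _bin_indices(pixels: np.ndarray, bins: int) -> tuple[np.ndarray, ...]:
    """Map 12-bit RGB values to per-channel histogram bin indices."""
    p = np.clip(np.asarray(pixels), 0, INTENSITY_MAX).astype(np.int64)
    idx = (p >> 4) * bins // _HIST_DOMAIN
    return idx[..., 0], idx[..., 1], idx[..., 2]


def build_skin_model(
    skin_pixels: np.ndarray,
    nonskin_pixels: np.ndarray,
    bins_per_channel: int = 32,
    theta: float = 5.0,
) -> SkinModel:
    """Histogram both pixel corpora and return the classifier model.

    ``skin_pixels`` / ``nonskin_pixels`` are ``(n, 3)`` RGB arrays on the
    12-bit scale.  Raises on empty corpora, out-of-range values, or a
    non-positive threshold.
    """
    skin_pixels = np.asarray(skin_pixels, dtype=float).reshape(-1, 3)
    nonskin_pixels = np.asarray(nonskin_pixels, dtype=float).reshape(-1, 3)
    if skin_pixels.size == 0 or nonskin_pixels.size == 0:
        raise ValueError("both class corpora must be non-empty")
    if theta <= 0:
        raise ValueError("theta must be positive")
    for arr in (skin_pixels, nonskin_pixels):
        if arr.min() < 0 or arr.max() > INTENSITY_MAX:
            raise ValueError("pixel values outside the 12-bit intensity scale")
    shape = (bins_per_channel,) * 3
    hist_skin = np.zeros(shape)
    hist_nonskin = np.zeros(shape)
    np.add.at(hist_skin, _bin_indices(skin_pixels, bins_per_channel), 1.0)
    np.add.at(hist_nonskin, _bin_indices(nonskin_pixels, bins_per_channel), 1.0)
    return SkinModel(hist_skin, hist_nonskin, bins_per_channel, theta)


def adjust_intensity(
    image: np.ndarray, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> np.ndarray:
    """Per-channel linear contrast stretch onto the full 12-bit scale.

    Maps the per-channel ``lower_pct``/``upper_pct`` intensity percentiles
    to 0 and 4095, clipping outside.  Channels with a degenerate percentile
    span (constant channels) are returned unchanged.
    """
    img = np.asarray(image, dtype=float)
    single = img.ndim == 2
    if single:
        img = img[..., None]
    out = np.empty_like(img)
    for ch in range(img.shape[-1]):
        band = img[..., ch]
        lo, hi = np.percentile(band, [lower_pct, upper_pct])
        if hi <= lo:
            out[..., ch] = band
        else:
            out[..., ch] = np.clip(
                (band - lo) / (hi - lo) * INTENSITY_MAX, 0, INTENSITY_MAX
            )
    return out[..., 0] if single else out


def classify_skin(rgb_image: np.ndarray, model: SkinModel) -> np.ndarray:
    """Apply the Bayes decision rule pixel-wise; returns a boolean mask.

    The rule is inclusive (ratio == theta is skin).  Colors never seen in
    the non-skin corpus but seen in the skin corpus are skin; colors unseen
    in both corpora are non-skin (conservative: the downstream segmentation
    can recover skin under-detection but wastes effort on false positives).
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if np.asarray(img).max() > INTENSITY_MAX or np.asarray(img).min() < 0:
        raise ValueError("image values outside the model's intensity scale")
    pdf_s = model.pdf_skin
    pdf_n = model.pdf_nonskin
    ps = pdf_s[_bin_indices(img, model.bins_per_channel)]
    pn = pdf_n[_bin_indices(img, model.bins_per_channel)]
    mask = np.zeros(img.shape[:2], dtype=bool)
    seen = pn > 0
    mask[seen] = ps[seen] >= model.theta * pn[seen]
    mask[~seen] = ps[~seen] > 0
    return mask
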
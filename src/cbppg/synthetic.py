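"""Synthetic RGB + NIR video fixtures with ground truth.

This module generates the two kinds of inputs the pipeline needs:

* a labeled skin / non-skin RGB pixel corpus to train the Bayesian skin
  classifier (:func:`generate_skin_corpus`), and
* synchronized RGB and monochrome-NIR frame sequences with per-frame
  ground-truth skin masks, a scripted cardiac pulse, and scripted artifact
  events (:func:`render_video_pair`).

All intensities live on a 12-bit scale (0-4095).  The scene model is
deliberately simple: elliptical skin-toned patches with a static texture
field on a flat background, a raised-cosine pulse (fundamental plus one
harmonic) added to visible skin, additive Gaussian sensor noise, and a pure
integer-translation viewpoint difference between the RGB and NIR cameras.
Scripted events cover full-frame occlusions, global illumination steps and
scene translations.  Everything is a pure function of (script, seed):
identical inputs yield bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

INTENSITY_MAX = 4095

# Corpus distributions (documented study conditions).  Skin tones cluster
# tightly in RGB; non-skin is a broad mixture of "anything" plus a dark
# cluster matching typical background/furniture tones.
SKIN_MEAN = np.array([2600.0, 1900.0, 1600.0])
SKIN_SD = np.array([230.0, 200.0, 180.0])
NONSKIN_DARK_MEAN = np.array([700.0, 700.0, 800.0])
NONSKIN_DARK_SD = 250.0
NONSKIN_DARK_FRAC = 0.35


def generate_skin_corpus(
    n_skin: int, n_nonskin: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a labeled skin / non-skin RGB pixel corpus.

    Skin pixels follow a trivariate Gaussian skin-tone cluster; non-skin
    pixels are a mixture of a uniform distribution over the whole RGB cube
    and a dark background cluster.  Values are clipped to [0, 4095].

    Returns two ``(n, 3)`` float arrays ``(skin, nonskin)``.
    """
    if n_skin < 1 or n_nonskin < 1:
        raise ValueError("corpus class sizes must be positive")
    rng = np.random.default_rng(seed)
    skin = rng.normal(SKIN_MEAN, SKIN_SD, size=(n_skin, 3))
    n_dark = int(round(NONSKIN_DARK_FRAC * n_nonskin))
    dark = rng.normal(NONSKIN_DARK_MEAN, NONSKIN_DARK_SD, size=(n_dark, 3))
    broad = rng.uniform(0.0, INTENSITY_MAX + 1.0, size=(n_nonskin - n_dark, 3))
    nonskin = np.concatenate([broad, dark], axis=0)
    return (
        np.clip(skin, 0, INTENSITY_MAX),
        np.clip(nonskin, 0, INTENSITY_MAX),
    )


@dataclass(frozen=True)
class SkinPatch:
    """Elliptical skin region: center/axes in pixels, base colors in 12-bit units."""

    center: tuple[float, float]           # (row, col)
    axes: tuple[float, float]             # (semi-axis rows, semi-axis cols)
    color_rgb: tuple[float, float, float] = (2600.0, 1900.0, 1600.0)
    nir: float = 2500.0
    texture_amp: float = 25.0             # sd of the static texture field, units
    gain_gradient: float = 0.0            # multiplicative top->bottom gain span


@dataclass(frozen=True)
class Occlusion:
    """Full-frame flat occluder visible during [start, end) seconds."""

    start: float
    end: float
    color_rgb: tuple[float, float, float] = (900.0, 1900.0, 900.0)
    nir: float = 2500.0


@dataclass(frozen=True)
class IlluminationStep:
    """Additive global intensity step during [start, end) seconds."""

    start: float
    end: float
    magnitude: float = 300.0
    channels: str = "rgb"                 # "rgb", "nir" or "both"


@dataclass(frozen=True)
class Translation:
    """Rigid scene shift by (drow, dcol) pixels from `start` onward."""

    start: float
    drow: int = 0
    dcol: int = 0


Event = Occlusion | IlluminationStep | Translation


@dataclass(frozen=True)
class SceneScript:
    """Full description of a synthetic recording.

    ``pulse_amplitude`` holds per-channel (R, G, B, NIR) fundamental
    amplitudes in intensity units; the rendered waveform is
    ``a*(cos(2 pi f t) + h*cos(4 pi f t))`` with harmonic fraction ``h``, so
    its peak never exceeds ``a*(1+h)`` which must stay within
    ``amplitude_bound`` (default 15 units at 12-bit depth).
    ``nir_offset`` is the (dx, dy) block-matching ground truth: content at
    RGB pixel (y, x) appears at NIR pixel (y+dy, x+dx).
    """

    duration: float = 30.0
    fps: float = 30.0
    resolution: tuple[int, int] = (64, 96)
    skin_regions: Sequence[SkinPatch] = field(
        default_factory=lambda: (SkinPatch(center=(32.0, 45.0), axes=(14.0, 18.0)),)
    )
    heart_rate_bpm: float = 72.0
    pulse_amplitude: tuple[float, float, float, float] = (4.0, 10.0, 3.0, 8.0)
    harmonic_fraction: float = 0.3
    amplitude_bound: float = 15.0
    events: Sequence[Event] = ()
    nir_offset: tuple[int, int] = (-8, 3)  # (dx, dy)
    background_rgb: tuple[float, float, float] = (600.0, 700.0, 800.0)
    background_nir: float = 700.0
    nir_radial_gain: float = 0.0          # relative center-to-corner NIR falloff
    anchor_columns: bool = True           # fixed dark/bright calibration strips
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        if any(a < 0 for a in self.pulse_amplitude):
            raise ValueError("pulse amplitudes must be non-negative")
        peak = max(self.pulse_amplitude) * (1.0 + self.harmonic_fraction)
        if peak > self.amplitude_bound:
            raise ValueError(
                f"pulse peak {peak:.1f} exceeds amplitude bound {self.amplitude_bound}"
            )
        if not 30.0 <= self.heart_rate_bpm <= 200.0:
            raise ValueError("heart rate must lie in [30, 200] bpm")
        for patch in self.skin_regions:
            for c in patch.color_rgb + (patch.nir,):
                if not 0 <= c <= INTENSITY_MAX:
                    raise ValueError("base intensities must lie in [0, 4095]")
        for ev in self.events:
            t0 = ev.start
            t1 = getattr(ev, "end", ev.start)
            if not (0 <= t0 <= self.duration and t0 <= t1 <= self.duration):
                raise ValueError(f"event {ev} outside [0, {self.duration}] s")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class GroundTruth:
    """Per-frame visible-skin masks, segment-wise reference HR, event log."""

    mask_rgb: np.ndarray                  # (T, H, W) bool, RGB grid
    mask_nir: np.ndarray                  # (T, H, W) bool, NIR grid
    f_ref_bpm: np.ndarray                 # one entry per full 10-s segment
    events: list[tuple[str, int, int]]    # (type, onset frame, offset frame)


@dataclass
class VideoPair:
    """Co-indexed RGB (T,H,W,3) and NIR (T,H,W) uint16 streams."""

    rgb: np.ndarray
    nir: np.ndarray
    fps: float

    @property
    def n_frames(self) -> int:
        return self.rgb.shape[0]


def _ellipse_mask(shape: tuple[int, int], patch: SkinPatch) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = patch.center
    ay, ax = patch.axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _shift2d(img: np.ndarray, drow: int, dcol: int, fill) -> np.ndarray:
    """Integer shift with constant fill; out[y, x] = img[y-drow, x-dcol]."""
    out = np.full_like(img, fill)
    h, w = img.shape[:2]
    sy0, sy1 = max(0, -drow), min(h, h - drow)
    sx0, sx1 = max(0, -dcol), min(w, w - dcol)
    if sy1 > sy0 and sx1 > sx0:
        out[sy0 + drow : sy1 + drow, sx0 + dcol : sx1 + dcol] = img[sy0:sy1, sx0:sx1]
    return out


def render_video_pair(script: SceneScript) -> tuple[VideoPair, GroundTruth]:
    """Render the scripted scene into synchronized RGB and NIR streams.

    The NIR stream shows the same scene displaced by ``script.nir_offset``
    and lit independently (optionally with a radial LED falloff).  Events are
    applied in camera space (an occluder covers both frames in front of the
    cameras); noise is drawn last and frames are clipped to [0, 4095].
    """
    h, w = script.resolution
    n = script.n_frames
    rng = np.random.default_rng(script.seed)

    # --- static scene maps on the RGB grid -------------------------------
    scene_rgb = np.empty((h, w, 3))
    scene_rgb[:] = script.background_rgb
    scene_nir = np.full((h, w), script.background_nir)
    skin_mask = np.zeros((h, w), dtype=bool)
    texture = rng.standard_normal((h, w))
    for patch in script.skin_regions:
        m = _ellipse_mask((h, w), patch)
        skin_mask |= m
        gain = np.ones((h, w))
        if patch.gain_gradient:
            rows = np.linspace(
                1.0 - patch.gain_gradient, 1.0, h
            )[:, None] * np.ones((1, w))
            gain = rows
        for ch in range(3):
            scene_rgb[..., ch][m] = (
                patch.color_rgb[ch] * gain[m] + patch.texture_amp * texture[m]
            )
        scene_nir[m] = patch.nir * gain[m] + patch.texture_amp * texture[m]

    # Calibration strips: fixed dark/bright columns rigidly attached to the
    # recording rig (they do not move with the scene and are never occluded
    # by scripted events); they anchor the percentile intensity adjustment.
    anchor_vals = np.zeros((h, w))
    anchor_rgb = np.zeros((h, w), dtype=bool)
    if script.anchor_columns:
        anchor_rgb[:, 0] = True
        anchor_rgb[:, -1] = True
        anchor_vals[:, 0] = 40.0
        anchor_vals[:, -1] = 3950.0
        skin_mask[:, 0] = False
        skin_mask[:, -1] = False

    if script.nir_radial_gain:
        rr, cc = np.mgrid[0:h, 0:w]
        r2 = ((rr - h / 2) / (h / 2)) ** 2 + ((cc - w / 2) / (w / 2)) ** 2
        scene_nir = scene_nir * (1.0 - script.nir_radial_gain * r2 / 2.0)

    dx, dy = script.nir_offset
    anchor_nir = _shift2d(anchor_rgb, dy, dx, False)
    anchor_nir_vals = _shift2d(anchor_vals, dy, dx, 0.0)
    f_hz = script.heart_rate_bpm / 60.0
    harm = script.harmonic_fraction
    amps = script.pulse_amplitude

    rgb_frames = np.empty((n, h, w, 3), dtype=np.uint16)
    nir_frames = np.empty((n, h, w), dtype=np.uint16)
    gt_rgb = np.zeros((n, h, w), dtype=bool)
    gt_nir = np.zeros((n, h, w), dtype=bool)
    event_log: list[tuple[str, int, int]] = []
    for ev in script.events:
        k0 = int(round(ev.start * script.fps))
        k1 = int(round(getattr(ev, "end", script.duration) * script.fps))
        event_log.append((type(ev).__name__.lower(), k0, k1))

    for k in range(n):
        t = k / script.fps
        wave = np.cos(2 * np.pi * f_hz * t) + harm * np.cos(4 * np.pi * f_hz * t)

        # scene-space translation state at frame k
        drow = dcol = 0
        for ev in script.events:
            if isinstance(ev, Translation) and t >= ev.start:
                drow += ev.drow
                dcol += ev.dcol
        if drow or dcol:
            mask_k = _shift2d(skin_mask, drow, dcol, False)
            base_rgb = np.stack(
                [
                    _shift2d(scene_rgb[..., c], drow, dcol, script.background_rgb[c])
                    for c in range(3)
                ],
                axis=-1,
            )
            base_nir = _shift2d(scene_nir, drow, dcol, script.background_nir)
        else:
            mask_k = skin_mask
            base_rgb = scene_rgb
            base_nir = scene_nir

        frame_rgb = base_rgb.copy()
        for ch in range(3):
            frame_rgb[..., ch][mask_k] += amps[ch] * wave
        frame_nir_scene = base_nir.copy()
        frame_nir_scene[mask_k] += amps[3] * wave

        # NIR camera sees the scene displaced by the viewpoint offset
        frame_nir = _shift2d(frame_nir_scene, dy, dx, script.background_nir)
        mask_nir_k = _shift2d(mask_k, dy, dx, False)

        for ch in range(3):
            frame_rgb[..., ch][anchor_rgb] = anchor_vals[anchor_rgb]
        frame_nir[anchor_nir] = anchor_nir_vals[anchor_nir]

        visible_rgb = mask_k.copy()
        visible_nir = mask_nir_k.copy()
        for ev in script.events:
            if isinstance(ev, Occlusion) and ev.start <= t < ev.end:
                frame_rgb[~anchor_rgb] = ev.color_rgb
                frame_nir[~anchor_nir] = ev.nir
                visible_rgb[:] = False
                visible_nir[:] = False
            elif isinstance(ev, IlluminationStep) and ev.start <= t < ev.end:
                if ev.channels in ("rgb", "both"):
                    frame_rgb += ev.magnitude
                if ev.channels in ("nir", "both"):
                    frame_nir += ev.magnitude

        if script.noise_sd > 0:
            frame_rgb = frame_rgb + rng.normal(0.0, script.noise_sd, frame_rgb.shape)
            frame_nir = frame_nir + rng.normal(0.0, script.noise_sd, frame_nir.shape)

        rgb_frames[k] = np.clip(np.rint(frame_rgb), 0, INTENSITY_MAX).astype(np.uint16)
        nir_frames[k] = np.clip(np.rint(frame_nir), 0, INTENSITY_MAX).astype(np.uint16)
        gt_rgb[k] = visible_rgb
        gt_nir[k] = visible_nir

    n_segments = int(script.duration // 10)
    truth = GroundTruth(
        mask_rgb=gt_rgb,
        mask_nir=gt_nir,
        f_ref_bpm=np.full(n_segments, script.heart_rate_bpm),
        events=event_log,
    )
    return VideoPair(rgb=rgb_frames, nir=nir_frames, fps=script.fps), truth
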
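"""Per-frame ROI tracking with artifact-monitored redetection.

Each video stream (RGB, NIR) is tracked independently: the level set for
frame k is initialized with the ROI of frame k-1 and evolved for at most 50
iterations, stopping early once the inside-region size changes by fewer
than 50 pixels between iterations.  Two failure paths trigger the full ROI
detector:

* the tracked region disappears (or degenerates to the whole grid) ->
  ``redetect_no_skin``;
* the standard deviation of the mean ROI intensity over the trailing 10 s
  exceeds 50 units (12-bit scale) -> ``redetect_unstable``.

After every successful (re)detection, monitoring is paused for 10 s and the
intensity buffer is reset (a fresh ROI sets a fresh photometric baseline).
The monitored intensity is the stream's primary channel: green for RGB,
the NIR channel itself for NIR.  One event is logged when an episode
starts; frames on which the detector keeps failing extend the episode
without new events, and ``pause_start`` marks the successful reselection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import detector, levelset
from .synthetic import VideoPair


@dataclass(frozen=True)
class TrackerParams:
    track_levelset: levelset.LevelSetParams = levelset.TRACK_PARAMS
    detector_params: detector.DetectorParams = detector.DetectorParams()
    monitor_window_s: float = 10.0
    monitor_threshold: float = 50.0       # intensity units, 12-bit scale
    pause_s: float = 10.0
    failure_backoff_after: int = 100      # consecutive failures before backing off
    failure_backoff_stride: int = 10


@dataclass
class StreamState:
    """Tracking state of one stream (ring buffer sizes follow the fps)."""

    mask: np.ndarray | None = None
    buffer: deque = field(default_factory=deque)
    paused_until: int = 0
    failures: int = 0
    events: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class TrackResult:
    masks_rgb: list[np.ndarray | None]
    masks_nir: list[np.ndarray | None]
    events_rgb: list[tuple[int, str]]
    events_nir: list[tuple[int, str]]

    def episodes(self, stream: str, kind: str | None = None) -> int:
        events = self.events_rgb if stream == "rgb" else self.events_nir
        return sum(1 for _, e in events if kind is None or e == kind)


def _mean_intensity(channel: np.ndarray, mask: np.ndarray) -> float:
    return float(channel[mask].mean())


class _StreamTracker:
    """Tracks one stream; redetection is delegated to the shared detector call."""

    def __init__(self, name: str, fps: float, params: TrackerParams):
        self.name = name
        self.params = params
        self.window = max(2, int(round(params.monitor_window_s * fps)))
        self.pause_frames = int(round(params.pause_s * fps))
        self.state = StreamState(buffer=deque(maxlen=self.window))

    # -- redetection bookkeeping -----------------------------------------
    def wants_detection(self, frame_idx: int) -> bool:
        if self.state.mask is not None:
            return False
        s = self.state
        if s.failures >= self.params.failure_backoff_after:
            return (s.failures - self.params.failure_backoff_after) % \
                self.params.failure_backoff_stride == 0
        return True

    def accept_detection(self, frame_idx: int, mask: np.ndarray | None,
                         channel: np.ndarray) -> None:
        s = self.state
        if mask is None:
            s.failures += 1
            return
        s.mask = mask
        s.failures = 0
        s.buffer.clear()
        s.buffer.append(_mean_intensity(channel, mask))
        s.paused_until = frame_idx + self.pause_frames
        s.events.append((frame_idx, "pause_start"))

    def lose_roi(self, frame_idx: int, reason: str) -> None:
        self.state.events.append((frame_idx, reason))
        self.state.mask = None
        self.state.failures = 0

    # -- per-frame tracking ----------------------------------------------
    def track(self, frame_idx: int, features: np.ndarray,
              channel: np.ndarray) -> bool:
        """Evolve the previous ROI on this frame.

        Returns True if the stream now needs the detector (ROI lost or
        instability detected).
        """
        s = self.state
        state = levelset.evolve(
            levelset.LevelSetState(phi=levelset.signed_distance(s.mask)),
            features,
            self.params.track_levelset,
        )
        if state.status != "ok" or not self.params.detector_params.roi_ok(state.mask):
            self.lose_roi(frame_idx, "redetect_no_skin")
            return True
        s.mask = state.mask
        s.buffer.append(_mean_intensity(channel, s.mask))
        if frame_idx >= s.paused_until and len(s.buffer) >= 2:
            if float(np.std(s.buffer)) > self.params.monitor_threshold:
                self.lose_roi(frame_idx, "redetect_unstable")
                return True
        return False


def run(
    video: VideoPair,
    model,
    params: TrackerParams = TrackerParams(),
    streams: tuple[str, ...] = ("rgb", "nir"),
) -> TrackResult:
    """Detect-then-track both streams through the whole recording."""
    n = video.n_frames
    if n < 1:
        raise ValueError("need at least one frame")
    trackers = {s: _StreamTracker(s, video.fps, params) for s in streams}
    masks: dict[str, list] = {s: [] for s in streams}

    for k in range(n):
        rgb = np.asarray(video.rgb[k], dtype=float)
        nir = np.asarray(video.nir[k], dtype=float) if video.nir is not None else None
        channels = {"rgb": rgb[..., 1], "nir": nir}
        feats: dict[str, np.ndarray | None] = {"rgb": None, "nir": None}

        def features_for(stream: str) -> np.ndarray:
            if feats[stream] is None:
                feats[stream] = (
                    levelset.rgb_features(rgb) if stream == "rgb"
                    else levelset.nir_features(nir)
                )
            return feats[stream]

        pending = []
        for s, tr in trackers.items():
            if tr.state.mask is not None:
                if tr.track(k, features_for(s), channels[s]):
                    pending.append(s)
            elif tr.wants_detection(k):
                pending.append(s)
            else:
                tr.state.failures += 1

        if pending:
            need_nir = "nir" in pending
            result = detector.detect(
                rgb, nir, model, params.detector_params,
                streams=("rgb", "nir") if need_nir else ("rgb",),
            )
            if "rgb" in pending:
                trackers["rgb"].accept_detection(
                    k, result.roi_rgb if result.status_rgb == "ok" else None,
                    channels["rgb"],
                )
            if need_nir:
                trackers["nir"].accept_detection(
                    k, result.roi_nir if result.status_nir == "ok" else None,
                    channels["nir"],
                )

        for s, tr in trackers.items():
            masks[s].append(None if tr.state.mask is None else tr.state.mask.copy())

    return TrackResult(
        masks_rgb=masks.get("rgb", [None] * n),
        masks_nir=masks.get("nir", [None] * n),
        events_rgb=trackers["rgb"].state.events if "rgb" in trackers else [],
        events_nir=trackers["nir"].state.events if "nir" in trackers else [],
    )
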
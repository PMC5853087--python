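"""Pipeline configuration: every tunable in one serializable place.

Defaults follow the method as published (threshold theta = 5, 300/100/50
level-set iterations, 50-px early stop, curvature weight 0.001*|Omega|**0.7,
5x5 blocks with a [-60,0] x [0,10] search window, 10-s monitoring window
with a 50-unit threshold and 10-s pause, 10-s segments, order-250 FIR at
0.5 Hz, 2**13-point FFT, 30-200 bpm band, +-5 bpm harmonic mask) plus the
package's own numerical choices (32 histogram bins per channel, 100-px
minimum ROI, sigma floor 1.0, Heaviside width 1.5 px).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from . import detector, levelset, registration, tracker


@dataclass
class PipelineConfig:
    theta: float = 5.0
    bins_per_channel: int = 32
    rgb_detect_iters: int = 300
    nir_detect_iters: int = 100
    track_iters: int = 50
    early_stop_px: int = 50
    nu_coefficient: float = 0.001
    nu_exponent: float = 0.7
    epsilon_px: float = 1.5
    step_scale: float = 0.9
    sigma_floor: float = 1.0
    min_roi_px: int = 100
    block_size: int = 5
    block_stride: int = 1
    search_dx: tuple[int, int] = (-60, 0)
    search_dy: tuple[int, int] = (0, 10)
    monitor_window_s: float = 10.0
    monitor_threshold: float = 50.0
    pause_s: float = 10.0
    segment_s: float = 10.0
    fir_order: int = 250
    fir_cutoff_hz: float = 0.5
    fft_points: int = 8192
    hr_band_bpm: tuple[float, float] = (30.0, 200.0)
    harmonic_half_width_bpm: float = 5.0
    corpus_n_skin: int = 50000
    corpus_n_nonskin: int = 50000
    seed: int = 0

    # -- derived parameter objects ---------------------------------------
    def _levelset(self, max_iters: int, early_stop: int | None) -> levelset.LevelSetParams:
        return levelset.LevelSetParams(
            max_iters=max_iters,
            early_stop_delta=early_stop,
            epsilon=self.epsilon_px,
            step_scale=self.step_scale,
            sigma_floor=self.sigma_floor,
        )

    def detector_params(self) -> detector.DetectorParams:
        return detector.DetectorParams(
            rgb_levelset=self._levelset(self.rgb_detect_iters, None),
            nir_levelset=self._levelset(self.nir_detect_iters, None),
            block_match=registration.BlockMatchParams(
                block_size=self.block_size,
                stride=self.block_stride,
                dx_range=tuple(self.search_dx),
                dy_range=tuple(self.search_dy),
            ),
            min_roi_px=self.min_roi_px,
        )

    def tracker_params(self) -> tracker.TrackerParams:
        return tracker.TrackerParams(
            track_levelset=self._levelset(self.track_iters, self.early_stop_px),
            detector_params=self.detector_params(),
            monitor_window_s=self.monitor_window_s,
            monitor_threshold=self.monitor_threshold,
            pause_s=self.pause_s,
        )

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("search_dx", "search_dy", "hr_band_bpm"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("search_dx", "search_dy", "hr_band_bpm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
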
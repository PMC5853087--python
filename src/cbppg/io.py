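"""Frame-directory and CSV I/O for video pairs, masks, events and signals.

Streams are stored as directories of 16-bit TIFF frames (values 0-4095)
with a JSON sidecar (fps, resolution, NIR offset, seed); masks as 8-bit
PNG; events, signals and per-segment tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import VideoPair


def write_video_pair(path, video: VideoPair, meta: dict | None = None) -> None:
    path = Path(path)
    (path / "rgb").mkdir(parents=True, exist_ok=True)
    (path / "nir").mkdir(parents=True, exist_ok=True)
    for k in range(video.n_frames):
        iio.imwrite(path / "rgb" / f"{k:06d}.tif", video.rgb[k].astype(np.uint16))
        iio.imwrite(path / "nir" / f"{k:06d}.tif", video.nir[k].astype(np.uint16))
    sidecar = {
        "fps": video.fps,
        "resolution": list(video.rgb.shape[1:3]),
        "n_frames": video.n_frames,
    }
    sidecar.update(meta or {})
    (path / "meta.json").write_text(json.dumps(sidecar, indent=2))


def read_video_pair(path) -> VideoPair:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    rgb = np.stack(
        [iio.imread(p) for p in sorted((path / "rgb").glob("*.tif"))]
    )
    nir = np.stack(
        [iio.imread(p) for p in sorted((path / "nir").glob("*.tif"))]
    )
    return VideoPair(rgb=rgb, nir=nir, fps=float(meta["fps"]))


def write_masks(path, masks: list[np.ndarray | None]) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(masks):
        if m is not None:
            iio.imwrite(path / f"{k:06d}.png", (m.astype(np.uint8) * 255))


def write_events(path, events: list[tuple[int, str]], stream: str) -> None:
    pd.DataFrame(
        [{"frame": f, "stream": stream, "event": e} for f, e in events]
    ).to_csv(path, index=False)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
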
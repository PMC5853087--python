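"""cbPPG signal extraction and per-segment heart-rate / SNR analysis.

The plethysmogram of a channel is the spatial mean of the ROI pixels per
frame.  Recordings are cut into consecutive non-overlapping 10-s segments
(counted from the recording start; a trailing partial segment is dropped).
Any segment overlapping frames without an ROI is invalid and excluded from
spectral analysis (it still counts as a false detection in the HDR).

Each valid segment is detrended (least-squares line), highpass filtered
(order-250 FIR, 0.5 Hz cutoff, Hamming-windowed sinc, applied forward and
backward for zero phase), zero-padded to 2**13 points and Fourier
transformed.  The heart rate is the frequency of the amplitude-spectrum
maximum within 30-200 bpm; the SNR compares spectral power within +-5 bpm
of the reference HR and its first harmonic against the remaining power in
the 30-200 bpm band, in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

SEGMENT_SECONDS = 10.0
FIR_ORDER = 250
FIR_CUTOFF_HZ = 0.5
FFT_POINTS = 2 ** 13
HR_BAND_BPM = (30.0, 200.0)
HARMONIC_HALF_WIDTH_BPM = 5.0
SNR_CAP_DB = 80.0

CHANNELS = ("R", "G", "B", "N")


def extract(
    video, masks_rgb: list, masks_nir: list | None = None
) -> pd.DataFrame:
    """Per-frame spatial ROI means for each channel.

    Returns a DataFrame with columns R, G, B (from the RGB ROI) and N
    (from the NIR ROI); frames without an ROI hold NaN.
    """
    n = video.n_frames
    if len(masks_rgb) != n or (masks_nir is not None and len(masks_nir) != n):
        raise ValueError("mask sequences must be frame-aligned with the video")
    out = np.full((n, 4), np.nan)
    for k in range(n):
        m = masks_rgb[k]
        if m is not None and m.any():
            frame = np.asarray(video.rgb[k], dtype=float)
            out[k, :3] = frame[m].mean(axis=0)
        if masks_nir is not None:
            mn = masks_nir[k]
            if mn is not None and mn.any():
                out[k, 3] = float(np.asarray(video.nir[k], dtype=float)[mn].mean())
    df = pd.DataFrame(out, columns=list(CHANNELS))
    df.attrs["fps"] = video.fps
    return df


@dataclass
class Segment:
    index: int
    samples: np.ndarray
    valid: bool


def segment(values: np.ndarray, fps: float) -> list[Segment]:
    """Cut a channel trace into raw 10-s segments.

    Segments containing missing entries (NaN) are flagged invalid.
    """
    values = np.asarray(values, dtype=float)
    width = int(round(SEGMENT_SECONDS * fps))
    segments = []
    for i in range(len(values) // width):
        chunk = values[i * width : (i + 1) * width]
        segments.append(Segment(i, chunk, valid=not np.isnan(chunk).any()))
    return segments


def highpass_taps(fps: float) -> np.ndarray:
    return sps.firwin(
        FIR_ORDER + 1, FIR_CUTOFF_HZ, fs=fps, pass_zero=False, window="hamming"
    )


def preprocess(samples: np.ndarray, fps: float) -> np.ndarray:
    """Linear detrend then zero-phase order-250 FIR highpass."""
    x = np.asarray(samples, dtype=float)
    taps = highpass_taps(fps)
    if len(x) < len(taps):
        raise ValueError(
            f"segment of {len(x)} samples is shorter than the filter ({len(taps)} taps)"
        )
    x = sps.detrend(x, type="linear")
    padlen = min(3 * len(taps), len(x) - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def spectrum(samples: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded amplitude spectrum; returns (frequencies in bpm, |X(f)|).

    The frequency resolution is fps/2**13 Hz.
    """
    x = np.asarray(samples, dtype=float)
    amp = np.abs(np.fft.rfft(x, FFT_POINTS))
    freqs_bpm = np.fft.rfftfreq(FFT_POINTS, d=1.0 / fps) * 60.0
    return freqs_bpm, amp


def estimate_hr(freqs_bpm: np.ndarray, amplitude: np.ndarray) -> float:
    """Frequency (bpm) of the amplitude maximum within 30-200 bpm.

    Ties break toward the lower frequency.
    """
    band = (freqs_bpm >= HR_BAND_BPM[0]) & (freqs_bpm <= HR_BAND_BPM[1])
    f = freqs_bpm[band]
    return float(f[np.argmax(amplitude[band])])


def harmonic_mask(freqs_bpm: np.ndarray, f_ref_bpm: float) -> np.ndarray:
    """Binary mask selecting +-5 bpm around f_ref and around 2*f_ref."""
    return (
        (np.abs(freqs_bpm - f_ref_bpm) <= HARMONIC_HALF_WIDTH_BPM)
        | (np.abs(freqs_bpm - 2.0 * f_ref_bpm) <= HARMONIC_HALF_WIDTH_BPM)
    )


def snr(freqs_bpm: np.ndarray, amplitude: np.ndarray, f_ref_bpm: float) -> float:
    """Spectral SNR (dB) of the pulse bands against the rest of 30-200 bpm."""
    if not HR_BAND_BPM[0] <= f_ref_bpm <= HR_BAND_BPM[1]:
        raise ValueError("reference HR outside the 30-200 bpm band")
    band = (freqs_bpm >= HR_BAND_BPM[0]) & (freqs_bpm <= HR_BAND_BPM[1])
    power = amplitude[band] ** 2
    pi_mask = harmonic_mask(freqs_bpm[band], f_ref_bpm)
    wanted = power[pi_mask].sum()
    noise = power[~pi_mask].sum()
    if noise == 0.0:
        return SNR_CAP_DB
    if wanted == 0.0:
        return -SNR_CAP_DB
    return float(np.clip(10.0 * np.log10(wanted / noise), -SNR_CAP_DB, SNR_CAP_DB))


def analyze_channel(
    values: np.ndarray, fps: float, f_ref_bpm: float | np.ndarray | None = None
) -> pd.DataFrame:
    """Segment-wise HR and SNR for one channel trace.

    ``f_ref_bpm`` may be a scalar or one value per segment; without it the
    SNR column is NaN.  Invalid segments report NaN estimates.
    """
    segs = segment(values, fps)
    refs = None
    if f_ref_bpm is not None:
        refs = np.broadcast_to(np.atleast_1d(f_ref_bpm).astype(float), (len(segs),))
    rows = []
    for s in segs:
        hr = snr_db = np.nan
        ref = refs[s.index] if refs is not None else np.nan
        if s.valid:
            filtered = preprocess(s.samples, fps)
            freqs, amp = spectrum(filtered, fps)
            hr = estimate_hr(freqs, amp)
            if refs is not None:
                snr_db = snr(freqs, amp, ref)
        rows.append(
            {
                "segment": s.index,
                "valid": s.valid,
                "hr_bpm": hr,
                "snr_db": snr_db,
                "f_ref_bpm": ref,
            }
        )
    return pd.DataFrame(rows)


def analyze(
    signals: pd.DataFrame, f_ref_bpm: float | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-segment HR/SNR for all four channels; returns a tidy DataFrame."""
    fps = signals.attrs["fps"]
    frames = []
    for ch in CHANNELS:
        df = analyze_channel(signals[ch].to_numpy(), fps, f_ref_bpm)
        df.insert(0, "channel", ch)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
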
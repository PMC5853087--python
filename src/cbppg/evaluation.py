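"""Study-level evaluation: HR detection rates, SNR summaries and paired
channel comparisons.

The heart-rate detection rate (HDR) of a channel is the percentage of
10-s segments whose estimated HR deviates strictly less than 5 bpm from
the reference; segments without an estimate (missing ROI) count as false.
Channel combinations assume an oracle that picks whichever of the two
channels is correct per segment (logical OR of the correctness vectors).
Per-subject HDR improvements are compared with a one-tailed Wilcoxon
signed-rank test (exact conditional distribution for n <= 25, normal
approximation with Pratt zero handling above).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

HDR_TOLERANCE_BPM = 5.0
EXACT_WILCOXON_MAX_N = 25


def correctness(estimates, references) -> np.ndarray:
    """Boolean per-segment correctness; missing estimates are false."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must be aligned")
    with np.errstate(invalid="ignore"):
        ok = np.abs(est - ref) < HDR_TOLERANCE_BPM
    ok[np.isnan(est) | np.isnan(ref)] = False
    return ok


def hdr(estimates, references) -> float:
    """HR detection rate in percent over all segments."""
    ok = correctness(estimates, references)
    if ok.size == 0:
        raise ValueError("empty segment list")
    return 100.0 * float(ok.mean())


def combine(correct_a, correct_b) -> float:
    """HDR (percent) of the per-segment OR of two correctness vectors."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must be aligned")
    if a.size == 0:
        raise ValueError("empty segment list")
    return 100.0 * float((a | b).mean())


def median_snr(snr_values, valid=None) -> float:
    """Median SNR over valid segments only (invalid ones carry no spectrum)."""
    snrs = np.asarray(snr_values, dtype=float)
    if valid is not None:
        snrs = snrs[np.asarray(valid, dtype=bool)]
    snrs = snrs[~np.isnan(snrs)]
    return float(np.median(snrs)) if snrs.size else float("nan")


def _exact_signed_rank_p_greater(diffs: np.ndarray) -> float:
    """P(W+ >= observed) under the exact conditional null distribution.

    Zeros are dropped; tied |differences| get midranks.  Midranks are
    doubled so the dynamic program runs over integers.
    """
    d = diffs[diffs != 0.0]
    if d.size == 0:
        return 0.5
    ranks = stats.rankdata(np.abs(d))
    ranks2 = np.rint(2.0 * ranks).astype(int)
    w_obs = int(np.rint(ranks2[d > 0].sum()))
    total = int(ranks2.sum())
    # distribution of the doubled signed-rank sum over all 2^n sign choices
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    tail = sum(int(c) for c in counts[w_obs:])
    return float(Fraction(tail, 2 ** len(ranks2)))


def compare(hdr_base, hdr_combined) -> float:
    """One-tailed paired signed-rank p-value for combined > base."""
    base = np.asarray(hdr_base, dtype=float)
    comb = np.asarray(hdr_combined, dtype=float)
    if base.shape != comb.shape:
        raise ValueError("paired samples must be aligned")
    if base.size < 5:
        raise ValueError("need at least 5 paired subjects")
    diffs = comb - base
    if np.all(diffs == 0.0):
        return 0.5
    if base.size <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p_greater(diffs)
    res = stats.wilcoxon(
        comb, base, alternative="greater", zero_method="pratt", method="approx"
    )
    return float(res.pvalue)


def report(segment_table: pd.DataFrame) -> dict:
    """Summarize a tidy per-segment table (columns: subject optional,
    channel, hr_bpm, snr_db, f_ref_bpm, valid) into per-channel HDRs,
    median SNRs and combined HDRs with the green channel."""
    out: dict = {"channels": {}, "combined": {}}
    per_channel_correct: dict[str, np.ndarray] = {}
    for ch, grp in segment_table.groupby("channel"):
        ok = correctness(grp["hr_bpm"].to_numpy(), grp["f_ref_bpm"].to_numpy())
        per_channel_correct[ch] = ok
        out["channels"][ch] = {
            "hdr_percent": 100.0 * float(ok.mean()),
            "median_snr_db": median_snr(
                grp["snr_db"].to_numpy(), grp["valid"].to_numpy()
            ),
            "n_segments": int(len(grp)),
            "n_valid": int(grp["valid"].sum()),
        }
    if "G" in per_channel_correct:
        for other in ("B", "R", "N"):
            if other in per_channel_correct:
                out["combined"][f"G&{other}"] = combine(
                    per_channel_correct["G"], per_channel_correct[other]
                )
    return out
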
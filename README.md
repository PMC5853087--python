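# cbppg

Anatomy-free ROI selection, tracking and pulse extraction for
**camera-based photoplethysmography (cbPPG)**.

Cameras can measure the blood-volume pulse remotely: skin pixels brighten
and darken slightly with every heartbeat (a few intensity units at 12-bit
depth).  Turning video into a usable plethysmogram requires choosing a
region of interest (ROI) on visible skin and keeping it valid while people
and lights move.  Face detectors fail when the face is draped, rotated or
partially blocked — the common situation in clinical settings — and
methods that look for the pulse itself fail when the pulse is weak.
`cbppg` implements a selection principle that needs neither: find skin by
color, then let a level-set segmentation carve out the most
**homogeneously illuminated** skin regions, which carry the cleanest pulse
signal and the least ballistocardiographic contamination.

The pipeline, for synchronized RGB and near-infrared (NIR) streams:

1. **Bayesian skin classifier** — a pixel with color `c` is skin when
   `p(c|skin)/p(c|¬skin) ≥ θ` (θ = 5), with class densities from
   normalized 3-D RGB histograms; images are percentile contrast-stretched
   first.
2. **Two-phase level-set segmentation** — gradient descent on
   `∂Φ/∂t = H'(Φ)[Σⱼ log(p₁ⱼ(Fⱼ)/p₂ⱼ(Fⱼ)) + ν·div(∇Φ/|∇Φ|)]` with
   features `F = (I_R, I_G, I_B, J_RGB)` (intensities + 5×5 local-SD
   texture), Gaussian region models re-estimated every iteration, and
   ν = 0.001·|Ω|^0.7.  The classifier output initializes Ω₁.
3. **Block-matching registration** — the ROI is transferred to the NIR
   grid by minimizing a mean-adjusted MSE over 5×5 green-channel blocks
   within d_x ∈ [−60, 0], d_y ∈ [0, 10], then refined by a second
   segmentation with `F = (I_N, J_N)`.
4. **Tracking with artifact monitoring** — each frame's segmentation
   starts from the previous ROI (≤50 iterations, early stop); the detector
   re-runs when the ROI disappears or when the 10-s standard deviation of
   the mean ROI intensity exceeds 50 units, with a 10-s monitoring pause
   after every reselection.
5. **Signal analysis** — per-channel ROI means → 10-s segments →
   detrend + order-250 FIR highpass (0.5 Hz, zero-phase) → FFT
   (zero-padded to 2¹³) → HR = spectral peak in 30–200 bpm, SNR = pulse
   band (±5 bpm around the reference HR and its harmonic) vs. the rest,
   heart-rate detection rate (HDR) = % of segments within 5 bpm.

A fully scripted synthetic scene generator (`cbppg.synthetic`) renders
RGB+NIR recordings with ground-truth masks, a bounded pulsatile component
(≤ ±15 units), occlusions, illumination steps and camera-viewpoint offsets
so every stage is testable end to end.  See `docs/methods.md` for the
model details and numerical choices.

## Worked example

```python
from cbppg import synthetic
from cbppg.config import PipelineConfig
from cbppg.pipeline import run_pipeline, train_default_skin_model

config = PipelineConfig()
model = train_default_skin_model(config)

script = synthetic.SceneScript(duration=30.0, fps=30.0,
                               heart_rate_bpm=72.0, seed=7)
video, truth = synthetic.render_video_pair(script)

result = run_pipeline(video, model, config, f_ref_bpm=truth.f_ref_bpm)
print(result.segments[result.segments.channel == "G"])
print(result.report["channels"]["G"])
```

prints

```
  channel  segment  valid     hr_bpm    snr_db  f_ref_bpm
3       G        0   True  71.630859  7.618532       72.0
4       G        1   True  71.630859  7.585303       72.0
5       G        2   True  71.630859  7.646965       72.0
{'hdr_percent': 100.0, 'median_snr_db': 7.618532..., 'n_segments': 3, 'n_valid': 3}
```

Three 10-s segments were extracted from the tracked green-channel ROI; in
each the spectral peak lands at 71.63 bpm (the FFT bin closest to the
scripted 72 bpm at this padding), well inside the 5-bpm HDR tolerance, so
the detection rate is 100%.  The ~7.6 dB SNR says the pulse band holds
roughly six times the power of the rest of the 30–200 bpm band under the
scripted noise (sd 5 units).

The same stages are available from the shell:

```bash
cbppg simulate work/vid --duration 30 --fps 30 --seed 7
cbppg run work/vid work/out          # detection → tracking → HR/SNR report
```

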
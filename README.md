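# turbiflim

Monte Carlo simulation and phasor analysis of **time-gated widefield
fluorescence lifetime imaging (FLIM) through turbid media**.

Near-infrared fluorophores such as indocyanine green (ICG, τ ≈ 0.65 ns)
and IRDye800 (τ ≈ 1.0 ns) can be told apart *inside* scattering tissue by
their fluorescence lifetimes even when their emission spectra overlap and
their images blur into each other. `turbiflim` is for researchers studying
that regime: it simulates the photon physics end to end — exponential
emission decay sampled by a zero-width time gate, random-walk transport
through an absorbing, scattering semi-infinite slab (Henyey–Greenstein
phase function, Fresnel surface), and detection by a pixelated
single-photon array — and then recovers lifetimes from the simulated gate
stacks exactly the way one would from a time-gated SPAD camera.

## Model and analysis in brief

Photons emitted at gate sample `t_k = (k−1)·g_s` number
`N(t_k) = round(A·e^{−t_k/τ})`, `A = round(a·QY)`. Each photon walks
through the medium (μ_a, μ_s, g, n) until absorbed or escaped; escaped
photons are thinned by the detector's photon efficiency and binned into
pixels, one image per gate. Per pixel the first-harmonic phasor is

    g = Σ_k F(t_k) cos(2πf t_k) / Σ_k F(t_k)
    s = Σ_k F(t_k) sin(2πf t_k) / Σ_k F(t_k)

with `f` the laser repetition rate. After calibration against a reference
of known lifetime, the phase lifetime per pixel is `τ_φ = tan(φ)/(2πf)`,
`φ = atan2(s, g)`. Single dyes are quantified by the mean of the per-pixel
`τ_φ` histogram; two adjacent dyes are unmixed by windowing the histogram
(0–1.5 ns), trimming extreme values with a symmetric percentile "cutoff",
and reading off the two most prominent peaks. See `docs/methods.md` for
the full model, the sparse-photon histogram ladder, and every numerical
choice.

## Worked example

Simulate the two-dye scene (ICG-like and IRDye800-like mimics 2 cm apart,
0.1 cm deep, photon budget scaled to 10%) and unmix the two lifetimes:

```bash
$ turbiflim multiplex --z 0.1 --dx 2.0 --scale 0.1 --seed 7 --out run/
tau_short=0.625  tau_long=1.065  (n=357 pixels after cutoff)
```

The two recovered components sit near the ground-truth lifetimes 0.65 and
1.0 ns: the scattered tails of both spots reach the detector window
between them, each pixel's calibrated phasor angle encodes a lifetime, and
after a 1% percentile cutoff the histogram of per-pixel phase lifetimes
shows one peak per dye. `run/` holds the gate stack (multi-page TIFF +
JSON sidecar), the histogram CSV, the per-pixel lifetime map (float32
TIFF), the phasor scatter CSV and `results.json`.

The same thing in Python:

```python
from turbiflim.config import RunConfig, AnalysisOptions, run_pipeline

cfg = RunConfig(scene="two_dye_depth", z=0.1, dx=2.0, scale=0.1, seed=7,
                analysis=AnalysisOptions(cutoff_percent=1.0,
                                         time_window=(0.0, 1.5)))
res = run_pipeline(cfg)
print(res["tau_short_ns"], res["tau_long_ns"])   # 0.625 1.065
```

Other entry points: `turbiflim fixtures` (scene JSONs), `simulate`
(forward model → TIFF), `analyze` (phasor analysis of a saved stack),
`stats` (mean intensity ⟨I⟩ and mean spot radius ⟨R⟩ versus depth), and
`turbiflim reproduce --figure {2,3,4,5}` for scaled-down sweeps of the
intensity/radius depth trends, single-dye lifetime-vs-depth series, and
the two-dye depth and separation series.

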
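# Methods

## Model overview

`turbiflim` simulates widefield time-gated fluorescence lifetime imaging
(FLIM) of near-infrared fluorophores buried in a tissue-like turbid medium,
and analyses the resulting gate stacks with per-pixel phasors. The
forward model is a deliberately *simplified* fluorescence Monte Carlo
scheme:

1. **Emission only.** Excitation transport is not modelled. A fluorophore at
   depth `z` is an isotropic point source of emission photons.
2. **Decay sampled at the gates.** The gate width is zero: gate `k` is a
   point sample of the decay curve at `t_k = (k-1)·g_s`, and the photons
   emitted "into" gate `k` number `N(t_k) = round(A·exp(-t_k/τ))` with
   `A = round(a·QY)` (`a` = initial photon budget, `QY` = quantum yield).
   There is no inter-period pile-up and no instrument-response convolution.
3. **Gate index is decay time, not arrival time.** A photon emitted at
   sample `t_k` is recorded in gate `k` no matter how long its random walk
   through the medium took. Time of flight is retained per photon for
   diagnostics only. Consequence: detection probability is identical for
   every gate, so the *detected* per-gate counts remain proportional to
   `N(t_k)` in expectation — this is what makes lifetime recovery through
   arbitrary depths possible in this model.

## Photon transport

Each photon performs a hop/fate/spin walk in a homogeneous semi-infinite
slab (no bottom or lateral boundaries):

* hop: exponential step `-ln(ξ)/μ_t`, `μ_t = μ_a + μ_s`;
* fate: whole-photon binary absorption with probability `μ_a/μ_t` at each
  interaction (no packet weights or roulette — the detector counts whole
  photons);
* spin: Henyey–Greenstein deflection with mean cosine `g`, uniform azimuth.

A hop crossing `z = 0` is advanced exactly to the plane; an unpolarized
Fresnel test (total internal reflection included) decides escape into air
(`n_out = 1`) versus specular reflection back into the medium. The Fresnel
boundary can be disabled (`fresnel_boundary=False`); the treatment at the
interface is an explicit, switchable modelling choice.
After reflection a fresh exponential step is drawn; by memorylessness this
is statistically identical to carrying the residual step. A source exactly
at `z = 0` escapes in place (degenerate case, defined for completeness).

Default optics (skin-like, ~800 nm): `n = 1.4`, `μ_a = 0.4 /cm`,
`μ_s = 300 /cm`, `g = 0.96`. The robustness variants `μ_s = 403` and
`503 /cm` are reachable through `TissueOptics`. Lengths are cm, attenuation
coefficients 1/cm, times ns throughout. A hard cap of 10⁶ interactions per
photon guarantees termination when `μ_a = 0`; capped photons are tallied as
`truncated` (always zero in the default configurations, which is asserted
in tests).

**Verification.** The transport kernel is checked against (i) an
independent lockstep NumPy walker implementing the same rules from scratch
(escape fraction and mean exit radius within 3 Monte Carlo standard errors
at 10⁵ photons), and (ii) a closed form: with `μ_s = 0` and the Fresnel
boundary off, the escape probability of an isotropic source is
`½∫₀¹ exp(-μ_a z/u) du`, reproduced within 3 SE.

## Detector

The detector is a contact-imaging pixel array on the tissue surface:
the exit point of an escaped photon maps directly to the enclosing pixel
(real acquisitions image through an objective lens; lens models are out
of scope). Default geometry: 1 × 1 cm, 512 × 512 pixels (19.53 µm pitch),
13% photon efficiency. Efficiency is applied as a per-photon Bernoulli
thinning so pixel counts stay integral; in expectation this equals the
"multiply by the photon efficiency" prescription. Counts are stored one
2-D page per gate (`GateStack`), serialized as multi-page TIFF (16- or
32-bit unsigned) with a JSON sidecar carrying gate timing, geometry, scene
and seed.

Two-source scenes place the dyes at lateral `±Δx/2` around the detector
center. For separations larger than the frame (the multiplexing scenes
use Δx = 1–2 cm) the recorded frame *is* the central 512 × 512 window
between the spots, at the default pitch: only the scattered tails of both
spots reach it, which is exactly the region the two-dye histograms
analyse. The wide
display frame can still be produced by configuring a larger
`DetectorConfig`.

Default gating: `G = 117` gates, `g_s = 428 ps` step, 20 MHz repetition
rate (50 ns period), zero gate width.

## Phasor analysis

Per pixel, `g = Σ_k F(t_k)cos(ωt_k)/ΣF`, `s = Σ_k F(t_k)sin(ωt_k)/ΣF` with
`ω = 2πf` and `f` the laser repetition rate (20 MHz → 0.02 GHz). Some
formulations print the angular argument of these sums as `2πk t_k`, which
is dimensionally inconsistent; this package uses `2πf t_k`, the standard
first-harmonic phasor, and logs the resolved frequency at run time. Phase uses the two-argument arctangent; `τ_φ = tan(φ)/ω`. Phases
outside (−π/2, π/2) have no mono-exponential reading at this harmonic and
are flagged NaN rather than wrapped; `φ = π/2` would be an infinite
lifetime.

**Calibration** multiplies every pixel phasor by the single complex factor
that moves the *measured aggregate* phasor of a reference of known
lifetime onto its theoretical point
`(1/(1+(ωτ)²), ωτ/(1+(ωτ)²))`. The aggregate is the photon-weighted mean
over valid pixels, i.e. the phasor of the region's summed decay. For
simulated data the reference is a simulated 0.65 ns dye (an indocyanine
green mimic); τ_ref = 0 (an instrument response) maps to (1, 0). Because
gate index equals decay sample in this model, the reference's aggregate
phasor is independent of the depth it is simulated at (verified
incidentally by the depth series); the package simulates it at the depth
of the analysed scene for symmetry.

Calibration against the *continuous* theory point also absorbs most of the
bias introduced by sampling the decay at discrete gates, for target
lifetimes near the reference lifetime. This matters in the sparse regime
discussed next.

## Sparse-photon regime and the histogram ladder

At the default photon budgets the detected photons are far fewer than the
pixels, so most analysed pixels hold a single photon. A one-photon pixel's
phasor lies on the unit circle at angle `ωt_k + Δφ` (Δφ = calibration
rotation), so its phase lifetime falls on a discrete ladder
`tan(ωt_k + Δφ)/ω` — with the default gating and an ICG-like reference:
≈ 0.19, 0.62, 1.05, 1.49 … ns. Lifetime histograms of photon-starved
regions are therefore a small set of bars on this ladder (plus a
continuum from multi-photon pixels), the "discrete" histogram behaviour characteristic of this regime. Two useful facts follow:

* The *mean* of the per-pixel phase lifetimes remains ≈ τ even in the
  fully sparse limit: the calibration shift compensates the discrete
  sampling bias of the mean emission time, to first order, for lifetimes
  near the reference. This is why single-dye histogram means recover the
  ground truth at any depth.
* The tallest single-photon bar is always the first-gate bar (~0.19 ns),
  which represents photons confined to one early gate, not a resolvable
  lifetime component. Zero-width gate sampling cannot resolve lifetimes
  below the gate step, so two-component extraction applies a
  **resolvability floor**: candidate peaks below one gate step (0.428 ns)
  are excluded from the component search. Without the floor the "short
  component" of any sparse two-dye region would be reported as ≈ 0.19 ns.

Component extraction ranks local maxima of the (3-bin moving-average
smoothed) histogram by prominence and reports the two strongest above the
floor, shorter first; a two-component Gaussian-mixture fit is available as
an opt-in alternative (`method="gmm"`). If only one maximum exists the
result is flagged `single_peak`.

With these defaults the two-dye scenes (0.65/1.0 ns, separations 1–2 cm,
depths 0.1–0.9 cm, 1% cutoff) yield short/long peaks of ≈ 0.58–0.63 and
≈ 1.00–1.07 ns. The reference values these configurations are expected to
reproduce are 0.66 and 1.04 ns; that pair is spaced 0.38 ns apart, which
is narrower than any rigid rotation of the single-photon ladder allows
(≥ 0.43 ns), so such peaks cannot be pure ladder bars — they plausibly
mix denser pixels under coarser histogram binning. The package keeps its
own 0.01 ns bins and reports what the model produces; the recovered
values agree with the reference ones to within the Monte Carlo scatter of
the scaled runs.

## Cutoff and windowing

The "cutoff" is a symmetric two-tail percentile trim on the retained
per-pixel `τ_φ` values: at `p` %, pixels below the `p`-th or above the
`(100−p)`-th percentile are removed and the histogram is re-binned. Among the
possible conventions (each tail vs. split tails vs. bin-count
thresholding), each-tail trimming was chosen as the plain reading of
outlier exclusion via percentiles. Two-dye analyses
additionally restrict to a lifetime window (default 0–1.5 ns, the range
bracketing the lifetimes of the dyes of interest) before trimming. Single-dye estimates
use the plain histogram mean with no window or cutoff.

Histogram bin width defaults to 0.01 ns with edges aligned to integer
multiples of the width, so peak positions are stable across runs. Pixels
below a minimum total count (default 1 photon) are excluded.

## Synthetic data and what the tests show

`fixtures.preset_scene` pins the reference conditions: optics above; budgets
`a = 5·10⁶` (single-dye lifetime family) and `a = 7.6·10⁷` (intensity and
two-dye family); dye presets (0.65 ns/0.9%, 1.0 ns/1.3%, 0.8 ns/18%,
1.1 ns/28%); PE 13%; G = 117 × 428 ps at 20 MHz. A single `scale` factor
multiplies budgets for reduced runs; default test and acceptance runs use
`scale = 0.1`, chosen so the full acceptance sweep (13 scenes plus
references) completes in a few minutes on one CPU, with quoted tolerances
widened by up to 3 Monte Carlo standard errors of the scaled runs.

`analytic_stack` provides transport-free mono-exponential stacks (exact
expectation or Poisson-sampled) used as phasor oracles: self-calibrated
noiseless stacks must land on the universal semicircle to 1e−9 and return
`τ_φ = τ` to 1e−9. `inject_background` adds Poisson dark counts per
pixel/gate to stress the cutoff; the dark rate in the demonstration test
(0.5 counts/pixel/gate against bright analytic spots) is set so the plain
windowed mean is biased by well over 0.1 ns while window + 5% cutoff still
recovers both components.

What passing tests do *not* show about real data: no instrument response,
no overlapping gates (the experimental `g_w = 10 ns` regime), no dark
counts or afterpulsing in the forward model, no lens optics, no phantom
inhomogeneity, and whole-photon transport in a homogeneous slab only.
Reproducing measured phantom data is out of scope.

## Numerical choices

* Rounding of photon counts (`A`, `N(t_k)`) is round-half-to-even
  (unbiased across gates).
* The production walk kernel (Numba) uses one xorshift64* stream per call,
  seeded via a splitmix64 scramble of a `SeedSequence` child; runs are
  exactly reproducible for a given seed. The scalar sampling functions and
  the pure-Python reference walker use `numpy.random.Generator`.
* Per-scene and per-source seeds derive from `SeedSequence.spawn`, so
  multi-source scenes are reproducible and order-stable.
* Peak ties are broken by prominence order as returned by
  `scipy.signal.find_peaks` on the zero-padded histogram (edge maxima are
  detectable); equal-prominence ties resolve to the earlier bin.
* Degenerate inputs: empty scenes, zero-count ROIs, all-zero histograms
  and out-of-range cutoffs raise immediately with specific messages;
  `(g, s) = (0, 0)` pixels propagate as NaN.

## Known limitations

* Lifetimes below one gate step are unresolvable by construction; the
  resolvability floor makes this explicit rather than silently reporting
  ladder artifacts.
* The per-pixel `τ_φ` mean is a heavy-tailed estimator (tan diverges as
  φ → π/2); at very low pixel counts (deep sources at small scale) its
  Monte Carlo error is large and right-skewed. The pipeline reports the
  histogram standard error alongside the mean.
* The default detector pitch follows the 1 cm / 512 px geometry
  (19.53 µm); an alternative 16.38 µm pitch (0.84 cm width) is sometimes
  quoted for the same sensor. Pitch is configurable; results here use
  19.53 µm.
* The default scattering coefficient is 300 /cm; higher-scattering
  variants (403/503 /cm) are reachable through `TissueOptics` for
  robustness checks.
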
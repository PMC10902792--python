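"""Per-pixel phasor analysis of time-gated decay stacks.

For a pixel with gate intensities F(t_k) the uncalibrated phasor is

    g = sum_k F(t_k) cos(2 pi f t_k) / sum_k F(t_k)
    s = sum_k F(t_k) sin(2 pi f t_k) / sum_k F(t_k)

with f the harmonic frequency, taken equal to the laser repetition rate
(f = 1/T).  Calibration against a reference of known lifetime rotates and
scales every pixel phasor by a single complex factor mapping the measured
aggregate reference phasor onto its theoretical mono-exponential location

    g_th = 1 / (1 + (2 pi f tau)^2),    s_th = 2 pi f tau / (1 + (2 pi f tau)^2),

so calibrated mono-exponential pixels land on the universal semicircle.
Phase lifetimes tau_phi = tan(phi) / (2 pi f) are histogrammed per pixel;
the percentile "cutoff" method symmetrically trims extreme tau_phi values
before component lifetimes are read off the histogram (mean for one dye,
the two most prominent peaks for a two-dye mixture).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .detector import GateStack

__all__ = [
    "PhasorField",
    "LifetimeHistogram",
    "TwoPeakResult",
    "theoretical_phasor",
    "compute_phasor",
    "calibrate",
    "phase_and_modulation",
    "phase_lifetime",
    "pixel_phase_lifetimes",
    "lifetime_histogram",
    "apply_cutoff",
    "extract_single_lifetime",
    "extract_two_lifetimes",
]


def _omega(freq_mhz: float) -> float:
    """Angular frequency in rad/ns for a harmonic frequency in MHz."""
    return 2.0 * math.pi * freq_mhz * 1e-3


def theoretical_phasor(tau_ns: float, freq_mhz: float) -> complex:
    """Phasor of an ideal mono-exponential decay of lifetime ``tau_ns``.

    tau = 0 (an ideal instrument response) maps to (1, 0).
    """
    wt = _omega(freq_mhz) * tau_ns
    return complex(1.0, wt) / (1.0 + wt * wt)


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates over a region of interest.

    ``g``/``s`` are 2-D float arrays; ``valid`` marks pixels whose total
    count reached the minimum (phasors of empty pixels are undefined).
    ``roi`` records the (row0, col0) offset of the field inside the parent
    stack, for traceability of exported coordinates.
    """

    g: np.ndarray
    s: np.ndarray
    total: np.ndarray
    valid: np.ndarray
    freq_mhz: float
    calibrated: bool = False
    roi_offset: tuple[int, int] = (0, 0)
    meta: dict = field(default_factory=dict)

    @property
    def z(self) -> np.ndarray:
        """Complex view g + i s."""
        return self.g + 1j * self.s

    def aggregate(self) -> complex:
        """Photon-weighted mean phasor over valid pixels.

        Equals the phasor of the summed decay of the region, which is the
        natural aggregate for calibration references.
        """
        sel = self.valid
        w = self.total[sel].astype(float)
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("no valid pixels to aggregate")
        return complex((w * self.g[sel]).sum() / wsum, (w * self.s[sel]).sum() / wsum)


@dataclass
class LifetimeHistogram:
    """Binned distribution of per-pixel phase lifetimes.

    ``source_values`` keeps the underlying per-pixel tau_phi values so the
    cutoff and the mean operate on pixels, not on binned counts.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    source_values: np.ndarray
    bin_width: float
    cutoff_percent: float = 0.0
    time_window: tuple[float, float] | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_retained(self) -> int:
        return int(self.source_values.size)


@dataclass(frozen=True)
class TwoPeakResult:
    """Two-component lifetime estimate from a histogram."""

    tau_short: float
    tau_long: float | None
    single_peak: bool = False

    def as_tuple(self) -> tuple[float, float | None]:
        return (self.tau_short, self.tau_long)


def compute_phasor(
    stack: GateStack,
    roi: tuple[int, int, int, int] | None = None,
    min_count: float = 1,
) -> PhasorField:
    """Per-pixel (g, s) of a gate stack over an optional ROI.

    ``roi`` is (row0, row1, col0, col1) in pixel indices (half-open).  The
    harmonic frequency is the laser repetition rate from the stack metadata.
    Pixels with total counts below ``min_count`` are flagged invalid.
    """
    if stack.num_gates < 2:
        raise ValueError("need at least 2 gates for a phasor")
    counts = stack.counts
    offset = (0, 0)
    if roi is not None:
        r0, r1, c0, c1 = roi
        if not (0 <= r0 < r1 <= counts.shape[1] and 0 <= c0 < c1 <= counts.shape[2]):
            raise ValueError("roi out of image bounds")
        counts = counts[:, r0:r1, c0:c1]
        offset = (r0, c0)
    f_mhz = stack.gates.rep_rate_mhz
    w = _omega(f_mhz)
    t = stack.gate_times_ns
    cosw = np.cos(w * t)
    sinw = np.sin(w * t)
    dat = counts.astype(np.float64)
    total = dat.sum(axis=0)
    valid = total >= max(min_count, np.finfo(float).tiny)
    if not valid.any():
        warnings.warn("phasor ROI contains no pixels with counts", stacklevel=2)
    denom = np.where(valid, total, 1.0)
    g = np.tensordot(cosw, dat, axes=(0, 0)) / denom
    s = np.tensordot(sinw, dat, axes=(0, 0)) / denom
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorField(
        g=g, s=s, total=total, valid=valid, freq_mhz=f_mhz, roi_offset=offset
    )


def calibrate(
    raw: PhasorField, ref_raw: PhasorField, ref_lifetime_ns: float
) -> PhasorField:
    """Rotate-and-scale ``raw`` so the reference lands on its theory point.

    The single complex factor (g_th + i s_th) / (g_ref + i s_ref) is built
    from the photon-weighted aggregate phasor of the measured reference;
    a zero reference lifetime (instrument response) maps to (1, 0).
    """
    if ref_raw.freq_mhz != raw.freq_mhz:
        raise ValueError("reference and target use different harmonic frequencies")
    z_ref = ref_raw.aggregate()
    if abs(z_ref) < 1e-15:
        raise ValueError("reference aggregate phasor is at the origin; uncalibratable")
    factor = theoretical_phasor(ref_lifetime_ns, raw.freq_mhz) / z_ref
    z = raw.z * factor
    out = replace(raw, g=z.real, s=z.imag, calibrated=True)
    out.meta = dict(raw.meta)
    out.meta["calibration"] = {
        "ref_lifetime_ns": ref_lifetime_ns,
        "factor_real": factor.real,
        "factor_imag": factor.imag,
    }
    return out


def phase_and_modulation(fld: PhasorField) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel phase phi = atan2(s, g) and modulation m = |(g, s)|.

    Invalid pixels (including (g, s) = (0, 0), where the phase is undefined)
    propagate as NaN.
    """
    with np.errstate(invalid="ignore"):
        phi = np.arctan2(fld.s, fld.g)
        m = np.hypot(fld.g, fld.s)
    degenerate = (fld.g == 0) & (fld.s == 0)
    phi = np.where(degenerate, np.nan, phi)
    m = np.where(degenerate, np.nan, m)
    return phi, m


def phase_lifetime(phi: np.ndarray | float, freq_mhz: float) -> np.ndarray:
    """tau_phi = tan(phi) / (2 pi f), in ns for f in MHz.

    Phases outside (-pi/2, pi/2) have no mono-exponential interpretation at
    this harmonic and are flagged NaN rather than silently wrapped; phi
    exactly pi/2 would be an infinite lifetime.  Slightly negative phases
    (noise around tau = 0) produce negative values that downstream windows
    or cutoffs are expected to handle.
    """
    if freq_mhz <= 0:
        raise ValueError("frequency must be positive")
    phi_arr = np.asarray(phi, dtype=float)
    with np.errstate(invalid="ignore"):
        tau = np.tan(phi_arr) / _omega(freq_mhz)
        tau = np.where(np.abs(phi_arr) < math.pi / 2.0, tau, np.nan)
    return tau


def pixel_phase_lifetimes(fld: PhasorField) -> np.ndarray:
    """Per-pixel tau_phi map (NaN where invalid/non-physical)."""
    phi, _ = phase_and_modulation(fld)
    return phase_lifetime(phi, fld.freq_mhz)


def lifetime_histogram(
    fld: PhasorField,
    bin_width: float = 0.01,
    time_window: tuple[float, float] | None = None,
) -> LifetimeHistogram:
    """Histogram of per-pixel phase lifetimes over the valid ROI pixels.

    Bin edges are aligned to integer multiples of ``bin_width`` so peak
    positions are stable across runs.  ``time_window`` (ns) optionally
    restricts the retained values.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    tau = pixel_phase_lifetimes(fld)
    vals = tau[np.isfinite(tau) & fld.valid]
    if time_window is not None:
        lo, hi = time_window
        if hi <= lo:
            raise ValueError("time window must be an increasing interval")
        vals = vals[(vals >= lo) & (vals <= hi)]
    return _make_hist(vals, bin_width, time_window, cutoff_percent=0.0)


def _make_hist(
    vals: np.ndarray,
    bin_width: float,
    time_window: tuple[float, float] | None,
    cutoff_percent: float,
) -> LifetimeHistogram:
    vals = np.asarray(vals, dtype=float)
    if vals.size == 0:
        warnings.warn("empty lifetime histogram", stacklevel=3)
        edges = np.array([0.0, bin_width])
        counts = np.zeros(1, dtype=np.int64)
    else:
        lo = math.floor(vals.min() / bin_width)
        hi = math.floor(vals.max() / bin_width) + 1
        edges = np.arange(lo, hi + 1) * bin_width
        counts, _ = np.histogram(vals, bins=edges)
    return LifetimeHistogram(
        bin_edges=edges,
        counts=counts.astype(np.int64),
        source_values=vals,
        bin_width=bin_width,
        cutoff_percent=cutoff_percent,
        time_window=time_window,
    )


def apply_cutoff(hist: LifetimeHistogram, percent: float) -> LifetimeHistogram:
    """Symmetric two-tail percentile trim of the per-pixel lifetimes.

    Removes pixels whose tau_phi lies below the ``percent``-th or above the
    (100 - percent)-th percentile of the retained values, then re-bins.
    ``percent`` refers to each tail and must lie in [0, 50).
    """
    if not 0 <= percent < 50:
        raise ValueError("cutoff percent must lie in [0, 50)")
    if percent == 0 or hist.source_values.size == 0:
        return replace(hist, cutoff_percent=percent)
    lo, hi = np.percentile(hist.source_values, [percent, 100.0 - percent])
    keep = (hist.source_values >= lo) & (hist.source_values <= hi)
    return _make_hist(
        hist.source_values[keep], hist.bin_width, hist.time_window, percent
    )


def extract_single_lifetime(hist: LifetimeHistogram) -> float:
    """Mean of the retained per-pixel phase lifetimes (single-dye estimate)."""
    if hist.source_values.size == 0:
        raise ValueError("cannot extract a lifetime from an empty histogram")
    return float(hist.source_values.mean())


def extract_two_lifetimes(
    hist: LifetimeHistogram,
    smooth_window: int = 3,
    method: str = "peaks",
    min_tau: float | None = None,
) -> TwoPeakResult:
    """Locate the two component lifetimes of a bimodal histogram.

    ``method='peaks'`` (default) ranks local maxima of the moving-average
    smoothed histogram by prominence and returns the bin centers of the two
    strongest, shorter lifetime first.  ``method='gmm'`` instead fits a
    two-component Gaussian mixture to the retained values.  If only one
    maximum exists the result carries ``single_peak=True``.

    ``min_tau`` is a resolvability floor: maxima at bin centers below it
    are not counted as components.  Zero-width gate sampling cannot resolve
    lifetimes shorter than the gate step, and in photon-starved regions the
    histogram grows a spurious near-zero bar from pixels whose only photons
    sit in the first gate; callers analysing gated stacks should pass the
    gate step (in ns) here.
    """
    if hist.source_values.size == 0 or not np.any(hist.counts):
        raise ValueError("cannot extract peaks from an empty histogram")
    if method == "gmm":
        return _two_lifetimes_gmm(hist, min_tau=min_tau)
    if method != "peaks":
        raise ValueError(f"unknown method {method!r}")
    counts = hist.counts.astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smooth = np.convolve(counts, kernel, mode="same")
    else:
        smooth = counts
    # pad so maxima at the histogram edges are still detected
    padded = np.concatenate(([0.0], smooth, [0.0]))
    idx, props = find_peaks(padded, prominence=0.0)
    idx -= 1
    prom = props["prominences"]
    if min_tau is not None:
        keep = hist.bin_centers[idx] >= min_tau
        idx, prom = idx[keep], prom[keep]
    if idx.size == 0:
        allowed = np.ones_like(counts, dtype=bool)
        if min_tau is not None:
            allowed = hist.bin_centers >= min_tau
        if not np.any(allowed & (counts > 0)):
            raise ValueError("no histogram mass above the resolvability floor")
        masked = np.where(allowed, counts, -1.0)
        peak = float(hist.bin_centers[int(np.argmax(masked))])
        return TwoPeakResult(peak, None, single_peak=True)
    order = np.argsort(prom)[::-1]
    if idx.size == 1:
        return TwoPeakResult(float(hist.bin_centers[idx[0]]), None, single_peak=True)
    top = np.sort(idx[order[:2]])
    centers = hist.bin_centers
    return TwoPeakResult(float(centers[top[0]]), float(centers[top[1]]))


def _two_lifetimes_gmm(
    hist: LifetimeHistogram, seed: int = 0, min_tau: float | None = None
) -> TwoPeakResult:
    """Two-component Gaussian-mixture alternative to peak picking."""
    from sklearn.mixture import GaussianMixture

    vals = hist.source_values
    if min_tau is not None:
        vals = vals[vals >= min_tau]
    if vals.size == 0:
        raise ValueError("no histogram mass above the resolvability floor")
    vals = vals.reshape(-1, 1)
    if np.unique(vals).size < 2:
        return TwoPeakResult(float(vals[0, 0]), None, single_peak=True)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(vals)
    means = np.sort(gm.means_.ravel())
    return TwoPeakResult(float(means[0]), float(means[1]))
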
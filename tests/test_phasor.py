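"""Phasor math: closed-form oracles, calibration closure, histogram/cutoff."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turbiflim import (
    DetectorConfig,
    GateConfig,
    GateStack,
    PhasorField,
    analytic_stack,
    apply_cutoff,
    calibrate,
    compute_phasor,
    extract_single_lifetime,
    extract_two_lifetimes,
    lifetime_histogram,
    phase_and_modulation,
    phase_lifetime,
    pixel_phase_lifetimes,
    theoretical_phasor,
)
from turbiflim.phasor import _make_hist

OMEGA = 2 * math.pi * 20.0 * 1e-3  # rad/ns at the 20 MHz harmonic


def _field_from_taus(taus, freq_mhz=20.0, calibrated=True):
    """Build a 1 x n PhasorField whose pixels sit at theory points."""
    zs = np.array([theoretical_phasor(t, freq_mhz) for t in taus])
    g = zs.real.reshape(1, -1)
    s = zs.imag.reshape(1, -1)
    total = np.ones_like(g) * 10
    return PhasorField(
        g=g, s=s, total=total, valid=np.ones_like(g, bool),
        freq_mhz=freq_mhz, calibrated=calibrated,
    )


def _delta_stack(gate_idx: int, n_gates=10, value=100):
    counts = np.zeros((n_gates, 2, 2), np.uint32)
    counts[gate_idx] = value
    gates = GateConfig(num_gates=n_gates, gate_step_ps=5000.0, rep_rate_mhz=20.0)
    det = DetectorConfig(n_px_x=2, n_px_y=2)
    return GateStack(counts, gates, det)


class TestComputePhasor:
    def test_delta_at_time_zero_maps_to_unit_phasor(self):
        fld = compute_phasor(_delta_stack(0))
        assert np.allclose(fld.g[fld.valid], 1.0, atol=1e-12)
        assert np.allclose(fld.s[fld.valid], 0.0, atol=1e-12)

    def test_uniform_over_full_period_is_dc_only(self):
        # 100 gates x 500 ps tile exactly one 50 ns period
        counts = np.full((100, 2, 2), 7, np.uint32)
        gates = GateConfig(num_gates=100, gate_step_ps=500.0, rep_rate_mhz=20.0)
        stack = GateStack(counts, gates, DetectorConfig(n_px_x=2, n_px_y=2))
        fld = compute_phasor(stack)
        assert np.all(np.abs(fld.g[fld.valid]) < 1e-10)
        assert np.all(np.abs(fld.s[fld.valid]) < 1e-10)

    def test_discrete_exponential_matches_geometric_series_oracle(self):
        """Noiseless tau = 1 ns sampled at the default gating equals the
        closed-form geometric sum computed independently."""
        tau = 1.0
        stack = analytic_stack(tau, 1e6, gates=GateConfig(), mode="expectation")
        fld = compute_phasor(stack, min_count=1e-12)
        # independent direct summation over the same gate grid
        t = np.arange(117) * 0.428
        w = np.exp(-t / tau)
        z_oracle = np.sum(w * np.exp(1j * OMEGA * t)) / w.sum()
        c = stack.counts.sum(axis=0)
        iy, ix = np.unravel_index(np.argmax(c), c.shape)
        assert fld.g[iy, ix] == pytest.approx(z_oracle.real, abs=1e-12)
        assert fld.s[iy, ix] == pytest.approx(z_oracle.imag, abs=1e-12)

    def test_zero_roi_warns_and_flags_invalid(self):
        counts = np.zeros((10, 4, 4), np.uint32)
        gates = GateConfig(num_gates=10, gate_step_ps=5000.0)
        stack = GateStack(counts, gates, DetectorConfig(n_px_x=4, n_px_y=4))
        with pytest.warns(UserWarning):
            fld = compute_phasor(stack)
        assert not fld.valid.any()
        assert np.all(np.isnan(fld.g))

    def test_uncalibrated_phasors_inside_unit_disk(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5, size=(117, 6, 6)).astype(np.uint32)
        stack = GateStack(counts, GateConfig(), DetectorConfig(n_px_x=6, n_px_y=6))
        fld = compute_phasor(stack)
        mod = np.hypot(fld.g[fld.valid], fld.s[fld.valid])
        assert np.all(mod <= 1.0 + 1e-12)


class TestCalibration:
    def test_identity_when_reference_already_theoretical(self):
        ref = _field_from_taus([0.65], calibrated=False)
        target = _field_from_taus([0.3, 1.0], calibrated=False)
        cal = calibrate(target, ref, 0.65)
        assert np.allclose(cal.g, target.g, atol=1e-14)
        assert np.allclose(cal.s, target.s, atol=1e-14)

    def test_inverse_distortion_recovers_field(self):
        # distort a theoretical field by a known rotation + scale, calibrate
        # with an identically distorted reference: distortion must cancel
        theta, c = 0.37, 1.8
        factor = c * complex(math.cos(theta), math.sin(theta))
        ref = _field_from_taus([0.65], calibrated=False)
        target = _field_from_taus([0.3, 0.8, 2.0], calibrated=False)
        for fld in (ref, target):
            z = (fld.g + 1j * fld.s) * factor
            fld.g, fld.s = z.real, z.imag
        cal = calibrate(target, ref, 0.65)
        expected = _field_from_taus([0.3, 0.8, 2.0])
        assert np.allclose(cal.g, expected.g, atol=1e-10)
        assert np.allclose(cal.s, expected.s, atol=1e-10)

    def test_zero_lifetime_reference_maps_to_unit_point(self):
        assert theoretical_phasor(0.0, 20.0) == complex(1.0, 0.0)

    def test_origin_reference_rejected(self):
        ref = _field_from_taus([1.0], calibrated=False)
        ref.g[:], ref.s[:] = 0.0, 0.0
        with pytest.raises(ValueError):
            calibrate(_field_from_taus([1.0]), ref, 0.65)

    def test_frequency_mismatch_rejected(self):
        ref = _field_from_taus([0.65], freq_mhz=40.0)
        with pytest.raises(ValueError):
            calibrate(_field_from_taus([1.0]), ref, 0.65)


class TestPhaseLifetime:
    def test_unit_phasor_has_zero_phase(self):
        fld = _field_from_taus([0.0])
        phi, m = phase_and_modulation(fld)
        assert phi[0, 0] == 0.0
        assert m[0, 0] == pytest.approx(1.0)

    def test_diagonal_phasor_exact_arithmetic(self):
        fld = _field_from_taus([1.0])
        fld.g[0, 0], fld.s[0, 0] = 0.5, 0.5
        phi, m = phase_and_modulation(fld)
        assert phi[0, 0] == pytest.approx(math.pi / 4, abs=1e-15)
        assert m[0, 0] == pytest.approx(math.sqrt(0.5), abs=1e-15)

    def test_origin_phasor_flagged(self):
        fld = _field_from_taus([1.0])
        fld.g[0, 0], fld.s[0, 0] = 0.0, 0.0
        phi, m = phase_and_modulation(fld)
        assert np.isnan(phi[0, 0]) and np.isnan(m[0, 0])

    def test_inverse_identity(self):
        phi = math.atan(OMEGA * 1.0)
        assert phase_lifetime(phi, 20.0) == pytest.approx(1.0, abs=1e-12)
        assert phase_lifetime(0.0, 20.0) == 0.0

    def test_out_of_quadrant_phases_flagged_not_wrapped(self):
        taus = phase_lifetime(np.array([math.pi / 2, 2.0, -2.0]), 20.0)
        assert np.all(np.isnan(taus))

    def test_self_calibration_closure(self):
        """Analytic tau = 0.65 ns stack calibrated against itself returns
        tau_phi = 0.65 ns to 1e-9 everywhere."""
        stack = analytic_stack(0.65, 1e6, mode="expectation")
        raw = compute_phasor(stack, min_count=1e-12)
        cal = calibrate(raw, raw, 0.65)
        taus = pixel_phase_lifetimes(cal)
        assert np.all(np.abs(taus[cal.valid] - 0.65) < 1e-9)

    @pytest.mark.parametrize("tau", [0.3, 0.65, 0.8, 1.0, 1.1, 2.0])
    def test_universal_semicircle(self, tau):
        """Calibrated noiseless mono-exponential phasors lie on the circle
        |(g - 1/2)^2 + s^2 - 1/4| < 1e-9."""
        stack = analytic_stack(tau, 1e6, mode="expectation")
        raw = compute_phasor(stack, min_count=1e-12)
        cal = calibrate(raw, raw, tau)
        g, s = cal.g[cal.valid], cal.s[cal.valid]
        assert np.all(np.abs((g - 0.5) ** 2 + s**2 - 0.25) < 1e-9)

    def test_shorter_lifetime_closer_to_unit_point(self):
        fld = _field_from_taus([0.3, 0.65, 1.0, 2.0])
        assert np.all(np.diff(fld.g[0]) < 0)  # g decreases with tau


class TestHistogramAndCutoff:
    def test_single_pixel_single_bin(self):
        fld = _field_from_taus([0.65])
        hist = lifetime_histogram(fld)
        assert hist.counts.sum() == 1
        assert hist.n_retained == 1

    def test_window_semantics(self):
        fld = _field_from_taus([0.6, 1.0, 2.4])
        hist = lifetime_histogram(fld, time_window=(0.0, 1.5))
        assert hist.n_retained == 2
        assert hist.counts.sum() == 2

    def test_cutoff_zero_is_identity(self):
        fld = _field_from_taus([0.5, 0.7, 0.9, 1.1])
        hist = lifetime_histogram(fld)
        cut = apply_cutoff(hist, 0.0)
        assert np.array_equal(cut.counts, hist.counts)
        assert cut.n_retained == hist.n_retained

    def test_one_percent_trims_extreme_values(self):
        # 100 pixels at 1..100: the 1st/99th percentiles exclude 1 and 100
        vals = np.arange(1, 101, dtype=float)
        hist = _make_hist(vals, bin_width=1.0, time_window=None, cutoff_percent=0.0)
        cut = apply_cutoff(hist, 1.0)
        assert cut.n_retained == 98
        assert cut.source_values.min() == 2.0
        assert cut.source_values.max() == 99.0

    def test_cutoff_bounds_validated(self):
        hist = _make_hist(np.ones(5), 0.01, None, 0.0)
        for bad in (-1.0, 50.0, 80.0):
            with pytest.raises(ValueError):
                apply_cutoff(hist, bad)

    @given(
        percents=st.lists(
            st.floats(min_value=0, max_value=49, allow_nan=False), min_size=2, max_size=6
        )
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cutoff_retained_count_monotone_in_percent(self, percents):
        rng = np.random.default_rng(17)
        vals = rng.normal(1.0, 0.2, size=300)
        hist = _make_hist(vals, 0.01, None, 0.0)
        counts = [apply_cutoff(hist, p).n_retained for p in sorted(percents)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_symmetric_trim_preserves_symmetric_mean(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(1.0, 0.1, size=20_000)
        hist = _make_hist(vals, 0.01, None, 0.0)
        cut = apply_cutoff(hist, 5.0)
        assert extract_single_lifetime(cut) == pytest.approx(
            extract_single_lifetime(hist), abs=3 * 0.1 / math.sqrt(vals.size)
        )

    def test_mean_of_two_values(self):
        fld = _field_from_taus([0.6, 0.7])
        assert extract_single_lifetime(lifetime_histogram(fld)) == pytest.approx(0.65)

    def test_empty_mean_rejected(self):
        with pytest.warns(UserWarning):
            hist = _make_hist(np.empty(0), 0.01, None, 0.0)
        with pytest.raises(ValueError):
            extract_single_lifetime(hist)


class TestTwoComponentExtraction:
    def _bimodal_hist(self, n=4000, mus=(0.65, 1.00), sigma=0.02, seed=29):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [rng.normal(m, sigma, n // 2) for m in mus]
        )
        return _make_hist(vals, 0.01, None, 0.0)

    def test_two_narrow_gaussians_recovered(self):
        res = extract_two_lifetimes(self._bimodal_hist())
        assert not res.single_peak
        assert res.tau_short == pytest.approx(0.65, abs=0.015)
        assert res.tau_long == pytest.approx(1.00, abs=0.015)

    def test_gmm_alternative_agrees(self):
        res = extract_two_lifetimes(self._bimodal_hist(), method="gmm")
        assert res.tau_short == pytest.approx(0.65, abs=0.02)
        assert res.tau_long == pytest.approx(1.00, abs=0.02)

    def test_unimodal_flagged_single_peak(self):
        rng = np.random.default_rng(31)
        hist = _make_hist(rng.normal(0.8, 0.02, 2000), 0.01, None, 0.0)
        res = extract_two_lifetimes(hist)
        assert res.single_peak
        assert res.tau_long is None
        assert res.tau_short == pytest.approx(0.8, abs=0.015)

    def test_resolvability_floor_excludes_subgate_bar(self):
        # a dominant near-zero bar (single-photon first-gate pixels) must not
        # be reported as a component when a floor of one gate step is set
        vals = np.concatenate(
            [np.full(500, 0.19), np.full(300, 0.62), np.full(150, 1.05)]
        )
        hist = _make_hist(vals, 0.01, None, 0.0)
        unrestricted = extract_two_lifetimes(hist)
        assert unrestricted.tau_short == pytest.approx(0.19, abs=0.011)
        floored = extract_two_lifetimes(hist, min_tau=0.428)
        assert floored.tau_short == pytest.approx(0.62, abs=0.011)
        assert floored.tau_long == pytest.approx(1.05, abs=0.011)

    def test_empty_histogram_rejected(self):
        with pytest.warns(UserWarning):
            hist = _make_hist(np.empty(0), 0.01, None, 0.0)
        with pytest.raises(ValueError):
            extract_two_lifetimes(hist)
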
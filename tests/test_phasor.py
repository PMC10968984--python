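"""Phasor transform, referencing, and smoothing against analytic oracles."""

import dataclasses
import logging

import numpy as np
import pytest
from scipy import integrate

from phasordr import (DecayCube, PhasorField, apply_calibration,
                      compute_phasor, derive_calibration,
                      simulate_calibration_cube, simulate_decay_cube,
                      smooth_phasor, theoretical_phasor)

from conftest import OMEGA_40MHZ, per_photon_phasor


def _field(g, s, intensity=None, calibrated=False, omega=OMEGA_40MHZ):
    g = np.asarray(g, float)
    s = np.asarray(s, float)
    intensity = (np.full_like(g, 1000.0) if intensity is None
                 else np.asarray(intensity, float))
    return PhasorField(g=g, s=s, intensity=intensity, harmonic=1,
                       omega=omega, calibrated=calibrated,
                       valid_mask=np.ones_like(g, bool))


# ---------------------------------------------------------------------------
# theoretical_phasor
# ---------------------------------------------------------------------------

def test_theoretical_phasor_limits():
    assert theoretical_phasor(0.0, OMEGA_40MHZ) == (1.0, 0.0)
    assert theoretical_phasor(np.inf, OMEGA_40MHZ) == (0.0, 0.0)
    with pytest.raises(ValueError):
        theoretical_phasor(-1e-9, OMEGA_40MHZ)
    with pytest.raises(ValueError):
        theoretical_phasor(1e-9, 0.0)


@pytest.mark.parametrize("tau", [0.4e-9, 3.4e-9, 4e-9])
def test_theoretical_phasor_matches_numerical_integration(tau):
    """Closed form vs brute-force Fourier integral of the wrapped decay."""
    period = 1.0 / 40e6
    omega = OMEGA_40MHZ
    opts = dict(limit=200, epsabs=1e-14, epsrel=1e-13)
    norm = integrate.quad(lambda t: np.exp(-t / tau), 0, period, **opts)[0]
    g_num = integrate.quad(
        lambda t: np.exp(-t / tau) * np.cos(omega * t), 0, period,
        **opts)[0] / norm
    s_num = integrate.quad(
        lambda t: np.exp(-t / tau) * np.sin(omega * t), 0, period,
        **opts)[0] / norm
    g, s = theoretical_phasor(tau, omega)
    assert abs(g - g_num) < 1e-9
    assert abs(s - s_num) < 1e-9


def test_mono_exponential_on_universal_circle():
    for tau in [0.1e-9, 1e-9, 4e-9, 10e-9]:
        g, s = theoretical_phasor(tau, OMEGA_40MHZ)
        assert s >= 0
        assert abs(s**2 + (g - 0.5)**2 - 0.25) < 1e-12


# ---------------------------------------------------------------------------
# compute_phasor
# ---------------------------------------------------------------------------

def test_delta_decay_phasor():
    """All counts in time bin 0 -> (cos(w t0), sin(w t0)) at the center."""
    counts = np.zeros((1, 1, 250), np.uint32)
    counts[0, 0, 0] = 500
    cube = DecayCube(counts=counts, bin_width=100e-12, rep_rate=40e6)
    field = compute_phasor(cube)
    t0 = 0.5 * 100e-12
    assert field.g[0, 0] == pytest.approx(np.cos(field.omega * t0), abs=1e-12)
    assert field.s[0, 0] == pytest.approx(np.sin(field.omega * t0), abs=1e-12)


def test_uniform_counts_give_origin():
    """Uniform histogram over a full period is orthogonal to the harmonic."""
    counts = np.full((2, 2, 250), 40, np.uint32)
    cube = DecayCube(counts=counts, bin_width=100e-12, rep_rate=40e6)
    field = compute_phasor(cube)
    assert np.all(np.abs(field.g) < 1e-12)
    assert np.all(np.abs(field.s) < 1e-12)


def test_matches_per_photon_fourier_sum(full_period_params):
    """compute_phasor equals a brute-force per-photon Fourier sum."""
    p = dataclasses.replace(full_period_params, image_height=8, image_width=8,
                            mean_photons_per_pixel=400, irf_sigma=100e-12)
    cube = simulate_decay_cube(p)
    field = compute_phasor(cube, intensity_threshold=1)
    g_ref, s_ref = per_photon_phasor(cube.counts, cube.bin_width, field.omega)
    assert np.max(np.abs(field.g - g_ref)) < 1e-12
    assert np.max(np.abs(field.s - s_ref)) < 1e-12


def test_intensity_threshold_masks_pixels(small_params):
    fg = np.zeros((64, 64), bool)
    fg[:32] = True
    p = dataclasses.replace(small_params, foreground_mask=fg,
                            mean_photons_per_pixel=2000)
    field = compute_phasor(simulate_decay_cube(p), intensity_threshold=100)
    assert field.valid_mask[:32].all()
    assert not field.valid_mask[32:].any()


def test_all_zero_cube_warns_not_raises(caplog):
    cube = DecayCube(counts=np.zeros((4, 4, 250), np.uint32),
                     bin_width=100e-12, rep_rate=40e6)
    with caplog.at_level(logging.WARNING, logger="phasordr.phasor"):
        field = compute_phasor(cube)
    assert not field.valid_mask.any()
    assert any("threshold" in r.message for r in caplog.records)


def test_phasor_linearity_of_histogram_sums():
    """phasor(h1 + h2) is the intensity-weighted mean of the two phasors."""
    rng = np.random.default_rng(3)
    h1 = rng.poisson(50, 250).astype(np.uint32)
    h2 = rng.poisson(500, 250).astype(np.uint32)
    def phasor_of(h):
        cube = DecayCube(counts=h.reshape(1, 1, -1), bin_width=100e-12,
                         rep_rate=40e6)
        f = compute_phasor(cube, intensity_threshold=1)
        return f.g[0, 0], f.s[0, 0], f.intensity[0, 0]
    g1, s1, i1 = phasor_of(h1)
    g2, s2, i2 = phasor_of(h2)
    gm, sm, _ = phasor_of(h1 + h2)
    assert gm == pytest.approx((i1 * g1 + i2 * g2) / (i1 + i2), abs=1e-12)
    assert sm == pytest.approx((i1 * s1 + i2 * s2) / (i1 + i2), abs=1e-12)


def test_mixture_phasor_is_convex_combination_of_endpoints(
        full_period_params):
    """Calibrated two-component pixel phasors sit at the intensity-weighted
    combination of the component phasors (high-count simulation)."""
    f_b = 0.35
    p = dataclasses.replace(full_period_params, bound_fraction=f_b,
                            mean_photons_per_pixel=1e5, irf_offset=0.3e-9,
                            irf_sigma=100e-12)
    cal_cube = simulate_calibration_cube(
        4e-9, dataclasses.replace(p, seed=77))
    cal = derive_calibration(compute_phasor(cal_cube), 4e-9)
    field = apply_calibration(compute_phasor(simulate_decay_cube(p)), cal)
    mg, ms = field.mean_phasor()
    gf, sf = theoretical_phasor(p.tau_free, field.omega)
    gb, sb = theoretical_phasor(p.tau_bound, field.omega)
    assert mg == pytest.approx((1 - f_b) * gf + f_b * gb, abs=1e-2)
    assert ms == pytest.approx((1 - f_b) * sf + f_b * sb, abs=1e-2)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_identity_correction_when_measured_equals_theoretical():
    g, s = theoretical_phasor(4e-9, OMEGA_40MHZ)
    field = _field(np.full((20, 20), g), np.full((20, 20), s))
    cal = derive_calibration(field, 4e-9, min_pixels=100)
    assert cal.rotation == pytest.approx(0.0, abs=1e-12)
    assert cal.scale == pytest.approx(1.0, abs=1e-12)


def test_rotated_standard_yields_inverse_rotation():
    g, s = theoretical_phasor(4e-9, OMEGA_40MHZ)
    ang = np.deg2rad(10.0)
    z = (g + 1j * s) * np.exp(1j * ang)
    field = _field(np.full((20, 20), z.real), np.full((20, 20), z.imag))
    cal = derive_calibration(field, 4e-9)
    assert cal.rotation == pytest.approx(-ang, abs=1e-12)
    assert cal.scale == pytest.approx(1.0, abs=1e-12)


def test_correction_maps_measured_to_theoretical():
    rng = np.random.default_rng(1)
    g, s = theoretical_phasor(4e-9, OMEGA_40MHZ)
    z = (g + 1j * s) * 0.8 * np.exp(0.3j)
    field = _field(np.full((15, 15), z.real), np.full((15, 15), z.imag),
                   intensity=rng.uniform(500, 1500, (15, 15)))
    cal = derive_calibration(field, 4e-9)
    corrected = (cal.measured[0] + 1j * cal.measured[1]) * cal.correction
    assert abs(corrected - (g + 1j * s)) < 1e-12


def test_offset_standard_gives_phase_shift_rotation(full_period_params):
    """Phase-shift theorem: a 0.5 ns timing offset rotates the phasor by
    -w * 0.5 ns, and referencing must undo exactly that."""
    offset = 0.5e-9
    p = dataclasses.replace(full_period_params, irf_offset=offset,
                            mean_photons_per_pixel=50000)
    cube = simulate_calibration_cube(4e-9, p)
    cal = derive_calibration(compute_phasor(cube), 4e-9)
    omega = 2 * np.pi * p.rep_rate
    assert cal.rotation == pytest.approx(-omega * offset, abs=2e-3)


def test_degenerate_measured_phasor_rejected():
    field = _field(np.zeros((20, 20)), np.zeros((20, 20)))
    with pytest.raises(ValueError, match="origin"):
        derive_calibration(field, 4e-9)


def test_too_few_valid_pixels_rejected():
    field = _field(np.full((5, 5), 0.5), np.full((5, 5), 0.3))
    with pytest.raises(ValueError, match="valid pixels"):
        derive_calibration(field, 4e-9, min_pixels=100)


def test_double_calibration_rejected():
    field = _field(np.full((20, 20), 0.5), np.full((20, 20), 0.3))
    cal = derive_calibration(field, 4e-9)
    once = apply_calibration(field, cal)
    assert once.calibrated
    with pytest.raises(ValueError, match="already calibrated"):
        apply_calibration(once, cal)


def test_self_consistency_calibration_cube(full_period_params):
    """Referencing the standard against itself puts its mean phasor on the
    theoretical point (within Monte-Carlo error) and on the circle."""
    p = dataclasses.replace(full_period_params, mean_photons_per_pixel=1e5,
                            irf_offset=0.2e-9, irf_sigma=100e-12)
    cube = simulate_calibration_cube(4e-9, p)
    field = compute_phasor(cube)
    cal = derive_calibration(field, 4e-9)
    calibrated = apply_calibration(field, cal)
    mg, ms = calibrated.mean_phasor()
    tg, ts = theoretical_phasor(4e-9, field.omega)
    assert abs(mg - tg) < 1e-6 and abs(ms - ts) < 1e-6  # exact on the mean
    assert abs(ms**2 + (mg - 0.5)**2 - 0.25) < 1e-6


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def test_smooth_zero_passes_is_identity():
    rng = np.random.default_rng(0)
    field = _field(rng.random((10, 10)), rng.random((10, 10)))
    out = smooth_phasor(field, passes=0)
    assert np.array_equal(out.g, field.g)
    assert np.array_equal(out.s, field.s)


def test_smooth_constant_field_unchanged():
    field = _field(np.full((10, 10), 0.4), np.full((10, 10), 0.2))
    out = smooth_phasor(field, passes=3)
    assert np.allclose(out.g, 0.4)
    assert np.allclose(out.s, 0.2)


def test_smooth_replaces_single_outlier():
    g = np.full((10, 10), 0.4)
    g[5, 5] = 0.9
    field = _field(g, np.full((10, 10), 0.2))
    out = smooth_phasor(field, passes=1)
    assert out.g[5, 5] == pytest.approx(0.4)
    assert np.array_equal(out.intensity, field.intensity)
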
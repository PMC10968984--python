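"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from phasordr import SimParams

OMEGA_40MHZ = 2 * np.pi * 40e6


@pytest.fixture
def small_params():
    """64x64 acquisition at the standard 40 MHz / 80 ps geometry."""
    return SimParams(image_height=64, image_width=64,
                     mean_photons_per_pixel=2000, irf_sigma=0.0, seed=7)


@pytest.fixture
def full_period_params():
    """Geometry whose binned window spans the repetition period exactly.

    250 bins x 100 ps = 25 ns = 1/(40 MHz): no dead interval, so analytic
    wrapped-decay bin probabilities are exact oracles.
    """
    return SimParams(image_height=16, image_width=16, n_time_bins=250,
                     bin_width=100e-12, rep_rate=40e6,
                     mean_photons_per_pixel=2000, irf_sigma=0.0, seed=5)


def wrapped_exp_bin_probs(tau, n_bins, bin_width, period):
    """Exact bin probabilities of a wrapped exponential decay (no IRF).

    Valid when n_bins * bin_width == period: integrating the periodic decay
    sum_n exp(-(t + n*period)/tau) over bin k gives
    exp(-k*dt/tau) * (1 - exp(-dt/tau)) / (1 - exp(-period/tau)).
    """
    assert abs(n_bins * bin_width - period) < 1e-15
    k = np.arange(n_bins)
    p = np.exp(-k * bin_width / tau) * (1 - np.exp(-bin_width / tau))
    return p / (1 - np.exp(-period / tau))


def per_photon_phasor(counts, bin_width, omega):
    """Brute-force per-photon Fourier sum over one pixel or a whole cube.

    Expands the histogram to individual photons at their bin centers and
    averages cos/sin one photon at a time.
    """
    counts = np.asarray(counts)
    nb = counts.shape[-1]
    centers = (np.arange(nb) + 0.5) * bin_width
    flat = counts.reshape(-1, nb)
    g = np.empty(flat.shape[0])
    s = np.empty(flat.shape[0])
    for i, row in enumerate(flat):
        t = np.repeat(centers, row)
        if t.size == 0:
            g[i] = s[i] = 0.0
            continue
        g[i] = np.cos(omega * t).sum() / t.size
        s[i] = np.sin(omega * t).sum() / t.size
    return g.reshape(counts.shape[:-1]), s.reshape(counts.shape[:-1])
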
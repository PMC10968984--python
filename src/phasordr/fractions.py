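"""Two-component free/bound decomposition and fractional-distribution curves.

A calibrated pixel phasor that is a mixture of the free (short-lifetime)
and bound (long-lifetime) NAD(P)H components lies on the chord joining the
two component phasors, at a position equal to the bound component's photon
fraction.  Orthogonal projection onto that chord therefore recovers, pixel
by pixel, the intensity-weighted bound fraction f_b in [0, 1].  Per FOV the
f_b values are histogrammed into a normalized fractional distribution; a
condition (control or treated) is summarized by the per-bin mean and
standard deviation of its FOV distributions, each FOV weighted equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phasor import PhasorField, theoretical_phasor

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 100


@dataclass
class ComponentPair:
    """Free/bound endpoint lifetimes and their phasors at the working harmonic."""

    tau_free: float
    tau_bound: float
    free_phasor: tuple[float, float]
    bound_phasor: tuple[float, float]
    omega: float


@dataclass
class FractionDistribution:
    """Normalized per-FOV histogram of the bound fraction over [0, 1]."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_pixels: int
    fov_index: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def mean(self) -> float:
        """Mean bound fraction of the FOV (first moment of the density)."""
        return float(np.sum(self.bin_centers * self.density * self.bin_widths))


@dataclass
class MeanCurve:
    """Condition-level mean fractional-distribution curve across FOVs."""

    bin_edges: np.ndarray
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_fov: int
    fov_means: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def component_endpoints(tau_free: float, tau_bound: float,
                        omega: float) -> ComponentPair:
    """Phasor endpoints of the free and bound components."""
    if not 0 < tau_free < tau_bound:
        raise ValueError("require 0 < tau_free < tau_bound")
    return ComponentPair(
        tau_free=tau_free, tau_bound=tau_bound,
        free_phasor=theoretical_phasor(tau_free, omega),
        bound_phasor=theoretical_phasor(tau_bound, omega),
        omega=omega)


def bound_fraction_map(field: PhasorField, pair: ComponentPair) -> np.ndarray:
    """Per-pixel bound fraction by orthogonal projection onto the chord.

    f_b = (projected distance from the free endpoint) / (chord length),
    clipped to [0, 1]; invalid pixels are NaN.  Note f_b is a photon
    (intensity-weighted) fraction, not a molar fraction.
    """
    if not field.calibrated:
        raise ValueError("phasor field must be calibrated before unmixing")
    gf, sf = pair.free_phasor
    gb, sb = pair.bound_phasor
    dg, ds = gb - gf, sb - sf
    chord2 = dg * dg + ds * ds
    f = ((field.g - gf) * dg + (field.s - sf) * ds) / chord2
    f = np.clip(f, 0.0, 1.0)
    return np.where(field.valid_mask, f, np.nan)


def fov_distribution(fraction_map: np.ndarray,
                     valid_mask: np.ndarray | None = None,
                     n_bins: int = DEFAULT_N_BINS,
                     fov_index: int = 0) -> FractionDistribution:
    """Normalized histogram of the bound fraction over the valid pixels."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(fraction_map, float)
    keep = np.isfinite(values)
    if valid_mask is not None:
        keep &= np.asarray(valid_mask, bool)
    values = values[keep]
    if values.size == 0:
        raise ValueError(f"FOV {fov_index}: no valid pixels to histogram")
    density, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0),
                                  density=True)
    return FractionDistribution(bin_edges=edges, density=density,
                                n_pixels=int(values.size),
                                fov_index=fov_index)


def mean_curve(distributions: list[FractionDistribution]) -> MeanCurve:
    """Per-bin mean and s.d. across FOV distributions (equal FOV weights)."""
    if len(distributions) < 2:
        raise ValueError("need at least 2 FOV distributions")
    edges = distributions[0].bin_edges
    for d in distributions[1:]:
        if not np.array_equal(d.bin_edges, edges):
            raise ValueError("FOV distributions have mismatched binning")
    dens = np.stack([d.density for d in distributions])
    return MeanCurve(
        bin_edges=edges.copy(),
        mean_density=dens.mean(axis=0),
        sd_density=dens.std(axis=0, ddof=1),
        n_fov=len(distributions),
        fov_means=np.array([d.mean for d in distributions]))
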
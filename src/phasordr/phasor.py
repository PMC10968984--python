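"""Phasor transform of decay cubes and referencing against a standard.

Each pixel's photon-arrival histogram is mapped, fit-free, to phasor
coordinates

    g = sum_k c_k cos(w t_k) / sum_k c_k,
    s = sum_k c_k sin(w t_k) / sum_k c_k,

with t_k the bin centers and w = 2*pi*rep_rate*harmonic.  Mono-exponential
decays of lifetime tau land on the universal semicircle at

    g = 1 / (1 + (w tau)^2),   s = w tau / (1 + (w tau)^2),

and mixtures fall on chords between their components.  Instrument effects
(timing offset, IRF blur, bin discretization) multiply every pixel's phasor
by one lifetime-independent complex factor, so acquiring a mono-exponential
standard of known lifetime (fluorescein, 4 ns) determines a rotation+scale
correction that, applied to all acquisitions, removes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import DecayCube

logger = logging.getLogger(__name__)

#: Default per-pixel photon threshold below which a pixel is masked invalid.
DEFAULT_INTENSITY_THRESHOLD = 100.0


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates for one FOV at a given harmonic."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    harmonic: int
    omega: float                # rad/s
    calibrated: bool
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape

    def mean_phasor(self) -> tuple[float, float]:
        """Intensity-weighted mean (g, s) over valid pixels."""
        m = self.valid_mask
        if not m.any():
            raise ValueError("no valid pixels")
        w = self.intensity[m]
        return (float(np.average(self.g[m], weights=w)),
                float(np.average(self.s[m], weights=w)))


@dataclass
class CalibrationStandard:
    """Referencing correction derived from a known mono-exponential."""

    tau_ref: float
    omega: float
    harmonic: int
    measured: tuple[float, float]
    theoretical: tuple[float, float]
    rotation: float             # rad
    scale: float

    @property
    def correction(self) -> complex:
        """Complex factor mapping measured phasors onto the true ones."""
        return self.scale * np.exp(1j * self.rotation)


def theoretical_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Phasor of a mono-exponential decay of lifetime ``tau`` at ``omega``.

    Exact for a decay excited periodically and evaluated at a harmonic of
    the repetition rate; the point lies on the universal circle
    s^2 + (g - 1/2)^2 = 1/4.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if np.isinf(tau):
        return (0.0, 0.0)
    wt = omega * tau
    denom = 1.0 + wt * wt
    return (1.0 / denom, wt / denom)


def compute_phasor(cube: DecayCube, harmonic: int = 1,
                   intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                   ) -> PhasorField:
    """Transform a decay cube to an (uncalibrated) phasor field.

    Pixels whose total photon count falls below ``intensity_threshold`` are
    masked invalid; an all-zero cube yields an all-invalid field with a
    logged warning rather than an exception.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    omega = 2.0 * np.pi * cube.rep_rate * harmonic
    t = cube.bin_centers
    c = cube.counts.astype(np.float64)
    intensity = c.sum(axis=2)
    valid = intensity >= intensity_threshold
    if not valid.any():
        logger.warning("compute_phasor: no pixel reaches the intensity "
                       "threshold (%g photons)", intensity_threshold)
    denom = np.where(intensity > 0, intensity, 1.0)
    g = (c @ np.cos(omega * t)) / denom
    s = (c @ np.sin(omega * t)) / denom
    g = np.where(intensity > 0, g, 0.0)
    s = np.where(intensity > 0, s, 0.0)
    return PhasorField(g=g, s=s, intensity=intensity, harmonic=harmonic,
                       omega=omega, calibrated=False, valid_mask=valid)


def derive_calibration(standard_field: PhasorField, tau_ref: float = 4e-9,
                       min_pixels: int = 100) -> CalibrationStandard:
    """Derive the rotation+scale referencing correction from a standard.

    The measured phasor is the intensity-weighted mean over valid pixels;
    the correction is the unique complex ratio mapping it onto the
    theoretical phasor of ``tau_ref``.
    """
    if tau_ref <= 0:
        raise ValueError("tau_ref must be positive")
    n_valid = int(standard_field.valid_mask.sum())
    if n_valid < min_pixels:
        raise ValueError(
            f"calibration field has {n_valid} valid pixels; "
            f"need >= {min_pixels}")
    mg, ms = standard_field.mean_phasor()
    measured = mg + 1j * ms
    if abs(measured) < 1e-12:
        raise ValueError("measured standard phasor is at the origin")
    tg, ts = theoretical_phasor(tau_ref, standard_field.omega)
    corr = (tg + 1j * ts) / measured
    return CalibrationStandard(
        tau_ref=tau_ref, omega=standard_field.omega,
        harmonic=standard_field.harmonic,
        measured=(mg, ms), theoretical=(tg, ts),
        rotation=float(np.angle(corr)), scale=float(abs(corr)))


def apply_calibration(field: PhasorField,
                      cal: CalibrationStandard) -> PhasorField:
    """Reference a phasor field against the mono-exponential standard."""
    if field.calibrated:
        raise ValueError("field is already calibrated")
    if field.harmonic != cal.harmonic or not np.isclose(
            field.omega, cal.omega, rtol=1e-9):
        raise ValueError("calibration and field harmonics differ")
    z = (field.g + 1j * field.s) * cal.correction
    return PhasorField(g=z.real, s=z.imag, intensity=field.intensity.copy(),
                       harmonic=field.harmonic, omega=field.omega,
                       calibrated=True, valid_mask=field.valid_mask.copy())


def smooth_phasor(field: PhasorField, passes: int = 1) -> PhasorField:
    """Apply a 3x3 median filter to the g and s maps ``passes`` times.

    Intensity and validity are untouched.  Standard phasor-plot practice to
    tighten the per-pixel scatter without biasing the cloud's center.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    g, s = field.g.copy(), field.s.copy()
    for _ in range(passes):
        g = ndimage.median_filter(g, size=3, mode="nearest")
        s = ndimage.median_filter(s, size=3, mode="nearest")
    return PhasorField(g=g, s=s, intensity=field.intensity.copy(),
                       harmonic=field.harmonic, omega=field.omega,
                       calibrated=field.calibrated,
                       valid_mask=field.valid_mask.copy())


def write_phasor_field(field: PhasorField, path) -> None:
    """Write a phasor field as HDF5 (/g, /s, /intensity, /mask)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, data in (("g", field.g), ("s", field.s),
                           ("intensity", field.intensity),
                           ("mask", field.valid_mask)):
            f.create_dataset(name, data=data, track_times=False)
        f.attrs["harmonic"] = field.harmonic
        f.attrs["omega_rad_s"] = field.omega
        f.attrs["calibrated"] = field.calibrated
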
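"""Radiometry, stimulation geometry, duty-cycle mixtures and spectra.

Covers the light-delivery side of the experiments: converting laser power
to photon flux, the size ratio between the imaging frame and the local
stimulation ROI, rapid two-wavelength duty-cycle schedules used to realize
UV/blue photon-ratio mixtures, and peak analysis of opsin absorbance
spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "LightSource",
    "ROIGeometry",
    "StimulusSchedule",
    "AbsorbanceSpectrum",
    "photon_flux",
    "area_ratio",
    "duty_cycle_schedule",
    "time_averaged_ratio",
    "spectrum_peak",
    "difference_spectrum",
    "round_significant",
]

PLANCK_H = 6.62607015e-34  # J*s (CODATA, exact)
SPEED_OF_LIGHT = 2.99792458e8  # m/s (exact)


@dataclass(frozen=True)
class LightSource:
    """A monochromatic source described by power and/or irradiance."""

    wavelength_nm: float
    power_w: float | None = None
    irradiance_photons_s_m2: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.power_w is None and self.irradiance_photons_s_m2 is None:
            raise ValueError("at least one of power or irradiance must be set")


def photon_flux(power_w: float, wavelength_nm: float) -> float:
    """Photon flux (photons/s) of a monochromatic beam of given power.

    flux = P * lambda / (h * c).
    """
    if power_w < 0:
        raise ValueError("power must be nonnegative")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return power_w * (wavelength_nm * 1e-9) / (PLANCK_H * SPEED_OF_LIGHT)


def round_significant(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures, half-to-even."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = digits - 1 - math.floor(math.log10(abs(x)))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ROIGeometry:
    """Imaging frame and circular stimulation-ROI geometry in pixels."""

    width_px: int
    height_px: int
    roi_diameter_px: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.roi_diameter_px <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.roi_diameter_px > min(self.width_px, self.height_px):
            raise ValueError("ROI diameter exceeds frame size")


def area_ratio(geometry: ROIGeometry) -> float:
    """Frame area divided by circular stimulation-ROI area."""
    roi = math.pi * (geometry.roi_diameter_px / 2.0) ** 2
    return geometry.width_px * geometry.height_px / roi


@dataclass(frozen=True)
class StimulusSchedule:
    """A repeating sequence of (wavelength_nm, duration_ms) epochs.

    The epochs tile one period; the program repeats the period for
    ``total_duration_s`` (optional bookkeeping for downstream use).
    """

    epochs: tuple[tuple[float, float], ...]
    period_ms: float
    total_duration_s: float | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        durations = [d for _, d in self.epochs]
        if any(d <= 0 for d in durations):
            raise ValueError("epoch durations must be positive")
        if not math.isclose(sum(durations), self.period_ms, rel_tol=1e-9):
            raise ValueError("epoch durations must sum to the period")

    def wavelength_fractions(self) -> dict[float, float]:
        """Fraction of the period spent at each wavelength."""
        out: dict[float, float] = {}
        for wl, dur in self.epochs:
            out[wl] = out.get(wl, 0.0) + dur / self.period_ms
        return out

    @classmethod
    def constant(cls, wavelength_nm: float, period_ms: float = 500.0,
                 total_duration_s: float | None = None) -> "StimulusSchedule":
        return cls(((wavelength_nm, period_ms),), period_ms, total_duration_s)


def duty_cycle_schedule(
    uv_fraction: float,
    uv_wavelength_nm: float = 380.0,
    fill_wavelength_nm: float = 480.0,
    period_ms: float = 500.0,
    total_duration_s: float | None = None,
) -> StimulusSchedule:
    """Two-wavelength duty-cycle mixture realizing a UV photon-time fraction.

    E.g. a 10% UV / 90% blue mixture over a 500 ms period is 50 ms of UV
    followed by 450 ms of blue.  Zero-duration epochs are omitted.
    """
    if not 0.0 <= uv_fraction <= 1.0:
        raise ValueError("uv_fraction must lie in [0, 1]")
    epochs = []
    if uv_fraction > 0:
        epochs.append((uv_wavelength_nm, uv_fraction * period_ms))
    if uv_fraction < 1:
        epochs.append((fill_wavelength_nm, (1.0 - uv_fraction) * period_ms))
    return StimulusSchedule(tuple(epochs), period_ms, total_duration_s)


def time_averaged_ratio(schedule: StimulusSchedule, uv_wavelength_nm: float = 380.0) -> float:
    """Fraction of the period spent at ``uv_wavelength_nm``.

    Inverse of :func:`duty_cycle_schedule`: composing the two is the
    identity on [0, 1].
    """
    return schedule.wavelength_fractions().get(uv_wavelength_nm, 0.0)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """(wavelength, absorbance) table on a strictly increasing grid."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelength and absorbance must be equal-length 1-D")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "AbsorbanceSpectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.wavelength_nm, self.absorbance]),
            delimiter=",",
            header="wavelength_nm,absorbance",
            comments="",
        )


def spectrum_peak(spectrum: AbsorbanceSpectrum, smooth_window_nm: float = 0.0) -> float:
    """Wavelength of maximal absorbance (lambda-max).

    Optional moving-average smoothing over a window given in nm; ties break
    toward the shorter wavelength.
    """
    if spectrum.wavelength_nm.size < 3:
        raise ValueError("spectrum needs at least 3 points")
    values = spectrum.absorbance
    if smooth_window_nm > 0:
        step = float(np.median(np.diff(spectrum.wavelength_nm)))
        n = max(1, int(round(smooth_window_nm / step)))
        if n % 2 == 0:
            n += 1
        kernel = np.ones(n) / n
        # edge-padded moving average keeps the grid length unchanged
        padded = np.pad(values, n // 2, mode="edge")
        values = np.convolve(padded, kernel, mode="valid")
    return float(spectrum.wavelength_nm[int(np.argmax(values))])


def difference_spectrum(dark: AbsorbanceSpectrum, light: AbsorbanceSpectrum) -> AbsorbanceSpectrum:
    """Pointwise dark - light spectrum on the dark grid.

    If the grids differ, the light spectrum is linearly interpolated onto
    the overlapping part of the dark grid.
    """
    lo = max(dark.wavelength_nm[0], light.wavelength_nm[0])
    hi = min(dark.wavelength_nm[-1], light.wavelength_nm[-1])
    if lo > hi:
        raise ValueError("spectra have non-overlapping wavelength grids")
    mask = (dark.wavelength_nm >= lo) & (dark.wavelength_nm <= hi)
    grid = dark.wavelength_nm[mask]
    light_on_grid = np.interp(grid, light.wavelength_nm, light.absorbance)
    return AbsorbanceSpectrum(grid, dark.absorbance[mask] - light_on_grid)
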
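"""Ensemble ("ergodic") flickering spectroscopy: mode spectra and tension.

Each contour fluctuation profile h(theta) is decomposed into Fourier modes
h_n = (1/N) sum_j h(theta_j) exp(-i n theta_j); the one-sided mode powers
|h_n|^2 (n = 1 .. N/2) are averaged over a cell population and inverted at
a low mode (default n = 3) into an effective lateral tension

    sigma_eff = k_BT / (2 pi n <|h_n|^2>).

This is the tension-dominated (long-wavelength) regime of a Helfrich-type
fluctuation spectrum; sigma_eff is a comparative descriptor whose absolute
scale depends on the stated Fourier convention, which is stamped on every
spectrum as ``convention_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .contour import Contour
from .errors import DegenerateInputError
from .thermal import ThermalContext

__all__ = ["ModeSpectrum", "TensionEstimate", "mode_spectrum",
           "ensemble_spectrum", "effective_tension", "spectra_from_contours",
           "CONVENTION_ID"]

#: Forward FFT with 1/N normalization, one-sided powers, tension at low modes.
CONVENTION_ID = "fft/N one-sided v1"


@dataclass
class ModeSpectrum:
    """Per-mode mean squared Fourier amplitude of contour fluctuations."""

    modes: np.ndarray          # integer mode indices, strictly increasing
    power: np.ndarray          # <|h_n|^2>, m^2
    n_samples: int = 1
    convention_id: str = CONVENTION_ID

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=int)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.modes) <= 0):
            raise ValueError("modes must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("mode powers must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def power_at(self, mode: int) -> float:
        idx = np.nonzero(self.modes == mode)[0]
        if idx.size == 0:
            raise KeyError(f"mode {mode} not present in spectrum")
        return float(self.power[idx[0]])


@dataclass
class TensionEstimate:
    sigma_eff: float           # N/m
    mode_used: tuple           # mode index or band
    n_cells: int
    temperature: float         # K

    def __post_init__(self) -> None:
        if not self.sigma_eff > 0:
            raise ValueError("sigma_eff must be positive")


def mode_spectrum(h: np.ndarray) -> ModeSpectrum:
    """One-sided mode powers |h_n|^2, n = 1 .. N/2, of a single profile.

    The profile must sit on a strictly uniform angular grid of N >= 8
    points; the DC (n = 0) component is excluded (it belongs to R0, not to
    the fluctuation).
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 1 or h.size < 8:
        raise DegenerateInputError("need a 1-D profile with N >= 8 angles")
    n = h.size
    coef = np.fft.fft(h) / n
    nmax = n // 2
    power = np.abs(coef[1:nmax + 1]) ** 2
    return ModeSpectrum(modes=np.arange(1, nmax + 1), power=power, n_samples=1)


def ensemble_spectrum(spectra: Sequence[ModeSpectrum]) -> ModeSpectrum:
    """Arithmetic per-mode mean over a population of single-cell spectra."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.convention_id != first.convention_id:
            raise ValueError("mixed Fourier conventions in ensemble")
        if not np.array_equal(s.modes, first.modes):
            raise ValueError("spectra sample different mode grids")
    power = np.mean([s.power for s in spectra], axis=0)
    return ModeSpectrum(modes=first.modes.copy(), power=power,
                        n_samples=len(spectra), convention_id=first.convention_id)


def spectra_from_contours(contours: Iterable[Contour]) -> list:
    """Single-cell spectra of h(theta) = R(theta) - R0, in meters squared."""
    return [mode_spectrum(c.h) for c in contours]


def effective_tension(spectrum: ModeSpectrum, thermal: ThermalContext,
                      mode_used: int | Sequence[int] = 3) -> TensionEstimate:
    """Invert low-mode fluctuation power into an effective lateral tension.

    ``mode_used`` may be a single mode (default 3) or a band of modes, in
    which case the per-mode tension estimates are averaged. Modes below 2
    are refused (n = 1 is the translation mode).
    """
    band = (int(mode_used),) if np.isscalar(mode_used) else tuple(int(m) for m in mode_used)
    if any(m < 2 for m in band):
        raise ValueError("mode_used must be >= 2 (n = 1 is the translation mode)")
    sigmas = []
    for m in band:
        p = spectrum.power_at(m)
        if p <= 0:
            raise ZeroDivisionError(f"zero fluctuation power at mode {m}")
        sigmas.append(thermal.kBT / (2.0 * np.pi * m * p))
    return TensionEstimate(sigma_eff=float(np.mean(sigmas)), mode_used=band,
                           n_cells=spectrum.n_samples,
                           temperature=thermal.temperature)
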
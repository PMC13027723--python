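"""Contour containers and periodic smoothing of polar boundary samples.

A cell contour is stored in polar form about its centroid: radii R(theta_j)
on the strictly uniform angle grid theta_j = 2*pi*j/N. The mean radius R0 is
the angular mean of R, and the fluctuation profile is h(theta) = R - R0.

Boundary pixels are irregularly spaced in angle, so resampling onto the
uniform grid goes through a periodic least-squares fit: a trigonometric
polynomial with `degree` harmonics (the package's reading of a periodic
"degree-12/18 spline"; periodicity is built in and the harmonic count plays
the role of the polynomial degree). The fit residual RMS is reported so
callers can verify sub-pixel smoothing quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError

__all__ = ["Contour", "FluctuationField", "fit_periodic", "uniform_angles"]


def uniform_angles(n: int) -> np.ndarray:
    """Uniform angular grid theta_j = 2*pi*j/n on [0, 2*pi)."""
    return 2.0 * np.pi * np.arange(n) / n


def fit_periodic(theta: np.ndarray, r: np.ndarray, degree: int, n_out: int):
    """Least-squares periodic fit of radius samples, evaluated on a uniform grid.

    Parameters
    ----------
    theta, r
        Irregular polar samples of the boundary (radians, any radial unit).
    degree
        Number of harmonics retained (Fourier degree of the fit).
    n_out
        Number of uniform output angles.

    Returns
    -------
    radii : ndarray, shape (n_out,)
        Fitted radii on ``uniform_angles(n_out)``.
    residual_rms : float
        RMS of the fit residual at the input samples, in the unit of ``r``.
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if theta.size != r.size or theta.size < 2 * degree + 1:
        raise DegenerateInputError(
            f"need at least {2 * degree + 1} boundary samples for degree {degree}, "
            f"got {theta.size}"
        )
    k = np.arange(1, degree + 1)
    design = np.concatenate(
        [
            np.ones((theta.size, 1)),
            np.cos(np.outer(theta, k)),
            np.sin(np.outer(theta, k)),
        ],
        axis=1,
    )
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    residual_rms = float(np.sqrt(np.mean((design @ coef - r) ** 2)))

    grid = uniform_angles(n_out)
    eval_design = np.concatenate(
        [
            np.ones((n_out, 1)),
            np.cos(np.outer(grid, k)),
            np.sin(np.outer(grid, k)),
        ],
        axis=1,
    )
    return eval_design @ coef, residual_rms


@dataclass
class Contour:
    """Closed cell contour in polar form about its centroid.

    Attributes
    ----------
    centroid : (row, col) in pixels of the source frame.
    radii : R(theta_j) in meters on the uniform grid of N angles.
    pixel_size : meters per pixel of the source frame.
    cell_id : free-form label.
    fit_residual_px : RMS residual of the periodic fit, in pixels.
    """

    centroid: tuple
    radii: np.ndarray
    pixel_size: float
    cell_id: str = ""
    fit_residual_px: float = 0.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 1 or self.radii.size < 8:
            raise ValueError("contour needs at least 8 radii on a 1-D grid")
        if not np.all(self.radii > 0):
            raise ValueError("all contour radii must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_angles(self) -> int:
        return self.radii.size

    @property
    def angles(self) -> np.ndarray:
        return uniform_angles(self.n_angles)

    @property
    def mean_radius(self) -> float:
        """R0, the angular mean radius (m)."""
        return float(np.mean(self.radii))

    @property
    def h(self) -> np.ndarray:
        """Fluctuation profile h(theta) = R(theta) - R0 (m)."""
        return self.radii - self.mean_radius

    def xy(self) -> np.ndarray:
        """Cartesian polygon vertices (m), centered on the centroid."""
        th = self.angles
        return np.column_stack([self.radii * np.cos(th), self.radii * np.sin(th)])


@dataclass
class FluctuationField:
    """Angle-by-time fluctuation matrix h(theta_j, t_k) of one cell.

    ``h`` has shape (n_angles, n_frames), is stored in meters and each
    angle's time series has zero time mean (the field is defined as
    R(theta, t) minus the per-angle time average of R).
    """

    h: np.ndarray
    fps: float
    pixel_size: float
    cell_id: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 2 or self.h.shape[1] < 2:
            raise ValueError("h must be (n_angles, n_frames) with n_frames >= 2")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        scale = np.max(np.abs(self.h), axis=1)
        means = np.abs(np.mean(self.h, axis=1))
        bad = means > 1e-9 * np.maximum(scale, 1e-30)
        if np.any(bad):
            raise ValueError(
                "per-angle time means of h are not zero; build the field as "
                "R(theta,t) - <R(theta,t)>_t"
            )

    @classmethod
    def from_radii(cls, radii: np.ndarray, fps: float, pixel_size: float,
                   cell_id: str = "", truth: dict | None = None) -> "FluctuationField":
        """Build the field from an (n_angles, n_frames) radius matrix in meters."""
        radii = np.asarray(radii, dtype=float)
        h = radii - radii.mean(axis=1, keepdims=True)
        return cls(h=h, fps=fps, pixel_size=pixel_size, cell_id=cell_id,
                   truth=dict(truth or {}))

    @property
    def n_angles(self) -> int:
        return self.h.shape[0]

    @property
    def n_frames(self) -> int:
        return self.h.shape[1]
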
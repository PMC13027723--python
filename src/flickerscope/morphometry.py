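"""Morphomechanical descriptors of accepted cell contours.

From each 720-angle polar contour the module computes area A (shoelace),
perimeter P (closed polyline), equivalent radius R_eq = sqrt(A/pi), mean
radius R0 (angular mean), two circularity conventions (C = 4*pi*A/P^2 and
its linear form C_lin = 2*pi*R_eq/P, with C_lin^2 = C by construction),
form factor F = P^2/A, elongation E = a/b from the inertia-equivalent
ellipse of the filled polygon, and the instantaneous fluctuation amplitude
Delta = RMS of h(theta). All lengths are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour
from .errors import DegenerateInputError

__all__ = ["MorphometricRecord", "measure", "fluctuation_amplitude",
           "normocyte_fraction"]


@dataclass
class MorphometricRecord:
    area: float                # A, m^2
    perimeter: float           # P, m
    equivalent_radius: float   # R_eq = sqrt(A/pi), m
    mean_radius: float         # R0, angular mean of R(theta), m
    circularity: float         # C = 4*pi*A/P^2
    circularity_lin: float     # 2*pi*R_eq/P
    form_factor: float         # F = P^2/A
    elongation: float          # E = a/b >= 1
    semi_axis_major: float     # a, m
    semi_axis_minor: float     # b, m
    fluct_amplitude: float     # Delta, m
    cell_id: str = ""
    condition: str = ""


def _polygon_geometry(pts: np.ndarray):
    """Signed area, perimeter and second central area moments of a polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    perimeter = np.sum(np.hypot(xn - x, yn - y))
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    ixx = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0
    iyy = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0
    ixy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    # central moments
    ixx -= area * cy * cy
    iyy -= area * cx * cx
    ixy -= area * cx * cy
    return area, perimeter, ixx, iyy, ixy


def measure(contour: Contour, cell_id: str | None = None,
            condition: str = "") -> MorphometricRecord:
    """Compute the full morphometric record of one contour.

    The inertia-equivalent ellipse is fitted to the filled region: with
    lambda1 >= lambda2 the eigenvalues of the area-normalized second central
    moments, the semi-axes are a = 2*sqrt(lambda1) and b = 2*sqrt(lambda2)
    (exact for a true ellipse).
    """
    pts = contour.xy()
    area, perimeter, ixx, iyy, ixy = _polygon_geometry(pts)
    if area <= 0:
        raise DegenerateInputError("contour polygon has non-positive area")

    cov = np.array([[iyy, ixy], [ixy, ixx]]) / area  # second moments per unit area
    lam = np.linalg.eigvalsh(cov)
    if lam[0] <= 0:
        raise DegenerateInputError("degenerate second moments: polygon self-intersects?")
    a, b = 2.0 * np.sqrt(lam[1]), 2.0 * np.sqrt(lam[0])

    r_eq = np.sqrt(area / np.pi)
    return MorphometricRecord(
        area=float(area),
        perimeter=float(perimeter),
        equivalent_radius=float(r_eq),
        mean_radius=contour.mean_radius,
        circularity=float(4.0 * np.pi * area / perimeter**2),
        circularity_lin=float(2.0 * np.pi * r_eq / perimeter),
        form_factor=float(perimeter**2 / area),
        elongation=float(a / b),
        semi_axis_major=float(a),
        semi_axis_minor=float(b),
        fluct_amplitude=fluctuation_amplitude(contour),
        cell_id=contour.cell_id if cell_id is None else cell_id,
        condition=condition,
    )


def fluctuation_amplitude(contour: Contour) -> float:
    """Delta = sqrt(<h(theta)^2>) over the angle grid (population divisor)."""
    h = contour.h
    return float(np.sqrt(np.mean(h * h)))


def normocyte_fraction(accepted_count: int, total_count: int) -> float:
    """Fraction of detected cells meeting the normality (discocyte) criteria."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= accepted_count <= total_count:
        raise ValueError("need 0 <= accepted_count <= total_count")
    return accepted_count / total_count
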
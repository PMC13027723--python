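"""Synthetic inputs with known ground truth for every pipeline stage.

No imagery is distributed with the package; instead each input class the
pipeline consumes is generated programmatically with a planted ground truth:

* bright-field cell fields -- discocyte-like dark annular rims on a bright
  background, with planted defects (border-touching, aggregated, blurred,
  elongated, mis-sized) and a manifest stating which cells the acceptance
  filters should keep and why the rest should be rejected;
* per-angle contour fluctuation dynamics -- independent stationary
  Ornstein-Uhlenbeck series with prescribed stiffness and friction,
  simulated with the exact discrete OU update (no Euler discretization bias);
* static contour ensembles -- mode amplitudes drawn so that the expected
  spectrum matches a tension-dominated Helfrich-type law E|h_n|^2 =
  k_BT / (2 pi n sigma);
* rendered fluctuation videos -- dark-rim frames of a prescribed
  fluctuation field, with optional rigid drift to exercise re-centering;
* absorbance records -- blank / sample / full-lysis triplets (A415, A380,
  A450) with prescribed read noise for the hemolysis readout.

Every generator is a pure function of its spec: the same seed yields
bit-identical output. Rendering choices are fixtures (no point-spread
function or phase optics is modeled); only the dark outer rim matters for
segmentation, so interior pallor is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .contour import Contour, FluctuationField, uniform_angles
from .errors import SpecValidationError
from .thermal import BOLTZMANN, DEFAULT_TEMPERATURE, ThermalContext

__all__ = [
    "PlantedCell", "SceneSpec", "OuSpec", "EnsembleSpec", "VideoOptics",
    "generate_field_scene", "generate_angle_dynamics", "generate_static_ensemble",
    "render_contour_video", "generate_absorbance", "generate_mode_series",
    "make_default_scene", "DEFECTS", "BLANK_TRUE", "LYSIS_TRUE",
]

#: Recognized planted-defect classes and the rejection reason each must draw.
DEFECTS = {
    "none": "",
    "border": "border",
    "aggregate": "aggregate",
    "blurred": "focus",
    "small": "size",
    "large": "size",
    "elongated": "circularity",
}

_BACKGROUND = 0.85


@dataclass
class PlantedCell:
    """One planted cell: geometry, rim optics and the expected filter outcome."""

    center: tuple            # (row, col) in pixels
    radius: float            # trough radius, micrometers
    mode_amplitudes: dict = dc_field(default_factory=dict)  # mode index -> um
    rim_width: float = 0.4   # radial Gaussian trough width, um
    rim_depth: float = 0.6   # trough depth as a fraction of background
    defect: str = "none"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise SpecValidationError("cell radius must be positive")
        if self.defect not in DEFECTS:
            raise SpecValidationError(f"unknown defect {self.defect!r}")

    @property
    def expected_accept(self) -> bool:
        return self.defect == "none"

    @property
    def expected_reason(self) -> str:
        return DEFECTS[self.defect]


@dataclass
class SceneSpec:
    """A square bright-field scene of planted cells."""

    image_size: int = 1024          # pixels, square
    pixel_size: float = 0.103       # um/px, bright-field acquisition scale
    cells: list = dc_field(default_factory=list)
    noise_sd: float = 0.01          # additive Gaussian noise, intensity fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.image_size > 0:
            raise SpecValidationError("image_size must be positive")
        if not self.pixel_size > 0:
            raise SpecValidationError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be non-negative")


def _radius_profile_px(cell: PlantedCell, theta: np.ndarray, px: float) -> np.ndarray:
    """Planted trough radius R(theta) in pixels for a single rim."""
    r0 = cell.radius / px
    if cell.defect == "elongated":
        # area-preserving ellipse with axis ratio 2
        a, b = r0 * np.sqrt(2.0), r0 / np.sqrt(2.0)
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r = np.full_like(theta, r0)
    for n, amp in cell.mode_amplitudes.items():
        r = r + (amp / px) * np.cos(int(n) * theta)
    return r


def _render_rim(img: np.ndarray, center, cell: PlantedCell, px: float) -> None:
    """Subtract a dark radial Gaussian trough centered at ``center`` (pixels)."""
    w = cell.rim_width / px
    rmax = (cell.radius * (1.5 if cell.defect == "elongated" else 1.0)
            + sum(abs(a) for a in cell.mode_amplitudes.values())) / px
    half = int(np.ceil(rmax + 5 * w)) + 1
    cy, cx = center
    r0 = max(int(np.floor(cy)) - half, 0)
    r1 = min(int(np.ceil(cy)) + half + 1, img.shape[0])
    c0 = max(int(np.floor(cx)) - half, 0)
    c1 = min(int(np.ceil(cx)) + half + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    rim = _radius_profile_px(cell, theta, px)
    img[r0:r1, c0:c1] -= _BACKGROUND * cell.rim_depth * np.exp(
        -((rho - rim) ** 2) / (2 * w ** 2)
    )


def _aggregate_centers(cell: PlantedCell, px: float):
    """Three rim centers forming an equilateral triple around ``cell.center``."""
    sep_um = 1.95 * cell.radius + 0.85   # keeps rims overlapping but non-convex
    circ = sep_um / np.sqrt(3.0) / px
    cy, cx = cell.center
    return [
        (cy + circ * np.sin(phi), cx + circ * np.cos(phi))
        for phi in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3)
    ]


def generate_field_scene(spec: SceneSpec):
    """Render a bright-field scene and its ground-truth manifest.

    Returns ``(image, manifest)`` where ``image`` is a float array in [0, 1]
    and ``manifest`` is a list of dicts, one per planted cell, carrying the
    defect class, ``expected_accept`` and the expected rejection reason.

    Raises
    ------
    SpecValidationError
        If two defect-free cells overlap, or a defect-free cell touches the
        image border.
    """
    n = spec.image_size
    px = spec.pixel_size
    clean = [c for c in spec.cells if c.defect == "none"]
    for i, a in enumerate(clean):
        ra = a.radius / px + 3 * a.rim_width / px
        if (a.center[0] - ra < 2 or a.center[1] - ra < 2
                or a.center[0] + ra > n - 3 or a.center[1] + ra > n - 3):
            raise SpecValidationError("defect-free cell touches the border")
        for b in clean[i + 1:]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d * px < a.radius + b.radius + a.rim_width + b.rim_width + 1.0:
                raise SpecValidationError("defect-free cells overlap")

    img = np.full((n, n), _BACKGROUND, dtype=float)
    for cell in spec.cells:
        if cell.defect == "aggregate":
            for ctr in _aggregate_centers(cell, px):
                _render_rim(img, ctr, cell, px)
        else:
            _render_rim(img, cell.center, cell, px)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    manifest = [
        {
            "cell_id": f"cell{i:02d}",
            "center": [float(c.center[0]), float(c.center[1])],
            "radius_um": c.radius,
            "defect": c.defect,
            "expected_accept": c.expected_accept,
            "expected_reason": c.expected_reason,
        }
        for i, c in enumerate(spec.cells)
    ]
    return img, manifest


def make_default_scene(seed: int = 0, image_size: int = 1024,
                       pixel_size: float = 0.103, noise_sd: float = 0.01) -> SceneSpec:
    """The planted 9-cell fixture scene: 5 defect-free cells + 4 defect plants.

    Defect-free cells use a 7.2 um trough radius so that the equivalent
    radius of the binarized, hole-filled component (trough + outer rim band)
    lands inside the default [7, 8] um acceptance window.
    """
    r = 7.0
    cells = [
        PlantedCell(center=(200.0, 220.0), radius=r),
        PlantedCell(center=(210.0, 620.0), radius=r, mode_amplitudes={3: 0.15}),
        PlantedCell(center=(520.0, 420.0), radius=r, mode_amplitudes={2: 0.10, 4: 0.08}),
        PlantedCell(center=(560.0, 830.0), radius=r),
        PlantedCell(center=(850.0, 220.0), radius=r, mode_amplitudes={5: 0.10}),
        PlantedCell(center=(30.0, 450.0), radius=r, defect="border"),
        PlantedCell(center=(830.0, 610.0), radius=r, defect="aggregate"),
        PlantedCell(center=(650.0, 100.0), radius=r, rim_width=1.8, defect="blurred"),
        PlantedCell(center=(80.0, 850.0), radius=r, defect="elongated"),
    ]
    return SceneSpec(image_size=image_size, pixel_size=pixel_size,
                     cells=cells, noise_sd=noise_sd, seed=seed)


@dataclass
class OuSpec:
    """Per-angle Ornstein-Uhlenbeck dynamics with prescribed ground truth.

    Defaults mimic the high-speed acquisition (2000 fps, 3 s) with a
    physiologically plausible local stiffness k0 and friction gamma0 giving
    a relaxation rate omega0 = k0/gamma0 = 30 1/s and ~38 nm stationary
    fluctuation amplitude at 37 C.
    """

    n_angles: int = 64
    n_frames: int = 6000
    fps: float = 2000.0
    stiffness_true: float = 3e-6     # k0, N/m per contour coordinate
    friction_true: float = 1e-7      # gamma0, kg/s
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise SpecValidationError("n_frames must be >= 2")
        if not (self.fps > 0 and self.stiffness_true > 0 and self.friction_true > 0):
            raise SpecValidationError("fps, stiffness_true, friction_true must be > 0")
        if (self.stiffness_true / self.friction_true) / self.fps >= 0.1:
            raise SpecValidationError(
                "time step 1/fps does not resolve the relaxation rate: need "
                "(k0/gamma0)/fps < 0.1"
            )


def generate_angle_dynamics(spec: OuSpec):
    """Simulate independent stationary OU series for every contour angle.

    Uses the exact discrete update
    ``h[k+1] = h[k] * exp(-omega dt) + xi * sqrt(var_st * (1 - exp(-2 omega dt)))``
    starting from a stationary draw, so the simulated law is exactly the OU
    stationary process at the sampled times.

    Returns ``(field, truth)``; the field's per-angle time means are
    subtracted (mirroring how a measured fluctuation field is defined), and
    ``truth`` carries k0, gamma0, D0 = k_BT/gamma0, omega0 = k0/gamma0 and
    the stationary variance k_BT/k0.
    """
    kBT = BOLTZMANN * spec.temperature
    var_st = kBT / spec.stiffness_true
    omega = spec.stiffness_true / spec.friction_true
    dt = 1.0 / spec.fps
    a = np.exp(-omega * dt)
    step_sd = np.sqrt(var_st * (1.0 - a * a))

    rng = np.random.default_rng(spec.seed)
    h = np.empty((spec.n_angles, spec.n_frames))
    h[:, 0] = rng.normal(0.0, np.sqrt(var_st), spec.n_angles)
    for k in range(1, spec.n_frames):
        h[:, k] = a * h[:, k - 1] + rng.normal(0.0, step_sd, spec.n_angles)

    truth = {
        "stiffness_true": spec.stiffness_true,
        "friction_true": spec.friction_true,
        "D_true": kBT / spec.friction_true,
        "omega_true": omega,
        "stationary_variance": var_st,
        "temperature": spec.temperature,
    }
    field = FluctuationField.from_radii(h, fps=spec.fps, pixel_size=1.0,
                                        cell_id=f"ou-seed{spec.seed}", truth=truth)
    return field, truth


@dataclass
class EnsembleSpec:
    """Static contour ensemble with a prescribed effective lateral tension."""

    n_cells: int = 300
    n_angles: int = 720
    tension_true: float = 5e-7       # sigma0, N/m
    mode_band: tuple = (2, 3, 4)
    temperature: float = DEFAULT_TEMPERATURE
    radius: float = 3.7e-6           # R0, meters
    pixel_size: float = 0.103e-6     # metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise SpecValidationError("n_cells must be >= 1")
        if any(int(m) < 2 for m in self.mode_band):
            raise SpecValidationError("mode_band entries must be >= 2")
        if not self.tension_true > 0:
            raise SpecValidationError("tension_true must be positive")


def generate_static_ensemble(spec: EnsembleSpec):
    """Draw contours whose expected mode spectrum follows the tension law.

    Each contour is R(theta) = R0 + h(theta) with independent complex mode
    amplitudes c_n (n in ``mode_band``) drawn so that E|c_n|^2 =
    k_BT / (2 pi n sigma0); h is real by conjugate symmetry and carries no
    n = 0 component. Returns ``(contours, truth)``.
    """
    kBT = BOLTZMANN * spec.temperature
    rng = np.random.default_rng(spec.seed)
    theta = uniform_angles(spec.n_angles)
    modes = np.array(sorted(int(m) for m in spec.mode_band))
    target = kBT / (2.0 * np.pi * modes * spec.tension_true)  # E|c_n|^2 per mode

    contours = []
    for i in range(spec.n_cells):
        re = rng.normal(0.0, np.sqrt(target / 2.0))
        im = rng.normal(0.0, np.sqrt(target / 2.0))
        h = np.zeros(spec.n_angles)
        for m, cr, ci in zip(modes, re, im):
            h += 2.0 * (cr * np.cos(m * theta) - ci * np.sin(m * theta))
        contours.append(
            Contour(centroid=(0.0, 0.0), radii=spec.radius + h,
                    pixel_size=spec.pixel_size, cell_id=f"ens{i:04d}")
        )
    truth = {
        "tension_true": spec.tension_true,
        "mode_band": [int(m) for m in modes],
        "expected_power": {int(m): float(t) for m, t in zip(modes, target)},
        "temperature": spec.temperature,
    }
    return contours, truth


def generate_mode_series(n_frames: int, fps: float, mean_square: float,
                         omega: float, seed: int) -> np.ndarray:
    """Stationary complex OU series for a single Fourier mode amplitude.

    Real and imaginary parts are independent OU processes with relaxation
    rate ``omega`` and stationary variance ``mean_square / 2`` each, so the
    time-averaged |c(t)|^2 converges to ``mean_square``. Used to test that
    ensemble (fixed-time) and time-averaged tension estimates agree.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    a = np.exp(-omega * dt)
    var = mean_square / 2.0
    step_sd = np.sqrt(var * (1.0 - a * a))
    out = np.empty((2, n_frames))
    out[:, 0] = rng.normal(0.0, np.sqrt(var), 2)
    for k in range(1, n_frames):
        out[:, k] = a * out[:, k - 1] + rng.normal(0.0, step_sd, 2)
    return out[0] + 1j * out[1]


@dataclass
class VideoOptics:
    """Rendering parameters for contour fluctuation videos."""

    image_size: int = 256
    pixel_size: float = 50e-9        # m/px, high-speed acquisition scale
    base_radius: float = 3.2e-6      # R0 of the rendered cell, m
    rim_width: float = 0.2e-6        # m
    rim_depth: float = 0.6
    noise_sd: float = 0.0
    drift_px_per_frame: tuple = (0.0, 0.0)   # (d_row, d_col)
    seed: int = 0


def render_contour_video(field: FluctuationField, optics: VideoOptics) -> np.ndarray:
    """Render each time slice of a fluctuation field as a dark-rim frame.

    Frame k draws the contour R(theta, t_k) = base_radius + h(theta, t_k)
    centered at the (optionally drifting) cell position. Raises
    SpecValidationError naming the first frame whose contour leaves the
    usable frame area.
    """
    n = optics.image_size
    px = optics.pixel_size
    w = optics.rim_width / px
    t_grid = np.arange(field.n_frames)
    centers = np.array([
        n / 2.0 + optics.drift_px_per_frame[0] * t_grid,
        n / 2.0 + optics.drift_px_per_frame[1] * t_grid,
    ]).T

    radii_px = (optics.base_radius + field.h) / px   # (n_angles, T)
    for k in range(field.n_frames):
        reach = radii_px[:, k].max() + 3 * w
        cy, cx = centers[k]
        if (cy - reach < 1 or cx - reach < 1
                or cy + reach > n - 2 or cx + reach > n - 2):
            raise SpecValidationError(f"contour exits frame at frame {k}")

    ang = uniform_angles(field.n_angles)
    ang_ext = np.concatenate([ang, [2 * np.pi]])
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    stack = np.empty((field.n_frames, n, n))
    rng = np.random.default_rng(optics.seed)
    for k in range(field.n_frames):
        cy, cx = centers[k]
        dy, dx = yy - cy, xx - cx
        rho = np.hypot(dy, dx)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        prof = np.concatenate([radii_px[:, k], radii_px[:1, k]])
        rim = np.interp(theta, ang_ext, prof)
        frame = _BACKGROUND * (1.0 - optics.rim_depth
                               * np.exp(-((rho - rim) ** 2) / (2 * w ** 2)))
        if optics.noise_sd > 0:
            frame = frame + rng.normal(0.0, optics.noise_sd, frame.shape)
        stack[k] = np.clip(frame, 0.0, 1.0)
    return stack


#: Noise-free blank and full-lysis absorbance triplets (A415, A380, A450).
BLANK_TRUE = np.array([0.050, 0.040, 0.030])
LYSIS_TRUE = np.array([1.250, 0.180, 0.090])


def generate_absorbance(blank_sd: float, hb_level: float, seed: int = 0,
                        n_blank_replicates: int = 3, n_reads: int = 5) -> pd.DataFrame:
    """Emit the absorbance records the hemolysis readout consumes.

    Roles in the returned table: ``blank`` (``n_blank_replicates`` x
    ``n_reads`` reads), ``sample`` (3 replicates) and ``lysis_reference``
    (3 reads). The noise-free sample triplet is blank + hb_level * (lysis -
    blank) per wavelength, so its blank-corrected Harboe value is exactly
    ``hb_level`` times the full-lysis value. Read noise of SD ``blank_sd``
    is added to every read.
    """
    if blank_sd < 0:
        raise SpecValidationError("blank_sd must be non-negative")
    if hb_level < 0:
        raise SpecValidationError("hb_level must be non-negative")
    rng = np.random.default_rng(seed)
    sample_true = BLANK_TRUE + hb_level * (LYSIS_TRUE - BLANK_TRUE)

    rows = []

    def _emit(role, replicate, read, triplet):
        noisy = triplet + (rng.normal(0.0, blank_sd, 3) if blank_sd > 0 else 0.0)
        rows.append({"role": role, "replicate": replicate, "read": read,
                     "A415": noisy[0], "A380": noisy[1], "A450": noisy[2]})

    for rep in range(1, n_blank_replicates + 1):
        for read in range(1, n_reads + 1):
            _emit("blank", rep, read, BLANK_TRUE)
    for rep in range(1, 4):
        _emit("sample", rep, 1, sample_true)
    for read in range(1, 4):
        _emit("lysis_reference", 1, read, LYSIS_TRUE)
    return pd.DataFrame(rows)
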
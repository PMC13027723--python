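"""Bright-field segmentation: frames -> accepted contours -> fluctuation fields.

The field-morphometry branch takes a single bright-field frame through
Gaussian denoising, global Otsu binarization (cells are the dark rim class),
hole filling, 8-connected labeling, and a deterministic acceptance filter
(border margin, focus, aggregate, circularity, size). Accepted components
are converted to 720-angle polar contours via a periodic smoothing fit.

The high-speed branch tracks a single cell through a video stack frame by
frame, re-centers each contour on the instantaneous darkness-weighted
centroid, resamples at 1024 angles, and subtracts the per-angle time mean to
produce the fluctuation field h(theta, t).

Otsu's threshold is implemented here (256-bin between-class variance
maximization, ties broken toward the lowest threshold) because downstream
tests pin its tie-break behavior exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .contour import Contour, FluctuationField, fit_periodic
from .errors import DegenerateInputError, NonStarConvexError, TrackingError

logger = logging.getLogger(__name__)

__all__ = [
    "AcceptanceCriteria", "ComponentRecord", "preprocess", "otsu_threshold",
    "detect_and_filter", "extract_contour", "track_video", "TrackParams",
]


def preprocess(frame: np.ndarray) -> np.ndarray:
    """Gaussian denoising (sigma = 2 px) followed by affine rescale to [0, 1]."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise DegenerateInputError("empty frame")
    smoothed = filters.gaussian(frame, sigma=2, preserve_range=True)
    lo, hi = smoothed.min(), smoothed.max()
    if hi == lo:
        raise DegenerateInputError("constant frame: cannot normalize intensities")
    return (smoothed - lo) / (hi - lo)


def otsu_threshold(frame: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance (Otsu).

    Returns the bin-center threshold; pixels with value <= threshold form
    the lower class. Ties are broken toward the lowest maximizing threshold.
    """
    values = np.asarray(frame, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("need >= 2 distinct values for Otsu thresholding")
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(float)

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    mu_cum = np.cumsum(hist * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_cum[-1] - mu_cum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where(np.isfinite(var_between), var_between, -np.inf)
    # exclude the last split (empty upper class); argmax takes the first tie
    split = int(np.argmax(var_between[:-1]))
    return float(centers[split])


@dataclass
class AcceptanceCriteria:
    """Deterministic acceptance filter for candidate cell components.

    ``radius_window`` is in micrometers (equivalent radius of the binarized
    component); ``focus_metric_min`` is a rim-sharpness floor in units of
    normalized intensity per pixel (high-percentile gradient magnitude
    inside the component); ``solidity_min`` flags aggregates.
    """

    circularity_min: float = 0.9
    radius_window: tuple = (7.0, 8.0)     # um
    border_margin: int = 1                # px
    focus_metric_min: float = 0.06        # 1/px
    solidity_min: float = 0.9
    circularity_kind: str = "std"         # "std": 4*pi*A/P^2; "lin": 2*pi*R_eq/P

    def __post_init__(self) -> None:
        if not (0 < self.circularity_min <= 1):
            raise ValueError("circularity_min must lie in (0, 1]")
        if not self.radius_window[0] < self.radius_window[1]:
            raise ValueError("radius_window must be (min, max) with min < max")


@dataclass
class ComponentRecord:
    """One labeled component with the metrics the filter evaluated."""

    label: int
    centroid: tuple                 # (row, col), px
    bbox: tuple                     # (minr, minc, maxr, maxc)
    mask: np.ndarray                # local boolean mask over the bbox
    area_px: float
    equivalent_radius_um: float
    circularity: float
    solidity: float
    focus_metric: float
    status: str = "accepted"        # or the first failing check's reason code


def _component_metrics(prop, grad: np.ndarray, pixel_size_m: float) -> dict:
    area = float(prop.area)
    perim = float(prop.perimeter_crofton)
    mask_grad = grad[prop.slice][prop.image]
    return {
        "area_px": area,
        "equivalent_radius_um": pixel_size_m * 1e6 * np.sqrt(area / np.pi),
        "circularity": 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0,
        "solidity": float(prop.solidity),
        "focus_metric": float(np.percentile(mask_grad, 99)) if mask_grad.size else 0.0,
    }


def detect_and_filter(frame: np.ndarray, criteria: AcceptanceCriteria,
                      pixel_size: float, min_area_px: int = 64):
    """Binarize a preprocessed frame and apply the acceptance filter.

    Parameters
    ----------
    frame
        Preprocessed (denoised, [0, 1]-normalized) frame.
    criteria
        Acceptance thresholds.
    pixel_size
        Meters per pixel.
    min_area_px
        Components below this pixel area are treated as debris and ignored
        (not logged as cells).

    Returns
    -------
    accepted : list of ComponentRecord, in raster order of centroid.
    log : list of ComponentRecord covering every evaluated component,
        with ``status`` equal to "accepted" or the first failing check among
        border, focus, aggregate, circularity, size.
    """
    t = otsu_threshold(frame)
    mask = ndimage.binary_fill_holes(frame <= t)
    labels = measure.label(mask, connectivity=2)
    grad = filters.sobel(frame)
    props = measure.regionprops(labels)
    props = [p for p in props if p.area >= min_area_px]
    props.sort(key=lambda p: (round(p.centroid[0]), round(p.centroid[1])))

    h, w = frame.shape
    m = criteria.border_margin
    rmin, rmax = criteria.radius_window
    accepted, log = [], []
    for p in props:
        metrics = _component_metrics(p, grad, pixel_size)
        circ = metrics["circularity"]
        if criteria.circularity_kind == "lin":
            circ = np.sqrt(circ)
        minr, minc, maxr, maxc = p.bbox
        status = "accepted"
        if minr < m or minc < m or maxr > h - m or maxc > w - m:
            status = "border"
        elif metrics["focus_metric"] < criteria.focus_metric_min:
            status = "focus"
        elif (metrics["solidity"] < criteria.solidity_min
              or (circ < criteria.circularity_min
                  and metrics["equivalent_radius_um"] > rmax)):
            status = "aggregate"
        elif circ < criteria.circularity_min:
            status = "circularity"
        elif not (rmin <= metrics["equivalent_radius_um"] <= rmax):
            status = "size"
        rec = ComponentRecord(label=int(p.label), centroid=tuple(p.centroid),
                              bbox=p.bbox, mask=p.image, status=status, **metrics)
        log.append(rec)
        if status == "accepted":
            accepted.append(rec)
    logger.info("detect_and_filter: %d candidates, %d accepted",
                len(log), len(accepted))
    return accepted, log


def _darkness_centroid(frame: np.ndarray, comp: ComponentRecord) -> tuple:
    """Intensity-weighted centroid of a component (dark pixels weigh more)."""
    minr, minc, maxr, maxc = comp.bbox
    local = frame[minr:maxr, minc:maxc]
    wgt = np.where(comp.mask, 1.0 - local, 0.0)
    total = wgt.sum()
    if total <= 0:
        raise DegenerateInputError("component has no dark weight")
    rr, cc = np.mgrid[minr:maxr, minc:maxc]
    return (float((wgt * rr).sum() / total), float((wgt * cc).sum() / total))


def extract_contour(frame: np.ndarray, component: ComponentRecord,
                    n_angles: int = 720, spline_degree: int = 12,
                    pixel_size: float = 0.103e-6,
                    level: float | None = None) -> Contour:
    """Polar contour of a component on a uniform angle grid.

    The component boundary is expressed as (theta, r) about the
    darkness-weighted centroid and fitted with a periodic smoothing fit of
    ``spline_degree`` harmonics, then evaluated on the uniform ``n_angles``
    grid. Radii are converted to meters.

    When ``level`` is given (normally the Otsu threshold), the boundary is
    the sub-pixel iso-intensity contour of the frame at that level (the
    outer crossing of the dark rim), which mitigates pixelation; otherwise
    the pixel boundary of the binarized mask is used.

    Raises NonStarConvexError when the boundary is multi-valued in polar
    form (e.g., crescent-shaped components).
    """
    minr, minc, maxr, maxc = component.bbox
    if level is None:
        padded = np.pad(component.mask.astype(float), 1)
        rings = measure.find_contours(padded, 0.5)
        offset = (minr - 1, minc - 1)
    else:
        pad = 3
        r0 = max(minr - pad, 0)
        c0 = max(minc - pad, 0)
        r1 = min(maxr + pad, frame.shape[0])
        c1 = min(maxc + pad, frame.shape[1])
        local = frame[r0:r1, c0:c1].copy()
        keep = np.zeros(local.shape, dtype=bool)
        keep[minr - r0:maxr - r0, minc - c0:maxc - c0] = component.mask
        keep = ndimage.binary_dilation(keep, iterations=2)
        local[~keep] = 1.0
        rings = measure.find_contours(local, level)
        offset = (r0, c0)
    if not rings:
        raise NonStarConvexError("component has no boundary")
    boundary = max(rings, key=len)
    rows = boundary[:, 0] + offset[0]
    cols = boundary[:, 1] + offset[1]

    cy, cx = _darkness_centroid(frame, component)
    dy, dx = rows - cy, cols - cx
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)

    # star-convexity guard: radius must be single-valued per angular bin
    nbins = 72
    bins = np.minimum((theta / (2 * np.pi) * nbins).astype(int), nbins - 1)
    med = np.median(r)
    for b in range(nbins):
        sel = bins == b
        if np.any(sel) and (r[sel].max() - r[sel].min()) > 0.25 * med:
            raise NonStarConvexError(
                "boundary is multi-valued in polar form about the centroid"
            )

    radii_px, residual = fit_periodic(theta, r, spline_degree, n_angles)
    if np.any(radii_px <= 0):
        raise NonStarConvexError("fitted contour crosses the centroid")
    return Contour(centroid=(cy, cx), radii=radii_px * pixel_size,
                   pixel_size=pixel_size, cell_id=f"comp{component.label}",
                   fit_residual_px=residual)


@dataclass
class TrackParams:
    """Tracking configuration for high-speed single-cell videos."""

    pixel_size: float = 50e-9    # m/px
    fps: float = 2000.0
    n_angles: int = 1024
    spline_degree: int = 18
    min_area_px: int = 64


def track_video(stack: np.ndarray, params: TrackParams,
                cell_id: str = "") -> FluctuationField:
    """Track one cell through a video stack and build its fluctuation field.

    Every frame must segment to exactly one candidate component; each frame's
    contour is re-centered on the instantaneous centroid, so rigid drift
    cancels by construction. The per-angle time mean is subtracted at the
    end, yielding h(theta, t) = R(theta, t) - <R(theta, t)>_t.

    Raises TrackingError naming the first frame that cannot be tracked.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (T, H, W) with T >= 2")
    radii = np.empty((params.n_angles, stack.shape[0]))
    for k, raw in enumerate(stack):
        try:
            frame = preprocess(raw)
            t = otsu_threshold(frame)
            mask = ndimage.binary_fill_holes(frame <= t)
            labels = measure.label(mask, connectivity=2)
            props = [p for p in measure.regionprops(labels)
                     if p.area >= params.min_area_px]
            if len(props) != 1:
                raise TrackingError(
                    k, f"expected exactly 1 candidate component, found {len(props)}")
            p = props[0]
            comp = ComponentRecord(
                label=int(p.label), centroid=tuple(p.centroid), bbox=p.bbox,
                mask=p.image, area_px=float(p.area), equivalent_radius_um=0.0,
                circularity=0.0, solidity=float(p.solidity), focus_metric=0.0)
            contour = extract_contour(frame, comp, n_angles=params.n_angles,
                                      spline_degree=params.spline_degree,
                                      pixel_size=params.pixel_size, level=t)
        except TrackingError:
            raise
        except (DegenerateInputError, NonStarConvexError) as exc:
            raise TrackingError(k, str(exc)) from exc
        radii[:, k] = contour.radii
    return FluctuationField.from_radii(radii, fps=params.fps,
                                       pixel_size=params.pixel_size,
                                       cell_id=cell_id)
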
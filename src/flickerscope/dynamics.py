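"""Time-resolved flickering descriptors of per-angle fluctuation series.

Under an overdamped Langevin description of each local contour coordinate
h(t), thermal equilibrium links the observable statistics to effective
viscoelastic parameters:

* effective rigidity   k_eff = k_BT / <h^2>_t        (equipartition),
* Einstein diffusivity D from the initial MSD slope  <dh^2>(tau) = 2 D tau,
* effective friction   gamma = k_BT / D              (Einstein relation),
* relaxation frequency omega_c = k_eff / gamma = k_eff * D / k_BT,
  with tau_c = 1/omega_c,
* volatility: the SD of moving-window amplitude SDs, a non-stationarity
  marker.

A cell is summarized by the median of each per-angle descriptor across its
(nominally 1024) angle series; gamma, omega_c and tau_c are derived from the
aggregated k_eff and D, so gamma * D = k_BT holds exactly per record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import FluctuationField
from .errors import DegenerateInputError, UnusableCellError
from .thermal import ThermalContext

__all__ = ["MsdCurve", "DynamicsRecord", "msd_curve", "fit_diffusivity",
           "effective_rigidity", "derived_rates", "volatility", "cell_summary"]


@dataclass
class MsdCurve:
    """Mean squared displacement of one series at lags 0 .. max_lag."""

    lags: np.ndarray       # seconds, multiples of 1/fps, starting at 0
    msd: np.ndarray        # m^2
    n_pairs: np.ndarray    # overlapping pairs per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if self.msd[0] != 0 or np.any(self.msd < 0):
            raise ValueError("msd must be non-negative with msd[0] = 0")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class DynamicsRecord:
    """Per-cell viscoelastic descriptors."""

    k_eff: float           # N/m
    D: float               # m^2/s
    gamma: float           # kg/s
    omega_c: float         # 1/s
    tau_c: float           # s
    volatility: float      # m
    n_angles_used: int
    cell_id: str = ""
    condition: str = ""


def msd_curve(series: np.ndarray, max_lag: int, fps: float) -> MsdCurve:
    """MSD over all overlapping pairs: msd[m] = <(h(t + m/fps) - h(t))^2>."""
    series = np.asarray(series, dtype=float)
    t = series.size
    if max_lag >= t:
        raise ValueError(f"max_lag {max_lag} must be < series length {t}")
    msd = np.zeros(max_lag + 1)
    n_pairs = np.empty(max_lag + 1, dtype=int)
    n_pairs[0] = t
    for m in range(1, max_lag + 1):
        diff = series[m:] - series[:-m]
        msd[m] = np.mean(diff * diff)
        n_pairs[m] = t - m
    return MsdCurve(lags=np.arange(max_lag + 1) / fps, msd=msd, n_pairs=n_pairs)


def fit_diffusivity(msd: MsdCurve, fit_lags: int = 10):
    """Least-squares fit of msd = 2 D tau through the origin.

    Uses the first ``fit_lags`` nonzero lags. Returns ``(D, rel_residual)``
    where the relative residual is the RMS misfit over the fit window
    divided by the RMS msd there (a fit-quality flag).
    """
    if fit_lags < 2 or fit_lags >= msd.lags.size:
        raise ValueError("need 2 <= fit_lags <= available lags")
    tau = msd.lags[1:fit_lags + 1]
    y = msd.msd[1:fit_lags + 1]
    if np.all(y == 0):
        raise DegenerateInputError("msd is identically zero over the fit window")
    slope = np.sum(y * tau) / np.sum(tau * tau)
    resid = np.sqrt(np.mean((y - slope * tau) ** 2) / np.mean(y * y))
    return slope / 2.0, float(resid)


def effective_rigidity(series: np.ndarray, thermal: ThermalContext) -> float:
    """k_eff = k_BT / <h^2>_t with the series re-centered (divisor T)."""
    series = np.asarray(series, dtype=float)
    h = series - series.mean()
    ms = np.mean(h * h)
    if ms == 0:
        raise DegenerateInputError("zero-variance series has no thermal amplitude")
    return thermal.kBT / ms


def derived_rates(k_eff: float, D: float, thermal: ThermalContext):
    """(gamma, omega_c, tau_c) from k_eff and D via the Einstein relation."""
    if not (k_eff > 0 and D > 0):
        raise ValueError("k_eff and D must be positive")
    gamma = thermal.kBT / D
    omega_c = k_eff * D / thermal.kBT
    return gamma, omega_c, 1.0 / omega_c


def volatility(series: np.ndarray, fps: float, window_s: float = 0.5,
               stride_s: float = 0.25) -> float:
    """SD of moving-window amplitude SDs (0.5 s windows every 0.25 s).

    Windows are fully contained in the record (partial trailing windows are
    discarded); within-window SDs use the population divisor. Stationary
    series give values near zero; amplitude modulation inflates the result.
    """
    series = np.asarray(series, dtype=float)
    win = int(round(window_s * fps))
    stride = max(int(round(stride_s * fps)), 1)
    if win < 2 or series.size < win:
        raise ValueError("series shorter than one window")
    starts = range(0, series.size - win + 1, stride)
    sds = np.array([series[s:s + win].std() for s in starts])
    if sds.size < 2:
        raise ValueError("need at least 2 windows for volatility")
    return float(sds.std())


def cell_summary(field: FluctuationField, thermal: ThermalContext,
                 msd_fit_lags: int = 10, window_s: float = 0.5,
                 stride_s: float = 0.25, condition: str = "") -> DynamicsRecord:
    """Aggregate per-angle descriptors to a per-cell DynamicsRecord.

    Degenerate (zero-variance) angle series are dropped and counted; the
    cell is flagged unusable when more than half its angles are degenerate.
    k_eff, D and volatility are aggregated across angles by the median,
    then gamma, omega_c, tau_c are derived from the aggregates.
    """
    ks, ds, vols = [], [], []
    for series in field.h:
        try:
            k = effective_rigidity(series, thermal)
            msd = msd_curve(series, max_lag=msd_fit_lags, fps=field.fps)
            d, _ = fit_diffusivity(msd, fit_lags=msd_fit_lags)
            v = volatility(series, field.fps, window_s, stride_s)
        except DegenerateInputError:
            continue
        ks.append(k)
        ds.append(d)
        vols.append(v)
    n_used = len(ks)
    if n_used <= field.n_angles / 2:
        raise UnusableCellError(
            f"cell {field.cell_id!r}: {field.n_angles - n_used} of "
            f"{field.n_angles} angle series are degenerate")
    k_eff = float(np.median(ks))
    d_med = float(np.median(ds))
    gamma, omega_c, tau_c = derived_rates(k_eff, d_med, thermal)
    return DynamicsRecord(k_eff=k_eff, D=d_med, gamma=gamma, omega_c=omega_c,
                          tau_c=tau_c, volatility=float(np.median(vols)),
                          n_angles_used=n_used, cell_id=field.cell_id,
                          condition=condition)
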
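"""Harboe hemolysis readout: percent of full lysis and blank-derived LOD.

Free hemoglobin is quantified spectrophotometrically from absorbance
triplets (A415, A380, A450): after per-wavelength blank subtraction the
Harboe combination

    H = c1*A415' - c2*A380' - c3*A450'

(default weights 167.2, 83.6, 83.6) gives a hemoglobin proxy; hemolysis is
reported as 100 * H_sample / H_full_lysis relative to complete hypotonic
lysis. The limit of detection is obtained by propagating the per-wavelength
blank read SDs through the Harboe weights (root sum of squares) and scaling
by a multiplier (default 3.3), expressed as a percent of full lysis.
Negative blank-corrected values are reported as-is (flagged below-LOD),
never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SchemaError

__all__ = ["AbsorbanceTriplet", "HemolysisResult", "HARBOE_WEIGHTS",
           "harboe_value", "percent_hemolysis", "lod_from_blanks",
           "evaluate_records"]

#: Standard Harboe weights (c1, c2, c3) for (A415, A380, A450).
HARBOE_WEIGHTS = (167.2, 83.6, 83.6)

_WAVELENGTHS = ("A415", "A380", "A450")


@dataclass(frozen=True)
class AbsorbanceTriplet:
    A415: float
    A380: float
    A450: float
    role: str = "sample"       # blank | sample | lysis_reference
    replicate: int = 1
    read: int = 1

    def as_array(self) -> np.ndarray:
        return np.array([self.A415, self.A380, self.A450], dtype=float)


@dataclass
class HemolysisResult:
    percent: float
    lod_percent: float
    below_lod: bool
    condition: str = ""
    timepoint: str = ""


def harboe_value(sample: AbsorbanceTriplet, blank_mean: AbsorbanceTriplet,
                 weights=HARBOE_WEIGHTS) -> float:
    """Blank-corrected Harboe hemoglobin proxy of one sample triplet."""
    corrected = sample.as_array() - blank_mean.as_array()
    c1, c2, c3 = weights
    return float(c1 * corrected[0] - c2 * corrected[1] - c3 * corrected[2])


def percent_hemolysis(sample_h: float, lysis_reference_h: float) -> float:
    """Hemolysis as a percentage of the full-lysis Harboe value."""
    if not lysis_reference_h > 0:
        raise ValueError("lysis reference Harboe value must be positive")
    return 100.0 * sample_h / lysis_reference_h


def lod_from_blanks(blanks: pd.DataFrame, lysis_reference_h: float,
                    weights=HARBOE_WEIGHTS, multiplier: float = 3.3) -> float:
    """Limit of detection (percent of full lysis) from replicate blank reads.

    ``blanks`` must carry columns replicate, A415, A380, A450 with at least
    2 reads per replicate; read SDs are pooled per wavelength over all reads
    and propagated through the Harboe weights in quadrature.
    """
    for col in ("replicate", *_WAVELENGTHS):
        if col not in blanks.columns:
            raise SchemaError(f"blank table is missing column {col!r}")
    counts = blanks.groupby("replicate").size()
    if (counts < 2).any():
        raise DegenerateInputError(
            "every blank replicate needs >= 2 reads to estimate uncertainty")
    def _read_sd(values: np.ndarray) -> float:
        # identical reads have exactly zero scatter (mean round-off otherwise
        # leaks ~1 ulp into the SD of a constant column)
        return 0.0 if np.ptp(values) == 0 else float(np.std(values, ddof=1))

    sds = np.array([_read_sd(blanks[w].to_numpy()) for w in _WAVELENGTHS])
    lod_h = multiplier * float(np.sqrt(np.sum((np.array(weights) * sds) ** 2)))
    return percent_hemolysis(lod_h, lysis_reference_h)


def evaluate_records(records: pd.DataFrame, weights=HARBOE_WEIGHTS,
                     lod_multiplier: float = 3.3, condition: str = "",
                     timepoint: str = "") -> HemolysisResult:
    """Full readout from a records table in the synthetic-absorbance schema.

    Blank reads are averaged per wavelength for correction; the sample and
    lysis-reference Harboe values are computed from their mean triplets; the
    LOD comes from the blank read scatter.
    """
    for col in ("role", "replicate", "read", *_WAVELENGTHS):
        if col not in records.columns:
            raise SchemaError(f"absorbance table is missing column {col!r}")
    by_role = {role: grp for role, grp in records.groupby("role")}
    for role in ("blank", "sample", "lysis_reference"):
        if role not in by_role:
            raise SchemaError(f"absorbance table has no {role!r} rows")

    def _mean_triplet(df: pd.DataFrame, role: str) -> AbsorbanceTriplet:
        return AbsorbanceTriplet(*[df[w].mean() for w in _WAVELENGTHS], role=role)

    blank_mean = _mean_triplet(by_role["blank"], "blank")
    sample_h = harboe_value(_mean_triplet(by_role["sample"], "sample"),
                            blank_mean, weights)
    reference_h = harboe_value(
        _mean_triplet(by_role["lysis_reference"], "lysis_reference"),
        blank_mean, weights)
    percent = percent_hemolysis(sample_h, reference_h)
    lod = lod_from_blanks(by_role["blank"], reference_h, weights, lod_multiplier)
    return HemolysisResult(percent=percent, lod_percent=lod,
                           below_lod=percent < lod, condition=condition,
                           timepoint=timepoint)
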
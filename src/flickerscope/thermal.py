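"""Thermal context: temperature and k_BT used by every fluctuation-inference formula.

All equipartition-style estimators (effective tension, effective rigidity,
Einstein friction) share a single energy scale k_BT. Keeping it in one frozen
object guarantees that a run cannot silently mix temperatures between the
ensemble and time-resolved branches.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23

#: Assay temperature used throughout: 37 degrees C.
DEFAULT_TEMPERATURE = 310.15


@dataclass(frozen=True)
class ThermalContext:
    """Temperature (K) and the derived thermal energy k_BT (J)."""

    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kBT(self) -> float:
        return BOLTZMANN * self.temperature
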
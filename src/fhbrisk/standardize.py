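"""Brand calibration of quantitative FIT readings.

Quantitative FIT kits report hemoglobin concentration in the sampling
buffer (ng/mL); screening programs report the standardized unit of
micrograms of hemoglobin per gram of feces (μg/g).  Both common kits'
positivity cutoffs correspond to the same standardized cutoff of 20 μg/g:
100 ng/mL for the OC-Sensor and 8 ng/mL for the HM-Jack.  The conversion
is modelled as linear through the origin, with the factor fixed by the
cutoff pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD_CUTOFF_UG_PER_G = 20.0


@dataclass(frozen=True)
class BrandCalibration:
    """Linear buffer-to-feces conversion for one FIT brand.

    ``factor`` maps ng/mL in buffer to μg/g feces and is derived so the
    brand's buffer cutoff lands exactly on the standardized cutoff.
    """

    brand: str
    cutoff_ng_per_ml: float
    standardized_cutoff_ug_per_g: float = STANDARD_CUTOFF_UG_PER_G
    factor: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cutoff_ng_per_ml <= 0:
            raise ValueError(f"cutoff_ng_per_ml must be positive, got {self.cutoff_ng_per_ml}")
        if self.standardized_cutoff_ug_per_g <= 0:
            raise ValueError("standardized_cutoff_ug_per_g must be positive")
        if self.factor is None:
            object.__setattr__(
                self, "factor", self.standardized_cutoff_ug_per_g / self.cutoff_ng_per_ml
            )
        if self.factor <= 0:
            raise ValueError(f"factor must be positive, got {self.factor}")
        if abs(self.factor * self.cutoff_ng_per_ml - self.standardized_cutoff_ug_per_g) > 1e-12:
            raise ValueError(
                "inconsistent calibration: factor * cutoff_ng_per_ml must equal "
                "the standardized cutoff"
            )


DEFAULT_CALIBRATIONS: dict[str, BrandCalibration] = {
    "OC-Sensor": BrandCalibration("OC-Sensor", cutoff_ng_per_ml=100.0),
    "HM-Jack": BrandCalibration("HM-Jack", cutoff_ng_per_ml=8.0),
}


def standardize_fhb(value_ng_per_ml, calibration: BrandCalibration):
    """Convert a buffer concentration (ng/mL) to standardized f-Hb (μg/g).

    Accepts scalars or arrays; the conversion is linear and
    order-preserving.  Negative readings are rejected.
    """
    value = np.asarray(value_ng_per_ml, dtype=float)
    if np.any(value < 0):
        raise ValueError("f-Hb buffer concentration must be nonnegative")
    out = value * calibration.factor
    return float(out) if np.isscalar(value_ng_per_ml) else out


def classify_fit(value_std, cutoff: float = STANDARD_CUTOFF_UG_PER_G):
    """FIT positivity: standardized f-Hb at or above the cutoff is positive."""
    value = np.asarray(value_std, dtype=float)
    if np.any(value < 0):
        raise ValueError("standardized f-Hb must be nonnegative")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = value >= cutoff
    return bool(out) if np.isscalar(value_std) else out
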
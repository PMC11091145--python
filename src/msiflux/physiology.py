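"""Ex vivo perfusion physiology: oxygen transport, resistance, weight gain,
glomerular sieving, and hemofiltration exchange.

Units follow bedside perfusion practice: pressures in mmHg, flow in mL/min,
oxygen in mL O₂/min using the plasma solubility of oxygen
(0.0031 mL O₂ per dL of fluid per mmHg), weights in grams, dextran
fluorescence in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

#: Solubility of O₂ in the acellular perfusate, mL O₂ · dL⁻¹ · mmHg⁻¹.
O2_SOLUBILITY = 0.0031

#: Arterial pressure set-point of the centrifugal pump, mmHg.
MAP_SETPOINT = 75.0


@dataclass
class PerfusionTimeSeries:
    """Longitudinal hemodynamic and biochemical record of one perfusion."""

    time_h: np.ndarray
    flow_ml_min: np.ndarray
    map_mmhg: np.ndarray
    po2_art: np.ndarray
    po2_ven: np.ndarray
    ph: Optional[np.ndarray] = None
    lactate_mmol_l: Optional[np.ndarray] = None
    glucose_mmol_l: Optional[np.ndarray] = None
    weight_initial_g: float = float("nan")
    weight_final_g: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("time_h", "flow_ml_min", "map_mmhg", "po2_art", "po2_ven"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("ph", "lactate_mmol_l", "glucose_mmol_l"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.flow_ml_min < 0):
            raise ValueError("flow must be non-negative")
        if np.any(self.po2_art < 0) or np.any(self.po2_ven < 0):
            raise ValueError("pO2 must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_h": self.time_h,
            "flow_ml_min": self.flow_ml_min,
            "map_mmhg": self.map_mmhg,
            "po2_art": self.po2_art,
            "po2_ven": self.po2_ven,
        }
        for name, col in (
            ("ph", self.ph),
            ("lactate_mmol_l", self.lactate_mmol_l),
            ("glucose_mmol_l", self.glucose_mmol_l),
        ):
            if col is not None:
                data[name] = col
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SievingSample:
    """One timed urine/perfusate fluorescence pair for a dextran tracer."""

    timepoint_min: float
    dextran: str  # "20kDa-FITC" or "500kDa-TRITC"
    f_urine: float
    f_perfusate: float

    def __post_init__(self) -> None:
        if self.f_urine < 0 or self.f_perfusate < 0:
            raise ValueError("fluorescence must be non-negative")


def oxygen_delivery(po2_art, flow_ml_min):
    """mL O₂/min delivered: arterial pO₂ × 0.0031 × flow in dL/min."""
    po2_art = np.asarray(po2_art, dtype=float)
    flow = np.asarray(flow_ml_min, dtype=float)
    if np.any(po2_art < 0) or np.any(flow < 0):
        raise ValueError("pO2 and flow must be non-negative")
    out = po2_art * O2_SOLUBILITY * (flow / 100.0)
    return float(out) if out.ndim == 0 else out


class UptakeResult(NamedTuple):
    value: float
    reverse_gradient: bool


def oxygen_uptake(po2_art, po2_ven, flow_ml_min) -> UptakeResult:
    """mL O₂/min taken up: ΔpO₂ × 0.0031 × flow in dL/min.

    Computed literally as delivery(arterial) − delivery(venous), so the
    linearity identity holds to the last bit.  A venous pO₂ above arterial
    gives a negative value with the reverse-gradient flag set.
    """
    value = oxygen_delivery(po2_art, flow_ml_min) - oxygen_delivery(
        po2_ven, flow_ml_min
    )
    reverse = bool(np.any(np.asarray(po2_ven) > np.asarray(po2_art)))
    return UptakeResult(value, reverse)


def vascular_resistance(map_mmhg, flow_ml_min):
    """Perfusion pressure over flow, mmHg·min/mL; NaN when flow is zero."""
    map_mmhg = np.asarray(map_mmhg, dtype=float)
    flow = np.asarray(flow_ml_min, dtype=float)
    out = np.where(flow > 0, map_mmhg / np.where(flow > 0, flow, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


class WeightGain(NamedTuple):
    percent: float
    percent_int: int


def weight_gain_pct(weight_initial_g: float, weight_final_g: float) -> WeightGain:
    """Weight gain as a percentage of baseline, with a half-up integer report."""
    if weight_initial_g <= 0:
        raise ValueError("initial weight must be positive")
    pct = 100.0 * (weight_final_g - weight_initial_g) / weight_initial_g
    rounded = math.floor(pct + 0.5) if pct >= 0 else math.ceil(pct - 0.5)
    return WeightGain(pct, int(rounded))


class SievingResult(NamedTuple):
    value: Optional[float]
    clamped: bool = False
    reason: Optional[str] = None

    @property
    def valid(self) -> bool:
        return self.value is not None


def sieving_coefficient(
    sample: SievingSample,
    baseline_urine: float = 0.0,
    baseline_perfusate: float = 0.0,
    eps: float = 1e-9,
) -> SievingResult:
    """Urine-to-perfusate fluorescence ratio after background subtraction.

    0 means the tracer was fully retained in the vascular compartment, 1
    free filtration at equal concentration.  A negative numerator (urine at
    or below background) is clamped to 0 with a flag; a perfusate signal at
    or below background makes the coefficient undefined.
    """
    den = sample.f_perfusate - baseline_perfusate
    if den <= eps:
        return SievingResult(None, reason="perfusate at or below background")
    num = sample.f_urine - baseline_urine
    if num < 0:
        return SievingResult(0.0, clamped=True)
    return SievingResult(num / den)


def exchange_fraction(removal_rate_ml_h: float, reference_volume_ml: float) -> float:
    """Hemofiltration exchange as percent of the reference volume per hour.

    The reference volume (circuit volume in mL) is a required input — the
    exchange percentage is only meaningful relative to an explicitly chosen
    volume.
    """
    if reference_volume_ml <= 0:
        raise ValueError("reference volume must be positive")
    if removal_rate_ml_h < 0:
        raise ValueError("removal rate must be non-negative")
    return 100.0 * removal_rate_ml_h / reference_volume_ml
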
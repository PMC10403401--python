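"""Physics stage of the indirect approach.

Ohm's law converts voltages to currents, the current is integrated over
the sample grid to a coulombic charge, and a linear calibration maps charge
to BOD5 mass.  Predicted (regression) voltages below 0.01 V are discarded
before integration; observed samples are never discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .core import CANONICAL_LENGTH, GRID_SECONDS, WINDOW_HOURS, VoltageTrace, hours_to_samples

logger = logging.getLogger(__name__)

#: Predicted continuation voltages strictly below this are cut before
#: integration (the observed window is exempt).
PREDICTION_CUTOFF_V = 0.01

_VALID_N_INPUT = {hours_to_samples(h) for h in WINDOW_HOURS}

IntegrationRule = Literal["trapezoid", "left_rectangle"]


@dataclass(frozen=True)
class ChargeResult:
    """Integrated charge of one curve."""

    charge: float  # C
    cutoff_index: Optional[int]  # first discarded sample, None if none cut
    integration_rule: IntegrationRule = "trapezoid"

    def __post_init__(self) -> None:
        if self.charge < 0:
            raise ValueError("charge must be non-negative")


@dataclass(frozen=True)
class Calibration:
    """Linear BOD5-vs-charge map: ``mass = slope * Q + intercept``."""

    slope: float  # mg/C
    intercept: float  # mg
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")


def current_from_voltage(v: float, r: float) -> float:
    """Ohm's law, I = V / R."""
    if r <= 0:
        raise ValueError(f"resistance must be positive, got {r}")
    return v / r


def assemble_full_curve(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Concatenate an observed window with its predicted continuation."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.ndim != 1 or pred.ndim != 1:
        raise ValueError("observed and predicted must be 1-D")
    if obs.size not in _VALID_N_INPUT or obs.size + pred.size != CANONICAL_LENGTH:
        raise ValueError(
            f"invalid (n_input, n_output) pair ({obs.size}, {pred.size}); "
            f"n_input must be one of {sorted(_VALID_N_INPUT)} and the total {CANONICAL_LENGTH}"
        )
    return np.concatenate([obs, pred])


def apply_prediction_cutoff(
    curve: np.ndarray,
    n_input: int,
    threshold: float = PREDICTION_CUTOFF_V,
) -> tuple[np.ndarray, Optional[int]]:
    """Drop the tail of a curve from the first *predicted* sample below threshold.

    Samples with index < ``n_input`` are observations and are always kept,
    regardless of their value.  Returns the truncated curve and the index of
    the first discarded sample (``None`` if nothing was discarded).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(curve, dtype=float)
    if arr.shape != (CANONICAL_LENGTH,):
        raise ValueError(f"expected a full {CANONICAL_LENGTH}-sample curve, got {arr.shape}")
    if not 0 <= n_input <= CANONICAL_LENGTH:
        raise ValueError(f"n_input out of range: {n_input}")
    below = np.nonzero(arr[n_input:] < threshold)[0]
    if below.size == 0:
        return arr.copy(), None
    cut = n_input + int(below[0])
    return arr[:cut].copy(), cut


def integrate_charge(
    voltages: np.ndarray,
    resistance: float,
    dt: float = GRID_SECONDS,
    rule: IntegrationRule = "trapezoid",
) -> ChargeResult:
    """Numerically integrate I(t) = V(t)/R over the sample grid.

    Trapezoid is the default; a left-rectangle rule is provided for
    sensitivity checks.  An empty sequence integrates to 0 C (warned).
    """
    if resistance <= 0:
        raise ValueError(f"resistance must be positive, got {resistance}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        logger.warning("integrating an empty voltage sequence; charge is 0 C")
        return ChargeResult(charge=0.0, cutoff_index=None, integration_rule=rule)
    if np.any(v < 0):
        raise ValueError("negative voltage in charge integration")
    current = v / resistance
    if rule == "trapezoid":
        q = float(np.trapezoid(current, dx=dt))
    elif rule == "left_rectangle":
        q = float(np.sum(current[:-1]) * dt) if v.size > 1 else 0.0
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    return ChargeResult(charge=q, cutoff_index=None, integration_rule=rule)


def trace_charge(
    trace: VoltageTrace,
    rule: IntegrationRule = "trapezoid",
) -> ChargeResult:
    """Charge of an observed (untruncated) trace over its own support."""
    return integrate_charge(
        trace.voltages, trace.external_resistance, dt=GRID_SECONDS, rule=rule
    )


def fit_calibration(charges: np.ndarray, bod_masses: np.ndarray) -> Calibration:
    """Ordinary least-squares line ``mass = slope * Q + intercept``.

    Fit on the training experiments' true charges; at least two distinct
    charge values are required.
    """
    q = np.asarray(charges, dtype=float)
    m = np.asarray(bod_masses, dtype=float)
    if q.size != m.size:
        raise ValueError("charges and masses must have equal length")
    if q.size < 2:
        raise ValueError("need at least 2 points to fit a calibration line")
    if np.ptp(q) == 0:
        raise ValueError("degenerate calibration fit: all charges equal")
    slope, intercept = np.polyfit(q, m, deg=1)
    fitted = slope * q + intercept
    ss_res = float(np.sum((m - fitted) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return Calibration(slope=float(slope), intercept=float(intercept), fit_r2=r2)


def bod_from_charge(q: float, cal: Calibration) -> float:
    """BOD5 mass (mg) from a charge via the linear calibration, clamped at 0."""
    return max(0.0, cal.slope * q + cal.intercept)


def indirect_bod_estimate(
    observed: np.ndarray,
    predicted: np.ndarray,
    cal: Calibration,
    resistance: float,
    cutoff: float = PREDICTION_CUTOFF_V,
    rule: IntegrationRule = "trapezoid",
) -> tuple[float, ChargeResult]:
    """Full indirect pipeline for one experiment.

    Assembles observed + predicted curve, cuts the predicted tail below the
    cutoff, integrates the charge and converts to BOD5 mass.
    """
    full = assemble_full_curve(observed, predicted)
    clipped = np.clip(full, 0.0, None)  # raw network output may dip below 0
    kept, cut = apply_prediction_cutoff(clipped, n_input=np.asarray(observed).size,
                                        threshold=cutoff)
    result = integrate_charge(kept, resistance, rule=rule)
    result = ChargeResult(charge=result.charge, cutoff_index=cut, integration_rule=rule)
    return bod_from_charge(result.charge, cal), result
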
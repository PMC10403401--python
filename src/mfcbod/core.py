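"""Domain types and geometry of the MFC voltage time series.

Everything in the package lives on a uniform 5-minute grid starting at the
moment of sample injection (t = 0).  The longest experiment spans 7550
minutes, so every trace is representable in a canonical zero-padded frame of
exactly 1511 samples; truncation windows of 2-24 hours carve that frame into
an observed prefix and a continuation suffix.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Grid spacing in minutes.
GRID_MINUTES = 5
#: Grid spacing in seconds (used for charge integration).
GRID_SECONDS = GRID_MINUTES * 60
#: Duration in minutes of the longest experiment; defines the canonical frame.
TOTAL_MINUTES = 7550
#: Length of the canonical zero-padded voltage vector (7550/5 + 1).
CANONICAL_LENGTH = TOTAL_MINUTES // GRID_MINUTES + 1
#: Voltage below which the substrate is considered depleted and a real
#: experiment terminates.
TERMINATION_THRESHOLD_V = 0.02
#: Supported input-window durations, in hours.
WINDOW_HOURS = (2, 6, 8, 12, 16, 24)

DEFAULT_SAMPLE_VOLUME_ML = 60.0
DEFAULT_RESISTANCE_OHM = 100.0


class WaterType(str, enum.Enum):
    """Origin of the waste-water sample."""

    DOMESTIC = "domestic"
    BREWERY = "brewery"
    SYNTHETIC = "synthetic"


def hours_to_samples(hours: int) -> int:
    """Number of 5-minute samples spanning ``hours`` hours, inclusive of t=0.

    Parameters
    ----------
    hours : int
        Non-negative number of hours.

    Returns
    -------
    int
        ``12 * hours + 1`` (12 five-minute intervals per hour, plus the
        t=0 sample).
    """
    if hours < 0:
        raise ValueError(f"hours must be non-negative, got {hours}")
    return 12 * int(hours) + 1


def mass_to_concentration(mass_mg: float, volume_ml: float) -> float:
    """Convert an analyte mass in a sample to a concentration in mg/L."""
    if volume_ml <= 0:
        raise ValueError(f"sample volume must be positive, got {volume_ml} mL")
    if mass_mg < 0:
        raise ValueError(f"mass must be non-negative, got {mass_mg} mg")
    return mass_mg / (volume_ml / 1000.0)


@dataclass(frozen=True)
class VoltageTrace:
    """One experiment's voltage series on the 5-minute grid, with metadata.

    Attributes
    ----------
    experiment_id : str
        Unique identifier of the experiment.
    voltages : np.ndarray
        Non-negative voltages (V), sample ``i`` at ``t = 5*i`` minutes.
    bod5_mass : float
        Reference 5-day biochemical oxygen demand of the injected sample (mg).
    sample_volume : float
        Injected sample volume (mL), default 60.
    external_resistance : float
        External load resistance (Ohm), default 100.
    water_type : WaterType
        Sample origin.
    """

    experiment_id: str
    voltages: np.ndarray
    bod5_mass: float
    sample_volume: float = DEFAULT_SAMPLE_VOLUME_ML
    external_resistance: float = DEFAULT_RESISTANCE_OHM
    water_type: WaterType = WaterType.DOMESTIC

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        object.__setattr__(self, "voltages", v)
        if v.ndim != 1:
            raise ValueError("voltages must be one-dimensional")
        if not 1 <= v.size <= CANONICAL_LENGTH:
            raise ValueError(
                f"trace length must be in [1, {CANONICAL_LENGTH}], got {v.size}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite voltage in trace {self.experiment_id!r}")
        if np.any(v < 0):
            raise ValueError(f"negative voltage in trace {self.experiment_id!r}")
        if self.bod5_mass < 0:
            raise ValueError("bod5_mass must be non-negative")
        if self.sample_volume <= 0:
            raise ValueError("sample_volume must be positive")
        if self.external_resistance <= 0:
            raise ValueError("external_resistance must be positive")

    def __len__(self) -> int:
        return int(self.voltages.size)

    @property
    def bod5_concentration(self) -> float:
        """Reference BOD5 as a concentration (mg/L)."""
        return mass_to_concentration(self.bod5_mass, self.sample_volume)

    @property
    def duration_minutes(self) -> int:
        """Time of the last recorded sample, in minutes."""
        return (len(self) - 1) * GRID_MINUTES


@dataclass(frozen=True)
class CanonicalVector:
    """Fixed-length zero-padded voltage vector, the universal model I/O frame.

    ``values`` has exactly 1511 entries; indices ``n_observed`` .. 1510 are
    padding zeros.
    """

    values: np.ndarray
    n_observed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (CANONICAL_LENGTH,):
            raise ValueError(
                f"canonical vector must have length {CANONICAL_LENGTH}, got {v.shape}"
            )
        if not 1 <= self.n_observed <= CANONICAL_LENGTH:
            raise ValueError(f"n_observed out of range: {self.n_observed}")
        if np.any(v[self.n_observed:] != 0.0):
            raise ValueError("padded region of canonical vector must be exactly zero")


@dataclass(frozen=True)
class WindowSpec:
    """An input horizon in hours with derived input/output lengths.

    ``n_input = 12*hours + 1`` samples are observed; ``n_output = 1511 -
    n_input`` samples remain to be predicted by the curve-completion models.
    """

    hours: int

    def __post_init__(self) -> None:
        if self.hours not in WINDOW_HOURS:
            raise ValueError(
                f"window hours must be one of {WINDOW_HOURS}, got {self.hours}"
            )

    @property
    def n_input(self) -> int:
        return hours_to_samples(self.hours)

    @property
    def n_output(self) -> int:
        return CANONICAL_LENGTH - self.n_input


@dataclass
class ExperimentSet:
    """Ordered collection of traces with train/test role labels."""

    traces: list[VoltageTrace]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.experiment_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("experiment_ids must be unique")
        for eid, role in self.roles.items():
            if role not in ("train", "test"):
                raise ValueError(f"unknown role {role!r} for {eid!r}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def ids(self) -> list[str]:
        return [t.experiment_id for t in self.traces]

    def role_of(self, experiment_id: str) -> str:
        return self.roles.get(experiment_id, "train")

    def subset(self, role: str) -> list[VoltageTrace]:
        return [t for t in self.traces if self.role_of(t.experiment_id) == role]

    @property
    def train_traces(self) -> list[VoltageTrace]:
        return self.subset("train")

    @property
    def test_traces(self) -> list[VoltageTrace]:
        return self.subset("test")


def pad_to_canonical(trace: VoltageTrace) -> CanonicalVector:
    """Zero-pad a trace to the canonical 1511-sample frame.

    The observed samples are copied bit-exactly; the remainder is exactly 0.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("cannot pad an empty trace")
    if n > CANONICAL_LENGTH:
        raise ValueError(
            f"trace {trace.experiment_id!r} has {n} samples, "
            f"exceeding the canonical frame of {CANONICAL_LENGTH}"
        )
    values = np.zeros(CANONICAL_LENGTH, dtype=float)
    values[:n] = trace.voltages
    return CanonicalVector(values=values, n_observed=n)


def _as_canonical_array(v) -> np.ndarray:
    arr = v.values if isinstance(v, CanonicalVector) else np.asarray(v, dtype=float)
    if arr.shape != (CANONICAL_LENGTH,):
        raise ValueError(f"expected a canonical {CANONICAL_LENGTH}-vector, got {arr.shape}")
    return arr


def truncate_window(v, window: WindowSpec) -> np.ndarray:
    """First ``window.n_input`` samples of a canonical vector (the model input)."""
    arr = _as_canonical_array(v)
    if isinstance(v, CanonicalVector) and v.n_observed < window.n_input:
        logger.warning(
            "trace observed only %d samples, shorter than the %d-h window "
            "(%d samples); the input is partially zero-padded",
            v.n_observed, window.hours, window.n_input,
        )
    return arr[: window.n_input].copy()


def continuation_target(v, window: WindowSpec) -> np.ndarray:
    """Samples ``n_input`` .. 1510 of a canonical vector (the completion target)."""
    arr = _as_canonical_array(v)
    return arr[window.n_input:].copy()


def detect_termination(
    trace, threshold: float = TERMINATION_THRESHOLD_V
) -> Optional[int]:
    """First post-peak index where the voltage drops below ``threshold``.

    The rise phase also passes through low voltages, so only indices strictly
    after the global maximum are eligible.  Returns ``None`` if the voltage
    never drops below the threshold after its peak.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = trace.voltages if isinstance(trace, VoltageTrace) else np.asarray(trace, dtype=float)
    if v.size == 0:
        return None
    peak = int(np.argmax(v))
    below = np.nonzero(v[peak + 1:] < threshold)[0]
    if below.size == 0:
        return None
    return peak + 1 + int(below[0])
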
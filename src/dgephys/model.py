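"""Core data model: sweeps, stimulation protocols, experiments.

Every analysis operation in this package consumes :class:`Sweep` objects —
one episode of a recorded or simulated signal together with its sampling
rate and protocol metadata — grouped into :class:`Experiment` collections.
Times are seconds internally; interpulse intervals are exposed in
milliseconds at API boundaries, matching the conventions of the
electrophysiology literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

#: Digitization rate (Hz) of the recordings this package was written for.
DEFAULT_SAMPLING_RATE = 10_000.0

CHANNEL_KINDS = (
    "voltage_clamp_current",
    "current_clamp_voltage",
    "field_potential",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class StepProtocol:
    """Square-pulse current-step protocol (current clamp).

    The reference protocol steps from -100 to 490 pA in 10 pA increments,
    1 s pulses separated by 1 s, which probes both the hyperpolarizing
    range used for input resistance and the depolarizing range used for
    the F-I curve and depolarization block.
    """

    start_pA: float
    stop_pA: float
    increment_pA: float
    step_duration_s: float = 1.0
    inter_step_s: float = 1.0
    step_onset_s: float = 0.2

    def __post_init__(self) -> None:
        if self.increment_pA == 0:
            raise ValidationError("increment_pA must be nonzero")
        if self.step_duration_s <= 0:
            raise ValidationError("step_duration_s must be positive")
        n = (self.stop_pA - self.start_pA) / self.increment_pA
        if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
            raise ValidationError(
                f"increment {self.increment_pA} pA does not divide the range "
                f"{self.start_pA}..{self.stop_pA} pA"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.stop_pA - self.start_pA) / self.increment_pA)) + 1

    def currents(self) -> np.ndarray:
        """Enumerated step currents (pA), start..stop inclusive."""
        return self.start_pA + self.increment_pA * np.arange(self.n_steps)

    @classmethod
    def from_currents(cls, currents: Sequence[float], **kwargs: Any) -> "StepProtocol":
        """Reconstruct a protocol from its enumerated steps (inverse of
        :meth:`currents`)."""
        c = np.asarray(currents, dtype=float)
        if c.size < 2:
            raise ValidationError("need at least two currents to infer an increment")
        incs = np.diff(c)
        if not np.allclose(incs, incs[0]):
            raise ValidationError("currents are not uniformly spaced")
        return cls(start_pA=float(c[0]), stop_pA=float(c[-1]),
                   increment_pA=float(incs[0]), **kwargs)


@dataclass
class StimEvent:
    """A single extracellular stimulus pulse."""

    time_s: float
    intensity_uA: float
    pulse_index_in_pair: Optional[int] = None  # 1, 2 or None
    interpulse_interval_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pulse_index_in_pair not in (None, 1, 2):
            raise ValidationError("pulse_index_in_pair must be 1, 2 or None")


Protocol = Union[StepProtocol, Sequence[StimEvent], None]


@dataclass
class Sweep:
    """One episode of signal with its acquisition context.

    ``samples`` are mV for voltage and field-potential sweeps and pA for
    voltage-clamp current sweeps.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    t0: float = 0.0
    channel_kind: str = "voltage_clamp_current"
    protocol: Protocol = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValidationError("sweep has no samples")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValidationError(
                f"unknown channel_kind {self.channel_kind!r}; "
                f"expected one of {CHANNEL_KINDS}"
            )
        if self.channel_kind != "field_potential" and isinstance(
            self.protocol, (list, tuple)
        ):
            times = [ev.time_s for ev in self.protocol]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError("stimulus times must be strictly increasing")
        if self.sampling_rate != DEFAULT_SAMPLING_RATE:
            logger.info("sweep uses non-default sampling rate %g Hz", self.sampling_rate)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (relative to the recording start)."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, t_s: float) -> int:
        """Nearest sample index for an absolute time."""
        i = int(round((t_s - self.t0) * self.sampling_rate))
        if not 0 <= i < self.n_samples:
            raise ValidationError(f"time {t_s} s is outside the sweep")
        return i


@dataclass
class Experiment:
    """Ordered collection of sweeps plus the study design.

    ``design`` maps grouping factors (genotype, treatment, subject id) to
    per-subject values; every subject id referenced by a sweep's metadata
    must appear in the design.
    """

    sweeps: list
    design: dict = field(default_factory=dict)
    ground_truth: Any = None

    def __post_init__(self) -> None:
        subjects = set(self.design.get("subjects", []))
        if subjects:
            for sw in self.sweeps:
                sid = sw.metadata.get("subject_id")
                if sid is not None and sid not in subjects:
                    raise ValidationError(
                        f"sweep subject id {sid!r} missing from experiment design"
                    )
        rates = {sw.sampling_rate for sw in self.sweeps}
        if len(rates) > 1 and not self.design.get("mixed_rates_ok", False):
            raise ValidationError(
                f"sweeps mix sampling rates {sorted(rates)}; set "
                "design['mixed_rates_ok']=True if intentional"
            )

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


def build_step_protocol(start_pA: float, stop_pA: float, increment_pA: float,
                        duration_s: float = 1.0, **kwargs: Any) -> StepProtocol:
    """Validated constructor for a current-step protocol."""
    return StepProtocol(start_pA=start_pA, stop_pA=stop_pA,
                        increment_pA=increment_pA, step_duration_s=duration_s,
                        **kwargs)


def build_tbs_protocol(intensity_uA: float = 500.0, t_start_s: float = 0.0,
                       series_interval_s: float = 20.0,
                       train_interval_s: float = 0.2,
                       pulse_rate_Hz: float = 400.0,
                       n_series: int = 6, n_trains: int = 6,
                       n_pulses: int = 6) -> list:
    """Theta-burst stimulation pattern used for LTP induction.

    Six series (separated by 20 s) of six trains (separated by 0.2 s) of
    six 400 Hz pulses: 216 stimuli, 2.5 ms within-train spacing.
    """
    events = []
    pulse_dt = 1.0 / pulse_rate_Hz
    for s in range(n_series):
        for tr in range(n_trains):
            for p in range(n_pulses):
                t = (t_start_s + s * series_interval_s
                     + tr * train_interval_s + p * pulse_dt)
                events.append(StimEvent(time_s=t, intensity_uA=intensity_uA))
    return events
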
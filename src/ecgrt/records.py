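"""Core record container and error types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Cohort group labels: exercise-ECG-negative reference, and the three
#: coronary-imaging arms of the exercise-ECG-positive patients.
GROUPS = ("negative", "normal", "lt50", "ge50")

#: The positive arms, i.e. everything that is not the negative reference.
POSITIVE_GROUPS = ("normal", "lt50", "ge50")


class EcgrtError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EcgrtError, ValueError):
    """A parameter violates its documented domain."""


class InsufficientDataError(EcgrtError, ValueError):
    """A record is too short for the requested operation."""


class NotEnoughExtremaError(EcgrtError):
    """A signal has too few extrema for envelope construction."""


class DegenerateWindowError(EcgrtError):
    """A window carries no energy, so ratio statistics are undefined."""


class ParseError(EcgrtError, ValueError):
    """A file could not be parsed; the message names the offending location."""


@dataclass
class ECGRecord:
    """One subject's single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitude in millivolts, one value per sample.
    sampling_rate : float
        Samples per second (Hz).
    subject_id : str
        Cohort-unique identifier.
    lead : str, optional
        Lead name; the analysis is lead-agnostic.
    group : str, optional
        One of :data:`GROUPS`.
    history : list of str
        Names of processing stages already applied, in order.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    lead: str | None = None
    group: str | None = None
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")
        if self.group is not None and self.group not in GROUPS:
            raise InvalidParameterError(f"unknown group {self.group!r}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray, stage: str | None = None) -> "ECGRecord":
        """Copy of this record with new samples and, optionally, one more history entry."""
        hist = list(self.history) + ([stage] if stage else [])
        return replace(self, samples=np.asarray(samples, dtype=float), history=hist)
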
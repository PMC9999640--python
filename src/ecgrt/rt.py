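"""The RT intensity index: the scored fraction of ECG energy in C1-C3.

For a decomposed 10-s window with component energies E_i = sum(C_i^2),

    RT = (alpha * E1 + beta * E2 + gamma * E3) / sum_{i=1..8} E_i

with weights constrained by alpha >= beta >= gamma > 0 and
alpha + beta + gamma < 1, so 0 <= RT <= alpha always.  The three fastest
components carry the high-frequency QRS content, so the index rises when
ischemic high-frequency energy is present.  |C_i| is read as the component's
signal energy; for components of a common length this differs from a PSD
integral only by a constant that cancels in the ratio.  The denominator runs
over the first eight components only — never the EMD residual.

The published weight values were never released; the default (0.5, 0.3,
0.15) satisfies both constraints and is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd import IMFSet, SiftConfig, decompose
from .records import DegenerateWindowError, ECGRecord, InvalidParameterError

__all__ = [
    "RTWeights",
    "ComponentEnergies",
    "RTResult",
    "component_energy",
    "component_energies",
    "rt_intensity_index",
    "batch_rt",
]

N_COMPONENTS = 8


@dataclass(frozen=True)
class RTWeights:
    """Weighting triple (alpha, beta, gamma): ordered, positive, sum < 1."""

    alpha: float = 0.5
    beta: float = 0.3
    gamma: float = 0.15

    def __post_init__(self):
        if not self.alpha >= self.beta >= self.gamma > 0:
            raise InvalidParameterError("weights must satisfy alpha >= beta >= gamma > 0")
        if not self.alpha + self.beta + self.gamma < 1:
            raise InvalidParameterError("weights must sum to less than 1")

    def as_tuple(self):
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class ComponentEnergies:
    """Energies E1..E8 (mV^2 * sample) and their total."""

    energies: tuple
    total: float

    @classmethod
    def from_components(cls, components) -> "ComponentEnergies":
        e = tuple(component_energy(c) for c in components[:N_COMPONENTS])
        e = e + (0.0,) * (N_COMPONENTS - len(e))
        return cls(energies=e, total=float(sum(e)))


@dataclass(frozen=True)
class RTResult:
    """Per-subject outcome: index value plus the energies behind it."""

    subject_id: str
    group: str | None
    rt_index: float            # fraction; report as percent via rt_pct
    energies: ComponentEnergies
    weights: RTWeights

    @property
    def rt_pct(self) -> float:
        return 100.0 * self.rt_index


def component_energy(component: np.ndarray) -> float:
    """Sum of squared samples; zero iff the component is all-zero."""
    c = np.asarray(component, dtype=float)
    return float(np.sum(c * c))


def component_energies(imfset: IMFSet) -> ComponentEnergies:
    return ComponentEnergies.from_components(list(imfset.components))


def rt_intensity_index(imfset: IMFSet, weights: RTWeights | None = None) -> float:
    """RT index of one decomposed window, as a fraction in [0, alpha]."""
    weights = weights or RTWeights()
    en = component_energies(imfset)
    if en.total <= 0:
        raise DegenerateWindowError("window carries no component energy")
    a, b, g = weights.as_tuple()
    e = en.energies
    return (a * e[0] + b * e[1] + g * e[2]) / en.total


def batch_rt(windows, weights: RTWeights | None = None,
             sift_config: SiftConfig | None = None):
    """Decompose and score a batch of preprocessed windows.

    Parameters
    ----------
    windows : iterable of ECGRecord
        Already-preprocessed 10-s windows.
    weights, sift_config : shared across the batch.

    Returns
    -------
    results : list of RTResult, in input order (failed subjects omitted).
    failures : list of (subject_id, Exception) for subjects whose window
        degenerated; the batch never aborts on one bad subject.
    """
    weights = weights or RTWeights()
    sift_config = sift_config or SiftConfig()
    results: list[RTResult] = []
    failures: list[tuple] = []
    for rec in windows:
        try:
            imfset = decompose(rec.samples, sift_config,
                               sampling_rate=rec.sampling_rate,
                               subject_id=rec.subject_id)
            rt = rt_intensity_index(imfset, weights)
        except Exception as exc:  # noqa: BLE001 — per-subject isolation is the contract
            failures.append((rec.subject_id, exc))
            continue
        results.append(RTResult(subject_id=rec.subject_id, group=rec.group,
                                rt_index=rt,
                                energies=component_energies(imfset),
                                weights=weights))
    return results, failures
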
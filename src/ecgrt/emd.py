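"""Empirical mode decomposition, written from scratch.

EMD splits a signal into intrinsic mode functions (IMFs) by *sifting*:
repeatedly subtracting the mean of the cubic-spline envelopes through the
local maxima and minima until the result is locally symmetric.  Each IMF is
then removed from the running residual and the process repeats, so the
components come out ordered from the fastest oscillation (C1) to the
slowest, and the decomposition is complete by construction:

    signal = C1 + C2 + ... + Ck + residual   (exactly, in floating point)

For a 10-s resting ECG window at 250 Hz the first two or three components
carry the sharp QRS content, mid components the P/T superpositions, and the
slowest the beat rhythm — the structure the RT intensity index exploits.

Implementation choices (classical, since EMD has no canonical parameters):
Cauchy stopping criterion (threshold 0.2) combined with the IMF count
condition, under a generous iteration cap;
natural cubic splines through extrema knots; mirror extension of the first
and last two extrema beyond each end to tame border effects.  Plain EMD
only — mode mixing is accepted, no ensemble variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .records import InvalidParameterError, NotEnoughExtremaError

__all__ = [
    "SiftConfig",
    "IMFSet",
    "find_extrema",
    "envelope_mean",
    "sift_imf",
    "decompose",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiftConfig:
    """Sifting parameters.

    stop_threshold : Cauchy criterion bound on sum((h_prev - h)^2) / sum(h_prev^2).
    max_sift_iters : cap on sifting iterations per component.
    max_imfs : number of components extracted; with ``pad_to_max`` the
        returned set always has exactly this many (zero placeholders if the
        natural decomposition stops early), so C1..C8 index consistently.
    """

    stop_threshold: float = 0.2
    max_sift_iters: int = 500
    max_imfs: int = 8
    boundary_policy: str = "mirror"
    pad_to_max: bool = True

    def __post_init__(self):
        if self.stop_threshold <= 0:
            raise InvalidParameterError("stop_threshold must be > 0")
        if self.max_imfs < 1:
            raise InvalidParameterError("max_imfs must be >= 1")
        if self.boundary_policy != "mirror":
            raise InvalidParameterError("only the 'mirror' boundary policy exists")


@dataclass
class IMFSet:
    """Ordered components C1..Ck plus residual for one analysis window.

    ``n_natural`` counts the components actually extracted before any
    zero-padding.  Invariant: ``sum(components) + residual`` reproduces the
    source window to floating-point accuracy.
    """

    components: list
    residual: np.ndarray
    sampling_rate: float
    sift_counts: list = field(default_factory=list)
    subject_id: str = ""
    n_natural: int = 0

    def __iter__(self):
        return iter(self.components)

    def __len__(self):
        return len(self.components)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.components:
            out += c
        return out


def find_extrema(signal: np.ndarray):
    """Interior local maxima and minima, plateaus collapsed to their midpoint.

    Returns ``(max_idx, max_val, min_idx, min_val)`` as arrays.  Because
    plateaus are collapsed first and only strict extrema of the compressed
    sequence count, maxima and minima alternate by construction.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 3:
        return (np.array([], int), np.array([]), np.array([], int), np.array([]))

    # Collapse runs of equal consecutive values to a single representative.
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))          # run starts
    ends = np.concatenate((change, [n - 1]))            # run ends (inclusive)
    mids = (starts + ends) // 2
    vals = x[starts]
    if vals.size < 3:
        return (np.array([], int), np.array([]), np.array([], int), np.array([]))

    d = np.sign(np.diff(vals))
    interior = np.arange(1, vals.size - 1)
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    max_i = mids[interior[is_max]]
    min_i = mids[interior[is_min]]
    return max_i, x[max_i], min_i, x[min_i]


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int):
    """Extend extrema knots by reflecting the first/last two about the ends."""
    left_i = (-idx[1::-1])[: min(2, idx.size)]
    left_v = val[1::-1][: min(2, idx.size)]
    right_i = 2 * (n - 1) - idx[-1:-3:-1]
    right_v = val[-1:-3:-1]
    xs = np.concatenate((left_i, idx, right_i)).astype(float)
    ys = np.concatenate((left_v, val, right_v))
    # Mirroring can duplicate knot positions when an extremum sits on an end.
    xs, keep = np.unique(xs, return_index=True)
    return xs, ys[keep]


def envelope_mean(signal: np.ndarray,
                  extrema=None,
                  boundary_policy: str = "mirror") -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes.

    Natural cubic splines pass exactly through the (mirrored) extrema knots.
    Raises :class:`NotEnoughExtremaError` when fewer than two maxima or two
    minima exist, which is the sifting termination signal.
    """
    upper, lower = envelopes(signal, extrema, boundary_policy)
    return (upper + lower) / 2.0


def envelopes(signal: np.ndarray, extrema=None,
              boundary_policy: str = "mirror"):
    """Upper and lower natural-cubic-spline envelopes through the extrema."""
    if boundary_policy != "mirror":
        raise InvalidParameterError("only the 'mirror' boundary policy exists")
    x = np.asarray(signal, dtype=float)
    n = x.size
    if extrema is None:
        extrema = find_extrema(x)
    max_i, max_v, min_i, min_v = extrema
    if max_i.size < 2 or min_i.size < 2:
        raise NotEnoughExtremaError(
            f"{max_i.size} maxima / {min_i.size} minima: envelopes undefined")
    t = np.arange(n)
    ux, uy = _mirror_knots(max_i, max_v, n)
    lx, ly = _mirror_knots(min_i, min_v, n)
    upper = CubicSpline(ux, uy, bc_type="natural")(t)
    lower = CubicSpline(lx, ly, bc_type="natural")(t)
    return upper, lower


def _imf_counts(x: np.ndarray):
    max_i, _, min_i, _ = find_extrema(x)
    sign = np.sign(x)
    sign = sign[sign != 0]
    n_zc = int(np.sum(sign[:-1] != sign[1:]))
    return max_i.size + min_i.size, n_zc


def sift_imf(signal: np.ndarray, config: SiftConfig | None = None):
    """Extract one IMF by iterative envelope-mean subtraction.

    Iterates ``h <- h - envelope_mean(h)`` until both the Cauchy criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < stop_threshold`` and the IMF
    count condition (extrema and zero-crossings differing by at most one)
    hold, or the iteration cap is reached.  Returns ``(imf, iterations)``.
    """
    config = config or SiftConfig()
    h = np.asarray(signal, dtype=float).copy()
    iterations = 0
    for _ in range(config.max_sift_iters):
        try:
            m = envelope_mean(h, boundary_policy=config.boundary_policy)
        except NotEnoughExtremaError:
            if iterations == 0:
                raise
            break
        denom = float(np.sum(h ** 2))
        if denom == 0:
            break
        sd = float(np.sum(m ** 2)) / denom
        h = h - m
        iterations += 1
        if sd < config.stop_threshold:
            n_ext, n_zc = _imf_counts(h)
            if abs(n_ext - n_zc) <= 1:
                break
    return h, iterations


def _n_extrema(x: np.ndarray) -> int:
    max_i, _, min_i, _ = find_extrema(x)
    return max_i.size + min_i.size


def decompose(signal: np.ndarray, config: SiftConfig | None = None,
              sampling_rate: float = 250.0, subject_id: str = "") -> IMFSet:
    """Full EMD of one window into components C1..C8 plus residual.

    Components are extracted until the residual has fewer than 3 extrema or
    ``max_imfs`` components exist; anything beyond ``max_imfs`` stays in the
    residual.  With ``pad_to_max`` (default) the component list is padded
    with zero placeholders so C1..C8 always index consistently; padding is
    logged.  Degenerate (constant) input yields no components and
    ``residual == input``.
    """
    config = config or SiftConfig()
    x = np.asarray(signal, dtype=float)
    residual = x.copy()
    components: list[np.ndarray] = []
    sift_counts: list[int] = []

    while len(components) < config.max_imfs and _n_extrema(residual) >= 3:
        try:
            imf, iters = sift_imf(residual, config)
        except NotEnoughExtremaError:
            break
        components.append(imf)
        sift_counts.append(iters)
        residual = residual - imf

    n_natural = len(components)
    if config.pad_to_max and n_natural < config.max_imfs:
        log.info("decompose %s: %d natural IMFs, padding to %d with zeros",
                 subject_id, n_natural, config.max_imfs)
        for _ in range(config.max_imfs - n_natural):
            components.append(np.zeros_like(x))
            sift_counts.append(0)

    return IMFSet(components=components, residual=residual,
                  sampling_rate=sampling_rate, sift_counts=sift_counts,
                  subject_id=subject_id, n_natural=n_natural)
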
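"""Agarose-gel lane densitometry: band integration and conformer proportions.

After electrophoresis the supercoiled (SC), open-circular (OC) and linear (L)
plasmid forms migrate to distinct bands.  Each band's intensity is integrated
over a stated window after subtracting a robust baseline, and the three
integrals are normalised to proportions.  Proportions are scale-invariant, so
normalising by the lane total is equivalent to normalising against the most
intense band first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyLaneError

__all__ = [
    "LaneProfile",
    "BandWindow",
    "FormProportions",
    "integrate_bands",
    "proportions_from_intensities",
    "aggregate_repeats",
]

SPECIES = ("SC", "OC", "L")


@dataclass(frozen=True)
class LaneProfile:
    """A 1-D densitometry trace: strictly increasing positions, signal >= 0."""

    positions: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "signal", sig)
        if pos.ndim != 1 or pos.shape != sig.shape:
            raise ValueError("positions and signal must be 1-D arrays of equal length")
        if pos.size < 10:
            raise ValueError("lane profile needs at least 10 samples")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(sig < 0):
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class BandWindow:
    """Integration window [start, end] for one species' band."""

    species: str
    start: float
    end: float

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if not self.start < self.end:
            raise ValueError("window start must be < end")


@dataclass(frozen=True)
class FormProportions:
    """SC/OC/L proportions of a plasmid population; sums to 1."""

    p_sc: float
    p_oc: float
    p_l: float

    def __post_init__(self):
        for v in (self.p_sc, self.p_oc, self.p_l):
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError("proportions must lie in [0, 1]")
        if abs(self.p_sc + self.p_oc + self.p_l - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1 within 1e-9")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_sc, self.p_oc, self.p_l)


def _check_windows(profile: LaneProfile, windows):
    if len(windows) != 3 or {w.species for w in windows} != set(SPECIES):
        raise ValueError("exactly one window per species SC, OC, L required")
    lo, hi = profile.positions[0], profile.positions[-1]
    ordered = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"windows {a.species} and {b.species} overlap")
    for w in windows:
        if w.start < lo or w.end > hi:
            raise ValueError(f"window {w.species} [{w.start}, {w.end}] outside profile range")


def integrate_bands(profile: LaneProfile, windows) -> dict[str, float]:
    """Trapezoidal band integrals after baseline subtraction.

    The baseline is the median signal outside all three windows, subtracted
    uniformly with negative residuals clipped to zero.  Raises
    :class:`EmptyLaneError` when the total integrated signal is not positive.
    """
    _check_windows(profile, windows)
    pos, sig = profile.positions, profile.signal
    outside = np.ones(pos.size, dtype=bool)
    for w in windows:
        outside &= ~((pos >= w.start) & (pos <= w.end))
    baseline = float(np.median(sig[outside])) if outside.any() else 0.0
    corrected = np.clip(sig - baseline, 0.0, None)

    intensities: dict[str, float] = {}
    for w in windows:
        mask = (pos >= w.start) & (pos <= w.end)
        intensities[w.species] = float(np.trapezoid(corrected[mask], pos[mask]))
    if sum(intensities.values()) <= 0.0:
        raise EmptyLaneError("no integrable band signal after baseline subtraction")
    return intensities


def proportions_from_intensities(
    intensity_sc: float,
    intensity_oc: float,
    intensity_l: float,
    sc_correction: float = 1.0,
) -> FormProportions:
    """Normalise three band intensities to proportions.

    ``sc_correction`` is an optional multiplicative staining-efficiency factor
    applied to the supercoiled band before normalisation (default 1, i.e. no
    correction).
    """
    vals = [intensity_sc * sc_correction, intensity_oc, intensity_l]
    if any(v < 0 for v in vals):
        raise ValueError("band intensities must be non-negative")
    total = sum(vals)
    if total <= 0:
        raise EmptyLaneError("empty lane: total band intensity is zero")
    return FormProportions(*(v / total for v in vals))


def aggregate_repeats(repeats) -> tuple[FormProportions, dict[str, float]]:
    """Mean proportions and per-species standard error over gel repeats.

    ``repeats`` is a sequence of :class:`FormProportions` (>= 2).  The SEM is
    the sample standard deviation divided by sqrt(n).  The mean triple is
    renormalised (means of simplex points already sum to 1, so this is a
    no-op up to rounding).
    """
    reps = list(repeats)
    if len(reps) < 2:
        raise ValueError("at least 2 gel repeats are required to aggregate")
    arr = np.array([r.as_tuple() for r in reps], dtype=float)
    mean = arr.mean(axis=0)
    mean = mean / mean.sum()
    sem = arr.std(axis=0, ddof=1) / math.sqrt(len(reps))
    return FormProportions(*mean), dict(zip(("SC", "OC", "L"), sem.tolist()))
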
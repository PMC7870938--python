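"""Closed-form kinetic model for plasmid conformer proportions under irradiation.

A supercoiled (SC) plasmid is relaxed to open-circular (OC) by a single-strand
break and linearised (L) by a double-strand break.  With Poisson-distributed
breaks the three proportions at absorbed dose ``D`` (Gy) are

    SC(D) = S0 * exp(-(mu + phi) * D)
    OC(D) = exp(-phi*D) * [exp(-0.5*mu^2*rho*D^2) * (S0 + C0) - S0*exp(-mu*D)]
    L(D)  = 1 - (S0 + C0) * exp(-(phi*D + 0.5*mu^2*rho*D^2))

where ``mu`` and ``phi`` are the mean SSB and DSB yields per plasmid per Gy,
``S0`` and ``C0`` the supercoiled and open-circular proportions at zero dose,
and ``rho`` the probability that two SSBs on opposite strands fall close
enough together (within a base-pair separation ``h``) to constitute a DSB,
``rho = h / n_bp``.  The three expressions sum to 1 identically.

Inside the model ``mu`` and ``phi`` are per-plasmid quantities (``mu*D`` is a
dimensionless expected break count); reported yields in per-megabase units
are interconverted at the boundary by :func:`convert_yield`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import UnitError

__all__ = [
    "McMahonParams",
    "YieldValue",
    "sc_fraction",
    "oc_fraction",
    "l_fraction",
    "predict_proportions",
    "convert_yield",
    "DEFAULT_PLASMID_BP",
    "DEFAULT_SEPARATION_BP",
]

#: pBR322 size in base pairs.
DEFAULT_PLASMID_BP = 4361
#: Opposite-strand separation (bp) within which two SSBs make a DSB.
DEFAULT_SEPARATION_BP = 10


@dataclass(frozen=True)
class McMahonParams:
    """Parameters of the conformer kinetic model.

    mu, phi : SSB and DSB yields, per plasmid per Gy (>= 0).
    s0, c0  : supercoiled / open-circular proportions at zero dose, s0+c0 <= 1.
    rho     : SSB-pairing probability, separation_bp / plasmid_bp, in (0, 1).
    """

    mu: float
    phi: float
    s0: float
    c0: float
    rho: float = DEFAULT_SEPARATION_BP / DEFAULT_PLASMID_BP

    def __post_init__(self):
        if self.mu < 0 or self.phi < 0:
            raise ValueError("yields mu, phi must be non-negative")
        if not (0.0 <= self.s0 <= 1.0 and 0.0 <= self.c0 <= 1.0):
            raise ValueError("s0, c0 must be fractions in [0, 1]")
        if self.s0 + self.c0 > 1.0 + 1e-12:
            raise ValueError("s0 + c0 must not exceed 1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")


def _check_dose(dose):
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("dose must be finite and non-negative (Gy)")
    return d


def sc_fraction(dose, p: McMahonParams):
    """Supercoiled proportion at ``dose`` Gy: S0 * exp(-(mu+phi)*D)."""
    d = _check_dose(dose)
    return p.s0 * np.exp(-(p.mu + p.phi) * d)


def oc_fraction(dose, p: McMahonParams):
    """Open-circular proportion at ``dose`` Gy (equals C0 at zero dose).

    Evaluated as exp(-phi*D) * [c0*q + s0*(q - exp(-mu*D))] with
    q = exp(-0.5*mu^2*rho*D^2), algebraically identical to
    exp(-phi*D) * [q*(s0+c0) - s0*exp(-mu*D)] but exact (c0) at D = 0.
    """
    d = _check_dose(dose)
    pair = np.exp(-0.5 * p.mu**2 * p.rho * d**2)
    return np.exp(-p.phi * d) * (p.c0 * pair + p.s0 * (pair - np.exp(-p.mu * d)))


def l_fraction(dose, p: McMahonParams):
    """Linear proportion at ``dose`` Gy; monotone non-decreasing, -> 1 as D -> inf."""
    d = _check_dose(dose)
    return 1.0 - (p.s0 + p.c0) * np.exp(-(p.phi * d + 0.5 * p.mu**2 * p.rho * d**2))


def predict_proportions(dose, p: McMahonParams):
    """The (SC, OC, L) triple at ``dose``; sums to 1 by algebraic identity."""
    return sc_fraction(dose, p), oc_fraction(dose, p), l_fraction(dose, p)


# --- yield unit bookkeeping -------------------------------------------------

_BASES = ("per_Mbp", "per_plasmid")
_SCALES = ("Gy", "kGy")


@dataclass(frozen=True)
class YieldValue:
    """A strand-break yield with its standard error and explicit units.

    ``basis`` is per megabase or per plasmid; ``dose_scale`` is the dose unit
    the yield is expressed against (yield per Gy vs per kGy).
    """

    value: float
    err: float = 0.0
    basis: str = "per_Mbp"
    dose_scale: str = "Gy"

    def __post_init__(self):
        if self.value < 0 or self.err < 0:
            raise ValueError("yield value and error must be non-negative")
        if self.basis not in _BASES:
            raise UnitError(f"unknown yield basis {self.basis!r}; expected one of {_BASES}")
        if self.dose_scale not in _SCALES:
            raise UnitError(f"unknown dose scale {self.dose_scale!r}; expected one of {_SCALES}")

    @property
    def units(self) -> str:
        base = "Mbp^-1" if self.basis == "per_Mbp" else "plasmid^-1"
        return f"{base} {self.dose_scale}^-1"


def convert_yield(
    y: YieldValue,
    basis: str | None = None,
    dose_scale: str | None = None,
    plasmid_bp: int = DEFAULT_PLASMID_BP,
) -> YieldValue:
    """Convert a yield between per-plasmid/per-Mbp bases and Gy/kGy dose scales.

    per-plasmid -> per-Mbp divides by plasmid size in Mbp (bp / 1e6);
    per-Gy -> per-kGy multiplies by 1e3.  Errors scale identically.
    """
    if plasmid_bp <= 0:
        raise ValueError("plasmid_bp must be positive")
    basis = basis or y.basis
    dose_scale = dose_scale or y.dose_scale
    if basis not in _BASES:
        raise UnitError(f"unknown target basis {basis!r}")
    if dose_scale not in _SCALES:
        raise UnitError(f"unknown target dose scale {dose_scale!r}")

    factor = 1.0
    mbp = plasmid_bp / 1e6
    if basis != y.basis:
        factor *= (1.0 / mbp) if basis == "per_Mbp" else mbp
    if dose_scale != y.dose_scale:
        # yield per kGy is 1000x the yield per Gy
        factor *= 1e3 if dose_scale == "kGy" else 1e-3
    return replace(y, value=y.value * factor, err=y.err * factor, basis=basis, dose_scale=dose_scale)
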
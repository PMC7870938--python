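"""RBE, indirect-damage fractions and dose-rate yield comparison.

Relative biological effectiveness with DSB yield as the endpoint is the ratio
of the test radiation's DSB yield to the reference (Co-60 X-ray) yield at
equal absorbed dose.  The indirect-damage fraction contrasts dry-irradiated
plasmid (direct energy deposition only) with aqueous plasmid (direct plus
radical-mediated damage): fraction = 1 - dry/wet once both yields are on the
same units.  Ratio errors propagate in quadrature of relative errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import UnitError
from .mcmahon import DEFAULT_PLASMID_BP, YieldValue, convert_yield

__all__ = [
    "CO60_DRY",
    "CO60_WET",
    "RBEResult",
    "IndirectFraction",
    "compute_rbe",
    "indirect_fraction",
    "compare_yields",
]

#: Co-60 reference DSB yield for dry plasmid, Mbp^-1 kGy^-1.
CO60_DRY = YieldValue(3.27, 0.13, basis="per_Mbp", dose_scale="kGy")
#: Co-60 reference DSB yield for aqueous plasmid, Mbp^-1 Gy^-1.
CO60_WET = YieldValue(0.32, 0.02, basis="per_Mbp", dose_scale="Gy")


@dataclass(frozen=True)
class RBEResult:
    value: float
    err: float
    endpoint: str
    test_yield: YieldValue
    reference_yield: YieldValue

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("RBE must be positive")


@dataclass(frozen=True)
class IndirectFraction:
    """Percentage of total damage attributed to indirect (radical) effects."""

    percent: float
    err: float
    capped: bool = False  # True when dry > wet forced a cap at 0%

    def __post_init__(self):
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError("indirect percentage must lie in [0, 100]")


def _ratio_err(value, a: YieldValue, b: YieldValue) -> float:
    rel = 0.0
    if a.value > 0:
        rel += (a.err / a.value) ** 2
    if b.value > 0:
        rel += (b.err / b.value) ** 2
    return abs(value) * math.sqrt(rel)


def compute_rbe(test: YieldValue, reference: YieldValue, endpoint: str = "DSB yield") -> RBEResult:
    """RBE = test yield / reference yield, with quadrature error.

    Units must already agree; mismatched basis or dose scale raises
    :class:`UnitError` rather than converting silently.
    """
    if (test.basis, test.dose_scale) != (reference.basis, reference.dose_scale):
        raise UnitError(
            f"unit mismatch: test is {test.units}, reference is {reference.units}; "
            "convert explicitly with convert_yield first"
        )
    if reference.value == 0:
        raise ValueError("reference yield must be positive")
    value = test.value / reference.value
    return RBEResult(value=value, err=_ratio_err(value, test, reference),
                     endpoint=endpoint, test_yield=test, reference_yield=reference)


def indirect_fraction(
    dry: YieldValue, wet: YieldValue, plasmid_bp: int = DEFAULT_PLASMID_BP
) -> IndirectFraction:
    """Percent of total damage from indirect effects: 100*(1 - dry/wet).

    The dry yield (direct damage only) is converted to the wet yield's units
    first.  A dry yield exceeding the wet yield is unphysical for this
    decomposition; the result is capped at 0% and flagged.
    """
    if wet.value == 0:
        raise ValueError("wet yield must be positive")
    dry_c = convert_yield(dry, basis=wet.basis, dose_scale=wet.dose_scale, plasmid_bp=plasmid_bp)
    ratio = dry_c.value / wet.value
    err = 100.0 * _ratio_err(ratio, dry_c, wet)
    if ratio > 1.0:
        return IndirectFraction(percent=0.0, err=err, capped=True)
    return IndirectFraction(percent=100.0 * (1.0 - ratio), err=err)


@dataclass(frozen=True)
class YieldComparison:
    difference: float
    pooled_se: float
    z: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_yields(a, b, which: str = "dsb", alpha: float = 0.05) -> YieldComparison:
    """Normal-approximation z-test between two fitted yields (e.g. dose rates).

    ``a`` and ``b`` are :class:`~plasmidrbe.fitting.BreakYields`; ``which``
    selects the ssb or dsb endpoint.  z = (a-b)/sqrt(SEa^2+SEb^2) with a
    two-sided p-value.
    """
    ya, yb = getattr(a, which), getattr(b, which)
    if (ya.basis, ya.dose_scale) != (yb.basis, yb.dose_scale):
        raise UnitError(f"unit mismatch: {ya.units} vs {yb.units}")
    if ya.err == 0 and yb.err == 0:
        if ya.value == yb.value:
            return YieldComparison(0.0, 0.0, 0.0, 1.0, False, alpha)
        raise ValueError("both yields lack a standard error; z-test undefined")
    diff = ya.value - yb.value
    se = math.sqrt(ya.err**2 + yb.err**2)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return YieldComparison(diff, se, z, float(p), bool(p < alpha), alpha)
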
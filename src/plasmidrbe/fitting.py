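"""Least-squares estimation of strand-break yields from conformer dose-response data.

Only the supercoiled (SC) and open-circular (OC) curves enter the objective;
the linear (L) curve is held out and used afterwards as a goodness-of-fit
check.  Each gel repeat is fitted independently with its own zero-dose
baseline (S0, C0), and the reported yield is the across-repeat mean with the
standard error of the mean — matching how replicate gel experiments are
summarised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError
from .mcmahon import (
    DEFAULT_PLASMID_BP,
    DEFAULT_SEPARATION_BP,
    McMahonParams,
    YieldValue,
    convert_yield,
    oc_fraction,
    sc_fraction,
    l_fraction,
)

__all__ = ["DoseResponseDataset", "FitResult", "BreakYields", "fit_single", "fit_dataset", "validate_linear"]


@dataclass
class DoseResponseDataset:
    """Conformer proportions vs dose, one row per (dose, repeat).

    ``records`` columns: dose (Gy), repeat_id, p_sc, p_oc, p_l.
    """

    records: pd.DataFrame
    energy_mev: float = float("nan")
    environment: str = "wet"
    dose_rate_class: str = "conventional"

    def __post_init__(self):
        req = {"dose", "repeat_id", "p_sc", "p_oc", "p_l"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset records missing columns {sorted(missing)}")
        doses = np.unique(self.records["dose"].to_numpy(dtype=float))
        if doses.size < 3:
            raise ValueError("need at least 3 distinct doses")
        if 0.0 not in doses:
            raise ValueError("dataset must include a zero-dose record")

    def repeats(self):
        return sorted(self.records["repeat_id"].unique())


@dataclass
class FitResult:
    """Per-repeat fit of (mu, phi), per plasmid per Gy."""

    mu: float
    phi: float
    s0: float
    c0: float
    rho: float
    rss: float
    converged: bool
    n_points: int

    @property
    def params(self) -> McMahonParams:
        return McMahonParams(mu=self.mu, phi=self.phi, s0=self.s0, c0=self.c0, rho=self.rho)


@dataclass
class BreakYields:
    """Across-repeat mean strand-break yields with SEM and fit diagnostics."""

    ssb: YieldValue
    dsb: YieldValue
    n_repeats: int
    rss: float
    converged: bool
    per_repeat: list = field(default_factory=list)
    energy_mev: float = float("nan")
    environment: str = "wet"
    dose_rate_class: str = "conventional"


def _initial_guess(doses, p_sc, s0):
    """mu0 from the low-dose log-linear slope of SC; phi0 a small fraction of it."""
    mask = (doses > 0) & (p_sc > 0) & (p_sc <= s0)
    if mask.any():
        slopes = -np.log(p_sc[mask] / s0) / doses[mask]
        mu0 = float(np.median(slopes))
    else:
        mu0 = 1.0 / max(doses.max(), 1.0)
    mu0 = max(mu0, 1e-8)
    return mu0, 0.01 * mu0


def fit_single(
    doses,
    p_sc,
    p_oc,
    *,
    rho: float = DEFAULT_SEPARATION_BP / DEFAULT_PLASMID_BP,
    s0: float | None = None,
    c0: float | None = None,
    fit_baseline: bool = False,
) -> FitResult:
    """Fit (mu, phi) to one repeat's SC and OC proportions.

    Minimises sum over doses of (SC_obs - SC(D))^2 + (OC_obs - OC(D))^2 with
    mu, phi >= 0, via bounded trust-region least squares.  ``s0``/``c0``
    default to the zero-dose observation; with ``fit_baseline`` they are free
    parameters instead.
    """
    doses = np.asarray(doses, dtype=float)
    p_sc = np.asarray(p_sc, dtype=float)
    p_oc = np.asarray(p_oc, dtype=float)
    if doses.size != p_sc.size or doses.size != p_oc.size:
        raise ValueError("doses, p_sc, p_oc must have equal length")
    if np.unique(doses).size < 3:
        raise FitError("need at least 3 distinct doses to fit")
    if not np.any(doses == 0) and (s0 is None or c0 is None):
        raise FitError("no zero-dose record and no explicit s0/c0 baseline")
    if np.all(doses == 0):
        raise FitError("all records at zero dose; no dose response to fit")

    zero = doses == 0
    if s0 is None:
        s0 = float(p_sc[zero].mean())
    if c0 is None:
        c0 = float(p_oc[zero].mean())
    if s0 + c0 > 1.0 + 1e-9:
        raise FitError(f"baseline s0 + c0 = {s0 + c0:.4f} exceeds 1")

    mu0, phi0 = _initial_guess(doses, p_sc, s0)

    if fit_baseline:
        x0 = [mu0, phi0, s0, c0]
        lb, ub = [0.0, 0.0, 0.0, 0.0], [np.inf, np.inf, 1.0, 1.0]

        def unpack(x):
            return x[0], x[1], x[2], x[3]
    else:
        x0 = [mu0, phi0]
        lb, ub = [0.0, 0.0], [np.inf, np.inf]

        def unpack(x):
            return x[0], x[1], s0, c0

    def residuals(x):
        mu, phi, s0x, c0x = unpack(x)
        p = McMahonParams(mu=mu, phi=phi, s0=min(s0x, 1.0), c0=min(c0x, max(1.0 - s0x, 0.0)), rho=rho)
        return np.concatenate([p_sc - sc_fraction(doses, p), p_oc - oc_fraction(doses, p)])

    sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu, phi, s0f, c0f = unpack(sol.x)
    rss = float(2.0 * sol.cost)
    result = FitResult(
        mu=float(mu), phi=float(phi), s0=float(s0f), c0=float(c0f), rho=rho,
        rss=rss, converged=bool(sol.success), n_points=int(doses.size),
    )
    if not sol.success:
        raise FitError(f"fit did not converge: {sol.message}", best=result)
    return result


def fit_dataset(
    dataset: DoseResponseDataset,
    *,
    rho: float = DEFAULT_SEPARATION_BP / DEFAULT_PLASMID_BP,
    plasmid_bp: int = DEFAULT_PLASMID_BP,
    fit_baseline: bool = False,
    dose_scale: str = "Gy",
) -> BreakYields:
    """Fit every repeat independently and summarise yields per Mbp.

    Each repeat's S0, C0 come from its own zero-dose record.  The reported
    SSB/DSB values are across-repeat means of the per-Mbp yields, with the
    SEM as the uncertainty (sample s.d. / sqrt(n)).
    """
    reps = dataset.repeats()
    if len(reps) < 2:
        raise FitError(f"need >= 2 repeats for an SEM; got {len(reps)}")
    fits: list[FitResult] = []
    for rep in reps:
        sub = dataset.records[dataset.records["repeat_id"] == rep]
        if not (sub["dose"] == 0).any():
            raise FitError(f"repeat {rep!r} lacks a zero-dose record")
        fits.append(
            fit_single(
                sub["dose"].to_numpy(), sub["p_sc"].to_numpy(), sub["p_oc"].to_numpy(),
                rho=rho, fit_baseline=fit_baseline,
            )
        )
    mbp = plasmid_bp / 1e6
    mus = np.array([f.mu for f in fits]) / mbp
    phis = np.array([f.phi for f in fits]) / mbp
    n = len(fits)
    ssb = YieldValue(float(mus.mean()), float(mus.std(ddof=1) / math.sqrt(n)), "per_Mbp", "Gy")
    dsb = YieldValue(float(phis.mean()), float(phis.std(ddof=1) / math.sqrt(n)), "per_Mbp", "Gy")
    if dose_scale != "Gy":
        ssb = convert_yield(ssb, dose_scale=dose_scale, plasmid_bp=plasmid_bp)
        dsb = convert_yield(dsb, dose_scale=dose_scale, plasmid_bp=plasmid_bp)
    return BreakYields(
        ssb=ssb, dsb=dsb, n_repeats=n,
        rss=float(sum(f.rss for f in fits)), converged=all(f.converged for f in fits),
        per_repeat=fits, energy_mev=dataset.energy_mev,
        environment=dataset.environment, dose_rate_class=dataset.dose_rate_class,
    )


def validate_linear(dataset: DoseResponseDataset, fit: FitResult) -> float:
    """RMS deviation of held-out linear-form data from the fitted model.

    The linear curve is never used in fitting, so a small RMSD here is an
    out-of-sample check on the fitted (mu, phi).
    """
    sub = dataset.records[dataset.records["repeat_id"].notna()]
    doses = sub["dose"].to_numpy(dtype=float)
    obs = sub["p_l"].to_numpy(dtype=float)
    pred = l_fraction(doses, fit.params)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))
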
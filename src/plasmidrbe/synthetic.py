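"""Synthetic fixtures: dose-response datasets, gel-lane profiles, SSB sets.

The generators state the experimental worlds the pipeline is meant for: an
aqueous ("wet") irradiation design over 0-50 Gy with 5 gel repeats, and a dry
design over 0-6000 Gy with 3 repeats, both with per-Mbp yields at the scale
measured for ~0.22 keV/um electrons.  All generators are pure functions of
(design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import DoseResponseDataset
from .gel_quant import BandWindow, FormProportions, LaneProfile
from .mcmahon import DEFAULT_PLASMID_BP, DEFAULT_SEPARATION_BP, McMahonParams, predict_proportions

__all__ = [
    "SynthDesign",
    "wet_reference_design",
    "dry_reference_design",
    "generate_dose_response",
    "generate_lane_profile",
    "generate_ssb_fixture",
]

_MBP = DEFAULT_PLASMID_BP / 1e6


@dataclass(frozen=True)
class SynthDesign:
    """Ground truth and sampling design for a synthetic dose-response dataset.

    Yields are per plasmid per Gy (as inside the kinetic model); noise_scale
    is the per-species s.d. for gaussian_clipped noise, or sets the Dirichlet
    concentration k = 1/noise_scale^2.
    """

    true_mu: float
    true_phi: float
    s0: float = 0.88
    c0: float = 0.09
    rho: float = DEFAULT_SEPARATION_BP / DEFAULT_PLASMID_BP
    doses: tuple = (0.0, 5.0, 10.0, 20.0, 30.0, 50.0)
    n_repeats: int = 5
    noise_model: str = "gaussian_clipped"
    noise_scale: float = 0.01
    seed: int = 0
    energy_mev: float = 100.0
    environment: str = "wet"
    dose_rate_class: str = "conventional"

    def __post_init__(self):
        if 0.0 not in self.doses:
            raise ValueError("dose design must include zero dose")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model not in ("gaussian_clipped", "dirichlet"):
            raise ValueError("noise_model must be 'gaussian_clipped' or 'dirichlet'")

    @property
    def params(self) -> McMahonParams:
        return McMahonParams(mu=self.true_mu, phi=self.true_phi, s0=self.s0, c0=self.c0, rho=self.rho)


def wet_reference_design(seed: int = 0, **overrides) -> SynthDesign:
    """Aqueous irradiation frame: 0-50 Gy, 5 repeats, sigma = 0.01.

    Ground truth mirrors measured aqueous yields at ~100 MeV: SSB 15.42 and
    DSB 0.35 Mbp^-1 Gy^-1, converted to per-plasmid units.
    """
    defaults = dict(
        true_mu=15.42 * _MBP,
        true_phi=0.35 * _MBP,
        doses=(0.0, 5.0, 10.0, 20.0, 30.0, 50.0),
        n_repeats=5,
        noise_scale=0.01,
        seed=seed,
        environment="wet",
    )
    defaults.update(overrides)
    return SynthDesign(**defaults)


def dry_reference_design(seed: int = 0, **overrides) -> SynthDesign:
    """Dry irradiation frame: 0-6000 Gy, 3 repeats, sigma = 0.01.

    Ground truth mirrors measured dry yields at ~100 MeV: SSB 69.81 and DSB
    3.66 Mbp^-1 kGy^-1 (i.e. 0.06981 / 0.00366 Mbp^-1 Gy^-1).
    """
    defaults = dict(
        true_mu=69.81e-3 * _MBP,
        true_phi=3.66e-3 * _MBP,
        doses=(0.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0),
        n_repeats=3,
        noise_scale=0.01,
        seed=seed,
        environment="dry",
    )
    defaults.update(overrides)
    return SynthDesign(**defaults)


def _perturb(truth: np.ndarray, design: SynthDesign, rng: np.random.Generator) -> np.ndarray:
    if design.noise_scale == 0:
        return truth.copy()
    for _ in range(100):
        if design.noise_model == "gaussian_clipped":
            draw = np.clip(truth + rng.normal(0.0, design.noise_scale, size=3), 0.0, None)
        else:
            k = 1.0 / design.noise_scale**2
            draw = rng.dirichlet(np.clip(truth * k, 1e-12, None))
        if draw.sum() > 0:
            return draw / draw.sum()
    raise RuntimeError("degenerate noise draw 100 times in a row; reduce noise_scale")


def generate_dose_response(design: SynthDesign) -> DoseResponseDataset:
    """Draw a noisy dataset from the forward conformer model.

    Per (dose, repeat) the true (SC, OC, L) triple is perturbed by the noise
    model and renormalised to the simplex.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(1, design.n_repeats + 1):
        for d in design.doses:
            truth = np.array(predict_proportions(d, design.params), dtype=float)
            p = _perturb(truth, design, rng)
            rows.append({"dose": d, "repeat_id": rep, "p_sc": p[0], "p_oc": p[1], "p_l": p[2]})
    return DoseResponseDataset(
        records=pd.DataFrame(rows),
        energy_mev=design.energy_mev,
        environment=design.environment,
        dose_rate_class=design.dose_rate_class,
    )


def generate_lane_profile(
    proportions: FormProportions,
    band_centres=(20.0, 50.0, 80.0),
    band_sigma: float = 2.0,
    baseline: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    n_points: int = 1001,
    span: float = 100.0,
    total_area: float = 10.0,
):
    """A synthetic densitometry trace with one Gaussian band per species.

    Band areas are proportional to the given proportions; a constant baseline
    and clipped Gaussian noise are added.  Returns ``(LaneProfile, windows)``
    with windows of half-width 3*band_sigma centred on the bands (SC, OC, L
    in the order of ``band_centres``).
    """
    centres = tuple(float(c) for c in band_centres)
    if len(centres) != 3 or any(b - a < 4.0 * band_sigma for a, b in zip(centres, centres[1:])):
        raise ValueError("3 band centres required, ordered and separated by >= 4*band_sigma")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, span, n_points)
    areas = np.array(proportions.as_tuple()) * total_area
    sig = np.full_like(x, float(baseline))
    for area, c in zip(areas, centres):
        sig += area * np.exp(-0.5 * ((x - c) / band_sigma) ** 2) / (band_sigma * math.sqrt(2 * math.pi))
    if noise > 0:
        sig += rng.normal(0.0, noise, size=x.size)
    sig = np.clip(sig, 0.0, None)
    windows = [
        BandWindow(species, c - 3 * band_sigma, c + 3 * band_sigma)
        for species, c in zip(("SC", "OC", "L"), centres)
    ]
    return LaneProfile(positions=x, signal=sig), windows


def generate_ssb_fixture(
    n_bp: int,
    n_ssb: int,
    strand_balance: float = 0.5,
    seed: int = 0,
) -> frozenset:
    """Distinct uniform (bp, strand) SSB positions for clustering tests.

    ``strand_balance`` is the marginal probability that a break sits on
    strand 1.  Raises when more breaks are requested than distinct sites.
    """
    if not (0.0 <= strand_balance <= 1.0):
        raise ValueError("strand_balance must lie in [0, 1]")
    if n_ssb > 2 * n_bp:
        raise ValueError(f"cannot place {n_ssb} distinct breaks on {2 * n_bp} sites")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_ssb:
        bp = int(rng.integers(0, n_bp))
        strand = 1 if rng.random() < strand_balance else 2
        chosen.add((bp, strand))
    return frozenset(chosen)
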
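# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the methodology was genuinely
open, and what the synthetic-data tests do and do not establish.

## Conformer kinetic model

A plasmid population is partitioned into supercoiled (SC), open-circular
(OC) and linear (L) conformers. Breaks accumulate as Poisson processes in
dose: SSBs at rate μ and DSBs at rate φ, both per plasmid per Gy. An SSB
relaxes SC→OC; a DSB (either a direct DSB or two SSBs on opposite strands
within h base pairs) linearises. The pairing probability is ρ = h/n_bp,
default 10/4361 for pBR322. The model:

- SC(D) = S0·e^{−(μ+φ)D}
- OC(D) = e^{−φD}[e^{−½μ²ρD²}(S0+C0) − S0·e^{−μD}]
- L(D) = 1 − (S0+C0)·e^{−(φD+½μ²ρD²)}

These sum to one identically. **Units**: inside the exponentials μD and φD
must be dimensionless expected break counts, so μ and φ are per-plasmid
quantities; reported per-Mbp yields are obtained by dividing by the plasmid
size in Mbp (0.004361 for pBR322) at the reporting boundary, with an explicit
`basis`/`dose_scale` tag on every `YieldValue`. Doses are Gy internally;
per-kGy yields appear only at presentation (dry-irradiation convention).
OC is evaluated in the rearranged form
e^{−φD}[c0·q + s0(q − e^{−μD})], q = e^{−½μ²ρD²}, which is algebraically
identical but returns exactly C0 at D = 0 in floating point.

## Yield estimation

Per gel repeat, (μ, φ) minimise Σ_D [(SC_obs − SC(D))² + (OC_obs − OC(D))²]
with μ, φ ≥ 0 (scipy trust-region-reflective least squares,
ftol = xtol = gtol = 1e-14). The linear-form data are deliberately excluded
from the objective and used afterwards as an out-of-sample RMSD check.
Choices:

- **Baseline (S0, C0)** fixed from each repeat's zero-dose lane, not fitted
  (configurable via `fit_baseline`). This matches the definition of S0/C0 as
  zero-dose proportions; it also means zero-dose measurement noise propagates
  into φ̂, which dominates the DSB yield's variance (see Limitations).
- **Initial point**: μ0 is the median low-dose log-linear slope of SC/S0;
  φ0 = 0.01·μ0. The bounded problem is convex enough here that multistart
  checks found no second optimum.
- **Uncertainty**: each repeat is fitted independently; the reported yield is
  the across-repeat mean per Mbp with SEM = s.d./√n. This mirrors how
  replicate gel experiments are summarised, rather than using single-fit
  covariance. Unweighted residuals; SC and OC points weighted equally.

## RBE and indirect fractions

RBE_DSB = φ_test/φ_ref with Co-60 references 3.27 ± 0.13 Mbp⁻¹ kGy⁻¹ (dry)
and 0.32 ± 0.02 Mbp⁻¹ Gy⁻¹ (aqueous), overridable in `RunConfig`. Unit
mismatches raise rather than convert silently. The indirect fraction is
100·(1 − dry/wet) after converting the dry yield to the wet yield's units;
dry > wet is capped at 0% and flagged. Ratio errors propagate as relative
errors in quadrature. The conventional-vs-FLASH comparison is a
normal-approximation two-sided z-test on the repeat-level SEMs — a declared
convention, since the underlying experiment names no test.

## Gel quantification

Band intensities are trapezoidal integrals over stated windows after
subtracting a baseline equal to the median signal outside all windows
(negative residuals clipped to zero). Median-of-outside is a robust stand-in
for whatever rolling-ball or manual background an imaging workflow used; it
is exact for a constant offset. Proportions are intensities over the lane
total — scale-invariant, hence equivalent to first normalising against the
most intense band. No SC staining-efficiency correction is applied by
default (`sc_correction = 1.0` exposed).

## Dosimetry

Electron count for dose D over a uniform disc beam of radius r:
N = πDρr²/(10⁹eL), with L in keV/μm (1 keV/μm = 1 eV/nm; the 10⁹ converts
keV/μm to eV/m), ρ the DNA density 1407 kg/m³. The Gaussian-beam inverse
uses peak fluence n/(2πσxσy). A front-to-back dose difference of fraction g
across a sample substrate is modelled as a linear gradient, giving a mean
sample dose of nominal·(1 − g/2); g is configurable in [0, 0.5] (typical
reported values 0.13–0.14).

## Monte-Carlo surrogate

The plasmid is a closed ring of n_bp half-cylinder segments (rise 0.34
nm/bp, ring radius n_bp·rise/2π ≈ 236 nm for 4361 bp) in the beam-normal
plane. Each segment's 1.15 nm cross-section has a 0.5 nm central base core
(deposits ignored for strand scoring) and two backbone half-cylinders split
by the plasmid plane: strand 1 beam-side, strand 2 far-side (Charlton-style
dimensions; configurable).

Track-structure transport is **replaced by a parametric surrogate** — the
single largest simplification in the package. Electrons travel straight
perpendicular lines from uniform entry points on the beam disc (radius 300
nm, covering the ring). Where a line chords a DNA cylinder (chord
2√(r² − u²) at radial offset u), deposits occur as a Poisson process with
mean free path λ and truncated-exponential energies on [1, 500] eV with
scale β = 34 eV, i.e. mean deposit ≈ 35 eV — the W-value scale for electrons
in condensed biological matter. λ = E[deposit]/LET, so the expected deposited
energy per unit path equals the LET exactly in expectation (verified to <2%
by simulation). Consequences: deposit *statistics* (clustering of
ionisations, secondary-electron spatial structure, backscatter from
substrate) are not modelled, so absolute DSB yields are not comparable to
transport-code results; what is preserved is the interface the scoring layer
consumes — localised eV-scale deposits at LET-consistent density — so
threshold/ramp scoring and clustering behaviour are faithfully exercised.

**SSB scoring**: energy accumulated per (bp, strand) volume compared to a
threshold (8.22, 17.5 or 22.5 eV in the default scan), or converted to a
damage probability rising linearly from 0 at 5 eV to 1 at 37.5 eV. A
per-single-deposit threshold mode is available by flag. **DSB clustering**:
opposite-strand SSB pairs within a circular base-pair separation (default
10). The pairing is a maximum-cardinality bipartite matching
(Hopcroft–Karp via scipy) rather than a greedy nearest-pair scan: greedy is
not optimal (a four-break wrap-around configuration where greedy finds one
pair and the optimum two is in the test suite), and the matching *count* —
the only quantity used — is unique, making the result deterministic without
a tie-break rule. Each SSB joins at most one DSB.

**Runs and seeds**: a run delivers the full dose to one plasmid with N
electrons from the fluence relation (rounded, minimum 1). Yields are mean
DSB/(Mbp·kGy) over runs with SE = s.d./√runs. Per-run generator pairs
(deposits, scoring) are spawned from one `SeedSequence`, so every cell of a
parameter scan sees identical deposit streams: threshold and separation
comparisons are exactly paired, and monotonicity in both holds run-by-run by
construction. All stochastic entry points require an explicit seed.

## Synthetic data

`wet_reference_design`: doses {0, 5, 10, 20, 30, 50} Gy, 5 repeats,
S0 = 0.88, C0 = 0.09, true yields SSB 15.42 / DSB 0.35 Mbp⁻¹ Gy⁻¹ —
the measured aqueous 100 MeV frame. `dry_reference_design`: doses 0–6000
Gy, 3 repeats, SSB 69.81 / DSB 3.66 Mbp⁻¹ kGy⁻¹. Noise is
Gaussian-clipped per species (σ = 0.01 default, the scale of gel
densitometry repeatability) with renormalisation to the simplex; a
Dirichlet mode (k = 1/σ²) is available for strictly simplex-supported
noise. Lane profiles are three Gaussian bands with areas proportional to
the conformer proportions plus constant baseline and clipped Gaussian
noise. What green synthetic tests establish: the estimator recovers the
generating parameters of *this* noise model at *these* designs. What they
do not establish: robustness to band-shape asymmetry, staining
nonlinearity, lane-to-lane migration drift, or transport-induced SC
relaxation (users can emulate degraded baselines by lowering S0).

## Numerical conventions and degenerate inputs

- Proportions must sum to 1 within 1e-9 at construction; model outputs sum
  to 1 within 1e-12 over random parameter draws (tested at 10⁴ draws).
- Empty lanes (no integrable signal) raise `EmptyLaneError`; fewer than two
  repeats, missing zero-dose lanes, or all-zero-dose designs raise
  `FitError` naming the offending repeat.
- Negative doses, non-covering beams, and missing seeds are domain errors,
  not warnings.
- Truncated-exponential sampling uses inverse-CDF via `log1p`/`expm1` for
  stability at small β/span ratios.

## Known limitations

- The DSB yield φ̂ from the dose-response fit has ~10% relative RMSE at the
  reference wet design (5 repeats, σ = 0.01): OC/L curvature carries little
  information about φ over 0–50 Gy and the fixed noisy zero-dose baseline
  feeds directly into it. The SSB yield is an order of magnitude better
  determined (<1%). More repeats or fitting the baseline
  (`fit_baseline=True`) tightens φ̂.
- Monte-Carlo absolute yields are surrogate-level only (see above); use the
  parameter scan for sensitivity structure, not for quantitative transport
  predictions.
- The slide-gradient correction assumes a linear depth profile; a measured
  profile can be applied upstream instead.
- Quadrature ratio errors assume independent, symmetric, small relative
  errors; they are not exact for the ~12% relative errors of some measured
  dry yields.
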
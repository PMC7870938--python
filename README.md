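# plasmidrbe

Analysis pipeline for **plasmid nicking-assay dosimetry**: quantifying DNA
strand-break induction by ionising radiation from agarose-gel electrophoresis
(AGE) of irradiated plasmid, and comparing modalities through relative
biological effectiveness (RBE).

Irradiated plasmid DNA separates on a gel into three conformers: supercoiled
(SC, undamaged), open-circular (OC, one single-strand break, SSB) and linear
(L, one double-strand break, DSB). With Poisson break statistics the
proportions at dose *D* (Gy) follow the closed-form kinetic model

```
SC(D) = S0 · exp(−(μ + φ)D)
OC(D) = exp(−φD) · [exp(−½μ²ρD²)(S0 + C0) − S0·exp(−μD)]
L(D)  = 1 − (S0 + C0) · exp(−(φD + ½μ²ρD²))
```

where μ and φ are the SSB and DSB yields per plasmid per Gy, S0 and C0 the
zero-dose SC/OC proportions, and ρ = h / n_bp the probability that two SSBs
on opposite strands fall within h base pairs (default 10/4361 for pBR322).
The three expressions sum to 1 identically. Fitting SC and OC by nonlinear
least squares (L held out for validation) yields μ̂ and φ̂ per gel repeat;
yields are reported per Mbp with the across-repeat SEM.

On top of the fit the package computes:

- **RBE (DSB endpoint)** — RBE = φ_test / φ_ref against Co-60 reference
  yields (3.27 Mbp⁻¹ kGy⁻¹ dry, 0.32 Mbp⁻¹ Gy⁻¹ aqueous), quadrature errors;
- **indirect-damage fractions** — 100·(1 − dry/wet) after unit conversion,
  contrasting dry plasmid (direct damage only) with aqueous plasmid (direct
  plus radical-mediated);
- **dose-rate comparisons** — z-test between conventional and ultra-high
  (FLASH) dose-rate yields;
- **beam dosimetry** — electron count for a target dose,
  N = πDρr²/(10⁹eL), Gaussian-fluence peak dose, and a linear slide-gradient
  dose correction;
- **a desk-scale Monte-Carlo surrogate** — circular plasmid of half-cylinder
  base-pair volumes, LET-calibrated stochastic energy deposits, SSB scoring by
  energy threshold (8.22–22.5 eV) or a 5–37.5 eV linear probability ramp, and
  DSB clustering by maximum pairing of opposite-strand SSBs within 10 bp.

## Layout

- `src/plasmidrbe/` — the library: `io_formats`, `gel_quant`, `mcmahon`,
  `fitting`, `rbe`, `dosimetry`, `mc`, `synthetic`, `pipeline`, `cli`.
- `analysis/01…05` — numbered narrative drivers: simulate synthetic data,
  quantify a gel lane, fit yields, reproduce the RBE/indirect tables, run the
  Monte-Carlo parameter scan. Outputs land in `results/`.
- `data/published_yields.csv` — measured VHEE strand-break yield table
  (100–200 MeV, dry and aqueous, conventional and FLASH) used as input.
- `tests/` — pytest suite including property tests and acceptance checks.

## Worked example

```sh
python analysis/04_rbe_indirect.py
```

prints (abridged):

```
RBE (DSB endpoint) vs Co-60:
 energy_mev environment dose_rate_class  rbe_dsb  rbe_err
        100         dry    conventional    1.119    0.139
        150         dry    conventional    1.135    0.056
        200         dry    conventional    1.171    0.145
        100         wet    conventional    1.094    0.093
        ...
Percent of damage from indirect effects (dry vs aqueous-conventional):
 energy_mev  ssb_indirect_pct  dsb_indirect_pct
        100             99.55             98.95
        150             99.54             98.94
        200             99.75             98.99
Dose-rate effect on aqueous DSB yield (conventional vs FLASH):
  100 MeV: z = -0.55, p = 0.58 -> not significant
```

RBE near unity says very-high-energy electrons damage DNA like Co-60 photons
at equal dose; ~99% indirect fractions reflect the low scavenging capacity of
dilute Tris buffer (radicals dominate); the non-significant z-tests show no
FLASH effect at the DNA damage level in this system.

The same computations are available as a CLI
(`plasmidrbe synth|quantify|fit|rbe|dose|simulate|scan|run`, see
`plasmidrbe --help` and `plasmidrbe --show-config`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the shipped yield table and through the library, the six
DSB-endpoint RBE values (targets t1–t6: dry then aqueous at 100/150/200 MeV)
and the six indirect-damage percentages (t7–t12: SSB then DSB at
100/150/200 MeV), after first exercising the synthetic-data → fit pipeline
with the given seed. Output is a JSON map of target id to
`{"value": …, "n": …}`.
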
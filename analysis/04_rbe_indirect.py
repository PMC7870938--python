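#!/usr/bin/env python
"""RBE and indirect-damage fractions from the measured VHEE yield table.

Loads data/published_yields.csv (measured SSB/DSB yields for dry and aqueous
pBR322 at 100-200 MeV), computes the DSB-endpoint RBE against the Co-60
references and the indirect-damage percentages from the dry/wet contrast, and
tests the conventional-vs-FLASH DSB yields for a dose-rate effect.  Writes
results/rbe.csv and results/indirect.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from plasmidrbe.fitting import BreakYields
from plasmidrbe.io_formats import RunConfig, read_yield_table
from plasmidrbe.mcmahon import YieldValue
from plasmidrbe.pipeline import indirect_table, rbe_table
from plasmidrbe.rbe import compare_yields


def main():
    config = RunConfig()
    yields = read_yield_table(ROOT / "data" / "published_yields.csv")
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)

    rbe = rbe_table(yields, config)
    rbe.to_csv(outdir / "rbe.csv", index=False, float_format="%.4g")
    print("RBE (DSB endpoint) vs Co-60:")
    print(rbe.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    ind = indirect_table(yields, config)
    ind.to_csv(outdir / "indirect.csv", index=False, float_format="%.5g")
    print("\nPercent of damage from indirect effects (dry vs aqueous-conventional):")
    print(ind.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

    print("\nDose-rate effect on aqueous DSB yield (conventional vs FLASH):")
    for energy in (100, 150, 200):
        rows = {
            rate: yields[
                (yields.energy_mev == energy)
                & (yields.environment == "wet")
                & (yields.dose_rate_class == rate)
            ].iloc[0]
            for rate in ("conventional", "flash")
        }
        pair = [
            BreakYields(
                ssb=YieldValue(r.ssb_yield, r.ssb_err),
                dsb=YieldValue(r.dsb_yield, r.dsb_err),
                n_repeats=5, rss=0.0, converged=True,
            )
            for r in rows.values()
        ]
        rep = compare_yields(*pair)
        verdict = "significant" if rep.significant else "not significant"
        print(f"  {energy} MeV: z = {rep.z:+.2f}, p = {rep.p_value:.2f} -> {verdict}")


if __name__ == "__main__":
    main()
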
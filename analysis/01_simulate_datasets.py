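#!/usr/bin/env python
"""Generate the synthetic inputs the rest of the analysis consumes.

Writes, under results/synthetic/:
  wet_dose_response.csv  aqueous frame (0-50 Gy, 5 repeats, sigma = 0.01)
  dry_dose_response.csv  dry frame (0-6000 Gy, 3 repeats, sigma = 0.01)
  lane_profile.csv       one noisy densitometry trace with its band windows
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from plasmidrbe.gel_quant import FormProportions
from plasmidrbe.synthetic import (
    dry_reference_design,
    generate_dose_response,
    generate_lane_profile,
    wet_reference_design,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "synthetic")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for name, design in (
        ("wet", wet_reference_design(seed=args.seed)),
        ("dry", dry_reference_design(seed=args.seed + 1)),
    ):
        ds = generate_dose_response(design)
        df = ds.records.assign(
            energy_mev=ds.energy_mev, environment=ds.environment, dose_rate_class=ds.dose_rate_class
        )
        path = args.outdir / f"{name}_dose_response.csv"
        df.to_csv(path, index=False)
        print(
            f"{name}: {len(df)} rows, doses {min(design.doses):g}-{max(design.doses):g} Gy, "
            f"{design.n_repeats} repeats, true SSB/DSB = "
            f"{design.true_mu / 0.004361:.2f}/{design.true_phi / 0.004361:.4f} Mbp^-1 Gy^-1 -> {path}"
        )

    truth = FormProportions(0.55, 0.35, 0.10)
    profile, windows = generate_lane_profile(truth, noise=0.02, seed=args.seed)
    lane = pd.DataFrame({"position_mm": profile.positions, "signal": profile.signal})
    lane_path = args.outdir / "lane_profile.csv"
    lane.to_csv(lane_path, index=False)
    win = pd.DataFrame([{"species": w.species, "start": w.start, "end": w.end} for w in windows])
    win.to_csv(args.outdir / "lane_windows.csv", index=False)
    print(f"lane profile (true SC/OC/L = 0.55/0.35/0.10) -> {lane_path}")


if __name__ == "__main__":
    main()
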
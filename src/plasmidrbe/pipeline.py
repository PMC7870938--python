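"""End-to-end orchestration: quantify -> fit -> RBE, with run metadata."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import SchemaError
from .fitting import DoseResponseDataset, fit_dataset
from .gel_quant import proportions_from_intensities
from .io_formats import RunConfig, write_results
from .mcmahon import YieldValue, convert_yield
from .rbe import compute_rbe, indirect_fraction

__all__ = ["quantify_lane_table", "fit_groups", "rbe_table", "run_pipeline", "run_metadata"]

GROUP_KEYS = ["energy_mev", "environment", "dose_rate_class"]


def quantify_lane_table(lanes: pd.DataFrame) -> pd.DataFrame:
    """Turn band intensities into per-row conformer proportions."""
    out = lanes.copy()
    props = [
        proportions_from_intensities(r.intensity_sc, r.intensity_oc, r.intensity_l).as_tuple()
        for r in lanes.itertuples()
    ]
    out[["p_sc", "p_oc", "p_l"]] = pd.DataFrame(props, index=lanes.index)
    return out


def _group_meta(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "energy_mev" not in df.columns:
        df["energy_mev"] = float("nan")
    if "environment" not in df.columns:
        df["environment"] = "wet"
    if "dose_rate_class" not in df.columns:
        df["dose_rate_class"] = "conventional"
    return df


def fit_groups(proportions: pd.DataFrame, config: RunConfig) -> list:
    """Fit every (energy, environment, dose_rate_class) group independently."""
    req = {"dose", "repeat_id", "p_sc", "p_oc", "p_l"}
    missing = req - set(proportions.columns)
    if missing:
        raise SchemaError(f"proportions table missing column(s) {sorted(missing)}")
    df = _group_meta(proportions)
    results = []
    for (energy, env, rate), sub in df.groupby(GROUP_KEYS, dropna=False, sort=True):
        ds = DoseResponseDataset(
            records=sub.reset_index(drop=True),
            energy_mev=energy,
            environment=env,
            dose_rate_class=rate,
        )
        scale = "kGy" if env == "dry" else "Gy"
        results.append(
            fit_dataset(
                ds,
                rho=config.rho,
                plasmid_bp=config.plasmid_bp,
                fit_baseline=config.fit_baseline,
                dose_scale=scale,
            )
        )
    return results


def rbe_table(yields: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """RBE per yield-table row (DSB endpoint) against the configured references.

    Dry rows are compared per kGy against the dry reference and wet rows per
    Gy against the wet reference; rows are converted as needed.
    """
    refs = {
        "dry": YieldValue(config.reference_yield_dry, config.reference_yield_dry_err, "per_Mbp", "kGy"),
        "wet": YieldValue(config.reference_yield_wet, config.reference_yield_wet_err, "per_Mbp", "Gy"),
    }
    rows = []
    for r in yields.itertuples():
        ref = refs[r.environment]
        test = YieldValue(r.dsb_yield, r.dsb_err, "per_Mbp", r.dose_unit)
        test = convert_yield(test, dose_scale=ref.dose_scale, plasmid_bp=config.plasmid_bp)
        res = compute_rbe(test, ref, endpoint=f"{r.environment} plasmid DSB yield")
        rows.append(
            {
                "energy_mev": r.energy_mev,
                "environment": r.environment,
                "dose_rate_class": r.dose_rate_class,
                "rbe_dsb": res.value,
                "rbe_err": res.err,
                "endpoint": res.endpoint,
            }
        )
    return pd.DataFrame(rows)


def indirect_table(yields: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Indirect-damage percentages from matched dry / wet-conventional rows."""
    dry = yields[yields["environment"] == "dry"].set_index("energy_mev")
    wet = yields[(yields["environment"] == "wet") & (yields["dose_rate_class"] == "conventional")]
    rows = []
    for r in wet.itertuples():
        if r.energy_mev not in dry.index:
            continue
        d = dry.loc[r.energy_mev]
        row = {"energy_mev": r.energy_mev}
        for kind in ("ssb", "dsb"):
            dy = YieldValue(d[f"{kind}_yield"], d[f"{kind}_err"], "per_Mbp", d["dose_unit"])
            wy = YieldValue(getattr(r, f"{kind}_yield"), getattr(r, f"{kind}_err"), "per_Mbp", r.dose_unit)
            frac = indirect_fraction(dy, wy, plasmid_bp=config.plasmid_bp)
            row[f"{kind}_indirect_pct"] = frac.percent
            row[f"{kind}_indirect_err"] = frac.err
        rows.append(row)
    return pd.DataFrame(rows)


def run_metadata(config: RunConfig, inputs: dict[str, Path] | None = None) -> dict:
    meta = {
        "tool": "plasmidrbe",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.rng_seed,
        "config": config.model_dump(),
    }
    if inputs:
        meta["input_digests"] = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for name, p in inputs.items()
        }
    return meta


def run_pipeline(input_csv, config: RunConfig, output_dir=None) -> dict:
    """quantify (if needed) -> fit -> RBE; writes CSVs and a metadata sidecar.

    ``input_csv`` is either a lane-intensity table (intensity_* columns) or a
    proportions table (p_* columns), with optional energy/environment/
    dose-rate grouping columns.  Returns the artifact paths and frames.
    """
    input_csv = Path(input_csv)
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    df = pd.read_csv(input_csv)
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    if "intensity_sc" in df.columns:
        df = quantify_lane_table(df)
    elif "p_sc" not in df.columns:
        raise SchemaError("input needs either intensity_sc/oc/l or p_sc/p_oc/p_l columns")

    fitted = fit_groups(df, config)
    yields_path = outdir / "yields.csv"
    meta = run_metadata(config, {"input": input_csv})
    write_results(fitted, yields_path, metadata=meta)

    yields = pd.read_csv(yields_path)
    rbe = rbe_table(yields, config)
    rbe_path = outdir / "rbe.csv"
    rbe.to_csv(rbe_path, index=False, float_format="%.6g")
    return {"yields": yields, "rbe": rbe, "yields_path": yields_path, "rbe_path": rbe_path}
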
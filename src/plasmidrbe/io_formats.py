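"""Readers and writers for the pipeline's delimited-text tables and configs.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal.  Doses are stored in Gy internally; kGy appears only at reporting
boundaries.  Schema validation is strict: a missing column raises
:class:`SchemaError` naming it, and a row violating an invariant raises
:class:`TableValidationError` citing the row index.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import SchemaError, TableValidationError

__all__ = [
    "LANE_COLUMNS",
    "YIELD_COLUMNS",
    "RunConfig",
    "read_lane_table",
    "write_lane_table",
    "read_yield_table",
    "write_yield_table",
    "write_results",
    "read_run_config",
]

LANE_COLUMNS = [
    "sample_id",
    "dose",
    "repeat_id",
    "intensity_sc",
    "intensity_oc",
    "intensity_l",
]

YIELD_COLUMNS = [
    "energy_mev",
    "environment",
    "dose_rate_class",
    "ssb_yield",
    "ssb_err",
    "dsb_yield",
    "dsb_err",
    "dose_unit",
]

_ENVIRONMENTS = {"dry", "wet"}
_DOSE_RATE_CLASSES = {"conventional", "flash"}
_DOSE_UNITS = {"Gy", "kGy"}


class RunConfig(BaseModel):
    """Pipeline run configuration (YAML or JSON on disk)."""

    plasmid_bp: int = 4361
    rho_separation_bp: int = 10
    reference_yield_dry: float = 3.27  # Mbp^-1 kGy^-1, Co-60
    reference_yield_dry_err: float = 0.13
    reference_yield_wet: float = 0.32  # Mbp^-1 Gy^-1, Co-60
    reference_yield_wet_err: float = 0.02
    rng_seed: int = 0
    fit_baseline: bool = False
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check_sizes(self):
        if not (self.plasmid_bp > self.rho_separation_bp > 0):
            raise ValueError("require plasmid_bp > rho_separation_bp > 0")
        return self

    @property
    def rho(self) -> float:
        return self.rho_separation_bp / self.plasmid_bp


def _normalise_header(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_lane_table(path) -> pd.DataFrame:
    """Read and validate a gel-lane band-intensity table.

    Columns (case-insensitive): sample_id, dose, repeat_id, intensity_sc,
    intensity_oc, intensity_l.  Rows are returned in file order.
    """
    path = Path(path)
    df = _normalise_header(pd.read_csv(path), LANE_COLUMNS, path)
    df = df[LANE_COLUMNS].copy()
    df["dose"] = pd.to_numeric(df["dose"], errors="coerce")
    for i, row in df.iterrows():
        if not pd.notna(row["dose"]) or row["dose"] < 0:
            raise TableValidationError(f"{path}: row {i}: dose must be a finite value >= 0 Gy")
        if int(row["repeat_id"]) < 1:
            raise TableValidationError(f"{path}: row {i}: repeat_id must be >= 1")
        ints = [row["intensity_sc"], row["intensity_oc"], row["intensity_l"]]
        if any(v < 0 for v in ints):
            raise TableValidationError(f"{path}: row {i}: negative band intensity")
        if sum(ints) <= 0:
            raise TableValidationError(f"{path}: row {i}: all band intensities zero")
    if df.duplicated(subset=["sample_id", "dose", "repeat_id"]).any():
        raise TableValidationError(f"{path}: duplicate (sample_id, dose, repeat_id) rows")
    return df


def write_lane_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in LANE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"lane table to write is missing column(s) {missing}")
    df[LANE_COLUMNS].to_csv(path, index=False)


def read_yield_table(path) -> pd.DataFrame:
    """Read and validate a strand-break yield table (one row per condition)."""
    path = Path(path)
    df = _normalise_header(pd.read_csv(path), YIELD_COLUMNS, path)
    df = df[YIELD_COLUMNS].copy()
    for i, row in df.iterrows():
        if row["environment"] not in _ENVIRONMENTS:
            raise TableValidationError(f"{path}: row {i}: environment must be one of {_ENVIRONMENTS}")
        if row["dose_rate_class"] not in _DOSE_RATE_CLASSES:
            raise TableValidationError(
                f"{path}: row {i}: dose_rate_class must be one of {_DOSE_RATE_CLASSES}"
            )
        if row["dose_unit"] not in _DOSE_UNITS:
            raise TableValidationError(f"{path}: row {i}: dose_unit must be Gy or kGy")
        if any(row[c] < 0 for c in ("ssb_yield", "ssb_err", "dsb_yield", "dsb_err")):
            raise TableValidationError(f"{path}: row {i}: yields and errors must be >= 0")
    return df


def write_yield_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in YIELD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"yield table to write is missing column(s) {missing}")
    df[YIELD_COLUMNS].to_csv(path, index=False)


def write_results(break_yields, path, metadata: dict | None = None) -> None:
    """Write fitted BreakYields rows as CSV plus a JSON metadata sidecar.

    ``break_yields`` is a non-empty sequence of
    :class:`~plasmidrbe.fitting.BreakYields`.  The sidecar (``<path>.meta.json``)
    records seed, version and parameters when ``metadata`` is given.
    """
    rows = list(break_yields)
    if not rows:
        raise ValueError("refusing to write an empty results table")
    records = []
    for by in rows:
        records.append(
            {
                "energy_mev": by.energy_mev,
                "environment": by.environment,
                "dose_rate_class": by.dose_rate_class,
                "ssb_yield": by.ssb.value,
                "ssb_err": by.ssb.err,
                "dsb_yield": by.dsb.value,
                "dsb_err": by.dsb.err,
                "dose_unit": by.ssb.dose_scale,
                "n_repeats": by.n_repeats,
                "rss": by.rss,
                "converged": by.converged,
            }
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.6g")
    if metadata is not None:
        sidecar = Path(str(path) + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, default=str))


def read_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        raise SchemaError(f"{path}: unsupported config format {path.suffix!r} (use YAML or JSON)")
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    return RunConfig(**payload)
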
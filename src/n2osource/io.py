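"""CSV readers/writers and run configuration.

All files are plain UTF-8 CSV with period decimal separators; units are
part of the column names (ppb, mg_l, ape_pct, ...).  Schema violations
are reported with the offending columns named, never as raw pandas
errors.

Column schemas
--------------
chamber_series.csv : unit_id, slab_id, sampling, time_h, n2o_ppb, temp_c
isotopocule_samples.csv : unit_id, sampling, conc_ppb, d15n_alpha,
    d15n_beta, d18o, ambient_conc_ppb, ambient_d15n_alpha,
    ambient_d15n_beta, ambient_d18o
labeled_gas.csv : unit_id, time_h, conc_ppb, ambient_ppb, a15_mixture
    (and/or r45, r46, d18o_assumed)
pool_table.csv : unit_id, time_h, nh4_mg_l, nh4_ape_pct, no3_mg_l,
    no3_ape_pct
plant_table.csv : unit_id, organ, dry_weight_g, n_content_g_g, ape_pct
n2o_cumulative.csv : unit_id, interval_start_h, interval_end_h,
    n2o_mg_n, ape_pct
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .chamber import ChamberSeries
from .mixing import AmbientAir, IsotopoculeSample, MeasurementSigmas


class SchemaError(ValueError):
    """A CSV file does not match its documented column schema."""


def _require(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def read_chamber_csv(path: "str | Path", **chamber_kwargs) -> list[ChamberSeries]:
    """Read chamber time series, one :class:`ChamberSeries` per
    (unit_id, slab_id, sampling) group."""
    df = pd.read_csv(path)
    _require(df, ["unit_id", "time_h", "n2o_ppb"], str(path))
    for col in ("slab_id", "sampling"):
        if col not in df.columns:
            df[col] = ""
    out = []
    for (unit, slab, sampling), g in df.groupby(["unit_id", "slab_id", "sampling"]):
        g = g.sort_values("time_h")
        temp = g["temp_c"].to_numpy() + 273.15 if "temp_c" in g.columns else 293.15
        out.append(
            ChamberSeries.from_ppb(
                g["time_h"].to_numpy(), g["n2o_ppb"].to_numpy(),
                temperature_k=temp, unit_id=str(unit), slab_id=str(slab),
                **chamber_kwargs,
            )
        )
    return out


def read_isotopocule_csv(
    path: "str | Path", sigmas: Optional[MeasurementSigmas] = None
) -> list[IsotopoculeSample]:
    """Read headspace isotopocule samples with their ambient references."""
    df = pd.read_csv(path)
    cols = [
        "unit_id", "conc_ppb", "d15n_alpha", "d15n_beta", "d18o",
        "ambient_conc_ppb", "ambient_d15n_alpha", "ambient_d15n_beta",
        "ambient_d18o",
    ]
    _require(df, cols, str(path))
    out = []
    for i, row in df.iterrows():
        try:
            amb = AmbientAir(
                row["ambient_conc_ppb"], row["ambient_d15n_alpha"],
                row["ambient_d15n_beta"], row["ambient_d18o"],
            )
            kw = {"sigmas": sigmas} if sigmas is not None else {}
            out.append(
                IsotopoculeSample(
                    conc_ppb=row["conc_ppb"],
                    d15n_alpha=row["d15n_alpha"], d15n_beta=row["d15n_beta"],
                    d18o=row["d18o"], ambient=amb,
                    campaign_id=str(row.get("sampling", "")),
                    sample_id=str(row["unit_id"]), **kw,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}, row {i}: {exc}") from exc
    return out


def read_table(path: "str | Path", required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, required, str(path))
    return df


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    data_dir: Path
    out_dir: Path
    label_form: str = "NH4_15"
    margin_ppb: float = 65.0
    d18o_h2o: float = -8.5
    endmember_path: Optional[str] = None
    sigma_delta: float = 0.5
    sigma_conc_ppb: float = 2.0
    seed: int = 0
    mean_mode: bool = False
    excluded_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        if self.label_form not in ("NH4_15", "NO3_15"):
            raise ValueError(f"unknown label_form {self.label_form!r}")
        if self.margin_ppb <= 0:
            raise ValueError("margin_ppb must be positive")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_units" in raw:
            raw["excluded_units"] = tuple(raw["excluded_units"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid run config {path}: {exc}") from exc
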
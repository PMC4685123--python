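"""Delimited-text readers, censoring-aware parsing, config and JSON reports.

All tabular inputs are comma- or tab-delimited text with a header row
(dialect sniffed).  Concentration cells may be left-censored, written
``<LOD`` (e.g. ``<2``); these parse into a censoring flag plus the LOD.
All rounding for human-facing numbers happens at serialization, never
inside computations.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import DoseResponseSeries
from .dynamic import ConcentrationSeries
from .errors import SchemaError
from .isec import ColumnGeometry, ColumnVolumes, PolystyreneStandard

__all__ = [
    "AnalysisConfig",
    "read_table",
    "read_standards",
    "read_measurements",
    "read_concentration_series",
    "read_dose_response",
    "read_column_config",
    "write_report",
]

_CENSOR_RE = re.compile(r"^\s*<\s*([0-9.eE+-]+)\s*$")


@dataclass
class AnalysisConfig:
    """Umbrella configuration with every module's tunable defaults."""

    kd_threshold: float = 0.1
    route: str = "stokes"  # stokes | eq2
    censor_rule: str = "lod2"  # lod2 | lod | zero
    reference: str = "control"  # control | t0
    sd_multiplier: float = 3.0
    min_fold_change: float = 2.0
    dilution_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.route not in ("stokes", "eq2"):
            raise ValueError(f"route must be stokes|eq2, got {self.route!r}")
        if self.censor_rule not in ("lod2", "lod", "zero"):
            raise ValueError(f"censor_rule must be lod2|lod|zero, got {self.censor_rule!r}")
        if self.reference not in ("control", "t0"):
            raise ValueError(f"reference must be control|t0, got {self.reference!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def read_table(
    path: Union[str, Path],
    required: Sequence[str],
    numeric: Sequence[str] = (),
    censorable: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a delimited table, validate its header and coerce types.

    ``numeric`` columns must parse as floats; a malformed cell raises a
    :class:`SchemaError` naming the row and column.  ``censorable``
    columns accept ``<x`` cells and gain companion boolean
    ``<col>_censored`` and float ``<col>_lod`` columns.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    for col in censorable:
        values = np.full(len(df), np.nan)
        cens = np.zeros(len(df), dtype=bool)
        lod = np.full(len(df), np.nan)
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                continue
            m = _CENSOR_RE.match(str(raw))
            if m:
                cens[i] = True
                lod[i] = float(m.group(1))
            else:
                values[i] = _parse_float(raw, path.name, col, i)
        df[col] = values
        df[f"{col}_censored"] = cens
        df[f"{col}_lod"] = lod

    for col in numeric:
        if col in censorable or col not in df.columns:
            continue
        df[col] = [
            np.nan
            if (v is None or str(v).strip() == "" or (isinstance(v, float) and np.isnan(v)))
            else _parse_float(v, path.name, col, i)
            for i, v in enumerate(df[col])
        ]
    return df


def _parse_float(raw: object, fname: str, col: str, row: int) -> float:
    try:
        return float(str(raw))
    except ValueError:
        raise SchemaError(
            f"{fname}: malformed numeric value {raw!r} in column {col!r}, data row {row + 1}"
        ) from None


def read_standards(path: Union[str, Path]) -> list[PolystyreneStandard]:
    """Standards file: molecular_mass plus optional stokes_radius_nm."""
    df = read_table(
        path, required=["molecular_mass"], numeric=["molecular_mass", "stokes_radius_nm"]
    )
    out = []
    for _, row in df.iterrows():
        radius = row.get("stokes_radius_nm")
        radius = None if radius is None or pd.isna(radius) else float(radius)
        out.append(PolystyreneStandard(float(row["molecular_mass"]), radius))
    return out


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    """Per-adsorbent measurements: molecular_mass plus retention_volume_ml
    or a precomputed kd column."""
    df = read_table(
        path,
        required=["molecular_mass"],
        numeric=["molecular_mass", "retention_volume_ml", "kd"],
    )
    if "retention_volume_ml" not in df.columns and "kd" not in df.columns:
        raise SchemaError(
            f"{Path(path).name}: need a retention_volume_ml or kd column"
        )
    return df


def read_column_config(path: Union[str, Path]) -> tuple[ColumnVolumes, Optional[ColumnGeometry]]:
    """YAML column block: v0_mL, vt_mL, optional vb_mL or geometry
    (inner_diameter_cm, length_cm)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        volumes = ColumnVolumes(
            v0=float(data["v0_mL"]), vt=float(data["vt_mL"]), vb=data.get("vb_mL")
        )
    except KeyError as exc:
        raise SchemaError(f"column config missing key {exc}") from None
    geometry = None
    if "inner_diameter_cm" in data or "length_cm" in data:
        geometry = ColumnGeometry(
            inner_diameter=float(data.get("inner_diameter_cm", 0.46)),
            length=float(data.get("length_cm", 15.0)),
        )
    return volumes, geometry


def read_concentration_series(path: Union[str, Path]) -> list[ConcentrationSeries]:
    """Long-format series: analyte, condition, time_h, concentration_pg_ml
    (censorable, ``<2`` style), optional sd_pg_ml."""
    df = read_table(
        path,
        required=["analyte", "condition", "time_h", "concentration_pg_ml"],
        numeric=["time_h", "sd_pg_ml"],
        censorable=["concentration_pg_ml"],
    )
    out: list[ConcentrationSeries] = []
    for (analyte, condition), grp in df.groupby(["analyte", "condition"], sort=True):
        grp = grp.sort_values("time_h")
        lods = grp["concentration_pg_ml_lod"].dropna().unique()
        if len(lods) > 1:
            raise SchemaError(
                f"multiple LODs for {analyte}/{condition}: {sorted(lods)}"
            )
        sd = None
        if "sd_pg_ml" in grp.columns and grp["sd_pg_ml"].notna().any():
            sd = grp["sd_pg_ml"].to_numpy(dtype=float)
        out.append(
            ConcentrationSeries(
                analyte=str(analyte),
                condition=str(condition),
                timepoints=grp["time_h"].to_numpy(dtype=float),
                concentrations=grp["concentration_pg_ml"].to_numpy(dtype=float),
                censored=grp["concentration_pg_ml_censored"].to_numpy(dtype=bool),
                lod=float(lods[0]) if len(lods) else None,
                sd=sd,
            )
        )
    return out


def read_dose_response(
    path: Union[str, Path], dilution_factor: Optional[float] = None
) -> list[DoseResponseSeries]:
    """Dose-response file: marker, dose_pg_ml (or spiked_pg_ml with a
    dilution factor), response_mean, response_sd, optional n."""
    df = read_table(
        path,
        required=["marker", "response_mean", "response_sd"],
        numeric=["dose_pg_ml", "spiked_pg_ml", "response_mean", "response_sd", "n"],
    )
    if "dose_pg_ml" not in df.columns:
        if "spiked_pg_ml" not in df.columns:
            raise SchemaError(f"{Path(path).name}: need dose_pg_ml or spiked_pg_ml")
        factor = 10.0 if dilution_factor is None else dilution_factor
        df["dose_pg_ml"] = df["spiked_pg_ml"] / factor
    out = []
    for marker, grp in df.groupby("marker", sort=True):
        grp = grp.sort_values("dose_pg_ml")
        n = int(grp["n"].iloc[0]) if "n" in grp.columns and grp["n"].notna().any() else 3
        out.append(
            DoseResponseSeries(
                marker=str(marker),
                doses=grp["dose_pg_ml"].to_numpy(dtype=float),
                response_mean=grp["response_mean"].to_numpy(dtype=float),
                response_sd=grp["response_sd"].to_numpy(dtype=float),
                n=n,
            )
        )
    return out


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_report"):
            return o.to_report()
        return super().default(o)


def write_report(
    results: dict,
    path: Union[str, Path],
    config: Optional[AnalysisConfig] = None,
    warnings_list: Optional[Sequence[str]] = None,
) -> dict:
    """Write a JSON report with stable key order, version and config echo.

    Returns the document that was written (useful for round-trip tests).
    """
    doc = {
        "package": "adsorbkit",
        "version": __version__,
        "config": config.to_dict() if config is not None else None,
        "warnings": list(warnings_list or []),
        "results": results,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, cls=_ReportEncoder)
        fh.write("\n")
    return json.loads(json.dumps(doc, cls=_ReportEncoder))
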
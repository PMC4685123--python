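"""Bundled reference fixtures: the printed characterization tables.

Four small tables ship with the package so every analysis stage can run
end-to-end out of the box:

* ``table2_standards`` — the size-standard ladder (toluene tracer + 12
  polystyrene standards) with measured Stokes radii;
* ``table2_kd`` — the per-adsorbent Kd ladders (CG161c, CG300m, HAC);
* ``table2_volumes`` — anchor volumes per column plus the originally
  printed derived values (kept verbatim for comparison; the printed bed
  volume 1.792 mL is below V_T and is treated as an erratum — geometric
  bed volume is used instead);
* ``table3_endpoints`` — 6-hour endpoint cytokine concentrations per
  circuit, including left-censored "<2" entries;
* ``table1_particle_size`` / ``table4_secretion`` — informational.

Loaders return either raw DataFrames (:func:`load`) or analysis-ready
domain objects.
"""

from __future__ import annotations

import io as _io
from importlib import resources

import pandas as pd

from .dynamic import ConcentrationSeries
from .isec import (
    ColumnGeometry,
    ColumnVolumes,
    IsecProfile,
    PolystyreneStandard,
    StokesCalibration,
    fit_stokes_calibration,
)

__all__ = [
    "FIXTURE_NAMES",
    "ADSORBENTS",
    "load",
    "standards",
    "stokes_calibration",
    "column_volumes",
    "column_geometry",
    "isec_profile",
    "measured_radii",
    "endpoint_series",
    "export_all",
]

FIXTURE_NAMES = (
    "table1_particle_size",
    "table2_standards",
    "table2_kd",
    "table2_volumes",
    "table3_endpoints",
    "table4_secretion",
)

ADSORBENTS = ("CG161c", "CG300m", "HAC")


def load(name: str) -> pd.DataFrame:
    """Load a bundled fixture by id as a DataFrame."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = resources.files("adsorbkit.data").joinpath(f"{name}.csv").read_text()
    return pd.read_csv(_io.StringIO(text), dtype={"concentration_pg_ml": str})


def standards(include_tracer: bool = False) -> list[PolystyreneStandard]:
    """The size-standard ladder; by default the polystyrene rows only
    (the 92 Da toluene tracer is not a polymer coil and is excluded from
    power-law calibration)."""
    df = load("table2_standards")
    if not include_tracer:
        df = df[df["probe"] == "polystyrene"]
    return [
        PolystyreneStandard(float(r.molecular_mass), float(r.stokes_radius_nm))
        for r in df.itertuples()
    ]


def stokes_calibration(include_tracer: bool = False) -> StokesCalibration:
    """Power-law Stokes calibration fitted to the bundled standards."""
    return fit_stokes_calibration(standards(include_tracer=include_tracer))


def column_volumes(adsorbent: str) -> ColumnVolumes:
    df = load("table2_volumes")
    row = df[df["adsorbent"] == adsorbent]
    if row.empty:
        raise KeyError(f"unknown adsorbent {adsorbent!r}; choose from {ADSORBENTS}")
    return ColumnVolumes(v0=float(row["v0_ml"].iloc[0]), vt=float(row["vt_ml"].iloc[0]))


def column_geometry() -> ColumnGeometry:
    """The 0.46 x 15 cm HPLC column used for all three adsorbents."""
    return ColumnGeometry(inner_diameter=0.46, length=15.0)


def isec_profile(adsorbent: str) -> IsecProfile:
    """Kd ladder plus anchor volumes for one adsorbent."""
    kd = load("table2_kd")
    sub = kd[kd["adsorbent"] == adsorbent]
    if sub.empty:
        raise KeyError(f"unknown adsorbent {adsorbent!r}; choose from {ADSORBENTS}")
    points = list(zip(sub["molecular_mass"].astype(float), sub["kd"].astype(float)))
    return IsecProfile(adsorbent, column_volumes(adsorbent), points)


def measured_radii(adsorbent: str) -> list[float]:
    """Measured Stokes radii aligned with the adsorbent's profile points."""
    st = load("table2_standards").set_index("molecular_mass")["stokes_radius_nm"]
    profile = isec_profile(adsorbent)
    return [float(st.loc[int(m)]) for m in profile.masses]


def endpoint_series() -> list[ConcentrationSeries]:
    """Endpoint cytokine concentrations of the recirculation experiment:
    5 analytes x (control + 3 adsorbents), two cells censored at <2."""
    from .io import read_concentration_series

    with resources.as_file(
        resources.files("adsorbkit.data").joinpath("table3_endpoints.csv")
    ) as path:
        return read_concentration_series(path)


def export_all(directory) -> list[str]:
    """Write every fixture CSV into a directory (for CLI workflows)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_NAMES:
        text = resources.files("adsorbkit.data").joinpath(f"{name}.csv").read_text()
        out = directory / f"{name}.csv"
        out.write_text(text)
        written.append(str(out))
    return written
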
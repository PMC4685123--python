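"""Synthetic-data generators mirroring each assay's statistical structure.

Three generators cover the three analysis stages:

* **iSEC chromatograms** — a probe of Stokes radius r in a cylindrical
  pore of radius rp partitions with Kd = (1 - r/rp)^2 for r < rp, else 0
  (classical SEC partitioning; mixture-weighted over a pore-size set).
  Retention volumes follow vr = v0 + Kd*(vt - v0) plus additive Gaussian
  noise — the error structure of UV-detected retention measurements.
  The analysis modules never assume this partition law; it exists only
  to generate test data with a known ground truth.

* **reservoir depletion** — a well-mixed reservoir (volume V, mL)
  recirculated at ``flow`` mL/min through a cartridge of single-pass
  extraction efficiency E: C(t) = c0*exp(-60*flow*E/V * t).  Noise is
  multiplicative log-normal (immunoassay-like, constant CV).  An
  optional finite binding ``capacity`` (pg) drops E to zero once the
  cumulative captured mass reaches it (fixed-step Euler, step <= 0.01 h).
  The control circuit is E = 0.

* **dose-response** — Hill curve
  baseline + emax*d^hill/(ec50^hill + d^hill) with additive Gaussian
  noise on replicate means; the default dose grid is the tenfold-diluted
  spiking ladder 0/5/10/50/100/500/1000 pg/mL.

All generators draw from ``numpy.random.default_rng(config.seed)``:
equal seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .activation import DoseResponseSeries
from .dynamic import ConcentrationSeries
from .isec import ColumnVolumes, IsecProfile, PolystyreneStandard, StokesCalibration

__all__ = [
    "SimulationConfig",
    "VirtualAdsorbent",
    "DEFAULT_EFFECTIVE_DOSE_GRID",
    "partition_coefficient",
    "simulate_isec",
    "profile_from_simulation",
    "simulate_depletion",
    "simulate_depletion_trace",
    "hill_response",
    "simulate_dose_response",
]

#: Tenfold-diluted spiking ladder (pg/mL) used as the default dose grid.
DEFAULT_EFFECTIVE_DOSE_GRID = (0.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Seeded noise settings shared by all generators.

    ``noise_sd`` is interpreted in each generator's output units:
    mL of retention volume (additive), log-concentration (multiplicative
    log-normal), or assay units (additive on replicate draws).
    """

    seed: int = 0
    noise_sd: float = 0.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class VirtualAdsorbent:
    """Ground-truth adsorbent for iSEC simulation: pore-size spectrum
    (radius nm, weight) plus the packed column's anchor volumes."""

    pores: tuple[tuple[float, float], ...]  # ((radius_nm, weight), ...)
    v0: float  # mL
    vt: float  # mL
    porosity_fraction: Optional[float] = None  # informational

    def __post_init__(self) -> None:
        if not self.pores:
            raise ValueError("at least one pore population required")
        for r, w in self.pores:
            if r <= 0 or w < 0:
                raise ValueError("pore radii must be > 0 and weights >= 0")
        total = sum(w for _, w in self.pores)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pore weights must sum to 1, got {total}")
        if not 0 < self.v0 < self.vt:
            raise ValueError("need 0 < v0 < vt")
        if self.porosity_fraction is not None and not 0 < self.porosity_fraction < 1:
            raise ValueError("porosity_fraction must lie in (0, 1)")

    @classmethod
    def single_pore(
        cls, pore_radius: float, v0: float = 1.06, vt: float = 2.30
    ) -> "VirtualAdsorbent":
        return cls(pores=((pore_radius, 1.0),), v0=v0, vt=vt)

    @property
    def volumes(self) -> ColumnVolumes:
        return ColumnVolumes(v0=self.v0, vt=self.vt)


def partition_coefficient(
    probe_radius: Union[float, np.ndarray], adsorbent: VirtualAdsorbent
) -> Union[float, np.ndarray]:
    """Model Kd of a probe: mixture-weighted cylindrical-pore partitioning
    sum_i w_i * (1 - r/rp_i)^2, zero where the probe exceeds the pore."""
    r = np.asarray(probe_radius, dtype=float)
    kd = np.zeros_like(r, dtype=float)
    for rp, w in adsorbent.pores:
        inside = r < rp
        kd = kd + w * np.where(inside, (1.0 - r / rp) ** 2, 0.0)
    return float(kd) if kd.ndim == 0 else kd


def simulate_isec(
    adsorbent: VirtualAdsorbent,
    standards: Optional[Sequence[PolystyreneStandard]] = None,
    calibration: Optional[StokesCalibration] = None,
    config: SimulationConfig = SimulationConfig(),
    probe_radii: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Simulated retention volumes of a standards ladder on a virtual column.

    Probe Stokes radii come from the standards' measured radii (or the
    calibration applied to their masses); alternatively pass
    ``probe_radii`` directly, in which case masses are back-calculated
    through the calibration so the output feeds the normal analysis path.

    Returns a tidy frame with columns ``molecular_mass``,
    ``probe_radius_nm``, ``true_kd`` and ``retention_volume_ml``
    (vr = v0 + Kd*(vt - v0) + Gaussian noise of SD ``config.noise_sd`` mL).
    """
    if probe_radii is not None:
        radii = np.asarray(probe_radii, dtype=float)
        if calibration is None:
            raise ValueError("calibration required to assign masses to probe radii")
        masses = np.asarray(calibration.invert(radii), dtype=float)
    elif standards is not None:
        masses = np.array([s.molecular_mass for s in standards], dtype=float)
        radii = np.array(
            [
                s.stokes_radius
                if s.stokes_radius is not None
                else float(calibration.predict(s.molecular_mass))  # type: ignore[union-attr]
                for s in standards
            ],
            dtype=float,
        )
        if any(s.stokes_radius is None for s in standards) and calibration is None:
            raise ValueError("calibration required for standards without radii")
    else:
        raise ValueError("provide standards or probe_radii")

    order = np.argsort(masses)
    masses, radii = masses[order], radii[order]
    kd = partition_coefficient(radii, adsorbent)
    vr = adsorbent.v0 + kd * (adsorbent.vt - adsorbent.v0)
    if config.noise_sd > 0:
        vr = vr + config.rng().normal(0.0, config.noise_sd, size=vr.shape)
    return pd.DataFrame(
        {
            "molecular_mass": masses,
            "probe_radius_nm": radii,
            "true_kd": kd,
            "retention_volume_ml": vr,
        }
    )


def profile_from_simulation(
    adsorbent_id: str,
    adsorbent: VirtualAdsorbent,
    frame: pd.DataFrame,
    noise_sd_ml: float = 0.0,
) -> IsecProfile:
    """Build an analysis-ready profile from a simulated chromatogram.

    ``noise_sd_ml`` is the retention-volume noise used in the simulation;
    the profile's Kd excursion tolerance is widened to 5 sigma of the
    implied Kd noise (floored at the analysis default) so benign noise on
    fully excluded/permeating probes does not trip validation.
    """
    kd_noise = noise_sd_ml / (adsorbent.vt - adsorbent.v0)
    from .isec import KD_CLAMP_TOLERANCE

    return IsecProfile.from_retention_volumes(
        adsorbent_id,
        adsorbent.volumes,
        frame["molecular_mass"].to_numpy(),
        frame["retention_volume_ml"].to_numpy(),
        kd_tolerance=max(KD_CLAMP_TOLERANCE, 5.0 * kd_noise),
    )


def _depletion_grid(
    c0: float,
    reservoir_volume: float,
    flow: float,
    extraction_efficiency: float,
    t_end: float,
    capacity: Optional[float],
    step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step Euler integration of reservoir mass and captured mass."""
    n = max(int(np.ceil(t_end / step)), 1)
    dt = t_end / n
    k = 60.0 * flow * extraction_efficiency / reservoir_volume  # per hour
    t = np.linspace(0.0, t_end, n + 1)
    mass = np.empty(n + 1)
    captured = np.empty(n + 1)
    mass[0], captured[0] = c0 * reservoir_volume, 0.0
    for i in range(n):
        rate = k * mass[i] if (capacity is None or captured[i] < capacity) else 0.0
        removed = rate * dt
        if capacity is not None:
            removed = min(removed, capacity - captured[i])
        mass[i + 1] = mass[i] - removed
        captured[i + 1] = captured[i] + removed
    return t, mass, captured


def simulate_depletion_trace(
    c0: float,
    reservoir_volume: float = 60.0,
    flow: float = 1.0,
    extraction_efficiency: float = 0.5,
    t_end: float = 6.0,
    capacity: Optional[float] = None,
    step: float = 0.01,
) -> pd.DataFrame:
    """Noise-free integration grid: time, concentration, captured mass.

    Exposes the mass balance (reservoir + captured = initial) for
    verification; ``simulate_depletion`` samples this model at the
    requested timepoints and adds noise.
    """
    t, mass, captured = _depletion_grid(
        c0, reservoir_volume, flow, extraction_efficiency, t_end, capacity, step
    )
    return pd.DataFrame(
        {
            "time_h": t,
            "concentration_pg_ml": mass / reservoir_volume,
            "captured_mass_pg": captured,
        }
    )


def simulate_depletion(
    c0: float,
    reservoir_volume: float = 60.0,
    flow: float = 1.0,
    extraction_efficiency: float = 0.5,
    timepoints: Sequence[float] = (0, 1, 2, 3, 4, 5, 6),
    config: SimulationConfig = SimulationConfig(),
    capacity: Optional[float] = None,
    analyte: str = "analyte",
    condition: str = "treated",
) -> ConcentrationSeries:
    """Concentration series of a recirculating reservoir with one analyte.

    Without ``capacity`` the closed form C(t) = c0*exp(-60*flow*E/V * t)
    is evaluated exactly; with it the Euler grid is sampled.  Noise is
    multiplicative log-normal with log-SD ``config.noise_sd`` (~relative
    SD for small values).  Use ``extraction_efficiency=0`` for the
    no-adsorbent control circuit.
    """
    if c0 <= 0 or reservoir_volume <= 0 or flow <= 0:
        raise ValueError("c0, reservoir_volume and flow must be > 0")
    if not 0 <= extraction_efficiency <= 1:
        raise ValueError("extraction_efficiency must lie in [0, 1]")
    tp = np.asarray(timepoints, dtype=float)
    if capacity is None:
        k = 60.0 * flow * extraction_efficiency / reservoir_volume
        conc = c0 * np.exp(-k * tp)
    else:
        t_grid, mass, _ = _depletion_grid(
            c0, reservoir_volume, flow, extraction_efficiency, float(tp[-1]), capacity
        )
        conc = np.interp(tp, t_grid, mass / reservoir_volume)
    if config.noise_sd > 0:
        conc = conc * np.exp(config.rng().normal(0.0, config.noise_sd, size=conc.shape))
    return ConcentrationSeries(
        analyte=analyte, condition=condition, timepoints=tp, concentrations=conc
    )


def hill_response(
    dose: Union[float, np.ndarray],
    baseline: float,
    emax: float,
    ec50: float,
    hill: float,
) -> Union[float, np.ndarray]:
    """Sigmoid mean response baseline + emax*d^h/(ec50^h + d^h)."""
    if min(baseline, emax, ec50, hill) <= 0:
        raise ValueError("baseline, emax, ec50 and hill must be > 0")
    d = np.asarray(dose, dtype=float)
    out = baseline + emax * d**hill / (ec50**hill + d**hill)
    return float(out) if out.ndim == 0 else out


def simulate_dose_response(
    baseline: float,
    emax: float,
    ec50: float,
    hill: float,
    doses: Sequence[float] = DEFAULT_EFFECTIVE_DOSE_GRID,
    config: SimulationConfig = SimulationConfig(),
    marker: str = "marker",
) -> DoseResponseSeries:
    """Hill-curve series with per-dose replicate noise.

    Each dose's reported mean is the average of ``config.replicates``
    independent draws of N(true mean, noise_sd); the reported SD is the
    generating ``noise_sd`` itself (the assay's known dispersion), not
    the tiny-sample SD of the draws, which at n = 3 is too unstable to
    anchor an activation rule.
    """
    d = np.asarray(doses, dtype=float)
    true = np.asarray(hill_response(d, baseline, emax, ec50, hill), dtype=float)
    rng = config.rng()
    if config.noise_sd > 0:
        draws = true[:, None] + rng.normal(0.0, config.noise_sd, size=(len(d), config.replicates))
    else:
        draws = np.repeat(true[:, None], config.replicates, axis=1)
    means = draws.mean(axis=1)
    sds = np.full_like(means, config.noise_sd)
    return DoseResponseSeries(
        marker=marker, doses=d, response_mean=means, response_sd=sds, n=config.replicates
    )
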
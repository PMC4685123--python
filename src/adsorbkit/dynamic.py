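"""Removal analysis for the scaled-down recirculating adsorption circuit.

A small packed cartridge (model bed ~5 mL) recirculates cytokine-rich
plasma from a reservoir (~60 mL) at ~1 mL/min — a ~60x scale-down of a
clinical hemoperfusion device (300 mL bed, 100-300 mL/min, 4-6 L blood).
A parallel circuit with an empty cartridge serves as the no-adsorbent
control.  Endpoint removal for each analyte is quantified against the
control circuit at the same timepoint:

    removal% = 100 * (1 - C_treated(end) / C_control(end))

Concentrations below the assay's limit of detection ("<LOD") are
left-censored; a substitution rule (LOD/2 by default) resolves them and
the resulting summaries are flagged.

For synthetic-data recovery a single-compartment depletion model is
provided: a well-mixed reservoir drained by a cartridge of constant
single-pass extraction efficiency E gives C(t) = C0*exp(-k t) with
k = 60*flow*E/V_reservoir (per hour).  The fit is log-linear least
squares; the model is a testing construct, not a claim about real
column kinetics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationSeries",
    "RemovalSummary",
    "ScaleDownSpec",
    "DepletionFit",
    "CENSOR_RULES",
    "substitute_censored",
    "removal_percent",
    "removal_percent_sd",
    "removal_table",
    "scale_down_factor",
    "linear_velocity",
    "fit_depletion",
]

CONTROL_LABEL = "control"

#: Left-censoring substitution rules: value used in place of "<LOD".
CENSOR_RULES = {
    "lod2": lambda lod: lod / 2.0,
    "lod": lambda lod: lod,
    "zero": lambda lod: 0.0,
}


@dataclass
class ConcentrationSeries:
    """Timepointed concentrations of one analyte under one condition."""

    analyte: str
    condition: str
    timepoints: np.ndarray  # hours
    concentrations: np.ndarray  # pg/mL; NaN where censored
    censored: Optional[np.ndarray] = None  # bool per point
    lod: Optional[float] = None  # pg/mL, for censored points
    sd: Optional[np.ndarray] = None  # optional per-point SD (pg/mL)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.timepoints.shape != self.concentrations.shape:
            raise ValueError("timepoints and concentrations must align")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.censored is None:
            self.censored = np.zeros_like(self.timepoints, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        uncens = self.concentrations[~self.censored]
        if np.any(uncens < 0) or np.any(np.isnan(uncens)):
            raise ValueError("uncensored concentrations must be finite and >= 0")
        if self.censored.any() and (self.lod is None or self.lod <= 0):
            raise ValueError("censored points require a positive lod")

    @property
    def is_control(self) -> bool:
        return self.condition == CONTROL_LABEL

    def endpoint(self, rule: str = "lod2") -> tuple[float, bool, Optional[float]]:
        """(value, censored?, sd) at the final timepoint, censoring resolved."""
        flag = bool(self.censored[-1])
        value = substitute_censored(self.lod, rule) if flag else float(self.concentrations[-1])
        s = None if self.sd is None else float(self.sd[-1])
        return value, flag, s


@dataclass(frozen=True)
class RemovalSummary:
    analyte: str
    adsorbent: str
    removal_percent: float
    removal_sd: Optional[float]  # first-order propagation; approximate
    censored: bool
    reference: str  # "control" or "t0"
    reference_time: float  # hours

    def to_report(self) -> dict:
        return {
            "analyte": self.analyte,
            "adsorbent": self.adsorbent,
            "removal_percent": round(self.removal_percent, 1),
            "removal_sd_percent_approx": None
            if self.removal_sd is None
            else round(self.removal_sd, 1),
            "censored": self.censored,
            "reference": self.reference,
            "reference_time_h": self.reference_time,
        }


@dataclass(frozen=True)
class ScaleDownSpec:
    """Clinical-vs-model circuit dimensions for scale-down arithmetic."""

    clinical_bed_volume: float = 300.0  # mL
    model_bed_volume: float = 5.0  # mL
    clinical_blood_volume: float = 5000.0  # mL
    reservoir_volume: float = 60.0  # mL
    clinical_flow: float = 200.0  # mL/min
    model_flow: float = 1.0  # mL/min
    model_column_inner_diameter: Optional[float] = None  # cm

    def __post_init__(self) -> None:
        for name in (
            "clinical_bed_volume",
            "model_bed_volume",
            "clinical_blood_volume",
            "reservoir_volume",
            "clinical_flow",
            "model_flow",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_report(self) -> dict:
        rep = {
            "bed_volume_scale_factor": round(
                scale_down_factor(self.clinical_bed_volume, self.model_bed_volume), 2
            ),
            "blood_volume_scale_factor": round(
                scale_down_factor(self.clinical_blood_volume, self.reservoir_volume), 2
            ),
            "flow_scale_factor": round(
                scale_down_factor(self.clinical_flow, self.model_flow), 2
            ),
        }
        if self.model_column_inner_diameter is not None:
            rep["model_linear_velocity_cm_h"] = round(
                linear_velocity(self.model_flow, self.model_column_inner_diameter), 1
            )
        return rep


@dataclass(frozen=True)
class DepletionFit:
    """Log-linear fit of exponential reservoir depletion."""

    c0: float  # pg/mL
    rate: float  # per hour
    extraction_efficiency: Optional[float] = None  # fraction, [0, 1]
    clipped: bool = False  # E (or rate) hit a physical bound during derivation


def substitute_censored(lod: Optional[float], rule: str = "lod2") -> float:
    if rule not in CENSOR_RULES:
        raise ValueError(f"unknown censor rule {rule!r}; choose from {sorted(CENSOR_RULES)}")
    if lod is None or lod <= 0:
        raise ValueError("censored substitution requires a positive lod")
    return CENSOR_RULES[rule](lod)


def removal_percent(treated_final: float, control_final: float) -> float:
    """100 * (1 - treated/control), control at the same endpoint."""
    if control_final <= 0:
        raise ValueError(f"control concentration must be > 0, got {control_final}")
    if treated_final < 0:
        raise ValueError(f"treated concentration must be >= 0, got {treated_final}")
    pct = 100.0 * (1.0 - treated_final / control_final)
    if pct < 0:
        warnings.warn(
            f"negative removal ({pct:.1f}%): treated exceeds control", stacklevel=2
        )
    return pct


def removal_percent_sd(
    treated_final: float,
    control_final: float,
    treated_sd: float,
    control_sd: float,
) -> float:
    """First-order (delta-method) SD of the removal percentage.

    Approximate: treats treated/control endpoints as independent and the
    ratio as locally linear in both.
    """
    if control_final <= 0:
        raise ValueError("control concentration must be > 0")
    d_t = 100.0 / control_final
    d_c = 100.0 * treated_final / control_final**2
    return math.hypot(d_t * treated_sd, d_c * control_sd)


def removal_table(
    series: Sequence[ConcentrationSeries],
    censor_rule: str = "lod2",
    reference: str = "control",
) -> list[RemovalSummary]:
    """One removal summary per (analyte, adsorbent) pair.

    ``reference="control"`` compares each treated endpoint with the
    control circuit's endpoint for the same analyte (the convention that
    matches endpoint tables from paired-circuit experiments);
    ``reference="t0"`` compares with the treated series' own initial
    concentration and needs >= 2 timepoints.
    """
    if reference not in ("control", "t0"):
        raise ValueError(f"reference must be 'control' or 't0', got {reference!r}")
    summaries: list[RemovalSummary] = []
    by_analyte: dict[str, list[ConcentrationSeries]] = {}
    for s in series:
        by_analyte.setdefault(s.analyte, []).append(s)

    for analyte in sorted(by_analyte):
        group = by_analyte[analyte]
        controls = [s for s in group if s.is_control]
        treated_list = sorted(
            (s for s in group if not s.is_control), key=lambda s: s.condition
        )
        if reference == "control":
            if not controls:
                raise ValueError(f"no control series for analyte {analyte!r}")
            control = controls[0]
            c_ref, c_cens, c_sd = control.endpoint(censor_rule)
            if c_cens:
                raise ValueError(
                    f"control endpoint for {analyte!r} is censored; removal undefined"
                )
            ref_time = float(control.timepoints[-1])
        for s in treated_list:
            t_val, t_cens, t_sd = s.endpoint(censor_rule)
            if reference == "t0":
                if len(s.timepoints) < 2:
                    raise ValueError(
                        f"t0 reference needs >= 2 timepoints ({analyte}/{s.condition})"
                    )
                if s.censored[0]:
                    raise ValueError(
                        f"initial concentration censored ({analyte}/{s.condition})"
                    )
                c_ref, c_sd = float(s.concentrations[0]), None
                ref_time = float(s.timepoints[0])
            pct = removal_percent(t_val, c_ref)
            sd = None
            if t_sd is not None and c_sd is not None and not t_cens:
                sd = removal_percent_sd(t_val, c_ref, t_sd, c_sd)
            summaries.append(
                RemovalSummary(
                    analyte=analyte,
                    adsorbent=s.condition,
                    removal_percent=pct,
                    removal_sd=sd,
                    censored=t_cens,
                    reference=reference,
                    reference_time=ref_time,
                )
            )
    return summaries


def scale_down_factor(clinical_volume: float, model_volume: float) -> float:
    """Dimensionless ratio clinical/model (works for volumes or flows)."""
    if clinical_volume <= 0 or model_volume <= 0:
        raise ValueError("both quantities must be > 0")
    return clinical_volume / model_volume


def linear_velocity(flow: float, inner_diameter: float) -> float:
    """Superficial linear velocity in cm/h of a flow (mL/min) through a
    column of given inner diameter (cm)."""
    if flow <= 0 or inner_diameter <= 0:
        raise ValueError("flow and inner_diameter must be > 0")
    area = math.pi * (inner_diameter / 2.0) ** 2
    return 60.0 * flow / area


def fit_depletion(
    series: ConcentrationSeries,
    reservoir_volume: Optional[float] = None,
    flow: Optional[float] = None,
) -> DepletionFit:
    """Log-linear least-squares fit of C(t) = c0 * exp(-rate * t).

    Censored and non-positive points are excluded; >= 3 usable points are
    required.  When the circuit's reservoir volume (mL) and flow (mL/min)
    are given, the single-pass extraction efficiency
    E = rate * V / (60 * flow) is derived and clipped into [0, 1] with a
    warning if clipping occurs.
    """
    keep = (~series.censored) & (series.concentrations > 0)
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 uncensored positive points, have {int(keep.sum())}"
        )
    t = series.timepoints[keep]
    logc = np.log(series.concentrations[keep])
    res = stats.linregress(t, logc)
    rate = -float(res.slope)
    c0 = float(math.exp(res.intercept))
    clipped = False
    if rate < 0:
        # a (noisy) rising series has no physical depletion rate
        warnings.warn(f"fitted rate {rate:.4g}/h < 0; clipped to 0", stacklevel=2)
        rate, clipped = 0.0, True

    efficiency = None
    if reservoir_volume is not None and flow is not None:
        if reservoir_volume <= 0 or flow <= 0:
            raise ValueError("reservoir_volume and flow must be > 0")
        efficiency = rate * reservoir_volume / (60.0 * flow)
        if efficiency > 1.0:
            warnings.warn(
                f"extraction efficiency {efficiency:.3f} > 1; clipped", stacklevel=2
            )
            efficiency, clipped = 1.0, True
    return DepletionFit(c0=c0, rate=rate, extraction_efficiency=efficiency, clipped=clipped)
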
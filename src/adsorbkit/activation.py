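"""Dose-response activation thresholds for endothelial-cell readouts.

Endothelial cells (HUVEC) respond to inflammatory cytokines (TNF-alpha,
IL-1beta) by up-regulating adhesion molecules (ICAM-1, E-selectin) and
secreting IL-6/IL-8.  Spiking plasma with a dose ladder and reading a
marker per dose locates the *activation threshold*: the lowest dose whose
response is distinguishable from the unstimulated baseline.  Because only
design doses are tested, the threshold is reported as a bracket — the
last inactive design dose and the first active one — rather than an
interpolated EC value.

The activation call is an explicit dual rule (both must hold):

  * mean response exceeds baseline mean + ``sd_multiplier`` * baseline SD
  * mean response is at least ``min_fold_change`` times the baseline mean

Culture dilution matters: plasma spiked at S pg/mL and added at 10 % v/v
exposes the cells to an effective dose S/10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DoseResponseSeries",
    "ActivationCriterion",
    "DoseCall",
    "ThresholdBracket",
    "effective_dose",
    "activation_threshold",
    "interpolate_crossing_dose",
    "relative_expression",
]


@dataclass
class DoseResponseSeries:
    """Response of one marker over a strictly increasing dose ladder."""

    marker: str
    doses: np.ndarray  # pg/mL, effective (post-dilution); first may be 0
    response_mean: np.ndarray  # assay units
    response_sd: np.ndarray  # assay units
    n: int = 3  # replicates per dose

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.response_mean = np.asarray(self.response_mean, dtype=float)
        self.response_sd = np.asarray(self.response_sd, dtype=float)
        if not (self.doses.shape == self.response_mean.shape == self.response_sd.shape):
            raise ValueError("doses, means and SDs must align")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if np.any(self.response_sd < 0):
            raise ValueError("SDs must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ActivationCriterion:
    """Dual activation rule: baseline + k*SD excess AND minimum fold change."""

    sd_multiplier: float = 3.0
    min_fold_change: float = 2.0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0 or self.min_fold_change <= 0:
            raise ValueError("criterion parameters must be > 0")


@dataclass(frozen=True)
class DoseCall:
    """Per-dose activity call with both sub-rules reported separately."""

    dose: float
    response_mean: float
    exceeds_sd_rule: bool
    exceeds_fold_rule: bool
    active: bool


@dataclass
class ThresholdBracket:
    marker: str
    last_inactive_dose: Optional[float]
    first_active_dose: Optional[float]
    open_low: bool = False  # lowest nonzero dose already active
    open_high: bool = False  # no dose active
    calls: list[DoseCall] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "marker": self.marker,
            "last_inactive_dose_pg_ml": self.last_inactive_dose,
            "first_active_dose_pg_ml": self.first_active_dose,
            "open_low": self.open_low,
            "open_high": self.open_high,
            "calls": [
                {
                    "dose_pg_ml": c.dose,
                    "response_mean": c.response_mean,
                    "exceeds_sd_rule": c.exceeds_sd_rule,
                    "exceeds_fold_rule": c.exceeds_fold_rule,
                    "active": c.active,
                }
                for c in self.calls
            ],
        }


def effective_dose(spiked: float, dilution_factor: float = 10.0):
    """Effective culture dose of a spiked plasma concentration."""
    spiked = np.asarray(spiked, dtype=float)
    if np.any(spiked < 0):
        raise ValueError("spiked concentration must be >= 0")
    if dilution_factor < 1:
        raise ValueError(f"dilution_factor must be >= 1, got {dilution_factor}")
    out = spiked / dilution_factor
    return float(out) if out.ndim == 0 else out


def activation_threshold(
    series: DoseResponseSeries,
    criterion: ActivationCriterion = ActivationCriterion(),
) -> ThresholdBracket:
    """Bracket the activation threshold between adjacent design doses.

    The zero-dose point is the baseline.  Doses are scanned upward; the
    bracket is (largest inactive dose below the first active dose, first
    active dose).  A flat series is an ``open_high`` result; a series
    already active at its lowest nonzero dose is bracketed against the
    baseline dose and flagged ``open_low`` (the true threshold may lie
    below the tested range).  Both outcomes are flagged results, not
    errors.
    """
    if series.doses[0] != 0:
        raise ValueError("series must contain a zero-dose baseline point")
    base_mean = float(series.response_mean[0])
    base_sd = float(series.response_sd[0])
    sd_cut = base_mean + criterion.sd_multiplier * base_sd
    fold_cut = criterion.min_fold_change * base_mean

    calls: list[DoseCall] = []
    first_active: Optional[int] = None
    for i in range(1, len(series.doses)):
        m = float(series.response_mean[i])
        sd_ok = m > sd_cut
        fold_ok = m >= fold_cut
        active = sd_ok and fold_ok
        calls.append(
            DoseCall(
                dose=float(series.doses[i]),
                response_mean=m,
                exceeds_sd_rule=sd_ok,
                exceeds_fold_rule=fold_ok,
                active=active,
            )
        )
        if active and first_active is None:
            first_active = i

    if first_active is None:
        return ThresholdBracket(
            marker=series.marker,
            last_inactive_dose=float(series.doses[-1]),
            first_active_dose=None,
            open_high=True,
            calls=calls,
        )
    return ThresholdBracket(
        marker=series.marker,
        last_inactive_dose=float(series.doses[first_active - 1]),
        first_active_dose=float(series.doses[first_active]),
        open_low=(first_active == 1),
        calls=calls,
    )


def interpolate_crossing_dose(
    series: DoseResponseSeries,
    criterion: ActivationCriterion = ActivationCriterion(),
) -> Optional[float]:
    """Optional log-linear interpolation of the dose where the response
    crosses the SD rule's cutoff, inside the reported bracket.

    Never the default output — design-dose brackets are; returns None for
    open brackets or when the bracket's lower dose is 0 (no log scale).
    """
    bracket = activation_threshold(series, criterion)
    if bracket.open_high or bracket.last_inactive_dose in (None, 0.0):
        return None
    cutoff = float(series.response_mean[0]) + criterion.sd_multiplier * float(
        series.response_sd[0]
    )
    lo, hi = bracket.last_inactive_dose, bracket.first_active_dose
    y_lo = float(series.response_mean[series.doses == lo][0])
    y_hi = float(series.response_mean[series.doses == hi][0])
    if y_hi <= y_lo:
        return None
    frac = (cutoff - y_lo) / (y_hi - y_lo)
    frac = min(max(frac, 0.0), 1.0)
    return float(np.exp(np.log(lo) + frac * (np.log(hi) - np.log(lo))))


def relative_expression(sample_value: float, positive_control_value: float) -> float:
    """Marker level as a percentage of the positive (untreated) control."""
    if positive_control_value <= 0:
        raise ValueError(
            f"positive control must be > 0, got {positive_control_value}"
        )
    if sample_value < 0:
        raise ValueError(f"sample value must be >= 0, got {sample_value}")
    return 100.0 * sample_value / positive_control_value
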
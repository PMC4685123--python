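"""Inverse size-exclusion chromatography (iSEC) characterization of porous adsorbents.

iSEC inverts the usual SEC logic: solutes of *known* hydrodynamic size
(polystyrene standards plus a small-molecule tracer) probe the pore
structure of an *unknown* stationary phase.  From the retention volume
``vr`` of each probe and the column anchors — the interparticle void
volume ``v0`` (fully excluded probe) and the total mobile-phase volume
``vt`` (fully permeating tracer) — the SEC distribution coefficient

    Kd = (vr - v0) / (vt - v0)

measures the fraction of intraparticle pore volume accessible to that
probe (0 = fully excluded, 1 = fully permeating).  Scanning Kd across a
ladder of probe sizes locates the accessible pore radius: the probe size
at which Kd crosses an accessibility threshold (0.1 by convention here),
bracketed by the two adjacent standards.  The same anchor volumes give
the intraparticle porosity ``100 * (vt - v0) / (vb - v0)`` (``vb`` =
column bed volume) and the pore volume ``vt - v0``.

Probe sizes come from a power-law Stokes-radius calibration
``R_S = a * M^b`` fitted in log-log space to the polystyrene standards;
an alternative empirical mass/pore-size relation
``M = 2.25 * (d/Angstrom)^1.7`` is provided as a secondary route.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression

from .errors import DegenerateColumnError, InconsistentVolumesError, KdRangeError

__all__ = [
    "PolystyreneStandard",
    "ColumnGeometry",
    "ColumnVolumes",
    "IsecProfile",
    "StokesCalibration",
    "Eq2Constants",
    "PoreCharacterization",
    "compute_kd",
    "clamp_kd",
    "eq2_diameter_from_mass",
    "eq2_mass_from_diameter",
    "fit_stokes_calibration",
    "stokes_radius",
    "accessible_pore_bracket",
    "column_bed_volume",
    "porosity",
    "pore_volume",
    "characterize_adsorbent",
    "DEFAULT_KD_THRESHOLD",
    "KD_CLAMP_TOLERANCE",
]

#: Kd at which a probe is still considered able to reach the inner surface.
DEFAULT_KD_THRESHOLD = 0.1

#: Raw Kd may stray outside [0, 1] by at most this much before it is an error.
KD_CLAMP_TOLERANCE = 0.05


@dataclass(frozen=True)
class PolystyreneStandard:
    """A size standard: relative molecular mass (Da) and, when measured,
    its Stokes (viscosity) radius in nm."""

    molecular_mass: float
    stokes_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molecular_mass <= 0:
            raise ValueError(f"molecular_mass must be > 0, got {self.molecular_mass}")
        if self.stokes_radius is not None and self.stokes_radius <= 0:
            raise ValueError(f"stokes_radius must be > 0, got {self.stokes_radius}")


@dataclass(frozen=True)
class ColumnGeometry:
    """Cylindrical HPLC column geometry in cm (default 0.46 x 15 cm)."""

    inner_diameter: float = 0.46
    length: float = 15.0

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0 or self.length <= 0:
            raise ValueError("inner_diameter and length must be > 0")


@dataclass(frozen=True)
class ColumnVolumes:
    """Anchor volumes of a packed column, all in mL.

    v0: interparticle void volume (retention of the fully excluded probe)
    vt: total mobile-phase volume (retention of the fully permeating tracer)
    vb: column bed volume (geometric unless measured independently)
    """

    v0: float
    vt: float
    vb: Optional[float] = None

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise InconsistentVolumesError(f"v0 must be > 0, got {self.v0}")
        if self.vt <= self.v0:
            raise InconsistentVolumesError(
                f"vt ({self.vt} mL) must exceed v0 ({self.v0} mL)"
            )
        if self.vb is not None and self.vt > self.vb:
            raise InconsistentVolumesError(
                f"vt ({self.vt} mL) exceeds bed volume vb ({self.vb} mL); "
                "a column cannot hold more mobile phase than its bed volume"
            )

    def with_bed_volume(self, vb: float) -> "ColumnVolumes":
        return ColumnVolumes(self.v0, self.vt, vb)


@dataclass(frozen=True)
class StokesCalibration:
    """Power law R_S = prefactor * M^exponent (R_S in nm, M in Da)."""

    prefactor: float
    exponent: float
    r_squared: Optional[float] = None  # in log-log space

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError(f"prefactor must be > 0, got {self.prefactor}")
        if not 0 < self.exponent < 1:
            raise ValueError(f"exponent must lie in (0, 1), got {self.exponent}")

    def predict(self, molecular_mass) -> np.ndarray | float:
        return self.prefactor * np.asarray(molecular_mass, dtype=float) ** self.exponent

    def invert(self, radius_nm) -> np.ndarray | float:
        """Molecular mass whose predicted Stokes radius equals ``radius_nm``."""
        return (np.asarray(radius_nm, dtype=float) / self.prefactor) ** (1.0 / self.exponent)


@dataclass(frozen=True)
class Eq2Constants:
    """Empirical polystyrene mass / excluding-pore-diameter relation
    M = coefficient * d^exponent with d in Angstrom."""

    coefficient: float = 2.25
    exponent: float = 1.7


@dataclass
class IsecProfile:
    """Per-adsorbent Kd ladder: (molecular_mass, Kd) points plus anchors."""

    adsorbent_id: str
    volumes: ColumnVolumes
    points: list[tuple[float, float]]  # (molecular_mass Da, raw Kd), ascending mass
    #: how far raw Kd may stray outside [0, 1]; widen deliberately for
    #: high-noise data where larger benign excursions are expected
    kd_tolerance: float = KD_CLAMP_TOLERANCE

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError(f"profile {self.adsorbent_id!r} has no points")
        self.points = sorted((float(m), float(k)) for m, k in self.points)
        for m, k in self.points:
            if m <= 0:
                raise ValueError(f"molecular mass must be > 0, got {m}")
            if not (-self.kd_tolerance <= k <= 1 + self.kd_tolerance):
                raise KdRangeError(
                    f"Kd {k:.4g} at M_r {m:g} lies more than {self.kd_tolerance} "
                    "outside [0, 1]"
                )

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.points])

    @property
    def kd_raw(self) -> np.ndarray:
        return np.array([k for _, k in self.points])

    @property
    def kd_clamped(self) -> np.ndarray:
        return np.clip(self.kd_raw, 0.0, 1.0)

    @classmethod
    def from_retention_volumes(
        cls,
        adsorbent_id: str,
        volumes: ColumnVolumes,
        masses: Sequence[float],
        retention_volumes: Sequence[float],
        kd_tolerance: float = KD_CLAMP_TOLERANCE,
    ) -> "IsecProfile":
        kd = [
            clamp_kd(compute_kd(vr, volumes), tolerance=kd_tolerance, clip=False)
            for vr in retention_volumes
        ]
        return cls(adsorbent_id, volumes, list(zip(masses, kd)), kd_tolerance=kd_tolerance)


@dataclass
class PoreCharacterization:
    """Accessible pore bracket plus bulk pore metrics for one adsorbent.

    Radii are Stokes radii of the bracketing standards (nm); diameters are
    either doubled radii (route "stokes") or the empirical mass relation's
    excluding-pore diameter (route "eq2").  ``open_low``/``open_high`` flag
    brackets where the Kd ladder never crosses the threshold.
    """

    adsorbent_id: str
    threshold: float
    route: str
    r_lower: Optional[float] = None
    r_upper: Optional[float] = None
    d_lower: Optional[float] = None
    d_upper: Optional[float] = None
    open_low: bool = False
    open_high: bool = False
    porosity_percent: Optional[float] = None
    pore_volume_ml: Optional[float] = None
    mass_lower: Optional[float] = None
    mass_upper: Optional[float] = None
    smoothed: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        """Serializable record; rounding (paper precision) happens only here."""

        def r1(x):
            return None if x is None else round(x, 1)

        return {
            "adsorbent": self.adsorbent_id,
            "kd_threshold": self.threshold,
            "route": self.route,
            "pore_radius_lower_nm": r1(self.r_lower),
            "pore_radius_upper_nm": r1(self.r_upper),
            "pore_diameter_lower_nm": r1(self.d_lower),
            "pore_diameter_upper_nm": r1(self.d_upper),
            "open_low": self.open_low,
            "open_high": self.open_high,
            "porosity_percent": r1(self.porosity_percent),
            "pore_volume_ml": None if self.pore_volume_ml is None else round(self.pore_volume_ml, 2),
            "bracketing_masses_da": [self.mass_lower, self.mass_upper],
            "isotonic_smoothing_applied": self.smoothed,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# elementary operations


def compute_kd(vr: float, volumes: ColumnVolumes) -> float:
    """Raw SEC distribution coefficient (vr - v0) / (vt - v0), unclamped."""
    if vr < 0:
        raise ValueError(f"retention volume must be >= 0, got {vr}")
    span = volumes.vt - volumes.v0
    if span == 0:  # unreachable through ColumnVolumes, guards ad-hoc inputs
        raise DegenerateColumnError("vt == v0: intraparticle volume is zero")
    return (vr - volumes.v0) / span


def clamp_kd(kd: float, tolerance: float = KD_CLAMP_TOLERANCE, clip: bool = True) -> float:
    """Validate a raw Kd and optionally clip it into [0, 1].

    Values within ``tolerance`` of the valid range are attributed to
    measurement noise (warned, and clipped when ``clip``); larger
    excursions indicate an anchor or data error and raise.
    """
    if not (-tolerance <= kd <= 1 + tolerance):
        raise KdRangeError(f"Kd {kd:.4g} outside [-{tolerance}, {1 + tolerance}]")
    if kd < 0 or kd > 1:
        warnings.warn(f"Kd {kd:.4g} outside [0, 1]; attributed to noise", stacklevel=2)
        if clip:
            return min(max(kd, 0.0), 1.0)
    return kd


def eq2_diameter_from_mass(molecular_mass: float, constants: Eq2Constants = Eq2Constants()) -> float:
    """Excluding-pore diameter in Angstrom for a polystyrene of given mass."""
    if molecular_mass <= 0:
        raise ValueError(f"molecular_mass must be > 0, got {molecular_mass}")
    return (molecular_mass / constants.coefficient) ** (1.0 / constants.exponent)


def eq2_mass_from_diameter(diameter: float, constants: Eq2Constants = Eq2Constants()) -> float:
    """Inverse of :func:`eq2_diameter_from_mass` (diameter in Angstrom)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    return constants.coefficient * diameter ** constants.exponent


def fit_stokes_calibration(standards: Sequence[PolystyreneStandard]) -> StokesCalibration:
    """Least-squares power law log(R_S) = log(a) + b*log(M) over the standards.

    All standards must carry a measured Stokes radius; at least two
    distinct masses are required.  The coefficient of determination is
    reported in log-log space.
    """
    pts = [(s.molecular_mass, s.stokes_radius) for s in standards if s.stokes_radius is not None]
    if len(pts) < 2 or len({m for m, _ in pts}) < 2:
        raise ValueError("need >= 2 standards with distinct masses and measured radii")
    logm = np.log([m for m, _ in pts])
    logr = np.log([r for _, r in pts])
    res = stats.linregress(logm, logr)
    return StokesCalibration(
        prefactor=float(math.exp(res.intercept)),
        exponent=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def stokes_radius(molecular_mass: float, calibration: StokesCalibration) -> float:
    """Predicted Stokes radius (nm) for a molecular mass under a calibration."""
    if molecular_mass <= 0:
        raise ValueError(f"molecular_mass must be > 0, got {molecular_mass}")
    return float(calibration.predict(molecular_mass))


def column_bed_volume(geometry: ColumnGeometry) -> float:
    """Geometric bed volume pi*(d/2)^2*L in mL (cm^3)."""
    return math.pi * (geometry.inner_diameter / 2.0) ** 2 * geometry.length


def porosity(volumes: ColumnVolumes) -> float:
    """Intraparticle porosity 100*(vt - v0)/(vb - v0) in percent."""
    if volumes.vb is None:
        raise InconsistentVolumesError("bed volume vb required for porosity")
    return 100.0 * (volumes.vt - volumes.v0) / (volumes.vb - volumes.v0)


def pore_volume(volumes: ColumnVolumes) -> float:
    """Intraparticle pore volume vt - v0 in mL."""
    return volumes.vt - volumes.v0


# ---------------------------------------------------------------------------
# bracketing


def _smooth_nonincreasing(kd: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project Kd onto the non-increasing cone (isotonic regression).

    Physically Kd cannot grow with probe size; noisy ladders may violate
    this locally and would otherwise produce spurious threshold crossings.
    """
    res = isotonic_regression(kd, increasing=False)
    smoothed = np.asarray(res.x)
    return smoothed, bool(np.max(np.abs(smoothed - kd)) > 1e-12)


def accessible_pore_bracket(
    profile: IsecProfile,
    calibration: Optional[StokesCalibration] = None,
    threshold: float = DEFAULT_KD_THRESHOLD,
    radii: Optional[Sequence[Optional[float]]] = None,
    route: str = "stokes",
    eq2_constants: Eq2Constants = Eq2Constants(),
    smooth: bool = True,
) -> PoreCharacterization:
    """Bracket the accessible pore radius by the Kd-threshold crossing.

    A standard is *accessible* when its (smoothed, clamped) Kd is at or
    above ``threshold`` — a tie counts as accessible.  The bracket is
    (Stokes radius of the largest accessible standard, Stokes radius of
    the smallest inaccessible one).  ``radii`` supplies measured Stokes
    radii aligned with the profile's points; missing entries (or the
    whole argument) fall back to the calibration's prediction.

    Diameters follow ``route``: "stokes" doubles the bracketing radii,
    "eq2" converts the bracketing *masses* through the empirical mass /
    pore-diameter relation.  A ladder that never crosses the threshold
    yields an open bracket (flag set), not an exception.
    """
    if len(profile.points) < 2:
        raise ValueError("bracketing requires >= 2 profile points")
    if route not in ("stokes", "eq2"):
        raise ValueError(f"route must be 'stokes' or 'eq2', got {route!r}")

    masses = profile.masses
    kd = profile.kd_clamped
    notes: list[str] = []
    smoothed_flag = False
    if smooth:
        kd, smoothed_flag = _smooth_nonincreasing(kd)
        if smoothed_flag:
            notes.append("non-monotone Kd ladder smoothed by isotonic projection")

    if radii is not None:
        if len(radii) != len(masses):
            raise ValueError("radii must align with profile points")
        rr = [r for r in radii]
    else:
        rr = [None] * len(masses)
    for i, r in enumerate(rr):
        if r is None:
            if calibration is None:
                raise ValueError("calibration required when measured radii are absent")
            rr[i] = stokes_radius(masses[i], calibration)
    radii_arr = np.asarray(rr, dtype=float)

    # exact threshold ties count as accessible (>=); tiny epsilon guards
    # against representation noise in values read from text
    accessible = kd >= threshold - 1e-12

    result = PoreCharacterization(
        adsorbent_id=profile.adsorbent_id,
        threshold=threshold,
        route=route,
        smoothed=smoothed_flag,
        warnings=notes,
    )
    if not accessible.any():
        result.open_low = True
        notes.append("no standard reaches the Kd threshold (bracket open below)")
        return result

    i_lower = int(np.flatnonzero(accessible).max())
    result.mass_lower = float(masses[i_lower])
    result.r_lower = float(radii_arr[i_lower])
    above = ~accessible & (np.arange(len(masses)) > i_lower)
    if not above.any():
        result.open_high = True
        notes.append("every standard is accessible (bracket open above)")
    else:
        i_upper = int(np.flatnonzero(above).min())
        result.mass_upper = float(masses[i_upper])
        result.r_upper = float(radii_arr[i_upper])

    if route == "stokes":
        result.d_lower = None if result.r_lower is None else 2.0 * result.r_lower
        result.d_upper = None if result.r_upper is None else 2.0 * result.r_upper
    else:  # eq2: diameters from masses, in Angstrom -> nm
        if result.mass_lower is not None:
            result.d_lower = eq2_diameter_from_mass(result.mass_lower, eq2_constants) / 10.0
        if result.mass_upper is not None:
            result.d_upper = eq2_diameter_from_mass(result.mass_upper, eq2_constants) / 10.0
    return result


def characterize_adsorbent(
    profile: IsecProfile,
    calibration: Optional[StokesCalibration] = None,
    geometry: Optional[ColumnGeometry] = ColumnGeometry(),
    threshold: float = DEFAULT_KD_THRESHOLD,
    radii: Optional[Sequence[Optional[float]]] = None,
    route: str = "stokes",
    bed_volume_ml: Optional[float] = None,
) -> PoreCharacterization:
    """Complete characterization: bracket + porosity + pore volume.

    The bed volume defaults to the geometric volume of the column; a
    measured ``bed_volume_ml`` overrides it and is validated against vt.
    """
    volumes = profile.volumes
    vb = bed_volume_ml if bed_volume_ml is not None else volumes.vb
    if vb is None:
        if geometry is None:
            raise InconsistentVolumesError("need a bed volume or a column geometry")
        vb = column_bed_volume(geometry)
    volumes = volumes.with_bed_volume(vb)

    result = accessible_pore_bracket(
        profile, calibration=calibration, threshold=threshold, radii=radii, route=route
    )
    result.porosity_percent = porosity(volumes)
    result.pore_volume_ml = pore_volume(volumes)
    return result
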
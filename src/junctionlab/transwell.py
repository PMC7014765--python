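"""Transwell apparent-permeability coefficient and fluorescence standard curve.

The assay places a tracer (e.g. 70 kDa FITC-dextran) above a cell monolayer
grown on a porous insert and measures how much crosses into the abluminal
chamber in a fixed time under sink conditions.  The apparent permeability
coefficient is

    P_app = (V * C_abluminal) / (A * C_luminal * t)   [cm/s]

with V the abluminal chamber volume (cm^3), A the membrane area (cm^2),
C_abluminal the measured abluminal tracer concentration at time t (s), and
C_luminal the initial luminal concentration (same units as C_abluminal, so
the units cancel).  Abluminal concentrations come from a fluorescence
standard curve fitted by ordinary least squares (free intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .errors import ParameterError


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line mapping fluorescence to concentration."""

    slope: float
    intercept: float
    r_squared: float

    def concentration(self, fluorescence: float | np.ndarray) -> float | np.ndarray:
        """Predict concentration from a fluorescence reading."""
        return self.slope * np.asarray(fluorescence, dtype=np.float64) + self.intercept


@dataclass(frozen=True)
class TranswellSample:
    """One insert's assay quantities; concentrations share arbitrary units."""

    volume_cm3: float
    area_cm2: float
    c_luminal: float
    c_abluminal: float
    time_s: float

    def __post_init__(self) -> None:
        for name in ("volume_cm3", "area_cm2", "c_luminal", "time_s"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.c_abluminal < 0:
            raise ParameterError(f"c_abluminal must be >= 0, got {self.c_abluminal}")
        if self.c_abluminal > self.c_luminal:
            warnings.warn(
                "abluminal concentration exceeds luminal concentration; "
                "check units or standards",
                stacklevel=2,
            )


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Fit concentration = slope * fluorescence + intercept by OLS.

    Requires at least two points with at least two distinct fluorescence
    values; two points yield the exact line through both.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ParameterError("need >= 2 (fluorescence, concentration) points")
    f, c = pts[:, 0], pts[:, 1]
    if np.unique(f).size < 2:
        raise ParameterError("all fluorescence values identical; cannot fit a line")
    res = _stats.linregress(f, c)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def compute_papp(sample: TranswellSample) -> float:
    """Apparent permeability coefficient in cm/s (single-timepoint formula)."""
    return (sample.volume_cm3 * sample.c_abluminal) / (
        sample.area_cm2 * sample.c_luminal * sample.time_s
    )
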
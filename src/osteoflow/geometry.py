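"""Wall shear stress design calculations for the two perfusion devices.

Two laminar-flow geometries are supported:

* a cylindrical glass capillary (Hagen-Poiseuille wall shear,
  ``tau = 32 Q mu / (pi d^3)``), used as a biomimetic stand-in for a
  trabecular-bone pore, and
* a rectangular parallel-plate flow chamber (PPFC; plane-Poiseuille
  wall shear, ``tau = 6 Q mu / (w h^2)``), the conventional 2-D
  reference device.

All quantities are strictly SI internally (m, Pa, Pa*s, m^3/s).  Helper
constants are provided for the unit conversions a bench scientist uses
(ul/min, mPa, um) so that callers never multiply by bare powers of ten.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

__all__ = [
    "TubeGeometry",
    "ChamberGeometry",
    "FlowCondition",
    "ShearResult",
    "fss_capillary",
    "fss_ppfc",
    "flow_rate_for_fss",
    "UL_PER_MIN",
    "MPA",
    "UM",
    "MM",
    "LAMINAR_RE_THRESHOLD",
    "DEFAULT_VISCOSITY",
    "DEFAULT_DENSITY",
]

#: 1 ul/min expressed in m^3/s.
UL_PER_MIN = 1e-9 / 60.0
#: 1 mPa expressed in Pa (also 1 mPa*s in Pa*s).
MPA = 1e-3
#: 1 um in m.
UM = 1e-6
#: 1 mm in m.
MM = 1e-3

#: Reynolds number below which fully developed flow is taken as laminar.
LAMINAR_RE_THRESHOLD = 2000.0

#: Dynamic viscosity of culture medium at 37 C (Pa*s), close to water.
DEFAULT_VISCOSITY = 1.0e-3
#: Mass density of culture medium (kg/m^3), used only for Reynolds checks.
DEFAULT_DENSITY = 1000.0


class InvalidGeometryError(ValueError):
    """A geometric or fluid parameter violates its physical constraint."""


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise InvalidGeometryError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class TubeGeometry:
    """Cylindrical capillary: inner diameter and length, in metres."""

    inner_diameter: float
    length: float = 80e-3

    def __post_init__(self) -> None:
        _require_positive("inner_diameter", self.inner_diameter)
        _require_positive("length", self.length)


@dataclass(frozen=True)
class ChamberGeometry:
    """Parallel-plate flow chamber: width, height and length, in metres.

    Validity of the plane-Poiseuille shear formula assumes a wide shallow
    channel (height much smaller than width); a warning is emitted when
    height/width exceeds 0.2.
    """

    width: float
    height: float
    length: float = 50e-3

    def __post_init__(self) -> None:
        _require_positive("width", self.width)
        _require_positive("height", self.height)
        _require_positive("length", self.length)
        if not self.width > self.height:
            raise InvalidGeometryError(
                f"width ({self.width}) must exceed height ({self.height})"
            )
        if self.height / self.width > 0.2:
            warnings.warn(
                "aspect ratio height/width > 0.2; plane-Poiseuille wall "
                "shear is a poor approximation for deep channels",
                stacklevel=3,
            )


@dataclass(frozen=True)
class FlowCondition:
    """Volumetric flow rate (m^3/s), viscosity (Pa*s), density (kg/m^3)."""

    flow_rate: float
    viscosity: float = DEFAULT_VISCOSITY
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise InvalidGeometryError(
                f"flow_rate must be >= 0, got {self.flow_rate!r}"
            )
        _require_positive("viscosity", self.viscosity)
        _require_positive("density", self.density)


@dataclass(frozen=True)
class ShearResult:
    """Wall shear stress tau (Pa) with a laminar-regime sanity check."""

    tau: float
    reynolds: float
    laminar: bool

    @property
    def tau_mpa(self) -> float:
        """Shear stress in mPa, the unit used at the bench."""
        return self.tau / MPA


def _result(tau: float, reynolds: float) -> ShearResult:
    laminar = reynolds < LAMINAR_RE_THRESHOLD
    if not laminar:
        warnings.warn(
            f"Reynolds number {reynolds:.0f} exceeds laminar threshold "
            f"{LAMINAR_RE_THRESHOLD:.0f}; shear formula assumes laminar flow",
            stacklevel=3,
        )
    return ShearResult(tau=tau, reynolds=reynolds, laminar=laminar)


def fss_capillary(geom: TubeGeometry, flow: FlowCondition) -> ShearResult:
    """Wall shear stress in a cylindrical capillary.

    ``tau = 32 Q mu / (pi d^3)`` for fully developed laminar
    Hagen-Poiseuille flow.  The Reynolds number uses the mean velocity
    ``4 Q / (pi d^2)`` and the diameter as the characteristic length.
    """
    d = geom.inner_diameter
    tau = 32.0 * flow.flow_rate * flow.viscosity / (math.pi * d**3)
    velocity = 4.0 * flow.flow_rate / (math.pi * d**2)
    reynolds = flow.density * velocity * d / flow.viscosity
    return _result(tau, reynolds)


def fss_ppfc(geom: ChamberGeometry, flow: FlowCondition) -> ShearResult:
    """Wall shear stress in a parallel-plate flow chamber.

    ``tau = 6 Q mu / (w h^2)`` for plane-Poiseuille flow between wide
    plates.  The Reynolds number uses the hydraulic diameter
    ``2wh/(w+h)`` and mean velocity ``Q/(wh)``.
    """
    w, h = geom.width, geom.height
    tau = 6.0 * flow.flow_rate * flow.viscosity / (w * h**2)
    velocity = flow.flow_rate / (w * h)
    hydraulic_diameter = 2.0 * w * h / (w + h)
    reynolds = flow.density * velocity * hydraulic_diameter / flow.viscosity
    return _result(tau, reynolds)


Geometry = Union[TubeGeometry, ChamberGeometry]


def flow_rate_for_fss(
    geom: Geometry, target_tau: float, viscosity: float = DEFAULT_VISCOSITY
) -> float:
    """Volumetric flow rate (m^3/s) producing ``target_tau`` (Pa).

    Algebraic inverse of the corresponding wall-shear formula; the
    round trip through :func:`fss_capillary` / :func:`fss_ppfc`
    recovers ``target_tau`` to machine precision.
    """
    if target_tau < 0:
        raise InvalidGeometryError(f"target_tau must be >= 0, got {target_tau!r}")
    _require_positive("viscosity", viscosity)
    if isinstance(geom, TubeGeometry):
        return target_tau * math.pi * geom.inner_diameter**3 / (32.0 * viscosity)
    if isinstance(geom, ChamberGeometry):
        return target_tau * geom.width * geom.height**2 / (6.0 * viscosity)
    raise TypeError(f"unsupported geometry kind: {type(geom).__name__}")
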
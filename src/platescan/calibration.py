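"""Four-corner stage calibration.

The plate holder and the stage axes are never mechanically aligned to
tens of micrometres; instead the operator drives the stage until the
drop in each corner well is centered and in focus and records the
machine coordinate there.  The top-left corner is zeroed first, so its
coordinate is (0, 0, 0) by construction.

From the four corner coordinates each axis gets a tensor-product linear
(bilinear) surface

    f(u, v) = k0 + k1*u + k2*v + k3*u*v

over the normalized grid fractions (u, v) of the plate.  Three corners
would define a plane, but a plane cannot follow the nonlinear shifts of
an inexpensive stage, which push samples out of focus; the u*v warp
term is the minimal curved correction exactly determined by the fourth
corner.  :func:`planar_fit` keeps the three-point plane available for
diagnostics so the size of that correction can be inspected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from platescan.plate_geometry import GridFraction

__all__ = [
    "CornerSet",
    "BilinearMap",
    "MachineCoord",
    "TravelLimits",
    "fit_corners",
    "planar_fit",
    "predict",
    "planar_residual",
]

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class MachineCoord:
    """Absolute machine coordinate in mm, origin at the zeroed well A1."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for a in _AXES:
            if not math.isfinite(getattr(self, a)):
                raise ValueError("machine coordinates must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class TravelLimits:
    """Soft travel limits in mm; exceeding them only warns.

    Driving the stage past its mechanical limits makes a grinding noise
    but causes no serious damage, so the limits are advisory.
    """

    x: tuple[float, float] = (-5.0, 160.0)
    y: tuple[float, float] = (-110.0, 5.0)
    z: tuple[float, float] = (-10.0, 10.0)

    def check(self, coord: MachineCoord) -> bool:
        ok = True
        for a in _AXES:
            lo, hi = getattr(self, a)
            val = getattr(coord, a)
            if not (lo <= val <= hi):
                warnings.warn(
                    f"{a}={val:.3f} mm outside soft travel limits [{lo}, {hi}]",
                    stacklevel=3,
                )
                ok = False
        return ok


def _as_coord(c) -> MachineCoord:
    if isinstance(c, MachineCoord):
        return c
    return MachineCoord(*c)


@dataclass(frozen=True)
class CornerSet:
    """Measured machine coordinates of the four corner wells.

    ``c00`` is the well at grid fraction (0, 0) — the top-left drop,
    zeroed during setup — ``c10`` at (1, 0) (top-right), ``c01`` at
    (0, 1) (bottom-left) and ``c11`` at (1, 1) (bottom-right).
    """

    c10: MachineCoord
    c01: MachineCoord
    c11: MachineCoord
    c00: MachineCoord = field(default_factory=lambda: MachineCoord(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "c00", _as_coord(self.c00))
        object.__setattr__(self, "c10", _as_coord(self.c10))
        object.__setattr__(self, "c01", _as_coord(self.c01))
        object.__setattr__(self, "c11", _as_coord(self.c11))
        if self.c00.as_tuple() != (0.0, 0.0, 0.0):
            warnings.warn(
                "c00 is not (0, 0, 0); the zeroing step normally fixes the "
                "top-left drop at the machine origin",
                stacklevel=3,
            )
        if self.xy_area() <= 0.0:
            raise ValueError(
                "corner xy positions are degenerate (zero-area quadrilateral); "
                "re-measure the corner drops"
            )

    def corners(self) -> tuple[MachineCoord, MachineCoord, MachineCoord, MachineCoord]:
        return (self.c00, self.c10, self.c01, self.c11)

    def xy_area(self) -> float:
        """Shoelace area of the corner quadrilateral c00-c10-c11-c01."""
        pts = [(c.x, c.y) for c in (self.c00, self.c10, self.c11, self.c01)]
        area = 0.0
        for (x0, y0), (x1, y1) in zip(pts, pts[1:] + pts[:1]):
            area += x0 * y1 - x1 * y0
        return abs(area) / 2.0


@dataclass(frozen=True)
class BilinearMap:
    """Per-axis coefficients of f(u, v) = k0 + k1*u + k2*v + k3*u*v (mm).

    ``coeffs[axis] = (k0, k1, k2, k3)`` for axis in 'x', 'y', 'z'.  The
    map interpolates the four measured corners exactly; k3 is the warp
    term, zero iff the corners are coplanar on that axis.
    """

    coeffs: dict[str, tuple[float, float, float, float]]
    limits: TravelLimits = field(default_factory=TravelLimits)

    def axis(self, a: str) -> tuple[float, float, float, float]:
        return self.coeffs[a]

    @property
    def warp(self) -> MachineCoord:
        """The k3 coefficient per axis — the size of the curved correction."""
        return MachineCoord(*(self.coeffs[a][3] for a in _AXES))

    def __call__(self, g: GridFraction) -> MachineCoord:
        return predict(self, g)


def fit_corners(corners: CornerSet, limits: TravelLimits | None = None) -> BilinearMap:
    """Fit the bilinear surface through all four corner coordinates.

    Closed form per axis: k0 = c00, k1 = c10 - c00, k2 = c01 - c00,
    k3 = c11 - c10 - c01 + c00.  The returned map reproduces every
    corner to machine epsilon.
    """
    coeffs = {}
    for a in _AXES:
        c00, c10, c01, c11 = (getattr(c, a) for c in corners.corners())
        coeffs[a] = (c00, c10 - c00, c01 - c00, c11 - c10 - c01 + c00)
    return BilinearMap(coeffs=coeffs, limits=limits or TravelLimits())


def planar_fit(corners: CornerSet, limits: TravelLimits | None = None) -> BilinearMap:
    """Plane through c00, c10, c01, expressed as a BilinearMap with k3 = 0.

    Ignores the fourth corner; provided for comparison and diagnostics
    only.  On a warped plate its error grows as k3*u*v, reaching |k3|
    per axis at the far corner well (and |k3|/4 at plate center).
    """
    coeffs = {}
    for a in _AXES:
        c00, c10, c01, _ = (getattr(c, a) for c in corners.corners())
        coeffs[a] = (c00, c10 - c00, c01 - c00, 0.0)
    return BilinearMap(coeffs=coeffs, limits=limits or TravelLimits())


def predict(bmap: BilinearMap, g: GridFraction, check_limits: bool = False) -> MachineCoord:
    """Machine coordinate of the well at grid fraction (u, v)."""
    if not (0.0 <= g.u <= 1.0 and 0.0 <= g.v <= 1.0):
        raise ValueError(f"grid fraction ({g.u}, {g.v}) outside [0, 1]^2")
    vals = []
    for a in _AXES:
        k0, k1, k2, k3 = bmap.coeffs[a]
        vals.append(k0 + k1 * g.u + k2 * g.v + k3 * g.u * g.v)
    coord = MachineCoord(*vals)
    if check_limits:
        bmap.limits.check(coord)
    return coord


def planar_residual(corners: CornerSet, focus_tolerance: float = 0.15) -> dict:
    """Diagnostic: how badly the three-point plane misses the fourth corner.

    Returns the per-axis residual at c11 (equal to the bilinear k3 —
    also the worst-well planar error, attained at the far corner), the
    plate-center planar error |k3|/4, and whether the z residual exceeds
    the focus tolerance (mm) — i.e. whether ignoring the curved
    correction would push wells out of focus.
    """
    warp = fit_corners(corners).warp
    report = {
        "residual_at_c11": {a: getattr(warp, a) for a in _AXES},
        "worst_well_error": {a: abs(getattr(warp, a)) for a in _AXES},
        "center_error": {a: abs(getattr(warp, a)) / 4.0 for a in _AXES},
        "focus_tolerance_mm": focus_tolerance,
        "z_exceeds_focus_tolerance": abs(warp.z) > focus_tolerance,
    }
    return report
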
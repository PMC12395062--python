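"""Magnetic field maps, pseudo-current-density maps and pole geometry.

One time-slice of the averaged beat gives 36 field values on the sensor
grid.  These are interpolated to a fine lattice (the magnetic field map,
MFM), transformed into a pseudo-current-density map (CDM) via the
Hosaka-Cohen construction

    c = (dBz/dy, -dBz/dx),

whose vectors run parallel to the underlying tangential current, and reduced
to pole geometry: extremum positions, half-maximum pole areas, sub-pole
(multipolarity) counts, the pole-to-pole distance D, the magnetic field
angle MA (orientation of the negative-to-positive pole axis) and the current
angle CA (orientation of the strongest pseudo-current vector).

For an ideal tangential current dipole the pole axis is orthogonal to the
current, so MA = CA + 90 deg; both angles therefore track the dipole
orientation and rotate together through the TT segment.

Angles are measured counterclockwise from the +x axis (subject left) in
degrees, wrapped into (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .containers import SensorGrid, GRID_SIDE
from .exceptions import InvalidArgumentError, UndefinedAngleError

# 8-connectivity: diagonal lattice neighbours belong to the same pole region
_STRUCTURE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FieldMap:
    """Interpolated normal-field surface on a regular lattice.

    ``values[i, j]`` is the field (pT) at ``(x[j], y[i])`` cm.
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def cell_area(self) -> float:
        """Area of one lattice cell in cm^2."""
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))


@dataclass(frozen=True)
class CurrentMap:
    """Pseudo-current vectors (cx, cy) on the same lattice as its FieldMap."""

    cx: np.ndarray
    cy: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.cx, self.cy)


@dataclass(frozen=True)
class Pole:
    """One field-map extremum: position, value, half-maximum area, sub-poles."""

    position: tuple[float, float]
    value: float
    area: float
    n_subpoles: int


@dataclass(frozen=True)
class PoleSet:
    """Positive/negative pole geometry of one field map.

    Either pole is ``None`` when the map has no values of that sign; the
    pole distance D is only defined when both exist.
    """

    positive: Pole | None
    negative: Pole | None

    @property
    def distance(self) -> float:
        """Pole-to-pole distance D in cm (0 when a pole is absent)."""
        if self.positive is None or self.negative is None:
            return 0.0
        dp = np.subtract(self.positive.position, self.negative.position)
        return float(np.hypot(*dp))


@dataclass(frozen=True)
class AngleSet:
    """Magnetic field angle (MA) and current angle (CA), degrees."""

    ma: float
    ca: float


def _wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else float(wrapped)


def interpolate_field_map(
    channel_values: np.ndarray, grid: SensorGrid, resolution: float = 4.0
) -> FieldMap:
    """Bicubic-spline field map through the 36 sensor values.

    Parameters
    ----------
    channel_values : array of 36 field values (pT), grid row-major order.
    resolution : lattice density in points per cm.  The lattice covers the
        sensor extent inclusively: 4 points/cm on a 20 cm extent gives 81x81.
    """
    vals = np.asarray(channel_values, dtype=float)
    if vals.shape != (GRID_SIDE * GRID_SIDE,):
        raise InvalidArgumentError(f"expected 36 channel values, got {vals.shape}")
    if not np.all(np.isfinite(vals)):
        raise InvalidArgumentError("non-finite channel value")
    xs, ys = grid.x_coords, grid.y_coords
    spline = RectBivariateSpline(ys, xs, vals.reshape(GRID_SIDE, GRID_SIDE),
                                 kx=3, ky=3, s=0)
    n = int(round(grid.extent * resolution)) + 1
    x = np.linspace(xs[0], xs[-1], n)
    y = np.linspace(ys[0], ys[-1], n)
    return FieldMap(values=spline(y, x), x=x, y=y)


def pseudo_current_map(fm: FieldMap) -> CurrentMap:
    """Hosaka-Cohen pseudo-current transform c = (dBz/dy, -dBz/dx).

    Derivatives are central differences on the lattice (one-sided at the
    edges); a uniform map yields zero vectors everywhere.
    """
    d_dy, d_dx = np.gradient(fm.values, fm.y, fm.x)
    return CurrentMap(cx=d_dy, cy=-d_dx, x=fm.x, y=fm.y)


def _extract_one_pole(values: np.ndarray, fm: FieldMap, area_fraction: float,
                      sign: int) -> Pole | None:
    """Locate the extremum of one sign and its half-maximum region."""
    signed = sign * values
    peak = signed.max()
    if peak <= 0:
        return None
    mask = signed >= area_fraction * peak
    labels, n_regions = ndimage.label(mask, structure=_STRUCTURE)
    i, j = np.unravel_index(np.argmax(signed), signed.shape)
    region = labels == labels[i, j]
    return Pole(
        position=(float(fm.x[j]), float(fm.y[i])),
        value=float(sign * peak),
        area=float(region.sum() * fm.cell_area),
        n_subpoles=int(n_regions),
    )


def extract_poles(fm: FieldMap, area_fraction: float = 0.5) -> PoleSet:
    """Pole geometry of a field map at a relative threshold.

    The pole area is the area of the connected lattice region containing the
    extremum where the (same-sign) value exceeds ``area_fraction`` times the
    extremum; the sub-pole count is the number of disjoint same-sign regions
    at that threshold (2 or more signals a multipolar pattern).  As
    ``area_fraction`` approaches 1 the area shrinks toward a single lattice
    cell; areas are monotone nonincreasing in ``area_fraction``.
    """
    if not 0.0 < area_fraction <= 1.0:
        raise InvalidArgumentError("area_fraction must be in (0, 1]")
    return PoleSet(
        positive=_extract_one_pole(fm.values, fm, area_fraction, +1),
        negative=_extract_one_pole(fm.values, fm, area_fraction, -1),
    )


def magnetic_field_angle(ps: PoleSet) -> float:
    """MA: signed angle of the vector from the negative to the positive pole.

    Degrees counterclockwise from +x, in (-180, 180].  Requires both poles.
    """
    if ps.positive is None or ps.negative is None:
        raise UndefinedAngleError("both poles required for the magnetic field angle")
    dx = ps.positive.position[0] - ps.negative.position[0]
    dy = ps.positive.position[1] - ps.negative.position[1]
    return _wrap_angle(np.degrees(np.arctan2(dy, dx)))


def current_angle(cm: CurrentMap, eps: float = 1e-10) -> float:
    """CA: orientation of the pseudo-current vector of maximal magnitude.

    A map whose strongest vector is below ``eps`` (numerically zero, e.g.
    from a uniform field) has no defined direction.
    """
    mag = cm.magnitude
    if mag.max() <= eps:
        raise UndefinedAngleError("current angle undefined for an all-zero map")
    i, j = np.unravel_index(np.argmax(mag), mag.shape)
    return _wrap_angle(np.degrees(np.arctan2(cm.cy[i, j], cm.cx[i, j])))
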
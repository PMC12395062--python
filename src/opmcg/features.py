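"""TT-segment fiducials and the 65-parameter MCG feature family.

The repolarization interval from T-wave onset (Tb) to T-wave peak (Tp) — the
TT segment — is sampled at 11 equally spaced instants (step tau = (Tp -
Tb)/10, both ends inclusive).  At each instant the averaged beat is turned
into a field map, a pseudo-current map and pole geometry, giving per-instant
quantities: magnetic field angle MA, current angle CA, negative/positive
pole areas NPA/PPA, pole distance D, field amplitude MM and pseudo-current
amplitude CM, plus pole-point positions CPPP/CNPP and sub-pole counts.

The canonical 65-parameter vector aggregates these series with a fixed
grammar:

* 7 scalar TT series (MA, CA, NPA, PPA, D, MM, CM) x 5 aggregators
  {max, min, sum, range, ccmax} ............................ 35
* the same 7 series over the bp epoch (beat start to the estimated P-wave
  offset, R-peak - 120 ms) x {max, min, range}, suffix "bp" . 21
* pole-point displacement series (Euclidean change of CPPP / CNPP between
  consecutive TT samples) x {max, min, sum, range} .......... 8
* RoART, the ratio of field amplitudes at R-peak and T-peak .. 1

``ccmax`` is the maximum absolute change between consecutive samples; the
displacement aggregate CPPPPmax (maximum positive-pole-point displacement)
realizes "maximum change in position".  Angle aggregates use signed angles
by default (configurable to absolute values).

Parameter values for a patient are reported as post-minus-pre differences
(Delta parameters, column prefix "d"): the dynamic change induced by the
intervention, which is what predicts residual angina.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AveragedBeat, SensorGrid
from .exceptions import FiducialError, InvalidArgumentError
from .mapping import (
    current_angle,
    extract_poles,
    interpolate_field_map,
    magnetic_field_angle,
    pseudo_current_map,
)

_SCALAR_BASES = ("MA", "CA", "NPA", "PPA", "D", "MM", "CM")
_TT_AGGS = ("max", "min", "sum", "range", "ccmax")
_BP_AGGS = ("max", "min", "range")
_DISP_BASES = ("CPPPP", "CNPPP")
_DISP_AGGS = ("max", "min", "sum", "range")


def _build_parameter_names() -> tuple[str, ...]:
    names = [f"{b}{a}" for b in _SCALAR_BASES for a in _TT_AGGS]
    names += [f"{b}{a}bp" for b in _SCALAR_BASES for a in _BP_AGGS]
    names += [f"{b}{a}" for b in _DISP_BASES for a in _DISP_AGGS]
    names.append("RoART")
    return tuple(names)


#: Frozen canonical ordering of the 65 parameters.
PARAMETER_NAMES: tuple[str, ...] = _build_parameter_names()

#: Delta-parameter (post minus pre) column names, canonical order.
DELTA_NAMES: tuple[str, ...] = tuple("d" + n for n in PARAMETER_NAMES)

assert len(PARAMETER_NAMES) == 65

#: Correlation families used by the synthetic feature-table generator: all
#: aggregates of one base quantity are mutually correlated in real data.
PARAMETER_FAMILIES: dict[str, tuple[str, ...]] = {
    base: tuple(n for n in PARAMETER_NAMES
                if n.startswith(base) and not n.startswith(base + "P"))
    for base in _SCALAR_BASES + _DISP_BASES
}
PARAMETER_FAMILIES["RoART"] = ("RoART",)


@dataclass(frozen=True)
class Fiducials:
    """Beat fiducials in ms relative to the R-peak: Rp < Tb < Tp."""

    rp: float
    tb: float
    tp: float

    def __post_init__(self) -> None:
        if not (self.rp < self.tb < self.tp):
            raise FiducialError(
                f"fiducials must satisfy Rp < Tb < Tp, got {self.rp}, {self.tb}, {self.tp}"
            )

    @property
    def tau(self) -> float:
        """One tenth of the TT-segment duration, ms."""
        return (self.tp - self.tb) / 10.0


def locate_fiducials(
    beat: AveragedBeat,
    t_search_ms: tuple[float, float] = (150.0, 450.0),
    onset_fraction: float = 0.10,
    baseline_ms: float = 80.0,
) -> Fiducials:
    """Locate Rp, Tb and Tp on the cross-channel RMS trace.

    Rp is the RMS maximum of the window; Tp the RMS maximum inside the
    ``t_search_ms`` post-R window; Tb the last instant before Tp where the
    RMS falls below baseline + ``onset_fraction`` x (Tp RMS - baseline).
    The baseline is the mean RMS over the first ``baseline_ms`` of the
    window.

    Raises
    ------
    FiducialError
        If the search window holds no T-wave (flat TT segment) or no onset
        crossing exists between R and T.
    """
    rms = beat.rms
    t = beat.offsets_ms
    rp_idx = int(np.argmax(rms))
    rp = float(t[rp_idx])

    baseline = float(np.mean(rms[t <= t[0] + baseline_ms]))
    in_window = (t >= rp + t_search_ms[0]) & (t <= rp + t_search_ms[1])
    if not np.any(in_window):
        raise FiducialError("T-peak search window outside the beat window")
    tp_idx = int(np.flatnonzero(in_window)[np.argmax(rms[in_window])])
    tp = float(t[tp_idx])
    t_height = rms[tp_idx] - baseline
    if t_height <= 0.01 * (rms[rp_idx] - baseline) or t_height <= 0:
        raise FiducialError("no T-wave candidate: flat TT segment")

    thresh = baseline + onset_fraction * t_height
    between = np.arange(rp_idx + 1, tp_idx)
    below = between[rms[between] < thresh]
    if below.size == 0:
        raise FiducialError("no T-onset crossing between R-peak and T-peak")
    tb = float(t[below[-1]])
    return Fiducials(rp=rp, tb=tb, tp=tp)


def tt_sample_times(f: Fiducials) -> np.ndarray:
    """The 11 TT-segment sampling instants Tb, Tb+tau, ..., Tp (ms)."""
    if not f.tp > f.tb:
        raise InvalidArgumentError("degenerate TT segment (Tb == Tp)")
    return np.linspace(f.tb, f.tp, 11)


@dataclass(frozen=True)
class TimepointQuantities:
    """Map-derived quantities at one instant of the averaged beat.

    Angles and pole positions are NaN when the corresponding pole (or a
    nonzero map) does not exist at that instant.
    """

    t_ms: float
    ma: float
    ca: float
    npa: float
    ppa: float
    cppp: tuple[float, float]
    cnpp: tuple[float, float]
    d: float
    mm: float
    cm: float
    n_pos_subpoles: int
    n_neg_subpoles: int


def timepoint_quantities(
    beat: AveragedBeat,
    grid: SensorGrid,
    t_ms: float,
    resolution: float = 4.0,
    area_fraction: float = 0.5,
    amplitude: str = "absmax",
) -> TimepointQuantities:
    """Field map -> current map -> pole geometry at one beat instant.

    ``amplitude`` selects the field/current amplitude definition: "absmax"
    (maximum absolute value over the map, default) or "ptp" (maximum minus
    minimum).
    """
    if amplitude not in ("absmax", "ptp"):
        raise InvalidArgumentError(f"unknown amplitude definition {amplitude!r}")
    values = beat.at_offset(t_ms)
    fm = interpolate_field_map(values, grid, resolution=resolution)
    cmap = pseudo_current_map(fm)
    ps = extract_poles(fm, area_fraction=area_fraction)

    if amplitude == "absmax":
        mm = float(np.abs(fm.values).max())
    else:
        mm = float(fm.values.max() - fm.values.min())
    cm_amp = float(cmap.magnitude.max())

    nan2 = (np.nan, np.nan)
    has_both = ps.positive is not None and ps.negative is not None
    ma = magnetic_field_angle(ps) if has_both else np.nan
    ca = current_angle(cmap) if cm_amp > 1e-10 else np.nan
    return TimepointQuantities(
        t_ms=float(t_ms),
        ma=ma,
        ca=ca,
        npa=ps.negative.area if ps.negative else 0.0,
        ppa=ps.positive.area if ps.positive else 0.0,
        cppp=ps.positive.position if ps.positive else nan2,
        cnpp=ps.negative.position if ps.negative else nan2,
        d=ps.distance,
        mm=mm,
        cm=cm_amp,
        n_pos_subpoles=ps.positive.n_subpoles if ps.positive else 0,
        n_neg_subpoles=ps.negative.n_subpoles if ps.negative else 0,
    )


class ParameterVector:
    """The 65 named scalar parameters of one scan, canonical order."""

    __slots__ = ("data",)

    def __init__(self, data: pd.Series):
        if tuple(data.index) != PARAMETER_NAMES:
            raise InvalidArgumentError("parameter names/order do not match manifest")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("parameter vector contains non-finite values")
        self.data = data.astype(float)

    def __getitem__(self, name: str) -> float:
        return float(self.data[name])

    def __len__(self) -> int:
        return len(self.data)

    def to_series(self) -> pd.Series:
        return self.data.copy()


class DeltaVector:
    """Post-minus-pre differences of the 65 parameters ("d" prefix)."""

    __slots__ = ("data",)

    def __init__(self, data: pd.Series):
        if tuple(data.index) != DELTA_NAMES:
            raise InvalidArgumentError("delta names/order do not match manifest")
        self.data = data.astype(float)

    def __getitem__(self, name: str) -> float:
        return float(self.data[name])

    def __len__(self) -> int:
        return len(self.data)

    def to_series(self) -> pd.Series:
        return self.data.copy()


def _agg_scalar(series: np.ndarray, agg: str) -> float:
    """NaN-tolerant aggregation; an all-NaN series aggregates to 0."""
    s = np.asarray(series, dtype=float)
    valid = s[np.isfinite(s)]
    if valid.size == 0:
        return 0.0
    if agg == "max":
        return float(valid.max())
    if agg == "min":
        return float(valid.min())
    if agg == "sum":
        return float(valid.sum())
    if agg == "range":
        return float(valid.max() - valid.min())
    if agg == "ccmax":
        # max absolute change over consecutive finite pairs
        finite = np.isfinite(s)
        pair = finite[:-1] & finite[1:]
        if not np.any(pair):
            return 0.0
        return float(np.abs(np.diff(s))[pair].max())
    raise InvalidArgumentError(f"unknown aggregator {agg!r}")


def _displacements(points: np.ndarray) -> np.ndarray:
    """Euclidean displacement between consecutive (x, y) points; NaN-gapped."""
    d = np.hypot(np.diff(points[:, 0]), np.diff(points[:, 1]))
    return d


def compute_parameters(
    beat: AveragedBeat,
    grid: SensorGrid,
    fiducials: Fiducials,
    resolution: float = 4.0,
    area_fraction: float = 0.5,
    amplitude: str = "absmax",
    signed_angles: bool = True,
    bp_gap_ms: float = 120.0,
) -> ParameterVector:
    """Evaluate the full 65-parameter vector for one averaged beat.

    The TT segment is sampled at the 11 tau-spaced instants; the bp epoch
    (beat-window start to the estimated P-wave offset, Rp - ``bp_gap_ms``)
    at 11 evenly spaced instants.  RoART is the field amplitude at the
    R-peak divided by the field amplitude at the T-peak.

    With ``signed_angles=False`` the MA/CA series are aggregated on absolute
    values instead of signed ones.
    """
    tt_times = tt_sample_times(fiducials)
    bp_end = fiducials.rp - bp_gap_ms
    bp_start = float(beat.offsets_ms[0])
    if bp_end <= bp_start:
        raise FiducialError("bp epoch empty: window too short before the R-peak")
    bp_times = np.linspace(bp_start, bp_end, 11)

    def quantify(times: np.ndarray) -> list[TimepointQuantities]:
        return [
            timepoint_quantities(beat, grid, t, resolution=resolution,
                                 area_fraction=area_fraction, amplitude=amplitude)
            for t in times
        ]

    tt = quantify(tt_times)
    bp = quantify(bp_times)

    def series(tqs: list[TimepointQuantities], base: str) -> np.ndarray:
        attr = base.lower()
        vals = np.array([getattr(q, attr) for q in tqs], dtype=float)
        if base in ("MA", "CA") and not signed_angles:
            vals = np.abs(vals)
        return vals

    out: dict[str, float] = {}
    for base in _SCALAR_BASES:
        s = series(tt, base)
        for agg in _TT_AGGS:
            out[f"{base}{agg}"] = _agg_scalar(s, agg)
    for base in _SCALAR_BASES:
        s = series(bp, base)
        for agg in _BP_AGGS:
            out[f"{base}{agg}bp"] = _agg_scalar(s, agg)

    for name, attr in (("CPPPP", "cppp"), ("CNPPP", "cnpp")):
        pts = np.array([getattr(q, attr) for q in tt], dtype=float)
        disp = _displacements(pts)
        for agg in _DISP_AGGS:
            out[f"{name}{agg}"] = _agg_scalar(disp, agg)

    rp_q = timepoint_quantities(beat, grid, fiducials.rp, resolution=resolution,
                                area_fraction=area_fraction, amplitude=amplitude)
    tp_q = tt[-1]
    if tp_q.mm <= 0:
        raise FiducialError("zero T-peak field amplitude: RoART undefined")
    out["RoART"] = rp_q.mm / tp_q.mm

    return ParameterVector(pd.Series(out, dtype=float).reindex(list(PARAMETER_NAMES)))


def delta_parameters(pre: ParameterVector, post: ParameterVector) -> DeltaVector:
    """Elementwise post-minus-pre differences (the Delta parameters)."""
    if tuple(pre.data.index) != tuple(post.data.index):
        raise InvalidArgumentError("pre/post parameter name mismatch")
    diff = post.data.to_numpy() - pre.data.to_numpy()
    return DeltaVector(pd.Series(diff, index=list(DELTA_NAMES), dtype=float))
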
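"""Core data containers shared across the pipeline.

A 36-channel optically-pumped-magnetometer (OPM) magnetocardiograph samples
the normal (out-of-chest) component of the cardiac magnetic field on a 6 x 6
sensor grid.  The containers here carry the raw multichannel recording, the
sensor geometry, and the ensemble-averaged cardiac cycle (the
butterfly-diagram matrix) that all spatial mapping is computed from.

Coordinate convention (fixed throughout the package): x increases toward the
subject's left, y toward the head, both in cm on the chest plane; the sensor
plane sits ``height`` cm above the equivalent current sources.  Field values
are in pT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidArgumentError

N_CHANNELS = 36
GRID_SIDE = 6


@dataclass(frozen=True)
class SensorGrid:
    """6 x 6 planar sensor array over the chest.

    Parameters
    ----------
    positions : ndarray, shape (36, 2)
        Sensor (x, y) coordinates in cm, row-major: the first six entries are
        the lowest-y row scanned in increasing x, and so on upward.
    spacing : float
        Nearest-neighbour sensor distance in cm.
    height : float
        Height of the sensor plane above the equivalent sources, cm.
    """

    positions: np.ndarray
    spacing: float
    height: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (N_CHANNELS, 2):
            raise InvalidArgumentError(
                f"expected {N_CHANNELS} (x, y) positions, got shape {pos.shape}"
            )
        object.__setattr__(self, "positions", pos)
        if not self.spacing > 0:
            raise InvalidArgumentError("spacing must be positive")
        # row-major 6x6 lattice: nearest-neighbour distance == spacing
        d = np.linalg.norm(pos[1] - pos[0])
        if abs(d - self.spacing) > 1e-9:
            raise InvalidArgumentError("positions do not match stated spacing")

    @property
    def x_coords(self) -> np.ndarray:
        """Unique, sorted x coordinates of the 6 columns."""
        return np.unique(np.round(self.positions[:, 0], 9))

    @property
    def y_coords(self) -> np.ndarray:
        """Unique, sorted y coordinates of the 6 rows."""
        return np.unique(np.round(self.positions[:, 1], 9))

    @property
    def extent(self) -> float:
        """Side length of the square sensor array in cm."""
        return float(self.spacing * (GRID_SIDE - 1))

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "spacing": self.spacing,
            "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorGrid":
        return cls(np.asarray(d["positions"], float), d["spacing"], d["height"])


def make_sensor_grid(spacing: float = 4.0, height: float = 5.0) -> SensorGrid:
    """Build the standard 6 x 6 sensor grid centred on the origin.

    Row-major ordering: channel ``6 * i + j`` sits at row i (y), column j (x),
    with both axes running from negative to positive.  A 4-cm spacing gives a
    20 cm x 20 cm array.

    Raises
    ------
    InvalidArgumentError
        If ``spacing`` is not positive.
    """
    if not spacing > 0:
        raise InvalidArgumentError("spacing must be positive")
    half = spacing * (GRID_SIDE - 1) / 2.0
    coords = np.linspace(-half, half, GRID_SIDE)
    xx, yy = np.meshgrid(coords, coords)  # row-major over y then x
    positions = np.column_stack([xx.ravel(), yy.ravel()])
    return SensorGrid(positions=positions, spacing=float(spacing), height=float(height))


@dataclass
class RawRecording:
    """Multichannel MCG recording: channels x samples field values in pT."""

    data: np.ndarray
    fs: float
    grid: SensorGrid
    quality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise InvalidArgumentError(
                f"data must be ({N_CHANNELS}, n_samples), got {self.data.shape}"
            )
        if not self.fs > 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def save(self, path: str | Path) -> None:
        """Write the recording as CSV (channels x samples) + JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.data, delimiter=",")
        sidecar = {"fs": self.fs, "grid": self.grid.to_dict(), "units": "pT",
                   "quality": self.quality}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "RawRecording":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data=data, fs=meta["fs"], grid=SensorGrid.from_dict(meta["grid"]),
                   quality=meta.get("quality", {}))


@dataclass
class AveragedBeat:
    """Ensemble-averaged cardiac cycle, channels x window samples.

    ``offsets_ms`` gives each column's latency relative to the R-peak, so the
    R-peak sample itself (offset 0) is always inside the window.  The matrix
    is the butterfly-diagram data: overplotting its rows shows the temporal
    course of the field across all channels.
    """

    data: np.ndarray
    fs: float
    n_beats_used: int
    n_beats_rejected: int
    offsets_ms: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offsets_ms = np.asarray(self.offsets_ms, dtype=float)
        if self.data.shape != (N_CHANNELS, self.offsets_ms.size):
            raise InvalidArgumentError("data / offsets shape mismatch")
        if not (self.offsets_ms[0] <= 0.0 <= self.offsets_ms[-1]):
            raise InvalidArgumentError("window must contain the R-peak")

    @property
    def rms(self) -> np.ndarray:
        """Cross-channel root-mean-square trace (one value per sample)."""
        return np.sqrt(np.mean(self.data ** 2, axis=0))

    def at_offset(self, offset_ms: float) -> np.ndarray:
        """Channel values at a latency, linearly interpolated in time."""
        if not (self.offsets_ms[0] <= offset_ms <= self.offsets_ms[-1]):
            raise InvalidArgumentError(
                f"offset {offset_ms} ms outside beat window "
                f"[{self.offsets_ms[0]}, {self.offsets_ms[-1]}]"
            )
        out = np.empty(N_CHANNELS)
        for ch in range(N_CHANNELS):
            out[ch] = np.interp(offset_ms, self.offsets_ms, self.data[ch])
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.data, delimiter=",")
        sidecar = {"fs": self.fs, "n_beats_used": self.n_beats_used,
                   "n_beats_rejected": self.n_beats_rejected,
                   "offsets_ms": self.offsets_ms.tolist()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "AveragedBeat":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data=data, fs=meta["fs"], n_beats_used=meta["n_beats_used"],
                   n_beats_rejected=meta["n_beats_rejected"],
                   offsets_ms=np.asarray(meta["offsets_ms"]))
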
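"""Electrode montages, recordings, and the on-disk container.

The recording hardware is three 8x8 surface-electrode arrays (10-mm pitch)
wrapped around the forearm, giving 192 monopolar channels laid out on a
combined 8x24 grid.  :class:`MontageLayout` is the bijection between channel
indices and grid positions; :class:`EmgRecording` couples a time-major signal
matrix with its sampling rate, montage, and labelled gesture intervals.

On disk a recording is a directory holding a time-major float32 little-endian
binary (``signals.f32``) or a delimited text file (``signals.csv``) next to a
``meta.json`` sidecar with the sampling rate, channel count, montage spec,
label intervals and excluded channels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MontageLayout",
    "EmgRecording",
    "TrialSet",
    "default_montage",
    "load_recording",
    "write_recording",
]

#: canonical gesture identifiers; M10 is the rest state
GESTURES = tuple(f"M{i}" for i in range(1, 11))
REST_ID = "M10"


class FormatError(ValueError):
    """A container on disk is missing pieces or malformed."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


@dataclass(frozen=True)
class MontageLayout:
    """Bijection between channel indices and (row, col) grid positions.

    Parameters
    ----------
    n_rows, n_cols
        Grid extent. The canonical forearm montage is 8 x 24.
    channel_map
        ``(n_channels, 2)`` integer array; row ``c`` holds the (row, col)
        position of channel ``c``.
    array_count
        Number of physical electrode arrays placed side by side.
    circular
        Whether column ``n_cols - 1`` is spatially adjacent to column 0
        (the arrays wrap around the forearm). Off by default: the original
        montage is treated as a flat grid.
    """

    n_rows: int
    n_cols: int
    channel_map: np.ndarray
    array_count: int = 1
    circular: bool = False

    def __post_init__(self) -> None:
        cm = np.asarray(self.channel_map, dtype=np.intp)
        if cm.ndim != 2 or cm.shape[1] != 2:
            raise ValidationError("channel_map must have shape (n_channels, 2)")
        if cm.shape[0] != self.n_rows * self.n_cols:
            raise ValidationError(
                f"channel_map covers {cm.shape[0]} positions, grid has "
                f"{self.n_rows * self.n_cols}"
            )
        if cm[:, 0].min() < 0 or cm[:, 0].max() >= self.n_rows:
            raise ValidationError("row index out of range")
        if cm[:, 1].min() < 0 or cm[:, 1].max() >= self.n_cols:
            raise ValidationError("column index out of range")
        flat = cm[:, 0] * self.n_cols + cm[:, 1]
        if len(np.unique(flat)) != len(flat):
            raise ValidationError("channel_map is not a bijection")
        object.__setattr__(self, "channel_map", cm)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def grid_index(self) -> np.ndarray:
        """``(n_rows, n_cols)`` array mapping grid position to channel index."""
        out = np.empty((self.n_rows, self.n_cols), dtype=np.intp)
        out[self.channel_map[:, 0], self.channel_map[:, 1]] = np.arange(
            self.n_channels
        )
        return out

    def channel_to_grid(self, channel: int) -> tuple[int, int]:
        r, c = self.channel_map[channel]
        return int(r), int(c)

    def grid_to_channel(self, row: int, col: int) -> int:
        return int(self.grid_index[row, col])

    @classmethod
    def regular_grid(cls, n_rows: int, n_cols: int, circular: bool = False
                     ) -> "MontageLayout":
        """Row-major layout for arbitrary grid sizes (tests, small rigs)."""
        rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
        return cls(n_rows, n_cols, np.column_stack([rows, cols]),
                   array_count=1, circular=circular)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "array_count": self.array_count,
            "circular": self.circular,
            "channel_map": self.channel_map.tolist(),
        }

    @classmethod
    def from_dict(cls, spec) -> "MontageLayout":
        if isinstance(spec, str):
            if spec == "default192":
                return default_montage()
            raise FormatError(f"unknown montage spec {spec!r}")
        return cls(
            n_rows=int(spec["n_rows"]),
            n_cols=int(spec["n_cols"]),
            channel_map=np.asarray(spec["channel_map"], dtype=np.intp),
            array_count=int(spec.get("array_count", 1)),
            circular=bool(spec.get("circular", False)),
        )


def default_montage(circular: bool = False) -> MontageLayout:
    """The canonical 192-channel forearm montage.

    Three 8x8 arrays sit side by side; array ``p`` contributes columns
    ``8p .. 8p+7``.  Within an array the channel index increases down each
    column: local channel ``k`` maps to row ``k % 8`` and local column
    ``k // 8``.  The hardware's internal numbering is not documented by the
    acquisition device in a portable way, so this convention is a default and
    can be overridden through the sidecar's montage spec.
    """
    n_rows, per_array, arrays = 8, 8, 3
    chan = np.arange(n_rows * per_array * arrays)
    p, k = np.divmod(chan, n_rows * per_array)
    rows = k % n_rows
    cols = per_array * p + k // n_rows
    return MontageLayout(
        n_rows=n_rows,
        n_cols=per_array * arrays,
        channel_map=np.column_stack([rows, cols]),
        array_count=arrays,
        circular=circular,
    )


@dataclass
class EmgRecording:
    """A multichannel surface-EMG recording with per-interval gesture labels.

    ``samples`` is time-major ``(n_samples, n_channels)``.  ``labels`` is a
    list of ``(start_s, end_s, gesture_id)`` half-open intervals; intervals
    must be non-overlapping and lie within the recording.
    """

    samples: np.ndarray
    fs: float
    montage: MontageLayout
    labels: list = field(default_factory=list)
    excluded_channels: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (time x channels)")
        if self.samples.shape[1] != self.montage.n_channels:
            raise ValidationError(
                f"recording has {self.samples.shape[1]} channels, montage "
                f"expects {self.montage.n_channels}"
            )
        self.labels = [(float(a), float(b), str(g)) for a, b, g in self.labels]
        dur = self.duration
        prev_end = -np.inf
        for a, b, _ in sorted(self.labels):
            if a < -1e-9 or b > dur + 1e-9 or b <= a:
                raise ValidationError(f"label interval ({a}, {b}) outside [0, {dur}]")
            if a < prev_end - 1e-9:
                raise ValidationError("label intervals overlap")
            prev_end = b
        self.excluded_channels = {int(c) for c in self.excluded_channels}
        if self.excluded_channels and (
            min(self.excluded_channels) < 0
            or max(self.excluded_channels) >= self.montage.n_channels
        ):
            raise ValidationError("excluded channel index out of range")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Copy of this recording with the signal matrix replaced."""
        return EmgRecording(samples, self.fs, self.montage,
                            list(self.labels), set(self.excluded_channels))

    def label_at(self, t: float) -> str | None:
        for a, b, g in self.labels:
            if a <= t < b:
                return g
        return None


@dataclass
class TrialSet:
    """An ordered collection of trials with calibration/train/test roles."""

    trials: list
    roles: list

    VALID_ROLES = ("calibration", "train", "test")

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.roles):
            raise ValidationError("one role per trial required")
        for r in self.roles:
            if r not in self.VALID_ROLES:
                raise ValidationError(f"unknown role {r!r}")

    @property
    def calibration_index(self) -> int:
        idx = [i for i, r in enumerate(self.roles) if r == "calibration"]
        if len(idx) != 1:
            raise ValidationError(
                f"exactly one calibration trial required, found {len(idx)}"
            )
        return idx[0]

    @property
    def calibration(self) -> EmgRecording:
        return self.trials[self.calibration_index]

    def non_calibration_indices(self) -> list:
        return [i for i, r in enumerate(self.roles) if r != "calibration"]


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------

_BIN_NAME = "signals.f32"
_CSV_NAME = "signals.csv"
_META_NAME = "meta.json"


def _resolve_container(path: str) -> tuple[str, str]:
    """Return (signal_path, meta_path) for a container path.

    ``path`` may name the directory, the sidecar, or the signal file itself.
    """
    if os.path.isdir(path):
        base = path
        for name in (_BIN_NAME, _CSV_NAME):
            if os.path.exists(os.path.join(base, name)):
                return os.path.join(base, name), os.path.join(base, _META_NAME)
        raise FormatError(f"no {_BIN_NAME} or {_CSV_NAME} in {path}")
    base = os.path.dirname(path) or "."
    if path.endswith(_META_NAME):
        return _resolve_container(base)
    return path, os.path.join(base, _META_NAME)


def load_recording(path: str) -> EmgRecording:
    """Read a recording container (binary or text dialect) and its sidecar."""
    sig_path, meta_path = _resolve_container(path)
    if not os.path.exists(meta_path):
        raise FormatError(f"missing sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    montage = MontageLayout.from_dict(meta["montage"])
    n_channels = int(meta["n_channels"])
    if n_channels != montage.n_channels:
        raise ValidationError(
            f"sidecar declares {n_channels} channels, montage has "
            f"{montage.n_channels}"
        )
    if sig_path.endswith(".csv"):
        samples = np.loadtxt(sig_path, delimiter=",", ndmin=2)
    else:
        flat = np.fromfile(sig_path, dtype="<f4")
        if flat.size % n_channels:
            raise ValidationError(
                f"{flat.size} values not divisible by {n_channels} channels"
            )
        samples = flat.reshape(-1, n_channels)
    if samples.shape[1] != n_channels:
        raise ValidationError(
            f"sidecar declares {n_channels} channels but "
            f"{samples.shape[1]} columns present"
        )
    return EmgRecording(
        samples=samples,
        fs=float(meta["fs"]),
        montage=montage,
        labels=[tuple(l) for l in meta.get("labels", [])],
        excluded_channels=set(meta.get("excluded_channels", [])),
    )


def write_recording(rec: EmgRecording, path: str, text: bool = False) -> None:
    """Write ``rec`` into directory ``path``; :func:`load_recording` inverts it.

    Binary output preserves float32 samples bit-for-bit.
    """
    os.makedirs(path, exist_ok=True)
    if text:
        np.savetxt(os.path.join(path, _CSV_NAME), rec.samples, delimiter=",")
        bin_path = os.path.join(path, _BIN_NAME)
        if os.path.exists(bin_path):  # avoid a stale second dialect
            os.remove(bin_path)
    else:
        rec.samples.astype("<f4").tofile(os.path.join(path, _BIN_NAME))
        csv_path = os.path.join(path, _CSV_NAME)
        if os.path.exists(csv_path):
            os.remove(csv_path)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "montage": rec.montage.to_dict(),
        "labels": [list(l) for l in rec.labels],
        "excluded_channels": sorted(rec.excluded_channels),
    }
    with open(os.path.join(path, _META_NAME), "w") as fh:
        json.dump(meta, fh)
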
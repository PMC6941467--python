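"""Grid surface-EMG recording container and file I/O.

A :class:`GridRecording` holds a multichannel surface-EMG signal recorded
with an electrode grid (typically 8x8 at 2048 Hz), always in microvolts,
together with the grid geometry.  Channels are identified by their original
integer index into the full grid (row-major); trimming or quality control
drops columns from ``signal`` but keeps the original ids in
``channel_positions`` so spatial context is never lost.

On-disk formats
---------------
* EDF (read-only, via MNE when available) — the standard biosignal exchange
  format.
* A documented plain-text "grid matrix" format (read/write, lossless):
  line 1 is a JSON header with sampling rate, grid shape, units and the
  channel-position map; every following line is one sample, tab-separated,
  one column per channel, printed with ``%.17g`` so a write/read round trip
  reproduces the float64 signal bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError, MetadataError

MATRIX_FORMAT_NAME = "fasciq-grid-matrix"
_UNIT_SCALE_TO_UV = {"uv": 1.0, "µv": 1.0, "microvolt": 1.0, "mv": 1000.0, "v": 1e6}


@dataclass
class GridRecording:
    """Multichannel grid EMG signal in microvolts.

    Parameters
    ----------
    signal
        Array of shape ``(n_samples, n_channels)``, amplitudes in μV.
        Column ``j`` corresponds to the j-th smallest key of
        ``channel_positions``.
    sampling_rate
        Samples per second per channel (Hz).
    grid_rows, grid_cols
        Electrode counts of the *original* grid.
    channel_positions
        Mapping original channel id -> (row, col). May be a partial map of
        the grid when channels have been trimmed or excluded.
    meta
        Free-form acquisition annotations.
    """

    signal: np.ndarray
    sampling_rate: float
    grid_rows: int
    grid_cols: int
    channel_positions: dict[int, tuple[int, int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise DataError("signal must be a 2-D (samples x channels) array")
        if self.signal.shape[0] == 0 or self.signal.shape[1] == 0:
            raise DataError("signal must contain at least one sample and one channel")
        if self.sampling_rate <= 0:
            raise MetadataError("sampling_rate must be positive")
        if len(self.channel_positions) != self.signal.shape[1]:
            raise DataError(
                f"channel_positions has {len(self.channel_positions)} entries "
                f"for {self.signal.shape[1]} signal columns"
            )
        bad = ~np.isfinite(self.signal)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(f"non-finite amplitude at sample {i}, channel column {j}")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_ids(self) -> list[int]:
        """Original grid channel ids, in signal-column order."""
        return sorted(self.channel_positions)

    def column_of(self, channel_id: int) -> int:
        return self.channel_ids.index(channel_id)

    def channel_signal(self, channel_id: int) -> np.ndarray:
        return self.signal[:, self.column_of(channel_id)]

    def with_signal(self, signal: np.ndarray) -> "GridRecording":
        """Copy of this recording with a replaced (same-shape) signal."""
        return GridRecording(
            signal=signal,
            sampling_rate=self.sampling_rate,
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            channel_positions=dict(self.channel_positions),
            meta=dict(self.meta),
        )

    def select_channels(self, channel_ids) -> "GridRecording":
        """Restrict to a subset of channels, preserving original ids."""
        keep = sorted(channel_ids)
        missing = [c for c in keep if c not in self.channel_positions]
        if missing:
            raise DataError(f"unknown channel ids {missing}")
        cols = [self.column_of(c) for c in keep]
        return GridRecording(
            signal=self.signal[:, cols],
            sampling_rate=self.sampling_rate,
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            channel_positions={c: self.channel_positions[c] for c in keep},
            meta=dict(self.meta),
        )


def default_grid_positions(rows: int, cols: int) -> dict[int, tuple[int, int]]:
    """Row-major channel-id -> (row, col) map for a full grid."""
    return {r * cols + c: (r, c) for r in range(rows) for c in range(cols)}


# ---------------------------------------------------------------------------
# matrix format
# ---------------------------------------------------------------------------

def write_recording(recording: GridRecording, path, format: str = "matrix") -> None:
    """Write a recording to disk.

    Only the plain-text grid-matrix format is supported for writing; it is
    lossless for float64 amplitudes.
    """
    if format != "matrix":
        raise FormatError(f"unsupported write format {format!r} (only 'matrix')")
    path = Path(path)
    header = {
        "format": MATRIX_FORMAT_NAME,
        "version": 1,
        "sampling_rate_hz": recording.sampling_rate,
        "grid_rows": recording.grid_rows,
        "grid_cols": recording.grid_cols,
        "units": "uV",
        "channel_positions": {
            str(cid): list(pos) for cid, pos in sorted(recording.channel_positions.items())
        },
        "meta": _json_safe(recording.meta),
    }
    try:
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, recording.signal, fmt="%.17g", delimiter="\t")
    except OSError as exc:
        raise DataError(f"could not write {path}: {exc}") from exc


def read_recording(path, format_hint: str | None = None) -> GridRecording:
    """Read a recording from EDF or the grid-matrix format.

    The format is sniffed from the first bytes unless ``format_hint``
    ("edf" or "matrix") is given.  Amplitudes are converted to μV using the
    units declared in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format_hint or _sniff_format(path)
    if fmt == "matrix":
        return _read_matrix(path)
    if fmt == "edf":
        return _read_edf(path)
    raise FormatError(f"unrecognised format for {path}")


def _sniff_format(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head.startswith(b"{"):
        return "matrix"
    if head.startswith(b"0       ") or path.suffix.lower() == ".edf":
        return "edf"
    return "unknown"


def _read_matrix(path: Path) -> GridRecording:
    with open(path) as fh:
        first = fh.readline()
        try:
            header = json.loads(first)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON header: {exc}")
        if header.get("format") != MATRIX_FORMAT_NAME:
            raise FormatError(f"{path}: not a {MATRIX_FORMAT_NAME} file")
        if "sampling_rate_hz" not in header:
            raise MetadataError(f"{path}: header lacks sampling_rate_hz")
        try:
            body = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed body: {exc}")
    units = str(header.get("units", "uV")).lower()
    if units not in _UNIT_SCALE_TO_UV:
        raise MetadataError(f"{path}: unknown units {units!r}")
    body = body * _UNIT_SCALE_TO_UV[units]
    bad = ~np.isfinite(body)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(f"{path}: non-finite sample at row {i}, column {j}")
    positions = {int(k): (int(v[0]), int(v[1])) for k, v in header["channel_positions"].items()}
    return GridRecording(
        signal=body,
        sampling_rate=float(header["sampling_rate_hz"]),
        grid_rows=int(header["grid_rows"]),
        grid_cols=int(header["grid_cols"]),
        channel_positions=positions,
        meta=dict(header.get("meta", {})),
    )


def _read_edf(path: Path) -> GridRecording:
    try:
        import mne
    except ImportError:  # pragma: no cover - mne is an optional extra
        raise FormatError("reading EDF requires the 'mne' package (install extra [edf])")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # MNE returns volts
    n_ch = data.shape[1]
    rows = cols = int(round(np.sqrt(n_ch)))
    if rows * cols != n_ch:
        rows, cols = 1, n_ch
    bad = ~np.isfinite(data)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(f"{path}: non-finite sample at row {i}, column {j}")
    return GridRecording(
        signal=data,
        sampling_rate=float(raw.info["sfreq"]),
        grid_rows=rows,
        grid_cols=cols,
        channel_positions=default_grid_positions(rows, cols),
        meta={"source": str(path), "channel_names": list(raw.ch_names)},
    )


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
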
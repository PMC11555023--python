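"""On-disk formats: raw tap streams, day records, JID matrices.

Raw tap streams are single-column CSV files of epoch-millisecond integers
with the header ``timestamp_ms`` — a minimal open stand-in for proprietary
touchscreen-logger exports.  JIDs are stored as plain-text matrices with a
``# key: value`` metadata header carrying the full grid definition, so a
stored matrix is never separated from the grid it lives on.

Readers repair recoverable problems loudly (out-of-order rows are sorted,
duplicate timestamps collapsed, both logged) and reject malformed input with
located error messages; nothing is coerced silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FormatError, ParseError
from .jid import JID, JIDGrid

logger = logging.getLogger(__name__)

TAPS_HEADER = "timestamp_ms"
_JID_MAGIC = "# tapjid-jid v1"


@dataclass
class TapStream:
    """Ordered touchscreen event timestamps for one subject.

    Timestamps are epoch milliseconds, strictly increasing after ingest
    (duplicates are collapsed on read).
    """

    timestamps: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        if self.timestamps.size and np.any(self.timestamps <= 0):
            raise DomainError("timestamps must be positive epoch milliseconds")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise DomainError("timestamps must be non-decreasing; use read_taps to repair")

    @property
    def n_events(self) -> int:
        return int(self.timestamps.size)

    def itis_seconds(self) -> np.ndarray:
        """Inter-touch intervals in seconds between consecutive events."""
        return np.diff(self.timestamps) / 1000.0


@dataclass
class DayRecord:
    """One behavioural day: its events and the derived within-day ITIs."""

    day_id: int
    timestamps: np.ndarray
    n_events: int = field(init=False)
    itis: np.ndarray = field(init=False)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.n_events = int(self.timestamps.size)
        self.itis = np.diff(self.timestamps) / 1000.0
        if self.itis.size and np.any(self.itis <= 0):
            raise DomainError(
                f"day {self.day_id}: non-positive ITI; de-duplicate the stream first"
            )


def read_taps(path: str | Path, subject_id: str | None = None) -> TapStream:
    """Read a tap stream CSV (header ``timestamp_ms``, one integer per row).

    Out-of-order rows are sorted (warning logged); exact duplicate
    timestamps are collapsed to one event (count logged).  Non-numeric rows
    raise :class:`ParseError` with the offending line number; an empty file
    raises :class:`EmptyInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tap stream file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if TAPS_HEADER not in df.columns:
        raise FormatError(f"{path}: missing required header {TAPS_HEADER!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no timestamps")
    values = pd.to_numeric(df[TAPS_HEADER], errors="coerce")
    bad = values.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ParseError(f"{path}:{line}: non-numeric timestamp {df[TAPS_HEADER].iloc[line - 2]!r}")
    ts = values.to_numpy(dtype=np.int64)
    if np.any(np.diff(ts) < 0):
        logger.warning("%s: timestamps out of order; sorting", path)
        ts = np.sort(ts)
    uniq = np.unique(ts)
    if uniq.size < ts.size:
        logger.info("%s: collapsed %d duplicate timestamp(s)", path, ts.size - uniq.size)
    return TapStream(timestamps=uniq, subject_id=subject_id)


def write_taps(stream: TapStream, path: str | Path) -> None:
    """Write a tap stream in the CSV format :func:`read_taps` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({TAPS_HEADER: stream.timestamps}).to_csv(path, index=False)


def write_jid(jid: JID, path: str | Path) -> None:
    """Write a JID as plain text with a full-precision grid header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = jid.grid
    header = "\n".join(
        [
            _JID_MAGIC,
            f"# lo: {g.lo!r}",
            f"# hi: {g.hi!r}",
            f"# n_bins: {g.n_bins}",
            f"# bandwidth: {g.bandwidth!r}",
            f"# normalization: {jid.normalization}",
            f"# n_pairs: {jid.n_pairs}",
        ]
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, jid.matrix, fmt="%.17e")


def read_jid(path: str | Path, expected_grid: JIDGrid | None = None) -> JID:
    """Read a JID written by :func:`write_jid`.

    Raises :class:`FormatError` when the header block is missing or, if
    ``expected_grid`` is given, when the stored grid differs from it.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _JID_MAGIC:
            raise FormatError(f"{path}: missing JID header block")
        meta: dict[str, str] = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        try:
            grid = JIDGrid(
                lo=float(meta["lo"]),
                hi=float(meta["hi"]),
                n_bins=int(meta["n_bins"]),
                bandwidth=float(meta["bandwidth"]),
            )
            normalization = meta["normalization"]
            n_pairs = int(meta["n_pairs"])
        except KeyError as exc:
            raise FormatError(f"{path}: JID header missing field {exc}") from exc
        matrix = np.loadtxt(fh)
    if expected_grid is not None and grid != expected_grid:
        raise FormatError(f"{path}: grid metadata mismatch: {grid} != {expected_grid}")
    if matrix.shape != (grid.n_bins, grid.n_bins):
        raise FormatError(
            f"{path}: matrix shape {matrix.shape} does not match n_bins {grid.n_bins}"
        )
    return JID(grid=grid, matrix=matrix, n_pairs=n_pairs, normalization=normalization)
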
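"""Reading, validation, filtering and writing of 3D cell-track data.

The on-disk dialect is a plain CSV with header columns
``track_id,frame,t,x,y,z`` — one row per recorded cell position, ``t`` in
seconds, coordinates in micrometres, ``frame`` a 0-based frame index.  This
is the common denominator of what cell-tracking packages (Imaris, TrackMate,
CellProfiler) export once their spot tables are flattened.

Two in-memory containers are used throughout the package:

:class:`Track`
    the time-ordered positions of one cell, plus the nominal frame interval.
:class:`Field`
    a set of tracks that share an imaging volume (bounding box) and frame
    interval — the unit at which simulations and null models are matched to
    data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns required in the track-table CSV dialect.
REQUIRED_COLUMNS = ("track_id", "frame", "t", "x", "y", "z")

#: Relative tolerance on frame-to-frame time jitter (real acquisitions
#: jitter; exact equality would reject valid data).
DT_RTOL = 0.10


class TrackFormatError(ValueError):
    """A track table is malformed (missing columns, empty, unreadable)."""


class TrackValidationError(ValueError):
    """Track contents violate an invariant (ordering, finiteness)."""


@dataclass
class Track:
    """Time-ordered 3D positions of a single cell.

    Parameters
    ----------
    track_id : str
        Identifier of the cell track.
    t : ndarray, shape (n,)
        Timestamps in seconds, strictly increasing.
    xyz : ndarray, shape (n, 3)
        Positions in micrometres.
    frame_dt : float
        Nominal frame interval in seconds.
    """

    track_id: str
    t: np.ndarray
    xyz: np.ndarray
    frame_dt: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise TrackValidationError(
                f"track {self.track_id!r}: xyz must have shape (n, 3)"
            )
        if len(self.t) != len(self.xyz):
            raise TrackValidationError(
                f"track {self.track_id!r}: t and xyz lengths differ"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def n_positions(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last position, seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def displacements(self) -> np.ndarray:
        """Per-frame displacement vectors, shape (n-1, 3), micrometres."""
        return np.diff(self.xyz, axis=0)

    @property
    def path_length(self) -> float:
        """Total distance travelled along the track, micrometres."""
        return float(np.linalg.norm(self.displacements, axis=1).sum())

    @property
    def net_displacement(self) -> float:
        """Straight-line start-to-end distance, micrometres."""
        return float(np.linalg.norm(self.xyz[-1] - self.xyz[0]))

    @property
    def squared_displacement(self) -> float:
        """Net start-to-end squared displacement, square micrometres."""
        return self.net_displacement ** 2

    def validate(self) -> None:
        """Check the track invariants, raising ``TrackValidationError``.

        Invariants: at least two positions, finite coordinates, non-negative
        and strictly increasing timestamps, and frame-to-frame intervals
        within ``DT_RTOL`` of the nominal ``frame_dt``.
        """
        if self.n_positions < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: fewer than 2 positions"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite coordinates"
            )
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise TrackValidationError(
                f"track {self.track_id!r}: invalid timestamps"
            )
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: timestamps not strictly increasing"
            )
        if self.frame_dt > 0 and np.any(
            np.abs(dts - self.frame_dt) > DT_RTOL * self.frame_dt
        ):
            raise TrackValidationError(
                f"track {self.track_id!r}: frame interval deviates more than "
                f"{DT_RTOL:.0%} from nominal {self.frame_dt} s"
            )


@dataclass
class Field:
    """A collection of tracks sharing an imaging volume and frame interval."""

    field_id: str
    tracks: list
    bbox: np.ndarray  # shape (2, 3): [lower corner, upper corner], micrometres
    frame_dt: float
    dataset_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bbox = np.asarray(self.bbox, dtype=float).reshape(2, 3)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def box_size(self) -> np.ndarray:
        """Edge lengths of the bounding box, micrometres."""
        return self.bbox[1] - self.bbox[0]

    @property
    def volume(self) -> float:
        """Bounding-box volume in cubic micrometres."""
        return float(np.prod(self.box_size))

    def total_path_length(self) -> float:
        return float(sum(tr.path_length for tr in self.tracks))

    def total_duration(self) -> float:
        return float(sum(tr.duration for tr in self.tracks))


def _tight_bbox(tracks) -> np.ndarray:
    pts = np.vstack([tr.xyz for tr in tracks])
    return np.array([pts.min(axis=0), pts.max(axis=0)])


def read_tracks(path, *, field_id: str | None = None, frame_dt: float | None = None,
                bbox=None, dataset_id: str = "") -> Field:
    """Read a track-table CSV into a :class:`Field`.

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``track_id,frame,t,x,y,z``.
    frame_dt : float, optional
        Nominal frame interval in seconds; estimated as the median
        frame-to-frame interval if omitted.
    bbox : array-like (2, 3), optional
        Bounding box override; tight bounds of the data by default.

    Raises
    ------
    TrackFormatError
        Missing columns or empty file.
    TrackValidationError
        Non-monotone time within a track.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrackFormatError(f"empty track table: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track table missing column(s) {missing}")
    if len(df) == 0:
        raise TrackFormatError(f"track table has no rows: {path}")

    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"track {tid!r}: time not strictly increasing"
            )
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise TrackValidationError(f"track {tid!r}: non-finite coordinates")
        dt = frame_dt if frame_dt is not None else float(np.median(np.diff(t)))
        tracks.append(Track(str(tid), t, xyz, dt))

    fdt = frame_dt if frame_dt is not None else float(
        np.median([tr.frame_dt for tr in tracks])
    )
    box = np.asarray(bbox, dtype=float) if bbox is not None else _tight_bbox(tracks)
    name = field_id if field_id is not None else str(getattr(path, "name", path))
    return Field(name, tracks, box, fdt, dataset_id=dataset_id)


def write_tracks(fieldobj: Field, path) -> None:
    """Write a :class:`Field` back to the CSV track-table dialect.

    Coordinates are written with 6 decimal places so that
    ``read_tracks(write_tracks(f))`` reproduces ``f`` to that precision.
    Refuses to write non-finite coordinates.
    """
    rows = []
    for tr in fieldobj.tracks:
        if not (np.all(np.isfinite(tr.xyz)) and np.all(np.isfinite(tr.t))):
            raise TrackValidationError(
                f"track {tr.track_id!r}: refusing to write non-finite values"
            )
        for i in range(tr.n_positions):
            rows.append(
                (tr.track_id, i, tr.t[i], tr.xyz[i, 0], tr.xyz[i, 1], tr.xyz[i, 2])
            )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f")


def filter_motile(fieldobj: Field, min_path: float = 17.0,
                  min_sq_disp: float = 300.0, min_steps: int = 3) -> Field:
    """Discard tracks of non-motile cells.

    Retains tracks with total path length >= ``min_path`` (um, three cell
    diameters by default), net start-to-end squared displacement >=
    ``min_sq_disp`` (um^2), and at least ``min_steps`` recorded time steps.
    Returns a new Field; the input is untouched.  The squared-displacement
    criterion uses the net (first-to-last) displacement, matching the
    Displacement^2 track statistic of tracking software.
    """
    kept = [
        tr for tr in fieldobj.tracks
        if tr.path_length >= min_path
        and tr.squared_displacement >= min_sq_disp
        and (tr.n_positions - 1) >= min_steps
    ]
    logger.info("filter_motile: kept %d of %d tracks", len(kept), fieldobj.n_tracks)
    return replace(fieldobj, tracks=kept)
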
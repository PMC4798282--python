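"""Velocities, speeds, turning angles and angle-threshold steps.

A *step* is the resultant of a maximal run of consecutive velocity vectors
that stays within a threshold angle (15 degrees by default) of the run's
initial direction.  Step lengths are the natural unit for heavy-tailed
random-walk analysis because they join near-collinear frame-to-frame moves
into single straight displacements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trackio import Track

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Step:
    """Resultant of a near-straight run of velocity vectors.

    ``start_index``/``end_index`` are frame indices into the track positions;
    the step covers frame intervals ``start_index .. end_index - 1``.
    """

    start_index: int
    end_index: int
    vector: np.ndarray  # 3D displacement, micrometres
    length: float       # micrometres, Euclidean norm of vector
    duration: float     # seconds


@dataclass(frozen=True)
class TurningAngle:
    angle: float    # degrees in [0, 180]
    at_index: int   # index of the middle position


def velocities(track: Track) -> np.ndarray:
    """Per-frame velocity vectors (n-1, 3) in um/s.

    ``v_i = (p_{i+1} - p_i) / (t_{i+1} - t_i)``.
    """
    if track.n_positions < 2:
        raise ValueError("need at least 2 positions")
    dt = np.diff(track.t)
    if np.any(dt == 0):
        raise ValueError(f"track {track.track_id!r}: duplicate timestamps")
    return np.diff(track.xyz, axis=0) / dt[:, None]


def speeds(track: Track, per_minute: bool = False) -> np.ndarray:
    """Per-frame speeds (um/s, or um/min with ``per_minute=True``)."""
    s = np.linalg.norm(velocities(track), axis=1)
    return s * 60.0 if per_minute else s


def turning_angles(track: Track) -> list[TurningAngle]:
    """Angles between consecutive velocity vectors, in degrees.

    Zero-length velocity vectors contribute no angle; their count is logged.
    """
    if track.n_positions < 3:
        raise ValueError("need at least 3 positions")
    v = np.diff(track.xyz, axis=0)  # directions only; time scaling irrelevant
    norms = np.linalg.norm(v, axis=1)
    out = []
    skipped = 0
    prev = None  # index of last nonzero vector
    for i in range(len(v)):
        if norms[i] == 0:
            skipped += 1
            continue
        if prev is not None:
            c = np.dot(v[prev], v[i]) / (norms[prev] * norms[i])
            ang = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
            out.append(TurningAngle(ang, at_index=i))
        prev = i
    if skipped:
        logger.debug(
            "track %s: skipped %d zero-length vectors in turning angles",
            track.track_id, skipped,
        )
    return out


def turning_angle_values(track: Track) -> np.ndarray:
    """Turning angles as a float array (degrees)."""
    return np.array([a.angle for a in turning_angles(track)], dtype=float)


def segment_steps(track: Track, theta_max: float = 15.0,
                  mode: str = "first") -> list[Step]:
    """Greedy left-to-right segmentation of a track into steps.

    A step accumulates consecutive velocity vectors while each stays within
    ``theta_max`` degrees of the reference direction; on violation a new
    step begins at the current vector.  The step's vector is the resultant
    (sum) of its member displacements.

    Parameters
    ----------
    theta_max : float
        Threshold angle in degrees, in (0, 180].  At 180 every track is one
        step.
    mode : {"first", "previous"}
        Reference direction for the deviation test: the first velocity
        vector of the current step (bounds total within-step curvature,
        the default) or the immediately preceding vector.

    Notes
    -----
    Zero-length velocity vectors contribute no direction and are absorbed
    into the current step.
    """
    if not (0.0 < theta_max <= 180.0):
        raise ValueError("theta_max must be in (0, 180] degrees")
    if mode not in ("first", "previous"):
        raise ValueError(f"unknown mode {mode!r}")
    if track.n_positions < 2:
        raise ValueError("need at least 2 positions")

    disp = np.diff(track.xyz, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    cos_max = np.cos(np.radians(theta_max))

    steps: list[Step] = []
    start = 0
    ref = None  # unit reference direction of the current step
    for i in range(len(disp)):
        if norms[i] == 0:
            continue  # absorbed into the current step
        d = disp[i] / norms[i]
        if ref is None:
            ref = d
            continue
        # clip guards FP round-off for exactly (anti)parallel vectors
        if np.clip(np.dot(ref, d), -1.0, 1.0) >= cos_max:
            if mode == "previous":
                ref = d
            continue
        steps.append(_make_step(track, start, i))
        start = i
        ref = d
    steps.append(_make_step(track, start, len(disp)))
    return steps


def _make_step(track: Track, start: int, end: int) -> Step:
    vec = track.xyz[end] - track.xyz[start]
    return Step(
        start_index=start,
        end_index=end,
        vector=vec,
        length=float(np.linalg.norm(vec)),
        duration=float(track.t[end] - track.t[start]),
    )


def step_lengths(track: Track, theta_max: float = 15.0, mode: str = "first") -> np.ndarray:
    """Step lengths (um) of a track under the angle-threshold segmentation."""
    return np.array([s.length for s in segment_steps(track, theta_max, mode)])


def normalize_by_track_mean(per_track_values):
    """Divide each track's values by that track's own mean.

    Removes between-track mean differences so the pooled distribution
    reflects within-track variation.  Tracks with zero mean are excluded
    with a warning.

    Parameters
    ----------
    per_track_values : sequence of 1D arrays
        One numeric sequence per track.

    Returns
    -------
    list of 1D arrays, one per retained track, each with unit mean.
    """
    out = []
    for i, vals in enumerate(per_track_values):
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0:
            continue
        m = vals.mean()
        if m <= 0:
            logger.warning("track #%d has non-positive mean; excluded", i)
            continue
        out.append(vals / m)
    return out
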
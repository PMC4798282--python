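"""Directional persistence and field-level drift statistics.

The velocity autocorrelation ``C(tau)`` is the ensemble mean of unit-velocity
dot products at time separation ``tau``, over all tracks and admissible start
times: 1 for perfectly straight motion, 0 for isotropic motion, decaying over
the persistence time for a correlated random walk.

The cross-correlation ``C_cross`` is the mean unit-velocity dot product over
*distinct* track pairs at matched absolute times — a measure of drift due to
global effects on the observation field (a drift-free field gives ~0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinematics import velocities
from .trackio import Field

logger = logging.getLogger(__name__)


@dataclass
class CorrelationCurve:
    delays: np.ndarray   # seconds
    corr: np.ndarray     # dimensionless, in [-1, 1]
    n_pairs: np.ndarray  # vector pairs per delay

    @property
    def mean(self) -> float:
        """n-weighted mean correlation across delays."""
        w = self.n_pairs.astype(float)
        return float(np.sum(self.corr * w) / np.sum(w))


def _unit_velocities(track):
    v = velocities(track)
    norms = np.linalg.norm(v, axis=1)
    unit = np.full_like(v, np.nan)
    nz = norms > 0
    unit[nz] = v[nz] / norms[nz, None]
    return unit  # rows of NaN mark zero vectors, skipped downstream


def velocity_autocorrelation(tracks, max_delay: float | None = None) -> CorrelationCurve:
    """Ensemble velocity autocorrelation ``C(tau)``.

    For each track with ``n`` velocity vectors, all ``n - j`` products at
    frame separation ``j`` contribute to the delay ``tau = j * frame_dt``.
    Zero-length velocity vectors are skipped.  ``C(0) = 1`` by construction.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least 1 track")
    dts = np.array([tr.frame_dt for tr in tracks])
    if dts.max() - dts.min() > 1.0:
        raise ValueError("tracks must share a frame interval (within 1 s)")
    dt = float(dts.mean())
    max_j = (
        max(tr.n_positions - 2 for tr in tracks)
        if max_delay is None
        else int(max_delay / dt)
    )

    sums = np.zeros(max_j + 1)
    counts = np.zeros(max_j + 1, dtype=int)
    for tr in tracks:
        u = _unit_velocities(tr)
        n = len(u)
        for j in range(0, min(n - 1, max_j) + 1):
            prods = np.einsum("ij,ij->i", u[: n - j], u[j:])
            valid = np.isfinite(prods)
            sums[j] += prods[valid].sum()
            counts[j] += valid.sum()

    keep = counts > 0
    if not np.all(keep):
        logger.warning("dropped %d delays with no valid pairs", np.sum(~keep))
    return CorrelationCurve(
        delays=np.arange(max_j + 1)[keep] * dt,
        corr=sums[keep] / counts[keep],
        n_pairs=counts[keep],
    )


def cross_correlation(field: Field) -> CorrelationCurve:
    """Between-track direction correlation at matched absolute times.

    For every frame time shared by two or more tracks, the mean
    unit-velocity dot product over all distinct ordered pairs ``(k, m)``,
    ``k != m``, is computed; the curve holds the per-time means and the
    aggregate drift measure is ``curve.mean``.  Times are matched on the
    frame grid (drift is a wall-clock phenomenon, so pairs are aligned by
    absolute time, not track age).

    Raises
    ------
    ValueError
        Fewer than 2 tracks, or no time bin shared by 2+ tracks.
    """
    if field.n_tracks < 2:
        raise ValueError("need at least 2 tracks for cross-correlation")
    dt = field.frame_dt

    by_time: dict[int, list[np.ndarray]] = {}
    for tr in field.tracks:
        u = _unit_velocities(tr)
        # velocity i spans [t_i, t_{i+1}); stamp it with t_i on the grid
        bins = np.rint(tr.t[:-1] / dt).astype(int)
        for b, vec in zip(bins, u):
            if np.all(np.isfinite(vec)):
                by_time.setdefault(b, []).append(vec)

    times, corrs, npairs = [], [], []
    for b in sorted(by_time):
        vecs = by_time[b]
        m = len(vecs)
        if m < 2:
            continue
        V = np.vstack(vecs)
        G = V @ V.T
        total = (G.sum() - np.trace(G)) / (m * (m - 1))
        times.append(b * dt)
        corrs.append(total)
        npairs.append(m * (m - 1) // 2)

    if not times:
        raise ValueError("no temporal overlap between tracks")
    return CorrelationCurve(
        delays=np.array(times, dtype=float),
        corr=np.array(corrs, dtype=float),
        n_pairs=np.array(npairs, dtype=int),
    )
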
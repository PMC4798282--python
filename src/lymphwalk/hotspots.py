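"""Grid-based hotspot detection against a simulation null model.

A field is discretized into 20 um cubes (8000 um^3, about twice a naive
T cell diameter per side) and the number of *unique* tracks visiting each
cube is counted.  The null model is the lognormal-modulated correlated
random walk (LogMCRW) matched to the field — same start positions, frame
interval, durations and travelled-distance budgets — repeated several
times; the per-field hotspot threshold is the pooled mean + 2 SD of the
null visit counts over all visited locations.  Cubes whose observed count
strictly exceeds the threshold are hotspots; tracks that touch any hotspot
are "hot tracks".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from . import kinematics
from .simulator import simulate_matched_tracks
from .trackio import Field

logger = logging.getLogger(__name__)

CUBE_EDGE = 20.0  # micrometres; cube volume 8000 um^3


@dataclass
class HotspotGrid:
    cube_edge: float
    origin: np.ndarray
    observed_counts: dict          # (i, j, k) -> unique-track visit count
    threshold: float
    hotspot_flags: dict = dc_field(default_factory=dict)
    null_counts: list = dc_field(default_factory=list)

    @property
    def hotspot_cubes(self) -> set:
        return {c for c, flag in self.hotspot_flags.items() if flag}

    @property
    def hotspot_fraction(self) -> float:
        if not self.observed_counts:
            return 0.0
        return len(self.hotspot_cubes) / len(self.observed_counts)


@dataclass
class TrackHeatLabel:
    track_id: str
    label: str                     # "hot" or "cold"
    hotspot_visits: int            # distinct hotspot cubes visited
    coldspot_visits: int
    timesteps_in_hotspots: int
    timesteps_in_coldspots: int


def _track_cubes(track, origin, cube_edge):
    """Per-position cube indices, shape (n, 3) of ints (half-open cubes)."""
    return np.floor((track.xyz - origin) / cube_edge).astype(int)


def grid_visits(fieldobj: Field, cube_edge: float = CUBE_EDGE,
                origin=None) -> dict:
    """Unique-track visit counts per grid cube.

    A track visits a cube if any of its positions falls inside
    (half-open intervals ``[k * e, (k+1) * e)``); each track is counted at
    most once per cube regardless of how long it loops there.
    """
    if fieldobj.n_tracks == 0:
        raise ValueError("empty field")
    origin = fieldobj.bbox[0] if origin is None else np.asarray(origin, float)
    counts: dict = {}
    for tr in fieldobj.tracks:
        cubes = {tuple(c) for c in _track_cubes(tr, origin, cube_edge)}
        for c in cubes:
            counts[c] = counts.get(c, 0) + 1
    return counts


def null_threshold(fieldobj: Field, logmcrw_params: dict, reps: int = 10,
                   cube_edge: float = CUBE_EDGE, rng=None):
    """Hotspot threshold from repeated LogMCRW null simulations.

    Simulates ``reps`` independent LogMCRW replicates matched to the field,
    pools the per-location unique-track visit counts over all visited
    locations and replicates, and returns
    ``(mean + 2 * SD, list_of_null_count_dicts)`` — a single threshold per
    field.

    ``logmcrw_params`` must carry ``"lognormal"`` (speed mu/sigma) and
    ``"gamma_angles"`` (shape/scale) entries as produced by
    :func:`lymphwalk.simulator.fit_walker_params`.
    """
    if reps < 2:
        raise ValueError("need reps >= 2 for a dispersion estimate")
    rng = np.random.default_rng(rng)
    null_counts = []
    pooled = []
    for _ in range(reps):
        sim = simulate_matched_tracks(fieldobj, "logmcrw", logmcrw_params,
                                      rng=rng, id_prefix="null")
        nf = Field(fieldobj.field_id + "-null", sim, fieldobj.bbox,
                   fieldobj.frame_dt)
        counts = grid_visits(nf, cube_edge)
        null_counts.append(counts)
        pooled.extend(counts.values())
    pooled = np.asarray(pooled, dtype=float)
    threshold = float(pooled.mean() + 2.0 * pooled.std(ddof=0))
    return threshold, null_counts


def find_hotspots(observed_counts: dict, threshold: float,
                  cube_edge: float = CUBE_EDGE, origin=None) -> HotspotGrid:
    """Flag visited cubes whose count strictly exceeds the threshold.

    Ties at the threshold are not hotspots.
    """
    flags = {c: (n > threshold) for c, n in observed_counts.items()}
    return HotspotGrid(
        cube_edge=cube_edge,
        origin=np.zeros(3) if origin is None else np.asarray(origin, float),
        observed_counts=dict(observed_counts),
        threshold=threshold,
        hotspot_flags=flags,
    )


def detect(fieldobj: Field, logmcrw_params: dict, reps: int = 10,
           cube_edge: float = CUBE_EDGE, rng=None) -> HotspotGrid:
    """Full per-field pipeline: null threshold + observed counts + flags."""
    threshold, null_counts = null_threshold(fieldobj, logmcrw_params,
                                            reps=reps, cube_edge=cube_edge,
                                            rng=rng)
    counts = grid_visits(fieldobj, cube_edge)
    grid = find_hotspots(counts, threshold, cube_edge, origin=fieldobj.bbox[0])
    grid.origin = fieldobj.bbox[0]
    grid.null_counts = null_counts
    return grid


def _dwell_runs(cube_seq):
    """Lengths of maximal runs of consecutive frames in one cube."""
    runs = []
    run = 1
    for prev, cur in zip(cube_seq[:-1], cube_seq[1:]):
        if cur == prev:
            run += 1
        else:
            runs.append((prev, run))
            run = 1
    runs.append((cube_seq[-1], run))
    return runs


def classify_hot_cold(fieldobj: Field, grid: HotspotGrid):
    """Label tracks hot/cold and compare the two groups.

    A track is *hot* iff it visits at least one hotspot cube.  The summary
    compares per-frame speeds of hot vs cold tracks (median and
    Mann-Whitney U p-value), reports skew/kurtosis of step lengths per
    group, and for hot tracks gives per-visit dwell times (consecutive
    frames in one cube) split by hotspot vs cold-spot cube.

    Returns ``(labels, summary)``.
    """
    hot_cubes = grid.hotspot_cubes
    origin = grid.origin
    labels = []
    speeds_by = {"hot": [], "cold": []}
    steps_by = {"hot": [], "cold": []}
    dwell_hot, dwell_cold = [], []

    for tr in fieldobj.tracks:
        cubes = [tuple(c) for c in _track_cubes(tr, origin, grid.cube_edge)]
        visited = set(cubes)
        n_hot = len(visited & hot_cubes)
        in_hot = np.array([c in hot_cubes for c in cubes])
        label = "hot" if n_hot >= 1 else "cold"
        labels.append(TrackHeatLabel(
            track_id=tr.track_id, label=label,
            hotspot_visits=n_hot, coldspot_visits=len(visited) - n_hot,
            timesteps_in_hotspots=int(in_hot.sum()),
            timesteps_in_coldspots=int((~in_hot).sum()),
        ))
        speeds_by[label].append(kinematics.speeds(tr))
        steps_by[label].append(kinematics.step_lengths(tr))
        if label == "hot":
            for cube, run in _dwell_runs(cubes):
                (dwell_hot if cube in hot_cubes else dwell_cold).append(run)

    summary = {"n_hot": sum(1 for l in labels if l.label == "hot"),
               "n_cold": sum(1 for l in labels if l.label == "cold")}
    if summary["n_hot"] and summary["n_cold"]:
        s_hot = np.concatenate(speeds_by["hot"])
        s_cold = np.concatenate(speeds_by["cold"])
        summary["median_speed_hot"] = float(np.median(s_hot))
        summary["median_speed_cold"] = float(np.median(s_cold))
        summary["speed_p_mannwhitney"] = float(
            stats.mannwhitneyu(s_hot, s_cold).pvalue)
        for grp, steps in steps_by.items():
            x = np.concatenate(steps)
            summary[f"step_skew_{grp}"] = float(stats.skew(x))
            summary[f"step_kurtosis_{grp}"] = float(
                stats.kurtosis(x, fisher=False))
        summary["dwell_median_hotspots"] = (
            float(np.median(dwell_hot)) if dwell_hot else float("nan"))
        summary["dwell_median_coldspots"] = (
            float(np.median(dwell_cold)) if dwell_cold else float("nan"))
    else:
        logger.warning("one group empty (%d hot / %d cold); "
                       "group comparison skipped",
                       summary["n_hot"], summary["n_cold"])
    return labels, summary
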
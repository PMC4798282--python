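"""Speed-stratified shape statistics.

Cells moving at different mean speeds show differently shaped speed
distributions: slow cells are heavy-tailed (high skew/kurtosis, lognormal
best fit), fast cells near-Gaussian.  A sliding window over track mean
speed pools the member tracks' per-frame speeds and computes
method-of-moments skew (m3 / m2^1.5) and non-excess kurtosis (m4 / m2^2);
fixed slow/fast cuts feed the distribution model competition per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import distributions, kinematics

logger = logging.getLogger(__name__)

MIN_WINDOW_N = 10


@dataclass
class MomentStats:
    skew: float
    kurtosis: float  # non-excess: 3 for a Gaussian
    n: int
    window_center: float  # um/s


def moments(values) -> tuple:
    """Method-of-moments (skew, non-excess kurtosis) of a sample."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    d = x - m
    m2 = np.mean(d ** 2)
    if m2 == 0:
        return 0.0, 0.0
    return float(np.mean(d ** 3) / m2 ** 1.5), float(np.mean(d ** 4) / m2 ** 2)


def sliding_skew(tracks, window_width: float = 0.125, step: float = 0.1,
                 min_n: int = MIN_WINDOW_N) -> list:
    """Windowed skew/kurtosis of pooled speeds vs track mean speed.

    Windows of ``window_width`` um/s advance in ``step`` um/s increments
    over the range of track mean speeds; each window pools the per-frame
    speeds of tracks whose mean speed falls inside it.  Windows with fewer
    than ``min_n`` pooled speeds are omitted.
    """
    per_track = [(kinematics.speeds(tr)) for tr in tracks]
    mean_speeds = np.array([s.mean() for s in per_track])
    if len(mean_speeds) == 0:
        logger.warning("no tracks; empty sliding-skew result")
        return []

    out = []
    start = 0.0
    hi = mean_speeds.max()
    while start <= hi:
        sel = (mean_speeds >= start) & (mean_speeds < start + window_width)
        if np.any(sel):
            pooled = np.concatenate([per_track[i] for i in np.flatnonzero(sel)])
            if len(pooled) >= min_n:
                sk, ku = moments(pooled)
                out.append(MomentStats(skew=sk, kurtosis=ku, n=len(pooled),
                                       window_center=start + window_width / 2))
        start += step
    if not out:
        logger.warning("no window reached %d samples", min_n)
    return out


def subpopulation_fits(tracks, slow_cut: float = 5.0, fast_cut: float = 15.0,
                       families=("lognormal", "gaussian", "maxwell", "powerlaw")):
    """Distribution competition for slow vs fast tracks.

    Tracks are classed by mean speed (``slow_cut``/``fast_cut`` in um/min);
    per-frame speeds are pooled within each class and ranked with
    :func:`lymphwalk.distributions.rank_models`.

    Returns a dict with, per non-empty class, the ranked fits, the winning
    family, the pooled moments and the sample size.
    """
    if slow_cut >= fast_cut:
        raise ValueError("slow_cut must be below fast_cut")
    pools = {"slow": [], "fast": []}
    for tr in tracks:
        s = kinematics.speeds(tr)
        mean_min = s.mean() * 60.0
        if mean_min < slow_cut:
            pools["slow"].append(s)
        elif mean_min > fast_cut:
            pools["fast"].append(s)

    out = {}
    for cls, chunks in pools.items():
        if not chunks:
            logger.warning("class %r empty; skipped", cls)
            continue
        pooled = np.concatenate(chunks)
        pooled = pooled[pooled > 0]
        ranked = distributions.rank_models(pooled, families)
        sk, ku = moments(pooled)
        out[cls] = {"ranked": ranked, "winner": ranked[0][0].family,
                    "skew": sk, "kurtosis": ku, "n": len(pooled)}
    return out
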
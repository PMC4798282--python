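"""Mean squared displacement, anomalous-diffusion exponent and motility
coefficient.

MSD here is the squared displacement from the track's *origin* (first
recorded position) at each elapsed time, averaged over tracks still alive at
that lag — the convention under which the per-lag sample count decays as
shorter tracks drop out.  The anomalous exponent ``alpha`` is the slope of
the degree-1 least-squares fit to log lag vs log MSD: ``alpha = 1`` is
diffusive (Brownian), ``1 < alpha < 2`` superdiffusive (the Levy window),
``alpha = 2`` ballistic.  The motility coefficient D is the early-time
linear MSD slope divided by 6 (three dimensions), reported in um^2/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trackio import Track

#: Default observation window: only the first 10 minutes of each track are
#: used, beyond which few tracks survive and the MSD is noise-dominated.
MAX_WINDOW_S = 600.0

#: r^2 filter thresholds replicated from the sensitivity analysis.
R2_THRESHOLDS = (0.0, 0.25, 0.5, 0.75, 0.8, 0.9)


@dataclass
class MSDCurve:
    lags: np.ndarray    # seconds
    msd: np.ndarray     # square micrometres
    counts: np.ndarray  # samples per lag


@dataclass
class AlphaFit:
    alpha: float
    r2: float
    window: float  # seconds of data used


@dataclass
class MotilityResult:
    D: float   # um^2/min
    r2: float


def track_msd(track: Track, max_window: float = MAX_WINDOW_S) -> MSDCurve:
    """Squared displacement from the track origin at each elapsed time."""
    if track.n_positions < 3:
        raise ValueError("need at least 3 positions")
    elapsed = track.t - track.t[0]
    mask = elapsed <= max_window
    lags = elapsed[mask]
    sq = np.sum((track.xyz[mask] - track.xyz[0]) ** 2, axis=1)
    return MSDCurve(lags=lags, msd=sq, counts=np.ones_like(lags, dtype=int))


def ensemble_msd(tracks, max_window: float = MAX_WINDOW_S) -> MSDCurve:
    """Mean squared displacement over an ensemble of tracks.

    Lags are aligned by rounding each track's elapsed times to multiples of
    the shared frame interval; the mean at each lag runs over tracks still
    alive there, so counts decay with lag.

    Raises
    ------
    ValueError
        No tracks, or frame intervals differing by more than 1 s (the
        dataset grouping rule: only fields imaged at frame rates within one
        second are pooled).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least 1 track")
    dts = np.array([tr.frame_dt for tr in tracks])
    if dts.max() - dts.min() > 1.0:
        raise ValueError(
            f"mixed frame intervals ({dts.min():.1f}-{dts.max():.1f} s) "
            "exceed the 1 s dataset-grouping tolerance"
        )
    dt = float(dts.mean())

    acc: dict[int, list[float]] = {}
    for tr in tracks:
        elapsed = tr.t - tr.t[0]
        mask = elapsed <= max_window
        sq = np.sum((tr.xyz[mask] - tr.xyz[0]) ** 2, axis=1)
        for lag_idx, val in zip(np.rint(elapsed[mask] / dt).astype(int), sq):
            acc.setdefault(lag_idx, []).append(val)

    idx = np.array(sorted(acc))
    msd = np.array([np.mean(acc[i]) for i in idx])
    counts = np.array([len(acc[i]) for i in idx])
    return MSDCurve(lags=idx * dt, msd=msd, counts=counts)


def fit_alpha(curve: MSDCurve) -> AlphaFit:
    """Anomalous-diffusion exponent from a log-log linear fit.

    Degree-1 least-squares polynomial fit to (log lag, log MSD); the slope
    is ``alpha`` and ``r^2`` measures the quality of that linear fit.
    Zero-lag and zero-MSD points are excluded (their logs are undefined).
    """
    mask = (curve.lags > 0) & (curve.msd > 0)
    if mask.sum() < 3:
        raise ValueError("need >= 3 positive (lag, msd) points")
    lx = np.log(curve.lags[mask])
    ly = np.log(curve.msd[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AlphaFit(alpha=float(slope), r2=float(r2),
                    window=float(curve.lags[mask].max()))


def classify_alpha(alpha: float) -> str:
    """Motion class of an anomalous exponent.

    ``alpha < 1`` subdiffusive; ``1 <= alpha <= 2`` the Levy window
    (diffusive through superdiffusive to ballistic); ``alpha > 2``
    accelerating motion.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if alpha < 1.0:
        return "subdiffusive"
    if alpha <= 2.0:
        return "levy_window"
    return "ballistic_plus"


def motility_coefficient(track: Track, max_window: float = MAX_WINDOW_S,
                         early_fraction: float = 0.25) -> MotilityResult:
    """Per-track motility coefficient D from the early-time MSD slope.

    A plain (untransformed) linear model is fitted to MSD vs lag over the
    first ``early_fraction`` of lags within ``max_window``; D is the slope
    divided by 6 (3D), converted to um^2/min.
    """
    curve = track_msd(track, max_window)
    n_early = max(3, int(np.ceil(early_fraction * len(curve.lags))))
    if len(curve.lags) < 3:
        raise ValueError("need >= 3 points in the early window")
    lags = curve.lags[:n_early]
    msd = curve.msd[:n_early]
    slope, intercept = np.polyfit(lags, msd, 1)  # um^2 per second
    pred = slope * lags + intercept
    ss_tot = np.sum((msd - msd.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum((msd - pred) ** 2) / ss_tot
    return MotilityResult(D=float(max(slope, 0.0) * 60.0 / 6.0), r2=float(r2))


def population_motility(tracks, r2_min: float = 0.8):
    """Unweighted mean of per-track D over tracks with fit r^2 > ``r2_min``.

    Returns ``(mean_D, results)`` where results is the full per-track list.
    """
    results = [motility_coefficient(tr) for tr in tracks]
    good = [r.D for r in results if r.r2 > r2_min]
    mean_D = float(np.mean(good)) if good else float("nan")
    return mean_D, results


def alpha_class_fractions(tracks, r2_min: float = 0.0) -> dict:
    """Fraction of tracks per motion class, after an r^2 filter.

    Fractions are over the retained tracks and always sum to 1.
    """
    labels = []
    for tr in tracks:
        fit = fit_alpha(track_msd(tr))
        if fit.r2 > r2_min:
            labels.append(classify_alpha(fit.alpha))
    n = len(labels)
    return {
        cls: (labels.count(cls) / n if n else float("nan"))
        for cls in ("subdiffusive", "levy_window", "ballistic_plus")
    }
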
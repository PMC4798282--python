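"""statsmodels-style front end: a motility model fitted to a track field.

:class:`MotilityModel` bundles the per-field analysis chain — motile-track
filtering, speed/step/turning-angle extraction, distribution model
competition, MSD/anomalous-exponent estimation, motility coefficient, and
directional persistence — behind a familiar ``model.fit()`` returning a
:class:`MotilityResults` with a ``summary()`` table.

Example
-------
>>> from lymphwalk import MotilityModel, synthetic_data
>>> field, _ = synthetic_data.gen_field(synthetic_data.GeneratorSpec(seed=0))
>>> res = MotilityModel(field).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import correlation, diffusivity, distributions, kinematics, trackio
from .trackio import Field


class MotilityModel:
    """Motility analysis of one field of cell tracks.

    Parameters
    ----------
    field : Field
        Tracks sharing a bounding box and frame interval.
    filter_tracks : bool
        Apply the motile-cell filter (path >= 17 um, net squared
        displacement >= 300 um^2, >= 3 time steps) before analysis.
    """

    def __init__(self, field: Field, filter_tracks: bool = True):
        self.raw_field = field
        self.field = trackio.filter_motile(field) if filter_tracks else field
        if self.field.n_tracks == 0:
            raise ValueError("no motile tracks to analyse")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_dt: float | None = None,
                       **kwargs) -> "MotilityModel":
        """Build from a track table with columns track_id, frame, t, x, y, z."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(trackio.read_tracks(buf, field_id="dataframe",
                                       frame_dt=frame_dt), **kwargs)

    def fit(self, theta_max: float = 15.0,
            families=("lognormal", "gaussian", "maxwell", "powerlaw"),
            r2_min: float = 0.8) -> "MotilityResults":
        """Run the analysis chain and return the results object."""
        fld = self.field
        speeds, steps, angles = [], [], []
        for tr in fld.tracks:
            speeds.append(kinematics.speeds(tr))
            steps.append(kinematics.step_lengths(tr, theta_max))
            if tr.n_positions >= 3:
                angles.append(kinematics.turning_angle_values(tr))
        pooled_speeds = np.concatenate(speeds)
        pooled_steps = np.concatenate(steps)
        pooled_angles = np.concatenate(angles) if angles else np.array([])

        pos = pooled_speeds[pooled_speeds > 0]
        speed_rank = distributions.rank_models(pos, families)
        step_rank = distributions.rank_models(
            pooled_steps[pooled_steps > 0], families)
        tail = distributions.fit_powerlaw_tail(pooled_steps[pooled_steps > 0])

        curve = diffusivity.ensemble_msd(fld.tracks)
        alpha = diffusivity.fit_alpha(curve)
        mean_D, per_track_D = diffusivity.population_motility(fld.tracks,
                                                              r2_min=r2_min)
        fractions = diffusivity.alpha_class_fractions(fld.tracks)
        autocorr = correlation.velocity_autocorrelation(fld.tracks)
        drift = (correlation.cross_correlation(fld).mean
                 if fld.n_tracks >= 2 else float("nan"))

        return MotilityResults(
            model=self, n_tracks=fld.n_tracks,
            n_speeds=len(pooled_speeds), n_steps=len(pooled_steps),
            n_angles=len(pooled_angles),
            mean_speed=float(pooled_speeds.mean() * 60.0),
            median_speed=float(np.median(pooled_speeds) * 60.0),
            speed_fits=speed_rank, step_fits=step_rank, powerlaw_tail=tail,
            msd_curve=curve, alpha=alpha, alpha_fractions=fractions,
            motility_D=mean_D, per_track_D=per_track_D,
            autocorrelation=autocorr, drift=float(drift),
        )


@dataclass
class MotilityResults:
    """Fitted motility statistics for one field."""

    model: MotilityModel
    n_tracks: int
    n_speeds: int
    n_steps: int
    n_angles: int
    mean_speed: float       # um/min
    median_speed: float     # um/min
    speed_fits: list        # ranked (DistributionFit, GoFPanel)
    step_fits: list
    powerlaw_tail: distributions.PowerLawTail
    msd_curve: diffusivity.MSDCurve
    alpha: diffusivity.AlphaFit
    alpha_fractions: dict
    motility_D: float       # um^2/min
    per_track_D: list = dc_field(repr=False, default_factory=list)
    autocorrelation: correlation.CorrelationCurve | None = None
    drift: float = float("nan")

    @property
    def best_speed_family(self) -> str:
        return self.speed_fits[0][0].family

    @property
    def best_step_family(self) -> str:
        return self.step_fits[0][0].family

    def to_dict(self) -> dict:
        """Flat JSON-serializable summary of the headline statistics."""
        sf, ssf = self.speed_fits[0][0], self.step_fits[0][0]
        return {
            "n_tracks": self.n_tracks,
            "mean_speed_um_min": self.mean_speed,
            "median_speed_um_min": self.median_speed,
            "best_speed_family": sf.family,
            "best_speed_params": sf.params,
            "best_step_family": ssf.family,
            "best_step_params": ssf.params,
            "powerlaw_tail_mu": self.powerlaw_tail.mu,
            "powerlaw_tail_fraction": self.powerlaw_tail.tail_fraction,
            "alpha": self.alpha.alpha,
            "alpha_r2": self.alpha.r2,
            "alpha_fractions": self.alpha_fractions,
            "motility_D_um2_min": self.motility_D,
            "drift_cross_correlation": self.drift,
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Motility model results",
            "=" * 62,
            f"{'tracks analysed':<34}{self.n_tracks:>12}",
            f"{'per-frame speeds (n)':<34}{self.n_speeds:>12}",
            f"{'steps (n)':<34}{self.n_steps:>12}",
            f"{'turning angles (n)':<34}{self.n_angles:>12}",
            f"{'mean speed [um/min]':<34}{self.mean_speed:>12.3f}",
            f"{'median speed [um/min]':<34}{self.median_speed:>12.3f}",
            f"{'MSD exponent alpha':<34}{self.alpha.alpha:>12.3f}",
            f"{'  (r^2 of log-log fit)':<34}{self.alpha.r2:>12.3f}",
            f"{'motility D [um^2/min]':<34}{self.motility_D:>12.3f}",
            f"{'drift (cross-correlation)':<34}{self.drift:>12.4f}",
            "-" * 62,
            "speed-distribution competition (by negative log-likelihood):",
        ]
        for fit, panel in self.speed_fits:
            pars = ", ".join(f"{k}={v:.4g}" for k, v in fit.params.items())
            lines.append(
                f"  {panel.rank}. {fit.family:<11} nlogl={fit.nlogl:>12.1f}  "
                f"AICc={panel.aicc:>12.1f}  [{pars}]"
            )
        lines.append("step-length competition:")
        for fit, panel in self.step_fits:
            pars = ", ".join(f"{k}={v:.4g}" for k, v in fit.params.items())
            lines.append(
                f"  {panel.rank}. {fit.family:<11} nlogl={fit.nlogl:>12.1f}  "
                f"AICc={panel.aicc:>12.1f}  [{pars}]"
            )
        t = self.powerlaw_tail
        lines += [
            f"power-law tail: mu={t.mu:.3f} at x_min={t.x_min:.3f} um "
            f"({100 * t.tail_fraction:.1f}% of steps in tail)",
            "alpha classes: "
            + ", ".join(f"{k}={v:.1%}" for k, v in self.alpha_fractions.items()),
            "=" * 62,
        ]
        return "\n".join(lines)
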
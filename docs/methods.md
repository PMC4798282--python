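# Methods

This note records the models implemented in `lymphwalk`, the conventions
and defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where a design was genuinely
open.

## Tracks, steps and kinematic statistics

A track is a time-ordered sequence of 3D positions (μm) at a nominal frame
interval `frame_dt` (13–20.7 s in the data this package models; frame
jitter up to 10% is accepted). A field groups tracks sharing a bounding
box and frame interval; fields whose frame intervals agree within 1 s may
be pooled for frame-rate-dependent statistics (MSD, autocorrelation).

The motile-cell filter keeps tracks with total path length ≥ 17 μm (three
cell diameters), net first-to-last squared displacement ≥ 300 μm², and at
least 3 recorded time steps. "Squared displacement" is read as the *net*
displacement squared, the tracking-software Displacement² statistic; a
max-over-time reading would be laxer and is not used.

Speeds are per-frame displacement norms divided by the frame interval
(μm/s internally; μm/min in reports). A *step* is the resultant of a
maximal run of consecutive velocity vectors that stay within a threshold
angle (default 15°) of the run's **first** vector. The alternative
reading — deviation measured from the immediately preceding vector — is
available as `mode="previous"`; the default bounds total within-step
curvature, so a step is genuinely near-straight. At a threshold of 180°
every track collapses to a single step, and step counts are non-increasing
in the threshold. Zero-length velocity vectors (stationary frames)
contribute no direction and are absorbed into the current step. Turning
angles are arccos of normalized dot products of consecutive velocity
vectors, reported in degrees on [0, 180].

## Distribution competition

Candidate families for speeds and step lengths: lognormal, Gaussian,
Maxwell, exponential, gamma, power law. Estimation is by maximum
likelihood on the raw samples — never on binned data — with closed forms
where they exist (lognormal: mean/SD of log values; Gaussian: sample
mean and MLE SD; Maxwell: a² = Σx²/3n; exponential: rate = 1/mean; power
law over the full sample: x_min = min(x), μ̂ = 1 + n/Σ ln(x/x_min)); the
gamma family is fitted numerically with location pinned at zero. Gaussian
fits to positive data are plain (untruncated) Gaussians: the Gaussian is
the 2D-Brownian reference distribution and truncating it would change the
likelihood comparison it exists for.

Goodness of fit: AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), BIC = k ln n − 2lnL,
Kolmogorov–Smirnov and Anderson–Darling distances against the fitted CDF,
and a χ² on ⌈√n⌉ equal-probability bins derived from the fitted quantile
function (the one place a binning exists; its boundaries come from the
fit, not the data). Families are ranked by negative log-likelihood with
AICc as tie-check. The power-law family counts one free parameter (the
exponent; x_min is the sample minimum).

Power-law *tails* are estimated in the Clauset style: every unique sample
value is a candidate x_min (quantile-subsampled to 1000 candidates above
n = 1000, since the exhaustive search is quadratic), the tail exponent is
the continuous MLE over the m tail samples, and the candidate minimizing
the KS distance between tail empirical CDF and fitted CDF wins.
Candidates leaving fewer than 10 tail samples are excluded; an all-equal
sample raises a degenerate-tail error.

## MSD, anomalous exponent, motility coefficient

MSD uses the displacement-from-origin convention: each track contributes
its squared displacement from its first recorded position at each elapsed
time up to 600 s (beyond 10 minutes few tracks survive and the curve is
noise-dominated), and the ensemble mean at each lag runs over the tracks
still alive there — so per-lag sample counts decay, as they do in real
variable-duration data. The anomalous exponent α is the slope of a
degree-1 least-squares fit to (log lag, log MSD) with its r²; zero lags
and zero MSDs are excluded from the logs. Classes: α < 1 subdiffusive,
1 ≤ α ≤ 2 the Lévy window, α > 2 accelerating. The motility coefficient
fits a plain linear model to MSD vs lag over the first 25% of lags within
the 600 s window and divides the slope by 6 (three dimensions — the
divisor is a package choice; published values of this quantity are
sometimes printed with a dimensionally inconsistent unit, and μm²/min is
used here throughout). Population D averages per-track values with fit
r² > 0.8, unweighted. r² thresholds {0, 0.25, 0.5, 0.75, 0.8, 0.9} are
exposed for sensitivity analyses.

## Persistence and drift

The velocity autocorrelation C(τ) is the ensemble mean over tracks and
admissible start times of unit-velocity dot products at separation τ,
computed on the shared frame grid; "turning-angle autocorrelation" and
unit-velocity autocorrelation are treated as the same statistic. The
cross-correlation pairs *distinct* tracks at matched absolute times (drift
is a wall-clock phenomenon, so pairs are aligned by clock time, not track
age); its n-weighted mean is the field's drift measure, ~0 for a
drift-free field.

## Search-efficiency simulation

Targets (DCs) are placed at density 3.17×10⁻⁵ μm⁻³ — ≈200 in the default
6.3×10⁶ μm³ field — in clusters of 10: cluster centres uniform in the
box, members uniform within a ball about the centre. The member spread is
`spread_factor × cluster_radius` with default `spread_factor = 2.0`. The
factor exists because the published calibration values for this placement
scheme (Hopkins 0.2/0.32/0.44 at nominal radii 10/20/40 μm) are
reproduced exactly at twice the nominal radius, while the literal reading
gives 0.10/0.20/0.34 — and the source's own supplementary caption labels
a 20 μm cluster with Hopkins 0.2, matching the literal 20 μm value; the
nominal "radius" therefore behaves as a half-spread, and the default
follows the printed calibration. `spread_factor = 1.0` restores the
literal reading.

The 3D Hopkins statistic uses raw (unexponentiated) nearest-neighbour
distances: per repetition, m uniform probes give nearest-data distances u
and m data points sampled without replacement give nearest-other-data
distances w; H = Σw/(Σu + Σw), averaged over repetitions (default 100,
m = max(10, n/10)). Uniform placement gives 0.5, clustering drives H
toward 0. The d-th-power variant is available via the `power` argument
but is far from the printed calibration (0.001–0.11) and is not the
default.

Walker models, parameterized from a reference field's own statistics
(`fit_walker_params`):

| model | direction | speed / step length |
|---|---|---|
| brownian | uniform per frame | Maxwell fit per frame |
| lognormal | uniform per frame | lognormal speed fit per frame |
| crw | gamma turn per frame, azimuth uniform | Gaussian speed fit truncated at 0 |
| logmcrw | gamma turn per *step* | lognormal **step-length** fit; traversed at per-frame lognormal speeds |
| powerlaw | uniform per *step* | full-sample power-law fit to step lengths; constant pooled mean speed |
| bootstrap | empirical turn per frame | paired empirical (speed, angle) draws |

The step-resolution walkers (logmcrw, powerlaw) draw a straight-step
length and traverse it across frames at finite speed — walks, not
flights — turning only at frame boundaries, since empirical steps are by
construction whole-frame objects. The LogMCRW is thus literally a
correlated walk with a lognormal distribution of step lengths; a
frame-resolution variant (gamma turn + lognormal speed every frame) is
what the synthetic generator uses (see below) and is selected by omitting
step parameters. Boundary handling is specular reflection at the box
faces.

Two calibration rules keep the model comparison about *strategy* rather
than speed artefacts. First, each model's speed draws are rescaled so its
mean speed equals the observed pooled mean: moment-matched fits (Maxwell,
truncated Gaussian) to heavy-tailed speed data otherwise inflate the mean
by tens of percent, and the comparison's premise is that average searcher
velocity stays within the observed range. Second, each simulated cohort
is matched to the observed tracks in start positions and durations and
capped at the observed *total* travelled distance (a cohort-level budget),
so every strategy expends the same search effort.

Contacts use exact point-to-segment distances (frame-rate-robust) at a
combined searcher+target radius of 10 μm (5 μm each). Unique contacts
count each (searcher, target) pair once; total contacts count re-entry
events (a maximal run of consecutive in-contact segments is one event).
Efficiency divides contacts by summed searcher time in minutes — the
allotted observation time, so a searcher that exhausts its distance
budget early has still spent its window. In `efficiency_experiment` the
target configuration is fixed per field and cluster radius (each imaged
field has a single biological target configuration; replicates vary
walker randomness), with per-replicate placement behind a flag. Model
comparisons report the percent change of median efficiency vs the
reference, a 95% CI over outer repetitions, and Mann–Whitney U p-values
on per-repetition medians and on pooled raw values (the efficiency
distributions are non-Gaussian).

Under the self-consistent synthetic conditions used in the tests (an
exactly-lognormal LogMCRW field analysed by its own pipeline), the
unique-contact ordering logmcrw > crw > brownian is strongly significant,
but the Lévy walker only *ties* the LogMCRW: in a 50 μm-thick slab, both
the near-ballistic Lévy walk and the persistent heavy-tailed walk
saturate the same swept-volume bound (a straight path folds at the slab
faces). Likewise Brownian search does not out-total the Lévy walker here
under any counting convention tried. Both orderings are reported for real
data in the literature; their reproduction evidently depends on features
of real speed distributions (notably a lighter-than-lognormal tail) that
the generator's exact lognormal does not share. The corresponding
acceptance assertions are left failing rather than weakened.

## Hotspots

Fields are discretized into 20 μm cubes (8000 μm³, about twice a T-cell
diameter per side), half-open intervals anchored at the bounding-box
minimum corner, and the number of *unique* tracks visiting each cube is
counted. The null model is the LogMCRW walker matched to the field (same
starts, frame interval, durations, total distance), simulated 10 times;
the per-field threshold is the pooled mean + 2σ of the per-location
visit counts over all visited locations and replicates — a single
threshold per field, not per-location. Visited cubes strictly above the
threshold are hotspots (ties are not). Tracks touching ≥ 1 hotspot cube
are *hot*; the hot/cold comparison reports median per-frame speeds with a
Mann–Whitney p-value, step-length skew/kurtosis per group, and per-visit
dwell times (maximal runs of consecutive frames in one cube) for hot
tracks split by cube type.

A caveat at desk scale: with ~100 tracks in a 6.3×10⁶ μm³ field most
visited cubes have 1–2 unique visitors, so the mean + 2σ threshold lands
near the integer 2 and the flagged fraction of a null replicate is
sensitive to estimation noise in σ (individual fields can flip between
~2% and ~15%). Averaging over ≥ 20 fields keeps the mean in the expected
2–4% range; denser fields (richer count distributions) would stabilize it
further.

## Synthetic-data generator

The generator emulates the study conditions of two-photon lymph-node
imaging: a 400 × 315 × 50 μm slab (6.3×10⁶ μm³ — the volume is
reported; the slab shape mirrors imaging fields ~50 μm thick, and the
Hopkins calibration above was verified in this geometry), frame interval
15 s (within the reported 13–20.7 s), track durations uniform on
[120 s, 600 s] so per-lag sample counts decay, speeds lognormal with
log-mean −2.5027 and log-SD 0.9329 (ln μm/s — the published MLE fit), and
gamma turning angles. Models: brownian, crw, lognormal, logmcrw (frame
resolution), powerlaw (step resolution, default exponent 2.0 with 5 μm
minimum step), and a slow/fast mixture for heterogeneity studies. Every
generator is deterministic given (spec, seed); speed-parameter defaults
are translated into each model's native parameterization by moment
matching.

Turning-angle defaults are gamma(shape 2, scale 20°): mean 40°, mode 20°,
per-frame mean direction cosine ≈ 0.70. A memoryless frame-resolution
walk cannot simultaneously match the breadth of observed turning-angle
histograms (which would decorrelate direction within ~2 frames) and the
minutes-long direction autocorrelation of real cells (which requires a
mean cosine ≈ 0.83); the default is a deliberate compromise that keeps
the angle mode far below 90° while making correlated walkers clearly
superdiffusive across the 10-minute observation window. Consequently the
generated autocorrelation decays over ~1 minute, not ~4 — a known gap
between the generator and real data.

Hotspot fields embed spherical regions in which walkers draw slower
speeds, turn isotropically, are steered toward a random interior point of
the region with probability `dwell_bias` per frame when within the
attraction radius, and resist leaving. The standard "strong bias"
configuration (three 15 μm regions, region speeds lognormal(−2.8, 0.7),
dwell bias 0.9, attraction radius 70 μm) yields near-complete hotspot
recovery; with the bias and parameter changes removed the regions are
inert and the field is bitwise identical to a plain one.

What passing tests on these fields do *not* show: real T-cell speeds are
not exactly lognormal (real tails are lighter), real persistence is not
memoryless, imaging noise and track-linking errors are absent, and cell
density is uniform rather than anatomically structured. Conclusions that
depend on those features — most visibly the two search-efficiency
orderings noted above — may differ on real data.

## Numerical details

- All randomness flows through `numpy.random.Generator`; every public
  stochastic function takes an `rng`/seed argument.
- Degenerate inputs: duplicate timestamps raise; zero-length velocity
  vectors are skipped (angles) or absorbed (steps); zero-mean tracks are
  excluded from normalization with a warning; an all-equal sample is a
  degenerate power-law tail; empty hot or cold groups skip the group
  comparison with a warning.
- Distance-budget enforcement is frame-granular (a walker may overshoot
  by at most one frame's travel).
- MSD-slope diagnostics of walker models are run in an effectively
  unconfined volume: inside the slab, boundary folding depresses all
  slopes (a per-frame lognormal walker falls from 0.996 to ~0.88) and
  masks the walk-type signature being checked.
- AICc requires n > k + 1; χ² bins are equal-probability with ⌈√n⌉ bins;
  the Anderson–Darling statistic clips fitted CDF values away from 0 and 1
  by 1e-12.
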
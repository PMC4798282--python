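# lymphwalk

Quantitative analysis of T-cell motility in lymph nodes, and of what that
motility buys the immune system.

Naive T cells must physically find antigen-bearing dendritic cells (DCs)
inside lymph nodes before an immune response can start. How they move —
diffusively like Brownian particles, with the heavy-tailed jumps of a Lévy
walk, or with the directional persistence of a correlated random walk —
determines how quickly they contact unique DCs (search *extent*) and how
often they re-contact nearby ones (search *thoroughness*). `lymphwalk`
implements the full analysis chain for 3D cell tracks from two-photon
microscopy:

- **Track I/O and filtering** — a plain CSV track-table dialect
  (`track_id,frame,t,x,y,z`), with the standard motile-cell filter
  (path ≥ 17 μm, net squared displacement ≥ 300 μm², ≥ 3 time steps).
- **Kinematics** — per-frame velocities and speeds, turning angles, and
  angle-threshold *steps*: maximal near-straight runs of motion that
  deviate less than 15° from the run's initial direction.
- **Distribution competition** — maximum-likelihood fits of lognormal,
  Gaussian, Maxwell, exponential, gamma and power-law families to speeds
  and step lengths, ranked by negative log-likelihood with AICc/BIC/KS/AD/χ²
  panels, plus Clauset-style power-law tail estimation (KS-optimal
  x<sub>min</sub>, MLE exponent μ̂ = 1 + m/Σln(x<sub>i</sub>/x<sub>min</sub>)).
- **Diffusivity** — mean squared displacement from the track origin, the
  anomalous exponent α from the log–log slope (α<1 subdiffusive, 1<α<2 the
  Lévy window, α=2 ballistic), and the motility coefficient
  D = slope/6 of the early-time linear MSD fit.
- **Persistence and drift** — unit-velocity autocorrelation C(τ) and the
  between-track cross-correlation
  C<sub>cross</sub> = ⟨v(p<sub>k</sub>(t))·v(p<sub>m</sub>(t))⟩ at matched
  times.
- **Search-efficiency simulation** — a continuous-3D agent-based model
  comparing six walker strategies (Brownian, CRW, lognormal, LogMCRW,
  power-law/Lévy, bootstrap) against clustered point targets at DC density
  3.17×10⁻⁵ μm⁻³, with exact point-to-segment contact detection at a 10 μm
  combined radius, unique- and total-contact efficiencies per
  searcher-minute, and a 3D Hopkins aggregation statistic (0.5 uniform → 0
  clustered) for the target placements.
- **Hotspot detection** — 20 μm grid cubes whose unique-track visit counts
  exceed the mean + 2σ of a matched LogMCRW simulation null model, and
  hot/cold track comparison.
- **Heterogeneity** — sliding-window skew/kurtosis of speeds and slow/fast
  subpopulation distribution fits.
- **Synthetic data** — seeded generators of whole track fields with known
  ground truth (lognormal speeds, gamma turning angles, 6.3×10⁶ μm³
  imaging slab, optional embedded hotspot regions), standing in for raw
  imaging data in every test.

## Worked example

```python
from lymphwalk import MotilityModel
from lymphwalk.synthetic_data import GeneratorSpec, gen_field

field, truth = gen_field(GeneratorSpec(model="logmcrw", n_tracks=150, seed=7))
res = MotilityModel(field).fit()
print(res.summary())
```

```
Motility model results
==============================================================
tracks analysed                             83
per-frame speeds (n)                      2296
steps (n)                                 1905
turning angles (n)                        2213
mean speed [um/min]                      7.815
median speed [um/min]                    5.043
MSD exponent alpha                       1.254
  (r^2 of log-log fit)                   0.996
motility D [um^2/min]                   14.595
drift (cross-correlation)              -0.0013
--------------------------------------------------------------
speed-distribution competition (by negative log-likelihood):
  1. lognormal   nlogl=     -2567.5  AICc=     -5130.9  [mu=-2.485, sigma=0.9492]
  2. gaussian    nlogl=     -1047.7  AICc=     -2091.5  [mu=0.1303, sigma=0.1533]
  3. powerlaw    nlogl=      -684.5  AICc=     -1367.1  [mu=1.305, x_min=0.003145]
  4. maxwell     nlogl=       544.6  AICc=      1091.2  [a=0.1161]
step-length competition:
  1. lognormal   nlogl=      3408.6  AICc=      6821.2  [mu=0.3863, sigma=0.9841]
  2. gaussian    nlogl=      4620.5  AICc=      9245.0  [mu=2.352, sigma=2.736]
  3. powerlaw    nlogl=      4994.7  AICc=      9991.4  [mu=1.291, x_min=0.04717]
  4. maxwell     nlogl=      6010.0  AICc=     12022.0  [a=2.083]
power-law tail: mu=2.892 at x_min=3.181 um (22.8% of steps in tail)
alpha classes: subdiffusive=14.5%, levy_window=49.4%, ballistic_plus=36.1%
==============================================================
```

Reading the table: 83 of the 150 generated tracks pass the motile filter.
The lognormal family wins the speed and step-length competitions (the
generator draws lognormal speeds, log-mean −2.5027 and log-SD 0.9329, and
the fit recovers them), the ensemble MSD slope α = 1.25 is superdiffusive
but sub-ballistic, the power-law tail fit rejects 77% of steps (so the
motion is not a Lévy walk), and the drift check is consistent with zero.

The same stages are scriptable from a shell:

```sh
lymphwalk synth tracks.csv --model logmcrw --n-tracks 150 --seed 7
lymphwalk filter tracks.csv motile.csv
lymphwalk fit motile.csv
lymphwalk hotspots motile.csv --seed 1
lymphwalk all --out results/ --seed 7       # full pipeline, one JSON summary
```

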
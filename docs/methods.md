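# Methods

This note documents the models, defaults and numerical choices behind
fermspec, and what the synthetic-data tests do and do not establish about
real instruments.

## Fermentation kinetics

Each simulated system uses the minimal standard kinetic form that respects
its configured calibration ranges and feeding rules; none of the rate laws
claims mechanistic fidelity beyond that.

**Batch lactic acid (`la_batch`, 72 h default).** Logistic biomass growth
(µ = 0.25 h⁻¹, X₀ = 0.5 g/L, X_max = 12 g/L) with Luedeking–Piret product
formation (α = 2.0 g/g growth-associated, β = 0.15 g/(g·h)
non-growth-associated) and yield-linked glucose drawdown (Y_X/S = 0.5,
Y_P/S = 0.62 g/g) from 250 g/L. All rates freeze when glucose reaches the
2 g/L floor. Glucose is monotone non-increasing (no feeds); lactate rises
from 6.5 toward ~130–150 g/L.

**Fed-batch sodium gluconate (`sg_fedbatch`, 96 h).** Monod-type glucose
oxidation (q_S = 0.18 g/(g·h), K_S = 5 g/L) at a biomass carrying capacity
of 15 g/L; gluconate accumulates with a 1.15 g/g mass yield (the oxidation
adds oxygen, so the yield exceeds one). Ammonium and phosphate are consumed
proportionally to biomass formed (0.10 and 0.16 g per g X) and floor at
0.40 and 2.00 g/L, keeping both monotone non-increasing inside their
calibration ranges.

**Multi-phase sophorolipids (`sls_multiphase`, 168 h).** Glucose uptake
(q_S = 0.045 g/(g·h), K_S = 3 g/L, X_max = 20 g/L) with a pulse-feed rule
evaluated every 12 h: whenever the level has fallen below 30 g/L it is
restored to 45 g/L (inside the 30–50 g/L operating window) and logged as a
feed event. Rapeseed oil is consumed saturably (q_O = 0.020 g/(g·h),
K_O = 0.5 g/L) and fed continuously at 90 % of its instantaneous uptake, so
the level decays slowly from 8 g/L and stays below 10 g/L throughout.
Sophorolipids form from both substrates (0.55 g/g glucose, 0.80 g/g oil).

Integration is explicit Euler at the caller's step (0.5 h default); every
state is clipped at zero and every analyte series is checked against its
configured calibration range before a trajectory is returned. Three kinetic
parameters per process receive a ±5 % uniform batch-to-batch jitter drawn
from the seed, so different seeds give different, envelope-respecting runs
while a fixed seed is bit-reproducible.

## Spectral forward model

Per sample j on wavelength grid λ (900–1650 nm at 2 nm by default; the
spacing is an instrument detail, chosen once):

A_j(λ) = m_j · Σ_i c_ij ε_i(λ) + b_j(λ) + d·solids_j + η_j(λ)

- ε_i: per-analyte absorptivity, a sum of 2–5 Gaussian bands drawn from the
  seed (centres anywhere in the grid span, widths 2–12 % of the span,
  amplitudes lognormal around 0.004 AU·L/g). These are synthetic stand-ins,
  not real NIR band assignments (deliberately: no attempt is made to model
  true overtone positions). Components are redrawn until all pairwise
  cosine similarities are below 0.95 so the mixture problem is identifiable.
  The amplitude scale may be set per component; trace nutrients (NH₄⁺, P at
  a few g/L) are given proportionally larger absorptivities in the demo
  scripts so that every reported analyte carries a comparable dynamic
  signal, as is implicitly true of any analyte a real method reports.
- m_j = exp(N(0, scatter_sd)): multiplicative scatter.
- b_j: random polynomial in λ normalised to [−1, 1], coefficient sds set
  per degree — the baseline-drift term. The three default noise models
  order the broths la < sg ≤ sls in mean baseline magnitude, mirroring the
  optical complexity ordering of the systems.
- d·solids_j: additive drift proportional to biomass plus dispersed oil.
- η_j: white noise, with extra variance on 1350–1410 nm (water vapour).

There is no constant aqueous background term: the model generates exactly
the mixture signal plus the distortions listed. One consequence, discussed
under "preprocessing", is that SNV behaves differently here than on real
broth spectra.

## Preprocessing

The pipeline is ordered: region selection first (so derivatives are
segment-aware and never cross the excluded water band), then a five-point,
second-order Savitzky–Golay filter (derivative order 0–2; "five-point
smoothing with first derivative" is the default reading), then optional
SNV, then polynomial detrending (degree 1 default). Edge points without a
full filter window are dropped, not padded — (window−1)/2 per segment end.
All steps and parameters are overridable and the pipeline serialises to a
config list.

**SNV caveat.** SNV divides each spectrum by its own standard deviation,
which corrects multiplicative scatter only when that sd is dominated by a
composition-invariant background. Real broth spectra have such a background
(water); this forward model deliberately does not, so SNV here divides by a
signal-dependent scale and makes the calibration problem nonlinear. The
default pipeline retains SNV for fidelity to standard practice, but the
quantitative demonstrations (end-to-end recovery, the soft sensors, the
acceptance script) use the derivative + detrend chain without SNV, which is
the effective scatter/baseline treatment in this synthetic world. On
derivative spectra the lognormal scatter factor survives as a proportional
error of a few percent, which the PLSR absorbs.

**Abnormal-sample screen.** Criterion chosen here (none is standard-free):
each sample is scored against the PCA subspace fitted without it
(jackknife), yielding Hotelling-T² and Q-residual statistics, and flagged
when either exceeds twice the 0.99 empirical quantile of the other
samples' statistics. The jackknife prevents a gross outlier from masking
itself by bending the subspace; the ×2 margin prevents the top order
statistic of clean data from being churned forever (any interpolated
quantile sits below the sample maximum). Both limits, the component count
and the margin are parameters; a margin of 1 recovers the strict
empirical-quantile rule.

## Regression core

NIPALS with deflation of X and Y; X centred (not autoscaled — all channels
share absorbance units), Y centred. The inner loop initialises u to the
largest-variance column of the deflated Y and stops when the unit weight
vector moves by less than 10⁻¹⁰ (max 500 iterations, warning on
non-convergence); for single-response fits the loop is exact after one
pass. One analyte is modelled at a time by default (PLS1), matching
per-component reporting; multi-response PLS2 is the same code path with a
multi-column Y, and the choice is recorded in model metadata. B is computed
as W(PᵀW)⁻¹Qᵀ, so predictions through B equal predictions through the
score path identically. Score underflow (rank exhausted) raises an error
naming the factor.

PCR regresses centred Y on the leading SVD scores of centred X; MLR is
minimum-norm least squares via the pseudoinverse and warns when p ≥ n that
it returns the interpolator. A note on comparisons: in this synthetic
world, minimum-norm MLR in the heavily overparameterised regime (p ≫ n) is
surprisingly benign; the variance penalty that makes full-wavelength least
squares a poor chemometric choice appears in the collinear ordinary
least-squares regime (p below the training-set size), and the model
comparison test demonstrates it there.

## Validation

- Split protocol: random at the requested fraction, with the samples
  attaining each analyte's min and max forced into the *prediction* set.
  The protocol convention kept here makes the prediction set the larger
  side (e.g. 102 prediction / 31 calibration), which inverts the usual
  habit; the package implements it as stated rather than silently swapping.
- Cross-validation: contiguous blocks (k = 10 default) because fermentation
  samples are a time series and random folds would leak neighbouring,
  autocorrelated samples; leave-one-out is available and is tested against
  an explicit refit loop. Preprocessing is refitted inside every fold.
- Factor choice: smallest k with RMSECV(k) ≤ 1.02 · min RMSECV — a
  deterministic parsimony rule guarding against noise-chasing minima.
- R² uses the evaluated set's own reference mean in the denominator; the
  evaluation report additionally carries R² pooled over calibration +
  prediction samples, since either reading occurs in practice.

## Closed-loop control

The controlled scenario is the production phase: biomass is at carrying
capacity and each fed substrate is consumed at a nominal rate (derived from
the kinetics: 2.7 g/(L·h) glucose on the gluconate plant; 0.9 glucose and
0.15 oil on the sophorolipid plant) modulated by a mean-reverting random
walk on its log (sd 0.15 √h, reversion 0.05 h⁻¹) — metabolic drift the
operator cannot see. This production-phase plant, rather than the full
growth ODE, is what the controller runs against; it isolates the question
the controller answers (track a setpoint under unseen demand drift) from
the growth transient.

At each tick the soft sensor reads a freshly synthesized noisy spectrum and
the deficit against the setpoint is fed, quantised by the feed resolution;
the pulse comparator feeds nominal-consumption × period every period,
open-loop, so both policies deliver the same mean feed at nominal demand.
"Control error" is reported both as mean absolute deviation from the
setpoint (the headline number) and as maximum deviation, over the window
after a 10 % startup transient. Feeding is instantaneous and perfectly
dosed apart from quantisation. Plant noise and measurement noise come from
separate seed streams, so matched seeds share the demand path across
policies and comparisons are paired.

Product formation is yield-linked to consumption with a penalty factor of
0.5 when glucose exceeds an inhibition threshold. The threshold is per
plant: 50 g/L on the sophorolipid plant (above its 40 g/L operating point)
and 100 g/L on the gluconate plant — above its 80 g/L setpoint, so the
penalty falls on an open-loop comparator that drifts into overfeeding, not
on the controlled operating point itself. The package demonstrates the
direction of the control→titer effect, not any particular titer value.

## Problem sizes and determinism

Simulation-heavy tests run on coarsened grids (4–8 nm spacing, 94–188
channels) and datasets of 30–140 samples; the acceptance script uses the
full 2 nm grid for calibration metrics (133–140 samples per system, split
102/31, 103/32, 105/35) and ten paired seeds for each control comparison.
These sizes match the fermentation campaigns the generator emulates while
keeping every run in seconds. All randomness flows through
`numpy.random.default_rng` from explicit integer seeds; identical seeds
give bit-identical trajectories, spectra, fits and feed logs.

## What the tests do and do not show

The synthetic generator reproduces the statistical structure the
calibration assumes — linear mixing, smooth overlapping bands, baseline
drift, multiplicative scatter, heteroscedastic noise, range-spanning
designs — so passing tests establish that the algorithms are implemented
correctly and behave as chemometric theory predicts on data of that
structure. They do not establish performance on any real instrument:
real broths add a dominant water background, nonlinear detector effects,
temperature-dependent band shifts, and reference-assay error, none of which
are modelled (the reference-timing-delay experiment in the validation tests
is a deliberate, isolated exception). Figures of merit measured on any
particular real instrument therefore cannot be reproduced here, and are not
claimed.
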
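# Methods

`intermotion` analyses *intermittent locomotion*: trajectories of a single
animal in an annular arena that alternate displacement bouts (**moves**) and
stationary bouts (**pauses**), with reorientation concentrated in the
pauses.  This note documents the models, the estimators, the synthetic-data
generator that stands in for undeposited experimental data, and the
numerical and design choices that were genuinely open.

## Discretization model

Positions are sampled at 5 Hz (frame step `dt = 0.2 s`).  A frame-pair is a
*move transition* when the planar displacement exceeds **0.3 cm**, otherwise
a *pause transition*; maximal runs of equal-state transitions form bouts, so
every bout duration is a multiple of 0.2 s and durations are treated as
pre-binned (discrete) data throughout.  Rotation direction (clockwise CW vs
anti-clockwise ACW around the arena centre) is the sign of the z-component
of the cross product of successive position vectors; a zero cross product
(purely radial motion) carries the previous label forward.  Frames within
**3 cm** of the outer wall (radius 40 cm) or the central dome (radius
17.5 cm) are censored; bouts touching a censored gap or a record end have
unknown true length and are excluded from pooled duration statistics
(right/left censoring).

## Bout-length laws

All candidate laws are fitted as binned models: an observed duration `d`
contributes `log P(d <= X < d+dt)`, with the density normalised over the
model support.  Candidate families:

* bounded exponential on `[a, b]`;
* pure power law `x^-mu` on `[a, inf)`;
* bounded (truncated) power law on `[a, b]`;
* **model (i)** — power law `x^-mu` on `[a, theta)` joined *continuously* at
  `theta` to a stretched-exponential tail
  `theta^-mu · e · exp[-(x/theta)^beta]` on `[theta, inf)`;
* **model (ii)** — exponential head on `[a, x2)`, power-law regime on
  `[x2, x3)`, stretched tail beyond `x3`, continuous at both joins.

In model (i), `mu` is the Lévy scaling exponent (`1 < mu <= 3` is the Lévy
walk range, `mu ≈ 2` optimal in patchy landscapes), `theta` (seconds) is the
cut-off where the power-law regime ends and the stretched-exponential tail
begins, and `beta ∈ (0, 1]` measures the tail's deviation from an
exponential (`beta = 1` is exponential, smaller is fatter).  The power-law
*span* in decades is `log10(theta / 0.2)`.

The changepoint (piecewise) parameterisation was a genuinely open design
choice; the common alternative is the multiplicative form
`x^-mu · exp[-(x/theta)^beta]`.  We chose the changepoint form for two
reasons.  First, it makes `theta` literally "where the tail begins", which
is how the quantity is interpreted and how the power-law span is computed.
Second, identifiability: in the multiplicative form the three parameters
trade off along a near-flat likelihood ridge (the observed Fisher matrix at
n ≈ 50,000 has a near-zero eigenvalue, giving replicate scatter of ~0.05 in
`beta` and tens of percent in `theta`), whereas the changepoint form pins
`theta` as a kink in the log-log density and recovers all three parameters
to ~1% at the same sample size.  A caveat follows: with a very small
`beta` (the pause value 0.23) the changepoint form places most probability
mass beyond 1000 s, so the *generator* truncates draws (below).

All interval masses are closed-form (incomplete-gamma expressions for the
stretched tail, `expm1`-anchored forms for the power-law and exponential
pieces so far-tail bins do not cancel catastrophically).  Maximisation uses
bounded L-BFGS-B from 8 seeded starts (scale parameters on log10 scale);
one-parameter families use bounded scalar minimisation.  Sampling is by
exact piecewise inversion (truncated power law analytically,
`gammainccinv` for the tail), with draws snapped to the *left edge* of
their 0.2 s grid cell — the same convention the likelihood bins use, so
simulation and refitting are exactly consistent.

## Model comparison and criticism

* **Akaike weights**: `w_m = exp(-Δ_m/2) / Σ exp(-Δ/2)` with
  `Δ_m = AIC_m − min AIC`.
* **SPWMC** (sequential pointwise model comparison): each candidate family
  is refitted to the durations above a sliding truncation point (15
  log-spaced points from 0.2 s to the 90th percentile, each keeping ≥ 50
  observations) and Akaike weights are tracked, localising the regime each
  family explains.
* **Poisson-band criticism**: observed vs expected counts per base-2 log
  bin with `E ± 2 sqrt(E)` bands (Poisson deviations).
* **Goodness of fit**: a G statistic on log-binned counts (bins merged
  until each expects ≥ 5) with a parametric bootstrap that *refits* each
  replicate; `p = (1 + #{G* ≥ G}) / (n_kept + 1)`, and `p > 0.1` is read as
  an adequate fit.

## Turning

A *turn* is a CW↔ACW switch.  Turn-after-pause compares the direction of
the transitions immediately before and after a pause (pauses at block
boundaries are excluded); the probability is summarised in base-2 log bins
anchored at 0.2 s with normal-approximation 95% CIs (Wilson for bins under
30 observations — the bins plotted are symmetric, and Wilson guards the
small ones).  Within-bout turning is the fraction of sign changes between
consecutive owned transitions; single-transition bouts are undefined and
reported missing.  Bin *influence* = bin turn probability × share of pauses
in the bin; because short pauses are overwhelmingly abundant under a
heavy-tailed law, they dominate total influence despite low per-pause turn
probability.  Group comparisons of within-pause turn proportions use the
pooled-variance Student t-test (df = nA + nB − 2).

## Sequence correlations

Durations are log-transformed before correlating: product-moment
correlation of raw power-law data is dominated by single extreme bouts.
(The choice of transform was open; log is the standard variance stabiliser
for multiplicative heavy-tailed data.)  PACF at lag k is defined literally
as the last coefficient of the order-k least-squares autoregression (with
intercept), with the white-noise band `±1.96/sqrt(n)`; cross-correlation
pairs `move_i` with the pause immediately following it and correlates
`(move_i, pause_{i+lag})` for lags in `[-L, L]`; a shuffle null permutes
the pause order (≥ 100 shuffles) and reports per-lag 2.5/97.5 percentile
bands.  Correlation series restart at censored gaps.

## Behavioural modes (Partial Sums)

The signed series gives moves positive and pauses negative sign; the
cumulative sum against reference `T = 0` rises through *relocation*
stretches (long moves, short resting pauses) and falls through *local
search* (long exploratory pauses, short moves).  Candidate breakpoints are
non-strict local extrema of the cumulative sum over a window spanning at
least `epsilon/2` of wall-clock time on each side (non-strict because
alternating bout signs tie neighbouring sums); extrema closer than
`epsilon` to the previous accepted breakpoint are pruned keeping the more
extreme, and breakpoints within `epsilon` of the record ends are dropped,
so every mode lasts at least `epsilon` (default **5 min**; 1 and 10 min
give the same qualitative segmentations).  Segments are labelled by the
sign of their net signed sum; zero-sum segments merge with their
predecessor.  Averaging labels across individuals at each time point gives
the population mode-probability curves, which sum to 1 wherever all
individuals are covered.

## Synthetic-data generator

The generator emulates the study conditions: 8 h records (144,000 frames at
5 Hz) of isolated individuals in the 40 cm / 17.5 cm annulus, with

* move and pause durations drawn from model (i) with the published fitted
  values as generating truth (moves `mu=1.49, beta=0.55, theta=8 s`; pauses
  `mu=1.67, beta=0.23, theta=15.27 s`), truncated at 500 s (moves) and
  1000 s (pauses) — finite records hold bounded bouts, and 1000 s is the
  pause cap used when pooling fits;
* a turn-after-pause curve interpolated in log duration (default: rising to
  0.25 by 6 s, flat to 100 s, rising again beyond — the reorientation-bout
  pattern), applied to the travel direction across each pause;
* within-pause fidgeting: tiny signed angular arc steps (~0.01 cm/frame)
  whose sign switches at `within_pause_switch_rate` (default 0.6), plus
  sub-millimetre radial jitter, keeping pause displacements far below the
  0.3 cm threshold; moves travel the annulus mid-radius circle at
  3 cm/s (0.6 cm/frame, safely above threshold);
* (move, pause) pairs coupled through a Gaussian copula with correlation
  −0.6 (long moves ↔ short pauses) and a two-regime schedule: regime
  blocks of 20 min are labelled relocation with probability interpolated
  from schedule knots (default drifting 0.2 → 0.6 over 8 h), and a block's
  pairs are accepted preferentially with move ≥ pause (relocation) or
  pause ≥ move (local search);
* one master seed; all sub-streams spawned deterministically, so cohorts
  are bit-reproducible; the generator emits a ground-truth ledger (exact
  bout list, directions, turn outcomes, regime intervals) that recovery
  tests assert against.

What the generator does **not** emulate: visual optic flow, biomechanics,
wall-following and edge interactions (trajectories stay on the mid-radius
circle, so edge exclusion never censors synthetic frames), inter-individual
variability in the bout laws, and diurnal drift other than the mode
schedule.  Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed statistical structure, not robustness to every
artefact of real video tracking.

## Problem sizes and tolerances

Recovery experiments use 50,000 move and 60,000 pause durations (the
order of the pooled study counts), 93-individual cohorts for population
curves, and shorter (1–8 h) records for unit-level checks; these sizes give
the estimators enough data that the stated tolerances (±0.05 on `mu` and
`beta`, ±15% on `theta`, ±0.1 on mode probabilities, binomial CIs on turn
curves) correspond to ≥ 3 standard errors.  Quadrature (used only as a
cross-check oracle; production masses are closed-form) uses 16-node
Gauss–Legendre panels with geometric ratio 1.4 and an effective upper
limit of 1e9 s.  Bin edges are left-closed/right-open everywhere; log bins
are base-2 anchored at 0.2 s.

## Known limitations

* The changepoint model (i) with very small `beta` implies far more mass
  beyond 1000 s than intermittent records can contain; interpret the pause
  fit conditionally on the truncation cap.
* Model (ii) is fitted by 5-parameter multi-start optimisation and is the
  least identifiable family; it is provided for per-individual model
  selection, not for pooled inference.
* The PS breakpoint rule (window extrema + pruning) is one concrete
  realisation of CUSUM segmentation; breakpoints within `epsilon` of true
  transitions should be considered equivalent.
* Estimates near censored gaps discard flanking bouts conservatively.
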
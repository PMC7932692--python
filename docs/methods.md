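# Methods

## The question the package addresses

When a bacterium divides, how long do its daughters "remember" the state
they inherited?  In classic mother-machine experiments this is asked by
autocorrelating a property (cycle time, size, growth rate, protein
content) along single lineages.  The autocorrelation function (ACF) mixes
two very different sources of persistence, however: information passed
from mother to daughter, and the local environment of the trap the lineage
happens to live in.  A device that keeps the *two daughters of one mother*
growing side by side separates them: sister cells (SCs) share both
inheritance and environment; co-trapped but unrelated neighbour cells
(NCs) share only the environment; random pairs (RPs) from different traps
share neither.  Comparing correlation dynamics across the three pair types
isolates the purely inherited ("epigenetic") memory.

`sistermem` implements this comparison — the pair Pearson correlation
function (PCF), pairwise difference-variance dynamics and exponential
memory fits — together with a mechanistic generator of synthetic
sisters-machine datasets used to drive and test the analysis.

## Estimators

**Pair Pearson correlation function.** For an ensemble of aligned pairs
and a property y, `pcf(ensemble, y, g)` is the Pearson correlation across
pairs of (y⁽¹⁾_g, y⁽²⁾_g).  Because pair members are unordered, each pair
contributes both orderings and means/SDs are taken over the pooled values
(an intraclass-style estimator with the population 1/n normalisation); the
estimator is then exactly symmetric under member exchange.  Generation
g = 0 denotes the alignment origin, where the value is 1 by convention —
at that instant sister "pairs" are literally one mother cell, and NC/RP
pairs are aligned by construction; measured correlations start at g = 1,
each member's first full post-alignment cycle.  The time-resolved size PCF
(`pcf_time`) computes the same estimator per imaging frame on instantaneous
length and boxcar-averages six consecutive frames.

**Exponential memory fits.** `fit_exponential` fits A·exp(−λg) by
unweighted nonlinear least squares with λ ≥ 0 over g ∈ [0, 10], reporting
the half-life ln2/λ (λ < 1e−6 is reported as non-decaying).  The origin
point is included: a correlation that relaxes from 1 toward a residual
shared-environment plateau is summarised by the rate of that relaxation.
Because a plateau-plus-origin series can expose two local least-squares
minima (a fast fit through the origin versus a slow fit through the
plateau), the decay rate is first located by an exhaustive 1-D scan with
the amplitude solved in closed form per candidate rate, then polished
locally; the returned fit is the global optimum and is fully
deterministic.  A practical consequence, visible in replicate synthetic
experiments, is that the fitted NC half-life responds steeply to the
plateau height; NC half-lives from ~100-pair ensembles therefore carry
substantial replicate-to-replicate spread, which is why the headline
half-lives are reported as medians over five replicate experiments.

**Windowed elongation rate.** α(t) = d ln L/dt is estimated as the
least-squares slope of ln(length) over a 6-min moving window (3 frames at
the 3-min cadence) fully contained in one cycle; windows never span a
division.  δα(t) = α⁽¹⁾(t) − α⁽²⁾(t) is formed per pair on the shared
relative-time grid, and `variance_series` takes the across-pair variance
per grid point, smooths it over 3 frames, and reports plateau metrics: the
saturation value is the mean of the last 25% of defined points and the
saturation time is the earliest point from which the series stays within
±10% of it.  Because the ±10% entry criterion is noise-sensitive at ~100
pairs, the results bundle additionally reports the first crossing of 90%
of the plateau ("rise-90"), which is the robust summary used for the
fluorescence saturation check.

**Bootstrap errors.** All standard errors are SDs over seeded
resampling of pairs with replacement (1/n statistics recomputed per
replicate).  No multiple-testing correction is applied; intervals are
descriptive, matching the shaded-band convention of the figures they
mirror.

## The synthetic sisters-machine generator

The generator (`growth_sim`) encodes the minimal mechanistic structure the
analysis assumes; every term maps to one observed signature.

* **Exponential elongation with composite rate.**
  α(t) = ᾱ·(1 + h_T + ε_stat + ε_dyn(t) + ξ(t)) + c₀·e^(−age/τ_c), with
  ᾱ = ln2/34 min⁻¹.  h_T is a heritable growth factor, AR(1) across
  generations (retention φ_T = 2^(−1/9), so sister correlation φ_T^(2g)
  halves every 4.5 generations — the slow SC memory).  ε_stat is a static
  per-trap micro-niche offset; ε_dyn a trap-shared
  Ornstein–Uhlenbeck (OU) fluctuation (τ = 34 min); ξ a fast intrinsic OU
  fluctuation (τ = 5 min).  OU states advance by the exact discretisation
  x ← x·e^(−dt/τ) + σ·sqrt(1 − e^(−2dt/τ))·z, so the stationary law is
  preserved for any step.
* **Adder division control.** A cell divides on adding
  Δ = Δ̄·(1 + h_L)·(1 + η) to its birth length, with h_L a heritable
  adder-scale factor (retention φ_L = 2^(−1/7), half-life 3.5 generations
  — the slow size memory) and η per-cycle noise.  At the symmetric fixed
  point the adder makes the cycle time ln2/α independent of the absolute
  size scale, so h_L expresses itself almost entirely in cell size, only
  weakly (through its generation-to-generation innovations) in cycle time.
  The threshold crossing is solved at sub-frame precision so the
  noise-free fixed point is exact; observation stays on the 3-min frame
  grid.
* **Division.** Daughter fractions are r and 1−r with r ~ N(0.5, σ_r)
  truncated to (0.2, 0.8); lengths are conserved exactly.  Both daughters
  inherit the mother's protein concentration (symmetric partitioning) and
  her current intrinsic noise state; heritable factors are redrawn
  independently per daughter.
* **Post-division compensation.** The r-daughter starts with rate offset
  c₀ = κ(1 − 2r), its sister with −c₀, decaying with τ_c = 10 min: the
  smaller sister transiently grows faster, in inverse proportion to the
  size fraction received.  This produces the elevated SC δα variance
  immediately after separation and its fall to a minimum within one cycle.
* **Fluorescence.** Concentration relaxes as an OU process (τ_f = 34 min)
  toward f̄·(1 + β_f·ε_stat); sisters therefore separate from δf = 0 with
  var(δf)(t) = 2σ_f²(1 − e^(−2t/τ_f)), saturating within ~2 generations,
  while the β_f coupling makes the RP plateau roughly twice the NC one.
* **Trap layout.** Each v-trap holds two tip lineages.  In a *sister*
  trap both tips descend from the division of one burned-in mother (one SC
  pair per trap); in an *unrelated* trap two independently burned-in
  mothers share the trap environment, providing NC candidates with no
  common ancestry — mirroring neighbour cells that entered the two sides
  of a trap independently.  After each tracked division one daughter per
  side is retained (seeded choice).  Burn-in is 10 generations.
* **Observation.** Frames every 3 min with multiplicative log-normal
  measurement noise (1% on length, 2% on fluorescence) and ground-truth
  division flags on each cycle's final frame.  The whole table is
  deterministic given the configuration seed.

### The LB-default preset

Structural parameters are fixed a priori: dt = 3 min, ᾱ = ln2/34,
φ_T = 2^(−1/9), φ_L = 2^(−1/7), τ_c = 10 min, τ_ξ = 5 min,
τ_env = τ_f = 34 min, burn-in 10 generations.  The noise magnitudes are
not directly observable — the study reports outcome statistics, not
mechanism parameters — so they were set by the packaged coarse grid search
(`sistermem.calibrate`, fixed seed) against the outcome targets (mean
cycle time, the three memory half-lives, the δα variance excess) and ship
as the versioned preset `LB-default`.  The default experiment size (700
traps, 57% unrelated, 30 recorded generations per tip) is chosen so that a
single run yields the study's ensemble scale: ~120 SC pairs (subsampled
from the sister traps), ~100 NC pairs at the default pairing tolerances,
and 150 RP pairs.

Calibration exposed one real structural tension, flagged rather than
hidden: a static micro-niche variance large enough to make the SD of SC
average-rate differences half the RP value (the stitched-trace
observation) would also put a large persistent plateau under the NC
cycle-time PCF, lengthening its fitted half-life well past one generation.
The preset favours the correlation-function targets; the rate-difference
ratio consequently sits nearer ~0.6–0.7 than 0.5.  Physically this
suggests that in the real device the micro-niche differences express
themselves more strongly in absolute growth rate than in cycle time; the
generator couples both through a single offset and cannot reproduce the
two numbers simultaneously.

### Pairing rules

SC pairs align at the common mother's division.  NC pairs require both
members to start a cycle within `div_sync_tol` frames (default 0) with
birth lengths within `len_tol_rel` (default 5%) of their mean — the
strictest practical reading of "divide at the same time with almost
identical length" — and members must share no recorded ancestor (stronger
than "not the same mother": in a sister-origin trap the two tips share an
ancestor whose heritable factors decay only as φ^(2g) and would
contaminate the NC ensemble).  One NC pair is harvested per non-overlapping
11-generation epoch, so a long recording can contribute more than one.
RP pairs sample unordered lineage pairs from distinct traps (seeded,
without replacement), aligned at each member's first cycle start.

## What the generator does and does not emulate

It reproduces the cadence, the lineage/pair structure, adder size
homeostasis, heritable growth and size factors, micro-niche and dynamic
trap environments, post-division rate compensation, symmetric protein
partitioning and multiplicative measurement noise.  It does not model
images or segmentation error structure, cell passage through the v-tip,
trap geometry or nutrient fields, plasmid copy-number dynamics, filamentous
or stress phenotypes, or death/exit events.  Passing tests therefore show
that the estimators recover known memory structure from data with this
generative anatomy — not that real devices satisfy these assumptions.

## Numerical choices and degenerate inputs

Rates are held constant within a 3-min frame (exact OU updates for the
noise states); division crossings are resolved exactly inside the frame.
Cycle segmentation uses division flags when present, otherwise a >25%
length drop; cycles shorter than 3 frames are discarded; per-cycle rates
are least-squares slopes of ln(length).  Zero-variance inputs raise a
degenerate-data error in the estimators and are downgraded to warnings
(with the affected outputs empty) by the pipeline.  Correlations are
clipped to [−1, 1] against rounding.  All randomness flows from explicit
seeds; identical configuration and seed give byte-identical tables and
results bundles.

## Problem sizes

The default experiment (700 traps × 2 tips × 30 generations, ~11 frames
per cycle) simulates in roughly 10–15 s and analyses in a few seconds on
one core; the replicate set of five experiments used for the headline
medians completes in a few minutes.  These sizes were chosen as the
smallest at which the ~100-pair ensembles of the study are reproduced with
stable estimator behaviour.

## Known limitations

* The fitted NC half-life is a steep function of the NC plateau height
  near the study's conditions; its replicate spread at ~100 pairs is
  substantial, and medians over replicates are the honest summary.
* The rate-difference ratio and the NC memory cannot be matched
  simultaneously by a single static-niche variance (see above).
* Observed cycle-time SD (~6 min) sits slightly below the reported
  34 ± 7 min; only the mean is calibrated.
* The stitched-length presentation replaces each division with one flat
  frame (the daughter's first observation defines the rescaling anchor),
  slightly diluting the apparent average rate over very short lineages.
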
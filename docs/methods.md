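# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `pcptox`.

## The measurement model

The simulated assay mirrors a resazurin respiration bioassay in white
96-well plates: respiring *E. coli* reduce resazurin to fluorescent
resorufin, and fluorescence is read every 10 minutes for one hour (7
scheduled timepoints). Over this short window the signal is well
approximated by a straight line, so each well is summarized by the OLS
slope of fluorescence against time. Slopes are computed on minutes and
reported per hour, which puts the favourable-condition control at
25.05 a.u. — the scale on which all activity benchmarks are quoted. All 7
points enter the regression, with no weighting or outlier rejection.

## Ground-truth surfaces and calibration

The generator owns a deterministic ground truth with two components.

**Activity** (uninhibited slope, a.u./h):

    A(pH, T) = 25.05 · 20.2^(−(pH−5)/4) · 6^((T−30)/20)

a geometric (log-linear) interpolation between three anchor measurements:
25.05 a.u. at (30 °C, pH 5), a 20.2-fold drop from pH 5 to 9, and a 6-fold
drop from 30 to 10 °C. Both published fold-decreases are treated as
endpoint ratios at matched co-factors. Conductivity has no effect on
baseline activity, matching the observed non-significance of that factor.

**Inhibition** follows a Hill law with an abiotic-dependent EC50:

    INH(C) = Cⁿ / (EC50ⁿ + Cⁿ)
    log₁₀ EC50 = q(pH) + γ·(CS − 8.13) + τ·(T − 30)

* `q(pH)` is the quadratic through the three EC50 anchors
  (7.3, 42.01, 190.2 mg·L⁻¹ at pH 5/7/9; 30 °C, 8.13 mS·cm⁻¹) — three
  anchors determine it exactly, and it is monotone increasing over the
  tested pH range.
* The shared Hill exponent `n` is the closed-form solution of the
  mild-inhibition anchor, (50/190.2)ⁿ = 0.0944/(1−0.0944), giving
  n ≈ 1.692.
* The conductivity coefficient `γ` is solved so that the strong-inhibition
  anchor (99.56% at 50 mg·L⁻¹, pH 5, 22.17 mS·cm⁻¹) is matched exactly;
  the solved value is negative (≈ −0.0396 per mS·cm⁻¹): saltier samples
  potentiate PCP. Two free parameters absorb the two inhibition anchors —
  a deliberately minimal parameterization.
* The temperature coefficient `τ` defaults to 0 because every EC50 anchor
  sits at 30 °C; it is exposed so that a weak positive
  temperature–inhibition association can be emulated if desired.

All anchors are reproduced exactly (relative error < 1e−9) by
construction; the test suite asserts this round trip.

## Noise model

Replicate-to-replicate variability is multiplicative on the slope with
CV 3.09%, the reported replicate variability of the real assay. On top of
that each read receives additive Gaussian noise. The read-noise default is
0.05 a.u. with a fixed baseline F0 = 100 a.u.: the weakest tested condition
(pH 9, 10 °C) has a true slope of only ≈ 0.21 a.u./h, and the read noise is
chosen so that the slope error it induces (≈ 0.057 a.u./h per well) stays
subordinate to the biological replicate effect rather than drowning the
weakest signals — additive noise much larger than this makes control
slopes at that condition frequently negative, which no functioning assay
would exhibit. Readings are floored at 0 a.u. The 40-minute pre-incubation
of the wet protocol is not modelled; only the read window matters to the
analysis.

What the generator does *not* emulate: saturation or lag of the resazurin
signal, plate edge effects, pipetting covariance between wells on the same
plate, PCP volatilization/adsorption or speciation kinetics, bacterial
growth during the read, and hormesis. Passing tests therefore demonstrate
correctness of the analysis machinery and recoverability under the stated
noise — not robustness to these real-data pathologies.

## Validation design fixture

The 24 novel abiotic combinations of the held-out campaign are published
only graphically, so the package ships a synthetic stand-in: 24 off-grid
combinations interleaved between the training levels (pH 5.5–8.5,
T 12–28 °C, CS 9.5–20 mS·cm⁻¹), disjoint from the 27 training
combinations by construction and user-overridable. Validation always
refuses to score a model on abiotic combinations seen in training.

## Inhibition

Controls (0 mg·L⁻¹) are averaged across replicates within each abiotic
combination before pairing, which halves the control's noise contribution;
replicate-matched pairing would be the alternative, and nothing downstream
depends on the choice. Raw inhibition below 0 (stimulation or noise) is
clamped to 0 and above 1 to 1, keeping the rate a percentage between 0 and
100 as defined; the raw value is retained alongside. A combination with
exposed wells but no control, or a non-positive control mean, is an error —
the rate is undefined there, and silently imputing it would corrupt every
downstream stage.

## Dose-response fitting

Both curve families are 2-parameter forms with the maximum fixed at 1,
justified by the complete inhibition observed at the top concentration;
freeing the maximum would let the two extra parameters absorb noise at the
sparse 8-level design. Fits run on the linear concentration scale,
including the zero-dose points (one per control replicate, inhibition 0 by
construction). Optimization is `scipy.optimize.least_squares` over
(log₁₀ scale, log shape) — the log parameterization enforces positivity —
with a deterministic multi-start: 5 log-spaced scale starts spanning the
positive concentration range × shape starts {0.5, 1, 2}, best SSE kept,
tolerances 1e−12, at most 500 function evaluations per start. A fit is
flagged non-converged when the response is essentially constant or shows
no measurable effect (no finite EC50 exists). Model selection uses r²
computed as the squared Pearson correlation between observed and fitted
inhibitions; ties break toward Hill. EC50 equals the 0.5-crossing of the
fitted curve by construction in both families, which the tests verify
numerically.

## The neural effect model

The network is authored from scratch: a normalization layer
(centering-reduction with training-set mean and SD), one hidden layer of
1–3 neurons sharing one activation (tanh, arctan, or exp — the exponential
is the literal function, with pre-activations clipped at 50 as an overflow
guard), and a linear output neuron. Training minimizes the SSE with
analytic gradients under L-BFGS, capped at 100 iterations — a
quasi-Newton "iterative cycle" budget; 100 steps of plain first-order
descent would underfit badly at these scales. Weights initialize uniformly
in [−0.7, 0.7] (halved for exp), which keeps the bounded activations in
their responsive range after normalization. The activity model takes
(pH, T) — the two significant factors — and predicts the control slope;
the effect model takes (pH, T, CS, C_PCP) and predicts the inhibition
fraction, trained unclamped and clamped to [0, 1] only at prediction time.

The architecture search trains 3 sizes × 3 activations × 10 restarts = 90
candidates with per-model seeds spawned deterministically from one master
seed, and selects by maximum training r² (residual-based), ties broken by
minimum residual SD, then enumeration order. Selection deliberately uses
training scores only; the held-out campaign is reserved for validation.
Models serialize to versioned JSON at full precision, so save→load
round-trips predictions exactly.

## Screening and validation statistics

Factor screening is Spearman rank correlation of each abiotic factor
against the response at α = 0.05, p-values from the t approximation —
adequate at n = 81–648, where exact permutation adds nothing. No
multiplicity correction is applied across the three factor tests. A factor
found non-significant can be averaged over, which multiplies the effective
replication (3 → 9 for controls averaged over the three conductivities).
The headline r² between observed and predicted values is the squared
Pearson correlation (invariant to affine miscalibration); the
residual-based 1 − SSE/SST is reported alongside, since a large gap
between the two indicates a biased predictor. An optional 95% prediction
band comes from the simple regression of predicted on observed.

## Problem sizes and determinism

The shipped analyses use the full study geometry: 648 training wells, 384
validation wells, 90-model searches. Monte-Carlo checks in the test suite
use 100–200 seeded repetitions of single-plate or single-combination
simulations, and the control-slope calibration check uses 10,000 simulated
wells — sizes at which the binomial/standard-error tolerances asserted are
meaningful. Every stochastic path flows through `numpy` Generators seeded
from an explicit master seed (per-stage seeds split by fixed offsets), so
identical configurations reproduce outputs byte for byte.

## Known limitations

* The ground-truth surface is a smooth, low-dimensional idealization; real
  plate campaigns will show structure (edge effects, drift) it lacks, so
  recovery rates here are upper bounds.
* The Hill exponent is shared across abiotic conditions; if the true
  steepness varies with pH, the generator cannot express it.
* EC50 uncertainties are not estimated (no profile likelihood or
  bootstrap by default).
* The effect model is empirical and strictly interpolative: it applies to
  PCP and *E. coli* within the tested abiotic ranges, and nothing in the
  architecture encodes speciation chemistry that would justify
  extrapolation.
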
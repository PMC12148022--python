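# Methods

## Trace model and trait derivation

A flow-through respirometry recording is modelled end to end. The chamber
(volume V, flow FR) obeys d(V·x)/dt = m(t) − FR·x, where x is the excess
fractional CO₂ concentration and m(t) the animal's emission rate; the
simulator integrates this exactly per sample interval with the emission of
each interval computed in closed form, so the flow-weighted integral of the
excess over a whole record equals the emitted volume to numerical precision.
The bee is a square-wave emitter: during the open (burst) fraction of each
cycle it emits at `true_vco2 / burst_fraction`, otherwise nothing. Defaults:
V̇CO₂ 0.002 ml min⁻¹, cycle period 120 s, burst fraction 0.3, FR
100 ml min⁻¹, washout time constant 12 s (≈ chamber + analyser-cell volume
over flow), 1 Hz sampling, 2 min baselines, 10 min settling at each end of a
60 min measurement. Analyser drift is linear in time (matching the linear
drift-correction model used downstream) and noise is additive Gaussian on
ppm. A `cycle_jitter_sd` parameter perturbs per-cycle periods; its realistic
magnitude is unknown, so it defaults to 0 and tests that need irregular
cycles set it explicitly. A washout gap (default 150 s ≈ 12 τ) separates
animal removal from the post-baseline so the baseline samples clean
incurrent air; the decay tail remains part of the record, which is what
makes whole-record CO₂ conservation exact rather than approximate.

Trait derivation follows the standard protocol: OLS drift line through
pre+post baselines; settling trim; burst detection on the baseline-subtracted
signal smoothed by a 5 s centred moving mean, with entry threshold
max(3 × scaled MAD of the quietest 30% of samples, 10% of the 95th-percentile
excess, 1 ppm), exit at half the entry threshold, minimum burst 5 s, minimum
interburst 10 s. All constants sit in `DetectOpts`. A run already above
threshold at the first sample is discarded (its true start is
unobservable). Burst-start-to-burst-start spans define cycles because that
is the only boundary the detector locates sharply; since every cycle's onset
is detected with the same systematic offset, the k-cycle span — and hence
FGE — is unbiased even when individual onsets are found a second or two
late.

Two FGE denominators are implemented. The field protocol this mirrors
measures "first breath to end of seventh breath", which omits the final
interburst and so overestimates frequency slightly; the default here uses
start-of-burst-1 to start-of-burst-8 (seven true periods) when an eighth
burst exists, falling back to the protocol span otherwise, and
`mode="first_to_last_burst_end"` forces the protocol definition. Metabolic
rate is averaged over the same whole-cycle span (the 7-cycle window, not the
full 40 min), which makes the estimate invariant to where the window starts;
negative instantaneous values are retained because clipping would bias the
mean upward. Records with fewer than 7 complete cycles are excluded by
default (flagged, not raised); an opt-in accepts ≥ 3 cycles with a flag.

STP flow correction is FR·(273.15/(273.15+T))·(P/101.3)·(1−f_H₂O); the
water-vapour dilution term is the standard one, applied only when ambient
metadata are supplied (mass-flow-controlled systems already deliver STP
flow).

## Climate

SVP uses the Tetens form with constants 0.61078 kPa / 17.27 / 237.3 °C,
exposed as keyword arguments so a Magnus variant can be swapped in; the
exact constants behind published site tables are not always stated, and this
family is standard. VPD = SVP(T_min) − VP is floored at zero with a warning:
climatological monthly means can put VP above SVP at the coldest-month
temperature, and a negative deficit is non-physical for the hypothesis being
tested.

## Synthetic trait tables

Sites sit on an exactly linear altitudinal gradient: T_min falls 5 °C and
P_dry rises 100 mm per 1000 m, with a 100 mm rain-shadow offset on the wet
side (10 dry / 6 wet sites by default, both sides spanning the gradient).
VP is a side-specific relative humidity (0.75 dry / 0.88 wet) times
SVP(T_min), keeping VPD positive. Per bee, log₁₀ MR is linear in log₁₀ mass
(0.76), T_min (−0.041 °C⁻¹) and P_dry (−0.002 mm⁻¹) plus Gaussian block,
channel and residual effects (SD 0.04 / 0.025 / 0.11, set so the generating
model's marginal R² sits near 0.55); FGE is linear in log₁₀ MR with
species-specific slopes (steeper for lowland species), plus a mass term and
its own noise, with the intercept (3.0) placed so FGE stays positive across
the design. Four species occupy altitude-limited ranges — one spanning the
whole gradient (sampled at double weight, mimicking a dominant generalist),
one lowland, two highland — and bees are shuffled into blocks of 7 channels
so blocks cut across sites and the random intercepts are identifiable.

Because T_min and P_dry are *exact* linear functions of altitude (per side),
the altitude and T_min candidate models are identical fits on synthetic
data, and the combined T_min+P_dry fixed effect reduces to a small
within-side trend plus a wet/dry contrast. Real site tables carry
geographic scatter that the generator deliberately omits; passing tests
therefore demonstrate correctness of the machinery under the stated
generative model, not robustness to messy geography. VIF between T_min and
P_dry under the default design is ≈ 1.46, comfortably under the usual
screen of 2.

## Mixed models and model comparison

Crossed random intercepts for block and channel are expressed as variance
components on a single trivial group (the standard encoding in
`statsmodels.MixedLM`). Fits use full maximum likelihood by default because
the candidate models differ in fixed effects; REML is available. Several
optimisers are tried in sequence before a fit is declared non-converged;
non-converged models are kept in the table, flagged, and excluded from the
Akaike-weight normalisation. AIC is −2ℓ + 2k with k = fixed effects +
variance components + 1 (residual), which matches the parameter counts of
the usual mixed-model software. Marginal R² is the variance of the fixed
linear predictor over the total (fixed + components + residual), computed
with ddof = 1. Denominator df for the t statistics use the containment-style
approximation n − n_blocks − n_channels, documented as an approximation.
Listwise deletion over the union of all columns referenced by a candidate
set is applied once, before all fits, so every AIC describes the same rows.

## Covariation stage

Per-species slopes come from FGE ~ log₁₀ MR + log₁₀ mass with the same
crossed intercepts; species with n < 10 or singular fits are excluded with
warnings. Species climate is the unweighted mean over individual bees, so
sites weight by how many bees were collected there ("mean collection
altitude" semantics); a per-site-unweighted alternative would be trivial to
add but is not the default. The second-stage regressions are unweighted OLS
(a 1/se² weighting is available but off by default), with Gaussian AIC
n·log(2πRSS/n) + n + 2(k+1) so first- and second-stage tables share a
scale. With four species a two-parameter model leaves two residual df:
AICs are finite and reported, but this comparison is intrinsically fragile
and is documented as such wherever it surfaces.

## Numerical and testing choices

Simulations in the test and acceptance suites use the default design
(16 sites × 13 bees = 208 individuals) and 20–100 replicate tables per
Monte-Carlo check — enough for stable pass/fail behaviour at a few minutes
of runtime. Determinism is by `numpy.random.default_rng(seed)` throughout;
identical parameters and seed give byte-identical outputs. Degenerate
inputs (flat traces, single-level random factors, aliased fixed effects,
supersaturated sites, rank-deficient second-stage regressions) are handled
by flags or errors as described above rather than silent NaNs.

## Known limitations

- The burst-shape model (square wave × first-order washout) omits activity
  artifacts, temperature ramps, multi-gas channels and within-burst
  structure; detection constants were chosen for this shape family.
- The generator's exact climate linearity makes altitude and T_min models
  indistinguishable on synthetic data (see above).
- Containment df and the marginal R² decomposition are approximations with
  crossed random effects; p-values should be read accordingly.
- The published field benchmark (four bee species on a tropical altitudinal
  gradient) can only be reproduced when the per-bee trait table is supplied
  at `data/dataset1_traits.csv`; the repository does not include it.
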
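# respclim

Flow-through respirometry trace processing and trait–climate mixed-model
inference for discontinuously breathing insects.

## The problem

Two long-debated hypotheses link insect physiology to climate. The
**metabolic cold adaptation (MCA)** hypothesis predicts that ectotherms from
cold environments evolve higher temperature-specific metabolic rates; the
**hygric hypothesis** predicts that dry environments select for
discontinuous gas exchange (DGC) and lower gas-exchange frequency, limiting
respiratory water loss. Because the frequency of gas exchange (FGE) rises
with metabolic rate (MR), the two traits must be analysed together. This
package implements the full analysis chain used to test both hypotheses
along an altitudinal climate gradient — such as the Fijian bee system it was
built around — and a synthetic-data module that makes every stage testable
with known ground truth.

## What it computes

**Traces → traits** (`respclim.respiro`). A recording is a ~1 Hz excurrent
CO₂ series (ppm) from a chamber flushed at mass-flow-controlled rate FR
(ml min⁻¹, STP), bracketed by empty-chamber baselines. Analyser drift is
removed by an OLS line through the baselines (giving the incurrent fraction
*F*i(t)); settling-in/out periods are discarded; CO₂ bursts are detected by
a robust threshold with hysteresis, and consecutive burst starts delimit DGC
cycles. Metabolic rate is the average of

&nbsp;&nbsp;&nbsp;&nbsp;V̇CO₂(t) = FR · (*F*e − *F*i) / (1 − *F*e)

over the first seven whole cycles, and FGE = 7 / span (min⁻¹) over the same
span.

**Climate** (`respclim.climate`). Saturated vapour pressure by the Tetens
relation SVP = 0.61078·exp(17.27·T/(T+237.3)) kPa and vapour pressure
deficit VPD = SVP(T) − VP, floored at zero.

**Inference** (`respclim.inference`). Two a-priori sets of five Gaussian
linear mixed models (climate term one of T_min, P_dry, VPD, T_min+P_dry,
altitude; log₁₀ mass always included; FGE models also carry log₁₀ MR;
measurement block and analyser channel as crossed random intercepts), fitted
by maximum likelihood and compared by AIC, ΔAIC, Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) and marginal R²
(σ²_fixed / (σ²_fixed + σ²_block + σ²_channel + σ²_resid)), with a VIF
collinearity screen.

**Covariation** (`respclim.covariation`). Per-species mass-adjusted FGE~MR
slopes (mixed models, n ≥ 10 rule), species climate summarised as the mean
over collected individuals, and five OLS regressions of slope on climate
compared by AIC and R².

**Synthetic data** (`respclim.synth`). DGC traces as a square-wave emitter
convolved with first-order chamber washout (drift, noise, jitter
configurable; conservation of CO₂ holds by construction) and trait tables
with the full generative structure above on a 16-site rain-shadow gradient.

## Worked example

```python
import respclim as rc

params = rc.TraceSimParams(true_vco2=0.002, cycle_period=120.0,
                           noise_sd=2.0, drift_slope=0.5, seed=42)
trace, truth = rc.simulate_trace(params)
record = rc.measure_bee(*rc.split_record(trace, truth))
print(record.vco2_ml_min, record.fge_min)
```

prints `0.002016 0.499`: despite noise and a 0.5 ppm min⁻¹ analyser ramp,
the 7-cycle average recovers the true 0.002 ml min⁻¹ within 0.8% and the
true 0.5 cycles min⁻¹ within one part in 500. On the modelling side,

```python
table, truth = rc.simulate_trait_table(rc.TraitSimParams(seed=7))
data = rc.prepare_traits(table)
print(rc.compare_models(rc.build_mca_set("within"), data).round(3))
```

ranks `T_min+P_dry` first (weight 1.000, marginal R² 0.66 for that seed)
with the fitted coefficients within sampling error of the generating values
(mass 0.76, T_min −0.041 °C⁻¹, P_dry −0.002 mm⁻¹) — the model-selection
machinery recovers the climate structure that was simulated into the data.
The scripts in `examples/` walk through each capability; the `respclim`
command exposes the same stages (`respclim simulate traits --seed 0 --out
traits.csv`, `respclim models compare ...`, `respclim covary ...`).

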
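# popcode

Population-code modelling of grating detection and spatial-frequency
discrimination in filtered visual noise.

## The scientific problem

When human observers discriminate the spatial frequencies of two gratings,
an ideal decoder of the underlying V1 population response only needs the
likelihoods of the two frequencies that can actually occur on a trial.
Spectrally filtered noise backgrounds (low-pass or high-pass around the
5.5 c/deg standard) distort the *likelihood function* of spatial frequency
mainly at task-irrelevant frequencies — so an ideal observer is essentially
unbiased, while an observer who reads the likelihood function out with
broad weighting functions inherits the distortion as a perceptual bias:
perceived frequency shifts toward the noise pass-band.  Jointly modelling
2AFC contrast detection and frequency discrimination therefore separates
how much frequency information is *encoded* from how precisely it is
*read out*.

`popcode` implements this analysis end to end for computational
psychophysicists:

* **Encoder** — a bank of 100 V1-like channels obeying the normalization
  model.  The mean rate of neuron *i* to a grating (frequency f_g,
  Michelson contrast c) in noise N is

  ```
  R_i = R_sp + a_exc·E_N + R_max · (c·E_s)^p / (c50^p + (c·G_s)^p + (a_inh·G_N)^p)
  ```

  with Gaussian spatial-frequency tuning on the octave axis (FWHH 0.9 oct
  excitatory, 2.9 oct gain pool), E/G the excitatory and gain-pool drives
  by the grating or noise amplitude spectrum, and spike-count variance
  `k·mean` with k = 1.5.
* **Decoder** — the reduced Poisson log likelihood
  `L(f) = Σ_i n_i · h_i(f)` (h_i the log of the neuron's assumed noise-free
  tuning curve), read out by unit-mass Gaussian read-out functions of FWHH
  `w` octaves centred on the trial's grating frequencies; interval decisions
  maximize the read-out log-likelihood ratio, and an efficiency parameter
  in (0, 1] rescales the decision signal-to-noise ratio.  `w → 0` is the
  ideal precision-pooling limit.
* **Inference** — binomial maximum likelihood throughout: Weibull
  psychometric fits with parametric Monte-Carlo bootstrap; joint
  total-deviance minimization of the population model over detection and
  discrimination data (multi-start Nelder–Mead on transformed parameters);
  AIC model comparison against a theory-free Weibull-per-condition
  reference; constrained (width ≈ 0) nested fits and read-out-width sweeps
  for the ideal-observer analysis.
* **Synthetic observers** — the experimental designs (8 log-spaced
  comparison frequencies 1.9–15.6 c/deg × 6 noise pairings × 100 trials;
  16/16/9 detection contrast levels in no/broadband/notched noise; the
  strong-bias control) simulated from the model itself, so every pipeline
  stage is testable without human data.

## Worked example

Simulate a paper-scale observer with a 4.2-octave read-out, then refit the
model from its choices alone:

```python
from popcode import (ModelParams, PopulationCodeModel, make_design,
                     simulate_observer, ideal_observer_analysis)

truth = ModelParams.defaults()          # encoder + 4.2-octave read-out decoder
disc = simulate_observer((truth.population, truth.decoder),
                         make_design("discrimination_main"), seed=1)
det = simulate_observer((truth.population, truth.decoder),
                        make_design("detection"), seed=2)
model = PopulationCodeModel(detection=det, discrimination=disc)
res = model.fit(restarts=2, seed=0, maxiter=1500, fatol=1e-3)
print(res.summary())
```

```
Population-code model fit
==========================================================
free parameters             7
restarts                    2
converged                   True
deviance (detection)        36.30
deviance (discrimination)   45.95
deviance (total)            82.25
log likelihood              -181.75
AIC                         377.50
----------------------------------------------------------
parameter         estimate  status
bw_exc              0.9034  free    oct
bw_gain              2.952  free    oct
c50                0.02968  free
a_exc                 4.05  free    Hz
a_inh               0.1195  free
width                4.496  free    oct
efficiency               1  free
```

The fit recovers the generating excitatory bandwidth (0.90 oct), gain-pool
bandwidth (2.95 oct), semisaturation contrast (3.0%) and read-out width
(4.5 vs 4.2 oct generating) from 8 900 binary choices.  The ideal-observer
sweep then shows the bias/accuracy trade-off as read-out width shrinks:

```python
print(ideal_observer_analysis(res.params, widths=[0.0, 1.5, 4.2]).round(3))
```

```
 width  pct_correct  bias_main_lowpass  bias_main_highpass  bias_control_lowpass  bias_control_highpass
   0.0        0.960              0.015              -0.014                -0.014                  0.013
   1.5        0.950             -0.050               0.050                 0.045                 -0.046
   4.2        0.857             -0.279               0.634                 0.166                 -0.472
```

Biases are in octaves relative to the 5.5 c/deg standard: at the fitted
width the model perceives the standard ~0.3 oct lower in low-pass noise and
higher in high-pass noise, while the zero-width ideal observer is
essentially unbiased and gains ~10 percentage points of accuracy.

A command-line interface wraps the same pipeline:

```bash
popcode simulate --task discrimination --seed 1 --out trials.csv
popcode fit --discrimination trials.csv --out fit.json
popcode predict --widths 0,1.5,4.2 --out sweep.csv
```

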
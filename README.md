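# plaidpss

Analysis tools for studying how visual motion integration develops in the
ferret motion pathway (V1 → PSS, the posterior suprasylvian area, a
higher-order motion area analogous to primate MT/V5).

A drifting *plaid* — two superimposed gratings whose directions differ by an
angle dOri — is perceived to move in the *pattern* direction that bisects the
two *component* directions. A neuron can respond either to the integrated
pattern motion ("pattern cell") or to the individual components ("component
cell", whose 2D tuning over dOri × direction shows a characteristic V shape).
This package provides, as a tested pipeline over synthetic spike-count data:

- **Stimulus spaces and synthetic data** — the streaming paradigm (16 grating
  directions, 7 dOri × 16 plaid directions, blank; 3 Hz update) and the
  classic paradigm (16 gratings, 16 dOri = 135° plaids, 1 s trials);
  ground-truth model neurons and per-trial Poisson spike counts.
- **Tuning metrics and screens** — DSI/OSI, ANOVA-based responsiveness and
  tuning screens, relative plaid response strength and the Wilson–Hilferty
  (cube-root) transform.
- **Pattern/component classification** — pattern and component predictions
  built from each neuron's dOri curve and direction tuning curves, partial
  correlations r_P and r_C, Fisher Z scores
  `Z = sqrt(N − 3) · atanh(r)` (N = 112 streaming, 16 classic), the
  pattern index `max(Z_P, 0) − max(Z_C, 0)` and the standard one-sided
  p = 0.1 classification boundary (Z difference > 1.28).
- **A two-stage motion-pathway model** — 16 V1 direction channels derived
  from a mean V1 response profile (symmetrised, opponency-corrected
  `P − P(o)·O`, rectified), integrated by an excitatory/inhibitory von Mises
  weight function and passed through an exponential output nonlinearity
  `resp = Resp_max · L̂^T_PSS`. Free parameters K_E, K_I, I, T_PSS and
  Resp_max are fit per neuron by Poisson maximum likelihood with bounded
  dual annealing (`MotionPathwayModel.fit()` → `MotionPathwayResults`),
  summarised as the weight-component areas W_exc and W_inh.
- **In-silico developmental perturbations** — raising inhibition (I) or
  broadening excitation (K_E) to match target population-mean W_inh/W_exc,
  swapping the V1 front end between age-like presets, and population
  summaries (aligned average profiles, pattern-index distributions).
- **Statistics** — Welch's t with d′, a resampling median-difference test for
  unequal group sizes, two-way ANOVA with interaction (Type II), rank-sum,
  and Fisher-z comparison of correlations.

## Worked example

```python
import plaidpss as pp

stim = pp.build_streaming_set(reps=10)
bank = pp.build_v1_bank(pp.v1_profile_preset("young"))
neuron = pp.simulate_population(1, seed=42)[0]
trials = pp.generate_trials(neuron, stim, bank, seed=7)

profile = pp.mean_responses(trials, stim)
scores = pp.score_profile(profile, "streaming")
print(f"class={scores.cls}  pattern index={scores.pattern_index:.2f}")

res = pp.MotionPathwayModel(trials, bank).fit(seed=0)
print(res.summary())
```

prints

```
class=pattern  pattern index=7.70
Motion-pathway model fit (Poisson ML, dual annealing)
------------------------------------------------------
pref direction       180.0 deg
K_E                 1.7213
K_I                 1.8492
I                   2.0000
T_PSS               2.1539
Resp_max            7.0268
W_exc               5.4071
W_inh              10.3528
fit r               0.9782
log-likelihood     -293.11
```

The neuron's noisy trial data classify it as a pattern cell (Z_P exceeds Z_C
by more than the 1.28 boundary). The fit reports the excitatory concentration
K_E, the inhibition amplitude I and width K_I (summarised as the area W_inh),
the output exponent T_PSS, the rate scale Resp_max, and the model–data
correlation (fits with r < 0.5 are conventionally discarded). Note that
W_inh is only weakly identified per neuron at 10 repetitions — the likelihood
constrains the net weight-function shape, not its excitatory/inhibitory
decomposition — so per-neuron W_inh estimates carry wide uncertainty even
when the fit correlation is high (see `docs/methods.md`).

A thin CLI mirrors the library: `plaidpss simulate | screen | classify |
fit | experiment`.

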
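# camoccu

Multispecies occupancy and diel-activity-overlap analysis for camera-trap
surveys, built around the kind of question island carnivore studies ask:
does a focal wild species (here, the European pine marten *Martes martes*)
co-occur with humans and free-roaming domestic cats in space, and how much
do their daily activity rhythms overlap in time?

The package covers the complete chain from tagged-video record tables to
the final tables:

- **`camoccu.camdata`** — independent detection events (1-min trigger
  rule), species × site × 1-day-occasion detection histories with an
  effort mask, covariate standardization and a Pearson collinearity screen.
- **`camoccu.msom`** — the S-species occupancy model with a multivariate
  Bernoulli latent state. The 2^S joint presence/absence states get
  probabilities through a multinomial-logit (softmax) link over *natural
  parameters*: first-order terms ƒ_s (one per species, covariate-driven),
  second-order terms ƒ_jk for pairwise dependence, orders above two fixed
  at zero and the all-absent state as reference:

  Ψ_z ∝ exp( Σ_{s: z_s=1} ƒ_s + Σ_{j<k: z_j=z_k=1} ƒ_jk ).

  Detection is an occasion-level logistic model per species. The
  marginal likelihood sums over states, handling imperfect detection;
  fitting is by maximum likelihood with the analytic score, and
  predictions (state, marginal and conditional occupancy) carry
  delta-method or parametric-bootstrap SEs.
- **`camoccu.selection`** — hypothesis-driven multistep AIC selection:
  detection structures first (constant / Julian date / date² / lockdown
  phase), then marginal occupancy (vegetation + elevation², optionally
  distance to settlements, with an uninformative-parameter deviance
  check), then seven co-occurrence structures (independence, constant
  dependence, dependence varying with distance to roads/settlements and
  their elevation interactions).
- **`camoccu.activity`** / **`camoccu.solar`** — double-anchored solar
  time (each day's sunrise/sunset mapped to their study means), von Mises
  kernel density estimates, activity level 1/(2π·max f̂), the
  Ridout–Linkie overlap coefficients Δ̂1/Δ̂4/Δ̂5 with a smoothed
  bootstrap (five CI variants, bias-based selection), and Wald tests for
  activity-level differences.
- **`camoccu.simulate`** — a synthetic-study generator emulating the Elba
  Island design (77 sites in four sequential arrays from February to July
  2020, 30 one-day occasions, five vegetation classes, 0–1019 m
  elevation, lockdown window, bimodal crepuscular vs. unimodal diurnal
  activity mixtures), with the latent truth kept aside for
  parameter-recovery experiments.
- **`camoccu.pipeline`** — one-call orchestration
  (`run_pipeline`/`summarize`) writing the paper-shaped output tables.

## Worked example

```python
from camoccu.selection import multistep_select
from camoccu.simulate import SimulationScenario, gen_dataset

ds = gen_dataset(SimulationScenario(n_sites=77, structure_label="Mod1"),
                 seed=2, with_events=False)
rep = multistep_select(ds.history, ds.covariates, seed=0)
print(rep.conditional_table.round(2))
```

prints the step-3 AIC ranking of the co-occurrence structures:

```
label  K   loglik     AIC  dAIC  weight
 Mod1 20 -2503.01 5046.02  0.00    0.42
 Mod2 22 -2501.25 5046.51  0.48    0.33
Mod3B 24 -2500.19 5048.39  2.36    0.13
 ...
```

The data were generated under independence, and the independence model
(Mod1, all ƒ_jk = 0) indeed ranks first: there is no evidence that marten
occupancy depends on human or cat presence in this replicate, and the AIC
weight 0.42 quantifies that support. The activity side
(`examples/04_activity_overlap.py`) prints, for the same kind of
synthetic study,

```
marten vs human: Dhat4 = 0.10 [0.07, 0.12] (perc_corrected, bias +0.040)
  Wald W = 31.70, p = 0.000 -> different activity levels
marten vs cat: Dhat4 = 0.81 [0.76, 0.87] (perc_corrected, bias +0.026)
```

a low marten–human and a high marten–cat activity overlap, mirroring a
nocturnal mustelid sharing its rhythm with cats but not with people.

Each script in `examples/` is a short narrative of one capability:
ingestion (01), model fitting and prediction (02), model selection (03),
activity overlap (04), and the full pipeline (05).

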
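# bgdcm — spectral DCM of the motor basal-ganglia loop

`bgdcm` estimates **effective connectivity** — directed, causal coupling —
in a four-node motor circuit (primary motor cortex M1, motor putamen,
subthalamic nucleus STN, motor thalamus) from resting-state fMRI time
series, and relates those couplings to clinical covariates across a cohort.
It is aimed at researchers studying basal-ganglia circuit dysfunction
(e.g. in Huntington's or Parkinson's disease) who want a self-contained,
testable implementation of the full analysis chain:

1. **ROI extraction** — discrete-cosine (DCT) modelling of the
   0.0078–0.1 Hz resting-state band, F-map peak / correlation-based sphere
   placement, principal eigenvariates adjusted for motion and nuisance
   signals, framewise-displacement motion summaries.
2. **Spectral DCM** — a linear stochastic network `dx/dt = A x + v` with
   power-law neuronal innovations and hemodynamic observation; the model
   predicts the complex cross-spectral density
   `G_y(f) = H(f) G_v(f) H(f)* + G_e(f)` with
   `H(f) = diag(h(f)) (i2πf I − A)^{-1}`, fitted to a multivariate
   autoregressive CSD estimate by variational Laplace (free-energy
   maximization).  The `A` matrix carries six directed couplings (Hz) —
   the direct (PUT→THAL), indirect (PUT→STN→THAL) and hyperdirect
   (M1→STN) pathways plus cortical input and thalamo-cortical output — and
   inhibitory self-connections `−0.5·exp(θ)` on every node.
3. **Group inference** — parametric empirical Bayes (PEB): subject
   posteriors enter a hierarchical linear model
   `θ_i = (x_i' ⊗ I) β + ε_i` whose design holds an intercept (group mean)
   and mean-centred clinical covariates; Bayesian model reduction scores
   reduced models in closed form; a greedy search plus exhaustive scoring
   of the final ≤256 models yields Bayesian-model-averaged effects and a
   posterior probability (pp) per effect.
4. **Prediction** — Bayesian leave-one-out estimation of a held-out
   subject's covariate from their connectivity, with no leakage.
5. **Synthetic cohorts** — a generator that plants known group means,
   covariate effects, between-subject variability, clinical demographics
   and BOLD-like noise, so the entire chain is testable without any data
   download; it also builds toy 4-D NIfTI volumes for the extraction stage.

## Worked example

```python
from bgdcm import (canonical_scenario, default_priors, estimate_csd,
                   invert_subject, simulate_bold)
from bgdcm.network import DCMParams, ParamLayout

scenario = canonical_scenario()            # planted ground truth
subject = DCMParams.from_vector(scenario.mean_vector())
ts = simulate_bold(subject, scenario, seed=42)   # 161 volumes at TR 3 s
post = invert_subject(estimate_csd(ts), default_priors())
print(round(post.variance_explained, 1))
for name, true, est in zip(ParamLayout().names(), scenario.mean_vector(), post.mean):
    print(f"{name:<10} true {true:+.2f}  estimated {est:+.2f}")
```

prints (seed 42; first six lines):

```
84.6
M1->PUT    true +0.20  estimated +0.24
M1->STN    true +0.00  estimated -0.09
PUT->THAL  true +0.43  estimated +0.45
PUT->STN   true -0.17  estimated -0.05
STN->THAL  true -0.10  estimated -0.08
THAL->M1   true -0.39  estimated -0.55
```

i.e. a single 8-minute scan constrains each coupling to roughly ±0.1 Hz
(positive = excitatory, negative = inhibitory influence of the source on
the target's rate of change), and the model explains ~80% of the variance
of the cross-spectral data.  Averaging n = 30 such subjects hierarchically
recovers group means to ~±0.03 Hz — see `examples/03_group_inference.py`
for the cohort-level run with covariate effects and model search, and the
other `examples/*.py` scripts for extraction and the end-to-end pipeline.

A thin CLI mirrors the pipeline stages:

```bash
bgdcm simulate --n 30 --seed 1 --out cohort/
bgdcm invert --timeseries cohort/sub-001_timeseries.tsv --out post.json
bgdcm peb --posteriors posts/ --clinical cohort/clinical.tsv --design motor --out peb.json
bgdcm run-all --out run/ --n 8 --seed 3
```

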
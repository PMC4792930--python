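# specdcm

Spectral dynamic causal modelling of resting-state effective
connectivity, with Bayesian model comparison and brain–behaviour
statistics over a synthetic lifespan cohort.

## The problem

Correlation-based functional connectivity of resting-state fMRI
confounds neural coupling with neurovascular signalling — a serious
issue in aging studies, where the vasculature itself changes. Spectral
DCM addresses this by fitting a *generative* model to the complex
cross-spectral density of the BOLD signal: directed neural coupling
`A` (with inhibitory self-connections `-0.5·exp(a_ii)` Hz on the
diagonal), power-law endogenous fluctuations
`g_v(ω) = exp(α)·ω^(−β)` per node, and a linearized balloon-model
hemodynamic response per node (transit time, signal decay, and the
intravascular/extravascular ratio ε):

    G_y(ω) = K(ω) (iωI − A)⁻¹ G_v(ω) (iωI − A)⁻ᴴ K(ω)ᴴ + G_e(ω)

Parameters are estimated by variational Laplace (Gauss–Newton ascent on
the free energy F = accuracy − complexity); competing network
architectures are compared by Bayesian model selection over a
plausibility-constrained space of binary coupling patterns (for three
nodes: 512 candidates, 54 surviving self-connection and connectedness
rules) and combined by Bayesian model averaging. Group analyses then
relate the per-subject parameters to age (multiple regression) and to
six cognitive scores (canonical correlation analysis with structure
correlations, and a moderation model testing whether the
connectivity–cognition coupling strengthens with age), with
Benjamini–Hochberg FDR control and a Fisher-z functional-connectivity
reanalysis as the baseline.

The package is aimed at researchers who want a transparent, fully
scriptable implementation of this analysis chain — including a seeded
synthetic cohort generator that reproduces its statistical structure
(age-dependent coupling, fluctuation and hemodynamic parameters;
cognition generated from a connectivity profile with an age-moderated
slope), so every claim can be validated end to end without access to
restricted cohort data.

## Worked example

Simulate one 70-year-old subject at the cohort acquisition parameters
(255 volumes, TR = 1.97 s), estimate the cross-spectrum, and invert:

```python
import numpy as np
from specdcm import PriorSpec, invert
from specdcm.cohort import CohortConfig, draw_subject_parameters, simulate_bold
from specdcm.forward import default_frequency_grid, model_to_vector, parameter_names
from specdcm.spectra import TimeSeries, estimate_csd

cfg = CohortConfig()
rng = np.random.default_rng(0)
model = draw_subject_parameters(cfg, age=70.0, rng=rng)
bold = simulate_bold(model, n_volumes=255, tr=1.97, rng=rng)

freqs = default_frequency_grid(255, 1.97)          # 0.002–0.1 Hz band
obs = estimate_csd(TimeSeries(data=bold, tr=1.97), order=8, freqs=freqs)
fit = invert(obs, PriorSpec.default(3))

names = parameter_names(3)
true = model_to_vector(model)
print(f"converged={fit.converged} iterations={fit.iterations}")
print(f"free energy = {fit.free_energy:.1f} nats, "
      f"variance explained = {fit.variance_explained:.2f}")
for nm in ("a_0_1", "a_1_0", "self_0"):
    i = names.index(nm)
    sd = np.sqrt(fit.posterior_cov[i, i])
    print(f"{nm:7s} true {true[i]:+.3f}  posterior "
          f"{fit.posterior_mean[i]:+.3f} +/- {sd:.3f}")
```

prints

```
converged=True iterations=13
free energy = -115.4 nats, variance explained = 0.86
a_0_1   true +0.220  posterior +0.243 +/- 0.046
a_1_0   true +0.219  posterior +0.255 +/- 0.051
self_0  true +0.090  posterior -0.043 +/- 0.058
```

The two between-node couplings (Hz) are recovered within one posterior
standard deviation; the model explains 86% of the band variance of the
observed spectrum — at this series length the diagnostic typically
exceeds the 75% quality bar across a cohort. `reduce_model` then scores
any reduced coupling pattern analytically from this one fit, which is
how the 54-model space is searched.

The same pipeline runs from the shell on a YAML config
(`specdcm simulate | estimate-csd | enumerate | fit | bms | bma |
stats | report`); `specdcm enumerate` prints the model-space counts
(512 full, 54 plausible) and `specdcm report` collates counts, the BMS
winner and the group statistics into one JSON summary.

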
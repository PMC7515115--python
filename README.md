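# bayesmi

Bayesian estimation of the mutual information between two discrete variables
when one of them is severely undersampled.

## The problem

Measuring the statistical dependence between a variable **X** with a huge
state space (neural population activity patterns, genotypes, word contexts)
and a variable **Y** with only a few well-sampled states (a binary choice, a
phenotype) is routine — and routinely botched: with `N` samples far below the
effective number of joint states, the plug-in estimator

```
Î_plugin = Ĥ(X) + Ĥ(Y) − Ĥ(X,Y)
```

overestimates the information badly, reporting strong dependence even for
independent variables.

`bayesmi` implements a Bayesian estimator built for exactly this asymmetric
regime.  Writing `I(X;Y) = Σ_x q_x D_KL(q_{y|x} ‖ q_y)`, the information is a
measure of the *spread* of the conditionals `q_{y|x}` around the marginal
`q_y`.  The estimator therefore places an i.i.d. Dirichlet prior on the
conditionals, centered at the empirical marginal `q̂_y` with concentration β:

```
p({q_{y|x}} | β) = Π_x Dir(q_{y|x}; β q̂_y)
```

Large β ⇒ conditionals huddle around the marginal ⇒ little information;
small β ⇒ conditionals near the simplex corners ⇒ much information.  The
marginal likelihood `p(n|β)` is closed form and develops a peak as soon as
the sample contains a few **coincidences** (x states observed at least
twice) — singletons are uninformative about β.  For binary symmetric Y with
at most pairwise coincidences, the maximizing concentration is simply

```
β* = f11 / (1/2 − f11)        (+∞ when f11 ≥ 1/2)
```

where `f11` is the fraction of twice-sampled x states showing one count of
each y value.  The posterior mean and variance of I given β are
digamma/trigamma expressions; the estimator evaluates them at β* (or
integrates over an information-uniform prior on log β when there are ≤ 2
coincidences).  The result is non-negative, consistent, and nearly unbiased
deep into the undersampled regime.  An optional Dirichlet-process prior on
`q_x` (concentration α) accounts for never-observed x states.

## Worked example

```python
import numpy as np
from bayesmi import MutualInfoModel
from bayesmi.generators import make_py_beta_model, sample_counts

model = make_py_beta_model(beta=2.3, seed=7)   # PY(0.55, 50) marginal, Beta(1.15, 1.15) conditionals
print("true I:", round(model.information, 4))  # true I: 0.1526

table = sample_counts(model, 500, seed=11)     # 500 samples, ~1000 effective joint states
print(MutualInfoModel(table).fit().summary())
```

```
        Bayesian Mutual Information
==============================================
I (posterior mean)        0.164608 nats
I (posterior sd)          0.012847 nats
95% interval          [0.139428, 0.189787]
H(Y) plug-in              0.693139 nats
plug-in I                 0.420481 nats
----------------------------------------------
beta (MAP)                 2.39901
alpha (MAP)           ---
method                map
N                     500
observed x states     237  (k_y = 2)
coincidences          78
f11                   0.3235294117647059
==============================================
```

With 500 samples spread over ~1000 effective joint states, the plug-in
estimate (0.420 nats) is nearly three times the true information (0.153
nats); the posterior mean (0.165 ± 0.013 nats) brackets the truth.  The
fitted β ≈ 2.4 recovers the concentration (2.3) that generated the
conditionals, from the coincidence statistics alone.

The same estimator is available from the shell:

```bash
bayesmi simulate --family py_beta --n 500 --seed 7 --out counts.tsv
bayesmi estimate --input counts.tsv --units nats
bayesmi bench --figure 2d --replicates 50 --seed 0 --out fig2d.csv
bayesmi calibrate --models 13500 --seed 0 --out calibration.csv
```

## What is in the package

* `bayesmi.counts` — contingency tables, multiplicity sufficient statistics,
  long-TSV / dense-CSV / pair-list readers and writers.
* `bayesmi.estimator` — β marginal likelihood, β*/α* inference, posterior
  mean and variance of I, the information-uniform prior on log β.
* `bayesmi.model` — `MutualInfoModel` / `MutualInfoResults` (fit, summary,
  confidence intervals, likelihood profiles).
* `bayesmi.baselines` — plug-in entropies/information, exact information of
  known joint models.
* `bayesmi.generators` — the three benchmark families (Pitman–Yor × Beta,
  rotation-invariant sphere, Bernoulli-parity mixture) plus the
  Dirichlet-process calibration ensemble.
* `bayesmi.experiments` — bias-versus-N and bias-versus-information curves,
  and the multiplicity-class calibration study.

See `docs/methods.md` for the model, its assumptions, and numerical choices.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the mean effective size `exp(H_XY)` of the
Pitman–Yor/Beta benchmark ensemble (100 draws); the effective size of the
tuned sphere model (exact 4096-state enumeration); and the fraction of
calibration-ensemble cases (13,500 models × 5 samples of N = 40) covered by
the 100 most frequent multiplicity classes.  Runtime is about a minute.
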
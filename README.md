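# irtkit

An estimation laboratory for one- and two-parameter logistic item
response theory (IRT) models, built for methodologists who want to
compare estimators — and prior choices — under controlled simulation.

Binary response data $y_{ik} \in \{0,1\}$ for persons $i = 1..S$ and
items $k = 1..L$ are modelled as

$$P(Y_{ik}=1 \mid \theta_i, b_k, a_k) = \frac{e^{a_k(\theta_i-b_k)}}{1+e^{a_k(\theta_i-b_k)}},$$

with ability $\theta_i$, difficulty $b_k$, and discrimination $a_k$
(fixed at 1 for the 1PL / Rasch model). Four estimators share one data
model and one evaluation pipeline:

* **CML** — conditional maximum likelihood for the 1PL via elementary
  symmetric functions, sum-to-zero normalization, ML person scoring;
* **MML** — Bock–Aitkin EM against a fixed N(0,1) ability distribution
  on a 41-node quadrature grid;
* **MCMC** — Metropolis-within-Gibbs with adaptive random-walk proposals
  and exact conjugate draws for hierarchical hyperparameters
  (burn-in 5000 / retain 1000 by default), plus PSRF / multivariate PSRF /
  Heidelberger–Welch diagnostics;
* **VB** — coordinate-ascent mean-field variational Bayes using the
  Saul–Jordan bound on the logistic function, with closed-form
  hierarchical hyper-factor updates.

The Bayesian estimators run under three prior regimes: **matched** (the
generating distributions), **standard vague** (variance 10³ difficulty
prior, variance-8 log-discrimination prior), and **hierarchical**
(normal-gamma hyperpriors). A study harness crosses sample size
(250–2000) × test length (10–40) × method with paired data, applies the
shift/scale identifiability alignment, and reports average RMSEs,
average SEs, marginal tables and η² ANOVAs.

## Worked example

```python
import numpy as np
import irtkit

truth = irtkit.draw_parameters(500, 10, "1PL", seed=7)
data = irtkit.simulate_responses(truth, seed=7)

cml = irtkit.fit_cml(data)
_, vb = irtkit.fit_vb(data, "1PL", irtkit.make_prior("matched", "1PL"))

res = irtkit.align(cml, truth, "1PL")
print(np.round(cml.difficulties, 2))
print(f"alignment shift t = {res.t:+.3f}")
```

```
CML difficulty estimates (sum-to-zero):
[-0.41  0.32  1.11  1.54  0.71 -2.25 -1.27  0.76 -0.37 -0.16]
true difficulties:
[ 0.21  0.67  1.61  1.8   1.04 -1.76 -0.76  1.23 -0.04  0.17]
alignment shift t = +0.422
CML difficulty RMSE (aligned): 0.110
VB  difficulty RMSE (aligned): 0.105
CML ability RMSE: 0.881
VB  ability RMSE: 0.604
mean ability SE: CML 0.83, VB 0.59
```

The CML difficulties are estimated up to a location (their sum is
constrained to zero); the alignment step finds the shift (+0.42 here,
the sample mean of the true difficulties) before errors are measured.
Both methods recover the difficulties to about 0.11 RMSE at S = 500.
The ability columns show the characteristic gap on a 10-item test:
person-wise ML (used by CML) has RMSE 0.88 — extreme scores must be
clamped and every person is scored from only 10 responses — while the
Bayesian posterior mean shrinks toward the population distribution and
reaches 0.60, with correspondingly smaller SEs.

## Command line

```sh
irtkit simulate --model 1PL -S 500 -L 20 --seed 7 -o data.csv --truth truth.csv
irtkit fit data.csv --method VB-hierarchical --model 1PL -o estimates.csv
irtkit study config.yaml -o results/          # crossed design; resumable
irtkit report results/results_1PL.csv --table T3
irtkit anova results/results_1PL.csv --metric rmse_b
```

A study config is a YAML file mirroring `StudyDesign`:

```yaml
model: 1PL
sample_sizes: [250, 500, 1000, 2000]
test_lengths: [10, 20, 40]
methods: [CML, MML, MCMC-matched, VB-matched, VB-hierarchical]
replications: 100
root_seed: 1
```

Finished cells are persisted as CSV and skipped on re-run; within a
replication every method consumes the identical response matrix.

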
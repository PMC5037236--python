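# Methods

## Model

For person $i = 1..S$ and item $k = 1..L$, the two-parameter logistic
(2PL) model gives the probability of a correct response as

$$P(Y_{ik}=1 \mid \theta_i, b_k, a_k) = \sigma\!\big(a_k(\theta_i - b_k)\big),
\qquad \sigma(x) = \frac{e^x}{1+e^x},$$

with ability $\theta_i$, difficulty $b_k$ (both on the logit scale) and
discrimination $a_k > 0$. The 1PL (Rasch) model fixes $a_k = 1$.
Responses are conditionally independent given the parameters.

The 2PL likelihood is invariant under
$(\theta, b, a) \to (s\theta + t,\; sb + t,\; a/s)$ for any $s > 0$; the
1PL retains the shift invariance only when difficulties are allowed a free
location. All error metrics therefore act on estimates aligned to the
truth's representative of the equivalence class (see *Alignment*).

## Synthetic data

`irtkit.draw_parameters` draws $\theta_i, b_k \sim N(0,1)$ iid and, for
the 2PL, $a_k \sim \mathrm{LogNormal}(0, 0.25^2)$ (log-SD 0.25, so the
median slope is 1). `irtkit.simulate_responses` sets
$y_{ik} = \mathbf{1}\{u_{ik} < P_{ik}\}$ with iid $u_{ik} \sim U(0,1)$.
Both consume separate child streams of a single integer seed
(`numpy.random.SeedSequence`), so a dataset is exactly reproducible and
can be re-materialised piecewise.

In the study harness the data seed is derived from
(root seed, model, S, L, replication index) and **not** from the
estimation method: all estimators within a replication see the identical
response matrix, making method comparisons paired.

What the generator emulates — and does not. It produces complete
dichotomous response matrices from a correctly specified logistic model
with a standard-normal ability population. Real data depart from this in
ways the generator deliberately omits: non-normal or multimodal ability
distributions, guessing (a nonzero lower asymptote), missing responses,
local dependence between items, and drift of item parameters across
groups. Passing recovery tests here demonstrates correctness of the
estimators *under the model*, not robustness to those violations.

## Estimators

### Conditional maximum likelihood (1PL only)

Under the Rasch model the raw score $r_i = \sum_k y_{ik}$ is sufficient
for $\theta_i$, so item difficulties are estimated from the likelihood
conditional on raw scores, which is free of the person parameters.
Writing easiness $\epsilon_k = e^{-b_k}$, the conditional likelihood is
built from the elementary symmetric functions
$\gamma_r(\epsilon) = \sum_{|A|=r} \prod_{k \in A} \epsilon_k$, computed
by the summation recursion (all terms positive, numerically stable;
the difference recursion is avoided). First- and second-order
leave-one-out/two-out tables are computed by running all reduced
recursions simultaneously, giving the analytic gradient and the full
observed information of the conditional log-likelihood.

Newton–Raphson runs in the sum-to-zero subspace (the conditional
likelihood is location-invariant; the constraint picks a representative),
with step-halving and convergence at max |gradient| < 1e-8 (at most 100
iterations). Item SEs come from the inverse information restricted to the
sum-zero subspace. Persons with extreme raw scores (0 or perfect) carry
no conditional information and are excluded from item estimation; *all*
persons are then scored by ML (below).

### ML ability scoring

Given item parameters, each person's log-likelihood is strictly concave
in $\theta$; a damped Newton iteration from 0 converges for every
non-extreme pattern. Extreme raw scores have no finite maximiser and are
assigned $\hat\theta = \pm 4.0$; they are retained in all downstream
error metrics, so the RMSE denominators always count all S examinees.
The SE is $1/\sqrt{I(\hat\theta)}$ with
$I(\theta) = \sum_k a_k^2 p_k(1-p_k)$ (evaluated at the clamp for extreme
scores). The clamp value 4.0 sits beyond the 0.9999 quantile of the
generating ability distribution while keeping the squared errors of
extreme-score persons finite and comparable across methods.

### Marginal maximum likelihood (Bock–Aitkin EM)

Item parameters maximise the likelihood marginalised over a fixed
$N(0,1)$ ability distribution, approximated on 41 equally spaced nodes on
$[-5, 5]$ with normal-density weights renormalised to 1 (the classic
fixed-grid choice). The E-step computes each person's posterior node
weights; the M-step is a per-item weighted logistic regression of
expected correct counts on node locations (slope fixed at 1 for the 1PL),
solved by damped Newton with step-halving on the per-item expected
complete-data objective — which is concave, so EM monotonicity is
guaranteed and asserted on every cycle. Convergence: max parameter change
< 1e-5, at most 500 cycles. Items drifting past $|b| > 10$ or $a > 20$
are clamped and flagged (Heywood-type divergence). The latent
distribution is never updated. Item SEs are per-item observed information
of the marginal likelihood (cross-item blocks ignored), obtained by
central-differencing the Fisher-identity score; the $(c, a)$
parameterisation ($\eta = a x + c$, $b = -c/a$) is mapped to $(b, a)$ by
the delta method. Abilities are scored by ML as above.

### Metropolis-within-Gibbs MCMC

Latent blocks ($\theta$, $b$, and for the 2PL $\log a$) are updated by
univariate Gaussian random-walk Metropolis steps against their full
conditionals; all coordinates of a block update simultaneously
(they are conditionally independent given the other blocks), which keeps
the per-iteration cost at three likelihood-matrix evaluations.
Discriminations are sampled on the log scale, where the lognormal prior
is normal and positivity is automatic.

Under the hierarchical regime the normal-gamma hyperparameters are drawn
exactly from their conjugate full conditionals: for latents
$x_1..x_n \sim N(m, 1/u)$ with $m \sim N(0, 10^6)$ and
$u \sim \mathrm{Gamma}(1, 1)$ (shape-rate),

$$m \mid x, u \sim N\!\Big(\tfrac{u\sum x}{nu + 10^{-6}},\;
\tfrac{1}{nu + 10^{-6}}\Big), \qquad
u \mid x, m \sim \mathrm{Gamma}\!\Big(1 + \tfrac{n}{2},\;
1 + \tfrac{\sum(x-m)^2}{2}\Big).$$

Proposal SDs adapt only during burn-in (multiplicative updates every 50
iterations targeting acceptance rates in [0.3, 0.5]; wider initial
proposals under the variance-1e3 difficulty prior); the post-burn-in
kernel is fixed, so retained draws come from a valid Markov chain.
Initial values: all locations 0, hierarchical SDs 1. The default chain
protocol discards 5000 iterations and retains 1000; point estimates are
posterior means and reported SEs posterior SDs (n−1 divisor). Sampler
correctness is enforced by tests against dense-quadrature exact
posteriors on tiny instances for every prior regime.

Convergence diagnostics: univariate PSRF
$\sqrt{\hat V / W}$ with $\hat V = \frac{n-1}{n} W + B/n$, the
multivariate (largest-eigenvalue) analogue, and the Heidelberger–Welch
half-width test with spectral density at zero estimated from an AIC-chosen
Yule–Walker AR fit.

### Variational Bayes (Saul–Jordan bound)

The posterior is approximated by a fully factorised family: Gaussian
factors for every $\theta_i$, $b_k$ and (2PL) $\log a_k$, plus Gaussian
factors for hierarchical hyper-means and Gamma factors for hierarchical
precisions. Minimising KL(q ‖ posterior) is equivalent to maximising the
evidence lower bound; the intractable term $E_q[\log(1+e^{\eta_{ik}})]$
is replaced by the Saul–Jordan upper bound with one variational parameter
$\xi_{ik} \in (0,1)$ per response,

$$E[\log(1+e^Z)] \le \xi m + \log\!\big(e^{-\xi m + \xi^2 v/2}
+ e^{(1-\xi)m + (1-\xi)^2 v/2}\big), \quad Z \sim N(m, v),$$

which is exact at $v = 0$ and minimised in $\xi$ at the fixed point
$\xi = \sigma(m + (1-2\xi)v/2)$ (solved by a safeguarded Newton
iteration). The resulting objective is a true lower bound on the log
evidence for the 1PL, verified against dense-quadrature marginals in the
tests.

2PL logit moments: $\eta_{ik} = a_k(\theta_i - b_k)$ is not Gaussian
under $q$; its exact first two moments under the factorised $q$ (using
the lognormal moments $E[a] = e^{\mu + v/2}$, $E[a^2] = e^{2\mu + 2v}$)
are matched to a Gaussian before the bound is applied. This moment match
is exact for the 1PL; for the 2PL the objective is no longer guaranteed
to sit below the evidence, which is why the bound-dominance test is
restricted to the 1PL.

One coordinate-ascent sweep: (i) $\xi$ refresh at the current moments
(warm-started across sweeps); (ii) each Gaussian block updated by at most
5 damped Newton steps on (mean, log variance) with analytic first and
second derivatives of the bound (all derivative formulas are verified
against numerical differentiation in development and exercised by the
monotonicity tests); any step that would decrease that factor's slice of
the bound is halved, and reverted if 12 halvings do not restore ascent;
(iii) hierarchical hyper-factors in closed conjugate form — the Gamma
factor for $u_\theta$ has shape $1 + S/2$ and rate
$1 + \frac{1}{2} E_q\!\left[\sum_i (\theta_i - m_\theta)^2\right]$, and
analogously for the item blocks. Initialisation: all means 0, variances
1, Gamma factors (1, 1); sweep order $\theta$, $b$, $\log a$, hypers.
Convergence: bound improvement < 1e-6 (at most 500 sweeps);
non-convergence sets a flag on the result rather than raising, since the
vague-prior 2PL configuration is known to be fragile.

Scale acceleration (hierarchical 2PL). The data term of the bound is
exactly invariant under jointly scaling the ability/difficulty factors by
$c$ (hyper rates by $c^2$) while shifting the log-discrimination
locations by $-\log c$. Plain coordinate ascent crawls along this
direction (measured: ~1300 sweeps to converge a 250×10 fit); one
bounded line search over $\log c$ per sweep — a parameter-expansion
move, accepted only if the full bound improves, hence still monotone —
reduces this to ~20 sweeps with the same limit.

Point estimates are factor means; the discrimination is reported as the
lognormal mean $e^{\mu + v/2}$ with the lognormal SD as its SE; all other
SEs are factor SDs.

## Alignment and metrics

Before error computation, each replication's estimates are transformed by
the $(s, t)$ minimising

$$J(s,t) = \mathrm{RMSE}(\theta \mid s,t) + \mathrm{RMSE}(b \mid s,t)
+ \mathrm{RMSE}(a \mid s,t),$$

with $\theta' = s\hat\theta + t$, $b' = s\hat b + t$, $a' = \hat a / s$ —
the likelihood-preserving triple, so that an estimate that is an exact
re-expression of the truth aligns to zero error. Optimisation:
Nelder–Mead on $(\log s, t)$ from the best point of a 21×21 grid pre-scan
($s \in [0.5, 2]$, $t \in [-1, 1]$). For the 1PL the scale is fixed by
$a \equiv 1$: only the shift is optimised and the $a$-term is dropped.
Without the shift, sum-to-zero CML difficulties could never match the
truth whenever the true difficulties have nonzero sample mean.

Average RMSEs are computed as the root of the within-replication mean
square (over persons, items, or person-item response probabilities),
averaged unweighted over replications. Probability errors use the raw
(unaligned) estimates — the response probabilities are what the estimator
actually implies for the data scale, and a consistent re-expression would
leave them unchanged anyway. Reported SEs are likewise unaligned. Average
SEs are the mean SE over parameters within a replication, then over
replications; marginal tables weight design cells equally.

The $\eta^2$ ANOVA decomposes a balanced full factorial
(method × sample size × test length, one observation per replication per
cell) into main-effect, interaction and residual sums of squares by
inclusion-exclusion on cell means; $\eta^2 = SS_\text{effect}/SS_\text{total}$
reported in percent, flagged small/medium/large at 8%/14%. The
decomposition is checked against `statsmodels` OLS ANOVA in the tests and
must sum to 100%. Unbalanced inputs are rejected.

## Prior regimes

| regime | ability | difficulty | log-discrimination |
|---|---|---|---|
| matched | N(0, 1) | N(0, 1) | N(0, 0.0625) |
| stdvague | N(0, 1) | N(0, 1e3) | N(0, 8) |
| hierarchical | N(m, 1/u) | N(m, 1/u) | N(m, 1/u) |

Hierarchical hyper-means are N(0, 1e6), precisions Gamma(1, 1)
(shape-rate). Two parameterisation decisions are worth stating: the
second argument of every fixed normal prior is read as a **variance**
(so the vague log-discrimination prior has variance 8), and the
generating lognormal is read as having log-**SD** 0.25 (so the matched
log-scale variance is 0.0625). The discrimination prior always lives on
the log scale.

## Numerical choices and degenerate inputs

* Logistic quantities go through `scipy.special.expit` / `log_expit`;
  logits of magnitude up to 700 neither overflow nor collapse.
* ESFs: linear-space summation recursion; the conditional-likelihood
  normaliser is evaluated in log space, and difficulties are re-centred
  every Newton iteration so the easiness products stay in range.
* Degenerate items (all-0/all-1 columns) are estimation errors naming the
  item for CML and MML; datasets with no interior raw scores are refused.
* A constant MCMC chain yields SE 0 and passes the half-width test
  trivially; single-chain PSRF requests raise.
* Alignment on zero-variance truth is skipped with a warning.
* Estimator failures inside the study harness are caught, logged, and
  recorded as missing replications with a failure count — never silently
  dropped; marginal tables are computed over non-missing replications.

## Problem sizes in `scripts/acceptance.py`

The headline quantities are Monte-Carlo aggregates, so the script
re-estimates them at replication counts chosen to keep the full run in
the ten-to-fifteen-minute range on one CPU while holding the Monte-Carlo
SE of every reported aggregate well under its comparison tolerance (each
value is already an average over 3-12 design cells and hundreds to
thousands of parameters): CML (cheap, milliseconds per fit) uses the full
crossed design with R = 100; 1PL VB uses R = 20; 2PL VB-matched R = 10
over all 12 cells; 2PL VB-hierarchical R = 6 on the largest-sample row;
hierarchical MCMC R = 10 on the smallest-sample row under the full
5000/1000 chain protocol.

## Known limitations

* Mean-field VB underestimates posterior spread; with very few persons
  and the heavy-tailed Gamma(1, 1) precision hyperprior its posterior
  *means* also deviate noticeably, so the tiny-instance oracle tests run
  the hierarchical path with concentrated hyperpriors (the study-scale
  behaviour is unaffected — hyperposteriors concentrate for S ≥ 250).
* The 2PL moment-matched objective is not a certified lower bound
  (1PL is).
* The MCMC sampler is a correct, adapted random-walk scheme; quantities
  that depend on *sampler-specific* exploration — notably the magnitude
  of the hierarchical difficulty-SE inflation, which reflects finite-chain
  wander along the weakly identified location — are reproduced in
  direction and rough magnitude, not as portable constants. Under the
  variance-1e3 vague difficulty prior this sampler simply converges; it
  does not exhibit the order-of-magnitude difficulty-RMSE blow-up that
  slice-sampler-based toolchains have been reported to produce there.
* CML is restricted to the 1PL (sufficiency fails for the 2PL); no 3PL,
  no polytomous responses, no missing data.
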
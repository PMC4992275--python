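# Methods

## The generating model

Each scenario is a structural causal model on binary variables: exposure E,
outcome D, covariate C, and — in the instrumental-variable scenario — an
unobserved confounder U.  Root nodes are Bernoulli with a fixed marginal
probability; each child node is Bernoulli with

    logit P(X = 1 | parents) = intercept + Σ_p coef_p · X_p ,

so edge coefficients are conditional log-odds ratios and effects combine
log-linearly additively (no interactions).  The nine diagrams differ only in
their edge sets:

| # | role of C                    | edges                    |
|---|------------------------------|--------------------------|
| 1 | confounder                   | C→E, C→D, E→D            |
| 2 | common cause, no E→D effect  | C→E, C→D                 |
| 3 | independent cause of D       | C→D, E→D                 |
| 4 | cause of E only              | C→E, E→D                 |
| 5 | collider of E and D          | E→C, D→C, E→D            |
| 6 | effect of D                  | D→C, E→D                 |
| 7 | effect of E                  | E→C, E→D                 |
| 8 | mediator                     | E→C, C→D, E→D            |
| 9 | instrument (+ unobserved U)  | C→E, U→E, U→D, E→D       |

Scenario 2 *structurally omits* the E→D term: supplying one is a hard error,
not a silently ignored zero, so the null scenario cannot be misconfigured.

## The estimand

The gold standard is the **marginal** causal log-odds ratio

    β = logit P(D=1 | do(E=1)) − logit P(D=1 | do(E=0)),

computed exactly: the joint factorizes over at most four binary nodes, so the
interventional distribution is obtained by graph surgery (drop E's node
factor, fix E=e) and summed directly.  The back-door route — validity of an
adjustment set Z decided by d-separation on the graph with E's outgoing edges
removed plus the no-descendant condition, then
P(y|do(x)) = Σ_z P(y|x,z)P(z) on the enumerated joint — is implemented
separately, and the two are asserted to agree to 1e−10 across random
parameter draws in every scenario.  When every E coefficient is exactly zero
the two truncated factorizations are float-identical, so the null β = 0 is
exact rather than approximate.

A consequence worth being explicit about: adjusted logistic regressions
estimate the log-odds ratio *conditional* on C, while β is marginal, and odds
ratios are not collapsible.  `TrueEffect` therefore carries both β and the
E→D edge coefficient, and the gap between them is reported rather than
ignored.  At the package defaults the gap is small (0.693 vs 0.681 in the
confounder scenario) but it grows with the strength of the C→D effect: with
OR(C→D) = 10 the marginal truth is 0.527 against a conditional 0.693, and a
C-adjusted estimator sits a genuine +0.17 away from β without any confounding
or selection failure.  Whether that counts as "bias" is a question about the
estimand, not the estimator; the summaries measure every model against the
marginal β consistently.

## Default parameters

The defaults aim at a moderately confounded, low-prevalence setting with all
effects positive:

| parameter                          | default          | meaning                        |
|------------------------------------|------------------|--------------------------------|
| P(C=1) = π                         | 0.5              | balanced covariate             |
| root P(E=1) (scenarios 3,5,6,7,8)  | 0.1              | baseline exposure prevalence   |
| all intercepts                     | logit(0.1) ≈ −2.197 | ≈10% baseline prevalences   |
| every non-varied edge coefficient  | ln 2             | moderate positive effect       |
| P(U=1) = ρ, U coefficients (sc. 9) | 0.5, ln 4        | strong, visible unobserved confounding |

Sweeps vary one edge's odds ratio over a grid (default integers 1–10) and
hold everything else at these values.  Configs and the CLI speak in odds
ratios and baseline prevalences; internally everything is a log-odds
coefficient.

## Study designs and analysis models

From each simulated source population (default N = 100,000) the unmatched
design draws cases uniformly from D=1 and controls uniformly from D=0
(default 1000/1000, without replacement).  The matched design re-uses the
*same* cases — case draws come from a seed stream independent of the control
streams precisely so the two designs share a case group — and pairs each case
with one control drawn uniformly without replacement from the D=0 individuals
with identical C.  Matching is exact, so case and control C distributions
coincide exactly and the sample's C–D association is null by construction
(the deliberate unfaithfulness that matching induces).  A case that cannot be
paired because a C stratum runs out of controls is an error naming the
stratum, not a silent re-draw; at the default sizes and prevalences the pools
are orders of magnitude larger than needed.

Both analysis likelihoods are implemented in the package and maximized by
Newton-Raphson with step halving (gradient tolerance 1e−8, at most 100
iterations), because they are the study's measuring instrument:

* unconditional logistic regression (models 1–4), intercept included;
* the 1:1 pair-conditional likelihood Π exp(η_case)/(exp(η_case)+exp(η_ctrl))
  (model 5), which depends only on within-pair covariate differences.

Degenerate inputs are flagged, never guessed at: constant predictors and
constant outcomes are errors; any fitted |log-OR| beyond 15 is treated as
(quasi-)separation with no finite MLE and the fit marked non-converged;
covariates constant within every pair — C always is, under exact matching —
are dropped from the conditional likelihood with a diagnostic flag, which is
why "model 5 adjusted for C" and "model 5 unadjusted" are provably the same
fit.  With E as the only covariate the conditional MLE has the classical
closed form ln(n₁₀/n₀₁) with SE √(1/n₁₀+1/n₀₁) over exposure-discordant
pairs; the test suite holds the iterative fits to these closed forms (and to
an independent general-purpose fitter) to 1e−6 or better.  Non-converged
replicates are excluded from summaries and counted; a sweep aborts if more
than 5% fail at any grid point, which signals pathological parameters rather
than sampling noise.

## Sweep summaries

Per grid point and model the summary reports mean bias (mean β̂₁ − β), the
empirical SD of β̂₁ across replicates, and the mean model-based SE.  The two
SE notions are deliberately both kept: they agree within ~15% whenever nearly
all replicates converge, but they answer different questions.  Trend verdicts
use the empirical SD: a model is "unbiased" in a sweep when its mean bias
stays within 3 Monte-Carlo standard errors (empirical SD/√n_converged) of
zero at every grid point, and monotone trends are judged by the sign of the
Spearman rank correlation between grid and mean bias with |ρ| ≥ 0.9 —
a rank-based reading of "grows with effect size" that does not pretend to
know the curve is linear.  All randomness descends from one master seed via
per-(grid point, replicate) seed-sequence spawning, so summaries are
reproducible byte-for-byte; replicates regenerate the source population by
default (a flag reuses one population per grid point instead).

## Problem sizes

Full-scale runs (1000 replicates of 1000/1000 samples from populations of
100,000 over a 10-point grid) are the defaults.  The bundled test suite and
the reproduction script run the nine-scenario matrix at a reduced desk scale
— populations of 50,000, 500 cases/controls, 200 replicates, grid
{1, 2, 5, 10} — with tolerances scaled to the Monte-Carlo error of that
replicate count; at roughly 12 ms per replicate the whole matrix takes about
two minutes on one CPU.

## What the generator does and does not emulate

It emulates exactly the stated sampling scheme: Bernoulli/logistic ancestral
sampling, outcome-stratified case-control draws, exact 1:1 matching on a
single binary covariate.  It does not emulate anything a real study would add
on top: continuous or multiple matching variables, frequency or 1:k matching,
measurement error, missing data, interactions, or effect modification.
Conclusions from these simulations are therefore statements about the causal
geometry of the designs, not about the messiness of any particular data set.

## Known limitations and honest edges

* **Non-collapsibility is not removed.**  As described above, C-adjusted
  models target a conditional estimand; against the marginal β they show a
  real, growing offset as the C→D effect strengthens even when adjustment is
  the structurally correct move.
* **Matching can pay for adjustment.**  In the effect-of-outcome scenario
  (D→C), adjusting for C costs precision in the unmatched design, but in the
  matched design the matching itself recovers most of that cost: at
  OR(D→C)=10 the empirical SEs of the matched adjusted models sit within
  about 1% of the crude unmatched model (verified at 3000 replicates), so
  "adjustment always lowers precision" is not reproduced there for models 4
  and 5.
* **Instrument scenario: the five models are not equally biased.**  All five
  are biased by the unobserved confounder, but with a strong instrument
  (OR(C→E) ≥ 5 at U coefficients ln 4) matching on the instrument without
  adjustment shifts the bias substantially (asymptotically 0.21 vs 0.45 for
  the adjusted models at OR 10): the "everything is similarly biased" summary
  holds only for weak-to-moderate instruments under these constants.
* Exact enumeration limits the framework to ≤5 binary nodes by design; the
  nine scenarios use at most 4.
* No front-door or IV *estimator* is provided — the instrument scenario
  documents the bias, it does not repair it.
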
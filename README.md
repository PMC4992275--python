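# matchbias

Simulation framework for a classic question in analytic epidemiology: when
estimating the causal effect of a binary exposure **E** on a binary outcome
**D** from a case-control study, should a covariate **C** be *matched on*,
*adjusted for*, both, or neither?  The answer depends entirely on C's causal
role, and `matchbias` makes that dependence quantitative.

The package is aimed at biostatisticians and epidemiologists who want to
explore (or teach) how matched case-control designs behave under different
causal structures, and at methodologists who need a seeded, fully
reproducible test bed for design-and-analysis strategies on binary causal
diagrams.

## What it does

Nine canonical causal diagrams over {C, E, D} (plus an unobserved confounder
U in the instrumental-variable case) are built in as validated structural
causal models: C as confounder, common cause without an E→D effect,
independent cause of D, cause of E, collider, effect of D, effect of E,
mediator, and instrument.  Every variable is Bernoulli; every child node
follows a logistic model in its parents, so each edge coefficient is a
conditional log-odds ratio.

For any scenario the package can:

1. **Compute the exact truth.**  The target estimand is the marginal causal
   log-odds ratio

   β = logit P(D=1 | do(E=1)) − logit P(D=1 | do(E=0)),

   computed exactly by enumerating the joint and performing graph surgery
   (delete edges into E, fix E).  The back-door adjustment formula
   P(y|do(x)) = Σ_z P(y|x,z) P(z) is implemented independently, and validity
   of an adjustment set is decided by d-separation, so identification
   arguments are executable and testable.

2. **Simulate the study.**  A seeded source population (default 100,000) is
   drawn by ancestral sampling; a case-control study is drawn from it either
   unmatched (uniform draws within outcome strata) or 1:1 exactly matched on
   C, with both designs sharing an identical case group.

3. **Fit the five standard analysis models** with in-repo, oracle-verified
   maximum-likelihood fits:

   | model | design    | analysis                                   |
   |-------|-----------|--------------------------------------------|
   | 1     | unmatched | logistic D ~ E                             |
   | 2     | unmatched | logistic D ~ E + C                         |
   | 3     | matched   | logistic D ~ E                             |
   | 4     | matched   | logistic D ~ E + C                         |
   | 5     | matched   | conditional logistic on the 1:1 pairs      |

4. **Sweep and summarize.**  `run_sweep` varies one edge's odds ratio over a
   grid, repeats the population→design→fit pipeline many times, and reports
   per grid point and model the mean bias (mean β̂₁ − β), the empirical SD of
   β̂₁ across replicates, and the mean model-based SE.  `summarize_trends`
   turns a sweep into machine-checked verdicts: monotone bias trends,
   zero-bias bands at 3 Monte-Carlo SEs, and SE orderings.

## Worked example

```python
import matchbias as mb

spec = mb.make_scenario(1)            # C is a confounder of E and D
eff = mb.true_causal_logodds(spec)
print(f"true marginal causal log-OR: {eff.beta:.4f}")
print(f"interventional risks: {eff.p_do1:.4f} vs {eff.p_do0:.4f}")
print(f"conditional (edge) log-OR:  {eff.conditional_beta:.4f}")

cfg = mb.SweepConfig(scenario_id=1, vary="CE", grid=(1.0, 2.0, 5.0, 10.0),
                     n_reps=200, pop_size=50_000, n_cases=500, n_controls=500,
                     master_seed=7)
summary = mb.BiasSweepStudy(cfg).run()
print(mb.summarize_trends(summary).render())
```

Output:

```
true marginal causal log-OR: 0.6810
interventional risks: 0.2448 vs 0.1409
conditional (edge) log-OR:  0.6931
scenario 1, varying CE:
  model 1: biased, bias trend increasing
  model 2: unbiased, bias trend none
  model 3: biased, bias trend decreasing
  model 4: unbiased, bias trend decreasing
  model 5: unbiased, bias trend decreasing
  SE order at OR=1 (smallest first): m1 < m3 < m4 < m2 < m5
  SE order at OR=2 (smallest first): m1 < m3 < m2 < m4 < m5
  SE order at OR=5 (smallest first): m3 < m1 < m2 < m4 < m5
  SE order at OR=10 (smallest first): m3 < m4 < m1 < m5 < m2
```

Reading this: under intervention, forcing everyone exposed raises the disease
risk from 14.1% to 24.5%, a true marginal log-odds ratio of 0.681 (the edge
coefficient is ln 2 = 0.693; the small gap is odds-ratio non-collapsibility).
As the confounder→exposure odds ratio grows from 1 to 10, the crude unmatched
analysis (model 1) acquires bias that grows with confounding strength (up to
+0.32 at OR 10 in this run), matching *without* adjustment (model 3)
over-corrects and becomes biased in the opposite direction (−0.11), and the
three C-adjusted analyses (models 2, 4, 5) stay within Monte-Carlo noise of
the truth — matching on a true confounder still requires adjusting for it.

The same experiment is available from the shell:

```
matchbias run --scenario 1 --vary CE --grid 1:10 --reps 1000 \
    --n-cases 1000 --n-controls 1000 --pop-size 100000 --seed 42 --out out/
matchbias truth --scenario 9
matchbias report out/summary.tsv
```

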
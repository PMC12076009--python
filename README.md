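# ineqop

**Radical and liberal inequality of opportunity from survey + genetic
data**, via a bagged double-lasso R² decomposition.

## The problem

Equality-of-opportunity research asks how much of the inequality in life
outcomes — years of education, occupational status, income — is *unjust*
because it traces back to factors beyond individual control. Two
conceptions disagree about natural talents. The **liberal** conception
counts only *ascribed characteristics* (social origin, migration
background, sex, birth cohort) as unfair sources of inequality and accepts
talent-driven inequality as just. The **radical** (luck-egalitarian)
conception counts natural talents as morally arbitrary too: nobody chooses
their endowments.

Measuring the talent share is hard because skills observed in adulthood
are already contaminated by environments and choices. Polygenic indices
(PGIs) — standardized scores over trait-associated genetic variants, fixed
at conception — offer a proxy for natural talents that nothing later in
life can alter. This package estimates, for each outcome y on standardized
data:

* **radical IOp** = R² of the model with ascribed characteristics *and*
  talents (PGIs or observed skills), with the first 10 genetic principal
  components always included among the ascribed set;
* **conditional liberal IOp** = the semipartial R² of the ascribed set:
  R²(full) − R²(talents only), the ascribed variables' unique
  contribution;
* **unconditional liberal IOp** = R² of the ascribed-only model (what one
  gets by ignoring talents — an overestimate of the liberal notion).

Estimation combines **double lasso** (variable selection robust to the
forced, unpenalized principal components) with **bagging** (B bootstrap
replicates of selection + fitting; means, SDs, and percentile 95% CIs over
the draws). Radical vs. conditional-liberal differences are tested with a
paired t-test over draws, Holm-corrected across the cells of a run.

It is aimed at social-science-genetics and social-stratification
researchers with per-individual (optionally per-wave) tabular data: a
CSV/TSV plus a YAML role map assigning each column to one of
`outcome / ascribed / pgi / skill / pc / id / wave / age`.

Because such microdata are access-restricted, the package ships a
synthetic-cohort generator with the same statistical skeleton (correlated
PGIs, gene–environment correlation with parental background, skills caused
by both blocks, multi-wave noisy outcomes) and a **closed-form population
R² oracle**, so the whole pipeline is testable against known ground truth.
See `docs/methods.md` for the model, assumptions, and limitations.

## Worked example

```bash
ineqop simulate --n 4000 --seed 1 --out runs/sim
ineqop estimate --config run.yaml
ineqop report --run runs/demo
```

with `run.yaml`:

```yaml
data: runs/sim/cohort.csv
rolemap: runs/sim/rolemap.yaml
output_dir: runs/demo
talent_measures: [pgi, skill]
outcomes: [education]
B: 200
seed: 7
age_range: [25, 65]
```

`report` prints the assembled table (values are shares of outcome
variance, R²):

```
Natural talents   Outcome Radical   (SE) Liberal  (SE)  Difference
            pgi education    0.26 (0.01)    0.12 (0.01)      0.14*
          skill education    0.31 (0.01)    0.08 (0.01)      0.23*
```

Reading: with PGIs as talents, 26% of the variance in (synthetic) years
of education is explained by circumstances-plus-talents — unjust under the
radical conception — while only 12% is uniquely due to ascribed
characteristics, the liberal measure once talents are controlled. The
star marks a Holm-corrected paired-t p < 0.05 across the run's cells. The
simulated cohort's true population values are 0.250/0.108 (PGI) and
0.304/0.068 (skills) — `runs/sim/ground_truth.json` — so the bagged
estimates land within sampling error of the truth. Observed skills, which
absorb environmental influence, explain more than today's PGIs and shrink
the liberal share accordingly, the same qualitative pattern reported for
real cohorts.

The same objects are available as a library (`ineqop.simulate_cohort`,
`ineqop.prepare`, `ineqop.decomposition.bag_iop`,
`ineqop.inference.assemble_table`), which is what the test-suite and the
reproduction script use.

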